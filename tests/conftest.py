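"""Shared simulation fixtures.

The heavier simulations are session-scoped so the homology → synteny →
Ks chain runs once and is reused across modules.
"""

import pytest

from wgdkit import pipeline
from wgdkit.simulate import Event, EvolutionScenario, simulate_scenario


@pytest.fixture(scope="session")
def one_wgd_result():
    """One WGD (truth Ks 0.40), full retention, 240 ancestral genes."""
    scenario = EvolutionScenario(
        n_chromosomes=2,
        genes_per_chromosome=120,
        cds_codons=150,
        events=(Event("wgd", 47.6, "anc", retention=1.0),),
        synonymous_rate=4.2e-9,
        seed=5,
    )
    return simulate_scenario(scenario)


@pytest.fixture(scope="session")
def outgroup_one_wgd_result():
    """Outgroup without WGD vs ingroup with one WGD (depth ratio 1:2)."""
    scenario = EvolutionScenario(
        n_chromosomes=2,
        genes_per_chromosome=100,
        cds_codons=150,
        events=(
            Event("speciation", 80.0, "anc", children=("out", "in")),
            Event("wgd", 47.6, "in", retention=1.0),
        ),
        synonymous_rate=4.2e-9,
        seed=6,
    )
    return simulate_scenario(scenario)


@pytest.fixture(scope="session")
def study_result():
    """The reference study design at full desk scale: no-WGD outgroup vs
    an ingroup with two WGDs (truth Ks 0.48 / 0.35), retention 0.7,
    1,000 ancestral genes."""
    return pipeline.simulate_outgroup_ingroup(
        n_ancestral_genes=1000, retention=0.7, seed=1234)


@pytest.fixture(scope="session")
def study_depth(study_result):
    """Depth-ratio pipeline (homology -> blocks -> depth) on the study
    design; shared because the homology stage dominates run time."""
    return pipeline.depth_ratio_between(study_result, "out", "in")


@pytest.fixture(scope="session")
def shared_wgd_result():
    """Two WGDs *before* speciation: both species share the duplications."""
    scenario = EvolutionScenario(
        n_chromosomes=4,
        genes_per_chromosome=55,
        cds_codons=150,
        events=(
            Event("wgd", 57.1, "anc", retention=1.0),
            Event("wgd", 41.7, "anc", retention=1.0),
            Event("speciation", 27.87, "anc", children=("A", "B")),
        ),
        synonymous_rate=4.2e-9,
        seed=7,
    )
    return simulate_scenario(scenario)


@pytest.fixture(scope="session")
def independent_wgd_result():
    """Speciation first, then two WGDs in each lineage independently."""
    scenario = EvolutionScenario(
        n_chromosomes=4,
        genes_per_chromosome=55,
        cds_codons=150,
        events=(
            Event("speciation", 60.0, "anc", children=("A", "B")),
            Event("wgd", 35.0, "A", retention=1.0),
            Event("wgd", 20.0, "A", retention=1.0),
            Event("wgd", 33.0, "B", retention=1.0),
            Event("wgd", 18.0, "B", retention=1.0),
        ),
        synonymous_rate=4.2e-9,
        seed=8,
    )
    return simulate_scenario(scenario)
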