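"""Forward-time simulation of genome evolution with a complete truth log.

The generator emulates the evolutionary structure that paleopolyploidy
inference assumes: one ancestral genome evolves along a lineage tree on
which whole-genome duplications (WGDs) and speciations are placed at known
ages.  A WGD duplicates every chromosome and then thins the duplicate gene
copies by independent loss (fractionation); gene order among survivors is
preserved, so collinearity is clean by construction.  Coding sequences
diverge neutrally at a configured synonymous rate so that a duplicate pair
created ``t`` years ago has expected synonymous divergence ``Ks = 2 r t``.

Every simulated gene traces to exactly one ancestral gene, and the truth
log records, for every pair of genes sharing an ancestor, the event at
which they diverged and the closed-form expected Ks — the oracle against
which the downstream estimators are validated.

Units: event ages in million years (My); substitution rates per site per
year.  The My→year factor of 1e6 is applied in exactly one place
(:data:`YEARS_PER_MY`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._codon import (
    NUCLEOTIDES,
    SENSE_CODONS,
    codon_sites,
    is_synonymous_change,
    translate,
)

YEARS_PER_MY = 1.0e6


class ScenarioError(ValueError):
    """An EvolutionScenario field violates its invariants."""


# ---------------------------------------------------------------------------
# Scenario description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Event:
    """One event on the lineage tree.

    ``kind`` is ``"wgd"`` (duplicates every chromosome of ``lineage``,
    duplicate genes each retained with probability ``retention``) or
    ``"speciation"`` (splits ``lineage`` into the two ``children``).
    ``age`` is in My before present.
    """

    kind: str
    age: float
    lineage: str
    retention: float | None = None
    children: tuple[str, str] | None = None


@dataclass(frozen=True)
class EvolutionScenario:
    n_chromosomes: int = 4
    genes_per_chromosome: int = 250
    cds_codons: int = 150
    events: tuple[Event, ...] = ()
    synonymous_rate: float = 4.2e-9  # substitutions / synonymous site / year
    omega: float = 0.2  # dN/dS; purifying selection on paralogs
    seed: int = 0
    root_lineage: str = "anc"

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(self.events))
        self.validate()

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ScenarioError("n_chromosomes must be >= 1")
        if self.genes_per_chromosome < 1:
            raise ScenarioError("genes_per_chromosome must be >= 1")
        if self.cds_codons < 2:
            raise ScenarioError("cds_codons must be >= 2")
        if not self.synonymous_rate > 0:
            raise ScenarioError("synonymous_rate must be > 0")
        if not 0.0 <= self.omega <= 1.0:
            raise ScenarioError("omega must be in [0, 1]")
        active = {self.root_lineage}
        prev_age = {self.root_lineage: float("inf")}
        for ev in self.events:
            if ev.kind not in ("wgd", "speciation"):
                raise ScenarioError(f"unknown event kind {ev.kind!r}")
            if ev.age < 0:
                raise ScenarioError(f"event age {ev.age} is negative")
            if ev.lineage not in active:
                raise ScenarioError(
                    f"event on unknown or extinct lineage {ev.lineage!r}"
                )
            if ev.age >= prev_age[ev.lineage]:
                raise ScenarioError(
                    "event ages must be strictly decreasing toward the "
                    f"present within lineage {ev.lineage!r}"
                )
            if ev.kind == "wgd":
                if ev.retention is None or not 0.0 < ev.retention <= 1.0:
                    raise ScenarioError("retention must be in (0, 1]")
                prev_age[ev.lineage] = ev.age
            else:
                if ev.children is None or len(ev.children) != 2:
                    raise ScenarioError("speciation needs two children")
                c1, c2 = ev.children
                if c1 == c2 or c1 in active or c2 in active:
                    raise ScenarioError("speciation children must be new labels")
                active.discard(ev.lineage)
                active |= {c1, c2}
                prev_age[c1] = prev_age[c2] = ev.age


def two_wgd_scenario(
    n_chromosomes: int = 4,
    genes_per_chromosome: int = 250,
    cds_codons: int = 150,
    retention: float = 0.7,
    wgd_ages: tuple[float, float] = (57.1, 41.7),
    outgroup_split: float | None = 80.0,
    synonymous_rate: float = 4.2e-9,
    seed: int = 0,
) -> EvolutionScenario:
    """Convenience scenario: an ingroup lineage carrying two WGDs and,
    optionally, an outgroup lineage that split earlier and carries none.

    With the default rate 4.2e-9/site/yr the WGD ages 57.1 and 41.7 My put
    the truth Ks of the two duplicate cohorts at 0.48 and 0.35.
    """
    events: list[Event] = []
    lineage = "anc"
    if outgroup_split is not None:
        events.append(
            Event("speciation", outgroup_split, "anc", children=("out", "in"))
        )
        lineage = "in"
    old, recent = sorted(wgd_ages, reverse=True)
    events.append(Event("wgd", old, lineage, retention=retention))
    events.append(Event("wgd", recent, lineage, retention=retention))
    return EvolutionScenario(
        n_chromosomes=n_chromosomes,
        genes_per_chromosome=genes_per_chromosome,
        cds_codons=cds_codons,
        events=tuple(events),
        synonymous_rate=synonymous_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Simulation state
# ---------------------------------------------------------------------------

class _Gene:
    __slots__ = ("ancestral", "history", "codons", "strand", "gene_id")

    def __init__(self, ancestral, history, codons, strand):
        self.ancestral = ancestral
        self.history = history  # tuple of (event_index, side)
        self.codons = codons  # list of codon strings
        self.strand = strand
        self.gene_id = None

    def copy(self):
        return _Gene(self.ancestral, self.history, list(self.codons), self.strand)


@dataclass
class Genome:
    """One extant genome: a rank-ordered gene catalog plus its CDS set."""

    lineage: str
    catalog: pd.DataFrame  # gene_id, chromosome, rank, strand
    cds: dict[str, str]

    def proteins(self) -> dict[str, str]:
        return {g: translate(s) for g, s in self.cds.items()}


@dataclass
class TruthLog:
    """Ground truth: per-gene ancestry and per-pair expected divergence."""

    genes: pd.DataFrame  # gene_id, lineage, ancestral_id, origin_event, copy
    pairs: pd.DataFrame  # gene_a, gene_b, event, kind, age_my, expected_ks


@dataclass
class SimulationResult:
    scenario: EvolutionScenario
    genomes: dict[str, Genome]
    truth: TruthLog


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _mutate_branch(gene: _Gene, dt_my: float, rate: float, omega: float,
                   rng: np.random.Generator) -> None:
    """Apply neutral divergence along one branch of duration ``dt_my``.

    Substitution counts are Poisson with mean rate·t per synonymous site
    (and ω·rate·t per nonsynonymous site), then placed by rejection
    sampling of codon-aware single-nucleotide changes; stops are never
    created, so the ORF stays intact and E[syn subs / syn site] = rate·t
    exactly.
    """
    if dt_my <= 0:
        return
    t_years = dt_my * YEARS_PER_MY
    cds = "".join(gene.codons)
    s_sites, n_sites = codon_sites(cds)
    n_syn = rng.poisson(rate * t_years * s_sites)
    n_non = rng.poisson(omega * rate * t_years * n_sites)
    codons = gene.codons
    L = len(codons)
    for want_syn, count in ((True, n_syn), (False, n_non)):
        applied = 0
        while applied < count:
            ci = int(rng.integers(L))
            pos = int(rng.integers(3))
            codon = codons[ci]
            alt = NUCLEOTIDES[int(rng.integers(4))]
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant not in SENSE_CODONS_SET:
                continue
            if is_synonymous_change(codon, pos, alt) != want_syn:
                continue
            codons[ci] = mutant
            applied += 1


SENSE_CODONS_SET = frozenset(SENSE_CODONS)


def _random_cds(n_codons: int, rng: np.random.Generator) -> list[str]:
    idx = rng.integers(len(SENSE_CODONS), size=n_codons - 1)
    return ["ATG"] + [SENSE_CODONS[i] for i in idx]


# ---------------------------------------------------------------------------
# Main driver
# ---------------------------------------------------------------------------

def simulate_scenario(scenario: EvolutionScenario) -> SimulationResult:
    """Run a scenario forward in time and return genomes plus truth log.

    Deterministic for a fixed scenario (including its seed).
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    rate, omega = scenario.synonymous_rate, scenario.omega

    # ancestral genome
    chroms: list[tuple[str, list[_Gene]]] = []
    anc_counter = itertools.count()
    for ci in range(scenario.n_chromosomes):
        genes = []
        for _ in range(scenario.genes_per_chromosome):
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                _Gene(next(anc_counter), (), _random_cds(scenario.cds_codons, rng), strand)
            )
        chroms.append((f"chr{ci + 1}", genes))

    state: dict[str, list[tuple[str, list[_Gene]]]] = {scenario.root_lineage: chroms}
    start_age = scenario.events[0].age if scenario.events else 0.0
    t_last: dict[str, float] = {scenario.root_lineage: start_age}

    def evolve_to(lineage: str, age: float) -> None:
        dt = t_last[lineage] - age
        if dt > 0:
            for _, genes in state[lineage]:
                for g in genes:
                    _mutate_branch(g, dt, rate, omega, rng)
        t_last[lineage] = age

    for idx, ev in enumerate(scenario.events):
        evolve_to(ev.lineage, ev.age)
        if ev.kind == "wgd":
            new_chroms: list[tuple[str, list[_Gene]]] = []
            for name, genes in state[ev.lineage]:
                dup_genes = []
                for g in genes:
                    g.history = g.history + ((idx, 0),)
                    if rng.random() < ev.retention:
                        d = g.copy()
                        d.history = d.history[:-1] + ((idx, 1),)
                        dup_genes.append(d)
                if dup_genes:
                    new_chroms.append((f"{name}w{idx}", dup_genes))
            state[ev.lineage].extend(new_chroms)
        else:
            c1, c2 = ev.children
            src = state.pop(ev.lineage)
            del t_last[ev.lineage]
            for side, child in enumerate((c1, c2)):
                child_chroms = []
                for name, genes in src:
                    cg = []
                    for g in genes:
                        h = g.history + ((idx, side),)
                        if side == 0:
                            g.history = h
                            cg.append(g)
                        else:
                            d = g.copy()
                            d.history = h
                            cg.append(d)
                    child_chroms.append((name, cg))
                state[child] = child_chroms
                t_last[child] = ev.age

    for lineage in sorted(state):
        evolve_to(lineage, 0.0)

    return _finalize(scenario, state)


def _finalize(scenario: EvolutionScenario,
              state: dict[str, list[tuple[str, list[_Gene]]]]) -> SimulationResult:
    genomes: dict[str, Genome] = {}
    gene_rows = []
    all_genes: list[_Gene] = []
    for lineage in sorted(state):
        rows, cds = [], {}
        counter = itertools.count(1)
        for chrom, genes in state[lineage]:
            for rank, g in enumerate(genes):
                gid = f"{lineage}_g{next(counter):05d}"
                g.gene_id = gid
                rows.append((gid, chrom, rank, g.strand))
                cds[gid] = "".join(g.codons)
                origin = "root"
                for eidx, side in g.history:
                    if scenario.events[eidx].kind == "wgd" and side == 1:
                        origin = f"e{eidx}"
                gene_rows.append(
                    (gid, lineage, g.ancestral, origin,
                     "".join(str(s) for _, s in g.history))
                )
                all_genes.append(g)
        genomes[lineage] = Genome(
            lineage,
            pd.DataFrame(rows, columns=["gene_id", "chromosome", "rank", "strand"]),
            cds,
        )

    pair_rows = []
    by_anc: dict[int, list[_Gene]] = {}
    for g in all_genes:
        by_anc.setdefault(g.ancestral, []).append(g)
    for members in by_anc.values():
        for a, b in itertools.combinations(members, 2):
            eidx = _mrca_event(a.history, b.history)
            if eidx is None:
                continue
            ev = scenario.events[eidx]
            expected = 2.0 * scenario.synonymous_rate * ev.age * YEARS_PER_MY
            ga, gb = sorted((a.gene_id, b.gene_id))
            pair_rows.append((ga, gb, eidx, ev.kind, ev.age, expected))

    truth = TruthLog(
        genes=pd.DataFrame(
            gene_rows,
            columns=["gene_id", "lineage", "ancestral_id", "origin_event", "path"],
        ),
        pairs=pd.DataFrame(
            pair_rows,
            columns=["gene_a", "gene_b", "event", "kind", "age_my", "expected_ks"],
        ),
    )
    return SimulationResult(scenario, genomes, truth)


def _mrca_event(ha: tuple, hb: tuple) -> int | None:
    for (ea, sa), (eb, sb) in zip(ha, hb):
        if (ea, sa) != (eb, sb):
            return ea
    return None  # identical histories: should not happen for distinct genes


# ---------------------------------------------------------------------------
# LTR cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedLTRPair:
    element_id: str
    ltr5: str
    ltr3: str
    true_age_my: float


def simulate_ltr_cohort(
    n: int,
    ages: float | list[float],
    ltr_length: int = 2000,
    rate: float = 1.6e-9,
    seed: int = 0,
) -> list[SimulatedLTRPair]:
    """Simulate ``n`` LTR retrotransposon insertions of known age.

    At insertion the 5' and 3' LTRs are identical copies; each then
    accumulates substitutions independently at ``rate`` per site per year,
    so the expected pairwise divergence of an element of age ``t`` is
    ``2 r t`` and its clock estimate T = K/(2r) recovers ``t``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if ltr_length <= 0:
        raise ValueError("ltr_length must be > 0")
    age_list = [float(ages)] * n if np.isscalar(ages) else [float(a) for a in ages]
    if len(age_list) != n:
        raise ValueError(f"expected {n} ages, got {len(age_list)}")
    if any(a < 0 for a in age_list):
        raise ValueError("ages must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for i, age in enumerate(age_list):
        seq = rng.integers(4, size=ltr_length)
        copies = []
        for _ in range(2):
            c = seq.copy()
            nsub = rng.poisson(rate * age * YEARS_PER_MY * ltr_length)
            for _ in range(nsub):
                pos = int(rng.integers(ltr_length))
                c[pos] = (c[pos] + 1 + int(rng.integers(3))) % 4
            copies.append("".join(NUCLEOTIDES[b] for b in c))
        out.append(SimulatedLTRPair(f"ltr{i:05d}", copies[0], copies[1], age))
    return out


# ---------------------------------------------------------------------------
# Metabolite tables
# ---------------------------------------------------------------------------

def simulate_metabolome(
    n_metabolites: int = 200,
    n_pathways: int = 10,
    group_sizes: tuple[int, int] = (3, 3),
    effect_log2fc: float = 3.0,
    noise_sd: float = 0.3,
    frac_up: float = 0.15,
    frac_down: float = 0.15,
    seed: int = 0,
    group_names: tuple[str, str] = ("summer", "winter"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a two-group metabolite abundance table with planted effects.

    Abundances are log-normal: log2 levels are drawn per metabolite with
    Gaussian replicate noise, and 'up'/'down' metabolites get +/-
    ``effect_log2fc`` added to the second group.  Three replicates per
    group mirror typical targeted-metabolomics designs.

    Returns ``(table, truth)``: the table has columns metabolite, pathway,
    then one linear-scale abundance column per sample; the truth frame
    records the planted status and log2 fold change of every metabolite.
    """
    if min(group_sizes) < 2:
        raise ValueError("each group needs >= 2 replicates")
    if frac_up + frac_down > 1:
        raise ValueError("frac_up + frac_down must be <= 1")
    rng = np.random.default_rng(seed)
    status = np.array(["ns"] * n_metabolites, dtype=object)
    n_up = int(round(frac_up * n_metabolites)) if effect_log2fc != 0 else 0
    n_down = int(round(frac_down * n_metabolites)) if effect_log2fc != 0 else 0
    idx = rng.permutation(n_metabolites)
    status[idx[:n_up]] = "up"
    status[idx[n_up : n_up + n_down]] = "down"

    pathways = [f"pw{1 + i % n_pathways:02d}" for i in range(n_metabolites)]
    samples = [f"{g}_{i + 1}" for g, k in zip(group_names, group_sizes)
               for i in range(k)]
    base = rng.uniform(10, 20, size=n_metabolites)
    rows, truth_rows = [], []
    for m in range(n_metabolites):
        shift = {"up": effect_log2fc, "down": -effect_log2fc, "ns": 0.0}[status[m]]
        log2_levels = np.concatenate([
            base[m] + rng.normal(0, noise_sd, group_sizes[0]),
            base[m] + shift + rng.normal(0, noise_sd, group_sizes[1]),
        ])
        rows.append([f"m{m:04d}", pathways[m], *np.power(2.0, log2_levels)])
        truth_rows.append((f"m{m:04d}", pathways[m], status[m], shift))
    table = pd.DataFrame(rows, columns=["metabolite", "pathway", *samples])
    truth = pd.DataFrame(truth_rows,
                         columns=["metabolite", "pathway", "status", "log2fc"])
    return table, truth


def sample_groups(group_sizes: tuple[int, int] = (3, 3),
                  group_names: tuple[str, str] = ("summer", "winter")) -> dict[str, str]:
    """Sample→group map matching :func:`simulate_metabolome` column names."""
    return {f"{g}_{i + 1}": g for g, k in zip(group_names, group_sizes)
            for i in range(k)}
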