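"""Collinear groups, NJ topology recovery, monophyly verdicts, frequencies."""

import io as _io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skbio import TreeNode

from wgdkit import pipeline
from wgdkit.synteny import Anchor, CollinearBlock
from wgdkit.wgdtree import (
    INDEPENDENT,
    SHARED,
    UNRESOLVED,
    classify_wgd_topology,
    extract_collinear_groups,
    nj_tree,
    shared_wgd_frequency,
)


def _block(pairs, bid=0):
    anchors = [Anchor(a, b, "c1", "c2", i, i) for i, (a, b) in enumerate(pairs)]
    return CollinearBlock(bid, "c1", "c2", "+", 1.0, anchors)


SPECIES = {"A1": "A", "A2": "A", "A3": "A", "A4": "A",
           "B1": "B", "B2": "B", "B3": "B", "B4": "B"}


class TestExtractGroups:
    def test_quartet_from_within_and_between_anchors(self):
        groups = extract_collinear_groups(
            [_block([("A1", "A2")])],
            [_block([("B1", "B2")], 1)],
            [_block([("A1", "B1"), ("A2", "B2")], 2)],
            SPECIES)
        assert len(groups) == 1
        assert groups[0].members == {"A": ["A1", "A2"], "B": ["B1", "B2"]}
        assert not groups[0].overflow

    def test_gene_without_between_anchor_excluded(self):
        groups = extract_collinear_groups(
            [_block([("A1", "A2"), ("A2", "A3")])],
            [_block([("B1", "B2")], 1)],
            [_block([("A1", "B1"), ("A2", "B2")], 2)],
            SPECIES)
        assert "A3" not in groups[0].genes

    def test_overflow_flagged_beyond_copy_cap(self):
        groups = extract_collinear_groups(
            [_block([("A1", "A2"), ("A2", "A3")])],
            [],
            [_block([(f"A{i}", f"B{i}") for i in (1, 2, 3)], 1)],
            SPECIES, max_copies_per_species=2)
        assert groups[0].overflow

    def test_unknown_species_label_rejected(self):
        with pytest.raises(ValueError, match="species"):
            extract_collinear_groups([], [], [_block([("A1", "Z9")])],
                                     SPECIES)

    def test_two_wgd_full_retention_recovers_octets(self, shared_wgd_result,
                                                    shared_groups):
        """Two WGDs, retention 1.0: >= 90% of ancestral genes yield a
        4 + 4 collinear group."""
        res = shared_wgd_result
        groups, _, _ = shared_groups
        n_anc = res.scenario.n_chromosomes * res.scenario.genes_per_chromosome
        octets = [g for g in groups
                  if sorted(len(v) for v in g.members.values()) == [4, 4]]
        assert len(octets) / n_anc >= 0.90


def _group_inputs(res):
    from wgdkit.synteny import detect_collinear_blocks

    cat_a, cat_b = res.genomes["A"].catalog, res.genomes["B"].catalog
    within_a = detect_collinear_blocks(
        pipeline.homologs_within(res, "A"), cat_a)
    within_b = detect_collinear_blocks(
        pipeline.homologs_within(res, "B"), cat_b)
    between = detect_collinear_blocks(
        pipeline.homologs_between(res, "A", "B"), cat_a, cat_b)
    species_of = {g: "A" for g in res.genomes["A"].cds}
    species_of.update({g: "B" for g in res.genomes["B"].cds})
    return within_a, within_b, between, species_of


@pytest.fixture(scope="module")
def shared_groups(shared_wgd_result):
    """Collinear groups + CDS for the shared-WGD scenario, built once."""
    res = shared_wgd_result
    inputs = _group_inputs(res)
    groups = extract_collinear_groups(*inputs)
    cds = {**res.genomes["A"].cds, **res.genomes["B"].cds}
    return groups, cds, inputs[3]


@pytest.fixture(scope="module")
def independent_groups(independent_wgd_result):
    res = independent_wgd_result
    inputs = _group_inputs(res)
    groups = extract_collinear_groups(*inputs)
    cds = {**res.genomes["A"].cds, **res.genomes["B"].cds}
    return groups, cds, inputs[3]


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _tree_distances(newick):
    tree = TreeNode.read(_io.StringIO(newick))
    tips = sorted(t.name for t in tree.tips())
    n = len(tips)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = tree.find(tips[i]).distance(tree.find(tips[j]))
            m[i, j] = m[j, i] = d
    return tips, m


def _splits(newick):
    tree = TreeNode.read(_io.StringIO(newick))
    leaves = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.traverse(include_self=False):
        below = frozenset(t.name for t in node.tips(include_self=True))
        if 1 < len(below) < len(leaves) - 1:
            out.add(frozenset((below, leaves - below)))
    return out


class TestNjTree:
    def test_three_taxa_unique_topology(self):
        ids = ["x", "y", "z"]
        m = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        nwk = nj_tree(ids, m)
        tree = TreeNode.read(_io.StringIO(nwk))
        assert {t.name for t in tree.tips()} == set(ids)

    def test_four_taxon_additive_matrix_recovered(self):
        truth = "((a:1.0,b:2.0):1.5,(c:1.0,d:3.0):0.5);"
        ids, m = _tree_distances(truth)
        assert _splits(nj_tree(ids, m)) == _splits(truth)

    def test_infinite_entry_rejected(self):
        m = np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]])
        with pytest.raises(ValueError, match="non-finite"):
            nj_tree(["a", "b", "c"], m)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="taxa"):
            nj_tree(["a", "b"], np.zeros((2, 2)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.2, 3.0), min_size=7, max_size=7),
           st.booleans())
    def test_additive_matrices_recovered(self, lengths, five_taxa):
        """NJ recovers the generating topology for additive 4- and
        5-taxon matrices."""
        if five_taxa:
            l = lengths
            truth = (f"((a:{l[0]},b:{l[1]}):{l[2]},(c:{l[3]},"
                     f"(d:{l[4]},e:{l[5]}):{l[6]}):0.3);")
        else:
            l = lengths
            truth = f"((a:{l[0]},b:{l[1]}):{l[2]},(c:{l[3]},d:{l[4]}):{l[5]});"
        ids, m = _tree_distances(truth)
        assert _splits(nj_tree(ids, m)) == _splits(truth)


# ---------------------------------------------------------------------------
# Topology classification
# ---------------------------------------------------------------------------

class TestClassify:
    SP = {f"A{i}": "A" for i in range(1, 5)} | {f"B{i}": "B" for i in range(1, 5)}

    def test_species_separated_topology_is_independent(self):
        nwk = "(A1:1,((A2:1,A3:1):1,(B1:1,B2:1):1):1);"
        assert classify_wgd_topology(nwk, "A1", self.SP) == INDEPENDENT

    def test_interleaved_species_topology_is_shared(self):
        nwk = "(A1:1,((A2:1,B1:1):1,(A3:1,B2:1):1):1);"
        assert classify_wgd_topology(nwk, "A1", self.SP) == SHARED

    def test_single_remaining_gene_unresolved(self):
        nwk = "(A1:1,(A2:1,(B1:1,B2:1):1):1);"
        assert classify_wgd_topology(nwk, "A1", self.SP) == UNRESOLVED

    def test_rooting_on_other_species_gene(self):
        # rooted on B1 the remaining B genes must be monophyletic
        nwk = "(B1:1,((A1:1,A2:1):1,(B2:1,B3:1):1):1);"
        assert classify_wgd_topology(nwk, "B1", self.SP) == INDEPENDENT

    def test_missing_rooting_gene_rejected(self):
        with pytest.raises(ValueError, match="rooting"):
            classify_wgd_topology("(A1:1,A2:1,B1:1);", "A9", self.SP)


# ---------------------------------------------------------------------------
# Frequencies on simulations
# ---------------------------------------------------------------------------

class TestSharedFrequency:
    def test_shared_history_yields_mostly_shared_trees(self, shared_groups):
        groups, cds, species_of = shared_groups
        summary = shared_wgd_frequency(groups, cds, species_of, "A", seed=10)
        assert summary["n_shared"] + summary["n_independent"] >= 200
        assert summary["f_shared"] > summary["f_independent"]

    def test_independent_history_reverses_direction(self, independent_groups):
        groups, cds, species_of = independent_groups
        summary = shared_wgd_frequency(groups, cds, species_of, "A", seed=10)
        assert summary["n_shared"] + summary["n_independent"] >= 200
        assert summary["f_independent"] > summary["f_shared"]

    def test_deterministic_given_seed(self, shared_groups):
        groups, cds, species_of = shared_groups
        sub = groups[:40]
        s1 = shared_wgd_frequency(sub, cds, species_of, "A", seed=3)
        s2 = shared_wgd_frequency(sub, cds, species_of, "A", seed=3)
        assert s1["f_shared"] == s2["f_shared"]
        assert s1["n_unresolved"] == s2["n_unresolved"]
        assert [t.rooting_gene for t in s1["trees"]] == \
               [t.rooting_gene for t in s2["trees"]]

    def test_no_classifiable_groups_rejected(self):
        with pytest.raises(ValueError, match="classifiable"):
            shared_wgd_frequency([], {}, {}, "A")
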