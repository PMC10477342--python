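"""Shared-vs-independent WGD test on collinear gene-group trees.

Collinear paralogs within each of two species, linked by between-species
collinear orthologs, form groups descending from one pre-WGD ancestral
gene.  For each group a distance gene tree is built (neighbor joining on
K2P distances of protein-guided codon alignments) and rooted on a
randomly chosen gene of the focal species.  If the WGDs happened after
the two species diverged (*independent* events), each species' surviving
duplicates cluster by species, so under that rooting the other species'
genes form a monophyletic clade; if the WGDs predate the split
(*shared*), orthologous duplicates pair up across species and no such
clade exists.  The fraction of gene trees supporting each verdict is the
genome-wide evidence.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .ksdist import align_codon_pair
from .ltrclock import k2p_distance
from .synteny import CollinearBlock

INDEPENDENT = "independent"
SHARED = "shared"
UNRESOLVED = "unresolved"


@dataclass
class CollinearGroup:
    """A connected set of collinear genes across two species."""

    group_id: int
    members: dict[str, list[str]]  # species -> sorted gene ids
    overflow: bool = False         # more copies than the assumed WGDs allow

    @property
    def genes(self) -> list[str]:
        return sorted(g for gs in self.members.values() for g in gs)


@dataclass
class GeneGroupTree:
    group_id: int
    newick: str | None
    rooting_gene: str | None
    verdict: str


# ---------------------------------------------------------------------------
# Group extraction
# ---------------------------------------------------------------------------

def _block_edges(blocks: list[CollinearBlock]):
    for blk in blocks:
        for a in blk.anchors:
            yield a.gene_a, a.gene_b


def extract_collinear_groups(
    within_blocks_a: list[CollinearBlock],
    within_blocks_b: list[CollinearBlock],
    between_blocks: list[CollinearBlock],
    species_of: dict[str, str],
    max_copies_per_species: int = 4,
) -> list[CollinearGroup]:
    """Connected components of the collinearity anchor graph.

    Only genes appearing in at least one between-species anchor enter the
    graph; within-species anchors then link the surviving paralogs.
    Groups with more than ``max_copies_per_species`` genes in a species —
    more than 2^(#assumed WGDs) copies — are flagged as overflow and later
    classified unresolved.
    """
    between_genes: set[str] = set()
    for ga, gb in _block_edges(between_blocks):
        between_genes.update((ga, gb))
    unknown = [g for g in between_genes if g not in species_of]
    if unknown:
        raise ValueError(f"gene ids without species label: {sorted(unknown)[:5]}")

    g = nx.Graph()
    g.add_nodes_from(between_genes)
    for blocks in (within_blocks_a, within_blocks_b, between_blocks):
        for ga, gb in _block_edges(blocks):
            if ga in between_genes and gb in between_genes:
                g.add_edge(ga, gb)

    groups = []
    comps = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    gid = 0
    for comp in comps:
        members: dict[str, list[str]] = {}
        for gene in sorted(comp):
            members.setdefault(species_of[gene], []).append(gene)
        if max(len(v) for v in members.values()) < 2:
            continue  # no retained duplicate anywhere: nothing to test
        overflow = any(len(v) > max_copies_per_species for v in members.values())
        groups.append(CollinearGroup(gid, members, overflow))
        gid += 1
    return groups


# ---------------------------------------------------------------------------
# Distances and trees
# ---------------------------------------------------------------------------

def group_distance_matrix(genes: list[str], cds_by_gene: dict[str, str]
                          ) -> tuple[list[str], np.ndarray]:
    """Pairwise K2P distances over protein-guided codon alignments.

    Saturated pairs get an infinite distance; callers treat groups with
    non-finite entries as unresolved.
    """
    ids = sorted(genes)
    n = len(ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln_a, aln_b = align_codon_pair(cds_by_gene[ids[i]], cds_by_gene[ids[j]])
            d = k2p_distance(aln_a, aln_b)
            m[i, j] = m[j, i] = d["K"] if d["valid"] else math.inf
    return ids, m


def nj_tree(ids: list[str], matrix: np.ndarray) -> str:
    """Neighbor-joining tree as a newick string.

    Requires a symmetric, finite matrix over >= 3 taxa; negative branch
    lengths (an NJ artefact) are clamped to zero.  Taxa are processed in
    label order, making ties deterministic.
    """
    matrix = np.asarray(matrix, dtype=float)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if matrix.shape != (len(ids), len(ids)):
        raise ValueError("matrix shape does not match taxa")
    if not np.isfinite(matrix).all():
        raise ValueError("non-finite distances (saturated pairs)")
    if not np.allclose(matrix, matrix.T):
        raise ValueError("distance matrix is not symmetric")
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    dm = DistanceMatrix(matrix[np.ix_(order, order)], [ids[i] for i in order])
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    buf = _io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# Topology classification
# ---------------------------------------------------------------------------

def classify_wgd_topology(newick: str, rooting_gene: str,
                          species_of: dict[str, str]) -> str:
    """Root on ``rooting_gene`` and test whether the tree separates the
    two species' paralog sets.

    In the tree rooted on the chosen focal-species gene, independent
    WGDs leave each species' surviving duplicates clustered: the other
    species' genes form a monophyletic clade (and the focal remainder
    sits basal to it).  WGDs predating the split instead interleave the
    species, duplicate by duplicate, so no such clade exists.  Returns
    ``"independent"``/``"shared"`` accordingly, or ``"unresolved"`` when
    fewer than 2 remaining focal genes or 2 other-species genes leave
    nothing to test.  Monophyly is decided on bipartitions: a set S is a
    clade under this rooting iff some edge splits the leaves into
    exactly S versus the rest (the rest containing the rooting gene).
    """
    tree = TreeNode.read(_io.StringIO(newick))
    leaves = {t.name for t in tree.tips()}
    if rooting_gene not in leaves:
        raise ValueError(f"rooting gene {rooting_gene!r} not in tree")
    focal = species_of[rooting_gene]
    remaining = frozenset(
        l for l in leaves if l != rooting_gene and species_of[l] == focal)
    others = frozenset(leaves - remaining - {rooting_gene})
    if len(remaining) < 2 or len(others) < 2:
        return UNRESOLVED
    for node in tree.traverse(include_self=False):
        below = frozenset(t.name for t in node.tips(include_self=True))
        if below == others or (leaves - below) == others:
            return INDEPENDENT
    return SHARED


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

def analyze_group(group: CollinearGroup, cds_by_gene: dict[str, str],
                  species_of: dict[str, str], focal_species: str,
                  rng: np.random.Generator, n_rootings: int = 1
                  ) -> GeneGroupTree:
    """Build one group's tree and vote over random rootings."""
    if group.overflow:
        return GeneGroupTree(group.group_id, None, None, UNRESOLVED)
    focal = group.members.get(focal_species, [])
    n_other = sum(len(v) for sp, v in group.members.items() if sp != focal_species)
    if len(focal) < 3 or n_other < 2 or len(group.genes) < 5:
        return GeneGroupTree(group.group_id, None, None, UNRESOLVED)
    try:
        ids, m = group_distance_matrix(group.genes, cds_by_gene)
        newick = nj_tree(ids, m)
    except (ValueError, KeyError):
        return GeneGroupTree(group.group_id, None, None, UNRESOLVED)
    votes = {INDEPENDENT: 0, SHARED: 0, UNRESOLVED: 0}
    last_root = None
    for _ in range(n_rootings):
        root = focal[int(rng.integers(len(focal)))]
        last_root = root
        votes[classify_wgd_topology(newick, root, species_of)] += 1
    if votes[INDEPENDENT] > votes[SHARED]:
        verdict = INDEPENDENT
    elif votes[SHARED] > votes[INDEPENDENT]:
        verdict = SHARED
    else:
        verdict = UNRESOLVED
    return GeneGroupTree(group.group_id, newick, last_root, verdict)


def shared_wgd_frequency(
    groups: list[CollinearGroup],
    cds_by_gene: dict[str, str],
    species_of: dict[str, str],
    focal_species: str,
    n_rootings: int = 1,
    seed: int = 0,
) -> dict:
    """Frequency of gene trees supporting shared vs independent WGDs.

    One random rooting gene per group (``n_rootings`` with majority vote
    when larger), drawn from a generator seeded with ``seed``.
    f_shared and f_independent are fractions of *classifiable* groups and
    sum to 1; the unresolved share of all groups is reported separately.
    """
    rng = np.random.default_rng(seed)
    trees = [
        analyze_group(g, cds_by_gene, species_of, focal_species, rng, n_rootings)
        for g in sorted(groups, key=lambda g: g.group_id)
    ]
    n_ind = sum(t.verdict == INDEPENDENT for t in trees)
    n_sha = sum(t.verdict == SHARED for t in trees)
    n_unr = sum(t.verdict == UNRESOLVED for t in trees)
    classifiable = n_ind + n_sha
    if classifiable == 0:
        raise ValueError("no classifiable groups")
    return {
        "n_groups": len(trees),
        "n_independent": n_ind,
        "n_shared": n_sha,
        "n_unresolved": n_unr,
        "f_independent": n_ind / classifiable,
        "f_shared": n_sha / classifiable,
        "f_unresolved": n_unr / len(trees),
        "seed": seed,
        "trees": trees,
    }
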