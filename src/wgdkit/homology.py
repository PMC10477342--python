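"""Homolog-pair detection by pairwise local protein alignment.

Stands in for an all-vs-all similarity search at desk scale: candidate
pairs are pre-filtered by shared k-mers (k = 5), aligned by Smith–Waterman
with affine gaps (BLOSUM62, BLAST-style gap open 11 / extend 1, i.e. a gap
of length k costs open + k·extend), and retained when both identity and
coverage pass their thresholds.  Thresholds default to 0.4/0.4, the
identity/coverage filters commonly used in gene-family screens.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_MIN_IDENTITY = 0.4
DEFAULT_MIN_COVERAGE = 0.4
DEFAULT_TOP_N = 5
KMER_SIZE = 5


@dataclass(frozen=True)
class AlignmentParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0


@dataclass(frozen=True)
class HomologPair:
    """An unordered homologous gene pair (stored lexicographically)."""

    gene_a: str
    gene_b: str
    score: float
    identity: float
    coverage: float

    @property
    def is_self(self) -> bool:
        return self.gene_a == self.gene_b


def _check_protein(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"empty protein sequence for {label}")
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"illegal residue(s) {sorted(bad)} in {label}")


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    # BLAST convention: gap of length k costs open + k*extend
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def align_proteins(seq_a: str, seq_b: str,
                   params: AlignmentParams = AlignmentParams()) -> dict:
    """Optimal local alignment of two proteins.

    Returns ``{"score", "identity", "coverage"}`` where identity is the
    match fraction over alignment columns and coverage the smaller of the
    two aligned-span fractions.  An all-mismatch pair has score 0 (the
    local-alignment floor) and identity/coverage 0.
    """
    _check_protein(seq_a, "seq_a")
    _check_protein(seq_b, "seq_b")
    aligner = _make_aligner(params)
    score = aligner.score(seq_a, seq_b)
    if score <= 0:
        return {"score": 0.0, "identity": 0.0, "coverage": 0.0}
    aln = aligner.align(seq_a, seq_b)[0]
    a_aln, b_aln = str(aln[0]), str(aln[1])
    matches = sum(x == y for x, y in zip(a_aln, b_aln) if x != "-" and y != "-")
    columns = len(a_aln)
    span_a = sum(c != "-" for c in a_aln)
    span_b = sum(c != "-" for c in b_aln)
    return {
        "score": float(score),
        "identity": matches / columns if columns else 0.0,
        "coverage": min(span_a / len(seq_a), span_b / len(seq_b)),
    }


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _candidate_pairs(proteome_a: dict[str, str], proteome_b: dict[str, str],
                     k: int) -> set[tuple[str, str]]:
    index: dict[str, list[str]] = {}
    for gid, seq in proteome_b.items():
        for km in _kmers(seq, k):
            index.setdefault(km, []).append(gid)
    cands: set[tuple[str, str]] = set()
    for gid, seq in proteome_a.items():
        hits = set()
        for km in _kmers(seq, k):
            hits.update(index.get(km, ()))
        cands.update((gid, h) for h in hits)
    return cands


def find_homolog_pairs(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str] | None = None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    top_n: int = DEFAULT_TOP_N,
    params: AlignmentParams = AlignmentParams(),
    prefilter: bool = True,
    include_self: bool = False,
) -> list[HomologPair]:
    """All-vs-all homolog pairs between two proteomes (or one vs itself).

    Pairs are unordered and reported once; a pair survives only if it is
    among the ``top_n`` best-scoring partners of *both* genes, keeping the
    output symmetric under swapping the proteomes.  Passing the same
    proteome (or ``proteome_b=None``) runs a self-comparison in which
    self-pairs are excluded unless ``include_self``.

    With ``prefilter`` (default), only pairs sharing at least one length-5
    amino-acid word are aligned; ``prefilter=False`` aligns every pair.
    """
    self_mode = proteome_b is None or proteome_b is proteome_a
    if proteome_b is None:
        proteome_b = proteome_a
    if len(set(proteome_a)) != len(proteome_a) or len(set(proteome_b)) != len(proteome_b):
        raise ValueError("duplicate gene ids in proteome")
    if not self_mode and set(proteome_a) & set(proteome_b):
        raise ValueError("gene ids shared between distinct proteomes")
    for label, prot in (("proteome_a", proteome_a), ("proteome_b", proteome_b)):
        for gid, seq in prot.items():
            _check_protein(seq, f"{label}:{gid}")

    if prefilter:
        cands = _candidate_pairs(proteome_a, proteome_b, KMER_SIZE)
    else:
        cands = {(a, b) for a in proteome_a for b in proteome_b}

    aligner = _make_aligner(params)
    results: dict[tuple[str, str], HomologPair] = {}
    for ga, gb in sorted(cands):
        if self_mode:
            if ga == gb:
                if include_self:
                    self_score = float(aligner.score(proteome_a[ga], proteome_a[ga]))
                    results[(ga, gb)] = HomologPair(ga, gb, self_score, 1.0, 1.0)
                continue
            if (min(ga, gb), max(ga, gb)) in results:
                continue
        sa, sb = proteome_a[ga], proteome_b[gb]
        score = aligner.score(sa, sb)
        if score <= 0:
            continue
        aln = aligner.align(sa, sb)[0]
        a_aln, b_aln = str(aln[0]), str(aln[1])
        matches = sum(x == y for x, y in zip(a_aln, b_aln) if x != "-" and y != "-")
        identity = matches / len(a_aln)
        coverage = min(sum(c != "-" for c in a_aln) / len(sa),
                       sum(c != "-" for c in b_aln) / len(sb))
        if identity < min_identity or coverage < min_coverage:
            continue
        key = (min(ga, gb), max(ga, gb))
        results[key] = HomologPair(key[0], key[1], float(score), identity, coverage)

    # per-gene top_n cap, symmetric: keep pairs ranked <= top_n for both genes
    by_gene: dict[str, list[HomologPair]] = {}
    for p in results.values():
        if p.is_self:
            continue
        by_gene.setdefault(p.gene_a, []).append(p)
        by_gene.setdefault(p.gene_b, []).append(p)
    keep: set[tuple[str, str]] = set()
    ranked: dict[str, set[tuple[str, str]]] = {}
    for gid, plist in by_gene.items():
        plist.sort(key=lambda p: (-p.score, p.gene_a, p.gene_b))
        ranked[gid] = {(p.gene_a, p.gene_b) for p in plist[:top_n]}
    for p in results.values():
        if p.is_self:
            keep.add((p.gene_a, p.gene_b))
            continue
        key = (p.gene_a, p.gene_b)
        if key in ranked.get(p.gene_a, ()) and key in ranked.get(p.gene_b, ()):
            keep.add(key)
    return sorted((results[k] for k in keep),
                  key=lambda p: (p.gene_a, p.gene_b))
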