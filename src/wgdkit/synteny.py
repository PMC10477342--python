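"""Collinear-block detection and synteny-depth ratios.

Anchors (homologous gene pairs) are placed in gene-rank space — 0-based
rank along each chromosome, the coordinate system of classical synteny
dot plots — and chained by sparse dynamic programming into maximal-scoring
runs that are strictly monotone in both genomes (increasing/increasing for
orientation '+', increasing/decreasing for '−').  Blocks are extracted
greedily by descending chain score so that each anchor belongs to at most
one block, which keeps depth counts well defined.

Synteny depth — for each gene of one genome, the number of distinct blocks
of the other genome covering its position — is the classical dot-plot
evidence of ploidy: against an unduplicated outgroup, a lineage that
underwent two whole-genome duplications shows a modal depth ratio of 1:4.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .homology import HomologPair


@dataclass(frozen=True)
class ChainParams:
    min_anchors: int = 5
    max_gap: int = 25          # ranks skipped between consecutive anchors
    gap_penalty: float = 0.05  # per skipped rank
    match_score: float = 1.0


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int


@dataclass
class CollinearBlock:
    block_id: int
    chrom_a: str
    chrom_b: str
    orientation: str  # '+' or '-'
    score: float
    anchors: list[Anchor]
    median_ks: float | None = None

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def span_a(self) -> tuple[int, int]:
        ranks = [a.rank_a for a in self.anchors]
        return min(ranks), max(ranks)

    @property
    def span_b(self) -> tuple[int, int]:
        ranks = [a.rank_b for a in self.anchors]
        return min(ranks), max(ranks)


@dataclass
class DepthProfile:
    """Per-gene block coverage counts on one side of a comparison."""

    counts: pd.Series  # indexed by gene_id
    modal_depth: int   # mode of nonzero counts, 0 when nothing is covered
    zero_fraction: float


# ---------------------------------------------------------------------------
# Anchor construction
# ---------------------------------------------------------------------------

def _rank_index(catalog: pd.DataFrame) -> dict[str, tuple[str, int]]:
    return {
        row.gene_id: (row.chromosome, int(row.rank))
        for row in catalog.itertuples()
    }


def build_anchors(pairs: list[HomologPair], catalog_a: pd.DataFrame,
                  catalog_b: pd.DataFrame, self_comparison: bool = False
                  ) -> list[Anchor]:
    """Map homolog pairs to rank-space anchors.

    In a self-comparison each unordered pair is used once, oriented so the
    chromosome pair (and within a chromosome, the ranks) are in canonical
    order; self-pairs and the trivial diagonal are dropped.
    """
    idx_a = _rank_index(catalog_a)
    idx_b = _rank_index(catalog_b)
    anchors = []
    for p in pairs:
        if p.is_self:
            continue
        if self_comparison:
            if p.gene_a not in idx_a or p.gene_b not in idx_a:
                raise KeyError(f"unknown gene id in pair {p.gene_a}/{p.gene_b}")
            ga, gb = p.gene_a, p.gene_b
            (ca, ra), (cb, rb) = idx_a[ga], idx_a[gb]
            if (cb, rb, gb) < (ca, ra, ga):
                ga, gb, ca, ra, cb, rb = gb, ga, cb, rb, ca, ra
            anchors.append(Anchor(ga, gb, ca, cb, ra, rb))
        else:
            if p.gene_a in idx_a and p.gene_b in idx_b:
                ga, gb = p.gene_a, p.gene_b
            elif p.gene_b in idx_a and p.gene_a in idx_b:
                ga, gb = p.gene_b, p.gene_a
            else:
                raise KeyError(f"unknown gene id in pair {p.gene_a}/{p.gene_b}")
            ca, ra = idx_a[ga]
            cb, rb = idx_b[gb]
            anchors.append(Anchor(ga, gb, ca, cb, ra, rb))
    return anchors


def collapse_tandem(anchors: list[Anchor]) -> list[Anchor]:
    """Collapse tandem-duplicate anchors (same partner, adjacent rank)."""
    kept: list[Anchor] = []
    seen: dict[tuple[str, str], Anchor] = {}
    for a in sorted(anchors, key=lambda x: (x.chrom_a, x.chrom_b, x.rank_a, x.rank_b)):
        drop = False
        kb = (a.chrom_a, a.chrom_b, "b", a.gene_b)
        ka = (a.chrom_a, a.chrom_b, "a", a.gene_a)
        pb = seen.get(kb)
        if pb is not None and abs(pb.rank_a - a.rank_a) <= 1:
            drop = True
        pa = seen.get(ka)
        if pa is not None and abs(pa.rank_b - a.rank_b) <= 1:
            drop = True
        seen[kb] = a
        seen[ka] = a
        if not drop:
            kept.append(a)
    return kept


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------

def chain_score(anchors_in_chain: list[Anchor], orientation: str,
                params: ChainParams) -> float:
    """Score of a given monotone chain (shared with the brute-force oracle)."""
    score = params.match_score * len(anchors_in_chain)
    for prev, cur in zip(anchors_in_chain, anchors_in_chain[1:]):
        da = cur.rank_a - prev.rank_a
        db = (cur.rank_b - prev.rank_b) if orientation == "+" else (prev.rank_b - cur.rank_b)
        score -= params.gap_penalty * ((da - 1) + (db - 1))
    return score


def _best_chain(anchors: list[Anchor], orientation: str,
                params: ChainParams) -> tuple[float, list[int]]:
    """Best-scoring monotone chain by DP.  Returns (score, anchor indices)."""
    sign = 1 if orientation == "+" else -1
    order = sorted(range(len(anchors)),
                   key=lambda i: (anchors[i].rank_a, sign * anchors[i].rank_b))
    best_score = -math.inf
    best_end = -1
    dp = [0.0] * len(anchors)
    back = [-1] * len(anchors)
    for oi, j in enumerate(order):
        aj = anchors[j]
        bj = sign * aj.rank_b
        dp[j] = params.match_score
        back[j] = -1
        for i in order[:oi]:
            ai = anchors[i]
            da = aj.rank_a - ai.rank_a
            db = bj - sign * ai.rank_b
            if da < 1 or db < 1 or da > params.max_gap or db > params.max_gap:
                continue
            cand = dp[i] + params.match_score - params.gap_penalty * ((da - 1) + (db - 1))
            if cand > dp[j]:
                dp[j] = cand
                back[j] = i
        if dp[j] > best_score:
            best_score = dp[j]
            best_end = j
    if best_end < 0:
        return -math.inf, []
    chain = []
    k = best_end
    while k != -1:
        chain.append(k)
        k = back[k]
    chain.reverse()
    return best_score, chain


def detect_collinear_blocks(
    pairs: list[HomologPair],
    catalog_a: pd.DataFrame,
    catalog_b: pd.DataFrame | None = None,
    params: ChainParams = ChainParams(),
) -> list[CollinearBlock]:
    """Chain homolog pairs into collinear blocks.

    ``catalog_b=None`` (or the same frame) runs a within-genome
    self-comparison.  Blocks with fewer than ``params.min_anchors``
    anchors are discarded; each anchor joins at most one block.
    """
    self_comparison = catalog_b is None or catalog_b is catalog_a
    if catalog_b is None:
        catalog_b = catalog_a
    anchors = collapse_tandem(
        build_anchors(pairs, catalog_a, catalog_b, self_comparison)
    )
    by_chrom: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        by_chrom.setdefault((a.chrom_a, a.chrom_b), []).append(a)

    blocks: list[CollinearBlock] = []
    bid = 0
    for (ca, cb), group in sorted(by_chrom.items()):
        pool = list(group)
        while len(pool) >= params.min_anchors:
            best = None
            for orientation in "+-":
                score, chain_idx = _best_chain(pool, orientation, params)
                if chain_idx and (best is None or score > best[0]):
                    best = (score, orientation, chain_idx)
            if best is None or len(best[2]) < params.min_anchors:
                break
            score, orientation, chain_idx = best
            chain = [pool[i] for i in chain_idx]
            blocks.append(CollinearBlock(bid, ca, cb, orientation, score, chain))
            bid += 1
            used = set(chain_idx)
            pool = [a for i, a in enumerate(pool) if i not in used]
    return blocks


# ---------------------------------------------------------------------------
# Depth and ratios
# ---------------------------------------------------------------------------

def synteny_depth(blocks: list[CollinearBlock], catalog: pd.DataFrame,
                  side: str = "a") -> DepthProfile:
    """Per-gene count of blocks whose ``side`` span covers the gene.

    ``side='a'`` profiles the genes of the comparison's first genome,
    ``'b'`` the second.  Genes outside every block have depth 0; the modal
    depth is taken over covered genes (0 when no gene is covered).
    """
    if side not in ("a", "b"):
        raise ValueError("side must be 'a' or 'b'")
    counts = {row.gene_id: 0 for row in catalog.itertuples()}
    by_pos = {}
    for row in catalog.itertuples():
        by_pos.setdefault(row.chromosome, {})[int(row.rank)] = row.gene_id
    for blk in blocks:
        chrom = blk.chrom_a if side == "a" else blk.chrom_b
        lo, hi = blk.span_a if side == "a" else blk.span_b
        ranks = by_pos.get(chrom, {})
        for r in range(lo, hi + 1):
            gid = ranks.get(r)
            if gid is not None:
                counts[gid] += 1
    series = pd.Series(counts, dtype=int)
    nonzero = series[series > 0]
    if len(nonzero):
        freq = Counter(nonzero)
        modal = min(d for d, c in freq.items() if c == max(freq.values()))
    else:
        modal = 0
    zero_fraction = float((series == 0).mean()) if len(series) else 1.0
    return DepthProfile(series, int(modal), zero_fraction)


def depth_ratio(profile_a: DepthProfile, profile_b: DepthProfile) -> dict:
    """Reduced modal synteny-depth ratio A:B with support fractions.

    ``profile_a`` profiles genome A's genes (how many blocks of the
    comparison cover each A gene) and ``profile_b`` genome B's.  Genome
    A's multiplicity in the ratio is the modal coverage observed *on B's
    genes* and vice versa: an unduplicated outgroup A whose every gene is
    covered by four regions of a twice-duplicated genome B, while each B
    gene is covered once, yields A:B = 1:4.
    """
    mult_a = profile_b.modal_depth  # copies of A seen per B gene
    mult_b = profile_a.modal_depth
    if mult_a == 0 and mult_b == 0:
        raise ValueError("no covered genes on either side")
    g = math.gcd(mult_a, mult_b) or 1
    support = {}
    for label, prof in (("a", profile_a), ("b", profile_b)):
        nz = prof.counts[prof.counts > 0]
        support[label] = float((nz == prof.modal_depth).mean()) if len(nz) else 0.0
    return {
        "ratio": (mult_a // g, mult_b // g),
        "modal_depth_a_genes": profile_a.modal_depth,
        "modal_depth_b_genes": profile_b.modal_depth,
        "support_a": support["a"],
        "support_b": support["b"],
    }


def dotplot_export(pairs: list[HomologPair], blocks: list[CollinearBlock],
                   catalog_a: pd.DataFrame, catalog_b: pd.DataFrame | None = None
                   ) -> pd.DataFrame:
    """Plot-ready anchor table in gene-rank space with block membership."""
    self_comparison = catalog_b is None or catalog_b is catalog_a
    if catalog_b is None:
        catalog_b = catalog_a
    anchors = build_anchors(pairs, catalog_a, catalog_b, self_comparison)
    membership: dict[tuple[str, str], int] = {}
    for blk in blocks:
        for a in blk.anchors:
            membership[(a.gene_a, a.gene_b)] = blk.block_id
    rows = [
        (a.gene_a, a.gene_b, a.chrom_a, a.chrom_b, a.rank_a, a.rank_b,
         membership.get((a.gene_a, a.gene_b), -1))
        for a in anchors
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "chrom_a", "chrom_b",
                 "rank_a", "rank_b", "block_id"],
    )
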