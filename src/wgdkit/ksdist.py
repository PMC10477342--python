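"""Ks estimation and WGD peak fitting.

The chain is the classical one: protein-guided codon alignment of each
collinear gene pair, Nei–Gojobori (1986) counting of synonymous and
nonsynonymous sites and differences with Jukes–Cantor multiple-hit
correction, one *median* Ks per collinear block, Gaussian-mixture fitting
of the block-median distribution by EM with BIC model selection, an
outgroup-anchored relative-rate correction of the fitted peaks, and the
molecular-clock conversion T = Ks/(2 r).

NG86 details.  The synonymous fraction of each codon position is the share
of its three possible changes that preserve the amino acid (changes to
stops count as nonsynonymous so sites per codon always sum to 3); site
counts are averaged over the two sequences.  Codons differing at several
positions are resolved by averaging the synonymous/nonsynonymous step
counts over all orderings of the changes, excluding pathways through stop
codons (falling back to all pathways if every ordering is blocked).
Proportions are corrected as Ks = −(3/4)·ln(1 − (4/3)·pS); pS or pN ≥ 3/4
saturates the correction and marks the estimate invalid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from sklearn.mixture import GaussianMixture

from ._codon import GENETIC_CODE, SYN_FRACTION, SYN_SITES, translate
from .synteny import CollinearBlock


@dataclass
class KsEstimate:
    pair_id: str
    n_codons: int       # gap-free aligned codons
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    ks: float | None
    ka: float | None
    valid: bool


@dataclass
class MixtureComponent:
    weight: float
    mean: float
    sd: float


@dataclass
class MixtureModel:
    components: list[MixtureComponent]
    bic: float
    bic_by_k: dict[int, float]
    fit_range: tuple[float, float]
    n_values: int
    seed: int

    @property
    def n_components(self) -> int:
        return len(self.components)


@dataclass
class WgdDate:
    peak_ks: float
    rate: float              # synonymous substitutions / site / year
    age_my: float
    interval_my: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------

def _check_cds(cds: str, label: str) -> str:
    if len(cds) % 3:
        raise ValueError(f"{label}: CDS length not divisible by 3")
    prot = translate(cds)
    if "*" in prot[:-1]:
        raise ValueError(f"{label}: internal stop codon")
    return prot.rstrip("*")


def codon_align(cds_a: str, cds_b: str, aligned_prot_a: str,
                aligned_prot_b: str) -> tuple[str, str]:
    """Back-translate a protein alignment onto the two CDS.

    Protein gaps become codon-triplet gaps; the caller's protein alignment
    must cover the full translations.
    """
    prot_a = _check_cds(cds_a, "cds_a")
    prot_b = _check_cds(cds_b, "cds_b")
    if aligned_prot_a.replace("-", "") != prot_a:
        raise ValueError("aligned_prot_a does not match translate(cds_a)")
    if aligned_prot_b.replace("-", "") != prot_b:
        raise ValueError("aligned_prot_b does not match translate(cds_b)")
    if len(aligned_prot_a) != len(aligned_prot_b):
        raise ValueError("protein alignment rows differ in length")
    out_a, out_b = [], []
    ia = ib = 0
    for ra, rb in zip(aligned_prot_a, aligned_prot_b):
        if ra == "-":
            out_a.append("---")
        else:
            out_a.append(cds_a[3 * ia : 3 * ia + 3])
            ia += 1
        if rb == "-":
            out_b.append("---")
        else:
            out_b.append(cds_b[3 * ib : 3 * ib + 3])
            ib += 1
    return "".join(out_a), "".join(out_b)


_PROT_ALIGNER = None


def _protein_aligner() -> Align.PairwiseAligner:
    global _PROT_ALIGNER
    if _PROT_ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -12.0
        a.extend_gap_score = -1.0
        _PROT_ALIGNER = a
    return _PROT_ALIGNER


def align_codon_pair(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Protein-guided codon alignment of two CDS (global, affine gaps)."""
    prot_a = _check_cds(cds_a, "cds_a")
    prot_b = _check_cds(cds_b, "cds_b")
    aln = _protein_aligner().align(prot_a, prot_b)[0]
    return codon_align(cds_a[: 3 * len(prot_a)], cds_b[: 3 * len(prot_b)],
                       str(aln[0]), str(aln[1]))


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts over all
    minimal substitution pathways between two sense codons."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in permutations(diff):
        cur = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if GENETIC_CODE[nxt] == "*":
                blocked = True
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((blocked, sd, nd))
    valid = [(s, n) for b, s, n in results if not b]
    if not valid:  # every ordering passes through a stop: keep them all
        valid = [(s, n) for _, s, n in results]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


def ng86(aligned_a: str, aligned_b: str, pair_id: str = "",
         min_codons: int = 30) -> KsEstimate:
    """NG86 Ka/Ks from an aligned codon pair (gapped columns excluded)."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    if len(aligned_a) % 3:
        raise ValueError("aligned length not divisible by 3")
    cods = []
    for i in range(0, len(aligned_a), 3):
        ca, cb = aligned_a[i : i + 3], aligned_b[i : i + 3]
        if "-" in ca or "-" in cb:
            continue
        if GENETIC_CODE.get(ca) in (None, "*") or GENETIC_CODE.get(cb) in (None, "*"):
            raise ValueError(f"non-sense codon pair {ca}/{cb} in alignment")
        cods.append((ca, cb))
    if not cods:
        raise ValueError("no gap-free codon columns")
    if len(cods) < min_codons:
        warnings.warn(
            f"only {len(cods)} gap-free codons for {pair_id or 'pair'}; "
            "Ks will be noisy", stacklevel=2)
    S = sum((SYN_SITES[a] + SYN_SITES[b]) / 2 for a, b in cods)
    N = 3 * len(cods) - S
    if S == 0:
        raise ValueError("zero synonymous sites")
    Sd = Nd = 0.0
    for a, b in cods:
        sd, nd = _pathway_counts(a, b)
        Sd += sd
        Nd += nd
    pS, pN = Sd / S, Nd / N if N else 0.0
    valid = pS < 0.75 and pN < 0.75
    ks = -0.75 * math.log(1 - (4.0 / 3.0) * pS) if pS < 0.75 else None
    ka = -0.75 * math.log(1 - (4.0 / 3.0) * pN) if pN < 0.75 else None
    return KsEstimate(pair_id, len(cods), S, N, Sd, Nd, pS, pN,
                      ks if valid else None, ka if valid else None, valid)


def ks_for_pair(cds_a: str, cds_b: str, pair_id: str = "") -> KsEstimate:
    """Protein-guided codon alignment followed by NG86."""
    aln_a, aln_b = align_codon_pair(cds_a, cds_b)
    return ng86(aln_a, aln_b, pair_id=pair_id)


# ---------------------------------------------------------------------------
# Block medians
# ---------------------------------------------------------------------------

def block_median_ks(block: CollinearBlock,
                    estimates: dict[tuple[str, str], KsEstimate]) -> float:
    """Median Ks over a block's valid anchor estimates (representative Ks).

    Raises ``ValueError`` when no anchor has a valid estimate; callers
    exclude such blocks.
    """
    vals = []
    for a in block.anchors:
        est = estimates.get((a.gene_a, a.gene_b)) or estimates.get((a.gene_b, a.gene_a))
        if est is not None and est.valid:
            vals.append(est.ks)
    if not vals:
        raise ValueError(f"block {block.block_id}: no valid Ks estimates")
    return float(np.median(vals))


def annotate_blocks_ks(blocks: list[CollinearBlock], cds: dict[str, str],
                       cds_b: dict[str, str] | None = None
                       ) -> tuple[list[float], dict[tuple[str, str], KsEstimate]]:
    """Compute anchor Ks and attach the median to each block.

    ``cds`` holds the A-side sequences (and both sides in a
    self-comparison); ``cds_b`` the B side for cross-genome blocks.
    Blocks whose anchors are all saturated keep ``median_ks=None`` and are
    omitted from the returned list of medians.
    """
    lookup_b = cds_b if cds_b is not None else cds
    estimates: dict[tuple[str, str], KsEstimate] = {}
    medians = []
    for blk in blocks:
        for a in blk.anchors:
            key = (a.gene_a, a.gene_b)
            if key in estimates:
                continue
            sa = cds.get(a.gene_a, lookup_b.get(a.gene_a))
            sb = lookup_b.get(a.gene_b, cds.get(a.gene_b))
            if sa is None or sb is None:
                raise KeyError(f"missing CDS for anchor {key}")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                estimates[key] = ks_for_pair(sa, sb, pair_id=f"{key[0]}|{key[1]}")
        try:
            blk.median_ks = block_median_ks(blk, estimates)
            medians.append(blk.median_ks)
        except ValueError:
            blk.median_ks = None
    return medians, estimates


# ---------------------------------------------------------------------------
# Mixture fitting
# ---------------------------------------------------------------------------

def fit_ks_mixture(values, fit_range: tuple[float, float] = (0.02, 2.0),
                   k_max: int = 5, restarts: int = 10, seed: int = 0,
                   min_values: int = 20) -> MixtureModel:
    """Gaussian-mixture fit of a Ks distribution with BIC model selection.

    Values outside ``fit_range`` (allelic/tandem noise below, saturation
    above) are excluded.  EM runs for k = 1..k_max with ``restarts``
    seeded initialisations each; the k with the lowest BIC wins, ties
    going to the smaller k.  Deterministic given ``seed``.
    """
    lo, hi = fit_range
    x = np.asarray([v for v in values if v is not None and lo < v <= hi],
                   dtype=float)
    if len(x) < min_values:
        raise ValueError(
            f"need >= {min_values} Ks values in range {fit_range}, got {len(x)}")
    X = x.reshape(-1, 1)
    best = None
    bic_by_k: dict[int, float] = {}
    for k in range(1, k_max + 1):
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             n_init=restarts, random_state=seed,
                             max_iter=500, reg_covar=1e-6)
        gm.fit(X)
        bic = float(gm.bic(X))
        bic_by_k[k] = bic
        if best is None or bic < best[0]:
            best = (bic, gm)
    bic, gm = best
    comps = sorted(
        (MixtureComponent(float(w), float(m[0]), float(math.sqrt(c[0][0])))
         for w, m, c in zip(gm.weights_, gm.means_, gm.covariances_)),
        key=lambda c: c.mean,
    )
    return MixtureModel(comps, bic, bic_by_k, fit_range, len(x), seed)


def ks_histogram(values, bin_width: float = 0.05,
                 fit_range: tuple[float, float] = (0.0, 2.5)) -> pd.DataFrame:
    """Plot-ready histogram counts over half-open bins (for peak curves)."""
    lo, hi = fit_range
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram([v for v in values if v is not None], bins=edges)
    return pd.DataFrame({
        "bin_start": edges[:-1], "bin_end": edges[1:], "count": counts,
    })


# ---------------------------------------------------------------------------
# Rate correction and dating
# ---------------------------------------------------------------------------

def rate_correct(paralog_peaks: dict[str, float],
                 ortholog_peaks: dict[str, float]) -> dict[str, float]:
    """Outgroup-anchored relative-rate correction of paralog Ks peaks.

    Each ingroup species' ortholog Ks peak against a common outgroup
    measures its lineage rate; species i is rescaled by
    c_i = mean(ortholog peaks)/ortholog_peak_i, so faster-evolving
    lineages have their paralog peaks shrunk toward the mean rate.
    """
    missing = set(paralog_peaks) - set(ortholog_peaks)
    if missing:
        raise ValueError(f"missing outgroup ortholog peak for {sorted(missing)}")
    if len(ortholog_peaks) < 2:
        raise ValueError("rate correction needs >= 2 ingroup species")
    if any(v <= 0 for v in ortholog_peaks.values()):
        raise ValueError("ortholog peaks must be positive")
    mean_peak = float(np.mean(list(ortholog_peaks.values())))
    return {
        sp: paralog_peaks[sp] * (mean_peak / ortholog_peaks[sp])
        for sp in paralog_peaks
    }


def date_wgd(peak_ks: float, rate: float, peak_sd: float | None = None) -> WgdDate:
    """Clock conversion of a (corrected) Ks peak to an age in My.

    age = Ks / (2 r) with r in substitutions/site/year; the optional
    interval is peak ± 1 sd pushed through the same linear map.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if peak_ks < 0:
        raise ValueError("peak Ks must be >= 0")
    to_my = 1.0 / (2.0 * rate * 1.0e6)
    age = peak_ks * to_my
    interval = None
    if peak_sd is not None:
        interval = (max(0.0, (peak_ks - peak_sd) * to_my),
                    (peak_ks + peak_sd) * to_my)
    return WgdDate(peak_ks, rate, age, interval)
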