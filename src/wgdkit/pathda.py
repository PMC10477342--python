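"""Differential-metabolite calling and pathway differential-abundance scores.

Abundances are compared on the log2 scale: each metabolite gets a
two-sample t-test p-value and a fold change (ratio of group geometric
means), and is called *up* when FC ≥ 2 and p < 0.05, *down* when
FC ≤ 1/2 and p < 0.05, otherwise *ns* — the raw-p / fold-change screen of
targeted metabolomics.  The per-pathway DA score is
(n_up − n_down)/n_diff over the pathway's differential metabolites, so +1
means every differential metabolite in the pathway moved up and −1 that
all moved down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_FC = 2.0
DEFAULT_P = 0.05


@dataclass
class PathwayDAResult:
    pathway: str
    n_annotated: int
    n_diff: int
    n_up: int
    n_down: int
    da_score: float | None  # None when the pathway has no differential member


def call_differential(
    table: pd.DataFrame,
    groups: dict[str, str],
    group_a: str,
    group_b: str,
    fc_threshold: float = DEFAULT_FC,
    p_threshold: float = DEFAULT_P,
    log2_input: bool = False,
    fdr: bool = False,
    max_missing: int = 0,
) -> pd.DataFrame:
    """Call up/down/ns status per metabolite between two groups.

    ``table`` needs ``metabolite`` and ``pathway`` columns plus one column
    per sample; ``groups`` maps sample column → group label.  Fold change
    is group_b over group_a on the linear scale (2^Δmean-log2).  With
    ``fdr`` the p threshold is applied to Benjamini–Hochberg-adjusted
    p-values instead of raw ones.  Metabolites with more than
    ``max_missing`` missing replicates in either group are flagged
    ``excluded`` and called ``ns``.
    """
    cols_a = [s for s, g in groups.items() if g == group_a]
    cols_b = [s for s, g in groups.items() if g == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs >= 2 replicate samples")
    missing = [c for c in cols_a + cols_b if c not in table.columns]
    if missing:
        raise ValueError(f"sample columns not in table: {missing}")

    out = table[["metabolite", "pathway"]].copy()
    log2fc = np.full(len(table), np.nan)
    pvals = np.full(len(table), np.nan)
    excluded = np.zeros(len(table), dtype=bool)
    for i, row in enumerate(table.itertuples(index=False)):
        va = np.array([getattr(row, c) for c in cols_a], dtype=float)
        vb = np.array([getattr(row, c) for c in cols_b], dtype=float)
        if not log2_input:
            va, vb = np.log2(va), np.log2(vb)
        ok_a, ok_b = va[~np.isnan(va)], vb[~np.isnan(vb)]
        if (len(va) - len(ok_a) > max_missing or len(vb) - len(ok_b) > max_missing
                or len(ok_a) < 2 or len(ok_b) < 2):
            excluded[i] = True
            continue
        log2fc[i] = ok_b.mean() - ok_a.mean()
        pvals[i] = stats.ttest_ind(ok_a, ok_b).pvalue

    out["log2fc"] = log2fc
    out["fold_change"] = np.power(2.0, log2fc)
    out["pvalue"] = pvals
    if fdr:
        adj = np.full(len(table), np.nan)
        mask = ~np.isnan(pvals)
        if mask.any():
            adj[mask] = multipletests(pvals[mask], method="fdr_bh")[1]
        out["p_adj"] = adj
        effective_p = adj
    else:
        effective_p = pvals
    status = np.array(["ns"] * len(table), dtype=object)
    sig = (effective_p < p_threshold) & ~excluded
    status[sig & (out["fold_change"] >= fc_threshold)] = "up"
    status[sig & (out["fold_change"] <= 1.0 / fc_threshold)] = "down"
    out["status"] = status
    out["excluded"] = excluded
    return out


def da_score(records: pd.DataFrame, pathway: str,
             denominator: str = "differential") -> PathwayDAResult:
    """DA score of one pathway from called metabolite records.

    ``denominator='differential'`` (default) divides by the number of
    differential metabolites, matching the ±1 endpoints meaning *all
    differential metabolites move the same way*; ``'annotated'`` divides
    by every metabolite annotated to the pathway.
    """
    if denominator not in ("differential", "annotated"):
        raise ValueError("denominator must be 'differential' or 'annotated'")
    sub = records[records["pathway"] == pathway]
    if sub.empty:
        raise KeyError(f"unknown pathway id {pathway!r}")
    n_up = int((sub["status"] == "up").sum())
    n_down = int((sub["status"] == "down").sum())
    n_diff = n_up + n_down
    n_annot = int(len(sub))
    denom = n_diff if denominator == "differential" else n_annot
    score = (n_up - n_down) / denom if denom else None
    return PathwayDAResult(pathway, n_annot, n_diff, n_up, n_down, score)


def pathway_da_scores(records: pd.DataFrame,
                      denominator: str = "differential") -> pd.DataFrame:
    """DA scores for every pathway, plot-ready for a lollipop chart.

    Pathways without differential metabolites get a missing score (they
    are excluded from DA charts).
    """
    rows = []
    for pw in sorted(records["pathway"].unique()):
        r = da_score(records, pw, denominator=denominator)
        rows.append((r.pathway, r.n_annotated, r.n_diff, r.n_up, r.n_down,
                     r.da_score))
    return pd.DataFrame(
        rows, columns=["pathway", "n_annotated", "n_diff", "n_up", "n_down",
                       "da_score"])
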