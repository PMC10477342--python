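"""NG86 vs an independent pathway-enumeration oracle; mixtures; dating."""

import itertools
import math

import numpy as np
import pytest

from wgdkit._codon import GENETIC_CODE, NUCLEOTIDES, SENSE_CODONS
from wgdkit.ksdist import (
    block_median_ks,
    codon_align,
    date_wgd,
    fit_ks_mixture,
    ks_for_pair,
    ng86,
    rate_correct,
)
from wgdkit.synteny import Anchor, CollinearBlock


# ---------------------------------------------------------------------------
# Independent NG86 oracle (site counting + recursive pathway walk)
# ---------------------------------------------------------------------------

def oracle_sites(codon):
    """Synonymous sites by direct enumeration of the 9 point mutants."""
    syn = 0
    for pos, alt in itertools.product(range(3), NUCLEOTIDES):
        if alt == codon[pos]:
            continue
        mut = codon[:pos] + alt + codon[pos + 1 :]
        if GENETIC_CODE[mut] == GENETIC_CODE[codon] and GENETIC_CODE[mut] != "*":
            syn += 1
    return syn / 3.0


def oracle_differences(ca, cb):
    """Average syn/nonsyn steps over all substitution orders, recursively."""
    paths = []

    def walk(cur, remaining, sd, nd, blocked):
        if not remaining:
            paths.append((blocked, sd, nd))
            return
        for pos in remaining:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            syn = GENETIC_CODE[nxt] == GENETIC_CODE[cur]
            walk(nxt, [p for p in remaining if p != pos],
                 sd + syn, nd + (not syn),
                 blocked or GENETIC_CODE[nxt] == "*")

    walk(ca, [i for i in range(3) if ca[i] != cb[i]], 0, 0, False)
    usable = [(s, n) for b, s, n in paths if not b] or \
             [(s, n) for _, s, n in paths]
    return (sum(s for s, _ in usable) / len(usable),
            sum(n for _, n in usable) / len(usable))


class TestNg86:
    def test_identical_sequences_zero_rates(self):
        cds = "ATG" + "GGT" * 99
        est = ng86(cds, cds)
        assert est.ks == 0.0 and est.ka == 0.0 and est.valid

    def test_hand_counted_glycine_example(self):
        """3 Gly codons, one third-position change: S=3, N=6, Sd=1,
        pS=1/3, Ks = -0.75 ln(5/9), Ka = 0."""
        est = ng86("GGGGGGGGG", "GGAGGGGGG", min_codons=1)
        assert est.S == pytest.approx(3.0)
        assert est.N == pytest.approx(6.0)
        assert est.Sd == pytest.approx(1.0)
        assert est.Nd == pytest.approx(0.0)
        assert est.pS == pytest.approx(1 / 3)
        assert est.ks == pytest.approx(-0.75 * math.log(5 / 9))
        assert est.ks == pytest.approx(0.4408, abs=2e-4)
        assert est.ka == 0.0

    def test_saturated_pair_flagged_invalid(self):
        # ten 4-fold third positions all changed: pS = 1 >= 3/4
        a = "GGT" * 10
        b = "GGA" * 10
        est = ng86(a, b, min_codons=1)
        assert est.pS >= 0.75
        assert not est.valid and est.ks is None

    def test_sites_sum_to_three_per_codon(self):
        a = "ATG" + "TTA" * 40
        b = "ATG" + "CTA" * 40
        est = ng86(a, b)
        assert est.S + est.N == pytest.approx(3 * est.n_codons)

    def test_all_codon_pairs_match_pathway_oracle(self):
        """NG86 counting equals the independent oracle on every sense
        codon pair (all differ at <= 3 positions)."""
        for ca, cb in itertools.product(SENSE_CODONS, repeat=2):
            s_exp = (oracle_sites(ca) + oracle_sites(cb)) / 2
            if s_exp == 0:  # e.g. ATG/TGG pairs: Ks undefined
                with pytest.raises(ValueError, match="synonymous"):
                    ng86(ca, cb, min_codons=1)
                continue
            est = ng86(ca, cb, min_codons=1)
            sd_exp, nd_exp = oracle_differences(ca, cb)
            assert est.S == pytest.approx(s_exp), (ca, cb)
            assert est.Sd == pytest.approx(sd_exp), (ca, cb)
            assert est.Nd == pytest.approx(nd_exp), (ca, cb)


class TestCodonAlign:
    def test_identical_cds_no_gaps(self):
        cds = "ATGGGTAAA"
        a, b = codon_align(cds, cds, "MGK", "MGK")
        assert a == b == cds

    def test_protein_gap_becomes_codon_triplet_gap(self):
        a, b = codon_align("ATGGGTAAA", "ATGAAA", "MGK", "M-K")
        assert b == "ATG---AAA"
        assert len(a) == len(b)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            codon_align("ATGTAAAAA", "ATGTAAAAA", "M*K", "M*K")

    def test_mismatched_protein_rejected(self):
        with pytest.raises(ValueError, match="match"):
            codon_align("ATGGGTAAA", "ATGGGTAAA", "MGW", "MGW")


class TestBlockMedian:
    def _block(self, ks_values):
        anchors = [Anchor(f"a{i}", f"b{i}", "c1", "c2", i, i)
                   for i in range(len(ks_values))]
        block = CollinearBlock(0, "c1", "c2", "+", 1.0, anchors)
        ests = {}
        for i, ks in enumerate(ks_values):
            est = ng86("GGT" * 40, "GGT" * 40)  # template, then override
            est.ks, est.valid = ks, ks is not None
            ests[(f"a{i}", f"b{i}")] = est
        return block, ests

    def test_median_of_three(self):
        block, ests = self._block([0.30, 0.35, 0.90])
        assert block_median_ks(block, ests) == pytest.approx(0.35)

    def test_single_valid_anchor(self):
        block, ests = self._block([0.42, None, None])
        assert block_median_ks(block, ests) == pytest.approx(0.42)

    def test_all_saturated_block_rejected(self):
        block, ests = self._block([None, None])
        with pytest.raises(ValueError, match="no valid"):
            block_median_ks(block, ests)


class TestMixture:
    def test_single_component_recovered(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0.40, 0.05, 500)
        model = fit_ks_mixture(values, seed=0)
        assert model.n_components == 1
        assert 0.38 <= model.components[0].mean <= 0.42

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="Ks values"):
            fit_ks_mixture([])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0.4, 0.08, 200)
        m1 = fit_ks_mixture(values, seed=42)
        m2 = fit_ks_mixture(values, seed=42)
        assert m1.bic == m2.bic
        assert [c.mean for c in m1.components] == [c.mean for c in m2.components]

    def test_out_of_range_values_excluded(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(0.4, 0.05, 100),
                                 [0.001] * 50, [5.0] * 50])
        model = fit_ks_mixture(values, seed=0)
        assert model.n_values == 100

    def test_single_cohort_selects_k1_in_most_replicates(self, one_wgd_result):
        """BIC picks one component in >= 90% of replicates of a
        single-WGD cohort, fitting block-median-scale values (the
        fitter's prescribed input: one median per collinear block)."""
        res = one_wgd_result
        cds = res.genomes["anc"].cds
        ks = [ks_for_pair(cds[r.gene_a], cds[r.gene_b]).ks
              for r in res.truth.pairs.itertuples()]
        ks = np.array([k for k in ks if k is not None])
        rng = np.random.default_rng(3)
        wins = 0
        for rep in range(10):
            # emulate blocks of 8 anchors each by random partition
            perm = rng.permutation(ks)[:240]
            medians = np.median(perm.reshape(30, 8), axis=1)
            if fit_ks_mixture(medians, seed=rep).n_components == 1:
                wins += 1
        assert wins >= 9


class TestRecovery:
    def test_median_relative_error_below_10pct_at_300_codons(self):
        """Ks estimator recovers simulator truth (Ks 0.40 <= 1)."""
        from wgdkit.simulate import Event, EvolutionScenario, simulate_scenario

        res = simulate_scenario(EvolutionScenario(
            n_chromosomes=2, genes_per_chromosome=50, cds_codons=300,
            events=(Event("wgd", 47.6, "anc", retention=1.0),),
            synonymous_rate=4.2e-9, seed=13))
        cds = res.genomes["anc"].cds
        errs = []
        for row in res.truth.pairs.itertuples():
            est = ks_for_pair(cds[row.gene_a], cds[row.gene_b])
            if est.valid:
                errs.append(abs(est.ks - row.expected_ks) / row.expected_ks)
        assert np.median(errs) < 0.10


class TestRateCorrectionAndDating:
    def test_equal_ortholog_peaks_identity(self):
        out = rate_correct({"A": 0.30, "B": 0.30},
                           {"A": 0.50, "B": 0.50})
        assert out == {"A": 0.30, "B": 0.30}

    def test_twofold_rate_difference_converges(self):
        """B evolves twice as fast: raw peaks 0.6 (B) and 0.3 (A) from one
        event are corrected to a common 0.45."""
        out = rate_correct({"A": 0.30, "B": 0.60},
                           {"A": 0.40, "B": 0.80})
        assert out["A"] == pytest.approx(0.45)
        assert out["B"] == pytest.approx(0.45)

    def test_missing_outgroup_peak_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            rate_correct({"A": 0.3, "B": 0.4}, {"A": 0.5})

    def test_simulated_rate_ratio_correction(self):
        # same event seen through a 2x lineage-rate ratio
        raw = {"slow": 0.32, "fast": 0.64}
        orth = {"slow": 0.45, "fast": 0.90}
        corr = rate_correct(raw, orth)
        spread = abs(corr["slow"] - corr["fast"]) / np.mean(list(corr.values()))
        assert spread < 0.10

    def test_date_arithmetic(self):
        assert date_wgd(0.32, 2.5e-9).age_my == pytest.approx(64.0)
        assert date_wgd(0.0, 1e-9).age_my == 0.0

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            date_wgd(0.3, 0.0)

    @pytest.mark.parametrize("ks,rate", [(0.1, 1e-9), (0.5, 3e-9), (1.2, 7e-9)])
    def test_linear_in_ks_inverse_in_rate(self, ks, rate):
        base = date_wgd(ks, rate).age_my
        assert date_wgd(2 * ks, rate).age_my == pytest.approx(2 * base)
        assert date_wgd(ks, 2 * rate).age_my == pytest.approx(base / 2)

    def test_interval_from_peak_sd(self):
        d = date_wgd(0.40, 4.2e-9, peak_sd=0.04)
        lo, hi = d.interval_my
        assert lo == pytest.approx(0.36 / (2 * 4.2e-9) / 1e6)
        assert hi == pytest.approx(0.44 / (2 * 4.2e-9) / 1e6)
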