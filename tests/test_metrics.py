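"""Concordance, correlation, confusion, binning, fixed-SNP and info-score metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imputeval.containers import MISSING, GenotypeMatrix, PanelPair
from imputeval.metrics import (
    af_binned_concordance,
    allele_frequency_correlation,
    concordance,
    correlation,
    fixed_snp_report,
    genotype_confusion,
    impute_info_score,
    info_filter_evaluation,
    panel_discordance,
)
from imputeval.simulate import ErrorModel, SimulationConfig, inject_errors, simulate_dataset

from conftest import make_matrix, make_pair


def _random_pair(seed, n=20, m=60, miss=0.1):
    rng = np.random.default_rng(seed)
    t = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    i = t.copy()
    flip = rng.random(t.shape) < 0.1
    i[flip] = rng.integers(0, 3, size=int(flip.sum()))
    t[rng.random(t.shape) < miss] = MISSING
    i[rng.random(t.shape) < miss] = MISSING
    return make_pair(t, i)


class TestConcordance:
    def test_identity_is_one_everywhere(self):
        pair = _random_pair(0)
        pair = make_pair(pair.truth.calls, pair.truth.calls)
        res = concordance(pair)
        assert res.overall_cr == 1.0
        assert (res.per_sample["cr"].dropna() == 1.0).all()
        assert (res.per_snp["cr"].dropna() == 1.0).all()

    def test_hand_enumeration_single_sample(self):
        pair = make_pair([[0, 1, 2, 1, 0]], [[0, 1, 1, 1, 0]])
        res = concordance(pair)
        assert res.per_sample["cr"].iloc[0] == pytest.approx(0.8)
        assert res.overall_cr == pytest.approx(4 / 5)

    def test_missing_excluded_from_denominator(self):
        pair = make_pair([[0, 1, 2, 1, 0]], [[0, 1, MISSING, 1, 0]])
        res = concordance(pair)
        assert res.per_sample["n_compared"].iloc[0] == 4
        assert res.per_sample["cr"].iloc[0] == 1.0

    def test_zero_compared_marker_is_undefined(self):
        pair = make_pair([[0, 1], [0, 1]], [[0, MISSING], [0, MISSING]])
        res = concordance(pair)
        assert np.isnan(res.per_snp["cr"].iloc[1])

    def test_brute_force_oracle(self):
        """Vectorized CR equals a double-loop enumeration."""
        pair = _random_pair(5)
        res = concordance(pair)
        match = total = 0
        for i in range(pair.n_samples):
            for j in range(pair.n_markers):
                a, b = pair.truth.calls[i, j], pair.imputed.calls[i, j]
                if a != MISSING and b != MISSING:
                    total += 1
                    match += a == b
        assert res.overall_cr == pytest.approx(match / total)


class TestCorrelation:
    def test_identical_polymorphic_vectors(self):
        pair = make_pair([[0], [1], [2]], [[0], [1], [2]])
        res = correlation(pair)
        assert res.per_snp["r"].iloc[0] == pytest.approx(1.0)

    def test_monomorphic_truth_undefined(self):
        pair = make_pair([[0], [0], [0]], [[0], [1], [2]])
        res = correlation(pair)
        assert np.isnan(res.per_snp["r"].iloc[0])
        assert res.n_undefined_snps == 1

    def test_against_scipy_pearson(self):
        t = np.array([[0], [1], [2], [0], [1]], dtype=np.int8)
        i = np.array([[0], [2], [2], [0], [0]], dtype=np.int8)
        res = correlation(make_pair(t, i))
        expect = stats.pearsonr(t.ravel(), i.ravel()).statistic
        assert res.per_snp["r"].iloc[0] == pytest.approx(expect)

    def test_pairwise_complete_against_scipy(self):
        pair = _random_pair(7, n=30, m=20)
        res = correlation(pair)
        for j in range(pair.n_markers):
            a = pair.truth.calls[:, j]
            b = pair.imputed.calls[:, j]
            ok = (a != MISSING) & (b != MISSING)
            r = res.per_snp["r"].iloc[j]
            if ok.sum() < 2 or len(set(a[ok])) < 2 or len(set(b[ok])) < 2:
                assert np.isnan(r)
            else:
                assert r == pytest.approx(
                    stats.pearsonr(a[ok], b[ok]).statistic, abs=1e-10
                )


class TestConfusion:
    def test_perfect_diagonal(self):
        pair = make_pair([[0, 1, 2]], [[0, 1, 2]])
        pct = genotype_confusion(pair).row_percent()
        np.testing.assert_allclose(np.diag(pct), [100, 100, 100])

    def test_het_row_hand_count(self):
        t = np.ones((10, 1), dtype=np.int8)
        i = np.ones((10, 1), dtype=np.int8)
        i[0, 0] = 2
        conf = genotype_confusion(make_pair(t, i))
        np.testing.assert_allclose(conf.row_percent()[1], [0, 90, 10])
        assert conf.het_error_rate == pytest.approx(10.0)

    def test_trace_identity_with_overall_cr(self):
        for seed in range(5):
            pair = _random_pair(seed)
            conf = genotype_confusion(pair)
            assert conf.overall_cr == pytest.approx(concordance(pair).overall_cr)

    def test_empty_row_undefined(self):
        pair = make_pair([[0, 0]], [[0, 1]])
        pct = genotype_confusion(pair).row_percent()
        assert np.isnan(pct[1]).all() and np.isnan(pct[2]).all()

    def test_row_percentages_sum_to_100(self):
        pair = _random_pair(9)
        pct = genotype_confusion(pair).row_percent()
        sums = np.nansum(pct, axis=1)
        np.testing.assert_allclose(sums[~np.isnan(pct[:, 0])], 100.0, atol=0.01)


class TestAlleleLabelInvariance:
    def test_flipping_both_panels(self):
        pair = _random_pair(13)
        t2 = pair.truth.calls.copy()
        i2 = pair.imputed.calls.copy()
        for arr in (t2, i2):
            nm = arr != MISSING
            arr[nm] = 2 - arr[nm]
        flipped = make_pair(t2, i2)
        assert concordance(flipped).overall_cr == pytest.approx(
            concordance(pair).overall_cr
        )
        np.testing.assert_allclose(
            genotype_confusion(flipped).counts,
            genotype_confusion(pair).counts[::-1, ::-1],
        )
        r1 = correlation(pair).per_snp["r"]
        r2 = correlation(flipped).per_snp["r"]
        np.testing.assert_allclose(np.abs(r1), np.abs(r2), equal_nan=True)


class TestBinnedConcordance:
    def test_hand_assignment(self):
        # frequencies 0.005 and 0.015 (10 samples): bins 0 and 1
        t = np.zeros((100, 2), dtype=np.int8)
        t[0, 0] = 1  # freq 0.005
        t[:3, 1] = 1  # freq 0.015
        i = t.copy()
        i[:20, 1] = np.where(i[:20, 1] == 0, 1, 0)  # 20% errors at marker 2
        bins = af_binned_concordance(make_pair(t, i))
        assert bins.loc[0, "n_markers"] == 1 and bins.loc[0, "mean_cr"] == 1.0
        assert bins.loc[1, "n_markers"] == 1
        assert bins.loc[1, "mean_cr"] == pytest.approx(0.8)

    def test_single_bin_equals_overall_mean(self):
        pair = _random_pair(3, miss=0.0)
        # force all truth frequencies into one bin by construction
        t = np.tile([0, 1, 1, 2], (pair.n_markers, 1)).T.astype(np.int8)
        pair = make_pair(t, t)
        bins = af_binned_concordance(pair)
        populated = bins[bins["n_markers"] > 0]
        assert len(populated) == 1
        assert populated["mean_cr"].iloc[0] == 1.0

    def test_frequency_one_goes_to_last_bin(self):
        t = np.full((4, 1), 2, dtype=np.int8)
        bins = af_binned_concordance(make_pair(t, t))
        assert bins.iloc[-1]["n_markers"] == 1

    def test_empty_bins_flagged_not_zero(self):
        t = np.ones((4, 1), dtype=np.int8)
        bins = af_binned_concordance(make_pair(t, t))
        empty = bins[bins["n_markers"] == 0]
        assert len(empty) == 99 and empty["mean_cr"].isna().all()

    def test_folded_maf_view(self):
        t = np.full((4, 1), 2, dtype=np.int8)  # ALT freq 1 -> MAF 0
        bins = af_binned_concordance(make_pair(t, t), use_maf=True)
        assert len(bins) == 50 and bins.iloc[0]["n_markers"] == 1


class TestAlleleFrequencyCorrelation:
    def test_identical_frequencies(self):
        pair = _random_pair(4, miss=0.0)
        pair = make_pair(pair.truth.calls, pair.truth.calls)
        assert allele_frequency_correlation(pair) == pytest.approx(1.0)

    def test_three_marker_toy_matches_pearson(self):
        t = np.array([[0, 1, 2], [1, 1, 2], [0, 0, 2], [0, 1, 1]], dtype=np.int8)
        i = np.array([[0, 1, 2], [0, 1, 2], [0, 1, 2], [1, 1, 2]], dtype=np.int8)
        pair = make_pair(t, i)
        ft = t.mean(axis=0) / 2
        fi = i.mean(axis=0) / 2
        expect = stats.pearsonr(ft, fi).statistic
        assert allele_frequency_correlation(pair) == pytest.approx(expect)

    def test_monomorphic_markers_contribute(self):
        t = np.array([[0, 2, 1], [0, 2, 1]], dtype=np.int8)
        assert allele_frequency_correlation(make_pair(t, t)) == pytest.approx(1.0)


class TestFixedSnpReport:
    def test_hand_counts(self):
        # 10 markers fixed hom-REF, 3 spuriously segregating in imputed
        t = np.zeros((10, 12), dtype=np.int8)
        t[:, 10] = 1  # polymorphic
        t[:, 11] = 1
        i = t.copy()
        for j in range(3):
            i[j, j] = 1
        rep = fixed_snp_report(make_pair(t, i))
        assert rep.n_monomorphic == 10
        assert rep.n_spurious == 3
        assert rep.spurious_fraction == pytest.approx(0.3)
        assert rep.mean_spurious_maf == pytest.approx(0.05)
        assert rep.concordance_on_monomorphic == pytest.approx(97 / 100)

    def test_printed_count_percentage(self):
        t = np.zeros((2, 4), dtype=np.int8)
        t[:, 0] = 1
        rep = fixed_snp_report(make_pair(t, t))
        assert rep.monomorphic_pct == pytest.approx(75.0)
        assert rep.n_spurious == 0
        assert rep.concordance_on_monomorphic == 1.0

    def test_no_monomorphic_markers(self):
        t = np.array([[0, 1], [1, 2]], dtype=np.int8)
        rep = fixed_snp_report(make_pair(t, t))
        assert rep.n_monomorphic == 0 and rep.spurious_fraction == 0.0


class TestPanelDiscordance:
    def test_identical_zero(self):
        gm = make_matrix(np.ones((4, 5), dtype=np.int8))
        rep = panel_discordance(gm, gm)
        assert rep.overall_discordance == 0.0

    def test_one_mismatch_in_200(self):
        t = np.zeros((10, 20), dtype=np.int8)
        b = t.copy()
        b[0, 0] = 1
        rep = panel_discordance(make_matrix(t), make_matrix(b))
        assert rep.overall_discordance == pytest.approx(0.005)

    def test_complement_of_concordance(self):
        pair = _random_pair(17)
        rep = panel_discordance(pair.truth, pair.imputed)
        cr = concordance(pair).overall_cr
        assert rep.overall_discordance == pytest.approx(1 - cr)

    def test_prefill_missing_decomposition(self):
        original = np.array([[MISSING, 0, 1], [0, MISSING, 2]], dtype=np.int8)
        filled = np.array([[1, 0, 1], [0, 2, 2]], dtype=np.int8)
        other = np.array([[0, 0, 1], [0, 2, 2]], dtype=np.int8)
        rep = panel_discordance(
            make_matrix(filled), make_matrix(other),
            original_a=make_matrix(original),
        )
        assert rep.n_prefill_missing_compared == 2
        assert rep.discordance_on_prefill_missing == pytest.approx(0.5)
        assert rep.overall_discordance == pytest.approx(1 / 6)

    def test_marker_subset_stratification(self):
        a = np.array([[0, 0, 0, 0]], dtype=np.int8)
        b = np.array([[1, 0, 0, 0]], dtype=np.int8)
        subset = np.array([True, True, False, False])
        rep = panel_discordance(make_matrix(a), make_matrix(b), marker_subset=subset)
        assert rep.discordance_on_subset == pytest.approx(0.5)
        assert rep.discordance_off_subset == 0.0


class TestInfoScore:
    def test_certain_posteriors_give_one(self):
        p = np.zeros((5, 3))
        p[:2, 1] = 1.0
        p[2:, 2] = 1.0
        assert impute_info_score(p) == pytest.approx(1.0)

    def test_theta_zero_convention(self):
        p = np.zeros((4, 3))
        p[:, 0] = 1.0
        assert impute_info_score(p) == 1.0

    def test_two_sample_uncertain_toy(self):
        """(0.25, 0.5, 0.25) twice: formula gives exactly zero information."""
        p = np.tile([0.25, 0.5, 0.25], (2, 1))
        e = 0.5 + 2 * 0.25
        f = 0.5 + 4 * 0.25
        theta = 2 * e / 4
        expect = 1 - 2 * (f - e**2) / (4 * theta * (1 - theta))
        assert impute_info_score(p) == pytest.approx(max(expect, 0.0))
        assert impute_info_score(p) == pytest.approx(0.0)

    def test_tensor_and_single_marker_agree(self):
        rng = np.random.default_rng(8)
        post = rng.dirichlet(np.ones(3), size=(10, 7))
        vec = impute_info_score(post)
        assert vec.shape == (7,)
        for j in range(7):
            assert vec[j] == pytest.approx(impute_info_score(post[:, j, :]))

    def test_bad_posterior_sum_rejected(self):
        p = np.tile([0.5, 0.5, 0.5], (2, 1))
        with pytest.raises(ValueError, match="sum to 1"):
            impute_info_score(p)


class TestInfoFilterEvaluation:
    def _per_snp(self, cr):
        n = len(cr)
        return pd.DataFrame(
            {
                "cr": cr,
                "truth_alt_freq": np.linspace(0.05, 0.95, n),
                "n_compared": np.full(n, 10),
            }
        )

    def test_ten_marker_hand_means(self):
        info = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
        cr = np.array([0.5, 0.6, 0.7, 0.8, 0.85, 0.9, 0.92, 0.95, 0.98, 1.0])
        rep = info_filter_evaluation(info, self._per_snp(cr), cutoff=0.6)
        assert rep.mean_cr_retained == pytest.approx(cr[5:].mean())
        assert rep.mean_cr_removed == pytest.approx(cr[:5].mean())
        assert rep.frac_calls_retained == pytest.approx(0.5)
        assert rep.frac_low_cr_before == pytest.approx(0.5)
        assert rep.frac_low_cr_after == pytest.approx(0.0)
        assert rep.r_info_cr == pytest.approx(
            stats.pearsonr(info, cr).statistic
        )

    def test_cutoff_zero_retains_all(self):
        info = np.array([0.0, 0.5, 1.0])
        rep = info_filter_evaluation(info, self._per_snp([0.9, 0.95, 1.0]), cutoff=0.0)
        assert rep.frac_calls_retained == 1.0
        assert np.isnan(rep.mean_cr_removed)

    def test_all_info_one_cutoff_one(self):
        info = np.ones(3)
        rep = info_filter_evaluation(info, self._per_snp([0.9, 0.95, 1.0]), cutoff=1.0)
        assert rep.frac_calls_retained == 1.0

    def test_cutoff_validation(self):
        with pytest.raises(ValueError):
            info_filter_evaluation(np.ones(1), self._per_snp([1.0]), cutoff=1.5)


class TestParameterRecovery:
    def test_confusion_recovers_transition_rows(self):
        """Row percentages converge to the injected matrix within 3 binomial SE."""
        t = np.array([[0.96, 0.03, 0.01], [0.04, 0.92, 0.04], [0.01, 0.03, 0.96]])
        rng = np.random.default_rng(50)
        calls = rng.integers(0, 3, size=(120, 300)).astype(np.int8)
        truth = make_matrix(calls, step=100)
        imputed, _ = inject_errors(truth, ErrorModel(transition=t), seed=51)
        conf = genotype_confusion(PanelPair(truth=truth, imputed=imputed))
        for g in range(3):
            n = conf.counts[g].sum()
            assert n >= 10_000
            for h in range(3):
                p_hat = conf.counts[g, h] / n
                se = np.sqrt(t[g, h] * (1 - t[g, h]) / n)
                assert abs(p_hat - t[g, h]) <= 3 * se + 1e-9

    def test_more_error_mass_lowers_cr(self):
        """Expected overall CR decreases as off-diagonal mass grows."""
        def model(err):
            m = np.full((3, 3), err / 2)
            np.fill_diagonal(m, 1 - err)
            return ErrorModel(transition=m)

        means = []
        for err in (0.02, 0.10, 0.25):
            crs = []
            for seed in (61, 62, 63):
                rng = np.random.default_rng(seed)
                calls = rng.integers(0, 3, size=(40, 400)).astype(np.int8)
                truth = make_matrix(calls, step=100)
                imputed, _ = inject_errors(truth, model(err), seed=seed + 100)
                crs.append(
                    concordance(PanelPair(truth=truth, imputed=imputed)).overall_cr
                )
            means.append(np.mean(crs))
        assert means[0] > means[1] > means[2]

    def test_perfect_imputation_limit(self, small_dataset):
        truth = small_dataset.truth
        pair = PanelPair(truth=truth, imputed=truth)
        assert concordance(pair).overall_cr == 1.0
        res = correlation(pair)
        defined = res.per_snp["r"].dropna()
        np.testing.assert_allclose(defined, 1.0)
        assert allele_frequency_correlation(pair) == pytest.approx(1.0)
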