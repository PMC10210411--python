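"""logCPM, EB variance prior, moderated t, wFisher, meta-DE pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.special import polygamma

import admixomics as ax
from admixomics.demeta import EBPrior, _trigamma_inverse


class TestLogCPM:
    def test_single_zero_count_closed_form(self):
        counts = pd.DataFrame({"s": [0, 10**6 - 0]})  # libsize 1e6
        out = ax.logcpm(counts)
        expect = np.log2(0.5 / (1e6 + 1.0) * 1e6)
        assert out.iloc[0, 0] == pytest.approx(expect, abs=1e-12)

    def test_scale_invariance_up_to_prior(self):
        # doubling counts and library sizes perturbs a value only through the
        # prior count; the shift is ~ 0.5 / (2 ln 2 * count), so ~0.36/count
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.integers(10, 5000, size=(200, 4)))
        a, b = ax.logcpm(counts), ax.logcpm(counts * 2)
        dev = np.abs(a.to_numpy() - b.to_numpy())
        assert dev.max() < 0.05
        assert dev[counts.to_numpy() >= 1000].max() < 5e-4

    def test_matches_hand_computation(self):
        counts = pd.DataFrame([[3, 7], [5, 1]], dtype=float)
        lib = counts.sum(axis=0)
        expect = np.log2((counts + 0.5) / (lib + 1.0) * 1e6)
        assert np.allclose(ax.logcpm(counts), expect, atol=1e-12)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            ax.logcpm(pd.DataFrame({"s": [0, 0]}))


class TestEBPrior:
    def test_identical_variances_give_infinite_d0(self):
        prior = ax.estimate_eb_prior(np.full(100, 0.37), df=10)
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.37, abs=1e-6)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(21)
        d0, s0, df = 4.0, 0.25, 10
        s_sq = (
            s0
            * (d0 / sps.chi2.rvs(d0, size=50_000, random_state=rng))
            * (sps.chi2.rvs(df, size=50_000, random_state=rng) / df)
        )
        prior = ax.estimate_eb_prior(s_sq, df)
        assert 3.2 < prior.d0 < 4.8
        assert 0.22 < prior.s0_sq < 0.28

    def test_trigamma_inverse_identity(self):
        assert _trigamma_inverse(float(polygamma(1, 2.5))) == pytest.approx(2.5, abs=1e-8)

    def test_nonpositive_variances_floored(self):
        with pytest.warns(UserWarning, match="floored"):
            prior = ax.estimate_eb_prior(np.r_[np.full(30, 0.5), 0.0], df=8)
        assert np.isfinite(prior.s0_sq)


class TestModeratedT:
    def test_shrinkage_off_equals_pooled_t(self):
        rng = np.random.default_rng(31)
        X = pd.DataFrame(rng.normal(size=(10, 12)))
        y = np.array(["AA"] * 6 + ["EA"] * 6)
        fit = ax.ModeratedTTest(prior=EBPrior(d0=0.0, s0_sq=1.0)).fit(X, y)
        t_ref, p_ref = sps.ttest_ind(X.iloc[:, :6], X.iloc[:, 6:], axis=1)
        assert np.allclose(fit.t_, t_ref, atol=1e-12)
        assert np.allclose(fit.p_, p_ref, atol=1e-12)

    def test_identical_group_means_null(self):
        X = pd.DataFrame(np.tile([[1.0, 2.0, 1.0, 2.0]], (5, 1)))
        y = np.array(["AA", "AA", "EA", "EA"])
        fit = ax.ModeratedTTest(prior=EBPrior(d0=0.0, s0_sq=1.0)).fit(X, y)
        assert np.allclose(fit.logfc_, 0.0)
        assert np.allclose(fit.p_, 1.0)

    def test_null_type_i_error_in_band(self):
        clinical = ax.make_clinical(50, 50, seed=12)
        cfg = ax.SimConfig(seed=12, n_AA=50, n_EA=50, G=2000, de_fraction=0.0, batch_effect_sd=0.0)
        counts, samples, _ = ax.make_counts(clinical, cfg)
        res = ax.batch_de(counts, samples["group"].to_numpy())
        rate = (res["p"] < 0.05).mean()
        band = 1.96 * np.sqrt(0.05 * 0.95 / 2000)
        assert 0.05 - band < rate < 0.05 + band


class TestWFisher:
    def test_single_batch_identity(self):
        for p in (0.001, 0.37, 0.9):
            mp, d = ax.wfisher_combine(np.array([p]), np.array([1.0]), np.array([40.0]))
            assert mp == pytest.approx(p, abs=1e-12)

    def test_equal_weights_reduce_to_classical_fisher(self):
        rng = np.random.default_rng(41)
        for _ in range(200):
            p = rng.uniform(0.001, 1.0, size=2)
            mp, _ = ax.wfisher_combine(p, np.array([1.0, 1.0]), np.array([50.0, 50.0]))
            stat = -2 * np.sum(np.log(p / 2))
            fisher_one = sps.chi2.sf(stat, 4)
            expect = min(1.0, 2 * min(fisher_one, 1 - fisher_one))
            assert mp == pytest.approx(expect, abs=1e-12)

    def test_worked_equal_weight_example(self):
        mp, d = ax.wfisher_combine(
            np.array([0.05, 0.05]), np.array([1.0, 1.0]), np.array([50.0, 50.0])
        )
        T = -2 * (np.log(0.025) + np.log(0.025))
        assert mp == pytest.approx(2 * sps.chi2.sf(T, 4), abs=1e-12)
        assert d == 1.0

    def test_null_meta_p_uniform(self):
        rng = np.random.default_rng(11)
        P = rng.uniform(size=(50_000, 2))
        S = rng.choice([-1.0, 1.0], size=(50_000, 2))
        mp, _ = ax.wfisher_combine(P, S, np.array([30.0, 70.0]))
        assert sps.kstest(mp, "uniform").pvalue > 0.01

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        p1=st.floats(1e-6, 0.5),
        p2=st.floats(1e-6, 0.5),
        bump=st.floats(1e-6, 0.4),
        idx=st.integers(0, 1),
    )
    def test_monotone_in_each_p_when_directions_agree(self, p1, p2, bump, idx):
        p = np.array([p1, p2])
        s = np.array([1.0, 1.0])
        n = np.array([30.0, 70.0])
        base, _ = ax.wfisher_combine(p, s, n)
        p_hi = p.copy()
        p_hi[idx] = min(p_hi[idx] + bump, 0.5)
        hi, _ = ax.wfisher_combine(p_hi, s, n)
        assert hi >= base - 1e-12

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            mp, _ = ax.wfisher_combine(np.array([0.0, 0.5]), np.array([1.0, 1.0]), np.array([50.0, 50.0]))
        assert 0.0 < mp < 1.0

    def test_zero_weight_batch_dropped(self):
        mp, _ = ax.wfisher_combine(
            np.array([0.2, 0.9]), np.array([1.0, -1.0]), np.array([50.0, 0.0])
        )
        assert mp == pytest.approx(0.2, abs=1e-12)


class TestCombineLogFC:
    def test_single_batch_identity(self):
        assert ax.combine_logfc(np.array([1.7]), np.array([10.0])) == pytest.approx(1.7)

    def test_equal_n_arithmetic_mean(self):
        assert ax.combine_logfc(np.array([1.0, 3.0]), np.array([5.0, 5.0])) == pytest.approx(2.0)

    def test_weighted_average(self):
        assert ax.combine_logfc(np.array([1.0, 2.0]), np.array([100.0, 300.0])) == pytest.approx(1.75)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            ax.combine_logfc(np.array([1.0]), np.array([0.0]))


class TestMetaDE:
    def test_bonferroni_cutoff_formula(self):
        clinical = ax.make_clinical(20, 20, seed=81)
        cfg = ax.SimConfig(seed=81, n_AA=20, n_EA=20, G=100)
        counts, samples, _ = ax.make_counts(clinical, cfg)
        _, meta = ax.meta_de(counts, samples, alpha_family=0.01)
        assert meta["cutoff"] == pytest.approx(0.01 / 100)
        # at the study's family size the cutoff is the published 1.0e-06
        assert 0.01 / 10_000 == pytest.approx(1.0e-06)

    def test_discordant_direction_never_significant(self, small_cohort):
        res, _ = ax.meta_de(small_cohort["counts"], small_cohort["samples"])
        assert not (res["significant"] & ~res["concordant"]).any()
        disc = res[~res["concordant"]]
        assert (~disc["significant"]).all()

    def test_pipeline_deterministic(self, small_cohort):
        a, _ = ax.meta_de(small_cohort["counts"], small_cohort["samples"])
        b, _ = ax.meta_de(small_cohort["counts"], small_cohort["samples"])
        pd.testing.assert_frame_equal(a, b)

    def test_global_null_yields_no_discoveries(self):
        zero_runs = 0
        for s in range(20):
            clinical = ax.make_clinical(50, 50, seed=100 + s)
            cfg = ax.SimConfig(
                seed=100 + s, n_AA=50, n_EA=50, G=2000, de_fraction=0.0, batch_effect_sd=0.0
            )
            counts, samples, _ = ax.make_counts(clinical, cfg)
            res, _ = ax.meta_de(counts, samples)
            zero_runs += int(res["significant"].sum() == 0)
        assert zero_runs >= 19

    def test_planted_effects_recovered_with_correct_signs(self):
        clinical = ax.make_clinical(200, 200, seed=13)
        cfg = ax.SimConfig(seed=13, n_AA=200, n_EA=200, G=2000, de_fraction=0.05, effect_size=2.0)
        counts, samples, truth = ax.make_counts(clinical, cfg)
        res, _ = ax.meta_de(counts, samples)
        beta = truth.set_index("gene")["beta"]
        de_genes = beta.index[beta != 0]
        sens = res.loc[de_genes, "significant"].mean()
        assert sens >= 0.8
        called = res.index[res["significant"] & (beta != 0)]
        assert (np.sign(res.loc[called, "meta_logFC"]) == np.sign(beta[called])).all()

    def test_batch_missing_group_rejected(self, small_cohort):
        samples = small_cohort["samples"].copy()
        samples.loc[samples["group"] == "AA", "batch"] = "v1"
        samples.loc[samples["group"] == "EA", "batch"] = "v2"
        with pytest.raises(ValueError):
            ax.meta_de(small_cohort["counts"], samples)
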