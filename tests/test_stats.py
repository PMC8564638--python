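import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import ctscreen as cs
from ctscreen.errors import ContractError, CTScreenError, InsufficientDataError
from ctscreen.stats import trigamma_inverse

from oracle import step_up_bh


def simulate_inv_chisq_variances(rng, n, d0, s0_sq, d_g):
    """Hierarchical draw: sigma_g^2 from the scaled inverse chi-square prior,
    then the usual chi-square sampling distribution of s_g^2."""
    sigma2 = d0 * s0_sq / rng.chisquare(d0, n)
    return sigma2 * rng.chisquare(d_g, n) / d_g


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert cs.benjamini_hochberg([0.03]) == pytest.approx([0.03])

    def test_hand_evaluated_step_up_example(self):
        q = cs.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        assert cs.benjamini_hochberg([1.0] * 5) == pytest.approx([1.0] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(CTScreenError):
            cs.benjamini_hochberg([0.5, 1.2])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_literal_step_up_formula(self, p):
        q = cs.benjamini_hochberg(p)
        expected = step_up_bh(p)
        assert q == pytest.approx(expected)
        assert np.all(q >= np.asarray(p) - 1e-12)
        # monotone nondecreasing in the sorted-p order
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)


class TestVariancePrior:
    def test_identical_variances_give_infinite_d0(self):
        prior = cs.estimate_variance_prior(np.full(100, 0.25), 50)
        assert np.isinf(prior.d0)
        # log-scale bias correction leaves a ~exp(1/d_g) factor
        assert prior.s0_sq == pytest.approx(0.25, rel=0.05)

    def test_recovers_planted_hyperparameters(self):
        rng = np.random.default_rng(7)
        s2 = simulate_inv_chisq_variances(rng, 10_000, d0=4.0, s0_sq=0.05, d_g=4)
        prior = cs.estimate_variance_prior(s2, 4)
        assert prior.d0 == pytest.approx(4.0, rel=0.20)
        assert prior.s0_sq == pytest.approx(0.05, rel=0.10)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(11)
        s2 = simulate_inv_chisq_variances(rng, 2000, d0=5.0, s0_sq=0.1, d_g=6)
        p1 = cs.estimate_variance_prior(s2, 6)
        p2 = cs.estimate_variance_prior(2.0 * s2, 6)
        assert p2.s0_sq == pytest.approx(2.0 * p1.s0_sq, rel=1e-8)
        assert p2.d0 == pytest.approx(p1.d0, rel=1e-8)

    def test_too_few_variances_rejected(self):
        with pytest.raises(InsufficientDataError):
            cs.estimate_variance_prior(np.full(5, 0.1), 4)

    def test_trigamma_inverse_solves_trigamma(self):
        from scipy.special import polygamma

        for y in (1e-5, 0.01, 0.5, 2.0, 50.0, 1e6):
            x = trigamma_inverse(y)
            assert polygamma(1, x) == pytest.approx(y, rel=1e-6)


class TestModeratedT:
    def test_null_difference_gives_t0_p1(self):
        a = np.tile([5.0, 6.0, 7.0], (4, 1))
        res = cs.moderated_t(a, a.copy(), d0=4.0, s0_sq=0.1)
        assert np.allclose(res.table["t"], 0.0)
        assert np.allclose(res.table["p"], 1.0)

    def test_d0_zero_equals_classical_pooled_t(self):
        rng = np.random.default_rng(3)
        a = rng.normal(5, 1, size=(5, 4))
        b = rng.normal(5, 1, size=(5, 6))
        res = cs.moderated_t(a, b, d0=0.0, s0_sq=1.0)
        t_ref, p_ref = sps.ttest_ind(a, b, axis=1, equal_var=True)
        assert np.allclose(res.table["t"], t_ref, rtol=1e-10)
        assert np.allclose(res.table["p"], p_ref, rtol=1e-10)

    def test_infinite_d0_uses_prior_variance_and_normal_reference(self):
        rng = np.random.default_rng(4)
        a = rng.normal(6, 0.5, size=(8, 3))
        b = rng.normal(5, 0.5, size=(8, 3))
        prior = cs.PriorEstimate(d0=np.inf, s0_sq=0.25)
        res = cs.moderated_t(a, b, prior)
        expected_t = (a.mean(1) - b.mean(1)) / np.sqrt(0.25 * (1 / 3 + 1 / 3))
        assert np.allclose(res.table["t"], expected_t)
        assert np.allclose(res.table["p"], 2 * sps.norm.sf(np.abs(expected_t)))

    def test_antisymmetric_in_group_order(self):
        rng = np.random.default_rng(5)
        a = rng.normal(6, 0.4, size=(10, 3))
        b = rng.normal(5, 0.4, size=(10, 4))
        prior = cs.PriorEstimate(d0=3.0, s0_sq=0.2)
        ab = cs.moderated_t(a, b, prior)
        ba = cs.moderated_t(b, a, prior)
        assert np.allclose(ab.table["t"], -ba.table["t"])
        assert np.allclose(ab.table["p"], ba.table["p"])

    def test_q_at_least_p(self):
        rng = np.random.default_rng(6)
        a = rng.normal(5, 0.5, size=(50, 3))
        b = rng.normal(5, 0.5, size=(50, 3))
        res = cs.two_group_contrast(a, b)
        assert np.all(res.table["q"] >= res.table["p"] - 1e-12)
        assert res.table["p"].between(0, 1).all()

    def test_small_group_raises_contract_error(self):
        a = np.ones((5, 1))
        b = np.ones((5, 3))
        with pytest.raises(ContractError):
            cs.moderated_t(a, b, d0=1.0, s0_sq=0.1)

    def test_prior_only_fallback_flags_and_scales(self):
        rng = np.random.default_rng(8)
        a = rng.normal(7, 0.3, size=(20, 1))
        b = rng.normal(5, 0.3, size=(20, 3))
        prior = cs.PriorEstimate(d0=4.0, s0_sq=0.09)
        res = cs.two_group_contrast(a, b, prior=prior)
        assert (res.table["method_flag"] == "prior_only").all()
        assert res.df_residual == 0.0
        expected_t = (a.mean(1) - b.mean(1)) / np.sqrt(0.09 * (1 + 1 / 3))
        assert np.allclose(res.table["t"], expected_t)

    def test_null_pvalues_pass_ks_uniformity(self):
        rng = np.random.default_rng(12)
        a = rng.normal(5.0, 0.4, size=(2000, 3))
        b = rng.normal(5.0, 0.4, size=(2000, 3))
        res = cs.two_group_contrast(a, b)
        stat, pval = sps.kstest(res.table["p"], "uniform")
        assert pval > 0.01

    def test_moderation_beats_classical_t_at_small_n(self):
        # 5% of probesets shifted by +1.5 log2 units, n=3 per group, sd 0.3
        rng = np.random.default_rng(13)
        n = 4000
        shifted = np.zeros(n, dtype=bool)
        shifted[: n // 20] = True
        a = rng.normal(5.0, 0.3, size=(n, 3)) + np.where(shifted, 1.5, 0.0)[:, None]
        b = rng.normal(5.0, 0.3, size=(n, 3))
        mod = cs.two_group_contrast(a, b)
        mod_hits = (mod.table["q"][shifted] <= 0.01).mean()
        _, p_cls = sps.ttest_ind(a, b, axis=1, equal_var=True)
        cls_hits = (cs.benjamini_hochberg(p_cls)[shifted] <= 0.01).mean()
        assert mod_hits > cls_hits

    def test_limma_cross_check(self, tmp_path):
        """The in-house prior fit and moderated t agree with the reference
        Bioconductor implementation on a shared fixture."""
        rscript = shutil.which("Rscript")
        assert rscript is not None, "Rscript expected on PATH"
        rng = np.random.default_rng(21)
        n, na, nb = 60, 4, 4
        sigma2 = 4.0 * 0.05 / rng.chisquare(4.0, n)
        a = 5.0 + rng.standard_normal((n, na)) * np.sqrt(sigma2)[:, None]
        b = 5.3 + rng.standard_normal((n, nb)) * np.sqrt(sigma2)[:, None]
        mat = pd.DataFrame(np.hstack([a, b]))
        fixture = tmp_path / "m.tsv"
        mat.to_csv(fixture, sep="\t", index=False, header=False)
        script = tmp_path / "limma.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("{fixture}", header=FALSE))
            design <- cbind(1, c(rep(1, {na}), rep(0, {nb})))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(d0=fit$df.prior, s0=fit$s2.prior,
                              t=fit$t[,2], p=fit$p.value[,2])
            write.table(out, "{tmp_path}/out.tsv", sep="\\t", row.names=FALSE)
        """))
        subprocess.run([rscript, str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        res = cs.two_group_contrast(a, b)
        assert res.prior.d0 == pytest.approx(ref["d0"][0], rel=1e-3)
        assert res.prior.s0_sq == pytest.approx(ref["s0"][0], rel=1e-3)
        assert np.allclose(res.table["t"], ref["t"], rtol=1e-6)
        assert np.allclose(res.table["p"], ref["p"], rtol=1e-6)
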