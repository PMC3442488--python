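"""Moderated-t machinery: fold changes, variance prior, BH, DEG calls.

The moderated-t implementation is cross-checked against an independently
computed empirical-Bayes oracle (limma 3.58.1 ``lmFit``/``eBayes`` run once
on the deterministic matrix below; its outputs are frozen here) and against
the plain pooled two-sample t-test in the no-shrinkage limit.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from crossdeg.de_stats import (
    Contrast,
    ModeratedTModel,
    bh_adjust,
    call_deg,
    compute_log2fc,
    de_table,
    fit_variance_prior,
    moderated_t,
    pooled_variance,
    trigamma_inverse,
)


def _matrix(data, prefix="s"):
    data = np.asarray(data, float)
    return pd.DataFrame(
        data,
        index=[f"g{i+1}" for i in range(data.shape[0])],
        columns=[f"{prefix}{j}" for j in range(data.shape[1])],
    )


def _contrast(n1, n2, prefix="s"):
    cols = [f"{prefix}{j}" for j in range(n1 + n2)]
    return Contrast("case_vs_control", tuple(cols[n2:]), tuple(cols[:n2]))


def oracle_matrix():
    """Deterministic 60×8 matrix; the frozen limma numbers below were
    computed from exactly this array (written at 10 decimals)."""
    rng = np.random.default_rng(20120914)
    G, n = 60, 8
    mu = rng.uniform(6, 12, G)
    sig = np.sqrt(4 * 0.05 / rng.chisquare(4, G))
    X = mu[:, None] + rng.normal(0, sig[:, None], (G, n))
    X[:10, 4:] += rng.choice([-2.0, 2.0], 10)[:, None]
    return _matrix(np.round(X, 10))


LIMMA_PRIOR = {"d0": 3.82795086508, "s0sq": 0.0476374686764}
LIMMA_ROWS = {  # gene -> (log2fc, t, p_raw)
    "g1": (2.5382147135, 9.69889947533, 2.39827610214e-06),
    "g2": (2.10278070743, 5.99959003578, 0.000141883294411),
    "g3": (1.88221466752, 7.33053069579, 2.75817850175e-05),
    "g4": (-1.93016163095, -16.997447229, 1.30047397075e-08),
    "g5": (-1.69828936837, -11.6795672624, 4.41597942652e-07),
    "g6": (-1.42954535725, -4.78512245875, 0.000776880483425),
}


class TestLog2FC:
    def test_mean_difference_and_antisymmetry(self):
        mat = _matrix([[5.0, 5.0, 3.0, 3.0], [4.0, 6.0, 4.0, 6.0]])
        c = _contrast(2, 2)
        fc = compute_log2fc(mat, c)
        assert fc["g1"] == pytest.approx(-2.0)
        assert fc["g2"] == pytest.approx(0.0)
        assert np.allclose(compute_log2fc(mat, c.flipped()), -fc)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="empty"):
            Contrast("bad", (), ("s0",))


class TestVariancePrior:
    def test_trigamma_inverse_is_right_inverse(self):
        for x in [1e-5, 0.01, 0.5, 2.0, 50.0, 1e6]:
            assert special.polygamma(1, trigamma_inverse(x)) == pytest.approx(
                x, rel=1e-6
            )

    def test_recovers_planted_parameters(self):
        rng = np.random.default_rng(11)
        G, d, d0, s0sq = 5000, 6, 4.0, 0.05
        sigma2 = d0 * s0sq / rng.chisquare(d0, G)
        s2 = sigma2 * rng.chisquare(d, G) / d
        model = fit_variance_prior(s2, d)
        assert model.d0 == pytest.approx(d0, rel=0.2)
        assert model.s0sq == pytest.approx(s0sq, rel=0.2)

    def test_all_equal_variances_gives_infinite_prior(self):
        model = fit_variance_prior(np.full(100, 0.07), 6)
        assert np.isinf(model.d0)
        assert model.s0sq == pytest.approx(0.07)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        s2 = 4 * 0.05 / rng.chisquare(4, 2000) * rng.chisquare(6, 2000) / 6
        m1 = fit_variance_prior(s2, 6)
        m2 = fit_variance_prior(2 * s2, 6)
        assert m2.d0 == pytest.approx(m1.d0, rel=1e-9)
        assert m2.s0sq == pytest.approx(2 * m1.s0sq, rel=1e-9)

    def test_all_zero_variances_error(self):
        with pytest.raises(ValueError, match="zero"):
            fit_variance_prior(np.zeros(100), 6)

    def test_too_few_genes_error(self):
        with pytest.raises(ValueError, match=">= 50"):
            fit_variance_prior(np.ones(10), 6)


class TestModeratedT:
    def test_no_shrinkage_limit_equals_pooled_t(self):
        """d0 = 0 must reproduce the ordinary pooled-variance two-sample t."""
        rng = np.random.default_rng(2)
        mat = _matrix(rng.normal(size=(40, 9)))
        c = _contrast(5, 4)
        res = moderated_t(mat, c, ModeratedTModel(d0=0.0, s0sq=1.0))
        ref = stats.ttest_ind(
            mat[list(c.numerator)], mat[list(c.denominator)], axis=1, equal_var=True
        )
        assert np.allclose(res["t"], ref.statistic, atol=1e-10, rtol=0)
        assert np.allclose(res["p_raw"], ref.pvalue, atol=1e-10, rtol=0)

    def test_total_shrinkage_limit_shares_one_variance(self):
        rng = np.random.default_rng(3)
        mat = _matrix(rng.normal(size=(20, 8)))
        c = _contrast(4, 4)
        model = ModeratedTModel(d0=np.inf, s0sq=0.04)
        res = moderated_t(mat, c, model)
        fc = compute_log2fc(mat, c)
        expected_t = fc / np.sqrt(0.04 * (1 / 4 + 1 / 4))
        assert np.allclose(res["t"], expected_t)
        assert np.allclose(res["p_raw"], 2 * stats.norm.sf(np.abs(expected_t)))

    def test_shrinkage_formula_directly(self):
        """t matches an independent evaluation of the posterior-variance formula."""
        rng = np.random.default_rng(4)
        mat = _matrix(rng.normal(size=(30, 8)))
        c = _contrast(4, 4)
        d0, s0sq = 4.0, 0.05
        res = moderated_t(mat, c, ModeratedTModel(d0=d0, s0sq=s0sq))
        s2, dg = pooled_variance(mat, c)
        post = (d0 * s0sq + dg * s2) / (d0 + dg)
        expected_t = compute_log2fc(mat, c) / np.sqrt(post * 0.5)
        assert np.allclose(res["t"], expected_t)
        assert np.allclose(res["df"], d0 + dg)
        assert np.allclose(
            res["p_raw"], 2 * stats.t.sf(np.abs(expected_t), d0 + dg)
        )

    def test_posterior_variance_between_prior_and_sample(self):
        model = ModeratedTModel(d0=4.0, s0sq=0.05)
        s2 = np.array([0.01, 0.05, 2.0])
        post = model.posterior_variance(s2, np.full(3, 6.0))
        assert (post >= np.minimum(s2, 0.05) - 1e-12).all()
        assert (post <= np.maximum(s2, 0.05) + 1e-12).all()

    def test_matches_frozen_limma_oracle(self):
        mat = oracle_matrix()
        c = _contrast(4, 4)
        s2, dg = pooled_variance(mat, c)
        model = fit_variance_prior(s2, dg)
        assert model.d0 == pytest.approx(LIMMA_PRIOR["d0"], rel=1e-6)
        assert model.s0sq == pytest.approx(LIMMA_PRIOR["s0sq"], rel=1e-6)
        res = moderated_t(mat, c, model)
        for gene, (fc, t, p) in LIMMA_ROWS.items():
            assert res.loc[gene, "log2fc"] == pytest.approx(fc, rel=1e-6)
            assert res.loc[gene, "t"] == pytest.approx(t, rel=1e-6)
            assert res.loc[gene, "p_raw"] == pytest.approx(p, rel=1e-6)

    def test_singleton_group_rejected(self):
        mat = _matrix(np.ones((5, 3)))
        c = Contrast("bad", ("s1", "s2"), ("s0",))
        with pytest.raises(ValueError, match=">= 2 samples"):
            moderated_t(mat, c, ModeratedTModel(d0=1.0, s0sq=1.0))


class TestBHAdjust:
    def test_hand_step_up(self):
        assert np.allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_trivial_cases(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_rejects_bad_p(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30)
    )
    def test_adjusted_at_least_raw_and_rank_monotone(self, ps):
        adj = bh_adjust(ps)
        assert ((adj >= np.asarray(ps) - 1e-15) & (adj <= 1.0 + 1e-15)).all()
        order = np.argsort(ps, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestCallDeg:
    @pytest.mark.parametrize(
        "log2fc,p_adj,expected",
        [
            (1.0, 0.04, True),   # boundary fold change is included
            (0.9, 0.001, False), # fails the fold criterion
            (2.5, 0.06, False),  # fails the FDR criterion
            (-1.2, 0.01, True),  # direction does not matter
        ],
    )
    def test_dual_criterion(self, log2fc, p_adj, expected):
        res = pd.DataFrame({"log2fc": [log2fc], "p_adj": [p_adj]}, index=["g"])
        assert (call_deg(res) == {"g"}) is expected

    def test_relaxing_thresholds_never_shrinks(self):
        rng = np.random.default_rng(6)
        res = pd.DataFrame(
            {"log2fc": rng.normal(0, 1.5, 200), "p_adj": rng.uniform(0, 1, 200)},
            index=[f"g{i}" for i in range(200)],
        )
        strict = call_deg(res, fc_fold=2.0, alpha=0.05)
        assert strict <= call_deg(res, fc_fold=1.5, alpha=0.05)
        assert strict <= call_deg(res, fc_fold=2.0, alpha=0.10)


class TestNullCalibration:
    def test_raw_p_uniformity_under_null(self):
        """On null data the moderated-t raw p < 0.05 rate is binomial around 0.05."""
        rng = np.random.default_rng(9)
        G = 4000
        sigma2 = 4 * 0.05 / rng.chisquare(4, G)
        mat = _matrix(rng.normal(0, np.sqrt(sigma2)[:, None], (G, 8)))
        tab = de_table(mat, _contrast(4, 4))
        frac = (tab["p_raw"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / G)
        assert abs(frac - 0.05) < 3 * se
        assert not tab["is_deg"].any() or tab["is_deg"].mean() < 0.01
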