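import numpy as np
import pytest

from pottsfocus.alignment import Q, frequencies
from pottsfocus.biasvar import (
    DegenerateFitError,
    FocusCurve,
    FocusPoint,
    ModelSpec,
    TradeoffRecord,
    bias_slope_fit,
    chance_null_rs,
    fit_bias_factor,
    focus_curve,
    predict_cutoff_bv,
    predict_cutoff_snr,
    snr,
    variance_estimate,
)
from pottsfocus.potts import infer_independent, infer_two_site
from pottsfocus.prediction import PredictionTable
from .conftest import make_alignment


def sigma2_oracle_independent(p_tilde, wt, b):
    """Direct arithmetic evaluation of the global variance for K = 0."""
    n = p_tilde.shape[0]
    total = 0.0
    for i in range(n):
        for a in range(Q):
            if a == wt[i]:
                continue
            total += 1.0 / p_tilde[i, a] + 1.0 / p_tilde[i, wt[i]]
    return total / (b * n * Q)


class TestVarianceEstimate:
    def test_independent_model_matches_direct_sum(self):
        aln = make_alignment(["A"] * 8 + ["C"] * 2, "A")
        f = frequencies(aln, pseudocount=0.01)
        model = infer_independent(f)
        s2 = variance_estimate(f, model, aln.wt, b=10.0)
        assert s2 == pytest.approx(sigma2_oracle_independent(f.p, aln.wt, 10.0))

    def test_inverse_b_scaling_exact(self, toy_alignment):
        f = frequencies(toy_alignment, pseudocount=0.01)
        model = infer_independent(f)
        s_1 = variance_estimate(f, model, toy_alignment.wt, b=50.0)
        s_2 = variance_estimate(f, model, toy_alignment.wt, b=100.0)
        assert s_1 == pytest.approx(2.0 * s_2, rel=1e-12)

    def test_couplings_add_pair_terms(self, toy_alignment):
        f = frequencies(toy_alignment, pseudocount=0.01)
        m0 = infer_independent(f)
        m1 = infer_two_site(f, [(0, 1)])
        s0 = variance_estimate(f, m0, toy_alignment.wt)
        s1 = variance_estimate(f, m1, toy_alignment.wt)
        # pair frequencies are rarer than site frequencies: variance grows
        assert s1 > s0

    def test_k_equal_one_zeroes_site_terms(self, toy_alignment):
        # with k_i = 1 everywhere, |k_i - 1| = 0: only pair terms remain
        f = frequencies(toy_alignment, pseudocount=0.01)
        model = infer_two_site(f, [(0, 1), (2, 3)])
        s2 = variance_estimate(f, model, toy_alignment.wt, b=1.0)
        n = toy_alignment.n_sites
        total = 0.0
        for (i, j) in [(0, 1), (1, 0), (2, 3), (3, 2)]:
            pij = f.pair(i, j)
            wt_i, wt_j = toy_alignment.wt[i], toy_alignment.wt[j]
            for a in range(Q):
                if a == wt_i:
                    continue
                total += 1.0 / pij[a, wt_j] + 1.0 / pij[wt_i, wt_j]
        # site 4 is unlinked: |0 - 1| = 1 keeps its site terms
        p = f.p
        for a in range(Q):
            if a == toy_alignment.wt[4]:
                continue
            total += 1.0 / p[4, a] + 1.0 / p[4, toy_alignment.wt[4]]
        assert s2 == pytest.approx(total / (n * Q))

    def test_bad_b_raises(self, toy_alignment):
        f = frequencies(toy_alignment, pseudocount=0.01)
        with pytest.raises(ValueError):
            variance_estimate(f, infer_independent(f), toy_alignment.wt, b=0.0)


def synthetic_records(rng, j0_true, n=60, noise=0.02, constant_sigma=False):
    d = rng.uniform(5, 25, size=n)
    s2 = np.full(n, 1.0) if constant_sigma else rng.uniform(0.2, 2.0, size=n)
    rho = -(j0_true * d + s2) + rng.normal(scale=noise, size=n)
    return [TradeoffRecord(b=100.0, d=float(di), sigma2=float(si), rho=float(ri))
            for di, si, ri in zip(d, s2, rho)]


class TestFitBiasFactor:
    def test_recovers_known_j0(self, rng):
        j0_true = 0.25
        fit = fit_bias_factor(synthetic_records(rng, j0_true))
        assert fit.r_s > 0.95
        assert j0_true / 2 <= fit.j0 <= j0_true * 2

    def test_monotone_transform_invariance(self, rng):
        recs = synthetic_records(rng, 0.1)
        fit1 = fit_bias_factor(recs)
        for r in recs:
            r.rho = np.tanh(3.0 * r.rho)  # strictly increasing transform
        fit2 = fit_bias_factor(recs)
        assert fit1.j0 == pytest.approx(fit2.j0)
        assert fit1.r_s == pytest.approx(fit2.r_s)

    def test_constant_sigma_returns_smallest_maximizer(self, rng):
        recs = synthetic_records(rng, 0.5, noise=0.0, constant_sigma=True)
        fit = fit_bias_factor(recs)
        assert fit.r_s == pytest.approx(1.0)
        # every sufficiently large J0 achieves r_S = 1; the fit must return
        # the smallest maximizing grid point
        scale = np.median([r.sigma2 for r in recs]) / np.median([r.d for r in recs])
        assert fit.j0 == pytest.approx(scale * 1e-6)

    def test_degenerate_rho_raises(self):
        recs = [TradeoffRecord(b=1, d=float(k), sigma2=1.0, rho=0.5) for k in range(12)]
        with pytest.raises(DegenerateFitError):
            fit_bias_factor(recs)

    def test_too_few_records_raises(self):
        with pytest.raises(ValueError):
            fit_bias_factor([TradeoffRecord(1, 1, 1, 0.1)] * 5)


class TestChanceNull:
    def test_deterministic(self, rng):
        recs = synthetic_records(rng, 0.2)
        n1 = chance_null_rs(recs, n_shuffles=20, seed=3)
        n2 = chance_null_rs(recs, n_shuffles=20, seed=3)
        assert np.array_equal(n1["null"], n2["null"])

    def test_structured_records_beat_null(self, rng):
        recs = synthetic_records(rng, 0.2, noise=0.01)
        null = chance_null_rs(recs, n_shuffles=30, seed=1)
        assert null["observed"] > null["mean"] + 2 * null["sd"]
        assert null["p"] < 0.05

    def test_unstructured_records_match_null(self, rng):
        recs = synthetic_records(rng, 0.2)
        shuffled_rho = rng.permutation([r.rho for r in recs])
        for r, val in zip(recs, shuffled_rho):
            r.rho = float(val)
        null = chance_null_rs(recs, n_shuffles=40, seed=2)
        assert abs(null["observed"] - null["mean"]) < 2.5 * null["sd"]


class TestSnrAndCutoffs:
    def _pred(self, values):
        vals = np.array(values, dtype=float)[None, :]
        full = np.concatenate([np.zeros((1, 1)), vals], axis=1)
        return PredictionTable(values=full, wt=np.zeros(1, dtype=int))

    def test_hand_arithmetic(self):
        pred = self._pred([0.0, 1.0, 2.0, 3.0])
        assert snr(pred, 0.25) == pytest.approx(5.0)  # population var 1.25

    def test_equal_predictions_zero(self):
        assert snr(self._pred([1.0, 1.0, 1.0]), 2.0) == 0.0

    def _curve(self, sigma2s, ds, snrs, rhos=None):
        pts = []
        for k, (s2, d, sn) in enumerate(zip(sigma2s, ds, snrs)):
            p = FocusPoint(d_cut=float(k + 1), b=10.0, d=d, sigma2=s2, snr=sn)
            if rhos is not None:
                p.rho = rhos[k]
            pts.append(p)
        return FocusCurve(points=pts)

    def test_bv_cutoff_limits_and_oracle(self, rng):
        ds = np.array([2.0, 5.0, 9.0, 14.0])
        s2 = np.array([4.0, 2.0, 1.0, 0.5])
        curve = self._curve(s2, ds, np.ones(4))
        assert predict_cutoff_bv(curve, 0.0) == 4.0      # variance-only
        assert predict_cutoff_bv(curve, 1e9) == 1.0      # bias-only
        for j0 in (0.01, 0.1, 0.3, 1.0):
            crit = j0 * ds + s2
            expected = float(np.argmin(crit) + 1)
            assert predict_cutoff_bv(curve, j0) == expected

    def test_bv_monotone_in_j0(self, rng):
        ds = np.sort(rng.uniform(1, 20, size=8))
        s2 = np.sort(rng.uniform(0.1, 4, size=8))[::-1]
        curve = self._curve(s2, ds, np.ones(8))
        cuts = [predict_cutoff_bv(curve, j0) for j0 in np.logspace(-3, 2, 30)]
        assert all(b <= a for a, b in zip(cuts, cuts[1:]))

    def test_bv_tie_takes_larger_cutoff(self):
        curve = self._curve([1.0, 1.0], [3.0, 3.0], [1.0, 1.0])
        assert predict_cutoff_bv(curve, 0.5) == 2.0

    def test_snr_cutoff_smallest_passing(self):
        curve = self._curve([1, 1, 1, 1], [1, 2, 3, 4], [1.0, 2.5, 3.5, 6.0])
        assert predict_cutoff_snr(curve, threshold=3.0) == 3.0

    def test_snr_cutoff_fallback(self):
        curve = self._curve([1, 1], [1, 2], [0.5, 0.2])
        assert predict_cutoff_snr(curve, threshold=3.0) == 2.0

    def test_d_opt_tie_takes_larger_cutoff(self):
        curve = self._curve([1, 1, 1], [1, 2, 3], [1, 1, 1], rhos=[0.2, 0.5, 0.5])
        assert curve.d_opt() == 3.0


def test_bias_slope_fit_recovers_line(rng):
    d = np.linspace(5, 20, 12)
    mu2 = 0.35 * d + 0.4 + rng.normal(scale=0.05, size=12)
    slope, r = bias_slope_fit(d, mu2)
    assert slope == pytest.approx(0.35, abs=0.05)
    assert r > 0.99
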