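"""Bias-variance estimators and focusing heuristics.

The prediction error of a K-link Potts fitness predictor decomposes into a
squared bias, which grows linearly with the mean Hamming distance D of the
training alignment to the wild type (mu^2 ~ J0 * D, with J0 the bias
factor measuring un-modeled epistasis), and a statistical variance sigma^2,
which is inversely proportional to the effective number of sequences B.
The sum J0 * D + sigma^2 predicts performance up to a monotone transform, so
J0 can be fitted by maximizing a Spearman correlation across sub-alignments,
and the optimal focusing cutoff is where the sum is minimal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .alignment import Alignment, FrequencyTables, MutationalScan, Q, frequencies
from .potts import PottsModel, frobenius_scores, infer_independent, infer_plm, infer_two_site, select_links
from .prediction import PredictionTable, UndefinedPerformanceError, performance, predict_all
from .subsampling import cutoff_filter

logger = logging.getLogger(__name__)

DEFAULT_SNR_THRESHOLD = 3.0


# ---------------------------------------------------------------------------
# analytic variance
# ---------------------------------------------------------------------------

def variance_estimate(
    freqs: FrequencyTables,
    model: PottsModel,
    wt: np.ndarray,
    b: float | None = None,
) -> float:
    """Global sampling variance of the fitness predictor.

    sigma^2 = 1/(B N Q) * sum over sites i and mutations a != wt_i of
    |k_i - 1| (1/p~_i(a) + 1/p~_i(wt_i))
    + sum over coupled sites j of (1/p~_ij(a, wt_j) + 1/p~_ij(wt_i, wt_j)),
    with Q = 20.  Rarely-seen residues (small p~) and extra couplings raise
    the variance; it scales exactly as 1/B.
    """
    if b is None:
        b = freqs.B
    if b <= 0:
        raise ValueError(f"effective count B must be positive, got {b}")
    if freqs.lam <= 0.0:
        raise ValueError("variance estimate requires a positive pseudocount")
    n = freqs.n_sites
    p = freqs.p
    degrees = model.degrees()
    nb = model.neighborhoods()
    total = 0.0
    for i in range(n):
        wt_i = wt[i]
        inv = 1.0 / p[i]
        site_sum = inv.sum() - inv[wt_i] + (Q - 1) * inv[wt_i]
        total += abs(degrees[i] - 1) * site_sum
        for j in nb[i]:
            pij = freqs.pair(i, j)
            col = 1.0 / pij[:, wt[j]]
            total += col.sum() - col[wt_i] + (Q - 1) * col[wt_i]
    return total / (b * n * Q)


# ---------------------------------------------------------------------------
# bias-factor fitting
# ---------------------------------------------------------------------------

@dataclass
class TradeoffRecord:
    """One sub-alignment's quantity, relevance, variance and performance."""

    b: float
    d: float          # raw site counts
    sigma2: float
    rho: float
    k: int = 0
    cell_id: str = ""


@dataclass
class J0Fit:
    j0: float
    r_s: float
    k: int = 0
    grid: dict = field(default_factory=dict)


class DegenerateFitError(ValueError):
    pass


def _records_arrays(records) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rho = np.array([r.rho for r in records])
    d = np.array([r.d for r in records])
    s2 = np.array([r.sigma2 for r in records])
    return rho, d, s2


def _scaling_r(j0: float, rho: np.ndarray, d: np.ndarray, s2: np.ndarray) -> float:
    return abs(float(spearmanr(rho, j0 * d + s2).statistic))


def fit_bias_factor(
    records: list[TradeoffRecord],
    n_grid: int = 200,
    refine_levels: int = 2,
) -> J0Fit:
    """Best-scaling fit of the bias factor.

    J0 maximizes |Spearman(rho, J0 D + sigma^2)| over a log-spaced grid made
    scale-aware by the ratio median(sigma^2)/median(D), followed by local
    grid refinement.  The smallest maximizing grid point wins ties, making
    the fit deterministic.
    """
    if len(records) < 10:
        raise ValueError(f"need at least 10 records, got {len(records)}")
    rho, d, s2 = _records_arrays(records)
    if np.ptp(rho) == 0.0:
        raise DegenerateFitError("performance rho is constant across records")
    scale = np.median(s2) / max(np.median(d), 1e-12)
    grid = scale * np.logspace(-6, 3, n_grid)
    r_vals = np.array([_scaling_r(j, rho, d, s2) for j in grid])
    best_idx = int(np.argmax(r_vals + 1e-15 * 0))  # first (=smallest) argmax
    best_j0, best_r = float(grid[best_idx]), float(r_vals[best_idx])
    lo = grid[max(best_idx - 1, 0)]
    hi = grid[min(best_idx + 1, n_grid - 1)]
    for _ in range(refine_levels):
        sub = np.geomspace(lo, hi, 25)
        sub_r = np.array([_scaling_r(j, rho, d, s2) for j in sub])
        idx = int(np.argmax(sub_r))
        if sub_r[idx] > best_r + 1e-12:
            best_j0, best_r = float(sub[idx]), float(sub_r[idx])
        lo = sub[max(idx - 1, 0)]
        hi = sub[min(idx + 1, len(sub) - 1)]
    k = records[0].k
    return J0Fit(j0=best_j0, r_s=best_r, k=k,
                 grid={"scale": float(scale), "n_grid": n_grid})


def chance_null_rs(
    records: list[TradeoffRecord],
    n_shuffles: int = 100,
    seed: int = 0,
    observed: float | None = None,
) -> dict:
    """Shuffle null for the scaling correlation.

    Permutes rho across records, re-runs the full J0 fit each time (so the
    null accounts for the maximization step), and summarizes the r_S
    distribution.  An empirical p-value is reported when ``observed`` is
    given (or computed from the unshuffled records).
    """
    rng = np.random.default_rng(seed)
    if observed is None:
        observed = fit_bias_factor(records).r_s
    null = np.empty(n_shuffles)
    base = [TradeoffRecord(r.b, r.d, r.sigma2, r.rho, r.k, r.cell_id) for r in records]
    rhos = np.array([r.rho for r in records])
    for t in range(n_shuffles):
        perm = rng.permutation(rhos.shape[0])
        for rec, val in zip(base, rhos[perm]):
            rec.rho = float(val)
        null[t] = fit_bias_factor(base).r_s
    p = (1.0 + float((null >= observed).sum())) / (1.0 + n_shuffles)
    return {"mean": float(null.mean()), "sd": float(null.std(ddof=1)),
            "p": p, "observed": float(observed), "null": null}


def bias_slope_fit(d: np.ndarray, mu2: np.ndarray) -> tuple[float, float]:
    """Least-squares line mu^2 = J0 * D + c; returns (slope, Pearson R)."""
    d = np.asarray(d, dtype=float)
    mu2 = np.asarray(mu2, dtype=float)
    slope, _ = np.polyfit(d, mu2, 1)
    r = float(pearsonr(d, mu2).statistic)
    return float(slope), r


# ---------------------------------------------------------------------------
# focusing curves and cutoff predictors
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Model class trained at each focusing step."""

    k: int = 0
    pseudocount: float = 0.01
    reg_h: float = 0.01
    reg_j: float = 0.01
    use_weights: bool = True


@dataclass
class FocusPoint:
    d_cut: float
    b: float
    d: float
    sigma2: float
    snr: float
    rho: float = np.nan
    n_overlap: int = 0
    pred: PredictionTable | None = None


@dataclass
class FocusCurve:
    points: list[FocusPoint]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "d_cut": p.d_cut, "B": p.b, "D": p.d, "sigma2": p.sigma2,
                    "SNR": p.snr, "rho": p.rho, "n_overlap": p.n_overlap,
                }
                for p in self.points
            ]
        )

    def d_opt(self) -> float:
        """Cutoff with the best measured performance; ties take more data."""
        pts = [p for p in self.points if np.isfinite(p.rho)]
        if not pts:
            raise ValueError("no performance values on this curve")
        best = max(p.rho for p in pts)
        return max(p.d_cut for p in pts if p.rho == best)

    def rho_at(self, d_cut: float) -> float:
        for p in self.points:
            if p.d_cut == d_cut:
                return p.rho
        raise KeyError(f"no point at d_cut={d_cut}")


def snr(pred: PredictionTable, sigma2: float) -> float:
    """Signal-to-noise ratio: population variance of the defined predicted
    effects divided by the statistical variance sigma^2."""
    if sigma2 <= 0:
        raise ValueError("sigma^2 must be positive")
    vals = pred.values[pred.defined]
    if vals.size < 2:
        raise ValueError("need at least 2 defined predictions")
    return float(vals.var()) / sigma2


def train_model_on(
    sub: Alignment,
    spec: ModelSpec,
    link_scores: np.ndarray | None = None,
) -> tuple[PottsModel, FrequencyTables]:
    freqs = frequencies(sub, pseudocount=spec.pseudocount)
    if spec.k == 0:
        model = infer_independent(freqs)
    else:
        if link_scores is None:
            _, j_flat = infer_plm(sub, reg_h=spec.reg_h, reg_j=spec.reg_j,
                                  pseudocount=spec.pseudocount,
                                  use_weights=spec.use_weights)
            link_scores = frobenius_scores(j_flat)
        links = select_links(link_scores, sub.n_sites, spec.k)
        model = infer_two_site(freqs, links)
    model.meta.update({"K": spec.k})
    return model, freqs


def focus_curve(
    aln: Alignment,
    scan: MutationalScan | None,
    model_spec: ModelSpec,
    d_cut_values,
    min_rows: int = 3,
) -> FocusCurve:
    """Sweep the focusing cutoff: filter, reweight, train, and measure.

    Each cell reports the achieved (B, D), the analytic variance, the SNR
    and, when a scan is available, the Spearman performance.  Cells whose
    sub-alignment is too small are skipped.
    """
    points: list[FocusPoint] = []
    for d_cut in d_cut_values:
        try:
            sub = cutoff_filter(aln, float(d_cut), reweight=model_spec.use_weights)
        except Exception as exc:
            logger.warning("d_cut=%s skipped: %s", d_cut, exc)
            continue
        if sub.n_rows < min_rows:
            logger.warning("d_cut=%s skipped: only %d rows", d_cut, sub.n_rows)
            continue
        model, freqs = train_model_on(sub, model_spec)
        b, d = float(freqs.B), float(np.dot(sub.weights, sub.distances_to_wt()) / freqs.B)
        s2 = variance_estimate(freqs, model, aln.wt, b=b)
        pred = predict_all(model, aln.wt)
        point = FocusPoint(d_cut=float(d_cut), b=b, d=d, sigma2=s2,
                           snr=snr(pred, s2), pred=pred)
        if scan is not None:
            try:
                point.rho, point.n_overlap = performance(pred, scan)
            except UndefinedPerformanceError:
                pass
        points.append(point)
    if not points:
        raise ValueError("every focusing cell was skipped")
    return FocusCurve(points=points)


def predict_cutoff_bv(curve: FocusCurve, j0: float) -> float:
    """Bias-variance cutoff: argmin of J0 D(d_cut) + sigma^2(d_cut).

    Ties resolve toward the larger cutoff (more data at equal criterion).
    """
    if j0 < 0:
        raise ValueError("J0 must be non-negative")
    if not curve.points:
        raise ValueError("empty focus curve")
    crit = np.array([j0 * p.d + p.sigma2 for p in curve.points])
    best = crit.min()
    return max(p.d_cut for p, c in zip(curve.points, crit) if c == best)


def predict_cutoff_snr(curve: FocusCurve, threshold: float = DEFAULT_SNR_THRESHOLD) -> float:
    """SNR cutoff: the smallest d_cut whose SNR still clears the threshold.

    Focuses as tightly as the signal allows; falls back to the largest swept
    cutoff (with a warning) when no cell reaches the threshold.
    """
    eligible = [p.d_cut for p in curve.points if p.snr >= threshold]
    if not eligible:
        logger.warning("no cutoff reaches SNR >= %.2f; returning the full range", threshold)
        return max(p.d_cut for p in curve.points)
    return min(eligible)
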