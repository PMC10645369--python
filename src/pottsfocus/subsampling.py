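"""Controlled sub-alignments: hard distance cutoffs and biased subsampling.

Focusing uses a hard cutoff on the Hamming distance to the wild type.  The
trade-off analysis instead needs sub-alignments with *prescribed* mean
distance D and size B0: rows are drawn without replacement with selection
weight exp(-alpha * d(s, wt)), and alpha is tuned until the realized D
matches the target within a precision measured on the normalized-distance
scale (default 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alignment import Alignment, AlignmentDataError, compute_weights, descriptors

logger = logging.getLogger(__name__)

DEFAULT_PRECISION = 0.01  # on normalized D
MAX_REFINE = 50


class SubsampleConvergenceError(RuntimeError):
    def __init__(self, target: float, best: float):
        super().__init__(
            f"could not reach target D={target:.3f}; closest achieved {best:.3f}"
        )
        self.best_achieved = best


@dataclass
class SubsampleSpec:
    """Target for one biased draw: mean distance (raw sites) and row count."""

    target_d: float
    b0: int
    seed: int = 0
    precision: float = DEFAULT_PRECISION
    alpha: float | None = None  # filled in on success


def cutoff_filter(aln: Alignment, d_cut: float, reweight: bool = True) -> Alignment:
    """Keep sequences with d(wt, s) <= d_cut (raw counts); recompute weights."""
    if not 0 <= d_cut <= aln.n_sites:
        raise ValueError(f"d_cut={d_cut} outside [0, {aln.n_sites}]")
    keep = np.where(aln.distances_to_wt() <= d_cut)[0]
    if keep.size == 0:
        raise AlignmentDataError(f"no sequences within d_cut={d_cut} of wt")
    sub = aln.subset(keep)
    if reweight:
        compute_weights(sub)
    else:
        sub.weights = np.ones(sub.n_rows)
    return sub


def _weighted_choice_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, k: int
) -> np.ndarray:
    """Efraimidis-Spirakis exponential-keys draw: exact, one pass, seedable."""
    keys = rng.exponential(size=weights.shape[0]) / weights
    return np.argpartition(keys, k - 1)[:k]


def _expected_first_draw_d(alpha: float, d: np.ndarray) -> float:
    logw = -alpha * d
    logw -= logw.max()
    w = np.exp(logw)
    return float(np.dot(w, d) / w.sum())


def _bracket_alpha(target: float, d: np.ndarray) -> float:
    """Bisection on the single-draw expectation of d under exp(-alpha d)."""
    lo, hi = -1.0, 1.0
    while _expected_first_draw_d(lo, d) < target and lo > -1e4:
        lo *= 2.0
    while _expected_first_draw_d(hi, d) > target and hi < 1e4:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _expected_first_draw_d(mid, d) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def biased_subsample(
    aln: Alignment,
    spec: SubsampleSpec,
    reweight: bool = True,
) -> Alignment:
    """Draw ``b0`` distinct rows with selection weight exp(-alpha d(s, wt)).

    alpha is initialized by root-finding on the analytic single-draw
    expectation, then refined with repeated draws (at most ``MAX_REFINE``)
    until the realized weighted D lands within ``precision`` (normalized
    scale) of the target.  The fitted alpha is recorded on the spec.
    """
    n = aln.n_sites
    if spec.b0 > aln.n_rows:
        raise ValueError(f"B0={spec.b0} exceeds {aln.n_rows} available rows")
    d = aln.distances_to_wt()
    d_sorted = np.sort(d)
    lo_feasible = d_sorted[: spec.b0].mean()
    hi_feasible = d_sorted[-spec.b0:].mean()
    if not lo_feasible - spec.precision * n <= spec.target_d <= hi_feasible + spec.precision * n:
        raise SubsampleConvergenceError(
            spec.target_d, lo_feasible if spec.target_d < lo_feasible else hi_feasible
        )

    rng = np.random.default_rng(spec.seed)
    alpha = _bracket_alpha(spec.target_d, d)
    best: tuple[float, Alignment, float] | None = None
    for _ in range(MAX_REFINE):
        logw = -alpha * d
        logw -= logw.max()
        rows = _weighted_choice_without_replacement(rng, np.exp(logw), spec.b0)
        sub = aln.subset(rows)
        if reweight:
            compute_weights(sub)
        else:
            sub.weights = np.ones(sub.n_rows)
        _, achieved = descriptors(sub)
        err = abs(achieved - spec.target_d) / n
        if best is None or err < best[0]:
            best = (err, sub, alpha)
        if err <= spec.precision:
            spec.alpha = alpha
            return sub
        # local linear correction: dE[d]/dalpha = -Var(d) under the draw weights
        var = max(float(np.var(d[rows])), 1e-9)
        alpha += (achieved - spec.target_d) / var
    assert best is not None
    err, sub, alpha = best
    raise SubsampleConvergenceError(spec.target_d, descriptors(sub)[1])


@dataclass
class GridCell:
    target_d: float
    b0: int
    seed: int
    alignment: Alignment | None
    b: float | None
    d: float | None
    alpha: float | None
    ok: bool
    reason: str = ""


def default_d_grid(n_sites: int, n_values: int = 16) -> np.ndarray:
    """16 evenly spaced mean-distance targets spanning [0.4 N, 0.8 N]."""
    return np.linspace(0.4 * n_sites, 0.8 * n_sites, n_values)


def default_b0_grid(n_rows: int, n_values: int = 10, lo: int = 30) -> np.ndarray:
    """Log-spaced draw sizes; the upper end scales with the pool size."""
    hi = max(lo + 1, min(n_rows // 2, 500))
    return np.unique(np.geomspace(lo, hi, n_values).round().astype(int))


def subsample_grid(
    aln: Alignment,
    d_values: np.ndarray | None = None,
    b0_values: np.ndarray | None = None,
    seed: int = 0,
    precision: float = DEFAULT_PRECISION,
    reweight: bool = True,
) -> list[GridCell]:
    """All (D, B0) combinations; unattainable cells are skipped with a log.

    Per-cell seeds derive deterministically from the master seed so the grid
    is reproducible as a whole and cell by cell.
    """
    if d_values is None:
        d_values = default_d_grid(aln.n_sites)
    if b0_values is None:
        b0_values = default_b0_grid(aln.n_rows)
    cells: list[GridCell] = []
    for di, target_d in enumerate(d_values):
        for bi, b0 in enumerate(b0_values):
            cell_seed = np.random.SeedSequence((seed, di, bi)).generate_state(1)[0]
            spec = SubsampleSpec(target_d=float(target_d), b0=int(b0),
                                 seed=int(cell_seed), precision=precision)
            try:
                sub = biased_subsample(aln, spec, reweight=reweight)
                b, d = descriptors(sub)
                cells.append(GridCell(spec.target_d, spec.b0, spec.seed,
                                      sub, b, d, spec.alpha, True))
            except (SubsampleConvergenceError, ValueError) as exc:
                logger.warning("grid cell (D=%.2f, B0=%d) skipped: %s",
                               target_d, b0, exc)
                cells.append(GridCell(float(target_d), int(b0), int(cell_seed),
                                      None, None, None, None, False, str(exc)))
    return cells
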