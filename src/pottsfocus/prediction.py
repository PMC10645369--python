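"""Score single-point mutations with a Potts model and evaluate against scans.

The predicted effect of mutating site i of the wild type to residue a is the
model log-probability difference between the mutant and the wild type.  All
normalization cancels, leaving the field difference plus coupling differences
over the sites linked to i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .alignment import MutationalScan, Q


class UndefinedPerformanceError(ValueError):
    pass


@dataclass
class PredictionTable:
    """N x q matrix of predicted fitness differences (log-probability units).

    Entries at a = wt_i are zero by construction; ``defined`` masks the
    scorable mutations (a != wt_i).
    """

    values: np.ndarray
    wt: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def defined(self) -> np.ndarray:
        mask = np.ones_like(self.values, dtype=bool)
        mask[np.arange(self.wt.shape[0]), self.wt] = False
        return mask

    @property
    def n_defined(self) -> int:
        return int(self.defined.sum())

    def lookup(self, sites: np.ndarray, targets: np.ndarray) -> np.ndarray:
        return self.values[sites, targets]


def delta_fitness(model, wt: np.ndarray, i: int, a: int) -> float:
    """Predicted fitness change for the single mutation wt_i -> a.

    Equals h_i(a) - h_i(wt_i) plus, for every site j coupled to i,
    J_ij(a, wt_j) - J_ij(wt_i, wt_j); identical to the log-probability
    difference between the mutated and wild-type sequences.
    """
    q = model.q
    if not 0 <= a < q:
        raise ValueError(f"residue code {a} outside the model alphabet (q={q})")
    wt_i = wt[i]
    val = model.h[i, a] - model.h[i, wt_i]
    for j in _neighbors(model, i):
        block = model.coupling(i, j)
        val += block[a, wt[j]] - block[wt_i, wt[j]]
    return float(val)


def _neighbors(model, i: int) -> list[int]:
    out = []
    for a, b in model.links:
        if a == i:
            out.append(b)
        elif b == i:
            out.append(a)
    return out


def predict_all(model, wt: np.ndarray) -> PredictionTable:
    """Vectorized predictor table for all single mutations of the wild type."""
    wt = np.asarray(wt)
    n, q = model.h.shape
    idx = np.arange(n)
    values = model.h - model.h[idx, wt][:, None]
    for i, j in model.links:
        block = model.J[(i, j)]
        values[i] += block[:, wt[j]] - block[wt[i], wt[j]]
        values[j] += block[wt[i], :] - block[wt[i], wt[j]]
    values[idx, wt] = 0.0
    return PredictionTable(values=values, wt=wt.copy(), meta=dict(model.meta))


def performance(
    pred: PredictionTable,
    scan: MutationalScan,
    sign: float = 1.0,
) -> tuple[float, int]:
    """Spearman rank correlation between predictions and measured effects.

    Computed over the intersection of defined predictions and scan records;
    average ranks handle ties.  ``sign`` = -1 flips the convention for scans
    where lower scores mean fitter.  Returns (rho, overlap count).
    """
    defined = pred.defined
    keep = defined[scan.sites, scan.targets]
    n_overlap = int(keep.sum())
    if n_overlap < 3:
        raise UndefinedPerformanceError(
            f"only {n_overlap} overlapping mutations; need at least 3"
        )
    predicted = pred.lookup(scan.sites[keep], scan.targets[keep])
    measured = sign * scan.effects[keep]
    rho = spearmanr(predicted, measured).statistic
    return float(rho), n_overlap


def write_predictions(pred: PredictionTable, aln, path) -> None:
    """Write the defined predictions as a mutant-code/score CSV."""
    import pandas as pd

    from .alignment import AMINO_ACIDS

    rows = []
    sites, targets = np.nonzero(pred.defined)
    for i, a in zip(sites, targets):
        code = f"{AMINO_ACIDS[aln.wt[i]]}{aln.col_map[i] + 1}{AMINO_ACIDS[a]}"
        rows.append((code, pred.values[i, a]))
    pd.DataFrame(rows, columns=["mutant", "predicted_effect"]).to_csv(path, index=False)


def scan_from_truth(effects: np.ndarray, wt: np.ndarray, mask: np.ndarray | None = None) -> MutationalScan:
    """Wrap a dense ground-truth effect matrix as a mutational scan.

    ``mask`` (same shape) optionally restricts the records, e.g. to
    observable mutations.
    """
    n, q = effects.shape
    defined = np.ones_like(effects, dtype=bool)
    defined[np.arange(n), wt] = False
    if mask is not None:
        defined &= mask
    sites, targets = np.nonzero(defined)
    return MutationalScan(sites=sites, targets=targets,
                          effects=effects[sites, targets].astype(float))
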