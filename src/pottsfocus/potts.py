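"""Sparse Potts models: pseudolikelihood inference, link ranking, re-inference.

The K-link model keeps site fields h_i(a) everywhere but restricts non-zero
couplings J_ij(a, b) to K selected pairs.  Link selection follows standard
DCA practice: fit a fully-connected model by (symmetric) pseudolikelihood
maximization, rank pairs by the Frobenius norm of the zero-sum-gauge
coupling block, take the top K.  The retained couplings are then re-inferred
with a two-site closed form (pointwise mutual information), which keeps the
K = 1-per-site predictor a pure function of pair frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numba
import numpy as np
from scipy.optimize import minimize

from .alignment import Alignment, FrequencyTables, Q, Q_SYM

DEFAULT_REG_H = 0.01
DEFAULT_REG_J = 0.01


class PlmConvergenceError(RuntimeError):
    pass


def n_pairs(n_sites: int) -> int:
    return n_sites * (n_sites - 1) // 2


def pair_index(i: int, j: int, n_sites: int) -> int:
    """Flat index of the ordered pair (i < j)."""
    if not 0 <= i < j < n_sites:
        raise ValueError(f"bad pair ({i}, {j}) for N={n_sites}")
    return i * n_sites - i * (i + 1) // 2 + (j - i - 1)


def pair_list(n_sites: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n_sites) for j in range(i + 1, n_sites)]


@dataclass
class PottsModel:
    """Fields plus couplings on an explicit link set.

    ``h`` has shape (N, q); each link (i, j) with i < j carries a q x q
    coupling block ``J[(i, j)]`` acting as J_ij(a_i, a_j).  ``q`` defaults to
    20 but small toy models may use fewer states.
    """

    h: np.ndarray
    links: list[tuple[int, int]] = field(default_factory=list)
    J: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    q: int = Q
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64)
        self.links = [tuple(sorted(l)) for l in self.links]
        for l in self.links:
            if l not in self.J:
                raise ValueError(f"link {l} has no coupling block")
            self.J[l] = np.asarray(self.J[l], dtype=np.float64)

    @property
    def n_sites(self) -> int:
        return self.h.shape[0]

    @property
    def K(self) -> int:
        return len(self.links)

    def neighborhoods(self) -> list[list[int]]:
        nb: list[list[int]] = [[] for _ in range(self.n_sites)]
        for i, j in self.links:
            nb[i].append(j)
            nb[j].append(i)
        return nb

    def degrees(self) -> np.ndarray:
        k = np.zeros(self.n_sites, dtype=int)
        for i, j in self.links:
            k[i] += 1
            k[j] += 1
        return k

    def coupling(self, i: int, j: int) -> np.ndarray:
        """J_ij block oriented as (a_i, a_j) for any site order."""
        if i < j:
            return self.J[(i, j)]
        return self.J[(j, i)].T

    def log_score(self, seq: np.ndarray) -> float:
        """Unnormalized log-probability of a full sequence."""
        val = float(self.h[np.arange(self.n_sites), seq].sum())
        for i, j in self.links:
            val += float(self.J[(i, j)][seq[i], seq[j]])
        return val


def infer_independent(freqs: FrequencyTables) -> PottsModel:
    """K = 0 model: h_i(a) = log p~_i(a), no couplings."""
    if freqs.lam <= 0.0:
        raise ValueError("independent-model fields need a positive pseudocount")
    return PottsModel(h=np.log(freqs.p), meta={"kind": "independent", "lam": freqs.lam})


def infer_two_site(freqs: FrequencyTables, links: Iterable[tuple[int, int]]) -> PottsModel:
    """K-link model with fields from marginals and PMI couplings.

    J_ij(a, b) = log p~_ij(a, b) - log p~_i(a) - log p~_j(b) on each selected
    link; exactly the independent model when the link set is empty.
    """
    if freqs.lam <= 0.0:
        raise ValueError("two-site re-inference needs a positive pseudocount")
    h = np.log(freqs.p)
    n = h.shape[0]
    links = [tuple(sorted(l)) for l in links]
    J: dict[tuple[int, int], np.ndarray] = {}
    for i, j in links:
        if not 0 <= i < j < n:
            raise ValueError(f"link ({i}, {j}) outside [0, {n})")
        pij = freqs.pair(i, j)
        J[(i, j)] = np.log(pij) - h[i][:, None] - h[j][None, :]
    return PottsModel(h=h, links=links, J=J, meta={"kind": "two_site", "lam": freqs.lam})


# ---------------------------------------------------------------------------
# pseudolikelihood maximization
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def _plm_value_grad(x, seqs, w, n, qt, qs, reg_h, reg_j, bw):  # pragma: no cover
    nh = n * qt
    f = 0.0
    g = np.zeros_like(x)
    nseq = seqs.shape[0]
    logits = np.empty(qt)
    probs = np.empty(qt)
    for s in range(nseq):
        ws = w[s]
        for i in range(n):
            si = seqs[s, i]
            if si >= qt:
                continue  # gap at the predicted site: no conditional term
            for a in range(qt):
                logits[a] = x[i * qt + a]
            for j in range(n):
                if j == i:
                    continue
                sj = seqs[s, j]
                if i < j:
                    base = nh + (i * n - i * (i + 1) // 2 + (j - i - 1)) * qs * qs
                    for a in range(qt):
                        logits[a] += x[base + a * qs + sj]
                else:
                    base = nh + (j * n - j * (j + 1) // 2 + (i - j - 1)) * qs * qs
                    for a in range(qt):
                        logits[a] += x[base + sj * qs + a]
            m = logits[0]
            for a in range(1, qt):
                if logits[a] > m:
                    m = logits[a]
            z = 0.0
            for a in range(qt):
                probs[a] = np.exp(logits[a] - m)
                z += probs[a]
            f += ws * (np.log(z) + m - logits[si])
            inv = ws / z
            for a in range(qt):
                probs[a] *= inv
            probs[si] -= ws
            for a in range(qt):
                g[i * qt + a] += probs[a]
            for j in range(n):
                if j == i:
                    continue
                sj = seqs[s, j]
                if i < j:
                    base = nh + (i * n - i * (i + 1) // 2 + (j - i - 1)) * qs * qs
                    for a in range(qt):
                        g[base + a * qs + sj] += probs[a]
                else:
                    base = nh + (j * n - j * (j + 1) // 2 + (i - j - 1)) * qs * qs
                    for a in range(qt):
                        g[base + sj * qs + a] += probs[a]
    for k in range(nh):
        f += reg_h * bw * x[k] * x[k]
        g[k] += 2.0 * reg_h * bw * x[k]
    for k in range(nh, x.size):
        f += reg_j * bw * x[k] * x[k]
        g[k] += 2.0 * reg_j * bw * x[k]
    return f, g


def zero_sum_gauge(block: np.ndarray) -> np.ndarray:
    """Project a coupling block to the zero-sum gauge (rows and columns)."""
    row = block.mean(axis=1, keepdims=True)
    col = block.mean(axis=0, keepdims=True)
    return block - row - col + block.mean()


def infer_plm(
    aln: Alignment,
    reg_h: float = DEFAULT_REG_H,
    reg_j: float = DEFAULT_REG_J,
    pseudocount: float = 0.01,
    max_iter: int = 150,
    use_weights: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Fully-connected Potts fit by weighted symmetric pseudolikelihood.

    Returns ``(h, J)`` with ``h`` of shape (N, 20) and ``J`` of shape
    (N(N-1)/2, 21, 21); each block is in the zero-sum gauge over the 20
    amino-acid states (gap rows/columns are contexts only and are left as
    fitted).  L2 penalties ``reg_h``/``reg_J`` are per parameter, scaled by
    the effective sequence count.
    """
    if aln.n_rows < 2 or aln.n_sites < 2:
        raise ValueError("pseudolikelihood needs at least 2 sequences and 2 sites")
    n = aln.n_sites
    qt, qs = Q, Q_SYM
    w = aln.weights if use_weights else np.ones(aln.n_rows)
    bw = float(w.sum())
    npar = n * qt + n_pairs(n) * qs * qs

    # warm start from the profile model
    x0 = np.zeros(npar)
    freqs = FrequencyTables(aln, pseudocount=max(pseudocount, 1e-3))
    x0[: n * qt] = np.log(freqs.p).ravel()

    seqs = np.ascontiguousarray(aln.seqs, dtype=np.int8)
    wc = np.ascontiguousarray(w, dtype=np.float64)

    def fun(x):
        return _plm_value_grad(x, seqs, wc, n, qt, qs, reg_h, reg_j, bw)

    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "maxfun": max_iter * 3})
    if not np.all(np.isfinite(res.x)):
        raise PlmConvergenceError(f"PLM optimizer failed: {res.message}")

    h = res.x[: n * qt].reshape(n, qt).copy()
    j_flat = res.x[n * qt:].reshape(n_pairs(n), qs, qs).copy()
    for p in range(j_flat.shape[0]):
        j_flat[p, :Q, :Q] = zero_sum_gauge(j_flat[p, :Q, :Q])
    return h, j_flat


def frobenius_scores(couplings: np.ndarray) -> np.ndarray:
    """Frobenius norm of each pair's 20 x 20 amino-acid coupling block."""
    blocks = couplings[:, :Q, :Q]
    return np.sqrt((blocks ** 2).sum(axis=(1, 2)))


def select_links(scores: np.ndarray, n_sites: int, k: int) -> list[tuple[int, int]]:
    """Top-K pairs by score; ties broken lexicographically on (i, j)."""
    pairs = pair_list(n_sites)
    if not 0 <= k <= len(pairs):
        raise ValueError(f"K={k} outside [0, {len(pairs)}]")
    if scores.shape[0] != len(pairs):
        raise ValueError("score vector length does not match the pair count")
    order = sorted(range(len(pairs)), key=lambda p: (-scores[p], pairs[p]))
    return sorted(pairs[p] for p in order[:k])


def infer_k_link(
    aln: Alignment,
    k: int,
    pseudocount: float = 0.01,
    reg_h: float = DEFAULT_REG_H,
    reg_j: float = DEFAULT_REG_J,
    use_weights: bool = True,
    link_scores: np.ndarray | None = None,
) -> PottsModel:
    """Full K-link pipeline: PLM ranking, top-K selection, two-site re-fit.

    ``link_scores`` short-circuits the PLM step when the ranking is already
    available (e.g. shared across several K on the same alignment).
    """
    freqs = FrequencyTables(aln if use_weights else _unit_weight_view(aln),
                            pseudocount=pseudocount)
    if k == 0:
        model = infer_independent(freqs)
    else:
        if link_scores is None:
            _, j_flat = infer_plm(aln, reg_h=reg_h, reg_j=reg_j,
                                  pseudocount=pseudocount, use_weights=use_weights)
            link_scores = frobenius_scores(j_flat)
        links = select_links(link_scores, aln.n_sites, k)
        model = infer_two_site(freqs, links)
    model.meta.update({"K": k, "B": freqs.B, "lam": pseudocount})
    return model


def _unit_weight_view(aln: Alignment) -> Alignment:
    view = aln.copy()
    view.weights = np.ones(aln.n_rows)
    return view


def save_model(model: PottsModel, path) -> None:
    """Serialize a model as a compressed array archive with JSON metadata."""
    import json

    arrays = {"h": model.h, "links": np.array(model.links, dtype=int).reshape(-1, 2)}
    for idx, link in enumerate(model.links):
        arrays[f"J{idx}"] = model.J[link]
    arrays["meta"] = np.frombuffer(
        json.dumps({"q": model.q, **model.meta}).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **arrays)


def load_model(path) -> PottsModel:
    import json

    with np.load(path) as payload:
        meta = json.loads(payload["meta"].tobytes().decode())
        links = [tuple(int(v) for v in row) for row in payload["links"]]
        J = {link: payload[f"J{idx}"] for idx, link in enumerate(links)}
        q = meta.pop("q")
        return PottsModel(h=payload["h"], links=links, J=J, q=q, meta=meta)


# ---------------------------------------------------------------------------
# Gibbs sampling (fixture generator for recovery tests)
# ---------------------------------------------------------------------------

def sample_from_potts(
    model: PottsModel,
    n: int,
    burn_in: int = 100,
    thin: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Gibbs-sample sequences from the model distribution.

    Returns an (n, N) int8 matrix; deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    rng = np.random.default_rng(seed)
    nsite, q = model.n_sites, model.q
    nb = model.neighborhoods()
    state = rng.integers(0, q, size=nsite)
    out = np.empty((n, nsite), dtype=np.int8)
    taken = 0
    sweep = 0
    while taken < n:
        for i in range(nsite):
            logits = model.h[i, :q].copy()
            for j in nb[i]:
                logits += model.coupling(i, j)[:q, state[j]]
            logits -= logits.max()
            p = np.exp(logits)
            p /= p.sum()
            state[i] = rng.choice(q, p=p)
        sweep += 1
        if sweep > burn_in and (sweep - burn_in) % thin == 0:
            out[taken] = state
            taken += 1
    return out
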