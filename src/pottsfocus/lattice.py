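"""Lattice-protein ground truth: folds, fitness, sampling, bias/variance.

Model proteins are 27-mers folding on the 3 x 3 x 3 cube.  A fold is a
Hamiltonian self-avoiding walk over the 27 sites; every maximally compact
fold carries exactly 28 residue-residue contacts (the cube has 54 lattice
edges, the chain uses 26 of them).  The energy of a sequence on a fold is
the sum of pairwise contact energies; the fitness of a sequence is the
log-probability that it occupies its native fold within a Boltzmann
competition against the other folds, which makes the exact effect of every
single mutation computable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numba
import numpy as np
from numba.typed import Dict as NumbaDict
from numba import types as nbtypes

from .alignment import Alignment, Q
from .mj import mj_matrix

logger = logging.getLogger(__name__)

N_SITES = 27
N_CONTACTS = 28
DEFAULT_THETA = 5.0
DEFAULT_BETA = 1000.0
DEFAULT_THIN = 1000
SAMPLING_GAMMAS = (0.0, 0.025, 0.050, 0.075)
PNAT_WINDOW = (0.990, 0.997)


# ---------------------------------------------------------------------------
# cube geometry and symmetries
# ---------------------------------------------------------------------------

def _coords() -> np.ndarray:
    c = np.empty((27, 3), dtype=np.int8)
    for p in range(27):
        c[p] = (p % 3, (p // 3) % 3, p // 9)
    return c


def _index(coord: np.ndarray) -> int:
    return int(coord[0] + 3 * coord[1] + 9 * coord[2])


def _neighbour_table() -> tuple[np.ndarray, np.ndarray]:
    coords = _coords()
    nbr = np.full((27, 6), -1, dtype=np.int8)
    cnt = np.zeros(27, dtype=np.int8)
    for p in range(27):
        for axis in range(3):
            for step in (-1, 1):
                c = coords[p].copy()
                c[axis] += step
                if 0 <= c[axis] <= 2:
                    nbr[p, cnt[p]] = _index(c)
                    cnt[p] += 1
    return nbr, cnt


def cube_symmetries() -> np.ndarray:
    """All 48 rotation/reflection site permutations of the 3 x 3 x 3 cube."""
    coords = _coords()
    perms = []
    from itertools import permutations
    for axes in permutations(range(3)):
        for flips in range(8):
            perm = np.empty(27, dtype=np.int8)
            for p in range(27):
                c = coords[p][list(axes)].copy()
                for k in range(3):
                    if flips >> k & 1:
                        c[k] = 2 - c[k]
                perm[p] = _index(c)
            perms.append(perm)
    return np.stack(perms)


@numba.njit(cache=True)
def _dfs_enumerate(nbr, cnt, syms, include_reversal, out):  # pragma: no cover
    """Depth-first enumeration of Hamiltonian walks, keeping one canonical
    (lexicographically minimal) representative per symmetry class."""
    n_syms = syms.shape[0]
    path = np.empty(27, dtype=np.int8)
    used = np.zeros(27, dtype=np.bool_)
    choice = np.zeros(28, dtype=np.int8)
    n_found = 0
    for start in range(27):
        depth = 0
        path[0] = start
        used[start] = True
        choice[0] = 0
        while depth >= 0:
            if depth == 26:
                # complete walk: keep iff minimal among all images
                keep = True
                for s in range(n_syms):
                    smaller = False
                    for k in range(27):
                        a = syms[s, path[k]]
                        b = path[k]
                        if a < b:
                            smaller = True
                            break
                        if a > b:
                            break
                    if smaller:
                        keep = False
                        break
                    if include_reversal:
                        smaller = False
                        for k in range(27):
                            a = syms[s, path[26 - k]]
                            b = path[k]
                            if a < b:
                                smaller = True
                                break
                            if a > b:
                                break
                        if smaller:
                            keep = False
                            break
                if keep:
                    for k in range(27):
                        out[n_found, k] = path[k]
                    n_found += 1
                used[path[depth]] = False
                depth -= 1
                continue
            # try next neighbour at this depth
            advanced = False
            cur = path[depth]
            c = choice[depth]
            while c < cnt[cur]:
                nxt = nbr[cur, c]
                c += 1
                if not used[nxt]:
                    choice[depth] = c
                    depth += 1
                    path[depth] = nxt
                    used[nxt] = True
                    choice[depth] = 0
                    advanced = True
                    break
            if not advanced:
                choice[depth] = c
                used[cur] = False
                depth -= 1
        used[:] = False
    return n_found


@numba.njit(cache=True)
def _dfs_count_classes(nbr, cnt, syms, include_reversal, starts, seen):  # pragma: no cover
    """Independent class count: enumerate walks from symmetry-distinct start
    cells only and hash a canonical key (maximal image, packed base 27)."""
    n_syms = syms.shape[0]
    path = np.empty(27, dtype=np.int8)
    used = np.zeros(27, dtype=np.bool_)
    choice = np.zeros(28, dtype=np.int8)
    image = np.empty(27, dtype=np.int8)
    best = np.empty(27, dtype=np.int8)
    for s_idx in range(starts.shape[0]):
        start = starts[s_idx]
        depth = 0
        path[0] = start
        used[start] = True
        choice[0] = 0
        while depth >= 0:
            if depth == 26:
                n_dir = 2 if include_reversal else 1
                for k in range(27):
                    best[k] = path[k]
                for s in range(n_syms):
                    for direction in range(n_dir):
                        for k in range(27):
                            src = path[k] if direction == 0 else path[26 - k]
                            image[k] = syms[s, src]
                        bigger = False
                        equal = True
                        for k in range(27):
                            if image[k] > best[k]:
                                bigger = True
                                equal = False
                                break
                            if image[k] < best[k]:
                                equal = False
                                break
                        if bigger:
                            for k in range(27):
                                best[k] = image[k]
                hi = np.int64(0)
                lo = np.int64(0)
                for k in range(14):
                    hi = hi * 27 + best[k]
                for k in range(14, 27):
                    lo = lo * 27 + best[k]
                seen[(hi, lo)] = np.uint8(1)
                used[path[depth]] = False
                depth -= 1
                continue
            advanced = False
            cur = path[depth]
            c = choice[depth]
            while c < cnt[cur]:
                nxt = nbr[cur, c]
                c += 1
                if not used[nxt]:
                    choice[depth] = c
                    depth += 1
                    path[depth] = nxt
                    used[nxt] = True
                    choice[depth] = 0
                    advanced = True
                    break
            if not advanced:
                choice[depth] = c
                used[cur] = False
                depth -= 1
        used[:] = False
    return len(seen)


def _contacts_of_path(path: np.ndarray, adjacency: np.ndarray) -> np.ndarray:
    pos = path.astype(np.intp)
    pairs = []
    for k in range(27):
        for l in range(k + 2, 27):
            if adjacency[pos[k], pos[l]]:
                pairs.append((k, l))
    return np.array(pairs, dtype=np.int8)


@dataclass
class FoldRepertoire:
    """Symmetry-distinct compact folds with their contact lists."""

    paths: np.ndarray         # (F, 27) lattice site of each residue
    contacts: np.ndarray      # (F, 28, 2) residue-index contact pairs
    dedup_reversal: bool

    @property
    def n_folds(self) -> int:
        return self.paths.shape[0]


_REPERTOIRE_CACHE: dict[bool, FoldRepertoire] = {}


def enumerate_folds(dedup_reversal: bool = False) -> FoldRepertoire:
    """Enumerate every compact 27-mer fold, canonicalized under the 48 cube
    symmetries (optionally also chain reversal).  Cached per process."""
    if dedup_reversal in _REPERTOIRE_CACHE:
        return _REPERTOIRE_CACHE[dedup_reversal]
    nbr, cnt = _neighbour_table()
    syms = cube_symmetries()
    out = np.empty((230000, 27), dtype=np.int8)
    n = _dfs_enumerate(nbr, cnt, syms, dedup_reversal, out)
    paths = out[:n].copy()

    coords = _coords()
    adjacency = np.zeros((27, 27), dtype=bool)
    for p in range(27):
        for q_ in range(27):
            adjacency[p, q_] = np.abs(coords[p] - coords[q_]).sum() == 1
    contacts = np.empty((n, N_CONTACTS, 2), dtype=np.int8)
    for f in range(n):
        pairs = _contacts_of_path(paths[f], adjacency)
        if pairs.shape[0] != N_CONTACTS:
            raise AssertionError(
                f"fold {f} has {pairs.shape[0]} contacts, expected {N_CONTACTS}"
            )
        contacts[f] = pairs
    rep = FoldRepertoire(paths=paths, contacts=contacts, dedup_reversal=dedup_reversal)
    _REPERTOIRE_CACHE[dedup_reversal] = rep
    return rep


def count_folds_oracle(dedup_reversal: bool = False, starts: tuple[int, ...] = (0, 1, 4, 13)) -> int:
    """Second, independently coded class count (hash of maximal images,
    walks enumerated from one start cell per symmetry orbit)."""
    nbr, cnt = _neighbour_table()
    syms = cube_symmetries()
    seen = NumbaDict.empty(
        key_type=nbtypes.UniTuple(nbtypes.int64, 2), value_type=nbtypes.uint8
    )
    return int(_dfs_count_classes(nbr, cnt, syms, dedup_reversal,
                                  np.array(starts, dtype=np.int8), seen))


# ---------------------------------------------------------------------------
# energies and fitness
# ---------------------------------------------------------------------------

def fold_energy(contacts: np.ndarray, seq: np.ndarray, mj: np.ndarray) -> float:
    """Contact-energy sum of a sequence threaded onto one fold."""
    seq = np.asarray(seq)
    if np.any(seq >= Q):
        raise ValueError("lattice sequences cannot contain gaps")
    return float(mj[seq[contacts[:, 0]], seq[contacts[:, 1]]].sum())


@dataclass
class LatticeWorld:
    """A fixed fitness landscape: a native fold competing with decoy folds.

    ``contacts`` stacks the native fold first, then the decoys.  The
    competition set may be the full repertoire or a seeded subsample of it
    (the desk-scale default), which defines a self-consistent, exactly
    solvable landscape of its own.
    """

    contacts: np.ndarray          # (M, 28, 2)
    native_path: np.ndarray
    fold_ids: np.ndarray          # indices into the full repertoire
    mj: np.ndarray = field(default_factory=mj_matrix)

    # CSR layout of contact endpoints grouped by residue index, used by the
    # incremental single-mutation energy updates
    _site_ptr: np.ndarray = None          # type: ignore[assignment]
    _site_fold: np.ndarray = None         # type: ignore[assignment]
    _site_partner: np.ndarray = None      # type: ignore[assignment]

    def __post_init__(self) -> None:
        m = self.contacts.shape[0]
        sites = np.concatenate([self.contacts[:, :, 0].ravel(),
                                self.contacts[:, :, 1].ravel()]).astype(np.int64)
        partners = np.concatenate([self.contacts[:, :, 1].ravel(),
                                   self.contacts[:, :, 0].ravel()]).astype(np.int8)
        folds = np.tile(np.repeat(np.arange(m, dtype=np.int64), N_CONTACTS), 2)
        order = np.argsort(sites, kind="stable")
        counts = np.bincount(sites, minlength=N_SITES)
        self._site_ptr = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
        self._site_fold = folds[order]
        self._site_partner = partners[order]

    @property
    def n_folds(self) -> int:
        return self.contacts.shape[0]

    def energies(self, seq: np.ndarray) -> np.ndarray:
        """Energy of ``seq`` on every fold in the competition set."""
        return self.mj[seq[self.contacts[..., 0]], seq[self.contacts[..., 1]]].sum(axis=1)

    def p_nat(self, seq: np.ndarray) -> float:
        e = self.energies(seq)
        e -= e.min()
        w = np.exp(-e)
        return float(w[0] / w.sum())

    def fitness(self, seq: np.ndarray) -> float:
        """H(s) = -log P_nat(s); lower is fitter."""
        e = self.energies(seq)
        m = e.min()
        z = np.exp(-(e - m)).sum()
        return float(e[0] - m + np.log(z))


def make_world(
    n_competitors: int = 2000,
    seed: int = 0,
    dedup_reversal: bool = False,
    repertoire: FoldRepertoire | None = None,
) -> LatticeWorld:
    """Pick a native fold and a seeded decoy set from the full repertoire.

    ``n_competitors`` counts the native plus decoys; pass the repertoire size
    (or None rows available) for the full competition.
    """
    rep = repertoire if repertoire is not None else enumerate_folds(dedup_reversal)
    rng = np.random.default_rng(seed)
    native = int(rng.integers(rep.n_folds))
    m = min(n_competitors, rep.n_folds)
    others = rng.choice(rep.n_folds - 1, size=m - 1, replace=False)
    others = np.where(others >= native, others + 1, others)
    fold_ids = np.concatenate(([native], np.sort(others)))
    return LatticeWorld(
        contacts=rep.contacts[fold_ids].copy(),
        native_path=rep.paths[native].copy(),
        fold_ids=fold_ids,
    )


def make_competitive_world(
    n_competitors: int = 2000,
    seed: int = 0,
    dedup_reversal: bool = False,
    repertoire: FoldRepertoire | None = None,
    competitive_fraction: float = 0.5,
) -> tuple["LatticeWorld", np.ndarray]:
    """World whose decoys mix the wild type's strongest competitors with a
    uniform fold sample.

    The full Boltzmann sum over all ~10^5 folds is dominated by its
    lowest-energy terms, so a desk-scale competition keeps a
    ``competitive_fraction`` of the decoy budget for the lowest-energy folds
    *for the selected wild type* (these carry the epistatic signal around
    wt) and fills the rest with a seeded uniform sample (these keep distant
    sequences honest without over-constraining the neutral network).  The
    reduced world and its wild type are returned together.
    """
    rep = repertoire if repertoire is not None else enumerate_folds(dedup_reversal)
    rng = np.random.default_rng(seed)
    m = min(n_competitors, rep.n_folds)
    last_error: Exception | None = None
    for _attempt in range(6):
        native = int(rng.integers(rep.n_folds))
        fold_ids_full = np.concatenate(
            ([native], np.delete(np.arange(rep.n_folds), native))
        )
        full_world = LatticeWorld(
            contacts=rep.contacts[fold_ids_full].copy(),
            native_path=rep.paths[native].copy(),
            fold_ids=fold_ids_full,
        )
        # Alternate wild-type selection (cheap, in the reduced world) with
        # decoy refreshes (one full-repertoire energy scan) until the
        # competitor set stabilizes; every returned quantity is consistent
        # within the final world.  Poorly designable native folds (no
        # sequence reaches the stability window against their strongest
        # competitors) are skipped.
        try:
            prelim_ids = np.concatenate(
                ([0], rng.choice(np.arange(1, rep.n_folds),
                                 size=min(4000, rep.n_folds) - 1, replace=False))
            )
            world = LatticeWorld(contacts=full_world.contacts[prelim_ids].copy(),
                                 native_path=full_world.native_path.copy(),
                                 fold_ids=full_world.fold_ids[prelim_ids])
            wt = select_wildtype(world, seed=seed)
            n_comp = int(round(competitive_fraction * (m - 1)))
            uniform = rng.choice(np.arange(1, rep.n_folds), size=m - 1 - n_comp,
                                 replace=False)
            keep_prev: np.ndarray | None = None
            for _ in range(4):
                energies = full_world.energies(wt)
                order = 1 + np.argsort(energies[1:], kind="stable")
                strongest = order[~np.isin(order, uniform)][:n_comp]
                keep = np.concatenate(([0], np.sort(np.concatenate([strongest, uniform]))))
                if keep_prev is not None and np.array_equal(keep, keep_prev):
                    break
                keep_prev = keep
                world = LatticeWorld(
                    contacts=full_world.contacts[keep].copy(),
                    native_path=full_world.native_path.copy(),
                    fold_ids=full_world.fold_ids[keep],
                )
                wt = select_wildtype(world, seed=seed, init=wt)
            return world, wt
        except WildtypeSearchError as exc:
            logger.warning("native fold %d rejected: %s", native, exc)
            last_error = exc
    raise WildtypeSearchError(f"no designable native fold found: {last_error}")


# ---------------------------------------------------------------------------
# incremental single-mutation machinery (numba)
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def _h_of(energies):  # pragma: no cover
    m = energies[0]
    for f in range(energies.shape[0]):
        if energies[f] < m:
            m = energies[f]
    z = 0.0
    for f in range(energies.shape[0]):
        z += np.exp(-(energies[f] - m))
    return energies[0] - m + np.log(z)


@numba.njit(cache=True)
def _mutant_energies(energies, seq, site, new_aa, mj, ptr, folds, partners, out):  # pragma: no cover
    old = seq[site]
    for f in range(energies.shape[0]):
        out[f] = energies[f]
    for k in range(ptr[site], ptr[site + 1]):
        f = folds[k]
        p = partners[k]
        out[f] += mj[new_aa, seq[p]] - mj[old, seq[p]]
    return out


@numba.njit(cache=True)
def _all_mutant_h(energies, seq, mj, ptr, folds, partners, out_h):  # pragma: no cover
    nf = energies.shape[0]
    scratch = np.empty(nf)
    for site in range(N_SITES):
        for aa in range(20):
            if aa == seq[site]:
                out_h[site, aa] = _h_of(energies)
            else:
                _mutant_energies(energies, seq, site, aa, mj, ptr, folds, partners, scratch)
                out_h[site, aa] = _h_of(scratch)
    return out_h


@numba.njit(cache=True)
def _metropolis(seq, wt, energies, mj, ptr, folds, partners,
                beta, gamma, normalize_bias, bias_sign,
                thin, n_samples, seed, out_seqs):  # pragma: no cover
    np.random.seed(seed)
    nf = energies.shape[0]
    scratch = np.empty(nf)
    h_cur = _h_of(energies)
    d_cur = 0
    for k in range(N_SITES):
        if seq[k] != wt[k]:
            d_cur += 1
    scale = 1.0 / N_SITES if normalize_bias else 1.0
    taken = 0
    step = 0
    while taken < n_samples:
        site = np.random.randint(N_SITES)
        new_aa = np.random.randint(19)
        if new_aa >= seq[site]:
            new_aa += 1
        _mutant_energies(energies, seq, site, new_aa, mj, ptr, folds, partners, scratch)
        h_new = _h_of(scratch)
        d_new = d_cur
        if seq[site] == wt[site]:
            d_new += 1
        elif new_aa == wt[site]:
            d_new -= 1
        delta = (h_new - h_cur) + bias_sign * gamma * scale * (d_new - d_cur)
        if delta <= 0.0 or np.random.random() < np.exp(-beta * delta):
            seq[site] = new_aa
            for f in range(nf):
                energies[f] = scratch[f]
            h_cur = h_new
            d_cur = d_new
        step += 1
        if step % thin == 0:
            for k in range(N_SITES):
                out_seqs[taken, k] = seq[k]
            taken += 1
    return taken


@dataclass
class SamplerConfig:
    """Metropolis settings for sequence sampling around a wild type.

    ``gamma`` sets the strength of the distance bias; sampling penalizes the
    normalized Hamming distance to the wild type so that larger gamma keeps
    the chain closer to it.  ``beta`` is the inverse temperature multiplying
    the biased fitness difference; ``thin`` the number of elementary steps
    between recorded sequences.
    """

    gamma: float = 0.0
    beta: float = DEFAULT_BETA
    thin: int = DEFAULT_THIN
    n_samples: int = 1000
    seed: int = 0
    n_chains: int = 1
    normalize_bias: bool = True
    bias_sign: float = 1.0   # +1 penalizes distance (focuses near wt)

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.beta <= 0 or self.thin < 1 or self.n_samples < 1:
            raise ValueError("invalid sampler configuration")


def metropolis_sample(world: LatticeWorld, wt: np.ndarray, cfg: SamplerConfig) -> Alignment:
    """Sample an alignment from the distance-biased landscape.

    Chains start at the wild type; one sequence is recorded every ``thin``
    proposals.  With ``n_chains`` > 1 the samples are split over independent
    restarts (the early records of each chain populate the close
    neighbourhood of wt, later ones its equilibrium distance).  No
    reweighting is applied to lattice alignments.
    """
    per_chain = int(np.ceil(cfg.n_samples / cfg.n_chains))
    rows = []
    for chain in range(cfg.n_chains):
        chain_seed = int(np.random.SeedSequence((cfg.seed, chain)).generate_state(1)[0] % (2 ** 31))
        seq = wt.copy().astype(np.int8)
        energies = world.energies(seq).astype(np.float64)
        out = np.empty((per_chain, N_SITES), dtype=np.int8)
        _metropolis(seq, wt.astype(np.int8), energies, world.mj,
                    world._site_ptr, world._site_fold, world._site_partner,
                    cfg.beta, cfg.gamma, cfg.normalize_bias, cfg.bias_sign,
                    cfg.thin, per_chain, chain_seed, out)
        rows.append(out)
    seqs = np.concatenate(rows)[: cfg.n_samples]
    ids = [f"g{cfg.gamma:g}_s{cfg.seed}_{k}" for k in range(seqs.shape[0])]
    return Alignment(ids=ids, seqs=seqs, wt=wt.astype(np.int8),
                     weights=np.ones(seqs.shape[0]))


def sample_pooled_alignment(
    world: LatticeWorld,
    wt: np.ndarray,
    n_per_gamma: int = 1200,
    gammas: tuple[float, ...] = SAMPLING_GAMMAS,
    n_chains: int = 24,
    seed: int = 0,
    beta: float = DEFAULT_BETA,
    thin: int = DEFAULT_THIN,
) -> Alignment:
    """Pool the four distance-biased alignments used for sub-sampling."""
    blocks = []
    for g_idx, gamma in enumerate(gammas):
        cfg = SamplerConfig(gamma=gamma, beta=beta, thin=thin,
                            n_samples=n_per_gamma, seed=seed * 1000 + g_idx,
                            n_chains=n_chains)
        blocks.append(metropolis_sample(world, wt, cfg))
    seqs = np.concatenate([b.seqs for b in blocks])
    ids = [i for b in blocks for i in b.ids]
    return Alignment(ids=ids, seqs=seqs, wt=wt.astype(np.int8),
                     weights=np.ones(seqs.shape[0]))


# ---------------------------------------------------------------------------
# wild-type selection and exact mutational effects
# ---------------------------------------------------------------------------

class WildtypeSearchError(RuntimeError):
    pass


def select_wildtype(
    world: LatticeWorld,
    seed: int = 0,
    pnat_window: tuple[float, float] = PNAT_WINDOW,
    max_steps: int = 3000,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy Monte-Carlo search for a wild type in the stability window.

    Starting from a random sequence (or ``init``), repeatedly applies the
    single mutation with the best native-fold probability until P_nat enters
    the window (stable, but leaving room for beneficial mutations).  Local
    optima below the window trigger a small random perturbation (stochastic
    escape, seeded); overshoots are walked back with the in-window mutant
    closest to the window center.
    """
    rng = np.random.default_rng(seed)
    lo, hi = pnat_window
    target = 0.5 * (lo + hi)
    if init is not None:
        seq = init.astype(np.int8).copy()
    else:
        seq = rng.integers(0, Q, size=N_SITES).astype(np.int8)
    best_seq, best_pnat = seq.copy(), -1.0
    mut_h = np.empty((N_SITES, Q))
    sites = np.arange(N_SITES)
    for _ in range(max_steps):
        pnat = world.p_nat(seq)
        if pnat > best_pnat:
            best_seq, best_pnat = seq.copy(), pnat
        energies = world.energies(seq).astype(np.float64)
        _all_mutant_h(energies, seq, world.mj, world._site_ptr,
                      world._site_fold, world._site_partner, mut_h)
        h_cur = world.fitness(seq)
        if lo <= pnat <= hi and (mut_h < h_cur - 1e-12).any():
            return seq
        pnats = np.exp(-mut_h)
        pnats[sites, seq] = -np.inf  # consider proper mutants only
        if pnat < lo:
            i, a = np.unravel_index(np.argmax(pnats), pnats.shape)
            if pnats[i, a] <= pnat:
                # local optimum below the window: perturb and keep searching
                seq = best_seq.copy()
                for site in rng.choice(N_SITES, size=3, replace=False):
                    seq[site] = rng.integers(0, Q)
                continue
        else:
            in_window = (pnats >= lo) & (pnats <= hi)
            if not in_window.any():
                raise WildtypeSearchError("overshot the stability window")
            score = np.where(in_window, -np.abs(pnats - target), -np.inf)
            i, a = np.unravel_index(np.argmax(score), score.shape)
        seq[i] = a
    raise WildtypeSearchError(
        f"no wild type found in {max_steps} steps (best P_nat={best_pnat:.4f})"
    )


@dataclass
class GroundTruth:
    """Exact single-mutant fitness effects around the wild type."""

    wt: np.ndarray
    effects: np.ndarray       # (27, 20), E_ia = H(wt_{i->a}) - H(wt); 0 at wt_i
    theta: float
    mask: np.ndarray          # observable mutations: a != wt_i and |E| < theta

    @property
    def n_observable(self) -> int:
        return int(self.mask.sum())

    @property
    def fitness_effects(self) -> np.ndarray:
        """Effects in fitness orientation (higher = fitter), the convention
        of log-probability predictors and experimental enrichments."""
        return -self.effects


def ground_truth_effects(world: LatticeWorld, wt: np.ndarray, theta: float = DEFAULT_THETA) -> GroundTruth:
    """Compute all 27 x 19 exact mutational effects and the observability mask."""
    energies = world.energies(wt).astype(np.float64)
    mut_h = np.empty((N_SITES, Q))
    _all_mutant_h(energies, wt, world.mj, world._site_ptr,
                  world._site_fold, world._site_partner, mut_h)
    effects = mut_h - world.fitness(wt)
    effects[np.arange(N_SITES), wt] = 0.0
    mask = np.abs(effects) < theta
    mask[np.arange(N_SITES), wt] = False
    return GroundTruth(wt=wt.copy(), effects=effects, theta=theta, mask=mask)


# ---------------------------------------------------------------------------
# numerical bias / variance of a predictor against the exact landscape
# ---------------------------------------------------------------------------

def numeric_bias_variance(
    prediction_values: list[np.ndarray],
    truth: GroundTruth,
) -> tuple[float, float, dict]:
    """Ground-truth squared bias and variance of repeated predictions.

    ``prediction_values`` holds one N x Q predicted-effect matrix per
    repeated inference at fixed (B, D).  Per mutation the signed bias is the
    mean prediction minus the exact effect (in fitness orientation, matching
    the log-probability predictors), and the variance the spread of the
    predictions over repeats.  Globally, the mean signed bias is removed
    (rank correlations ignore constant shifts), so the squared bias is the
    across-mutation variance of the signed bias; the global variance is the
    across-mutation mean of the per-mutation variances.  All averages run
    over the observable mutations only.
    """
    if len(prediction_values) < 2:
        raise ValueError("need at least 2 repeated inferences")
    mask = truth.mask
    if not mask.any():
        raise ValueError("observability mask is empty")
    stack = np.stack(prediction_values)                    # (n, N, Q)
    mean_pred = stack.mean(axis=0)
    bias = (mean_pred - truth.fitness_effects)[mask]       # signed, per mutation
    var = stack.var(axis=0)[mask]
    mu2_global = float(bias.var())                 # mean-square minus squared mean
    sigma2_global = float(var.mean())
    per_mut = {"bias": bias, "variance": var}
    return mu2_global, sigma2_global, per_mut


# ---------------------------------------------------------------------------
# structural vs non-structural couplings
# ---------------------------------------------------------------------------

def structural_coupling_analysis(
    big_alignment: Alignment,
    world: LatticeWorld,
    k_range: np.ndarray | list[int],
    reg_h: float = 0.01,
    reg_j: float = 0.01,
) -> dict:
    """Contrast the native-contact couplings of a dense Potts fit with the rest.

    Fits a fully-connected model by pseudolikelihood on a large unbiased
    alignment, pools the coupling-entry variances over native-contact pairs
    (V_struct) and all other pairs (V_nonstruct), and evaluates the
    effective un-modeled-epistasis curve
    ``J0(K) = (Nc - min(K, Nc)) V_struct + (Kmax - Nc - max(0, K - Nc)) V_nonstruct``
    normalized by its K = 0 value (the sparse model is assumed to pick up
    structural pairs first).
    """
    from .potts import infer_plm, n_pairs, pair_index

    n = big_alignment.n_sites
    k_max = n_pairs(n)
    k_range = np.asarray(k_range, dtype=int)
    if k_range.min() < 0 or k_range.max() > k_max:
        raise ValueError(f"K range outside [0, {k_max}]")
    _, j_flat = infer_plm(big_alignment, reg_h=reg_h, reg_j=reg_j, use_weights=False)
    struct_pairs = {
        pair_index(int(min(a, b)), int(max(a, b)), n)
        for a, b in world.contacts[0]
    }
    struct_idx = np.array(sorted(struct_pairs))
    other_idx = np.array([p for p in range(k_max) if p not in struct_pairs])
    v_struct = float(j_flat[struct_idx, :Q, :Q].var())
    v_nonstruct = float(j_flat[other_idx, :Q, :Q].var())

    nc = len(struct_pairs)
    def j0_eff(k: int) -> float:
        return ((nc - min(k, nc)) * v_struct
                + (k_max - nc - max(0, k - nc)) * v_nonstruct)

    j0_0 = j0_eff(0)
    curve = {int(k): j0_eff(int(k)) / j0_0 for k in k_range}
    return {"v_struct": v_struct, "v_nonstruct": v_nonstruct,
            "j0_curve": curve, "n_contacts": nc, "k_max": k_max}
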