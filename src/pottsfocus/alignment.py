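"""Alignment container, I/O, reweighting and frequency statistics.

Sequences are stored as integer-coded matrices over the 20 canonical amino
acids plus a gap state.  All frequency tables are computed on the 20
amino-acid states only: gap-carrying observations at a site are excluded
from that site's counts, since the downstream Potts machinery works with
Q = 20 states.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numba
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
Q = 20                      # number of amino-acid states
GAP_CODE = 20               # gap stored as a 21st symbol
Q_SYM = 21
GAP_CHARS = "-.*"

_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

DEFAULT_PSEUDOCOUNT = 0.01
REWEIGHT_THRESHOLD = 0.2    # normalized distance below which sequences cluster


class AlignmentFormatError(ValueError):
    """Raised for ragged or otherwise malformed alignment input."""


class AlignmentDataError(ValueError):
    """Raised when filtering leaves no usable data."""


def encode_sequence(seq: str) -> np.ndarray:
    """Map an amino-acid string to integer codes; unknowns become gaps."""
    out = np.empty(len(seq), dtype=np.int8)
    for k, ch in enumerate(seq.upper()):
        out[k] = _CODE.get(ch, GAP_CODE)
    return out


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[c] if c < Q else "-" for c in codes)


@dataclass
class Alignment:
    """Integer-coded gapped alignment with per-sequence weights.

    Attributes
    ----------
    ids : sequence identifiers, one per row.
    seqs : (B_rows, N) int8 matrix; codes 0..19 are amino acids, 20 is gap.
    wt : length-N reference sequence the mutations are scored against.
    weights : per-row weights in (0, 1]; effective size is ``weights.sum()``.
    col_map : indices of the retained columns in the original (unfiltered)
        coordinate system, used to remap mutation positions.
    """

    ids: list[str]
    seqs: np.ndarray
    wt: np.ndarray
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    col_map: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.seqs = np.ascontiguousarray(self.seqs, dtype=np.int8)
        self.wt = np.asarray(self.wt, dtype=np.int8)
        if self.seqs.ndim != 2:
            raise AlignmentFormatError("sequence matrix must be 2-D")
        if self.wt.shape[0] != self.seqs.shape[1]:
            raise AlignmentFormatError("wt length does not match alignment width")
        if self.weights is None:
            self.weights = np.ones(self.seqs.shape[0])
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.col_map is None:
            self.col_map = np.arange(self.seqs.shape[1])
        if self.seqs.size and (self.seqs.min() < 0 or self.seqs.max() >= Q_SYM):
            raise AlignmentFormatError("residue codes outside [0, 21)")

    @property
    def n_rows(self) -> int:
        return self.seqs.shape[0]

    @property
    def n_sites(self) -> int:
        return self.seqs.shape[1]

    @property
    def effective_size(self) -> float:
        """B, the reweighted number of sequences."""
        return float(self.weights.sum())

    def distances_to_wt(self, normalized: bool = False) -> np.ndarray:
        d = (self.seqs != self.wt[None, :]).sum(axis=1).astype(np.float64)
        return d / self.n_sites if normalized else d

    def subset(self, rows: np.ndarray) -> "Alignment":
        rows = np.asarray(rows)
        return Alignment(
            ids=[self.ids[r] for r in rows],
            seqs=self.seqs[rows],
            wt=self.wt.copy(),
            weights=self.weights[rows].copy(),
            col_map=self.col_map.copy(),
        )

    def copy(self) -> "Alignment":
        return self.subset(np.arange(self.n_rows))


def hamming(seq1: np.ndarray, seq2: np.ndarray, normalized: bool = False) -> float:
    """Hamming distance between two coded sequences.

    Gap-vs-residue and gap-vs-gap positions are compared literally (a gap
    matches a gap, mismatches a residue).
    """
    s1 = np.asarray(seq1)
    s2 = np.asarray(seq2)
    if s1.shape != s2.shape:
        raise ValueError(f"length mismatch: {s1.shape} vs {s2.shape}")
    d = float(np.count_nonzero(s1 != s2))
    return d / s1.shape[0] if normalized else d


@numba.njit(cache=True)
def _neighbour_counts(seqs: np.ndarray, cut: float) -> np.ndarray:  # pragma: no cover
    b, n = seqs.shape
    counts = np.ones(b, dtype=np.float64)   # each sequence counts itself
    limit = cut * n
    for i in range(b):
        for j in range(i + 1, b):
            d = 0
            for k in range(n):
                if seqs[i, k] != seqs[j, k]:
                    d += 1
                    if d >= limit:
                        break
            if d < limit:
                counts[i] += 1.0
                counts[j] += 1.0
    return counts


def compute_weights(aln: Alignment, similarity_threshold: float = REWEIGHT_THRESHOLD) -> np.ndarray:
    """Standard similarity reweighting: z(s) = 1 / #{s': d_norm(s, s') < cut}.

    The sequence itself is always counted, so weights lie in (0, 1].  The
    comparison is strict (< threshold), matching an 80% homology threshold
    for the default 0.2 cutoff.  Weights are stored on the alignment and
    returned.
    """
    if aln.n_rows == 0:
        raise AlignmentDataError("cannot reweight an empty alignment")
    counts = _neighbour_counts(aln.seqs, similarity_threshold)
    aln.weights = 1.0 / counts
    return aln.weights


def descriptors(aln: Alignment, normalized: bool = False) -> tuple[float, float]:
    """Quantity and relevance descriptors (B, D).

    B is the summed sequence weight; D the weighted mean Hamming distance to
    the wild type, in raw site counts by default (``normalized=True`` divides
    by N).
    """
    if aln.n_rows == 0:
        raise AlignmentDataError("empty alignment has no descriptors")
    b = aln.effective_size
    d = float(np.dot(aln.weights, aln.distances_to_wt(normalized=normalized))) / b
    return b, d


def read_alignment(
    fasta_path: str | Path,
    wt: str | Sequence[str],
    max_gap_fraction: float = 0.5,
) -> Alignment:
    """Read an aligned FASTA, deduplicate rows and drop gappy columns.

    Parameters
    ----------
    wt : either a record id present in the file or an explicit sequence
        string matching one record exactly (before column filtering).
    max_gap_fraction : columns with strictly more than this fraction of gaps
        are removed, and the same columns are removed from the wild type.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentDataError(f"no sequences in {fasta_path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise AlignmentFormatError(f"ragged alignment: lengths {sorted(lengths)}")

    ids = [r.id for r in records]
    mat = np.stack([encode_sequence(str(r.seq)) for r in records])

    wt_row = None
    if isinstance(wt, str) and wt in ids:
        wt_row = ids.index(wt)
    else:
        wt_codes = encode_sequence(str(wt))
        if wt_codes.shape[0] != mat.shape[1]:
            raise KeyError("wild type not found by id and sequence length differs")
        hits = np.where((mat == wt_codes[None, :]).all(axis=1))[0]
        if hits.size == 0:
            raise KeyError("wild type not resolvable by id or exact sequence")
        wt_row = int(hits[0])
    wt_seq = mat[wt_row].copy()

    # deduplicate, keeping first occurrences in file order
    _, first = np.unique(mat, axis=0, return_index=True)
    keep_rows = np.sort(first)
    mat = mat[keep_rows]
    ids = [ids[i] for i in keep_rows]

    gap_frac = (mat == GAP_CODE).mean(axis=0)
    keep_cols = np.where(gap_frac <= max_gap_fraction)[0]
    if keep_cols.size == 0:
        raise AlignmentDataError("no columns survive the gap filter")
    mat = mat[:, keep_cols]
    wt_seq = wt_seq[keep_cols]

    return Alignment(ids=ids, seqs=mat, wt=wt_seq, col_map=keep_cols)


def write_alignment(aln: Alignment, fasta_path: str | Path) -> None:
    records = [
        SeqRecord(Seq(decode_sequence(row)), id=name, description="")
        for name, row in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


# ---------------------------------------------------------------------------
# frequency tables
# ---------------------------------------------------------------------------

class FrequencyTables:
    """Weighted single-site and pairwise amino-acid frequencies.

    Gap observations are excluded from the 20-state tables.  Regularized
    tables mix the empirical frequencies with the uniform distribution:
    ``p~ = (1 - lam) p + lam / Q`` (and ``lam / Q**2`` for pairs), keeping
    every log-frequency finite for lam > 0.
    """

    def __init__(self, aln: Alignment, pseudocount: float = DEFAULT_PSEUDOCOUNT):
        if not 0.0 <= pseudocount < 1.0:
            raise ValueError(f"pseudocount must be in [0, 1), got {pseudocount}")
        self.lam = float(pseudocount)
        self.B = aln.effective_size
        self._seqs = aln.seqs
        self._weights = aln.weights
        self.n_sites = aln.n_sites
        self._pair_cache: dict[tuple[int, int], np.ndarray] = {}

        n, w, s = aln.n_sites, aln.weights, aln.seqs
        counts = np.zeros((n, Q))
        for a in range(Q):
            counts[:, a] = (w[:, None] * (s == a)).sum(axis=0)
        denom = counts.sum(axis=1)
        denom[denom == 0.0] = 1.0
        self._p_raw = counts / denom[:, None]

    @property
    def p(self) -> np.ndarray:
        """Regularized site marginals, shape (N, 20)."""
        return (1.0 - self.lam) * self._p_raw + self.lam / Q

    def p_raw(self) -> np.ndarray:
        return self._p_raw.copy()

    def pair(self, i: int, j: int) -> np.ndarray:
        """Regularized joint table for sites (i, j), shape (20, 20)."""
        if i > j:
            return self.pair(j, i).T
        key = (i, j)
        if key not in self._pair_cache:
            si, sj = self._seqs[:, i], self._seqs[:, j]
            ok = (si < Q) & (sj < Q)
            table = np.zeros((Q, Q))
            np.add.at(table, (si[ok], sj[ok]), self._weights[ok])
            tot = table.sum()
            if tot > 0:
                table /= tot
            self._pair_cache[key] = table
        raw = self._pair_cache[key]
        return (1.0 - self.lam) * raw + self.lam / (Q * Q)


def frequencies(aln: Alignment, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> FrequencyTables:
    """Build weighted frequency tables from an alignment."""
    return FrequencyTables(aln, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# mutational scans
# ---------------------------------------------------------------------------

_MUT_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


@dataclass
class MutationalScan:
    """Measured single-mutant effects keyed by (site, target residue).

    Sites are 0-based indices into the *filtered* alignment coordinates.
    """

    sites: np.ndarray        # int, 0-based
    targets: np.ndarray      # int codes 0..19
    effects: np.ndarray      # measured values
    n_rejected: int = 0

    def __len__(self) -> int:
        return self.sites.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"site": self.sites, "target": self.targets, "effect": self.effects}
        )


def parse_mutation_code(code: str) -> tuple[str, int, str]:
    """Split a code like ``G24A`` into (wt aa, 1-based position, mutant aa)."""
    m = _MUT_RE.match(code.strip())
    if m is None:
        raise AlignmentFormatError(f"unparsable mutation code: {code!r}")
    return m.group(1).upper(), int(m.group(2)), m.group(3).upper()


def read_scan(table_path: str | Path, aln: Alignment) -> MutationalScan:
    """Read a single-mutant scan table and map it onto alignment coordinates.

    Accepts either a ``mutant,score`` table (codes like ``G24A``, 1-based
    positions in the original, unfiltered coordinates) or explicit
    ``pos,wt,mut,score`` columns.  Records whose stated wild-type residue
    disagrees with the alignment wild type, or that fall on filtered-out
    columns, are dropped and counted in ``n_rejected``.
    """
    df = pd.read_csv(table_path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    if "mutant" in cols and ("score" in cols or "effect" in cols):
        score_col = cols.get("score", cols.get("effect"))
        parsed = [parse_mutation_code(c) for c in df[cols["mutant"]]]
        wt_aas = [p[0] for p in parsed]
        positions = np.array([p[1] for p in parsed])
        mut_aas = [p[2] for p in parsed]
        scores = df[score_col].to_numpy(dtype=float)
    elif {"pos", "wt", "mut", "score"} <= set(cols):
        wt_aas = [str(x).upper() for x in df[cols["wt"]]]
        positions = df[cols["pos"]].to_numpy(dtype=int)
        mut_aas = [str(x).upper() for x in df[cols["mut"]]]
        scores = df[cols["score"]].to_numpy(dtype=float)
    else:
        raise AlignmentFormatError(
            f"scan table needs 'mutant,score' or 'pos,wt,mut,score' columns, got {list(df.columns)}"
        )

    # original (1-based) position -> filtered 0-based index
    remap = {orig: k for k, orig in enumerate(aln.col_map)}
    sites, targets, effects = [], [], []
    n_rejected = 0
    seen: set[tuple[int, int]] = set()
    for wt_aa, pos, mut_aa, score in zip(wt_aas, positions, mut_aas, scores):
        filt = remap.get(pos - 1)
        code_mut = _CODE.get(mut_aa)
        if filt is None or code_mut is None:
            n_rejected += 1
            continue
        if aln.wt[filt] != _CODE.get(wt_aa, -1):
            n_rejected += 1
            continue
        if code_mut == aln.wt[filt] or (filt, code_mut) in seen:
            n_rejected += 1
            continue
        seen.add((filt, code_mut))
        sites.append(filt)
        targets.append(code_mut)
        effects.append(score)

    if not sites:
        raise AlignmentDataError("all scan records were rejected")
    return MutationalScan(
        sites=np.array(sites, dtype=int),
        targets=np.array(targets, dtype=int),
        effects=np.array(effects, dtype=float),
        n_rejected=n_rejected,
    )


def write_scan(scan: MutationalScan, aln: Alignment, table_path: str | Path) -> None:
    """Write a scan back out as a ``mutant,score`` CSV in original coordinates."""
    rows = []
    for site, target, effect in zip(scan.sites, scan.targets, scan.effects):
        code = f"{AMINO_ACIDS[aln.wt[site]]}{aln.col_map[site] + 1}{AMINO_ACIDS[target]}"
        rows.append((code, effect))
    pd.DataFrame(rows, columns=["mutant", "score"]).to_csv(table_path, index=False)
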