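"""Position-specific scoring matrices and promoter scanning.

A :class:`PSSM` holds per-position base probabilities for a transcription
factor binding motif together with a background base composition.  Sequences
are scored window-by-window with the log-odds score

    S(x) = sum_i log2( p_i(x_i) / b(x_i) )      [bits]

and every score is assigned an exact p-value, ``P(S >= s)`` under the
background model, computed by dynamic programming on an integer score
lattice (the approach used by FIMO-style scanners).  Discretisation floors
per-column scores onto the lattice, so reported p-values are conservative
at the stated resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT_INDEX = np.array([3, 2, 1, 0], dtype=np.int64)  # A<->T, C<->G
_N_INDEX = 4  # sentinel row for ambiguous bases

#: uniform background over A, C, G, T
UNIFORM_BACKGROUND = np.full(4, 0.25)

# IUPAC degeneracy used when importing consensus strings
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def encode(sequence: str) -> np.ndarray:
    """Encode a DNA string as integer indices; any non-ACGT base maps to N."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, _N_INDEX, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass(frozen=True)
class MotifHit:
    """A single scored motif occurrence on one strand of one sequence."""

    sequence_id: str
    offset: int          # 0-based start on the forward strand
    strand: str          # '+' or '-'
    score: float         # log-odds score in bits
    score_pvalue: float  # P(score >= observed) under the background model


class PSSM:
    """A probability matrix over {A,C,G,T} with background and pseudocount.

    Parameters
    ----------
    name:
        Motif / transcription factor symbol.
    matrix:
        ``(w, 4)`` array of per-position base probabilities (columns sum
        to one before pseudocount regularisation).
    background:
        Length-4 background composition; default uniform.
    pseudocount:
        Probability mass added to every cell before renormalising, keeping
        log-odds finite for degenerate matrices.
    """

    def __init__(
        self,
        name: str,
        matrix: Iterable[Sequence[float]],
        background: Sequence[float] | None = None,
        pseudocount: float = 0.01,
    ):
        mat = np.asarray(matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != 4 or mat.shape[0] < 1:
            raise ValueError("matrix must have shape (w, 4) with w >= 1")
        if np.any(mat < 0):
            raise ValueError("matrix probabilities must be non-negative")
        if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("matrix columns must each sum to 1")
        if pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValueError("background must be a length-4 probability vector")
        if np.any(bg <= 0):
            raise ValueError("background entries must be strictly positive")

        self.name = name
        self.raw_matrix = mat
        self.pseudocount = float(pseudocount)
        self.background = bg
        # pseudocount regularisation: p' = (p + c) / (1 + 4c)
        self.probs = (mat + pseudocount) / (1.0 + 4.0 * pseudocount)
        if np.any(self.probs <= 0):
            raise ValueError("zero probability cell; use a positive pseudocount")

    @property
    def width(self) -> int:
        return self.raw_matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.probs, axis=1))

    def log_odds(self) -> np.ndarray:
        """``(w, 4)`` matrix of ``log2(p / background)`` in bits."""
        return np.log2(self.probs / self.background[None, :])

    @cached_property
    def _scorer(self) -> "_LatticeScorer":
        return _LatticeScorer(self, resolution=1000)

    def score_distribution(self, resolution: int = 1000) -> "ScoreDistribution":
        """Exact null distribution of window scores (see module docstring)."""
        if resolution == 1000:
            return self._scorer.distribution
        return _LatticeScorer(self, resolution).distribution

    def __repr__(self) -> str:  # pragma: no cover
        return f"PSSM({self.name!r}, w={self.width})"


def consensus_to_pssm(
    name: str,
    consensus: str,
    pseudocount: float = 0.01,
    background: Sequence[float] | None = None,
) -> PSSM:
    """Import a consensus string (IUPAC allowed) as a near-degenerate PSSM.

    Each position puts all probability mass uniformly on the bases the
    IUPAC letter allows; the pseudocount softens the zeros.
    """
    rows = []
    for ch in consensus.upper():
        allowed = _IUPAC.get(ch)
        if allowed is None:
            raise ValueError(f"unknown consensus letter {ch!r}")
        row = np.zeros(4)
        for b in allowed:
            row[_BASE_INDEX[b]] = 1.0 / len(allowed)
        rows.append(row)
    return PSSM(name, rows, background=background, pseudocount=pseudocount)


class ScoreDistribution:
    """Exact lattice distribution of window log-odds scores.

    ``tail(s_int)`` returns ``P(S_int >= s_int)`` where ``S_int`` is the sum
    of per-column lattice scores of a background-drawn window.  Lattice
    scores are ``floor(log_odds * resolution)`` per cell.
    """

    def __init__(self, int_matrix: np.ndarray, background: np.ndarray, resolution: int):
        self.int_matrix = int_matrix          # (w, 4) integer lattice scores
        self.resolution = resolution
        lo = int(int_matrix.min(axis=1).sum())
        hi = int(int_matrix.max(axis=1).sum())
        probs = np.zeros(1)
        probs[0] = 1.0
        offset = 0  # score value of index 0
        for col in int_matrix:
            cmin, cmax = int(col.min()), int(col.max())
            new = np.zeros(len(probs) + (cmax - cmin))
            for b in range(4):
                shift = int(col[b]) - cmin
                new[shift:shift + len(probs)] += background[b] * probs
            probs = new
            offset += cmin
        assert offset == lo and offset + len(probs) - 1 == hi
        self.min_score = lo
        self.max_score = hi
        self.pmf = probs
        # tail[i] = P(S >= lo + i)
        self.tail = np.cumsum(probs[::-1])[::-1]
        total = self.tail[0]
        if abs(total - 1.0) > 1e-6:
            raise AssertionError(f"score distribution mass {total} != 1")

    def pvalue(self, int_score: int) -> float:
        """``P(S >= int_score)``; clipped to (0, 1]."""
        if int_score <= self.min_score:
            return 1.0
        if int_score > self.max_score:
            int_score = self.max_score  # unreachable for lattice-scored windows
        p = float(self.tail[int_score - self.min_score])
        return min(max(p, np.finfo(float).tiny), 1.0)

    def score_threshold(self, pvalue: float) -> int:
        """Smallest lattice score whose tail probability is <= ``pvalue``."""
        idx = np.searchsorted(-self.tail, -pvalue, side="left")
        if idx >= len(self.tail):
            return self.max_score + 1  # no achievable score is that significant
        return self.min_score + int(idx)


class _LatticeScorer:
    """Precomputed integer/float scoring tables for one PSSM."""

    def __init__(self, pssm: PSSM, resolution: int):
        if resolution < 100:
            raise ValueError("resolution must be >= 100")
        lo = pssm.log_odds()
        self.float_lo = lo
        self.int_lo = np.floor(lo * resolution).astype(np.int64)
        self.distribution = ScoreDistribution(self.int_lo, pssm.background, resolution)
        w = pssm.width
        # reverse-complement tables: score of revcomp(window) under the motif
        self.float_lo_rc = lo[::-1][:, _COMPLEMENT_INDEX]
        self.int_lo_rc = self.int_lo[::-1][:, _COMPLEMENT_INDEX]
        # extra N row: -inf-ish so windows containing N never score
        big = np.int64(-(1 << 40))
        self.int_ext = np.hstack([self.int_lo, np.full((w, 1), big)])
        self.int_ext_rc = np.hstack([self.int_lo_rc, np.full((w, 1), big)])
        self.n_sentinel = big


def _window_scores(encoded: np.ndarray, table: np.ndarray, w: int) -> np.ndarray:
    """Sum table[i, encoded[o+i]] over i for every offset o (1-D sequence)."""
    n_off = len(encoded) - w + 1
    if n_off <= 0:
        return np.zeros(0, dtype=table.dtype)
    out = np.zeros(n_off, dtype=table.dtype)
    for i in range(w):
        out += table[i, encoded[i:i + n_off]]
    return out


def scan(
    sequence: str,
    pssm: PSSM,
    both_strands: bool = True,
    sequence_id: str = "",
) -> list[MotifHit]:
    """Score every window of ``sequence`` against ``pssm``.

    Windows containing an ambiguous base (N) are skipped.  Reverse-strand
    hits are reported at their forward-strand offset.  Sequences shorter
    than the motif yield an empty list.
    """
    enc = encode(sequence)
    w = pssm.width
    sc = pssm._scorer
    dist = sc.distribution
    hits: list[MotifHit] = []
    n_off = len(enc) - w + 1
    if n_off <= 0:
        return hits
    int_f = _window_scores(enc, sc.int_ext, w)
    flo_f = _window_scores(enc.clip(max=3), sc.float_lo, w)
    strands = [("+", int_f, flo_f)]
    if both_strands:
        int_r = _window_scores(enc, sc.int_ext_rc, w)
        flo_r = _window_scores(enc.clip(max=3), sc.float_lo_rc, w)
        strands.append(("-", int_r, flo_r))
    for strand, int_s, flo_s in strands:
        valid = int_s > sc.n_sentinel // 2
        for off in np.nonzero(valid)[0]:
            hits.append(
                MotifHit(
                    sequence_id=sequence_id,
                    offset=int(off),
                    strand=strand,
                    score=float(flo_s[off]),
                    score_pvalue=dist.pvalue(int(int_s[off])),
                )
            )
    return hits


def best_hit(
    sequence: str, pssm: PSSM, both_strands: bool = True, sequence_id: str = ""
) -> MotifHit | None:
    """Most significant hit; ties break to the smallest offset, then '+'.

    Returns ``None`` when no window is scorable (short or all-N sequence).
    """
    hits = scan(sequence, pssm, both_strands=both_strands, sequence_id=sequence_id)
    if not hits:
        return None
    return min(hits, key=lambda h: (h.score_pvalue, h.offset, h.strand != "+"))


def batch_best_int_scores(sequences: Sequence[str], pssm: PSSM, both_strands: bool = True) -> np.ndarray:
    """Best lattice score per sequence (vectorised fast path for enrichment).

    Returns the sentinel minimum for sequences with no valid window.  All
    sequences must have equal length for the fully vectorised path; ragged
    input falls back to a per-sequence loop.
    """
    sc = pssm._scorer
    w = pssm.width
    lengths = {len(s) for s in sequences}
    if len(lengths) == 1 and lengths.pop() >= w:
        mat = np.stack([encode(s) for s in sequences])
        n_off = mat.shape[1] - w + 1
        best = np.full(mat.shape[0], sc.n_sentinel, dtype=np.int64)
        tables = [sc.int_ext, sc.int_ext_rc] if both_strands else [sc.int_ext]
        for table in tables:
            scores = np.zeros((mat.shape[0], n_off), dtype=np.int64)
            for i in range(w):
                scores += table[i][mat[:, i:i + n_off]]
            best = np.maximum(best, scores.max(axis=1))
        return best
    out = np.full(len(sequences), sc.n_sentinel, dtype=np.int64)
    for k, s in enumerate(sequences):
        enc = encode(s)
        if len(enc) < w:
            continue
        vals = [_window_scores(enc, sc.int_ext, w)]
        if both_strands:
            vals.append(_window_scores(enc, sc.int_ext_rc, w))
        out[k] = max(int(v.max()) for v in vals if len(v))
    return out
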