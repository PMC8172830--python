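"""Motif models, MEME minimal I/O, and log-odds scanning.

A motif is a base-frequency matrix (rows = positions, columns = A/C/G/T).
Before scoring, every cell is smoothed with a pseudo-count against the
background: ``(f + c*pi) / (1 + c)`` with ``c = 0.1`` by default.  Scores
are log-likelihood ratios against a zero-order (i.i.d.) background, in
bits, quantized to a fixed granularity so that the score threshold for a
given match p-value can be computed exactly by dynamic programming over
the per-position score distribution (the classic PWM p-value DP).

Scanning covers both strands of the 3 kb window centered on each ROI;
only the best hit per window is kept, ties broken by proximity to the
window center and then by the + strand.  ``N`` bases score zero (the
background expectation) rather than disqualifying a window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MotifModel",
    "Background",
    "MotifHit",
    "read_meme",
    "write_meme",
    "background_from_sequences",
    "pvalue_to_score_threshold",
    "motif_gc",
    "MotifScorer",
    "best_hit",
    "encode",
    "reverse_complement",
]

_BASES = "ACGT"
DEFAULT_PSEUDO_COUNT = 0.1
DEFAULT_GRANULARITY = 1e-3  # bits per quantization step

_ENCODE_TABLE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _ENCODE_TABLE[ord(_b)] = _i
    _ENCODE_TABLE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Background:
    """Zero-order background base frequencies (A, C, G, T), all positive."""

    freqs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.freqs, dtype=float)
        if arr.shape != (4,) or not math.isclose(arr.sum(), 1.0, abs_tol=1e-6):
            raise ValueError("background frequencies must be 4 values summing to 1")
        if np.any(arr <= 0):
            raise ValueError("background frequencies must be > 0")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=float)


UNIFORM_BACKGROUND = Background((0.25, 0.25, 0.25, 0.25))


@dataclass(frozen=True)
class MotifModel:
    """A named base-frequency matrix with a smoothing pseudo-count."""

    name: str
    matrix: np.ndarray  # L x 4 raw frequencies, rows sum to 1
    pseudo_count: float = DEFAULT_PSEUDO_COUNT

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError("motif matrix must be L x 4 with L >= 1")
        if np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-3):
            raise ValueError(f"motif {self.name!r}: rows must sum to 1")
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def smoothed(self, background: Background = UNIFORM_BACKGROUND) -> np.ndarray:
        """Pseudo-count smoothed matrix: (f + c*pi) / (1 + c)."""
        c = self.pseudo_count
        return (self.matrix + c * background.array) / (1.0 + c)

    @property
    def gc_content(self) -> float:
        """Mean per-position probability of C or G on the smoothed matrix."""
        sm = self.smoothed()
        return float(sm[:, 1:3].sum(axis=1).mean())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))


def motif_gc(motif: MotifModel) -> float:
    return motif.gc_content


@dataclass(frozen=True)
class MotifHit:
    """Best-scoring motif match for one window."""

    position: float  # center of the matched span, genomic/window coordinate
    score: float  # log-likelihood ratio, bits
    strand: str  # '+' or '-'


def background_from_sequences(seqs: Iterable[str]) -> Background:
    """Average base frequency over sequences (single strand, N excluded),
    floored with the standard 0.1-pseudo-count smoothing so every
    frequency is positive."""
    counts = np.zeros(4, dtype=float)
    for seq in seqs:
        enc = encode(seq)
        counts += np.bincount(enc[enc < 4], minlength=4)
    total = counts.sum()
    if total == 0:
        raise ValueError("no countable (non-N) bases in input sequences")
    freqs = counts / total
    freqs = (freqs + DEFAULT_PSEUDO_COUNT * 0.25) / (1.0 + DEFAULT_PSEUDO_COUNT)
    return Background(tuple(freqs))


# ---------------------------------------------------------------------------
# MEME minimal format


def read_meme(path: str | Path, pseudo_count: float = DEFAULT_PSEUDO_COUNT) -> list[MotifModel]:
    """Read motifs from a MEME minimal-format file."""
    motifs: list[MotifModel] = []
    name: str | None = None
    rows: list[list[float]] = []
    expect = 0

    def flush() -> None:
        nonlocal name, rows
        if name is not None:
            if len(rows) != expect:
                raise ValueError(
                    f"motif {name!r}: expected {expect} matrix rows, got {len(rows)}"
                )
            motifs.append(MotifModel(name, np.array(rows), pseudo_count))
        name, rows = None, []

    with open(path) as fh:
        lines = iter(fh)
        header = next(lines, "")
        if not header.startswith("MEME version"):
            raise ValueError(f"{path}: not a MEME minimal file")
        in_matrix = False
        for line in lines:
            line = line.strip()
            if line.startswith("MOTIF"):
                flush()
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"{path}: MOTIF line without a name")
                name = parts[1]
                in_matrix = False
            elif line.startswith("letter-probability matrix"):
                fields = dict(
                    zip(line.split()[2::2], line.split()[3::2])
                )
                expect = int(fields.get("w=", 0))
                in_matrix = True
            elif in_matrix and line and line[0] in "0123456789.":
                vals = [float(v) for v in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"{path}: matrix row with {len(vals)} columns")
                if not math.isclose(sum(vals), 1.0, abs_tol=1e-3):
                    raise ValueError(
                        f"{path}: motif {name!r} row sums to {sum(vals):.4f}, not 1"
                    )
                rows.append(vals)
            elif in_matrix and not line:
                in_matrix = False
        flush()
    if not motifs:
        raise ValueError(f"{path}: no motifs found")
    return motifs


def write_meme(
    motifs: Sequence[MotifModel],
    path: str | Path,
    background: Background = UNIFORM_BACKGROUND,
) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(
                f"{b} {f:.5f}" for b, f in zip(_BASES, background.freqs)
            )
            + "\n\n"
        )
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(m)} "
                f"nsites= 20 E= 0\n"
            )
            for row in m.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Exact p-value -> score threshold (PWM DP)


def _quantized_log_odds(
    motif: MotifModel, background: Background, granularity: float
) -> np.ndarray:
    """Integer log-odds matrix (L x 5), in units of `granularity` bits;
    column 4 (N) scores 0."""
    sm = motif.smoothed(background)
    lo = np.log2(sm / background.array) / granularity
    q = np.rint(lo).astype(np.int64)
    return np.hstack([q, np.zeros((len(motif), 1), dtype=np.int64)])


def _score_distribution(
    q: np.ndarray, background: Background
) -> tuple[np.ndarray, int]:
    """Exact distribution of the total integer score of a random i.i.d.
    background sequence.  Returns (probabilities, offset) where index i
    holds P(S = i + offset)."""
    pi = background.array
    dist = np.ones(1)
    offset = 0
    for row in q[:, :4]:
        lo, hi = int(row.min()), int(row.max())
        # the per-position distribution has <= 4 support points, so the
        # convolution is 4 shifted adds rather than a dense product
        new = np.zeros(len(dist) + hi - lo)
        for b in range(4):
            shift = int(row[b]) - lo
            new[shift : shift + len(dist)] += pi[b] * dist
        dist = new
        offset += lo
    return dist, offset


def pvalue_to_score_threshold(
    motif: MotifModel,
    background: Background = UNIFORM_BACKGROUND,
    p: float = 1e-6,
    granularity: float = DEFAULT_GRANULARITY,
) -> float:
    """Smallest score s (bits) with P(score >= s | background) <= p.

    Computed exactly on the quantized score scale shared with the scanner.
    Returns +inf when even the maximum score is more probable than p
    (the motif can never match at that stringency).
    """
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    q = _quantized_log_odds(motif, background, granularity)
    dist, offset = _score_distribution(q, background)
    tail = np.cumsum(dist[::-1])[::-1]  # tail[i] = P(S >= i + offset)
    # smallest attained score whose tail probability is <= p (scores between
    # support points admit the same match set)
    passing = np.nonzero((tail <= p) & (dist > 0))[0]
    if len(passing) == 0:
        return math.inf
    return float((passing[0] + offset) * granularity)


# ---------------------------------------------------------------------------
# Scanning


class MotifScorer:
    """Quantized log-odds scanner for one motif against one background.

    The same integer score matrix is used for the p-value DP and for
    sequence scoring, so thresholding is exact by construction.
    """

    def __init__(
        self,
        motif: MotifModel,
        background: Background = UNIFORM_BACKGROUND,
        pvalue: float | None = 1e-6,
        score_threshold: float | None = None,
        granularity: float = DEFAULT_GRANULARITY,
    ) -> None:
        self.motif = motif
        self.background = background
        self.granularity = granularity
        self.q_plus = _quantized_log_odds(motif, background, granularity)
        # reverse complement: reverse positions, swap A<->T / C<->G
        L = len(motif)
        q_rc = np.zeros_like(self.q_plus)
        q_rc[:, :4] = self.q_plus[::-1, [3, 2, 1, 0]]
        self.q_minus = q_rc
        if score_threshold is not None:
            self.threshold_q: float = math.ceil(score_threshold / granularity)
        elif pvalue is not None:
            t = pvalue_to_score_threshold(motif, background, pvalue, granularity)
            self.threshold_q = math.inf if math.isinf(t) else round(t / granularity)
        else:
            raise ValueError("either pvalue or score_threshold is required")

    def _strand_scores(self, enc: np.ndarray, q: np.ndarray) -> np.ndarray:
        """Total integer score at every offset; enc is (n, W) int8."""
        L = len(self.motif)
        n, W = enc.shape
        n_pos = W - L + 1
        if n_pos <= 0:
            return np.zeros((n, 0), dtype=np.int32)
        scores = np.zeros((n, n_pos), dtype=np.int32)
        q32 = q.astype(np.int32)
        for l in range(L):
            scores += q32[l][enc[:, l : l + n_pos]]
        return scores

    def scan_batch(
        self, enc: np.ndarray
    ) -> list[MotifHit | None]:
        """Best hit per row of an encoded sequence matrix.

        Hit positions are reported as the center of the matched span in
        window coordinates (offset + L/2 from the window start).  Ties on
        score are broken by distance from the window center, then by
        strand (+ preferred).
        """
        if enc.ndim == 1:
            enc = enc[None, :]
        n, W = enc.shape
        L = len(self.motif)
        hits: list[MotifHit | None] = [None] * n
        if math.isinf(self.threshold_q) or W < L:
            return hits
        center = W / 2
        rows_all, cols_all, scores_all, strands_all = [], [], [], []
        for strand_idx, q in enumerate((self.q_plus, self.q_minus)):
            s = self._strand_scores(enc, q)
            r, c = np.nonzero(s >= self.threshold_q)
            if len(r):
                rows_all.append(r)
                cols_all.append(c)
                scores_all.append(s[r, c])
                strands_all.append(np.full(len(r), strand_idx, dtype=np.int8))
        if not rows_all:
            return hits
        rows = np.concatenate(rows_all)
        cols = np.concatenate(cols_all)
        scores = np.concatenate(scores_all)
        strands = np.concatenate(strands_all)
        pos = cols + L / 2
        dist = np.abs(pos - center)
        order = np.lexsort((strands, dist, -scores, rows))
        rows_sorted = rows[order]
        first = np.unique(rows_sorted, return_index=True)[1]
        for idx in order[first]:
            hits[rows[idx]] = MotifHit(
                position=float(pos[idx]),
                score=float(scores[idx] * self.granularity),
                strand="+-"[strands[idx]],
            )
        return hits


def best_hit(
    window: str,
    motif: MotifModel,
    background: Background = UNIFORM_BACKGROUND,
    pvalue: float | None = 1e-6,
    score_threshold: float | None = None,
    mu_hat: float | None = None,
    granularity: float = DEFAULT_GRANULARITY,
) -> MotifHit | None:
    """Best motif match in one window (both strands, threshold applied).

    If ``mu_hat`` is given, the hit position is translated to the genomic
    coordinate assuming the window is centered on ``mu_hat``; otherwise it
    stays in window coordinates.
    """
    scorer = MotifScorer(motif, background, pvalue, score_threshold, granularity)
    hit = scorer.scan_batch(encode(window))[0]
    if hit is not None and mu_hat is not None:
        hit = MotifHit(
            position=mu_hat - len(window) / 2 + hit.position,
            score=hit.score,
            strand=hit.strand,
        )
    return hit
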