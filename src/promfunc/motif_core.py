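"""Position weight matrices and locally-conditioned log-odds scanning.

A PWM models a transcription factor's binding preference as per-position
nucleotide frequencies over a fixed width W.  Candidate windows are scored
as summed log2 likelihood ratios against a *local* background: the
nucleotide composition of a window (default 100 bp) centered on the
candidate site, so that scores are comparable between GC-rich promoters
and AT-rich genomic background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Abundance floor applied to local background frequencies after smoothing.
BACKGROUND_FLOOR = 1e-3

#: Sentinel for windows that cannot be scored (ambiguity codes present).
NEG_INF = float("-inf")


class InvalidMatrixError(ValueError):
    """Raised when a count matrix cannot be normalized into a PWM."""


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as integer codes A=0,C=1,G=2,T=3; anything else 4."""
    out = np.full(len(seq), 4, dtype=np.int8)
    su = seq.upper()
    for base, code in BASE_INDEX.items():
        out[np.frombuffer(su.encode(), dtype=np.uint8) == ord(base)] = code
    return out


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: W x 4 counts (columns A, C, G, T).

    Frequencies are derived as ``(count + pseudocount) /
    (rowsum + 4 * pseudocount)`` per position.
    """

    name: str
    counts: np.ndarray
    pseudocount: float = 0.0
    frequencies: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] < 1:
            raise InvalidMatrixError(f"counts must be W x 4 with W >= 1, got {counts.shape}")
        if np.any(counts < 0):
            raise InvalidMatrixError("negative counts")
        if self.pseudocount < 0:
            raise InvalidMatrixError("pseudocount must be >= 0")
        rowsum = counts.sum(axis=1)
        if self.pseudocount == 0 and np.any(rowsum == 0):
            raise InvalidMatrixError("all-zero row with pseudocount 0")
        freqs = (counts + self.pseudocount) / (rowsum + 4 * self.pseudocount)[:, None]
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "frequencies", freqs)

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.frequencies.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.counts[::-1, ::-1], self.pseudocount)


@dataclass(frozen=True)
class LocalBackground:
    """Nucleotide abundances estimated from a local window."""

    abundances: np.ndarray
    window_bp: int = 100

    def __post_init__(self):
        ab = np.asarray(self.abundances, dtype=float)
        if ab.shape != (4,) or np.any(ab < 0):
            raise ValueError("abundances must be 4 non-negative reals")
        ab = np.maximum(ab / ab.sum(), BACKGROUND_FLOOR)
        object.__setattr__(self, "abundances", ab / ab.sum())


UNIFORM_BACKGROUND = LocalBackground(np.full(4, 0.25))


@dataclass(frozen=True)
class ScoredSite:
    """A scored motif match: half-open interval [start, end), log-odds in bits."""

    chrom: str
    start: int
    end: int
    strand: str
    score: float
    tf: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def build_pwm(counts, pseudocount: float = 0.0, name: str = "pwm") -> PWM:
    """Construct a PWM from a count (or frequency) matrix.

    Raises :class:`InvalidMatrixError` for negative counts or an all-zero
    row with ``pseudocount == 0``.
    """
    return PWM(name=name, counts=np.asarray(counts, dtype=float), pseudocount=pseudocount)


def information_content(pwm: PWM) -> np.ndarray:
    """Per-position information content in bits against a uniform background.

    ``IC_j = 2 + sum_b f_jb * log2 f_jb`` with the convention 0*log(0) = 0;
    each value lies in [0, 2].
    """
    f = pwm.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
    return 2.0 + plogp.sum(axis=1)


def log_odds_score(pwm: PWM, window: str, bg: LocalBackground = UNIFORM_BACKGROUND) -> float:
    """Log2 likelihood-ratio score of one window of length W.

    Windows containing any non-ACGT character score ``-inf`` (excluded from
    best-site selection downstream).
    """
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != PWM width {pwm.width}")
    codes = encode(window)
    if np.any(codes == 4):
        return NEG_INF
    f = pwm.frequencies[np.arange(pwm.width), codes]
    q = bg.abundances[codes]
    with np.errstate(divide="ignore"):
        return float(np.log2(f / q).sum())


def _local_background_freqs(codes: np.ndarray, width: int, bg_window: int) -> np.ndarray:
    """Per-start-position local background frequencies, shape (L-W+1, 4).

    The background window is ``bg_window`` bp centered on each candidate
    window, clipped at the sequence ends.  Non-ACGT bases are ignored in the
    composition.  Frequencies are floored at BACKGROUND_FLOOR and renormalized.
    """
    L = len(codes)
    n = L - width + 1
    onehot = np.zeros((L + 1, 4))
    valid = codes < 4
    onehot[1:][valid, codes[valid]] = 1.0
    cum = np.cumsum(onehot, axis=0)

    starts = np.arange(n)
    centers = starts + width / 2.0
    lo = np.clip(np.floor(centers - bg_window / 2.0).astype(int), 0, L)
    hi = np.clip(np.ceil(centers + bg_window / 2.0).astype(int), 0, L)
    counts = cum[hi] - cum[lo]
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, 0.25)
    freqs = np.maximum(freqs, BACKGROUND_FLOOR)
    return freqs / freqs.sum(axis=1, keepdims=True)


def _scan_one_strand(pwm: PWM, codes: np.ndarray, bg_window: int) -> np.ndarray:
    """Scores for every start position on the given (already oriented) strand."""
    W = pwm.width
    n = len(codes) - W + 1
    with np.errstate(divide="ignore"):
        logf = np.log2(pwm.frequencies)
    scores = np.zeros(n)
    bad = np.zeros(n, dtype=bool)
    qfreqs = _local_background_freqs(codes, W, bg_window)
    logq = np.log2(qfreqs)
    for j in range(W):
        cj = codes[j : j + n]
        ok = cj < 4
        bad |= ~ok
        cj_safe = np.where(ok, cj, 0)
        scores += logf[j, cj_safe] - logq[np.arange(n), cj_safe]
    scores[bad] = NEG_INF
    return scores


def scan(
    pwm: PWM,
    seq: str,
    both_strands: bool = True,
    threshold: float = NEG_INF,
    bg_window: int = 100,
    chrom: str = "seq",
) -> list[ScoredSite]:
    """Scan a sequence for motif matches scoring at least ``threshold`` bits.

    Minus-strand hits are scored by scanning the reverse complement, so
    scanning the reverse complement of a sequence yields the same multiset
    of scores with strands flipped.  Sites are returned sorted by position,
    plus strand first at equal positions.
    """
    W = pwm.width
    L = len(seq)
    if L < W:
        warnings.warn(f"sequence length {L} shorter than PWM width {W}; no sites")
        return []
    codes = encode(seq)
    sites: list[ScoredSite] = []
    plus = _scan_one_strand(pwm, codes, bg_window)
    for i in np.nonzero(plus >= threshold)[0]:
        sites.append(ScoredSite(chrom, int(i), int(i) + W, "+", float(plus[i]), pwm.name))
    if both_strands:
        minus = _scan_one_strand(pwm, encode(reverse_complement(seq)), bg_window)
        for k in np.nonzero(minus >= threshold)[0]:
            start = L - W - int(k)
            sites.append(ScoredSite(chrom, start, start + W, "-", float(minus[k]), pwm.name))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def sample_site(pwm: PWM, rng: np.random.Generator) -> str:
    """Draw one site sequence from the PWM's observed base frequencies.

    Emission uses the raw counts, not the pseudocount-smoothed scoring
    frequencies: the pseudocount regularizes scoring of unseen bases and is
    not part of the motif's emission model, so a near-deterministic matrix
    emits its consensus.
    """
    out = []
    for j in range(pwm.width):
        row = pwm.counts[j]
        p = row / row.sum() if row.sum() > 0 else pwm.frequencies[j]
        out.append(BASES[rng.choice(4, p=p)])
    return "".join(out)
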