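"""From ChIP-seq peak regions to a filtered binding-site prediction set.

Peaks are inputs (called elsewhere, e.g. by MACS); this module samples
length-matched unbound background sequence, scores the best motif match in
each region on both strands, ranks candidate PWMs by ROC AUC against the
background, and applies the score / peak-quality filters used to nominate
sites for mutagenesis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .motif_core import PWM, ScoredSite, scan


@dataclass(frozen=True)
class PeakRegion:
    """A ChIP-seq peak: half-open [start, end), summit offset from start,
    and the peak-caller's reported false discovery rate."""

    chrom: str
    start: int
    end: int
    summit: int
    peak_fdr: float

    def __post_init__(self):
        if not 0 <= self.summit < self.end - self.start:
            raise ValueError("summit offset outside peak")
        if not 0.0 <= self.peak_fdr <= 1.0:
            raise ValueError("peak_fdr must lie in [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, site: ScoredSite) -> bool:
        return (
            site.chrom == self.chrom and site.start >= self.start and site.end <= self.end
        )


@dataclass(frozen=True)
class PwmEvaluation:
    pwm_name: str
    auc: float
    n_peaks: int
    n_background: int


class BackgroundSamplingError(RuntimeError):
    """Not enough unbound sequence to host all length-matched samples."""


def _merge_intervals(intervals):
    out = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1][1] = max(out[-1][1], end)
        else:
            out.append([start, end])
    return out


def sample_background(
    peaks: list[PeakRegion],
    genome: dict[str, str],
    excluded: list[tuple[str, int, int]] | None = None,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 1000,
) -> list[tuple[str, int, int]]:
    """Draw one length-matched unbound interval per peak, uniformly at random.

    Samples avoid the peaks themselves, any ``excluded`` intervals and each
    other (sampling without replacement across peaks).  Reproducible under
    ``seed``.  Raises :class:`BackgroundSamplingError` listing the lengths
    that could not be placed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    forbidden: dict[str, list] = {c: [] for c in genome}
    for p in peaks:
        forbidden.setdefault(p.chrom, []).append([p.start, p.end])
    for chrom, start, end in excluded or []:
        forbidden.setdefault(chrom, []).append([start, end])

    chroms = list(genome)
    weights = np.array([len(genome[c]) for c in chroms], dtype=float)
    samples: list[tuple[str, int, int]] = []
    failed: list[int] = []
    for peak in peaks:
        length = peak.length
        placed = False
        for _ in range(max_attempts):
            chrom = chroms[rng.choice(len(chroms), p=weights / weights.sum())]
            limit = len(genome[chrom]) - length
            if limit < 0:
                continue
            start = int(rng.integers(0, limit + 1))
            end = start + length
            merged = _merge_intervals(forbidden.get(chrom, []))
            if any(start < e and end > s for s, e in merged):
                continue
            forbidden.setdefault(chrom, []).append([start, end])
            samples.append((chrom, start, end))
            placed = True
            break
        if not placed:
            failed.append(length)
    if failed:
        raise BackgroundSamplingError(
            f"could not place {len(failed)} length-matched background samples "
            f"(lengths: {sorted(set(failed))})"
        )
    return samples


def best_site_per_region(
    pwm: PWM, region_seq: str, bg_window: int = 100, chrom: str = "region", offset: int = 0
) -> ScoredSite:
    """The single highest-scoring window over both strands of a region.

    Ties break leftmost, plus strand first.  ``offset`` shifts the reported
    coordinates (e.g. the region's genomic start).
    """
    if len(region_seq) < pwm.width:
        raise ValueError(
            f"region length {len(region_seq)} < PWM width {pwm.width}"
        )
    sites = scan(pwm, region_seq, both_strands=True, bg_window=bg_window, chrom=chrom)
    best = min(sites, key=lambda s: (-s.score, s.start, s.strand))
    if offset:
        best = ScoredSite(
            best.chrom, best.start + offset, best.end + offset, best.strand, best.score, best.tf
        )
    return best


def compute_auc(fg_scores, bg_scores) -> float:
    """ROC AUC via the Mann-Whitney U identity, ties counted 1/2.

    Equals the probability that a random foreground score exceeds a random
    background score, + half the probability of a tie.
    """
    fg = np.asarray(fg_scores, dtype=float)
    bg = np.asarray(bg_scores, dtype=float)
    if fg.size == 0 or bg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([fg, bg]))
    u = ranks[: fg.size].sum() - fg.size * (fg.size + 1) / 2.0
    return float(u / (fg.size * bg.size))


def select_pwm(
    candidates: list[PWM],
    peak_seqs: list[str],
    background_seqs: list[str],
    bg_window: int = 100,
) -> list[PwmEvaluation]:
    """Evaluate each candidate PWM by its ability to discriminate peaks from
    matched background (best-site score per region, AUC); stable sort by
    descending AUC."""
    if not candidates:
        raise ValueError("need at least one candidate PWM")
    evals = []
    for pwm in candidates:
        fg = [best_site_per_region(pwm, s, bg_window).score for s in peak_seqs]
        bg = [best_site_per_region(pwm, s, bg_window).score for s in background_seqs]
        evals.append(PwmEvaluation(pwm.name, compute_auc(fg, bg), len(fg), len(bg)))
    return sorted(evals, key=lambda e: -e.auc)


def evaluations_to_tsv(evals: list[PwmEvaluation], path) -> None:
    pd.DataFrame(
        [(e.pwm_name, e.auc, e.n_peaks, e.n_background) for e in evals],
        columns=["pwm", "auc", "n_fg", "n_bg"],
    ).to_csv(path, sep="\t", index=False)


def filter_predictions(
    sites: list[ScoredSite],
    peaks: list[PeakRegion],
    min_lr: float = 10.0,
    max_peak_fdr: float = 0.05,
) -> list[ScoredSite]:
    """Keep sites whose likelihood ratio vs background is >= ``min_lr``
    (log-odds >= log2(min_lr) bits) and whose peak FDR is strictly below
    ``max_peak_fdr``.  Each site must lie inside exactly one supplied peak."""
    min_bits = math.log2(min_lr)
    kept = []
    for site in sites:
        matches = [p for p in peaks if p.contains(site)]
        if not matches:
            raise ValueError(f"site {site.chrom}:{site.start}-{site.end} not inside any peak")
        peak = matches[0]
        if site.score >= min_bits and peak.peak_fdr < max_peak_fdr:
            kept.append(site)
    return kept


def summit_offsets(sites: list[ScoredSite], peaks: list[PeakRegion]) -> np.ndarray:
    """Signed offsets: site midpoint minus summit position, one per site.

    On average predicted sites should center on ChIP summits; the mean of
    this vector is the diagnostic of interest.
    """
    offsets = []
    for site, peak in zip(sites, peaks, strict=True):
        offsets.append(site.midpoint - (peak.start + peak.summit))
    return np.asarray(offsets)
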