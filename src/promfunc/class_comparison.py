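"""Comparisons between functional classes of binding sites.

Functionally verified sites are contrasted with unverified ones (and
activating with repressing) by evolutionary conservation, distance to the
transcription start site, per-position motif information content
(permutation test), homotypic site clustering, secondary-motif enrichment
and normalized CpG content of the host promoter.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .motif_core import PWM, ScoredSite, build_pwm, information_content, scan


@dataclass(frozen=True)
class PromoterAnnotation:
    """A cloned promoter fragment with its conservation track.

    Coordinates (``tss``, ``translational_start``) are in fragment-local
    space, matching ``sequence``.  ``strand`` is the transcript strand of
    the fragment in the genome; site/TSS distances are reported in
    transcript orientation (downstream positive).
    """

    promoter_id: str
    chrom: str
    strand: str
    tss: int
    translational_start: int
    sequence: str
    conservation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "conservation", np.asarray(self.conservation, dtype=float))
        if len(self.sequence) != len(self.conservation):
            raise ValueError("sequence and conservation track lengths differ")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class SiteConservation:
    """One site's contribution to a conservation summary."""

    mean: float
    profile: np.ndarray  # oriented to motif strand, length = width + 2*flank


@dataclass(frozen=True)
class DistanceDistribution:
    """Signed TSS distances (downstream positive) and their cumulative law.

    ``cumulative(M)`` is the probability of finding a site within |M| bp of
    the TSS, i.e. the empirical CDF of |distance| evaluated at M.
    """

    distances: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "distances", np.asarray(self.distances))

    def cumulative(self, m) -> np.ndarray | float:
        sorted_abs = np.sort(np.abs(self.distances))
        res = np.searchsorted(sorted_abs, np.asarray(m), side="right") / len(sorted_abs)
        return float(res) if np.isscalar(m) else res


def site_conservation(site: ScoredSite, ann: PromoterAnnotation, flank: int = 0) -> SiteConservation:
    """Mean conservation over the site's bases, plus a per-position profile.

    The profile covers ``flank`` bases either side (clipped at the fragment
    ends) and is reversed for minus-strand sites so position 1 is always the
    motif's 5' end.
    """
    L = len(ann.sequence)
    if site.start < 0 or site.end > L:
        raise ValueError(
            f"site {site.start}-{site.end} outside annotated sequence of length {L}"
        )
    core = ann.conservation[site.start : site.end]
    lo = max(0, site.start - flank)
    hi = min(L, site.end + flank)
    profile = ann.conservation[lo:hi]
    if site.strand == "-":
        profile = profile[::-1]
    return SiteConservation(mean=float(core.mean()), profile=profile.copy())


def conservation_summary(contribs: list[SiteConservation]) -> dict:
    """Aggregate equal-length per-site profiles: mean and standard error."""
    profiles = np.vstack([c.profile for c in contribs])
    return {
        "per_site_means": np.array([c.mean for c in contribs]),
        "profile_mean": profiles.mean(axis=0),
        "profile_sem": profiles.std(axis=0, ddof=1) / math.sqrt(len(contribs)),
        "n_sites": len(contribs),
    }


def compare_distributions(a, b, method: str = "KS") -> tuple[float, float]:
    """Two-sided comparison of two samples.

    ``method='KS'``: Kolmogorov-Smirnov, D = sup |ECDF difference|, exact
    small-sample null where feasible.  ``method='wilcoxon'``: Wilcoxon rank
    sum (Mann-Whitney), exact for small tie-free samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs at least 3 observations")
    if method.upper() == "KS":
        res = stats.ks_2samp(a, b, alternative="two-sided", method="auto")
        return float(res.statistic), float(res.pvalue)
    if method.lower() == "wilcoxon":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


def tss_distance(site: ScoredSite, ann: PromoterAnnotation) -> float:
    """Signed site-to-TSS distance in transcript orientation (downstream > 0)."""
    d = site.midpoint - ann.tss
    return float(d if ann.strand == "+" else -d)


def tss_distance_distribution(
    sites: list[ScoredSite],
    annotations: dict[str, PromoterAnnotation],
) -> DistanceDistribution:
    """Distances of sites to their promoters' TSS; sites map by chrom =
    promoter id.  Unmapped sites are an error."""
    distances = []
    for site in sites:
        if site.chrom not in annotations:
            raise ValueError(f"site on {site.chrom!r} has no promoter annotation")
        distances.append(tss_distance(site, annotations[site.chrom]))
    return DistanceDistribution(np.asarray(distances))


def _ic_at(seqs: list[str], position: int, pseudocount: float = 0.5) -> float:
    counts = np.zeros((1, 4))
    for s in seqs:
        base = s[position].upper()
        if base in "ACGT":
            counts[0, "ACGT".index(base)] += 1
    pwm = build_pwm(counts, pseudocount=pseudocount)
    return float(information_content(pwm)[0])


def position_ic_permutation_test(
    sites_a: list[str],
    sites_b: list[str],
    position: int,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Permutation test for excess information content in group B at one
    motif position.

    Observed statistic: ``dIC = IC_B(position) - IC_A(position)`` with
    per-group frequency matrices built at pseudocount 0.5.  The null is
    built by shuffling group labels; the one-sided p-value is
    ``(1 + #{dIC_perm >= dIC_obs}) / (n_perm + 1)``.  For groups smaller
    than 5 a warning is issued and exact enumeration over label
    assignments is used when feasible.
    """
    widths = {len(s) for s in sites_a + sites_b}
    if len(widths) != 1:
        raise ValueError("all site sequences must have the same width")
    if position >= widths.pop():
        raise ValueError("position beyond motif width")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    na, nb = len(sites_a), len(sites_b)
    pooled = list(sites_a) + list(sites_b)
    obs = _ic_at(sites_b, position) - _ic_at(sites_a, position)

    exact = False
    if min(na, nb) < 5:
        warnings.warn("group size < 5; using exact enumeration where feasible")
        exact = math.comb(na + nb, na) <= 100_000

    if exact:
        null = []
        for idx_a in itertools.combinations(range(na + nb), na):
            mask = np.zeros(na + nb, dtype=bool)
            mask[list(idx_a)] = True
            perm_a = [pooled[i] for i in range(na + nb) if mask[i]]
            perm_b = [pooled[i] for i in range(na + nb) if not mask[i]]
            null.append(_ic_at(perm_b, position) - _ic_at(perm_a, position))
        null = np.asarray(null)
        p = float((null >= obs - 1e-12).sum() / null.size)
        return obs, p

    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(na + nb)
        perm_a = [pooled[i] for i in perm[:na]]
        perm_b = [pooled[i] for i in perm[na:]]
        if _ic_at(perm_b, position) - _ic_at(perm_a, position) >= obs - 1e-12:
            count += 1
    return obs, (1 + count) / (n_perm + 1)


def homotypic_count(
    ann: PromoterAnnotation, pwm: PWM, threshold: float, bg_window: int = 100
) -> int:
    """Number of non-overlapping motif instances at or above the prediction
    threshold on the promoter (both strands, overlaps resolved best-first)."""
    hits = scan(pwm, ann.sequence, both_strands=True, threshold=threshold,
                bg_window=bg_window, chrom=ann.promoter_id)
    kept: list[ScoredSite] = []
    for hit in sorted(hits, key=lambda s: (-s.score, s.start, s.strand)):
        if all(hit.end <= k.start or hit.start >= k.end for k in kept):
            kept.append(hit)
    return len(kept)


def secondary_motif_enrichment(
    promoters_func: list[str],
    promoters_nonfunc: list[str],
    motif: PWM,
    threshold: float,
    bg_window: int = 100,
) -> tuple[float, float]:
    """Fisher exact test for overrepresentation of a secondary motif on
    promoters with functional sites versus promoters with unverified sites.

    Presence = at least one scan hit at or above ``threshold``.  One-sided
    (greater); a p-value near 1 indicates underrepresentation.  Returns
    ``(odds_ratio, p)``.
    """
    if len(promoters_func) == 0 or len(promoters_nonfunc) == 0:
        raise ValueError("both promoter classes must be non-empty")
    if min(len(promoters_func), len(promoters_nonfunc)) < 5:
        warnings.warn("fewer than 5 promoters in a class; Fisher p may be unstable")

    def present(seq: str) -> bool:
        return any(
            s.score >= threshold
            for s in scan(motif, seq, both_strands=True, threshold=threshold,
                          bg_window=bg_window)
        )

    a = sum(present(s) for s in promoters_func)
    b = len(promoters_func) - a
    c = sum(present(s) for s in promoters_nonfunc)
    d = len(promoters_nonfunc) - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)


def normalized_cpg(seq: str) -> float:
    """Observed/expected CpG: (#CG / (L-1)) / ((#C/L) * (#G/L)).

    High-CpG promoters (island-like) score near or above 1; the measure is
    invariant under reverse complement.  Requires at least one C and one G.
    """
    seq = seq.upper()
    L = len(seq)
    if L < 2:
        raise ValueError("sequence too short")
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c == 0 or n_g == 0:
        raise ValueError("normalized CpG undefined without both C and G")
    n_cg = sum(1 for i in range(L - 1) if seq[i : i + 2] == "CG")
    return (n_cg / (L - 1)) / ((n_c / L) * (n_g / L))
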