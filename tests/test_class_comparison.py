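"""Conservation, TSS distances, IC permutation test, clusters, enrichment, CpG."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from promfunc import (
    PromoterAnnotation,
    ScoredSite,
    build_pwm,
    compare_distributions,
    homotypic_count,
    normalized_cpg,
    position_ic_permutation_test,
    secondary_motif_enrichment,
    site_conservation,
    tss_distance_distribution,
)
from promfunc.class_comparison import tss_distance

from conftest import random_sequence


def make_ann(seq, strand="+", tss=None, ts=None, conservation=None):
    L = len(seq)
    return PromoterAnnotation(
        "p1", "p1", strand,
        tss if tss is not None else L // 2,
        ts if ts is not None else L // 2 + 10,
        seq,
        conservation if conservation is not None else np.zeros(L),
    )


class TestSiteConservation:
    def test_constant_track(self):
        ann = make_ann("A" * 50, conservation=np.full(50, 3.7))
        sc = site_conservation(ScoredSite("p1", 10, 22, "+", 1.0, "tf"), ann)
        assert sc.mean == pytest.approx(3.7)

    def test_arithmetic_oracle(self):
        ann = make_ann("ACGTACGTAC", conservation=np.arange(1.0, 11.0))
        sc = site_conservation(ScoredSite("p1", 2, 6, "+", 1.0, "tf"), ann)
        assert sc.mean == pytest.approx((3 + 4 + 5 + 6) / 4)

    def test_minus_strand_profile_reversed(self):
        ann = make_ann("ACGTACGTAC", conservation=np.arange(1.0, 11.0))
        plus = site_conservation(ScoredSite("p1", 2, 6, "+", 1.0, "tf"), ann, flank=2)
        minus = site_conservation(ScoredSite("p1", 2, 6, "-", 1.0, "tf"), ann, flank=2)
        assert minus.profile.tolist() == plus.profile[::-1].tolist()
        assert minus.mean == plus.mean

    def test_outside_sequence_errors(self):
        ann = make_ann("ACGT" * 5)
        with pytest.raises(ValueError):
            site_conservation(ScoredSite("p1", 15, 25, "+", 1.0, "tf"), ann)


class TestCompareDistributions:
    def test_identical_samples_ks(self):
        a = [1.0, 2.0, 3.0, 4.0]
        d, p = compare_distributions(a, a, "KS")
        assert d == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = compare_distributions(np.arange(10), np.arange(100, 110), "KS")
        assert d == pytest.approx(1.0)

    def test_undersized_sample_errors(self):
        with pytest.raises(ValueError):
            compare_distributions([1, 2], [1, 2, 3], "KS")

    def test_exact_enumeration_oracle_n5(self):
        """KS D and p match full enumeration over all C(10,5) label splits
        of the pooled sample (tie-free toy vectors)."""
        a = np.array([0.3, 1.1, 2.2, 3.5, 4.1])
        b = np.array([0.9, 1.8, 2.9, 5.2, 6.3])
        d_obs, p_obs = compare_distributions(a, b, "KS")

        def ks_stat(x, y):
            allv = np.sort(np.concatenate([x, y]))
            fx = np.searchsorted(np.sort(x), allv, side="right") / len(x)
            fy = np.searchsorted(np.sort(y), allv, side="right") / len(y)
            return np.abs(fx - fy).max()

        pooled = np.concatenate([a, b])
        assert d_obs == pytest.approx(ks_stat(a, b))
        count = 0
        total = 0
        for idx in itertools.combinations(range(10), 5):
            mask = np.zeros(10, dtype=bool)
            mask[list(idx)] = True
            if ks_stat(pooled[mask], pooled[~mask]) >= d_obs - 1e-12:
                count += 1
            total += 1
        assert p_obs == pytest.approx(count / total)

    def test_wilcoxon_exact_enumeration_oracle_n5(self):
        a = np.array([0.3, 1.1, 2.2, 3.5, 4.1])
        b = np.array([0.9, 1.8, 2.9, 5.2, 6.3])
        u_obs, p_obs = compare_distributions(a, b, "wilcoxon")
        pooled = np.concatenate([a, b])

        def u_stat(x, y):
            return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)

        assert u_obs == pytest.approx(u_stat(a, b))
        null = []
        for idx in itertools.combinations(range(10), 5):
            mask = np.zeros(10, dtype=bool)
            mask[list(idx)] = True
            null.append(u_stat(pooled[mask], pooled[~mask]))
        null = np.array(null)
        lo = (null <= u_obs + 1e-12).mean()
        hi = (null >= u_obs - 1e-12).mean()
        assert p_obs == pytest.approx(min(1.0, 2 * min(lo, hi)))

    def test_ks_monotone_transform_invariance(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(1, 1, size=15)
        d1, p1 = compare_distributions(a, b, "KS")
        d2, p2 = compare_distributions(np.exp(a), np.exp(b), "KS")
        assert (d1, p1) == pytest.approx((d2, p2))


class TestTssDistances:
    def test_site_centered_on_tss(self):
        ann = make_ann("A" * 100, tss=50)
        site = ScoredSite("p1", 44, 56, "+", 1.0, "tf")
        assert tss_distance(site, ann) == 0.0

    def test_minus_strand_orientation(self):
        """Site 50 bp genomically left of a minus-strand TSS lies downstream:
        distance +50."""
        ann = make_ann("A" * 200, strand="-", tss=150)
        site = ScoredSite("p1", 94, 106, "+", 1.0, "tf")  # midpoint 100
        assert tss_distance(site, ann) == 50.0

    def test_cumulative_counting_oracle(self):
        ann = make_ann("A" * 400, tss=200)
        mids = [200, 190, 210, 100, 300]  # distances 0, -10, +10, -100, +100
        sites = [ScoredSite("p1", m - 5, m + 5, "+", 1.0, "tf") for m in mids]
        dist = tss_distance_distribution(sites, {"p1": ann})
        assert sorted(dist.distances) == [-100, -10, 0, 10, 100]
        assert dist.cumulative(10) == pytest.approx(0.6)
        assert dist.cumulative(1000) == pytest.approx(1.0)
        ms = np.array([0, 5, 10, 50, 100, 500])
        cum = dist.cumulative(ms)
        assert np.all(np.diff(cum) >= 0)

    def test_unmapped_site_errors(self):
        site = ScoredSite("missing", 0, 10, "+", 1.0, "tf")
        with pytest.raises(ValueError):
            tss_distance_distribution([site], {})


class TestPositionIcPermutation:
    def test_null_case_not_significant(self, rng):
        seqs = [random_sequence(rng, 6) for _ in range(12)]
        _, p = position_ic_permutation_test(seqs, list(seqs), 2, n_perm=499, seed=3)
        assert p > 0.05

    def test_planted_g_preference_detected(self, rng):
        """Group B (n=16) all carrying G at the position vs a uniform group A
        (n=9): one-sided p <= 0.01 at n_perm = 9999."""
        a = [random_sequence(rng, 6) for _ in range(9)]
        b = [s[:3] + "G" + s[4:] for s in (random_sequence(rng, 6) for _ in range(16))]
        d, p = position_ic_permutation_test(a, b, 3, n_perm=9999, seed=5)
        assert d > 0
        assert p <= 0.01

    def test_exact_enumeration_on_tiny_groups(self):
        a = ["AAAA", "ACAA", "AAGA"]
        b = ["GGGG", "GGGG", "GGCG", "GGGT"]
        with pytest.warns(UserWarning):
            d_obs, p = position_ic_permutation_test(a, b, 0, seed=0)
        # independent enumeration oracle
        from promfunc.class_comparison import _ic_at

        pooled = a + b
        null = []
        for idx in itertools.combinations(range(7), 3):
            ga = [pooled[i] for i in idx]
            gb = [pooled[i] for i in range(7) if i not in idx]
            null.append(_ic_at(gb, 0) - _ic_at(ga, 0))
        expected = np.mean(np.array(null) >= d_obs - 1e-12)
        assert p == pytest.approx(expected)


class TestHomotypicCount:
    def _pwm(self):
        return build_pwm(
            [[97, 1, 1, 1]] * 2 + [[1, 97, 1, 1]] * 2 + [[1, 1, 97, 1]] * 2
            + [[1, 1, 1, 97]] * 2,
            pseudocount=0.5, name="AACCGGTT",
        )

    def test_no_sites_above_threshold(self, rng):
        pwm = self._pwm()
        ann = make_ann("T" * 100 + "A" * 100)
        assert homotypic_count(ann, pwm, threshold=10.0) == 0

    def test_three_planted_instances(self, rng):
        pwm = self._pwm()
        filler = random_sequence(rng, 60)
        seq = filler + "AACCGGTT" + filler + "AACCGGTT" + filler + "AACCGGTT" + filler
        ann = make_ann(seq)
        assert homotypic_count(ann, pwm, threshold=10.0) == 3

    def test_overlapping_hits_collapse_to_best(self):
        pwm = build_pwm([[97, 1, 1, 1]] * 4, pseudocount=0.5, name="AAAA")
        ann = make_ann("TTTTTTAAAAATTTTTT")  # AAAAA hosts two overlapping AAAA hits
        assert homotypic_count(ann, pwm, threshold=4.0) == 1


class TestSecondaryMotifEnrichment:
    def _pwm(self):
        return build_pwm([[97, 1, 1, 1]] * 3 + [[1, 1, 97, 1]] * 3,
                         pseudocount=0.5, name="AAAGGG")

    def _with_motif(self, rng, n):
        return ["T" * 20 + "AAAGGG" + "T" * 20 for _ in range(n)]

    def _without_motif(self, n):
        return ["TCTCTCTCTCTCTCTCTCTCTCTCTCTCTC" for _ in range(n)]

    def test_perfect_separation_hypergeometric(self, rng):
        func = self._with_motif(rng, 10)
        nonf = self._without_motif(10)
        _, p = secondary_motif_enrichment(func, nonf, self._pwm(), threshold=8.0)
        assert p == pytest.approx(1 / math.comb(20, 10))

    def test_identical_rates_odds_one(self, rng):
        func = self._with_motif(rng, 3) + self._without_motif(3)
        nonf = self._with_motif(rng, 3) + self._without_motif(3)
        odds, _ = secondary_motif_enrichment(func, nonf, self._pwm(), threshold=8.0)
        assert odds == pytest.approx(1.0)

    def test_undersized_class_warns(self, rng):
        func = self._with_motif(rng, 3)
        nonf = self._without_motif(3)
        with pytest.warns(UserWarning):
            secondary_motif_enrichment(func, nonf, self._pwm(), threshold=8.0)

    def test_fisher_matches_hypergeometric_tail(self, rng):
        """2x2 table (8,2 / 3,7): one-sided p equals the hypergeometric tail."""
        func = self._with_motif(rng, 8) + self._without_motif(2)
        nonf = self._with_motif(rng, 3) + self._without_motif(7)
        _, p = secondary_motif_enrichment(func, nonf, self._pwm(), threshold=8.0)
        expected = sum(
            stats.hypergeom.pmf(k, 20, 11, 10) for k in range(8, 11)
        )
        assert p == pytest.approx(expected)


class TestNormalizedCpg:
    def test_arithmetic(self):
        assert normalized_cpg("CGCGCG") == pytest.approx((3 / 5) / 0.25)

    def test_no_cpg_dinucleotide(self):
        assert normalized_cpg("GGGCCC") == 0.0

    def test_reverse_complement_invariance(self, rng):
        from promfunc import reverse_complement

        for _ in range(10):
            seq = random_sequence(rng, 50)
            assert normalized_cpg(seq) == pytest.approx(
                normalized_cpg(reverse_complement(seq))
            )

    def test_missing_base_errors(self):
        with pytest.raises(ValueError):
            normalized_cpg("AATT")
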