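import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comorbnet import (
    AgeProfile,
    Cohort,
    DifferenceResult,
    EncounterRecord,
    Enrichment,
    Sex,
    age_profiles,
    classify_enrichment,
    cluster_age_profiles,
    compare_subgroups,
    comorbidity_universe,
    mean_comorbidity_trend,
    prevalence_with_ci,
    relative_difference,
    stratify,
    two_proportion_ztest,
)


class TestPrevalenceCI:
    def test_large_cohort_hypertension_row(self):
        est = prevalence_with_ci(6435, 18311)
        assert round(100 * est.prevalence, 2) == 35.14
        assert round(100 * est.ci_low, 1) == 34.5
        assert round(100 * est.ci_high, 1) == 35.8

    def test_large_cohort_diabetes_row(self):
        est = prevalence_with_ci(3080, 18311)
        assert round(100 * est.prevalence, 2) == 16.82
        assert round(100 * est.ci_low, 1) == 16.3
        assert round(100 * est.ci_high, 1) == 17.4

    def test_zero_count_boundary(self):
        est = prevalence_with_ci(0, 100)
        assert est.prevalence == 0.0
        assert est.ci_low == 0.0
        assert est.ci_high > 0.0

    def test_full_count_boundary(self):
        est = prevalence_with_ci(100, 100)
        assert est.prevalence == 1.0 and est.ci_high == 1.0 and est.ci_low < 1.0

    def test_zero_denominator(self):
        with pytest.raises(ValueError, match="undefined prevalence"):
            prevalence_with_ci(0, 0)

    def test_wilson_narrower_near_boundary(self):
        wald = prevalence_with_ci(2, 100)
        wilson = prevalence_with_ci(2, 100, method="wilson")
        assert wilson.ci_low > wald.ci_low  # Wilson avoids the boundary clamp

    def test_wald_coverage(self):
        # 95% Wald interval covers the true p in 93-97% of 1,000 binomials
        rng = np.random.default_rng(12345)
        p, N = 0.2, 500
        hits = 0
        for n in rng.binomial(N, p, size=1000):
            est = prevalence_with_ci(int(n), N)
            hits += est.ci_low <= p <= est.ci_high
        assert 930 <= hits <= 970


class TestRelativeDifference:
    @pytest.mark.parametrize("p_a,p_b,expected", [
        (0.1, 0.1, 0.0),
        (0.20, 0.10, 2 / 3),
        (0.10, 0.0, 2.0),
        (0.0, 0.10, -2.0),
    ])
    def test_values(self, p_a, p_b, expected):
        assert relative_difference(p_a, p_b) == pytest.approx(expected, abs=1e-9)

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            relative_difference(0.0, 0.0)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=200, derandomize=True)
    def test_antisymmetric_and_bounded(self, p_a, p_b):
        if p_a + p_b == 0:
            return
        d = relative_difference(p_a, p_b)
        assert -2.0 <= d <= 2.0
        assert d == pytest.approx(-relative_difference(p_b, p_a), abs=1e-12)


class TestZTest:
    def test_equal_proportions(self):
        z, p = two_proportion_ztest(50, 500, 50, 500)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_pooled_variance_value(self):
        z, p = two_proportion_ztest(200, 1000, 100, 1000)
        assert z == pytest.approx(6.262, abs=1e-3)
        assert p < 1e-9

    def test_degenerate_pooled(self):
        with pytest.raises(ValueError, match="degenerate"):
            two_proportion_ztest(0, 100, 0, 100)

    def test_tiny_strata_flagged_low_count(self):
        a = Cohort([EncounterRecord(f"A{i}", 50, Sex.MALE,
                                    frozenset({"E04", "I10"})) for i in range(3)])
        b = Cohort([EncounterRecord(f"B{i}", 50, Sex.FEMALE,
                                    frozenset({"E04", "K29"})) for i in range(3)])
        res = compare_subgroups(a, b, ["I10", "K29"])
        assert all(r.low_count for r in res)


def make_diff(p_a, p_b, N=5000):
    n_a, n_b = int(round(p_a * N)), int(round(p_b * N))
    z, p = two_proportion_ztest(n_a, N, n_b, N)
    return DifferenceResult(
        code="X00", p_a=n_a / N, p_b=n_b / N, n_a=n_a, N_a=N, n_b=n_b, N_b=N,
        absolute_difference=p_a - p_b,
        relative_difference=relative_difference(n_a / N, n_b / N), z=z, p_value=p,
    )


class TestClassifyEnrichment:
    def test_enriched(self):
        # d ~ 0.857, ratio 2.5, z-test p << .05
        assert classify_enrichment(make_diff(0.10, 0.04)) == Enrichment.ENRICHED_IN_A

    def test_small_relative_difference_not_different(self):
        # d ~ 0.049 < 0.1 even with a significant z at large n
        assert classify_enrichment(make_diff(0.105, 0.100, N=2_000_000)) == \
            Enrichment.NOT_DIFFERENT

    def test_equal_not_different(self):
        assert classify_enrichment(make_diff(0.1, 0.1)) == Enrichment.NOT_DIFFERENT

    def test_different_but_below_fold(self):
        # d ~ 0.29 > 0.1, significant, but ratio 4/3 < 1.5
        assert classify_enrichment(make_diff(0.40, 0.30)) == Enrichment.DIFFERENT

    def test_zero_opposite_prevalence_is_enriched(self):
        d = make_diff(0.05, 0.0)
        assert classify_enrichment(d) == Enrichment.ENRICHED_IN_A

    def test_symmetry(self):
        assert classify_enrichment(make_diff(0.04, 0.10)) == Enrichment.ENRICHED_IN_B

    def test_monotone_in_p_a(self):
        # raising p_a with p_b fixed never moves away from enriched_in_a
        order = [Enrichment.NOT_DIFFERENT, Enrichment.DIFFERENT,
                 Enrichment.ENRICHED_IN_A]
        ranks = []
        for p_a in np.arange(0.05, 0.30, 0.01):
            label = classify_enrichment(make_diff(round(p_a, 3), 0.05))
            assert label in order  # never flips to the b side
            ranks.append(order.index(label))
        assert ranks == sorted(ranks)


def age_cohort():
    """Prevalence of I70 strictly increasing over the 5 age bins."""
    records = []
    i = 0
    for age, p in [(30, 0.1), (45, 0.2), (55, 0.3), (65, 0.4), (80, 0.5)]:
        for j in range(100):
            codes = {"E04", "K29"}
            if j < int(p * 100):
                codes.add("I70")
            records.append(EncounterRecord(f"R{i}", age, Sex.FEMALE,
                                           frozenset(codes)))
            i += 1
    return Cohort(records)


class TestAgeProfiles:
    def test_strictly_increasing_gives_rho_one(self):
        profiles = age_profiles(age_cohort(), ["I70"])
        assert profiles[0].spearman_rho == pytest.approx(1.0)
        assert profiles[0].spearman_p < 0.05

    def test_constant_profile_rho_zero(self):
        profiles = age_profiles(age_cohort(), ["K29"])
        assert profiles[0].spearman_rho == 0.0

    def test_generator_age_slope_detected(self, recovery_cohort):
        profiles = age_profiles(recovery_cohort, ["I70"])
        assert profiles[0].spearman_rho > 0
        assert profiles[0].spearman_p < 0.05

    def test_mean_comorbidity_trend_increases(self, recovery_cohort):
        universe = comorbidity_universe(recovery_cohort)
        means, rho, p = mean_comorbidity_trend(recovery_cohort, universe)
        assert rho > 0 and p < 0.05
        assert means[-1] > means[0]

    def test_profiles_match_age_strata(self, recovery_cohort):
        profiles = {p.code: p for p in age_profiles(recovery_cohort, ["I10"])}
        strata = stratify(recovery_cohort, "age_bin")
        first = strata["18-39"]
        expected = first.prevalence_counts().get("I10", 0) / len(first.records)
        assert profiles["I10"].prevalence[0] == pytest.approx(expected)


def profile(code, values):
    return AgeProfile(code, [f"b{i}" for i in range(len(values))],
                      np.asarray(values, dtype=float), 0.0, 1.0)


class TestClusterAgeProfiles:
    def test_planted_separation(self):
        lo = [profile(f"L{i:02d}", 0.02 + 0.001 * np.arange(5) + 0.001 * i)
              for i in range(8)]
        hi = [profile(f"H{i:02d}", 0.40 + 0.005 * np.arange(5) + 0.002 * i)
              for i in range(8)]
        out, k, _ = cluster_age_profiles(lo + hi, k=2, seed=0)
        lo_ids = {p.cluster_id for p in out[:8]}
        hi_ids = {p.cluster_id for p in out[8:]}
        assert len(lo_ids) == len(hi_ids) == 1 and lo_ids != hi_ids

    def test_k_one_single_cluster(self):
        out, k, _ = cluster_age_profiles(
            [profile("A00", [0.1] * 5), profile("B00", [0.5] * 5)], k=1)
        assert {p.cluster_id for p in out} == {0}

    def test_duplicates_co_clustered(self):
        profs = [profile("A00", [0.1] * 5), profile("A01", [0.1] * 5),
                 profile("B00", [0.5] * 5), profile("B01", [0.5] * 5)]
        out, _, _ = cluster_age_profiles(profs, k=2)
        assert out[0].cluster_id == out[1].cluster_id
        assert out[2].cluster_id == out[3].cluster_id

    def test_k_too_large(self):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_age_profiles([profile("A00", [0.1] * 5),
                                  profile("B00", [0.5] * 5)], k=5)

    def test_elbow_finds_planted_two_groups(self):
        rng = np.random.default_rng(0)
        profs = [profile(f"L{i:02d}", 0.02 + 0.002 * rng.random(5))
                 for i in range(10)]
        profs += [profile(f"H{i:02d}", 0.40 + 0.002 * rng.random(5))
                  for i in range(10)]
        _, k, inertias = cluster_age_profiles(profs, seed=0)
        assert k == 2
        assert np.all(np.diff(inertias) <= 1e-9)  # inertia non-increasing in k

    def test_order_invariance(self):
        profs = [profile(f"C{i:02d}", 0.02 * (i % 3) + 0.01 * np.arange(5))
                 for i in range(9)]
        a, _, _ = cluster_age_profiles([profile(p.code, p.prevalence.copy())
                                        for p in profs], k=3, seed=1)
        rev = [profile(p.code, p.prevalence.copy()) for p in reversed(profs)]
        b, _, _ = cluster_age_profiles(rev, k=3, seed=1)
        part_a = {}
        for p in a:
            part_a.setdefault(p.cluster_id, set()).add(p.code)
        part_b = {}
        for p in b:
            part_b.setdefault(p.cluster_id, set()).add(p.code)
        assert sorted(map(sorted, part_a.values())) == \
            sorted(map(sorted, part_b.values()))
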