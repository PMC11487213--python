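"""Prevalence estimation, subgroup difference/enrichment tests, age profiles.

Prevalence is reported with a Wald binomial confidence interval. Subgroup
contrasts use the symmetric relative difference d = 2(p_a - p_b)/(p_a + p_b)
with a pooled two-proportion z-test; a comorbidity counts as *different* when
|d| exceeds a threshold and the z-test is significant, and as *enriched* when
its prevalence ratio additionally reaches a fold cutoff. Age structure is
summarized as per-disease prevalence vectors over age bins, tested for
monotone trend with Spearman rank correlation and grouped by K-means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .emr_io import Cohort
from .filters import AGE_BINS, stratify

__all__ = [
    "PrevalenceEstimate",
    "DifferenceResult",
    "Enrichment",
    "AgeProfile",
    "prevalence_with_ci",
    "relative_difference",
    "two_proportion_ztest",
    "compare_subgroups",
    "classify_enrichment",
    "age_profiles",
    "mean_comorbidity_trend",
    "cluster_age_profiles",
]


@dataclass(frozen=True)
class PrevalenceEstimate:
    code: str
    n: int
    N: int
    prevalence: float
    ci_low: float
    ci_high: float


def prevalence_with_ci(n: int, N: int, level: float = 0.95,
                       code: str = "", method: str = "wald") -> PrevalenceEstimate:
    """Crude prevalence n/N with a binomial confidence interval.

    The default Wald interval p +/- z*sqrt(p(1-p)/N), clamped to [0, 1], is the
    convention matched by published prevalence tables in this setting; a Wilson
    score interval is available via ``method="wilson"``.
    """
    if N <= 0:
        raise ValueError("undefined prevalence: N must be positive")
    if not 0 <= n <= N:
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    p = n / N
    z = stats.norm.ppf(0.5 + level / 2)
    if method == "wald":
        half = z * math.sqrt(p * (1 - p) / N)
        lo, hi = p - half, p + half
        if n == 0:  # degenerate Wald interval; report the exact upper bound
            hi = 1 - (1 - level) ** (1 / N)
        if n == N:
            lo = (1 - level) ** (1 / N)
    elif method == "wilson":
        denom = 1 + z * z / N
        center = (p + z * z / (2 * N)) / denom
        half = z * math.sqrt(p * (1 - p) / N + z * z / (4 * N * N)) / denom
        lo, hi = center - half, center + half
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return PrevalenceEstimate(code, n, N, p, max(0.0, lo), min(1.0, hi))


def relative_difference(p_a: float, p_b: float) -> float:
    """Symmetric relative difference 2(p_a - p_b)/(p_a + p_b), in [-2, 2]."""
    if p_a + p_b <= 0:
        raise ValueError("undefined relative difference: both prevalences are zero")
    return 2.0 * (p_a - p_b) / (p_a + p_b)


def two_proportion_ztest(n_a: int, N_a: int, n_b: int, N_b: int) -> tuple[float, float]:
    """Pooled two-proportion z statistic with a two-sided p-value."""
    if N_a <= 0 or N_b <= 0:
        raise ValueError("denominators must be positive")
    p_a, p_b = n_a / N_a, n_b / N_b
    pooled = (n_a + n_b) / (N_a + N_b)
    if pooled in (0.0, 1.0):
        raise ValueError("degenerate z-test: pooled proportion is 0 or 1")
    se = math.sqrt(pooled * (1 - pooled) * (1 / N_a + 1 / N_b))
    z = (p_a - p_b) / se
    return z, 2 * stats.norm.sf(abs(z))


class Enrichment(str, Enum):
    NOT_DIFFERENT = "not_different"
    DIFFERENT = "different"
    ENRICHED_IN_A = "enriched_in_a"
    ENRICHED_IN_B = "enriched_in_b"


@dataclass
class DifferenceResult:
    code: str
    p_a: float
    p_b: float
    n_a: int
    N_a: int
    n_b: int
    N_b: int
    absolute_difference: float
    relative_difference: float
    z: float
    p_value: float
    classification: Enrichment = Enrichment.NOT_DIFFERENT
    low_count: bool = False


def classify_enrichment(diff: DifferenceResult, d_threshold: float = 0.1,
                        fold: float = 1.5, alpha: float = 0.05) -> Enrichment:
    """Label a subgroup contrast.

    *different*: |relative difference| > ``d_threshold`` and z-test p < alpha.
    *enriched_in_a/b*: additionally a prevalence ratio >= ``fold`` in that
    direction (a zero opposite prevalence counts as an infinite ratio).
    """
    if not (abs(diff.relative_difference) > d_threshold and diff.p_value < alpha):
        return Enrichment.NOT_DIFFERENT
    if diff.p_a > diff.p_b:
        ratio = math.inf if diff.p_b == 0 else diff.p_a / diff.p_b
        return Enrichment.ENRICHED_IN_A if ratio >= fold else Enrichment.DIFFERENT
    ratio = math.inf if diff.p_a == 0 else diff.p_b / diff.p_a
    return Enrichment.ENRICHED_IN_B if ratio >= fold else Enrichment.DIFFERENT


def compare_subgroups(cohort_a: Cohort, cohort_b: Cohort, codes: Sequence[str],
                      d_threshold: float = 0.1, fold: float = 1.5,
                      alpha: float = 0.05,
                      low_count_n: int = 30) -> list[DifferenceResult]:
    """Per-code prevalence contrast between two cohorts, classified."""
    N_a, N_b = len(cohort_a.records), len(cohort_b.records)
    counts_a = cohort_a.prevalence_counts()
    counts_b = cohort_b.prevalence_counts()
    out: list[DifferenceResult] = []
    for code in codes:
        n_a, n_b = counts_a.get(code, 0), counts_b.get(code, 0)
        if n_a + n_b == 0:
            continue  # undefined relative difference; pair skipped
        p_a, p_b = n_a / N_a, n_b / N_b
        z, p_value = two_proportion_ztest(n_a, N_a, n_b, N_b)
        res = DifferenceResult(
            code=code, p_a=p_a, p_b=p_b, n_a=n_a, N_a=N_a, n_b=n_b, N_b=N_b,
            absolute_difference=p_a - p_b,
            relative_difference=relative_difference(p_a, p_b),
            z=z, p_value=p_value, low_count=min(N_a, N_b) < low_count_n,
        )
        res.classification = classify_enrichment(res, d_threshold, fold, alpha)
        out.append(res)
    return out


@dataclass
class AgeProfile:
    code: str
    bins: list[str]
    prevalence: np.ndarray  # one value per age bin
    spearman_rho: float
    spearman_p: float
    cluster_id: Optional[int] = None


def age_profiles(cohort: Cohort, codes: Sequence[str],
                 bins=AGE_BINS) -> list[AgeProfile]:
    """Per-disease prevalence over age bins with a Spearman trend test.

    The correlation is taken between the bin ordinal (not the bin midpoint) and
    the bin prevalence, making it invariant to bin-width choices. Empty bins
    are dropped from the trend.
    """
    strata = stratify(cohort, "age_bin")
    labels = [f">={lo}" if hi is None else f"{lo}-{hi}" for lo, hi in bins]
    sizes = np.array([len(strata[lab].records) for lab in labels])
    counts = {lab: strata[lab].prevalence_counts() for lab in labels}
    keep = sizes > 0
    profiles = []
    for code in codes:
        prev = np.array([
            counts[lab].get(code, 0) / n if n else np.nan
            for lab, n in zip(labels, sizes)
        ])
        x = np.arange(len(labels))[keep]
        y = prev[keep]
        if len(x) >= 2 and np.ptp(y) > 0:
            rho, p = stats.spearmanr(x, y)
        else:
            rho, p = 0.0, 1.0  # constant profile: no trend, ties throughout
        profiles.append(AgeProfile(code, labels, prev, float(rho), float(p)))
    return profiles


def mean_comorbidity_trend(cohort: Cohort, comorbidity_codes: Sequence[str],
                           bins=AGE_BINS) -> tuple[np.ndarray, float, float]:
    """Mean comorbidity count per age bin and its Spearman trend.

    Counts only codes in ``comorbidity_codes`` (thyroid codes excluded), the
    quantity whose rise with age signals accumulating multimorbidity.
    """
    strata = stratify(cohort, "age_bin")
    labels = [f">={lo}" if hi is None else f"{lo}-{hi}" for lo, hi in bins]
    universe = set(comorbidity_codes)
    means = []
    for lab in labels:
        recs = strata[lab].records
        means.append(
            np.mean([len(r.codes & universe) for r in recs]) if recs else np.nan
        )
    means = np.array(means)
    keep = ~np.isnan(means)
    x = np.arange(len(labels))[keep]
    if keep.sum() >= 2 and np.ptp(means[keep]) > 0:
        rho, p = stats.spearmanr(x, means[keep])
    else:
        rho, p = 0.0, 1.0
    return means, float(rho), float(p)


def cluster_age_profiles(profiles: list[AgeProfile], k: Optional[int] = None,
                         seed: int = 0, k_max: int = 10,
                         n_init: int = 50) -> tuple[list[AgeProfile], int, np.ndarray]:
    """K-means on raw (unscaled) age-prevalence vectors.

    Profiles are clustered on unscaled prevalence so groups separate by
    magnitude as well as shape. When ``k`` is not given it is chosen by the
    elbow of the within-cluster sum of squares over k = 1..k_max (largest
    second difference). Returns the annotated profiles, the chosen k, and the
    inertia curve.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    X = np.vstack([np.nan_to_num(p.prevalence) for p in profiles])
    k_hi = min(k_max, len(profiles))
    if k is not None and k > len(profiles):
        raise ValueError(f"k={k} exceeds the number of profiles ({len(profiles)})")
    inertias = np.array([
        KMeans(n_clusters=kk, n_init=n_init, random_state=seed).fit(X).inertia_
        for kk in range(1, k_hi + 1)
    ])
    if k is None:
        if k_hi >= 3:
            second_diff = inertias[:-2] - 2 * inertias[1:-1] + inertias[2:]
            k = int(np.argmax(second_diff)) + 2  # elbow at the middle k
        else:
            k = k_hi
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    for prof, lab in zip(profiles, km.labels_):
        prof.cluster_id = int(lab)
    return profiles, k, inertias
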