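"""Cohort-level statistics on segment records.

Two aggregation rules coexist and must not be conflated:

* overall two-cohort comparisons use *patient-level* units — every
  parameter is first averaged over all of a subject's vessel segments
  (all four views pooled), one value per subject;
* per-diameter-group comparisons use *segment-level* units — values of
  all segments falling in the group, per cohort, with no per-patient
  averaging.

Continuous comparisons are normality-gated: Kolmogorov–Smirnov on each
arm (parameters estimated from the sample; a Lilliefors variant is
available), then an independent-samples t-test when both arms look
normal, a Mann–Whitney U test otherwise.  Categorical 2x2 tables use
Pearson chi-square, or Fisher's exact test when any expected count is
below 5.  Multi-group comparisons run a one-way ANOVA followed by
Bonferroni-corrected pairwise t-tests when Levene's test accepts
homogeneous variances, Games–Howell otherwise.

Test–retest repeatability is summarised by the coefficient of
repeatability CR = 1.96 x SD of the paired differences: the interval
within which 95% of repeat differences are expected to fall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .hemodynamics import SegmentRecord

__all__ = [
    "CohortTable",
    "ComparisonResult",
    "RepeatabilityResult",
    "PosthocPair",
    "AnovaResult",
    "aggregate_per_patient",
    "aggregate_per_group",
    "compare_two_cohorts",
    "compare_categorical",
    "anova_posthoc",
    "games_howell",
    "repeatability",
]

PARAMETERS = {"D": "diameter_um", "Va": "va_mm_s", "Q": "q_pl_s", "WSR": "wsr_per_s"}
COHORTS = ("control", "MI")


@dataclass
class CohortTable:
    """Segment records joined to subject metadata.

    ``records`` is a DataFrame with one row per vessel segment (columns
    of :class:`~hemoflow.hemodynamics.SegmentRecord`); ``subjects`` maps
    subject_id to a cohort label ('control' or 'MI') plus optional
    covariates.
    """

    records: pd.DataFrame
    subjects: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.records):
            unknown = set(self.records["subject_id"]) - set(self.subjects["subject_id"])
            if unknown:
                raise ValueError(f"records reference unknown subjects: {sorted(unknown)}")
        bad = set(self.subjects["cohort"]) - set(COHORTS)
        if bad:
            raise ValueError(f"cohort labels must be in {COHORTS}, got {sorted(bad)}")

    @classmethod
    def from_records(
        cls, records: Sequence[SegmentRecord], subjects: pd.DataFrame
    ) -> "CohortTable":
        df = pd.DataFrame([vars(r) for r in records])
        return cls(df, subjects.reset_index(drop=True))

    def cohort_of(self, subject_id: str) -> str:
        row = self.subjects.loc[self.subjects["subject_id"] == subject_id, "cohort"]
        return str(row.iloc[0])


@dataclass
class ComparisonResult:
    """Outcome of a two-sample comparison."""

    parameter: str
    test: str  # 't-test' | 'mann-whitney' | 'chi-square' | 'fisher'
    p_value: float
    means: Tuple[float, float] = (np.nan, np.nan)
    sds: Tuple[float, float] = (np.nan, np.nan)
    cis: Tuple[Tuple[float, float], Tuple[float, float]] = ((np.nan, np.nan), (np.nan, np.nan))
    n: Tuple[int, int] = (0, 0)
    normal: Tuple[bool, bool] = (True, True)
    statistic: float = np.nan


@dataclass
class RepeatabilityResult:
    """Coefficient-of-repeatability summary of paired re-measurements."""

    parameter: str
    mean_diff: float
    sd_diff: float
    cr: float
    ci: Tuple[float, float]
    n_pairs: int


@dataclass
class PosthocPair:
    group_a: int
    group_b: int
    mean_diff: float
    p_value: float


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    levene_p: float
    posthoc_method: str  # 'bonferroni' | 'games-howell'
    pairwise: List[PosthocPair] = field(default_factory=list)


def aggregate_per_patient(table: CohortTable, parameter: str) -> pd.Series:
    """One value per subject: the mean over all the subject's segments.

    All four views are pooled. Subjects with zero analysed segments are
    omitted. Returned Series is indexed by subject_id, sorted.
    """
    col = _param_col(parameter)
    if not len(table.records):
        raise ValueError("empty cohort table")
    means = table.records.groupby("subject_id")[col].mean().sort_index()
    missing = set(table.subjects["subject_id"]) - set(means.index)
    if missing:
        import warnings

        warnings.warn(f"subjects with no records omitted: {sorted(missing)}")
    return means


def aggregate_per_group(
    table: CohortTable, parameter: str, vessel_group: int
) -> Dict[str, np.ndarray]:
    """Segment-level values restricted to one diameter group, per cohort.

    Deliberately NOT per-patient averaged — group-stratified comparisons
    use the individual segments as units.
    """
    if vessel_group not in (1, 2, 3, 4):
        raise ValueError(f"vessel_group must be 1-4, got {vessel_group}")
    col = _param_col(parameter)
    sub = table.records[table.records["group"] == vessel_group]
    if not len(sub):
        import warnings

        warnings.warn(f"no records in vessel group {vessel_group}")
        return {c: np.array([]) for c in COHORTS}
    cohorts = sub["subject_id"].map(
        table.subjects.set_index("subject_id")["cohort"]
    )
    return {c: sub.loc[cohorts == c, col].to_numpy() for c in COHORTS}


def _param_col(parameter: str) -> str:
    if parameter in PARAMETERS:
        return PARAMETERS[parameter]
    if parameter in PARAMETERS.values():
        return parameter
    raise ValueError(f"unknown parameter {parameter!r}; use one of {sorted(PARAMETERS)}")


def _ks_normal(x: np.ndarray, alpha: float, lilliefors: bool = False) -> bool:
    """Kolmogorov–Smirnov normality check with parameters estimated from
    the sample. The Lilliefors variant corrects the estimated-parameter
    bias of the plain KS p-value."""
    x = np.asarray(x, float)
    if x.std(ddof=1) == 0:
        return True  # degenerate; location tests handle it
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        _, p = _lf(x, dist="norm")
    else:
        _, p = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return p > alpha


def _mean_ci(x: np.ndarray, level: float = 0.95) -> Tuple[float, float]:
    n = len(x)
    m, s = x.mean(), x.std(ddof=1)
    if n < 2 or s == 0:
        return (m, m)
    h = stats.t.ppf(0.5 + level / 2, n - 1) * s / np.sqrt(n)
    return (m - h, m + h)


def compare_two_cohorts(
    control: Sequence[float],
    mi: Sequence[float],
    alpha: float = 0.05,
    parameter: str = "",
    lilliefors: bool = False,
) -> ComparisonResult:
    """Normality-gated two-sample comparison of control vs MI values.

    Both arms normal by KS → independent-samples t-test; otherwise
    Mann–Whitney U. Requires at least 3 values per arm.
    """
    a = np.asarray(control, float)
    b = np.asarray(mi, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError(f"need >= 3 values per arm, got {len(a)} and {len(b)}")
    norm_a = _ks_normal(a, alpha, lilliefors)
    norm_b = _ks_normal(b, alpha, lilliefors)
    if norm_a and norm_b:
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
            test, stat, p = "t-test", 0.0, 1.0
        else:
            stat, p = stats.ttest_ind(a, b)
            test = "t-test"
    else:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann-whitney"
    return ComparisonResult(
        parameter=parameter,
        test=test,
        p_value=float(p),
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        cis=(_mean_ci(a), _mean_ci(b)),
        n=(len(a), len(b)),
        normal=(norm_a, norm_b),
        statistic=float(stat),
    )


def compare_categorical(counts, parameter: str = "") -> ComparisonResult:
    """Pearson chi-square or Fisher's exact test on a 2x2 table.

    Fisher's exact is used when any expected cell count is below 5 or
    any observed cell is zero; the asymptotic chi-square approximation
    is unreliable in both situations.
    """
    t = np.asarray(counts, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("counts must be a non-negative 2x2 table")
    if t.sum() == 0:
        raise ValueError("all-zero contingency table")
    expected = stats.contingency.expected_freq(t)
    if np.any(expected < 5) or np.any(t == 0):
        stat, p = stats.fisher_exact(t)
        test = "fisher"
    else:
        res = stats.chi2_contingency(t, correction=False)
        stat, p = res.statistic, res.pvalue
        test = "chi-square"
    row_tot = t.sum(axis=1)
    props = tuple(t[i, 0] / row_tot[i] if row_tot[i] else np.nan for i in range(2))
    return ComparisonResult(
        parameter=parameter,
        test=test,
        p_value=float(p),
        means=props,
        n=tuple(row_tot),
        statistic=float(stat),
    )


def games_howell(groups: Sequence[np.ndarray]) -> List[PosthocPair]:
    """Games–Howell pairwise comparisons (unequal variances).

    Welch-type standard errors and degrees of freedom with p-values from
    the studentized-range distribution.
    """
    res = []
    stats_ = [(np.mean(g), np.var(g, ddof=1), len(g)) for g in groups]
    for (i, (mi_, vi, ni)), (j, (mj, vj, nj)) in combinations(enumerate(stats_), 2):
        se2 = vi / ni + vj / nj
        t = abs(mi_ - mj) / np.sqrt(se2)
        df = se2**2 / ((vi / ni) ** 2 / (ni - 1) + (vj / nj) ** 2 / (nj - 1))
        p = stats.studentized_range.sf(t * np.sqrt(2), len(groups), df)
        res.append(PosthocPair(i, j, float(mi_ - mj), float(np.clip(p, 0, 1))))
    return res


def _bonferroni(groups: Sequence[np.ndarray]) -> List[PosthocPair]:
    pairs = list(combinations(range(len(groups)), 2))
    res = []
    for i, j in pairs:
        _, p = stats.ttest_ind(groups[i], groups[j])
        res.append(
            PosthocPair(
                i, j, float(np.mean(groups[i]) - np.mean(groups[j])), float(min(1.0, p * len(pairs)))
            )
        )
    return res


def anova_posthoc(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA with variance-gated post-hoc pairwise tests.

    Levene's test (center=mean) decides between Bonferroni-corrected
    pairwise t-tests (homogeneous variances) and Games–Howell.
    """
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 3:
        raise ValueError(f"need >= 3 groups, got {len(gs)}")
    if any(len(g) < 3 for g in gs):
        raise ValueError("each group needs >= 3 values")
    if all(g.std(ddof=1) == 0 for g in gs) and len({g.mean() for g in gs}) == 1:
        return AnovaResult(0.0, 1.0, 1.0, "bonferroni", [PosthocPair(i, j, 0.0, 1.0) for i, j in combinations(range(len(gs)), 2)])
    f, p = stats.f_oneway(*gs)
    _, lev_p = stats.levene(*gs, center="mean")
    if lev_p > alpha:
        method, pairs = "bonferroni", _bonferroni(gs)
    else:
        method, pairs = "games-howell", games_howell(gs)
    return AnovaResult(float(f), float(p), float(lev_p), method, pairs)


def repeatability(
    pairs: Sequence[Tuple[float, float]], parameter: str = ""
) -> RepeatabilityResult:
    """Coefficient of repeatability from paired test–retest measurements.

    CR = 1.96 x SD of the paired differences (sample SD); the 95%
    interval for a repeat difference is mean_diff ± CR.
    """
    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (m1, m2) pairs")
    d = arr[:, 0] - arr[:, 1]
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    cr = 1.96 * sd_diff
    return RepeatabilityResult(
        parameter=parameter,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        cr=cr,
        ci=(mean_diff - cr, mean_diff + cr),
        n_pairs=arr.shape[0],
    )
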