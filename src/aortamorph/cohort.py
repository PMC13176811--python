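"""Matched-cohort statistics: eligibility, optimal matching, tests, agreement.

Implements the statistical layer of the study design: dilated cases are
matched 1:2 against nondilated controls by optimal pair matching on the
Mahalanobis distance over (age, sex, body surface area), without
replacement; group contrasts use the Mann-Whitney U test (continuous) and
Pearson chi-square (categorical); within-patient systole-vs-diastole
contrasts use the Wilcoxon signed-rank test with percentile bootstrap
confidence intervals (1000 replicates) for the median difference; and
inter-reader agreement is summarised by ICC(2,1) and Bland-Altman limits.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .synthetic import PatientRecord

__all__ = [
    "MatchedCohort",
    "ComparisonResult",
    "filter_eligible",
    "match_cohort",
    "compare_groups",
    "paired_test",
    "bootstrap_median_ci",
    "reader_agreement",
]


@dataclass(frozen=True)
class MatchedCohort:
    pairs: tuple  # ((case_id, (control_id, control_id)), ...)
    unmatched_controls: tuple
    balance_table: dict  # covariate -> {"smd_before": x, "smd_after": y}
    total_distance: float

    @property
    def matched_controls(self) -> list:
        return [c for _, ctrls in self.pairs for c in ctrls]


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    group_summaries: dict
    test_name: str
    p_value: float
    statistic: float
    ci: tuple | None = None
    ci_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if self.ci is not None and self.ci[0] > self.ci[1]:
            raise ValueError("CI lower bound exceeds upper bound")


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

def filter_eligible(records: list[PatientRecord]) -> tuple[list[PatientRecord], dict]:
    """Drop records with any raised exclusion flag; log counts per reason."""
    eligible = [r for r in records if r.eligible]
    log = Counter(flag for r in records for flag in r.eligibility_flags)
    return eligible, dict(log)


# ---------------------------------------------------------------------------
# optimal matching
# ---------------------------------------------------------------------------

def _covariate_matrix(records: list[PatientRecord], covariates) -> np.ndarray:
    cols = []
    for cov in covariates:
        if cov == "sex":
            cols.append([1.0 if r.sex == "male" else 0.0 for r in records])
        else:
            cols.append([float(getattr(r, cov)) for r in records])
    return np.array(cols, dtype=float).T


def _smd(x_case: np.ndarray, x_ctrl: np.ndarray) -> float:
    """Standardised mean difference with the pooled-variance denominator."""
    v = 0.5 * (x_case.var(ddof=1) + x_ctrl.var(ddof=1))
    if v <= 0:
        return 0.0
    return float((x_case.mean() - x_ctrl.mean()) / np.sqrt(v))


def match_cohort(
    cases: list[PatientRecord],
    controls: list[PatientRecord],
    covariates: tuple[str, ...] = ("age", "sex", "bsa"),
    ratio: int = 2,
) -> MatchedCohort:
    """Optimal 1:``ratio`` Mahalanobis matching without replacement.

    The Mahalanobis distance uses the covariance of (age, sex as 0/1, BSA)
    pooled over all eligible patients.  The globally cost-minimising
    assignment is found by replicating each case ``ratio`` times and solving
    the rectangular assignment problem, which is exactly the optimal
    fixed-ratio match when controls cannot be reused.
    """
    if len(controls) < ratio * len(cases):
        raise ValueError(
            f"insufficient controls: need {ratio * len(cases)}, have {len(controls)} "
            f"(deficit {ratio * len(cases) - len(controls)})"
        )
    xc = _covariate_matrix(cases, covariates)
    xk = _covariate_matrix(controls, covariates)
    pooled = np.vstack([xc, xk])
    cov = np.cov(pooled, rowvar=False)
    cov = np.atleast_2d(cov)
    # guard rank deficiency (e.g. single-sex toy cohorts)
    vi = np.linalg.pinv(cov)
    dist = cdist(xc, xk, metric="mahalanobis", VI=vi)

    cost = np.repeat(dist, ratio, axis=0)  # rows: case 0 x ratio, case 1 x ratio, ...
    row_ind, col_ind = linear_sum_assignment(cost)
    assigned: dict[int, list] = {i: [] for i in range(len(cases))}
    total = 0.0
    for r, c in zip(row_ind, col_ind):
        assigned[r // ratio].append(controls[c].patient_id)
        total += cost[r, c]
    pairs = tuple(
        (cases[i].patient_id, tuple(sorted(assigned[i]))) for i in range(len(cases))
    )
    matched_ids = {c for _, ctrls in pairs for c in ctrls}
    unmatched = tuple(r.patient_id for r in controls if r.patient_id not in matched_ids)

    ctrl_by_id = {r.patient_id: j for j, r in enumerate(controls)}
    sel = [ctrl_by_id[c] for _, ctrls in pairs for c in ctrls]
    balance = {}
    for j, cov_name in enumerate(covariates):
        balance[cov_name] = {
            "smd_before": _smd(xc[:, j], xk[:, j]),
            "smd_after": _smd(xc[:, j], xk[sel, j]),
        }
    return MatchedCohort(
        pairs=pairs,
        unmatched_controls=unmatched,
        balance_table=balance,
        total_distance=float(total),
    )


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

def _summary(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"n": int(values.size), "median": float(med), "q1": float(q1), "q3": float(q3)}


def compare_groups(values_by_group: dict, kind: str, variable: str = "") -> ComparisonResult:
    """Two-group contrast: Mann-Whitney U (continuous) or chi-square (categorical).

    Continuous: two-sided Mann-Whitney U, exact when both groups have n <= 8
    and no ties, otherwise the tie-corrected normal approximation.
    Categorical: Pearson chi-square on the 2 x k contingency table without
    continuity correction; ``values_by_group`` then maps group -> counts per
    category (sequence) or category labels per subject.
    """
    if len(values_by_group) != 2:
        raise ValueError("exactly two groups required")
    (g1, v1), (g2, v2) = values_by_group.items()
    if kind == "continuous":
        a = np.asarray(v1, float)
        b = np.asarray(v2, float)
        exact = a.size <= 8 and b.size <= 8 and np.unique(np.r_[a, b]).size == a.size + b.size
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="exact" if exact else "asymptotic")
        return ComparisonResult(
            variable=variable,
            group_summaries={g1: _summary(a), g2: _summary(b)},
            test_name="mann-whitney-u" + ("-exact" if exact else ""),
            p_value=float(res.pvalue),
            statistic=float(res.statistic),
        )
    if kind == "categorical":
        c1, c2 = np.asarray(v1), np.asarray(v2)
        if c1.dtype.kind in "OUS" or c2.dtype.kind in "OUS":
            cats = sorted(set(c1) | set(c2))
            c1 = np.array([np.sum(np.asarray(v1) == c) for c in cats], float)
            c2 = np.array([np.sum(np.asarray(v2) == c) for c in cats], float)
        table = np.vstack([c1, c2]).astype(float)
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
        summaries = {
            g: {"counts": row.astype(int).tolist(), "pct": (100 * row / row.sum()).tolist()}
            for g, row in ((g1, table[0]), (g2, table[1]))
        }
        return ComparisonResult(
            variable=variable,
            group_summaries=summaries,
            test_name="chi-square",
            p_value=float(p),
            statistic=float(chi2),
        )
    raise ValueError(f"unknown kind {kind!r}")


def paired_test(systolic, diastolic, variable: str = "") -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired measurements.

    Zero differences are dropped; exact null distribution when the number of
    informative pairs is <= 12 and ranks are untied, otherwise the
    tie-corrected normal approximation.  All-zero differences give p = 1
    (no informative pairs).
    """
    a = np.asarray(systolic, float)
    b = np.asarray(diastolic, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d_nz = d[d != 0]
    if d_nz.size == 0:
        return ComparisonResult(
            variable=variable,
            group_summaries={"differences": _summary(d)},
            test_name="wilcoxon-signed-rank",
            p_value=1.0,
            statistic=0.0,
        )
    exact = d_nz.size <= 12 and np.unique(np.abs(d_nz)).size == d_nz.size
    res = stats.wilcoxon(d_nz, zero_method="wilcox", alternative="two-sided",
                         method="exact" if exact else "asymptotic")
    return ComparisonResult(
        variable=variable,
        group_summaries={"differences": _summary(d)},
        test_name="wilcoxon-signed-rank" + ("-exact" if exact else ""),
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
    )


def bootstrap_median_ci(
    differences,
    replicates: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI for the median of paired differences."""
    d = np.asarray(differences, float)
    if d.size < 2:
        raise ValueError("need at least two observations")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(replicates, d.size))
    medians = np.median(d[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(medians, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# inter-reader agreement
# ---------------------------------------------------------------------------

def reader_agreement(reader1, reader2) -> dict:
    """ICC(2,1) and Bland-Altman summary for two readers of the same series.

    ICC(2,1) — two-way random effects, absolute agreement, single
    measurement — is computed from the two-way ANOVA mean squares::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with n subjects, k = 2 raters.  Bland-Altman limits of agreement are
    mean difference +/- 1.96 SD of the differences.
    """
    x = np.asarray(reader1, float)
    y = np.asarray(reader2, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("readers must supply equal-length 1D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired measurements")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = 1.0 if denom == 0 else float((msr - mse) / denom)

    d = x - y
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    return {
        "icc2_1": icc,
        "bland_altman": {
            "mean_difference": mean_diff,
            "sd_difference": sd_diff,
            "loa_lower": mean_diff - 1.96 * sd_diff,
            "loa_upper": mean_diff + 1.96 * sd_diff,
        },
        "n": int(n),
    }
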