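"""Statistical layer: matching optimality, test oracles, bootstrap, ICC."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aortamorph import cohort, synthetic
from aortamorph.synthetic import PatientRecord


def make_record(pid, age, sex, bsa, group="nondilated", flags=()):
    return PatientRecord(patient_id=pid, age=age, sex=sex, bsa=bsa, group=group,
                         eligibility_flags=frozenset(flags))


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_match_cost(dist: np.ndarray, ratio: int = 2) -> float:
    """Exact optimal 1:ratio matching cost by bitmask dynamic programming."""
    n_cases, n_ctrl = dist.shape
    pair_costs = {}
    for combo in itertools.combinations(range(n_ctrl), ratio):
        bits = sum(1 << c for c in combo)
        pair_costs[bits] = sum(dist[:, list(combo)].T)  # (n_cases,) per case
    best = {0: 0.0}
    for case in range(n_cases):
        nxt = {}
        for used, cost in best.items():
            for bits, costs in pair_costs.items():
                if used & bits:
                    continue
                key = used | bits
                cand = cost + costs[case]
                if cand < nxt.get(key, np.inf):
                    nxt[key] = cand
        best = nxt
    return min(best.values())


def exact_mannwhitney_p(a, b):
    """Two-sided p by full enumeration of group assignments."""
    pooled = np.r_[a, b]
    n = len(a)

    def ustat(idx):
        x = pooled[list(idx)]
        y = np.delete(pooled, list(idx))
        u = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
        return u

    obs = ustat(range(n))
    mu = n * (len(pooled) - n) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        total += 1
        if abs(ustat(idx) - mu) >= abs(obs - mu) - 1e-12:
            count += 1
    return count / total


def exact_wilcoxon_p(d):
    """Two-sided signed-rank p by enumerating all sign patterns."""
    d = np.asarray(d, float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    count = 0
    n = len(d)
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, bool)].sum()
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / 2**n


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

class TestFilterEligible:
    def test_all_clear_is_identity(self):
        recs = [make_record(f"p{i}", 80, "male", 1.8) for i in range(4)]
        eligible, log = cohort.filter_eligible(recs)
        assert eligible == recs and log == {}

    def test_flagged_record_excluded_and_logged(self):
        recs = [make_record("p0", 80, "male", 1.8),
                make_record("p1", 81, "female", 1.7, flags=["lvef_below_30"])]
        eligible, log = cohort.filter_eligible(recs)
        assert [r.patient_id for r in eligible] == ["p0"]
        assert log == {"lvef_below_30": 1}

    def test_log_matches_generator_bookkeeping(self):
        recs = synthetic.sample_cohort(40, 80, seed=23, exclusion_rate=0.3)
        eligible, log = cohort.filter_eligible(recs)
        n_flagged = sum(not r.eligible for r in recs)
        assert len(eligible) == len(recs) - n_flagged
        assert sum(log.values()) == n_flagged


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

class TestMatchCohort:
    def test_35_cases_get_70_distinct_controls(self, default_cohort):
        cases = [r for r in default_cohort if r.group == "dilated"]
        controls = [r for r in default_cohort if r.group == "nondilated"]
        m = cohort.match_cohort(cases, controls)
        assert len(m.pairs) == 35
        matched = m.matched_controls
        assert len(matched) == 70 and len(set(matched)) == 70

    def test_toy_instance_equals_exhaustive_enumeration(self):
        cases = [make_record("c0", 80, "male", 1.8, group="dilated"),
                 make_record("c1", 70, "female", 1.6, group="dilated"),
                 make_record("c2", 85, "male", 2.1, group="dilated")]
        controls = [make_record(f"k{i}", a, s, b)
                    for i, (a, s, b) in enumerate(
                        [(79, "male", 1.9), (71, "female", 1.6), (84, "male", 2.0),
                         (60, "female", 1.5), (82, "male", 1.7), (75, "female", 1.8)])]
        m = cohort.match_cohort(cases, controls)
        # recompute the distance matrix exactly as the implementation defines it
        xc = cohort._covariate_matrix(cases, ("age", "sex", "bsa"))
        xk = cohort._covariate_matrix(controls, ("age", "sex", "bsa"))
        vi = np.linalg.pinv(np.cov(np.vstack([xc, xk]), rowvar=False))
        from scipy.spatial.distance import cdist
        dist = cdist(xc, xk, metric="mahalanobis", VI=vi)
        assert m.total_distance == pytest.approx(brute_force_match_cost(dist))

    @pytest.mark.parametrize("n_cases,n_ctrl,seed", [(2, 5, 0), (4, 9, 1), (5, 12, 2)])
    def test_optimality_matches_brute_force(self, n_cases, n_ctrl, seed):
        rng = np.random.default_rng(seed)
        cases = [make_record(f"c{i}", int(rng.integers(60, 95)),
                             "male" if rng.random() < 0.5 else "female",
                             float(rng.uniform(1.4, 2.4)), group="dilated")
                 for i in range(n_cases)]
        controls = [make_record(f"k{i}", int(rng.integers(60, 95)),
                                "male" if rng.random() < 0.5 else "female",
                                float(rng.uniform(1.4, 2.4)))
                    for i in range(n_ctrl)]
        m = cohort.match_cohort(cases, controls)
        xc = cohort._covariate_matrix(cases, ("age", "sex", "bsa"))
        xk = cohort._covariate_matrix(controls, ("age", "sex", "bsa"))
        vi = np.linalg.pinv(np.cov(np.vstack([xc, xk]), rowvar=False))
        from scipy.spatial.distance import cdist
        dist = cdist(xc, xk, metric="mahalanobis", VI=vi)
        assert m.total_distance == pytest.approx(brute_force_match_cost(dist))

    def test_identical_covariates_zero_cost(self):
        cases = [make_record(f"c{i}", 80, "male", 1.8, group="dilated") for i in range(3)]
        controls = [make_record(f"k{i}", 80, "male", 1.8) for i in range(6)]
        m = cohort.match_cohort(cases, controls)
        assert m.total_distance == pytest.approx(0.0, abs=1e-9)

    def test_insufficient_controls_reports_deficit(self):
        cases = [make_record(f"c{i}", 80, "male", 1.8, group="dilated") for i in range(3)]
        controls = [make_record(f"k{i}", 80, "male", 1.8) for i in range(4)]
        with pytest.raises(ValueError, match="deficit 2"):
            cohort.match_cohort(cases, controls)

    def test_balance_does_not_worsen_on_default_cohort(self, default_cohort):
        cases = [r for r in default_cohort if r.group == "dilated"]
        controls = [r for r in default_cohort if r.group == "nondilated"]
        m = cohort.match_cohort(cases, controls)
        for cov_name, row in m.balance_table.items():
            assert abs(row["smd_after"]) <= abs(row["smd_before"]) + 1e-9, cov_name


# ---------------------------------------------------------------------------
# group comparisons and paired tests
# ---------------------------------------------------------------------------

class TestCompareGroups:
    def test_mann_whitney_matches_exact_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = cohort.compare_groups({"g1": a, "g2": b}, "continuous")
        assert res.p_value == pytest.approx(0.1)
        assert res.p_value == pytest.approx(exact_mannwhitney_p(a, b))
        # a second, asymmetric toy vector
        a2, b2 = [1.0, 5.0, 2.5], [3.0, 6.0, 7.0, 8.0]
        res2 = cohort.compare_groups({"g1": a2, "g2": b2}, "continuous")
        assert res2.p_value == pytest.approx(exact_mannwhitney_p(a2, b2))

    def test_identical_groups_p_near_one(self):
        vals = list(np.linspace(1, 9, 9))
        res = cohort.compare_groups({"g1": vals, "g2": vals}, "continuous")
        assert res.p_value > 0.9

    def test_chi_square_statistic(self):
        res = cohort.compare_groups({"g1": [20, 10], "g2": [10, 20]}, "categorical")
        assert res.statistic == pytest.approx(6.667, abs=1e-3)

    def test_categorical_accepts_labels(self):
        g1 = ["male"] * 20 + ["female"] * 10
        g2 = ["male"] * 10 + ["female"] * 20
        res = cohort.compare_groups({"g1": g1, "g2": g2}, "categorical")
        assert res.statistic == pytest.approx(6.667, abs=1e-3)


class TestPairedTest:
    def test_all_zero_differences(self):
        res = cohort.paired_test([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert res.p_value == 1.0

    def test_exact_p_for_five_positive_differences(self):
        res = cohort.paired_test([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert res.p_value == pytest.approx(0.0625)
        assert res.p_value == pytest.approx(exact_wilcoxon_p([1, 2, 3, 4, 5]))

    def test_matches_enumeration_on_mixed_signs(self):
        d = [0.4, -1.2, 2.2, 0.9, -0.3, 1.7]
        res = cohort.paired_test(d, [0.0] * 6)
        assert res.p_value == pytest.approx(exact_wilcoxon_p(d))

    def test_antisymmetric_differences_at_null_mean(self):
        d = np.array([1.0, -1.5, 1.5, -1.0, 2.0, -2.0])
        res = cohort.paired_test(d, np.zeros_like(d))
        # W+ equals its null expectation n(n+1)/4
        assert res.statistic == pytest.approx(len(d) * (len(d) + 1) / 4)


class TestBootstrapMedianCI:
    def test_constant_vector_degenerate_ci(self):
        lo, hi = cohort.bootstrap_median_ci([0.4] * 10, seed=1)
        assert lo == hi == pytest.approx(0.4)

    def test_seed_determinism(self):
        d = np.random.default_rng(3).normal(0.4, 0.1, 50)
        assert cohort.bootstrap_median_ci(d, seed=7) == cohort.bootstrap_median_ci(d, seed=7)

    @settings(derandomize=True, max_examples=20)
    @given(st.floats(-5.0, 5.0))
    def test_shift_equivariance(self, c):
        d = np.random.default_rng(5).normal(0.0, 1.0, 40)
        lo0, hi0 = cohort.bootstrap_median_ci(d, seed=11)
        lo1, hi1 = cohort.bootstrap_median_ci(d + c, seed=11)
        assert lo1 == pytest.approx(lo0 + c, abs=1e-12)
        assert hi1 == pytest.approx(hi0 + c, abs=1e-12)


class TestReaderAgreement:
    def test_identical_readers(self):
        x = np.linspace(30, 45, 20)
        res = cohort.reader_agreement(x, x)
        assert res["icc2_1"] == pytest.approx(1.0)
        assert res["bland_altman"]["loa_lower"] == res["bland_altman"]["loa_upper"] == 0.0

    def test_constant_shift_appears_as_bias(self):
        x = np.linspace(30, 45, 20)
        res = cohort.reader_agreement(x, x + 0.5)
        assert res["bland_altman"]["mean_difference"] == pytest.approx(-0.5)

    def test_icc_matches_pingouin(self):
        """Independent cross-check of the mean-squares ICC(2,1) formula."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(31)
        x = rng.normal(38, 3, 60)
        r1 = x + rng.normal(0, 0.4, 60)
        r2 = x + rng.normal(0, 0.4, 60)
        ours = cohort.reader_agreement(r1, r2)["icc2_1"]
        df = pd.DataFrame({
            "targets": np.r_[np.arange(60), np.arange(60)],
            "raters": ["a"] * 60 + ["b"] * 60,
            "scores": np.r_[r1, r2],
        })
        icc = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                       ratings="scores")
        # two-way random effects, absolute agreement, single rater
        sel = icc["Type"].isin(["ICC2", "ICC(A,1)"])
        ref = float(icc.loc[sel, "ICC"].iloc[0])
        assert ours == pytest.approx(ref, abs=1e-9)

    def test_default_noise_model_exceeds_point_nine(self):
        rng = np.random.default_rng(42)
        base = rng.normal(38, 3, 105)  # between-patient SD 3 mm
        r1, r2 = synthetic.simulate_readers(base, 0.3, seed=1)
        assert cohort.reader_agreement(r1, r2)["icc2_1"] > 0.9
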