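from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bpequant as bq
from bpequant.errors import (
    CollinearityError,
    DegenerateTableError,
    EmptyGroupError,
    InvalidSpecError,
    MatchPreconditionError,
)


def enumeration_p(xs, ys):
    """Independent oracle: two-sided p by enumerating every labeling and
    recomputing U by direct pair counting (ties count half)."""
    pooled = list(xs) + list(ys)
    n, nx = len(pooled), len(xs)
    mu = nx * (n - nx) / 2.0

    def u_of(idx):
        chosen = set(idx)
        x = [pooled[i] for i in idx]
        y = [pooled[i] for i in range(n) if i not in chosen]
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)

    u_obs = u_of(range(nx))
    hits = total = 0
    for idx in combinations(range(n), nx):
        total += 1
        hits += abs(u_of(idx) - mu) >= abs(u_obs - mu) - 1e-9
    return hits / total


class TestMannWhitney:
    def test_fully_separated_exact_p(self):
        res = bq.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u == 0
        assert res.p == pytest.approx(0.1)
        assert res.method == "exact"

    def test_exact_mode_matches_enumeration_oracle(self, rng):
        for _ in range(40):
            nx, ny = rng.integers(1, 6, size=2)
            vals = rng.integers(0, 5, size=nx + ny).astype(float)  # heavy ties
            xs, ys = vals[:nx], vals[nx:]
            got = bq.mann_whitney(xs, ys)
            assert got.method == "exact"
            assert got.p == pytest.approx(enumeration_p(xs, ys))

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=12),
           st.lists(st.floats(-50, 50), min_size=1, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_u_statistics_sum_to_product(self, xs, ys):
        ux = bq.mann_whitney(xs, ys).u
        uy = bq.mann_whitney(ys, xs).u
        assert ux + uy == pytest.approx(len(xs) * len(ys))

    def test_large_samples_use_asymptotic(self, rng):
        res = bq.mann_whitney(rng.normal(size=50), rng.normal(size=50))
        assert res.method == "asymptotic"
        assert 0 < res.p <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(EmptyGroupError):
            bq.mann_whitney([], [1.0])


class TestChiSquared:
    # the study's printed 2x2 / 2x4 characteristic tables and p-values
    @pytest.mark.parametrize(
        "table, printed_p, decimals",
        [
            ([[72, 227], [23, 48]], 0.20, 2),   # hormone tx, high vs nonhigh
            ([[72, 227], [53, 112]], 0.08, 2),  # hormone tx, high vs BRCA
            ([[7, 80, 114, 98], [4, 27, 32, 8]], 0.002, 3),   # FGT levels
            ([[7, 80, 114, 98], [10, 55, 61, 39]], 0.03, 2),  # FGT levels
            ([[198, 101], [91, 74]], 0.02, 2),  # menopause, high vs BRCA
        ],
    )
    def test_reproduces_printed_p_values(self, table, printed_p, decimals):
        _, _, p = bq.chi_squared(table)
        assert round(p, decimals) == pytest.approx(printed_p)

    def test_below_printed_floor(self):
        for table in ([[198, 101], [19, 52]],           # menopause
                      [[61, 96, 96, 46], [34, 17, 20, 0]],   # BPE grades
                      [[61, 96, 96, 46], [72, 55, 33, 5]]):
            _, _, p = bq.chi_squared(table)
            assert p < 0.001

    def test_uniform_table_is_null(self):
        stat, df, p = bq.chi_squared([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0 and df == 1

    def test_degrees_of_freedom(self):
        _, df, _ = bq.chi_squared([[5, 6, 7], [8, 9, 10]])
        assert df == 2

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            bq.chi_squared([[0, 0], [5, 6]])

    def test_non_integer_rejected(self):
        with pytest.raises(InvalidSpecError):
            bq.chi_squared([[1.5, 2], [3, 4]])


class TestBonferroni:
    def test_adjustment_and_flag(self):
        (adj, sig), = bq.bonferroni_family([0.01], m=6, fwer=0.1)
        assert adj == pytest.approx(0.06) and sig

    def test_capped_at_one(self):
        (adj, sig), = bq.bonferroni_family([0.2], m=6, fwer=0.1)
        assert adj == 1.0 and not sig

    def test_decision_equivalence_multiply_vs_divide(self, rng):
        for _ in range(10_000):
            p = float(rng.uniform(1e-6, 1.0))
            m = int(rng.integers(2, 11))
            fwer = 0.1
            assert (min(1.0, m * p) < fwer) == (p < fwer / m)
            (adj, sig), = bq.bonferroni_family([p], m=m, fwer=fwer)
            assert sig == (p < fwer / m)

    def test_family_smaller_than_tests_rejected(self):
        with pytest.raises(InvalidSpecError):
            bq.bonferroni_family([0.1, 0.2, 0.3], m=2)


class TestLinearRegression:
    def test_perfect_fit(self):
        df = pd.DataFrame({"id": range(10), "group": "brca", "age": np.arange(10.0) + 30,
                           "bmi": 25.0, "menopausal": 0, "hormone_tx": 0,
                           "fgt_level": 2})
        df["y"] = 3.0 + 2.0 * df["age"]
        r = bq.fit_linear(df, "y", ["age"], "univariate")
        coef = next(x for x in r if x.covariate == "age")
        assert coef.coefficient == pytest.approx(2.0)
        assert coef.ci_high - coef.ci_low == pytest.approx(0.0, abs=1e-8)

    def test_intercept_only_is_mean(self, default_cohort):
        r = bq.fit_linear(default_cohort, "pe_fgt", [], "multivariable")
        assert r[0].covariate == "intercept"
        assert r[0].coefficient == pytest.approx(default_cohort["pe_fgt"].mean())

    def test_collinear_design_names_columns(self, default_cohort):
        df = default_cohort.copy()
        df["age_twice"] = 2 * df["age"]
        with pytest.raises(CollinearityError) as exc:
            bq.fit_linear(df, "pe_fgt", ["age", "age_twice"], "multivariable")
        assert set(exc.value.columns) & {"age", "age_twice"}

    def test_constant_covariate_rejected(self, default_cohort):
        df = default_cohort.copy()
        df["constant"] = 1.0
        with pytest.raises(CollinearityError):
            bq.fit_linear(df, "pe_fgt", ["constant"], "univariate")

    def test_univariate_and_multivariable_modes(self, default_cohort):
        covs = ["age", "bmi", "menopausal", "hormone_tx", "fgt_level", "group"]
        uni = bq.fit_linear(default_cohort, "pe_breast", covs, "univariate")
        multi = bq.fit_linear(default_cohort, "pe_breast", covs, "multivariable")
        assert {r.covariate for r in multi} == {"intercept", "age", "bmi",
                                                "menopausal", "hormone_tx",
                                                "fgt_level", "brca"}
        age_uni = next(r for r in uni if r.covariate == "age")
        # programmed direction: BPE falls with age
        assert age_uni.coefficient < 0 and age_uni.ci_low <= age_uni.coefficient <= age_uni.ci_high
        assert len(uni) == 2 * 6  # intercept + slope per covariate


class TestPropensityMatch:
    def test_duplicate_control_group_self_matches(self):
        rng = np.random.default_rng(0)
        n = 25
        base = pd.DataFrame({
            "age": rng.uniform(30, 70, n).round(1),
            "bmi": rng.uniform(18, 35, n).round(1),
            "menopausal": rng.integers(0, 2, n),
            "hormone_tx": rng.integers(0, 2, n),
            "fgt_level": rng.integers(1, 5, n),
        })
        treated = base.copy()
        treated["group"] = "nonhigh"
        treated["id"] = [f"t{i}" for i in range(n)]
        control = base.copy()
        control["group"] = "high_nonbrca"
        control["id"] = [f"c{i}" for i in range(n)]
        cohort = pd.concat([treated, control], ignore_index=True)
        res = bq.propensity_match(cohort, "nonhigh", "high_nonbrca")
        assert len(res.pairs) == n
        for cov, smd in res.smd_after.items():
            assert smd == pytest.approx(0.0, abs=1e-12)

    def test_treated_larger_than_control_rejected(self, default_cohort):
        with pytest.raises(MatchPreconditionError):
            bq.propensity_match(default_cohort, "high_nonbrca", "nonhigh")

    def test_pairs_disjoint_and_complete(self, default_cohort):
        res = bq.propensity_match(default_cohort, "nonhigh", "high_nonbrca")
        controls = [c for _, c in res.pairs]
        assert len(res.pairs) == (default_cohort["group"] == "nonhigh").sum()
        assert len(set(controls)) == len(controls)  # without replacement

    def test_matching_reduces_confounding_on_study_cohort(self, default_cohort):
        res = bq.propensity_match(default_cohort, "nonhigh", "high_nonbrca")
        before = np.mean([abs(v) for v in res.smd_before.values()])
        after = np.mean([abs(v) for v in res.smd_after.values()])
        assert after < before


class TestCompareGroups:
    def test_identical_groups_never_flagged(self):
        rng = np.random.default_rng(3)
        n = 40
        rows = []
        for g in ("nonhigh", "high_nonbrca"):
            df = pd.DataFrame({
                "id": [f"{g}{i}" for i in range(n)], "group": g,
                "age": 50.0, "bmi": 25.0, "menopausal": 0, "hormone_tx": 0,
                "fgt_level": 2,
            })
            for m in bq.MEASURE_COLUMNS:
                df[m] = rng.permutation(np.arange(n, dtype=float))
            rows.append(df)
        # identical value multisets in both groups
        rows[1][list(bq.MEASURE_COLUMNS)] = rows[0][list(bq.MEASURE_COLUMNS)].values
        cohort = pd.concat(rows, ignore_index=True)
        res = bq.compare_groups(cohort, ("nonhigh", "high_nonbrca"))
        assert all(r.p_adjusted == 1.0 and not r.significant for r in res)

    def test_family_wiring(self, default_cohort):
        res = bq.compare_groups(default_cohort, ("high_nonbrca", "nonhigh"), m=6)
        for r in res:
            assert r.m == 6
            assert r.p_adjusted == pytest.approx(min(1.0, 6 * r.p_unadjusted))

    def test_strata_definitions(self, default_cohort):
        dense = bq.compare_groups(default_cohort, ("high_nonbrca", "nonhigh"),
                                  stratum="dense")
        assert all(r.stratum == "dense" for r in dense)
        n_dense = dense[0].n_a + dense[0].n_b
        nondense = bq.compare_groups(default_cohort, ("high_nonbrca", "nonhigh"),
                                     stratum="nondense")
        n_all = bq.compare_groups(default_cohort, ("high_nonbrca", "nonhigh"))[0]
        assert n_dense + nondense[0].n_a + nondense[0].n_b == n_all.n_a + n_all.n_b

    def test_matched_pairs_restriction(self, default_cohort):
        match = bq.propensity_match(default_cohort, "nonhigh", "high_nonbrca")
        res = bq.compare_groups(default_cohort, ("high_nonbrca", "nonhigh"),
                                pairs=match)
        assert res[0].n_a == res[0].n_b == len(match.pairs)

    def test_empty_stratum_raises(self, default_cohort):
        df = default_cohort[default_cohort["menopausal"] == 0]
        with pytest.raises(EmptyGroupError):
            bq.compare_groups(df, ("high_nonbrca", "nonhigh"),
                              stratum="postmenopausal")

    def test_programmed_group_effect_detected(self):
        spec = bq.shifted_cohort_spec("pe_fgt", shift=4.0, seed=2,
                                      n_per_group={"high_nonbrca": 100,
                                                   "nonhigh": 100})
        cohort = bq.generate_cohort(spec)
        res = {r.measure: r for r in
               bq.compare_groups(cohort, ("high_nonbrca", "nonhigh"))}
        assert res["pe_fgt"].significant
        assert res["pe_fgt"].median_a > res["pe_fgt"].median_b
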