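import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecotoxbench import (
    AdStatus,
    AnalogueRecord,
    ChemicalRecord,
    SolubilityVerdict,
    SyntheticSpec,
    build_category,
    category_ad_check,
    flag_outliers,
    gen_analogue_db,
    read_across,
    remove_outliers,
    solubility_check,
    trend_analysis,
)


def analogue(cas, kow, lc50, groups=("aryl",)):
    return AnalogueRecord(
        chemical=ChemicalRecord(
            cas_number=cas, log_kow=kow, functional_groups=frozenset(groups)
        ),
        lc50=lc50,
    )


def target(kow=2.0, groups=("aryl",), cas="T-0-0"):
    return ChemicalRecord(
        cas_number=cas, log_kow=kow, functional_groups=frozenset(groups)
    )


class TestBuildCategory:
    def test_strict_mode_requires_equal_group_sets(self):
        db = [
            analogue("1-0-0", 1.0, 5.0, groups=("aryl", "phenol")),
            analogue("2-0-0", 1.5, 5.0, groups=("aryl",)),
        ]
        cat = build_category(target(groups=("aryl", "phenol")), db)
        assert [a.chemical.cas_number for a in cat] == ["1-0-0"]

    def test_subset_mode_allows_partial_profiles(self):
        db = [
            analogue("1-0-0", 1.0, 5.0, groups=("aryl", "phenol")),
            analogue("2-0-0", 1.5, 5.0, groups=("aryl",)),
        ]
        cat = build_category(target(groups=("aryl", "phenol")), db, mode="subset")
        assert len(cat) == 2

    def test_target_itself_excluded_by_cas(self):
        db = [analogue("T-0-0", 2.0, 5.0), analogue("1-0-0", 1.0, 5.0)]
        cat = build_category(target(), db)
        assert [a.chemical.cas_number for a in cat] == ["1-0-0"]

    def test_synthetic_single_group_db_fully_matched(self):
        spec = SyntheticSpec(
            n_chemicals=20,
            group_vocabulary=("aryl",),
            n_groups_per_chemical=1,
            seed=5,
        )
        db = gen_analogue_db(spec)
        assert len(build_category(target(groups=("aryl",)), db)) == 20


class TestReadAcross:
    def test_constant_category_returns_constant(self):
        db = [analogue(f"{i}-0-0", 1.0 + i, 2.0) for i in range(5)]
        assert read_across(target(), db).lc50 == pytest.approx(2.0)

    def test_geometric_mean_closed_form(self):
        db = [analogue("1-0-0", 1.9, 1.0), analogue("2-0-0", 2.1, 100.0)]
        assert read_across(target(), db, k=2).lc50 == pytest.approx(10.0)

    def test_arithmetic_mode(self):
        db = [analogue("1-0-0", 1.9, 1.0), analogue("2-0-0", 2.1, 100.0)]
        assert read_across(target(), db, k=2, average="arithmetic").lc50 == pytest.approx(50.5)

    def test_selects_nearest_by_kow_against_brute_force(self):
        rng = np.random.default_rng(17)
        db = [
            analogue(f"{i}-0-0", float(k), float(v))
            for i, (k, v) in enumerate(
                zip(rng.uniform(-1, 6, 40), rng.uniform(0.1, 50, 40))
            )
        ]
        t = target(kow=2.7)
        result = read_across(t, db, k=5)
        # independent oracle: exhaustive sort on distance then CAS
        expected = sorted(
            db, key=lambda a: (abs(a.chemical.log_kow - 2.7), a.chemical.cas_number)
        )[:5]
        assert result.analogue_ids == [a.chemical.cas_number for a in expected]
        values = [a.lc50 for a in expected]
        assert min(values) <= result.lc50 <= max(values)

    def test_kow_distance_ties_break_by_cas(self):
        db = [
            analogue("9-0-0", 3.0, 1.0),
            analogue("1-0-0", 1.0, 8.0),  # same |distance| = 1
        ]
        result = read_across(target(kow=2.0), db, k=1)
        assert result.analogue_ids == ["1-0-0"]

    def test_no_analogues_gives_missing(self):
        assert read_across(target(), []) is None

    @given(st.integers(min_value=1, max_value=9), st.integers(0, 2**31 - 1))
    def test_prediction_bounded_by_selected_analogues(self, k, seed):
        rng = np.random.default_rng(seed)
        db = [
            analogue(f"{i}-0-0", float(kv), float(v))
            for i, (kv, v) in enumerate(
                zip(rng.uniform(-1, 6, 12), rng.uniform(0.01, 1000, 12))
            )
        ]
        result = read_across(target(kow=float(rng.uniform(-1, 6))), db, k=k)
        selected = {a.chemical.cas_number: a.lc50 for a in db}
        values = [selected[c] for c in result.analogue_ids]
        assert min(values) * (1 - 1e-9) <= result.lc50 <= max(values) * (1 + 1e-9)


class TestTrendAnalysis:
    def line_db(self, slope=-0.8, intercept=2.0, n=10, noise=None, seed=0):
        kows = np.linspace(0.0, 5.0, n)
        log_lc50 = intercept + slope * kows
        if noise is not None:
            log_lc50 = log_lc50 + np.random.default_rng(seed).normal(0, noise, n)
        return [
            analogue(f"{i}-0-0", float(k), float(10**y))
            for i, (k, y) in enumerate(zip(kows, log_lc50))
        ]

    def test_noiseless_line_recovered_exactly(self):
        result = trend_analysis(target(kow=2.5), self.line_db())
        assert result.slope == pytest.approx(-0.8, abs=1e-12)
        assert result.intercept == pytest.approx(2.0, abs=1e-12)
        assert result.r2 == pytest.approx(1.0)
        assert result.lc50 == pytest.approx(10 ** (2.0 - 0.8 * 2.5))

    def test_noisy_slope_within_three_standard_errors(self):
        db = self.line_db(n=200, noise=0.3, seed=1)
        result = trend_analysis(target(kow=2.5), db)
        x = np.array([a.chemical.log_kow for a in db])
        y = np.log10([a.lc50 for a in db])
        # independent oracle: closed-form OLS via polyfit + SE formula
        slope_hat, intercept_hat = np.polyfit(x, y, 1)
        assert result.slope == pytest.approx(slope_hat, rel=1e-9)
        assert result.intercept == pytest.approx(intercept_hat, rel=1e-9)
        resid = y - (intercept_hat + slope_hat * x)
        se = math.sqrt((resid**2).sum() / (len(x) - 2) / ((x - x.mean()) ** 2).sum())
        assert abs(result.slope - (-0.8)) < 3 * se

    def test_log_mode_always_positive_linear_mode_can_go_negative(self):
        # steeply declining linear trend extrapolated far right
        db = [
            analogue("1-0-0", 0.0, 100.0),
            analogue("2-0-0", 1.0, 50.0),
            analogue("3-0-0", 2.0, 1.0),
        ]
        log_result = trend_analysis(target(kow=8.0), db, space="log")
        linear_result = trend_analysis(target(kow=8.0), db, space="linear")
        assert log_result.lc50 > 0
        assert linear_result.lc50 < 0

    def test_too_few_or_degenerate_analogues(self):
        assert trend_analysis(target(), self.line_db(n=2)) is None
        flat = [analogue(f"{i}-0-0", 1.0, v) for i, v in enumerate((1.0, 2.0, 3.0))]
        assert trend_analysis(target(), flat) is None


class TestOutlierHandling:
    def test_explicit_removal_only(self):
        db = [analogue(f"{i}-0-0", float(i), 2.0) for i in range(6)]
        assert len(remove_outliers(db, ["3-0-0"])) == 5
        assert remove_outliers(db, []) == list(db)

    def test_planted_outlier_flagged_by_studentized_residuals(self):
        db = TestTrendAnalysis().line_db(n=20, noise=0.05, seed=3)
        bad = analogue("BAD-0-0", 2.5, 10 ** (2.0 - 0.8 * 2.5 + 2.0))  # 100x off
        flagged = flag_outliers(db + [bad], threshold=3.0)
        assert flagged == ["BAD-0-0"]

    def test_flagger_never_removes(self):
        db = TestTrendAnalysis().line_db(n=10)
        assert flag_outliers(db) == []


class TestAdCheck:
    def test_inside_when_kow_in_range_and_groups_covered(self):
        db = [analogue("1-0-0", 1.5, 1.0), analogue("2-0-0", 3.0, 1.0)]
        assert category_ad_check(target(kow=2.0), db) is AdStatus.INSIDE

    def test_outside_on_kow_extrapolation(self):
        db = [analogue("1-0-0", 1.5, 1.0), analogue("2-0-0", 3.0, 1.0)]
        assert category_ad_check(target(kow=5.0), db) is AdStatus.OUTSIDE

    def test_outside_on_uncovered_group(self):
        db = [analogue("1-0-0", 1.5, 1.0, groups=("aryl",))]
        t = target(kow=1.5, groups=("aryl", "nitrile"))
        assert category_ad_check(t, db) is AdStatus.OUTSIDE

    @given(st.data())
    def test_monotone_adding_analogues_never_flips_inside_to_outside(self, data):
        kows = data.draw(
            st.lists(st.floats(-2, 7, allow_nan=False), min_size=1, max_size=8)
        )
        extra_kow = data.draw(st.floats(-2, 7, allow_nan=False))
        db = [analogue(f"{i}-0-0", k, 1.0) for i, k in enumerate(kows)]
        t = target(kow=data.draw(st.floats(-2, 7, allow_nan=False)))
        before = category_ad_check(t, db)
        after = category_ad_check(t, db + [analogue("X-0-0", extra_kow, 1.0)])
        if before is AdStatus.INSIDE:
            assert after is AdStatus.INSIDE


class TestSolubilityScreen:
    @pytest.mark.parametrize(
        "lc50, solubility, verdict",
        [
            (68.0, 0.106, SolubilityVerdict.IMPLAUSIBLE),  # far above solubility
            (0.0356, 0.047, SolubilityVerdict.PLAUSIBLE),
            (5.0, 5.0, SolubilityVerdict.PLAUSIBLE),  # boundary: strict >
            (1.0, None, SolubilityVerdict.UNKNOWN),
        ],
    )
    def test_verdicts(self, lc50, solubility, verdict):
        assert solubility_check(lc50, solubility) is verdict

    def test_fixture_screen_reproduces_known_implausible_cases(self):
        from ecotoxbench.io import load_solubility

        table = load_solubility()
        implausible = {
            row["name"]
            for _, row in table.iterrows()
            if solubility_check(row["exp_lc50"], row["water_solubility"])
            is SolubilityVerdict.IMPLAUSIBLE
        }
        # the two perfluorinated acids exceed solubility by orders of magnitude
        assert "Heptadecafluorooctanesulfonic acid" in implausible
        assert "Pentadecafluorooctanoic acid" in implausible
        assert "Anthracene" not in implausible
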