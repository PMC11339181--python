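"""Study enumeration, power-law fitting and cohort statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stentflow.porous import load_hr_scenarios
from stentflow.study import (
    enumerate_runs,
    fit_power_law,
    group_stats,
    render_report,
    threshold_classification,
    welch_from_summaries,
)


class TestEnumerateRuns:
    def test_full_study_design(self):
        plan = enumerate_runs(load_hr_scenarios(), ["g0", "g1", "g2", "g3", "g4"])
        assert (plan["kind"] == "treated").sum() == 80
        assert (plan["kind"] == "pre").sum() == 5

    def test_single_geometry(self):
        plan = enumerate_runs(load_hr_scenarios(), ["g0"])
        assert (plan["kind"] == "treated").sum() == 16
        assert (plan["kind"] == "pre").sum() == 1

    def test_empty_geometry_list(self):
        plan = enumerate_runs(load_hr_scenarios(), [])
        assert len(plan) == 0

    def test_duplicate_scenario_ids_rejected(self):
        df = load_hr_scenarios()
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError):
            enumerate_runs(dup, ["g0"])


class TestPowerLawFit:
    def test_exact_points_recovered(self):
        lc = np.array([1.0, 5.0, 20.0, 100.0])
        fit = fit_power_law(lc, 0.1 * lc**0.3)
        assert fit.a == pytest.approx(0.1)
        assert fit.b == pytest.approx(0.3)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_values_give_flat_fit(self):
        fit = fit_power_law([1.0, 5.0, 20.0], [0.4, 0.4, 0.4])
        assert fit.b == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_noisy_exponent_recovery(self):
        rng = np.random.default_rng(42)
        lc = np.logspace(0, 2.3, 30)
        amvr = 0.08 * lc**0.35 * np.exp(rng.normal(0, 0.05, len(lc)))
        fit = fit_power_law(lc, amvr)
        assert fit.b == pytest.approx(0.35, rel=0.10)

    @given(a=st.floats(0.01, 0.3), b=st.floats(0.05, 0.8))
    @settings(max_examples=30, deadline=None)
    def test_round_trip_on_exact_power_laws(self, a, b):
        lc = np.array([2.0, 8.0, 30.0, 120.0])
        fit = fit_power_law(lc, a * lc**b)
        assert fit.a == pytest.approx(a, rel=1e-6)
        assert fit.b == pytest.approx(b, rel=1e-6)

    def test_nonpositive_amvr_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            fit = fit_power_law([1, 5, 20, 100], [-0.1, 0.2, 0.3, 0.5])
        assert fit.lc_range == (5.0, 100.0)

    def test_nonpositive_lc_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([0.0, 1.0, 2.0], [0.1, 0.2, 0.3])

    def test_refine_linear_stays_close(self):
        lc = np.array([1.0, 5.0, 20.0, 100.0])
        fit = fit_power_law(lc, 0.1 * lc**0.3, refine_linear=True)
        assert fit.a == pytest.approx(0.1, rel=1e-4)
        assert fit.b == pytest.approx(0.3, rel=1e-4)


class TestWelchFromSummaries:
    def test_nominal_device_comparison_from_published_summaries(self):
        p = welch_from_summaries(51.9, 11.8, 20, 60.3, 9.5, 15)
        assert 0.024 <= p <= 0.028

    def test_oversized_device_comparison_from_published_summaries(self):
        p = welch_from_summaries(25.7, 9.4, 20, 27.5, 8.8, 25)
        assert 0.50 <= p <= 0.53

    def test_equal_means_give_p_one(self):
        assert welch_from_summaries(10, 2, 10, 10, 2, 10) == pytest.approx(1.0)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_from_summaries(10, 2, 1, 11, 2, 10)


def synthetic_results(rng=None):
    """Per-run table with known group structure (two devices × two sizings)."""
    rng = rng or np.random.default_rng(3)
    rows = []
    specs = [("PED", 48, "nominal", 0.50), ("P64", 64, "nominal", 0.60),
             ("PED", 48, "oversized", 0.25), ("P64", 64, "oversized", 0.27)]
    sid = 1
    for dev, wires, dep, mean in specs:
        for _ in range(5):
            rows.append({
                "geometry_id": 0, "scenario_id": sid, "device": dev,
                "wire_count": wires, "deployment": dep,
                "l_c": float(rng.uniform(5, 180)), "q_c": 200.0,
                "stav_pre": 0.1, "stav_fd": 0.1 * (1 - mean),
                "amvr": mean + rng.normal(0, 0.04),
            })
            sid += 1
    return pd.DataFrame(rows)


class TestGroupStats:
    def test_per_run_welch_matches_summary_welch(self):
        res = synthetic_results()
        gs = group_stats(res)
        for dep in ("nominal", "oversized"):
            sub = res[res.deployment == dep]
            g1 = sub[sub.device == "P64"]["amvr"] * 100
            g2 = sub[sub.device == "PED"]["amvr"] * 100
            p_summary = welch_from_summaries(
                g1.mean(), g1.std(ddof=1), len(g1),
                g2.mean(), g2.std(ddof=1), len(g2),
            )
            assert gs.p_by_deployment[dep] == pytest.approx(p_summary, abs=1e-3)

    def test_identical_groups_give_p_one(self):
        res = synthetic_results()
        res.loc[res.device == "P64", "amvr"] = (
            res.loc[res.device == "PED", "amvr"].values
        )
        gs = group_stats(res)
        assert gs.p_by_deployment["nominal"] == pytest.approx(1.0)

    def test_derived_quantities(self):
        res = synthetic_results()
        gs = group_stats(res)
        tab = gs.table
        expect = (tab.loc[("P64", "nominal"), "mean_pct"]
                  - tab.loc[("PED", "nominal"), "mean_pct"])
        assert gs.mean_diff_nominal_pct == pytest.approx(expect)
        for dev in ("PED", "P64"):
            nom = tab.loc[(dev, "nominal"), "mean_pct"]
            ovs = tab.loc[(dev, "oversized"), "mean_pct"]
            assert gs.relative_decrease[dev] == pytest.approx((nom - ovs) / nom)

    def test_small_group_excluded_with_warning(self):
        res = synthetic_results()
        res = res[~((res.device == "P64") & (res.deployment == "oversized")
                    & (res.scenario_id > 16))]
        res = pd.concat([res[~((res.device == "P64")
                               & (res.deployment == "oversized"))],
                         res[(res.device == "P64")
                             & (res.deployment == "oversized")].iloc[:1]])
        with pytest.warns(UserWarning):
            gs = group_stats(res)
        assert "oversized" not in gs.p_by_deployment


class TestThresholdClassification:
    def test_boundary_value_passes_inclusively(self):
        res = synthetic_results()
        res.loc[res.index[0], "amvr"] = 0.35
        out, _ = threshold_classification(res, 0.35)
        assert bool(out.iloc[0]["passes"])

    def test_all_zero_amvr_all_fail(self):
        res = synthetic_results()
        res["amvr"] = 0.0
        out, rates = threshold_classification(res)
        assert not out["passes"].any()
        assert (rates == 0).all()

    def test_pass_count_matches_brute_force(self):
        res = synthetic_results()
        out, _ = threshold_classification(res, 0.35)
        brute = sum(1 for v in res["amvr"] if v >= 0.35)
        assert out["passes"].sum() == brute

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            threshold_classification(pd.DataFrame())


def test_render_report_contains_cohort_tables():
    res = synthetic_results()
    fit = fit_power_law(res["l_c"], res["amvr"].clip(lower=0.01))
    text = render_report(res, fit)
    assert "| PED | nominal |" in text
    assert "Power law" in text
    assert "threshold" in text.lower()
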