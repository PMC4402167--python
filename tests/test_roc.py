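"""ROC construction, cutpoint indices, selection policies and DeLong."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenocut.roc_cutpoint import (auc_with_variance, build_roc, delong_test,
                                   distance01, lr_plus, round2,
                                   scenario_filter, select_cutpoint,
                                   stepwise_report, youden)


def _brute_auc(x, y):
    pos = x[y == 1]
    neg = x[y == 0]
    c = sum(1.0 if a > b else (0.5 if a == b else 0.0)
            for a in pos for b in neg)
    return c / (len(pos) * len(neg))


class TestScenarioFilter:
    def _table(self):
        return pd.DataFrame({
            "phenotype": ["HNW", "MONW", "OW_HEALTHY", "OW_SICK", "MHO",
                          "MDO"] * 4,
            "wc_cm": np.linspace(70, 120, 24),
        })

    def test_six_group_keeps_everyone(self):
        sub, y = scenario_filter(self._table(), "six_group")
        assert len(sub) == 24
        assert set(y) == {0, 1}

    def test_four_group_drops_atypicals(self):
        sub, _ = scenario_filter(self._table(), "four_group")
        assert not sub["phenotype"].isin(["MONW", "MHO"]).any()
        assert len(sub) == 16

    def test_two_group_keeps_extremes_only(self):
        sub, y = scenario_filter(self._table(), "two_group")
        assert set(sub["phenotype"]) == {"HNW", "MDO"}
        assert (y == sub["phenotype"].eq("MDO").to_numpy()).all()

    def test_single_class_rejected(self):
        df = pd.DataFrame({"phenotype": ["HNW"] * 5,
                           "wc_cm": np.arange(5.0)})
        with pytest.raises(ValueError):
            scenario_filter(df, "two_group")


class TestBuildROC:
    def test_perfect_separation(self):
        curve = build_roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert curve.auc == pytest.approx(1.0)

    def test_uninformative_marker_near_half(self, rng):
        x = rng.normal(size=5000)
        y = rng.integers(0, 2, 5000)
        assert abs(build_roc(x, y).auc - 0.5) < 0.03

    def test_matches_pairwise_concordance_oracle(self, rng):
        for _ in range(10):
            x = np.round(rng.normal(size=30), 1)  # induce ties
            y = rng.integers(0, 2, 30)
            if y.sum() in (0, 30):
                continue
            assert build_roc(x, y).auc == pytest.approx(
                _brute_auc(x, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            build_roc([1.0, 2.0], [1, 1])

    def test_endpoints_present(self, rng):
        curve = build_roc(rng.normal(size=40), rng.integers(0, 2, 40))
        assert curve.sens[0] == 1.0 and curve.spec[0] == 0.0
        assert curve.sens[-1] == 0.0 and curve.spec[-1] == 1.0

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.tuples(st.integers(-5, 5), st.booleans()),
                    min_size=4, max_size=40))
    def test_trapezoid_equals_concordance_everywhere(self, pairs):
        x = np.array([p[0] for p in pairs], dtype=float)
        y = np.array([p[1] for p in pairs], dtype=int)
        if y.sum() in (0, len(y)):
            return
        curve = build_roc(x, y)  # raises internally beyond 1e-10
        assert curve.auc == pytest.approx(_brute_auc(x, y), abs=1e-10)


class TestIndices:
    def test_published_operating_points(self):
        # women six-group at 91.25 cm and men six/four/two-group at 98.15 cm
        assert round2(youden(0.733, 0.685)) == 0.42
        assert round2(distance01(0.733, 0.685)) == 0.41
        assert round2(youden(0.748, 0.697)) == 0.45
        assert round2(distance01(0.748, 0.697)) == 0.39
        assert round2(lr_plus(0.838, 0.823)) == 4.73
        assert round2(lr_plus(0.960, 0.995)) == 192.00

    def test_perfect_point(self):
        assert youden(1, 1) == pytest.approx(1.0)
        assert distance01(1, 1) == 0.0
        assert lr_plus(1, 1) == math.inf

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            youden(1.2, 0.5)
        with pytest.raises(ValueError):
            distance01(-0.1, 0.5)


class TestSelectCutpoint:
    def test_unique_maximum(self, rng):
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(4, 1, 200)])
        y = np.repeat([0, 1], 200)
        curve = build_roc(x, y)
        rep = select_cutpoint(curve, policy="youden")
        finite = np.isfinite(curve.thresholds)
        J = curve.sens[finite] + curve.spec[finite] - 1
        assert rep.youden == pytest.approx(J.max())

    def test_policy_prefers_sensitivity_within_epsilon(self, rng):
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(3, 1, 300)])
        y = np.repeat([0, 1], 300)
        rep_y = select_cutpoint(build_roc(x, y), policy="youden")
        rep_s = select_cutpoint(build_roc(x, y), policy="youden_sens")
        assert rep_s.sens >= rep_y.sens
        assert rep_s.cutpoint <= rep_y.cutpoint

    def test_agrees_with_exhaustive_scan(self, rng):
        x = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        if y.sum() in (0, 50):
            y[0] = 1 - y[0]
        curve = build_roc(x, y)
        rep = select_cutpoint(curve, policy="youden_sens", epsilon=0.005)
        finite = np.isfinite(curve.thresholds)
        t, se, sp = (curve.thresholds[finite], curve.sens[finite],
                     curve.spec[finite])
        J = se + sp - 1
        best = None
        for i in range(len(t)):
            key = (J[i] >= J.max() - 0.005, se[i], -t[i])
            if J[i] >= J.max() - 0.005 and (best is None or
                                            key > best[0]):
                best = (key, i)
        assert rep.cutpoint == t[best[1]]

    def test_identities_hold_exactly(self, rng):
        x = rng.normal(size=80)
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        rep = select_cutpoint(build_roc(x, y))
        assert rep.youden == pytest.approx(rep.sens + rep.spec - 1, abs=1e-12)
        assert rep.distance01 == pytest.approx(
            math.hypot(1 - rep.sens, 1 - rep.spec), abs=1e-12)
        if rep.spec < 1:
            assert rep.lr_plus == pytest.approx(
                rep.sens / (1 - rep.spec), abs=1e-12)


class TestDeLong:
    def test_identical_subsets_null_result(self, rng):
        x = rng.normal(size=100)
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        mask = np.ones(100, dtype=bool)
        res = delong_test(x, y, mask, mask)
        assert res["z"] == 0.0 and res["p"] == 1.0 and res["paired"]

    def test_variance_close_to_bootstrap(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 1, 250), rng.normal(1, 1, 250)])
        y = np.repeat([0, 1], 250)
        auc, var = auc_with_variance(x, y)
        boots = []
        for _ in range(600):
            idx = rng.integers(0, 500, 500)
            xb, yb = x[idx], y[idx]
            if yb.sum() in (0, 500):
                continue
            a, _ = auc_with_variance(xb, yb)
            boots.append(a)
        assert var == pytest.approx(np.var(boots, ddof=1), rel=0.15)

    def test_detects_a_real_difference(self, rng):
        xa = np.concatenate([rng.normal(0, 1, 300), rng.normal(3, 1, 300)])
        xb = np.concatenate([rng.normal(0, 1, 300), rng.normal(0.3, 1, 300)])
        x = np.concatenate([xa, xb])
        y = np.concatenate([np.repeat([0, 1], 300)] * 2)
        a_mask = np.arange(1200) < 600
        res = delong_test(x, y, a_mask, ~a_mask)
        assert res["p"] < 1e-6 and not res["paired"]


class TestStepwiseReport:
    def test_demo_cohort_emits_six_reports(self):
        from phenocut.cohort_synth import default_spec, generate_cohort
        from phenocut.phenotyping import run_phenotyping
        from phenocut.preprocessing import derive_columns

        df = derive_columns(generate_cohort(default_spec(2000), seed=9))
        table, _, _ = run_phenotyping(df, seed=9)
        rep = stepwise_report(table)
        reports = [rep["genders"][g]["cutpoints"][s]
                   for g in ("F", "M")
                   for s in ("six_group", "four_group", "two_group")]
        assert len(reports) == 6
        for r in reports:
            assert 60 < r.cutpoint < 140
        for g in ("F", "M"):
            assert len(rep["genders"][g]["delong"]) == 3

    def test_empty_gender_rejected(self):
        df = pd.DataFrame({"gender": ["F"] * 6,
                           "wc_cm": np.arange(6.0) + 80,
                           "phenotype": ["HNW", "MDO"] * 3})
        with pytest.raises(ValueError):
            stepwise_report(df)
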