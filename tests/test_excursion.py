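"""Incremental AUC: hand examples, quadrature oracle, invariances, cohort tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ogttmet.excursion import (classify_responsiveness, cohort_aucs,
                               compare_auc_phases, incremental_auc, subject_aucs)
from ogttmet.preprocess import presence_filter, sum_normalize
from ogttmet.synthetic import CohortConfig, generate_cohort

T = np.array([0, 30, 60, 90, 120], dtype=float)


class TestIncrementalAuc:
    def test_constant_series_zero(self):
        assert incremental_auc(T, [100] * 5) == 0.0

    def test_hand_trapezoid_positive(self):
        # segments 150 + 450 + 450 + 150
        assert incremental_auc(T, [0, 10, 20, 10, 0]) == pytest.approx(1200.0)

    def test_hand_trapezoid_negative_plateau(self):
        # v - v0 = (0, -10, -10, -10, -10): -150 - 900
        assert incremental_auc(T, [10, 0, 0, 0, 0]) == pytest.approx(-1050.0)

    def test_interior_missing_bridged_linearly(self):
        full = incremental_auc(T, [0, 10, 20, 30, 40])
        gap = incremental_auc(T, [0, 10, np.nan, 30, 40])
        assert gap == pytest.approx(full)  # linear series: bridge is exact

    def test_missing_terminal_integrates_observed_span(self):
        short = incremental_auc(T, [0, 10, 20, np.nan, np.nan])
        assert short == pytest.approx(incremental_auc(T[:3], [0, 10, 20]))

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            incremental_auc(T, [np.nan, 1, 2, 3, 4])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            incremental_auc(T, [1, 2, np.nan, np.nan, np.nan])

    @given(st.lists(st.floats(-50, 50), min_size=5, max_size=5),
           st.floats(0.1, 10), st.floats(-100, 100))
    @settings(max_examples=100, deadline=None)
    def test_linearity_and_baseline_invariance(self, vals, a, b):
        v = np.asarray(vals)
        base = incremental_auc(T, v)
        assert incremental_auc(T, a * v + b) == pytest.approx(a * base, rel=1e-9, abs=1e-7)

    def test_time_reversal_antisymmetry(self, rng):
        """Reversing an odd-symmetric baseline-0 excursion negates the AUC."""
        v = np.array([0.0, 3.0, 0.0, -3.0, 0.0])
        assert incremental_auc(T, v) == pytest.approx(-incremental_auc(T, v[::-1]))

    def test_dense_quadrature_oracle(self, rng):
        for _ in range(200):
            v = rng.normal(size=5) * 10
            t_dense = np.linspace(0, 120, 4801)
            v_dense = np.interp(t_dense, T, v - v[0])
            oracle = np.trapezoid(v_dense, t_dense)
            assert incremental_auc(T, v) == pytest.approx(oracle, abs=1e-9)

    def test_total_mode_keeps_baseline(self):
        assert incremental_auc(T, [10, 0, 0, 0, 0], total=True) == pytest.approx(150.0)


def _mini_panel(aucs_by_subject):
    """Panel with one metabolite whose per-subject series produce the given AUCs
    via a rectangle-ish bump: value(t) = base + c * bump."""
    rows = []
    bump = np.array([0, 1, 1, 1, 0], dtype=float)  # trapezoid area = 90
    for s, target in aucs_by_subject.items():
        c = target / 90.0
        for t, u in zip(T, bump):
            rows.append({"subject_id": s, "phase": "pre", "time_min": int(t),
                         "metabolite_id": "m", "intensity": 100 + c * u})
    return pd.DataFrame(rows)


class TestCohortAucs:
    def test_hand_t_statistic(self):
        panel = _mini_panel({"A": 1.0, "B": 2.0, "C": 3.0})
        out = cohort_aucs(panel)
        row = out.iloc[0]
        assert row["n"] == 3
        assert row["mean_auc"] == pytest.approx(2.0)
        assert row["t"] == pytest.approx(3.464, abs=1e-3)
        assert row["p"] == pytest.approx(0.0742, abs=1e-4)
        assert not row["nonzero"]

    def test_flat_series_degenerate(self):
        panel = _mini_panel({"A": 0.0, "B": 0.0, "C": 0.0})
        out = cohort_aucs(panel)
        assert bool(out.iloc[0]["degenerate"])
        assert out.iloc[0]["mean_auc"] == pytest.approx(0.0)

    def test_small_phase_untestable(self):
        panel = _mini_panel({"A": 1.0, "B": 2.0})
        out = cohort_aucs(panel)
        assert bool(out.iloc[0]["untestable"])

    def test_planted_archetype_detected(self):
        """Strong carbohydrate-responder excursions test nonzero in >= 95%
        of seeds at amplitude 2 total-SD with 12 completers."""
        hits = 0
        trials = 0
        for seed in range(10):
            cfg = CohortConfig(n_metabolites=12, n_planted=0, amp_range=(2.0, 2.0),
                               missing_frac=0.0, seed=4000 + seed)
            cohort = generate_cohort(cfg)
            carb = set(cohort.metabolite_info.loc[
                cohort.metabolite_info["archetype"] == "carb_raised", "metabolite_id"])
            out = cohort_aucs(cohort.panel)
            post = out[(out["phase"] == "post") & out["metabolite_id"].isin(carb)]
            hits += int(post["nonzero"].sum())
            trials += len(post)
        assert hits / trials >= 0.95


class TestClassification:
    @pytest.mark.parametrize("pre,post,expect", [
        (True, True, "both"), (True, False, "pre_only"),
        (False, True, "post_only"), (False, False, "neither"),
    ])
    def test_truth_table(self, pre, post, expect):
        exc = pd.DataFrame([
            {"metabolite_id": "m", "phase": "pre", "nonzero": pre, "untestable": False},
            {"metabolite_id": "m", "phase": "post", "nonzero": post, "untestable": False},
        ])
        out = classify_responsiveness(exc)
        assert out.iloc[0]["class"] == expect
        assert not out.iloc[0]["flagged"]

    def test_untestable_phase_flagged_neither(self):
        exc = pd.DataFrame([
            {"metabolite_id": "m", "phase": "pre", "nonzero": False, "untestable": True},
            {"metabolite_id": "m", "phase": "post", "nonzero": False, "untestable": False},
        ])
        out = classify_responsiveness(exc)
        assert out.iloc[0]["class"] == "neither"
        assert bool(out.iloc[0]["flagged"])


class TestCompareAucPhases:
    def test_identical_phases_null(self):
        rows = []
        for s, a in zip("ABCDE", [1.0, 2.0, 3.0, 2.5, 1.5]):
            rows.append({"metabolite_id": "m", "phase": "pre", "subject_id": s, "auc": a})
            rows.append({"metabolite_id": "m", "phase": "post", "subject_id": s, "auc": a})
        delta, p = compare_auc_phases(pd.DataFrame(rows))
        assert delta == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_planted_auc_shift_power(self):
        """Planted AUC responders at 1.5 total-SD are detected (p<0.05) with
        power >= 0.7 across seeds and responders."""
        detected = 0
        total = 0
        for seed in range(8):
            cfg = CohortConfig(n_metabolites=20, n_planted=8, effect_size_auc=1.5,
                               missing_frac=0.0, seed=6000 + seed)
            cohort = generate_cohort(cfg)
            per_subject = subject_aucs(cohort.panel)
            auc_resp = cohort.truth.loc[cohort.truth["channel"] == "auc", "metabolite_id"]
            for mid in auc_resp:
                sub = per_subject[per_subject["metabolite_id"] == mid]
                _, p = compare_auc_phases(sub)
                detected += int(p < 0.05)
                total += 1
        assert detected / total >= 0.7

    def test_sign_flip_recovered(self):
        """Negative pre excursion turning positive post yields a positive delta."""
        rows = []
        for s in "ABCDEFGH":
            rows.append({"metabolite_id": "m", "phase": "pre", "subject_id": s,
                         "auc": -100 + np.random.default_rng(ord(s)).normal(0, 5)})
            rows.append({"metabolite_id": "m", "phase": "post", "subject_id": s,
                         "auc": 100 + np.random.default_rng(ord(s) + 1).normal(0, 5)})
        delta, p = compare_auc_phases(pd.DataFrame(rows))
        assert delta > 0
        assert p < 0.01


def test_subject_aucs_skips_unusable_series(small_cohort):
    per_subject = subject_aucs(small_cohort.panel)
    # non-OGTT pre subjects (t=0 only) can never contribute
    pre = per_subject[per_subject["phase"] == "pre"]
    assert pre["subject_id"].nunique() <= 13
    assert per_subject["auc"].notna().all()


def test_pipeline_counts_match_archetype_mix():
    """With a null intervention, responsive metabolites are the dynamic
    archetypes; inert/fasting-shifted land in 'neither'."""
    cfg = CohortConfig(n_metabolites=60, n_planted=0, missing_frac=0.0, seed=99)
    cohort = generate_cohort(cfg)
    panel, _ = presence_filter(cohort.panel)
    panel = sum_normalize(panel)
    classes = classify_responsiveness(cohort_aucs(panel)).merge(
        cohort.metabolite_info, on="metabolite_id")
    dynamic = classes["archetype"].isin(["lipid_suppressed", "carb_raised", "late_rise_xeno"])
    responsive = classes["class"] != "neither"
    # dynamic metabolites are predominantly responsive, flat ones are not
    assert responsive[dynamic].mean() > 0.8
    assert responsive[~dynamic].mean() < 0.3
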