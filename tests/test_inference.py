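"""The four comparison stages: contracts, degenerate inputs, exact recovery."""

import numpy as np
import pandas as pd
import pytest

from troutsperm import (DeformityModel, DragModel, MorphologyModel, SpeedModel,
                        compare_deformity, compare_morphology, drag_model,
                        lsmeans_contrasts, speed_vs_morphology)
from troutsperm.inference import DesignError


def _counts(cold, warm, total=100):
    rows = []
    for i, d in enumerate(cold):
        rows.append(("c%d" % i, "cold", d, total))
    for i, d in enumerate(warm):
        rows.append(("w%d" % i, "warm", d, total))
    return pd.DataFrame(rows, columns=["male_id", "group", "n_deformed", "n_total"])


class TestDeformity:
    def test_identical_proportions_zero_log_odds(self):
        res = compare_deformity(_counts([30, 30], [30, 30]))
        assert res.params.iloc[1] == pytest.approx(0.0, abs=1e-10)

    def test_matches_hand_computed_odds_ratio(self):
        # pooled 2×2: cold 20/100 vs warm 40/100 -> OR = (40/60)/(20/80) = 8/3
        res = compare_deformity(_counts([10, 10], [20, 20], total=50))
        assert np.exp(res.params.iloc[1]) == pytest.approx(8 / 3, rel=1e-6)

    def test_design_errors(self):
        with pytest.raises(DesignError):
            DeformityModel(_counts([30], [30, 30]))
        bad = _counts([30, 30], [30, 30])
        bad.loc[0, "n_total"] = 0
        with pytest.raises(DesignError):
            DeformityModel(bad)

    def test_separation_flagged_not_fatal(self):
        res = compare_deformity(_counts([0, 0], [100, 100]))
        assert any("separation" in f for f in res.flags)

    def test_from_males_frame(self, males_frame):
        res = DeformityModel.from_males_frame(males_frame).fit()
        assert res.n_obs == 16
        assert 0.0 <= res.pvalues.iloc[1] <= 1.0


def _cells(values_by_male, groups, measure="ratio_LF_AH_per_um"):
    rows = []
    for male, vals in values_by_male.items():
        for v in vals:
            rows.append((male, groups[male], v))
    return pd.DataFrame(rows, columns=["male_id", "group", measure])


class TestMorphology:
    def test_log_transform_selected_for_sizes(self, derived):
        assert compare_morphology("A_H_um2", derived).transform == "log"
        assert compare_morphology("ratio_LF_AH_per_um", derived).transform == "identity"

    def test_group_effect_recovered_without_noise(self):
        groups = {"c1": "cold", "c2": "cold", "w1": "warm", "w2": "warm"}
        cells = _cells({"c1": [1.0, 1.0], "c2": [1.2, 1.2],
                        "w1": [1.5, 1.5], "w2": [1.7, 1.7]}, groups)
        res = compare_morphology("ratio_LF_AH_per_um", cells)
        assert res.params.iloc[1] == pytest.approx(0.5, rel=1e-8)
        assert any("degenerate" in f for f in res.flags)

    def test_all_identical_degenerate_flag(self):
        groups = {"c1": "cold", "c2": "cold", "w1": "warm", "w2": "warm"}
        cells = _cells({m: [2.0, 2.0] for m in groups}, groups)
        res = compare_morphology("ratio_LF_AH_per_um", cells)
        assert any("degenerate" in f for f in res.flags)

    def test_design_and_data_errors(self, derived):
        one_male = derived[derived.male_id.isin(["C1", "W1", "W2"])]
        with pytest.raises(DesignError, match="2 males"):
            MorphologyModel(one_male, "A_H_um2")
        neg = derived.copy()
        neg.loc[neg.index[0], "A_H_um2"] = -1.0
        with pytest.raises(DesignError, match="non-positive"):
            MorphologyModel(neg, "A_H_um2")

    def test_study_scale_result_contract(self, derived):
        res = compare_morphology("ratio_LF_AH_per_um", derived)
        assert res.n_obs == 640 and res.n_groups == 16
        assert list(res.terms.columns) == ["estimate", "se", "statistic", "df", "pvalue"]
        assert 13.0 < res.terms["df"].iloc[1] < 15.0  # male-level group test


def _per_male(ratio, vap, groups=None):
    n = len(ratio)
    d = pd.DataFrame({"male_id": [f"m{i}" for i in range(n)],
                      "ratio_LF_AH_per_um": ratio, "vap": vap})
    if groups is not None:
        d["group"] = groups
    return d


class TestSpeed:
    def test_exact_linear_recovery(self):
        ratio = np.linspace(1.0, 2.5, 16)
        res = speed_vs_morphology(_per_male(ratio, 10 + 2 * ratio),
                                  "ratio_LF_AH_per_um", "vap", 8.0)
        assert res.params.iloc[1] == pytest.approx(2.0, rel=1e-10)
        assert res.transform == "identity"

    def test_log_response_at_13C(self):
        ratio = np.linspace(1.0, 2.5, 16)
        res = speed_vs_morphology(_per_male(ratio, np.exp(0.3 + 0.5 * ratio)),
                                  "ratio_LF_AH_per_um", "vap", 13.0)
        assert res.transform == "log"
        assert res.params.iloc[1] == pytest.approx(0.5, rel=1e-8)

    def test_constant_predictor_degenerate(self):
        res = speed_vs_morphology(_per_male(np.full(16, 1.5), np.arange(16.0) + 50),
                                  "ratio_LF_AH_per_um", "vap", 8.0)
        assert any("degenerate" in f for f in res.flags)
        assert not res.converged

    def test_acclimation_term_included(self):
        ratio = np.linspace(1.0, 2.5, 16)
        groups = ["cold"] * 8 + ["warm"] * 8
        res = speed_vs_morphology(_per_male(ratio, 10 + 2 * ratio, groups),
                                  "ratio_LF_AH_per_um", "vap", 8.0,
                                  include_acclimation=True)
        assert "group[warm]" in res.terms.index

    def test_too_few_males(self):
        with pytest.raises(DesignError, match="males"):
            SpeedModel(_per_male(np.arange(4.0), np.arange(4.0)),
                       "ratio_LF_AH_per_um", "vap", 8.0)


def _drag_frame(effect_act=0.0, effect_int=0.0, noise=0.0, seed=0, base=5.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(16):
        grp = "cold" if i < 8 else "warm"
        for t, is13 in ((8.0, 0), (13.0, 1)):
            mu = base + effect_act * is13 + effect_int * is13 * (grp == "warm")
            rows.append((f"m{i}", grp, t, mu + noise * rng.standard_normal()))
    return pd.DataFrame(rows, columns=["male_id", "group",
                                       "activation_temp_C", "mean_D_pN"])


class TestDrag:
    def test_identical_values_all_effects_zero(self):
        res = drag_model(_drag_frame())
        assert np.allclose(res.params.iloc[1:], 0.0, atol=1e-10)
        assert np.allclose(res.contrasts["estimate"], 0.0, atol=1e-10)
        assert any("degenerate" in f for f in res.flags)

    def test_pure_activation_effect_exact(self):
        res = drag_model(_drag_frame(effect_act=-1.0))
        assert res.terms.loc["activation[13C]", "estimate"] == pytest.approx(-1.0, rel=1e-8)
        inter = [t for t in res.terms.index if ":" in t][0]
        assert abs(res.terms.loc[inter, "estimate"]) < 1e-8

    def test_contrasts_equal_marginal_mean_differences(self):
        # balanced, additive, noise-free: LS-means == raw marginal means
        d = _drag_frame(effect_act=-0.8, effect_int=-0.3)
        res = drag_model(d)
        raw = d.pivot_table(index="group", columns="activation_temp_C",
                            values="mean_D_pN")
        want = {"cold": raw.loc["cold", 13.0] - raw.loc["cold", 8.0],
                "warm": raw.loc["warm", 13.0] - raw.loc["warm", 8.0]}
        for _, row in res.contrasts.iterrows():
            assert row["estimate"] == pytest.approx(want[row["within"]], abs=1e-9)

    def test_contrast_df_is_14_for_study_design(self):
        res = drag_model(_drag_frame(effect_act=-0.8, noise=0.3, seed=1))
        assert np.allclose(res.contrasts["df"], 14.0, atol=0.05)

    def test_missing_design_cell_rejected(self):
        d = _drag_frame().drop(index=0)
        with pytest.raises(DesignError, match="m0"):
            DragModel(d)

    def test_residual_df_method(self):
        res = drag_model(_drag_frame(effect_act=-0.8, noise=0.3, seed=1),
                         df_method="residual")
        assert (res.terms["df"] == 28.0).all()

    def test_unknown_contrast_factor(self):
        res = drag_model(_drag_frame(noise=0.3, seed=2))
        with pytest.raises(DesignError, match="season"):
            lsmeans_contrasts(res, within="season")

    def test_null_contrasts_non_significant_large_n(self):
        # zero effects, tiny noise relative to n: both contrasts ~0, p >> 0.05
        res = drag_model(_drag_frame(noise=0.2, seed=3))
        assert (res.contrasts["pvalue"] > 0.05).all()
        assert np.allclose(res.contrasts["estimate"], 0.0, atol=0.3)

    def test_reproducible_bit_for_bit(self):
        d = _drag_frame(effect_act=-0.8, noise=0.3, seed=4)
        a, b = drag_model(d), drag_model(d)
        assert a.terms.equals(b.terms)
        assert a.contrasts.equals(b.contrasts)

    def test_summary_contains_contrasts(self):
        s = drag_model(_drag_frame(noise=0.3, seed=5)).summary()
        assert "Post-hoc contrasts" in s and "13C - 8C" in s
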