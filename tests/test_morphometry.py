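"""Prolate-spheroid geometry and per-cell derivations.

The closed-form head surface area is validated against an independent
numerical oracle: the surface of revolution of the meridional ellipse,
S = 2π ∫ x(z) sqrt(1 + x'(z)²) dz, integrated with adaptive quadrature.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from troutsperm import (SpermCellRecord, derive_cell, derive_cells,
                        ellipticity, head_surface_area, summarize_per_male)
from troutsperm.morphometry import (DeformedCellError, ProlateViolationError,
                                    prolate_violations)

# value pinned from the quadrature oracle below for (L_H, W_H) = (4, 2):
# oracle returns 21.47843532788372; 2π(1 + 2·arcsin(√3/2)/(√3/2)) agrees
AREA_4_2 = 21.478435327883734


def spheroid_area_numeric(L_H: float, W_H: float) -> float:
    """Surface-of-revolution oracle, independent of the closed form."""
    r_p, r_e = 0.5 * L_H, 0.5 * W_H

    def integrand(z):
        # x(z) = r_e * sqrt(1 - z²/r_p²); handle the pole analytically
        u = 1.0 - (z / r_p) ** 2
        x = r_e * math.sqrt(max(u, 0.0))
        if u <= 0:
            return 0.0
        dxdz = -r_e * z / (r_p**2 * math.sqrt(u))
        return x * math.sqrt(1.0 + dxdz**2)

    val, _ = quad(integrand, -r_p, r_p, limit=200)
    return 2.0 * math.pi * val


class TestEllipticity:
    def test_sphere_is_zero(self):
        assert ellipticity(1.0, 1.0) == 0.0

    def test_two_to_one_spheroid(self):
        # foci oracle: c = sqrt(r_p² - r_e²) = sqrt(3), e = c / r_p
        assert ellipticity(1.0, 2.0) == pytest.approx(math.sqrt(3) / 2, rel=1e-12)

    @pytest.mark.parametrize("r_e,r_p", [(2.0, 1.0), (-1.0, 2.0), (1.0, 0.0)])
    def test_domain_errors(self, r_e, r_p):
        with pytest.raises(ProlateViolationError):
            ellipticity(r_e, r_p)

    @given(st.floats(0.2, 5.0), st.floats(1.0001, 30.0))
    @settings(max_examples=100, deadline=None)
    def test_increasing_in_elongation(self, w, ratio):
        # e grows strictly with L_H/W_H at fixed width
        e1 = ellipticity(0.5 * w, 0.5 * w * ratio)
        e2 = ellipticity(0.5 * w, 0.5 * w * ratio * 1.05)
        assert 0.0 < e1 < e2 < 1.0


class TestHeadSurfaceArea:
    def test_sphere(self):
        assert head_surface_area(2.0, 2.0) == pytest.approx(4 * math.pi, rel=1e-12)

    def test_pinned_oracle_value(self):
        assert head_surface_area(4.0, 2.0) == pytest.approx(AREA_4_2, rel=1e-9)
        assert spheroid_area_numeric(4.0, 2.0) == pytest.approx(AREA_4_2, rel=1e-9)

    def test_continuity_at_sphere_limit(self):
        a = head_surface_area(2.0, 2.0 - 1e-10)
        assert a == pytest.approx(4 * math.pi, rel=1e-6)

    @pytest.mark.parametrize("L,W", [(2.0, 3.0), (0.0, 1.0), (2.0, -1.0)])
    def test_domain_errors(self, L, W):
        with pytest.raises(ProlateViolationError):
            head_surface_area(L, W)

    @given(st.floats(0.5, 5.0),
           st.floats(1e-6, 3.0).map(lambda x: 1.0 + x))  # aspect ratios up to 4
    @settings(max_examples=150, deadline=None)
    def test_matches_numerical_oracle(self, W, aspect):
        L = W * aspect
        assert head_surface_area(L, W) == pytest.approx(
            spheroid_area_numeric(L, W), rel=1e-9)

    @given(st.floats(1.0, 10.0), st.floats(0.1, 0.999), st.floats(0.01, 100.0))
    @settings(max_examples=100, deadline=None)
    def test_scaling_law(self, L, frac, s):
        """Areas scale as s², ellipticity is scale free."""
        W = frac * L
        assert head_surface_area(s * L, s * W) == pytest.approx(
            s**2 * head_surface_area(L, W), rel=1e-10)
        assert ellipticity(0.5 * s * W, 0.5 * s * L) == pytest.approx(
            ellipticity(0.5 * W, 0.5 * L), rel=1e-10)

    def test_monotone_in_width(self):
        L = 4.0
        widths = np.linspace(0.2, L, 50)
        areas = head_surface_area(np.full_like(widths, L), widths)
        assert np.all(np.diff(areas) > 0)


class TestDeriveCell:
    def test_sphere_head_arithmetic(self):
        d = derive_cell(SpermCellRecord("m", "c", L_H=2, W_H=2, L_F=30))
        assert d.L_T == 32
        assert d.ratio_LF_LH == 15
        assert d.ratio_LF_AH == pytest.approx(30 / (4 * math.pi), rel=1e-12)
        assert d.e == 0.0

    def test_prolate_head_via_pinned_value(self):
        d = derive_cell(SpermCellRecord("m", "c", L_H=4, W_H=2, L_F=30))
        assert d.ratio_LF_AH == pytest.approx(30 / AREA_4_2, rel=1e-9)

    def test_deformed_cell_rejected(self):
        cell = SpermCellRecord("m", "c", L_H=3, W_H=2, L_F=0, category="tailless")
        with pytest.raises(DeformedCellError, match="tailless"):
            derive_cell(cell)

    @given(st.floats(1.0, 8.0), st.floats(0.1, 0.99), st.floats(5.0, 60.0),
           st.floats(0.01, 50.0))
    @settings(max_examples=100, deadline=None)
    def test_derived_scaling_laws(self, L, frac, LF, s):
        a = derive_cell(SpermCellRecord("m", "c", L_H=L, W_H=frac * L, L_F=LF))
        b = derive_cell(SpermCellRecord("m", "c", L_H=s * L, W_H=s * frac * L,
                                        L_F=s * LF))
        assert b.e == pytest.approx(a.e, rel=1e-9, abs=1e-12)
        assert b.ratio_LF_LH == pytest.approx(a.ratio_LF_LH, rel=1e-9)
        assert b.L_T == pytest.approx(s * a.L_T, rel=1e-9)
        assert b.A_H == pytest.approx(s**2 * a.A_H, rel=1e-9)
        assert b.ratio_LF_AH == pytest.approx(a.ratio_LF_AH / s, rel=1e-9)


class TestFrameDerivations:
    def test_matches_scalar_path(self, derived):
        row = derived.iloc[17]
        d = derive_cell(SpermCellRecord(row.male_id, row.cell_id,
                                        row.L_H_um, row.W_H_um, row.L_F_um))
        assert row.A_H_um2 == pytest.approx(d.A_H, rel=1e-12)
        assert row.e == pytest.approx(d.e, rel=1e-12)
        assert row.L_T_um == row.L_H_um + row.L_F_um

    def test_deformed_rows_rejected(self):
        df = pd.DataFrame({"male_id": ["m"], "cell_id": ["c"], "L_H_um": [3.0],
                           "W_H_um": [2.0], "L_F_um": [30.0], "category": ["kink"]})
        with pytest.raises(DeformedCellError):
            derive_cells(df)

    def test_prolate_violation_listed_and_rejected(self):
        df = pd.DataFrame({"male_id": ["m", "m"], "cell_id": ["a", "b"],
                           "L_H_um": [2.0, 3.0], "W_H_um": [3.0, 2.0],
                           "L_F_um": [30.0, 30.0]})
        assert list(prolate_violations(df)["cell_id"]) == ["a"]
        with pytest.raises(ProlateViolationError, match="a"):
            derive_cells(df)


class TestSummarizePerMale:
    def test_identical_cells_mean(self):
        df = pd.DataFrame({"male_id": ["m"] * 2, "ratio_LF_AH_per_um": [1.5, 1.5]})
        out = summarize_per_male(df)
        assert out.loc[0, "ratio_LF_AH_per_um"] == 1.5
        assert out.loc[0, "n_cells"] == 2

    def test_simple_mean(self):
        df = pd.DataFrame({"male_id": ["m"] * 3, "ratio_LF_AH_per_um": [1.0, 2.0, 3.0]})
        assert summarize_per_male(df).loc[0, "ratio_LF_AH_per_um"] == 2.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_per_male(pd.DataFrame(columns=["male_id"]))

    def test_generated_means_near_configured_expectation(self, derived):
        # lognormal median 32 µm with per-male/per-cell log SDs ~0.08:
        # per-male means over 40 cells must sit within a few SE of the
        # population mean ~ 32·exp(σ²/2)
        pm = summarize_per_male(derived)
        assert pm["n_cells"].eq(40).all()
        grand = pm["L_F_um"].mean()
        se = pm["L_F_um"].std() / np.sqrt(len(pm))
        assert abs(grand - 32.0 * np.exp(0.5 * (0.05**2 + 0.06**2 + 0.02**2))) < 3 * se
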