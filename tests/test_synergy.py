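"""Loewe/Bliss nulls, sham additivity, synergy scores, isobolograms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mapkdual import (DoseGrid, bliss_expected, build_surface, isobole,
                      loewe_expected, synergy_score)
from mapkdual.doseresponse import default_dose_grid
from mapkdual.network import ValidationError
from mapkdual.synergy import (invert_curve, loewe_expected_scan,
                              max_perpendicular_deviation)
from mapkdual.synthetic import make_true_curve


def curve(top=100.0, bottom=0.0, ec50=10.0, hill=1.0):
    return make_true_curve(top=top, bottom=bottom, ec50=ec50, hill=hill)


# ---------------------------------------------------------------------------
# curve inversion
# ---------------------------------------------------------------------------

class TestInvertCurve:
    def test_inverse_of_forward(self):
        c = curve(ec50=25.0, hill=1.7)
        for d in (0.5, 25.0, 400.0):
            e = float(c.effect_at(d)) / 100.0
            assert invert_curve(c, e) == pytest.approx(d, rel=1e-9)

    def test_top_asymptote_gives_infinite_dose_sentinel(self):
        assert math.isinf(invert_curve(curve(), 1.0))

    def test_hyperbolic_three_quarters_effect_at_three_ec50(self):
        # d/(d+10) = 0.75  =>  d = 30
        assert invert_curve(curve(), 0.75) == pytest.approx(30.0, rel=1e-12)


# ---------------------------------------------------------------------------
# Bliss
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ea,eb,expected", [
    (0.5, 0.5, 0.75),
    (0.0, 0.3, 0.3),
    (1.0, 0.4, 1.0),
])
def test_bliss_closed_form(ea, eb, expected):
    assert bliss_expected(ea, eb) == pytest.approx(expected)


def test_bliss_rejects_out_of_range():
    with pytest.raises(ValidationError):
        bliss_expected(1.2, 0.1)


# ---------------------------------------------------------------------------
# Loewe
# ---------------------------------------------------------------------------

class TestLoeweExpected:
    def test_single_agent_margin_is_exact(self):
        a, b = curve(ec50=10.0), curve(ec50=40.0, hill=2.0)
        e = loewe_expected(a, b, 7.0, 0.0)
        assert e == float(a.effect_at(7.0)) / 100.0

    def test_sham_half_doses_reproduce_full_dose_effect(self):
        c = curve(ec50=12.0, hill=1.4)
        d = 20.0
        e = loewe_expected(c, c, d / 2, d / 2)
        assert e == pytest.approx(float(c.effect_at(d)) / 100.0, abs=1e-12)

    def test_hill_one_identical_curves_solve_algebraically(self):
        # identical hyperbolic curves at (d, d): Loewe effect = curve(2d)
        c = curve(ec50=10.0, hill=1.0)
        for d in (1.0, 10.0, 250.0):
            assert loewe_expected(c, c, d, d) == \
                pytest.approx(2 * d / (2 * d + 10.0), abs=1e-10)

    def test_unequal_tops_saturate_at_shared_ceiling(self):
        a, b = curve(top=100.0), curve(top=60.0)
        r = loewe_expected(a, b, 1e6, 1e6, full_result=True)
        assert r.saturated and r.effect == pytest.approx(0.6)

    def test_oracle_equivalence_on_random_curve_pairs(self, rng):
        doses = default_dose_grid()
        worst = 0.0
        for _ in range(20):
            a = curve(top=rng.uniform(70, 100), ec50=10 ** rng.uniform(0, 2),
                      hill=rng.uniform(0.5, 3.0))
            b = curve(top=rng.uniform(70, 100), ec50=10 ** rng.uniform(0, 2),
                      hill=rng.uniform(0.5, 3.0))
            for da in doses[::2]:
                for db in doses[::2]:
                    worst = max(worst, abs(
                        loewe_expected(a, b, da, db)
                        - loewe_expected_scan(a, b, da, db)))
        assert worst < 1e-3


# ---------------------------------------------------------------------------
# surfaces and scores
# ---------------------------------------------------------------------------

def _sham_grid(c, doses):
    eff = np.empty((doses.size, doses.size))
    for i, da in enumerate(doses):
        for j, db in enumerate(doses):
            eff[i, j] = float(c.effect_at(da + db)) / 100.0
    return DoseGrid(doses_a=doses, doses_b=doses, effects=eff,
                    provenance="synthetic")


def test_bliss_null_grid_has_zero_excess():
    a, b = curve(ec50=10.0), curve(ec50=100.0, hill=1.5)
    doses = default_dose_grid()
    eff = np.empty((9, 9))
    for i, da in enumerate(doses):
        for j, db in enumerate(doses):
            eff[i, j] = bliss_expected(float(a.effect_at(da)) / 100.0,
                                       float(b.effect_at(db)) / 100.0)
    grid = DoseGrid(doses_a=doses, doses_b=doses, effects=eff)
    surf = build_surface(grid, a, b, null_model="bliss")
    assert np.max(np.abs(surf.excess)) < 1e-12


def test_loewe_sham_grid_has_zero_excess():
    c = curve(ec50=30.0, hill=1.8, top=95.0)
    surf = build_surface(_sham_grid(c, default_dose_grid()), c, c, "loewe")
    assert np.max(np.abs(surf.excess)) < 1e-6


@settings(max_examples=25, deadline=None, derandomize=True)
@given(ec50=st.floats(1.0, 300.0), hill=st.floats(0.5, 3.0),
       top=st.floats(60.0, 100.0))
def test_sham_additivity_property(ec50, hill, top):
    """Self-combination is exactly Loewe-additive for any monotone 4PL."""
    c = curve(top=top, ec50=ec50, hill=hill)
    surf = build_surface(_sham_grid(c, default_dose_grid()), c, c, "loewe")
    assert np.max(np.abs(surf.excess)) < 1e-6


class TestSynergyScore:
    def test_zero_excess_scores_zero(self):
        a, b = curve(), curve(ec50=30.0)
        doses = default_dose_grid()
        eff = np.empty((9, 9))
        for i, da in enumerate(doses):
            for j, db in enumerate(doses):
                eff[i, j] = loewe_expected(a, b, da, db)
        surf = build_surface(DoseGrid(doses, doses, eff), a, b, "loewe")
        assert surf.score("uniform") == pytest.approx(0.0, abs=1e-8)

    def test_constant_excess_scores_mean_times_100(self):
        a, b = curve(top=80.0), curve(top=80.0, ec50=30.0)
        doses = default_dose_grid()
        eff = np.empty((9, 9))
        for i, da in enumerate(doses):
            for j, db in enumerate(doses):
                eff[i, j] = loewe_expected(a, b, da, db)
        surf = build_surface(DoseGrid(doses, doses, np.clip(eff + 0.1, 0, 1)),
                             a, b, "loewe")
        assert surf.score("uniform") == pytest.approx(10.0, abs=1e-6)

    def test_relabelling_drugs_transposes_surface_and_keeps_score(self):
        a, b = curve(ec50=5.0, hill=2.0), curve(ec50=80.0)
        doses = default_dose_grid()
        eff = np.empty((9, 9))
        for i, da in enumerate(doses):
            for j, db in enumerate(doses):
                eff[i, j] = min(loewe_expected(a, b, da, db) + 0.05, 1.0)
        surf = build_surface(DoseGrid(doses, doses, eff), a, b, "loewe")
        swapped = build_surface(DoseGrid(doses, doses, eff.T), b, a, "loewe")
        assert swapped.score("uniform") == pytest.approx(surf.score("uniform"),
                                                         abs=1e-9)
        np.testing.assert_allclose(swapped.excess, surf.excess.T, atol=1e-12)

    def test_effect_weighted_scheme_downweights_inactive_corner(self):
        a, b = curve(), curve(ec50=30.0)
        doses = default_dose_grid()
        exp = np.empty((9, 9))
        for i, da in enumerate(doses):
            for j, db in enumerate(doses):
                exp[i, j] = loewe_expected(a, b, da, db)
        # put excess only where expected effect is tiny
        obs = exp.copy()
        obs[0, 0] = min(exp[0, 0] + 0.2, 1.0)
        surf = build_surface(DoseGrid(doses, doses, obs), a, b, "loewe")
        assert surf.score("effect_weighted") < surf.score("uniform")


# ---------------------------------------------------------------------------
# isobolograms
# ---------------------------------------------------------------------------

class TestIsobole:
    def test_sham_isoboles_are_straight_lines(self):
        c = curve(ec50=20.0, hill=1.3, top=95.0)
        surf = build_surface(_sham_grid(c, default_dose_grid()), c, c, "loewe")
        for level in (0.3, 0.5, 0.7):
            iso = isobole(surf, level)
            assert not iso.empty and iso.reference is not None
            assert iso.max_deviation_from_line() < 0.02

    def test_synergistic_surface_bows_inside_the_additivity_line(self):
        a = b = curve(ec50=50.0, hill=1.0)
        doses = default_dose_grid()
        # multiplicative (Bliss-like) survival: synergistic vs Loewe for
        # hyperbolic curves; contour must lie below the straight line
        eff = np.empty((9, 9))
        for i, da in enumerate(doses):
            for j, db in enumerate(doses):
                eff[i, j] = 1 - (1 - a.effect_at(da) / 100) * (1 - b.effect_at(db) / 100)
        surf = build_surface(DoseGrid(doses, doses, eff), a, b, "loewe")
        iso = surf.isobole(0.70)
        assert not iso.empty
        d_a, d_b = iso.reference[0, 0], iso.reference[1, 1]
        # interior contour points (away from the axes, where the sham and
        # multiplicative surfaces coincide) lie inside the reference line
        s = iso.points[:, 0] / d_a + iso.points[:, 1] / d_b
        interior = ((iso.points[:, 0] > 0.05 * d_a)
                    & (iso.points[:, 1] > 0.05 * d_b))
        assert interior.sum() >= 3
        assert np.all(s[interior] <= 1.0)
        assert s[interior].min() < 0.85  # clear inward bowing at mid-ratio

    def test_level_above_surface_maximum_is_empty(self):
        c = curve(top=60.0)
        iso = isobole(_sham_grid(c, default_dose_grid()), 0.9)
        assert iso.empty and iso.points.size == 0

    def test_perpendicular_deviation_helper(self):
        pts = np.array([[0.5, 0.5], [0.25, 0.75]])
        dev = max_perpendicular_deviation(pts, (1.0, 0.0), (0.0, 1.0))
        assert dev == pytest.approx(0.0, abs=1e-12)
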