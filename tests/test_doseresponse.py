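"""Viability link, dose matrices, 4PL fitting and GI50 extraction."""

import math

import numpy as np
import pytest

from mapkdual import (ViabilityLink, fit_4pl, run_matrix, run_sham_matrix,
                      viability_from_output)
from mapkdual.doseresponse import (DoseGrid, FourParamLogistic, ReadoutMode,
                                   _logistic4, default_dose_grid,
                                   single_agent_effects,
                                   zero_anchored_dose_grid)
from mapkdual.network import DrugTarget, ValidationError


# ---------------------------------------------------------------------------
# viability link
# ---------------------------------------------------------------------------

class TestViabilityLink:
    def test_vehicle_output_gives_full_viability(self):
        link = ViabilityLink(emax=0.9, k_out=100.0, hill=1.0)
        assert viability_from_output(5000.0, link, vehicle_output=5000.0) == 1.0

    def test_zero_output_reaches_the_kill_floor(self):
        link = ViabilityLink(emax=0.9, k_out=100.0, hill=1.0)
        assert viability_from_output(0.0, link, vehicle_output=5000.0) == \
            pytest.approx(0.1, abs=1e-12)

    def test_half_effect_at_k_out_when_vehicle_is_large(self):
        # the normalised Hill reduces to the plain Hill for vehicle >> k_out
        link = ViabilityLink(emax=1.0, k_out=100.0, hill=1.0)
        v = viability_from_output(100.0, link, vehicle_output=1e9)
        assert v == pytest.approx(0.5, abs=1e-6)

    def test_monotone_in_output(self):
        link = ViabilityLink()
        outs = np.linspace(0.0, 7000.0, 50)
        v = [viability_from_output(o, link, vehicle_output=7000.0) for o in outs]
        assert np.all(np.diff(v) >= -1e-12)

    def test_negative_output_rejected(self):
        with pytest.raises(ValidationError):
            viability_from_output(-1.0, ViabilityLink(), vehicle_output=100.0)


# ---------------------------------------------------------------------------
# dose grids and matrix runs
# ---------------------------------------------------------------------------

def test_default_grid_is_nine_half_log_steps():
    g = default_dose_grid()
    assert g.size == 9
    assert g[0] == pytest.approx(0.1) and g[-1] == pytest.approx(1000.0)
    assert np.allclose(np.diff(np.log10(g)), 0.5)


def test_zero_anchored_grid_layout():
    g = zero_anchored_dose_grid()
    assert g.size == 9 and g[0] == 0.0 and g[-1] == pytest.approx(1000.0)
    assert np.allclose(np.diff(np.log10(g[1:])), 0.5)


def test_dose_grid_validation():
    with pytest.raises(ValidationError):
        DoseGrid(doses_a=[1.0, 1.0], doses_b=[1.0, 2.0],
                 effects=np.zeros((2, 2)))
    with pytest.raises(ValidationError):
        DoseGrid(doses_a=[1.0, 2.0], doses_b=[1.0, 2.0],
                 effects=np.full((2, 2), 1.5))


def test_dose_grid_csv_round_trip(tmp_path):
    g = DoseGrid(doses_a=[0.0, 1.0, 10.0], doses_b=[0.0, 2.0, 20.0],
                 effects=np.linspace(0, 1, 9).reshape(3, 3),
                 provenance="synthetic", metadata={"seed": 3})
    path = tmp_path / "grid.csv"
    g.to_csv(path)
    back = DoseGrid.from_csv(path)
    assert np.allclose(back.doses_a, g.doses_a)
    assert np.allclose(back.effects, g.effects)
    assert back.provenance == "synthetic"


@pytest.mark.parametrize("grid_kind", ["small"])
def test_matrix_margins_reproduce_single_agent_responses(kras_network, link,
                                                         grid_kind):
    doses = np.array([0.0, 3.0, 100.0])
    grid = run_matrix(kras_network, doses, doses, link)
    assert grid.effects.shape == (3, 3)
    assert grid.effects[0, 0] == pytest.approx(0.0, abs=1e-9)
    ea = single_agent_effects(kras_network, DrugTarget.MEK, doses, link)
    eb = single_agent_effects(kras_network, DrugTarget.ERK, doses, link)
    # zero-dose margins equal independently simulated single agents (same solver)
    np.testing.assert_array_equal(grid.effects[:, 0], ea)
    np.testing.assert_array_equal(grid.effects[0, :], eb)


def test_matrix_effects_monotone_in_dose(kras_network, link):
    doses = np.array([0.0, 1.0, 30.0, 1000.0])
    grid = run_matrix(kras_network, doses, doses, link)
    assert np.all(np.diff(grid.effects, axis=0) >= -1e-9)
    assert np.all(np.diff(grid.effects, axis=1) >= -1e-9)


def test_saturating_doses_reach_the_link_ceiling(kras_network, link):
    doses = np.array([0.0, 2000.0])
    grid = run_matrix(kras_network, doses, doses, link)
    assert grid.effects[1, 1] == pytest.approx(link.emax, abs=0.01)


def test_sham_matrix_depends_only_on_total_dose(kras_network, link):
    doses = np.array([0.0, 1.0, 2.0])
    grid = run_sham_matrix(kras_network, DrugTarget.MEK, doses, doses, link)
    # (1,2) and (2,1) and (0,3)... same totals -> identical effects
    assert grid.effects[1, 2] == grid.effects[2, 1]
    assert grid.effects[0, 2] == grid.effects[2, 0]


# ---------------------------------------------------------------------------
# 4PL fitting
# ---------------------------------------------------------------------------

DOSES8 = np.logspace(-1, 2.5, 8) * 10  # 1 nM - 3.16 uM


class TestFourParamLogistic:
    def test_noiseless_parameters_recovered_exactly(self):
        effects = _logistic4(DOSES8, 100.0, 0.0, 1.0, 1.0)  # ec50 10 nM
        fit = fit_4pl(DOSES8, effects)
        assert fit.top == pytest.approx(100.0, abs=1e-5)
        assert fit.bottom == pytest.approx(0.0, abs=1e-5)
        assert fit.ec50 == pytest.approx(10.0, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)

    def test_gross_outlier_is_down_weighted(self, rng):
        clean = _logistic4(DOSES8, 100.0, 0.0, 1.3, 1.2)
        fit_clean = fit_4pl(DOSES8, clean)
        dirty = clean.copy()
        dirty[3] += 50.0
        fit_dirty = fit_4pl(DOSES8, dirty)
        assert fit_dirty.outlier_mask[3]
        shift = abs(math.log10(fit_dirty.ec50) - math.log10(fit_clean.ec50))
        assert shift < 0.05

    def test_screening_bounds_constrain_the_max_effect_asymptote(self):
        effects = _logistic4(DOSES8, 40.0, 0.0, 1.0, 1.0)  # shallow responder
        fit = fit_4pl(DOSES8, effects, lower_asymptote_bounds=(50.0, 100.0))
        assert 50.0 - 1e-6 <= fit.top <= 100.0 + 1e-6

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValidationError):
            FourParamLogistic([1, 10, 100, 1000], [0, 10, 50, 90])

    def test_narrow_dose_span_rejected(self):
        d = np.linspace(10, 50, 6)
        with pytest.raises(ValidationError):
            FourParamLogistic(d, np.linspace(0, 90, 6))

    def test_flat_data_is_degenerate(self):
        with pytest.raises(ValidationError):
            fit_4pl(DOSES8, np.full(8, 37.0))

    def test_summary_mentions_gi50(self):
        effects = _logistic4(DOSES8, 100.0, 0.0, 1.0, 1.0)
        text = fit_4pl(DOSES8, effects).summary()
        assert "GI50" in text and "ec50" in text


class TestGi50:
    @pytest.mark.parametrize("hill", [1.0, 2.0])
    def test_symmetric_curve_gi50_equals_ec50(self, hill):
        effects = _logistic4(DOSES8, 100.0, 0.0, 1.0, hill)
        fit = fit_4pl(DOSES8, effects)
        g = fit.gi50()
        assert not g.censored
        assert g.value == pytest.approx(10.0, rel=1e-4)

    def test_unreachable_effect_is_censored(self):
        effects = _logistic4(DOSES8, 100.0, 60.0, 1.0, 1.0)  # bottom above 50
        fit = fit_4pl(DOSES8, effects)
        g = fit.gi50()
        assert g.censored and math.isinf(g.value)
        assert g.limit == pytest.approx(DOSES8.max())

    def test_asymmetric_inverse_solved_analytically(self):
        # top 100, bottom 20, hill 1.5, ec50 30: solve for 50% by hand
        fit = fit_4pl(DOSES8, _logistic4(DOSES8, 100.0, 20.0, np.log10(30.0), 1.5))
        frac = (50.0 - 20.0) / 80.0
        expected = 30.0 * (frac / (1 - frac)) ** (1 / 1.5)
        assert fit.gi50().value == pytest.approx(expected, rel=1e-4)
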