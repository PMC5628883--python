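"""Combination-synergy analysis: Loewe and Bliss nulls, isobolograms, scores.

All synergy mathematics operates on *fraction affected* (1 - fractional
viability) in [0, 1].  Loewe additivity is the dose-equivalence null for two
drugs in the same pathway: the expected combined effect E* of doses
(dA, dB) solves

    dA / D_A(E*) + dB / D_B(E*) = 1,

where D_i(E) is the dose of drug i alone producing effect E (analytic 4PL
inversion).  Bliss independence is the probabilistic null
E = EA + EB - EA*EB.  A drug combined with itself (the sham combination) is
exactly additive under Loewe and serves as the additivity control: its
isoboles are straight lines in linear dose space.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .doseresponse import DoseGrid, DoseResponseFit
from .network import ValidationError

__all__ = [
    "SynergySurface", "Isobologram", "invert_curve", "loewe_expected",
    "bliss_expected", "build_surface", "synergy_score", "isobole",
    "max_perpendicular_deviation",
]

_E_EPS = 1e-12


def _frac_curve(curve: DoseResponseFit):
    """View a percent-scale fitted curve on the fraction-affected scale."""
    return (curve.bottom / 100.0, curve.top / 100.0)


def invert_curve(curve: DoseResponseFit, effect: float) -> float:
    """Dose D(E) producing fractional effect ``effect`` for a single agent.

    Returns ``math.inf`` (infinite-dose sentinel) for effects at or above the
    top asymptote; 0.0 for effects at or below the bottom.
    """
    if not 0.0 <= effect <= 1.0 + 1e-12:
        raise ValidationError("effect must be a fraction in [0, 1]")
    if curve.hill <= 0:
        raise ValidationError("curve must be strictly monotone (hill > 0)")
    return curve.invert(effect * 100.0)


def bliss_expected(ea: float, eb: float) -> float:
    """Bliss independence: E = EA + EB - EA*EB (fractions)."""
    ea, eb = float(ea), float(eb)
    if not (0.0 <= ea <= 1.0 and 0.0 <= eb <= 1.0):
        raise ValidationError("Bliss effects must lie in [0, 1]")
    return ea + eb - ea * eb


@dataclass(frozen=True)
class LoeweResult:
    effect: float
    saturated: bool = False


def loewe_expected(curve_a: DoseResponseFit, curve_b: DoseResponseFit,
                   dose_a: float, dose_b: float,
                   full_result: bool = False):
    """Expected combined effect under Loewe additivity (fraction affected).

    Solves ``dA/D_A(E) + dB/D_B(E) = 1`` by bracketed root finding on the
    shared achievable effect range.  With one dose zero the other agent's
    effect is returned exactly.  If the combination demands more effect than
    the shared ceiling min(topA, topB), the ceiling is returned with a
    saturation flag (``full_result=True``).
    """
    if curve_a.hill <= 0 or curve_b.hill <= 0:
        raise ValidationError("curves must be strictly monotone (hill > 0)")
    if dose_a < 0 or dose_b < 0:
        raise ValidationError("doses must be non-negative")
    if dose_a == 0 and dose_b == 0:
        ba, _ = _frac_curve(curve_a)
        bb, _ = _frac_curve(curve_b)
        e = max(ba, bb, 0.0)
        return LoeweResult(e) if full_result else e
    if dose_b == 0:
        e = float(curve_a.effect_at(dose_a)) / 100.0
        return LoeweResult(e) if full_result else e
    if dose_a == 0:
        e = float(curve_b.effect_at(dose_b)) / 100.0
        return LoeweResult(e) if full_result else e

    ba, ta = _frac_curve(curve_a)
    bb, tb = _frac_curve(curve_b)
    lo = max(ba, bb, 0.0)
    hi = min(ta, tb, 1.0)
    if hi <= lo:
        e = min(hi, 1.0)
        return LoeweResult(e, saturated=True) if full_result else e

    def g(e):
        da_e = invert_curve(curve_a, e)
        db_e = invert_curve(curve_b, e)
        term_a = dose_a / da_e if math.isfinite(da_e) else 0.0
        term_b = dose_b / db_e if math.isfinite(db_e) else 0.0
        if da_e == 0.0 or db_e == 0.0:
            return math.inf
        return term_a + term_b - 1.0

    lo_e = lo + (hi - lo) * _E_EPS
    hi_e = hi - (hi - lo) * _E_EPS
    g_hi = g(hi_e)
    if g_hi > 0:
        # even at the shared ceiling the dose pair exceeds the isobole
        return LoeweResult(hi, saturated=True) if full_result else hi
    g_lo = g(lo_e)
    if g_lo < 0:
        # dose pair below the smallest solvable effect; return the floor
        return LoeweResult(lo) if full_result else lo
    e_star = brentq(g, lo_e, hi_e, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    return LoeweResult(float(e_star)) if full_result else float(e_star)


def loewe_expected_scan(curve_a: DoseResponseFit, curve_b: DoseResponseFit,
                        dose_a: float, dose_b: float, n: int = 10_000) -> float:
    """Brute-force oracle for the Loewe effect: dense scan over n effect points.

    Independent of the root-finding path; used to cross-check
    :func:`loewe_expected`.
    """
    if dose_b == 0:
        return float(curve_a.effect_at(dose_a)) / 100.0
    if dose_a == 0:
        return float(curve_b.effect_at(dose_b)) / 100.0
    ba, ta = _frac_curve(curve_a)
    bb, tb = _frac_curve(curve_b)
    lo, hi = max(ba, bb, 0.0), min(ta, tb, 1.0)
    es = np.linspace(lo + (hi - lo) * 1e-9, hi - (hi - lo) * 1e-9, n)
    # vectorised analytic inversion of both 4PLs
    def dvec(curve, es):
        b, t = _frac_curve(curve)
        frac = (es - b) / (t - b)
        frac = np.clip(frac, 1e-300, 1 - 1e-16)
        return curve.ec50 * (frac / (1.0 - frac)) ** (1.0 / curve.hill)
    g = dose_a / dvec(curve_a, es) + dose_b / dvec(curve_b, es) - 1.0
    sign = np.sign(g)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if idx.size == 0:
        return hi if g[-1] > 0 else float(es[np.argmin(np.abs(g))])
    i = idx[0]
    # linear interpolation between bracketing grid points
    e0, e1, g0, g1 = es[i], es[i + 1], g[i], g[i + 1]
    return float(e0 - g0 * (e1 - e0) / (g1 - g0))


# --------------------------------------------------------------------------
# surfaces
# --------------------------------------------------------------------------

@dataclass
class SynergySurface:
    """Observed/expected/excess effect matrices under a named null model."""

    grid: DoseGrid
    expected: np.ndarray
    null_model: str
    curve_a: Optional[DoseResponseFit] = None
    curve_b: Optional[DoseResponseFit] = None
    saturated: Optional[np.ndarray] = None

    @property
    def observed(self) -> np.ndarray:
        return self.grid.effects

    @property
    def excess(self) -> np.ndarray:
        return self.observed - self.expected

    def score(self, weighting: str = "uniform") -> float:
        return synergy_score(self, weighting=weighting)

    def isobole(self, level: float = 0.70) -> "Isobologram":
        return isobole(self, level)

    def transpose(self) -> "SynergySurface":
        g = DoseGrid(doses_a=self.grid.doses_b, doses_b=self.grid.doses_a,
                     effects=self.grid.effects.T, provenance=self.grid.provenance,
                     metadata=dict(self.grid.metadata))
        return SynergySurface(grid=g, expected=self.expected.T,
                              null_model=self.null_model,
                              curve_a=self.curve_b, curve_b=self.curve_a,
                              saturated=None if self.saturated is None
                              else self.saturated.T)


def build_surface(grid: DoseGrid, curve_a: DoseResponseFit,
                  curve_b: DoseResponseFit, null_model: str = "loewe",
                  margin_tolerance: float = 0.05) -> SynergySurface:
    """Expected-effect surface under Loewe or Bliss, plus the excess matrix.

    For Bliss the single-agent effects EA, EB are taken from the fitted
    curves at the row/column doses.  If the grid contains explicit zero-dose
    margins they are checked against the curves; a mismatch beyond
    ``margin_tolerance`` triggers a warning.
    """
    null_model = null_model.lower()
    if null_model not in ("loewe", "bliss"):
        raise ValidationError("null_model must be 'loewe' or 'bliss'")
    da, db = grid.doses_a, grid.doses_b
    # margin consistency check where explicit zero doses exist
    if db.size and db[0] == 0:
        marg = grid.effects[:, 0]
        pred = np.array([curve_a.effect_at(d) / 100.0 if d > 0 else
                         curve_a.bottom / 100.0 for d in da])
        if np.max(np.abs(marg - pred)) > margin_tolerance:
            warnings.warn("drug-A margin disagrees with the supplied curve "
                          "beyond tolerance; consider refitting the margins")
    exp = np.empty_like(grid.effects)
    sat = np.zeros_like(grid.effects, dtype=bool)
    for i, a in enumerate(da):
        for j, b in enumerate(db):
            if null_model == "loewe":
                r = loewe_expected(curve_a, curve_b, a, b, full_result=True)
                exp[i, j] = r.effect
                sat[i, j] = r.saturated
            else:
                ea = float(curve_a.effect_at(a)) / 100.0 if a > 0 else 0.0
                eb = float(curve_b.effect_at(b)) / 100.0 if b > 0 else 0.0
                exp[i, j] = bliss_expected(min(max(ea, 0.0), 1.0),
                                           min(max(eb, 0.0), 1.0))
    exp = np.clip(exp, 0.0, 1.0)
    return SynergySurface(grid=grid, expected=exp, null_model=null_model,
                          curve_a=curve_a, curve_b=curve_b, saturated=sat)


def synergy_score(surface: SynergySurface, weighting: str = "uniform") -> float:
    """Scalar synergy score: weighted sum of excess over the additivity null.

    ``uniform``: mean excess x 100 (positive = synergy, negative =
    antagonism).  ``effect_weighted``: excess weighted by the expected effect,
    down-weighting the inactive low-dose corner; normalised by the weight sum
    and scaled by 100.  Scores are comparable only within one scheme.
    """
    ex = surface.excess
    if weighting == "uniform":
        return float(np.mean(ex) * 100.0)
    if weighting == "effect_weighted":
        w = surface.expected
        tot = float(np.sum(w))
        if tot <= 0:
            return 0.0
        return float(np.sum(ex * w) / tot * 100.0)
    raise ValidationError("weighting must be 'uniform' or 'effect_weighted'")


# --------------------------------------------------------------------------
# isobolograms
# --------------------------------------------------------------------------

@dataclass
class Isobologram:
    """Constant-effect contour in the two-drug dose plane.

    ``points`` is an (n, 2) array of (dose_a, dose_b) in nM ordered along the
    contour; ``reference`` holds the Loewe straight-line endpoints
    (D_A(level), 0) and (0, D_B(level)) when the level is achievable by each
    single agent.
    """

    level: float
    points: np.ndarray
    empty: bool = False
    reference: Optional[np.ndarray] = None
    interpolation: str = "pchip-logdose"

    def max_deviation_from_line(self) -> float:
        """Max perpendicular deviation of contour points from the Loewe
        reference line, as a fraction of the line (chord) length."""
        if self.empty or self.reference is None:
            raise ValidationError("no contour or reference line available")
        return max_perpendicular_deviation(self.points, self.reference[0],
                                           self.reference[1])


def max_perpendicular_deviation(points: np.ndarray, p0, p1) -> float:
    """Max perpendicular distance from points to segment p0-p1, / chord length."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    chord = float(np.hypot(*d))
    if chord == 0:
        raise ValidationError("degenerate reference line")
    rel = np.asarray(points, dtype=float) - p0
    cross = np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0]) / chord
    return float(np.max(cross) / chord)


def _logit(e):
    e = np.clip(e, 1e-9, 1.0 - 1e-9)
    return np.log(e / (1.0 - e))


def _line_crossings(doses_fixed, doses_var, effects_2d, level, axis,
                    ceiling=1.0):
    """Crossings of `level` along each grid line, interpolated in log dose.

    Effects are interpolated on the logit scale after normalising by the
    surface's effect ceiling: a 4PL-shaped line is then exactly linear in log
    dose, so the monotone (PCHIP) interpolant locates crossings far more
    accurately than raw-effect interpolation on the coarse half-log lattice.
    """
    pts = []
    log_var = np.log10(doses_var)
    level_t = float(_logit(level / ceiling))
    for k, dfix in enumerate(doses_fixed):
        e = effects_2d[k, :] if axis == 0 else effects_2d[:, k]
        if np.all(e < level) or np.all(e > level):
            continue
        # PCHIP requires monotone x; effects need not be monotone, so locate
        # sign changes of (e - level) and refine within each bracket
        et = _logit(e / ceiling) - level_t
        f = PchipInterpolator(log_var, et, extrapolate=False)
        s = np.sign(et)
        for i in np.nonzero(np.diff(s) != 0)[0]:
            try:
                x = brentq(f, log_var[i], log_var[i + 1], xtol=1e-12)
            except ValueError:
                continue
            dv = 10.0 ** x
            pts.append((dfix, dv) if axis == 0 else (dv, dfix))
    return pts


def isobole(surface_or_grid, level: float = 0.70) -> Isobologram:
    """Extract the constant-effect contour at ``level`` from a response surface.

    Crossings are located along every grid row and column by monotone PCHIP
    interpolation of the effect values against log dose, then ordered along
    the contour.  The Loewe reference line endpoints come from the
    single-agent curves when available (surface input), else from the grid
    margins.
    """
    if isinstance(surface_or_grid, SynergySurface):
        grid = surface_or_grid.grid
        curve_a, curve_b = surface_or_grid.curve_a, surface_or_grid.curve_b
    else:
        grid = surface_or_grid
        curve_a = curve_b = None
    if not 0.0 < level < 1.0:
        raise ValidationError("effect level must lie in (0, 1)")
    eff = grid.effects
    da, db = grid.doses_a, grid.doses_b
    pa = da > 0
    pb = db > 0
    # estimate the effect ceiling (shared top asymptote) from the surface so
    # the logit linearisation holds for sub-maximal-efficacy drugs too
    ceiling = max(float(np.max(eff)) * (1.0 + 1e-9), level * (1.0 + 1e-9))
    ceiling = min(ceiling / (1.0 - 1e-9), 1.0 + 1e-9)
    pts = _line_crossings(da[pa], db[pb], eff[np.ix_(pa, pb)], level, axis=0,
                          ceiling=ceiling)
    pts += _line_crossings(db[pb], da[pa], eff[np.ix_(pa, pb)], level, axis=1,
                           ceiling=ceiling)
    if not pts:
        return Isobologram(level=level, points=np.empty((0, 2)), empty=True)
    pts = np.unique(np.asarray(pts, dtype=float), axis=0)
    # order along the contour: sort by angle around the origin in log space
    with np.errstate(divide="ignore"):
        ang = np.arctan2(np.log10(np.maximum(pts[:, 1], 1e-12)),
                         -np.log10(np.maximum(pts[:, 0], 1e-12)))
    pts = pts[np.argsort(ang)]
    reference = None
    if curve_a is not None and curve_b is not None:
        d_a = invert_curve(curve_a, level)
        d_b = invert_curve(curve_b, level)
        if math.isfinite(d_a) and math.isfinite(d_b) and d_a > 0 and d_b > 0:
            reference = np.array([[d_a, 0.0], [0.0, d_b]])
    return Isobologram(level=level, points=pts, empty=False, reference=reference)
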