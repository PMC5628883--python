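"""Dose-response machinery: viability link, dose matrices, robust 4PL fits, GI50.

Two effect conventions coexist in this field and both are supported
explicitly: percent effect (0-100, the GI50/screening convention, used by the
fitting code) and fraction affected (0-1, used by the synergy surfaces).
Converters are :func:`percent_to_fraction` / :func:`fraction_to_percent`.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import lmfit

from .network import (DrugTarget, ReactionNetwork, ValidationError, simulate)

__all__ = [
    "ViabilityLink", "DoseGrid", "FourParamLogistic", "DoseResponseFit",
    "fit_4pl", "gi50", "viability_from_output", "run_matrix", "run_sham_matrix",
    "default_dose_grid", "percent_to_fraction", "fraction_to_percent",
]


def percent_to_fraction(x):
    return np.asarray(x, dtype=float) / 100.0


def fraction_to_percent(x):
    return np.asarray(x, dtype=float) * 100.0


def default_dose_grid(n: int = 9) -> np.ndarray:
    """Default combination dose axis: 9 half-log-spaced doses, 0.1-1000 nM.

    A strict 1-to-1000 nM half-log ladder yields 7 values; the 9-value grid
    keeps the half-log spacing and the 1000 nM top by extending the low end to
    0.1 nM.  An 8-step-plus-zero alternative is available via
    ``default_dose_grid(8)`` prepended with 0 by the caller.
    """
    return np.logspace(-1, 3, n)


def zero_anchored_dose_grid() -> np.ndarray:
    """Alternative combination axis: an explicit zero dose plus 8 half-log
    steps ending at 1000 nM (0, 0.316 ... 1000).  The zero row/column anchors
    the single-agent margins exactly, the standard layout for Loewe analysis."""
    return np.concatenate([[0.0], np.logspace(-0.5, 3, 8)])


# --------------------------------------------------------------------------
# viability link
# --------------------------------------------------------------------------

class ReadoutMode(str, enum.Enum):
    STEADY_STATE = "steady_state_output"
    TIME_INTEGRATED = "time_integrated_output"


@dataclass(frozen=True)
class ViabilityLink:
    """Monotone Hill link from pathway output to fractional viability.

    ``viability(o) = 1 - emax * H(o)`` with ``H`` the vehicle-normalised
    decreasing Hill transform ``H(o) = (f(o) - f(v)) / (1 - f(v))``,
    ``f(o) = k_out^h / (k_out^h + o^h)`` and ``v`` the vehicle output.  By
    construction viability is exactly 1 at vehicle output and exactly
    ``1 - emax`` at zero output; ``k_out`` is the output level of
    half-maximal effect in the vehicle >> k_out regime.

    ``k_out`` shares units with the readout: nM for steady-state output,
    nM*h for the 0-72 h time integral.  The defaults are the calibrated
    values for the shipped KRAS-mutant parameter set (time-integrated mode;
    half-effect at ~35% of the vehicle 72-h output integral, slope steep
    enough that viability demands sustained pathway suppression).
    """

    emax: float = 0.95
    k_out: float = 2400.0
    hill: float = 3.5
    mode: ReadoutMode = ReadoutMode.TIME_INTEGRATED

    def __post_init__(self):
        if not 0.0 <= self.emax <= 1.0:
            raise ValidationError("emax must lie in [0, 1]")
        if self.k_out <= 0 or self.hill < 0:
            raise ValidationError("k_out must be positive and hill non-negative")
        object.__setattr__(self, "mode", ReadoutMode(self.mode))

    def viability(self, output: float, vehicle_output: float) -> float:
        if output < 0:
            raise ValidationError("pathway output must be non-negative")
        if vehicle_output <= 0:
            raise ValidationError("vehicle output must be positive")
        h = self.hill
        kh = self.k_out ** h
        f = lambda o: kh / (kh + o ** h) if o > 0 else 1.0
        fv = f(vehicle_output)
        H = (f(output) - fv) / (1.0 - fv)
        return float(1.0 - self.emax * min(max(H, 0.0), 1.0))


def viability_from_output(output: float, link: ViabilityLink,
                          vehicle_output: float) -> float:
    """Fractional viability implied by a pathway-output level (see ViabilityLink)."""
    return link.viability(output, vehicle_output)


# --------------------------------------------------------------------------
# dose grids
# --------------------------------------------------------------------------

@dataclass
class DoseGrid:
    """Two-drug response matrix: rows = drug A doses, columns = drug B doses.

    ``effects`` are fraction affected (1 - fractional viability) in [0, 1].
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    effects: np.ndarray
    provenance: str = "simulated"   # simulated | measured | synthetic
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.shape != (self.doses_a.size, self.doses_b.size):
            raise ValidationError("effects shape must match the dose axes")
        for d in (self.doses_a, self.doses_b):
            dd = d[d > 0] if d[0] == 0 else d
            if d[0] == 0 and np.count_nonzero(d == 0) > 1:
                raise ValidationError("at most one leading zero dose")
            if np.any(np.diff(dd) <= 0):
                raise ValidationError("dose vectors must be strictly increasing")
        if np.any(self.effects < -1e-9) or np.any(self.effects > 1 + 1e-9):
            raise ValidationError("effects must lie in [0, 1]")

    def to_csv(self, path, sidecar: bool = True) -> None:
        df = pd.DataFrame(self.effects, index=self.doses_a, columns=self.doses_b)
        df.index.name = "dose_a_nM"
        df.to_csv(path)
        if sidecar:
            meta = dict(self.metadata)
            meta["provenance"] = self.provenance
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=2, default=float)

    @classmethod
    def from_csv(cls, path) -> "DoseGrid":
        df = pd.read_csv(path, index_col=0)
        meta, prov = {}, "measured"
        try:
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
            prov = meta.pop("provenance", "measured")
        except FileNotFoundError:
            pass
        return cls(doses_a=df.index.to_numpy(dtype=float),
                   doses_b=df.columns.to_numpy(dtype=float),
                   effects=df.to_numpy(dtype=float),
                   provenance=prov, metadata=meta)


def _effect_for_doses(network: ReactionNetwork, dose_mek: float, dose_erk: float,
                      link: ViabilityLink, t_end: float = 72.0) -> float:
    """One simulation -> fraction affected, under the configured readout mode."""
    veh_ss = network.vehicle_output
    if link.mode is ReadoutMode.TIME_INTEGRATED:
        traj = simulate(network, dose_mek, dose_erk, t_end=t_end)
        out = traj.output_auc()
        veh = veh_ss * t_end
    else:
        from .network import steady_state as _ss
        out = _ss(network, dose_mek, dose_erk).pathway_output
        veh = veh_ss
    return 1.0 - link.viability(out, veh)


def run_matrix(network: ReactionNetwork, doses_a: Sequence[float],
               doses_b: Sequence[float], link: ViabilityLink,
               t_end: float = 72.0) -> DoseGrid:
    """Simulate the full MEKi x ERKi combination matrix.

    Drug A (rows) is the MEK inhibitor, drug B (columns) the ERK inhibitor.
    One 0-72 h simulation (or steady-state solve) per dose pair; a zero dose
    row/column reproduces the single-agent response exactly because the same
    solver settings are used throughout.
    """
    for t in (DrugTarget.MEK, DrugTarget.ERK):
        if t not in network.inhibitors:
            raise ValidationError(f"network has no {t.value} inhibitor registered")
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    eff = np.empty((doses_a.size, doses_b.size))
    for i, da in enumerate(doses_a):
        for j, db in enumerate(doses_b):
            try:
                eff[i, j] = _effect_for_doses(network, da, db, link, t_end)
            except Exception as exc:
                raise RuntimeError(
                    f"matrix aborted at dose pair (MEKi={da} nM, ERKi={db} nM)"
                ) from exc
    return DoseGrid(doses_a=doses_a, doses_b=doses_b, effects=eff,
                    provenance="simulated",
                    metadata={"drug_a": "MEKi", "drug_b": "ERKi",
                              "link": {"emax": link.emax, "k_out": link.k_out,
                                       "hill": link.hill, "mode": link.mode.value},
                              "t_end_h": t_end})


def run_sham_matrix(network: ReactionNetwork, target: DrugTarget,
                    doses_a: Sequence[float], doses_b: Sequence[float],
                    link: ViabilityLink, t_end: float = 72.0) -> DoseGrid:
    """Sham combination: one drug 'combined with itself' (dose = row + column).

    The Loewe additivity control: the resulting surface must be exactly
    additive with straight isoboles.
    """
    target = DrugTarget(target)
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    # cache single-total responses: effect depends only on da+db
    eff = np.empty((doses_a.size, doses_b.size))
    cache: dict = {}
    for i, da in enumerate(doses_a):
        for j, db in enumerate(doses_b):
            tot = da + db
            if tot not in cache:
                dm, de = (tot, 0.0) if target is DrugTarget.MEK else (0.0, tot)
                cache[tot] = _effect_for_doses(network, dm, de, link, t_end)
            eff[i, j] = cache[tot]
    return DoseGrid(doses_a=doses_a, doses_b=doses_b, effects=eff,
                    provenance="simulated",
                    metadata={"drug_a": target.value, "drug_b": target.value,
                              "sham": True, "t_end_h": t_end})


def single_agent_effects(network: ReactionNetwork, target: DrugTarget,
                         doses: Sequence[float], link: ViabilityLink,
                         t_end: float = 72.0) -> np.ndarray:
    """Fraction affected at each dose of one agent alone."""
    target = DrugTarget(target)
    out = []
    for d in np.asarray(doses, dtype=float):
        dm, de = (d, 0.0) if target is DrugTarget.MEK else (0.0, d)
        out.append(_effect_for_doses(network, dm, de, link, t_end))
    return np.asarray(out)


# --------------------------------------------------------------------------
# 4-parameter logistic fitting
# --------------------------------------------------------------------------

def _logistic4(dose, top, bottom, log_ec50, hill):
    d = np.asarray(dose, dtype=float)
    ec50 = 10.0 ** log_ec50
    with np.errstate(divide="ignore"):
        ratio = np.where(d > 0, (ec50 / np.where(d > 0, d, 1.0)) ** hill, np.inf)
    return bottom + (top - bottom) / (1.0 + ratio)


@dataclass
class DoseResponseFit:
    """Results of a 4PL fit: parameters, uncertainties, diagnostics.

    Effects are in percent (0-100).  The forward model is
    ``E(d) = bottom + (top - bottom) / (1 + (ec50/d)^hill)``.
    """

    top: float
    bottom: float
    ec50: float
    hill: float
    stderr: dict
    residual_scale: float
    outlier_mask: np.ndarray      # True where a point was down-weighted
    doses: np.ndarray
    effects: np.ndarray
    converged: bool = True
    method: str = "irls-bisquare"

    def __post_init__(self):
        if self.bottom > self.top:
            raise ValidationError("bottom asymptote exceeds top")
        if not self.ec50 > 0:
            raise ValidationError("ec50 must be positive")

    # forward / inverse -----------------------------------------------------

    def predict(self, dose) -> np.ndarray:
        return _logistic4(dose, self.top, self.bottom, math.log10(self.ec50),
                          self.hill)

    def effect_at(self, dose) -> np.ndarray:
        return self.predict(dose)

    def invert(self, effect: float) -> float:
        """Analytic 4PL inversion: dose D(E) at which effect = E (percent).

        Returns ``math.inf`` for effects at/above the top asymptote and 0.0
        for effects at/below the bottom (the infinite/zero-dose sentinels used
        by the Loewe solver).
        """
        if effect >= self.top:
            return math.inf
        if effect <= self.bottom:
            return 0.0
        frac = (effect - self.bottom) / (self.top - self.bottom)
        return self.ec50 * (frac / (1.0 - frac)) ** (1.0 / self.hill)

    def gi50(self, max_dose: Optional[float] = None):
        return gi50(self, max_dose=max_dose)

    def summary(self) -> str:
        lines = [
            "4-parameter logistic fit",
            "=" * 40,
            f"{'parameter':<12}{'estimate':>12}{'stderr':>12}",
            f"{'top (%)':<12}{self.top:>12.4g}{self.stderr.get('top', float('nan')):>12.3g}",
            f"{'bottom (%)':<12}{self.bottom:>12.4g}{self.stderr.get('bottom', float('nan')):>12.3g}",
            f"{'ec50 (nM)':<12}{self.ec50:>12.4g}{self.stderr.get('ec50', float('nan')):>12.3g}",
            f"{'hill':<12}{self.hill:>12.4g}{self.stderr.get('hill', float('nan')):>12.3g}",
            "-" * 40,
            f"n points: {self.doses.size}   outliers down-weighted: {int(self.outlier_mask.sum())}",
            f"robust residual scale: {self.residual_scale:.3g} %   converged: {self.converged}",
        ]
        g = self.gi50(max_dose=float(np.max(self.doses)))
        gi = f"> {g.limit:.4g} nM (censored)" if g.censored else f"{g.value:.4g} nM"
        lines.append(f"GI50: {gi}")
        return "\n".join(lines)


@dataclass(frozen=True)
class GI50Result:
    value: float
    censored: bool
    limit: Optional[float] = None


class FourParamLogistic:
    """4PL dose-response model, statsmodels-style: construct with data, ``fit()``.

    ``doses`` in nM (zeros allowed, treated as baseline anchors), ``effects``
    in percent.  ``fit`` performs an iteratively reweighted least-squares fit
    with Tukey bisquare weights (3 iterations, c = 4.685), a standard,
    reproducible robust-outlier scheme.
    """

    TUKEY_C = 4.685
    IRLS_ITER = 3

    def __init__(self, doses, effects):
        self.doses = np.asarray(doses, dtype=float)
        self.effects = np.asarray(effects, dtype=float)
        if self.doses.shape != self.effects.shape:
            raise ValidationError("doses and effects must have equal length")
        pos = self.doses[self.doses > 0]
        if pos.size < 5:
            raise ValidationError("need at least 5 positive dose points")
        if np.log10(pos.max() / pos.min()) < 2.0:
            raise ValidationError("doses must span at least 2 log10 units")

    # -- internals ----------------------------------------------------------

    def _initial_guess(self):
        lo, hi = float(np.min(self.effects)), float(np.max(self.effects))
        pos = self.doses > 0
        d, e = self.doses[pos], self.effects[pos]
        mid = (lo + hi) / 2.0
        above = d[e >= mid]
        ec50 = float(above.min()) if above.size else float(np.median(d))
        return dict(top=hi, bottom=lo, log_ec50=math.log10(max(ec50, 1e-12)), hill=1.0)

    def _grid_search(self):
        """Fallback estimate on a coarse parameter grid (non-convergent fits)."""
        pos = self.doses > 0
        d, e = self.doses[pos], self.effects[pos]
        lo, hi = float(np.min(self.effects)), float(np.max(self.effects))
        best, best_sse = None, np.inf
        for lec in np.linspace(np.log10(d.min()), np.log10(d.max()), 25):
            for h in (0.5, 1.0, 1.5, 2.0, 3.0):
                pred = _logistic4(self.doses, hi, lo, lec, h)
                sse = float(np.sum((self.effects - pred) ** 2))
                if sse < best_sse:
                    best_sse, best = sse, (hi, lo, lec, h)
        return best

    def fit(self, robust: bool = True,
            lower_asymptote_bounds: Optional[tuple] = None) -> DoseResponseFit:
        """Fit the 4PL.

        ``lower_asymptote_bounds`` activates the screening convention: the
        high-dose asymptote (maximal effect) is constrained to the given
        percent interval, e.g. ``(50, 100)``.  (The screening language speaks
        of the viability curve's lower asymptote, which is the effect curve's
        upper plateau; the constraint is applied in effect space.)
        """
        guess = self._initial_guess()
        params = lmfit.Parameters()
        if lower_asymptote_bounds is not None:
            lo_b, hi_b = lower_asymptote_bounds
            params.add("top", value=min(max(guess["top"], lo_b), hi_b),
                       min=lo_b, max=hi_b)
        else:
            params.add("top", value=guess["top"], min=-50.0, max=200.0)
        params.add("bottom", value=guess["bottom"], min=-50.0, max=150.0)
        params.add("delta", value=max(guess["top"] - guess["bottom"], 1e-3),
                   min=0.0, expr=None)  # enforce top >= bottom via delta
        params["bottom"].set(expr="top - delta")
        params.add("log_ec50", value=guess["log_ec50"],
                   min=guess["log_ec50"] - 6, max=guess["log_ec50"] + 6)
        params.add("hill", value=guess["hill"], min=0.05, max=10.0)

        weights = np.ones_like(self.effects)

        def residual(p):
            pred = _logistic4(self.doses, p["top"], p["bottom"], p["log_ec50"],
                              p["hill"])
            return (self.effects - pred) * weights

        converged = True
        try:
            result = lmfit.minimize(residual, params, method="leastsq")
            if robust:
                # resistant re-start: Cauchy loss keeps a gross outlier from
                # being absorbed by the 4 free parameters (a plain
                # least-squares fit lets a steep-hill curve chase it); the
                # loss scale adapts to the noise level of the plain fit
                res0 = self.effects - _logistic4(
                    self.effects * 0 + self.doses, result.params["top"],
                    result.params["bottom"], result.params["log_ec50"],
                    result.params["hill"])
                mad0 = float(np.median(np.abs(res0 - np.median(res0))))
                f_scale = max(2.0, 1.4826 * mad0)
                result = lmfit.minimize(residual, params, method="least_squares",
                                        loss="cauchy", f_scale=f_scale)
            n_rounds = self.IRLS_ITER if robust else 0
            for _ in range(n_rounds):
                res = self.effects - _logistic4(
                    self.doses, result.params["top"], result.params["bottom"],
                    result.params["log_ec50"], result.params["hill"])
                mad = float(np.median(np.abs(res - np.median(res))))
                scale = 1.4826 * mad if mad > 0 else float(np.std(res)) or 1.0
                u = res / (self.TUKEY_C * scale)
                weights = np.where(np.abs(u) < 1, (1 - u ** 2), 0.0)
                weights = np.sqrt(np.maximum(weights, 0.0))
                # restart from the data-driven initial guess: the reweighted
                # problem is clean, and a start distorted by the outlier can
                # trap leastsq in a steep-hill local minimum
                result = lmfit.minimize(residual, params, method="leastsq")
            p = result.params
            top, bottom = float(p["top"]), float(p["bottom"])
            lec, hill = float(p["log_ec50"]), float(p["hill"])
            stderr = {}
            for name, key in (("top", "top"), ("bottom", "bottom"), ("hill", "hill")):
                err = p[key].stderr
                stderr[name] = float(err) if err is not None else float("nan")
            lec_err = p["log_ec50"].stderr
            stderr["ec50"] = (float(lec_err) * math.log(10) * 10 ** lec
                              if lec_err is not None else float("nan"))
        except Exception:
            converged = False
            top, bottom, lec, hill = self._grid_search()
            stderr = {k: float("nan") for k in ("top", "bottom", "ec50", "hill")}

        res = self.effects - _logistic4(self.doses, top, bottom, lec, hill)
        if np.ptp(self.effects) < 1e-9:
            raise ValidationError("all-flat data: degenerate dose-response curve")
        mad = float(np.median(np.abs(res - np.median(res))))
        scale = 1.4826 * mad
        outliers = weights < 0.5 if robust else np.zeros_like(weights, dtype=bool)
        return DoseResponseFit(
            top=top, bottom=bottom, ec50=10.0 ** lec, hill=hill, stderr=stderr,
            residual_scale=scale, outlier_mask=np.asarray(outliers, dtype=bool),
            doses=self.doses, effects=self.effects, converged=converged)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dose_col: str = "dose_nM",
                       effect_col: str = "effect_pct") -> "FourParamLogistic":
        return cls(df[dose_col].to_numpy(), df[effect_col].to_numpy())


def fit_4pl(doses, effects, lower_asymptote_bounds: Optional[tuple] = None,
            robust: bool = True) -> DoseResponseFit:
    """Robust 4PL fit (percent effects); see :class:`FourParamLogistic`."""
    return FourParamLogistic(doses, effects).fit(
        robust=robust, lower_asymptote_bounds=lower_asymptote_bounds)


def gi50(curve: DoseResponseFit, max_dose: Optional[float] = None) -> GI50Result:
    """Dose at 50% effect from a fitted curve.

    When 50% lies outside the fitted asymptote range the value is censored
    and reported relative to the highest tested dose, matching the screening
    convention.
    """
    if max_dose is None:
        max_dose = float(np.max(curve.doses)) if curve.doses.size else float("nan")
    if not (curve.bottom < 50.0 < curve.top):
        return GI50Result(value=math.inf, censored=True, limit=max_dose)
    return GI50Result(value=curve.invert(50.0), censored=False, limit=None)
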