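"""Synthetic-data generators with the statistical structure the analyses assume.

Every generator is a pure function of its :class:`GeneratorSpec` (seed
included) and emits a machine-readable truth record alongside the data, so
parameter-recovery tests can close the loop without any external download.
Noise models: additive Gaussian on fractional effects (clipped to [0, 1]);
multiplicative lognormal on tumour volumes (caliper noise is
scale-proportional).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .network import ValidationError
from .doseresponse import DoseGrid, DoseResponseFit, default_dose_grid
from .efficacy import TumorCohort
from . import synergy as _synergy

__all__ = ["Scenario", "GeneratorSpec", "gen_curves", "gen_matrix",
           "gen_cohort", "edu_dose_layout", "make_true_curve"]


def edu_dose_layout() -> np.ndarray:
    """Plate layout used for measured combination data: 8 concentrations from
    50 uM in decreasing 3-fold dilutions (returned in nM, ascending)."""
    return np.sort(50_000.0 / 3.0 ** np.arange(8))


class Scenario(str, enum.Enum):
    SINGLE_AGENT_CURVES = "single_agent_curves"
    COMBO_MATRIX = "combo_matrix"
    XENOGRAFT_COHORT = "xenograft_cohort"


def make_true_curve(top: float = 100.0, bottom: float = 0.0, ec50: float = 100.0,
                    hill: float = 1.0) -> DoseResponseFit:
    """A noiseless 4PL 'curve object' for use as ground truth (percent scale)."""
    return DoseResponseFit(top=top, bottom=bottom, ec50=ec50, hill=hill,
                           stderr={}, residual_scale=0.0,
                           outlier_mask=np.zeros(0, dtype=bool),
                           doses=np.zeros(0), effects=np.zeros(0),
                           method="truth")


@dataclass
class GeneratorSpec:
    """Scenario + true parameters + noise model + size + seed.

    Defaults mirror the study conditions each scenario stands in for: the
    8-dose 3-fold screening layout for single-agent curves, the 9x9 half-log
    combination matrix, and 10-animal twice-weekly 21-day xenograft cohorts.
    """

    scenario: Scenario
    seed: int = 0
    n: int = 1
    # single-agent curves / combination matrices (percent-scale 4PL truth)
    curve_a: dict = field(default_factory=lambda: dict(
        top=100.0, bottom=0.0, ec50=100.0, hill=1.0))
    curve_b: dict = field(default_factory=lambda: dict(
        top=100.0, bottom=0.0, ec50=300.0, hill=1.2))
    doses: Optional[np.ndarray] = None
    effect_sd: float = 0.05            # Gaussian sd on fractional effect
    null_model: str = "loewe"          # loewe | bliss | sham
    bump_amplitude: float = 0.0        # localized synergy bump (fraction)
    # xenograft cohorts
    groups: dict = field(default_factory=lambda: {
        "vehicle": dict(doubling_days=7.0, n_animals=10),
        "combo": dict(doubling_days=18.5, n_animals=10)})
    baseline_mm3: float = 200.0
    schedule_days: tuple = (0, 3, 7, 10, 14, 17, 21)
    volume_sd: float = 0.1             # lognormal sigma on measurements
    slope_jitter_sd: float = 0.0       # animal-level sd on log2 slope (1/day)

    def __post_init__(self):
        self.scenario = Scenario(self.scenario)
        if self.effect_sd < 0 or self.volume_sd < 0 or self.slope_jitter_sd < 0:
            raise ValidationError("noise sd must be non-negative")
        if self.n < 1:
            raise ValidationError("n must be at least 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# --------------------------------------------------------------------------
# single-agent dose-response curves
# --------------------------------------------------------------------------

def gen_curves(spec: GeneratorSpec):
    """Noisy single-agent 4PL effect tables plus their truth table.

    Returns ``(data, truth)`` DataFrames.  ``n`` curves are drawn; each curve
    randomises the true EC50 (log-uniform within the central two decades of
    the dose range) and hill slope (uniform 0.8-2.0) around ``curve_a`` as a
    template, mimicking a screening panel.  Effects are percent with additive
    Gaussian noise of ``effect_sd`` (fraction) x 100, clipped to [0, 100].
    """
    if spec.scenario is not Scenario.SINGLE_AGENT_CURVES:
        raise ValidationError("spec.scenario must be single_agent_curves")
    doses = np.asarray(spec.doses if spec.doses is not None else edu_dose_layout(),
                       dtype=float)
    if np.unique(doses[doses > 0]).size < 5:
        raise ValidationError("degenerate dose layout: need >= 5 distinct doses")
    rng = spec.rng()
    pos = doses[doses > 0]
    lo, hi = np.log10(pos.min()), np.log10(pos.max())
    rows, truth_rows = [], []
    for cid in range(spec.n):
        ec50 = 10.0 ** rng.uniform(lo + (hi - lo) / 4, hi - (hi - lo) / 4)
        hill = rng.uniform(0.8, 2.0)
        top = spec.curve_a["top"]
        bottom = spec.curve_a["bottom"]
        truth_rows.append(dict(curve_id=cid, top=top, bottom=bottom,
                               ec50_nM=ec50, hill=hill))
        clean = bottom + (top - bottom) / (1.0 + (ec50 / doses) ** hill)
        noisy = clean + rng.normal(0.0, spec.effect_sd * 100.0, size=doses.size)
        noisy = np.clip(noisy, 0.0, 100.0)
        for d, e in zip(doses, noisy):
            rows.append(dict(curve_id=cid, dose_nM=d, effect_pct=e))
    data = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    data.attrs["seed"] = truth.attrs["seed"] = spec.seed
    return data, truth


# --------------------------------------------------------------------------
# combination matrices
# --------------------------------------------------------------------------

def _null_surface(curve_a: DoseResponseFit, curve_b: DoseResponseFit,
                  doses_a, doses_b, null_model: str) -> np.ndarray:
    exp = np.empty((len(doses_a), len(doses_b)))
    for i, a in enumerate(doses_a):
        for j, b in enumerate(doses_b):
            if null_model == "loewe":
                exp[i, j] = _synergy.loewe_expected(curve_a, curve_b, a, b)
            elif null_model == "bliss":
                ea = float(np.clip(curve_a.effect_at(a) / 100.0, 0, 1)) if a > 0 else 0.0
                eb = float(np.clip(curve_b.effect_at(b) / 100.0, 0, 1)) if b > 0 else 0.0
                exp[i, j] = _synergy.bliss_expected(ea, eb)
            elif null_model == "sham":
                exp[i, j] = float(curve_a.effect_at(a + b)) / 100.0
            else:
                raise ValidationError("null_model must be loewe, bliss or sham")
    return exp


def gen_matrix(spec: GeneratorSpec) -> DoseGrid:
    """Combination matrix under a chosen interaction null, plus options.

    Observed = null-model expectation (Loewe via the same solver used in the
    analysis, Bliss closed form, or a sham self-combination) + an optional
    localized synergy bump over the mid-dose quadrant + Gaussian noise,
    clipped to [0, 1].  Truth metadata records the null, the curves, the
    injected bump mass and the seed.
    """
    if spec.scenario is not Scenario.COMBO_MATRIX:
        raise ValidationError("spec.scenario must be combo_matrix")
    doses = np.asarray(spec.doses if spec.doses is not None
                       else default_dose_grid(), dtype=float)
    curve_a = make_true_curve(**spec.curve_a)
    curve_b = (curve_a if spec.null_model == "sham"
               else make_true_curve(**spec.curve_b))
    expected = _null_surface(curve_a, curve_b, doses, doses, spec.null_model)
    bump = np.zeros_like(expected)
    if spec.bump_amplitude != 0.0:
        # raised-cosine bump centred on the mid-dose quadrant (log-dose space)
        li = np.arange(doses.size, dtype=float)
        c = (doses.size - 1) / 2.0
        w = doses.size / 2.0
        r = np.sqrt((li[:, None] - c) ** 2 + (li[None, :] - c) ** 2) / w
        bump = spec.bump_amplitude * np.where(r < 1, 0.5 * (1 + np.cos(np.pi * r)), 0.0)
        if np.max(expected + bump) > 1.2:
            import warnings
            warnings.warn("synergy bump pushes effects above 1 by more than 0.2 "
                          "before clipping")
    rng = spec.rng()
    noisy = expected + bump + rng.normal(0.0, spec.effect_sd, size=expected.shape)
    observed = np.clip(noisy, 0.0, 1.0)
    return DoseGrid(
        doses_a=doses, doses_b=doses, effects=observed, provenance="synthetic",
        metadata={"seed": spec.seed, "null_model": spec.null_model,
                  "effect_sd": spec.effect_sd,
                  "bump_amplitude": spec.bump_amplitude,
                  "bump_mass": float(np.sum(bump)),
                  "curve_a": dict(spec.curve_a),
                  "curve_b": dict(spec.curve_a if spec.null_model == "sham"
                                  else spec.curve_b)})


# --------------------------------------------------------------------------
# xenograft cohorts
# --------------------------------------------------------------------------

def gen_cohort(spec: GeneratorSpec):
    """Exponential xenograft growth cohorts with lognormal caliper noise.

    Per animal: volume(t) = baseline * 2^(slope*t) with slope drawn around the
    group slope (``slope_jitter_sd``), measured on the twice-weekly schedule
    with multiplicative lognormal noise (``volume_sd``).  Returns
    ``(TumorCohort, truth)`` where truth records group slopes and doubling
    times.
    """
    if spec.scenario is not Scenario.XENOGRAFT_COHORT:
        raise ValidationError("spec.scenario must be xenograft_cohort")
    rng = spec.rng()
    rows, truth_rows = [], []
    days = np.asarray(spec.schedule_days, dtype=float)
    aid = 0
    for group, g in spec.groups.items():
        if "slope_per_day" in g:
            slope = float(g["slope_per_day"])
        else:
            dbl = float(g["doubling_days"])
            if dbl <= 0:
                raise ValidationError("doubling time must be positive")
            slope = 1.0 / dbl
        n_animals = int(g.get("n_animals", 10))
        truth_rows.append(dict(group=group, slope_per_day=slope,
                               doubling_days=(1.0 / slope if slope > 0
                                              else math.inf),
                               n_animals=n_animals))
        for _ in range(n_animals):
            a_slope = slope + (rng.normal(0.0, spec.slope_jitter_sd)
                               if spec.slope_jitter_sd > 0 else 0.0)
            base = spec.baseline_mm3
            clean = base * 2.0 ** (a_slope * days)
            noise = (np.exp(rng.normal(0.0, spec.volume_sd, size=days.size))
                     if spec.volume_sd > 0 else np.ones(days.size))
            for d, v in zip(days, clean * noise):
                rows.append(dict(animal=f"a{aid:03d}", group=group, day=d,
                                 volume_mm3=v))
            aid += 1
    cohort = TumorCohort(pd.DataFrame(rows),
                         metadata={"seed": spec.seed,
                                   "volume_sd": spec.volume_sd,
                                   "slope_jitter_sd": spec.slope_jitter_sd})
    truth = pd.DataFrame(truth_rows)
    truth.attrs["seed"] = spec.seed
    return cohort, truth
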