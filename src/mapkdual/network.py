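"""Mass-action model of the RAS-RAF-MEK-ERK cascade under MEK/ERK inhibition.

The model follows the negative-feedback-amplifier picture of oncogenic MAPK
signalling: a clamped Grb2-SOS input catalyses Ras-GDP -> Ras-GTP exchange,
Ras-GTP activates RAF, active RAF phosphorylates MEK, and active (singly
phosphorylated) MEK carries out distributive two-step phosphorylation of ERK.
Doubly phosphorylated free ERK (ppERK) is the pathway output and drives three
canonical negative feedbacks:

* ``fb_phospho`` -- fast inhibitory phosphorylation of MEK and of
  CRAF-containing active RAF by ppERK (minutes-to-hour timescale);
* ``fb_dusp``   -- ppERK-induced synthesis of DUSP phosphatases that
  dephosphorylate ERK (transcriptional, hours timescale);
* ``fb_spry``   -- ppERK-induced synthesis of SPRY, which inhibits the
  Grb2-SOS -> Ras activation step (transcriptional, hours timescale).

Two pharmacological agents can be registered: a MEK inhibitor and an ERK
inhibitor.  Drug binding is reversible mass action, with state-independent
affinity for every phosphoform of the target.  Bound forms keep their
phosphorylation state and remain substrates for (de)phosphorylation, but have
zero catalytic activity; drug-bound ppERK contributes nothing to the pathway
output or to any feedback drive, which is precisely how ERK inhibition
relieves feedback.

The ``ras_coupled`` switch distinguishes the KRAS-mutant topology (RAF
activation requires Ras-GTP, feedbacks act productively on the input node)
from a BRAF-mutant mimic in which RAF activates constitutively; the
constitutive rate is sized by root finding so that the vehicle steady state is
unchanged, isolating the topology difference.  Mutant-BRAF-like constitutive
RAF is additionally insensitive to the CRAF-directed inhibitory feedback
phosphorylation, so those reactions are absent when ``ras_coupled=False``.

Units: concentrations in nM, time in hours, bimolecular rate constants in
1/(nM*h), first-order rate constants in 1/h.
"""

from __future__ import annotations

import enum
import importlib.resources
import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "FeedbackConfig",
    "ModelParameters",
    "DrugTarget",
    "InhibitorSpec",
    "Reaction",
    "ReactionNetwork",
    "MapkCascade",
    "Trajectory",
    "SteadyState",
    "build_network",
    "simulate",
    "steady_state",
    "craf_activity",
    "load_default_parameters",
    "default_inhibitors",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent model configurations (e.g. duplicate drug targets)."""


class ValidationError(ValueError):
    """Raised for invalid numeric inputs (negative doses, non-positive totals...)."""


class IntegrationError(RuntimeError):
    """Raised when the stiff integrator fails; carries step diagnostics."""


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FeedbackConfig:
    """Feedback topology switches.

    Defaults encode the KRAS-mutant setting: all three feedbacks on and RAF
    activation coupled to Ras-GTP.
    """

    fb_phospho: bool = True
    fb_dusp: bool = True
    fb_spry: bool = True
    ras_coupled: bool = True


class DrugTarget(str, enum.Enum):
    MEK = "MEK"
    ERK = "ERK"


@dataclass(frozen=True)
class InhibitorSpec:
    """Reversible inhibitor of MEK or ERK.

    ``kon`` in 1/(nM*h), ``koff`` in 1/h; Kd = koff/kon in nM.  The bound
    target retains its phosphorylation state, remains a substrate for kinases
    and phosphatases, but is catalytically dead and (for ERK) invisible to the
    pathway output and to all feedback drives.
    """

    target: DrugTarget
    kon: float
    koff: float
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "target", DrugTarget(self.target))
        if not (self.kon > 0 and self.koff > 0):
            raise ValidationError("inhibitor kon and koff must be strictly positive")

    @property
    def kd(self) -> float:
        return self.koff / self.kon


_RATE_FIELDS = (
    "k_ras_act", "k_ras_hyd",
    "k_raf_act", "k_raf_deact", "k_raf_fb", "k_raf_fb_rec",
    "k_mek_cat", "k_mek_dephos", "k_mek_fb", "k_mek_fb_rec",
    "k_erk_cat", "k_erk_dephos", "k_dusp_cat",
    "v_dusp", "k_half_dusp", "hill_dusp", "k_deg_dusp",
    "v_spry", "k_half_spry", "hill_spry", "k_deg_spry",
    "k_spry_inh",
)
_TOTAL_FIELDS = ("gs_total", "ras_total", "raf_total", "mek_total", "erk_total")

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class ModelParameters:
    """Totals (nM) and rate constants (1/h or 1/(nM*h)) of the cascade.

    ``k_raf_const`` is the constitutive RAF activation rate used only when
    ``ras_coupled=False``; leave it ``None`` to have :func:`build_network`
    size it against the coupled vehicle steady state.
    """

    # totals (nM)
    gs_total: float
    ras_total: float
    raf_total: float
    mek_total: float
    erk_total: float
    # Ras module
    k_ras_act: float      # 1/(nM h): rate = k * GS_eff * [RasGDP]
    k_ras_hyd: float      # 1/h
    # RAF module
    k_raf_act: float      # 1/(nM h): rate = k * [RasGTP] * [RAF]
    k_raf_deact: float    # 1/h
    k_raf_fb: float       # 1/(nM h): ppERK-driven RAFa -> RAFi
    k_raf_fb_rec: float   # 1/h
    # MEK module
    k_mek_cat: float      # 1/(nM h): RAFa-catalysed MEK phosphorylation
    k_mek_dephos: float   # 1/h
    k_mek_fb: float       # 1/(nM h): ppERK-driven MEK -> MEKf
    k_mek_fb_rec: float   # 1/h
    # ERK module (distributive two-step phosphorylation by active MEK)
    k_erk_cat: float      # 1/(nM h), both steps
    k_erk_dephos: float   # 1/h basal, each step
    k_dusp_cat: float     # 1/(nM h): DUSP-catalysed dephosphorylation, each step
    # DUSP transcriptional feedback (Hill-activated by free ppERK)
    v_dusp: float         # nM/h
    k_half_dusp: float    # nM
    hill_dusp: float
    k_deg_dusp: float     # 1/h
    # SPRY transcriptional feedback
    v_spry: float         # nM/h
    k_half_spry: float    # nM
    hill_spry: float
    k_deg_spry: float     # 1/h
    k_spry_inh: float     # nM: GS_eff = GS / (1 + [SPRY]/k_spry_inh)
    # constitutive RAF activation (decoupled variant only)
    k_raf_const: Optional[float] = None

    def __post_init__(self):
        for name in _TOTAL_FIELDS:
            if not getattr(self, name) > 0:
                raise ValidationError(f"total {name!r} must be strictly positive")
        for name in _RATE_FIELDS:
            if getattr(self, name) < 0:
                raise ValidationError(f"rate {name!r} must be non-negative")
        # transcriptional feedback must be slower than phosphorylation cycles
        for name in ("k_deg_dusp", "k_deg_spry"):
            k = getattr(self, name)
            if k > 0 and _LN2 / k < 1.0:
                raise ValidationError(
                    f"{name!r} implies a half-life below 1 h; transcriptional "
                    "feedback must be slower than the phosphorylation cycles"
                )

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in _TOTAL_FIELDS}
        d.update({name: getattr(self, name) for name in _RATE_FIELDS})
        if self.k_raf_const is not None:
            d["k_raf_const"] = self.k_raf_const
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "totals" in doc or "rates" in doc:
            flat = {}
            flat.update(doc.get("totals", {}))
            flat.update(doc.get("rates", {}))
            return cls.from_dict(flat)
        return cls.from_dict(doc)

    def to_yaml(self, path) -> None:
        doc = {
            "units": {"concentration": "nM", "time": "h",
                      "first_order_rates": "1/h", "second_order_rates": "1/(nM h)"},
            "totals": {name: float(getattr(self, name)) for name in _TOTAL_FIELDS},
            "rates": {name: float(getattr(self, name)) for name in _RATE_FIELDS},
        }
        if self.k_raf_const is not None:
            doc["rates"]["k_raf_const"] = float(self.k_raf_const)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def load_default_parameters() -> ModelParameters:
    """Load the frozen, calibrated default parameter set shipped with the package."""
    ref = importlib.resources.files("mapkdual").joinpath("params_default.yaml")
    with importlib.resources.as_file(ref) as path:
        return ModelParameters.from_yaml(path)


def default_inhibitors() -> list[InhibitorSpec]:
    """Default MEK and ERK inhibitor specs (low-nanomolar reversible binders).

    The Kd values are placeholders in the published range for allosteric MEK
    inhibitors and ATP-competitive ERK inhibitors; exact affinities for the
    clinical compounds are not public.
    """
    ref = importlib.resources.files("mapkdual").joinpath("params_default.yaml")
    with importlib.resources.as_file(ref) as path:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    specs = []
    for item in doc.get("inhibitors", []):
        specs.append(InhibitorSpec(target=DrugTarget(item["target"]),
                                   kon=item["kon"], koff=item["koff"],
                                   name=item.get("name", "")))
    return specs


# --------------------------------------------------------------------------
# species / reactions
# --------------------------------------------------------------------------

SPECIES = (
    "RasGDP", "RasGTP",
    "RAF", "RAFa", "RAFi",
    "MEK", "pMEK", "MEKf", "MEK_D", "pMEK_D", "MEKf_D",
    "ERK", "pERK", "ppERK", "ERK_D", "pERK_D", "ppERK_D",
    "DUSP", "SPRY",
)
_IDX = {name: i for i, name in enumerate(SPECIES)}

#: conserved protein moieties: name -> species carrying that moiety
MOIETIES = {
    "Ras": ("RasGDP", "RasGTP"),
    "RAF": ("RAF", "RAFa", "RAFi"),
    "MEK": ("MEK", "pMEK", "MEKf", "MEK_D", "pMEK_D", "MEKf_D"),
    "ERK": ("ERK", "pERK", "ppERK", "ERK_D", "pERK_D", "ppERK_D"),
}

# rate-law kinds
_MASS_ACTION = "mass_action"          # k * prod(factors); factors may include DOSE_* clamps
_HILL = "hill_synthesis"              # vmax * d^n / (K^n + d^n), d = driver species
_INHIBITED_INPUT = "inhibited_input"  # k * GS * [sub] / (1 + [inh]/Ki)


@dataclass(frozen=True)
class Reaction:
    """One reaction: stoichiometry plus a named rate law.

    ``factors`` are species names (or the clamp tokens ``DOSE_MEK``/``DOSE_ERK``)
    whose concentrations multiply the rate constant ``k``.
    """

    name: str
    stoich: dict            # species -> integer change
    kind: str
    k: float = 0.0
    factors: tuple = ()
    vmax: float = 0.0
    khalf: float = 0.0
    hill: float = 1.0
    driver: str = ""
    ki: float = 0.0
    substrate: str = ""


def _mass(name, stoich, k, *factors):
    return Reaction(name=name, stoich=stoich, kind=_MASS_ACTION, k=k, factors=factors)


class ReactionNetwork:
    """Compiled mass-action reaction system with clamped drug inputs.

    Built by :func:`build_network`; integrates via :func:`simulate` /
    :func:`steady_state`.  Free MEK- and ERK-inhibitor concentrations are
    clamped (no depletion), so they enter the binding on-rates as constant
    multipliers chosen at right-hand-side compile time.
    """

    #: integrator tolerances (stiff solver); part of the determinism contract
    RTOL = 1e-8
    ATOL = 1e-10

    def __init__(self, params: ModelParameters, config: FeedbackConfig,
                 inhibitors: Sequence[InhibitorSpec]):
        self.params = params
        self.config = config
        self.inhibitors = {inh.target: inh for inh in inhibitors}
        if len(self.inhibitors) != len(inhibitors):
            raise ConfigurationError("at most one inhibitor per target")
        self.species = SPECIES
        self.reactions = self._build_reactions()
        self._compile()
        self._vehicle_ss: Optional[np.ndarray] = None

    # -- reaction list ------------------------------------------------------

    def _build_reactions(self) -> list[Reaction]:
        p, cfg = self.params, self.config
        rxns: list[Reaction] = []

        # Ras GDP/GTP cycle
        if cfg.fb_spry:
            rxns.append(Reaction(
                name="ras_activation", stoich={"RasGDP": -1, "RasGTP": +1},
                kind=_INHIBITED_INPUT, k=p.k_ras_act * p.gs_total,
                ki=p.k_spry_inh, substrate="RasGDP", driver="SPRY"))
        else:
            rxns.append(_mass("ras_activation", {"RasGDP": -1, "RasGTP": +1},
                              p.k_ras_act * p.gs_total, "RasGDP"))
        rxns.append(_mass("ras_hydrolysis", {"RasGTP": -1, "RasGDP": +1},
                          p.k_ras_hyd, "RasGTP"))

        # RAF activation
        if cfg.ras_coupled:
            rxns.append(_mass("raf_activation", {"RAF": -1, "RAFa": +1},
                              p.k_raf_act, "RasGTP", "RAF"))
        else:
            if p.k_raf_const is None:
                raise ConfigurationError(
                    "k_raf_const unset for a RAS-decoupled network; use "
                    "build_network() to size it against the coupled baseline")
            rxns.append(_mass("raf_activation_const", {"RAF": -1, "RAFa": +1},
                              p.k_raf_const, "RAF"))
        rxns.append(_mass("raf_deactivation", {"RAFa": -1, "RAF": +1},
                          p.k_raf_deact, "RAFa"))

        # CRAF-directed feedback phosphorylation requires the RAS-coupled complex
        if cfg.fb_phospho and cfg.ras_coupled:
            rxns.append(_mass("raf_fb_phospho", {"RAFa": -1, "RAFi": +1},
                              p.k_raf_fb, "ppERK", "RAFa"))
            rxns.append(_mass("raf_fb_recovery", {"RAFi": -1, "RAF": +1},
                              p.k_raf_fb_rec, "RAFi"))

        # MEK (de)phosphorylation, free and drug-bound substrates
        for sub, prod, tag in (("MEK", "pMEK", ""), ("MEK_D", "pMEK_D", "_bound")):
            rxns.append(_mass(f"mek_phospho{tag}", {sub: -1, prod: +1},
                              p.k_mek_cat, "RAFa", sub))
            rxns.append(_mass(f"mek_dephospho{tag}", {prod: -1, sub: +1},
                              p.k_mek_dephos, prod))
        if cfg.fb_phospho:
            for sub, prod, tag in (("MEK", "MEKf", ""), ("MEK_D", "MEKf_D", "_bound")):
                rxns.append(_mass(f"mek_fb_phospho{tag}", {sub: -1, prod: +1},
                                  p.k_mek_fb, "ppERK", sub))
                rxns.append(_mass(f"mek_fb_recovery{tag}", {prod: -1, sub: +1},
                                  p.k_mek_fb_rec, prod))

        # distributive two-step ERK phosphorylation by free active MEK
        for a, b, c, tag in (("ERK", "pERK", "ppERK", ""),
                             ("ERK_D", "pERK_D", "ppERK_D", "_bound")):
            rxns.append(_mass(f"erk_phospho1{tag}", {a: -1, b: +1},
                              p.k_erk_cat, "pMEK", a))
            rxns.append(_mass(f"erk_phospho2{tag}", {b: -1, c: +1},
                              p.k_erk_cat, "pMEK", b))
            rxns.append(_mass(f"erk_dephospho2{tag}", {c: -1, b: +1},
                              p.k_erk_dephos, c))
            rxns.append(_mass(f"erk_dephospho1{tag}", {b: -1, a: +1},
                              p.k_erk_dephos, b))

        # DUSP feedback: synthesis, degradation, catalysed ERK dephosphorylation
        if cfg.fb_dusp:
            rxns.append(Reaction(name="dusp_synthesis", stoich={"DUSP": +1},
                                 kind=_HILL, vmax=p.v_dusp, khalf=p.k_half_dusp,
                                 hill=p.hill_dusp, driver="ppERK"))
            rxns.append(_mass("dusp_degradation", {"DUSP": -1},
                              p.k_deg_dusp, "DUSP"))
            for a, b, c, tag in (("ERK", "pERK", "ppERK", ""),
                                 ("ERK_D", "pERK_D", "ppERK_D", "_bound")):
                rxns.append(_mass(f"dusp_dephospho2{tag}", {c: -1, b: +1},
                                  p.k_dusp_cat, "DUSP", c))
                rxns.append(_mass(f"dusp_dephospho1{tag}", {b: -1, a: +1},
                                  p.k_dusp_cat, "DUSP", b))

        # SPRY feedback: synthesis + degradation (action is on ras_activation)
        if cfg.fb_spry:
            rxns.append(Reaction(name="spry_synthesis", stoich={"SPRY": +1},
                                 kind=_HILL, vmax=p.v_spry, khalf=p.k_half_spry,
                                 hill=p.hill_spry, driver="ppERK"))
            rxns.append(_mass("spry_degradation", {"SPRY": -1},
                              p.k_deg_spry, "SPRY"))

        # reversible drug binding to every phosphoform of the target
        bind_forms = {DrugTarget.MEK: (("MEK", "MEK_D"), ("pMEK", "pMEK_D"),
                                       ("MEKf", "MEKf_D")),
                      DrugTarget.ERK: (("ERK", "ERK_D"), ("pERK", "pERK_D"),
                                       ("ppERK", "ppERK_D"))}
        for target, inh in self.inhibitors.items():
            clamp = "DOSE_MEK" if target is DrugTarget.MEK else "DOSE_ERK"
            for free, bound in bind_forms[target]:
                rxns.append(_mass(f"bind_{free}", {free: -1, bound: +1},
                                  inh.kon, clamp, free))
                rxns.append(_mass(f"unbind_{bound}", {bound: -1, free: +1},
                                  inh.koff, bound))
        return rxns

    # -- compilation --------------------------------------------------------

    def _compile(self) -> None:
        n_sp, n_rx = len(SPECIES), len(self.reactions)
        N = np.zeros((n_sp, n_rx))
        k = np.zeros(n_rx)
        i1 = np.zeros(n_rx, dtype=np.intp)
        i2 = np.full(n_rx, -1, dtype=np.intp)
        mek_dose_rows, erk_dose_rows, special = [], [], []
        for j, rx in enumerate(self.reactions):
            for sp, nu in rx.stoich.items():
                N[_IDX[sp], j] = nu
            if rx.kind == _MASS_ACTION:
                k[j] = rx.k
                idxs = []
                for f in rx.factors:
                    if f == "DOSE_MEK":
                        mek_dose_rows.append(j)
                    elif f == "DOSE_ERK":
                        erk_dose_rows.append(j)
                    else:
                        idxs.append(_IDX[f])
                if len(idxs) >= 1:
                    i1[j] = idxs[0]
                if len(idxs) == 2:
                    i2[j] = idxs[1]
                if len(idxs) > 2:  # pragma: no cover
                    raise ConfigurationError("mass action supports <= 2 species factors")
            else:
                special.append(j)
        self._N = N
        self._k = k
        self._i1 = i1
        self._i2 = i2
        self._i2safe = np.where(i2 < 0, 0, i2)
        self._has_i2 = (i2 >= 0).astype(float)
        self._mek_dose_rows = np.asarray(mek_dose_rows, dtype=np.intp)
        self._erk_dose_rows = np.asarray(erk_dose_rows, dtype=np.intp)
        self._special = [(j, self.reactions[j]) for j in special]

    def make_rhs(self, dose_mek: float, dose_erk: float):
        """Compile the ODE right-hand side for clamped drug doses (nM)."""
        if dose_mek < 0 or dose_erk < 0:
            raise ValidationError("drug doses must be non-negative")
        if dose_mek > 0 and DrugTarget.MEK not in self.inhibitors:
            raise ConfigurationError("no MEK inhibitor registered in this network")
        if dose_erk > 0 and DrugTarget.ERK not in self.inhibitors:
            raise ConfigurationError("no ERK inhibitor registered in this network")
        k = self._k.copy()
        k[self._mek_dose_rows] *= dose_mek
        k[self._erk_dose_rows] *= dose_erk
        N, i1, i2safe, has_i2 = self._N, self._i1, self._i2safe, self._has_i2
        specials = []
        for j, rx in self._special:
            if rx.kind == _HILL:
                specials.append(("hill", j, rx.vmax, rx.khalf ** rx.hill, rx.hill,
                                 _IDX[rx.driver]))
            elif rx.kind == _INHIBITED_INPUT:
                specials.append(("inh", j, rx.k, rx.ki, _IDX[rx.substrate],
                                 _IDX[rx.driver]))
        def rhs(t, x):
            xc = np.maximum(x, 0.0)
            v = k * xc[i1]
            v *= 1.0 + has_i2 * (xc[i2safe] - 1.0)
            for s in specials:
                if s[0] == "hill":
                    _, j, vmax, khn, n, di = s
                    dn = xc[di] ** n
                    v[j] = vmax * dn / (khn + dn)
                else:
                    _, j, kk, ki, si, di = s
                    v[j] = kk * xc[si] / (1.0 + xc[di] / ki)
            return N @ v
        return rhs

    # -- invariants ---------------------------------------------------------

    def stoichiometry_matrix(self) -> np.ndarray:
        return self._N.copy()

    def check_conservation(self) -> None:
        """Verify that every reaction conserves each protein moiety."""
        for name, members in MOIETIES.items():
            c = np.zeros(len(SPECIES))
            for sp in members:
                c[_IDX[sp]] = 1.0
            col = c @ self._N
            if np.any(np.abs(col) > 0):
                bad = [self.reactions[j].name for j in np.nonzero(np.abs(col) > 0)[0]]
                raise ConfigurationError(f"moiety {name!r} not conserved by {bad}")

    def initial_state(self) -> np.ndarray:
        p = self.params
        x0 = np.zeros(len(SPECIES))
        x0[_IDX["RasGDP"]] = p.ras_total
        x0[_IDX["RAF"]] = p.raf_total
        x0[_IDX["MEK"]] = p.mek_total
        x0[_IDX["ERK"]] = p.erk_total
        return x0

    def vehicle_steady_state(self) -> np.ndarray:
        """Drug-free steady state (cached); the pre-equilibrated initial condition."""
        if self._vehicle_ss is None:
            ss = steady_state(self, 0.0, 0.0)
            if not ss.converged:
                warnings.warn("vehicle pre-equilibration did not converge")
            self._vehicle_ss = ss.state
        return self._vehicle_ss.copy()

    @property
    def vehicle_output(self) -> float:
        return float(self.vehicle_steady_state()[_IDX["ppERK"]])


# --------------------------------------------------------------------------
# result objects
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-resolved species concentrations from one simulation.

    ``states`` is (n_times, n_species) in nM; derived series are exposed as
    properties.  The pathway output is free (non-drug-bound) ppERK.
    """

    times: np.ndarray
    states: np.ndarray
    network: ReactionNetwork
    dose_mek: float
    dose_erk: float

    def __getitem__(self, species: str) -> np.ndarray:
        return self.states[:, _IDX[species]]

    @property
    def pathway_output(self) -> np.ndarray:
        return self["ppERK"]

    @property
    def dusp(self) -> np.ndarray:
        return self["DUSP"]

    @property
    def spry(self) -> np.ndarray:
        return self["SPRY"]

    @property
    def craf_active(self) -> np.ndarray:
        """Active, non-feedback-phosphorylated RAF (nM)."""
        return self["RAFa"]

    def output_auc(self) -> float:
        """Time integral of the pathway output over the trajectory (nM*h)."""
        return float(np.trapezoid(self.pathway_output, self.times))

    def conservation_drift(self) -> dict:
        """Max relative drift of each conserved moiety along the trajectory."""
        p = self.network.params
        totals = {"Ras": p.ras_total, "RAF": p.raf_total,
                  "MEK": p.mek_total, "ERK": p.erk_total}
        out = {}
        for name, members in MOIETIES.items():
            s = sum(self[sp] for sp in members)
            out[name] = float(np.max(np.abs(s - totals[name])) / totals[name])
        return out

    def to_frame(self):
        """Tidy (time, species, concentration, units) table."""
        import pandas as pd
        n_t = len(self.times)
        return pd.DataFrame({
            "time_h": np.repeat(self.times, len(SPECIES)),
            "species": list(SPECIES) * n_t,
            "concentration_nM": self.states.reshape(-1),
            "units": "nM",
        })


@dataclass
class SteadyState:
    state: np.ndarray
    converged: bool
    t_reached: float
    max_rel_rate: float

    def __getitem__(self, species: str) -> float:
        return float(self.state[_IDX[species]])

    @property
    def pathway_output(self) -> float:
        return self["ppERK"]


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def build_network(params: ModelParameters, config: FeedbackConfig = FeedbackConfig(),
                  inhibitors: Sequence[InhibitorSpec] = ()) -> ReactionNetwork:
    """Assemble the reaction network for a feedback configuration.

    For ``ras_coupled=False`` with ``params.k_raf_const`` unset, the
    constitutive RAF activation rate is sized by 1-D root finding so that the
    vehicle steady-state pathway output matches the RAS-coupled twin's,
    isolating the topology difference from a baseline difference.
    """
    targets = [inh.target for inh in inhibitors]
    if len(set(targets)) != len(targets):
        raise ConfigurationError("duplicate inhibitor target")
    if not config.ras_coupled and params.k_raf_const is None:
        coupled = ReactionNetwork(params, replace(config, ras_coupled=True), inhibitors)
        target_out = coupled.vehicle_output

        def mismatch(log10_k):
            trial = replace(params, k_raf_const=10.0 ** log10_k)
            net = ReactionNetwork(trial, config, inhibitors)
            return net.vehicle_output - target_out

        lo, hi = -6.0, 4.0
        flo, fhi = mismatch(lo), mismatch(hi)
        if not flo < 0 < fhi:
            raise ConfigurationError(
                "could not bracket the constitutive RAF activation rate")
        log10_k = brentq(mismatch, lo, hi, xtol=1e-10, rtol=1e-12)
        params = replace(params, k_raf_const=10.0 ** log10_k)
    net = ReactionNetwork(params, config, inhibitors)
    net.check_conservation()
    return net


def _integrate(network: ReactionNetwork, x0: np.ndarray, t_span, t_eval,
               dose_mek: float, dose_erk: float) -> np.ndarray:
    rhs = network.make_rhs(dose_mek, dose_erk)
    sol = solve_ivp(rhs, t_span, x0, method="LSODA", t_eval=t_eval,
                    rtol=ReactionNetwork.RTOL, atol=ReactionNetwork.ATOL)
    if not sol.success:
        raise IntegrationError(
            f"stiff integration failed at t={sol.t[-1] if sol.t.size else t_span[0]:.4g} h "
            f"(doses MEKi={dose_mek} nM, ERKi={dose_erk} nM): {sol.message}; "
            f"last state={sol.y[:, -1] if sol.y.size else x0}")
    y = sol.y.T
    if np.min(y) < -1e-9:
        raise IntegrationError(
            f"concentration floor violated (min={np.min(y):.3e} nM)")
    return np.maximum(y, 0.0)


def simulate(network: ReactionNetwork, dose_mek: float = 0.0, dose_erk: float = 0.0,
             t_end: float = 72.0, n_points: int = 289) -> Trajectory:
    """Integrate the cascade for ``t_end`` hours under clamped drug doses.

    The initial condition is the drug-free (vehicle) steady state; drug is
    applied as a step at t=0 and its free concentration is held constant.
    """
    if dose_mek < 0 or dose_erk < 0:
        raise ValidationError("doses must be non-negative")
    if t_end <= 0:
        raise ValidationError("t_end must be positive")
    x0 = network.vehicle_steady_state()
    t_eval = np.linspace(0.0, t_end, n_points)
    y = _integrate(network, x0, (0.0, t_end), t_eval, dose_mek, dose_erk)
    return Trajectory(times=t_eval, states=y, network=network,
                      dose_mek=dose_mek, dose_erk=dose_erk)


def steady_state(network: ReactionNetwork, dose_mek: float = 0.0,
                 dose_erk: float = 0.0, x0: Optional[np.ndarray] = None,
                 t_max: float = 1000.0) -> SteadyState:
    """Integrate to steady state (max relative rate < 1e-8/h) or t_max hours.

    Non-convergence (e.g. a sustained oscillation) is flagged on the result,
    not raised.
    """
    if x0 is None:
        if dose_mek == 0 and dose_erk == 0:
            x0 = network.initial_state()
        else:
            x0 = network.vehicle_steady_state()
    rhs = network.make_rhs(dose_mek, dose_erk)
    x = np.asarray(x0, dtype=float)
    t = 0.0
    chunk = 50.0
    tol = 1e-8
    while t < t_max:
        t_next = min(t + chunk, t_max)
        y = _integrate(network, x, (t, t_next), np.array([t_next]),
                       dose_mek, dose_erk)
        x = y[-1]
        t = t_next
        dx = rhs(t, x)
        rel = np.max(np.abs(dx) / np.maximum(np.abs(x), 1e-3))
        if rel < tol:
            return SteadyState(state=x, converged=True, t_reached=t, max_rel_rate=rel)
        chunk = min(chunk * 2.0, 200.0)
    dx = rhs(t, x)
    rel = np.max(np.abs(dx) / np.maximum(np.abs(x), 1e-3))
    return SteadyState(state=x, converged=rel < tol, t_reached=t, max_rel_rate=rel)


def craf_activity(traj: Trajectory) -> np.ndarray:
    """Active-CRAF fold-change series, normalised to the vehicle steady state.

    The active pool is RAF* excluding feedback-phosphorylated forms; vehicle
    fold-change is identically 1.
    """
    veh = traj.network.vehicle_steady_state()[_IDX["RAFa"]]
    if veh <= 0:
        raise ValidationError("vehicle CRAF activity is zero; fold-change undefined")
    return traj.craf_active / veh


# --------------------------------------------------------------------------
# model-object facade
# --------------------------------------------------------------------------

class MapkCascade:
    """Model object wrapping a configured cascade.

    Thin facade over :func:`build_network` and the simulation operations, for
    interactive use::

        model = MapkCascade.default()
        traj = model.simulate(dose_mek=10, t_end=72)
    """

    def __init__(self, params: ModelParameters,
                 config: FeedbackConfig = FeedbackConfig(),
                 inhibitors: Sequence[InhibitorSpec] = ()):
        self.network = build_network(params, config, inhibitors)

    @classmethod
    def default(cls, config: FeedbackConfig = FeedbackConfig()) -> "MapkCascade":
        return cls(load_default_parameters(), config, default_inhibitors())

    @property
    def params(self) -> ModelParameters:
        return self.network.params

    @property
    def config(self) -> FeedbackConfig:
        return self.network.config

    def simulate(self, dose_mek: float = 0.0, dose_erk: float = 0.0,
                 t_end: float = 72.0, n_points: int = 289) -> Trajectory:
        return simulate(self.network, dose_mek, dose_erk, t_end, n_points)

    def steady_state(self, dose_mek: float = 0.0, dose_erk: float = 0.0) -> SteadyState:
        return steady_state(self.network, dose_mek, dose_erk)

    def output_ec50(self, target: DrugTarget, t_end: float = 72.0,
                    dose_range=(1e-3, 1e4)) -> float:
        """Pharmacodynamic output-EC50: dose halving the 0-72 h time-integrated
        pathway output relative to vehicle (the model analogue of a cellular
        EC50 measured over the assay window)."""
        return output_ec50(self.network, target, t_end=t_end, dose_range=dose_range)


def output_ec50(network: ReactionNetwork, target: DrugTarget, t_end: float = 72.0,
                dose_range=(1e-3, 1e4)) -> float:
    """Dose halving the 0-t_end time integral of pathway output vs vehicle (nM).

    The integral readout matches the exposure window of the cellular assays
    the model emulates; it reflects both the depth of initial suppression and
    any feedback-driven reactivation over the window.
    """
    target = DrugTarget(target)
    if target not in network.inhibitors:
        raise ConfigurationError(f"no {target.value} inhibitor registered")
    veh_auc = network.vehicle_output * t_end

    def auc_frac(log10_dose):
        d = 10.0 ** log10_dose
        dm, de = (d, 0.0) if target is DrugTarget.MEK else (0.0, d)
        traj = simulate(network, dm, de, t_end=t_end, n_points=145)
        return traj.output_auc() / veh_auc - 0.5

    lo, hi = np.log10(dose_range[0]), np.log10(dose_range[1])
    flo, fhi = auc_frac(lo), auc_frac(hi)
    if not (flo > 0 > fhi):
        raise ValidationError(
            f"output-EC50 not bracketed in dose range {dose_range}")
    log10_d = brentq(auc_frac, lo, hi, xtol=1e-4)
    return 10.0 ** log10_d
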