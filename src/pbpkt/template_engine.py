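"""The configurable whole-body PBPK superstructure.

A single maximal model -- 53 state variables, 105 algebraic output
variables, 32 conditional evaluation sites -- from which chemical-specific
models are obtained by switching compartments, pathways and routes off via
configuration and zero-valued parameters.  States whose derivatives are
identically zero under a configuration can be pruned without changing the
solution of the remaining system.

Model forms are the standard ones of the flow-limited PBPK family:
perfusion-limited tissue balances, a Ramsey-Andersen gas-exchange relation
(steady-state or explicit state), Michaelis-Menten plus first-order
metabolism, and first-order GI absorption/transit.  Blood and the
gas-exchange region can each be represented either by a steady-state
algebraic approximation or by explicit state variables.

State roster (53)
-----------------
17 compartment amounts, 9 cumulative-metabolism accumulators, 13
cumulative intake/elimination accumulators, 14 AUC accumulators.

The roster, output map and conditional-site placement are normative for
this package; see the repository documentation for their composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ConsistencyError, DomainError
from .params_io import (
    BLOOD_POOLS,
    FO_PATHWAYS,
    PATHWAY_HOST,
    PATHWAYS,
    SAT_PATHWAYS,
    TISSUES,
    ChemicalParams,
    PhysiologyParams,
    ScaledParams,
    renormalize_flows,
    scale_physiology,
)

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Compartments beyond the perfused tissues that a configuration may activate.
EXTRA_COMPARTMENTS: tuple[str, ...] = (
    "gas_exchange",
    "stomach_lumen",
    "intestine_lumen",
    "chamber",
    "dermal_vehicle",
    "depot",
)

ALL_COMPARTMENTS: tuple[str, ...] = TISSUES + EXTRA_COMPARTMENTS

ROUTES: tuple[str, ...] = ("inhalation_open", "inhalation_closed", "oral", "dermal", "iv")

# mode constants
SS_APPROX = "SS_APPROX"
STATE_VARS = "STATE_VARS"
GE_SS = "GE_SS"
GE_STATE = "GE_STATE"
INPUT_TABLE = "INPUT_TABLE"
FIXED_DYNAMIC = "FIXED_DYNAMIC"
FIXED_INIT = "FIXED_INIT"
BRANCH = "BRANCH"
SWITCH = "SWITCH"


@dataclass(frozen=True)
class TemplateConfig:
    """Which features of the superstructure are switched on, and how.

    ``active_compartments`` and ``active_pathways`` follow the canonical
    rosters in :mod:`pbpkt.params_io`; ``urinary_excretion`` and
    ``fecal_excretion`` flag the two non-respiratory elimination routes
    (their rate parameters must be nonzero exactly when flagged).
    """

    active_compartments: frozenset = frozenset(TISSUES + ("gas_exchange", "stomach_lumen"))
    active_pathways: frozenset = frozenset()
    routes: frozenset = frozenset(("inhalation_open", "oral"))
    blood_mode: str = STATE_VARS
    gas_exchange_mode: str = GE_SS
    lung_present: bool = True
    bw_mode: str = FIXED_INIT
    conditional_mode: str = BRANCH
    prune: bool = False
    urinary_excretion: bool = False
    fecal_excretion: bool = False
    reduced_outputs: bool = False
    chamber_volume: float = 1000.0  # L
    chamber_loss_rate: float = 0.0  # /h
    vehicle_volume: float = 1.0  # L

    def __post_init__(self) -> None:
        comps = set(self.active_compartments)
        unknown = comps - set(ALL_COMPARTMENTS)
        if unknown:
            raise ConfigurationError(f"unknown compartments: {sorted(unknown)}")
        unknown = set(self.active_pathways) - set(PATHWAYS)
        if unknown:
            raise ConfigurationError(f"unknown pathways: {sorted(unknown)}")
        unknown = set(self.routes) - set(ROUTES)
        if unknown:
            raise ConfigurationError(f"unknown routes: {sorted(unknown)}")
        if self.blood_mode not in (SS_APPROX, STATE_VARS):
            raise ConfigurationError(f"bad blood_mode: {self.blood_mode}")
        if self.gas_exchange_mode not in (GE_SS, GE_STATE):
            raise ConfigurationError(f"bad gas_exchange_mode: {self.gas_exchange_mode}")
        if self.bw_mode not in (INPUT_TABLE, FIXED_DYNAMIC, FIXED_INIT):
            raise ConfigurationError(f"bad bw_mode: {self.bw_mode}")
        if self.conditional_mode not in (BRANCH, SWITCH):
            raise ConfigurationError(f"bad conditional_mode: {self.conditional_mode}")
        if not any(t in comps for t in TISSUES):
            raise ConfigurationError("at least one perfused compartment must be active")
        if {"inhalation_open", "inhalation_closed"} <= set(self.routes):
            raise ConfigurationError("closed-chamber inhalation excludes open inhalation")
        if self.lung_present != ("lung" in comps):
            raise ConfigurationError("lung_present must match 'lung' in active_compartments")
        if self.gas_exchange_mode == GE_STATE and not self.lung_present:
            raise ConfigurationError("GE_STATE requires an explicit lung compartment")
        if self.gas_exchange_mode == GE_STATE and "gas_exchange" not in comps:
            raise ConfigurationError("GE_STATE requires an active gas-exchange region")
        for p in self.active_pathways:
            if PATHWAY_HOST[p] not in comps:
                raise ConfigurationError(
                    f"pathway {p} requires active compartment {PATHWAY_HOST[p]}"
                )
        inhaling = bool({"inhalation_open", "inhalation_closed"} & set(self.routes))
        if inhaling and "gas_exchange" not in comps:
            raise ConfigurationError("inhalation routes require the gas-exchange region")
        if ("chamber" in comps) != ("inhalation_closed" in self.routes):
            raise ConfigurationError("chamber is active iff inhalation_closed is routed")
        if ("dermal_vehicle" in comps) != ("dermal" in self.routes):
            raise ConfigurationError("dermal_vehicle is active iff dermal is routed")
        if "dermal" in self.routes and "skin" not in comps:
            raise ConfigurationError("dermal route requires an active skin compartment")
        if ("oral" in self.routes) != ("stomach_lumen" in comps):
            raise ConfigurationError("oral route is present iff stomach_lumen is active")
        if "intestine_lumen" in comps and "oral" not in self.routes:
            raise ConfigurationError("intestine_lumen requires the oral route")
        if "oral" in self.routes and "liver" not in comps:
            raise ConfigurationError("oral absorption requires an active liver")
        if self.urinary_excretion and "kidney" not in comps:
            raise ConfigurationError("urinary excretion requires an active kidney")
        if self.fecal_excretion and "intestine_lumen" not in comps:
            raise ConfigurationError("fecal excretion requires an active intestine lumen")
        if self.chamber_volume <= 0 or self.vehicle_volume <= 0:
            raise ConfigurationError("chamber/vehicle volumes must be > 0")
        if self.chamber_loss_rate < 0:
            raise ConfigurationError("chamber_loss_rate must be >= 0")


def full_template_config(**overrides) -> TemplateConfig:
    """The maximal configuration: every compartment, pathway and route on.

    Uses the closed chamber (open and closed inhalation are mutually
    exclusive) and flags both non-respiratory elimination routes.
    """
    base = dict(
        active_compartments=frozenset(ALL_COMPARTMENTS),
        active_pathways=frozenset(PATHWAYS),
        routes=frozenset(("inhalation_closed", "oral", "dermal", "iv")),
        blood_mode=STATE_VARS,
        gas_exchange_mode=GE_STATE,
        lung_present=True,
        urinary_excretion=True,
        fecal_excretion=True,
        chamber_loss_rate=0.01,
    )
    base.update(overrides)
    return TemplateConfig(**base)


# ---------------------------------------------------------------------------
# State roster
# ---------------------------------------------------------------------------

_AMOUNT_NAMES: tuple[str, ...] = tuple(f"a_{t}" for t in TISSUES) + (
    "a_arterial",
    "a_venous",
    "a_gas_exchange",
    "a_stomach_lumen",
    "a_intestine_lumen",
    "a_chamber",
    "a_dermal_vehicle",
    "a_depot",
)
_MET_NAMES: tuple[str, ...] = tuple(f"m_{p}" for p in PATHWAYS)
_IE_NAMES: tuple[str, ...] = (
    "e_inhaled",
    "e_oral_dose",
    "e_total_intake",
    "e_gi_absorbed",
    "e_systemic_absorbed",
    "e_exhaled",
    "e_excreted",
    "e_total_eliminated",
    "e_met_liver",
    "e_met_extrahepatic",
    "e_met_saturable",
    "e_met_total",
    "e_cleared_total",
)
_AUC_NAMES: tuple[str, ...] = (
    "auc_arterial",
    "auc_venous",
    "auc_fat",
    "auc_liver",
    "auc_kidney",
    "auc_richly",
    "auc_slowly",
    "auc_skin",
    "auc_lung",
    "auc_stomach_tissue",
    "auc_intestine_tissue",
    "auc_alveolar",
    "auc_exhaled",
    "auc_blood_mean",
)

FULL_STATE_NAMES: tuple[str, ...] = _AMOUNT_NAMES + _MET_NAMES + _IE_NAMES + _AUC_NAMES
assert len(FULL_STATE_NAMES) == 53

STATE_GROUPS: dict[str, str] = {}
for _n in _AMOUNT_NAMES:
    STATE_GROUPS[_n] = "compartment_amount"
for _n in _MET_NAMES:
    STATE_GROUPS[_n] = "cumulative_metabolism"
for _n in _IE_NAMES:
    STATE_GROUPS[_n] = "cumulative_intake_elimination"
for _n in _AUC_NAMES:
    STATE_GROUPS[_n] = "auc"

_IDX: dict[str, int] = {n: i for i, n in enumerate(FULL_STATE_NAMES)}


@dataclass(frozen=True)
class StateRoster:
    """Ordered list of state names with group tags."""

    names: tuple[str, ...]
    groups: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.names)

    def group_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.groups:
            out[g] = out.get(g, 0) + 1
        return out

    def units(self) -> tuple[str, ...]:
        return tuple("mg*h/L" if g == "auc" else "mg" for g in self.groups)


def _state_live(name: str, config: TemplateConfig) -> bool:
    """Whether a state's derivative can be nonzero under ``config``."""
    comps = config.active_compartments
    routes = config.routes
    inhaling = bool({"inhalation_open", "inhalation_closed"} & set(routes))
    gx = "gas_exchange" in comps
    if name.startswith("a_"):
        c = name[2:]
        if c in ("arterial", "venous"):
            return config.blood_mode == STATE_VARS
        if c == "gas_exchange":
            return gx and config.gas_exchange_mode == GE_STATE
        return c in comps
    if name.startswith("m_"):
        return name[2:] in config.active_pathways
    if name.startswith("auc_"):
        c = name[4:]
        if c in ("arterial", "venous", "blood_mean"):
            return True
        if c in ("alveolar", "exhaled"):
            return gx
        if c in ("stomach_tissue", "intestine_tissue"):
            return c in comps
        return c in comps  # plain tissues
    # intake/elimination accumulators
    liver_paths = {"liver1_sat", "liver2_sat", "liver_fo"}
    any_liver = bool(liver_paths & set(config.active_pathways))
    any_xh = bool(set(config.active_pathways) - liver_paths)
    any_sat = bool({"liver1_sat", "liver2_sat", "lung_sat", "kidney_sat"} & set(config.active_pathways))
    any_path = bool(config.active_pathways)
    excreting = config.urinary_excretion or config.fecal_excretion
    table = {
        "e_inhaled": inhaling,
        "e_oral_dose": "oral" in routes,
        "e_total_intake": bool(routes),
        "e_gi_absorbed": "oral" in routes,
        "e_systemic_absorbed": bool({"oral", "dermal", "iv"} & set(routes)) or "depot" in comps,
        "e_exhaled": gx,
        "e_excreted": excreting,
        "e_total_eliminated": gx or excreting,
        "e_met_liver": any_liver,
        "e_met_extrahepatic": any_xh,
        "e_met_saturable": any_sat,
        "e_met_total": any_path,
        "e_cleared_total": gx or excreting or any_path,
    }
    return table[name]


def prune_states(config: TemplateConfig) -> StateRoster:
    """Retain exactly the states whose derivative can be nonzero.

    The removed states are structurally inert: their right-hand sides are
    identically zero under ``config`` for trajectories started at the zero
    state, so eliminating them does not perturb the retained solution.
    Retained states keep full-roster order.
    """
    names = tuple(n for n in FULL_STATE_NAMES if _state_live(n, config))
    return StateRoster(names=names, groups=tuple(STATE_GROUPS[n] for n in names))


def full_roster() -> StateRoster:
    return StateRoster(
        names=FULL_STATE_NAMES,
        groups=tuple(STATE_GROUPS[n] for n in FULL_STATE_NAMES),
    )


# ---------------------------------------------------------------------------
# Conditional sites
# ---------------------------------------------------------------------------

INITIALIZE = "INITIALIZE"
DYNAMICS = "DYNAMICS"


@dataclass(frozen=True)
class ConditionalSite:
    """One registered two-way selection point in the model code."""

    id: str
    section: str  # INITIALIZE | DYNAMICS
    predicate: str


def _conditional_sites() -> tuple[ConditionalSite, ...]:
    init = [
        ConditionalSite("init_bw_source", INITIALIZE, "bw_mode == INPUT_TABLE"),
        ConditionalSite("init_blood_mode", INITIALIZE, "blood_mode == SS_APPROX"),
        ConditionalSite("init_lung_ge_mode", INITIALIZE, "gas_exchange_mode == GE_SS"),
        ConditionalSite("init_param_placement", INITIALIZE, "bw_mode == FIXED_INIT"),
    ]
    dyn = [
        ConditionalSite("dyn_chamber_closed", DYNAMICS, "inhalation_closed routed"),
        ConditionalSite("dyn_inhalation", DYNAMICS, "any inhalation routed"),
        ConditionalSite("dyn_gi_stomach", DYNAMICS, "stomach absorption active"),
        ConditionalSite("dyn_gi_intestine", DYNAMICS, "intestine chain active"),
        ConditionalSite("dyn_dermal", DYNAMICS, "dermal routed"),
        ConditionalSite("dyn_iv", DYNAMICS, "iv routed"),
    ]
    dyn += [ConditionalSite(f"dyn_pathway_{p}", DYNAMICS, f"{p} active") for p in PATHWAYS]
    dyn += [ConditionalSite(f"dyn_compartment_{t}", DYNAMICS, f"{t} active") for t in TISSUES]
    dyn += [
        ConditionalSite("dyn_compartment_depot", DYNAMICS, "depot active"),
        ConditionalSite("dyn_bw_interp", DYNAMICS, "body weight given as table"),
        ConditionalSite("dyn_blood_ss", DYNAMICS, "blood steady-state approximation"),
        ConditionalSite("dyn_ge_ss", DYNAMICS, "gas-exchange steady-state approximation"),
    ]
    sites = tuple(init + dyn)
    assert len(sites) == 32
    return sites


CONDITIONAL_SITES: tuple[ConditionalSite, ...] = _conditional_sites()


def evaluate_conditional(site: ConditionalSite, predicate_value: bool, a, b, mode: str):
    """Select between ``a`` and ``b``.

    ``BRANCH`` uses an if/else; ``SWITCH`` multiplies by a 0/1 constant
    (``s*a + (1-s)*b``).  For finite operands the two are bitwise identical.
    """
    if mode == BRANCH:
        return a if predicate_value else b
    s = 1.0 if predicate_value else 0.0
    return s * a + (1.0 - s) * b


def _branch_sel(pred: bool, s: float, a: float, b: float) -> float:
    return a if pred else b


def _switch_sel(pred: bool, s: float, a: float, b: float) -> float:
    return s * a + (1.0 - s) * b


# ---------------------------------------------------------------------------
# Elementary relations (also used by the stand-alone models)
# ---------------------------------------------------------------------------


def arterial_ss(
    c_ven: float,
    c_inh: float,
    cardiac_output: float,
    alveolar_ventilation: float,
    blood_air_partition: float,
) -> float:
    """Steady-state arterial (pulmonary venous) concentration.

    ``(Qc*Cven + Qalv*Cinh) / (Qc + Qalv/Pba)``; the matching exhaled-air
    concentration is the returned value divided by ``Pba``.
    """
    if blood_air_partition <= 0:
        raise DomainError("blood_air_partition must be > 0")
    qc, qalv = cardiac_output, alveolar_ventilation
    return (qc * c_ven + qalv * c_inh) / (qc + qalv / blood_air_partition)


def venous_ss(
    venous_returns: Sequence[tuple[float, float]],
    cardiac_output: float,
    iv_rate: float = 0.0,
) -> float:
    """Steady-state mixed venous concentration from per-tissue returns."""
    flow_sum = sum(q for q, _ in venous_returns)
    if cardiac_output <= 0:
        raise DomainError("cardiac_output must be > 0")
    if abs(flow_sum - cardiac_output) > 1e-9 * cardiac_output:
        raise ConsistencyError(
            f"venous return flows ({flow_sum}) do not sum to cardiac output "
            f"({cardiac_output})"
        )
    return (sum(q * c for q, c in venous_returns) + iv_rate) / cardiac_output


def saturable_rate(vmax: float, km: float, c: float) -> float:
    """Michaelis-Menten rate ``vmax*c/(km+c)`` in mg/h."""
    if c < 0:
        raise DomainError("concentration must be >= 0")
    if vmax == 0.0:
        return 0.0
    if km <= 0:
        raise DomainError("km must be > 0 for an active saturable pathway")
    return vmax * c / (km + c)


def _mm(vmax: float, km: float, c: float) -> float:
    # RHS-internal Michaelis-Menten: tolerates the solver's tiny negative
    # concentration excursions instead of aborting the step
    if vmax == 0.0:
        return 0.0
    return vmax * c / (km + c)


# ---------------------------------------------------------------------------
# Body-weight input
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BodyWeightInput:
    """Constant body weight or a piecewise-linear (t, bw) table.

    Evaluation clamps to the nearest endpoint outside the table range,
    matching the semantics of ODE forcing-function input tables.
    """

    times: tuple[float, ...] = ()
    weights: tuple[float, ...] = ()
    constant: float | None = None

    def __post_init__(self) -> None:
        if self.constant is not None:
            if self.constant <= 0:
                raise DomainError("body weight must be > 0")
            return
        if len(self.times) != len(self.weights) or len(self.times) < 1:
            raise DomainError("table must have matching, nonempty times/weights")
        if any(w <= 0 for w in self.weights):
            raise DomainError("body weight must be > 0 everywhere")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise DomainError("table times must be strictly increasing")

    @property
    def is_table(self) -> bool:
        return self.constant is None

    def at(self, t: float) -> float:
        if self.constant is not None:
            return self.constant
        ts, ws = self.times, self.weights
        if t <= ts[0]:
            return ws[0]
        if t >= ts[-1]:
            return ws[-1]
        # small tables; linear scan is fine
        for i in range(1, len(ts)):
            if t <= ts[i]:
                f = (t - ts[i - 1]) / (ts[i] - ts[i - 1])
                return ws[i - 1] + f * (ws[i] - ws[i - 1])
        return ws[-1]  # pragma: no cover


def resolve_bw(
    t: float,
    bw_input: BodyWeightInput,
    mode: str,
    phys: PhysiologyParams,
    chem: ChemicalParams,
    cache: dict | None = None,
) -> tuple[float, ScaledParams]:
    """Resolve body weight at ``t`` and the 28 scaled quantities.

    ``INPUT_TABLE`` interpolates and rescales on every call;
    ``FIXED_DYNAMIC`` uses the constant weight but still rescales per call;
    ``FIXED_INIT`` computes the scaled set once (memoised in ``cache``).
    """
    if mode == INPUT_TABLE:
        bw = bw_input.at(t)
        return bw, scale_physiology(phys, chem, bw)
    bw = bw_input.constant if bw_input.constant is not None else bw_input.at(0.0)
    if mode == FIXED_DYNAMIC:
        return bw, scale_physiology(phys, chem, bw)
    if mode == FIXED_INIT:
        if cache is not None and "scaled" in cache:
            return bw, cache["scaled"]
        scaled = scale_physiology(phys, chem, bw)
        if cache is not None:
            cache["scaled"] = scaled
        return bw, scaled
    raise ConfigurationError(f"bad bw mode: {mode}")


# ---------------------------------------------------------------------------
# Output map
# ---------------------------------------------------------------------------

_CONC_NAMES = tuple(f"c_{t}" for t in TISSUES) + (
    "c_arterial",
    "c_venous",
    "c_gas_exchange",
    "c_stomach_lumen",
    "c_intestine_lumen",
    "c_chamber",
    "c_dermal_vehicle",
    "c_depot",
)
_CV_NAMES = tuple(f"cv_{t}" for t in TISSUES) + ("cv_gas_exchange",)
_COMPOSITE_NAMES = ("c_mixed_venous", "c_blood_mean", "c_blood_avg")
_AIR_NAMES = ("c_inhaled", "c_alveolar", "c_exhaled")
_RATE_NAMES = tuple(f"r_met_{p}" for p in PATHWAYS)
_INTAKE_NAMES = (
    "r_intake_inhalation",
    "r_intake_oral",
    "r_intake_dermal",
    "r_intake_iv",
    "r_intake_depot",
)
_MB_NAMES = ("mb_total_intake", "mb_in_body", "mb_total_out", "mb_error")
_AKG_NAMES = tuple(n.replace("a_", "akg_", 1) for n in _AMOUNT_NAMES)
_FRAC_NAMES = (
    "frac_inhaled",
    "frac_oral",
    "frac_gi_absorbed",
    "frac_systemic_absorbed",
    "frac_exhaled",
    "frac_excreted",
    "frac_met_liver",
    "frac_met_extrahepatic",
    "frac_met_total",
    "frac_eliminated",
)
_TWA_NAMES = tuple(n.replace("auc_", "twa_", 1) for n in _AUC_NAMES)
_ECHO_NAMES = (
    ("p_body_weight", "p_cardiac_output", "p_alveolar_ventilation")
    + tuple(f"p_flow_{t}" for t in TISSUES)
    + ("p_volume_total",)
)

FULL_OUTPUT_NAMES: tuple[str, ...] = (
    _CONC_NAMES
    + _CV_NAMES
    + _COMPOSITE_NAMES
    + _AIR_NAMES
    + _RATE_NAMES
    + _INTAKE_NAMES
    + _MB_NAMES
    + _AKG_NAMES
    + _FRAC_NAMES
    + _TWA_NAMES
    + _ECHO_NAMES
)
assert len(FULL_OUTPUT_NAMES) == 105

#: Outputs omitted from the reduced (76-entry) map: the per-kilogram amount
#: table, the cumulative dose fractions, and two convenience scalars.
_REDUCED_DROPS = frozenset(_AKG_NAMES) | frozenset(_FRAC_NAMES) | {
    "c_blood_avg",
    "p_volume_total",
}
REDUCED_OUTPUT_NAMES: tuple[str, ...] = tuple(
    n for n in FULL_OUTPUT_NAMES if n not in _REDUCED_DROPS
)
assert len(REDUCED_OUTPUT_NAMES) == 76


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------


class Engine:
    """A built model: roster + derivative contract + output contract.

    The derivative and output callables take ``(t, y, c_inh, oral_rate,
    iv_rate, dermal_rate)`` where the last four are the forcing values on
    the current integration segment (piecewise constant).  ``y`` follows
    :attr:`roster` -- the pruned roster when ``config.prune`` is set,
    otherwise the full 53-entry roster.
    """

    def __init__(
        self,
        config: TemplateConfig,
        chem: ChemicalParams,
        phys: PhysiologyParams,
        bw_input: BodyWeightInput | None = None,
    ):
        self.config = config
        self.chem = chem
        self._validate_params(config, chem)
        self.full_roster = full_roster()
        live = prune_states(config)
        self.roster: StateRoster = live if config.prune else self.full_roster
        self.live_roster: StateRoster = live
        self._live_idx = np.array([_IDX[n] for n in self.roster.names], dtype=np.intp)
        self._pruned = bool(config.prune)
        self.conditional_sites = CONDITIONAL_SITES
        self._sel = _branch_sel if config.conditional_mode == BRANCH else _switch_sel
        self.output_names: tuple[str, ...] = (
            REDUCED_OUTPUT_NAMES if config.reduced_outputs else FULL_OUTPUT_NAMES
        )
        self.event_mirrors: dict[str, tuple[str, ...]] = {
            "a_stomach_lumen": ("e_oral_dose", "e_total_intake"),
            "a_dermal_vehicle": ("e_total_intake",),
            "a_depot": ("e_total_intake",),
            "a_chamber": (),
        }
        self._gates()
        self.set_subject(phys, bw_input)

    # -- construction helpers ------------------------------------------

    @staticmethod
    def _validate_params(config: TemplateConfig, chem: ChemicalParams) -> None:
        """Zero/nonzero parameter pattern must match the configuration."""
        for p in SAT_PATHWAYS:
            pid = f"{p}_sat" if p in ("liver1", "liver2") else f"{p}_sat"
            active = pid in config.active_pathways
            if active != (chem.vmax_c.get(p, 0.0) > 0):
                raise ConfigurationError(
                    f"vmax_c_{p} must be nonzero exactly when {pid} is active"
                )
        for p in FO_PATHWAYS:
            pid = f"{p}_fo"
            active = pid in config.active_pathways
            if active != (chem.kf_c.get(p, 0.0) > 0):
                raise ConfigurationError(
                    f"kf_c_{p} must be nonzero exactly when {pid} is active"
                )
        comps = config.active_compartments
        if ("intestine_lumen" in comps) != (chem.stomach_to_intestine_rate > 0):
            raise ConfigurationError(
                "stomach_to_intestine_rate must be nonzero exactly when "
                "intestine_lumen is active"
            )
        if "intestine_lumen" not in comps and chem.oral_absorption_rate_intestine > 0:
            raise ConfigurationError(
                "oral_absorption_rate_intestine requires an active intestine_lumen"
            )
        if config.urinary_excretion != (chem.urinary_clearance_c > 0):
            raise ConfigurationError(
                "urinary_clearance_c must be nonzero exactly when urinary_excretion is set"
            )
        if config.fecal_excretion != (chem.fecal_transit_rate > 0):
            raise ConfigurationError(
                "fecal_transit_rate must be nonzero exactly when fecal_excretion is set"
            )
        if ("dermal" in config.routes) != (chem.dermal_permeability > 0):
            raise ConfigurationError(
                "dermal_permeability must be nonzero exactly when dermal is routed"
            )
        if ("depot" in comps) != (chem.depot_release_rate > 0):
            raise ConfigurationError(
                "depot_release_rate must be nonzero exactly when depot is active"
            )

    def _gates(self) -> None:
        cfg = self.config
        comps = cfg.active_compartments
        self._g_tissue = {t: (t in comps) for t in TISSUES}
        self._s_tissue = {t: (1.0 if t in comps else 0.0) for t in TISSUES}
        self._g_path = {p: (p in cfg.active_pathways) for p in PATHWAYS}
        self._s_path = {p: (1.0 if p in cfg.active_pathways else 0.0) for p in PATHWAYS}
        self._g_depot = "depot" in comps
        self._g_closed = "inhalation_closed" in cfg.routes
        self._g_inh = bool({"inhalation_open", "inhalation_closed"} & set(cfg.routes))
        self._g_gi_st = "oral" in cfg.routes
        self._g_gi_int = "intestine_lumen" in comps
        self._g_dermal = "dermal" in cfg.routes
        self._g_iv = "iv" in cfg.routes
        self._g_blood_ss = cfg.blood_mode == SS_APPROX
        self._g_ge_ss = cfg.gas_exchange_mode == GE_SS
        self._gx_active = "gas_exchange" in comps

    # -- subject binding ------------------------------------------------

    def set_subject(
        self, phys: PhysiologyParams, bw_input: BodyWeightInput | None = None
    ) -> None:
        """Bind one (virtual) subject's physiology; cheap per-subject update."""
        cfg = self.config
        self.phys = renormalize_flows(phys, cfg)
        for t in TISSUES:
            if t in cfg.active_compartments and phys.volume_fraction[t] <= 0:
                raise ConfigurationError(f"active compartment {t} has zero volume")
        if bw_input is None:
            bw_input = BodyWeightInput(constant=phys.body_weight)
        if cfg.bw_mode != INPUT_TABLE and bw_input.is_table:
            raise ConfigurationError("a body-weight table requires bw_mode=INPUT_TABLE")
        self.bw_input = bw_input
        self._scale_calls = 0
        sel = self._sel
        # INITIALIZE-section conditional sites (evaluated once per subject).
        bw0 = evaluate_conditional(
            self.conditional_sites[0],
            cfg.bw_mode == INPUT_TABLE,
            bw_input.at(0.0),
            (bw_input.constant if bw_input.constant is not None else bw_input.at(0.0)),
            cfg.conditional_mode,
        )
        self._blood_ss_flag = evaluate_conditional(
            self.conditional_sites[1], self._g_blood_ss, 1.0, 0.0, cfg.conditional_mode
        )
        self._ge_ss_flag = evaluate_conditional(
            self.conditional_sites[2], self._g_ge_ss, 1.0, 0.0, cfg.conditional_mode
        )
        precompute = evaluate_conditional(
            self.conditional_sites[3],
            cfg.bw_mode == FIXED_INIT,
            1.0,
            0.0,
            cfg.conditional_mode,
        )
        self._cached_scaled: ScaledParams | None = None
        if precompute == 1.0:
            self._cached_scaled = self._scale(bw0)

    @property
    def scale_call_count(self) -> int:
        """How many times the body-weight scaling routine has run."""
        return self._scale_calls

    def _scale(self, bw: float) -> ScaledParams:
        self._scale_calls += 1
        return scale_physiology(self.phys, self.chem, bw)

    def _resolve_scaled(self, t: float) -> ScaledParams:
        mode = self.config.bw_mode
        if mode == FIXED_INIT:
            return self._cached_scaled  # type: ignore[return-value]
        if mode == FIXED_DYNAMIC:
            return self._scale(self.bw_input.at(0.0))
        # INPUT_TABLE: interpolation is itself a dynamics-section site
        bw = self._sel(
            self.bw_input.is_table,
            1.0 if self.bw_input.is_table else 0.0,
            self.bw_input.at(t),
            self.bw_input.constant or self.bw_input.at(0.0),
        )
        return self._scale(bw)

    # -- state helpers ---------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.roster)

    def y0(self) -> np.ndarray:
        return np.zeros(self.n_states)

    def state_index(self, name: str) -> int:
        try:
            return list(self.roster.names).index(name)
        except ValueError as exc:
            raise ConfigurationError(
                f"state {name!r} is not in the {'pruned ' if self._pruned else ''}roster"
            ) from exc

    def expand(self, y) -> np.ndarray:
        """Map a roster-ordered vector onto the full 53-entry layout."""
        if not self._pruned:
            return np.asarray(y, dtype=float)
        full = np.zeros(53)
        full[self._live_idx] = y
        return full

    # -- dynamics --------------------------------------------------------

    def rhs(
        self,
        t: float,
        y,
        c_inh: float = 0.0,
        oral_rate: float = 0.0,
        iv_rate: float = 0.0,
        dermal_rate: float = 0.0,
    ):
        """Time derivative of the roster state vector (mg/h, mg/L*h for AUC)."""
        if self._pruned:
            full = np.zeros(53)
            full[self._live_idx] = y
            # the pruned variant has had the dead equations removed from its
            # model code, so their expressions are not evaluated at all
            dy = self._rhs_full(t, full, c_inh, oral_rate, iv_rate, dermal_rate, lazy=True)
            return [dy[i] for i in self._live_idx]
        return self._rhs_full(t, y, c_inh, oral_rate, iv_rate, dermal_rate)

    def _rhs_full(self, t, y, c_inh_f, oral_rate, iv_rate, dermal_rate, lazy=False):
        cfg = self.config
        sel = self._sel
        sp = self._resolve_scaled(t)
        V = sp.volumes
        Q = sp.flows
        qc = sp.cardiac_output
        qalv = sp.alveolar_ventilation
        chem = self.chem
        P = chem.tissue_blood_partition
        pba = chem.blood_air_partition

        a = y  # full 53 layout
        if not np.all(np.isfinite(a)):
            raise SolverStateError(t)

        # tissue concentrations and venous-equilibrated concentrations
        gt = self._g_tissue
        st = self._s_tissue
        c = {}
        cv = {}
        for i, tis in enumerate(TISSUES):
            if lazy and not gt[tis]:
                c[tis] = 0.0
                cv[tis] = 0.0
                continue
            vol = V[tis]
            ci = a[i] / vol if vol > 0 else 0.0
            c[tis] = ci
            cv[tis] = ci / P[tis]

        a_art = a[9]
        a_ven = a[10]
        a_gx = a[11]
        a_stl = a[12]
        a_intl = a[13]
        a_ch = a[14]
        a_veh = a[15]
        a_dep = a[16]

        # venous return (GI tissues drain through the liver)
        q_liv_total = Q["liver"] + Q["stomach_tissue"] + Q["intestine_tissue"]
        vr = (
            Q["fat"] * cv["fat"]
            + Q["kidney"] * cv["kidney"]
            + Q["richly"] * cv["richly"]
            + Q["slowly"] * cv["slowly"]
            + Q["skin"] * cv["skin"]
            + Q["lung"] * cv["lung"]
            + q_liv_total * cv["liver"]
        )

        # parenteral inputs
        r_iv = sel(self._g_iv, 1.0 if self._g_iv else 0.0, iv_rate, 0.0)
        r_dep = sel(
            self._g_depot,
            1.0 if self._g_depot else 0.0,
            chem.depot_release_rate * a_dep,
            0.0,
        )

        # inhaled concentration: closed chamber overrides the open forcing
        c_ch = a_ch / cfg.chamber_volume
        cinh = sel(self._g_closed, 1.0 if self._g_closed else 0.0, c_ch, c_inh_f)
        cinh = sel(self._g_inh, 1.0 if self._g_inh else 0.0, cinh, 0.0)

        # blood: steady-state approximation vs state variables
        v_ven = V["venous"]
        v_art = V["arterial"]
        cven_state = a_ven / v_ven if v_ven > 0 else 0.0
        cven_ss = (vr + r_iv + r_dep) / qc
        ss_s = self._blood_ss_flag
        cven = sel(self._g_blood_ss, ss_s, cven_ss, cven_state)

        # gas exchange region: steady state vs explicit air-side state
        if self._gx_active:
            calv_state = a_gx / self.phys.gas_exchange_volume
            calv_ss = (qalv * cinh + qc * cven) / (qalv + qc * pba)
            calv = sel(self._g_ge_ss, self._ge_ss_flag, calv_ss, calv_state)
            cpo = calv * pba
            r_inh = qalv * cinh
            r_exh = qalv * calv
        else:
            calv = 0.0
            cpo = cven
            r_inh = 0.0
            r_exh = 0.0

        cart_state = a_art / v_art if v_art > 0 else 0.0
        cart = sel(self._g_blood_ss, ss_s, cpo, cart_state)

        # metabolism
        vm = sp.vmax
        km = sp.km
        kf = sp.kf
        gp = self._g_path
        spath = self._s_path
        if lazy:
            r_l1 = _mm(vm["liver1"], km["liver1"], cv["liver"]) if gp["liver1_sat"] else 0.0
            r_l2 = _mm(vm["liver2"], km["liver2"], cv["liver"]) if gp["liver2_sat"] else 0.0
            r_lu1 = _mm(vm["lung"], km["lung"], cv["lung"]) if gp["lung_sat"] else 0.0
            r_k1 = _mm(vm["kidney"], km["kidney"], cv["kidney"]) if gp["kidney_sat"] else 0.0
            r_lfo = kf["liver"] * cv["liver"] * V["liver"] if gp["liver_fo"] else 0.0
            r_lufo = kf["lung"] * cv["lung"] * V["lung"] if gp["lung_fo"] else 0.0
            r_kfo = kf["kidney"] * cv["kidney"] * V["kidney"] if gp["kidney_fo"] else 0.0
            r_stfo = kf["stomach"] * cv["stomach_tissue"] * V["stomach_tissue"] if gp["stomach_fo"] else 0.0
            r_intfo = kf["intestine"] * cv["intestine_tissue"] * V["intestine_tissue"] if gp["intestine_fo"] else 0.0
        else:
            r_l1 = sel(gp["liver1_sat"], spath["liver1_sat"], _mm(vm["liver1"], km["liver1"], cv["liver"]), 0.0)
            r_l2 = sel(gp["liver2_sat"], spath["liver2_sat"], _mm(vm["liver2"], km["liver2"], cv["liver"]), 0.0)
            r_lu1 = sel(gp["lung_sat"], spath["lung_sat"], _mm(vm["lung"], km["lung"], cv["lung"]), 0.0)
            r_k1 = sel(gp["kidney_sat"], spath["kidney_sat"], _mm(vm["kidney"], km["kidney"], cv["kidney"]), 0.0)
            r_lfo = sel(gp["liver_fo"], spath["liver_fo"], kf["liver"] * cv["liver"] * V["liver"], 0.0)
            r_lufo = sel(gp["lung_fo"], spath["lung_fo"], kf["lung"] * cv["lung"] * V["lung"], 0.0)
            r_kfo = sel(gp["kidney_fo"], spath["kidney_fo"], kf["kidney"] * cv["kidney"] * V["kidney"], 0.0)
            r_stfo = sel(gp["stomach_fo"], spath["stomach_fo"], kf["stomach"] * cv["stomach_tissue"] * V["stomach_tissue"], 0.0)
            r_intfo = sel(gp["intestine_fo"], spath["intestine_fo"], kf["intestine"] * cv["intestine_tissue"] * V["intestine_tissue"], 0.0)

        met_liver = r_l1 + r_l2 + r_lfo
        met_xh = r_lu1 + r_k1 + r_lufo + r_kfo + r_stfo + r_intfo
        met_sat = r_l1 + r_l2 + r_lu1 + r_k1
        met_total = met_liver + met_xh

        # GI absorption and transit
        gi_st_s = 1.0 if self._g_gi_st else 0.0
        gi_int_s = 1.0 if self._g_gi_int else 0.0
        r_abs_st = sel(self._g_gi_st, gi_st_s, chem.oral_absorption_rate_stomach * a_stl, 0.0)
        r_trans = sel(self._g_gi_int, gi_int_s, chem.stomach_to_intestine_rate * a_stl, 0.0)
        r_abs_int = sel(self._g_gi_int, gi_int_s, chem.oral_absorption_rate_intestine * a_intl, 0.0)
        r_fec = chem.fecal_transit_rate * a_intl

        # dermal
        derm_s = 1.0 if self._g_dermal else 0.0
        c_veh = a_veh / cfg.vehicle_volume
        r_derm = sel(
            self._g_dermal,
            derm_s,
            chem.dermal_permeability * sp.skin_area * c_veh / 1000.0,
            0.0,
        )
        r_derm_applied = sel(self._g_dermal, derm_s, dermal_rate, 0.0)

        # urinary (taken from the kidney at its venous-equilibrated conc.)
        r_ur = sp.urinary_clearance * cv["kidney"]

        dy = [0.0] * 53
        dy[0] = sel(gt["fat"], st["fat"], Q["fat"] * (cart - cv["fat"]), 0.0)
        dy[1] = sel(
            gt["liver"],
            st["liver"],
            Q["liver"] * cart
            + Q["stomach_tissue"] * cv["stomach_tissue"]
            + Q["intestine_tissue"] * cv["intestine_tissue"]
            - q_liv_total * cv["liver"]
            + r_abs_st
            + r_abs_int
            - met_liver,
            0.0,
        )
        dy[2] = sel(gt["kidney"], st["kidney"], Q["kidney"] * (cart - cv["kidney"]) - r_k1 - r_kfo - r_ur, 0.0)
        dy[3] = sel(gt["richly"], st["richly"], Q["richly"] * (cart - cv["richly"]), 0.0)
        dy[4] = sel(gt["slowly"], st["slowly"], Q["slowly"] * (cart - cv["slowly"]), 0.0)
        dy[5] = sel(gt["skin"], st["skin"], Q["skin"] * (cart - cv["skin"]) + r_derm, 0.0)
        dy[6] = sel(gt["lung"], st["lung"], Q["lung"] * (cart - cv["lung"]) - r_lu1 - r_lufo, 0.0)
        dy[7] = sel(gt["stomach_tissue"], st["stomach_tissue"], Q["stomach_tissue"] * (cart - cv["stomach_tissue"]) - r_stfo, 0.0)
        dy[8] = sel(gt["intestine_tissue"], st["intestine_tissue"], Q["intestine_tissue"] * (cart - cv["intestine_tissue"]) - r_intfo, 0.0)
        # blood states (zero when the steady-state approximation is selected)
        dy[9] = sel(self._g_blood_ss, ss_s, 0.0, qc * (cpo - cart))
        dy[10] = sel(self._g_blood_ss, ss_s, 0.0, vr - qc * cven + r_iv + r_dep)
        if self._gx_active:
            dy[11] = sel(
                self._g_ge_ss,
                self._ge_ss_flag,
                0.0,
                qalv * (cinh - calv) + qc * (cven - calv * pba),
            )
        dy[12] = oral_rate - r_abs_st - r_trans
        dy[13] = r_trans - r_abs_int - r_fec
        dy[14] = sel(
            self._g_closed,
            1.0 if self._g_closed else 0.0,
            qalv * (calv - c_ch) - cfg.chamber_loss_rate * a_ch,
            0.0,
        )
        dy[15] = r_derm_applied - r_derm
        dy[16] = -r_dep

        # cumulative metabolism
        dy[17] = r_l1
        dy[18] = r_l2
        dy[19] = r_lu1
        dy[20] = r_k1
        dy[21] = r_lfo
        dy[22] = r_lufo
        dy[23] = r_kfo
        dy[24] = r_stfo
        dy[25] = r_intfo

        # cumulative intake / elimination
        dy[26] = r_inh
        dy[27] = oral_rate
        dy[28] = r_inh + oral_rate + r_derm_applied + r_iv
        dy[29] = r_abs_st + r_abs_int
        dy[30] = r_abs_st + r_abs_int + r_derm + r_iv + r_dep
        dy[31] = r_exh
        dy[32] = r_ur + r_fec
        dy[33] = r_exh + r_ur + r_fec
        dy[34] = met_liver
        dy[35] = met_xh
        dy[36] = met_sat
        dy[37] = met_total
        dy[38] = r_exh + r_ur + r_fec + met_total

        # AUC accumulators
        dy[39] = cart
        dy[40] = cven
        dy[41] = sel(gt["fat"], st["fat"], c["fat"], 0.0)
        dy[42] = sel(gt["liver"], st["liver"], c["liver"], 0.0)
        dy[43] = sel(gt["kidney"], st["kidney"], c["kidney"], 0.0)
        dy[44] = sel(gt["richly"], st["richly"], c["richly"], 0.0)
        dy[45] = sel(gt["slowly"], st["slowly"], c["slowly"], 0.0)
        dy[46] = sel(gt["skin"], st["skin"], c["skin"], 0.0)
        dy[47] = sel(gt["lung"], st["lung"], c["lung"], 0.0)
        dy[48] = sel(gt["stomach_tissue"], st["stomach_tissue"], c["stomach_tissue"], 0.0)
        dy[49] = sel(gt["intestine_tissue"], st["intestine_tissue"], c["intestine_tissue"], 0.0)
        if self._gx_active:
            dy[50] = calv
            dy[51] = 0.7 * calv + 0.3 * cinh
        v_blood = v_art + v_ven
        dy[52] = (cart * v_art + cven * v_ven) / v_blood if v_blood > 0 else 0.0

        return dy

    # -- outputs ---------------------------------------------------------

    def outputs(
        self,
        t: float,
        y,
        c_inh: float = 0.0,
        oral_rate: float = 0.0,
        iv_rate: float = 0.0,
        dermal_rate: float = 0.0,
        oral_cum: float = 0.0,  # used by stand-alone models; the template
    ) -> np.ndarray:  # tracks cumulative intake in its own state variables
        """Evaluate the algebraic output map (105 entries, or 76 reduced)."""
        cfg = self.config
        sel = self._sel
        a = self.expand(y)
        sp = self._resolve_scaled(t) if cfg.bw_mode == INPUT_TABLE else (
            self._cached_scaled if cfg.bw_mode == FIXED_INIT else self._scale(self.bw_input.at(0.0))
        )
        V = sp.volumes
        Q = sp.flows
        qc = sp.cardiac_output
        qalv = sp.alveolar_ventilation
        chem = self.chem
        P = chem.tissue_blood_partition
        pba = chem.blood_air_partition
        bw = sp.body_weight

        vals: dict[str, float] = {}
        c = {}
        cv = {}
        for i, tis in enumerate(TISSUES):
            vol = V[tis]
            ci = a[i] / vol if vol > 0 and self._g_tissue[tis] else 0.0
            c[tis] = ci
            cv[tis] = ci / P[tis]
            vals[f"c_{tis}"] = ci
            vals[f"cv_{tis}"] = cv[tis]

        a_art, a_ven, a_gx = a[9], a[10], a[11]
        a_stl, a_intl, a_ch, a_veh, a_dep = a[12], a[13], a[14], a[15], a[16]

        q_liv_total = Q["liver"] + Q["stomach_tissue"] + Q["intestine_tissue"]
        vr = (
            Q["fat"] * cv["fat"]
            + Q["kidney"] * cv["kidney"]
            + Q["richly"] * cv["richly"]
            + Q["slowly"] * cv["slowly"]
            + Q["skin"] * cv["skin"]
            + Q["lung"] * cv["lung"]
            + q_liv_total * cv["liver"]
        )
        r_iv = iv_rate if self._g_iv else 0.0
        r_dep = chem.depot_release_rate * a_dep if self._g_depot else 0.0
        c_ch = a_ch / cfg.chamber_volume
        cinh = c_ch if self._g_closed else c_inh
        if not self._g_inh:
            cinh = 0.0
        cven_ss = (vr + r_iv + r_dep) / qc
        cven = cven_ss if self._g_blood_ss else (a_ven / V["venous"] if V["venous"] > 0 else 0.0)
        if self._gx_active:
            calv = (
                (qalv * cinh + qc * cven) / (qalv + qc * pba)
                if self._g_ge_ss
                else a_gx / self.phys.gas_exchange_volume
            )
            cpo = calv * pba
            r_inh = qalv * cinh
        else:
            calv, cpo, r_inh = 0.0, cven, 0.0
        cart = cpo if self._g_blood_ss else (a_art / V["arterial"] if V["arterial"] > 0 else 0.0)

        vals["c_arterial"] = cart
        vals["c_venous"] = cven
        vals["c_gas_exchange"] = cpo
        vals["c_stomach_lumen"] = a_stl
        vals["c_intestine_lumen"] = a_intl
        vals["c_chamber"] = c_ch
        vals["c_dermal_vehicle"] = a_veh / cfg.vehicle_volume
        vals["c_depot"] = a_dep
        vals["cv_gas_exchange"] = cpo
        vals["c_mixed_venous"] = cven_ss
        v_blood = V["arterial"] + V["venous"]
        vals["c_blood_mean"] = (
            (cart * V["arterial"] + cven * V["venous"]) / v_blood if v_blood > 0 else 0.0
        )
        vals["c_blood_avg"] = 0.5 * (cart + cven)
        vals["c_inhaled"] = cinh
        vals["c_alveolar"] = calv
        vals["c_exhaled"] = 0.7 * calv + 0.3 * cinh

        vm, km, kf = sp.vmax, sp.km, sp.kf
        vals["r_met_liver1_sat"] = _mm(vm["liver1"], km["liver1"], cv["liver"]) if self._g_path["liver1_sat"] else 0.0
        vals["r_met_liver2_sat"] = _mm(vm["liver2"], km["liver2"], cv["liver"]) if self._g_path["liver2_sat"] else 0.0
        vals["r_met_lung_sat"] = _mm(vm["lung"], km["lung"], cv["lung"]) if self._g_path["lung_sat"] else 0.0
        vals["r_met_kidney_sat"] = _mm(vm["kidney"], km["kidney"], cv["kidney"]) if self._g_path["kidney_sat"] else 0.0
        vals["r_met_liver_fo"] = kf["liver"] * cv["liver"] * V["liver"] if self._g_path["liver_fo"] else 0.0
        vals["r_met_lung_fo"] = kf["lung"] * cv["lung"] * V["lung"] if self._g_path["lung_fo"] else 0.0
        vals["r_met_kidney_fo"] = kf["kidney"] * cv["kidney"] * V["kidney"] if self._g_path["kidney_fo"] else 0.0
        vals["r_met_stomach_fo"] = kf["stomach"] * cv["stomach_tissue"] * V["stomach_tissue"] if self._g_path["stomach_fo"] else 0.0
        vals["r_met_intestine_fo"] = kf["intestine"] * cv["intestine_tissue"] * V["intestine_tissue"] if self._g_path["intestine_fo"] else 0.0

        vals["r_intake_inhalation"] = r_inh
        vals["r_intake_oral"] = oral_rate if self._g_gi_st else 0.0
        vals["r_intake_dermal"] = dermal_rate if self._g_dermal else 0.0
        vals["r_intake_iv"] = r_iv
        vals["r_intake_depot"] = r_dep

        in_body = float(np.sum(a[:14])) + a[15] + a[16]  # excludes the chamber
        total_in = a[_IDX["e_total_intake"]]
        total_out = a[_IDX["e_cleared_total"]]
        vals["mb_total_intake"] = total_in
        vals["mb_in_body"] = in_body
        vals["mb_total_out"] = total_out
        vals["mb_error"] = total_in - in_body - total_out

        for i, name in enumerate(_AKG_NAMES):
            vals[name] = a[i] / bw

        denom = total_in if total_in > 0 else 0.0
        frac_src = (
            ("frac_inhaled", "e_inhaled"),
            ("frac_oral", "e_oral_dose"),
            ("frac_gi_absorbed", "e_gi_absorbed"),
            ("frac_systemic_absorbed", "e_systemic_absorbed"),
            ("frac_exhaled", "e_exhaled"),
            ("frac_excreted", "e_excreted"),
            ("frac_met_liver", "e_met_liver"),
            ("frac_met_extrahepatic", "e_met_extrahepatic"),
            ("frac_met_total", "e_met_total"),
            ("frac_eliminated", "e_total_eliminated"),
        )
        for fname, sname in frac_src:
            vals[fname] = a[_IDX[sname]] / denom if denom > 0 else 0.0

        inv_t = 1.0 / t if t > 0 else 0.0
        for auc_name, twa_name in zip(_AUC_NAMES, _TWA_NAMES):
            vals[twa_name] = a[_IDX[auc_name]] * inv_t

        vals["p_body_weight"] = bw
        vals["p_cardiac_output"] = qc
        vals["p_alveolar_ventilation"] = qalv
        for tis in TISSUES:
            vals[f"p_flow_{tis}"] = Q[tis]
        vals["p_volume_total"] = sum(V.values())

        return np.array([vals[n] for n in self.output_names])


class SolverStateError(FloatingPointError):
    """Raised when the state handed to the RHS contains NaN/Inf."""

    def __init__(self, t: float):
        super().__init__(f"non-finite state at t={t}")
        self.t = t


def build_engine(
    config: TemplateConfig,
    chem: ChemicalParams,
    phys: PhysiologyParams,
    bw_input: BodyWeightInput | None = None,
) -> Engine:
    """Construct an :class:`Engine` after validating the configuration."""
    return Engine(config, chem, phys, bw_input)


def export_roster_csv(roster: StateRoster, path) -> None:
    """Write a roster as CSV (name, group, units)."""
    import csv as _csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = _csv.writer(fh)
        w.writerow(["name", "group", "units"])
        for name, group, unit in zip(roster.names, roster.groups, roster.units()):
            w.writerow([name, group, unit])
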