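"""Chemical and physiological parameter tables.

This module defines the two input tables the simulator consumes --
chemical/species-specific model parameters and exposure/dosing parameters --
together with validation, CSV (de)serialisation, body-weight scaling of the
28 body-weight-dependent quantities, and renormalisation of blood-flow
fractions when compartments are switched off.

Tables are plain CSV with header ``name,value,units`` (UTF-8, decimal
point).  Unknown keys are hard errors: silent misconfiguration is the main
failure mode this layer guards against.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ConfigurationError, DomainError, ValidationError

# ---------------------------------------------------------------------------
# Canonical compartment / pathway rosters
# ---------------------------------------------------------------------------

#: Perfused tissue compartments (each has a volume, a flow and a
#: tissue:blood partition coefficient).
TISSUES: tuple[str, ...] = (
    "fat",
    "liver",
    "kidney",
    "richly",
    "slowly",
    "skin",
    "lung",
    "stomach_tissue",
    "intestine_tissue",
)

#: Blood pools.  Together with :data:`TISSUES` these carry the 11 volume
#: fractions.
BLOOD_POOLS: tuple[str, ...] = ("arterial", "venous")

VOLUME_COMPARTMENTS: tuple[str, ...] = TISSUES + BLOOD_POOLS

#: Saturable (Michaelis-Menten) metabolic pathways.
SAT_PATHWAYS: tuple[str, ...] = ("liver1", "liver2", "lung", "kidney")

#: First-order metabolic pathways.
FO_PATHWAYS: tuple[str, ...] = ("liver", "lung", "kidney", "stomach", "intestine")

#: Full pathway roster (9 entries) in canonical order.
PATHWAYS: tuple[str, ...] = (
    "liver1_sat",
    "liver2_sat",
    "lung_sat",
    "kidney_sat",
    "liver_fo",
    "lung_fo",
    "kidney_fo",
    "stomach_fo",
    "intestine_fo",
)

#: Tissue hosting each pathway (used to validate configs).
PATHWAY_HOST: Mapping[str, str] = {
    "liver1_sat": "liver",
    "liver2_sat": "liver",
    "lung_sat": "lung",
    "kidney_sat": "kidney",
    "liver_fo": "liver",
    "lung_fo": "lung",
    "kidney_fo": "kidney",
    "stomach_fo": "stomach_tissue",
    "intestine_fo": "intestine_tissue",
}

# Allometric exponents (standard PBPK conventions).
EXP_FLOW = 0.75  # flows, ventilation, vmax, clearances
EXP_VOLUME = 1.0
EXP_SKIN_AREA = 0.667


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChemicalParams:
    """Chemical- and species-specific model parameters.

    Unused features are expressed by zero-valued parameters, mirroring how a
    chemical-specific model is mapped onto the superstructure by switching
    pieces off.
    """

    blood_air_partition: float
    tissue_blood_partition: Mapping[str, float]  # one entry per tissue
    vmax_c: Mapping[str, float]  # mg/h/kg^0.75, saturable pathways
    km: Mapping[str, float]  # mg/L, saturable pathways
    kf_c: Mapping[str, float]  # /h, first-order pathways
    oral_absorption_rate_stomach: float = 0.0  # /h
    oral_absorption_rate_intestine: float = 0.0  # /h
    stomach_to_intestine_rate: float = 0.0  # /h
    fecal_transit_rate: float = 0.0  # /h
    dermal_permeability: float = 0.0  # cm/h
    urinary_clearance_c: float = 0.0  # L/h/kg^0.75
    depot_release_rate: float = 0.0  # /h

    def __post_init__(self) -> None:
        if self.blood_air_partition <= 0:
            raise DomainError(
                f"blood_air_partition must be > 0, got {self.blood_air_partition}"
            )
        for t in TISSUES:
            if t not in self.tissue_blood_partition:
                raise ValidationError(f"missing tissue_blood_partition entry: {t}")
            if self.tissue_blood_partition[t] <= 0:
                raise DomainError(f"partition_{t} must be > 0")
        for p in SAT_PATHWAYS:
            v = self.vmax_c.get(p, 0.0)
            k = self.km.get(p, 0.0)
            if v < 0:
                raise DomainError(f"vmax_c_{p} must be >= 0")
            if v > 0 and k <= 0:
                raise DomainError(f"km_{p} must be > 0 when vmax_c_{p} > 0")
        for p in FO_PATHWAYS:
            if self.kf_c.get(p, 0.0) < 0:
                raise DomainError(f"kf_c_{p} must be >= 0")
        for name in (
            "oral_absorption_rate_stomach",
            "oral_absorption_rate_intestine",
            "stomach_to_intestine_rate",
            "fecal_transit_rate",
            "dermal_permeability",
            "urinary_clearance_c",
            "depot_release_rate",
        ):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")

    # -- flat key view used by the CSV layer -------------------------------

    def to_mapping(self) -> dict[str, float]:
        out: dict[str, float] = {"blood_air_partition": self.blood_air_partition}
        for t in TISSUES:
            out[f"partition_{t}"] = self.tissue_blood_partition[t]
        for p in SAT_PATHWAYS:
            out[f"vmax_c_{p}"] = self.vmax_c.get(p, 0.0)
            out[f"km_{p}"] = self.km.get(p, 0.0)
        for p in FO_PATHWAYS:
            out[f"kf_c_{p}"] = self.kf_c.get(p, 0.0)
        out["oral_absorption_rate_stomach"] = self.oral_absorption_rate_stomach
        out["oral_absorption_rate_intestine"] = self.oral_absorption_rate_intestine
        out["stomach_to_intestine_rate"] = self.stomach_to_intestine_rate
        out["fecal_transit_rate"] = self.fecal_transit_rate
        out["dermal_permeability"] = self.dermal_permeability
        out["urinary_clearance_c"] = self.urinary_clearance_c
        out["depot_release_rate"] = self.depot_release_rate
        return out

    @classmethod
    def from_mapping(cls, m: Mapping[str, float]) -> "ChemicalParams":
        m = dict(m)
        required = set(_chemical_keys())
        missing = required - m.keys()
        if missing:
            raise ValidationError(
                "missing required chemical keys: " + ", ".join(sorted(missing))
            )
        unknown = m.keys() - required
        if unknown:
            raise ValidationError(
                "unknown chemical keys: " + ", ".join(sorted(unknown))
            )
        return cls(
            blood_air_partition=m["blood_air_partition"],
            tissue_blood_partition={t: m[f"partition_{t}"] for t in TISSUES},
            vmax_c={p: m[f"vmax_c_{p}"] for p in SAT_PATHWAYS},
            km={p: m[f"km_{p}"] for p in SAT_PATHWAYS},
            kf_c={p: m[f"kf_c_{p}"] for p in FO_PATHWAYS},
            oral_absorption_rate_stomach=m["oral_absorption_rate_stomach"],
            oral_absorption_rate_intestine=m["oral_absorption_rate_intestine"],
            stomach_to_intestine_rate=m["stomach_to_intestine_rate"],
            fecal_transit_rate=m["fecal_transit_rate"],
            dermal_permeability=m["dermal_permeability"],
            urinary_clearance_c=m["urinary_clearance_c"],
            depot_release_rate=m["depot_release_rate"],
        )


@dataclass(frozen=True)
class PhysiologyParams:
    """Anatomical and physiological parameters for one (virtual) subject."""

    body_weight: float  # kg
    volume_fraction: Mapping[str, float]  # L/kg, 11 entries incl. blood pools
    flow_fraction: Mapping[str, float]  # fraction of cardiac output, 9 entries
    cardiac_output_c: float  # L/h/kg^0.75
    alveolar_ventilation_c: float  # L/h/kg^0.75
    skin_area_c: float  # cm^2/kg^0.667
    gas_exchange_volume: float = 1.4  # L, air-side mixing volume (not BW-scaled)

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise DomainError(f"body_weight must be > 0, got {self.body_weight}")
        for c in VOLUME_COMPARTMENTS:
            if c not in self.volume_fraction:
                raise ValidationError(f"missing volume_fraction entry: {c}")
            if self.volume_fraction[c] < 0:
                raise DomainError(f"volume_fraction_{c} must be >= 0")
        if sum(self.volume_fraction.values()) > 1.0 + 1e-12:
            raise DomainError("volume fractions must sum to <= 1 L/kg")
        for t in TISSUES:
            if t not in self.flow_fraction:
                raise ValidationError(f"missing flow_fraction entry: {t}")
            if self.flow_fraction[t] < 0:
                raise DomainError(f"flow_fraction_{t} must be >= 0")
        for name in ("cardiac_output_c", "alveolar_ventilation_c", "skin_area_c"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.gas_exchange_volume <= 0:
            raise DomainError("gas_exchange_volume must be > 0")

    def to_mapping(self) -> dict[str, float]:
        out: dict[str, float] = {"body_weight": self.body_weight}
        for c in VOLUME_COMPARTMENTS:
            out[f"volume_fraction_{c}"] = self.volume_fraction[c]
        for t in TISSUES:
            out[f"flow_fraction_{t}"] = self.flow_fraction[t]
        out["cardiac_output_c"] = self.cardiac_output_c
        out["alveolar_ventilation_c"] = self.alveolar_ventilation_c
        out["skin_area_c"] = self.skin_area_c
        out["gas_exchange_volume"] = self.gas_exchange_volume
        return out

    @classmethod
    def from_mapping(cls, m: Mapping[str, float]) -> "PhysiologyParams":
        m = dict(m)
        required = set(_physiology_keys())
        missing = required - m.keys()
        if missing:
            raise ValidationError(
                "missing required physiology keys: " + ", ".join(sorted(missing))
            )
        unknown = m.keys() - required
        if unknown:
            raise ValidationError(
                "unknown physiology keys: " + ", ".join(sorted(unknown))
            )
        return cls(
            body_weight=m["body_weight"],
            volume_fraction={c: m[f"volume_fraction_{c}"] for c in VOLUME_COMPARTMENTS},
            flow_fraction={t: m[f"flow_fraction_{t}"] for t in TISSUES},
            cardiac_output_c=m["cardiac_output_c"],
            alveolar_ventilation_c=m["alveolar_ventilation_c"],
            skin_area_c=m["skin_area_c"],
            gas_exchange_volume=m["gas_exchange_volume"],
        )


@dataclass(frozen=True)
class ScaledParams:
    """Body-weight-scaled quantities at a given body weight.

    Exactly 28 scalar quantities derive from body weight; their names are
    listed in :attr:`bw_dependent_names`.  First-order rate constants are
    intrinsic (/h) and are copied through unscaled -- see the repository
    notes on the composition of the 28-name roster.
    """

    body_weight: float
    volumes: Mapping[str, float]  # L, 11 entries
    flows: Mapping[str, float]  # L/h, 9 entries
    cardiac_output: float  # L/h
    alveolar_ventilation: float  # L/h
    vmax: Mapping[str, float]  # mg/h, saturable pathways
    km: Mapping[str, float]  # mg/L (copied)
    kf: Mapping[str, float]  # /h (copied)
    urinary_clearance: float  # L/h
    skin_area: float  # cm^2
    bw_dependent_names: tuple[str, ...] = field(repr=False, default=())


#: Canonical roster of the 28 body-weight-dependent quantity names.
BW_DEPENDENT_NAMES: tuple[str, ...] = (
    tuple(f"volume_{c}" for c in VOLUME_COMPARTMENTS)  # 11
    + tuple(f"flow_{t}" for t in TISSUES)  # 9
    + ("cardiac_output", "alveolar_ventilation")  # 2
    + tuple(f"vmax_{p}" for p in SAT_PATHWAYS)  # 4
    + ("urinary_clearance", "skin_area")  # 2
)
assert len(BW_DEPENDENT_NAMES) == 28


def scale_physiology(
    phys: PhysiologyParams, chem: ChemicalParams, bw: float
) -> ScaledParams:
    """Compute the 28 body-weight-dependent quantities at body weight ``bw``.

    Volumes scale linearly; flows, ventilation, vmax and urinary clearance
    scale with ``bw**0.75``; skin area scales with ``bw**0.667``.  At
    ``bw = 1`` every scaled value equals its coefficient.
    """
    if bw <= 0:
        raise DomainError(f"body weight must be > 0, got {bw}")
    bw75 = bw**EXP_FLOW
    qc = phys.cardiac_output_c * bw75
    return ScaledParams(
        body_weight=bw,
        volumes={c: phys.volume_fraction[c] * bw for c in VOLUME_COMPARTMENTS},
        flows={t: phys.flow_fraction[t] * qc for t in TISSUES},
        cardiac_output=qc,
        alveolar_ventilation=phys.alveolar_ventilation_c * bw75,
        vmax={p: chem.vmax_c.get(p, 0.0) * bw75 for p in SAT_PATHWAYS},
        km=dict(chem.km),
        kf=dict(chem.kf_c),
        urinary_clearance=chem.urinary_clearance_c * bw75,
        skin_area=phys.skin_area_c * bw**EXP_SKIN_AREA,
        bw_dependent_names=BW_DEPENDENT_NAMES,
    )


def renormalize_flows(phys: PhysiologyParams, config) -> PhysiologyParams:
    """Zero the flow fractions of inactive tissues and rescale the rest to 1.

    ``config`` may be a :class:`~pbpkt.template_engine.TemplateConfig` (its
    ``active_compartments`` attribute is used) or any iterable of active
    tissue names.  Idempotent.
    """
    active = getattr(config, "active_compartments", config)
    active_tissues = [t for t in TISSUES if t in active]
    if not active_tissues:
        raise ConfigurationError("at least one perfused compartment must be active")
    total = sum(phys.flow_fraction[t] for t in active_tissues)
    if total <= 0:
        raise ConfigurationError("active flow fractions sum to zero")
    new_fracs = {
        t: (phys.flow_fraction[t] / total if t in active_tissues else 0.0)
        for t in TISSUES
    }
    return replace(phys, flow_fraction=new_fracs)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_EXPOSURE_KEYS = ("scenario_kind", "dose_level", "duration_weeks")


def _chemical_keys() -> list[str]:
    keys = ["blood_air_partition"]
    keys += [f"partition_{t}" for t in TISSUES]
    for p in SAT_PATHWAYS:
        keys += [f"vmax_c_{p}", f"km_{p}"]
    keys += [f"kf_c_{p}" for p in FO_PATHWAYS]
    keys += [
        "oral_absorption_rate_stomach",
        "oral_absorption_rate_intestine",
        "stomach_to_intestine_rate",
        "fecal_transit_rate",
        "dermal_permeability",
        "urinary_clearance_c",
        "depot_release_rate",
    ]
    return keys


def _physiology_keys() -> list[str]:
    keys = ["body_weight"]
    keys += [f"volume_fraction_{c}" for c in VOLUME_COMPARTMENTS]
    keys += [f"flow_fraction_{t}" for t in TISSUES]
    keys += [
        "cardiac_output_c",
        "alveolar_ventilation_c",
        "skin_area_c",
        "gas_exchange_volume",
    ]
    return keys


def _read_table(path: str | Path) -> dict[str, float]:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"parameter table not found: {path}")
    values: dict[str, float] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "name" not in reader.fieldnames:
            raise ValidationError(f"{path}: header row 'name,value,units' required")
        for row in reader:
            name = (row.get("name") or "").strip()
            if not name:
                continue
            try:
                values[name] = float(row["value"])
            except (KeyError, TypeError, ValueError) as exc:
                raise ValidationError(f"{path}: bad value for key {name!r}") from exc
    return values


def load_params(table_path: str | Path, schema: str):
    """Load a parameter table.

    Parameters
    ----------
    table_path:
        CSV file with header ``name,value,units``.
    schema:
        One of ``"chemical"``, ``"physiology"`` or ``"exposure"``.

    Returns
    -------
    ChemicalParams, PhysiologyParams or a plain dict (exposure record).
    """
    values = _read_table(table_path)
    if schema == "chemical":
        return ChemicalParams.from_mapping(values)
    if schema == "physiology":
        return PhysiologyParams.from_mapping(values)
    if schema == "exposure":
        missing = set(_EXPOSURE_KEYS) - values.keys()
        if missing:
            raise ValidationError(
                "missing required exposure keys: " + ", ".join(sorted(missing))
            )
        unknown = values.keys() - set(_EXPOSURE_KEYS)
        if unknown:
            raise ValidationError(
                "unknown exposure keys: " + ", ".join(sorted(unknown))
            )
        return {k: values[k] for k in _EXPOSURE_KEYS}
    raise ValidationError(f"unknown schema: {schema!r}")


_UNITS: dict[str, str] = {}


def _units_for(key: str) -> str:
    if key.startswith("partition_") or key == "blood_air_partition":
        return "dimensionless"
    if key.startswith("vmax_c_"):
        return "mg/h/kg^0.75"
    if key.startswith("km_"):
        return "mg/L"
    if key.startswith("kf_c_") or key.endswith("_rate") or key.endswith("_rate_stomach") or key.endswith("_rate_intestine"):
        return "/h"
    if key == "dermal_permeability":
        return "cm/h"
    if key == "urinary_clearance_c":
        return "L/h/kg^0.75"
    if key == "body_weight":
        return "kg"
    if key.startswith("volume_fraction_"):
        return "L/kg"
    if key.startswith("flow_fraction_"):
        return "dimensionless"
    if key in ("cardiac_output_c", "alveolar_ventilation_c"):
        return "L/h/kg^0.75"
    if key == "skin_area_c":
        return "cm^2/kg^0.667"
    if key == "gas_exchange_volume":
        return "L"
    return ""


def write_params(record, path: str | Path) -> None:
    """Write a ChemicalParams/PhysiologyParams record (or mapping) as CSV."""
    mapping = record.to_mapping() if hasattr(record, "to_mapping") else dict(record)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "value", "units"])
        for key, value in mapping.items():
            writer.writerow([key, repr(float(value)), _units_for(key)])
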