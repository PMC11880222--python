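"""Shipped fixture parameter sets and chemical-specific configurations.

The dichloromethane (DCM) and chloroform (CF) parameter sets are plausible
human parameterisations assembled for structural and timing work; they
emulate -- but do not reproduce -- any published archive.  Each chemical's
configuration switches off the superstructure features its model does not
use (unused parameters are zero, unused compartments carry no blood flow).
"""

from __future__ import annotations

from dataclasses import replace
from importlib import resources

from .errors import ConfigurationError
from .params_io import ChemicalParams, PhysiologyParams, load_params
from .template_engine import (
    GE_SS,
    GE_STATE,
    STATE_VARS,
    TemplateConfig,
    full_template_config,
)

CHEMICALS = ("dcm", "cf")


def _data_path(name: str):
    return resources.files("pbpkt.data") / name


def fixture_chemical(name: str) -> ChemicalParams:
    """Load a shipped chemical parameter set (``dcm``, ``cf`` or ``full``)."""
    if name not in CHEMICALS + ("full",):
        raise ConfigurationError(f"unknown fixture chemical: {name!r}")
    with resources.as_file(_data_path(f"chemical_{name}.csv")) as p:
        return load_params(p, "chemical")


def fixture_physiology() -> PhysiologyParams:
    """Reference human physiology (70 kg)."""
    with resources.as_file(_data_path("physiology_human.csv")) as p:
        return load_params(p, "physiology")


def dcm_config(**overrides) -> TemplateConfig:
    """Superstructure mapping of the DCM model.

    Fat, liver, richly and slowly perfused tissues plus a metabolising lung;
    gas exchange by steady-state approximation; blood amounts as state
    variables; oral dosing absorbed from the stomach lumen only.
    """
    base = dict(
        active_compartments=frozenset(
            ("fat", "liver", "richly", "slowly", "lung", "gas_exchange", "stomach_lumen")
        ),
        active_pathways=frozenset(("liver1_sat", "liver_fo", "lung_sat", "lung_fo")),
        routes=frozenset(("inhalation_open", "oral")),
        blood_mode=STATE_VARS,
        gas_exchange_mode=GE_SS,
        lung_present=True,
    )
    base.update(overrides)
    return TemplateConfig(**base)


def cf_config(**overrides) -> TemplateConfig:
    """Superstructure mapping of the CF model.

    No explicit lung compartment; saturable metabolism in liver and kidney;
    a two-segment GI lumen (stomach and intestine absorption).
    """
    base = dict(
        active_compartments=frozenset(
            (
                "fat",
                "liver",
                "kidney",
                "richly",
                "slowly",
                "gas_exchange",
                "stomach_lumen",
                "intestine_lumen",
            )
        ),
        active_pathways=frozenset(("liver1_sat", "kidney_sat")),
        routes=frozenset(("inhalation_open", "oral")),
        blood_mode=STATE_VARS,
        gas_exchange_mode=GE_SS,
        lung_present=False,
    )
    base.update(overrides)
    return TemplateConfig(**base)


def chemical_config(name: str, **overrides) -> TemplateConfig:
    if name == "dcm":
        return dcm_config(**overrides)
    if name == "cf":
        return cf_config(**overrides)
    if name == "full":
        return full_template_config(**overrides)
    raise ConfigurationError(f"unknown fixture chemical: {name!r}")


def chemical_without_lung(chem: ChemicalParams) -> ChemicalParams:
    """Variant with lung metabolism zeroed (the 'no lung compartment' option).

    Dropping the explicit lung compartment also drops lung metabolism, so a
    DCM model run this way omits a biologically relevant feature.
    """
    vmax = dict(chem.vmax_c)
    km = dict(chem.km)
    kf = dict(chem.kf_c)
    vmax["lung"] = 0.0
    km["lung"] = 0.0
    kf["lung"] = 0.0
    return replace(chem, vmax_c=vmax, km=km, kf_c=kf)


def config_without_lung(config: TemplateConfig) -> TemplateConfig:
    comps = frozenset(config.active_compartments - {"lung"})
    paths = frozenset(p for p in config.active_pathways if not p.startswith("lung"))
    return replace(
        config,
        active_compartments=comps,
        active_pathways=paths,
        lung_present=False,
        gas_exchange_mode=GE_SS,
    )


def config_with_lung(config: TemplateConfig, ge_state: bool = False) -> TemplateConfig:
    comps = frozenset(config.active_compartments | {"lung"})
    return replace(
        config,
        active_compartments=comps,
        lung_present=True,
        gas_exchange_mode=GE_STATE if ge_state else GE_SS,
    )


#: Default dose levels per scenario kind (air mg/L, mg/h, air mg/L, mg bolus).
DEFAULT_DOSE = {1: 0.35, 2: 4.0, 3: 0.35, 4: 20.0}
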