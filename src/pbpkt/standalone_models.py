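"""Dedicated minimal implementations of the DCM and CF models.

These are written as stand-alone model codes -- fixed body weight, all
parameters computed once at initialisation, no superstructure gating -- so
they can be compared against template-implemented versions of the same
models both for output equivalence and for CPU time.

State rosters: DCM 21 states / 22 outputs; CF 19 states / 26 outputs.
"""

from __future__ import annotations

import numpy as np

from .errors import ComparisonError, ConfigurationError
from .params_io import (
    ChemicalParams,
    PhysiologyParams,
    renormalize_flows,
    scale_physiology,
)
from .template_engine import StateRoster, _mm, arterial_ss

_DCM_ACTIVE = ("fat", "liver", "richly", "slowly", "lung")
_CF_ACTIVE = ("fat", "liver", "kidney", "richly", "slowly")

_DCM_STATES = (
    "a_arterial",
    "a_venous",
    "a_lung",
    "a_fat",
    "a_liver",
    "a_richly",
    "a_slowly",
    "a_stomach_lumen",
    "m_liver1_sat",
    "m_liver_fo",
    "m_lung_sat",
    "m_lung_fo",
    "e_inhaled",
    "e_exhaled",
    "auc_arterial",
    "auc_venous",
    "auc_fat",
    "auc_liver",
    "auc_lung",
    "auc_richly",
    "auc_slowly",
)
_CF_STATES = (
    "a_arterial",
    "a_venous",
    "a_fat",
    "a_liver",
    "a_kidney",
    "a_richly",
    "a_slowly",
    "a_stomach_lumen",
    "a_intestine_lumen",
    "m_liver1_sat",
    "m_kidney_sat",
    "e_inhaled",
    "e_exhaled",
    "auc_arterial",
    "auc_venous",
    "auc_fat",
    "auc_liver",
    "auc_kidney",
    "auc_slowly",
)

_DCM_OUTPUTS = (
    "c_arterial",
    "c_venous",
    "c_fat",
    "c_liver",
    "c_lung",
    "c_richly",
    "c_slowly",
    "c_stomach_lumen",
    "c_alveolar",
    "c_exhaled",
    "r_met_liver1_sat",
    "r_met_liver_fo",
    "r_met_lung_sat",
    "r_met_lung_fo",
    "mb_total_intake",
    "mb_in_body",
    "mb_total_out",
    "mb_error",
    "twa_arterial",
    "twa_venous",
    "c_blood_mean",
    "r_intake_oral",
)
_CF_OUTPUTS = (
    "c_arterial",
    "c_venous",
    "c_fat",
    "c_liver",
    "c_kidney",
    "c_richly",
    "c_slowly",
    "c_stomach_lumen",
    "c_intestine_lumen",
    "c_alveolar",
    "c_exhaled",
    "r_met_liver1_sat",
    "r_met_kidney_sat",
    "mb_total_intake",
    "mb_in_body",
    "mb_total_out",
    "mb_error",
    "twa_arterial",
    "twa_venous",
    "twa_fat",
    "twa_liver",
    "twa_kidney",
    "twa_slowly",
    "c_blood_mean",
    "r_intake_oral",
    "r_intake_inhalation",
)


def _group_of(name: str) -> str:
    if name.startswith("a_"):
        return "compartment_amount"
    if name.startswith("m_"):
        return "cumulative_metabolism"
    if name.startswith("e_"):
        return "cumulative_intake_elimination"
    return "auc"


class StandaloneModel:
    """A stand-alone chemical-specific model (protocol-compatible with Engine).

    Body weight is a constant parameter and every body-weight-dependent
    quantity is computed once, at initialisation.
    """

    def __init__(self, name: str, chem: ChemicalParams, phys: PhysiologyParams):
        if name not in ("dcm", "cf"):
            raise ConfigurationError(f"unknown stand-alone model: {name!r}")
        self.name = name
        self.chem = chem
        states = _DCM_STATES if name == "dcm" else _CF_STATES
        self.roster = StateRoster(names=states, groups=tuple(_group_of(n) for n in states))
        self.output_names = _DCM_OUTPUTS if name == "dcm" else _CF_OUTPUTS
        self.event_mirrors: dict[str, tuple[str, ...]] = {"a_stomach_lumen": ()}
        self.set_subject(phys)

    # -- protocol ------------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.roster)

    def y0(self) -> np.ndarray:
        return np.zeros(self.n_states)

    def state_index(self, name: str) -> int:
        try:
            return list(self.roster.names).index(name)
        except ValueError as exc:
            raise ConfigurationError(f"state {name!r} not in roster") from exc

    def set_subject(self, phys: PhysiologyParams, bw_input=None) -> None:
        active = _DCM_ACTIVE if self.name == "dcm" else _CF_ACTIVE
        phys = renormalize_flows(phys, active)
        sp = scale_physiology(phys, self.chem, phys.body_weight)
        chem = self.chem
        self._qc = sp.cardiac_output
        self._qalv = sp.alveolar_ventilation
        self._pba = chem.blood_air_partition
        self._v = sp.volumes
        self._q = sp.flows
        self._p = chem.tissue_blood_partition
        self._vmax = sp.vmax
        self._km = sp.km
        self._kf = sp.kf
        self._ka_st = chem.oral_absorption_rate_stomach
        self._ka_int = chem.oral_absorption_rate_intestine
        self._k_trans = chem.stomach_to_intestine_rate

    # -- dynamics ------------------------------------------------------

    def rhs(self, t, y, c_inh=0.0, oral_rate=0.0, iv_rate=0.0, dermal_rate=0.0):
        if self.name == "dcm":
            return self._rhs_dcm(t, y, c_inh, oral_rate)
        return self._rhs_cf(t, y, c_inh, oral_rate)

    def _rhs_dcm(self, t, y, c_inh, oral_rate):
        v, q, p = self._v, self._q, self._p
        qc, qalv, pba = self._qc, self._qalv, self._pba
        cart = y[0] / v["arterial"]
        cven = y[1] / v["venous"]
        cv_lung = y[2] / v["lung"] / p["lung"]
        cv_fat = y[3] / v["fat"] / p["fat"]
        cv_liv = y[4] / v["liver"] / p["liver"]
        cv_rich = y[5] / v["richly"] / p["richly"]
        cv_slow = y[6] / v["slowly"] / p["slowly"]

        calv = arterial_ss(cven, c_inh, qc, qalv, pba) / pba
        cpo = calv * pba

        r_l1 = _mm(self._vmax["liver1"], self._km["liver1"], cv_liv)
        r_lfo = self._kf["liver"] * cv_liv * v["liver"]
        r_lu1 = _mm(self._vmax["lung"], self._km["lung"], cv_lung)
        r_lufo = self._kf["lung"] * cv_lung * v["lung"]
        r_abs = self._ka_st * y[7]

        vr = (
            q["fat"] * cv_fat
            + q["lung"] * cv_lung
            + q["richly"] * cv_rich
            + q["slowly"] * cv_slow
            + q["liver"] * cv_liv
        )

        dy = [0.0] * 21
        dy[0] = qc * (cpo - cart)
        dy[1] = vr - qc * cven
        dy[2] = q["lung"] * (cart - cv_lung) - r_lu1 - r_lufo
        dy[3] = q["fat"] * (cart - cv_fat)
        dy[4] = q["liver"] * (cart - cv_liv) + r_abs - r_l1 - r_lfo
        dy[5] = q["richly"] * (cart - cv_rich)
        dy[6] = q["slowly"] * (cart - cv_slow)
        dy[7] = oral_rate - r_abs
        dy[8] = r_l1
        dy[9] = r_lfo
        dy[10] = r_lu1
        dy[11] = r_lufo
        dy[12] = qalv * c_inh
        dy[13] = qalv * calv
        dy[14] = cart
        dy[15] = cven
        dy[16] = y[3] / v["fat"]
        dy[17] = y[4] / v["liver"]
        dy[18] = y[2] / v["lung"]
        dy[19] = y[5] / v["richly"]
        dy[20] = y[6] / v["slowly"]
        return dy

    def _rhs_cf(self, t, y, c_inh, oral_rate):
        v, q, p = self._v, self._q, self._p
        qc, qalv, pba = self._qc, self._qalv, self._pba
        cart = y[0] / v["arterial"]
        cven = y[1] / v["venous"]
        cv_fat = y[2] / v["fat"] / p["fat"]
        cv_liv = y[3] / v["liver"] / p["liver"]
        cv_kid = y[4] / v["kidney"] / p["kidney"]
        cv_rich = y[5] / v["richly"] / p["richly"]
        cv_slow = y[6] / v["slowly"] / p["slowly"]

        calv = arterial_ss(cven, c_inh, qc, qalv, pba) / pba
        cpo = calv * pba

        r_l1 = _mm(self._vmax["liver1"], self._km["liver1"], cv_liv)
        r_k1 = _mm(self._vmax["kidney"], self._km["kidney"], cv_kid)
        r_abs_st = self._ka_st * y[7]
        r_trans = self._k_trans * y[7]
        r_abs_int = self._ka_int * y[8]

        vr = (
            q["fat"] * cv_fat
            + q["kidney"] * cv_kid
            + q["richly"] * cv_rich
            + q["slowly"] * cv_slow
            + q["liver"] * cv_liv
        )

        dy = [0.0] * 19
        dy[0] = qc * (cpo - cart)
        dy[1] = vr - qc * cven
        dy[2] = q["fat"] * (cart - cv_fat)
        dy[3] = q["liver"] * (cart - cv_liv) + r_abs_st + r_abs_int - r_l1
        dy[4] = q["kidney"] * (cart - cv_kid) - r_k1
        dy[5] = q["richly"] * (cart - cv_rich)
        dy[6] = q["slowly"] * (cart - cv_slow)
        dy[7] = oral_rate - r_abs_st - r_trans
        dy[8] = r_trans - r_abs_int
        dy[9] = r_l1
        dy[10] = r_k1
        dy[11] = qalv * c_inh
        dy[12] = qalv * calv
        dy[13] = cart
        dy[14] = cven
        dy[15] = y[2] / v["fat"]
        dy[16] = y[3] / v["liver"]
        dy[17] = y[4] / v["kidney"]
        dy[18] = y[6] / v["slowly"]
        return dy

    # -- outputs -------------------------------------------------------

    def outputs(
        self,
        t,
        y,
        c_inh=0.0,
        oral_rate=0.0,
        iv_rate=0.0,
        dermal_rate=0.0,
        oral_cum=0.0,
    ) -> np.ndarray:
        v = self._v
        qc, qalv, pba = self._qc, self._qalv, self._pba
        inv_t = 1.0 / t if t > 0 else 0.0
        vals: dict[str, float] = {}
        if self.name == "dcm":
            cart = y[0] / v["arterial"]
            cven = y[1] / v["venous"]
            calv = arterial_ss(cven, c_inh, qc, qalv, pba) / pba
            cv_liv = y[4] / v["liver"] / self._p["liver"]
            cv_lung = y[2] / v["lung"] / self._p["lung"]
            vals["c_arterial"] = cart
            vals["c_venous"] = cven
            vals["c_fat"] = y[3] / v["fat"]
            vals["c_liver"] = y[4] / v["liver"]
            vals["c_lung"] = y[2] / v["lung"]
            vals["c_richly"] = y[5] / v["richly"]
            vals["c_slowly"] = y[6] / v["slowly"]
            vals["c_stomach_lumen"] = y[7]
            vals["c_alveolar"] = calv
            vals["c_exhaled"] = 0.7 * calv + 0.3 * c_inh
            vals["r_met_liver1_sat"] = _mm(self._vmax["liver1"], self._km["liver1"], cv_liv)
            vals["r_met_liver_fo"] = self._kf["liver"] * cv_liv * v["liver"]
            vals["r_met_lung_sat"] = _mm(self._vmax["lung"], self._km["lung"], cv_lung)
            vals["r_met_lung_fo"] = self._kf["lung"] * cv_lung * v["lung"]
            in_body = float(np.sum(y[0:8]))
            met = float(np.sum(y[8:12]))
            intake = oral_cum + y[12]
            out = met + y[13]
            vals["mb_total_intake"] = intake
            vals["mb_in_body"] = in_body
            vals["mb_total_out"] = out
            vals["mb_error"] = intake - in_body - out
            vals["twa_arterial"] = y[14] * inv_t
            vals["twa_venous"] = y[15] * inv_t
            v_blood = v["arterial"] + v["venous"]
            vals["c_blood_mean"] = (y[0] + y[1]) / v_blood
            vals["r_intake_oral"] = oral_rate
        else:
            cart = y[0] / v["arterial"]
            cven = y[1] / v["venous"]
            calv = arterial_ss(cven, c_inh, qc, qalv, pba) / pba
            cv_liv = y[3] / v["liver"] / self._p["liver"]
            cv_kid = y[4] / v["kidney"] / self._p["kidney"]
            vals["c_arterial"] = cart
            vals["c_venous"] = cven
            vals["c_fat"] = y[2] / v["fat"]
            vals["c_liver"] = y[3] / v["liver"]
            vals["c_kidney"] = y[4] / v["kidney"]
            vals["c_richly"] = y[5] / v["richly"]
            vals["c_slowly"] = y[6] / v["slowly"]
            vals["c_stomach_lumen"] = y[7]
            vals["c_intestine_lumen"] = y[8]
            vals["c_alveolar"] = calv
            vals["c_exhaled"] = 0.7 * calv + 0.3 * c_inh
            vals["r_met_liver1_sat"] = _mm(self._vmax["liver1"], self._km["liver1"], cv_liv)
            vals["r_met_kidney_sat"] = _mm(self._vmax["kidney"], self._km["kidney"], cv_kid)
            in_body = float(np.sum(y[0:9]))
            met = float(np.sum(y[9:11]))
            intake = oral_cum + y[11]
            out = met + y[12]
            vals["mb_total_intake"] = intake
            vals["mb_in_body"] = in_body
            vals["mb_total_out"] = out
            vals["mb_error"] = intake - in_body - out
            vals["twa_arterial"] = y[13] * inv_t
            vals["twa_venous"] = y[14] * inv_t
            vals["twa_fat"] = y[15] * inv_t
            vals["twa_liver"] = y[16] * inv_t
            vals["twa_kidney"] = y[17] * inv_t
            vals["twa_slowly"] = y[18] * inv_t
            v_blood = v["arterial"] + v["venous"]
            vals["c_blood_mean"] = (y[0] + y[1]) / v_blood
            vals["r_intake_oral"] = oral_rate
            vals["r_intake_inhalation"] = qalv * c_inh
        return np.array([vals[n] for n in self.output_names])


def build_standalone(
    name: str, chem: ChemicalParams, phys: PhysiologyParams
) -> StandaloneModel:
    """Construct the stand-alone DCM or CF model."""
    return StandaloneModel(name, chem, phys)


def max_discrepancy(a, b, shared_outputs=None) -> float:
    """Maximum absolute difference over shared outputs and time points.

    ``a`` and ``b`` are :class:`~pbpkt.simulator.SimulationResult` objects on
    identical requested time grids.
    """
    if len(a.times) != len(b.times) or not np.allclose(a.times, b.times, rtol=0, atol=1e-12):
        raise ComparisonError("results are on different time grids")
    cols_a = set(a.outputs.columns) - {"time"}
    cols_b = set(b.outputs.columns) - {"time"}
    shared = sorted(cols_a & cols_b) if shared_outputs is None else list(shared_outputs)
    missing = [c for c in shared if c not in cols_a or c not in cols_b]
    if missing or not shared:
        raise ComparisonError(f"outputs not shared: {missing or 'none in common'}")
    worst = 0.0
    for col in shared:
        d = float(np.max(np.abs(a.outputs[col].to_numpy() - b.outputs[col].to_numpy())))
        worst = max(worst, d)
    return worst
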