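import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbpkt.errors import ConfigurationError, ConsistencyError, DomainError
from pbpkt.fixtures import cf_config, dcm_config
from pbpkt.params_io import ChemicalParams, TISSUES, scale_physiology
from pbpkt.template_engine import (
    BRANCH,
    CONDITIONAL_SITES,
    DYNAMICS,
    FIXED_DYNAMIC,
    FIXED_INIT,
    FULL_OUTPUT_NAMES,
    GE_STATE,
    INITIALIZE,
    INPUT_TABLE,
    REDUCED_OUTPUT_NAMES,
    SS_APPROX,
    SWITCH,
    BodyWeightInput,
    TemplateConfig,
    arterial_ss,
    build_engine,
    evaluate_conditional,
    full_roster,
    full_template_config,
    prune_states,
    resolve_bw,
    saturable_rate,
    venous_ss,
)


def _inert_chem(**overrides) -> ChemicalParams:
    """A chemical with every optional feature switched off."""
    base = dict(
        blood_air_partition=8.0,
        tissue_blood_partition={t: 1.5 for t in TISSUES},
        vmax_c={p: 0.0 for p in ("liver1", "liver2", "lung", "kidney")},
        km={p: 0.0 for p in ("liver1", "liver2", "lung", "kidney")},
        kf_c={p: 0.0 for p in ("liver", "lung", "kidney", "stomach", "intestine")},
    )
    base.update(overrides)
    return ChemicalParams(**base)


class TestRosters:
    def test_full_roster_is_53_with_tagged_groups(self):
        r = full_roster()
        assert len(r) == 53
        assert len(set(r.names)) == 53
        assert r.group_sizes() == {
            "compartment_amount": 17,
            "cumulative_metabolism": 9,
            "cumulative_intake_elimination": 13,
            "auc": 14,
        }

    def test_full_config_prunes_nothing(self):
        assert len(prune_states(full_template_config())) == 53

    def test_dcm_config_removes_19(self):
        retained = prune_states(dcm_config())
        assert len(retained) == 53 - 19 == 34

    def test_cf_config_removes_20_retains_33(self):
        retained = prune_states(cf_config())
        assert len(retained) == 33

    def test_retained_states_keep_full_roster_order(self):
        retained = prune_states(dcm_config())
        full = list(full_roster().names)
        positions = [full.index(n) for n in retained.names]
        assert positions == sorted(positions)

    def test_unpruned_engine_has_53_states_under_any_config(self, chem_dcm, phys):
        eng = build_engine(dcm_config(), chem_dcm, phys)
        assert eng.n_states == 53

    def test_pruned_engine_roster(self, chem_dcm, phys):
        eng = build_engine(dcm_config(prune=True), chem_dcm, phys)
        assert eng.n_states == 34


class TestConfigValidation:
    def test_ge_state_requires_lung(self):
        with pytest.raises(ConfigurationError):
            cf_config(gas_exchange_mode=GE_STATE)

    def test_open_and_closed_chamber_exclusive(self):
        with pytest.raises(ConfigurationError):
            TemplateConfig(routes=frozenset(("inhalation_open", "inhalation_closed", "oral")))

    def test_pathway_requires_host_compartment(self):
        with pytest.raises(ConfigurationError):
            dcm_config(active_pathways=frozenset(("kidney_sat",)))

    def test_no_perfused_compartment_rejected(self):
        with pytest.raises(ConfigurationError):
            TemplateConfig(
                active_compartments=frozenset(("gas_exchange",)),
                routes=frozenset(),
                lung_present=False,
            )

    def test_zero_params_must_match_config(self, phys, chem_dcm):
        # kidney_sat flagged active but vmax_c_kidney is zero in the fixture
        cfg = dcm_config(
            active_compartments=frozenset(
                dcm_config().active_compartments | {"kidney"}
            ),
            active_pathways=frozenset(
                dcm_config().active_pathways | {"kidney_sat"}
            ),
        )
        with pytest.raises(ConfigurationError):
            build_engine(cfg, chem_dcm, phys)


class TestElementaryRelations:
    def test_arterial_ss_zero_inputs(self):
        assert arterial_ss(0.0, 0.0, 5.0, 4.0, 10.0) == 0.0

    def test_arterial_ss_oracle(self):
        # (5*1 + 4*0.2) / (5 + 4/10) = 5.8/5.4
        assert arterial_ss(1.0, 0.2, 5.0, 4.0, 10.0) == pytest.approx(
            5.8 / 5.4, rel=1e-15
        )

    def test_arterial_ss_infinite_partition_limit(self):
        val = arterial_ss(1.0, 0.2, 5.0, 4.0, 1e14)
        assert val == pytest.approx((5.0 * 1.0 + 4.0 * 0.2) / 5.0, rel=1e-9)

    def test_arterial_ss_bad_partition(self):
        with pytest.raises(DomainError):
            arterial_ss(1.0, 0.2, 5.0, 4.0, 0.0)

    def test_venous_ss_mixing_identity(self):
        assert venous_ss([(3.0, 0.7), (2.0, 0.7)], 5.0) == pytest.approx(0.7, rel=1e-15)

    def test_venous_ss_oracle(self):
        assert venous_ss([(3.0, 1.0), (2.0, 0.5)], 5.0) == pytest.approx(0.8, rel=1e-15)

    def test_venous_ss_iv_contribution(self):
        assert venous_ss([(5.0, 0.0)], 5.0, iv_rate=5.0) == pytest.approx(1.0)

    def test_venous_ss_flow_mismatch(self):
        with pytest.raises(ConsistencyError):
            venous_ss([(3.0, 1.0)], 5.0)

    def test_saturable_rate_zero_conc(self):
        assert saturable_rate(10.0, 0.5, 0.0) == 0.0

    def test_saturable_rate_half_saturation(self):
        assert saturable_rate(10.0, 0.5, 0.5) == pytest.approx(5.0)

    def test_saturable_rate_oracle(self):
        assert saturable_rate(10.0, 0.5, 1.5) == pytest.approx(7.5)

    def test_saturable_rate_negative_conc(self):
        with pytest.raises(DomainError):
            saturable_rate(10.0, 0.5, -1.0)

    @given(
        vmax=st.floats(min_value=0.01, max_value=100.0),
        km=st.floats(min_value=0.01, max_value=10.0),
        c1=st.floats(min_value=0.0, max_value=1e3),
        c2=st.floats(min_value=0.0, max_value=1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_saturable_rate_monotone_and_bounded(self, vmax, km, c1, c2):
        lo, hi = sorted((c1, c2))
        r_lo, r_hi = saturable_rate(vmax, km, lo), saturable_rate(vmax, km, hi)
        assert r_lo <= r_hi <= vmax


class TestConditionalSites:
    def test_32_sites_4_init_28_dynamics(self):
        assert len(CONDITIONAL_SITES) == 32
        by_section = {}
        for s in CONDITIONAL_SITES:
            by_section[s.section] = by_section.get(s.section, 0) + 1
        assert by_section == {INITIALIZE: 4, DYNAMICS: 28}
        assert len({s.id for s in CONDITIONAL_SITES}) == 32

    def test_branch_and_switch_pick_a_when_true(self):
        site = CONDITIONAL_SITES[0]
        assert evaluate_conditional(site, True, 3.5, -1.0, BRANCH) == 3.5
        assert evaluate_conditional(site, True, 3.5, -1.0, SWITCH) == 3.5

    def test_branch_and_switch_pick_b_when_false(self):
        site = CONDITIONAL_SITES[0]
        assert evaluate_conditional(site, False, 3.5, -1.0, BRANCH) == -1.0
        assert evaluate_conditional(site, False, 3.5, -1.0, SWITCH) == -1.0

    def test_modes_identical_over_random_operands(self):
        # BRANCH is the oracle; SWITCH must agree bit-for-bit
        rng = np.random.default_rng(7)
        site = CONDITIONAL_SITES[5]
        for _ in range(1000):
            a, b = rng.normal(scale=1e3, size=2)
            pred = bool(rng.integers(2))
            assert evaluate_conditional(site, pred, a, b, SWITCH) == evaluate_conditional(
                site, pred, a, b, BRANCH
            )


class TestRhs:
    def _toy(self, phys):
        cfg = TemplateConfig(
            active_compartments=frozenset(("liver", "slowly", "gas_exchange")),
            active_pathways=frozenset(),
            routes=frozenset(("inhalation_open",)),
            blood_mode=SS_APPROX,
            lung_present=False,
        )
        chem = _inert_chem()
        return build_engine(cfg, chem, phys), chem, cfg

    def test_zero_state_zero_exposure_gives_zero_derivative(self, phys):
        eng, _, _ = self._toy(phys)
        dy = eng.rhs(0.0, np.zeros(53), c_inh=0.0)
        assert np.allclose(dy, 0.0, atol=0.0)

    def test_flow_limited_equilibrium(self, phys):
        # amounts at a common venous-equilibrated concentration x and inhaled
        # air at x/Pba put every tissue at equilibrium
        eng, chem, _ = self._toy(phys)
        sp = scale_physiology(eng.phys, chem, phys.body_weight)
        x = 0.8
        y = np.zeros(53)
        y[TISSUES.index("liver")] = x * sp.volumes["liver"] * chem.tissue_blood_partition["liver"]
        y[TISSUES.index("slowly")] = x * sp.volumes["slowly"] * chem.tissue_blood_partition["slowly"]
        dy = eng.rhs(0.0, y, c_inh=x / chem.blood_air_partition)
        assert dy[TISSUES.index("liver")] == pytest.approx(0.0, abs=1e-9)
        assert dy[TISSUES.index("slowly")] == pytest.approx(0.0, abs=1e-9)

    def test_two_compartment_toy_matches_hand_computed_balance(self, phys):
        # independent evaluation of the stated flow-limited balance equations
        eng, chem, _ = self._toy(phys)
        y = np.zeros(53)
        i_liv, i_slow = TISSUES.index("liver"), TISSUES.index("slowly")
        y[i_liv], y[i_slow] = 2.0, 3.0
        cinh = 0.5
        dy = eng.rhs(0.0, y, c_inh=cinh)

        bw = phys.body_weight
        qc = phys.cardiac_output_c * bw**0.75
        qalv = phys.alveolar_ventilation_c * bw**0.75
        fl = phys.flow_fraction["liver"]
        fs = phys.flow_fraction["slowly"]
        q_liv = qc * fl / (fl + fs)
        q_slow = qc * fs / (fl + fs)
        pba = chem.blood_air_partition
        cv_liv = 2.0 / (phys.volume_fraction["liver"] * bw) / chem.tissue_blood_partition["liver"]
        cv_slow = 3.0 / (phys.volume_fraction["slowly"] * bw) / chem.tissue_blood_partition["slowly"]
        cven = (q_liv * cv_liv + q_slow * cv_slow) / qc
        cart = (qc * cven + qalv * cinh) / (qc + qalv / pba)

        assert dy[i_liv] == pytest.approx(q_liv * (cart - cv_liv), rel=1e-12)
        assert dy[i_slow] == pytest.approx(q_slow * (cart - cv_slow), rel=1e-12)
        # cumulative intake/elimination rates from the same hand algebra
        assert dy[26] == pytest.approx(qalv * cinh, rel=1e-12)  # e_inhaled
        assert dy[31] == pytest.approx(qalv * cart / pba, rel=1e-12)  # e_exhaled

    def test_nan_state_aborts(self, phys, chem_dcm):
        eng = build_engine(dcm_config(), chem_dcm, phys)
        y = np.zeros(53)
        y[0] = float("nan")
        with pytest.raises(FloatingPointError):
            eng.rhs(0.0, y)


class TestOutputs:
    def test_full_output_map_is_105(self, phys, chem_dcm):
        eng = build_engine(dcm_config(), chem_dcm, phys)
        assert len(eng.output_names) == len(FULL_OUTPUT_NAMES) == 105

    def test_reduced_output_map_is_76(self, phys, chem_dcm):
        eng = build_engine(dcm_config(reduced_outputs=True), chem_dcm, phys)
        assert len(eng.output_names) == len(REDUCED_OUTPUT_NAMES) == 76

    def test_reduced_is_subset_of_full(self):
        assert set(REDUCED_OUTPUT_NAMES) < set(FULL_OUTPUT_NAMES)

    def test_zero_state_gives_zero_concentrations(self, phys, chem_dcm):
        eng = build_engine(dcm_config(), chem_dcm, phys)
        out = dict(zip(eng.output_names, eng.outputs(0.0, np.zeros(53))))
        for name, val in out.items():
            if name.startswith(("c_", "cv_")):
                assert val == 0.0

    def test_inactive_compartment_reports_zero(self, phys, chem_dcm):
        eng = build_engine(dcm_config(), chem_dcm, phys)
        y = np.zeros(53)
        y[TISSUES.index("kidney")] = 5.0  # unreachable, but outputs must gate
        out = dict(zip(eng.output_names, eng.outputs(0.0, y)))
        assert out["c_kidney"] == 0.0


class TestResolveBw:
    def test_constant_table_all_modes_agree(self, phys, chem_dcm):
        table = BodyWeightInput(times=(0.0, 336.0), weights=(70.0, 70.0))
        const = BodyWeightInput(constant=70.0)
        _, a = resolve_bw(10.0, table, INPUT_TABLE, phys, chem_dcm)
        _, b = resolve_bw(10.0, const, FIXED_DYNAMIC, phys, chem_dcm)
        _, c = resolve_bw(10.0, const, FIXED_INIT, phys, chem_dcm, cache={})
        assert a.cardiac_output == b.cardiac_output == c.cardiac_output
        assert a.volumes == b.volumes == c.volumes

    def test_linear_midpoint(self):
        table = BodyWeightInput(times=(0.0, 100.0), weights=(70.0, 80.0))
        assert table.at(50.0) == pytest.approx(75.0)

    def test_clamps_outside_range(self):
        table = BodyWeightInput(times=(10.0, 100.0), weights=(70.0, 80.0))
        assert table.at(0.0) == 70.0
        assert table.at(500.0) == 80.0

    def test_fixed_init_scales_once_per_simulation(self, phys, chem_dcm):
        from pbpkt.exposure import make_scenario
        from pbpkt.simulator import simulate

        eng = build_engine(dcm_config(bw_mode=FIXED_INIT), chem_dcm, phys)
        simulate(eng, make_scenario(1, 0.1), n_points=20)
        assert eng.scale_call_count == 1

    def test_bad_table_rejected(self):
        with pytest.raises(DomainError):
            BodyWeightInput(times=(0.0, 0.0), weights=(70.0, 70.0))
        with pytest.raises(DomainError):
            BodyWeightInput(times=(0.0, 1.0), weights=(70.0, -1.0))
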