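import math
from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbpkt.errors import ConfigurationError, DomainError, ValidationError
from pbpkt.params_io import (
    BW_DEPENDENT_NAMES,
    TISSUES,
    ChemicalParams,
    load_params,
    renormalize_flows,
    scale_physiology,
    write_params,
)


class TestLoadParams:
    def test_dcm_fixture_has_cf_only_pathways_zero(self, chem_dcm):
        # features absent from the DCM mapping are switched off by zeros
        assert chem_dcm.vmax_c["kidney"] == 0.0
        assert chem_dcm.vmax_c["liver2"] == 0.0
        assert chem_dcm.kf_c["kidney"] == 0.0
        assert chem_dcm.stomach_to_intestine_rate == 0.0
        assert chem_dcm.oral_absorption_rate_intestine == 0.0
        # ... while its own pathways are on
        assert chem_dcm.vmax_c["liver1"] > 0
        assert chem_dcm.vmax_c["lung"] > 0

    def test_negative_partition_is_domain_error(self, tmp_path, chem_dcm):
        m = chem_dcm.to_mapping()
        m["blood_air_partition"] = -1.0
        path = tmp_path / "bad.csv"
        write_params(m, path)
        with pytest.raises(DomainError):
            load_params(path, "chemical")

    def test_roundtrip_identity(self, tmp_path, chem_cf):
        path = tmp_path / "cf.csv"
        write_params(chem_cf, path)
        again = load_params(path, "chemical")
        assert again == chem_cf

    def test_physiology_roundtrip(self, tmp_path, phys):
        path = tmp_path / "phys.csv"
        write_params(phys, path)
        assert load_params(path, "physiology") == phys

    def test_missing_key_named(self, tmp_path, chem_dcm):
        m = chem_dcm.to_mapping()
        del m["km_liver1"]
        path = tmp_path / "missing.csv"
        write_params(m, path)
        with pytest.raises(ValidationError, match="km_liver1"):
            load_params(path, "chemical")

    def test_unknown_key_rejected_by_name(self, tmp_path, chem_dcm):
        m = chem_dcm.to_mapping()
        m["mystery_rate"] = 1.0
        path = tmp_path / "unknown.csv"
        write_params(m, path)
        with pytest.raises(ValidationError, match="mystery_rate"):
            load_params(path, "chemical")

    def test_missing_file(self, tmp_path):
        with pytest.raises(ValidationError):
            load_params(tmp_path / "nope.csv", "chemical")

    def test_km_required_with_vmax(self, chem_dcm):
        m = chem_dcm.to_mapping()
        m["km_liver1"] = 0.0
        with pytest.raises(DomainError):
            ChemicalParams.from_mapping(m)


class TestScalePhysiology:
    def test_unit_body_weight_returns_coefficients(self, phys, chem_dcm):
        sp = scale_physiology(phys, chem_dcm, 1.0)
        assert sp.cardiac_output == phys.cardiac_output_c
        assert sp.alveolar_ventilation == phys.alveolar_ventilation_c
        assert sp.skin_area == phys.skin_area_c
        for t in TISSUES:
            assert sp.volumes[t] == phys.volume_fraction[t]

    def test_cardiac_output_at_70kg(self, phys, chem_dcm):
        # direct arithmetic oracle: qc = coeff * bw**0.75
        p = replace(phys, cardiac_output_c=14.0)
        sp = scale_physiology(p, chem_dcm, 70.0)
        assert sp.cardiac_output == pytest.approx(14.0 * 70.0**0.75, rel=1e-12)
        assert sp.cardiac_output == pytest.approx(338.8, rel=1e-3)

    def test_28_bw_dependent_names(self, phys, chem_dcm):
        sp = scale_physiology(phys, chem_dcm, 70.0)
        assert len(sp.bw_dependent_names) == 28
        assert len(set(sp.bw_dependent_names)) == 28
        assert sp.bw_dependent_names == BW_DEPENDENT_NAMES

    def test_nonpositive_bw_rejected(self, phys, chem_dcm):
        with pytest.raises(DomainError):
            scale_physiology(phys, chem_dcm, 0.0)

    @given(c=st.floats(min_value=0.1, max_value=1.4))
    @settings(max_examples=25, deadline=None)
    def test_homogeneity_in_coefficients(self, phys, chem_dcm, c):
        # scaling every coefficient by c scales every output by c at fixed bw
        scaled_phys = replace(
            phys,
            volume_fraction={k: 0.5 * v * c for k, v in phys.volume_fraction.items()},
            cardiac_output_c=phys.cardiac_output_c * c,
            alveolar_ventilation_c=phys.alveolar_ventilation_c * c,
            skin_area_c=phys.skin_area_c * c,
        )
        a = scale_physiology(phys, chem_dcm, 60.0)
        b = scale_physiology(scaled_phys, chem_dcm, 60.0)
        assert b.cardiac_output == pytest.approx(c * a.cardiac_output, rel=1e-12)
        assert b.alveolar_ventilation == pytest.approx(c * a.alveolar_ventilation, rel=1e-12)
        for t in TISSUES:
            assert b.volumes[t] == pytest.approx(0.5 * c * a.volumes[t], rel=1e-12)


class TestRenormalizeFlows:
    def test_identity_when_all_active_and_normalized(self, phys):
        out = renormalize_flows(phys, TISSUES)
        assert sum(out.flow_fraction.values()) == pytest.approx(1.0, abs=1e-12)
        for t in TISSUES:
            assert out.flow_fraction[t] == pytest.approx(phys.flow_fraction[t], rel=1e-12)

    def test_deactivation_rescales_by_remaining_mass(self, phys):
        # arithmetic oracle: drop a compartment holding fraction f; the rest
        # divide by (1 - f)
        f = phys.flow_fraction["slowly"]
        active = tuple(t for t in TISSUES if t != "slowly")
        out = renormalize_flows(phys, active)
        assert out.flow_fraction["slowly"] == 0.0
        for t in active:
            assert out.flow_fraction[t] == pytest.approx(
                phys.flow_fraction[t] / (1.0 - f), rel=1e-12
            )

    def test_single_active_compartment_gets_everything(self, phys):
        out = renormalize_flows(phys, ("liver",))
        assert out.flow_fraction["liver"] == pytest.approx(1.0, rel=1e-15)
        assert sum(out.flow_fraction.values()) == pytest.approx(1.0, rel=1e-15)

    def test_idempotent(self, phys):
        active = ("fat", "liver", "richly", "slowly", "lung")
        once = renormalize_flows(phys, active)
        twice = renormalize_flows(once, active)
        for t in TISSUES:
            assert twice.flow_fraction[t] == pytest.approx(
                once.flow_fraction[t], rel=1e-14
            )

    def test_no_active_compartment_is_error(self, phys):
        with pytest.raises(ConfigurationError):
            renormalize_flows(phys, ())
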