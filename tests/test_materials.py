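"""Constitutive material model: property curves and disease classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mwablate.materials import (DISEASE_FAT_MEANS, MaterialModelParams,
                                classify_disease, disease_property_table,
                                export_property_table, mix_dielectric,
                                perfusion_rate, properties_for,
                                thermal_conductivity)


class TestThermalConductivity:
    @pytest.mark.parametrize("f, expected", [
        (0.0, 0.521), (3.9, 0.461), (14.70, 0.349), (29.90, 0.271),
    ])
    def test_disease_state_values(self, params, f, expected):
        assert thermal_conductivity(f, params) == pytest.approx(expected, abs=5e-4)

    def test_large_fat_approaches_pure_fat_from_above(self, params):
        assert thermal_conductivity(1000.0, params) == pytest.approx(params.k_fat, abs=1e-10)
        assert thermal_conductivity(100.0, params) > params.k_fat
        assert thermal_conductivity(200.0, params) < thermal_conductivity(100.0, params)

    def test_negative_fat_rejected(self, params):
        with pytest.raises(ValueError):
            thermal_conductivity(-1.0, params)

    @given(st.floats(0, 34.9), st.floats(0.01, 35))
    def test_strictly_decreasing(self, f, df):
        p = MaterialModelParams()
        assert thermal_conductivity(f + df, p) < thermal_conductivity(f, p)


class TestMixDielectric:
    def test_endpoints_exact(self, params):
        assert mix_dielectric(0.0, params) == (0.861, 46.8)
        assert mix_dielectric(100.0, params) == pytest.approx((0.11, 10.8))

    def test_printed_rounded_entries(self, params):
        sigma, _ = mix_dielectric(21.20, params)
        assert round(sigma, 2) == 0.70
        _, eps = mix_dielectric(3.9, params)
        assert round(eps, 1) == 45.4

    @pytest.mark.parametrize("f, sigma_ref, eps_ref", [
        (3.9, 0.831, 45.4), (14.70, 0.749, 41.6),
        (21.20, 0.7, 39.3), (29.90, 0.634, 36.2),
    ])
    def test_table_entries_within_rounding_slack(self, params, f, sigma_ref, eps_ref):
        sigma, eps = mix_dielectric(f, params)
        assert sigma == pytest.approx(sigma_ref, abs=3e-3)
        assert eps == pytest.approx(eps_ref, abs=0.2)

    def test_out_of_range_rejected(self, params):
        with pytest.raises(ValueError):
            mix_dielectric(101.0, params)
        with pytest.raises(ValueError):
            mix_dielectric(-0.1, params)


class TestPerfusion:
    @pytest.mark.parametrize("f, expected", [
        (0.0, 0.018), (3.9, 0.01722), (14.70, 0.01506),
        (21.20, 0.01376), (29.90, 0.01202),
    ])
    def test_disease_state_values_exact(self, params, f, expected):
        assert perfusion_rate(f, params) == pytest.approx(expected, rel=1e-12)

    def test_saturates_at_cirrhotic_floor(self, params):
        assert perfusion_rate(50.0, params) == pytest.approx(0.011)
        assert perfusion_rate(35.0, params) == pytest.approx(0.011)

    @given(st.floats(0, 200))
    def test_bounded_and_monotone(self, f):
        p = MaterialModelParams()
        w = perfusion_rate(f, p)
        assert p.omega_cirr - 1e-15 <= w <= p.omega_0
        if f < p.f_sat:
            assert perfusion_rate(f + 1.0, p) < w + 1e-15


class TestPropertiesFor:
    def test_parenchyma_zero_fat_is_table_index0(self, params):
        p = properties_for("parenchyma", 0.0, params)
        assert (p.k, p.sigma, p.eps_r, p.omega_b) == (0.521, 0.861, 46.8, 0.018)
        assert (p.cp, p.rho) == (3400.0, 1050.0)

    def test_tumor_constants_independent_of_fat(self, params):
        for f in (0.0, 29.9):
            p = properties_for("tumor", f, params)
            assert (p.k, p.sigma, p.eps_r) == (0.624, 1.24, 55.7)
            # bulk and Arrhenius constants stay at the liver values
            assert (p.A, p.dE) == (7.39e39, 2.58e5)
        # tumor perfusion follows the surrounding parenchyma
        assert properties_for("tumor", 29.90, params).omega_b == pytest.approx(0.01202)

    def test_pure_fat_constants(self, params):
        p = properties_for("pure_fat", params=params)
        assert (p.A, p.dE, p.cp, p.rho) == (4.43e16, 1.30e5, 2348.0, 911.0)

    def test_unknown_role_rejected(self, params):
        with pytest.raises(ValueError):
            properties_for("bone", 0.0, params)

    def test_mu_r_fixed_at_unity(self, params):
        assert properties_for("parenchyma", 10.0, params).mu_r == 1.0


class TestClassifyDisease:
    @pytest.mark.parametrize("f, index, label", [
        (0.0, 0, "None"), (3.9, 1, "Low"), (14.70, 2, "Mild"),
        (21.20, 3, "Moderate"), (29.90, 4, "High"),
        # boundary convention: left-closed at 6, 17, 22
        (5.999, 1, "Low"), (6.0, 2, "Mild"), (17.0, 3, "Moderate"),
        (22.0, 4, "High"),
    ])
    def test_classes(self, f, index, label):
        s = classify_disease(f)
        assert (s.index, s.label) == (index, label)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_disease(-0.1)


class TestParamsAndExport:
    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            MaterialModelParams(k_fat=1.0)       # k_liver > k_fat violated
        with pytest.raises(ValueError):
            MaterialModelParams(tau_k=0.01)

    def test_yaml_roundtrip(self, tmp_path, params):
        path = tmp_path / "mat.yaml"
        params.to_yaml(path)
        assert MaterialModelParams.from_yaml(path) == params

    def test_property_table_regenerates_all_states(self, params):
        t = disease_property_table(params)
        for idx, f in DISEASE_FAT_MEANS.items():
            col = t[str(idx)]
            assert col["fat_percent"] == f
            assert col["thermal_conductivity_W_per_mK"] == pytest.approx(
                thermal_conductivity(f, params))
        assert t["Tumor"]["electrical_conductivity_S_per_m"] == 1.24

    def test_export_csv_and_json(self, tmp_path, params):
        export_property_table(tmp_path / "t.csv", params)
        export_property_table(tmp_path / "t.json", params)
        assert (tmp_path / "t.csv").read_text().startswith(",0,1,2,3,4")
        assert '"0"' in (tmp_path / "t.json").read_text()
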