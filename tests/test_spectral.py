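import numpy as np
import pytest

import hupotency as hp
from hupotency.spectral import WATER


VOLTAGES = (80.0, 100.0, 120.0, 140.0)


class TestEffectiveWeight:
    def test_zero_thickness_is_fluence_times_detector(self, synthetic_model):
        grid = synthetic_model.xs.grid
        spectrum = synthetic_model.spectra[80.0]
        weight = hp.effective_weight(
            spectrum,
            hp.FilterSpec(thickness=0.0),
            synthetic_model.detector,
            synthetic_model.xs,
        )
        np.testing.assert_allclose(
            weight, spectrum.fluence * synthetic_model.detector.values
        )

    def test_transmission_compounds_exponentially(self, synthetic_model):
        spectrum = synthetic_model.spectra[80.0]
        args = (synthetic_model.detector, synthetic_model.xs)
        w0 = hp.effective_weight(spectrum, hp.FilterSpec(thickness=0.0), *args)
        w1 = hp.effective_weight(spectrum, hp.FilterSpec(thickness=0.01), *args)
        w2 = hp.effective_weight(spectrum, hp.FilterSpec(thickness=0.02), *args)
        mask = w0 > 0
        np.testing.assert_allclose(
            (w1[mask] / w0[mask]) ** 2, w2[mask] / w0[mask], rtol=1e-10
        )

    def test_beam_hardening_raises_mean_energy(self, synthetic_model):
        spectrum = synthetic_model.spectra[120.0]
        energies = synthetic_model.xs.grid.energies
        means = []
        for t in (0.0, 0.005, 0.01, 0.02, 0.04):
            w = hp.effective_weight(
                spectrum,
                hp.FilterSpec(thickness=t),
                synthetic_model.detector,
                synthetic_model.xs,
            )
            means.append(np.sum(w * energies) / np.sum(w))
        assert np.all(np.diff(means) > 0)

    def test_grid_mismatch_rejected(self, synthetic_model):
        other = hp.default_grid(max_kev=100.0)
        spectrum = hp.synthetic_spectrum(80.0, other)
        with pytest.raises(ValueError, match="grid"):
            hp.effective_weight(
                spectrum,
                synthetic_model.filter,
                synthetic_model.detector,
                synthetic_model.xs,
            )


class TestMuStar:
    def test_water_at_reference_density_is_one(self, synthetic_model):
        n0 = synthetic_model.water_molar_density
        for kv in VOLTAGES:
            weight = synthetic_model.weight(kv)
            assert hp.mu_star(WATER, n0, weight, synthetic_model) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_single_line_spectrum_collapses_to_ratio(self):
        grid = hp.default_grid(max_kev=80.0)
        fluence = np.zeros(len(grid))
        line = 42
        fluence[line - 1 : line + 2] = [0.0, 1.0, 0.0]
        model = hp.AcquisitionModel(
            spectra={80.0: hp.Spectrum(grid, fluence, 80.0)},
            filter=hp.FilterSpec(thickness=0.0),
            detector=hp.DetectorResponse.unity(grid),
            xs=hp.synthetic_cross_sections(list(hp.ATOMIC_MASS), grid),
        )
        c = hp.parse_formula("CaCO3")
        n = 1234.0
        expected = (
            n
            * model.xs.compound_sigma(c)[line]
            / (model.water_molar_density * model.xs.compound_sigma(WATER)[line])
        )
        weight = model.weight(80.0)
        assert hp.mu_star(c, n, weight, model) == pytest.approx(expected, rel=1e-9)

    def test_linear_in_concentration(self, synthetic_model):
        weight = synthetic_model.weight(100.0)
        c = hp.parse_formula("NaCl")
        one = hp.mu_star(c, 500.0, weight, synthetic_model)
        two = hp.mu_star(c, 1000.0, weight, synthetic_model)
        assert two == pytest.approx(2 * one, rel=1e-14)


class TestPotencies:
    def test_water_molar_potency_is_scale_constant(self, synthetic_model):
        expected = 1000 * hp.molar_mass(WATER) / hp.WATER_DENSITY
        for kv in VOLTAGES:
            assert hp.molar_potency(WATER, kv, synthetic_model) == pytest.approx(
                expected, rel=1e-12
            )

    def test_additive_over_composition(self, synthetic_model):
        water = hp.molar_potency(WATER, 80.0, synthetic_model)
        h = hp.molar_potency(hp.Composition({"H": 1}), 80.0, synthetic_model)
        o = hp.molar_potency(hp.Composition({"O": 1}), 80.0, synthetic_model)
        assert water == pytest.approx(2 * h + o, rel=1e-12)

    def test_calcium_exceeds_carbon(self, synthetic_model):
        assert hp.molar_potency(
            hp.Composition({"Ca": 1}), 80.0, synthetic_model
        ) > hp.molar_potency(hp.Composition({"C": 1}), 80.0, synthetic_model)

    def test_water_mass_potency_is_unity(self, synthetic_model):
        for kv in VOLTAGES:
            assert hp.mass_potency(WATER, kv, synthetic_model) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_same_stoichiometric_ratio_same_mass_potency(self, synthetic_model):
        pe = hp.mass_potency(hp.parse_formula("C2H4"), 100.0, synthetic_model)
        pmp = hp.mass_potency(hp.parse_formula("C6H12"), 100.0, synthetic_model)
        assert pe == pytest.approx(pmp, rel=1e-12)

    def test_invariant_to_fluence_rescaling(self, synthetic_model):
        scaled = hp.AcquisitionModel(
            spectra={
                kv: hp.Spectrum(s.grid, 7.5 * s.fluence, s.tube_voltage)
                for kv, s in synthetic_model.spectra.items()
            },
            filter=synthetic_model.filter,
            detector=synthetic_model.detector,
            xs=synthetic_model.xs,
        )
        c = hp.parse_formula("CaCl2")
        assert hp.mass_potency(c, 120.0, scaled) == pytest.approx(
            hp.mass_potency(c, 120.0, synthetic_model), rel=1e-13
        )

    def test_mass_potency_decreases_with_voltage_above_oxygen(self, synthetic_model):
        for symbol in ("Na", "Al", "S", "Ca"):
            values = [
                hp.mass_potency(hp.Composition({symbol: 1}), kv, synthetic_model)
                for kv in VOLTAGES
            ]
            assert np.all(np.diff(values) < 0)


class TestElementPotencyMatrix:
    def test_study_dimensions(self, synthetic_potencies):
        assert synthetic_potencies.values.shape == (13, 4)
        assert synthetic_potencies.elements == hp.STUDY_ELEMENTS

    def test_elemental_contrast_shrinks_with_voltage(self, synthetic_potencies):
        spread_80 = np.ptp(synthetic_potencies.values[:, 0])
        spread_140 = np.ptp(synthetic_potencies.values[:, -1])
        assert spread_140 < spread_80


class TestLoaders:
    def test_xcom_unit_conversion_and_interpolation(self, tmp_path):
        # synthetic XCOM-style export: exact power law sigma = E^-2 cm^2/g
        energies_mev = np.array([0.005, 0.01, 0.02, 0.05, 0.08, 0.15])
        mu_rho = (energies_mev * 1000) ** -2.0
        path = tmp_path / "C.txt"
        np.savetxt(path, np.column_stack([energies_mev, mu_rho]))
        grid = hp.EnergyGrid(np.array([10.0, 14.0, 50.0]))
        xs = hp.load_xcom({"C": path}, grid)
        # tabulated point: unit algebra only
        assert xs.sigma["C"][0] == pytest.approx(
            (10.0**-2.0) * 0.1 * 0.012011, rel=1e-10
        )
        # midpoint: log-log interpolation of a power law is exact
        assert xs.sigma["C"][1] == pytest.approx(
            (14.0**-2.0) * 0.1 * 0.012011, rel=1e-10
        )
        assert xs.provenance == "xcom"

    def test_xcom_grid_out_of_range(self, tmp_path):
        path = tmp_path / "H.txt"
        np.savetxt(path, np.column_stack([[0.01, 0.1], [1.0, 0.1]]))
        with pytest.raises(ValueError, match="range"):
            hp.load_xcom({"H": path}, hp.EnergyGrid(np.array([5.0, 150.0])))

    def test_tasmics_cutoff_and_grid(self, tmp_path):
        # synthetic spectrum table in the per-keV, column-per-potential layout
        energies = np.arange(1.0, 141.0)
        header = "energy,80,100,120,140"
        columns = [np.clip(kv / energies - 1, 0, None) for kv in (80, 100, 120, 140)]
        table = np.column_stack([energies] + columns)
        path = tmp_path / "spectra.csv"
        np.savetxt(path, table, delimiter=",", header=header, comments="")
        endpoints = []
        for kv in (80.0, 100.0, 120.0, 140.0):
            spectrum = hp.load_tasmics(path, kv)
            assert np.all(spectrum.fluence[spectrum.grid.energies > kv] == 0)
            assert np.all(np.diff(spectrum.grid.energies) == 1.0)
            endpoints.append(spectrum.grid.energies[spectrum.fluence > 0][-1])
        assert endpoints == sorted(endpoints) and len(set(endpoints)) == 4

    def test_tasmics_unknown_voltage(self, tmp_path):
        path = tmp_path / "spectra.csv"
        path.write_text("energy,80\n10,1.0\n20,0.5\n")
        with pytest.raises(ValueError, match="90"):
            hp.load_tasmics(path, 90.0)
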