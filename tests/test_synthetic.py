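import numpy as np
import pytest

import hupotency as hp
from hupotency.synthetic import AVOGADRO, THOMSON_CROSS_SECTION, klein_nishina


class TestCrossSections:
    def test_klein_nishina_thomson_limit(self):
        assert klein_nishina(1e-9) == pytest.approx(6.652e-29, rel=1e-3)
        assert klein_nishina(0.01) == pytest.approx(THOMSON_CROSS_SECTION, rel=1e-3)

    def test_doubling_photoelectric_scale(self):
        grid = hp.default_grid(max_kev=140.0)
        p1 = hp.SyntheticXsParams()
        p2 = hp.SyntheticXsParams(photoelectric_scale=2 * p1.photoelectric_scale)
        xs1 = hp.synthetic_cross_sections(["Ca"], grid, p1)
        xs2 = hp.synthetic_cross_sections(["Ca"], grid, p2)
        compton = 20 * klein_nishina(grid.energies) * AVOGADRO
        np.testing.assert_allclose(
            xs2.sigma["Ca"] - compton, 2 * (xs1.sigma["Ca"] - compton), rtol=1e-12
        )

    def test_ratio_matches_direct_formula(self):
        grid = hp.EnergyGrid(np.array([59.0, 60.0, 61.0]))
        params = hp.SyntheticXsParams()
        xs = hp.synthetic_cross_sections([20, 1], grid, params)
        e = 60.0

        def direct(z):
            return (
                params.photoelectric_scale * z**4.5 * e**-3.0
                + z * klein_nishina(e) * AVOGADRO
            )

        ratio = xs.sigma["Ca"][1] / xs.sigma["H"][1]
        assert ratio == pytest.approx(direct(20) / direct(1), rel=1e-12)

    def test_positive_and_decreasing(self):
        grid = hp.default_grid(max_kev=140.0)
        xs = hp.synthetic_cross_sections(list(hp.ATOMIC_MASS), grid)
        for values in xs.sigma.values():
            assert np.all(values > 0)
            assert np.all(np.diff(values) < 0)

    def test_empty_elements_rejected(self):
        with pytest.raises(ValueError):
            hp.synthetic_cross_sections([], hp.default_grid())


class TestSpectrum:
    def test_endpoint_and_cutoff(self):
        grid = hp.default_grid(max_kev=140.0)
        spectrum = hp.synthetic_spectrum(80.0, grid)
        assert spectrum.fluence[grid.energies == 80.0] == 0
        assert np.all(spectrum.fluence[grid.energies > 80.0] == 0)

    def test_positive_integral_and_decreasing(self):
        grid = hp.default_grid(max_kev=140.0)
        spectrum = hp.synthetic_spectrum(120.0, grid)
        assert np.trapezoid(spectrum.fluence, grid.energies) > 0
        interior = (grid.energies > 5.0) & (grid.energies < 120.0)
        assert np.all(np.diff(spectrum.fluence[interior]) < 0)

    @pytest.mark.parametrize("kv", [30.0, 160.0])
    def test_voltage_range_enforced(self, kv):
        with pytest.raises(ValueError):
            hp.synthetic_spectrum(kv, hp.default_grid(max_kev=150.0))


@pytest.fixture(scope="module")
def compounds():
    return [hp.parse_formula(f) for f in ("H2O", "CaCO3", "NaCl", "C", "K2SO4")]


class TestCompoundTableSimulator:

    def test_noiseless_matches_linear_model(self, synthetic_potencies, compounds):
        table = hp.simulate_compound_table(
            synthetic_potencies, compounds, hp.NoiseModel(sd=0.0)
        )
        H = hp.compound_potency_matrix(table).to_numpy()
        C = hp.build_design_matrix(table.records, hp.STUDY_ELEMENTS)
        np.testing.assert_allclose(C.counts @ synthetic_potencies.values, H, atol=1e-14)

    def test_same_seed_reproduces(self, synthetic_potencies, compounds):
        noise = hp.NoiseModel(sd=1e-3, seed=42)
        t1 = hp.simulate_compound_table(synthetic_potencies, compounds, noise)
        t2 = hp.simulate_compound_table(synthetic_potencies, compounds, noise)
        for r1, r2 in zip(t1.records, t2.records):
            assert r1.mass_potency == r2.mass_potency

    def test_empirical_noise_sd(self, synthetic_potencies, compounds):
        """~1e4 sampled cells recover the nominal residual SD within 2%."""
        sd = 1e-3
        base = hp.compound_potency_matrix(
            hp.simulate_compound_table(synthetic_potencies, compounds, hp.NoiseModel())
        ).to_numpy()
        residuals = []
        for seed in range(500):
            noisy = hp.compound_potency_matrix(
                hp.simulate_compound_table(
                    synthetic_potencies, compounds, hp.NoiseModel(sd=sd, seed=seed)
                )
            ).to_numpy()
            residuals.append((noisy - base).ravel())
        empirical = np.std(np.concatenate(residuals))
        assert empirical == pytest.approx(sd, rel=0.02)

    def test_unknown_element_rejected(self, synthetic_model):
        A = hp.element_potency_matrix(synthetic_model, ("H", "O"))
        with pytest.raises(ValueError, match="Ca"):
            hp.simulate_compound_table(A, [hp.parse_formula("CaCO3")])


class TestBottleSimulator:
    GEOM = hp.CylinderSpec(center=(8e-3, 8e-3, 8e-3), radius=4e-3, height=10e-3,
                           wall_thickness=1e-3)
    SHAPE = (64, 64, 32)
    SPACING = (0.25e-3, 0.25e-3, 0.5e-3)

    def test_uniform_fill_integral(self):
        geom = hp.CylinderSpec(center=(8e-3, 8e-3, 8e-3), radius=4e-3, height=10e-3)
        phantom = hp.simulate_bottle_volume(
            self.SHAPE, self.SPACING, geom, mu_star_fill=1.0, mu_star_wall=1.0
        )
        voxel = np.prod(self.SPACING)
        expected = phantom.fill_mask.sum() * voxel
        assert phantom.integral_mu_star_fill == pytest.approx(expected, rel=1e-12)

    def test_determinism(self):
        kwargs = dict(mu_star_fill=1.5, noise_sd_hu=5.0, seed=7)
        a = hp.simulate_bottle_volume(self.SHAPE, self.SPACING, self.GEOM, **kwargs)
        b = hp.simulate_bottle_volume(self.SHAPE, self.SPACING, self.GEOM, **kwargs)
        np.testing.assert_array_equal(a.volume.values, b.volume.values)

    def test_zero_radius_degenerates(self):
        geom = hp.CylinderSpec(center=(8e-3, 8e-3, 8e-3), radius=0.0, height=10e-3)
        phantom = hp.simulate_bottle_volume(
            self.SHAPE, self.SPACING, geom, mu_star_fill=1.0
        )
        assert phantom.integral_mu_star_fill == 0.0

    def test_geometry_outside_grid_rejected(self):
        geom = hp.CylinderSpec(center=(1e-3, 8e-3, 8e-3), radius=4e-3, height=10e-3)
        with pytest.raises(ValueError, match="fit"):
            hp.simulate_bottle_volume(self.SHAPE, self.SPACING, geom, mu_star_fill=1.0)

    def test_air_background_level(self):
        phantom = hp.simulate_bottle_volume(
            self.SHAPE, self.SPACING, self.GEOM, mu_star_fill=1.5
        )
        outside = ~(phantom.fill_mask | phantom.wall_mask)
        assert np.all(phantom.volume.values[outside] == -1000.0)

    def test_blur_conserves_integral(self):
        sharp = hp.simulate_bottle_volume(
            self.SHAPE, self.SPACING, self.GEOM, mu_star_fill=1.5
        )
        blurred = hp.simulate_bottle_volume(
            self.SHAPE, self.SPACING, self.GEOM, mu_star_fill=1.5, blur_sigma_vox=1.0
        )
        voxel = np.prod(self.SPACING)
        total_sharp = (sharp.volume.values / 1000.0 + 1.0).sum() * voxel
        total_blurred = (blurred.volume.values / 1000.0 + 1.0).sum() * voxel
        assert total_blurred == pytest.approx(total_sharp, rel=1e-6)
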