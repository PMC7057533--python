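"""Forward model: source spectrum, attenuation, expected counts, Poisson draws."""

import math

import numpy as np
import pytest

from ssaxs.geometry import DetectorGeometry, compute_angle_map, q_transfer
from ssaxs.materials import make_amyloid_template, make_pmma_template, combine, zero_template
from ssaxs.simulate import (
    AcquisitionConfig,
    attenuation_factor,
    expected_counts,
    kramers_spectrum,
    sample_events,
    simulate_acquisition,
    simulate_histogram,
    _blur_matrix,
)


class TestKramersSpectrum:
    def test_endpoint_bin_has_zero_fluence(self):
        spec = kramers_spectrum(kvp=50.0, e_min=5.0, bin_width=1.0)
        # fluence tends to zero approaching the endpoint
        assert spec.relative_fluence[-1] == spec.relative_fluence.min()
        assert spec.relative_fluence[-1] < 0.1 * spec.relative_fluence[0]
        assert np.all(spec.relative_fluence[spec.energy_centers > 50.0] == 0)

    def test_fluence_ratio_20_over_40_kev(self):
        # grid with bin centres exactly at 20 and 40 keV
        spec = kramers_spectrum(kvp=50.0, e_min=10.0, bin_width=20.0)
        np.testing.assert_allclose(spec.energy_centers, [20.0, 40.0])
        ratio = spec.relative_fluence[0] / spec.relative_fluence[1]
        assert ratio == pytest.approx(6.0, rel=1e-12)

    def test_normalised_to_unit_sum(self):
        spec = kramers_spectrum()
        assert spec.relative_fluence.sum() == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("kwargs", [dict(e_min=0.0), dict(e_min=60.0), dict(bin_width=-1.0)])
    def test_invalid_bounds_rejected(self, kwargs):
        with pytest.raises(ValueError):
            kramers_spectrum(kvp=50.0, **{"bin_width": 1.0, **kwargs})


class TestAttenuation:
    def test_zero_thickness_gives_unity(self):
        cfg = AcquisitionConfig(sample_thickness=0.0)
        assert attenuation_factor(30.0, cfg) == 1.0

    def test_disabled_gives_unity(self):
        cfg = AcquisitionConfig(attenuation_enabled=False)
        assert attenuation_factor(30.0, cfg) == 1.0

    def test_half_value_identity(self):
        # constant mu/rho with (mu/rho)*rho*t = ln 2 transmits exactly one half
        mu = math.log(2.0)  # cm^2/g with rho = 1 g/cm^3 and t = 1 cm
        cfg = AcquisitionConfig(
            sample_thickness=10.0, sample_density=1000.0,
            mass_atten_coeff={20.0: mu, 50.0: mu},
        )
        assert attenuation_factor(35.0, cfg) == pytest.approx(0.5, rel=1e-12)

    def test_monotone_in_energy_for_decreasing_table(self):
        cfg = AcquisitionConfig()
        energies = np.linspace(15.0, 50.0, 40)
        t = attenuation_factor(energies, cfg)
        assert np.all(np.diff(t) > 0)


class TestExpectedCounts:
    def test_zero_exposure_gives_zero_means(self):
        geom = DetectorGeometry(n_rows=4, n_cols=4)
        spec = kramers_spectrum(bin_width=5.0)
        lam = expected_counts(geom, spec, make_pmma_template(), AcquisitionConfig(exposure=0.0))
        assert np.all(lam == 0)

    def test_linear_in_flux_scale(self):
        geom = DetectorGeometry(n_rows=4, n_cols=4, beam_center=(-0.5, -0.5))
        spec = kramers_spectrum(bin_width=5.0)
        a1 = AcquisitionConfig(flux_scale=1000.0)
        a2 = AcquisitionConfig(flux_scale=2000.0)
        lam1 = expected_counts(geom, spec, make_pmma_template(), a1)
        lam2 = expected_counts(geom, spec, make_pmma_template(), a2)
        np.testing.assert_allclose(lam2, 2 * lam1, rtol=1e-12)

    def test_single_cell_hand_computation(self):
        # one off-axis pixel, one energy bin: lambda is the product of five factors
        geom = DetectorGeometry(n_rows=1, n_cols=1, pixel_pitch=0.5, sdd=100.0,
                                beam_center=(0.0, -20.0))  # r = 10 mm
        spec = kramers_spectrum(kvp=50.0, e_min=30.0, bin_width=20.0)  # one bin, centre 40
        tpl = make_pmma_template()
        cfg = AcquisitionConfig(exposure=100.0, flux_scale=500.0, attenuation_enabled=False)
        lam = expected_counts(geom, spec, tpl, cfg)
        two_theta = math.atan(10.0 / 100.0)
        solid = (0.5**2 / 100.0**2) * math.cos(two_theta) ** 3
        q = q_transfer(40.0, two_theta)
        expected = 100.0 * 500.0 * 1.0 * tpl(q) * solid  # fluence = 1 (single bin)
        assert lam[0, 0, 0] == pytest.approx(expected, rel=1e-12)

    def test_blur_conserves_total_mean(self):
        geom = DetectorGeometry(n_rows=6, n_cols=6, beam_center=(-0.5, -0.5))
        spec = kramers_spectrum(bin_width=1.0)
        base = AcquisitionConfig(attenuation_enabled=False)
        blurred = AcquisitionConfig(attenuation_enabled=False, energy_blur_enabled=True,
                                    energy_blur_sigma=1.5)
        lam0 = expected_counts(geom, spec, make_pmma_template(), base)
        lam1 = expected_counts(geom, spec, make_pmma_template(), blurred)
        assert lam1.sum() == pytest.approx(lam0.sum(), rel=1e-9)
        assert not np.allclose(lam0, lam1)

    def test_blur_matrix_rows_are_stochastic(self):
        edges = np.arange(5.0, 51.0, 1.0)
        k = _blur_matrix(edges, 1.0)
        np.testing.assert_allclose(k.sum(axis=1), 1.0, rtol=1e-12)


class TestSampleEvents:
    def _wrap(self, means, seed):
        geom = DetectorGeometry(n_rows=means.shape[0], n_cols=means.shape[1])
        edges = np.arange(means.shape[2] + 1, dtype=float)
        return sample_events(means, seed, energy_bin_edges=edges, exposure=1.0, geometry=geom)

    def test_zero_means_give_zero_counts(self):
        h = self._wrap(np.zeros((3, 3, 2)), seed=7)
        assert h.total_counts == 0

    def test_same_seed_is_bit_identical(self):
        means = np.full((4, 4, 3), 2.5)
        h1 = self._wrap(means, seed=11)
        h2 = self._wrap(means, seed=11)
        np.testing.assert_array_equal(h1.counts, h2.counts)

    def test_poisson_moments_at_lambda_4(self):
        # 10 000 replicate cells at lambda = 4: mean and variance within 3 SE
        means = np.full((100, 100, 1), 4.0)
        h = self._wrap(means, seed=3)
        x = h.counts.ravel().astype(float)
        n = x.size
        se_mean = math.sqrt(4.0 / n)
        se_var = math.sqrt(2 * 4.0**2 / (n - 1) + 4.0 / n)  # approx SE of Poisson variance
        assert abs(x.mean() - 4.0) < 3 * se_mean
        assert abs(x.var(ddof=1) - 4.0) < 3 * se_var

    def test_negative_means_rejected(self):
        with pytest.raises(ValueError):
            self._wrap(np.full((2, 2, 1), -1.0), seed=0)


class TestSimulateAcquisition:
    def _setup(self):
        geom = DetectorGeometry(n_rows=8, n_cols=8, beam_center=(-0.5, -0.5))
        spec = kramers_spectrum(bin_width=5.0)
        cfg = AcquisitionConfig(seed=42, attenuation_enabled=False)
        return geom, spec, cfg

    def test_zero_background_template_gives_empty_histogram(self):
        geom, spec, cfg = self._setup()
        _, bg = simulate_acquisition(make_pmma_template(), zero_template(), geom, spec, cfg)
        assert bg.total_counts == 0

    def test_mixture_means_strictly_exceed_component_means(self):
        geom, spec, cfg = self._setup()
        pmma = make_pmma_template()
        mix = combine([pmma, make_amyloid_template()], [1.0, 1.0])
        lam_mix = expected_counts(geom, spec, mix, cfg)
        lam_pmma = expected_counts(geom, spec, pmma, cfg)
        assert np.all(lam_mix > lam_pmma)  # beam centre off-grid: every cell has q > 0

    def test_subseeds_recorded_and_deterministic(self):
        geom, spec, cfg = self._setup()
        s1, b1 = simulate_acquisition(make_pmma_template(), make_amyloid_template(), geom, spec, cfg)
        s2, b2 = simulate_acquisition(make_pmma_template(), make_amyloid_template(), geom, spec, cfg)
        assert s1.meta["seed_sample"] == 42 and s1.meta["seed_background"] == 43
        assert b1.meta["seed_background"] == 43
        np.testing.assert_array_equal(s1.counts, s2.counts)
        np.testing.assert_array_equal(b1.counts, b2.counts)

    def test_expected_total_scales_linearly_with_exposure(self):
        geom, spec, _ = self._setup()
        lam_1 = expected_counts(geom, spec, make_pmma_template(), AcquisitionConfig(exposure=100.0))
        lam_3 = expected_counts(geom, spec, make_pmma_template(), AcquisitionConfig(exposure=300.0))
        assert lam_3.sum() == pytest.approx(3 * lam_1.sum(), rel=1e-12)


def test_simulate_histogram_provenance(bench):
    h = simulate_histogram(
        make_amyloid_template(), bench.geometry, bench.spectrum, bench.acquisition, seed=5
    )
    assert h.meta["template"] == "amyloid_unheated"
    assert h.meta["seed"] == 5
    assert "config_hash" in h.meta
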