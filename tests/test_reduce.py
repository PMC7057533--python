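"""Reduction chain: windowing, q-binning conservation, background subtraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssaxs.geometry import DetectorGeometry
from ssaxs.materials import ScatteringTemplate, make_amyloid_template
from ssaxs.reduce import (
    QProfile,
    ReductionConfig,
    bin_index,
    fine_config,
    radial_q_binning,
    select_energy_window,
    subtract_background,
)
from ssaxs.simulate import AcquisitionConfig, EventHistogram, expected_counts, kramers_spectrum


def _hist(counts, geom=None, e_lo=5.0):
    counts = np.asarray(counts)
    if geom is None:
        geom = DetectorGeometry(n_rows=counts.shape[0], n_cols=counts.shape[1],
                                beam_center=(-0.5, -0.5))
    edges = e_lo + np.arange(counts.shape[2] + 1, dtype=float)
    return EventHistogram(counts=counts, energy_bin_edges=edges, exposure=1.0, geometry=geom)


class TestEnergyWindow:
    def test_full_window_is_identity(self):
        h = _hist(np.arange(2 * 2 * 5).reshape(2, 2, 5))
        w = select_energy_window(h, (0.0, 100.0))
        np.testing.assert_array_equal(w.counts, h.counts)

    def test_30_to_45_on_unit_grid_keeps_15_bins(self):
        h = _hist(np.ones((2, 2, 45), dtype=int), e_lo=5.0)  # grid 5..50 keV
        w = select_energy_window(h, (30.0, 45.0))
        assert w.counts.shape[2] == 15
        assert w.energy_centers[0] == 30.5 and w.energy_centers[-1] == 44.5

    def test_retained_counts_bounded_by_total(self):
        rng = np.random.default_rng(0)
        h = _hist(rng.poisson(3.0, size=(3, 3, 10)))
        w = select_energy_window(h, (8.0, 12.0))
        assert w.total_counts <= h.total_counts

    def test_empty_overlap_rejected(self):
        h = _hist(np.ones((2, 2, 3), dtype=int))
        with pytest.raises(ValueError):
            select_energy_window(h, (100.0, 110.0))


class TestBinAssignment:
    def test_exact_edge_goes_to_upper_bin(self):
        cfg = ReductionConfig(q_min=1.0, q_max=9.0, q_bin_width=0.5, anchor="edge")
        edges, _ = cfg.bin_grid()
        assert edges[0] == 1.0
        idx = bin_index([1.0, 1.5, 2.0, 1.49999], cfg)
        np.testing.assert_array_equal(idx, [0, 1, 2, 0])

    def test_out_of_range_flagged(self):
        cfg = ReductionConfig(q_min=1.0, q_max=5.0, q_bin_width=1.0, anchor="edge")
        idx = bin_index([0.5, 5.0, 4.999, 1.0], cfg)
        np.testing.assert_array_equal(idx, [-1, -1, 3, 0])

    def test_center_anchor_grid(self):
        cfg = ReductionConfig()  # q_min 1.3, step 1.2, centre-anchored
        _, centers = cfg.bin_grid()
        assert centers[0] == pytest.approx(1.3)
        assert centers[4] == pytest.approx(6.1)
        assert centers[10] == pytest.approx(13.3)


class TestRadialBinning:
    def test_single_photon_lands_in_one_bin(self):
        counts = np.zeros((4, 4, 3), dtype=int)
        counts[2, 3, 1] = 1
        h = _hist(counts, e_lo=30.0)
        cfg = ReductionConfig(energy_window=(30.0, 33.0), q_min=0.1, q_max=10.0,
                              q_bin_width=0.5, normalize_solid_angle=False,
                              normalize_cell_count=False)
        prof = radial_q_binning(h, config=cfg)
        raw = prof.meta["raw_bin_counts"]
        assert raw.sum() == 1
        assert np.count_nonzero(raw) == 1

    @settings(derandomize=True, max_examples=100)
    @given(seed=st.integers(0, 10_000))
    def test_count_conservation_is_exact(self, seed):
        rng = np.random.default_rng(seed)
        h = _hist(rng.poisson(2.0, size=(6, 6, 8)), e_lo=28.0)
        cfg = ReductionConfig(energy_window=(30.0, 34.0), q_min=1.0, q_max=6.0, q_bin_width=0.7)
        prof = radial_q_binning(h, config=cfg)
        raw_total = int(prof.meta["raw_bin_counts"].sum())
        assert raw_total + prof.meta["dropped_counts"] == prof.meta["windowed_total"]

    def test_reduction_is_linear_in_raw_counts(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(2.0, size=(5, 5, 6))
        b = rng.poisson(5.0, size=(5, 5, 6))
        cfg = ReductionConfig(energy_window=(5.0, 11.0), q_min=0.5, q_max=8.0, q_bin_width=0.5)
        raw = lambda arr: radial_q_binning(_hist(arr), config=cfg).meta["raw_bin_counts"]
        np.testing.assert_array_equal(raw(a + b), raw(a) + raw(b))

    def test_shape_mismatch_rejected(self):
        h = _hist(np.ones((3, 3, 4), dtype=int))
        with pytest.raises(ValueError):
            radial_q_binning(h, geom=DetectorGeometry(n_rows=4, n_cols=4))

    def test_flat_template_is_flat_after_solid_angle_normalisation(self, bench):
        # constant-intensity sample, attenuation off: the solid-angle-normalised
        # profile matches the noise-free expectation within Poisson scatter
        flat = ScatteringTemplate(name="flat", baseline=(0.0, 0.0, 5.0))
        cfg = AcquisitionConfig(attenuation_enabled=False, seed=9)
        lam = expected_counts(bench.geometry, bench.spectrum, flat, cfg)
        rng = np.random.default_rng(9)
        h = EventHistogram(counts=rng.poisson(lam), energy_bin_edges=bench.spectrum.energy_bin_edges,
                           exposure=cfg.exposure, geometry=bench.geometry)
        mean_h = EventHistogram(counts=lam, energy_bin_edges=bench.spectrum.energy_bin_edges,
                                exposure=cfg.exposure, geometry=bench.geometry)
        red = ReductionConfig(q_min=2.0, q_max=14.0, normalize_cell_count=False)
        prof = radial_q_binning(h, bench.geometry, red)
        expected = radial_q_binning(mean_h, bench.geometry, red)
        ok = ~prof.is_empty
        # expectation itself is flat to a few percent across fully-sampled bins
        rel_spread = np.ptp(expected.counts[ok]) / np.mean(expected.counts[ok])
        assert rel_spread < 0.05
        z = (prof.counts[ok] - expected.counts[ok]) / prof.sigma[ok]
        assert np.mean(np.abs(z) <= 3.0) >= 0.9
        assert np.max(np.abs(z)) < 5.0

    def test_fine_binned_amyloid_peaks_near_references(self, unheated_fine_profile):
        prof = unheated_fine_profile
        assert prof.meta["windowed_total"] >= 1e5
        from ssaxs.detect import find_peaks

        peaks = sorted(p.q_center for p in find_peaks(prof, min_snr=10))
        assert min(abs(p - 6.2832) for p in peaks) < 0.3
        assert min(abs(p - 13.3685) for p in peaks) < 0.3


class TestSubtraction:
    def _profile(self, counts, sigma=None, n_cells=None, exposure=None):
        n = len(counts)
        meta = {} if exposure is None else {"exposure": exposure}
        return QProfile(
            bin_centers=1.0 + 0.5 * np.arange(n),
            counts=np.asarray(counts, dtype=float),
            sigma=np.asarray(sigma if sigma is not None else np.sqrt(np.abs(counts)), dtype=float),
            n_cells=np.asarray(n_cells if n_cells is not None else np.ones(n), dtype=np.int64),
            meta=meta,
        )

    def test_self_subtraction_identity(self):
        p = self._profile([4.0, 9.0, 16.0])
        out = subtract_background(p, p, scale=1.0)
        np.testing.assert_array_equal(out.counts, 0.0)
        np.testing.assert_allclose(out.sigma, np.sqrt(2.0) * p.sigma, rtol=1e-12)

    def test_zero_scale_returns_sample(self):
        p = self._profile([4.0, 9.0, 16.0])
        b = self._profile([100.0, 100.0, 100.0])
        out = subtract_background(p, b, scale=0.0)
        np.testing.assert_array_equal(out.counts, p.counts)
        np.testing.assert_array_equal(out.sigma, p.sigma)

    def test_default_scale_is_exposure_ratio(self):
        p = self._profile([10.0, 10.0, 10.0], exposure=600.0)
        b = self._profile([2.0, 2.0, 2.0], exposure=1200.0)
        out = subtract_background(p, b)
        np.testing.assert_allclose(out.counts, 10.0 - 0.5 * 2.0)

    def test_negative_values_retained(self):
        p = self._profile([1.0, 1.0, 1.0])
        b = self._profile([5.0, 0.0, 5.0])
        out = subtract_background(p, b, scale=1.0)
        assert out.counts[0] == -4.0

    def test_empty_flags_propagate_as_or(self):
        p = self._profile([1.0, 1.0, 1.0], n_cells=[0, 3, 3])
        b = self._profile([1.0, 1.0, 1.0], n_cells=[3, 0, 3])
        out = subtract_background(p, b, scale=1.0)
        np.testing.assert_array_equal(out.is_empty, [True, True, False])

    def test_mismatched_grids_rejected(self):
        p = self._profile([1.0, 2.0, 3.0])
        q = QProfile(bin_centers=np.array([1.0, 2.0, 3.0]), counts=np.zeros(3),
                     sigma=np.zeros(3), n_cells=np.ones(3, dtype=np.int64))
        with pytest.raises(ValueError):
            subtract_background(p, q)

    def test_end_to_end_phantom_subtraction_recovers_amyloid(self, bench):
        from ssaxs.detect import classify_amyloid, find_peaks
        from ssaxs.materials import make_pmma_template, combine
        from ssaxs.simulate import simulate_acquisition

        pmma = make_pmma_template()
        mix = combine([pmma, make_amyloid_template(variant="unheated")], [1.0, 1.0])
        cfg = AcquisitionConfig(exposure=1200.0, seed=17)
        s, b = simulate_acquisition(mix, pmma, bench.geometry, bench.spectrum, cfg)
        fine = fine_config(bench.reduction)
        corr = subtract_background(
            radial_q_binning(s, bench.geometry, fine),
            radial_q_binning(b, bench.geometry, fine),
        )
        res = classify_amyloid(find_peaks(corr, min_snr=5))
        assert res.is_amyloid
        assert abs(res.sheet_peak.q_center - 6.2832) < 0.3
        assert abs(res.strand_peak.q_center - 13.3685) < 0.3
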