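"""Forward model of the spectral SAXS bench: synthetic photon-count events.

The chain is

    source spectrum Φ(E)  →  sample scattering I(q)  →  detector geometry
    →  expected counts λ(pixel, E)  →  Poisson draw  →  EventHistogram

with

    λ(p, E) = exposure · flux_scale · Φ(E) · T(E) · I(q(E, 2θ_p)) · ΔΩ_p,

where ``T(E) = exp(−(μ/ρ)(E)·ρ·t)`` is optional self-attenuation in the
sample and ``ΔΩ_p`` the pixel solid angle.  The source is an unfiltered
Kramers continuum — the reduction only uses 30–45 keV, where tungsten
characteristic lines play no role.  Counts are binned at the true photon
energy by default; an optional Gaussian energy blur redistributes the means
across energy bins before sampling.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .geometry import AngleMap, DetectorGeometry, compute_angle_map, q_transfer
from .materials import ScatteringTemplate, evaluate_intensity

#: Expected detected photons per second at unit template intensity, chosen so
#: that a 600 s unheated-model syringe run yields ≈5×10⁵ detected photons in
#: the 30–45 keV window under the default bench geometry.  A simulator knob,
#: not a measured quantity.
DEFAULT_FLUX_SCALE = 3.1e5

#: Approximate mass attenuation coefficients μ/ρ in cm²/g, compiled from
#: standard photon cross-section tabulations for a protein-like solid and for
#: PMMA.  Stand-in values adequate for a smooth Beer–Lambert factor; not
#: asserted to match any specific measurement.
MASS_ATTEN_CM2_G = {
    "protein": {20.0: 0.700, 30.0: 0.335, 40.0: 0.245, 50.0: 0.212},
    "pmma": {20.0: 0.571, 30.0: 0.301, 40.0: 0.235, 50.0: 0.208},
}


@dataclass(frozen=True)
class SourceSpectrum:
    """Relative source fluence per energy bin (arbitrary normalisation)."""

    kvp: float
    energy_bin_edges: np.ndarray
    relative_fluence: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.energy_bin_edges, dtype=float)
        flu = np.asarray(self.relative_fluence, dtype=float)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("energy_bin_edges must be strictly increasing, length >= 2")
        if flu.shape != (edges.size - 1,):
            raise ValueError("relative_fluence must have one value per energy bin")
        if np.any(flu < 0):
            raise ValueError("relative_fluence must be non-negative")
        centers = 0.5 * (edges[:-1] + edges[1:])
        if np.any(flu[centers > self.kvp] > 0):
            raise ValueError("fluence must vanish above the kVp endpoint")
        object.__setattr__(self, "energy_bin_edges", edges)
        object.__setattr__(self, "relative_fluence", flu)

    @property
    def energy_centers(self) -> np.ndarray:
        return 0.5 * (self.energy_bin_edges[:-1] + self.energy_bin_edges[1:])


def kramers_spectrum(kvp: float = 50.0, e_min: float = 5.0, bin_width: float = 1.0) -> SourceSpectrum:
    """Unfiltered Kramers bremsstrahlung continuum on a uniform energy grid.

    Relative fluence ∝ (kVp − E)/E at bin centres within [e_min, kVp], zero
    outside, normalised to unit sum.
    """
    if not (0 < e_min < kvp):
        raise ValueError("require 0 < e_min < kvp")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n = int(round((kvp - e_min) / bin_width))
    edges = e_min + bin_width * np.arange(n + 1)
    if edges[-1] < kvp - 1e-9 * kvp:
        edges = np.append(edges, kvp)
    centers = 0.5 * (edges[:-1] + edges[1:])
    flu = np.clip((kvp - centers) / centers, 0.0, None)
    total = flu.sum()
    if total <= 0:
        raise ValueError("spectrum is empty on the requested grid")
    return SourceSpectrum(kvp=kvp, energy_bin_edges=edges, relative_fluence=flu / total)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Exposure, flux, sample attenuation and RNG seed for one acquisition.

    ``sample_thickness`` is the beam path through the sample in mm (6.4 mm
    syringe, 10 mm phantom interior presets), ``sample_density`` the packing
    density in mg/cm³ (677 preset for the protein powder).
    """

    exposure: float = 600.0
    flux_scale: float = DEFAULT_FLUX_SCALE
    sample_thickness: float = 6.4
    sample_density: float = 677.0
    sample_material: str = "protein"
    mass_atten_coeff: dict | None = None
    attenuation_enabled: bool = True
    energy_blur_enabled: bool = False
    energy_blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("exposure", "flux_scale", "sample_thickness", "sample_density"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.energy_blur_sigma <= 0:
            raise ValueError("energy_blur_sigma must be positive")
        if self.mass_atten_coeff is None and self.sample_material not in MASS_ATTEN_CM2_G:
            raise ValueError(
                f"unknown sample_material {self.sample_material!r}; "
                f"provide mass_atten_coeff or one of {sorted(MASS_ATTEN_CM2_G)}"
            )


@dataclass(frozen=True)
class EventHistogram:
    """Photon counts indexed (row, col, energy bin) with acquisition metadata."""

    counts: np.ndarray
    energy_bin_edges: np.ndarray
    exposure: float
    geometry: DetectorGeometry
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        edges = np.asarray(self.energy_bin_edges, dtype=float)
        if counts.ndim != 3:
            raise ValueError("counts must be 3-D (row, col, energy bin)")
        if counts.shape[:2] != self.geometry.shape:
            raise ValueError("counts grid does not match geometry")
        if counts.shape[2] != edges.size - 1:
            raise ValueError("energy axis does not match bin edges")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "energy_bin_edges", edges)
        object.__setattr__(self, "meta", dict(self.meta))

    @property
    def energy_centers(self) -> np.ndarray:
        return 0.5 * (self.energy_bin_edges[:-1] + self.energy_bin_edges[1:])

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


def _mu_rho_table(config: AcquisitionConfig) -> dict:
    table = config.mass_atten_coeff
    if table is None:
        table = MASS_ATTEN_CM2_G[config.sample_material]
    return table


def attenuation_factor(energy, config: AcquisitionConfig):
    """Transmitted fraction exp(−(μ/ρ)(E)·ρ·t) through the sample.

    μ/ρ is log-log interpolated (and extrapolated) on the tabulated
    reference energies.  Returns 1 when attenuation is disabled or the
    sample thickness is zero.
    """
    energy = np.asarray(energy, dtype=float)
    if np.any(energy <= 0):
        raise ValueError("energy must be positive")
    if not config.attenuation_enabled or config.sample_thickness == 0 or config.sample_density == 0:
        out = np.ones_like(energy)
        return out if out.ndim else float(out)
    table = _mu_rho_table(config)
    e_ref = np.array(sorted(table), dtype=float)
    mu_ref = np.array([table[e] for e in sorted(table)], dtype=float)
    log_mu = np.interp(
        np.log(energy), np.log(e_ref), np.log(mu_ref),
    )
    # np.interp clamps outside the table; linear log-log extrapolation below/above:
    lo, hi = np.log(e_ref[0]), np.log(e_ref[-1])
    le = np.log(energy)
    if e_ref.size >= 2:
        slope_lo = (np.log(mu_ref[1]) - np.log(mu_ref[0])) / (np.log(e_ref[1]) - np.log(e_ref[0]))
        slope_hi = (np.log(mu_ref[-1]) - np.log(mu_ref[-2])) / (
            np.log(e_ref[-1]) - np.log(e_ref[-2])
        )
        log_mu = np.where(le < lo, np.log(mu_ref[0]) + slope_lo * (le - lo), log_mu)
        log_mu = np.where(le > hi, np.log(mu_ref[-1]) + slope_hi * (le - hi), log_mu)
    mu_rho = np.exp(log_mu)  # cm²/g
    rho_g_cm3 = config.sample_density / 1000.0
    t_cm = config.sample_thickness / 10.0
    out = np.exp(-mu_rho * rho_g_cm3 * t_cm)
    return out if out.ndim else float(out)


def _blur_matrix(edges: np.ndarray, sigma: float) -> np.ndarray:
    """Row-stochastic kernel redistributing each bin's mean across the grid.

    Row i holds the probability that a photon of true energy = centre_i is
    recorded in each energy bin, renormalised over the grid so that counts
    are conserved (no leakage off the recorded energy axis).
    """
    centers = 0.5 * (edges[:-1] + edges[1:])
    cdf_hi = norm.cdf(edges[None, 1:], loc=centers[:, None], scale=sigma)
    cdf_lo = norm.cdf(edges[None, :-1], loc=centers[:, None], scale=sigma)
    k = cdf_hi - cdf_lo
    return k / k.sum(axis=1, keepdims=True)


def expected_counts(
    geom: DetectorGeometry,
    spectrum: SourceSpectrum,
    template: ScatteringTemplate,
    config: AcquisitionConfig,
    angle_map: AngleMap | None = None,
) -> np.ndarray:
    """Mean detected counts λ(row, col, energy bin) for one acquisition."""
    if angle_map is None:
        angle_map = compute_angle_map(geom)
    e_centers = spectrum.energy_centers
    q = q_transfer(e_centers[None, None, :], angle_map.two_theta[:, :, None])
    intensity = np.zeros_like(q)
    pos = q > 0
    if np.any(pos):
        intensity[pos] = evaluate_intensity(template, q[pos])
    att = attenuation_factor(e_centers, config)
    lam = (
        config.exposure
        * config.flux_scale
        * spectrum.relative_fluence[None, None, :]
        * np.asarray(att)[None, None, :]
        * intensity
        * angle_map.solid_angle[:, :, None]
    )
    if config.energy_blur_enabled:
        k = _blur_matrix(spectrum.energy_bin_edges, config.energy_blur_sigma)
        lam = lam @ k
    return lam


def sample_events(
    means: np.ndarray,
    seed: int,
    *,
    energy_bin_edges: np.ndarray,
    exposure: float,
    geometry: DetectorGeometry,
    meta: dict | None = None,
) -> EventHistogram:
    """Independent Poisson draws per (pixel, energy bin); seeded, reproducible."""
    means = np.asarray(means, dtype=float)
    if np.any(~np.isfinite(means)) or np.any(means < 0):
        raise ValueError("means must be finite and non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(means).astype(np.int64)
    full_meta = {"seed": int(seed)}
    if meta:
        full_meta.update(meta)
    return EventHistogram(
        counts=counts,
        energy_bin_edges=energy_bin_edges,
        exposure=exposure,
        geometry=geometry,
        meta=full_meta,
    )


def config_hash(config: AcquisitionConfig) -> str:
    """Short stable hash of the acquisition settings, for provenance."""
    payload = repr(config).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def simulate_histogram(
    template: ScatteringTemplate,
    geom: DetectorGeometry,
    spectrum: SourceSpectrum,
    config: AcquisitionConfig,
    seed: int | None = None,
) -> EventHistogram:
    """Convenience: expected counts then one Poisson draw, with provenance."""
    if seed is None:
        seed = config.seed
    lam = expected_counts(geom, spectrum, template, config)
    return sample_events(
        lam,
        seed,
        energy_bin_edges=spectrum.energy_bin_edges,
        exposure=config.exposure,
        geometry=geom,
        meta={"template": template.name, "config_hash": config_hash(config)},
    )


def simulate_acquisition(
    sample_template: ScatteringTemplate,
    background_template: ScatteringTemplate,
    geom: DetectorGeometry,
    spectrum: SourceSpectrum,
    config: AcquisitionConfig,
) -> tuple[EventHistogram, EventHistogram]:
    """Paired sample / background acquisitions with matched exposure.

    Sub-seeds are derived deterministically from ``config.seed``: the sample
    draw uses ``seed`` and the background draw ``seed + 1``; both are recorded
    in each histogram's metadata.
    """
    seed_sample = int(config.seed)
    seed_background = seed_sample + 1
    sample = simulate_histogram(sample_template, geom, spectrum, config, seed=seed_sample)
    background = simulate_histogram(background_template, geom, spectrum, config, seed=seed_background)
    for h in (sample, background):
        h.meta.update({"seed_sample": seed_sample, "seed_background": seed_background})
    return sample, background


def with_seed(config: AcquisitionConfig, seed: int) -> AcquisitionConfig:
    """Copy of an acquisition config with a different seed."""
    return replace(config, seed=int(seed))
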