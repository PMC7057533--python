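"""Detector geometry and the energy-angle-to-momentum-transfer mapping.

An energy-dispersive SAXS bench records, for each photon, a pixel position
(hence a scattering angle ``2θ`` given the sample-to-detector distance) and
an energy ``E``.  The two combine into the momentum transfer

    q = 4π E sin(θ) / hc,    hc = 1.24 keV nm,

so a polychromatic beam plus a spectroscopic pixel detector samples a wide
q-range without moving anything.  Real-space periodicities follow from
``d = 2π/q``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Planck constant times speed of light in keV·nm, as used on the bench.
HC_KEV_NM = 1.24


@dataclass(frozen=True)
class DetectorGeometry:
    """Pixelated detector geometry for a pencil-beam scattering setup.

    Parameters
    ----------
    n_rows, n_cols
        Pixel grid shape (default 80×80, an energy-resolving CdTe array).
    pixel_pitch
        Pixel pitch in mm.  0.25 mm is standard for this detector class.
    sdd
        Sample-to-detector distance in mm.
    beam_center
        (row, col) of the direct-beam axis in fractional 0-based pixel
        coordinates.  May lie outside the grid (offset detector).  ``None``
        selects the geometric centre of the grid.
    """

    n_rows: int = 80
    n_cols: int = 80
    pixel_pitch: float = 0.25
    sdd: float = 214.0
    beam_center: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("detector grid must have at least one pixel")
        for name in ("pixel_pitch", "sdd"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"invalid geometry: {name} must be finite and > 0, got {v}")
        bc = self.beam_center
        if bc is None:
            bc = ((self.n_rows - 1) / 2.0, (self.n_cols - 1) / 2.0)
        bc = (float(bc[0]), float(bc[1]))
        if not (math.isfinite(bc[0]) and math.isfinite(bc[1])):
            raise ValueError("invalid geometry: beam_center must be finite")
        object.__setattr__(self, "beam_center", bc)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def corner_radius(self) -> float:
        """Largest pixel-centre distance from the beam axis, in mm."""
        rows = np.array([0.0, self.n_rows - 1.0])
        cols = np.array([0.0, self.n_cols - 1.0])
        dr = (rows - self.beam_center[0]) * self.pixel_pitch
        dc = (cols - self.beam_center[1]) * self.pixel_pitch
        return float(np.max(np.hypot(dr[:, None], dc[None, :])))


@dataclass(frozen=True)
class AngleMap:
    """Per-pixel scattering angle (rad) and subtended solid angle (sr)."""

    two_theta: np.ndarray
    solid_angle: np.ndarray

    def __post_init__(self) -> None:
        if self.two_theta.shape != self.solid_angle.shape:
            raise ValueError("two_theta and solid_angle must share a shape")


def compute_angle_map(geom: DetectorGeometry) -> AngleMap:
    """Scattering angle and solid angle of every pixel centre.

    Uses the pixel-centre point approximation: for a pixel whose centre sits
    a radial distance ``r`` from the beam axis, ``2θ = atan(r / sdd)`` and the
    subtended solid angle is ``(pitch² / sdd²)·cos³(2θ)`` (inverse-square
    distance plus obliquity).
    """
    rows = (np.arange(geom.n_rows) - geom.beam_center[0]) * geom.pixel_pitch
    cols = (np.arange(geom.n_cols) - geom.beam_center[1]) * geom.pixel_pitch
    r = np.hypot(rows[:, None], cols[None, :])
    two_theta = np.arctan(r / geom.sdd)
    solid_angle = (geom.pixel_pitch**2 / geom.sdd**2) * np.cos(two_theta) ** 3
    return AngleMap(two_theta=two_theta, solid_angle=solid_angle)


def q_transfer(energy, two_theta):
    """Momentum transfer q = 4π·E·sin(2θ/2)/hc in nm⁻¹.

    ``energy`` in keV, ``two_theta`` in radians; both may be arrays
    (broadcast).  Valid for ``energy > 0`` and ``0 ≤ 2θ < π``.
    """
    energy = np.asarray(energy, dtype=float)
    two_theta = np.asarray(two_theta, dtype=float)
    if np.any(energy <= 0):
        raise ValueError("energy must be positive")
    if np.any(two_theta < 0) or np.any(two_theta >= np.pi):
        raise ValueError("two_theta must lie in [0, pi)")
    q = 4.0 * np.pi * energy * np.sin(two_theta / 2.0) / HC_KEV_NM
    return q if q.ndim else float(q)


def d_spacing(q):
    """Real-space spacing d = 2π/q in nm for q in nm⁻¹ (q > 0)."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be positive")
    d = 2.0 * np.pi / q
    return d if d.ndim else float(d)


def accessible_q_range(
    geom: DetectorGeometry,
    energy_window: tuple[float, float],
    r_min: float = 0.0,
) -> tuple[float, float]:
    """q-range reachable by the detector within an energy window.

    The smallest q pairs the window's low edge with the innermost usable
    radius ``r_min`` (beam-stop / direct-beam exclusion, mm); the largest q
    pairs the high edge with the farthest pixel centre.
    """
    e_lo, e_hi = energy_window
    if not (e_lo < e_hi):
        raise ValueError("energy window must be ordered (low < high)")
    if r_min < 0:
        raise ValueError("r_min must be non-negative")
    q_min = q_transfer(e_lo, math.atan(r_min / geom.sdd))
    q_max = q_transfer(e_hi, math.atan(geom.corner_radius() / geom.sdd))
    return (q_min, q_max)
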