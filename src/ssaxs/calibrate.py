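"""Geometry calibration against a powder calibrant with known d-spacings.

A powder with known Bragg spacings d_i scatters rings at q_i = 2π/d_i.  On
an energy-dispersive bench the dominant geometric unknown is the
sample-to-detector distance (SDD), which rescales every pixel's scattering
angle and hence every observed q.  Calibration re-reduces the calibrant
histogram at fine binning under candidate SDDs, finds the peaks, matches
them to the reference positions and minimises the summed squared mismatch.
Beam-centre refinement (two extra parameters, derivative-free simplex) is
optional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .detect import find_peaks
from .geometry import DetectorGeometry
from .reduce import ReductionConfig, fine_config, radial_q_binning
from .simulate import EventHistogram


class CalibrationError(RuntimeError):
    """Raised when the calibrant data cannot constrain the geometry."""


@dataclass(frozen=True)
class CalibrationResult:
    refined_sdd: float
    refined_beam_center: tuple[float, float]
    residual: float  # RMS of matched (q_obs − q_ref), nm⁻¹
    n_peaks_used: int

    def __post_init__(self) -> None:
        if self.refined_sdd <= 0:
            raise ValueError("refined_sdd must be positive")
        if self.residual < 0:
            raise ValueError("residual must be non-negative")


def match_reference_peaks(
    observed_peaks,
    reference_d,
    tolerance: float = 1.0,
):
    """One-to-one greedy nearest matching of observed q to reference 2π/d.

    Returns ``(pairs, unmatched_refs)`` with ``pairs`` a list of
    ``(q_reference, q_observed)``.  Candidate pairs are taken in order of
    increasing distance; at equal distance the lower-q observed peak wins.
    Raises :class:`CalibrationError` when nothing matches within tolerance.
    """
    obs = [float(q) for q in observed_peaks]
    refs = [2.0 * math.pi / float(d) for d in reference_d]
    if not obs or not refs:
        raise ValueError("observed_peaks and reference_d must be non-empty")
    cands = sorted(
        ((abs(o - r), o, ri) for ri, r in enumerate(refs) for o in obs),
        key=lambda t: (t[0], t[1]),
    )
    used_obs: set[float] = set()
    matched: dict[int, float] = {}
    for dist, o, ri in cands:
        if dist > tolerance or ri in matched or o in used_obs:
            continue
        matched[ri] = o
        used_obs.add(o)
    if not matched:
        raise CalibrationError(
            f"no observed peak within {tolerance} nm^-1 of any reference position"
        )
    pairs = [(refs[ri], matched[ri]) for ri in sorted(matched)]
    unmatched = [refs[ri] for ri in range(len(refs)) if ri not in matched]
    return pairs, unmatched


def _mismatch(
    hist: EventHistogram,
    geom: DetectorGeometry,
    reference_d,
    reduction: ReductionConfig,
    tolerance: float,
    min_snr: float,
):
    """(cost, pairs) for one candidate geometry; unmatched refs are penalised."""
    profile = radial_q_binning(hist, geom, reduction)
    try:
        peaks = find_peaks(profile, min_snr=min_snr, fit_refine=True)
    except ValueError:
        return math.inf, []
    if not peaks:
        return math.inf, []
    try:
        pairs, unmatched = match_reference_peaks(
            [p.q_center for p in peaks], reference_d, tolerance
        )
    except CalibrationError:
        return math.inf, []
    cost = sum((o - r) ** 2 for r, o in pairs) + tolerance**2 * len(unmatched)
    return cost, pairs


def calibrate_sdd(
    hist: EventHistogram,
    geom0: DetectorGeometry,
    reference_d,
    reduction: ReductionConfig | None = None,
    *,
    match_tolerance: float = 1.0,
    min_snr: float = 3.0,
    refine_beam_center: bool = False,
    n_grid: int = 121,
) -> CalibrationResult:
    """Refine the SDD from a calibrant acquisition.

    The SDD is scanned on a grid over the bracket [0.5·sdd0, 2·sdd0]
    (peak-matching makes the objective non-convex, so a global scan precedes
    local refinement by bounded scalar minimisation).  With
    ``refine_beam_center`` a Nelder–Mead simplex then polishes
    (SDD, beam-centre row, beam-centre col) jointly.
    """
    if reduction is None:
        reduction = fine_config()
    reference_d = list(reference_d)
    if not reference_d or any(d <= 0 for d in reference_d):
        raise ValueError("reference_d must be non-empty and positive")

    def cost_at(sdd: float, bc=None) -> float:
        geom = replace(geom0, sdd=float(sdd), beam_center=bc or geom0.beam_center)
        return _mismatch(hist, geom, reference_d, reduction, match_tolerance, min_snr)[0]

    lo, hi = 0.5 * geom0.sdd, 2.0 * geom0.sdd
    grid = np.linspace(lo, hi, n_grid)
    costs = np.array([cost_at(s) for s in grid])
    if not np.any(np.isfinite(costs)):
        raise CalibrationError("no matched peaks at any candidate SDD in the bracket")
    best = int(np.argmin(costs))
    b_lo = grid[max(best - 1, 0)]
    b_hi = grid[min(best + 1, n_grid - 1)]
    res = minimize_scalar(cost_at, bounds=(b_lo, b_hi), method="bounded", options={"xatol": 1e-3})
    sdd_star = float(res.x) if res.fun <= costs[best] else float(grid[best])
    bc_star = geom0.beam_center

    if refine_beam_center:
        x0 = np.array([sdd_star, *geom0.beam_center])
        nm = minimize(
            lambda x: cost_at(x[0], (x[1], x[2])),
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-10, "maxiter": 400},
        )
        if math.isfinite(nm.fun) and nm.fun <= cost_at(sdd_star):
            sdd_star = float(nm.x[0])
            bc_star = (float(nm.x[1]), float(nm.x[2]))

    geom_star = replace(geom0, sdd=sdd_star, beam_center=bc_star)
    cost, pairs = _mismatch(hist, geom_star, reference_d, reduction, match_tolerance, min_snr)
    if not pairs:
        raise CalibrationError("calibration did not converge to a peak-matched geometry")
    residual = math.sqrt(sum((o - r) ** 2 for r, o in pairs) / len(pairs))
    return CalibrationResult(
        refined_sdd=sdd_star,
        refined_beam_center=bc_star,
        residual=residual,
        n_peaks_used=len(pairs),
    )
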