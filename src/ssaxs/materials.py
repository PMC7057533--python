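"""Parametric relative-intensity templates I(q) for the bench samples.

Each sample is modelled as a smooth decaying background plus Gaussian peaks:

    I(q) = Σ_k [ a_k·q^(−b_k) + c_k ]  +  Σ_j A_j·exp(−4 ln2 (q − q_j)² / w_j²)

with peak centre ``q_j``, FWHM ``w_j`` and amplitude ``A_j`` in relative
units.  Presets cover the materials measured on the bench:

* cross-β amyloid models (heated / unheated protein aggregates) with the two
  signature peaks at 2π/d for the β-sheet spacing (d ≈ 1.0 nm) and β-strand
  spacing (d ≈ 0.47 nm);
* PMMA, an amorphous scatterer with a broad halo near 9.64 nm⁻¹;
* a powder calibrant (caffeine-like) with narrow Bragg peaks at user-supplied
  d-spacings.

Templates are purely relative: absolute count levels come from the
acquisition model (exposure, flux, solid angle) in :mod:`ssaxs.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Default cross-β real-space spacings, nm (β-sheet, β-strand).
D_SHEET_NM = 1.0
D_STRAND_NM = 0.47

#: Corresponding momentum-transfer centres, nm⁻¹.
Q_SHEET = 2.0 * math.pi / D_SHEET_NM  # 6.2832
Q_STRAND = 2.0 * math.pi / D_STRAND_NM  # 13.3685

#: PMMA amorphous-halo centre, nm⁻¹.
Q_PMMA_HALO = 9.64

#: Stand-in reference d-spacings (nm) for the powder calibrant.  These are a
#: configurable default, not literature values; calibration treats them purely
#: as input and tests use synthetic lists.
DEFAULT_CAFFEINE_D_NM = (0.75, 0.42, 0.32)

#: Peak widths (FWHM, nm⁻¹): the unheated aggregate shows sharper cross-β
#: peaks than the heated one.
FWHM_UNHEATED = 0.8
FWHM_HEATED = 1.4

#: Concentration presets for the heated model, mg/ml → β-sheet signal fraction.
CONCENTRATION_PRESETS = {20.0: 0.5, 30.0: 0.75, 40.0: 1.0}

_DEFAULT_BASELINE = (50.0, 1.5, 1.0)
_AMYLOID_PEAK_AMPLITUDE = 12.0


@dataclass(frozen=True)
class GaussPeak:
    """One Gaussian peak: centre (nm⁻¹), FWHM (nm⁻¹), relative amplitude."""

    center: float
    fwhm: float
    amplitude: float

    def __post_init__(self) -> None:
        for name in ("center", "fwhm", "amplitude"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"peak {name} must be finite")
        if self.center <= 0 or self.fwhm <= 0:
            raise ValueError("peak center and fwhm must be positive")
        if self.amplitude < 0:
            raise ValueError("peak amplitude must be non-negative")


@dataclass(frozen=True)
class ScatteringTemplate:
    """Relative scattering intensity model: baseline terms plus peaks.

    ``baseline`` may be a single ``(a, b, c)`` triple or a sequence of
    triples; mixtures produced by :func:`combine` carry one scaled triple per
    component so that evaluation stays exactly linear.
    """

    name: str
    baseline: tuple = _DEFAULT_BASELINE
    peaks: tuple[GaussPeak, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        bl = self.baseline
        if bl and np.isscalar(bl[0]):
            bl = (tuple(float(x) for x in bl),)
        else:
            bl = tuple(tuple(float(x) for x in term) for term in bl)
        for a, b, c in bl:
            if a < 0 or b < 0 or c < 0:
                raise ValueError("baseline coefficients must be non-negative")
        object.__setattr__(self, "baseline", bl)
        object.__setattr__(self, "peaks", tuple(self.peaks))

    def __call__(self, q):
        return evaluate_intensity(self, q)


def evaluate_intensity(template: ScatteringTemplate, q):
    """Evaluate I(q) (relative units) at q > 0 in nm⁻¹; deterministic."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be positive")
    out = np.zeros_like(q)
    for a, b, c in template.baseline:
        out = out + a * q ** (-b) + c
    for p in template.peaks:
        out = out + p.amplitude * np.exp(-4.0 * math.log(2.0) * (q - p.center) ** 2 / p.fwhm**2)
    return out if out.ndim else float(out)


def make_amyloid_template(
    beta_sheet_fraction: float = 1.0,
    variant: str = "unheated",
    *,
    d_sheet: float = D_SHEET_NM,
    d_strand: float = D_STRAND_NM,
    peak_amplitude: float = _AMYLOID_PEAK_AMPLITUDE,
    baseline: tuple = _DEFAULT_BASELINE,
) -> ScatteringTemplate:
    """Cross-β amyloid-model template with peaks at 2π/d_sheet and 2π/d_strand.

    Peak amplitudes scale linearly with ``beta_sheet_fraction`` (the handle
    that emulates changing protein concentration); the unheated variant uses
    sharper peaks than the heated one.
    """
    if not 0.0 <= beta_sheet_fraction <= 1.0:
        raise ValueError("beta_sheet_fraction must lie in [0, 1]")
    if variant not in ("heated", "unheated"):
        raise ValueError(f"unknown variant {variant!r}; expected 'heated' or 'unheated'")
    fwhm = FWHM_UNHEATED if variant == "unheated" else FWHM_HEATED
    amp = peak_amplitude * beta_sheet_fraction
    peaks = (
        GaussPeak(center=2.0 * math.pi / d_sheet, fwhm=fwhm, amplitude=amp),
        GaussPeak(center=2.0 * math.pi / d_strand, fwhm=fwhm, amplitude=amp),
    )
    return ScatteringTemplate(name=f"amyloid_{variant}", baseline=baseline, peaks=peaks)


def make_pmma_template(
    *,
    halo_center: float = Q_PMMA_HALO,
    halo_fwhm: float = 2.5,
    halo_amplitude: float = 8.0,
    baseline: tuple = _DEFAULT_BASELINE,
) -> ScatteringTemplate:
    """PMMA template: one broad amorphous halo near 9.64 nm⁻¹ over baseline."""
    peaks = (GaussPeak(center=halo_center, fwhm=halo_fwhm, amplitude=halo_amplitude),)
    return ScatteringTemplate(name="pmma", baseline=baseline, peaks=peaks)


def make_caffeine_template(
    reference_d=DEFAULT_CAFFEINE_D_NM,
    *,
    fwhm: float = 0.3,
    amplitude: float = 20.0,
    baseline: tuple = _DEFAULT_BASELINE,
) -> ScatteringTemplate:
    """Powder-calibrant template: narrow Bragg peaks at q_i = 2π/d_i."""
    reference_d = tuple(float(d) for d in reference_d)
    if not reference_d:
        raise ValueError("reference_d must be non-empty")
    if any(d <= 0 for d in reference_d):
        raise ValueError("reference d-spacings must be positive")
    peaks = tuple(
        GaussPeak(center=2.0 * math.pi / d, fwhm=fwhm, amplitude=amplitude) for d in reference_d
    )
    return ScatteringTemplate(name="caffeine", baseline=baseline, peaks=peaks)


def make_baseline_template(baseline: tuple = _DEFAULT_BASELINE) -> ScatteringTemplate:
    """Peak-free template (instrument/parasitic background stand-in)."""
    return ScatteringTemplate(name="baseline", baseline=baseline, peaks=())


def zero_template() -> ScatteringTemplate:
    """Template that evaluates to zero everywhere."""
    return ScatteringTemplate(name="zero", baseline=(0.0, 0.0, 0.0), peaks=())


def combine(templates, weights, name: str | None = None) -> ScatteringTemplate:
    """Linear mixture: evaluate(result, q) == Σ w_i · evaluate(template_i, q).

    Baseline terms and peaks are scaled and concatenated, so linearity holds
    to machine precision even across different power-law exponents.
    """
    templates = list(templates)
    weights = [float(w) for w in weights]
    if len(templates) != len(weights):
        raise ValueError("templates and weights must have equal length")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be non-negative")
    baseline = []
    peaks = []
    for t, w in zip(templates, weights):
        for a, b, c in t.baseline:
            baseline.append((w * a, b, w * c))
        for p in t.peaks:
            peaks.append(GaussPeak(center=p.center, fwhm=p.fwhm, amplitude=w * p.amplitude))
    if name is None:
        name = "+".join(t.name for t in templates)
    return ScatteringTemplate(name=name, baseline=tuple(baseline), peaks=tuple(peaks))


def concentration_to_fraction(concentration_mg_ml: float) -> float:
    """Map a heated-model preparation concentration preset to signal fraction.

    Presets 20/30/40 mg/ml map linearly to 0.5/0.75/1.0; intermediate values
    interpolate on the same line (fraction = concentration / 40), clipped to
    [0, 1].
    """
    if concentration_mg_ml < 0:
        raise ValueError("concentration must be non-negative")
    return float(min(1.0, concentration_mg_ml / 40.0))
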