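#!/usr/bin/env python
"""Phantom study: unheated amyloid model inside the PMMA cylinder.

Simulates paired 1200 s acquisitions (PMMA+amyloid vs PMMA-only), reduces
both, subtracts the phantom background, and reports the PMMA halo and the
recovered cross-β peaks.  Writes results/phantom_study.csv plus the
uncorrected and corrected profiles as text.
"""

from pathlib import Path

import pandas as pd

from ssaxs import io as ssio
from ssaxs.config import build_run_config
from ssaxs.detect import classify_amyloid, find_peaks
from ssaxs.pipeline import run_phantom_study
from ssaxs.reduce import fine_config, radial_q_binning
from ssaxs.materials import make_pmma_template
from ssaxs.simulate import AcquisitionConfig, simulate_histogram

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = build_run_config({"acquisition": {"seed": 31}})
    corrected, result = run_phantom_study(cfg)
    ssio.write_qprofile(corrected, RESULTS / "phantom_corrected_profile.txt")

    # PMMA-only reference: the uncorrected phantom halo
    acq = AcquisitionConfig(exposure=1200.0, sample_material="pmma",
                            sample_thickness=10.0, sample_density=1190.0, seed=32)
    pmma_hist = simulate_histogram(make_pmma_template(), cfg.geometry, cfg.spectrum, acq)
    pmma_fine = radial_q_binning(pmma_hist, cfg.geometry, fine_config(cfg.reduction))
    ssio.write_qprofile(pmma_fine, RESULTS / "phantom_pmma_only_profile.txt")
    halo = max(find_peaks(pmma_fine, min_snr=5), key=lambda p: p.prominence)
    pmma_only = classify_amyloid(find_peaks(pmma_fine, min_snr=5))

    table = pd.DataFrame(
        [
            {
                "scene": "pmma_only",
                "is_amyloid": pmma_only.is_amyloid,
                "halo_q": halo.q_center,
                "sheet_peak_q": None,
                "strand_peak_q": None,
            },
            {
                "scene": "pmma+unheated, background-subtracted",
                "is_amyloid": result.is_amyloid,
                "halo_q": None,
                "sheet_peak_q": result.sheet_peak.q_center if result.sheet_peak else None,
                "strand_peak_q": result.strand_peak.q_center if result.strand_peak else None,
            },
        ]
    )
    table.to_csv(RESULTS / "phantom_study.csv", index=False)
    print(table.to_string(index=False))
    print(
        f"\nPMMA alone shows only its halo near {halo.q_center:.2f} nm^-1 and never "
        "classifies as amyloid; after subtracting the PMMA-only background the "
        "cross-beta pair is recovered despite the strong phantom scattering."
    )


if __name__ == "__main__":
    main()
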