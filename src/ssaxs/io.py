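"""File formats: HDF5 event histograms and text Q-profiles.

EventHistogram container (HDF5): datasets ``counts`` (int,
[n_rows, n_cols, n_energy_bins]), ``energy_bin_edges_keV``, ``exposure_s``;
group ``meta`` with geometry attributes and provenance.  QProfile: delimited
text with '#'-prefixed header lines carrying provenance, then rows
``q_center counts sigma n_cells``; round-trips losslessly at 9 significant
digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .geometry import DetectorGeometry
from .reduce import QProfile
from .simulate import EventHistogram

FORMAT_VERSION = 1

_HIST_DATASETS = ("counts", "energy_bin_edges_keV", "exposure_s")


def write_event_histogram(hist: EventHistogram, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.create_dataset("counts", data=np.asarray(hist.counts, dtype=np.int64))
        f.create_dataset("energy_bin_edges_keV", data=hist.energy_bin_edges)
        f.create_dataset("exposure_s", data=float(hist.exposure))
        g = f.create_group("meta")
        geom = hist.geometry
        g.attrs["n_rows"] = geom.n_rows
        g.attrs["n_cols"] = geom.n_cols
        g.attrs["pixel_pitch_mm"] = geom.pixel_pitch
        g.attrs["sdd_mm"] = geom.sdd
        g.attrs["beam_center_row"] = geom.beam_center[0]
        g.attrs["beam_center_col"] = geom.beam_center[1]
        g.attrs["provenance"] = json.dumps(hist.meta, default=str)


def read_event_histogram(path) -> EventHistogram:
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in _HIST_DATASETS:
            if name not in f:
                raise ValueError(f"{path}: missing dataset {name!r}")
        if "meta" not in f:
            raise ValueError(f"{path}: missing group 'meta'")
        g = f["meta"]
        geom = DetectorGeometry(
            n_rows=int(g.attrs["n_rows"]),
            n_cols=int(g.attrs["n_cols"]),
            pixel_pitch=float(g.attrs["pixel_pitch_mm"]),
            sdd=float(g.attrs["sdd_mm"]),
            beam_center=(float(g.attrs["beam_center_row"]), float(g.attrs["beam_center_col"])),
        )
        meta = json.loads(g.attrs.get("provenance", "{}"))
        return EventHistogram(
            counts=f["counts"][...],
            energy_bin_edges=f["energy_bin_edges_keV"][...],
            exposure=float(f["exposure_s"][()]),
            geometry=geom,
            meta=meta,
        )


def write_qprofile(profile: QProfile, path) -> None:
    path = Path(path)
    lines = [f"# ssaxs qprofile format_version={FORMAT_VERSION}"]
    for key in sorted(profile.meta):
        val = profile.meta[key]
        if isinstance(val, np.ndarray):
            continue  # raw per-bin arrays are derivable; keep the header scalar
        lines.append(f"# {key}={val}")
    lines.append("# columns: q_center counts sigma n_cells")
    for q, c, s, n in zip(profile.bin_centers, profile.counts, profile.sigma, profile.n_cells):
        lines.append(f"{q:.9g} {c:.9g} {s:.9g} {int(n)}")
    path.write_text("\n".join(lines) + "\n")


def read_qprofile(path) -> QProfile:
    path = Path(path)
    meta: dict = {}
    q, c, s, n = [], [], [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body and not body.startswith("columns"):
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
        try:
            q.append(float(parts[0]))
            c.append(float(parts[1]))
            s.append(float(parts[2]))
            n.append(int(parts[3]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparsable row: {exc}") from exc
    if not q:
        raise ValueError(f"{path}: no data rows found")
    q_arr = np.array(q)
    if np.any(np.diff(q_arr) <= 0):
        raise ValueError(f"{path}: q_center column must be strictly increasing")
    return QProfile(
        bin_centers=q_arr, counts=np.array(c), sigma=np.array(s),
        n_cells=np.array(n, dtype=np.int64), meta=meta,
    )


def write_detection_report(result, path) -> None:
    """Machine-readable key-value detection report."""
    path = Path(path)
    lines = [
        f"format_version={FORMAT_VERSION}",
        f"is_amyloid={str(result.is_amyloid).lower()}",
        f"signal_strength={result.signal_strength:.6g}",
        f"n_peaks={len(result.peaks)}",
    ]
    for tag, peak in (("sheet", result.sheet_peak), ("strand", result.strand_peak)):
        if peak is not None:
            lines.append(f"{tag}_peak_q={peak.q_center:.6g}")
            lines.append(f"{tag}_peak_snr={peak.snr:.6g}")
    for i, p in enumerate(result.peaks):
        lines.append(f"peak_{i}=q:{p.q_center:.6g} height:{p.height:.6g} snr:{p.snr:.6g}")
    path.write_text("\n".join(lines) + "\n")
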