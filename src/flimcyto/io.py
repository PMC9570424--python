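"""Reading and writing TCSPC stacks, lifetime maps and cohort bundles.

Stacks travel as multi-page TIFF (one page per time bin, unsigned 16-bit
counts) or HDF5 (dataset ``counts``, dims y, x, t); lifetime maps as a
4-layer 32-bit float TIFF (tm, a2, t2, intensity) with a JSON fit report.
A cohort directory holds one stack per image, a JSON ground-truth sidecar
and a CSV manifest.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .containers import LifetimeMaps, TCSPCImage

__all__ = ["write_stack", "read_stack", "write_stack_h5", "read_stack_h5",
           "write_maps", "read_maps", "write_cohort", "read_cohort_manifest"]


def write_stack(image: TCSPCImage, path) -> None:
    """Multi-page TIFF, pages = time bins, uint16 counts; sidecar JSON
    carries the bin width and metadata."""
    path = Path(path)
    pages = np.moveaxis(image.counts.astype(np.uint16), 2, 0)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {"bin_width_ps": image.bin_width_ps, "meta": image.meta}
    path.with_suffix(".json").write_text(json.dumps(sidecar, default=float))


def read_stack(path, bin_width_ps: float | None = None) -> TCSPCImage:
    path = Path(path)
    pages = tifffile.imread(path)
    counts = np.moveaxis(pages, 0, 2)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        bin_width_ps = bin_width_ps or info.get("bin_width_ps")
        meta = info.get("meta", {})
    if bin_width_ps is None:
        raise ValueError(f"no bin width for {path}; pass bin_width_ps")
    return TCSPCImage(counts=counts, bin_width_ps=float(bin_width_ps),
                      meta=meta)


def write_stack_h5(image: TCSPCImage, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("counts", data=image.counts.astype(np.uint16))
        d.attrs["bin_width_ps"] = image.bin_width_ps


def read_stack_h5(path) -> TCSPCImage:
    with h5py.File(path, "r") as f:
        d = f["counts"]
        return TCSPCImage(counts=d[()].astype(np.int64),
                          bin_width_ps=float(d.attrs["bin_width_ps"]))


def write_maps(maps: LifetimeMaps, path) -> None:
    """4-layer float32 TIFF (tm, a2, t2, intensity) + JSON fit report.

    Invalid pixels carry zeros in every layer; on read, validity is
    recovered as ``tm > 0`` (valid fits always have tm >= t1 > 0).
    """
    path = Path(path)
    layers = np.stack([
        np.where(maps.valid, maps.tm_ps, 0.0),
        np.where(maps.valid, maps.a2_frac, 0.0),
        np.where(maps.valid, maps.t2_ps, 0.0),
        maps.intensity.astype(np.float64),
    ]).astype(np.float32)
    tifffile.imwrite(path, layers, photometric="minisblack")
    report = {"t1_ps": maps.t1_ps, "n_valid": int(maps.valid.sum()),
              "shape": list(maps.shape), "meta": maps.meta}
    path.with_suffix(".json").write_text(json.dumps(report, default=float))


def read_maps(path) -> LifetimeMaps:
    path = Path(path)
    layers = tifffile.imread(path).astype(np.float64)
    t1_ps, meta = 460.0, {}
    report_path = path.with_suffix(".json")
    if report_path.exists():
        report = json.loads(report_path.read_text())
        t1_ps = float(report.get("t1_ps", t1_ps))
        meta = report.get("meta", {})
    tm, a2, t2, intensity = layers
    return LifetimeMaps(tm_ps=tm, a2_frac=a2, t2_ps=t2, intensity=intensity,
                        valid=tm > 0, t1_ps=t1_ps, meta=meta)


def write_cohort(bundle, out_dir) -> Path:
    """One TIFF stack + ground-truth JSON per image, plus a CSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for patient in bundle.patients:
        for rec in patient.images:
            stack_path = out_dir / f"{rec.image_id}.tif"
            write_stack(rec.image, stack_path)
            truth = {
                "image_id": rec.image_id,
                "truth_label": rec.truth_label,
                "origin_group": rec.origin_group,
                "phantoms": [
                    {"center": list(p.center), "axes": list(p.axes),
                     "orientation": p.orientation,
                     "nucleus_fraction": p.nucleus_fraction,
                     "a2_frac": p.a2_frac, "t2_ps": p.t2_ps,
                     "amplitude": p.amplitude}
                    for p in rec.phantoms],
            }
            (out_dir / f"{rec.image_id}.truth.json").write_text(
                json.dumps(truth, default=float))
            rows.append({"patient_id": patient.patient_id,
                         "group": patient.group,
                         "image_id": rec.image_id,
                         "path": stack_path.name})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort_manifest(manifest_path) -> pd.DataFrame:
    return pd.read_csv(manifest_path)
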