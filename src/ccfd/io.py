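"""Standard-format I/O for scan bundles.

One directory per eye per visit with the layout::

    flow.tiff       16-bit grayscale flow image
    structure.tiff  16-bit grayscale structure image
    mnv.png         8-bit binary MNV mask (0/255)
    halo.png        8-bit binary dark-halo mask
    vessels.png     8-bit binary retinal-vessel mask (optional)
    meta.json       pixel_scale_um, eye_id, timepoint, signal_strength
    truth.json      planted ground-truth summary (synthetic bundles only)
    deficit.png     planted deficit mask (synthetic bundles only)

Images are stored as 16-bit counts; float images in [0, 1] are scaled by
65535 on write and divided back on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import imageio.v3 as iio
import numpy as np
import tifffile

from .synthetic import GroundTruth
from .types import EnFaceScan, LesionROISet

__all__ = ["write_scan_bundle", "read_scan_bundle"]

_SCALE16 = 65535.0


def _write_mask(path: Path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))


def _read_mask(path: Path) -> np.ndarray:
    return np.asarray(iio.imread(path)) > 127


def write_scan_bundle(
    out_dir: Path,
    scan: EnFaceScan,
    roi: LesionROISet,
    truth: Optional[GroundTruth] = None,
) -> Path:
    """Write one eye/visit bundle; returns the bundle directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        out_dir / "flow.tiff", np.round(scan.flow * _SCALE16).astype(np.uint16)
    )
    tifffile.imwrite(
        out_dir / "structure.tiff",
        np.round(scan.structure * _SCALE16).astype(np.uint16),
    )
    _write_mask(out_dir / "mnv.png", roi.mnv_mask)
    _write_mask(out_dir / "halo.png", roi.halo_mask)
    meta = {
        "pixel_scale_um": scan.pixel_scale_um,
        "eye_id": scan.eye_id,
        "timepoint": scan.timepoint,
        "signal_strength": int(scan.signal_strength),
    }
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=2))
    if truth is not None:
        _write_mask(out_dir / "vessels.png", truth.vessel_mask)
        _write_mask(out_dir / "deficit.png", truth.deficit_mask)
        (out_dir / "truth.json").write_text(
            json.dumps(
                {
                    "deficit_fraction_per_region": truth.deficit_fraction_per_region,
                    "component_count_per_region": truth.component_count_per_region,
                },
                indent=2,
            )
        )
    return out_dir


def read_scan_bundle(
    bundle_dir: Path,
) -> Tuple[EnFaceScan, LesionROISet, np.ndarray]:
    """Read one bundle back: (scan, roi, vessel_mask).

    A missing ``vessels.png`` defaults to an empty vessel mask.  Grid
    mismatches and missing mandatory files raise with the offending
    filenames.
    """
    bundle_dir = Path(bundle_dir)
    for name in ("flow.tiff", "structure.tiff", "mnv.png", "halo.png", "meta.json"):
        if not (bundle_dir / name).exists():
            raise FileNotFoundError(f"missing mandatory file {bundle_dir / name}")
    flow = tifffile.imread(bundle_dir / "flow.tiff").astype(float) / _SCALE16
    structure = tifffile.imread(bundle_dir / "structure.tiff").astype(float) / _SCALE16
    meta = json.loads((bundle_dir / "meta.json").read_text())
    for key in ("pixel_scale_um", "eye_id", "timepoint"):
        if key not in meta:
            raise KeyError(f"meta.json in {bundle_dir} is missing key '{key}'")

    def _checked(path: Path) -> np.ndarray:
        mask = _read_mask(path)
        if mask.shape != flow.shape:
            raise ValueError(
                f"grid mismatch: {path.name} is {mask.shape} but flow.tiff "
                f"is {flow.shape} in {bundle_dir}"
            )
        return mask

    mnv = _checked(bundle_dir / "mnv.png")
    halo = _checked(bundle_dir / "halo.png")
    vessels_path = bundle_dir / "vessels.png"
    vessels = (
        _checked(vessels_path)
        if vessels_path.exists()
        else np.zeros(flow.shape, dtype=bool)
    )
    if structure.shape != flow.shape:
        raise ValueError(
            f"grid mismatch: structure.tiff {structure.shape} vs flow.tiff "
            f"{flow.shape} in {bundle_dir}"
        )
    scan = EnFaceScan(
        flow=flow,
        structure=structure,
        pixel_scale_um=float(meta["pixel_scale_um"]),
        eye_id=str(meta["eye_id"]),
        timepoint=str(meta["timepoint"]),
        signal_strength=int(meta.get("signal_strength", 10)),
    )
    return scan, LesionROISet(mnv_mask=mnv, halo_mask=halo), vessels
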