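"""Flow-deficit quantification: Phansalkar binarization and per-ring metrics.

The compensated CC image is binarized with the Phansalkar local adaptive
threshold — designed to pick out darker regions in low-contrast images:

    t(x) = m(x) · (1 + p·exp(−q·m(x)) + k·(s(x)/r − 1))

with m, s the mean and standard deviation of the min-max-normalized image
over a circular neighborhood (radius 15 px by default, edge-replicated,
k = 0.25, r = 0.5, p = 2, q = 10 — the canonical auto-local-threshold
constants).  A pixel is a flow deficit iff its normalized intensity is ≤ t
(ties count as deficit).

Per ring, deficits are clipped at the ring boundary and connected
components (8-connectivity, the particle-analysis convention) yield:
FD% (deficit area as % of the analyzable ring area), FDa (mean component
area, µm²) and FDn (component count), with the conservation identity
FDn · FDa = total deficit area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.signal import fftconvolve
from skimage.measure import label as cc_label
from skimage.morphology import disk

from .types import RingMetrics

__all__ = [
    "PhansalkarParams",
    "phansalkar_binarize",
    "fd_metrics",
    "mnv_area",
]


@dataclass(frozen=True)
class PhansalkarParams:
    """Phansalkar threshold constants.  ``radius_px`` is the circular
    window radius in pixels (15 px as used for CC flow-deficit analysis);
    k, r, p, q are the method's standard constants."""

    radius_px: int = 15
    k: float = 0.25
    r: float = 0.5
    p: float = 2.0
    q: float = 10.0

    def __post_init__(self) -> None:
        if self.radius_px < 1:
            raise ValueError("radius_px must be >= 1")
        for name in ("k", "r", "p", "q"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} must be finite")


def _normalize(image: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Min-max normalization to [0, 1] over the valid pixels.  A constant
    image is passed through unchanged (clipped to [0, 1]) so the threshold
    formula stays well defined."""
    vals = image[valid]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return np.clip(image, 0.0, 1.0)
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def phansalkar_binarize(
    image: np.ndarray,
    params: PhansalkarParams = PhansalkarParams(),
    valid_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Binarize an intensity image into a deficit map (True = deficit).

    The image is min-max normalized internally over the non-excluded
    pixels.  Local statistics use a circular window with edge-replicated
    padding; excluded pixels are omitted from the window mean and standard
    deviation (not zero-filled), and are always False in the output.

    Raises
    ------
    ValueError
        If the image is smaller than the window diameter or contains
        non-finite values.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    rad = params.radius_px
    if min(img.shape) < 2 * rad + 1:
        raise ValueError(
            f"image {img.shape} smaller than the window diameter {2 * rad + 1}"
        )
    if valid_mask is None:
        valid = np.ones(img.shape, dtype=bool)
    else:
        valid = np.asarray(valid_mask, dtype=bool)
        if valid.shape != img.shape:
            raise ValueError("valid_mask grid mismatch")
        if not valid.any():
            return np.zeros(img.shape, dtype=bool)

    norm = _normalize(img, valid)

    foot = disk(rad).astype(float)
    pad = ((rad, rad), (rad, rad))
    norm_p = np.pad(norm, pad, mode="edge")
    valid_p = np.pad(valid.astype(float), pad, mode="edge")

    cnt = fftconvolve(valid_p, foot, mode="valid")
    s1 = fftconvolve(norm_p * valid_p, foot, mode="valid")
    s2 = fftconvolve(norm_p**2 * valid_p, foot, mode="valid")
    with np.errstate(invalid="ignore", divide="ignore"):
        m = s1 / cnt
        var = np.maximum(s2 / cnt - m**2, 0.0)
    s = np.sqrt(var)

    t = m * (1.0 + params.p * np.exp(-params.q * m) + params.k * (s / params.r - 1.0))
    deficit = (norm <= t) & valid
    # windows with no valid pixel at all cannot be classified
    deficit &= cnt > 0
    return deficit


def fd_metrics(
    deficit_map: np.ndarray,
    ring: np.ndarray,
    pixel_scale_um: float,
    connectivity: int = 8,
) -> RingMetrics:
    """Particle-style flow-deficit metrics within one analyzable ring.

    The deficit map is clipped at the ring boundary before labelling, so a
    deficit spanning two rings contributes a clipped fragment to each.

    Returns an undefined-flagged result (NaN metrics) when the analyzable
    ring is empty.
    """
    deficit_map = np.asarray(deficit_map, dtype=bool)
    ring = np.asarray(ring, dtype=bool)
    if deficit_map.shape != ring.shape:
        raise ValueError(
            f"deficit map {deficit_map.shape} / ring {ring.shape} grid mismatch"
        )
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    ring_px = int(ring.sum())
    if ring_px == 0:
        return RingMetrics(
            fd_percent=float("nan"),
            fd_avg_area_um2=float("nan"),
            fd_count=0,
            analyzable_area_um2=0.0,
            defined=False,
        )
    clipped = deficit_map & ring
    total_px = int(clipped.sum())
    skimage_conn = 2 if connectivity == 8 else 1
    n_comp = int(cc_label(clipped, connectivity=skimage_conn).max())
    px_area_um2 = float(pixel_scale_um) ** 2
    avg_area = (total_px / n_comp) * px_area_um2 if n_comp else 0.0
    return RingMetrics(
        fd_percent=100.0 * total_px / ring_px,
        fd_avg_area_um2=avg_area,
        fd_count=n_comp,
        analyzable_area_um2=ring_px * px_area_um2,
        defined=True,
    )


def mnv_area(mnv_mask: np.ndarray, pixel_scale_um: float) -> float:
    """Lesion area in mm²: pixel count × (pixel scale / 1000)²."""
    mnv_mask = np.asarray(mnv_mask, dtype=bool)
    if not mnv_mask.any():
        raise ValueError("mnv_mask is empty")
    if pixel_scale_um <= 0:
        raise ValueError("pixel_scale_um must be positive")
    return float(mnv_mask.sum()) * (pixel_scale_um / 1000.0) ** 2
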