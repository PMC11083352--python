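"""Shadow compensation and pixel-exclusion assembly.

En-face CC flow signal is attenuated wherever the overlying tissue casts a
shadow (large retinal vessels, elevated RPE over drusen).  Because the same
attenuation acts on the co-registered structure image, dividing the flow by
a smoothed structure image cancels it:

    compensated(x) = flow(x) · S_ref / max(structure_smoothed(x), ε)

where ``structure_smoothed`` is a Gaussian blur of the structure image,
``S_ref`` its median (so an unshadowed scan is returned unchanged up to a
global constant), and ε a low quantile acting as a floor: pixels whose
smoothed structure falls below ε are unrecoverable and are flagged for
exclusion instead of being amplified.

The compensation is invariant to any global rescaling of the structure
image and never produces negative intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .types import EnFaceScan, ExclusionMask

__all__ = ["GateDecision", "quality_gate", "compensate_flow", "build_exclusion_mask"]


@dataclass(frozen=True)
class GateDecision:
    accepted: bool
    reason: str

    def __bool__(self) -> bool:
        return self.accepted


def quality_gate(scan: EnFaceScan, motion_artifact_flag: bool = False) -> GateDecision:
    """Scan-quality gate: reject scans with signal-strength index below
    8/10 or with a significant motion artifact.  Total function."""
    if scan.signal_strength < 8:
        return GateDecision(
            False, f"signal_strength {scan.signal_strength} < 8"
        )
    if motion_artifact_flag:
        return GateDecision(False, "motion artifact flagged")
    return GateDecision(True, "accepted")


def compensate_flow(
    scan: EnFaceScan,
    smoothing_sigma_um: float = 50.0,
    floor_quantile: float = 0.02,
    exclusion: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Remove multiplicative shadowing from the flow image.

    Parameters
    ----------
    scan : EnFaceScan
        Flow and structure images on one grid.
    smoothing_sigma_um : float
        Gaussian sigma (µm) applied to the structure image before division;
        suppresses structure-image granularity so only the smooth shadow
        field is divided out.
    floor_quantile : float
        Quantile of the smoothed structure used as the divisor floor ε;
        must lie in (0, 0.5).
    exclusion : ndarray of bool, optional
        Pixels ignored when computing the reference level S_ref.

    Returns
    -------
    compensated : ndarray of float
        Shadow-compensated flow, clipped to the input dtype's range
        (non-negative; never exceeds the representable maximum for integer
        inputs).
    low_signal : ndarray of bool
        Pixels where the smoothed structure fell below ε — unrecoverable,
        to be merged into the exclusion mask.
    """
    if not 0.0 < floor_quantile < 0.5:
        raise ValueError("floor_quantile must lie in (0, 0.5)")
    structure = np.asarray(scan.structure, dtype=float)
    flow = np.asarray(scan.flow, dtype=float)
    if not np.any(structure):
        raise ValueError("structure image is identically zero")
    if exclusion is not None:
        exclusion = np.asarray(exclusion, dtype=bool)
        if exclusion.shape != scan.shape:
            raise ValueError(
                f"exclusion grid {exclusion.shape} does not match scan {scan.shape}"
            )

    sigma_px = smoothing_sigma_um / scan.pixel_scale_um
    smoothed = gaussian_filter(structure, sigma_px, mode="nearest")
    eps = float(np.quantile(smoothed, floor_quantile))
    low_signal = smoothed < eps
    valid = ~exclusion if exclusion is not None else np.ones_like(low_signal)
    s_ref = float(np.median(smoothed[valid])) if valid.any() else float(np.median(smoothed))

    compensated = flow * s_ref / np.maximum(smoothed, eps)

    compensated = np.maximum(compensated, 0.0)
    if np.issubdtype(scan.flow.dtype, np.integer):
        compensated = np.minimum(compensated, np.iinfo(scan.flow.dtype).max)
    elif scan.flow.max() <= 1.0:
        # unit-normalized float input: keep the unit range
        compensated = np.minimum(compensated, 1.0)
    return compensated, low_signal


def build_exclusion_mask(
    vessel_mask: np.ndarray,
    low_signal: np.ndarray,
    outside_scan: Optional[np.ndarray] = None,
) -> ExclusionMask:
    """Union the exclusion sources into one mask with per-reason provenance.
    Overlapping pixels are counted once; each reason keeps its own layer.
    Idempotent under repeated application."""
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    low_signal = np.asarray(low_signal, dtype=bool)
    if vessel_mask.shape != low_signal.shape:
        raise ValueError(
            f"vessel {vessel_mask.shape} / low_signal {low_signal.shape} grid mismatch"
        )
    provenance = {"vessel": vessel_mask, "low_signal": low_signal}
    union = vessel_mask | low_signal
    if outside_scan is not None:
        outside_scan = np.asarray(outside_scan, dtype=bool)
        if outside_scan.shape != vessel_mask.shape:
            raise ValueError("outside_scan grid mismatch")
        provenance["outside_scan"] = outside_scan
        union = union | outside_scan
    return ExclusionMask(mask=union, provenance=provenance)
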