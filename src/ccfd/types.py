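"""Core in-memory containers shared across the pipeline stages.

All images are 2-D numpy arrays on a common pixel grid; geometry is carried
in physical units (µm) via ``pixel_scale_um`` so that ring widths, areas and
margins are resolution independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional

import numpy as np

TIMEPOINTS = ("T0", "T1", "T2")

__all__ = [
    "TIMEPOINTS",
    "EnFaceScan",
    "LesionROISet",
    "ExclusionMask",
    "RingMaskSet",
    "RingMetrics",
    "FDResult",
]


def _as_bool(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D image, got shape {arr.shape}")
    return arr.astype(bool)


@dataclass
class EnFaceScan:
    """One eye/visit en-face OCTA acquisition: co-registered flow and
    structure images of the choriocapillaris slab.

    Parameters
    ----------
    flow : ndarray
        En-face flow (angiography) intensity image, non-negative.
    structure : ndarray
        Co-registered structure (reflectance) image on the same grid; used
        to estimate and remove shadowing attenuation.
    pixel_scale_um : float
        Physical size of one pixel in µm (e.g. 12 µm for a 6 mm field
        exported at 500 px).
    eye_id : str
        Cohort identifier for the eye.
    timepoint : str
        Visit label: ``T0`` (baseline, before the first injection), ``T1``
        (one month later), ``T2`` (four weeks after the third injection).
    signal_strength : int
        Device-reported 0-10 scan-quality index.
    """

    flow: np.ndarray
    structure: np.ndarray
    pixel_scale_um: float
    eye_id: str = "eye00"
    timepoint: str = "T0"
    signal_strength: int = 10

    def __post_init__(self) -> None:
        self.flow = np.asarray(self.flow)
        self.structure = np.asarray(self.structure)
        if self.flow.ndim != 2 or self.structure.ndim != 2:
            raise ValueError("flow and structure must be 2-D images")
        if self.flow.shape != self.structure.shape:
            raise ValueError(
                f"flow {self.flow.shape} and structure {self.structure.shape} "
                "must share one grid"
            )
        if self.pixel_scale_um <= 0:
            raise ValueError("pixel_scale_um must be positive")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        if not 0 <= int(self.signal_strength) <= 10:
            raise ValueError("signal_strength must be in 0..10")

    @property
    def shape(self) -> tuple:
        return self.flow.shape


@dataclass
class LesionROISet:
    """Manually (or synthetically) outlined lesion geometry: the MNV mask
    and the surrounding dark-halo (DH) annulus, on the scan grid."""

    mnv_mask: np.ndarray
    halo_mask: np.ndarray
    grader_id: str = "G1"

    def __post_init__(self) -> None:
        self.mnv_mask = _as_bool(self.mnv_mask, "mnv_mask")
        self.halo_mask = _as_bool(self.halo_mask, "halo_mask")
        if self.mnv_mask.shape != self.halo_mask.shape:
            raise ValueError("mnv_mask and halo_mask must share one grid")
        if np.any(self.mnv_mask & self.halo_mask):
            raise ValueError("halo_mask must not overlap mnv_mask")

    @property
    def lesion_mask(self) -> np.ndarray:
        """MNV ∪ DH — the region rings are grown from."""
        return self.mnv_mask | self.halo_mask

    @property
    def shape(self) -> tuple:
        return self.mnv_mask.shape


@dataclass
class ExclusionMask:
    """Pixels removed from every denominator (large retinal vessels,
    unrecoverable low signal), with per-reason provenance masks."""

    mask: np.ndarray
    provenance: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = _as_bool(self.mask, "mask")
        for reason, m in self.provenance.items():
            m = _as_bool(m, f"provenance[{reason}]")
            if m.shape != self.mask.shape:
                raise ValueError(f"provenance[{reason}] grid mismatch")
            self.provenance[reason] = m

    @property
    def shape(self) -> tuple:
        return self.mask.shape

    def fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class RingMaskSet:
    """Concentric perilesional ring ROIs.

    ``ring_labels`` holds 0 for no ring and k ∈ 1..n_rings for ring Rk;
    ``analyzable`` is an (n_rings, H, W) boolean stack of the rings after
    exclusion-mask removal.  Geometric ring areas stay recoverable from the
    label image after exclusions are applied.
    """

    ring_labels: np.ndarray
    analyzable: np.ndarray
    ring_width_um: float = 200.0
    n_rings: int = 5
    pixel_scale_um: float = 12.0

    def __post_init__(self) -> None:
        self.ring_labels = np.asarray(self.ring_labels).astype(np.int16)
        self.analyzable = np.asarray(self.analyzable).astype(bool)
        if self.analyzable.shape != (self.n_rings,) + self.ring_labels.shape:
            raise ValueError("analyzable must be an (n_rings, H, W) stack")
        if self.ring_width_um <= 0:
            raise ValueError("ring_width_um must be positive")

    @property
    def shape(self) -> tuple:
        return self.ring_labels.shape

    def ring_mask(self, k: int) -> np.ndarray:
        """Geometric (pre-exclusion) mask of ring Rk, k in 1..n_rings."""
        if not 1 <= k <= self.n_rings:
            raise ValueError(f"ring index {k} outside 1..{self.n_rings}")
        return self.ring_labels == k

    def analyzable_mask(self, k: int) -> np.ndarray:
        if not 1 <= k <= self.n_rings:
            raise ValueError(f"ring index {k} outside 1..{self.n_rings}")
        return self.analyzable[k - 1]

    def geometric_area_um2(self, k: int) -> float:
        return float(self.ring_mask(k).sum()) * self.pixel_scale_um**2

    def analyzable_area_um2(self, k: int) -> float:
        return float(self.analyzable_mask(k).sum()) * self.pixel_scale_um**2


@dataclass
class RingMetrics:
    """Flow-deficit metrics for one ring of one scan.

    ``fd_percent`` is the deficit area fraction of the analyzable ring area
    (in %), ``fd_avg_area_um2`` the mean connected-deficit size, and
    ``fd_count`` the number of deficit components.  ``defined`` is False
    when the analyzable ring area is zero (metrics are then meaningless).
    """

    fd_percent: float
    fd_avg_area_um2: float
    fd_count: int
    analyzable_area_um2: float
    defined: bool = True


@dataclass
class FDResult:
    """Per-scan quantification: metrics for every ring plus lesion area."""

    eye_id: str
    timepoint: str
    rings: Dict[int, RingMetrics]
    mnv_area_mm2: float

    def to_records(self) -> List[dict]:
        """One flat record per ring (CSV-row shaped)."""
        out = []
        for k in sorted(self.rings):
            m = self.rings[k]
            out.append(
                {
                    "eye_id": self.eye_id,
                    "timepoint": self.timepoint,
                    "ring": k,
                    "fd_percent": m.fd_percent,
                    "fd_avg_area_um2": m.fd_avg_area_um2,
                    "fd_count": m.fd_count,
                    "analyzable_area_um2": m.analyzable_area_um2,
                    "defined": m.defined,
                    "mnv_area_mm2": self.mnv_area_mm2,
                }
            )
        return out

    def __iter__(self) -> Iterator[int]:
        return iter(sorted(self.rings))
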