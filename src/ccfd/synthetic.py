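"""Synthetic en-face OCTA generator with planted ground truth.

Emulates the statistical structure the flow-deficit analysis assumes on a
6 × 6 mm choriocapillaris slab:

* a stationary granular flow texture with planted low-flow deficits whose
  per-region area fraction is controlled exactly (smoothed Gaussian noise
  thresholded at the empirical quantile, region by region);
* a centred type-1 MNV lesion of prescribed area surrounded by a dark halo
  rendered as a multiplicative low-flow attenuation;
* large retinal-vessel shadow stripes and drusen-like shadow bumps applied
  as one multiplicative attenuation field to BOTH the structure image and
  the flow image, so shadow compensation is testable by construction;
* paired T0/T1/T2 cohorts sharing one lesion geometry per eye, with a
  reperfusion effect (mean FD drop) planted in the innermost ring at T2.

Every source of randomness derives from the seed in the parameter object
via named ``numpy`` seed sequences: identical seeds give bit-identical
output, and each eye/visit owns an independent substream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter
from skimage.measure import label as cc_label

from .rings import build_rings, validate_edge_margin
from .types import TIMEPOINTS, EnFaceScan, LesionROISet

__all__ = [
    "SynthParams",
    "GroundTruth",
    "CohortEffectSpec",
    "CohortScan",
    "generate_lesion_geometry",
    "generate_scan",
    "sample_cohort_fractions",
    "generate_paired_cohort",
]

# Table-2-like baseline FD% profile, innermost → outermost ring.
DEFAULT_FD_T0_MEAN = (50.5, 44.5, 39.7, 36.9, 34.9)
DEFAULT_FD_T0_SD = (10.2, 9.6, 8.6, 7.5, 6.8)


@dataclass
class SynthParams:
    """Acquisition and texture parameters of one synthetic scan.

    Defaults reflect a 6 × 6 mm swept-source en-face export at 500 px
    (12 µm/px).  ``deficit_fraction`` is the planted flow-deficit area
    fraction outside MNV ∪ halo; ``deficit_scale_um`` the correlation
    length of the deficit texture; ``mnv_area_mm2`` the lesion area.
    Intensity constants (base level, granularity, deficit contrast, halo
    and vessel attenuation) model a compensated CC slab where deficits are
    near-black voids in a bright granular background.
    """

    image_size_px: int = 500
    field_mm: float = 6.0
    deficit_fraction: float = 0.45
    deficit_scale_um: float = 60.0
    mnv_area_mm2: float = 0.52
    mnv_area_sd_mm2: float = 0.12  # between-eye lesion-size spread (cohorts)
    halo_width_um: float = 150.0
    vessel_count: int = 3
    noise_sd: float = 0.02
    seed: int = 0
    # texture / rendering constants
    base_level: float = 0.65
    texture_sd: float = 0.07
    texture_scale_um: float = 24.0
    deficit_contrast: float = 0.18
    halo_attenuation: float = 0.5
    vessel_attenuation: float = 0.5
    vessel_width_um: float = 120.0
    drusen_count: int = 6
    drusen_sigma_um: float = 90.0
    drusen_depth: float = 0.25
    edge_margin_mm: float = 1.0
    ring_width_um: float = 200.0
    n_rings: int = 5

    def __post_init__(self) -> None:
        if self.image_size_px < 64:
            raise ValueError("image_size_px must be >= 64")
        if not 0.0 <= self.deficit_fraction <= 1.0:
            raise ValueError("deficit_fraction must lie in [0, 1]")
        if self.mnv_area_mm2 >= self.field_mm**2:
            raise ValueError("mnv_area_mm2 must be smaller than the field area")
        if self.mnv_area_mm2 <= 0:
            raise ValueError("mnv_area_mm2 must be positive")
        # lesion must fit with the edge margin: centred disk equivalent
        r_mm = float(np.sqrt(self.mnv_area_mm2 / np.pi))
        if r_mm + self.edge_margin_mm > self.field_mm / 2:
            raise ValueError(
                f"mnv_area_mm2={self.mnv_area_mm2} cannot satisfy the "
                f"{self.edge_margin_mm} mm edge margin in a {self.field_mm} mm field"
            )

    @property
    def pixel_scale_um(self) -> float:
        return self.field_mm * 1000.0 / self.image_size_px


@dataclass
class GroundTruth:
    """Exact planted truth for one synthetic scan.

    ``region_labels``: -1 inside MNV ∪ halo, 0 perilesional background,
    k = 1..n_rings for ring Rk.  Region keys in the per-region maps are
    "R1".."Rn" and "background".  ``flow_ideal`` is the shadow-free flow
    image (before the multiplicative attenuation field was applied).
    """

    deficit_mask: np.ndarray
    deficit_fraction_per_region: Dict[str, float]
    component_count_per_region: Dict[str, int]
    mnv_mask: np.ndarray
    halo_mask: np.ndarray
    vessel_mask: np.ndarray
    flow_ideal: np.ndarray
    attenuation: np.ndarray
    region_labels: np.ndarray


def _smooth_noise(rng: np.random.Generator, shape, scale_px: float) -> np.ndarray:
    """Standardized Gaussian-smoothed white noise (zero mean, unit sd).

    ``scale_px`` is the texture's full decorrelation diameter: the Gaussian
    kernel uses sigma = scale/4, so the field's autocorrelation
    (exp(-d²/4σ²)) has decayed to e⁻⁴ at distance ``scale_px`` — pixels
    further apart than the stated scale are effectively independent.
    """
    z = rng.standard_normal(shape)
    if scale_px > 0:
        z = gaussian_filter(z, scale_px / 4.0, mode="reflect")
    sd = z.std()
    return (z - z.mean()) / (sd if sd > 0 else 1.0)


def generate_lesion_geometry(
    params: SynthParams, center_px: Optional[Tuple[float, float]] = None
) -> LesionROISet:
    """Create a connected, mildly irregular MNV blob of the target area with
    a surrounding dark-halo annulus of the configured width.

    The blob is star-shaped around its centre (radius modulated by low-order
    harmonics) and its pixel count matches ``mnv_area_mm2`` exactly at the
    pixel scale: the target number of pixels with the smallest normalized
    radial coordinate is selected.  The halo is the set of outside pixels
    within ``halo_width_um`` of the MNV, so it touches the MNV boundary and
    never overlaps it.

    Raises
    ------
    ValueError
        If the geometry violates the edge margin (default 1 mm).
    """
    n = params.image_size_px
    scale = params.pixel_scale_um
    if center_px is None:
        center_px = ((n - 1) / 2.0, (n - 1) / 2.0)

    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 101]))
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    dy, dx = yy - center_px[0], xx - center_px[1]
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    rho = np.ones_like(theta)
    for m in range(2, 6):
        amp = 0.08 / (m - 1)
        phase = rng.uniform(0, 2 * np.pi)
        rho += amp * np.cos(m * theta + phase)
    rho = np.clip(rho, 0.5, None)

    target_px = int(round(params.mnv_area_mm2 * 1e6 / scale**2))
    if target_px < 1:
        raise ValueError("mnv_area_mm2 too small for this pixel scale")
    d_norm = r / rho
    flat = np.argsort(d_norm, axis=None, kind="stable")[:target_px]
    mnv = np.zeros((n, n), dtype=bool)
    mnv.flat[flat] = True

    halo_px = params.halo_width_um / scale
    dist = distance_transform_edt(~mnv)
    halo = (dist <= halo_px) & ~mnv

    roi = LesionROISet(mnv_mask=mnv, halo_mask=halo)
    if not validate_edge_margin(roi, scale, params.edge_margin_mm):
        raise ValueError(
            f"MNV violates the {params.edge_margin_mm} mm scan-edge margin"
        )
    return roi


def _region_labels(params: SynthParams, roi: LesionROISet) -> np.ndarray:
    """-1 = lesion (MNV ∪ halo), 0 = far background, 1..n = rings."""
    rings = build_rings(roi, params.pixel_scale_um, params.ring_width_um, params.n_rings)
    labels = rings.ring_labels.astype(np.int16)
    labels[roi.lesion_mask] = -1
    return labels


def _plant_deficits(
    noise: np.ndarray,
    region_labels: np.ndarray,
    fraction_per_region: Mapping[int, float],
) -> np.ndarray:
    """Mark, per region, exactly round(f·n_region) pixels with the lowest
    smoothed-noise values as deficits.  Exact planted fractions by
    construction; lesion pixels (label -1) never carry deficits."""
    deficit = np.zeros(noise.shape, dtype=bool)
    for rid, frac in fraction_per_region.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"deficit fraction {frac} for region {rid} outside [0,1]")
        sel = np.nonzero((region_labels == rid).ravel())[0]
        if sel.size == 0:
            continue
        k = int(round(frac * sel.size))
        if k == 0:
            continue
        order = np.argsort(noise.ravel()[sel], kind="stable")
        deficit.ravel()[sel[order[:k]]] = True
    return deficit


def _vessel_field(
    params: SynthParams, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Large-retinal-vessel shadow stripes: random chords with multiplicative
    attenuation.  Returns (attenuation, vessel_mask)."""
    n = params.image_size_px
    scale = params.pixel_scale_um
    atten = np.ones((n, n))
    mask = np.zeros((n, n), dtype=bool)
    if params.vessel_count == 0:
        return atten, mask
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    half_w = params.vessel_width_um / scale / 2.0
    for _ in range(params.vessel_count):
        angle = rng.uniform(0, np.pi)
        nx, ny = np.cos(angle), np.sin(angle)
        offset = rng.uniform(0.15, 0.85) * n
        d = np.abs(nx * (xx - offset) + ny * (yy - offset))
        stripe = d <= half_w
        factor = rng.uniform(params.vessel_attenuation * 0.9, params.vessel_attenuation * 1.2)
        atten = np.where(stripe, atten * factor, atten)
        mask |= stripe
    # soften stripe edges slightly (real shadows are not knife-edged)
    atten = gaussian_filter(atten, 1.0, mode="nearest")
    return atten, mask


def _drusen_field(params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """Drusen-like smooth shadow bumps (RPE elevation attenuates both the
    structure and the flow signal)."""
    n = params.image_size_px
    atten = np.ones((n, n))
    if params.drusen_count == 0:
        return atten
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    sig_px = params.drusen_sigma_um / params.pixel_scale_um
    for _ in range(params.drusen_count):
        cy, cx = rng.uniform(0, n, size=2)
        depth = rng.uniform(0.5, 1.0) * params.drusen_depth
        bump = depth * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig_px**2))
        atten *= 1.0 - bump
    return np.clip(atten, 0.3, 1.0)


def generate_scan(
    params: SynthParams,
    roi: Optional[LesionROISet] = None,
    ring_fractions: Optional[Mapping[int, float]] = None,
    eye_id: str = "eye00",
    timepoint: str = "T0",
    seed_seq: Optional[np.random.SeedSequence] = None,
) -> Tuple[EnFaceScan, GroundTruth]:
    """Render one flow/structure pair with exact planted ground truth.

    Parameters
    ----------
    params : SynthParams
        Texture, geometry and seed configuration.
    roi : LesionROISet, optional
        Reuse an existing lesion geometry (cohorts share one geometry per
        eye across visits); generated from ``params`` when omitted.
    ring_fractions : mapping ring-index → fraction, optional
        Per-ring planted deficit fractions overriding the global
        ``params.deficit_fraction`` inside rings 1..n_rings; the global
        value still applies to the remaining background.
    seed_seq : numpy.random.SeedSequence, optional
        Externally supplied randomness substream (used by the cohort
        generator); defaults to one derived from ``params.seed``.

    Returns
    -------
    (EnFaceScan, GroundTruth)
    """
    if seed_seq is None:
        seed_seq = np.random.SeedSequence([int(params.seed), 202])
    rng = np.random.default_rng(seed_seq)

    n = params.image_size_px
    scale = params.pixel_scale_um
    if roi is None:
        roi = generate_lesion_geometry(params)
    if roi.shape != (n, n):
        raise ValueError("roi grid does not match image_size_px")

    regions = _region_labels(params, roi)
    fractions: Dict[int, float] = {0: params.deficit_fraction}
    for k in range(1, params.n_rings + 1):
        fractions[k] = params.deficit_fraction
    if ring_fractions:
        for k, f in ring_fractions.items():
            if k not in fractions or k == 0:
                raise ValueError(f"unknown ring index {k}")
            fractions[int(k)] = float(f)

    # deficit texture: smoothed noise thresholded at the per-region quantile
    deficit_noise = _smooth_noise(rng, (n, n), params.deficit_scale_um / scale)
    deficit = _plant_deficits(deficit_noise, regions, fractions)

    # granular CC background texture
    granule = _smooth_noise(rng, (n, n), params.texture_scale_um / scale)
    flow_ideal = params.base_level + params.texture_sd * granule
    flow_ideal = np.where(deficit, flow_ideal * params.deficit_contrast, flow_ideal)
    flow_ideal = np.where(roi.halo_mask, flow_ideal * params.halo_attenuation, flow_ideal)
    flow_ideal = flow_ideal + rng.normal(0.0, params.noise_sd, size=(n, n))
    flow_ideal = np.clip(flow_ideal, 0.0, 1.0)

    # shared multiplicative shadow field → structure and flow
    vessel_atten, vessel_mask = _vessel_field(params, rng)
    atten = vessel_atten * _drusen_field(params, rng)
    structure_base = 0.75 + 0.08 * _smooth_noise(rng, (n, n), 500.0 / scale)
    structure = np.clip(
        structure_base * atten + rng.normal(0.0, 0.01, size=(n, n)), 0.0, 1.0
    )
    flow = np.clip(flow_ideal * atten, 0.0, 1.0)

    # exact recounted per-region truth
    frac_per_region: Dict[str, float] = {}
    comp_per_region: Dict[str, int] = {}
    for rid, name in [(0, "background")] + [
        (k, f"R{k}") for k in range(1, params.n_rings + 1)
    ]:
        m = regions == rid
        npx = int(m.sum())
        frac_per_region[name] = float((deficit & m).sum() / npx) if npx else 0.0
        comp_per_region[name] = int(cc_label(deficit & m, connectivity=2).max())

    scan = EnFaceScan(
        flow=flow,
        structure=structure,
        pixel_scale_um=scale,
        eye_id=eye_id,
        timepoint=timepoint,
        signal_strength=10,
    )
    truth = GroundTruth(
        deficit_mask=deficit,
        deficit_fraction_per_region=frac_per_region,
        component_count_per_region=comp_per_region,
        mnv_mask=roi.mnv_mask.copy(),
        halo_mask=roi.halo_mask.copy(),
        vessel_mask=vessel_mask,
        flow_ideal=flow_ideal,
        attenuation=atten,
        region_labels=regions,
    )
    return scan, truth


@dataclass
class CohortEffectSpec:
    """Planted longitudinal effect for a paired T0/T1/T2 cohort.

    Per-ring baseline FD% is drawn per eye from N(fd_t0_mean, fd_t0_sd);
    visits share an eye-level random effect so that values at two visits
    correlate at ``within_eye_correlation``.  The only planted mean change
    is ``delta_r1_t2`` in ring 1 at T2 (negative = reperfusion); all other
    ring/visit means are flat.  Values are clipped to [0, 100].
    """

    n_eyes: int = 25
    fd_t0_mean: Sequence[float] = DEFAULT_FD_T0_MEAN
    fd_t0_sd: Sequence[float] = DEFAULT_FD_T0_SD
    delta_r1_t2: float = -4.1
    within_eye_correlation: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_eyes < 2:
            raise ValueError("n_eyes must be >= 2")
        if not 0.0 <= self.within_eye_correlation <= 1.0:
            raise ValueError("within_eye_correlation must lie in [0, 1]")
        if np.isscalar(self.fd_t0_mean):
            self.fd_t0_mean = (float(self.fd_t0_mean),) * 5
        if np.isscalar(self.fd_t0_sd):
            self.fd_t0_sd = (float(self.fd_t0_sd),) * 5
        self.fd_t0_mean = tuple(float(v) for v in self.fd_t0_mean)
        self.fd_t0_sd = tuple(float(v) for v in self.fd_t0_sd)
        if len(self.fd_t0_mean) != len(self.fd_t0_sd):
            raise ValueError("fd_t0_mean and fd_t0_sd must have equal length")


@dataclass
class CohortScan:
    """One rendered cohort element (one eye at one visit)."""

    eye_id: str
    timepoint: str
    scan: EnFaceScan
    roi: LesionROISet
    truth: GroundTruth


def sample_cohort_fractions(spec: CohortEffectSpec) -> List[dict]:
    """Draw the planted per-eye, per-visit, per-ring FD% values.

    The correlation model is a shared eye-level effect:
    value = μ(ring, visit) + sd·(√ρ·b_eye + √(1−ρ)·ε_visit), clipped to
    [0, 100], giving corr(visit_a, visit_b) = ρ within an eye.

    Returns a list of records ``{eye_id, timepoint, ring, fd_percent}`` —
    the exact fractions the image generator plants (÷100).
    """
    n_rings = len(spec.fd_t0_mean)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 303]))
    rho = spec.within_eye_correlation
    records = []
    for e in range(spec.n_eyes):
        eye_id = f"eye{e:02d}"
        b = rng.standard_normal(n_rings)  # eye-level effect per ring
        for t_idx, tp in enumerate(TIMEPOINTS):
            eps = rng.standard_normal(n_rings)
            for r in range(n_rings):
                mu = spec.fd_t0_mean[r]
                if r == 0 and tp == "T2":
                    mu = mu + spec.delta_r1_t2
                sd = spec.fd_t0_sd[r]
                val = mu + sd * (np.sqrt(rho) * b[r] + np.sqrt(1 - rho) * eps[r])
                records.append(
                    {
                        "eye_id": eye_id,
                        "timepoint": tp,
                        "ring": r + 1,
                        "fd_percent": float(np.clip(val, 0.0, 100.0)),
                    }
                )
    return records


def generate_paired_cohort(
    spec: CohortEffectSpec, params: SynthParams
) -> List[CohortScan]:
    """Render a paired longitudinal cohort.

    Each eye gets one lesion geometry, reused for all three visits (the
    ring configuration is fixed across visits), and three scans whose
    per-ring planted deficit fractions follow ``sample_cohort_fractions``.
    Identical seeds reproduce the cohort bit-for-bit; each eye/visit draws
    from its own named substream, so enlarging the cohort does not perturb
    existing eyes.
    """
    fractions = sample_cohort_fractions(spec)
    by_eye_visit: Dict[Tuple[str, str], Dict[int, float]] = {}
    for rec in fractions:
        by_eye_visit.setdefault((rec["eye_id"], rec["timepoint"]), {})[
            rec["ring"]
        ] = rec["fd_percent"] / 100.0

    out: List[CohortScan] = []
    for e in range(spec.n_eyes):
        eye_id = f"eye{e:02d}"
        eye_params = SynthParams(
            **{**params.__dict__, "seed": int(params.seed)}
        )
        # geometry substream named by eye only (shared across visits)
        geo_seed = np.random.SeedSequence([int(params.seed), int(spec.seed), e, 7])
        geo_rng = np.random.default_rng(geo_seed)
        area = float(
            np.clip(
                geo_rng.normal(params.mnv_area_mm2, params.mnv_area_sd_mm2),
                0.05,
                3.0,
            )
        )
        geo_params = SynthParams(
            **{
                **params.__dict__,
                "seed": geo_rng_int(geo_seed),
                "mnv_area_mm2": area,
            }
        )
        roi = generate_lesion_geometry(geo_params)
        for t_idx, tp in enumerate(TIMEPOINTS):
            ss = np.random.SeedSequence(
                [int(params.seed), int(spec.seed), e, t_idx, 11]
            )
            scan, truth = generate_scan(
                eye_params,
                roi=roi,
                ring_fractions=by_eye_visit[(eye_id, tp)],
                eye_id=eye_id,
                timepoint=tp,
                seed_seq=ss,
            )
            out.append(CohortScan(eye_id, tp, scan, roi, truth))
    return out


def geo_rng_int(ss: np.random.SeedSequence) -> int:
    """Collapse a seed sequence to one 31-bit integer seed."""
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
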