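"""Phansalkar binarization and flow-deficit metrics against independent
brute-force oracles."""

import numpy as np
import pytest
from skimage.morphology import disk

from ccfd.quantify import PhansalkarParams, fd_metrics, mnv_area, phansalkar_binarize


def phansalkar_oracle(image, params):
    """Independent per-pixel loop: min-max normalization, circular window
    with edge-replicated padding, explicit mean/std, threshold formula."""
    img = np.asarray(image, float)
    lo, hi = img.min(), img.max()
    norm = np.clip((img - lo) / (hi - lo), 0, 1) if hi > lo else np.clip(img, 0, 1)
    rad = params.radius_px
    foot = disk(rad).astype(bool)
    padded = np.pad(norm, rad, mode="edge")
    out = np.zeros(img.shape, bool)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            win = padded[i : i + 2 * rad + 1, j : j + 2 * rad + 1][foot]
            m, s = win.mean(), win.std()
            t = m * (1 + params.p * np.exp(-params.q * m) + params.k * (s / params.r - 1))
            out[i, j] = norm[i, j] <= t
    return out


def flood_fill_metrics(deficit, ring, scale):
    """Independent oracle: restrict to ring, BFS flood-fill labelling at
    8-connectivity, then FD%, FDa, FDn by direct counting."""
    clipped = deficit & ring
    seen = np.zeros_like(clipped)
    sizes = []
    h, w = clipped.shape
    for i in range(h):
        for j in range(w):
            if clipped[i, j] and not seen[i, j]:
                stack, size = [(i, j)], 0
                seen[i, j] = True
                while stack:
                    y, x = stack.pop()
                    size += 1
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if 0 <= ny < h and 0 <= nx < w and clipped[ny, nx] and not seen[ny, nx]:
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                sizes.append(size)
    total = sum(sizes)
    fd_percent = 100.0 * total / ring.sum()
    fda = (total / len(sizes)) * scale**2 if sizes else 0.0
    return fd_percent, fda, len(sizes)


class TestPhansalkar:
    def test_constant_image_has_no_deficit(self):
        img = np.ones((40, 40))
        # closed form: t = 1·(1 + 2e^{-10} - 0.25) ≈ 0.7501 < 1
        assert not phansalkar_binarize(img, PhansalkarParams(radius_px=5)).any()

    def test_constant_dark_image_all_deficit(self):
        img = np.full((40, 40), 0.1)
        # t = 0.1·(1 + 2e^{-1} - 0.25) ≈ 0.149 > 0.1
        assert phansalkar_binarize(img, PhansalkarParams(radius_px=5)).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 1, (32, 32))
        params = PhansalkarParams(radius_px=15)
        assert np.array_equal(phansalkar_binarize(img, params), phansalkar_oracle(img, params))

    def test_matches_oracle_small_radius(self, rng):
        img = rng.uniform(0, 1, (48, 48))
        params = PhansalkarParams(radius_px=4)
        assert np.array_equal(phansalkar_binarize(img, params), phansalkar_oracle(img, params))

    def test_recovers_planted_dark_disks(self, rng):
        img = np.full((128, 128), 0.9)
        yy, xx = np.mgrid[0:128, 0:128]
        disks = (np.hypot(yy - 40, xx - 40) <= 20) | (np.hypot(yy - 90, xx - 90) <= 18)
        img[disks] = 0.1
        img += rng.normal(0, 0.02, img.shape)
        out = phansalkar_binarize(img, PhansalkarParams(radius_px=15))
        dice = 2 * (out & disks).sum() / (out.sum() + disks.sum())
        assert dice > 0.9

    def test_affine_intensity_invariance(self, rng):
        img = rng.uniform(0, 1, (64, 64))
        params = PhansalkarParams(radius_px=8)
        assert np.array_equal(
            phansalkar_binarize(img, params),
            phansalkar_binarize(3.0 * img + 7.0, params),
        )

    def test_excluded_pixels_never_deficit_and_omitted(self, rng):
        img = rng.uniform(0, 1, (64, 64))
        valid = np.ones((64, 64), bool)
        valid[:, :20] = False
        out = phansalkar_binarize(img, PhansalkarParams(radius_px=8), valid_mask=valid)
        assert not out[:, :20].any()
        # far from the excluded strip the mask has no influence
        ref = phansalkar_binarize(img, PhansalkarParams(radius_px=8))
        assert np.array_equal(out[:, 40:], ref[:, 40:])

    def test_image_smaller_than_window_rejected(self):
        with pytest.raises(ValueError):
            phansalkar_binarize(np.ones((20, 20)), PhansalkarParams(radius_px=15))

    def test_non_finite_rejected(self):
        img = np.ones((40, 40))
        img[0, 0] = np.nan
        with pytest.raises(ValueError):
            phansalkar_binarize(img, PhansalkarParams(radius_px=5))


class TestFDMetrics:
    def test_empty_deficit(self):
        ring = np.zeros((32, 32), bool)
        ring[10:20, 10:20] = True
        m = fd_metrics(np.zeros((32, 32), bool), ring, 12.0)
        assert (m.fd_percent, m.fd_avg_area_um2, m.fd_count) == (0.0, 0.0, 0)

    def test_single_component_arithmetic(self):
        ring = np.zeros((32, 32), bool)
        ring[:10, :10] = True  # 100 px
        deficit = np.zeros((32, 32), bool)
        deficit[0, :10] = True  # 10 px strip
        m = fd_metrics(deficit, ring, 12.0)
        assert m.fd_percent == 10.0
        assert m.fd_count == 1
        assert m.fd_avg_area_um2 == 10 * 144.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        deficit = rng.random((64, 64)) < 0.3
        ring = rng.random((64, 64)) < 0.5
        if not ring.any():
            ring[0, 0] = True
        m = fd_metrics(deficit, ring, 12.0)
        fp, fa, fn = flood_fill_metrics(deficit, ring, 12.0)
        assert m.fd_percent == fp
        assert m.fd_count == fn
        assert m.fd_avg_area_um2 == fa

    @pytest.mark.parametrize("seed", range(3))
    def test_conservation_identity(self, seed):
        """FDn · FDa equals the total deficit area in the ring exactly
        (in px² before unit conversion)."""
        rng = np.random.default_rng(seed)
        deficit = rng.random((48, 48)) < 0.4
        ring = rng.random((48, 48)) < 0.6
        m = fd_metrics(deficit, ring, 10.0)
        total_px = (deficit & ring).sum()
        assert m.fd_count * (m.fd_avg_area_um2 / 100.0) == pytest.approx(total_px, abs=1e-9)

    def test_connectivity_four_vs_eight(self):
        deficit = np.zeros((16, 16), bool)
        deficit[2, 2] = deficit[3, 3] = True  # diagonal touch
        ring = np.ones((16, 16), bool)
        assert fd_metrics(deficit, ring, 10.0, connectivity=8).fd_count == 1
        assert fd_metrics(deficit, ring, 10.0, connectivity=4).fd_count == 2

    def test_empty_ring_flagged_undefined(self):
        m = fd_metrics(np.ones((8, 8), bool), np.zeros((8, 8), bool), 12.0)
        assert not m.defined
        assert np.isnan(m.fd_percent)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            fd_metrics(np.zeros((8, 8), bool), np.zeros((9, 9), bool), 12.0)


class TestFDMetricsProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @given(
        deficit=arrays(bool, (24, 24)),
        ring=arrays(bool, (24, 24)),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_metrics_ranges_and_conservation(self, deficit, ring):
        m = fd_metrics(deficit, ring, 10.0)
        if not ring.any():
            assert not m.defined
            return
        assert 0.0 <= m.fd_percent <= 100.0
        assert m.fd_count >= 0 and m.fd_avg_area_um2 >= 0.0
        total_px = (deficit & ring).sum()
        assert m.fd_count * m.fd_avg_area_um2 == pytest.approx(total_px * 100.0)


class TestMNVArea:
    def test_area_examples(self):
        mask = np.zeros((2000, 1), bool)
        mask[:1597] = True
        assert mnv_area(mask, 12.0) == pytest.approx(0.2300, abs=5e-5)
        assert mnv_area(np.ones((500, 500), bool), 12.0) == pytest.approx(36.0)
        one = np.zeros((4, 4), bool)
        one[0, 0] = True
        assert mnv_area(one, 10.0) == pytest.approx(1e-4)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mnv_area(np.zeros((8, 8), bool), 12.0)
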