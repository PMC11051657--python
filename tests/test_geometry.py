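"""Plane fitting, flattening, surface estimation and depth computation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lamellakit import geometry


def normal_equations_plane(pts):
    """Independent closed-form oracle: solve the 3x3 normal equations."""
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    A = np.array(
        [
            [np.sum(x * x), np.sum(x * y), np.sum(x)],
            [np.sum(x * y), np.sum(y * y), np.sum(y)],
            [np.sum(x), np.sum(y), len(x)],
        ]
    )
    b = np.array([np.sum(x * z), np.sum(y * z), np.sum(z)])
    return np.linalg.solve(A, b)


class TestFitReferencePlane:
    def test_exact_plane_interpolated(self, rng):
        x = rng.uniform(0, 100, 50)
        y = rng.uniform(0, 100, 50)
        z = 0.1 * x + 0.2 * y + 50
        a, b, c = geometry.fit_reference_plane(np.column_stack([x, y, z]))
        assert np.allclose([a, b, c], [0.1, 0.2, 50], atol=1e-9)

    def test_constant_plane(self, rng):
        pts = np.column_stack(
            [rng.uniform(0, 10, 20), rng.uniform(0, 10, 20), np.full(20, 42.0)]
        )
        assert np.allclose(geometry.fit_reference_plane(pts), [0, 0, 42], atol=1e-9)

    def test_noisy_plane_recovers_truth(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 500, 500)
        y = rng.uniform(0, 500, 500)
        z = 0.05 * x - 0.1 * y + 30 + rng.normal(0, 2, 500)
        a, b, c = geometry.fit_reference_plane(np.column_stack([x, y, z]))
        assert abs(a - 0.05) < 0.01 and abs(b + 0.1) < 0.01 and abs(c - 30) < 1

    def test_residuals_sum_to_zero(self, rng):
        pts = rng.uniform(0, 100, (40, 3))
        a, b, c = geometry.fit_reference_plane(pts)
        res = pts[:, 2] - (a * pts[:, 0] + b * pts[:, 1] + c)
        assert abs(res.sum()) < 1e-8 * len(pts)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 30)
        pts = rng.uniform(-50, 50, (n, 3))
        fitted = geometry.fit_reference_plane(pts)
        oracle = normal_equations_plane(pts)
        assert np.allclose(fitted, oracle, rtol=1e-6, atol=1e-6)

    @pytest.mark.parametrize(
        "pts",
        [
            np.array([[0.0, 0, 1], [1, 1, 2]]),  # too few
            np.array([[0.0, 0, 1], [1, 1, 2], [2, 2, 3], [3, 3, 1]]),  # collinear xy
        ],
    )
    def test_degenerate_geometry_raises(self, pts):
        with pytest.raises(geometry.DegenerateGeometryError, match="tomo_x"):
            geometry.fit_reference_plane(pts, tomogram_id="tomo_x")


class TestFlattenZ:
    def test_on_plane_gives_zero_and_identity_plane(self):
        df = pd.DataFrame({"x": [100.0], "y": [200.0], "z": [80.0]})
        out = geometry.flatten_z(df, (0.1, 0.2, 10.0))
        assert out["z_flat"].iloc[0] == pytest.approx(20.0)
        out0 = geometry.flatten_z(df, (0.0, 0.0, 0.0))
        assert (out0["z_flat"] == df["z"]).all()

    def test_flatten_then_refit_is_zero_plane(self, rng):
        x = rng.uniform(0, 300, 200)
        y = rng.uniform(0, 300, 200)
        z = 0.3 * x - 0.2 * y + 100 + rng.normal(0, 3, 200)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        plane = geometry.fit_reference_plane(df[["x", "y", "z"]].to_numpy())
        flat = geometry.flatten_z(df, plane)
        refit = geometry.fit_reference_plane(
            flat[["x", "y", "z_flat"]].to_numpy()
        )
        assert np.allclose(refit, [0, 0, 0], atol=1e-8)
        assert abs(flat["z_flat"].mean()) < 1e-8


def histogram_edge_oracle(z_nm, bin_width, fraction):
    """Brute-force edge scan on the same anchored histogram."""
    lo = np.floor(z_nm.min() / bin_width) - 1
    hi = np.ceil(z_nm.max() / bin_width) + 1
    edges = bin_width * np.arange(lo, hi + 1)
    counts, _ = np.histogram(z_nm, bins=edges)
    occ = np.nonzero(counts)[0]
    plateau = np.median(counts[occ[1:-1]])
    thr = fraction * plateau
    center = int(np.searchsorted(edges, np.median(z_nm)) - 1)
    i = j = center
    while i - 1 >= 0 and counts[i - 1] >= thr:
        i -= 1
    while j + 1 < len(counts) and counts[j + 1] >= thr:
        j += 1
    return edges[i], edges[j + 1]


class TestEstimateSurfaces:
    def test_uniform_slab_recovers_edges(self):
        rng = np.random.default_rng(5)
        z_nm = rng.uniform(-75, 75, 20000)
        z_vox = z_nm / 0.49  # pixel size 4.9 A
        zb, zt = geometry.estimate_surfaces(z_vox, 4.9, 5.0, 0.5)
        assert abs(zb + 75) <= 5 and abs(zt - 75) <= 5
        assert (zb, zt) == histogram_edge_oracle(z_nm, 5.0, 0.5)

    def test_offset_slab_thickness(self):
        rng = np.random.default_rng(6)
        z_nm = rng.uniform(10, 110, 20000)
        zb, zt = geometry.estimate_surfaces(z_nm / 0.49, 4.9, 5.0, 0.5)
        assert abs((zt - zb) - 100) <= 10

    @pytest.mark.parametrize("thickness", [50.0, 150.0, 250.0])
    def test_thickness_recovery_within_two_bins(self, thickness):
        rng = np.random.default_rng(int(thickness))
        z_nm = rng.uniform(-thickness / 2, thickness / 2, 12000)
        zb, zt = geometry.estimate_surfaces(z_nm * 10, 1.0, 5.0, 0.5)
        assert abs((zt - zb) - thickness) <= 2 * 5.0

    def test_insufficient_support(self):
        with pytest.raises(geometry.InsufficientSupportError):
            geometry.estimate_surfaces(np.arange(10.0), 4.9)

    def test_parameter_validation(self):
        z = np.random.default_rng(0).uniform(-10, 10, 500)
        with pytest.raises(ValueError):
            geometry.estimate_surfaces(z, 4.9, bin_width_nm=0)
        with pytest.raises(ValueError):
            geometry.estimate_surfaces(z, 4.9, dropoff_fraction=1.5)


class TestParticleDepth:
    @pytest.mark.parametrize(
        "z, expected",
        [(0.0, 75.0), (75.0, 0.0), (-60.0, 15.0)],
    )
    def test_hand_values(self, z, expected):
        depth, in_slab = geometry.particle_depth(np.array([z]), -75.0, 75.0)
        assert depth[0] == pytest.approx(expected)
        assert in_slab[0]

    def test_outside_slab_negative_and_flagged(self):
        depth, in_slab = geometry.particle_depth(np.array([90.0]), -75.0, 75.0)
        assert depth[0] == pytest.approx(-15.0) and not in_slab[0]

    @given(st.floats(-74.9, 74.9))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_reflection_invariance_and_bound(self, z):
        zb, zt = -75.0, 75.0
        d1, _ = geometry.particle_depth(np.array([z]), zb, zt)
        d2, _ = geometry.particle_depth(np.array([zb + zt - z]), zb, zt)
        assert d1[0] == pytest.approx(d2[0], abs=1e-9)
        assert d1[0] <= (zt - zb) / 2 + 1e-12


class TestWedgeProfile:
    def _frame(self, tomo, thickness):
        return geometry.LamellaFrame(
            tomogram_id=tomo,
            plane=(0, 0, 0),
            z_bottom_nm=-thickness / 2,
            z_top_nm=thickness / 2,
            bin_width_nm=5.0,
            n_support=100,
            pixel_size_a=4.9,
        )

    def test_single_frame(self):
        frame = self._frame("t1", 150.0)
        assert geometry.local_thickness(frame) == pytest.approx(150.0)
        prof = geometry.wedge_profile([frame])
        assert len(prof) == 1

    def test_profile_sorted_front_to_back(self):
        frames = [self._frame(f"t{i}", 50 + 20 * i) for i in range(5)]
        prof = geometry.wedge_profile(frames, positions=[4, 3, 2, 1, 0][::-1])
        assert list(prof["position"]) == sorted(prof["position"])

    def test_synthetic_wedge_monotone(self):
        # 0.02 nm thickness per nm of position over 5 positions
        positions = [0, 1000, 2000, 3000, 4000]
        frames = [self._frame(f"t{i}", 100 + 0.02 * p) for i, p in enumerate(positions)]
        prof = geometry.wedge_profile(frames, positions)
        assert (np.diff(prof["thickness_nm"]) >= 0).all()

    def test_invalid_frame_rejected(self):
        with pytest.raises(ValueError):
            self._frame("bad", -10.0)
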