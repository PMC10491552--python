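"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from us3dqa.acquisition import (
    AcquisitionConfig,
    FrameStream,
    ProbePose,
    TrackingNoise,
    TrackingStream,
    TremorModel,
    acquire,
)
from us3dqa.imaging import BeamProfile, ImageGeometry
from us3dqa.phantom import PhantomSpec, PointTarget, default_phantom
from us3dqa.reconstruct import stack_volume

NO_TREMOR = TremorModel(amplitude_mm=(0.0, 0.0, 0.0), drift_rate_mm_s=0.0,
                        angular_jitter_deg=0.0)
NO_NOISE = TrackingNoise(position_rms_mm=0.0, orientation_rms_deg=0.0,
                         temporal_offset_ms=0.0)


def geometry(rows, cols, dax=0.12, dlat=0.12, fps=15.0) -> ImageGeometry:
    return ImageGeometry(rows=rows, cols=cols, pixel_spacing_axial_mm=dax,
                         pixel_spacing_lateral_mm=dlat,
                         depth_cm=rows * dax / 10.0, fps=fps)


def wire_phantom(center=(0.0, 10.0, 3.0), speckle=0.0) -> PhantomSpec:
    """Uniform (surfaceless) background with a single wire target."""
    return PhantomSpec(surface_height=None, wire_targets=[PointTarget(center)],
                       speckle_sigma=speckle, elevation_extent_mm=(-5.0, 320.0))


@pytest.fixture(scope="session")
def ideal_ma_volume():
    """Noise-free motorized stack of the full default phantom (step 0.5)."""
    phantom = default_phantom(speckle_sigma=0.0)
    cfg = AcquisitionConfig(method="motorized", movement="stepwise",
                            step_size_mm=0.5, sweep_length_mm=60.0)
    frames, _ = acquire(phantom, cfg, BeamProfile(), ImageGeometry(), seed=0)
    return stack_volume(frames, 0.5), phantom


# ---------------------------------------------------------------------------
# Independent brute-force PNN oracle (explicit loops, no shared code paths)
# ---------------------------------------------------------------------------

def pnn_brute_force(frames: FrameStream, tracking: TrackingStream,
                    voxel_mm: float, fill_distance: int,
                    origin_mm, shape) -> np.ndarray:
    """Exhaustive deposit-and-fill reference implementation.

    Deposits every pixel of every frame into its nearest voxel with
    maximum compounding, then fills each empty voxel lying within the
    Chebyshev ``fill_distance`` of a filled voxel with the value of the
    Euclidean-nearest filled voxel (ties: smallest flattened voxel
    index). Returns a uint8 array; unreached voxels are 0.
    """
    geom = frames.geometry
    o = np.array([origin_mm[1], origin_mm[0], origin_mm[2]])  # (x, y, z)
    vol = -np.ones(shape, dtype=float)
    for m, t in enumerate(frames.timestamps):
        if t < tracking.timestamps[0] or t > tracking.timestamps[-1]:
            continue
        pos = np.array([np.interp(t, tracking.timestamps, tracking.positions[:, a])
                        for a in range(3)])
        ang = np.array([np.interp(t, tracking.timestamps, tracking.orientations[:, a])
                        for a in range(3)])
        rot = Rotation.from_euler("xyz", ang, degrees=True)
        for i in range(geom.rows):
            for j in range(geom.cols):
                p = pos + rot.apply([geom.lateral_coords_mm[j],
                                     geom.axial_coords_mm[i], 0.0])
                idx = np.rint((p - o) / voxel_mm).astype(int)  # (x, y, z)
                ii, jj, kk = idx[1], idx[0], idx[2]
                if 0 <= ii < shape[0] and 0 <= jj < shape[1] and 0 <= kk < shape[2]:
                    vol[ii, jj, kk] = max(vol[ii, jj, kk],
                                          float(frames.frames[m, i, j]))
    filled = vol >= 0
    out = vol.copy()
    fd = fill_distance
    for ii in range(shape[0]):
        for jj in range(shape[1]):
            for kk in range(shape[2]):
                if filled[ii, jj, kk]:
                    continue
                best = None
                for di in range(-fd, fd + 1):
                    for dj in range(-fd, fd + 1):
                        for dk in range(-fd, fd + 1):
                            if di == dj == dk == 0:
                                continue
                            ni, nj, nk = ii + di, jj + dj, kk + dk
                            if not (0 <= ni < shape[0] and 0 <= nj < shape[1]
                                    and 0 <= nk < shape[2]):
                                continue
                            if not filled[ni, nj, nk]:
                                continue
                            key = (di * di + dj * dj + dk * dk,
                                   (ni * shape[1] + nj) * shape[2] + nk)
                            if best is None or key < best[0]:
                                best = (key, vol[ni, nj, nk])
                if best is not None:
                    out[ii, jj, kk] = best[1]
    return np.where(out < 0, 0, out).astype(np.uint8)


def random_pnn_instance(seed: int):
    """A tiny random PNN problem: 3 small frames, jittered/tilted poses,
    an explicit 6x6x6 voxel grid."""
    rng = np.random.default_rng(seed)
    geom = geometry(4, 5, dax=0.25, dlat=0.25)
    n = 3
    frames = rng.integers(0, 256, size=(n, 4, 5), dtype=np.uint8)
    times = np.arange(n, dtype=float)
    positions = np.column_stack([
        rng.uniform(-0.3, 0.3, n),
        rng.uniform(-0.3, 0.3, n),
        np.arange(n) * 0.45 + rng.uniform(-0.15, 0.15, n),
    ])
    orientations = rng.uniform(-4.0, 4.0, (n, 3))
    stream = FrameStream(frames, times, geom)
    tracking = TrackingStream(times, positions, orientations)
    origin = (-0.75, -0.75, -0.4)  # (ax, lat, elev)
    shape = (6, 6, 6)
    return stream, tracking, origin, shape
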