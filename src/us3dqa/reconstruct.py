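"""3D volume reconstruction from 2D sweep data.

Motorized sweeps are stacked slice-by-slice into a 3D array — no
interpolation, the rail's step size *is* the elevation spacing. Freehand
sweeps are gridded by the pixel-nearest-neighbor (PNN) algorithm: every
frame pixel is mapped through its (interpolated) tracked pose onto an
isotropic voxel grid, collisions keep the maximum pixel value, and holes
within a small distance of filled voxels are closed with the value of
the nearest filled voxel. Before gridding, the constant clock offset
between tracking and image streams is estimated by cross-correlating the
tracked axial position with the image-derived axial motion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.spatial.transform import Rotation

from .acquisition import FrameStream, TrackingStream
from .imaging import ImageGeometry

__all__ = [
    "Volume",
    "PNNConfig",
    "stack_volume",
    "temporal_offset",
    "pnn_reconstruct",
    "read_volume",
    "write_volume",
]

logger = logging.getLogger(__name__)

#: Volume formats handled by read_volume/write_volume.
SUPPORTED_VOLUME_SUFFIXES = (".nrrd", ".nii", ".nii.gz", ".mha")


@dataclass
class Volume:
    """A reconstructed 3D gray volume.

    ``data`` is indexed (axial, lateral, elevation); ``spacing_mm`` and
    ``origin_mm`` follow the same axis order, with the origin expressed
    in phantom coordinates (axial depth y, lateral x, elevation z).
    """

    data: np.ndarray  # (ax, lat, elev) uint8
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive on all axes")

    def world_to_voxel(self, point_xyz_mm) -> np.ndarray:
        """Map an (x lateral, y axial, z elevation) mm point to fractional
        voxel indices (i axial, j lateral, k elevation)."""
        x, y, z = point_xyz_mm
        o = self.origin_mm
        s = self.spacing_mm
        return np.array([(y - o[0]) / s[0], (x - o[1]) / s[1], (z - o[2]) / s[2]])

    def voxel_to_world(self, ijk) -> np.ndarray:
        i, j, k = ijk
        o = self.origin_mm
        s = self.spacing_mm
        return np.array([o[1] + j * s[1], o[0] + i * s[0], o[2] + k * s[2]])


@dataclass
class PNNConfig:
    """Pixel-nearest-neighbor gridding parameters."""

    voxel_spacing_mm: float = 0.22
    fill_distance_px: int = 3
    compounding: str = "maximum"

    def __post_init__(self):
        if int(self.fill_distance_px) != self.fill_distance_px or self.fill_distance_px < 0:
            raise ValueError("fill_distance_px must be a non-negative integer")
        if self.compounding != "maximum":
            raise ValueError("only maximum-value compounding is supported")


def stack_volume(
    frames: FrameStream, step_size_mm: float, geom: ImageGeometry | None = None
) -> Volume:
    """Stack motorized-sweep frames into a volume — voxel (i, j, k) is
    exactly pixel (i, j) of frame k; elevation spacing is the step size."""
    geom = geom or frames.geometry
    arr = np.asarray(frames.frames)
    if arr.ndim != 3:
        raise ValueError("all frames must share the same shape")
    data = np.moveaxis(arr, 0, -1)  # (rows, cols, n)
    if frames.poses is not None:
        p0 = frames.poses[0].position
        origin = (p0[1], p0[0] + geom.lateral_coords_mm[0], p0[2])
    else:
        origin = (0.0, geom.lateral_coords_mm[0], 0.0)
    return Volume(
        np.ascontiguousarray(data),
        (geom.pixel_spacing_axial_mm, geom.pixel_spacing_lateral_mm, float(step_size_mm)),
        origin,
        provenance={"method": "stack", "step_size_mm": float(step_size_mm)},
    )


class UndefinedLagError(ValueError):
    """The streams carry too little motion to identify a clock offset."""


def _surface_rows(frames: FrameStream, threshold: float) -> np.ndarray:
    """Per-frame surface row: first axial index with gray >= threshold,
    median over the five central columns."""
    arr = frames.frames
    mid = arr.shape[2] // 2
    cols = arr[:, :, max(0, mid - 2): mid + 3]  # (N, rows, 5)
    supra = cols >= threshold
    any_ = supra.any(axis=1)
    first = supra.argmax(axis=1).astype(float)
    first[~any_] = np.nan
    return np.nanmedian(first, axis=1)


def temporal_offset(
    tracking: TrackingStream,
    frames: FrameStream,
    threshold: float = 100.0,
    max_lag_s: float = 0.25,
    lag_step_s: float = 0.002,
) -> float:
    """Estimate the tracking-vs-image clock offset in milliseconds.

    The image-derived axial motion signal (the surface row per frame,
    converted to mm) is cross-correlated, after linear detrending,
    against the tracked axial position interpolated at shifted frame
    times; the lag maximizing the normalized correlation is returned.
    A positive return value means tracking timestamps run ahead of the
    image clock (the paper's system calibrates at −30 ms).
    """
    tf = frames.timestamps
    tt = tracking.timestamps
    if min(tf[-1], tt[-1]) - max(tf[0], tt[0]) < 2.0:
        raise ValueError("streams must overlap by at least 2 s of motion")
    rows = _surface_rows(frames, threshold)
    if np.isnan(rows).any():
        raise UndefinedLagError("no suprathreshold surface in some frames")
    img_sig = -rows * frames.geometry.pixel_spacing_axial_mm  # ∝ probe axial position
    if np.std(img_sig) < 0.5 * frames.geometry.pixel_spacing_axial_mm:
        raise UndefinedLagError("image stream shows no axial motion")
    trk_sig = tracking.positions[:, 1]
    if np.std(trk_sig) < 1e-9:
        raise UndefinedLagError("tracking stream shows no axial motion")

    def detrend(t, v):
        a, b = np.polyfit(t, v, 1)
        return v - (a * t + b)

    img_d = detrend(tf, img_sig)
    lags = np.arange(-max_lag_s, max_lag_s + lag_step_s / 2, lag_step_s)
    best = (-np.inf, 0.0)
    for lag in lags:
        t_query = tf + lag
        inside = (t_query >= tt[0]) & (t_query <= tt[-1])
        if inside.sum() < max(8, 0.5 * tf.size):
            continue
        v = np.interp(t_query[inside], tt, trk_sig)
        v = detrend(tf[inside], v)
        u = img_d[inside] - img_d[inside].mean()
        v = v - v.mean()
        denom = np.linalg.norm(u) * np.linalg.norm(v)
        if denom == 0:
            continue
        r = float(u @ v / denom)
        if r > best[0]:
            best = (r, float(lag))
    if not np.isfinite(best[0]):
        raise UndefinedLagError("normalized correlation undefined at every lag")
    return best[1] * 1000.0


def _fill_offsets(fd: int) -> list[tuple[int, int, int]]:
    """Neighborhood offsets within Chebyshev radius fd, sorted by
    (squared Euclidean distance, offset lexicographic order) — the
    documented nearest-filled-voxel rule with smallest-voxel-index
    tie-break."""
    offs = [
        (di, dj, dk)
        for di in range(-fd, fd + 1)
        for dj in range(-fd, fd + 1)
        for dk in range(-fd, fd + 1)
        if (di, dj, dk) != (0, 0, 0)
    ]
    offs.sort(key=lambda o: (o[0] ** 2 + o[1] ** 2 + o[2] ** 2, o))
    return offs


def pnn_reconstruct(
    frames: FrameStream,
    tracking: TrackingStream,
    pnn: PNNConfig | None = None,
    origin_mm: tuple[float, float, float] | None = None,
    shape: tuple[int, int, int] | None = None,
) -> Volume:
    """Pixel-nearest-neighbor reconstruction with maximum compounding.

    Tracking timestamps must already be on the image clock (apply the
    :func:`temporal_offset` correction first). Frames without bracketing
    tracking samples are dropped with a logged count.

    Bin step: each frame pixel is mapped through the pose linearly
    interpolated at the frame time (linear in position and in the
    small-angle orientation triple) to its nearest voxel; colliding
    deposits keep the maximum value. Fill step: empty voxels within the
    Chebyshev ``fill_distance_px`` of any filled voxel receive the value
    of the Euclidean-nearest filled voxel (distance ties broken by the
    smallest voxel index); voxels farther away stay 0.
    """
    pnn = pnn or PNNConfig()
    geom = frames.geometry
    vs = pnn.voxel_spacing_mm
    tt = tracking.timestamps

    keep = (frames.timestamps >= tt[0]) & (frames.timestamps <= tt[-1])
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropping %d frames without bracketing tracking samples", dropped)
    if keep.sum() == 0:
        raise ValueError("no frames have bracketing tracking samples")

    tq = frames.timestamps[keep]
    pos = np.column_stack(
        [np.interp(tq, tt, tracking.positions[:, a]) for a in range(3)]
    )
    ori = np.column_stack(
        [np.interp(tq, tt, tracking.orientations[:, a]) for a in range(3)]
    )

    xj = geom.lateral_coords_mm
    yi = geom.axial_coords_mm
    gx, gy = np.meshgrid(xj, yi)
    base_pts = np.stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)], axis=1)

    def frame_world(m: int) -> np.ndarray:
        if np.all(ori[m] == 0.0):
            return pos[m] + base_pts
        return pos[m] + Rotation.from_euler("xyz", ori[m], degrees=True).apply(base_pts)

    # Bounds from frame corners — the pixel→world map is affine per frame.
    corners = np.array(
        [(xj[0], yi[0], 0.0), (xj[-1], yi[0], 0.0), (xj[0], yi[-1], 0.0), (xj[-1], yi[-1], 0.0)]
    )
    mins, maxs = [], []
    for m in range(tq.size):
        if np.all(ori[m] == 0.0):
            w = pos[m] + corners
        else:
            w = pos[m] + Rotation.from_euler("xyz", ori[m], degrees=True).apply(corners)
        mins.append(w.min(axis=0))
        maxs.append(w.max(axis=0))
    all_min = np.min(mins, axis=0)
    all_max = np.max(maxs, axis=0)
    if origin_mm is None:
        # origin in (ax, lat, elev) order from (x, y, z) bounds
        o_xyz = np.rint(all_min / vs) * vs
        origin_mm = (float(o_xyz[1]), float(o_xyz[0]), float(o_xyz[2]))
    if shape is None:
        o_xyz = np.array([origin_mm[1], origin_mm[0], origin_mm[2]])
        shape_xyz = np.rint((all_max - o_xyz) / vs).astype(int) + 1
        shape = (int(shape_xyz[1]), int(shape_xyz[0]), int(shape_xyz[2]))

    vol = np.full(shape, -1, dtype=np.int16)
    flat = vol.reshape(-1)
    o_xyz = np.array([origin_mm[1], origin_mm[0], origin_mm[2]])
    frames_kept = frames.frames[keep]
    for m in range(tq.size):
        w = frame_world(m)
        idx = np.rint((w - o_xyz) / vs).astype(np.int64)  # (P, 3) in (x, y, z)
        i, j, k = idx[:, 1], idx[:, 0], idx[:, 2]
        ok = (
            (i >= 0) & (i < shape[0])
            & (j >= 0) & (j < shape[1])
            & (k >= 0) & (k < shape[2])
        )
        lin = (i[ok] * shape[1] + j[ok]) * shape[2] + k[ok]
        vals = frames_kept[m].reshape(-1)[ok].astype(np.int16)
        # segmented max per voxel (much faster than np.maximum.at)
        order = np.argsort(lin, kind="stable")
        sl = lin[order]
        sv = vals[order]
        starts = np.flatnonzero(np.r_[True, sl[1:] != sl[:-1]])
        seg_max = np.maximum.reduceat(sv, starts)
        ulin = sl[starts]
        flat[ulin] = np.maximum(flat[ulin], seg_max)

    filled = vol >= 0
    fd = int(pnn.fill_distance_px)
    if fd > 0 and not filled.all():
        eligible = maximum_filter(filled.astype(np.uint8), size=2 * fd + 1).astype(bool)
        targets = np.argwhere(eligible & ~filled)
        if targets.size:
            ti, tj, tk = targets[:, 0], targets[:, 1], targets[:, 2]
            out_val = np.full(ti.size, -1, dtype=np.int16)
            unresolved = np.ones(ti.size, dtype=bool)
            for di, dj, dk in _fill_offsets(fd):
                if not unresolved.any():
                    break
                u = np.flatnonzero(unresolved)
                ni, nj, nk = ti[u] + di, tj[u] + dj, tk[u] + dk
                ok = (
                    (ni >= 0) & (ni < shape[0])
                    & (nj >= 0) & (nj < shape[1])
                    & (nk >= 0) & (nk < shape[2])
                )
                if not ok.any():
                    continue
                sel = u[ok]
                hit = filled[ni[ok], nj[ok], nk[ok]]
                sel = sel[hit]
                if sel.size:
                    out_val[sel] = vol[
                        ti[sel] + di, tj[sel] + dj, tk[sel] + dk
                    ]
                    unresolved[sel] = False
            resolved = out_val >= 0
            vol[ti[resolved], tj[resolved], tk[resolved]] = out_val[resolved]

    data = np.where(vol < 0, 0, vol).astype(np.uint8)
    return Volume(
        data,
        (vs, vs, vs),
        origin_mm,
        provenance={
            "method": "pnn",
            "voxel_spacing_mm": vs,
            "fill_distance_px": fd,
            "compounding": pnn.compounding,
            "dropped_frames": dropped,
        },
    )


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def write_volume(volume: Volume, path) -> None:
    """Write a volume to NRRD (primary) or NIfTI/MetaImage; array,
    spacing and origin round-trip losslessly."""
    import SimpleITK as sitk

    path = Path(path)
    if _suffix(path) not in SUPPORTED_VOLUME_SUFFIXES:
        raise ValueError(
            f"unsupported volume format {path.suffix!r}; supported: "
            f"{', '.join(SUPPORTED_VOLUME_SUFFIXES)}"
        )
    # sitk image axes: x = lateral, y = axial, z = elevation
    arr = np.ascontiguousarray(np.transpose(volume.data, (2, 0, 1)))  # (z, y, x)
    img = sitk.GetImageFromArray(arr)
    s = volume.spacing_mm
    o = volume.origin_mm
    img.SetSpacing((float(s[1]), float(s[0]), float(s[2])))
    img.SetOrigin((float(o[1]), float(o[0]), float(o[2])))
    sitk.WriteImage(img, str(path))


def read_volume(path) -> Volume:
    """Read a volume written by :func:`write_volume`."""
    import SimpleITK as sitk

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    if _suffix(path) not in SUPPORTED_VOLUME_SUFFIXES:
        raise ValueError(
            f"unsupported volume format {path.suffix!r}; supported: "
            f"{', '.join(SUPPORTED_VOLUME_SUFFIXES)}"
        )
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.ascontiguousarray(np.transpose(arr, (1, 2, 0)))  # (ax, lat, elev)
    sx, sy, sz = img.GetSpacing()
    ox, oy, oz = img.GetOrigin()
    return Volume(
        data.astype(np.uint8),
        (float(sy), float(sx), float(sz)),
        (float(oy), float(ox), float(oz)),
        provenance={"method": "file", "path": str(path)},
    )
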