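"""Phantom-based image-quality metrics on reconstructed 3D volumes.

Five metrics, following standard quality-control guidance for ultrasound
systems:

* **contrast resolution** — slope (gray value/dB) of the ordinary
  least-squares line through the mean gray values of the five grayscale
  cylinders plotted against their nominal levels (−9, −6, −3, +3, +6 dB);
* **axial / elevation resolution** — full width at half maximum (−6 dB
  width) of the line profile through a 0.1-mm wire target;
* **axial / elevation distance-calibration error** — absolute difference
  between the measured and the actual separation of the two most distant
  calibration filaments (30 mm axially, 50 mm in elevation):
  ``error = |D_a − D_m|``;
* **stability** — RMS (with min and max) of the slice-to-slice derivative
  of the segmented phantom-surface height along elevation, converted to
  mm by the axial voxel spacing: ``RMS = sqrt(mean(Df^2)) · Δ_ax``. The
  surface is segmented by thresholding the mid-lateral plane at gray 100;
  the baseline spans the central 25% of the elevation extent. The
  phantom's gentle curvature is deliberately not detrended.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .phantom import PhantomSpec
from .reconstruct import Volume

__all__ = [
    "ROISpec",
    "ContrastResult",
    "LineProfile",
    "ResolutionResult",
    "DistanceMeasurement",
    "SurfaceProfile",
    "StabilityResult",
    "contrast_resolution",
    "find_marker_peak",
    "distance_error",
    "line_profile",
    "fwhm",
    "surface_profile",
    "stability",
    "run_qa",
    "NoMarkerError",
    "SurfaceNotFoundError",
    "PeakClippedError",
]

logger = logging.getLogger(__name__)


class NoMarkerError(ValueError):
    """The ROI contains no peak above background."""


class SurfaceNotFoundError(ValueError):
    """Some baseline columns contain no suprathreshold surface pixel."""


class PeakClippedError(ValueError):
    """The half level is never crossed on one side of the peak."""


@dataclass(frozen=True)
class ROISpec:
    """Region of interest in voxel space.

    ``center_voxel`` is (i axial, j lateral, k elevation); ``shape`` is
    ``'box'`` (half-extents per axis, mm) or ``'cylinder'`` (radius in
    the axial–lateral plane plus half-length along elevation, mm).
    """

    center_voxel: tuple[int, int, int]
    shape: str = "box"
    extents_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    axis: str = "elevation"


def _roi_mask(volume: Volume, roi: ROISpec) -> np.ndarray:
    s = volume.spacing_mm
    ci, cj, ck = roi.center_voxel
    ii = (np.arange(volume.data.shape[0]) - ci) * s[0]
    jj = (np.arange(volume.data.shape[1]) - cj) * s[1]
    kk = (np.arange(volume.data.shape[2]) - ck) * s[2]
    if roi.shape == "box":
        return (
            (np.abs(ii)[:, None, None] <= roi.extents_mm[0])
            & (np.abs(jj)[None, :, None] <= roi.extents_mm[1])
            & (np.abs(kk)[None, None, :] <= roi.extents_mm[2])
        )
    if roi.shape == "cylinder":
        r, half_len = roi.extents_mm[0], roi.extents_mm[2]
        return (
            (ii[:, None, None] ** 2 + jj[None, :, None] ** 2 <= r**2)
            & (np.abs(kk)[None, None, :] <= half_len)
        )
    raise ValueError(f"unknown ROI shape {roi.shape!r}")


@dataclass
class ContrastResult:
    mean_grays: np.ndarray
    nominal_db: np.ndarray
    slope: float
    intercept: float
    r_squared: float


def contrast_resolution(
    volume: Volume,
    rois: list[ROISpec],
    nominal_levels_db,
    phantom: PhantomSpec | None = None,
) -> ContrastResult:
    """OLS regression of cylinder-ROI mean gray on nominal dB level."""
    levels = np.asarray(nominal_levels_db, dtype=float)
    if len(rois) != 5 or levels.size != 5:
        raise ValueError("contrast resolution needs exactly 5 ROIs and 5 levels")
    if phantom is not None:
        for roi in rois:
            c = volume.voxel_to_world(roi.center_voxel)
            for t in phantom.all_point_targets():
                if np.linalg.norm(np.asarray(t.center) - c) < max(roi.extents_mm):
                    logger.warning("contrast ROI at %s overlaps a wire/filament", c)
    means = np.array([volume.data[_roi_mask(volume, r)].mean() for r in rois])
    fit = sps.linregress(levels, means)
    return ContrastResult(means, levels, float(fit.slope), float(fit.intercept),
                          float(fit.rvalue**2))


def find_marker_peak(volume: Volume, search_roi: ROISpec) -> tuple[int, int, int]:
    """Locate a distance marker as the brightest voxel in the ROI.

    Ties on the maximum gray value are resolved to the tied voxel closest
    to the centroid of the tied set (the automated analogue of choosing
    the center pixel), remaining ties to the smallest voxel index.
    Raises :class:`NoMarkerError` when no voxel exceeds the ROI
    background (median) by 3 standard deviations.
    """
    mask = _roi_mask(volume, search_roi)
    if not mask.any():
        raise ValueError("ROI lies outside the volume")
    vals = volume.data[mask].astype(float)
    vmax = vals.max()
    if vmax <= np.median(vals) + 3.0 * vals.std():
        raise NoMarkerError("no marker peak above background + 3 sigma in ROI")
    coords = np.argwhere(mask & (volume.data == vmax))
    if len(coords) == 1:
        return tuple(int(c) for c in coords[0])
    centroid = coords.mean(axis=0)
    d2 = ((coords - centroid) ** 2).sum(axis=1)
    best = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], d2))[0]
    return tuple(int(c) for c in coords[best])


@dataclass
class DistanceMeasurement:
    actual_mm: float
    measured_mm: float
    error_mm: float


def distance_error(p1, p2, spacing_mm, actual_mm: float) -> DistanceMeasurement:
    """Distance-calibration error ``|D_a − D_m|`` with ``D_m`` the
    Euclidean marker separation in mm (per-axis voxel spacing)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.all(p1 == p2):
        raise ValueError("marker voxels must differ")
    d = (p1 - p2) * np.asarray(spacing_mm, dtype=float)
    dm = float(np.linalg.norm(d))
    return DistanceMeasurement(float(actual_mm), dm, abs(float(actual_mm) - dm))


@dataclass
class LineProfile:
    positions_mm: np.ndarray
    values: np.ndarray
    axis: str


def line_profile(volume: Volume, through: tuple[int, int, int], axis: str) -> LineProfile:
    """Gray values along the axial or elevation axis through a voxel."""
    i, j, k = through
    if axis == "axial":
        vals = volume.data[:, j, k].astype(float)
        pos = volume.origin_mm[0] + np.arange(vals.size) * volume.spacing_mm[0]
    elif axis == "elevation":
        vals = volume.data[i, j, :].astype(float)
        pos = volume.origin_mm[2] + np.arange(vals.size) * volume.spacing_mm[2]
    else:
        raise ValueError(
            f"unsupported profile axis {axis!r}: resolution is measured in the "
            "axial and elevation directions only"
        )
    return LineProfile(pos, vals, axis)


@dataclass
class ResolutionResult:
    fwhm_mm: float
    peak_gray: float
    half_level_gray: float
    crossings_mm: tuple[float, float]


def fwhm(profile: LineProfile) -> ResolutionResult:
    """Full width at half maximum of a line-profile peak.

    The background floor is the median of the outer 10% of samples at
    each end; the half level sits midway between floor and peak (−6 dB
    of the background-subtracted signal); the two crossings are located
    by linear interpolation between the bracketing samples nearest the
    peak on each side.
    """
    v = profile.values
    x = profile.positions_mm
    n = v.size
    tail = max(1, int(round(0.1 * n)))
    background = float(np.median(np.concatenate([v[:tail], v[-tail:]])))
    ipk = int(np.argmax(v))
    peak = float(v[ipk])
    if peak <= background:
        raise NoMarkerError("profile has no peak above background")
    half = background + (peak - background) / 2.0

    def crossing(direction: int) -> float:
        idx = ipk
        while 0 <= idx + direction < n and v[idx + direction] >= half:
            idx += direction
        nxt = idx + direction
        if nxt < 0 or nxt >= n:
            raise PeakClippedError(
                "half level never crossed on one side: peak clipped by volume edge"
            )
        frac = (v[idx] - half) / (v[idx] - v[nxt])
        return float(x[idx] + frac * (x[nxt] - x[idx]))

    left = crossing(-1)
    right = crossing(+1)
    return ResolutionResult(right - left, peak, half, (left, right))


@dataclass
class SurfaceProfile:
    columns: np.ndarray  # elevation indices x_1..x_n of the baseline
    f_px: np.ndarray  # perpendicular distance baseline→surface, pixels
    df_px: np.ndarray  # forward differences, n−1 entries
    axial_spacing_mm: float
    baseline_row: int


def surface_profile(
    volume: Volume,
    threshold_gray: float = 100.0,
    baseline_fraction: float = 0.25,
    baseline_offset_px: int = 10,
) -> SurfaceProfile:
    """Segment the phantom surface in the mid-lateral plane.

    Per elevation column, the surface is the first axial index with
    gray ≥ ``threshold_gray``. The baseline is a fixed axial row
    ``baseline_offset_px`` above the shallowest surface point, spanning
    the central ``baseline_fraction`` of the elevation columns;
    ``f(x)`` is the surface-to-baseline distance in pixels and ``Df``
    its forward difference.
    """
    plane = volume.data[:, volume.data.shape[1] // 2, :]  # (axial, elevation)
    n_elev = plane.shape[1]
    n = int(np.ceil(baseline_fraction * n_elev))
    start = (n_elev - n) // 2
    cols = np.arange(start, start + n)
    supra = plane[:, cols] >= threshold_gray
    has = supra.any(axis=0)
    if not has.all():
        missing = cols[~has].tolist()
        raise SurfaceNotFoundError(
            f"no suprathreshold surface pixel in elevation columns {missing}"
        )
    surf = supra.argmax(axis=0)
    baseline_row = int(surf.min()) - int(baseline_offset_px)
    f = surf.astype(float) - baseline_row
    return SurfaceProfile(cols, f, np.diff(f), float(volume.spacing_mm[0]),
                          baseline_row)


@dataclass
class StabilityResult:
    rms_mm: float
    min_df_mm: float
    max_df_mm: float
    n: int


def stability(profile: SurfaceProfile) -> StabilityResult:
    """RMS / min / max of the surface-height derivative, in mm.

    ``RMS = sqrt(mean(Df^2))``, converted to mm by the axial spacing;
    the surface curvature is kept (no detrending), so a perfectly smooth
    but curved surface yields a small nonzero RMS.
    """
    df = profile.df_px
    if df.size == 0:
        raise ValueError("Df is empty")
    s = profile.axial_spacing_mm
    return StabilityResult(
        float(np.sqrt(np.mean(df**2)) * s),
        float(df.min() * s),
        float(df.max() * s),
        int(profile.f_px.size),
    )


# ---------------------------------------------------------------------------
# Report row driving all five metrics from generator ground truth
# ---------------------------------------------------------------------------

#: Metric column names of a QA report row.
METRIC_COLUMNS = (
    "contrast_resolution",
    "resolution_axial",
    "resolution_elevation",
    "distance_calibration_error_axial",
    "distance_calibration_error_elevation",
    "stability_rms",
    "stability_min",
    "stability_max",
)


@dataclass
class QAReportRow:
    metrics: dict = field(default_factory=dict)
    absent: dict = field(default_factory=dict)  # metric -> reason

    def as_dict(self) -> dict:
        out = {}
        for name in METRIC_COLUMNS:
            out[name] = self.metrics.get(name, np.nan)
        return out


def _search_roi(volume: Volume, world_xyz, half_extent_mm=2.0) -> ROISpec | None:
    ijk = np.rint(volume.world_to_voxel(world_xyz)).astype(int)
    if np.any(ijk < 0) or np.any(ijk >= np.array(volume.data.shape)):
        return None
    return ROISpec(tuple(int(v) for v in ijk), "box",
                   (half_extent_mm, half_extent_mm, half_extent_mm))


def run_qa(
    volume: Volume,
    phantom: PhantomSpec,
    surface_threshold: float = 100.0,
) -> QAReportRow:
    """Compute all five metrics on a volume using the phantom's ground
    truth to place ROIs. Metrics that cannot be computed are recorded as
    absent with a reason, never silently dropped."""
    row = QAReportRow()

    def attempt(name, fn):
        try:
            row.metrics.update(fn())
        except Exception as exc:  # propagate reason with metric name attached
            row.absent[name] = f"{type(exc).__name__}: {exc}"

    def do_contrast():
        cyls = phantom.contrast_cylinders
        if len(cyls) != 5:
            raise ValueError("phantom does not expose 5 contrast cylinders")
        rois = []
        for c in cyls:
            x0, y0, _ = c.center
            # center the ROI on the volume's elevation mid-plane
            zmid = volume.origin_mm[2] + (volume.data.shape[2] // 2) * volume.spacing_mm[2]
            roi = _search_roi(volume, (x0, y0, zmid))
            if roi is None:
                raise ValueError("contrast cylinder outside volume")
            margin = c.radius_mm - max(volume.spacing_mm[:2]) * 2.0
            half_len = min(5.0, (volume.data.shape[2] // 2 - 1) * volume.spacing_mm[2])
            rois.append(ROISpec(roi.center_voxel, "cylinder",
                                (margin, margin, half_len)))
        res = contrast_resolution(volume, rois, [c.nominal_db for c in cyls])
        return {"contrast_resolution": res.slope}

    def do_resolution():
        if not phantom.wire_targets:
            raise ValueError("phantom has no resolution wire")
        roi = _search_roi(volume, phantom.wire_targets[0].center)
        if roi is None:
            raise ValueError("resolution wire outside volume")
        peak = find_marker_peak(volume, roi)
        out = {}
        out["resolution_axial"] = fwhm(line_profile(volume, peak, "axial")).fwhm_mm
        out["resolution_elevation"] = fwhm(
            line_profile(volume, peak, "elevation")
        ).fwhm_mm
        return out

    def do_axial_distance():
        fils = phantom.axial_filaments
        if len(fils) < 2:
            raise ValueError("phantom has no axial filament pair")
        ordered = sorted(fils, key=lambda t: t.center[1])
        pair = (ordered[0], ordered[-1])
        peaks = []
        for t in pair:
            roi = _search_roi(volume, t.center)
            if roi is None:
                raise ValueError("axial filament outside volume")
            peaks.append(find_marker_peak(volume, roi))
        res = distance_error(peaks[0], peaks[1], volume.spacing_mm,
                             phantom.nominal_axial_span_mm)
        return {"distance_calibration_error_axial": res.error_mm}

    def do_elev_distance():
        fils = phantom.elevation_filaments
        if len(fils) < 2:
            raise ValueError("phantom has no elevation filament pair")
        ordered = sorted(fils, key=lambda t: t.center[2])
        pair = (ordered[0], ordered[-1])
        peaks = []
        for t in pair:
            roi = _search_roi(volume, t.center)
            if roi is None:
                raise ValueError("elevation filament outside volume")
            peaks.append(find_marker_peak(volume, roi))
        res = distance_error(peaks[0], peaks[1], volume.spacing_mm,
                             phantom.nominal_elevation_span_mm)
        return {"distance_calibration_error_elevation": res.error_mm}

    def do_stability():
        prof = surface_profile(volume, threshold_gray=surface_threshold)
        res = stability(prof)
        return {
            "stability_rms": res.rms_mm,
            "stability_min": res.min_df_mm,
            "stability_max": res.max_df_mm,
        }

    attempt("contrast_resolution", do_contrast)
    attempt("resolution", do_resolution)
    attempt("distance_calibration_error_axial", do_axial_distance)
    attempt("distance_calibration_error_elevation", do_elev_distance)
    attempt("stability", do_stability)
    return row
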