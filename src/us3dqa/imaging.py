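"""Forward imaging model: Gaussian beam, image geometry, frame rendering.

The renderer is a geometric stand-in for the scanner's imaging chain: no
wave propagation, attenuation/TGC or refraction is modeled. Point targets
(0.1-mm wires and filaments) are rendered as the separable Gaussian beam
response; contrast cylinders as piecewise-constant gray regions through
the configured dB→gray map; the tissue surface as a bright interface with
the axial beam profile; speckle as additive zero-mean Gaussian gray noise
(a documented fidelity limit — real speckle is multiplicative and
correlated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .phantom import PhantomSpec

__all__ = ["BeamProfile", "ImageGeometry", "render_frame", "FWHM_TO_SIGMA"]

#: FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian profile.
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

_K = 4.0 * np.log(2.0)  # exp(-K (d/fwhm)^2) has full width fwhm at half max


@dataclass(frozen=True)
class BeamProfile:
    """Separable Gaussian point-spread function of the transducer.

    Widths are full widths at half maximum in mm; ``elevation_fwhm_mm``
    is the slice thickness at the focus depth (necessarily larger than
    the 0.1-mm wire diameter).
    """

    axial_fwhm_mm: float = 0.33
    lateral_fwhm_mm: float = 0.5
    elevation_fwhm_mm: float = 1.02

    def __post_init__(self):
        for name in ("axial_fwhm_mm", "lateral_fwhm_mm", "elevation_fwhm_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class ImageGeometry:
    """2D frame geometry: rows are axial (depth), columns lateral."""

    rows: int = 480
    cols: int = 420
    pixel_spacing_axial_mm: float = 0.11
    pixel_spacing_lateral_mm: float = 0.11
    depth_cm: float = 5.0
    fps: float = 15.0

    def __post_init__(self):
        for s in (self.pixel_spacing_axial_mm, self.pixel_spacing_lateral_mm):
            if not (0.08 <= s <= 0.30):
                raise ValueError(f"pixel spacing {s} mm outside [0.08, 0.30]")
        extent = self.rows * self.pixel_spacing_axial_mm
        if abs(extent - 10.0 * self.depth_cm) > 0.15 * 10.0 * self.depth_cm:
            raise ValueError(
                f"rows × axial spacing = {extent:.1f} mm does not match the "
                f"{self.depth_cm} cm depth setting"
            )

    @property
    def axial_coords_mm(self) -> np.ndarray:
        return np.arange(self.rows) * self.pixel_spacing_axial_mm

    @property
    def lateral_coords_mm(self) -> np.ndarray:
        return (np.arange(self.cols) - (self.cols - 1) / 2.0) * self.pixel_spacing_lateral_mm


class PoseOutsidePhantomError(ValueError):
    """The probe pose lies outside the phantom's rendered field of view."""


def _rotation(orientation_deg) -> Rotation | None:
    o = np.asarray(orientation_deg, dtype=float)
    if np.all(o == 0.0):
        return None
    return Rotation.from_euler("xyz", o, degrees=True)


def render_frame(
    phantom: PhantomSpec,
    pose,
    beam: BeamProfile,
    geom: ImageGeometry,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Render one 8-bit frame of ``phantom`` seen from ``pose``.

    ``pose`` is a :class:`~us3dqa.acquisition.ProbePose` (or anything with
    ``position`` (x, y, z) mm and ``orientation`` (rx, ry, rz) deg). The
    image origin (pixel (0, 0)) maps to the top-center of the transducer
    face; pixel (i, j) sits at probe-frame coordinates
    (lateral ``x_j``, axial ``y_i``, 0).

    Deterministic given the same ``rng`` seed state.
    """
    pos = np.asarray(pose.position, dtype=float)
    if not (
        phantom.lateral_extent_mm[0] <= pos[0] <= phantom.lateral_extent_mm[1]
        and phantom.elevation_extent_mm[0] <= pos[2] <= phantom.elevation_extent_mm[1]
    ):
        raise PoseOutsidePhantomError(
            f"probe at (x={pos[0]:.1f}, z={pos[2]:.1f}) mm is outside the phantom "
            f"extent x∈{phantom.lateral_extent_mm}, z∈{phantom.elevation_extent_mm}"
        )
    rot = _rotation(pose.orientation)

    xj = geom.lateral_coords_mm  # (cols,)
    yi = geom.axial_coords_mm  # (rows,)

    # Phantom-frame coordinates of every pixel.
    if rot is None:
        X = pos[0] + np.broadcast_to(xj, (geom.rows, geom.cols))
        Y = pos[1] + yi[:, None] + np.zeros((1, geom.cols))
        Z = np.full((geom.rows, geom.cols), pos[2])
    else:
        gx, gy = np.meshgrid(xj, yi)
        pts = np.stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)], axis=1)
        world = pos + rot.apply(pts)
        X = world[:, 0].reshape(geom.rows, geom.cols)
        Y = world[:, 1].reshape(geom.rows, geom.cols)
        Z = world[:, 2].reshape(geom.rows, geom.cols)

    img = np.full((geom.rows, geom.cols), float(phantom.water_gray))

    # Tissue background below the surface, plus the bright interface line.
    if phantom.surface_height is not None:
        h = phantom.surface_height(X, Z)
        img[Y >= h] = phantom.background_gray
        d = Y - h
        band = np.abs(d) < 2.0 * beam.axial_fwhm_mm
        if np.any(band):
            img[band] = np.maximum(
                img[band],
                phantom.surface_gray
                * np.exp(-_K * (d[band] / beam.axial_fwhm_mm) ** 2),
            )

    # Contrast cylinders (axis along elevation).
    for cyl in phantom.contrast_cylinders:
        cx, cy, cz = cyl.center
        mask = (X - cx) ** 2 + (Y - cy) ** 2 <= cyl.radius_mm**2
        if np.isfinite(cyl.half_length_mm):
            mask &= np.abs(Z - cz) <= cyl.half_length_mm
        img[mask] = phantom.cylinder_gray(cyl.nominal_db)

    # Point targets: separable Gaussian beam response in the probe frame.
    for tgt in phantom.all_point_targets():
        t = np.asarray(tgt.center, dtype=float)
        d = t - pos if rot is None else rot.inv().apply(t - pos)
        dx, dy, dz = d
        if abs(dz) > 4.0 * beam.elevation_fwhm_mm:
            continue
        amp = phantom.target_gray * np.exp(-_K * (dz / beam.elevation_fwhm_mm) ** 2)
        gy_ = np.exp(-_K * ((yi - dy) / beam.axial_fwhm_mm) ** 2)
        gx_ = np.exp(-_K * ((xj - dx) / beam.lateral_fwhm_mm) ** 2)
        img += amp * np.outer(gy_, gx_)

    if phantom.speckle_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        elif not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        img += rng.normal(0.0, phantom.speckle_sigma, img.shape)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)
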