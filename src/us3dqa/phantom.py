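"""Digital calibration phantom for 3D ultrasound quality assurance.

The phantom emulates a CIRS-040GSE-style multi-purpose grayscale phantom:
five grayscale contrast cylinders (nominal −9, −6, −3, +3, +6 dB), 0.1-mm
nylon wire point targets, vertical (axial) and horizontal (elevation)
distance-calibration filament groups at 10-mm spacing, and a gently curved
tissue surface under a ~10-mm water standoff (the water well used to mimic
a submerged specimen).

Coordinate convention (used everywhere in this package):

* ``x`` — lateral (image columns), mm, centered on the probe midline,
* ``y`` — axial depth (image rows), mm, positive downward from the
  transducer face,
* ``z`` — elevation (sweep direction, volume slices), mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ContrastCylinder",
    "PointTarget",
    "PhantomSpec",
    "default_phantom",
    "flat_surface_phantom",
    "jittered_surface",
    "apply_calibration_scale",
]

#: Nominal contrast levels available on the grayscale target group, dB.
NOMINAL_CONTRAST_LEVELS = (-9.0, -6.0, -3.0, 3.0, 6.0)

#: Nominal filament-group spans used for distance calibration, mm.
AXIAL_SPAN_MM = 30.0
ELEVATION_SPAN_MM = 50.0
FILAMENT_SPACING_MM = 10.0
WIRE_DIAMETER_MM = 0.1


@dataclass(frozen=True)
class ContrastCylinder:
    """A grayscale contrast cylinder with its axis along elevation.

    ``center`` is (x, y, z) mm; ``z`` is only meaningful when
    ``half_length_mm`` is finite.
    """

    center: tuple[float, float, float]
    radius_mm: float
    nominal_db: float
    half_length_mm: float = np.inf


@dataclass(frozen=True)
class PointTarget:
    """A thin filament/wire crossing the scan plane; imaged as a point."""

    center: tuple[float, float, float]
    diameter_mm: float = WIRE_DIAMETER_MM


@dataclass
class PhantomSpec:
    """Geometric and echogenic ground truth of the digital phantom.

    Parameters
    ----------
    surface_height
        Vectorized callable ``(x_mm, z_mm) -> axial depth mm`` of the
        tissue surface, or ``None`` for a phantom without a surface
        (used by some synthetic test fixtures).
    water_standoff_mm
        Depth of the water column above the shallowest surface point.
    background_gray
        Mean echo level of the tissue background (8-bit gray).
    water_gray
        Mean echo level of the water standoff.
    surface_gray
        Peak brightness of the surface interface line.
    target_gray
        Peak amplitude added by a wire/filament response.
    speckle_sigma
        Scale of the additive zero-mean gray-value noise.
    contrast_slope_gray_per_db
        Slope ``g`` of the linear dB→gray map ``gray = background + g·dB``
        used for the contrast cylinders when ``contrast_mode='linear'``.
    contrast_mode
        ``'linear'`` (default) or ``'amplitude'``
        (``gray = background · 10^(dB/20)``).
    lateral_extent_mm, elevation_extent_mm
        Valid (min, max) probe positions; poses outside raise at render
        time.
    """

    surface_height: Callable | None
    water_standoff_mm: float = 10.0
    contrast_cylinders: list[ContrastCylinder] = field(default_factory=list)
    wire_targets: list[PointTarget] = field(default_factory=list)
    axial_filaments: list[PointTarget] = field(default_factory=list)
    elevation_filaments: list[PointTarget] = field(default_factory=list)
    background_gray: float = 90.0
    water_gray: float = 8.0
    surface_gray: float = 220.0
    target_gray: float = 160.0
    speckle_sigma: float = 6.0
    contrast_slope_gray_per_db: float = 6.3
    contrast_mode: str = "linear"
    lateral_extent_mm: tuple[float, float] = (-25.0, 25.0)
    elevation_extent_mm: tuple[float, float] = (-5.0, 65.0)
    nominal_axial_span_mm: float = AXIAL_SPAN_MM
    nominal_elevation_span_mm: float = ELEVATION_SPAN_MM

    # -- ground-truth accessors -------------------------------------------------

    def cylinder_gray(self, nominal_db: float) -> float:
        """Noise-free interior gray value of a cylinder at ``nominal_db``."""
        if self.contrast_mode == "linear":
            return self.background_gray + self.contrast_slope_gray_per_db * nominal_db
        if self.contrast_mode == "amplitude":
            return self.background_gray * 10.0 ** (nominal_db / 20.0)
        raise ValueError(f"unknown contrast_mode {self.contrast_mode!r}")

    def all_point_targets(self) -> list[PointTarget]:
        return list(self.wire_targets) + list(self.axial_filaments) + list(
            self.elevation_filaments
        )

    def target_positions(self) -> dict[str, np.ndarray]:
        """Exact (x, y, z) mm coordinates of every rendered point target."""
        return {
            "wires": np.array([t.center for t in self.wire_targets]).reshape(-1, 3),
            "axial_filaments": np.array(
                [t.center for t in self.axial_filaments]
            ).reshape(-1, 3),
            "elevation_filaments": np.array(
                [t.center for t in self.elevation_filaments]
            ).reshape(-1, 3),
        }


def default_phantom(
    curvature_amplitude_mm: float = 0.8,
    contrast_slope_gray_per_db: float = 6.3,
    speckle_sigma: float = 6.0,
) -> PhantomSpec:
    """Build the default phantom.

    Layout (mm): surface at 10-mm depth (the water well) with gentle
    quadratic curvature; a vertical group of four axial filaments at
    x = −12, z = 30, depths 20…50 (30-mm span, 10-mm spacing); six
    elevation filaments at x = 12, depth 20, z = 5…55 (50-mm span); a
    dedicated 0.1-mm resolution wire at 1-cm phantom depth (20 mm in the
    image, under the 10-mm standoff); five contrast cylinders of radius
    3.5 mm at 35-mm depth, laterally spread, levels −9…+6 dB.
    """

    def surface(x, z):
        x = np.asarray(x, dtype=float)
        z = np.asarray(z, dtype=float)
        return 10.0 + curvature_amplitude_mm * (
            (x / 23.0) ** 2 + ((z - 30.0) / 30.0) ** 2
        )

    cylinders = [
        ContrastCylinder((x0, 35.0, 30.0), 3.5, db)
        for x0, db in zip((-18.0, -9.0, 0.0, 9.0, 18.0), NOMINAL_CONTRAST_LEVELS)
    ]
    axial = [PointTarget((-12.0, 20.0 + d, 30.0)) for d in (0.0, 10.0, 20.0, 30.0)]
    elev = [PointTarget((12.0, 20.0, 5.0 + 10.0 * k)) for k in range(6)]
    wire = [PointTarget((4.5, 20.0, 25.0))]
    return PhantomSpec(
        surface_height=surface,
        contrast_cylinders=cylinders,
        wire_targets=wire,
        axial_filaments=axial,
        elevation_filaments=elev,
        contrast_slope_gray_per_db=contrast_slope_gray_per_db,
        speckle_sigma=speckle_sigma,
    )


def flat_surface_phantom(
    surface_depth_mm: float = 10.0, speckle_sigma: float = 0.0
) -> PhantomSpec:
    """A minimal phantom with a flat surface and no targets."""

    def surface(x, z):
        return np.broadcast_arrays(
            np.full_like(np.asarray(x, dtype=float), surface_depth_mm),
            np.asarray(z, dtype=float),
        )[0]

    return PhantomSpec(surface_height=surface, speckle_sigma=speckle_sigma)


def jittered_surface(
    base_depth_mm: float,
    slice_positions_mm: Sequence[float],
    increment_std_mm: float,
    rng: np.random.Generator,
) -> Callable:
    """Surface-height function carrying a per-slice random-walk jitter.

    The surface depth is piecewise constant in elevation: at the k-th
    slice position it equals ``base + cumsum(N(0, increment_std))_k``, so
    consecutive slice-to-slice height *increments* are i.i.d. Gaussian
    with the requested standard deviation — the forward model behind the
    stability (surface-smoothness) metric.
    """
    z_grid = np.asarray(slice_positions_mm, dtype=float)
    heights = base_depth_mm + np.cumsum(
        rng.normal(0.0, increment_std_mm, size=z_grid.size)
    )

    def surface(x, z):
        x = np.asarray(x, dtype=float)
        z = np.asarray(z, dtype=float)
        k = np.clip(np.searchsorted(z_grid, z, side="right") - 1, 0, z_grid.size - 1)
        return np.broadcast_arrays(heights[k], x)[0]

    return surface


def apply_calibration_scale(
    phantom: PhantomSpec,
    axial_scale: float = 1.0,
    elevation_scale: float = 1.0,
) -> PhantomSpec:
    """Return a phantom whose rendered target coordinates carry a scanner
    distance-calibration error.

    A miscalibrated scan converter maps true distances to image distances
    through a scale factor; applying ``axial_scale`` (resp.
    ``elevation_scale``) rescales every point-target depth about the
    shallowest axial filament (resp. elevation coordinate about the first
    elevation filament), so a filament pair with nominal span ``D_a``
    renders at ``D_a·scale``. The nominal spans (the ground-truth ``D_a``
    of Eq.-style distance-error measurements) are left untouched.
    """
    targets = phantom.target_positions()

    def scale_group(group: list[PointTarget], axis: int, about: float, s: float):
        return [
            PointTarget(
                tuple(
                    c if i != axis else about + (c - about) * s
                    for i, c in enumerate(t.center)
                ),
                t.diameter_mm,
            )
            for t in group
        ]

    axial = list(phantom.axial_filaments)
    elev = list(phantom.elevation_filaments)
    if axial and axial_scale != 1.0:
        about = float(min(t.center[1] for t in axial))
        axial = scale_group(axial, 1, about, axial_scale)
    if elev and elevation_scale != 1.0:
        about = float(min(t.center[2] for t in elev))
        elev = scale_group(elev, 2, about, elevation_scale)
    del targets
    return replace(phantom, axial_filaments=axial, elevation_filaments=elev)
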