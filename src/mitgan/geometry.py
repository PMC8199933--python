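"""Imaging grid, coil array and conductivity phantoms.

The imaging domain is a circular field of radius ``field_radius`` (default
0.1 m) sampled on a uniform square lattice.  Pixels whose centers fall inside
the circle are "active"; the conductivity image is the vector of values over
active pixels in row-major lattice order.  With the default 67x67 lattice the
circular mask keeps exactly 3409 pixels.

Coordinate conventions (fixed; the measurement/pixel correspondence used by
the data-augmentation rotation depends on them):

* origin at the field center, x rightward, y upward;
* polar angle theta measured counterclockwise from +x, in degrees;
* pixels enumerated row-major over the full lattice, from y = -R upward,
  x = -R rightward, skipping masked-out nodes;
* coils numbered counterclockwise starting at angle 0.

Anomalies are spheres in the physical model; on the 2-D imaging plane they
are rasterized as their equatorial disks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Conductivity of healthy background tissue, S/m.
BACKGROUND_CONDUCTIVITY = 0.25
#: Conductivity of the anomaly (hematoma-like inclusion), S/m.
ANOMALY_CONDUCTIVITY = 0.05
#: Sphere anomaly radius, m.
ANOMALY_RADIUS = 0.02
#: Radius of the circular imaging field, m.
FIELD_RADIUS = 0.1
#: Pixels per axis of the standard sampling lattice.
SIDE_COUNT = 67


@dataclass(frozen=True)
class ImagingGrid:
    """Uniform square lattice with a circular active-pixel mask.

    Attributes
    ----------
    side_count : int
        Lattice nodes per axis.
    field_radius : float
        Radius of the circular imaging field, m.
    pixel_centers : (active_count, 2) ndarray
        Cartesian coordinates of active pixel centers, row-major order.
    active_mask : (side_count, side_count) bool ndarray
        True where the lattice node is inside the field.
    """

    side_count: int
    field_radius: float
    pixel_centers: np.ndarray
    active_mask: np.ndarray

    @property
    def active_count(self) -> int:
        return self.pixel_centers.shape[0]

    @property
    def pixel_spacing(self) -> float:
        if self.side_count == 1:
            return 2.0 * self.field_radius
        return 2.0 * self.field_radius / (self.side_count - 1)

    @property
    def pixel_area(self) -> float:
        return self.pixel_spacing**2

    def embed(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter an active-pixel vector back onto the full square lattice."""
        values = np.asarray(values)
        if values.shape[-1] != self.active_count:
            raise ValueError(
                f"expected {self.active_count} active-pixel values, "
                f"got {values.shape[-1]}"
            )
        img = np.full(self.active_mask.shape, fill, dtype=float)
        img[self.active_mask] = values
        return img


@dataclass(frozen=True)
class CoilArray:
    """Circular array of identical excitation/detection coils.

    Defaults follow an 8-channel bench: eight 30-turn coils of radius
    0.025 m, centers 0.11 m from the field center, driven at 1 A rms,
    10 MHz, numbered counterclockwise from angle 0.
    """

    coil_count: int = 8
    coil_radius: float = 0.025
    turns: int = 30
    center_distance: float = 0.11
    current_rms: float = 1.0
    frequency: float = 1.0e7

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.coil_count) * (360.0 / self.coil_count)

    @property
    def centers(self) -> np.ndarray:
        """(coil_count, 2) Cartesian coil centers."""
        th = np.deg2rad(self.angles_deg)
        return self.center_distance * np.column_stack([np.cos(th), np.sin(th)])

    @property
    def measurement_count(self) -> int:
        """Distinct (excite, receive) pairs per full excitation cycle."""
        return self.coil_count * (self.coil_count - 1)

    @property
    def dipole_moment(self) -> float:
        """Magnetic dipole moment of one coil, A*m^2 (turns * I * area)."""
        return self.turns * self.current_rms * np.pi * self.coil_radius**2


@dataclass(frozen=True)
class AnomalySpec:
    """A spherical anomaly given by the polar position of its center."""

    rho: float
    theta_deg: float
    radius: float = ANOMALY_RADIUS
    conductivity: float = ANOMALY_CONDUCTIVITY

    def __post_init__(self):
        if self.rho < 0:
            raise ValueError(f"rho must be >= 0, got {self.rho}")
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")

    @property
    def center(self) -> np.ndarray:
        th = np.deg2rad(self.theta_deg)
        return self.rho * np.array([np.cos(th), np.sin(th)])

    def rotated(self, steps_45deg: int) -> "AnomalySpec":
        return replace(self, theta_deg=(self.theta_deg + 45.0 * steps_45deg) % 360.0)


@dataclass(frozen=True)
class Phantom:
    """Conductivity distribution over the active pixels of a grid.

    ``specs`` records the anomaly provenance when the phantom was built by
    :func:`place_anomalies`; rotation requires it.
    """

    grid: ImagingGrid
    values: np.ndarray
    background: float = BACKGROUND_CONDUCTIVITY
    specs: tuple[AnomalySpec, ...] | None = field(default=None, compare=False)

    @property
    def delta(self) -> np.ndarray:
        """Conductivity perturbation relative to the homogeneous background."""
        return self.values - self.background


def build_grid(side_count: int = SIDE_COUNT, field_radius: float = FIELD_RADIUS) -> ImagingGrid:
    """Build the circular imaging grid.

    Pixel centers lie on ``linspace(-R, R, side_count)`` per axis and a pixel
    is active iff its center is within ``field_radius`` of the origin
    (boundary inclusive).  This convention yields exactly 3409 active pixels
    at ``side_count=67`` and is symmetric under the dihedral group of the
    square.
    """
    if side_count < 1:
        raise ValueError(f"side_count must be >= 1, got {side_count}")
    if field_radius <= 0:
        raise ValueError(f"field_radius must be > 0, got {field_radius}")
    if side_count == 1:
        axis = np.array([0.0])
    else:
        axis = np.linspace(-field_radius, field_radius, side_count)
    X, Y = np.meshgrid(axis, axis)  # row-major: rows sweep y, cols sweep x
    # small tolerance so boundary nodes are robust to floating rounding
    mask = X**2 + Y**2 <= field_radius**2 * (1 + 1e-12)
    centers = np.column_stack([X[mask], Y[mask]])
    return ImagingGrid(side_count, field_radius, centers, mask)


def build_coil_array(**kwargs) -> CoilArray:
    """Construct a :class:`CoilArray`; keyword arguments override defaults."""
    arr = CoilArray(**kwargs)
    if arr.coil_count < 2:
        raise ValueError(f"coil_count must be >= 2, got {arr.coil_count}")
    return arr


def place_anomalies(
    grid: ImagingGrid,
    anomalies: Sequence[AnomalySpec],
    background: float = BACKGROUND_CONDUCTIVITY,
) -> Phantom:
    """Rasterize anomaly disks onto a homogeneous background.

    A pixel takes an anomaly's conductivity iff its center lies strictly
    within the anomaly radius of the anomaly center (the disk cross-section
    of the sphere on the imaging plane).  Later anomalies overwrite earlier
    ones where disks overlap.
    """
    values = np.full(grid.active_count, background, dtype=float)
    for spec in anomalies:
        if spec.rho - spec.radius >= grid.field_radius:
            raise ValueError(
                f"anomaly at rho={spec.rho} r={spec.radius} lies entirely "
                f"outside the field of radius {grid.field_radius}"
            )
        d2 = np.sum((grid.pixel_centers - spec.center) ** 2, axis=1)
        values[d2 < spec.radius**2] = spec.conductivity
    return Phantom(grid, values, background, specs=tuple(anomalies))


def rotate_phantom(phantom: Phantom, steps_45deg: int) -> Phantom:
    """Rotate a phantom by ``steps_45deg * 45`` degrees counterclockwise.

    Rotation acts on the recorded anomaly specs (polar angle shift) followed
    by re-rasterization on the same grid, so repeated rotation does not
    accumulate resampling error.
    """
    if phantom.specs is None:
        raise TypeError("phantom has no anomaly-spec provenance; cannot rotate")
    rotated = [s.rotated(steps_45deg) for s in phantom.specs]
    return place_anomalies(phantom.grid, rotated, phantom.background)
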