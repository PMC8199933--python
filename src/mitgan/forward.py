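"""Surrogate forward model: dipole coil fields, sensitivity matrix, noise.

A full eddy-current finite-element solve is out of scope; the forward map is
the standard linearization of magnetic induction tomography.  The phase
perturbation of the voltage induced on receive coil j when coil i excites is,
to first order in the conductivity perturbation,

    dV_ij = omega * integral  A_i(r) . A_j(r)  dsigma(r)  dr

where A_k is the magnetic vector potential of coil k in the imaging plane.
Coils are modelled as magnetic dipoles normal to the plane, so A_k is the
azimuthal field of a dipole: magnitude proportional to
turns * current * coil_area / distance^2.  Discretized on the imaging grid
this gives the sensitivity matrix S with one row per ordered (excite,
receive) pair and one column per active pixel:

    S[(i,j), p] = scale * omega * A_i(p) . A_j(p) * pixel_area.

The model is reciprocal (row (i,j) == row (j,i)), weighs the field center
less than the periphery (soft-field effect), and inherits the coil array's
8-fold rotational symmetry, which the data-augmentation scheme relies on.
Absolute calibration of phase units is deliberately absorbed into a single
global ``scale`` (and later into dataset min-max normalization): only the
spatial structure of S matters downstream.

Row ordering is excitation-major with receivers enumerated cyclically from
the excitation coil: (1,2) ... (1,8), (2,3) ... (2,8), (2,1), (3,4), ...
Under this ordering a 45 degree counterclockwise rotation of the phantom is
exactly a forward roll of the 56-vector by coil_count-1 = 7 positions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import CoilArray, ImagingGrid, Phantom, place_anomalies, AnomalySpec

MU0_OVER_4PI = 1.0e-7  # vacuum permeability / 4 pi, T*m/A


@dataclass(frozen=True)
class MeasurementFrame:
    """One full excitation cycle of boundary phase differences.

    ``values`` holds the 56 phase differences relative to the homogeneous
    background measurement (difference imaging), ``snr_db`` the SNR of any
    added noise (``inf`` for noiseless), ``seed`` the noise seed.
    """

    values: np.ndarray
    snr_db: float = np.inf
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not (self.snr_db > 0):
            raise ValueError(f"snr_db must be in (0, inf], got {self.snr_db}")


@dataclass(frozen=True)
class SensitivityModel:
    """Linearized forward map V = S (sigma - background).

    Attributes
    ----------
    matrix : (n_pairs, active_count) ndarray
    pairs : list of (excite, receive) 1-based coil index tuples, row order.
    """

    matrix: np.ndarray
    pairs: tuple[tuple[int, int], ...]
    grid: ImagingGrid
    coils: CoilArray
    scale: float

    @property
    def measurement_count(self) -> int:
        return self.matrix.shape[0]


def measurement_pairs(coil_count: int = 8) -> tuple[tuple[int, int], ...]:
    """Ordered (excite, receive) pairs, receivers cyclic from the exciter."""
    pairs = []
    for i in range(1, coil_count + 1):
        for step in range(1, coil_count):
            j = (i - 1 + step) % coil_count + 1
            pairs.append((i, j))
    return tuple(pairs)


def coil_vector_potential(coils: CoilArray, coil_index: int, points: np.ndarray) -> np.ndarray:
    """In-plane vector potential of one coil at the given points.

    The coil is a magnetic dipole of moment ``turns * I * pi * r^2`` normal
    to the imaging plane; its vector potential in the plane is azimuthal
    about the coil center with magnitude ``mu0/(4 pi) * m / d^2``.

    Parameters
    ----------
    coil_index : 1-based coil number.
    points : (N, 2) Cartesian coordinates, m.

    Returns
    -------
    (N, 2) ndarray of vector-potential components, T*m.
    """
    if not 1 <= coil_index <= coils.coil_count:
        raise ValueError(f"coil_index must be in 1..{coils.coil_count}")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    rel = points - coils.centers[coil_index - 1]
    d2 = np.sum(rel**2, axis=1)
    if np.any(d2 == 0):
        raise ZeroDivisionError("vector potential is singular at the coil center")
    d = np.sqrt(d2)
    # azimuthal direction: z_hat x u_hat = (-u_y, u_x)
    az = np.column_stack([-rel[:, 1], rel[:, 0]]) / d[:, None]
    mag = MU0_OVER_4PI * coils.dipole_moment / d2
    return mag[:, None] * az


def build_sensitivity(grid: ImagingGrid, coils: CoilArray) -> SensitivityModel:
    """Assemble the reciprocity-symmetric sensitivity matrix.

    The global scale is calibrated once so that a standard anomaly (radius
    0.02 m, conductivity 0.05 S/m on the 0.25 S/m background) placed halfway
    out along +x produces a peak |signal| of exactly 1.  This fixes the
    otherwise arbitrary phase units; it has no effect downstream because the
    dataset is min-max normalized.
    """
    omega = 2 * np.pi * coils.frequency
    A = np.stack(
        [coil_vector_potential(coils, i, grid.pixel_centers) for i in range(1, coils.coil_count + 1)]
    )  # (n_coils, n_pix, 2)
    pairs = measurement_pairs(coils.coil_count)
    raw = np.empty((len(pairs), grid.active_count))
    for row, (i, j) in enumerate(pairs):
        raw[row] = omega * np.sum(A[i - 1] * A[j - 1], axis=1) * grid.pixel_area
    # calibration phantom: default anomaly halfway between center and boundary
    ref = place_anomalies(grid, [AnomalySpec(rho=grid.field_radius / 2, theta_deg=0.0)])
    peak = np.max(np.abs(raw @ ref.delta))
    scale = 1.0 / peak if peak > 0 else 1.0
    return SensitivityModel(raw * scale, pairs, grid, coils, scale)


def forward_project(model: SensitivityModel, phantom: Phantom) -> MeasurementFrame:
    """Noiseless phase-difference frame for a phantom: V = S * delta_sigma."""
    if phantom.values.shape[0] != model.matrix.shape[1]:
        raise ValueError(
            f"phantom has {phantom.values.shape[0]} pixels but model expects "
            f"{model.matrix.shape[1]}"
        )
    return MeasurementFrame(model.matrix @ phantom.delta)


def add_noise(frame: MeasurementFrame, snr_db: float, seed: int) -> MeasurementFrame:
    """Add white Gaussian noise at the requested SNR.

    Noise power is ``mean(signal^2) / 10^(snr_db/10)``; the draw is fully
    determined by ``seed``.  ``snr_db = inf`` returns the frame unchanged.
    """
    if not (snr_db > 0):
        raise ValueError(f"snr_db must be positive, got {snr_db}")
    if np.isinf(snr_db):
        return frame
    signal_power = float(np.mean(frame.values**2))
    sigma = np.sqrt(signal_power / 10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    noisy = frame.values + rng.normal(0.0, sigma, size=frame.values.shape)
    return replace(frame, values=noisy, snr_db=snr_db, seed=seed)


def roll_measurements(values: np.ndarray, steps_45deg: int, coil_count: int = 8) -> np.ndarray:
    """Measurement-vector image of a phantom rotation by ``steps * 45deg``.

    Rotating the conductivity by one 45 degree step counterclockwise permutes
    coil roles k -> k+1, which under the cyclic row ordering is a forward
    roll by ``coil_count - 1`` positions.
    """
    return np.roll(values, (coil_count - 1) * steps_45deg, axis=-1)
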