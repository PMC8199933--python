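"""Training-corpus construction: placement sweeps, augmentation, normalization.

The corpus pairs a 56-component phase-difference vector with the
conductivity image it came from.  Single-anomaly samples come from a polar
sweep (angle step 9 degrees, radial step 0.1 cm out to 7.0 cm, which
enumerates 71 x 40 = 2840 positions); two-anomaly samples pair a swept
anomaly with a partner at a controlled center separation.  The corpus is
expanded by the 45-degree rotation trick: the conductivity is re-rasterized
at theta + 45 deg while the measurement vector is rolled by 7 positions,
exploiting the 8-fold symmetry of the coil array instead of re-simulating.

Voltages and conductivities are each min-max normalized to [0, 1] with one
global (min, max) per block, so the two-valued conductivity maps onto {0, 1}
exactly and the sigmoid output layer of the reconstructor acts as a
per-pixel classifier.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .geometry import (
    ANOMALY_RADIUS,
    AnomalySpec,
    ImagingGrid,
    place_anomalies,
)
from .forward import MeasurementFrame, SensitivityModel, forward_project, roll_measurements

#: Sweep parameters of the single-anomaly corpus.
RADIAL_STEP = 0.001  # m
ANGLE_STEP = 9.0  # degrees
RADIAL_MAX = 0.070  # m


@dataclass(frozen=True)
class Normalization:
    """Global per-block min-max parameters; invertible where max > min."""

    v_min: float
    v_max: float
    s_min: float
    s_max: float

    def _scale(self, x: np.ndarray, lo: float, hi: float) -> np.ndarray:
        if hi == lo:
            return np.zeros_like(x)
        return (x - lo) / (hi - lo)

    def normalize_voltage(self, v: np.ndarray) -> np.ndarray:
        return self._scale(np.asarray(v, float), self.v_min, self.v_max)

    def normalize_conductivity(self, s: np.ndarray) -> np.ndarray:
        return self._scale(np.asarray(s, float), self.s_min, self.s_max)

    def denormalize_conductivity(self, s: np.ndarray) -> np.ndarray:
        return np.asarray(s, float) * (self.s_max - self.s_min) + self.s_min

    def denormalize_voltage(self, v: np.ndarray) -> np.ndarray:
        return np.asarray(v, float) * (self.v_max - self.v_min) + self.v_min


@dataclass
class SampleSet:
    """Paired (voltage, conductivity) corpus.

    ``voltages`` is (N, n_meas), ``conductivities`` (N, n_pix).  Rows are
    raw physical values until :func:`normalize` stamps ``normalization``.
    ``provenance`` keeps, per sample, the anomaly specs and rotation index
    so augmentation and audits can re-rasterize.
    """

    voltages: np.ndarray
    conductivities: np.ndarray
    grid: ImagingGrid
    background: float
    provenance: list[dict] = field(default_factory=list)
    normalization: Normalization | None = None
    split: dict[str, np.ndarray] | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return self.voltages.shape[0]

    def subset(self, idx: np.ndarray) -> "SampleSet":
        return SampleSet(
            self.voltages[idx],
            self.conductivities[idx],
            self.grid,
            self.background,
            [self.provenance[i] for i in idx] if self.provenance else [],
            self.normalization,
            None,
            self.seed,
        )

    def part(self, name: str) -> "SampleSet":
        if self.split is None or name not in self.split:
            raise KeyError(f"no split part named {name!r}")
        return self.subset(self.split[name])


def enumerate_single_placements(
    radial_step: float = RADIAL_STEP,
    angle_step: float = ANGLE_STEP,
    radial_max: float = RADIAL_MAX,
    field_radius: float = 0.1,
    radius: float = ANOMALY_RADIUS,
) -> list[AnomalySpec]:
    """Polar sweep of a single anomaly, radius-major ordering.

    Radii run 0, radial_step, ..., radial_max inclusive; angles run 0,
    angle_step, ..., 360 - angle_step.  The defaults give 71 x 40 = 2840
    placements.  The rho = 0 row is kept at every angle even though the
    placements coincide spatially (their rotation-augmented measurement
    vectors differ).
    """
    if radial_step <= 0 or angle_step <= 0:
        raise ValueError("steps must be positive")
    if radial_max >= field_radius:
        raise ValueError(f"radial_max {radial_max} must be inside the field {field_radius}")
    n_r = int(round(radial_max / radial_step)) + 1
    n_a = int(round(360.0 / angle_step))
    return [
        AnomalySpec(rho=ir * radial_step, theta_deg=ia * angle_step, radius=radius)
        for ir in range(n_r)
        for ia in range(n_a)
    ]


def enumerate_two_anomaly_placements(
    separations: tuple[float, ...] = (2 * ANOMALY_RADIUS, 3 * ANOMALY_RADIUS),
    base_sweep: list[AnomalySpec] | None = None,
    orientation_step: float = 45.0,
    field_radius: float = 0.1,
) -> list[tuple[AnomalySpec, AnomalySpec]]:
    """Pairs of equal anomalies at controlled center separations.

    For each base placement, a partner anomaly is placed at every requested
    separation and at orientations in ``orientation_step`` multiples; pairs
    with the partner's disk reaching outside the field are dropped.
    ``separations`` may include 0 (coincident disks) through 3R, matching
    the resolution-distance study grid {0, R, 2R, 3R}.
    """
    if base_sweep is None:
        base_sweep = enumerate_single_placements(
            radial_step=0.01, angle_step=45.0, field_radius=field_radius
        )
    out = []
    for base in base_sweep:
        for sep in separations:
            if sep < 0:
                raise ValueError("separations must be >= 0")
            for phi in np.arange(0.0, 360.0, orientation_step):
                c = base.center + sep * np.array(
                    [np.cos(np.deg2rad(phi)), np.sin(np.deg2rad(phi))]
                )
                rho2 = float(np.hypot(*c))
                if rho2 + base.radius > field_radius:
                    continue
                if base.rho + base.radius > field_radius:
                    continue
                partner = AnomalySpec(
                    rho=rho2,
                    theta_deg=float(np.rad2deg(np.arctan2(c[1], c[0]))) % 360.0,
                    radius=base.radius,
                    conductivity=base.conductivity,
                )
                out.append((base, partner))
    return out


def simulate_samples(
    placements: list,
    model: SensitivityModel,
    grid: ImagingGrid,
) -> SampleSet:
    """Rasterize and forward-project every placement into a raw SampleSet.

    Each placement is an :class:`AnomalySpec` or a tuple of them.
    """
    n = len(placements)
    V = np.empty((n, model.measurement_count))
    C = np.empty((n, grid.active_count))
    prov = []
    background = None
    for k, pl in enumerate(placements):
        specs = [pl] if isinstance(pl, AnomalySpec) else list(pl)
        ph = place_anomalies(grid, specs)
        background = ph.background
        V[k] = forward_project(model, ph).values
        C[k] = ph.values
        prov.append({"specs": specs, "rotation": 0})
    return SampleSet(V, C, grid, background, prov)


def augment_by_rotation(sset: SampleSet, times: int) -> SampleSet:
    """Expand a corpus by 45-degree rotation copies.

    For each rotation index num in 1..times the conductivity is
    re-rasterized at theta + num*45 deg and the measurement vector rolled
    forward 7 positions per step; originals are retained, so the result has
    ``len(sset) * (times + 1)`` samples.
    """
    if not 0 <= times <= 7:
        raise ValueError("times must be in 0..7")
    if times and not sset.provenance:
        raise TypeError("sample set lacks provenance; cannot augment")
    if sset.normalization is not None:
        raise ValueError("augment before normalization")
    Vs, Cs, prov = [sset.voltages], [sset.conductivities], list(sset.provenance)
    for num in range(1, times + 1):
        C = np.empty_like(sset.conductivities)
        for k, p in enumerate(sset.provenance):
            specs = [s.rotated(num) for s in p["specs"]]
            C[k] = place_anomalies(sset.grid, specs, sset.background).values
            prov.append({"specs": specs, "rotation": num})
        Vs.append(roll_measurements(sset.voltages, num))
        Cs.append(C)
    return SampleSet(
        np.vstack(Vs), np.vstack(Cs), sset.grid, sset.background, prov, seed=sset.seed
    )


def normalize(sset: SampleSet) -> SampleSet:
    """Min-max scale the voltage and conductivity blocks to [0, 1] globally."""
    if len(sset) == 0:
        raise ValueError("cannot normalize an empty sample set")
    v_min, v_max = float(sset.voltages.min()), float(sset.voltages.max())
    s_min, s_max = float(sset.conductivities.min()), float(sset.conductivities.max())
    for name, lo, hi in [("voltage", v_min, v_max), ("conductivity", s_min, s_max)]:
        if lo == hi:
            warnings.warn(f"{name} block is constant; normalized to 0")
    norm = Normalization(v_min, v_max, s_min, s_max)
    return replace(
        sset,
        voltages=norm.normalize_voltage(sset.voltages),
        conductivities=norm.normalize_conductivity(sset.conductivities),
        normalization=norm,
    )


def normalize_frame(frame: MeasurementFrame, norm: Normalization) -> np.ndarray:
    """Scale a measurement frame into the training voltage space."""
    return norm.normalize_voltage(frame.values)


def split_samples(
    sset: SampleSet, fractions: tuple[float, float, float], seed: int
) -> SampleSet:
    """Seeded shuffle followed by a train/validation/test partition.

    Validation and test sizes are floored; the remainder goes to train, so
    the parts are disjoint and exhaustive.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(sset)
    perm = np.random.default_rng(seed).permutation(n)
    n_val = int(n * fractions[1])
    n_test = int(n * fractions[2])
    n_train = n - n_val - n_test
    split = {
        "train": perm[:n_train],
        "validation": perm[n_train : n_train + n_val],
        "test": perm[n_train + n_val :],
    }
    return replace(sset, split=split, seed=seed)


def save(sset: SampleSet, path: str | Path) -> None:
    """Persist as ``<path>.npz`` plus a JSON metadata sidecar."""
    path = Path(path)
    arrays = {"voltages": sset.voltages, "conductivities": sset.conductivities}
    if sset.split is not None:
        for k, v in sset.split.items():
            arrays[f"split_{k}"] = v
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    meta = {
        "n_samples": len(sset),
        "side_count": sset.grid.side_count,
        "field_radius": sset.grid.field_radius,
        "background": sset.background,
        "seed": sset.seed,
        "normalization": (
            None
            if sset.normalization is None
            else {
                "v_min": sset.normalization.v_min,
                "v_max": sset.normalization.v_max,
                "s_min": sset.normalization.s_min,
                "s_max": sset.normalization.s_max,
            }
        ),
        "provenance": [
            {
                "rotation": p["rotation"],
                "specs": [
                    {
                        "rho": s.rho,
                        "theta_deg": s.theta_deg,
                        "radius": s.radius,
                        "conductivity": s.conductivity,
                    }
                    for s in p["specs"]
                ],
            }
            for p in sset.provenance
        ],
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta))


def load(path: str | Path) -> SampleSet:
    """Reload a persisted SampleSet; inverse of :func:`save`."""
    from .geometry import build_grid

    path = Path(path)
    meta_path = path.with_suffix(".meta.json")
    try:
        meta = json.loads(meta_path.read_text())
    except (FileNotFoundError, json.JSONDecodeError) as e:
        raise ValueError(f"bad or missing metadata sidecar {meta_path}: {e}") from e
    for key in ("side_count", "field_radius", "background"):
        if key not in meta:
            raise ValueError(f"metadata sidecar missing field {key!r}")
    with np.load(path.with_suffix(".npz")) as z:
        V = z["voltages"]
        C = z["conductivities"]
        split = {
            k[len("split_") :]: z[k] for k in z.files if k.startswith("split_")
        } or None
    grid = build_grid(meta["side_count"], meta["field_radius"])
    norm = None
    if meta.get("normalization"):
        norm = Normalization(**meta["normalization"])
    prov = [
        {
            "rotation": p["rotation"],
            "specs": [AnomalySpec(**s) for s in p["specs"]],
        }
        for p in meta.get("provenance", [])
    ]
    return SampleSet(V, C, grid, meta["background"], prov, norm, split, meta.get("seed"))
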