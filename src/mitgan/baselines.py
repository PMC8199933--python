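"""Comparison reconstructors: single-step Tikhonov and the supervised BPNN.

Tikhonov solves the regularized normal equations of the linearized forward
model,

    sigma_hat = (S^T S + lambda I)^-1 S^T V,

on the difference signal and adds the background for display.  The
regularization weight is not part of the physical model; it is selected by
a deterministic grid search minimizing mean validation RMSE.

The BPNN baseline is the classic fully-connected reconstructor of the
pre-deep-learning tomography literature: a single sigmoid hidden layer sized
by the geometric-mean rule ``round(sqrt(n_in * n_out))``, sigmoid output,
trained with the same supervised L2/Adam protocol as the generator's
pretraining stage (no adversarial stage).  :func:`bpnn_reconstruct` is
generic over architectures — handed the generator's own spec and seed it
reproduces the GAN's pretrained initialization exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .dataset import Normalization, SampleSet
from .forward import MeasurementFrame, SensitivityModel
from .gan import NetworkSpec, TrainConfig, TrainState, pretrain_generator
from .geometry import Phantom


@dataclass(frozen=True)
class TikhonovConfig:
    lam: float = 1e-2
    solver_tol: float = 1e-10

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")


def tikhonov_reconstruct(
    model: SensitivityModel,
    frame: MeasurementFrame,
    config: TikhonovConfig = TikhonovConfig(),
) -> Phantom:
    """Closed-form regularized inverse of the linear forward model."""
    S = model.matrix
    v = frame.values
    if v.shape[0] != S.shape[0]:
        raise ValueError(f"frame has {v.shape[0]} values, model expects {S.shape[0]}")
    A = S.T @ S + config.lam * np.eye(S.shape[1])
    delta = scipy.linalg.solve(A, S.T @ v, assume_a="pos")
    from .geometry import BACKGROUND_CONDUCTIVITY

    background = BACKGROUND_CONDUCTIVITY
    return Phantom(model.grid, background + delta, background)


def select_lambda(
    model: SensitivityModel,
    val_truth: np.ndarray,
    val_frames: list[MeasurementFrame],
    norm: Normalization,
    candidates: np.ndarray | None = None,
) -> float:
    """Grid-search lambda minimizing mean normalized-image RMSE.

    ``val_truth`` is the (N, n_pix) block of normalized validation images;
    ``val_frames`` the matching raw measurement frames.  Deterministic:
    ties resolve to the first (smallest) candidate.
    """
    if len(val_frames) == 0:
        raise ValueError("need at least one validation sample")
    if candidates is None:
        candidates = np.logspace(-6, 2, 17)
    candidates = np.atleast_1d(np.asarray(candidates, dtype=float))
    from .metrics import rmse

    best_lam, best_err = float(candidates[0]), np.inf
    for lam in candidates:
        cfg = TikhonovConfig(lam=float(lam))
        errs = [
            rmse(y, norm.normalize_conductivity(tikhonov_reconstruct(model, f, cfg).values))
            for y, f in zip(val_truth, val_frames)
        ]
        err = float(np.mean(errs))
        if err < best_err:
            best_err, best_lam = err, float(lam)
    return best_lam


def classic_bpnn_spec(n_meas: int, n_pix: int, init_seed: int = 0) -> NetworkSpec:
    """Single-hidden-layer BPNN sized by the geometric-mean rule."""
    hidden = int(round(np.sqrt(n_meas * n_pix)))
    return NetworkSpec((n_meas, hidden, n_pix), ("sigmoid", "sigmoid"), init_seed)


def bpnn_reconstruct(
    spec: NetworkSpec, sset: SampleSet, config: TrainConfig
) -> TrainState:
    """Train a supervised-only fully-connected baseline (stage 1 alone)."""
    return pretrain_generator(spec, sset, config)
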