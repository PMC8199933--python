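"""End-to-end experiment harness: corpus, training, model comparison.

An :class:`ExperimentConfig` fully determines an experiment: geometry,
placement sweeps, network sizes, training hyperparameters, SNR levels and
seeds.  Two profiles ship with the package:

* ``desk`` (default) — a 33x33 grid, reduced sweeps and shrunk networks so
  the complete pipeline (corpus generation, both training stages for the
  GAN, the BPNN ablation, Tikhonov lambda selection, and the four-metric
  noise sweep) runs in minutes on one CPU.
* ``paper`` — the full-scale protocol: 67x67 grid / 3409 pixels, the
  2840-placement single-anomaly sweep, the
  {56,128,256,512,1024,2048,4096,3409} generator, 1000 pretraining epochs
  at batch 50 and adversarial batch 4000.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import dataset as ds
from . import gan as gan_mod
from .baselines import (
    TikhonovConfig,
    bpnn_reconstruct,
    classic_bpnn_spec,
    select_lambda,
    tikhonov_reconstruct,
)
from .forward import MeasurementFrame, build_sensitivity, forward_project
from .gan import NetworkSpec, TrainConfig, TrainState, forward_pass
from .geometry import (
    ANOMALY_RADIUS,
    AnomalySpec,
    build_coil_array,
    build_grid,
    place_anomalies,
)
from .metrics import MetricsReport, evaluate_models


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    profile: str = "desk"
    # geometry
    side_count: int = 33
    field_radius: float = 0.1
    # single-anomaly sweep
    radial_step: float = 0.005
    angle_step: float = 9.0
    radial_max: float = 0.070
    # two-anomaly sweep
    pair_base_radial_step: float = 0.01
    pair_base_angle_step: float = 45.0
    pair_separations: tuple[float, ...] = (0.0, ANOMALY_RADIUS, 2 * ANOMALY_RADIUS, 3 * ANOMALY_RADIUS)
    pair_orientation_step: float = 90.0
    # augmentation / split
    rotation_copies: int = 1
    split_fractions: tuple[float, float, float] = (0.80, 0.10, 0.10)
    # networks
    gen_hidden: tuple[int, ...] = (256, 512)
    gen_hidden_activations: tuple[str, ...] = ("relu", "tanh")
    disc_hidden: tuple[int, ...] = (128, 32)
    # training
    train: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            pretrain_epochs=120,
            pretrain_batch=50,
            gan_epochs=40,
            gan_batch=500,
            learning_rate=1e-3,
            l2_coeff=1e-5,
        )
    )
    # evaluation
    snr_levels: tuple[float, ...] = (np.inf, 80.0, 40.0, 20.0)
    n_test: int = 200
    seed: int = 0

    def generator_spec(self, n_pix: int) -> NetworkSpec:
        sizes = (56,) + tuple(self.gen_hidden) + (n_pix,)
        acts = tuple(self.gen_hidden_activations) + ("sigmoid",)
        return NetworkSpec(sizes, acts, init_seed=self.seed)

    def discriminator_spec(self, n_pix: int) -> NetworkSpec:
        sizes = (n_pix,) + tuple(self.disc_hidden) + (1,)
        acts = ("leaky_relu",) * len(self.disc_hidden) + ("sigmoid",)
        return NetworkSpec(sizes, acts, init_seed=self.seed + 1)


def paper_profile(seed: int = 0) -> ExperimentConfig:
    """Full-scale configuration following the published protocol."""
    return ExperimentConfig(
        profile="paper",
        side_count=67,
        radial_step=0.001,
        angle_step=9.0,
        pair_base_radial_step=0.005,
        pair_base_angle_step=15.0,
        pair_orientation_step=45.0,
        rotation_copies=3,
        gen_hidden=(128, 256, 512, 1024, 2048, 4096),
        gen_hidden_activations=("relu", "relu", "relu", "tanh", "tanh", "tanh"),
        disc_hidden=(512, 128),
        train=TrainConfig(
            pretrain_epochs=1000,
            pretrain_batch=50,
            gan_epochs=200,
            gan_batch=4000,
            learning_rate=1e-4,
            l2_coeff=1e-5,
        ),
        n_test=500,
        seed=seed,
    )


def desk_profile(seed: int = 0) -> ExperimentConfig:
    return ExperimentConfig(seed=seed)


def smoke_profile(seed: int = 0) -> ExperimentConfig:
    """Minutes-not-hours sanity profile for integration tests."""
    return ExperimentConfig(
        profile="smoke",
        side_count=15,
        radial_step=0.014,
        angle_step=45.0,
        pair_base_radial_step=0.035,
        pair_base_angle_step=90.0,
        pair_orientation_step=180.0,
        rotation_copies=0,
        gen_hidden=(32,),
        gen_hidden_activations=("tanh",),
        disc_hidden=(16,),
        train=TrainConfig(
            pretrain_epochs=30,
            pretrain_batch=20,
            gan_epochs=5,
            gan_batch=50,
            learning_rate=1e-3,
            l2_coeff=1e-5,
        ),
        n_test=10,
        seed=seed,
    )


PROFILES = {"desk": desk_profile, "paper": paper_profile, "smoke": smoke_profile}


def build_corpus(config: ExperimentConfig) -> ds.SampleSet:
    """Sweep, simulate, augment, normalize and split the training corpus."""
    grid = build_grid(config.side_count, config.field_radius)
    coils = build_coil_array()
    model = build_sensitivity(grid, coils)
    singles = ds.enumerate_single_placements(
        config.radial_step, config.angle_step, config.radial_max, config.field_radius
    )
    base = ds.enumerate_single_placements(
        config.pair_base_radial_step,
        config.pair_base_angle_step,
        config.radial_max,
        config.field_radius,
    )
    pairs = ds.enumerate_two_anomaly_placements(
        config.pair_separations, base, config.pair_orientation_step, config.field_radius
    )
    sset = ds.simulate_samples(list(singles) + list(pairs), model, grid)
    sset = ds.augment_by_rotation(sset, config.rotation_copies)
    sset = ds.normalize(sset)
    return ds.split_samples(sset, config.split_fractions, config.seed)


def random_test_samples(
    config: ExperimentConfig, model, grid, n: int, seed: int
) -> tuple[np.ndarray, list[MeasurementFrame]]:
    """Freshly drawn phantoms + noiseless frames for final evaluation.

    Mixes single- and two-anomaly cases evenly; anomaly centers are uniform
    in radius over [0, radial_max] and in angle.
    """
    rng = np.random.default_rng(seed)
    truths, frames = [], []
    for k in range(n):
        n_anom = 1 if k % 2 == 0 else 2
        specs = [
            AnomalySpec(
                rho=float(rng.uniform(0, config.radial_max)),
                theta_deg=float(rng.uniform(0, 360)),
            )
            for _ in range(n_anom)
        ]
        ph = place_anomalies(grid, specs)
        truths.append(ph.values)
        frames.append(forward_project(model, ph))
    return np.array(truths), frames


@dataclass
class StudyResult:
    config: ExperimentConfig
    reports: list[MetricsReport]
    gan_state: TrainState
    bpnn_state: TrainState
    tikhonov_lambda: float
    normalization: ds.Normalization
    corpus_size: int


def run_study(config: ExperimentConfig) -> StudyResult:
    """Train GAN, BPNN and Tikhonov on one corpus and benchmark them.

    The GAN is the deep generator: supervised pretraining followed by the
    adversarial stage with validation-MSE checkpoint selection.  The BPNN
    baseline is the classic single-hidden-layer fully-connected
    reconstructor trained with the same supervised protocol.  Tikhonov's
    lambda comes from a validation grid search.  Returns averaged metric
    reports per model and SNR level.
    """
    grid = build_grid(config.side_count, config.field_radius)
    coils = build_coil_array()
    model = build_sensitivity(grid, coils)
    corpus = build_corpus(config)
    norm = corpus.normalization
    train, val = corpus.part("train"), corpus.part("validation")

    gspec = config.generator_spec(grid.active_count)
    dspec = config.discriminator_spec(grid.active_count)
    tcfg = replace(config.train, seed=config.seed)
    pretrained = gan_mod.pretrain_generator(gspec, train, tcfg)
    gan = gan_mod.train_gan(pretrained, dspec, train, val, tcfg)
    bpnn = bpnn_reconstruct(
        classic_bpnn_spec(56, grid.active_count, init_seed=config.seed + 2), train, tcfg
    )

    # lambda selection on raw validation frames
    val_frames = [MeasurementFrame(norm.denormalize_voltage(v)) for v in val.voltages]
    lam = select_lambda(model, val.conductivities, val_frames, norm)
    tik_cfg = TikhonovConfig(lam=lam)

    truths, frames = random_test_samples(
        config, model, grid, config.n_test, seed=config.seed + 12345
    )
    truths_norm = norm.normalize_conductivity(truths)

    def net_recon(state):
        def _recon(frame):
            v = norm.normalize_voltage(frame.values)
            return forward_pass(state.gen_spec, state.gen_params, v)

        return _recon

    def tik_recon(frame):
        return norm.normalize_conductivity(
            tikhonov_reconstruct(model, frame, tik_cfg).values
        )

    models = {"GAN": net_recon(gan), "BPNN": net_recon(bpnn), "Tikhonov": tik_recon}
    reports = evaluate_models(
        models, truths_norm, frames, config.snr_levels, noise_seed=config.seed + 999
    )
    return StudyResult(config, reports, gan, bpnn, lam, norm, len(corpus))
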