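"""Two-stage GAN reconstructor for magnetic induction tomography.

The generator is a fully-connected network mapping a normalized 56-component
phase-difference vector to the normalized conductivity image (sigmoid output,
so each pixel behaves as a soft anomaly/background classifier).  Training has
two stages:

1. **Pretraining** — supervised minimization of the squared reconstruction
   error ``||sigma - G(V)||^2`` with L2 weight decay, by Adam on mini-batches.
2. **Adversarial fine-tuning** — a discriminator D scores conductivity
   images; the discriminator ascends

       (1/M) sum [ log D(sigma) + log(1 - D(G(V))) ]

   for ``k_disc_steps`` steps per iteration, then the generator descends
   ``(1/M) sum log(1 - D(G(V)))``.  At the (unique) optimum
   ``D = p_real / (p_real + p_gen)``, which equals 1/2 when the generated
   and real image distributions coincide.

A held-out validation set is scored with per-dimension MSE after every
epoch; training stops when the generator's adversarial loss drops below the
discriminator's and validation MSE is below ``val_threshold``, or at the
epoch cap.  The returned generator parameters are the validation-MSE-best
checkpoint seen during fine-tuning (pretrained state included), so the
adversarial stage can only be kept when cross-validation says it helped.

All networks, gradients and the Adam optimizer are implemented here in
numpy; gradient correctness is pinned by finite-difference tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
import json

import numpy as np

from .dataset import Normalization, SampleSet, normalize_frame
from .forward import MeasurementFrame
from .geometry import ImagingGrid, Phantom

# ---------------------------------------------------------------------------
# activations

def _relu(z):
    return np.maximum(z, 0.0)


def _drelu(z, a):
    return (z > 0).astype(z.dtype)


def _leaky_relu(z, slope=0.2):
    return np.where(z > 0, z, slope * z)


def _dleaky_relu(z, a, slope=0.2):
    return np.where(z > 0, 1.0, slope)


def _tanh(z):
    return np.tanh(z)


def _dtanh(z, a):
    return 1.0 - a**2


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _dsigmoid(z, a):
    return a * (1.0 - a)


def _linear(z):
    return z


def _dlinear(z, a):
    return np.ones_like(z)


ACTIVATIONS = {
    "relu": (_relu, _drelu),
    "leaky_relu": (_leaky_relu, _dleaky_relu),
    "tanh": (_tanh, _dtanh),
    "sigmoid": (_sigmoid, _dsigmoid),
    "linear": (_linear, _dlinear),
}

#: Full-scale generator: 56 -> ... -> 3409, sigmoid output.
GENERATOR_SIZES = (56, 128, 256, 512, 1024, 2048, 4096, 3409)
GENERATOR_ACTIVATIONS = ("relu", "relu", "relu", "tanh", "tanh", "tanh", "sigmoid")


@dataclass(frozen=True)
class NetworkSpec:
    """Layer widths and per-layer activations of a fully-connected net."""

    layer_sizes: tuple[int, ...]
    activations: tuple[str, ...]
    init_seed: int = 0

    def __post_init__(self):
        if len(self.activations) != len(self.layer_sizes) - 1:
            raise ValueError(
                f"need {len(self.layer_sizes) - 1} activations for "
                f"{len(self.layer_sizes)} layer sizes, got {len(self.activations)}"
            )
        unknown = set(self.activations) - set(ACTIVATIONS)
        if unknown:
            raise ValueError(f"unknown activations: {sorted(unknown)}")

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes) - 1


def default_generator_spec(
    n_meas: int = 56, n_pix: int = 3409, init_seed: int = 0
) -> NetworkSpec:
    sizes = (n_meas,) + GENERATOR_SIZES[1:-1] + (n_pix,)
    return NetworkSpec(sizes, GENERATOR_ACTIVATIONS, init_seed)


def default_discriminator_spec(n_pix: int = 3409, init_seed: int = 1) -> NetworkSpec:
    return NetworkSpec((n_pix, 512, 128, 1), ("leaky_relu", "leaky_relu", "sigmoid"), init_seed)


def init_params(spec: NetworkSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """He-style seeded initialization: W ~ N(0, 2/fan_in), b = 0."""
    rng = np.random.default_rng(spec.init_seed)
    params = []
    for n_in, n_out in zip(spec.layer_sizes[:-1], spec.layer_sizes[1:]):
        W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        params.append((W, np.zeros(n_out)))
    return params


def _forward_cached(spec, params, X):
    """Forward pass keeping per-layer pre-activations and activations."""
    a = np.atleast_2d(np.asarray(X, dtype=float))
    if a.shape[1] != spec.layer_sizes[0]:
        raise ValueError(
            f"input width {a.shape[1]} != first layer size {spec.layer_sizes[0]}"
        )
    zs, acts = [], [a]
    for (W, b), name in zip(params, spec.activations):
        z = a @ W.T + b
        a = ACTIVATIONS[name][0](z)
        zs.append(z)
        acts.append(a)
    return zs, acts


def forward_pass(spec: NetworkSpec, params, X: np.ndarray) -> np.ndarray:
    """Network output for a single vector or a batch of row vectors."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    out = _forward_cached(spec, params, X)[1][-1]
    return out[0] if single else out


def _backward_full(spec, params, zs, acts, grad_out, wrt="output"):
    """Backpropagate to parameter gradients and the gradient wrt the input.

    ``wrt='output'`` means grad_out is d(loss)/d(final activation);
    ``wrt='preact'`` means d(loss)/d(final pre-activation), the numerically
    stable route for sigmoid + log losses.
    """
    if wrt == "output":
        name = spec.activations[-1]
        delta = grad_out * ACTIVATIONS[name][1](zs[-1], acts[-1])
    else:
        delta = grad_out
    grads = [None] * len(params)
    for layer in range(len(params) - 1, -1, -1):
        W, _ = params[layer]
        grads[layer] = (delta.T @ acts[layer], delta.sum(axis=0))
        delta = delta @ W
        if layer > 0:
            prev = spec.activations[layer - 1]
            delta = delta * ACTIVATIONS[prev][1](zs[layer - 1], acts[layer])
    return grads, delta


class Adam:
    """Adam optimizer over a list of (W, b) parameter pairs."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
        self.v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        out = []
        for i, ((W, b), (gW, gb)) in enumerate(zip(params, grads)):
            mW, mb = self.m[i]
            vW, vb = self.v[i]
            mW = b1 * mW + (1 - b1) * gW
            mb = b1 * mb + (1 - b1) * gb
            vW = b2 * vW + (1 - b2) * gW**2
            vb = b2 * vb + (1 - b2) * gb**2
            self.m[i], self.v[i] = (mW, mb), (vW, vb)
            c1 = 1 - b1**self.t
            c2 = 1 - b2**self.t
            W = W - self.lr * (mW / c1) / (np.sqrt(vW / c2) + self.eps)
            b = b - self.lr * (mb / c1) / (np.sqrt(vb / c2) + self.eps)
            out.append((W, b))
        return out


@dataclass
class TrainConfig:
    """Hyperparameters of the two training stages.

    Defaults follow the full-scale protocol: 1000 pretraining epochs at
    batch 50, adversarial batch 4000, validation-MSE stopping threshold
    0.05.  The learning rate, L2 coefficient, discriminator steps per
    generator step and the adversarial epoch cap are configuration choices.
    """

    pretrain_epochs: int = 1000
    pretrain_batch: int = 50
    gan_epochs: int = 500
    gan_batch: int = 4000
    learning_rate: float = 1e-4
    l2_coeff: float = 1e-5
    k_disc_steps: int = 1
    val_threshold: float = 0.05
    non_saturating: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.pretrain_epochs, self.pretrain_batch, self.gan_epochs, self.gan_batch, self.k_disc_steps) <= 0:
            raise ValueError("epoch/batch/step counts must be positive")
        if not 0 < self.val_threshold < 1:
            raise ValueError("val_threshold must be in (0, 1)")


@dataclass
class TrainState:
    """Trained parameters plus loss histories and the stop reason."""

    gen_spec: NetworkSpec
    gen_params: list
    disc_spec: NetworkSpec | None = None
    disc_params: list | None = None
    history: dict = dc_field(default_factory=dict)
    stop_reason: str | None = None


def pretrain_generator(
    spec: NetworkSpec, sset: SampleSet, config: TrainConfig
) -> TrainState:
    """Stage 1: supervised L2 training of the generator by Adam.

    Minimizes the mean per-sample squared error ``||sigma - G(V)||^2`` plus
    ``l2_coeff * ||theta||^2`` over mini-batches of ``pretrain_batch``.
    """
    if len(sset) == 0:
        raise ValueError("cannot pretrain on an empty sample set")
    X, Y = sset.voltages, sset.conductivities
    params = init_params(spec)
    opt = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    losses = []
    n = len(sset)
    bs = min(config.pretrain_batch, n)
    for _ in range(config.pretrain_epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = perm[start : start + bs]
            xb, yb = X[idx], Y[idx]
            zs, acts = _forward_cached(spec, params, xb)
            resid = acts[-1] - yb
            epoch_loss += float(np.sum(resid**2))
            grad_out = 2.0 * resid / len(idx)
            grads, _ = _backward_full(spec, params, zs, acts, grad_out)
            if config.l2_coeff:
                grads = [
                    (gW + 2 * config.l2_coeff * W, gb)
                    for (gW, gb), (W, _) in zip(grads, params)
                ]
            params = opt.step(params, grads)
        losses.append(epoch_loss / n)
    return TrainState(spec, params, history={"pretrain_loss": losses}, stop_reason="max_iters")


def _disc_probs(disc_spec, disc_params, images):
    return forward_pass(disc_spec, disc_params, images).ravel()


def train_gan(
    gen_state: TrainState,
    disc_spec: NetworkSpec,
    sset: SampleSet,
    val_set: SampleSet,
    config: TrainConfig,
) -> TrainState:
    """Stage 2: adversarial fine-tuning with validation-MSE monitoring.

    Each iteration draws a fresh mini-batch, ascends the discriminator's
    value ``k_disc_steps`` times, then descends the generator's adversarial
    loss once.  After every epoch the validation MSE and both adversarial
    losses are logged; training stops once the generator loss is below the
    discriminator loss and validation MSE is below ``val_threshold``.  The
    generator returned carries the parameters with the best validation MSE
    observed (the pretrained initialization counts as a candidate).
    """
    spec = gen_state.gen_spec
    gen_params = [(W.copy(), b.copy()) for W, b in gen_state.gen_params]
    disc_params = init_params(disc_spec)
    X, Y = sset.voltages, sset.conductivities
    n = len(sset)
    bs = min(config.gan_batch, n)
    gen_opt = Adam(gen_params, lr=config.learning_rate)
    disc_opt = Adam(disc_params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    def val_mse(params):
        pred = forward_pass(spec, params, val_set.voltages)
        return float(np.mean((pred - val_set.conductivities) ** 2))

    best_params = [(W.copy(), b.copy()) for W, b in gen_params]
    best_val = val_mse(gen_params)
    hist = {"disc_loss": [], "gen_loss": [], "val_mse": [best_val]}
    stop_reason = "max_iters"
    batches_per_epoch = max(1, n // bs)
    for _ in range(config.gan_epochs):
        for _ in range(batches_per_epoch):
            # --- discriminator ascent -------------------------------------
            for _ in range(config.k_disc_steps):
                idx = rng.choice(n, size=bs, replace=False)
                fake = forward_pass(spec, gen_params, X[idx])
                real = Y[rng.choice(n, size=bs, replace=False)]
                zs_r, acts_r = _forward_cached(disc_spec, disc_params, real)
                zs_f, acts_f = _forward_cached(disc_spec, disc_params, fake)
                d_real = acts_r[-1]
                d_fake = acts_f[-1]
                # minimize -(1/M)[log D(real) + log(1 - D(fake))]
                g_real, _ = _backward_full(
                    disc_spec, disc_params, zs_r, acts_r, -(1.0 - d_real) / bs, wrt="preact"
                )
                g_fake, _ = _backward_full(
                    disc_spec, disc_params, zs_f, acts_f, d_fake / bs, wrt="preact"
                )
                grads = [(a[0] + b[0], a[1] + b[1]) for a, b in zip(g_real, g_fake)]
                disc_params = disc_opt.step(disc_params, grads)
            # --- generator descent ----------------------------------------
            idx = rng.choice(n, size=bs, replace=False)
            zs_g, acts_g = _forward_cached(spec, gen_params, X[idx])
            fake = acts_g[-1]
            zs_d, acts_d = _forward_cached(disc_spec, disc_params, fake)
            d_fake = acts_d[-1]
            if config.non_saturating:
                grad_z = -(1.0 - d_fake) / bs  # minimize -(1/M) sum log D(fake)
            else:
                grad_z = -d_fake / bs  # minimize (1/M) sum log(1 - D(fake))
            _, grad_images = _backward_full(
                disc_spec, disc_params, zs_d, acts_d, grad_z, wrt="preact"
            )
            gen_grads, _ = _backward_full(spec, gen_params, zs_g, acts_g, grad_images)
            gen_params = gen_opt.step(gen_params, gen_grads)

        # --- epoch-end monitoring -----------------------------------------
        idx = rng.choice(n, size=bs, replace=False)
        fake = forward_pass(spec, gen_params, X[idx])
        d_fake = np.clip(_disc_probs(disc_spec, disc_params, fake), 1e-12, 1 - 1e-12)
        d_real = np.clip(
            _disc_probs(disc_spec, disc_params, Y[rng.choice(n, size=bs, replace=False)]),
            1e-12,
            1 - 1e-12,
        )
        gen_loss = float(-np.mean(np.log(d_fake)))
        disc_loss = float(-0.5 * np.mean(np.log(d_real) + np.log(1.0 - d_fake)))
        v = val_mse(gen_params)
        hist["gen_loss"].append(gen_loss)
        hist["disc_loss"].append(disc_loss)
        hist["val_mse"].append(v)
        if v < best_val:
            best_val = v
            best_params = [(W.copy(), b.copy()) for W, b in gen_params]
        if gen_loss < disc_loss and v < config.val_threshold:
            stop_reason = "converged"
            break

    return TrainState(
        spec,
        best_params,
        disc_spec,
        disc_params,
        history={**gen_state.history, **hist, "best_val_mse": best_val},
        stop_reason=stop_reason,
    )


def optimal_discriminator(p_real: np.ndarray, p_gen: np.ndarray) -> np.ndarray:
    """Closed-form optimal discriminator ``p_real / (p_real + p_gen)``.

    Equals 1/2 wherever the generated density matches the true density.
    """
    p_real = np.asarray(p_real, dtype=float)
    p_gen = np.asarray(p_gen, dtype=float)
    if np.any(p_real < 0) or np.any(p_gen < 0):
        raise ValueError("densities must be non-negative")
    denom = p_real + p_gen
    if np.any(denom == 0):
        raise ZeroDivisionError("optimal discriminator undefined where both densities vanish")
    return p_real / denom


def reconstruct(
    state: TrainState,
    frame: MeasurementFrame,
    normalization: Normalization,
    grid: ImagingGrid,
    background: float | None = None,
) -> Phantom:
    """Run the generator on one measurement frame and denormalize.

    The frame's raw phase values are scaled with the *training* voltage
    normalization, pushed through the generator, and the sigmoid outputs are
    mapped back to S/m with the conductivity normalization.
    """
    if normalization is None:
        raise ValueError("a training Normalization is required for reconstruction")
    v = normalize_frame(frame, normalization)
    out = forward_pass(state.gen_spec, state.gen_params, v)
    values = normalization.denormalize_conductivity(out)
    if background is None:
        background = float(normalization.s_max)
    return Phantom(grid, values, background)


# ---------------------------------------------------------------------------
# checkpoint persistence

def save_checkpoint(state: TrainState, path: str | Path) -> None:
    """Persist a TrainState as ``<path>.npz`` + JSON descriptor."""
    path = Path(path)
    arrays = {}
    for i, (W, b) in enumerate(state.gen_params):
        arrays[f"gen_W{i}"] = W
        arrays[f"gen_b{i}"] = b
    if state.disc_params is not None:
        for i, (W, b) in enumerate(state.disc_params):
            arrays[f"disc_W{i}"] = W
            arrays[f"disc_b{i}"] = b
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    desc = {
        "gen_spec": {
            "layer_sizes": list(state.gen_spec.layer_sizes),
            "activations": list(state.gen_spec.activations),
            "init_seed": state.gen_spec.init_seed,
        },
        "disc_spec": None
        if state.disc_spec is None
        else {
            "layer_sizes": list(state.disc_spec.layer_sizes),
            "activations": list(state.disc_spec.activations),
            "init_seed": state.disc_spec.init_seed,
        },
        "history": state.history,
        "stop_reason": state.stop_reason,
    }
    path.with_suffix(".json").write_text(json.dumps(desc))


def load_checkpoint(path: str | Path) -> TrainState:
    path = Path(path)
    desc = json.loads(path.with_suffix(".json").read_text())
    gspec = NetworkSpec(
        tuple(desc["gen_spec"]["layer_sizes"]),
        tuple(desc["gen_spec"]["activations"]),
        desc["gen_spec"]["init_seed"],
    )
    dspec = None
    if desc["disc_spec"]:
        dspec = NetworkSpec(
            tuple(desc["disc_spec"]["layer_sizes"]),
            tuple(desc["disc_spec"]["activations"]),
            desc["disc_spec"]["init_seed"],
        )
    with np.load(path.with_suffix(".npz")) as z:
        gen_params = []
        i = 0
        while f"gen_W{i}" in z:
            gen_params.append((z[f"gen_W{i}"], z[f"gen_b{i}"]))
            i += 1
        disc_params = None
        if dspec is not None:
            disc_params = []
            i = 0
            while f"disc_W{i}" in z:
                disc_params.append((z[f"disc_W{i}"], z[f"disc_b{i}"]))
                i += 1
    return TrainState(gspec, gen_params, dspec, disc_params, desc["history"], desc["stop_reason"])
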