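"""Image-quality indices: RMSE, SSIM, PSNR, CC, and the evaluation harness.

All metrics operate on the normalized [0, 1] conductivity vectors over the
active pixels (the network's output space).  SSIM is the single-window
(global) form — means, variances and covariance over the whole masked
vector with c1 = (k1 L)^2, c2 = (k2 L)^2, k1 = 0.01, k2 = 0.03, L = 1.
PSNR uses peak 1 for unit-range images, i.e. psnr = -20 log10(rmse); this is
the convention consistent with standard RMSE/PSNR tables for normalized
reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

K1 = 0.01
K2 = 0.03

#: Returned by psnr when the reconstruction is exact (MSE = 0).
PSNR_INF = np.inf


@dataclass(frozen=True)
class MetricsReport:
    model_name: str
    snr_db: float
    n_samples: int
    rmse: float
    ssim: float
    psnr: float
    cc: float


def _check(y, y_hat):
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    return y, y_hat


def mse(y, y_hat) -> float:
    """Per-dimension mean squared error (1/m) sum (y_i - yhat_i)^2."""
    y, y_hat = _check(y, y_hat)
    return float(np.mean((y - y_hat) ** 2))


def rmse(y, y_hat) -> float:
    """Root of :func:`mse`."""
    return float(np.sqrt(mse(y, y_hat)))


def ssim(y, y_hat, L: float = 1.0) -> float:
    """Global structural similarity of two masked-pixel vectors."""
    if L <= 0:
        raise ValueError(f"L must be positive, got {L}")
    y, y_hat = _check(y, y_hat)
    c1 = (K1 * L) ** 2
    c2 = (K2 * L) ** 2
    mu_y, mu_h = y.mean(), y_hat.mean()
    var_y, var_h = y.var(), y_hat.var()
    cov = np.mean((y - mu_y) * (y_hat - mu_h))
    return float(
        (2 * mu_y * mu_h + c1)
        * (2 * cov + c2)
        / ((mu_y**2 + mu_h**2 + c1) * (var_y + var_h + c2))
    )


def psnr(y, y_hat, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio, dB; ``inf`` for an exact reconstruction."""
    m = mse(y, y_hat)
    if m == 0:
        return PSNR_INF
    return float(10.0 * np.log10(peak**2 / m))


def psnr_from_rmse(r: float, peak: float = 1.0) -> float:
    """PSNR implied by an RMSE under the unit-peak convention."""
    if r == 0:
        return PSNR_INF
    return float(20.0 * np.log10(peak / r))


def cc(y, y_hat) -> float:
    """Pearson correlation coefficient of the two images."""
    y, y_hat = _check(y, y_hat)
    sy, sh = y.std(), y_hat.std()
    if sy == 0 or sh == 0:
        raise ValueError("correlation undefined for a constant image")
    cov = np.mean((y - y.mean()) * (y_hat - y_hat.mean()))
    return float(cov / (sy * sh))


def score_pair(y, y_hat) -> dict:
    return {
        "rmse": rmse(y, y_hat),
        "ssim": ssim(y, y_hat),
        "psnr": psnr(y, y_hat),
        "cc": cc(y, y_hat),
    }


def evaluate_models(
    models: dict,
    truths: np.ndarray,
    frames: list,
    snr_levels: tuple[float, ...],
    noise_seed: int = 0,
) -> list[MetricsReport]:
    """Average the four indices per (model, SNR) cell on a shared test set.

    Parameters
    ----------
    models : mapping name -> callable(MeasurementFrame) -> normalized image
    truths : (N, n_pix) normalized ground-truth images
    frames : list of N noiseless MeasurementFrames
    snr_levels : SNRs in dB (``inf`` = noiseless); noise draws are seeded
        per (level, sample) so every model sees identical noisy inputs.
    """
    from .forward import add_noise

    truths = np.asarray(truths, dtype=float)
    reports = []
    for level_idx, snr_db in enumerate(snr_levels):
        noisy = [
            add_noise(f, snr_db, seed=noise_seed + 100_000 * level_idx + k)
            if np.isfinite(snr_db)
            else f
            for k, f in enumerate(frames)
        ]
        for name, recon in models.items():
            scores = np.array(
                [
                    [
                        s["rmse"],
                        s["ssim"],
                        s["psnr"],
                        s["cc"],
                    ]
                    for y, f in zip(truths, noisy)
                    for s in [score_pair(y, recon(f))]
                ]
            )
            reports.append(
                MetricsReport(
                    model_name=name,
                    snr_db=float(snr_db),
                    n_samples=len(frames),
                    rmse=float(scores[:, 0].mean()),
                    ssim=float(scores[:, 1].mean()),
                    psnr=float(scores[:, 2].mean()),
                    cc=float(scores[:, 3].mean()),
                )
            )
    return reports


def reports_to_frame(reports: list[MetricsReport]):
    """Tabulate reports as a pandas DataFrame (model x SNR rows)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "model": r.model_name,
                "snr_db": r.snr_db,
                "n_samples": r.n_samples,
                "rmse": r.rmse,
                "ssim": r.ssim,
                "psnr": r.psnr,
                "cc": r.cc,
            }
            for r in reports
        ]
    )
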