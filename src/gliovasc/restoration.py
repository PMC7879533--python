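"""PSF-based image restoration.

Confocal stacks are blurred by the microscope's point spread function (PSF);
this module models the PSF as a separable 3D Gaussian and restores channels
with Richardson–Lucy (RL) multiplicative deconvolution. RL assumes photon
(Poisson) statistics, preserves non-negativity at every iteration, and
approximately conserves total flux for structures away from the borders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve


@dataclass(frozen=True)
class PSFModel:
    """Parametric Gaussian PSF: σ per axis (z, y, x) in µm."""

    sigmas: tuple
    truncation: float = 4.0

    def __post_init__(self):
        sig = tuple(float(s) for s in np.broadcast_to(np.asarray(self.sigmas, float), (3,)))
        object.__setattr__(self, "sigmas", sig)
        if any(s <= 0 for s in sig):
            raise ValueError("PSF sigmas must be > 0")
        if self.truncation <= 0:
            raise ValueError("truncation must be > 0")


def gaussian_psf(model: PSFModel, voxel_size) -> np.ndarray:
    """Discrete, normalized, centered Gaussian kernel on the voxel grid.

    Kernel half-extent is ``ceil(truncation * σ / voxel)`` per axis, so the
    full extent is ``2·ceil(truncation·σ/voxel) + 1`` voxels. Warns when a σ
    is below half a voxel (undersampled PSF).
    """
    voxel = np.asarray(voxel_size, float)
    if voxel.shape != (3,) or np.any(voxel <= 0):
        raise ValueError("voxel_size must be 3 positive values")
    sig = np.asarray(model.sigmas)
    if np.any(sig < voxel / 2):
        warnings.warn("PSF σ below half a voxel: the kernel is undersampled", stacklevel=2)
    half = np.ceil(model.truncation * sig / voxel).astype(int)
    axes = [np.arange(-h, h + 1) * v for h, v in zip(half, voxel)]
    k = np.exp(
        -(axes[0][:, None, None] ** 2 / (2 * sig[0] ** 2)
          + axes[1][None, :, None] ** 2 / (2 * sig[1] ** 2)
          + axes[2][None, None, :] ** 2 / (2 * sig[2] ** 2))
    )
    return k / k.sum()


def deconvolve_rl(channel: np.ndarray, psf: np.ndarray, iterations: int = 10) -> np.ndarray:
    """Richardson–Lucy deconvolution.

    Multiplicative updates ``est ← est · (obs / (est ⊛ psf)) ⊛ psf̃`` with the
    flat image as the initial estimate. The input must be non-negative
    (photon-count semantics); the output is non-negative by construction.
    """
    channel = np.asarray(channel, float)
    if np.any(channel < 0):
        raise ValueError("restoration assumes photon counts: input has negative voxels")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    psf = np.asarray(psf, float)
    if abs(psf.sum() - 1.0) > 1e-6:
        psf = psf / psf.sum()
    mirror = psf[::-1, ::-1, ::-1] if psf.ndim == 3 else np.flip(psf)
    peak = float(channel.max())
    if peak == 0.0:
        return channel.copy()
    # where the re-blurred estimate predicts essentially no photons the
    # multiplicative correction is left at zero instead of exploding
    floor = 1e-12 * peak
    est = np.full_like(channel, max(channel.mean(), floor))
    for _ in range(iterations):
        conv = fftconvolve(est, psf, mode="same")
        ratio = np.where(conv > floor, channel / np.maximum(conv, floor), 0.0)
        est = est * fftconvolve(ratio, mirror, mode="same")
        np.clip(est, 0.0, None, out=est)
    return est
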