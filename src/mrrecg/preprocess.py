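"""Wavelet denoising and training-time data augmentation.

Denoising decomposes each lead with a Daubechies-6 ("db6") wavelet and
soft-thresholds the detail coefficients with the universal threshold
``sigma * sqrt(2 log n)``, where sigma is the robust noise estimate
(median absolute deviation of the finest detail band / 0.6745). The
approximation band is left untouched, so the DC level survives.

Three augmentations emulate natural variation without changing labels:

* amplitude scaling by ``1 + tau`` with ``tau ~ N(0, 0.1)`` — different
  constitutions give different waveform amplitudes;
* whole-signal translation — the same heart recorded at a different
  moment (circular by default so length is preserved);
* random zero-masking of one contiguous segment of up to 1 s — prevents
  a model from over-committing to one local feature (training only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .io import ECGRecord

__all__ = [
    "AugmentConfig",
    "DenoiseConfig",
    "denoise",
    "denoise_record",
    "augment_scale",
    "augment_shift",
    "augment_mask",
    "random_augment",
]


@dataclass(frozen=True)
class DenoiseConfig:
    wavelet: str = "db6"
    level: int | None = None  # None: min(8, max feasible for the length)
    threshold_rule: str = "universal-soft"

    def __post_init__(self) -> None:
        if self.level is not None and self.level < 1:
            raise ValueError("decomposition level must be >= 1")
        if self.threshold_rule != "universal-soft":
            raise ValueError("only the universal-soft rule is implemented")


@dataclass(frozen=True)
class AugmentConfig:
    """Draw parameters for the three augmentation schemes."""

    tau_sd: float = 0.1  # SD of the amplitude scaling factor tau
    max_mask_s: float = 1.0  # upper bound of the zero-mask length, seconds
    shift_max_s: float = 2.0  # maximum |translation|, seconds
    mask_probability: float = 0.5  # chance a copy receives a mask

    def __post_init__(self) -> None:
        if self.tau_sd < 0:
            raise ValueError("tau_sd must be non-negative")
        if self.max_mask_s <= 0:
            raise ValueError("max_mask_s must be positive")


def denoise(signal: np.ndarray, cfg: DenoiseConfig = DenoiseConfig()) -> np.ndarray:
    """Denoise one 1-D signal; output has the same length as the input."""
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1:
        raise ValueError("denoise operates on one lead at a time")
    n = signal.shape[0]
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(cfg.wavelet).dec_len)
    level = cfg.level if cfg.level is not None else min(8, max_level)
    if level < 1 or level > max_level:
        raise ValueError(
            f"level {level} infeasible for length {n} (max {max_level})"
        )
    coeffs = pywt.wavedec(signal, cfg.wavelet, level=level, mode="symmetric")
    detail_finest = coeffs[-1]
    sigma = np.median(np.abs(detail_finest - np.median(detail_finest))) / 0.6745
    threshold = sigma * np.sqrt(2.0 * np.log(max(n, 2)))
    def soft(c):  # robust to threshold == 0 (noise-free input)
        return np.sign(c) * np.maximum(np.abs(c) - threshold, 0.0)

    coeffs = [coeffs[0]] + [soft(c) for c in coeffs[1:]]
    out = pywt.waverec(coeffs, cfg.wavelet, mode="symmetric")
    return out[:n]


def denoise_record(rec: ECGRecord, cfg: DenoiseConfig = DenoiseConfig()) -> ECGRecord:
    """Apply :func:`denoise` independently to every lead."""
    return rec.with_signal(np.stack([denoise(lead, cfg) for lead in rec.signal]))


def augment_scale(rec: ECGRecord, tau: float) -> ECGRecord:
    """Scale every sample by ``(1 + tau)``; labels and shape unchanged."""
    if 1.0 + tau <= 0:
        raise ValueError("1 + tau must be positive")
    return rec.with_signal(rec.signal * (1.0 + tau))


def augment_shift(
    rec: ECGRecord, shift_samples: int, *, mode: str = "circular"
) -> ECGRecord:
    """Translate the whole record by ``shift_samples`` on every lead.

    ``circular`` wraps around (sample multiset preserved); ``zero`` shifts
    and fills the vacated end with zeros.
    """
    if abs(shift_samples) >= rec.n_samples:
        raise ValueError("|shift| must be smaller than the record length")
    if mode == "circular":
        return rec.with_signal(np.roll(rec.signal, shift_samples, axis=1))
    if mode == "zero":
        out = np.zeros_like(rec.signal)
        if shift_samples >= 0:
            out[:, shift_samples:] = rec.signal[:, : rec.n_samples - shift_samples]
        else:
            out[:, :shift_samples] = rec.signal[:, -shift_samples:]
        return rec.with_signal(out)
    raise ValueError(f"unknown shift mode {mode!r}")


def augment_mask(
    rec: ECGRecord,
    seed: int | np.random.Generator,
    cfg: AugmentConfig = AugmentConfig(),
) -> ECGRecord:
    """Zero one contiguous segment, same position on all leads.

    The mask length L (samples) is drawn uniformly from
    ``(0, max_mask_s * fs]`` and the start uniformly over feasible
    positions; deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    max_len = int(round(cfg.max_mask_s * rec.fs))
    max_len = min(max_len, rec.n_samples)
    length = int(rng.integers(1, max_len + 1))  # uniform on {1..max_len}
    start = int(rng.integers(0, rec.n_samples - length + 1))
    signal = rec.signal.copy()
    signal[:, start : start + length] = 0.0
    return rec.with_signal(signal)


def random_augment(
    rec: ECGRecord,
    rng: np.random.Generator,
    cfg: AugmentConfig = AugmentConfig(),
) -> ECGRecord:
    """One augmented copy: scale, shift, and (with some probability) mask.

    tau is redrawn per copy. Used on training folds only.
    """
    tau = rng.normal(0.0, cfg.tau_sd)
    tau = max(tau, -0.9)  # keep 1 + tau positive
    out = augment_scale(rec, tau)
    max_shift = int(round(cfg.shift_max_s * rec.fs))
    if max_shift > 0:
        shift = int(rng.integers(-max_shift, max_shift + 1))
        shift = int(np.clip(shift, -(rec.n_samples - 1), rec.n_samples - 1))
        out = augment_shift(out, shift)
    if rng.random() < cfg.mask_probability:
        out = augment_mask(out, rng, cfg)
    return out
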