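"""Synthetic multichannel windows with controllable inter-channel dependence.

Each window mixes a shared oscillatory latent source into every channel:

    channel_c = rho * g_c * s(t) + (1 - rho) * noise_c(t)

where ``s`` is a unit-variance order-2 autoregressive process with resonant
poles (spectral mass near 6 Hz at 256 Hz sampling, loosely EEG-like), ``g_c``
is a per-channel gain drawn once per dataset, and ``rho`` is the coupling —
high for seizure-labelled windows, low for non-seizure ones.  Everything is
deterministic per (seed, window index, label).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np

from eegsync.partitioning import APConfig
from eegsync.synchrony import build_cmapcpmi
from eegsync.windowing import NON_SEIZURE, SEIZURE

__all__ = [
    "SyntheticSpec",
    "channel_gains",
    "generate_window",
    "generate_windows",
    "generate_labeled_dataset",
]

_AR_POLE_RADIUS = 0.97
_AR_FREQ_HZ = 6.0
_BURN_IN = 200


@dataclass(frozen=True)
class SyntheticSpec:
    n_channels: int = 23
    samples_per_window: int = 2048
    sampling_rate: float = 256.0
    coupling_high: float = 0.8
    coupling_low: float = 0.2
    noise_sd: float = 1.0
    n_windows_per_class: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for rho in (self.coupling_high, self.coupling_low):
            if not 0.0 <= rho <= 1.0:
                raise ValueError("couplings must be in [0, 1]")
        if min(self.n_channels, self.samples_per_window,
               self.n_windows_per_class) < 1:
            raise ValueError("sizes must be positive")
        if self.sampling_rate <= 0 or self.noise_sd < 0:
            raise ValueError("invalid sampling_rate or noise_sd")

    def fast(self) -> "SyntheticSpec":
        """Desk-scale profile: 8 channels, 512 samples."""
        return replace(self, n_channels=8, samples_per_window=512)


def _latent_source(n_samples: int, sampling_rate: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Unit-variance AR(2) source with poles at radius 0.97, ~6 Hz."""
    theta = 2.0 * np.pi * _AR_FREQ_HZ / sampling_rate
    a1 = 2.0 * _AR_POLE_RADIUS * np.cos(theta)
    a2 = -(_AR_POLE_RADIUS**2)
    e = rng.standard_normal(n_samples + _BURN_IN)
    s = np.empty_like(e)
    s[0], s[1] = e[0], e[1]
    for t in range(2, s.size):
        s[t] = a1 * s[t - 1] + a2 * s[t - 2] + e[t]
    s = s[_BURN_IN:]
    return s / s.std()


def channel_gains(spec: SyntheticSpec) -> np.ndarray:
    """Per-channel gains in [0.5, 1.5), drawn once per dataset (seeded)."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(2,)))
    return rng.uniform(0.5, 1.5, size=spec.n_channels)


def generate_window(
    spec: SyntheticSpec,
    label: int,
    index: int = 0,
    gains: Union[np.ndarray, None] = None,
    coupling: Union[float, None] = None,
) -> np.ndarray:
    """One channels x samples window.

    ``label`` selects the coupling (seizure -> ``coupling_high``), unless
    ``coupling`` overrides it.  Bit-identical for identical
    (seed, index, label).
    """
    if label not in (SEIZURE, NON_SEIZURE):
        raise ValueError("label must be 0 (non-seizure) or 1 (seizure)")
    rho = coupling
    if rho is None:
        rho = spec.coupling_high if label == SEIZURE else spec.coupling_low
    g = channel_gains(spec) if gains is None else np.asarray(gains, dtype=float)
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(int(label), int(index)))
    )
    s = _latent_source(spec.samples_per_window, spec.sampling_rate, rng)
    noise = rng.standard_normal((spec.n_channels, spec.samples_per_window))
    return rho * g[:, None] * s[None, :] + (1.0 - rho) * spec.noise_sd * noise


def generate_windows(spec: SyntheticSpec) -> tuple:
    """Balanced raw windows: ``(list of windows, labels array)``."""
    gains = channel_gains(spec)
    windows, labels = [], []
    for label in (SEIZURE, NON_SEIZURE):
        for i in range(spec.n_windows_per_class):
            windows.append(generate_window(spec, label, index=i, gains=gains))
            labels.append(label)
    return windows, np.asarray(labels, dtype=int)


def generate_labeled_dataset(
    spec: SyntheticSpec, ap_config: APConfig = APConfig()
) -> tuple:
    """Balanced synchronization-matrix features: ``(X, labels, matrices)``.

    ``X`` stacks each window's flattened matrix (shape
    ``(2 * n_windows_per_class, n_channels**2)``).
    """
    windows, labels = generate_windows(spec)
    matrices = [build_cmapcpmi(w, config=ap_config) for w in windows]
    X = np.stack([m.flatten() for m in matrices])
    return X, labels, matrices
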