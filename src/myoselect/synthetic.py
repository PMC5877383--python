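"""Synthetic multichannel sEMG generator.

Each trial is envelope-modulated, band-limited Gaussian noise: white noise
filtered to a class-specific frequency band, scaled by a class-and-channel
gain, shaped by a 0.25 s onset ramp / 1 s plateau / 0.25 s offset ramp, and
mixed with a broadband noise floor plus optional 50 Hz power-line
interference.  The spectral signatures mimic the qualitative structure of
real forearm sEMG: fist clenching (MF) strongest at low frequencies
(10-105 Hz), wrist flexion (WF) strongest at 105-195 Hz, wrist extension
(WE) broad-band, and rest (REST) at a small fraction of movement amplitude.
Per-channel gains emulate muscle-electrode coupling, with each movement
loudest on one electrode site.

A second generator emits abstract feature matrices with a chosen set of
"planted" discriminative features (class-dependent mean and variance) among
i.i.d. noise features, for testing selection criteria in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .features import FeatureMatrix
from .recording import CLASSES, Recording, TrialAnnotation


def _default_bands() -> dict[str, tuple[float, float]]:
    return {
        "REST": (10.0, 450.0),
        "MF": (10.0, 105.0),
        "WE": (20.0, 250.0),
        "WF": (105.0, 195.0),
    }


def _default_gains() -> dict[str, tuple[float, ...]]:
    # rows: class; columns: channels APL, ECR, ECU, FCU.
    # Each movement couples most strongly to one electrode site.
    return {
        "REST": (0.05, 0.05, 0.05, 0.05),
        "MF": (1.0, 0.5, 0.5, 0.6),
        "WE": (0.4, 1.0, 0.8, 0.4),
        "WF": (0.4, 0.4, 0.5, 1.0),
    }


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults give well-separated four-class data."""

    n_channels: int = 4
    fs: float = 1000.0
    channel_names: tuple[str, ...] = ("APL", "ECR", "ECU", "FCU")
    classes: tuple[str, ...] = CLASSES
    trials_per_class: int = 40
    class_bands: dict = field(default_factory=_default_bands)
    class_gains: dict = field(default_factory=_default_gains)
    onset_s: float = 0.25
    plateau_s: float = 1.0
    offset_s: float = 0.25
    mains_hz: float = 50.0
    mains_amplitude: float = 0.2
    noise_floor: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for cls in self.classes:
            lo, hi = self.class_bands[cls]
            if not (0 < lo < hi < self.fs / 2):
                raise ValueError(f"band {lo}-{hi} Hz invalid for fs={self.fs}")
            gains = self.class_gains[cls]
            if len(gains) != self.n_channels or min(gains) < 0:
                raise ValueError("need one non-negative gain per channel")
        rest = max(self.class_gains.get("REST", (0,)))
        for cls in self.classes:
            if cls != "REST" and min(self.class_gains[cls]) <= rest:
                raise ValueError("REST gain must be below movement gains")

    @property
    def trial_duration_s(self) -> float:
        return self.onset_s + self.plateau_s + self.offset_s


def _envelope(config: SyntheticConfig) -> np.ndarray:
    fs = config.fs
    n_on = int(round(config.onset_s * fs))
    n_plateau = int(round(config.plateau_s * fs))
    n_off = int(round(config.offset_s * fs))
    ramp_on = 0.5 * (1 - np.cos(np.pi * np.arange(n_on) / max(n_on, 1)))
    ramp_off = 0.5 * (1 + np.cos(np.pi * np.arange(n_off) / max(n_off, 1)))
    return np.concatenate([ramp_on, np.ones(n_plateau), ramp_off])


def _band_noise(
    rng: np.random.Generator, n: int, band: tuple[float, float], fs: float
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band``."""
    sos = sps.butter(4, band, "bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n + 200))[100:-100]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate(config: SyntheticConfig | None = None) -> Recording:
    """Generate a labelled recording of concatenated 1.5 s trials.

    Trial order is a seeded shuffle of a balanced class sequence; the
    output is deterministic for a fixed config (including seed).
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    order = np.repeat(np.arange(len(config.classes)), config.trials_per_class)
    rng.shuffle(order)

    env = _envelope(config)
    n_trial = env.size
    fs = config.fs
    t = np.arange(n_trial) / fs
    n_total = n_trial * order.size
    samples = np.zeros((config.n_channels, n_total))
    trials = []
    for ti, cls_idx in enumerate(order):
        cls = config.classes[cls_idx]
        lo = ti * n_trial
        band = config.class_bands[cls]
        gains = config.class_gains[cls]
        phase = rng.uniform(0, 2 * np.pi)
        for ch in range(config.n_channels):
            burst = gains[ch] * env * _band_noise(rng, n_trial, band, fs)
            floor = config.noise_floor * rng.standard_normal(n_trial)
            mains = config.mains_amplitude * np.sin(
                2 * np.pi * config.mains_hz * t + phase
            )
            samples[ch, lo : lo + n_trial] = burst + floor + mains
        trials.append(
            TrialAnnotation(
                onset_s=lo / fs,
                label=cls,
                task_duration_s=config.trial_duration_s,
                execution_window=(config.onset_s, config.onset_s + config.plateau_s),
            )
        )
    return Recording(
        samples=samples,
        fs=fs,
        channel_names=list(config.channel_names),
        trials=trials,
    )


def generate_planted_features(
    n_windows: int,
    n_features: int,
    planted: list[int],
    effect_size: float,
    seed: int = 0,
    classes: tuple[str, ...] = CLASSES,
    feature_names: list[str] | None = None,
) -> FeatureMatrix:
    """Feature matrix with class-discriminative features planted among noise.

    ``n_windows`` is per class.  Planted features carry both a
    class-dependent mean shift (``effect_size`` standard deviations between
    adjacent classes) and a class-dependent variance inflation, so
    variance-based, distance-based and margin-based criteria can all detect
    them; all other features are i.i.d. standard normal regardless of
    class.  ``effect_size = 0`` gives fully exchangeable features (the null
    case).
    """
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    if any(j < 0 or j >= n_features for j in planted):
        raise ValueError("planted indices outside feature range")
    rng = np.random.default_rng(seed)
    labels = np.repeat(list(classes), n_windows)
    values = rng.standard_normal((n_windows * len(classes), n_features))
    for k, _cls in enumerate(classes):
        rows = slice(k * n_windows, (k + 1) * n_windows)
        shift = effect_size * k
        scale = 1.0 + 0.5 * effect_size * k
        for j in planted:
            values[rows, j] = values[rows, j] * scale + shift
    names = feature_names or [f"F{j + 1}" for j in range(n_features)]
    return FeatureMatrix(values=values, feature_names=names, labels=labels)
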