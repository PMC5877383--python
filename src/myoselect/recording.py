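"""Data model for multichannel surface-EMG recordings.

A :class:`Recording` holds the raw voltage matrix (channels x samples), the
sampling rate and a list of trial annotations.  Trials follow the cue-paced
protocol used for myoelectric interfaces: each trial lasts 1.5 s, split into
a 0.25 s onset transient, a 1 s execution period and a 0.25 s offset
transient.  Features are normally computed from the execution period only,
cut into analysis windows by either disjoint (non-overlapping) or overlapped
sliding segmentation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The four movement classes: rest, make-a-fist, wrist extension, wrist flexion.
CLASSES = ("REST", "MF", "WE", "WF")

DEFAULT_FS = 1000.0


@dataclass
class TrialAnnotation:
    """One cued trial: onset time, movement label and internal timing.

    ``execution_window`` is expressed in seconds relative to ``onset_s``;
    the default ``(0.25, 1.25)`` carves the one-second execution period out
    of a 1.5 s task.
    """

    onset_s: float
    label: str
    task_duration_s: float = 1.5
    execution_window: tuple[float, float] = (0.25, 1.25)

    def __post_init__(self) -> None:
        start, end = self.execution_window
        if not (0 <= start < end <= self.task_duration_s):
            raise ValueError(
                f"execution window {self.execution_window} must satisfy "
                f"0 <= start < end <= task_duration ({self.task_duration_s})"
            )
        if self.onset_s < 0:
            raise ValueError("trial onset must be non-negative")


@dataclass
class Recording:
    """Multichannel sEMG signal with sampling rate and trial annotations.

    ``samples`` has shape (n_channels, n_samples); all channels share a
    common time base.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    channel_names: list[str] | None = None
    trials: list[TrialAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n_ch = self.samples.shape[0]
        if self.channel_names is None:
            self.channel_names = [f"ch{i + 1}" for i in range(n_ch)]
        if len(self.channel_names) != n_ch:
            raise ValueError("channel_names length must match channel count")
        for tr in self.trials:
            if (tr.onset_s + tr.task_duration_s) * self.fs > self.n_samples + 0.5:
                raise ValueError(
                    f"trial at {tr.onset_s}s extends past the end of the signal"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray) -> "Recording":
        """Copy of this recording with the signal matrix replaced."""
        return Recording(
            samples=samples,
            fs=self.fs,
            channel_names=list(self.channel_names),
            trials=list(self.trials),
        )


@dataclass
class WindowSpec:
    """Analysis-window geometry.

    ``overlap_frac`` = 0 gives disjoint segmentation; anything in (0, 1)
    gives overlapped segmentation with stride ``length_s * (1 - overlap_frac)``.
    """

    length_s: float
    overlap_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.length_s <= 0:
            raise ValueError("window length must be positive")
        if not (0 <= self.overlap_frac < 1):
            raise ValueError("overlap fraction must lie in [0, 1)")

    @property
    def mode(self) -> str:
        return "disjoint" if self.overlap_frac == 0 else "overlapped"

    def length_samples(self, fs: float) -> int:
        n = int(np.floor(self.length_s * fs))
        if n < 1:
            raise ValueError("window shorter than one sample at this rate")
        return n

    def stride_samples(self, fs: float) -> int:
        # fractional strides floored, minimum one sample
        return max(1, int(np.floor(self.length_s * (1 - self.overlap_frac) * fs)))


@dataclass
class Window:
    """One analysis window: per-channel data plus provenance."""

    data: np.ndarray  # (n_channels, n_window_samples)
    label: str | None
    trial_index: int | None
    start_s: float


def segment(
    recording: Recording,
    spec: WindowSpec,
    scope: str = "execution_only",
) -> list[Window]:
    """Cut a recording into analysis windows.

    ``scope='execution_only'`` restricts each trial to its execution period
    (the steady-state portion of the movement); ``scope='full'`` uses the
    whole task interval.  When the recording carries no trial annotations
    the entire signal is treated as one unlabelled interval.  Sample
    intervals are half-open ``[start, end)`` and trailing partial windows
    are dropped, so a 1 s execution period yields exactly four 250 ms
    disjoint windows.
    """
    if scope not in ("execution_only", "full"):
        raise ValueError(f"unknown scope {scope!r}")
    fs = recording.fs
    win = spec.length_samples(fs)
    stride = spec.stride_samples(fs)

    if recording.trials:
        intervals = []
        for idx, tr in enumerate(recording.trials):
            if scope == "execution_only":
                t0 = tr.onset_s + tr.execution_window[0]
                t1 = tr.onset_s + tr.execution_window[1]
            else:
                t0 = tr.onset_s
                t1 = tr.onset_s + tr.task_duration_s
            intervals.append((t0, t1, tr.label, idx))
    else:
        intervals = [(0.0, recording.duration_s, None, None)]

    out: list[Window] = []
    for t0, t1, label, idx in intervals:
        start = int(np.floor(t0 * fs))
        stop = min(int(np.floor(t1 * fs)), recording.n_samples)
        if stop - start < win:
            raise ValueError(
                f"window of {win} samples does not fit in interval of "
                f"{stop - start} samples"
            )
        for s in range(start, stop - win + 1, stride):
            out.append(
                Window(
                    data=recording.samples[:, s : s + win],
                    label=label,
                    trial_index=idx,
                    start_s=s / fs,
                )
            )
    return out


def load_recording(
    path: str,
    fs: float = DEFAULT_FS,
    format: str | None = None,
    trials: list[TrialAnnotation] | None = None,
) -> Recording:
    """Read a recording from CSV (one column per channel) or WAV.

    For WAV files the sample rate embedded in the file overrides ``fs``.
    CSV files must have a header row of channel names and numeric cells.
    """
    if format is None:
        format = os.path.splitext(path)[1].lstrip(".").lower() or "csv"
    if format == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        for col in df.columns:
            if not pd.api.types.is_numeric_dtype(df[col]):
                raise ValueError(f"non-numeric sample in column {col!r}")
        return Recording(
            samples=df.to_numpy(dtype=float).T,
            fs=fs,
            channel_names=[str(c) for c in df.columns],
            trials=trials or [],
        )
    if format == "wav":
        from scipy.io import wavfile

        rate, data = wavfile.read(path)
        data = np.atleast_2d(np.asarray(data, dtype=float))
        if data.shape[0] > data.shape[1]:  # wavfile returns (samples, channels)
            data = data.T
        return Recording(samples=data, fs=float(rate), trials=trials or [])
    raise ValueError(f"unsupported format {format!r}")


def save_recording(recording: Recording, path: str) -> None:
    """Write samples to CSV with full float precision (round-trip safe)."""
    df = pd.DataFrame(recording.samples.T, columns=recording.channel_names)
    df.to_csv(path, index=False, float_format="%.17g")


def load_trials(path: str) -> list[TrialAnnotation]:
    """Read trial annotations from a CSV with columns onset_s,label[,task_duration_s]."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        kwargs = {"onset_s": float(row["onset_s"]), "label": str(row["label"])}
        if "task_duration_s" in df.columns:
            kwargs["task_duration_s"] = float(row["task_duration_s"])
        out.append(TrialAnnotation(**kwargs))
    return out


def save_trials(trials: list[TrialAnnotation], path: str) -> None:
    pd.DataFrame(
        {
            "onset_s": [t.onset_s for t in trials],
            "label": [t.label for t in trials],
            "task_duration_s": [t.task_duration_s for t in trials],
        }
    ).to_csv(path, index=False)
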