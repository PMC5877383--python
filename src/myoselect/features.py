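"""The 42-dimension per-channel sEMG feature bank.

Time domain: MAV, MMAV1, MMAV2, RMS, VAR, WL, ZC (2 thresholds), SSC,
WAMP (5 thresholds), SSI, HEMG (6 bins).  Frequency domain: 4th-order AR
coefficients (Burg), median and mean frequency of the Welch PSD.
Time-frequency domain: a short-time-Fourier PSD scalar and the average
power / standard deviation of 6-level DB4 wavelet coefficients in each of
the 7 sub-bands (D1..D6, A6).

Definitions follow the conventions standard in the myoelectric-control
literature (Phinyomark et al.); threshold-bearing counters (ZC, SSC, WAMP)
take their deadbands as configurable fractions of the window RMS by
default, since results are sensitive to the absolute threshold choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

from .recording import Window

#: Canonical per-channel feature order; exactly 42 names.
FEATURE_NAMES: tuple[str, ...] = (
    "MAV",
    "MMAV1",
    "MMAV2",
    "RMS",
    "VAR",
    "WL",
    "ZC1",
    "ZC2",
    "SSC",
    "WAMP1",
    "WAMP2",
    "WAMP3",
    "WAMP4",
    "WAMP5",
    "SSI",
    "HEMG1",
    "HEMG2",
    "HEMG3",
    "HEMG4",
    "HEMG5",
    "HEMG6",
    "AR1",
    "AR2",
    "AR3",
    "AR4",
    "MDF",
    "MNF",
    "STFT",
    "APWC_D1",
    "APWC_D2",
    "APWC_D3",
    "APWC_D4",
    "APWC_D5",
    "APWC_D6",
    "APWC_A6",
    "SDWC_D1",
    "SDWC_D2",
    "SDWC_D3",
    "SDWC_D4",
    "SDWC_D5",
    "SDWC_D6",
    "SDWC_A6",
)

assert len(FEATURE_NAMES) == 42


@dataclass
class FeatureSpec:
    """Tunable parameters of the feature bank.

    ``threshold_mode='rms_fraction'`` interprets the ZC/SSC/WAMP thresholds
    as fractions of the window RMS; ``'absolute'`` uses them as voltages.
    """

    wamp_thresholds: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3, 0.4)
    zc_thresholds: tuple[float, ...] = (0.0, 0.05)
    ssc_threshold: float = 0.05
    threshold_mode: str = "rms_fraction"
    hemg_bins: int = 6
    hemg_span_std: float = 3.0
    ar_order: int = 4
    dwt_wavelet: str = "db4"
    dwt_levels: int = 6
    welch_nperseg: int = 256
    stft_nperseg: int = 64

    def __post_init__(self) -> None:
        if list(self.wamp_thresholds) != sorted(self.wamp_thresholds):
            raise ValueError("WAMP thresholds must be increasing")
        if list(self.zc_thresholds) != sorted(self.zc_thresholds):
            raise ValueError("ZC thresholds must be increasing")
        if self.threshold_mode not in ("rms_fraction", "absolute"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")

    def resolve_thresholds(self, window: np.ndarray):
        """Return (zc, ssc, wamp) thresholds in volts for this window."""
        if self.threshold_mode == "absolute":
            scale = 1.0
        else:
            scale = float(np.sqrt(np.mean(window**2)))
        return (
            tuple(t * scale for t in self.zc_thresholds),
            self.ssc_threshold * scale,
            tuple(t * scale for t in self.wamp_thresholds),
        )


def extract_time_features(window: np.ndarray, spec: FeatureSpec | None = None) -> dict:
    """Amplitude-domain features of a single-channel window."""
    spec = spec or FeatureSpec()
    x = np.asarray(window, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise ValueError("window must contain at least 3 samples")
    zc_thr, ssc_thr, wamp_thr = spec.resolve_thresholds(x)

    absx = np.abs(x)
    out = {"MAV": absx.mean()}

    # MMAV1: weight 1 on the central half of the window, 0.5 on the flanks.
    i = np.arange(1, n + 1)
    w1 = np.where((i >= 0.25 * n) & (i <= 0.75 * n), 1.0, 0.5)
    out["MMAV1"] = np.mean(w1 * absx)
    # MMAV2: continuous ramp weighting rising 4i/n on the leading flank and
    # falling 4(n-i)/n on the trailing flank.
    w2 = np.ones(n)
    lead = i < 0.25 * n
    trail = i > 0.75 * n
    w2[lead] = 4 * i[lead] / n
    w2[trail] = 4 * (n - i[trail]) / n
    out["MMAV2"] = np.mean(w2 * absx)

    out["RMS"] = np.sqrt(np.mean(x**2))
    out["VAR"] = np.var(x, ddof=1)
    d = np.diff(x)
    out["WL"] = np.sum(np.abs(d))

    for j, thr in enumerate(zc_thr, start=1):
        out[f"ZC{j}"] = int(np.sum((x[:-1] * x[1:] < 0) & (np.abs(d) >= thr)))

    mid, prev, nxt = x[1:-1], x[:-2], x[2:]
    turning = (mid - prev) * (mid - nxt) > 0
    big = np.maximum(np.abs(mid - prev), np.abs(mid - nxt)) >= ssc_thr
    out["SSC"] = int(np.sum(turning & big))

    for j, thr in enumerate(wamp_thr, start=1):
        out[f"WAMP{j}"] = int(np.sum(np.abs(d) > thr))

    out["SSI"] = np.sum(x**2)

    std = x.std()
    span = spec.hemg_span_std * std if std > 0 else 1.0
    counts, _ = np.histogram(x, bins=spec.hemg_bins, range=(-span, span))
    for j, c in enumerate(counts, start=1):
        out[f"HEMG{j}"] = int(c)
    return out


def extract_frequency_features(
    window: np.ndarray, fs: float, spec: FeatureSpec | None = None
) -> dict:
    """AR coefficients (Burg) and median/mean frequency of the Welch PSD."""
    from statsmodels.regression.linear_model import burg

    spec = spec or FeatureSpec()
    x = np.asarray(window, dtype=float).ravel()
    if x.size < 2 * spec.ar_order:
        raise ValueError("window too short for AR estimation")
    if np.ptp(x) == 0:
        raise ValueError("constant window: AR/MDF/MNF undefined")

    ar, _ = burg(x, order=spec.ar_order, demean=True)
    out = {f"AR{j + 1}": float(ar[j]) for j in range(spec.ar_order)}

    f, p = sps.welch(x, fs=fs, nperseg=min(spec.welch_nperseg, x.size))
    total = p.sum()
    cum = np.cumsum(p)
    out["MDF"] = float(f[np.searchsorted(cum, total / 2.0)])
    out["MNF"] = float(np.sum(f * p) / total)
    return out


def dwt_subbands(
    window: np.ndarray, wavelet: str = "db4", levels: int = 6
) -> dict[str, np.ndarray]:
    """Wavelet coefficients per sub-band, keyed D1..D{levels}, A{levels}.

    Periodized decomposition, so the coefficient energies sum to the signal
    energy (exactly at power-of-two lengths).
    """
    x = np.asarray(window, dtype=float).ravel()
    if x.size < 2**levels:
        raise ValueError(f"window of {x.size} samples too short for {levels} levels")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, wavelet, level=levels, mode="periodization")
    bands = {f"A{levels}": coeffs[0]}
    for k, c in enumerate(coeffs[1:]):
        bands[f"D{levels - k}"] = c
    return bands


def extract_timefreq_features(
    window: np.ndarray, fs: float, spec: FeatureSpec | None = None
) -> dict:
    """STFT PSD scalar plus average power and std of DWT sub-band coefficients."""
    spec = spec or FeatureSpec()
    x = np.asarray(window, dtype=float).ravel()

    _, _, sxx = sps.spectrogram(x, fs=fs, nperseg=min(spec.stft_nperseg, x.size))
    out = {"STFT": float(sxx.mean())}

    bands = dwt_subbands(x, spec.dwt_wavelet, spec.dwt_levels)
    order = [f"D{k}" for k in range(1, spec.dwt_levels + 1)] + [f"A{spec.dwt_levels}"]
    for b in order:
        out[f"APWC_{b}"] = float(np.mean(bands[b] ** 2))
    for b in order:
        out[f"SDWC_{b}"] = float(np.std(bands[b]))
    return out


def extract_channel_features(
    window: np.ndarray, fs: float, spec: FeatureSpec | None = None
) -> dict:
    """All 42 features of one channel window, in canonical order."""
    spec = spec or FeatureSpec()
    vals = {}
    vals.update(extract_time_features(window, spec))
    vals.update(extract_frequency_features(window, fs, spec))
    vals.update(extract_timefreq_features(window, fs, spec))
    return {name: vals[name] for name in FEATURE_NAMES}


@dataclass
class FeatureMatrix:
    """Windows x features table with class labels and channel provenance.

    Cascading C channels yields 42*C columns named ``<channel>_<feature>``;
    a single-channel matrix uses the bare feature names.
    """

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (windows x features)")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match column count")
        if self.values.shape[0] != self.labels.size:
            raise ValueError("labels length must match window count")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels.tolist()))

    def select(self, names: list[str]) -> "FeatureMatrix":
        """Column subset in the order given."""
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            values=self.values[:, idx],
            feature_names=list(names),
            labels=self.labels.copy(),
            channel_names=list(self.channel_names),
        )

    def subset_classes(self, classes) -> "FeatureMatrix":
        mask = np.isin(self.labels, list(classes))
        return FeatureMatrix(
            values=self.values[mask],
            feature_names=list(self.feature_names),
            labels=self.labels[mask],
            channel_names=list(self.channel_names),
        )

    def per_channel(self, channel: str) -> "FeatureMatrix":
        """The 42-column single-channel view of a cascaded matrix."""
        prefix = f"{channel}_"
        names = [n for n in self.feature_names if n.startswith(prefix)]
        if not names:
            raise KeyError(f"no columns for channel {channel!r}")
        sub = self.select(names)
        sub.feature_names = [n[len(prefix) :] for n in names]
        sub.channel_names = [channel]
        return sub

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        return df

    def to_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy()
        return cls(
            values=df.to_numpy(dtype=float),
            feature_names=list(df.columns),
            labels=labels,
        )


def extract_all(
    windows: list[Window],
    fs: float,
    spec: FeatureSpec | None = None,
    channel_names: list[str] | None = None,
) -> FeatureMatrix:
    """Extract the full bank for every window, cascading channels in order.

    One channel gives 42 columns; four channels give 168.
    """
    spec = spec or FeatureSpec()
    if not windows:
        raise ValueError("no windows to extract")
    n_ch = windows[0].data.shape[0]
    if channel_names is None:
        channel_names = [f"ch{i + 1}" for i in range(n_ch)]
    if n_ch == 1:
        columns = list(FEATURE_NAMES)
    else:
        columns = [f"{ch}_{f}" for ch in channel_names for f in FEATURE_NAMES]

    rows = np.empty((len(windows), len(columns)))
    for wi, w in enumerate(windows):
        vec = []
        for ch in range(n_ch):
            feats = extract_channel_features(w.data[ch], fs, spec)
            vec.extend(feats.values())
        rows[wi] = vec
    labels = np.array([w.label for w in windows])
    return FeatureMatrix(
        values=rows,
        feature_names=columns,
        labels=labels,
        channel_names=list(channel_names),
    )
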