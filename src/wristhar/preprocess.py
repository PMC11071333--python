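"""Signal conditioning and feature extraction for six-axis IMU recordings.

The stages implemented here turn a raw inertial recording (3-axis
acceleration + 3-axis angular velocity at ~50 Hz) into the fixed-length
feature vectors consumed by the window classifier:

1. :func:`mean_filter` — centred moving-average denoising, applied per
   channel before windowing.
2. :func:`slide_windows` — fixed sliding windows (default 50 samples with
   step 10, i.e. ~1 s windows at 50 Hz with 80% overlap), each labelled by
   the per-sample majority class.
3. :func:`extract_features` — ten time-domain statistics per channel,
   concatenated channel-major into a 60-dimensional vector.
4. :class:`FeatureNormalizer` — per-column z-scoring so that features with
   different physical units contribute on the same scale.

Conventions used throughout: 0-based sample indices, half-open windows
``[s, s + length)``, and the sample (``W - 1`` denominator) standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CHANNEL_NAMES",
    "STAT_NAMES",
    "N_CHANNELS",
    "ImuRecording",
    "WindowSpec",
    "FeatureDataset",
    "FeatureNormalizer",
    "mean_filter",
    "slide_windows",
    "window_starts",
    "majority_label",
    "extract_features",
    "extract_features_batch",
    "build_feature_dataset",
    "fit_normalizer",
    "apply_normalizer",
]

CHANNEL_NAMES: tuple[str, ...] = ("ax", "ay", "az", "gx", "gy", "gz")
N_CHANNELS = len(CHANNEL_NAMES)

#: The ten per-channel statistics, in the fixed order used for feature
#: columns. Channel c, statistic k lands in column ``c * 10 + k``.
STAT_NAMES: tuple[str, ...] = (
    "mean",
    "std",
    "var",
    "max",
    "min",
    "range",
    "median",
    "rms",
    "skew",
    "kurtosis",
)


@dataclass
class ImuRecording:
    """A timestamped six-axis inertial recording.

    Parameters
    ----------
    sample_rate_hz
        Sampling frequency in Hz; strictly positive.
    samples
        ``(T, 6)`` array with columns ``ax, ay, az`` (acceleration, g) and
        ``gx, gy, gz`` (angular velocity, deg/s).
    labels
        Optional per-sample integer activity labels of length ``T``.
    subject_id
        Optional free-form identifier of the recorded subject/sequence.
    """

    sample_rate_hz: float
    samples: np.ndarray
    labels: np.ndarray | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ValueError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        if self.samples.ndim != 2 or self.samples.shape[1] != N_CHANNELS:
            raise ValueError(
                f"samples must be a (T, {N_CHANNELS}) array, got shape {self.samples.shape}"
            )
        if self.samples.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.samples.shape[0],):
                raise ValueError(
                    f"labels length {self.labels.shape} does not match "
                    f"T={self.samples.shape[0]}"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.sample_rate_hz

    def filtered(self, width: int) -> "ImuRecording":
        """Return a copy with each channel mean-filtered with window `width`."""
        out = np.column_stack(
            [mean_filter(self.samples[:, c], width) for c in range(N_CHANNELS)]
        )
        return ImuRecording(self.sample_rate_hz, out, self.labels, self.subject_id)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: `length` samples advancing by `step`."""

    length: int = 50
    step: int = 10

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError(f"window length must be >= 2, got {self.length}")
        if self.step < 1 or self.step > self.length:
            raise ValueError(
                f"step must satisfy 1 <= step <= length, got step={self.step}, "
                f"length={self.length}"
            )

    def n_windows(self, n_samples: int) -> int:
        if n_samples < self.length:
            return 0
        return (n_samples - self.length) // self.step + 1


@dataclass
class FeatureDataset:
    """Per-window feature matrix with labels and window provenance.

    ``features`` is ``(W, 10 * 6)``; column ``c * 10 + k`` holds statistic
    ``stat_names[k]`` of channel ``c``.
    """

    features: np.ndarray
    labels: np.ndarray
    window_starts: np.ndarray
    stat_names: tuple[str, ...] = STAT_NAMES

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.window_starts = np.asarray(self.window_starts, dtype=int)
        w = self.features.shape[0]
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        expected = len(self.stat_names) * N_CHANNELS
        if self.features.shape[1] != expected:
            raise ValueError(
                f"features must have {expected} columns "
                f"({len(self.stat_names)} stats x {N_CHANNELS} channels), "
                f"got {self.features.shape[1]}"
            )
        if self.labels.shape != (w,) or self.window_starts.shape != (w,):
            raise ValueError("labels and window_starts must match the number of windows")

    @property
    def n_windows(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def stat_columns(self, stats: Sequence[str]) -> np.ndarray:
        """Column indices selecting the given statistics on every channel."""
        k = len(self.stat_names)
        idx = []
        for c in range(N_CHANNELS):
            for s in stats:
                idx.append(c * k + self.stat_names.index(s))
        return np.asarray(idx, dtype=int)


def mean_filter(signal: np.ndarray, window: int) -> np.ndarray:
    """Centred moving-average filter with edge truncation.

    ``y[n]`` is the mean of ``x[n + k]`` for ``k`` in
    ``[-(N-1)/2, (N-1)/2]``; at the two boundaries the averaging window is
    truncated to the valid index range (no padding), which keeps constant
    signals exactly invariant. Output length equals input length.

    Parameters
    ----------
    signal : 1-D array of length T
    window : odd int, 1 <= window <= T
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("mean_filter expects a 1-D signal")
    n = x.shape[0]
    if window % 2 == 0:
        raise ValueError(f"filter window must be odd, got {window}")
    if window < 1 or window > n:
        raise ValueError(f"filter window must satisfy 1 <= N <= T={n}, got {window}")
    half = (window - 1) // 2
    # Prefix-sum formulation: window mean over the clipped range
    # [n - half, n + half] intersected with [0, T).
    csum = np.concatenate(([0.0], np.cumsum(x)))
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def window_starts(n_samples: int, spec: WindowSpec) -> np.ndarray:
    """Start indices ``0, step, 2*step, ...`` of all full windows."""
    return np.arange(spec.n_windows(n_samples)) * spec.step


def majority_label(labels: np.ndarray) -> int:
    """Majority vote with ties broken by the earliest tied sample.

    Among the classes achieving the maximal count, the winner is the label
    of the earliest sample in the window that belongs to a tied class.
    """
    labels = np.asarray(labels, dtype=int)
    values, counts = np.unique(labels, return_counts=True)
    best = counts.max()
    tied = set(values[counts == best])
    if len(tied) == 1:
        return int(next(iter(tied)))
    for lab in labels:
        if int(lab) in tied:
            return int(lab)
    raise AssertionError("unreachable")  # pragma: no cover


def slide_windows(
    recording: ImuRecording, spec: WindowSpec = WindowSpec()
) -> list[tuple[np.ndarray, int | None]]:
    """Cut a recording into labelled fixed-length windows.

    Returns a list of ``(window, label)`` pairs, where ``window`` is a
    ``(length, 6)`` view and ``label`` is the majority per-sample label
    (``None`` when the recording is unlabelled). Windows start at
    ``0, step, 2*step, ...``; the count is ``floor((T - length)/step) + 1``.
    """
    t = recording.n_samples
    if t < spec.length:
        raise ValueError(
            f"recording has {t} samples but at least {spec.length} are needed "
            f"for one window"
        )
    out: list[tuple[np.ndarray, int | None]] = []
    for s in window_starts(t, spec):
        win = recording.samples[s : s + spec.length]
        if recording.labels is None:
            lab: int | None = None
        else:
            lab = majority_label(recording.labels[s : s + spec.length])
        out.append((win, lab))
    return out


def _stats_along(x: np.ndarray, axis: int) -> list[np.ndarray]:
    """The ten statistics of STAT_NAMES computed along `axis`.

    Skewness and excess kurtosis use population central moments
    (m3 / m2^1.5 and m4 / m2^2 - 3) and are defined as 0 when the variance
    is zero, so constant windows remain legal inputs. The standard
    deviation and variance features use the sample (W-1) denominator.
    """
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=axis)
    centred = x - np.expand_dims(mean, axis)
    m2 = np.mean(centred**2, axis=axis)
    m3 = np.mean(centred**3, axis=axis)
    m4 = np.mean(centred**4, axis=axis)
    var = x.var(axis=axis, ddof=1)
    std = np.sqrt(var)
    mx = x.max(axis=axis)
    mn = x.min(axis=axis)
    rng = mx - mn
    median = np.median(x, axis=axis)
    rms = np.sqrt(np.mean(x**2, axis=axis))
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(m2 > 0, m3 / np.where(m2 > 0, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(m2 > 0, m4 / np.where(m2 > 0, m2, 1.0) ** 2 - 3.0, 0.0)
    return [mean, std, var, mx, mn, rng, median, rms, skew, kurt]


def extract_features(window: np.ndarray) -> np.ndarray:
    """60-dimensional statistical feature vector of one ``(length, 6)`` window.

    For each of the six channels the ten statistics of :data:`STAT_NAMES`
    are computed and concatenated channel-major:
    ``[stats(ax), stats(ay), ..., stats(gz)]``.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 2 or w.shape[1] != N_CHANNELS or w.shape[0] < 2:
        raise ValueError(
            f"window must be a (length >= 2, {N_CHANNELS}) array, got shape {w.shape}"
        )
    if not np.all(np.isfinite(w)):
        raise ValueError("window contains non-finite values")
    stats = _stats_along(w, axis=0)  # each entry shape (6,)
    stacked = np.stack(stats, axis=1)  # (6, 10)
    return stacked.reshape(-1)


def extract_features_batch(windows: np.ndarray) -> np.ndarray:
    """Vectorised :func:`extract_features` over a ``(W, length, 6)`` stack."""
    w = np.asarray(windows, dtype=float)
    if w.ndim != 3 or w.shape[2] != N_CHANNELS or w.shape[1] < 2:
        raise ValueError(f"expected a (W, length >= 2, {N_CHANNELS}) stack, got {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ValueError("windows contain non-finite values")
    stats = _stats_along(w, axis=1)  # each entry shape (W, 6)
    stacked = np.stack(stats, axis=2)  # (W, 6, 10)
    return stacked.reshape(w.shape[0], -1)


def build_feature_dataset(
    recording: ImuRecording,
    spec: WindowSpec = WindowSpec(),
    filter_width: int | None = 5,
) -> FeatureDataset:
    """Filter, window and featurise one labelled recording.

    ``filter_width=None`` skips denoising. Unlabelled recordings yield a
    dataset whose labels are all -1.
    """
    rec = recording.filtered(filter_width) if filter_width is not None else recording
    t = rec.n_samples
    if t < spec.length:
        raise ValueError(
            f"recording has {t} samples but at least {spec.length} are needed"
        )
    starts = window_starts(t, spec)
    idx = starts[:, None] + np.arange(spec.length)[None, :]
    feats = extract_features_batch(rec.samples[idx])
    if rec.labels is None:
        labels = np.full(len(starts), -1, dtype=int)
    else:
        labels = np.array([majority_label(rec.labels[s : s + spec.length]) for s in starts])
    return FeatureDataset(feats, labels, starts)


@dataclass
class FeatureNormalizer:
    """Per-column z-score parameters fitted on training features.

    Zero-variance columns are flagged and stored with deviation 1, so
    applying the normalizer maps them to exactly 0.
    """

    mean: np.ndarray
    std: np.ndarray
    constant_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.constant_mask is None:
            self.constant_mask = np.zeros(self.mean.shape, dtype=bool)
        else:
            self.constant_mask = np.asarray(self.constant_mask, dtype=bool)
        if not np.all(self.std > 0):
            raise ValueError("stored deviations must all be > 0")

    def transform(self, features: np.ndarray) -> np.ndarray:
        x = np.asarray(features, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.mean.shape[0]:
            raise ValueError(
                f"feature width {x.shape} does not match normalizer "
                f"({self.mean.shape[0]} columns)"
            )
        return (x - self.mean) / self.std


def fit_normalizer(features: np.ndarray) -> FeatureNormalizer:
    """Fit per-column mean/sd (sample sd, W-1 denominator) on >= 2 rows."""
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("normalizer requires a 2-D matrix with at least 2 rows")
    mean = x.mean(axis=0)
    std = x.std(axis=0, ddof=1)
    constant = std == 0
    std = np.where(constant, 1.0, std)
    return FeatureNormalizer(mean, std, constant)


def apply_normalizer(normalizer: FeatureNormalizer, features: np.ndarray) -> np.ndarray:
    """Return ``(x - mean) / sd`` per column; constant columns map to 0."""
    return normalizer.transform(features)
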