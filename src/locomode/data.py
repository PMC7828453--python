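"""Labeled IMU recordings: CSV I/O, synthetic simulation, windowing and features.

The raw substrate is a 6-channel inertial stream (tri-axial acceleration
``ax, ay, az`` and tri-axial angular rate ``gx, gy, gz``) sampled at 100 Hz and
labeled with one of nine locomotion modes: slow / medium / fast level walking
(SLW, MLW, FLW), ramp descent/ascent (RD, RA), stair descent/ascent (SD, SA),
Sit and Stand.  Recordings are cut into short fixed-length time windows
(100/150/200 ms); each window — either the flattened raw samples or a
24-dimensional summary (max, min, mean, sd per channel) — is one
classification instance.

Because real below-knee IMU data is not bundled, :func:`simulate_recording`
generates quasi-periodic surrogate signals whose default per-mode profiles
reproduce the qualitative similarity structure of human gait sensing: the
three walking speeds differ mainly in cadence and amplitude, the two ramp
modes resemble each other (opposite shank tilt), the two stair modes resemble
each other, and Sit/Stand are near-static with subtly different gravity
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

#: Frozen locomotion-mode order; all one-hot encodings and confusion matrices
#: use this order.
MODES: tuple[str, ...] = ("SLW", "MLW", "FLW", "RD", "SD", "Sit", "Stand", "RA", "SA")
MODE_INDEX: dict[str, int] = {m: i for i, m in enumerate(MODES)}

#: Channel order used everywhere (CSV columns, flattening, feature blocks).
CHANNELS: tuple[str, ...] = ("ax", "ay", "az", "gx", "gy", "gz")

_CSV_COLUMNS = ("subject_id", "mode", "t", *CHANNELS)


@dataclass
class IMURecording:
    """One contiguous labeled 6-channel recording.

    ``samples`` has shape (T, 6) in CHANNELS order; units are consistent but
    abstract (the simulator uses m/s^2-like accelerations and rad/s-like rates).
    """

    samples: np.ndarray
    rate_hz: float
    mode: str
    subject_id: str = "sim"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != len(CHANNELS):
            raise ValueError(f"samples must be (T, 6), got {self.samples.shape}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.mode not in MODE_INDEX:
            raise ValueError(f"unknown locomotion mode {self.mode!r}; expected one of {MODES}")

    def __len__(self) -> int:
        return self.samples.shape[0]


@dataclass
class WindowInstance:
    """One fixed-length window flattened to an input vector with its label."""

    vector: np.ndarray
    label: str
    window_ms: int


@dataclass
class Dataset:
    """A matrix of window instances.

    ``X`` is (n_instances, dim); ``labels`` holds the 9-way mode strings.
    ``y``/``n_classes`` are set once instances have been given node-local (or
    flat 9-way) integer targets for training.
    """

    X: np.ndarray
    labels: np.ndarray
    window_ms: int
    split_tag: str | None = None
    y: np.ndarray | None = None
    n_classes: int | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.X.ndim != 2 or self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("X and labels disagree on instance count")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def instances(self) -> Iterable[WindowInstance]:
        for row, lab in zip(self.X, self.labels):
            yield WindowInstance(row, str(lab), self.window_ms)

    def targets_onehot(self) -> np.ndarray:
        if self.y is None or self.n_classes is None:
            raise ValueError("dataset has no integer targets; relabel it first")
        T = np.zeros((len(self), self.n_classes))
        T[np.arange(len(self)), self.y] = 1.0
        return T

    def with_flat_targets(self) -> "Dataset":
        """Attach 9-way integer targets in the frozen mode order."""
        y = np.array([MODE_INDEX[str(m)] for m in self.labels])
        return replace(self, y=y, n_classes=len(MODES))


# ---------------------------------------------------------------------------
# CSV I/O


def read_recordings(path: str | Path) -> list[IMURecording]:
    """Read labeled recordings from CSV.

    Expects header columns ``subject_id, mode, t, ax, ay, az, gx, gy, gz``.
    Each contiguous (subject_id, mode) block becomes one recording; the
    sampling rate is inferred from the median time step of the block (120 s at
    100 Hz is the study protocol, but any uniform rate is accepted).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    values = df[list(CHANNELS)].to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"{path}: non-finite value in column {CHANNELS[c]!r} at data row {r}")
    unknown = set(df["mode"].astype(str)) - set(MODES)
    if unknown:
        row = int(np.argmax(df["mode"].astype(str).isin(unknown).to_numpy()))
        raise ValueError(
            f"{path}: unknown mode label(s) {sorted(unknown)} (first at data row {row}); "
            f"expected one of {MODES}"
        )

    keys = list(zip(df["subject_id"].astype(str), df["mode"].astype(str)))
    # contiguous-block boundaries, order preserved
    breaks = [0] + [i for i in range(1, len(keys)) if keys[i] != keys[i - 1]] + [len(keys)]
    recs = []
    t = df["t"].to_numpy(dtype=float)
    for a, b in zip(breaks[:-1], breaks[1:]):
        if b - a >= 2:
            dt = float(np.median(np.diff(t[a:b])))
            rate = 1.0 / dt if dt > 0 else 100.0
        else:
            rate = 100.0
        subject, mode = keys[a]
        recs.append(IMURecording(values[a:b], rate_hz=round(rate, 6), mode=mode, subject_id=subject))
    return recs


def write_recordings(recs: Sequence[IMURecording], path: str | Path) -> None:
    """Write recordings to the CSV schema read by :func:`read_recordings`."""
    frames = []
    for rec in recs:
        t = np.arange(len(rec)) / rec.rate_hz
        frame = pd.DataFrame(rec.samples, columns=list(CHANNELS))
        frame.insert(0, "t", t)
        frame.insert(0, "mode", rec.mode)
        frame.insert(0, "subject_id", rec.subject_id)
        frames.append(frame)
    # %.17g + round_trip parsing on read makes the cycle bit-exact
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Simulator


@dataclass
class ModeProfile:
    """Generative profile of one locomotion mode.

    Each channel is ``baseline + sum_k decay_k * amplitude * sin(2*pi*k*f*t +
    phase)`` plus Gaussian noise; ``freq_hz`` is the stride (cadence)
    fundamental, ``jitter`` scales random per-harmonic phase offsets drawn once
    per recording (so two recordings of the same mode are not phase-locked).
    Static modes have zero amplitudes and are distinguished by baseline alone.
    """

    baseline: tuple[float, ...]
    freq_hz: float
    amplitudes: tuple[float, ...]
    noise_sd: float
    jitter: float = 0.3

    def __post_init__(self) -> None:
        if len(self.baseline) != 6 or len(self.amplitudes) != 6:
            raise ValueError("baseline and amplitudes must have 6 entries")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


# Relative strength of harmonics 1..3 of the stride frequency.
_HARMONIC_DECAY = (1.0, 0.45, 0.2)
# Fixed per-channel phase lags (quarter-cycle steps) giving each channel a
# distinct but repeatable waveform shape.
_CHANNEL_PHASE = tuple(c * np.pi / 3 for c in range(6))

#: Default per-mode profiles. Walking speeds share a baseline and differ in
#: cadence/amplitude; RA/RD differ from walking only by a small shank-tilt
#: gravity component (opposite signs for ascent/descent) and a slightly raised
#: gz signature; SA/SD are slow-cadence with a strong gx (sagittal swing)
#: signature; Sit/Stand are static with distinct but subtly different gravity
#: orientation, so separating them requires a focused decision.
DEFAULT_PROFILES: dict[str, ModeProfile] = {
    "SLW": ModeProfile((9.81, 0.0, 0.3, 0.0, 0.0, 0.0), 1.3, (1.0, 0.4, 1.5, 0.3, 1.35, 0.3), 0.60, jitter=0.5),
    "MLW": ModeProfile((9.81, 0.0, 0.3, 0.0, 0.0, 0.0), 1.9, (1.7, 0.7, 2.6, 0.6, 2.3, 0.6), 0.60, jitter=0.5),
    "FLW": ModeProfile((9.81, 0.0, 0.3, 0.0, 0.0, 0.0), 2.5, (2.7, 1.15, 3.9, 1.0, 3.5, 0.95), 0.60, jitter=0.5),
    "RD": ModeProfile((9.77, 0.0, -0.9, 0.0, 0.0, 0.0), 1.9, (1.55, 0.68, 2.45, 0.55, 2.1, 1.0), 0.60, jitter=0.5),
    "SD": ModeProfile((9.81, 0.0, -0.8, 0.0, 0.0, 0.0), 1.1, (2.6, 0.9, 1.4, 2.1, 1.0, 0.5), 0.60, jitter=0.5),
    "Sit": ModeProfile((9.75, 0.15, 0.6, 0.0, 0.0, 0.0), 0.0, (0.0,) * 6, 0.25, jitter=0.0),
    "Stand": ModeProfile((9.81, 0.0, 0.0, 0.0, 0.0, 0.0), 0.0, (0.0,) * 6, 0.25, jitter=0.0),
    "RA": ModeProfile((9.77, 0.0, 0.9, 0.0, 0.0, 0.0), 1.9, (1.6, 0.7, 2.55, 0.57, 2.2, 1.05), 0.60, jitter=0.5),
    "SA": ModeProfile((9.81, 0.0, 0.8, 0.0, 0.0, 0.0), 1.1, (3.2, 1.05, 1.8, 2.5, 1.3, 0.7), 0.60, jitter=0.5),
}


def simulate_recording(
    mode: str,
    duration_s: float,
    rate_hz: float = 100.0,
    profile: ModeProfile | None = None,
    seed: int = 0,
    subject_id: str = "sim",
) -> IMURecording:
    """Generate one quasi-periodic labeled recording, deterministic per seed."""
    if mode not in MODE_INDEX:
        raise ValueError(f"unknown locomotion mode {mode!r}")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if profile is None:
        profile = DEFAULT_PROFILES[mode]
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    phases = rng.normal(scale=profile.jitter, size=(6, len(_HARMONIC_DECAY)))
    samples = np.empty((n, 6))
    for c in range(6):
        sig = np.full(n, profile.baseline[c])
        for k, decay in enumerate(_HARMONIC_DECAY, start=1):
            sig = sig + decay * profile.amplitudes[c] * np.sin(
                2 * np.pi * k * profile.freq_hz * t + _CHANNEL_PHASE[c] + phases[c, k - 1]
            )
        samples[:, c] = sig
    samples += rng.normal(scale=profile.noise_sd, size=samples.shape)
    return IMURecording(samples, rate_hz=rate_hz, mode=mode, subject_id=subject_id)


def simulate_recordings(
    duration_s: float,
    rate_hz: float = 100.0,
    profiles: dict[str, ModeProfile] | None = None,
    seed: int = 0,
    subject_id: str = "sim",
) -> list[IMURecording]:
    """One recording per mode, with per-mode seeds derived from ``seed``."""
    profiles = profiles or DEFAULT_PROFILES
    return [
        simulate_recording(
            mode, duration_s, rate_hz, profiles[mode], seed=(seed * 1009 + i) % (2**31), subject_id=subject_id
        )
        for i, mode in enumerate(MODES)
    ]


def load_profiles(path: str | Path) -> dict[str, ModeProfile]:
    """Read a YAML mapping mode -> profile fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    profiles = {}
    for mode, spec in raw.items():
        if mode not in MODE_INDEX:
            raise ValueError(f"profile file names unknown mode {mode!r}")
        profiles[mode] = ModeProfile(
            baseline=tuple(spec["baseline"]),
            freq_hz=float(spec["freq_hz"]),
            amplitudes=tuple(spec["amplitudes"]),
            noise_sd=float(spec["noise_sd"]),
            jitter=float(spec.get("jitter", 0.3)),
        )
    return profiles


def save_profiles(profiles: dict[str, ModeProfile], path: str | Path) -> None:
    raw = {
        mode: {
            "baseline": [float(v) for v in p.baseline],
            "freq_hz": float(p.freq_hz),
            "amplitudes": [float(v) for v in p.amplitudes],
            "noise_sd": float(p.noise_sd),
            "jitter": float(p.jitter),
        }
        for mode, p in profiles.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh)


# ---------------------------------------------------------------------------
# Windowing and features


def make_windows(rec: IMURecording, window_ms: int, stride_ms: int | None = None) -> Dataset:
    """Cut a recording into flattened raw windows.

    The raw vector is the channel-major flattening of the (samples, 6) window:
    all ax values first, then ay, and so on. Trailing partial windows are
    dropped. ``stride_ms`` defaults to ``window_ms`` (non-overlapping).
    """
    if stride_ms is None:
        stride_ms = window_ms
    w = window_ms * rec.rate_hz / 1000.0
    s = stride_ms * rec.rate_hz / 1000.0
    if w <= 0 or s <= 0 or abs(w - round(w)) > 1e-9 or abs(s - round(s)) > 1e-9:
        raise ValueError("window_ms and stride_ms must be positive multiples of the sample period")
    w, s = int(round(w)), int(round(s))
    n = len(rec)
    if n < w:
        X = np.empty((0, w * 6))
        return Dataset(X, np.empty(0, dtype=object), window_ms)
    starts = range(0, n - w + 1, s)
    X = np.stack([rec.samples[a : a + w].T.reshape(-1) for a in starts])
    labels = np.array([rec.mode] * len(X), dtype=object)
    return Dataset(X, labels, window_ms)


def windows_from_recordings(
    recs: Sequence[IMURecording], window_ms: int, stride_ms: int | None = None
) -> Dataset:
    parts = [make_windows(r, window_ms, stride_ms) for r in recs]
    parts = [p for p in parts if len(p)]
    if not parts:
        raise ValueError("no recording long enough for the requested window")
    return Dataset(
        np.concatenate([p.X for p in parts]),
        np.concatenate([p.labels for p in parts]),
        window_ms,
    )


def extract_features(ds: Dataset) -> Dataset:
    """Per-channel time-domain summary: (max, min, mean, sd) for each channel.

    The standard deviation uses the population divisor n. Output is 24-dim,
    channel-major blocks of four statistics in ax..gz order.
    """
    n_inst, dim = ds.X.shape
    if dim % 6:
        raise ValueError("raw window length is not a multiple of 6 channels")
    w = dim // 6
    per_channel = ds.X.reshape(n_inst, 6, w)
    feats = np.stack(
        [
            per_channel.max(axis=2),
            per_channel.min(axis=2),
            per_channel.mean(axis=2),
            per_channel.std(axis=2),  # ddof=0: population sd
        ],
        axis=2,
    ).reshape(n_inst, 24)
    return replace(ds, X=feats)


# ---------------------------------------------------------------------------
# Normalization and splitting


@dataclass
class MinMaxNormalizer:
    """Per-dimension min-max scaling to [0, 1], fitted on the training split.

    Held-out values are clipped into [0, 1]; degenerate dimensions (hi == lo)
    map to 0.5, the sigmoid midpoint.
    """

    lo: np.ndarray
    hi: np.ndarray

    def transform(self, ds: Dataset) -> Dataset:
        if ds.dim != self.lo.shape[0]:
            raise ValueError(f"normalizer fitted on dim {self.lo.shape[0]}, dataset has dim {ds.dim}")
        span = self.hi - self.lo
        out = np.where(span > 0, np.clip((ds.X - self.lo) / np.where(span > 0, span, 1.0), 0.0, 1.0), 0.5)
        return replace(ds, X=out)

    def to_dict(self) -> dict:
        return {"lo": self.lo.tolist(), "hi": self.hi.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxNormalizer":
        return cls(np.asarray(d["lo"], dtype=float), np.asarray(d["hi"], dtype=float))


def fit_normalizer(train: Dataset) -> MinMaxNormalizer:
    if len(train) == 0:
        raise ValueError("cannot fit a normalizer on an empty dataset")
    return MinMaxNormalizer(train.X.min(axis=0), train.X.max(axis=0))


def apply_normalizer(ds: Dataset, normalizer: MinMaxNormalizer) -> Dataset:
    return normalizer.transform(ds)


def split_dataset(ds: Dataset, ratio: float = 0.8, seed: int = 0) -> tuple[Dataset, Dataset]:
    """Shuffle and partition into train/test at ``ratio`` (8:2 by default)."""
    n = len(ds)
    if n < 5:
        raise ValueError("need at least 5 instances to split")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(round(n * ratio))
    tr, te = perm[:n_train], perm[n_train:]
    train = Dataset(ds.X[tr], ds.labels[tr], ds.window_ms, split_tag="train")
    test = Dataset(ds.X[te], ds.labels[te], ds.window_ms, split_tag="test")
    if ds.y is not None:
        train = replace(train, y=ds.y[tr], n_classes=ds.n_classes)
        test = replace(test, y=ds.y[te], n_classes=ds.n_classes)
    return train, test
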