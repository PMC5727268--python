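"""Evoked-EMG signal handling: reading two-channel recordings, stimulus
trigger detection, epoch segmentation, grand averaging, and peak-to-peak
CMAP amplitude extraction.

A recording holds a continuous EMG channel (microvolts) synchronized with a
stimulus trigger channel at a common sampling rate (2 kHz in the reference
setup).  Each trigger marks a stimulus; the CMAP follows at a short latency.
Epochs are cut from -pre_ms to +post_ms around each trigger, averaged across
repeated trains per intensity, and summarized by the peak-to-peak voltage
(Vpp) inside a 1-15 ms post-stimulus feature window.

Conventions: sample indexing is 0-based; epoch windows are half-open
[-pre, post) in milliseconds; millisecond-to-sample mapping uses floor.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .protocol import StimulusSchedule

logger = logging.getLogger("cmaplin")

__all__ = [
    "Recording",
    "EpochWindow",
    "Epoch",
    "read_recording",
    "detect_triggers",
    "segment_epochs",
    "grand_average",
    "extract_vpp",
    "process_recording",
]

#: Default amplifier gain of the acquisition chain (dimensionless).
DEFAULT_GAIN = 1000.0


@dataclass
class Recording:
    """Synchronized EMG + trigger channels at a common sampling rate.

    ``emg`` is in microvolts at the electrode; ``trigger`` is in arbitrary
    units (any channel with clear rectangular pulses works).  ``meta`` is a
    free-form annotation dict (subject id, condition label, amplifier gain,
    ground-truth fields for synthetic data, ...).
    """

    emg: np.ndarray
    trigger: np.ndarray
    fs: float = 2000.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.emg = np.asarray(self.emg, dtype=float)
        self.trigger = np.asarray(self.trigger, dtype=float)
        if self.emg.ndim != 1 or self.trigger.ndim != 1:
            raise ValueError("channels must be 1-D sample arrays")
        if len(self.emg) != len(self.trigger):
            raise ValueError(
                f"channel lengths differ: emg {len(self.emg)} vs "
                f"trigger {len(self.trigger)}"
            )
        if len(self.emg) < 1:
            raise ValueError("recording is empty")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        for name, ch in (("emg", self.emg), ("trigger", self.trigger)):
            bad = np.flatnonzero(~np.isfinite(ch))
            if bad.size:
                raise ValueError(
                    f"non-finite sample in {name} channel at index {bad[0]}"
                )

    def __len__(self) -> int:
        return len(self.emg)

    @property
    def duration_s(self) -> float:
        return len(self.emg) / self.fs


@dataclass(frozen=True)
class EpochWindow:
    """Epoch extent and Vpp feature window, relative to the trigger (ms)."""

    pre_ms: float = 5.0
    post_ms: float = 20.0
    feature_start_ms: float = 1.0
    feature_end_ms: float = 15.0

    def __post_init__(self):
        if self.pre_ms < 0:
            raise ValueError("pre_ms must be >= 0")
        if not (self.post_ms > self.feature_end_ms > self.feature_start_ms >= 0):
            raise ValueError(
                "require post_ms > feature_end_ms > feature_start_ms >= 0"
            )

    def n_pre(self, fs: float) -> int:
        return int(np.floor(self.pre_ms * fs / 1000.0))

    def n_samples(self, fs: float) -> int:
        return int(round((self.pre_ms + self.post_ms) * fs / 1000.0))


@dataclass
class Epoch:
    """One trigger-aligned CMAP segment.

    Sample index ``floor(pre_ms * fs / 1000)`` corresponds to trigger time 0.
    ``intensity_index`` runs 1..5 over the ascending intensity ladder,
    ``train_index`` 1..n_trains (0 for a grand average), ``condition_index``
    0..3 over nerve conditions (0 = initial/healthy baseline).
    """

    samples: np.ndarray
    fs: float
    intensity_index: int
    train_index: int
    condition_index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)


def _read_csv_recording(path, fs=None, gain=1.0):
    df = pd.read_csv(path)
    expected = ["time_s", "emg_uV", "trigger"]
    if list(df.columns[:3]) != expected:
        raise ValueError(
            f"CSV header must start with {','.join(expected)}; got "
            f"{','.join(map(str, df.columns[:3]))}"
        )
    for col in ("emg_uV", "trigger"):
        vals = df[col].to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            raise ValueError(
                f"non-finite value in column {col} at data row {bad[0]}"
            )
    if fs is None:
        t = df["time_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError("cannot infer fs from fewer than 2 samples; pass fs")
        dt = np.diff(t)
        if dt.min() <= 0 or (dt.max() - dt.min()) / dt.mean() > 1e-6:
            raise ValueError("time column is not uniform within 1 ppm; pass fs")
        fs = 1.0 / dt.mean()
    emg = df["emg_uV"].to_numpy(dtype=float) / gain
    return Recording(emg=emg, trigger=df["trigger"].to_numpy(dtype=float), fs=float(fs))


def _read_edf_recording(path, emg_channel="EMG", trig_channel="TRIG", gain=1.0):
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = {name.strip().lower(): name for name in raw.ch_names}

    def pick(wanted):
        key = wanted.strip().lower()
        if key not in labels:
            raise ValueError(
                f"channel {wanted!r} not found in EDF; available: {raw.ch_names}"
            )
        return labels[key]

    if len(raw.ch_names) != 2 and (emg_channel == "EMG" and trig_channel == "TRIG"):
        # >2 channels require an explicit mapping only if defaults don't match
        if "emg" not in labels or "trig" not in labels:
            raise ValueError(
                f"EDF has {len(raw.ch_names)} channels; name the EMG and "
                f"trigger channels explicitly (found {raw.ch_names})"
            )
    data = raw.get_data(picks=[pick(emg_channel), pick(trig_channel)], units="uV")
    rec = Recording(
        emg=data[0] / gain,
        trigger=data[1],
        fs=float(raw.info["sfreq"]),
        meta={"edf_channels": list(raw.ch_names)},
    )
    return rec


def read_recording(
    path,
    format: str | None = None,
    fs: float | None = None,
    emg_channel: str = "EMG",
    trig_channel: str = "TRIG",
    gain: float = 1.0,
) -> Recording:
    """Read a two-channel recording from CSV or EDF.

    CSV dialect: header ``time_s,emg_uV,trigger``, one row per sample; the
    sampling rate is inferred from the time column (uniform within 1 ppm)
    unless ``fs`` is given.  EDF channels are matched case-insensitively on
    ``emg_channel`` / ``trig_channel``.  If the file stores post-amplifier
    voltages, pass the amplifier ``gain`` to recover electrode microvolts.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.lower().endswith(".edf") else "csv"
    if format == "csv":
        rec = _read_csv_recording(path, fs=fs, gain=gain)
    elif format == "edf":
        rec = _read_edf_recording(path, emg_channel, trig_channel, gain=gain)
    else:
        raise ValueError(f"unknown format {format!r} (expected csv or edf)")
    rec.meta.setdefault("source", path)
    if gain != 1.0:
        rec.meta["gain"] = gain
    return rec


def detect_triggers(
    rec: Recording,
    threshold_fraction: float = 0.5,
    refractory_ms: float = 200.0,
    min_width: int = 2,
) -> np.ndarray:
    """Rising-edge stimulus onsets on the trigger channel.

    The threshold is ``min + threshold_fraction * (max - min)``; crossings
    within ``refractory_ms`` of an accepted onset are suppressed, which
    absorbs contact chatter on slow pulse edges (the refractory period is
    far below the ~1 s interstimulus interval and far above the 500 us
    pulse width).  A crossing counts only if the level stays above threshold
    for ``min_width`` consecutive samples, which rejects single-sample noise
    spikes while keeping 1 ms rectangular pulses (2 samples at 2 kHz).
    """
    trig = rec.trigger
    lo, hi = float(trig.min()), float(trig.max())
    if hi <= lo:
        raise ValueError("no trigger dynamics: trigger channel is flat")
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    thr = lo + threshold_fraction * (hi - lo)
    above = trig >= thr
    onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        onsets = np.concatenate([[0], onsets])
    if min_width > 1:
        onsets = np.array(
            [
                i
                for i in onsets
                if i + min_width <= len(above) and above[i : i + min_width].all()
            ],
            dtype=int,
        )
    refractory = int(round(refractory_ms * rec.fs / 1000.0))
    kept: List[int] = []
    last = -np.inf
    for idx in onsets:
        if idx - last >= refractory:
            kept.append(int(idx))
            last = idx
    return np.asarray(kept, dtype=int)


def segment_epochs(
    rec: Recording,
    triggers: Sequence[int],
    window: EpochWindow | None = None,
    schedule: StimulusSchedule | None = None,
    condition_index: int = 0,
) -> List[Epoch]:
    """Cut one epoch per trigger and assign intensity/train indices.

    Triggers are grouped positionally into trains of ``n_levels`` ascending
    intensities (the protocol stimulates P1..P5 in order within each train),
    so epoch ``i`` gets ``intensity_index = i % n_levels + 1`` and
    ``train_index = i // n_levels + 1``.  Epochs whose window would cross a
    recording edge are dropped with a warning, never padded.
    """
    window = window or EpochWindow()
    n_levels = schedule.n_levels if schedule is not None else 5
    triggers = np.asarray(triggers, dtype=int)
    if len(triggers) == 0:
        raise ValueError("no triggers to segment")
    if len(triggers) % n_levels != 0:
        raise ValueError(
            f"trigger count is not a multiple of {n_levels}: expected a "
            f"multiple of {n_levels}, found {len(triggers)}"
        )
    n_pre = window.n_pre(rec.fs)
    n_samp = window.n_samples(rec.fs)
    # inter-train gaps should dwarf the within-train ISI; log a sanity check
    if schedule is not None and len(triggers) > n_levels:
        gaps = np.diff(triggers) / rec.fs
        train_gaps = gaps[n_levels - 1 :: n_levels]
        if train_gaps.size and train_gaps.min() < schedule.isi_s:
            logger.warning(
                "inter-train gap (%.3f s) below the within-train ISI (%.3f s); "
                "positional train grouping may be wrong",
                train_gaps.min(),
                schedule.isi_s,
            )
    epochs: List[Epoch] = []
    for i, trig in enumerate(triggers):
        start = trig - n_pre
        stop = start + n_samp
        if start < 0 or stop > len(rec):
            logger.warning(
                "epoch %d (trigger at sample %d) crosses the recording edge; dropped",
                i,
                trig,
            )
            continue
        epochs.append(
            Epoch(
                samples=rec.emg[start:stop].copy(),
                fs=rec.fs,
                intensity_index=i % n_levels + 1,
                train_index=i // n_levels + 1,
                condition_index=condition_index,
            )
        )
    return epochs


def grand_average(epochs: Sequence[Epoch], n_levels: int = 5) -> Dict[int, Epoch]:
    """Pointwise mean waveform across trains, per stimulus intensity.

    Averaging the waveforms before Vpp extraction (not averaging per-train
    Vpp values) is a deliberate pipeline order: max - min is nonlinear, so
    the two do not commute, and waveform averaging is what suppresses
    uncorrelated noise before the peak search.
    """
    if not epochs:
        raise ValueError("no epochs to average")
    fs = epochs[0].fs
    n = len(epochs[0].samples)
    cond = epochs[0].condition_index
    for ep in epochs:
        if ep.fs != fs or len(ep.samples) != n or ep.condition_index != cond:
            raise ValueError("epochs differ in fs, length or condition")
    out: Dict[int, Epoch] = {}
    for k in range(1, n_levels + 1):
        group = [ep for ep in epochs if ep.intensity_index == k]
        if not group:
            raise ValueError(f"no epochs for intensity index {k}")
        mean = np.mean([ep.samples for ep in group], axis=0)
        out[k] = Epoch(
            samples=mean,
            fs=fs,
            intensity_index=k,
            train_index=0,
            condition_index=cond,
            meta={"n_averaged": len(group)},
        )
    return out


def extract_vpp(epoch: Epoch, window: EpochWindow | None = None) -> float:
    """Peak-to-peak voltage (uV) of the CMAP inside the feature window.

    The pre-stimulus mean (-pre_ms..0) is subtracted first, making the
    feature invariant to DC offset and slow drift; the result is
    max - min over trigger-relative times [feature_start_ms, feature_end_ms).
    """
    window = window or EpochWindow()
    n_pre = window.n_pre(epoch.fs)
    i0 = n_pre + int(np.floor(window.feature_start_ms * epoch.fs / 1000.0))
    i1 = n_pre + int(np.floor(window.feature_end_ms * epoch.fs / 1000.0))
    if i1 > len(epoch.samples):
        raise ValueError("feature window extends past the end of the epoch")
    if i0 >= i1:
        raise ValueError("empty feature window")
    baseline = epoch.samples[:n_pre].mean() if n_pre > 0 else 0.0
    seg = epoch.samples[i0:i1] - baseline
    return float(seg.max() - seg.min())


def process_recording(
    rec: Recording,
    window: EpochWindow | None = None,
    schedule: StimulusSchedule | None = None,
    condition_index: int = 0,
    threshold_fraction: float = 0.5,
    refractory_ms: float = 200.0,
) -> np.ndarray:
    """Full single-recording pipeline: triggers -> epochs -> average -> Vpp.

    Returns the grand-averaged peak-to-peak amplitude (uV) per intensity,
    as a vector of length ``n_levels`` in ascending-intensity order.
    """
    window = window or EpochWindow()
    n_levels = schedule.n_levels if schedule is not None else 5
    triggers = detect_triggers(rec, threshold_fraction, refractory_ms)
    epochs = segment_epochs(rec, triggers, window, schedule, condition_index)
    averaged = grand_average(epochs, n_levels=n_levels)
    return np.array([extract_vpp(averaged[k], window) for k in range(1, n_levels + 1)])
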