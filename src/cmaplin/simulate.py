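"""Synthetic nerve cohort generator with known ground truth.

The generator models a nerve as a population of motor axons.  Each axon has
a recruitment threshold (lognormal over stimulus intensity, in units of the
motor threshold MT) and a unit contribution to the compound peak-to-peak
amplitude (lognormal, microvolts).  At stimulus intensity P the noiseless
CMAP amplitude is the summed contribution of all conducting axons whose
threshold is <= P, which yields the familiar sigmoidal recruitment curve;
the experimental ladder 100-140 %MT samples its rising segment.

Injury is modeled as graded conduction block.  By default the block is
applied in *descending threshold order* (the axons recruited last are lost
first), which caps the recruitment curve at a damage-dependent ceiling and
flattens the suprathreshold segment - the signature that both normalization
modes, including the scale-invariant per-trial mode, can detect.  Blocking a
random subset instead (``block_order="random"``) rescales the curve almost
uniformly, a deliberate trap configuration: the per-trial normalization is
invariant under uniform rescaling and is then blind to the injury.  A
multiplicative threshold elevation for surviving axons is also available;
note that on its own it *steepens* the self-normalized curve (it pushes the
recruitment sigmoid's low tail into the test window), so it is not the
default injury mechanism.

All randomness flows from explicit integer seeds; the same seed reproduces
the same axon population, block assignment and noise.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import List, Tuple

import numpy as np

from .io_signal import Recording
from .nerve_model import CmapMatrix
from .protocol import StimulusSchedule

__all__ = [
    "AxonPopulation",
    "InjuryModel",
    "SimConfig",
    "simulate_amplitudes",
    "recruitment_amplitudes",
    "simulate_recording",
    "cohort_populations",
    "generate_cohort",
    "write_recording",
]

_NOISE_STREAM = 7919  # sub-seed tag separating noise from axon sampling


@dataclass(frozen=True)
class AxonPopulation:
    """Motor-axon population of one nerve.

    Thresholds are in MT units (median 1.0 means the median axon recruits
    exactly at motor threshold); unit amplitudes are the per-axon
    contribution to the compound Vpp in microvolts.  Explicit ``thresholds``
    / ``amps`` arrays override the lognormal draws (useful for closed-form
    test cases).
    """

    n_axons: int = 200
    threshold_median: float = 1.0
    threshold_sigma: float = 0.25
    amp_median_uv: float = 3.0
    amp_sigma: float = 0.5
    thresholds: tuple | None = None
    amps: tuple | None = None

    def __post_init__(self):
        if self.n_axons < 1:
            raise ValueError("n_axons must be >= 1")
        for name in ("threshold_median", "threshold_sigma", "amp_median_uv", "amp_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def sample(self, rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
        """Draw (thresholds, unit amplitudes); explicit arrays pass through."""
        if self.thresholds is not None:
            thr = np.asarray(self.thresholds, dtype=float)
            if self.amps is not None:
                amp = np.asarray(self.amps, dtype=float)
            else:
                amp = np.full(len(thr), self.amp_median_uv)
            if len(thr) != len(amp):
                raise ValueError("thresholds and amps must have equal length")
            return thr, amp
        thr = self.threshold_median * np.exp(
            rng.normal(0.0, self.threshold_sigma, self.n_axons)
        )
        amp = self.amp_median_uv * np.exp(rng.normal(0.0, self.amp_sigma, self.n_axons))
        return thr, amp


@dataclass(frozen=True)
class InjuryModel:
    """Graded conduction block across damage levels 0..3.

    ``block_fraction[L]`` axons stop conducting at level ``L``; blocks are
    nested (an axon blocked at one level stays blocked at higher levels).
    ``block_order`` picks which axons are lost first: ``"descending_threshold"``
    (default; flattens the recruitment curve) or ``"random"`` (near-uniform
    rescaling; the per-trial-normalization blind spot).  ``threshold_shift``
    multiplies surviving axons' thresholds per level.
    """

    block_fraction: tuple = (0.0, 0.15, 0.45, 0.75)
    threshold_shift: tuple = (1.0, 1.0, 1.0, 1.0)
    block_order: str = "descending_threshold"

    def __post_init__(self):
        bf = tuple(float(v) for v in self.block_fraction)
        ts = tuple(float(v) for v in self.threshold_shift)
        object.__setattr__(self, "block_fraction", bf)
        object.__setattr__(self, "threshold_shift", ts)
        if len(bf) != len(ts):
            raise ValueError("block_fraction and threshold_shift lengths differ")
        if any(not 0 <= v < 1 for v in bf):
            raise ValueError("block fractions must lie in [0, 1)")
        if any(b < a for a, b in zip(bf, bf[1:])):
            raise ValueError("block fractions must be non-decreasing")
        if any(v < 1 for v in ts):
            raise ValueError("threshold shifts must be >= 1")
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("threshold shifts must be non-decreasing")
        if self.block_order not in ("descending_threshold", "random"):
            raise ValueError(f"unknown block_order {self.block_order!r}")

    @property
    def n_levels(self) -> int:
        return len(self.block_fraction)


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings.

    ``noise_sd`` is the amplitude-noise SD in microvolts: applied directly
    to Vpp values in :func:`simulate_amplitudes` (representing residual
    post-averaging measurement noise) and as white sample noise in
    :func:`simulate_recording`.  The biphasic CMAP template starts
    ``latency_ms`` after the trigger with a positive lobe of ``pos_ms`` and
    a negative lobe of ``neg_ms``; ``pos_fraction`` splits the peak-to-peak
    amplitude between the lobes.
    """

    seed: int = 0
    noise_sd: float = 15.0
    fs: float = 2000.0
    latency_ms: float = 3.0
    pos_ms: float = 2.0
    neg_ms: float = 3.0
    pos_fraction: float = 0.6
    n_subjects: int = 16
    trigger_height: float = 5.0
    trigger_width_ms: float = 1.0
    lead_in_s: float = 0.5

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 0 < self.pos_fraction < 1:
            raise ValueError("pos_fraction must lie in (0, 1)")
        if self.latency_ms + self.pos_ms + self.neg_ms >= 20.0:
            raise ValueError("CMAP template must end before the 20 ms epoch edge")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def _axons_and_block(pop, injury, seed):
    """Sample one nerve's axons plus its nested block order (seed-stable)."""
    rng = np.random.default_rng(seed)
    thr, amp = pop.sample(rng)
    n = len(thr)
    if injury.block_order == "descending_threshold":
        order = np.argsort(-thr, kind="stable")
    else:
        order = rng.permutation(n)
    return thr, amp, order


def _conducting_mask(n, order, fraction):
    blocked = order[: int(round(fraction * n))]
    mask = np.ones(n, dtype=bool)
    mask[blocked] = False
    return mask


def recruitment_amplitudes(
    pop: AxonPopulation,
    injury: InjuryModel,
    level: int,
    schedule: StimulusSchedule,
    seed: int,
) -> np.ndarray:
    """Noiseless recruitment row: summed unit amplitudes per intensity (uV)."""
    if not 0 <= level < injury.n_levels:
        raise ValueError(f"damage level must lie in 0..{injury.n_levels - 1}")
    thr, amp, order = _axons_and_block(pop, injury, seed)
    mask = _conducting_mask(len(thr), order, injury.block_fraction[level])
    shifted = thr * injury.threshold_shift[level]
    intensities_mt = np.asarray(schedule.levels_pct_mt, dtype=float) / 100.0
    return np.array(
        [amp[mask & (shifted <= p)].sum() for p in intensities_mt]
    )


def simulate_amplitudes(
    pop: AxonPopulation,
    injury: InjuryModel,
    level: int,
    schedule: StimulusSchedule,
    seed: int,
    noise_sd: float = 15.0,
) -> np.ndarray:
    """Measured Vpp row for one nerve condition (uV, length n_levels).

    The noiseless recruitment sum plus Gaussian amplitude noise, truncated
    at zero (a peak-to-peak measurement cannot be negative).  The axon draw
    and block assignment depend only on ``seed`` and are shared across
    levels, so conditions of one nerve are paired; the noise stream is
    level-specific.
    """
    true_vpp = recruitment_amplitudes(pop, injury, level, schedule, seed)
    noise_rng = np.random.default_rng([seed, level, _NOISE_STREAM])
    noisy = true_vpp + noise_rng.normal(0.0, noise_sd, len(true_vpp))
    return np.maximum(noisy, 0.0)


def _biphasic_template(cfg: SimConfig) -> np.ndarray:
    """Unit-Vpp biphasic waveform: positive then negative half-sine lobes."""
    n_pos = max(int(round(cfg.pos_ms * cfg.fs / 1000.0)), 2)
    n_neg = max(int(round(cfg.neg_ms * cfg.fs / 1000.0)), 2)
    pos = np.sin(np.linspace(0.0, np.pi, n_pos)) * cfg.pos_fraction
    neg = -np.sin(np.linspace(0.0, np.pi, n_neg)) * (1.0 - cfg.pos_fraction)
    tpl = np.concatenate([pos, neg])
    # renormalize: the sampled lobe maxima fall short of the continuous ones
    return tpl / (tpl.max() - tpl.min())


def simulate_recording(
    pop: AxonPopulation,
    injury: InjuryModel,
    level: int,
    schedule: StimulusSchedule,
    cfg: SimConfig,
) -> Recording:
    """Continuous two-channel recording for one nerve condition.

    ``n_trains`` trains of ascending-intensity biphasic CMAPs, each scaled
    to the nerve's noiseless recruitment amplitude, with rectangular trigger
    pulses at the programmed stimulus times and white sample noise on the
    EMG channel.  Ground truth (trigger indices and the programmed Vpp per
    epoch) is stored in ``meta``.
    """
    fs = cfg.fs
    true_vpp = recruitment_amplitudes(pop, injury, level, schedule, cfg.seed)
    n_levels = schedule.n_levels
    train_span = (n_levels - 1) * schedule.isi_s
    train_starts = [
        cfg.lead_in_s + t * (train_span + schedule.inter_train_s)
        for t in range(schedule.n_trains)
    ]
    duration = train_starts[-1] + train_span + cfg.lead_in_s
    n = int(round(duration * fs))
    emg = np.zeros(n)
    trig = np.zeros(n)
    template = _biphasic_template(cfg)
    lat = int(round(cfg.latency_ms * fs / 1000.0))
    trig_w = max(int(round(cfg.trigger_width_ms * fs / 1000.0)), 1)

    trigger_indices = []
    programmed = []
    for start in train_starts:
        for j in range(n_levels):
            idx = int(round((start + j * schedule.isi_s) * fs))
            trigger_indices.append(idx)
            programmed.append(true_vpp[j])
            trig[idx : idx + trig_w] = cfg.trigger_height
            seg = slice(idx + lat, idx + lat + len(template))
            emg[seg] += template * true_vpp[j]
    if cfg.noise_sd > 0:
        noise_rng = np.random.default_rng([cfg.seed, level, _NOISE_STREAM, 1])
        emg += noise_rng.normal(0.0, cfg.noise_sd, n)
    return Recording(
        emg=emg,
        trigger=trig,
        fs=fs,
        meta={
            "trigger_indices": trigger_indices,
            "programmed_vpp": programmed,
            "true_vpp_row": true_vpp.tolist(),
            "damage_level": level,
            "seed": cfg.seed,
        },
    )


def cohort_populations(
    cfg: SimConfig,
    schedule: StimulusSchedule | None = None,
    base_pop: AxonPopulation | None = None,
):
    """Per-subject (subject_id, population, schedule, seed) draws.

    Hyperparameters are jittered around the base population with lognormal
    multipliers to emulate inter-subject variability; the motor threshold
    varies per subject but cancels out of the %MT stimulus ladder.
    Deterministic for a fixed ``cfg.seed``.
    """
    schedule = schedule or StimulusSchedule(mt=0.3)
    base_pop = base_pop or AxonPopulation()
    master = np.random.default_rng(cfg.seed)
    out = []
    for s in range(cfg.n_subjects):
        sub_seed = int(master.integers(2**31))
        jitter = np.random.default_rng([cfg.seed, s, 104729])
        pop = replace(
            base_pop,
            threshold_median=base_pop.threshold_median * float(np.exp(jitter.normal(0, 0.05))),
            threshold_sigma=base_pop.threshold_sigma * float(np.exp(jitter.normal(0, 0.10))),
            amp_median_uv=base_pop.amp_median_uv * float(np.exp(jitter.normal(0, 0.20))),
        )
        mt = schedule.mt * float(np.exp(jitter.normal(0, 0.2)))
        out.append((f"S{s + 1:02d}", pop, replace(schedule, mt=mt), sub_seed))
    return out


def generate_cohort(
    cfg: SimConfig,
    schedule: StimulusSchedule | None = None,
    injury: InjuryModel | None = None,
    base_pop: AxonPopulation | None = None,
) -> List[CmapMatrix]:
    """Simulate a cohort of nerves, each measured at every damage level.

    Ground truth (injury model, subject hyperparameters) rides along in
    ``meta``.  Deterministic for a fixed ``cfg.seed``.
    """
    injury = injury or InjuryModel()
    matrices: List[CmapMatrix] = []
    for subject_id, pop, sched, sub_seed in cohort_populations(cfg, schedule, base_pop):
        vpp = np.vstack(
            [
                simulate_amplitudes(pop, injury, lvl, sched, sub_seed, cfg.noise_sd)
                for lvl in range(injury.n_levels)
            ]
        )
        matrices.append(
            CmapMatrix(
                vpp=vpp,
                schedule=sched,
                subject_id=subject_id,
                meta={
                    "seed": sub_seed,
                    "injury": {
                        "block_fraction": injury.block_fraction,
                        "threshold_shift": injury.threshold_shift,
                        "block_order": injury.block_order,
                    },
                    "population": {
                        "n_axons": pop.n_axons,
                        "threshold_median": pop.threshold_median,
                        "threshold_sigma": pop.threshold_sigma,
                        "amp_median_uv": pop.amp_median_uv,
                    },
                },
            )
        )
    return matrices


# --------------------------------------------------------------------------
# recording output: CSV (exact) and a minimal EDF writer (16-bit quantized)
# --------------------------------------------------------------------------

def _edf_pad(s, width):
    s = str(s)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(path, signals, labels, fs, phys_dims):
    """Write an EDF file with 1-second data records and int16 samples.

    The last record is padded by repeating the final sample; physical
    min/max per channel are set to the data range, so amplitude resolution
    is range/65535.  Compatible with standard EDF readers (verified against
    mne's).
    """
    n_sig = len(signals)
    n = len(signals[0])
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = int(np.ceil(n / spr))

    pmins, pmaxs = [], []
    for sig in signals:
        pmin, pmax = float(np.min(sig)), float(np.max(sig))
        if pmax == pmin:
            pmax = pmin + 1.0
        pmins.append(pmin)
        pmaxs.append(pmax)

    def fields(vals, width):
        return b"".join(_edf_pad(v, width) for v in vals)

    header = b"".join(
        [
            _edf_pad("0", 8),
            _edf_pad("X X X X", 80),
            _edf_pad("Startdate 01-JAN-2000 X X X", 80),
            _edf_pad("01.01.00", 8),
            _edf_pad("00.00.00", 8),
            _edf_pad(256 * (1 + n_sig), 8),
            _edf_pad("", 44),
            _edf_pad(n_rec, 8),
            _edf_pad(1, 8),
            _edf_pad(n_sig, 4),
            fields(labels, 16),
            fields([""] * n_sig, 80),
            fields(phys_dims, 8),
            fields([f"{v:.6g}" for v in pmins], 8),
            fields([f"{v:.6g}" for v in pmaxs], 8),
            fields([-32768] * n_sig, 8),
            fields([32767] * n_sig, 8),
            fields([""] * n_sig, 80),
            fields([spr] * n_sig, 8),
            fields([""] * n_sig, 32),
        ]
    )
    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_rec):
            for sig, pmin, pmax in zip(signals, pmins, pmaxs):
                chunk = np.asarray(sig[r * spr : (r + 1) * spr], dtype=float)
                if len(chunk) < spr:
                    fill = chunk[-1] if len(chunk) else pmin
                    chunk = np.concatenate([chunk, np.full(spr - len(chunk), fill)])
                dig = np.round(
                    (chunk - pmin) / (pmax - pmin) * 65535.0 - 32768.0
                ).astype("<i2")
                f.write(dig.tobytes())


def write_recording(rec: Recording, path, format: str = "csv") -> None:
    """Write a recording as CSV (lossless) or EDF (16-bit quantized).

    CSV uses the ``time_s,emg_uV,trigger`` dialect read back by
    :func:`cmaplin.io_signal.read_recording`.  A JSON-serializable subset of
    ``rec.meta`` is written alongside as ``<path>.meta.json``.
    """
    import pandas as pd

    path = str(path)
    if format == "csv":
        t = np.arange(len(rec)) / rec.fs
        pd.DataFrame(
            {"time_s": t, "emg_uV": rec.emg, "trigger": rec.trigger}
        ).to_csv(path, index=False)
    elif format == "edf":
        _write_edf(path, [rec.emg, rec.trigger], ["EMG", "TRIG"], rec.fs, ["uV", "uV"])
    else:
        raise ValueError(f"unknown format {format!r} (expected csv or edf)")
    if rec.meta:
        serializable = {}
        for k, v in rec.meta.items():
            try:
                json.dumps(v)
            except TypeError:
                continue
            serializable[k] = v
        with open(path + ".meta.json", "w") as fh:
            json.dump(serializable, fh, indent=1)
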