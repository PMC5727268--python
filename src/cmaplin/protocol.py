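"""Experimental protocol: stimulus schedules, graded damage levels, load-cell
calibration, motor-threshold search and incision quantification.

The stimulation protocol delivers trains of five ascending intensities anchored
at the motor threshold (MT): P1 = 100 %MT up to P5 = 140 %MT, 500 µs pulses,
~1 s between pulses and ~5 s between trains.  Nerve injury is graded either by
compression force (grams, read from a load cell) or by incision extent
(percent of nerve tissue removed, measured from binarized images).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "StimulusSchedule",
    "DamageSchedule",
    "LoadCellCalibration",
    "loadcell_to_force",
    "make_damage_schedule",
    "find_motor_threshold",
    "quantify_incision",
]

#: Default graded-damage fractions of the maximum tolerated injury level.
DEFAULT_DAMAGE_FRACTIONS = (1.0 / 3.0, 2.0 / 3.0, 1.0)

#: Variant with the middle level at half maximum (selectable alternative).
HALF_MAX_DAMAGE_FRACTIONS = (1.0 / 3.0, 1.0 / 2.0, 1.0)


@dataclass(frozen=True)
class StimulusSchedule:
    """Train of graded stimulus intensities expressed as percent of MT.

    Parameters
    ----------
    mt : float
        Motor threshold in mA; the 100 % anchor of the intensity ladder.
    levels_pct_mt : tuple of float
        Intensities as %MT, strictly increasing, first element 100.
    pulse_width_us : float
        Stimulus pulse width in microseconds.
    isi_s : float
        Interstimulus interval within a train, seconds.
    inter_train_s : float
        Gap between successive trains, seconds.
    n_trains : int
        Number of repeated trains averaged per nerve condition.
    """

    mt: float = 1.0
    levels_pct_mt: tuple = (100.0, 110.0, 120.0, 130.0, 140.0)
    pulse_width_us: float = 500.0
    isi_s: float = 1.0
    inter_train_s: float = 5.0
    n_trains: int = 4

    def __post_init__(self):
        levels = tuple(float(v) for v in self.levels_pct_mt)
        object.__setattr__(self, "levels_pct_mt", levels)
        if self.mt <= 0:
            raise ValueError("motor threshold must be positive")
        if self.n_trains < 1:
            raise ValueError("n_trains must be >= 1")
        if len(levels) < 2:
            raise ValueError("need at least two stimulus levels")
        if levels[0] != 100.0:
            raise ValueError("first stimulus level must be 100 %MT")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("stimulus levels must be strictly increasing")

    @property
    def n_levels(self) -> int:
        return len(self.levels_pct_mt)

    @property
    def intensities_ma(self) -> np.ndarray:
        """Absolute intensities in mA (MT scaled by the percent ladder)."""
        return self.mt * np.asarray(self.levels_pct_mt) / 100.0


@dataclass(frozen=True)
class DamageSchedule:
    """Graded injury levels as fractions of the maximum tolerated level.

    ``modality`` is ``"compression"`` (levels in grams) or ``"incision"``
    (levels in percent tissue removed).  The maximum level is the one at
    which the CMAP response at 140 %MT disappears.
    """

    modality: str
    max_level: float
    fractions: tuple = DEFAULT_DAMAGE_FRACTIONS

    def __post_init__(self):
        if self.modality not in ("compression", "incision"):
            raise ValueError(f"unknown damage modality: {self.modality!r}")
        if self.max_level <= 0:
            raise ValueError("max_level must be positive")
        fr = tuple(float(f) for f in self.fractions)
        object.__setattr__(self, "fractions", fr)
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("fractions must be strictly increasing")
        if not all(0 < f <= 1 for f in fr):
            raise ValueError("fractions must lie in (0, 1]")
        if fr[-1] != 1.0:
            raise ValueError("last fraction must be 1 (the maximum level)")

    @property
    def levels(self) -> list:
        return make_damage_schedule(self.max_level, self.modality, self.fractions)


@dataclass(frozen=True)
class LoadCellCalibration:
    """Affine map from the load cell's digital reading to force in grams."""

    slope: float = 0.6556  # grams per digital count
    intercept: float = 2.7617  # grams

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")


def loadcell_to_force(x: float, cal: LoadCellCalibration | None = None) -> float:
    """Convert a load-cell digital reading to compression force in grams.

    The compression tool was calibrated against a reference scale; force is
    linear in the digitized load-cell output: ``force = slope * x + intercept``.
    """
    if cal is None:
        cal = LoadCellCalibration()
    x = float(x)
    if not np.isfinite(x):
        raise ValueError("digital reading must be finite")
    return cal.slope * x + cal.intercept


def make_damage_schedule(
    max_level: float,
    modality: str,
    fractions: Sequence[float] = DEFAULT_DAMAGE_FRACTIONS,
) -> list:
    """Split the maximum tolerated injury into graded levels.

    Compression levels are rounded to the nearest gram, incision levels to
    the nearest percent.  With the default fractions a 90 g maximum yields
    the 30/60/90 g ladder.
    """
    sched = DamageSchedule(modality=modality, max_level=max_level, fractions=tuple(fractions))
    raw = [f * sched.max_level for f in sched.fractions]
    return [float(int(np.rint(v))) for v in raw]


def find_motor_threshold(
    vpp_by_intensity: Mapping[float, float],
    noise_sd: float,
    k: float = 3.0,
) -> float:
    """Computational surrogate for the visual motor-threshold search.

    MT is defined experimentally as the lowest intensity producing a visible
    twitch; here it is the lowest tested intensity whose peak-to-peak CMAP
    amplitude exceeds ``k`` times the recording noise SD.
    """
    if not vpp_by_intensity:
        raise ValueError("no intensities tested")
    items = sorted((float(i), float(v)) for i, v in vpp_by_intensity.items())
    criterion = k * noise_sd
    for intensity, vpp in items:
        if vpp > criterion:
            return intensity
    raise ValueError(
        f"MT not reached: no tested intensity exceeded {criterion:g} uV "
        f"(= {k:g} x noise SD {noise_sd:g} uV)"
    )


def quantify_incision(
    image: np.ndarray,
    baseline_image: np.ndarray,
    threshold: float | None = None,
    roi: tuple | None = None,
) -> float:
    """Percent of nerve tissue removed, from grayscale images.

    Both images are binarized (white = tissue) and the loss of white pixels
    relative to the pre-incision baseline is reported as a percentage:
    ``100 * (W_baseline - W_incised) / W_baseline``.

    The binarization threshold is computed from the baseline image by Otsu's
    method and applied to both images (pass ``threshold`` to override);
    ``roi = (row0, col0, row1, col1)`` restricts the count to a rectangle.
    """
    image = np.asarray(image, dtype=float)
    baseline_image = np.asarray(baseline_image, dtype=float)
    if image.shape != baseline_image.shape:
        raise ValueError(
            f"image shapes differ: {image.shape} vs {baseline_image.shape}"
        )
    if roi is not None:
        r0, c0, r1, c1 = roi
        image = image[r0:r1, c0:c1]
        baseline_image = baseline_image[r0:r1, c0:c1]
        if image.size == 0:
            raise ValueError("empty ROI")
    if threshold is None:
        from skimage.filters import threshold_otsu

        threshold = threshold_otsu(baseline_image)
    w_base = int(np.count_nonzero(baseline_image > threshold))
    w_inc = int(np.count_nonzero(image > threshold))
    if w_base == 0:
        raise ValueError("baseline image has no white (tissue) pixels")
    # regrown/brighter pixels cannot make the incision negative
    return float(np.clip(100.0 * (w_base - w_inc) / w_base, 0.0, 100.0))
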