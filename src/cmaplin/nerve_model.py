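"""Linear stimulus-response nerve model.

The nerve is summarized by the straight line y = a*x + b fitted to five
(stimulus, response) pairs per condition.  Stimulus intensities P1..P5 are
normalized to a percent scale anchored at P1:

    x[n] = (P_n - P_1) / P_5 * 100

Responses (grand-averaged peak-to-peak CMAP amplitudes) are normalized in
one of two modes:

* baseline mode  — y[n] = (CMAP_n^x - CMAP_1^x) / CMAP_5^0 * 100, scaled by
  the *initial* condition's maximal-intensity response; requires a healthy
  pre-injury recording.
* per-trial mode — y[n] = (CMAP_n^x - CMAP_1^x) / CMAP_5^x * 100, scaled by
  the same condition's own maximal-intensity response; baseline-free and
  invariant to any uniform rescaling of the condition's amplitudes, so it
  sees injury only through a change in recruitment-curve *shape*.

The fitted slope a falls as injury flattens the suprathreshold recruitment
segment; a is the primary nerve-function feature, b a diagnostic intercept.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

from .protocol import StimulusSchedule

__all__ = [
    "CmapMatrix",
    "NormalizedCurve",
    "LinearNerveModel",
    "NonConductingError",
    "normalize_stimulus",
    "normalize_baseline",
    "normalize_per_trial",
    "normalized_curve",
    "fit_linear_model",
    "fit_condition",
    "read_cmap_csv",
    "write_cmap_csv",
]

CONDITION_NAMES = ("initial", "damage1", "damage2", "damage3")

MODES = ("baseline", "per_trial")


class NonConductingError(ValueError):
    """Raised when the normalizing response is absent (CMAP at 140 %MT = 0).

    A vanished maximal-intensity CMAP marks the nerve as non-conducting at
    that condition; callers should record the condition rather than fit a
    meaningless curve.
    """


@dataclass
class CmapMatrix:
    """Grand-averaged Vpp amplitudes (uV), condition x intensity.

    ``vpp[x, n]`` is the amplitude for nerve condition ``x`` (0 = initial,
    1..3 = graded damage) at intensity index ``n`` (0-based over the
    ascending P1..P5 ladder).
    """

    vpp: np.ndarray
    schedule: StimulusSchedule = field(default_factory=StimulusSchedule)
    subject_id: str = "subject"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vpp = np.asarray(self.vpp, dtype=float)
        if self.vpp.ndim != 2:
            raise ValueError("vpp must be a 2-D condition x intensity array")
        if self.vpp.shape[1] != self.schedule.n_levels:
            raise ValueError(
                f"vpp has {self.vpp.shape[1]} intensity columns; schedule "
                f"defines {self.schedule.n_levels}"
            )
        if not np.all(np.isfinite(self.vpp)):
            raise ValueError("vpp entries must be finite")
        if np.any(self.vpp < 0):
            raise ValueError("vpp entries must be >= 0")

    @property
    def n_conditions(self) -> int:
        return self.vpp.shape[0]


@dataclass
class NormalizedCurve:
    """Percent-scale stimulus/response pairs for one condition and mode."""

    x_pct: np.ndarray
    y_pct: np.ndarray
    mode: str
    condition_index: int

    def __post_init__(self):
        self.x_pct = np.asarray(self.x_pct, dtype=float)
        self.y_pct = np.asarray(self.y_pct, dtype=float)


@dataclass
class LinearNerveModel:
    """Fitted line y = a*x + b on percent scales; the nerve-function feature."""

    a: float
    b: float
    mode: str = "per_trial"
    condition_index: int = 0
    residual_ss: float = 0.0
    subject_id: str = "subject"


def normalize_stimulus(levels: Sequence[float]) -> np.ndarray:
    """Normalize intensities to percent: x[n] = (P_n - P_1) / P_5 * 100.

    Scale-free (multiplying all intensities by a constant changes nothing),
    anchored at x[0] = 0.
    """
    p = np.asarray(levels, dtype=float)
    if p.ndim != 1 or len(p) < 2:
        raise ValueError("need a 1-D vector of at least two intensities")
    if np.any(np.diff(p) <= 0):
        raise ValueError("intensities must be strictly increasing")
    if p[-1] <= 0:
        raise ValueError("maximal intensity must be positive")
    return (p - p[0]) / p[-1] * 100.0


def normalize_baseline(m: CmapMatrix, x: int) -> np.ndarray:
    """Baseline-based response normalization (needs the initial condition).

    y[n] = (CMAP_n^x - CMAP_1^x) / CMAP_5^0 * 100; the denominator is fixed
    to the initial condition's maximal-intensity response, so amplitude loss
    under injury scales the whole curve down.
    """
    row = m.vpp[x]
    denom = m.vpp[0, -1]
    if denom <= 0:
        raise NonConductingError(
            "baseline response absent: initial-condition CMAP at maximal "
            "intensity is zero"
        )
    return (row - row[0]) / denom * 100.0


def normalize_per_trial(m: CmapMatrix, x: int) -> np.ndarray:
    """Per-trial (baseline-free) response normalization.

    y[n] = (CMAP_n^x - CMAP_1^x) / CMAP_5^x * 100; each condition is scaled
    by its own maximal-intensity response.  Coincides with the baseline mode
    on the initial condition.
    """
    row = m.vpp[x]
    denom = row[-1]
    if denom <= 0:
        raise NonConductingError(
            "response absent: nerve non-conducting at the maximal intensity "
            f"(condition {x})"
        )
    return (row - row[0]) / denom * 100.0


def normalized_curve(m: CmapMatrix, x: int, mode: str) -> NormalizedCurve:
    """Build the (x_pct, y_pct) curve for one condition under a mode."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    y = normalize_baseline(m, x) if mode == "baseline" else normalize_per_trial(m, x)
    return NormalizedCurve(
        x_pct=normalize_stimulus(m.schedule.levels_pct_mt),
        y_pct=y,
        mode=mode,
        condition_index=x,
    )


def fit_linear_model(
    x_pct: Sequence[float],
    y_pct: Sequence[float],
    mode: str = "per_trial",
    condition_index: int = 0,
    subject_id: str = "subject",
) -> LinearNerveModel:
    """Ordinary least squares fit of y = a*x + b.

    Solves the normal equations through a QR-based least-squares solve on
    the design matrix [1, x]; no weighting or robustification.  Fields are
    named (slope ``a``, intercept ``b``) rather than positional to keep the
    parameter order unambiguous.
    """
    x = np.asarray(x_pct, dtype=float)
    y = np.asarray(y_pct, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(np.unique(x)) < 2:
        raise ValueError("all x values identical: singular design matrix")
    X = np.column_stack([np.ones_like(x), x])
    theta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    b, a = theta
    resid = y - X @ theta
    return LinearNerveModel(
        a=float(a),
        b=float(b),
        mode=mode,
        condition_index=condition_index,
        residual_ss=float(resid @ resid),
        subject_id=subject_id,
    )


def fit_condition(
    m: CmapMatrix,
    x: int,
    mode: str,
    raw_intensity: bool = False,
) -> LinearNerveModel:
    """Normalize one condition of a CMAP matrix and fit the line.

    ``raw_intensity=True`` fits against the raw %MT ladder instead of the
    percent-normalized x (for comparison; the percent scale is the default
    used throughout).
    """
    curve = normalized_curve(m, x, mode)
    xv = (
        np.asarray(m.schedule.levels_pct_mt, dtype=float)
        if raw_intensity
        else curve.x_pct
    )
    return fit_linear_model(
        xv, curve.y_pct, mode=mode, condition_index=x, subject_id=m.subject_id
    )


def write_cmap_csv(matrices: Iterable[CmapMatrix], path) -> None:
    """Serialize matrices as tidy CSV: subject,condition,intensity_pct_mt,vpp_uv."""
    rows = []
    for m in matrices:
        for cond in range(m.n_conditions):
            for pct, v in zip(m.schedule.levels_pct_mt, m.vpp[cond]):
                rows.append(
                    {
                        "subject": m.subject_id,
                        "condition": cond,
                        "intensity_pct_mt": pct,
                        "vpp_uv": v,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cmap_csv(path, schedule: StimulusSchedule | None = None) -> List[CmapMatrix]:
    """Read matrices written by :func:`write_cmap_csv` (one per subject)."""
    df = pd.read_csv(path)
    required = {"subject", "condition", "intensity_pct_mt", "vpp_uv"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CMAP CSV is missing columns: {sorted(missing)}")
    out = []
    for subject, sub in df.groupby("subject", sort=False):
        levels = np.sort(sub["intensity_pct_mt"].unique())
        sched = schedule or StimulusSchedule(levels_pct_mt=tuple(levels))
        conds = np.sort(sub["condition"].unique())
        if not np.array_equal(conds, np.arange(len(conds))):
            raise ValueError(
                f"subject {subject}: conditions must be 0..k, got {conds}"
            )
        vpp = np.empty((len(conds), len(levels)))
        for c in conds:
            row = sub[sub["condition"] == c].sort_values("intensity_pct_mt")
            if len(row) != len(levels):
                raise ValueError(
                    f"subject {subject} condition {c}: expected "
                    f"{len(levels)} intensities, found {len(row)}"
                )
            vpp[int(c)] = row["vpp_uv"].to_numpy()
        out.append(CmapMatrix(vpp=vpp, schedule=sched, subject_id=str(subject)))
    return out
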