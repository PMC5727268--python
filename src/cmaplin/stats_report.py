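"""Condition-wise statistics on fitted parameters and run orchestration.

Paired t-tests on the fitted slope a (and optionally the intercept b)
between nerve conditions follow the study's within-nerve design: every
nerve is its own control, so the test acts on per-subject differences.
``run_pipeline`` chains the whole method - simulate or load amplitudes,
normalize, fit, label, split, train the SVM, evaluate, compare conditions -
and writes a reproducible report bundle.
"""
from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, Iterable, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__ as _pkg_version
from .classifier import (
    SplitConfig,
    classify,
    cross_normalization_eval,
    evaluate,
    label_points,
    split_data,
    train_svm,
)
from .nerve_model import (
    CmapMatrix,
    LinearNerveModel,
    MODES,
    NonConductingError,
    fit_condition,
    read_cmap_csv,
    write_cmap_csv,
)
from .simulate import SimConfig, generate_cohort

logger = logging.getLogger("cmaplin")

__all__ = ["RunConfig", "ComparisonResult", "compare_conditions", "run_pipeline"]

CONDITION_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass
class ComparisonResult:
    """Paired t-test between two nerve conditions on one fitted parameter."""

    pair: Tuple[int, int]
    parameter: str
    mean_difference: float
    t: float
    p: float
    n: int
    degenerate_variance: bool = False


@dataclass
class RunConfig:
    """Settings for one end-to-end run.

    With ``input_csv`` set, amplitudes are read from a tidy CMAP CSV;
    otherwise a synthetic cohort is generated (``n_subjects`` nerves at
    ``seed``).  ``modes`` selects which normalizations are fitted and
    classified.
    """

    out_dir: str = "cmaplin_run"
    input_csv: str | None = None
    seed: int = 1
    n_subjects: int = 16
    noise_sd: float = 15.0
    from_recordings: bool = False
    modes: tuple = MODES
    train_fraction: float = 0.7
    stratified: bool = True
    svm_c: float = 1.0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        cfg = cls(**data)
        cfg.modes = tuple(cfg.modes)
        return cfg


def compare_conditions(
    models: Iterable[LinearNerveModel],
    parameter: str = "a",
    pair: Tuple[int, int] = (0, 3),
) -> ComparisonResult:
    """Paired t-test on per-subject parameter differences between conditions.

    The statistic is t = mean(d) / (sd(d) / sqrt(n)) on differences
    d = value(pair[0]) - value(pair[1]), with a two-sided p from Student's t
    on n - 1 degrees of freedom.  Zero-variance differences are flagged:
    all-zero d gives t = 0, p = 1; a constant nonzero d gives t = +-inf,
    p = 0, with a warning.
    """
    if parameter not in ("a", "b"):
        raise ValueError("parameter must be 'a' or 'b'")
    i, j = pair
    by_subject: Dict[str, Dict[int, float]] = {}
    for m in models:
        by_subject.setdefault(m.subject_id, {})[m.condition_index] = getattr(
            m, parameter
        )
    unpaired = sorted(
        s for s, conds in by_subject.items() if i not in conds or j not in conds
    )
    if unpaired:
        raise ValueError(
            f"subjects missing condition {i} or {j}: {', '.join(unpaired)}"
        )
    d = np.array([by_subject[s][i] - by_subject[s][j] for s in sorted(by_subject)])
    n = len(d)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 subjects")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return ComparisonResult(pair, parameter, 0.0, 0.0, 1.0, n, True)
        warnings.warn(
            "zero-variance paired differences: t is infinite", RuntimeWarning
        )
        t = np.inf if mean > 0 else -np.inf
        return ComparisonResult(pair, parameter, mean, float(t), 0.0, n, True)
    t = mean / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return ComparisonResult(pair, parameter, mean, float(t), p, n)


def _matrices_from_recordings(cfg: RunConfig):
    """Simulate continuous recordings and run the full signal chain on them.

    Exercises trigger detection -> segmentation -> grand averaging -> Vpp
    instead of drawing amplitude rows directly; noise is applied at the
    sample level.
    """
    from dataclasses import replace as _replace

    from .io_signal import process_recording
    from .simulate import InjuryModel, cohort_populations, simulate_recording

    sim = SimConfig(seed=cfg.seed, n_subjects=cfg.n_subjects, noise_sd=cfg.noise_sd)
    injury = InjuryModel()
    matrices = []
    for subject_id, pop, sched, sub_seed in cohort_populations(sim):
        rows = []
        for level in range(injury.n_levels):
            rec = simulate_recording(
                pop, injury, level, sched, _replace(sim, seed=sub_seed)
            )
            rows.append(process_recording(rec, schedule=sched, condition_index=level))
        matrices.append(
            CmapMatrix(vpp=np.vstack(rows), schedule=sched, subject_id=subject_id)
        )
    return matrices


def _fit_all(matrices, mode):
    """Fit every (subject, condition); returns (models, non_conducting list)."""
    models, non_conducting = [], []
    for m in matrices:
        for cond in range(m.n_conditions):
            try:
                models.append(fit_condition(m, cond, mode))
            except NonConductingError:
                non_conducting.append({"subject": m.subject_id, "condition": cond})
    return models, non_conducting


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Outputs in ``cfg.out_dir``: ``cohort.csv`` (the amplitude matrices, when
    simulated), ``params.csv`` (fitted a, b per subject/condition/mode),
    ``comparisons.csv`` (paired t-tests on a and b), ``report.json``
    (classification results, boundary, config hash, versions) and
    ``run.log``.  Deterministic for a fixed seed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_pipeline(cfg, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_pipeline(cfg: RunConfig, out: Path) -> dict:
    logger.info("config hash %s", _config_hash(cfg))
    if cfg.input_csv:
        logger.info("stage load: reading %s", cfg.input_csv)
        matrices = read_cmap_csv(cfg.input_csv)
    elif cfg.from_recordings:
        logger.info(
            "stage simulate+segment: %d subjects from full recordings, seed %d",
            cfg.n_subjects,
            cfg.seed,
        )
        matrices = _matrices_from_recordings(cfg)
        write_cmap_csv(matrices, out / "cohort.csv")
    else:
        logger.info(
            "stage simulate: %d subjects, seed %d", cfg.n_subjects, cfg.seed
        )
        matrices = generate_cohort(
            SimConfig(seed=cfg.seed, n_subjects=cfg.n_subjects, noise_sd=cfg.noise_sd)
        )
        write_cmap_csv(matrices, out / "cohort.csv")

    split_cfg = SplitConfig(
        train_fraction=cfg.train_fraction, seed=cfg.seed, stratified=cfg.stratified
    )
    report: dict = {
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "versions": _versions(),
        "n_subjects": len(matrices),
        "modes": {},
        "non_conducting": {},
    }
    params_rows = []
    comparison_rows = []
    for mode in cfg.modes:
        logger.info("stage fit: mode %s", mode)
        models, non_conducting = _fit_all(matrices, mode)
        report["non_conducting"][mode] = non_conducting
        for m in models:
            params_rows.append(
                {
                    "subject": m.subject_id,
                    "condition": m.condition_index,
                    "mode": mode,
                    "a": m.a,
                    "b": m.b,
                    "residual_ss": m.residual_ss,
                }
            )
        logger.info("stage classify: mode %s", mode)
        points = label_points(models)
        train, test = split_data(points, split_cfg)
        boundary = train_svm(train, C=cfg.svm_c)
        result = evaluate(classify(boundary, test), test)
        report["modes"][mode] = {
            "n_train": len(train),
            "n_test": len(test),
            "test_accuracy": result.accuracy,
            "test_accuracy_rounded": result.rounded().accuracy,
            "per_condition": result.per_condition,
            "boundary": {
                "w_a": boundary.weights[0],
                "w_b": boundary.weights[1],
                "bias": boundary.bias,
            },
        }
        logger.info("stage compare: mode %s", mode)
        complete = [
            m
            for m in models
            if m.subject_id
            not in {nc["subject"] for nc in non_conducting}
        ]
        for parameter in ("a", "b"):
            for pair in CONDITION_PAIRS:
                try:
                    comp = compare_conditions(complete, parameter, pair)
                except ValueError as exc:
                    logger.warning("comparison %s %s skipped: %s", parameter, pair, exc)
                    continue
                comparison_rows.append(
                    {
                        "mode": mode,
                        "parameter": parameter,
                        "condition_i": pair[0],
                        "condition_j": pair[1],
                        "mean_difference": comp.mean_difference,
                        "t": comp.t,
                        "p": comp.p,
                        "n": comp.n,
                        "degenerate_variance": comp.degenerate_variance,
                    }
                )

    logger.info("stage transfer: baseline -> per_trial")
    if set(cfg.modes) >= set(MODES):
        try:
            report["transfer"] = cross_normalization_eval(
                matrices, split_cfg, C=cfg.svm_c
            )
        except NonConductingError as exc:
            logger.warning("transfer evaluation skipped: %s", exc)
            report["transfer"] = {"skipped": str(exc)}

    pd.DataFrame(params_rows).to_csv(out / "params.csv", index=False)
    pd.DataFrame(comparison_rows).to_csv(out / "comparisons.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    logger.info("report bundle written to %s", out)
    return report


def _versions() -> dict:
    import numpy
    import scipy
    import sklearn

    return {
        "cmaplin": _pkg_version,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }


def plot_parameter_scatter(points, ax=None):
    """Quick-look (a, b) scatter colored by condition (optional; needs matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for cond in sorted({p.condition_index for p in points}):
        sel = [p for p in points if p.condition_index == cond]
        ax.scatter(
            [p.a for p in sel], [p.b for p in sel], label=f"condition {cond}", s=20
        )
    ax.set_xlabel("slope a (% response / % intensity)")
    ax.set_ylabel("intercept b (%)")
    ax.legend()
    return ax
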