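"""Synthetic experiments: stimulus sampling, simulated responses, CSV I/O.

Generates complete trial tables with the statistical structure of the study:
12 participants, four sessions each, with display set size 4.  Sessions 1 and
4 draw colors uniformly from the wheel; sessions 2 and 3 draw them from a von
Mises distribution with concentration 1.422 (60 degrees circular SD) around a
participant-specific random prior mean.  Responses are generated by a chosen
observer model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import wrap_signed, wrap_unsigned
from .observer import (
    TRUE_PRIOR_KAPPA,
    ArcGrid,
    ModelSpec,
    ObserverParams,
    simulate_responses,
)

__all__ = [
    "TRIAL_COLUMNS",
    "ExperimentDesign",
    "sample_display",
    "simulate_dataset",
    "read_trials",
    "write_trials",
    "validate_trials",
    "add_error_column",
    "draw_ground_truth_params",
    "GROUND_TRUTH_RANGES",
]

TRIAL_COLUMNS = [
    "participant", "session", "condition", "prior_mean",
    "c1", "c2", "c3", "c4", "probe_index", "stimulus", "estimate", "arc_size",
]

_CONDITIONS = ("uniform", "von_mises")


@dataclass(frozen=True)
class ExperimentDesign:
    """Shape of a synthetic experiment.

    Defaults reproduce the study's averages: 12 participants, 645 uniform
    trials (sessions 1 and 4) and 561 von Mises trials (sessions 2 and 3)
    each, stimulus concentration 1.422 in the von Mises sessions.
    """

    n_participants: int = 12
    trials_uniform: int = 645
    trials_von_mises: int = 561
    stim_kappa: float = TRUE_PRIOR_KAPPA
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 0 or self.trials_uniform < 0 or self.trials_von_mises < 0:
            raise ValueError("counts must be nonnegative")
        if self.stim_kappa < 0:
            raise ValueError("stim_kappa must be >= 0")


def sample_display(condition: str, prior_mean: float, kappa_true: float, rng, n: int = 1):
    """Sample ``n`` displays: 4 i.i.d. colors, a uniform probe, the probed color.

    Returns ``(display_colors (n,4), probe_index (n,), stimulus (n,))``.
    Colors are raw wheel values in [0, 360); ``probe_index`` is 1-based.
    """
    if condition not in _CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if condition == "uniform":
        colors = rng.uniform(0.0, 360.0, size=(n, 4))
    else:
        draws = rng.vonmises(np.deg2rad(prior_mean), kappa_true, size=(n, 4))
        colors = wrap_unsigned(np.rad2deg(draws))
    probe = rng.integers(1, 5, size=n)
    stimulus = colors[np.arange(n), probe - 1]
    return colors, probe, stimulus


def _as_list(x, n, what):
    if isinstance(x, (ObserverParams, ModelSpec)):
        return [x] * n
    x = list(x)
    if len(x) != n:
        raise ValueError(f"need one {what} per participant ({n}), got {len(x)}")
    return x


def simulate_dataset(design: ExperimentDesign, params, model, rng=None,
                     grid: ArcGrid = None) -> pd.DataFrame:
    """Simulate a full experiment; returns a trial table (one row per trial).

    ``params`` and ``model`` may be single objects or per-participant lists
    (the latter supports model-recovery studies).  Deterministic given
    ``design.seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    if grid is None:
        grid = ArcGrid()
    n_p = design.n_participants
    params = _as_list(params, n_p, "ObserverParams")
    model = _as_list(model, n_p, "ModelSpec")
    frames = []
    for i in range(n_p):
        pid = i + 1
        prior_mean = float(wrap_unsigned(rng.uniform(0.0, 360.0)))
        for condition in _CONDITIONS:
            n_trials = design.trials_uniform if condition == "uniform" else design.trials_von_mises
            if n_trials == 0:
                continue
            colors, probe, stim = sample_display(
                condition, prior_mean, design.stim_kappa, rng, n=n_trials)
            est, arcs = simulate_responses(
                stim, params[i], model[i], condition, rng,
                prior_mean=prior_mean, grid=grid)
            sessions = (np.where(np.arange(n_trials) < n_trials // 2, 1, 4)
                        if condition == "uniform"
                        else np.where(np.arange(n_trials) < n_trials // 2, 2, 3))
            frames.append(pd.DataFrame({
                "participant": pid,
                "session": sessions,
                "condition": condition,
                "prior_mean": prior_mean if condition == "von_mises" else np.nan,
                "c1": colors[:, 0], "c2": colors[:, 1],
                "c3": colors[:, 2], "c4": colors[:, 3],
                "probe_index": probe,
                "stimulus": stim,
                "estimate": wrap_unsigned(est),
                "arc_size": arcs,
            }))
    if not frames:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    table = pd.concat(frames, ignore_index=True)
    return add_error_column(table)


def add_error_column(table: pd.DataFrame) -> pd.DataFrame:
    """Attach the derived signed error column: wrap_signed(estimate - stimulus)."""
    table = table.copy()
    if len(table):
        table["error"] = wrap_signed(table["estimate"].to_numpy()
                                     - table["stimulus"].to_numpy())
    else:
        table["error"] = pd.Series(dtype=float)
    return table


def validate_trials(table: pd.DataFrame) -> None:
    """Schema check; raises ValueError naming the first offending row."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if not len(table):
        return
    checks = [
        ("condition", ~table["condition"].isin(_CONDITIONS), "unknown condition"),
        ("probe_index", ~table["probe_index"].isin([1, 2, 3, 4]), "probe_index not in 1..4"),
        ("arc_size", (table["arc_size"] < 0) | (table["arc_size"] > 180),
         "arc_size outside [0, 180]"),
        ("stimulus", ~np.isfinite(table["stimulus"].astype(float)), "non-finite stimulus"),
        ("estimate", ~np.isfinite(table["estimate"].astype(float)), "non-finite estimate"),
    ]
    vm = table["condition"] == "von_mises"
    if vm.any():
        bad_prior = vm & ~np.isfinite(table["prior_mean"].astype(float))
        checks.append(("prior_mean", bad_prior, "von Mises row lacks prior_mean"))
    for col, bad, msg in checks:
        if bad.any():
            row = int(table.index[bad][0])
            raise ValueError(f"trial table row {row}: {msg} (column {col!r})")


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table to CSV (UTF-8, header, full float precision)."""
    validate_trials(table)
    table[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial CSV; returns the table with the error column."""
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return add_error_column(pd.DataFrame(columns=TRIAL_COLUMNS))
    validate_trials(table)
    return add_error_column(table)


#: Ground-truth parameter ranges for recovery studies (uniform draws).
GROUND_TRUTH_RANGES = {
    "gamma_mean": (2.0, 20.0),
    "gamma_scale": (0.5, 5.0),
    "est_exponent": (0.5, 4.0),
    "softmax_temp": (1.0, 20.0),
    "risk_alpha": (0.5, 1.5),
    "lapse_rate": (0.01, 0.1),
    "kappa_w": (0.2, 2.0),
    "kappa_fixed": (2.0, 20.0),
    "kappa_threshold": (0.5, 5.0),
    "kappa_const": (2.0, 20.0),
}


def draw_ground_truth_params(rng, n: int = 1, model: ModelSpec = None):
    """Draw ``n`` ground-truth ObserverParams uniformly within the stated ranges."""
    out = []
    for _ in range(n):
        kwargs = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in GROUND_TRUTH_RANGES.items()}
        p = ObserverParams(**kwargs)
        if model is not None:
            p.validate(model)
        out.append(p)
    return out if n > 1 else out[0]
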