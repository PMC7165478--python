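"""Descriptive and inferential behavioral analyses of arc-report experiments.

Implements the study's statistics: per-participant Spearman correlations with
group t tests on Fisher-transformed coefficients, quantile-bin summaries,
shift-toward-prior measures (with Wilcoxon signed-rank group tests),
split-half analyses of prior use, and stratified-permutation null
distributions for stimulus-driven confounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .circular import circ_sd_sample, wrap_signed

__all__ = [
    "CorrelationReport",
    "error_arc_correlation",
    "shift_arc_correlation",
    "quantile_bin_summary",
    "shift_toward_prior",
    "ShiftReport",
    "split_half_analyses",
    "confound_null_correlation",
    "ConfoundNullReport",
    "compute_confound",
    "behavior_report",
]


@dataclass
class CorrelationReport:
    """Group summary of per-participant Spearman correlations."""

    per_participant: pd.Series
    mean: float
    sem: float
    t: float
    p: float
    df: int

    def summary(self) -> str:
        return (f"r_s = {self.mean:.3f} +/- {self.sem:.3f}, "
                f"t({self.df}) = {self.t:.2f}, p = {self.p:.3g}")


def _group_correlation(table: pd.DataFrame, xcol: str, y_values: np.ndarray,
                       min_trials: int = 3) -> CorrelationReport:
    y = pd.Series(np.asarray(y_values, dtype=float), index=table.index)
    rs = {}
    for pid, sub in table.groupby("participant"):
        if len(sub) < min_trials:
            raise ValueError(f"participant {pid}: need >= {min_trials} trials")
        x = sub[xcol].to_numpy(dtype=float)
        yy = y.loc[sub.index].to_numpy()
        if np.ptp(x) == 0 or np.ptp(yy) == 0:
            warnings.warn(f"participant {pid}: constant vector, r_s undefined")
            rs[pid] = np.nan
            continue
        rs[pid] = sps.spearmanr(x, yy).statistic
    rs = pd.Series(rs)
    valid = rs.dropna().to_numpy()
    n = len(valid)
    mean = float(np.mean(valid))
    sem = float(np.std(valid, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    z = np.arctanh(np.clip(valid, -1 + 1e-12, 1 - 1e-12))
    if n > 1 and np.ptp(z) > 0:
        t, p = sps.ttest_1samp(z, 0.0)
    else:
        t, p = np.nan, np.nan
    return CorrelationReport(rs, mean, sem, float(t), float(p), n - 1)


def error_arc_correlation(table: pd.DataFrame) -> CorrelationReport:
    """Per-participant Spearman correlation between |error| and arc size,
    with a two-tailed group t test on the Fisher-transformed coefficients."""
    return _group_correlation(table, "arc_size",
                              np.abs(table["error"].to_numpy(dtype=float)))


def _shift_values(table: pd.DataFrame) -> np.ndarray:
    """Signed per-trial shift toward (+) / away from (-) the prior mean."""
    stim_rel = wrap_signed(table["stimulus"].to_numpy(dtype=float)
                           - table["prior_mean"].to_numpy(dtype=float))
    err = table["error"].to_numpy(dtype=float)
    return err * (-np.sign(stim_rel))


def shift_arc_correlation(table: pd.DataFrame) -> CorrelationReport:
    """Correlation of the shift toward the prior with arc size (von Mises rows)."""
    vm = table[table["condition"] == "von_mises"]
    return _group_correlation(vm, "arc_size", _shift_values(vm))


@dataclass
class ShiftReport:
    per_trial: pd.Series
    participant_means: pd.Series
    mean: float
    sem: float
    wilcoxon_stat: float
    p: float


def shift_toward_prior(table: pd.DataFrame) -> ShiftReport:
    """Mean shift toward the prior with a two-tailed Wilcoxon signed-rank test
    across participant means (von Mises rows only).

    The shift is the signed error multiplied by minus the sign of the
    stimulus relative to the prior mean; a stimulus exactly at the prior mean
    contributes 0 by convention.
    """
    vm = table[table["condition"] == "von_mises"]
    if not len(vm):
        raise ValueError("no von Mises rows")
    shift = pd.Series(_shift_values(vm), index=vm.index)
    means = shift.groupby(vm["participant"]).mean()
    if len(means) > 1 and np.ptp(means.to_numpy()) > 0:
        stat, p = sps.wilcoxon(means.to_numpy(), alternative="two-sided")
    else:
        stat, p = np.nan, np.nan
    sem = (float(means.std(ddof=1) / np.sqrt(len(means)))
           if len(means) > 1 else np.nan)
    return ShiftReport(shift, means, float(means.mean()), sem, float(stat), float(p))


def _quantile_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile-bin labels; ties never straddle an edge (searchsorted on edges)."""
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def quantile_bin_summary(table: pd.DataFrame, n_bins: int = 15,
                         x: str = "arc_size", y: str = "abs_error") -> pd.DataFrame:
    """Across-participant quantile-bin summary (the study's 15-bin curves).

    Per participant the data are split into ``n_bins`` quantiles of ``x``;
    per-bin means of ``x`` and ``y`` are then averaged across participants
    (mean +/- SEM).  ``y`` may be ``'abs_error'`` or ``'shift'`` (derived) or
    any numeric column.
    """
    table = table.copy()
    if y == "abs_error":
        table[y] = np.abs(table["error"].to_numpy(dtype=float))
    elif y == "shift":
        table[y] = _shift_values(table)
    per = []
    for pid, sub in table.groupby("participant"):
        bins = _quantile_bins(sub[x].to_numpy(dtype=float), n_bins)
        g = sub.groupby(bins).agg(x_mean=(x, "mean"), y_mean=(y, "mean"))
        g["participant"] = pid
        per.append(g)
    per = pd.concat(per)
    out = per.groupby(per.index).agg(
        x_mean=("x_mean", "mean"),
        y_mean=("y_mean", "mean"),
        y_sem=("y_mean", lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan),
        n_participants=("participant", "nunique"),
    )
    return out


def _lower_half_mask(values: np.ndarray) -> np.ndarray:
    """Median-split mask: True for the lower half; with an odd count the
    median trial joins the lower half (stable sort order breaks ties)."""
    order = np.argsort(values, kind="stable")
    n = len(values)
    mask = np.zeros(n, dtype=bool)
    mask[order[: (n + 1) // 2]] = True
    return mask


def split_half_analyses(table: pd.DataFrame) -> dict:
    """Two split-half checks of prior use on von Mises rows.

    (a) Does stimulus-to-prior distance drive arc size?  Median split on
    |stimulus - prior mean|; paired t test across participants on mean arc.
    (b) Is the prior pull stronger when reported uncertainty is high?
    Median split on arc size ("confidence"); per half, correlation of the
    signed response error with the prior error (prior mean minus stimulus);
    paired t test across participants.  Pearson and Spearman are both
    reported.
    """
    vm = table[table["condition"] == "von_mises"]
    if not len(vm):
        raise ValueError("no von Mises rows")
    dist = np.abs(wrap_signed(vm["stimulus"].to_numpy(dtype=float)
                              - vm["prior_mean"].to_numpy(dtype=float)))
    prior_err = wrap_signed(vm["prior_mean"].to_numpy(dtype=float)
                            - vm["stimulus"].to_numpy(dtype=float))
    err = vm["error"].to_numpy(dtype=float)
    arc = vm["arc_size"].to_numpy(dtype=float)
    pid = vm["participant"].to_numpy()

    arc_small, arc_large = [], []
    corr = {("pearson", "low"): [], ("pearson", "high"): [],
            ("spearman", "low"): [], ("spearman", "high"): []}
    for p in np.unique(pid):
        sel = pid == p
        near = _lower_half_mask(dist[sel])
        arc_small.append(arc[sel][near].mean())
        arc_large.append(arc[sel][~near].mean())
        confident = _lower_half_mask(arc[sel])  # small arc = confident
        for meth, fn in (("pearson", sps.pearsonr), ("spearman", sps.spearmanr)):
            for name, half in (("high", confident), ("low", ~confident)):
                x, yv = prior_err[sel][half], err[sel][half]
                r = fn(x, yv).statistic if (np.ptp(x) > 0 and np.ptp(yv) > 0) else np.nan
                corr[(meth, "low" if name == "low" else "high")].append(r)

    t_arc, p_arc = sps.ttest_rel(arc_small, arc_large)
    out = {
        "arc_by_prior_distance": {
            "mean_arc_near": float(np.mean(arc_small)),
            "mean_arc_far": float(np.mean(arc_large)),
            "t": float(t_arc), "p": float(p_arc),
        },
    }
    for meth in ("pearson", "spearman"):
        lo = np.asarray(corr[(meth, "low")], dtype=float)
        hi = np.asarray(corr[(meth, "high")], dtype=float)
        ok = np.isfinite(lo) & np.isfinite(hi)
        if ok.sum() > 1 and np.ptp(lo[ok] - hi[ok]) > 0:
            t, pv = sps.ttest_rel(lo[ok], hi[ok])
        else:
            t, pv = np.nan, np.nan
        out[f"prior_corr_by_confidence_{meth}"] = {
            "r_low_confidence": float(np.nanmean(lo)),
            "r_high_confidence": float(np.nanmean(hi)),
            "t": float(t), "p": float(pv),
        }
    return out


CONFOUNDS = ("stimulus_color", "display_dispersion", "nearest_item_distance")


def compute_confound(table: pd.DataFrame, confound: str) -> np.ndarray:
    """Per-trial confound values derived from the display columns."""
    if confound == "stimulus_color":
        return table["stimulus"].to_numpy(dtype=float)
    colors = table[["c1", "c2", "c3", "c4"]].to_numpy(dtype=float)
    if confound == "display_dispersion":
        return np.array([circ_sd_sample(row) for row in colors])
    if confound == "nearest_item_distance":
        stim = table["stimulus"].to_numpy(dtype=float)
        probe = table["probe_index"].to_numpy(dtype=int) - 1
        dist = np.abs(wrap_signed(colors - stim[:, None]))
        dist[np.arange(len(table)), probe] = np.inf
        return dist.min(axis=1)
    raise ValueError(f"unknown confound {confound!r}")


def _confound_strata(values: np.ndarray, confound: str) -> np.ndarray:
    if confound == "stimulus_color":
        return np.floor(np.mod(values, 360.0) / 18.0).astype(int)  # 20 color bins
    return _quantile_bins(values, 10)  # decile bins for continuous confounds


@dataclass
class ConfoundNullReport:
    """Stratified-permutation null for the error-arc correlation."""

    confound: str
    observed: pd.Series          # per-participant observed r_s
    null_draws: pd.DataFrame     # reps x participants
    p_values: pd.Series          # per-participant: fraction of null >= observed
    group_null: np.ndarray       # per-rep mean across participants
    percentiles: dict            # 5/25/50/75/95 of the group null

    def summary(self) -> str:
        return (f"confound={self.confound}: observed mean r_s = "
                f"{self.observed.mean():.3f}; null mean = "
                f"{self.group_null.mean():.4f}; max per-participant p = "
                f"{self.p_values.max():.4g}")


def confound_null_correlation(table: pd.DataFrame, confound: str,
                              reps: int = 1000,
                              seed: Optional[int] = None) -> ConfoundNullReport:
    """Null distribution of the error-arc correlation if arcs were driven
    solely by a stimulus property.

    Per replicate, arc sizes are permuted among trials within confound
    strata (18-degree stimulus-color bins; decile bins for continuous
    confounds) separately per participant, and the per-participant Spearman
    error-arc correlation is recomputed.  Strata of size 1 are left
    unchanged (a permutation no-op).
    """
    if confound not in CONFOUNDS:
        raise ValueError(f"confound must be one of {CONFOUNDS}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    observed = error_arc_correlation(table).per_participant
    pids = observed.index.to_numpy()
    null = np.empty((reps, len(pids)))
    for j, pid in enumerate(pids):
        sub = table[table["participant"] == pid]
        arc = sub["arc_size"].to_numpy(dtype=float)
        abs_err = np.abs(sub["error"].to_numpy(dtype=float))
        strata = _confound_strata(compute_confound(sub, confound), confound)
        order = np.argsort(strata, kind="stable")
        bounds = np.flatnonzero(np.diff(strata[order])) + 1
        groups = np.split(order, bounds)
        for r in range(reps):
            perm_arc = arc.copy()
            for g in groups:
                if len(g) > 1:
                    perm_arc[g] = arc[g[rng.permutation(len(g))]]
            null[r, j] = sps.spearmanr(perm_arc, abs_err).statistic
    null_df = pd.DataFrame(null, columns=pids)
    pvals = pd.Series(
        {pid: float(np.mean(null_df[pid].to_numpy() >= observed[pid]))
         for pid in pids})
    group = null.mean(axis=1)
    pct = {q: float(np.percentile(group, q)) for q in (5, 25, 50, 75, 95)}
    return ConfoundNullReport(confound, observed, null_df, pvals, group, pct)


def behavior_report(table: pd.DataFrame) -> dict:
    """All behavioral statistics as one JSON-serializable dictionary."""
    out = {}
    uni = table[table["condition"] == "uniform"]
    if len(uni):
        rep = error_arc_correlation(uni)
        out["error_arc_correlation_uniform"] = {
            "mean": rep.mean, "sem": rep.sem, "t": rep.t, "p": rep.p, "df": rep.df,
            "per_participant": rep.per_participant.to_dict(),
        }
    vm = table[table["condition"] == "von_mises"]
    if len(vm):
        rep = error_arc_correlation(vm)
        out["error_arc_correlation_von_mises"] = {
            "mean": rep.mean, "sem": rep.sem, "t": rep.t, "p": rep.p, "df": rep.df,
        }
        sh = shift_toward_prior(table)
        out["shift_toward_prior"] = {
            "mean": sh.mean, "sem": sh.sem, "p": sh.p,
            "participant_means": sh.participant_means.to_dict(),
        }
        rep = shift_arc_correlation(table)
        out["shift_arc_correlation"] = {
            "mean": rep.mean, "sem": rep.sem, "t": rep.t, "p": rep.p, "df": rep.df,
        }
        out["split_half"] = split_half_analyses(table)
    return out
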