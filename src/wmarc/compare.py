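"""Model comparison: k-fold cross-validated log-likelihood, information
criteria, bootstrap confidence intervals, and random-effects Bayesian model
selection (BMS).

The headline criterion is 10-fold cross-validated log-likelihood (LLcv),
summed across folds and normalized per participant: the per-trial LLcv is
averaged and multiplied by the mean trial count across participants, limiting
the influence of participants who completed more trials.  BMS treats the
per-participant LLcv as log model evidence and estimates population model
frequencies with the variational Dirichlet scheme of Stephan et al. (2009).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import digamma, gammaln, logsumexp

from .likelihood import LikelihoodConfig, dataset_loglik
from .model import ObserverModel, ObserverResults
from .observer import ModelSpec

__all__ = [
    "kfold_llcv",
    "aic_bic",
    "bootstrap_delta_ci",
    "bms_random_effects",
    "hierarchical_vs_single_bayes_factor",
    "BMSResult",
    "ComparisonTable",
    "compare_models",
]


def _fold_assignment(table: pd.DataFrame, k: int, rng) -> np.ndarray:
    """Seeded fold labels, stratified by condition (cycled within condition)."""
    folds = np.empty(len(table), dtype=int)
    for _, sub in table.groupby("condition"):
        loc = np.flatnonzero(table["condition"].to_numpy() == sub["condition"].iloc[0])
        perm = rng.permutation(len(loc))
        folds[loc[perm]] = np.arange(len(loc)) % k
    return folds


def kfold_llcv(table: pd.DataFrame, model: ModelSpec, k: int = 10,
               seed: Optional[int] = None, fit_config: LikelihoodConfig = None,
               n_starts: int = 10, maxfev: Optional[int] = None,
               warm_start: bool = False,
               fold_maxfev: Optional[int] = None) -> pd.Series:
    """Per-participant normalized k-fold cross-validated log-likelihood.

    For each participant: seeded condition-stratified folds; fit on k-1
    folds, evaluate the held-out fold, sum across folds; then normalize by
    (summed LLcv / participant trial count) * mean trial count across
    participants in ``table``.

    With ``warm_start=True`` a multi-start fit of the participant's full
    data is run first and each fold fit refines from that optimum (one
    start); this suppresses optimizer noise in the fold fits at a fraction
    of the cost and affects all compared models identically.
    ``fold_maxfev`` caps the per-fold refinement (default: same as
    ``maxfev``); fold fits must genuinely re-optimize on their training
    fold or cross-validation cannot penalize overparameterized models.

    Returns a Series indexed by participant.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if fit_config is None:
        fit_config = LikelihoodConfig.fast()
    counts = table.groupby("participant").size()
    mean_n = counts.mean()
    out = {}
    for j, (pid, sub) in enumerate(table.groupby("participant")):
        sub = sub.reset_index(drop=True)
        if len(sub) < k:
            raise ValueError(f"participant {pid}: fewer trials than folds")
        rng = np.random.default_rng(None if seed is None else seed + 1000 * j)
        folds = _fold_assignment(sub, k, rng)
        conds = sub["condition"].unique()
        for f in range(k):
            held = folds == f
            for c in conds:
                if not np.any((sub["condition"].to_numpy() == c) & ~held):
                    warnings.warn(
                        f"fold {f} leaves no training trials of condition {c}; "
                        "reassigning one trial")
                    move = np.flatnonzero((sub["condition"].to_numpy() == c) & held)[0]
                    folds[move] = (f + 1) % k
        anchor = None
        if warm_start:
            full = ObserverModel(sub, model, fit_config).fit(
                n_starts=n_starts, maxfev=maxfev,
                seed=None if seed is None else seed + 1000 * j + 999)
            if not full.converged:
                raise RuntimeError(f"participant {pid}: full-data fit failed")
            anchor = full.mle_params
        total = 0.0
        for f in range(k):
            train = sub[folds != f]
            test = sub[folds == f]
            m = ObserverModel(train, model, fit_config)
            if warm_start:
                fit = m.fit(n_starts=1,
                            maxfev=maxfev if fold_maxfev is None else fold_maxfev,
                            start_params=anchor,
                            seed=None if seed is None else seed + 1000 * j + f)
            else:
                fit = m.fit(n_starts=n_starts, maxfev=maxfev,
                            seed=None if seed is None else seed + 1000 * j + f)
            if not fit.converged:
                raise RuntimeError(f"participant {pid} fold {f}: fit did not converge")
            total += dataset_loglik(test, fit.mle_params, model, fit_config)
        out[pid] = total / len(sub) * mean_n
    return pd.Series(out, name=f"llcv_{model.label}")


def aic_bic(fit: ObserverResults):
    """(AIC, BIC) of a converged fit: 2q - 2LL and q ln(n) - 2LL."""
    if not fit.converged:
        raise ValueError("aic_bic requires a converged fit")
    return fit.aic, fit.bic


def bootstrap_delta_ci(deltas, reps: int = 10000, seed: Optional[int] = None,
                       confidence_level: float = 0.95):
    """Mean and BCa bootstrap CI of per-participant LLcv differences.

    Uses the bias-corrected and accelerated percentile method; an all-equal
    sample returns a point interval.
    """
    deltas = np.asarray(deltas, dtype=float)
    if len(deltas) < 2:
        raise ValueError("need at least 2 values")
    mean = float(np.mean(deltas))
    if np.ptp(deltas) == 0.0:
        return mean, (mean, mean)
    rng = np.random.default_rng(seed)
    res = sps.bootstrap((deltas,), np.mean, n_resamples=reps, method="BCa",
                        confidence_level=confidence_level, random_state=rng)
    return mean, (float(res.confidence_interval.low),
                  float(res.confidence_interval.high))


@dataclass
class BMSResult:
    """Random-effects BMS outputs (variational Dirichlet scheme)."""

    alpha: np.ndarray            # Dirichlet concentrations
    expected_freq: np.ndarray    # E[r_k]
    exceedance: np.ndarray       # P(r_k is the largest)
    responsibilities: np.ndarray  # participants x models
    free_energy: float           # variational lower bound on log evidence
    n_iter: int
    converged: bool


def bms_random_effects(evidence, alpha0: float = 1.0, max_iter: int = 10000,
                       tol: float = 1e-6, n_samples: int = 200000,
                       seed: Optional[int] = None) -> BMSResult:
    """Random-effects Bayesian model selection over a participants x models
    log-evidence matrix.

    Iterates the variational updates (responsibilities proportional to
    exp(evidence + digamma terms); Dirichlet concentrations alpha0 + counts)
    until the concentrations change by less than ``tol``.  Exceedance
    probabilities are estimated by seeded Dirichlet Monte-Carlo.
    """
    L = np.asarray(evidence, dtype=float)
    if L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("evidence must be (participants x >=2 models)")
    n, m = L.shape
    alpha = np.full(m, float(alpha0))
    trace = []
    converged = False
    for it in range(1, max_iter + 1):
        logu = L + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        g = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        new_alpha = alpha0 + g.sum(axis=0)
        delta = np.max(np.abs(new_alpha - alpha))
        trace.append(delta)
        alpha = new_alpha
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"BMS failed to converge after {max_iter} iterations; "
            f"last deltas: {trace[-5:]}")

    expected = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    exceed = np.bincount(np.argmax(draws, axis=1), minlength=m) / n_samples

    # variational lower bound on the hierarchical log evidence
    psi_term = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.sum(np.where(g > 0, g * np.log(g), 0.0))
    a0 = np.full(m, float(alpha0))
    kl_dir = (gammaln(alpha.sum()) - gammaln(alpha).sum()
              - gammaln(a0.sum()) + gammaln(a0).sum()
              + np.sum((alpha - a0) * psi_term))
    free_energy = float(np.sum(g * (L + psi_term[None, :])) + ent - kl_dir)
    return BMSResult(alpha, expected, exceed, g, free_energy, it, converged)


def hierarchical_vs_single_bayes_factor(evidence, bms: BMSResult = None,
                                        seed: Optional[int] = None) -> float:
    """Bayes factor of the hierarchical (random-effects) model over the best
    single model.

    The hierarchical marginal likelihood is approximated by the variational
    bound; the single-model evidence for model k is the summed log evidence
    across participants, maximized over k.  With a single model the factor
    is 1 by construction.
    """
    L = np.atleast_2d(np.asarray(evidence, dtype=float))
    if L.shape[1] == 1:
        return 1.0
    if bms is None:
        bms = bms_random_effects(L, seed=seed)
    best_single = float(np.max(L.sum(axis=0)))
    return float(np.exp(bms.free_energy - best_single))


@dataclass
class ComparisonTable:
    """Per-participant x model comparison with deltas, CIs and BMS outputs."""

    llcv: pd.DataFrame                  # participants x models
    aic: pd.DataFrame
    bic: pd.DataFrame
    reference: str
    deltas: dict = field(default_factory=dict)   # model -> (mean, (lo, hi))
    bms: BMSResult = None

    def summary(self) -> str:
        lines = ["Model comparison (LLcv, reference: %s)" % self.reference,
                 "=" * 60]
        for m in self.llcv.columns:
            mean, (lo, hi) = self.deltas[m]
            lines.append(f"{m:<28s} dLLcv = {mean:8.2f}  [{lo:8.2f} {hi:8.2f}]")
        if self.bms is not None:
            lines.append("-" * 60)
            for m, f, x in zip(self.llcv.columns, self.bms.expected_freq,
                               self.bms.exceedance):
                lines.append(f"{m:<28s} freq = {f:.3f}  exceedance = {x:.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "reference": self.reference,
            "llcv": {c: self.llcv[c].to_dict() for c in self.llcv.columns},
            "aic": {c: self.aic[c].to_dict() for c in self.aic.columns},
            "bic": {c: self.bic[c].to_dict() for c in self.bic.columns},
            "deltas": {m: {"mean": v[0], "ci": list(v[1])}
                       for m, v in self.deltas.items()},
        }
        if self.bms is not None:
            out["bms"] = {
                "alpha": self.bms.alpha.tolist(),
                "expected_freq": self.bms.expected_freq.tolist(),
                "exceedance": self.bms.exceedance.tolist(),
                "free_energy": self.bms.free_energy,
            }
        return out


def compare_models(table: pd.DataFrame, models: Sequence[ModelSpec],
                   k: int = 10, seed: Optional[int] = None,
                   fit_config: LikelihoodConfig = None, n_starts: int = 10,
                   maxfev: Optional[int] = None, reps: int = 10000,
                   reference: Optional[str] = None,
                   run_bms: bool = True) -> ComparisonTable:
    """Full comparison pipeline: LLcv, AIC/BIC, deltas with BCa CIs, BMS.

    Folds are shared across models (seeded per participant) so every model
    sees identical train/test splits.
    """
    if fit_config is None:
        fit_config = LikelihoodConfig.fast()
    llcv = {}
    aic = {}
    bic = {}
    for spec in models:
        llcv[spec.label] = kfold_llcv(table, spec, k=k, seed=seed,
                                      fit_config=fit_config, n_starts=n_starts,
                                      maxfev=maxfev)
        a, b = {}, {}
        for j, (pid, sub) in enumerate(table.groupby("participant")):
            fit = ObserverModel(sub.reset_index(drop=True), spec, fit_config).fit(
                n_starts=n_starts, maxfev=maxfev,
                seed=None if seed is None else seed + 7919 * j)
            a[pid], b[pid] = aic_bic(fit)
        aic[spec.label] = pd.Series(a)
        bic[spec.label] = pd.Series(b)
    llcv = pd.DataFrame(llcv)
    aic = pd.DataFrame(aic)
    bic = pd.DataFrame(bic)
    if reference is None:
        reference = llcv.mean(axis=0).idxmax()
    deltas = {}
    for m in llcv.columns:
        d = (llcv[m] - llcv[reference]).to_numpy()
        if m == reference:
            deltas[m] = (0.0, (0.0, 0.0))
        else:
            deltas[m] = bootstrap_delta_ci(d, reps=reps, seed=seed)
    bms = bms_random_effects(llcv.to_numpy(), seed=seed) if (
        run_bms and llcv.shape[1] >= 2) else None
    return ComparisonTable(llcv, aic, bic, reference, deltas, bms)
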