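"""Trial likelihoods by numerical marginalization over latent precision and memory.

The density of one trial's response pair (estimate, arc) given the stimulus is

    p(est, arc | s) = lambda * p_lapse(est) * p_lapse(arc)
        + (1 - lambda) * E_kappa[ integral dm p(m | s, kappa)
                                  * p(est | posterior(m, kappa*))
                                  * p(arc | EU(posterior width)) ]

The gamma mixture over encoding precision kappa is marginalized at
equal-weight quantile midpoints; the memory m on an equispaced circular grid
(periodic trapezoid rule, spectrally accurate for these smooth integrands).
Estimate densities are per degree; the arc likelihood is the softmax policy
mass of the response's grid bin divided by the bin width, making it a proper
density comparable across grids.

Two algebraically equivalent routes exist for sessions where the believed
prior is uniform: a fast path that collapses the memory integral (the arc
policy does not depend on m there) and the general prior-frame path.  Their
agreement is asserted in the test suite.  For fitting, optional lookup-table
acceleration (`est_lookup_step`, `kappa_policy_nodes`) replaces exact
per-trial evaluation by dense-grid interpolation; the exact settings are the
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps
from scipy.special import gammainc, i0e

from .circular import wrap_signed
from .observer import (
    ArcGrid,
    ModelSpec,
    ObserverParams,
    log_arc_policy_matrix,
    memory_uncertainty,
)

__all__ = [
    "LikelihoodConfig",
    "trial_loglik",
    "trial_logliks",
    "dataset_loglik",
    "count_free_params",
    "free_param_names",
    "PARAM_BOUNDS",
]

_DEG = np.pi / 180.0


@dataclass(frozen=True)
class LikelihoodConfig:
    """Quadrature and discretization settings for the likelihood.

    Parameters
    ----------
    kappa_grid_size : int
        Number of equal-weight gamma strata for the encoding-precision
        mixture (each evaluated at its conditional mean).
    memory_grid_size : int
        Equispaced circular grid size for the memory variable m.
    arc_grid : ArcGrid
        Discretization of arc half-sizes (default 1-degree steps).
    est_lookup_step : float
        If > 0, tabulate the uniform-prior estimate marginal on a dense
        circular grid of this spacing (degrees) and interpolate per trial
        instead of exact per-trial evaluation.  0 = exact.
    kappa_policy_nodes : int
        If > 0, interpolate arc log-policies over this many posterior-width
        nodes in the prior-frame path.  0 = exact per unique width.
    policy_fine_per_deg : int
        Resolution (points per degree) of the hit-mass integration grid
        behind the arc policy.
    density_floor : float
        Lower bound applied to the mixture density before taking the log.
    """

    kappa_grid_size: int = 100
    memory_grid_size: int = 360
    arc_grid: ArcGrid = field(default_factory=ArcGrid)
    est_lookup_step: float = 0.0
    kappa_policy_nodes: int = 0
    policy_fine_per_deg: int = 16
    density_floor: float = 1e-300

    def __post_init__(self):
        if self.kappa_grid_size < 1 or self.memory_grid_size < 4:
            raise ValueError("grids must be nonempty")

    @classmethod
    def fast(cls, kappa_grid_size=16, memory_grid_size=120,
             kappa_policy_nodes=64, est_lookup_step=0.125,
             policy_fine_per_deg=8, **kw):
        """Reduced-accuracy preset for iterative fitting."""
        return cls(kappa_grid_size=kappa_grid_size,
                   memory_grid_size=memory_grid_size,
                   kappa_policy_nodes=kappa_policy_nodes,
                   est_lookup_step=est_lookup_step,
                   policy_fine_per_deg=policy_fine_per_deg, **kw)

    def replace(self, **kw):
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Free-parameter ledger
# ---------------------------------------------------------------------------

#: Box bounds used by the fitter (generous, transform-friendly).
PARAM_BOUNDS = {
    "gamma_mean": (0.05, 200.0),
    "gamma_scale": (0.01, 100.0),
    "est_exponent": (0.05, 20.0),
    "softmax_temp": (0.01, 1000.0),
    "risk_alpha": (0.1, 4.0),
    "lapse_rate": (1e-4, 0.5),
    "kappa_w": (1e-3, 50.0),
    "kappa_fixed": (1e-3, 200.0),
    "kappa_threshold": (0.01, 200.0),
    "kappa_const": (0.05, 200.0),
}


def free_param_names(model: ModelSpec):
    """Ordered names of the parameters free under ``model``."""
    if model.knowledge == "fixed_precision":
        names = ["kappa_const"]
    else:
        names = ["gamma_mean", "gamma_scale"]
    names += ["est_exponent", "softmax_temp", "risk_alpha", "lapse_rate"]
    if model.knowledge == "no_knowledge":
        names.append("kappa_fixed")
    elif model.knowledge == "limited":
        names += ["kappa_fixed", "kappa_threshold"]
    if model.prior_use in ("YY", "YN", "NY"):
        names.append("kappa_w")
    return names


def count_free_params(model: ModelSpec) -> int:
    """Free-parameter count: Known 6, No-Knowledge 7, Limited 8, Fixed 5;
    +1 for a free believed-prior width (YY/YN/NY); TT pins it."""
    return len(free_param_names(model))


# ---------------------------------------------------------------------------
# Quadrature pieces
# ---------------------------------------------------------------------------

def kappa_quadrature(params: ObserverParams, model: ModelSpec, config: LikelihoodConfig):
    """Encoding-precision nodes and weights: equal-weight gamma stratification
    with each stratum evaluated at its conditional mean (centroid).

    Centroid placement makes the rule exact for integrands linear in kappa
    within each stratum, which converges markedly faster than quantile
    midpoints while remaining robust to extreme gamma shapes.
    """
    if model.knowledge == "fixed_precision":
        return np.array([params.kappa_const]), np.array([1.0])
    k = config.kappa_grid_size
    shape = params.gamma_mean / params.gamma_scale
    edges = sps.gamma.ppf(np.linspace(0.0, 1.0, k + 1), shape,
                          scale=params.gamma_scale)
    # E[kappa | stratum] via the shape+1 incomplete-gamma identity
    cdf1 = gammainc(shape + 1.0, edges / params.gamma_scale)
    nodes = params.gamma_mean * np.diff(cdf1) * k
    return nodes, np.full(k, 1.0 / k)


def _log_i0(x):
    return np.log(i0e(x)) + x


def _vm_dens_deg(delta_deg, beta):
    """Von Mises density per degree at offsets ``delta_deg``, concentration beta."""
    return np.exp(beta * np.cos(delta_deg * _DEG) - _log_i0(beta) - np.log(360.0))


def _grid_density(beta, m_grid_deg):
    """VM(0, beta) sampled on the memory grid, normalized to unit discrete mass."""
    w = np.exp(beta[:, None] * (np.cos(m_grid_deg * _DEG)[None, :] - 1.0))
    return w / w.sum(axis=1, keepdims=True)


def _conv_lookup(kappas, betas, m_size, step_deg):
    """Estimate-marginal lookup tables f_i(delta) by FFT convolution.

    f_i = (VM(kappa_i) * VM(beta_i)) evaluated on a dense circular grid via
    spectral upsampling; returns (tables (K, n_up), n_up).
    """
    n_up = int(round(360.0 / step_deg))
    grid = np.arange(m_size) * (360.0 / m_size)
    a = _grid_density(np.asarray(kappas, float), grid)      # discrete mass
    b = _grid_density(np.asarray(betas, float), grid)
    spec = np.fft.rfft(a, axis=1) * np.fft.rfft(b, axis=1)
    n_keep = min(spec.shape[1], n_up // 2 + 1)
    padded = np.zeros((spec.shape[0], n_up // 2 + 1), dtype=complex)
    padded[:, :n_keep] = spec[:, :n_keep]
    dens = np.fft.irfft(padded, n=n_up, axis=1) * (n_up / m_size)
    # convert discrete mass per fine cell to density per degree
    dens = np.maximum(dens, 0.0) / (360.0 / m_size)
    return dens, n_up


def _interp_circular(tables, n_up, delta_deg):
    """Linear periodic interpolation of per-row tables at angles (degrees)."""
    pos = np.mod(delta_deg, 360.0) * (n_up / 360.0)
    i0_ = np.floor(pos).astype(int) % n_up
    i1_ = (i0_ + 1) % n_up
    frac = pos - np.floor(pos)
    return tables[:, i0_] * (1.0 - frac) + tables[:, i1_] * frac


# ---------------------------------------------------------------------------
# Core density computation
# ---------------------------------------------------------------------------

def _nonlapse_uniform_prior(delta_est, arc_bins, params, model, config):
    """Mixture density over kappa when the believed prior is uniform.

    ``delta_est`` = wrap(estimate - stimulus).  The arc policy depends only on
    kappa* here, so the memory integral acts on the estimate alone (a circular
    convolution of the encoding and estimation kernels).
    """
    kappas, wts = kappa_quadrature(params, model, config)
    kstar = np.atleast_1d(memory_uncertainty(kappas, params, model)).astype(float)
    k_est = kappas if model.belief_weight_true_kappa else kstar
    betas = params.est_exponent * np.asarray(k_est, dtype=float)
    grid = config.arc_grid

    log_pol = log_arc_policy_matrix(kstar, params, grid,
                                    config.policy_fine_per_deg)  # (K, n_arc)
    arc_dens = np.exp(log_pol[:, arc_bins]) / grid.step        # (K, T)

    if config.est_lookup_step > 0:
        tables, n_up = _conv_lookup(kappas, betas, config.memory_grid_size,
                                    config.est_lookup_step)
        est_dens = _interp_circular(tables, n_up, delta_est)   # (K, T)
    else:
        m_grid = np.arange(config.memory_grid_size) * (360.0 / config.memory_grid_size)
        w = _grid_density(kappas, m_grid)                      # (K, M)
        est_dens = np.empty((len(kappas), len(delta_est)))
        for i in range(len(kappas)):
            d = _vm_dens_deg(delta_est[:, None] - m_grid[None, :], betas[i])
            est_dens[i] = d @ w[i]
    return wts @ (est_dens * arc_dens)


class _PolicyTable:
    """Shared arc log-policy lookup over posterior widths.

    Built once per likelihood evaluation; queried per precision node.  With
    ``n_nodes == 0`` (or few distinct widths) rows are computed exactly per
    unique width; otherwise log-policies are linearly interpolated between
    log-spaced width nodes covering ``[k_min, k_max]``.
    """

    def __init__(self, k_min, k_max, params, grid, n_nodes, fine_per_deg=16):
        self.params = params
        self.grid = grid
        self.n_nodes = n_nodes
        self.fine_per_deg = fine_per_deg
        if n_nodes > 0:
            self.lo = np.log(0.01 + k_min)
            self.hi = max(np.log(0.01 + k_max), self.lo + 1e-12)
            nodes_k = np.exp(np.linspace(self.lo, self.hi, n_nodes)) - 0.01
            self.lp = log_arc_policy_matrix(np.maximum(nodes_k, 0.0),
                                            params, grid,
                                            fine_per_deg)   # (Q, n_arc)

    def rows(self, kappa_vals, arc_bins):
        """Log-policy at (kappa_vals[j], arc_bins[t]); (len(kappa_vals), T)."""
        kappa_vals = np.asarray(kappa_vals, float)
        if self.n_nodes <= 0 or len(np.unique(kappa_vals)) <= 4:
            uniq, inv = np.unique(kappa_vals, return_inverse=True)
            lp = log_arc_policy_matrix(uniq, self.params, self.grid,
                                       self.fine_per_deg)
            return lp[inv][:, arc_bins]
        lp_t = self.lp[:, arc_bins]                          # (Q, T)
        u = np.log(0.01 + kappa_vals)
        pos = np.clip((u - self.lo) / (self.hi - self.lo) * (self.n_nodes - 1),
                      0, self.n_nodes - 1 - 1e-9)
        j0 = pos.astype(int)
        frac = (pos - j0)[:, None]
        return lp_t[j0] * (1.0 - frac) + lp_t[j0 + 1] * frac


def _nonlapse_prior_frame(delta_s, delta_est, arc_bins, kappa_w, params, model, config):
    """General path: explicit memory grid in the believed-prior frame.

    ``delta_s``/``delta_est`` are stimulus/estimate angles relative to the
    prior mean; ``kappa_w`` >= 0 is the believed prior concentration.  The
    memory weight, estimate density and arc density are fused into a single
    exponential per precision node; the memory-weight normalization uses the
    spectrally exact identity sum_j exp(kappa cos(x - m_j)) = M I0(kappa)
    (aliasing terms are below machine precision for the grids used).
    """
    kappas, wts = kappa_quadrature(params, model, config)
    kstar = np.atleast_1d(memory_uncertainty(kappas, params, model)).astype(float)
    grid = config.arc_grid
    m_size = config.memory_grid_size
    m_grid = np.arange(m_size) * (360.0 / m_size)
    cos_m, sin_m = np.cos(m_grid * _DEG), np.sin(m_grid * _DEG)
    cos_e, sin_e = np.cos(delta_est * _DEG), np.sin(delta_est * _DEG)
    # kappa-independent (T, M) matrix cos(delta_s - m_j)
    cos_sm = (np.cos(delta_s * _DEG)[:, None] * cos_m[None, :]
              + np.sin(delta_s * _DEG)[:, None] * sin_m[None, :])
    log_step = np.log(grid.step)
    # posterior widths lie within |kstar - kappa_w| .. kstar + kappa_w
    k_min = float(np.min(np.abs(kstar - kappa_w)))
    k_max = float(np.max(kstar + kappa_w))
    policy = _PolicyTable(k_min, k_max, params, grid, config.kappa_policy_nodes,
                          config.policy_fine_per_deg)

    k_est_nodes = kappas if model.belief_weight_true_kappa else kstar

    out = np.zeros(len(delta_est))
    for i in range(len(kappas)):
        # arc decision reflects the believed posterior width
        c = kstar[i] * cos_m + kappa_w
        s = kstar[i] * sin_m
        k_post = np.hypot(c, s)                                # (M,)
        # estimate posterior may weight the likelihood with the true kappa
        c_e = k_est_nodes[i] * cos_m + kappa_w
        s_e = k_est_nodes[i] * sin_m
        k_post_e = np.hypot(c_e, s_e)
        beta = params.est_exponent * k_post_e
        safe = np.where(k_post_e > 0, k_post_e, 1.0)
        a_coef = beta * c_e / safe                             # beta * cos(mu_post)
        b_coef = beta * s_e / safe                             # beta * sin(mu_post)
        log_pol = policy.rows(k_post, arc_bins)               # (M, T)
        # fused log integrand: memory weight + estimate density + arc density
        logf = (kappas[i] * cos_sm
                + cos_e[:, None] * a_coef[None, :]
                + sin_e[:, None] * b_coef[None, :]
                + log_pol.T)
        logf -= (_log_i0(kappas[i]) + np.log(m_size) + _log_i0(beta)[None, :]
                 + np.log(360.0) + log_step)
        out += wts[i] * np.exp(logf).sum(axis=1)
    return out


def _lapse_density(delta_est_prior, arc_bins, use_prior, kappa_w, params, config):
    """Lapse-branch density: estimate from uniform or the believed prior."""
    grid = config.arc_grid
    k_lapse = kappa_w if use_prior else 0.0
    log_pol = log_arc_policy_matrix(np.array([k_lapse]), params, grid,
                                    config.policy_fine_per_deg)[0]
    arc_dens = np.exp(log_pol[arc_bins]) / grid.step
    if use_prior and k_lapse > 0:
        est_dens = _vm_dens_deg(delta_est_prior, params.est_exponent * k_lapse)
    else:
        # estimate ~ uniform (a zero-concentration posterior stays uniform
        # under any estimation exponent)
        est_dens = np.full(len(arc_bins), 1.0 / 360.0)
    return est_dens * arc_dens


def trial_logliks(table, params: ObserverParams, model: ModelSpec,
                  config: LikelihoodConfig = None) -> np.ndarray:
    """Log density per (degree x degree) response cell for every trial row.

    Vectorized over the table; rows may mix conditions, participants and
    prior means.  Returns an array aligned with ``table`` rows.
    """
    if config is None:
        config = LikelihoodConfig()
    params.validate(model)
    n = len(table)
    out = np.empty(n)
    if n == 0:
        return out
    grid = config.arc_grid
    condition = table["condition"].to_numpy()
    stim = table["stimulus"].to_numpy(dtype=float)
    est = table["estimate"].to_numpy(dtype=float)
    arc = table["arc_size"].to_numpy(dtype=float)
    prior_mean = (table["prior_mean"].to_numpy(dtype=float)
                  if "prior_mean" in table.columns else np.zeros(n))
    lam = params.lapse_rate

    for cond in np.unique(condition):
        sel = condition == cond
        idx = np.flatnonzero(sel)
        bins = grid.bin_index(arc[sel])
        is_vm = cond == "von_mises"
        kw_nl = params.effective_kappa_w(model) if (is_vm and model.uses_prior_nonlapse) else 0.0
        kw_lp = params.effective_kappa_w(model) if (is_vm and model.uses_prior_lapse) else 0.0

        if lam < 1.0:
            if kw_nl > 0:
                d_s = wrap_signed(stim[sel] - prior_mean[sel])
                d_e = wrap_signed(est[sel] - prior_mean[sel])
                nonlapse = _nonlapse_prior_frame(d_s, d_e, bins, kw_nl,
                                                 params, model, config)
            else:
                d = wrap_signed(est[sel] - stim[sel])
                nonlapse = _nonlapse_uniform_prior(np.atleast_1d(d), bins,
                                                   params, model, config)
        else:
            nonlapse = 0.0

        if lam > 0.0:
            d_ep = wrap_signed(est[sel] - prior_mean[sel]) if is_vm else np.zeros(sel.sum())
            lapse = _lapse_density(np.atleast_1d(d_ep), bins,
                                   kw_lp > 0, kw_lp, params, config)
        else:
            lapse = 0.0

        dens = lam * lapse + (1.0 - lam) * nonlapse
        out[idx] = np.log(np.maximum(dens, config.density_floor))
    return out


def trial_loglik(trial, params: ObserverParams, model: ModelSpec,
                 config: LikelihoodConfig = None) -> float:
    """Log density of a single trial (a table row, Series or dict)."""
    import pandas as pd

    if isinstance(trial, pd.Series):
        table = trial.to_frame().T
    elif isinstance(trial, dict):
        table = pd.DataFrame([trial])
    else:
        table = trial
    return float(trial_logliks(table, params, model, config)[0])


def dataset_loglik(table, params: ObserverParams, model: ModelSpec,
                   config: LikelihoodConfig = None) -> float:
    """Summed log-likelihood of a trial table (0 for an empty table)."""
    if len(table) == 0:
        return 0.0
    return float(np.sum(trial_logliks(table, params, model, config)))
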