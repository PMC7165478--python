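"""Generative observer models for rewarded arc-report working-memory decisions.

The task: on each trial four colors are shown; after a delay the observer
reports an estimate of a probed color on a 360-degree wheel, then draws a
symmetric arc around the estimate.  A stimulus inside the arc ("hit") earns
points that fall linearly from 100 (arc half-size A = 0) to 0 (A = 180);
a miss earns nothing.

Model family
------------
Encoding: the stimulus is stored as a noisy memory m ~ VonMises(s, kappa)
with trial-to-trial precision kappa ~ Gamma(mean, scale) (variable precision)
or a single constant (fixed precision).  The observer's *represented* memory
uncertainty kappa* may equal kappa (Known), a fitted constant (No-Knowledge),
or a thresholded two-level value (Limited).  The belief posterior combines
VonMises(m, kappa*) with a believed stimulus prior VonMises(mu_p, kappa_w)
by Bayes' rule.  Estimates are noisy samples from the posterior (posterior
raised to a power ``est_exponent``); arc sizes are sampled from a softmax
over the expected utility EU(A) = p(hit | A) * points(A)**risk_alpha, with
temperature ``softmax_temp``.  With probability ``lapse_rate`` the observer
has no memory information and responds from a default distribution.

Prior-use codes (von Mises stimulus sessions only): two letters give whether
the believed prior is used on nonlapse / lapse trials -- YY, YN, NY, NN;
TT is YY with the believed prior width pinned to the true stimulus
concentration (1.422).  In uniform sessions the believed prior is uniform
and all codes coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from .circular import VonMises, vm_interval_mass, vm_product, wrap_signed

__all__ = [
    "TRUE_PRIOR_KAPPA",
    "KNOWLEDGE_VARIANTS",
    "PRIOR_USE_CODES",
    "ModelSpec",
    "ObserverParams",
    "ArcGrid",
    "points_fn",
    "draw_encoding_precision",
    "encode",
    "memory_uncertainty",
    "belief_posterior",
    "sample_estimate",
    "expected_utility_curve",
    "arc_policy",
    "log_arc_policy_matrix",
    "lapse_branch",
    "simulate_trial",
    "simulate_responses",
]

#: Concentration of the true von Mises stimulus distribution (60 deg circular SD).
TRUE_PRIOR_KAPPA = 1.422

KNOWLEDGE_VARIANTS = ("known", "no_knowledge", "limited", "fixed_precision")
PRIOR_USE_CODES = ("YY", "YN", "NY", "NN", "TT", "uniform_only")


@dataclass(frozen=True)
class ModelSpec:
    """One member of the model family: knowledge variant x prior-use code.

    Parameters
    ----------
    knowledge : str
        'known', 'no_knowledge', 'limited' or 'fixed_precision'.
    prior_use : str
        'YY', 'YN', 'NY', 'NN', 'TT' or 'uniform_only'.
    belief_weight_true_kappa : bool
        If True, No-Knowledge/Limited observers weight the likelihood against
        the prior with the *true* encoding precision instead of kappa*.
        Default False: kappa* governs everything the observer believes.
    """

    knowledge: str = "known"
    prior_use: str = "uniform_only"
    belief_weight_true_kappa: bool = False

    def __post_init__(self):
        if self.knowledge not in KNOWLEDGE_VARIANTS:
            raise ValueError(f"unknown knowledge variant {self.knowledge!r}")
        if self.prior_use not in PRIOR_USE_CODES:
            raise ValueError(f"unknown prior-use code {self.prior_use!r}")

    @property
    def uses_prior_nonlapse(self) -> bool:
        return self.prior_use in ("YY", "YN", "TT")

    @property
    def uses_prior_lapse(self) -> bool:
        return self.prior_use in ("YY", "NY", "TT")

    @property
    def kappa_w_fixed(self) -> Optional[float]:
        """Pinned believed-prior concentration, or None if free/absent."""
        if self.prior_use == "TT":
            return TRUE_PRIOR_KAPPA
        return None

    @property
    def label(self) -> str:
        return f"{self.knowledge}-{self.prior_use}"


@dataclass(frozen=True)
class ObserverParams:
    """All observer-model parameters; only those the ModelSpec needs are used.

    Attributes
    ----------
    gamma_mean, gamma_scale : float
        Mean and scale of the gamma distribution over encoding precision
        kappa (shape = mean/scale).  Variable-precision variants only.
    est_exponent : float
        Estimation-noise power p: estimates ~ posterior**p renormalized.
    softmax_temp : float
        Decision-noise temperature T of the softmax over expected utility
        (same units as utility, i.e. points**risk_alpha).
    risk_alpha : float
        Risk-attitude power applied to points.
    lapse_rate : float
        Probability lambda of a no-information (lapse) trial.
    kappa_fixed : float
        Assumed constant memory uncertainty (No-Knowledge, Limited).
    kappa_threshold : float
        Encoding-precision threshold below which the Limited observer
        represents uncertainty as kappa* = 0.
    kappa_w : float
        Believed prior concentration (free in YY/YN/NY; 1.422 in TT).
    kappa_const : float
        Single encoding precision of the fixed-precision variant.
    """

    gamma_mean: float = 8.0
    gamma_scale: float = 2.0
    est_exponent: float = 1.0
    softmax_temp: float = 5.0
    risk_alpha: float = 1.0
    lapse_rate: float = 0.03
    kappa_fixed: float = 8.0
    kappa_threshold: float = 2.0
    kappa_w: float = 1.0
    kappa_const: float = 8.0

    def validate(self, model: ModelSpec) -> None:
        if model.knowledge == "fixed_precision":
            if not self.kappa_const > 0:
                raise ValueError("kappa_const must be > 0")
        else:
            if not (self.gamma_mean > 0 and self.gamma_scale > 0):
                raise ValueError("gamma_mean and gamma_scale must be > 0")
        if not self.est_exponent > 0:
            raise ValueError("est_exponent must be > 0")
        if not self.softmax_temp > 0:
            raise ValueError("softmax_temp must be > 0")
        if not self.risk_alpha > 0:
            raise ValueError("risk_alpha must be > 0")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must be in [0, 1]")
        if model.knowledge in ("no_knowledge", "limited") and self.kappa_fixed < 0:
            raise ValueError("kappa_fixed must be >= 0")
        if model.knowledge == "limited" and self.kappa_threshold < 0:
            raise ValueError("kappa_threshold must be >= 0")
        if model.prior_use in ("YY", "YN", "NY") and self.kappa_w < 0:
            raise ValueError("kappa_w must be >= 0")

    def effective_kappa_w(self, model: ModelSpec) -> float:
        """Believed prior concentration under ``model`` (0 where unused)."""
        if model.kappa_w_fixed is not None:
            return model.kappa_w_fixed
        if model.prior_use in ("YY", "YN", "NY"):
            return self.kappa_w
        return 0.0

    def replace(self, **kwargs) -> "ObserverParams":
        return replace(self, **kwargs)


def _default_arc_values():
    return np.arange(0.0, 181.0, 1.0)


@dataclass(frozen=True)
class ArcGrid:
    """Uniform discretization of arc half-sizes over [0, 180] degrees."""

    step: float = 1.0
    values: np.ndarray = field(default_factory=_default_arc_values)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v[0] != 0.0 or v[-1] != 180.0 or not np.allclose(np.diff(v), self.step):
            raise ValueError("ArcGrid must span [0, 180] with uniform spacing")
        object.__setattr__(self, "values", v)

    @classmethod
    def with_step(cls, step: float) -> "ArcGrid":
        n = int(round(180.0 / step))
        if abs(n * step - 180.0) > 1e-9:
            raise ValueError("step must divide 180")
        return cls(step=step, values=np.linspace(0.0, 180.0, n + 1))

    @property
    def n(self) -> int:
        return len(self.values)

    def bin_index(self, arc):
        """Index of the grid value nearest to ``arc`` (degrees)."""
        idx = np.rint(np.asarray(arc, dtype=float) / self.step).astype(int)
        return np.clip(idx, 0, self.n - 1)


def points_fn(A):
    """Points earned by a hit with arc half-size ``A`` degrees: 100*(180-A)/180."""
    A = np.asarray(A, dtype=float)
    if np.any(A < 0) or np.any(A > 180):
        raise ValueError("arc size must be in [0, 180]")
    out = 100.0 * (180.0 - A) / 180.0
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Generative steps
# ---------------------------------------------------------------------------

def draw_encoding_precision(params: ObserverParams, model: ModelSpec, rng, size=None):
    """Trial encoding precision(s): gamma draw, or the constant for fixed precision."""
    if model.knowledge == "fixed_precision":
        if size is None:
            return params.kappa_const
        return np.full(size, params.kappa_const)
    shape = params.gamma_mean / params.gamma_scale
    return rng.gamma(shape, params.gamma_scale, size=size)


def encode(s, kappa, rng):
    """Noisy memory sample(s) m ~ VonMises(s, kappa); kappa = 0 gives uniform."""
    s = np.asarray(s, dtype=float)
    m = rng.vonmises(np.deg2rad(s), np.asarray(kappa, dtype=float))
    out = wrap_signed(np.rad2deg(m))
    return out


def memory_uncertainty(kappa, params: ObserverParams, model: ModelSpec):
    """Represented memory uncertainty kappa* for encoding precision ``kappa``."""
    kappa = np.asarray(kappa, dtype=float)
    if model.knowledge == "known":
        out = kappa.copy()
    elif model.knowledge == "no_knowledge":
        out = np.full_like(kappa, params.kappa_fixed)
    elif model.knowledge == "limited":
        out = np.where(kappa < params.kappa_threshold, 0.0, params.kappa_fixed)
    elif model.knowledge == "fixed_precision":
        out = np.full_like(kappa, params.kappa_const)
    else:  # pragma: no cover
        raise ValueError(model.knowledge)
    return float(out) if out.ndim == 0 else out


def belief_posterior(m, kappa_star, prior_belief: VonMises, model: ModelSpec = None) -> VonMises:
    """Posterior belief: VonMises(m, kappa*) combined with the believed prior."""
    return vm_product(VonMises(m, kappa_star), prior_belief)


def sample_estimate(posterior: VonMises, est_exponent, rng):
    """Noisy estimate: a draw from posterior**p renormalized, i.e. VM(mu, p*kappa)."""
    if est_exponent <= 0:
        raise ValueError("est_exponent must be > 0")
    draw = rng.vonmises(np.deg2rad(posterior.mu), est_exponent * posterior.kappa)
    return float(wrap_signed(np.rad2deg(draw)))


# ---------------------------------------------------------------------------
# Arc decision
# ---------------------------------------------------------------------------

# fine integration grid for interval masses: 0.0625 deg so that any ArcGrid
# with step a multiple of 0.0625 deg indexes it exactly
_FINE_PER_DEG = 16


def _mass_matrix(kappas, grid: ArcGrid, fine_per_deg: int = _FINE_PER_DEG):
    """p(hit | A) for each kappa (rows) and arc value (columns).

    Mass of VonMises(0, kappa) within +/- A, computed by an overflow-free
    normalized trapezoid rule on a 1/fine_per_deg-degree grid.
    """
    kappas = np.asarray(kappas, dtype=float)
    n_fine = 180 * fine_per_deg + 1
    theta = np.linspace(0.0, np.pi, n_fine)
    out = np.empty((len(kappas), grid.n))
    pos = grid.values * fine_per_deg
    idx = np.clip(np.floor(pos + 1e-9).astype(int), 0, n_fine - 1)
    exact = np.max(np.abs(pos - idx)) < 1e-6
    cos_term = np.cos(theta)
    chunk = max(1, int(2e7) // n_fine)
    for lo in range(0, len(kappas), chunk):
        kk = kappas[lo : lo + chunk, None]
        f = np.exp(kk * (cos_term - 1.0))
        cum = np.concatenate(
            [np.zeros((f.shape[0], 1)), np.cumsum((f[:, 1:] + f[:, :-1]) / 2.0, axis=1)],
            axis=1,
        )
        cum /= cum[:, -1:]
        if exact:
            out[lo : lo + chunk] = cum[:, idx]
        else:
            frac = pos - idx
            nxt = np.minimum(idx + 1, n_fine - 1)
            out[lo : lo + chunk] = cum[:, idx] + frac * (cum[:, nxt] - cum[:, idx])
    return out


def expected_utility_curve(posterior: VonMises, risk_alpha, grid: ArcGrid = None):
    """EU(A) = p(hit | A) * points(A)**alpha over the arc grid.

    Uses the tractability approximation that the observer integrates the
    posterior around its own mean, so EU depends only on the posterior width.
    """
    if grid is None:
        grid = ArcGrid()
    mass = vm_interval_mass(posterior, grid.values)
    return mass * points_fn(grid.values) ** risk_alpha


def arc_policy(eu, softmax_temp):
    """Softmax over expected utilities: p(A) proportional to exp(EU(A)/T)."""
    if softmax_temp <= 0:
        raise ValueError("softmax_temp must be > 0")
    logits = np.asarray(eu, dtype=float) / softmax_temp
    logits -= logits.max()
    p = np.exp(logits)
    return p / p.sum()


def log_arc_policy_matrix(kappa_post, params: ObserverParams, grid: ArcGrid,
                          fine_per_deg: int = _FINE_PER_DEG):
    """Log arc-choice probabilities for an array of posterior widths.

    Returns an (n_kappa, grid.n) matrix of log p(A | kappa_post); each row is
    the log-softmax of EU(A) = mass(A; kappa) * points(A)**alpha at
    temperature ``softmax_temp``.
    """
    kappa_post = np.atleast_1d(np.asarray(kappa_post, dtype=float))
    mass = _mass_matrix(kappa_post, grid, fine_per_deg)
    eu = mass * points_fn(grid.values) ** params.risk_alpha
    logits = eu / params.softmax_temp
    logits -= logits.max(axis=1, keepdims=True)
    return logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))


# ---------------------------------------------------------------------------
# Lapse process and trial simulation
# ---------------------------------------------------------------------------

def _believed_prior(model: ModelSpec, params: ObserverParams, condition: str,
                    prior_mean: float, lapse: bool) -> VonMises:
    """The believed stimulus prior entering a (non)lapse trial's computation."""
    if condition != "von_mises":
        return VonMises(0.0, 0.0)
    used = model.uses_prior_lapse if lapse else model.uses_prior_nonlapse
    if not used:
        return VonMises(0.0, 0.0)
    return VonMises(prior_mean, params.effective_kappa_w(model))


def lapse_branch(model: ModelSpec, params: ObserverParams, condition: str,
                 prior_mean: float = 0.0, grid: ArcGrid = None):
    """Estimate distribution and arc policy on a lapse (no-information) trial.

    Returns ``(est_dist, policy)`` where ``est_dist`` is the VonMises the
    estimate is sampled from (via :func:`sample_estimate`, i.e. with the
    estimation exponent applied) -- uniform when the prior is not used -- and
    ``policy`` is the arc-choice probability vector over ``grid``.
    """
    if grid is None:
        grid = ArcGrid()
    prior = _believed_prior(model, params, condition, prior_mean, lapse=True)
    eu = expected_utility_curve(prior, params.risk_alpha, grid)
    policy = arc_policy(eu, params.softmax_temp)
    return prior, policy


def simulate_trial(s, params: ObserverParams, model: ModelSpec, condition: str,
                   rng, prior_mean: float = 0.0, grid: ArcGrid = None):
    """Simulate one trial: returns ``(estimate, arc_size)`` in degrees.

    ``s`` is the probed stimulus color.  With probability ``lapse_rate`` the
    lapse branch runs; otherwise encoding precision, memory, represented
    uncertainty, posterior, estimate and arc are drawn in sequence.
    """
    if grid is None:
        grid = ArcGrid()
    params.validate(model)
    if rng.random() < params.lapse_rate:
        est_dist, policy = lapse_branch(model, params, condition, prior_mean, grid)
        estimate = sample_estimate(est_dist, params.est_exponent, rng)
        arc = float(grid.values[rng.choice(grid.n, p=policy)])
        return estimate, arc
    kappa = draw_encoding_precision(params, model, rng)
    m = encode(s, kappa, rng)
    kappa_star = memory_uncertainty(kappa, params, model)
    prior = _believed_prior(model, params, condition, prior_mean, lapse=False)
    posterior = belief_posterior(m, kappa_star, prior, model)
    est_posterior = (belief_posterior(m, kappa, prior, model)
                     if model.belief_weight_true_kappa else posterior)
    estimate = sample_estimate(est_posterior, params.est_exponent, rng)
    eu = expected_utility_curve(posterior, params.risk_alpha, grid)
    policy = arc_policy(eu, params.softmax_temp)
    arc = float(grid.values[rng.choice(grid.n, p=policy)])
    return estimate, arc


def _sample_arcs_from_kappas(kappa_post, params, grid, rng, max_exact=4096):
    """Vectorized arc draws for an array of posterior widths.

    Exact per unique width when few; otherwise widths are snapped to 2048
    empirical-quantile nodes (node-to-node policy differences are far below
    Monte-Carlo noise at any simulation size used here).
    """
    kappa_post = np.asarray(kappa_post, dtype=float)
    n = len(kappa_post)
    uniq, inv = np.unique(kappa_post, return_inverse=True)
    if len(uniq) > max_exact:
        qs = (np.arange(2048) + 0.5) / 2048
        nodes = np.unique(np.quantile(kappa_post, qs))
        inv = np.clip(np.searchsorted(nodes, kappa_post), 0, len(nodes) - 1)
        left = np.maximum(inv - 1, 0)
        pick_left = np.abs(kappa_post - nodes[left]) < np.abs(kappa_post - nodes[inv])
        inv = np.where(pick_left, left, inv)
        uniq = nodes
    # 0.25-degree hit-mass integration: ample next to Monte-Carlo noise
    logp = log_arc_policy_matrix(uniq, params, grid, fine_per_deg=4)
    cdf = np.cumsum(np.exp(logp), axis=1)
    u = rng.random(n)
    # group draws by policy row and invert each row's CDF once
    order = np.argsort(inv, kind="stable")
    counts = np.bincount(inv, minlength=len(uniq))
    idx = np.empty(n, dtype=int)
    start = 0
    for node in np.flatnonzero(counts):
        stop = start + counts[node]
        sel = order[start:stop]
        idx[sel] = np.searchsorted(cdf[node], u[sel], side="right")
        start = stop
    idx = np.minimum(idx, grid.n - 1)
    return grid.values[idx]


def simulate_responses(stimuli, params: ObserverParams, model: ModelSpec,
                       condition: str, rng, prior_mean: float = 0.0,
                       grid: ArcGrid = None):
    """Vectorized trial simulation: returns ``(estimates, arcs)`` arrays.

    Statistically identical to looping :func:`simulate_trial`; used for
    datasets and for large Monte-Carlo checks of the likelihood.
    """
    if grid is None:
        grid = ArcGrid()
    params.validate(model)
    s = np.atleast_1d(np.asarray(stimuli, dtype=float))
    n = len(s)
    estimates = np.empty(n)
    arcs = np.empty(n)
    lapse = rng.random(n) < params.lapse_rate

    # honour one rng stream: draw everything in a fixed order
    n_lapse = int(lapse.sum())
    n_norm = n - n_lapse

    if n_norm:
        kappa = np.asarray(draw_encoding_precision(params, model, rng, size=n_norm), dtype=float)
        m = encode(s[~lapse], kappa, rng)
        kstar = np.asarray(memory_uncertainty(kappa, params, model), dtype=float)
        prior = _believed_prior(model, params, condition, prior_mean, lapse=False)
        mu_rel = np.deg2rad(m - prior.mu)
        # estimates may weight the likelihood with the true precision while
        # the arc still reflects the believed uncertainty
        k_est = kappa if model.belief_weight_true_kappa else kstar
        c_e = k_est * np.cos(mu_rel) + prior.kappa
        s_e = k_est * np.sin(mu_rel)
        k_post_est = np.hypot(c_e, s_e)
        mu_post = prior.mu + np.rad2deg(np.arctan2(s_e, c_e))
        est = rng.vonmises(np.deg2rad(mu_post), params.est_exponent * k_post_est)
        estimates[~lapse] = wrap_signed(np.rad2deg(est))
        c = kstar * np.cos(mu_rel) + prior.kappa
        sn = kstar * np.sin(mu_rel)
        k_post = np.hypot(c, sn)
        arcs[~lapse] = _sample_arcs_from_kappas(k_post, params, grid, rng)

    if n_lapse:
        est_dist, policy = lapse_branch(model, params, condition, prior_mean, grid)
        est = rng.vonmises(np.deg2rad(est_dist.mu),
                           params.est_exponent * est_dist.kappa, size=n_lapse)
        estimates[lapse] = wrap_signed(np.rad2deg(est))
        arcs[lapse] = grid.values[rng.choice(grid.n, p=policy, size=n_lapse)]

    return estimates, arcs
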