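"""Circular arithmetic and von Mises machinery on the 360-degree color wheel.

All public interfaces speak degrees (responses live on a wheel of 360
equidistant colors); internal computation is done in radians for numerical
stability.  A concentration of exactly zero is a first-class value meaning
"uniform on the circle" -- no epsilon floor is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy.optimize import brentq

__all__ = [
    "VonMises",
    "wrap_signed",
    "wrap_unsigned",
    "vm_pdf",
    "vm_product",
    "vm_interval_mass",
    "kappa_to_circ_sd",
    "circ_sd_to_kappa",
    "circ_mean",
    "circ_sd_sample",
]

_DEG = np.pi / 180.0


def wrap_signed(x):
    """Wrap angle(s) in degrees to the signed interval (-180, 180].

    Parameters
    ----------
    x : float or array_like
        Angle(s) in degrees; must be finite.

    Returns
    -------
    float or ndarray
        ``x`` reduced modulo 360 into (-180, 180].
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("wrap_signed requires finite input")
    out = -np.mod(-x + 180.0, 360.0) + 180.0
    if out.ndim == 0:
        return float(out)
    return out


def wrap_unsigned(x):
    """Wrap angle(s) in degrees to [0, 360) -- the raw color-wheel convention."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("wrap_unsigned requires finite input")
    out = np.mod(x, 360.0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class VonMises:
    """Von Mises distribution on the color wheel.

    Parameters
    ----------
    mu : float
        Circular mean in degrees.
    kappa : float
        Concentration (dimensionless, >= 0).  ``kappa == 0`` is the uniform
        distribution with density 1/360 per degree.
    """

    mu: float
    kappa: float

    def __post_init__(self):
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if not (np.isfinite(self.kappa) and self.kappa >= 0):
            raise ValueError("kappa must be finite and >= 0")
        object.__setattr__(self, "mu", float(wrap_signed(self.mu)))
        object.__setattr__(self, "kappa", float(self.kappa))

    def pdf(self, theta):
        return vm_pdf(theta, self)


def _log_i0(kappa):
    # log I0(kappa) via the exponentially scaled Bessel function: stable for
    # arbitrarily large kappa.
    kappa = np.asarray(kappa, dtype=float)
    return np.log(special.i0e(kappa)) + kappa


def vm_pdf(theta, d: VonMises):
    """Von Mises density per *degree* at angle(s) ``theta`` (degrees).

    Normalized so that the numeric integral over any 360-degree window is 1.
    ``d.kappa == 0`` gives the uniform density 1/360.
    """
    if d.kappa < 0:
        raise ValueError("kappa must be >= 0")
    theta = np.asarray(theta, dtype=float)
    delta = (theta - d.mu) * _DEG
    logpdf = d.kappa * np.cos(delta) - _log_i0(d.kappa) - np.log(360.0)
    out = np.exp(logpdf)
    if out.ndim == 0:
        return float(out)
    return out


def vm_product(a: VonMises, b: VonMises) -> VonMises:
    """Product of two von Mises densities, renormalized (Bayes' rule).

    The product of two von Mises densities is again von Mises; the parameters
    follow the resultant-vector rule
    ``kappa_out * exp(i mu_out) = kappa_a * exp(i mu_a) + kappa_b * exp(i mu_b)``.
    A zero-concentration factor (uniform) leaves the other unchanged.
    """
    ca = a.kappa * np.cos(a.mu * _DEG) + b.kappa * np.cos(b.mu * _DEG)
    sa = a.kappa * np.sin(a.mu * _DEG) + b.kappa * np.sin(b.mu * _DEG)
    kappa = float(np.hypot(ca, sa))
    if kappa == 0.0:
        return VonMises(0.0, 0.0)
    mu = float(np.arctan2(sa, ca) / _DEG)
    return VonMises(mu, kappa)


def _interval_mass_kappa(kappa, half_width_deg, n_grid=2881):
    """Mass of VonMises(0, kappa) within +/- half_width (vectorized over both).

    Uses a normalized trapezoid integral of exp(kappa*(cos t - 1)), which is
    overflow-free for any kappa.
    """
    kappa = np.atleast_1d(np.asarray(kappa, dtype=float))
    hw = np.atleast_1d(np.asarray(half_width_deg, dtype=float))
    theta = np.linspace(0.0, np.pi, n_grid)
    f = np.exp(kappa[:, None] * (np.cos(theta)[None, :] - 1.0))
    cum = np.concatenate(
        [np.zeros((len(kappa), 1)), np.cumsum((f[:, 1:] + f[:, :-1]) / 2.0, axis=1)],
        axis=1,
    )
    total = cum[:, -1]
    # interpolate the cumulative at hw for each kappa row
    pos = hw * _DEG / (np.pi / (n_grid - 1))
    idx = np.clip(np.floor(pos).astype(int), 0, n_grid - 2)
    frac = pos - idx
    if cum.shape[0] == 1:
        c = cum[0, idx] + frac * (cum[0, idx + 1] - cum[0, idx])
        return c / total[0]
    # kappa and hw broadcast elementwise when both are arrays of equal length
    rows = np.arange(cum.shape[0])
    c = cum[rows, idx] + frac * (cum[rows, idx + 1] - cum[rows, idx])
    return c / total


def vm_interval_mass(d: VonMises, half_width):
    """Probability mass of ``d`` within +/- ``half_width`` degrees of its mean.

    ``half_width`` must lie in [0, 180].  Monotone nondecreasing in
    ``half_width``; equals ``half_width/180`` for the uniform case.
    """
    hw = np.asarray(half_width, dtype=float)
    if np.any(hw < 0) or np.any(hw > 180):
        raise ValueError("half_width must be in [0, 180]")
    if d.kappa == 0.0:
        out = hw / 180.0
        return float(out) if out.ndim == 0 else out
    out = _interval_mass_kappa(d.kappa, np.atleast_1d(hw))
    if np.ndim(half_width) == 0:
        return float(out[0])
    return out.reshape(np.shape(half_width))


def _bessel_ratio(kappa):
    """I1(kappa)/I0(kappa), stable for large kappa via scaled Bessels."""
    kappa = np.asarray(kappa, dtype=float)
    return special.i1e(kappa) / special.i0e(kappa)


def kappa_to_circ_sd(kappa):
    """Circular standard deviation (degrees) of a von Mises with concentration kappa.

    sd = sqrt(-2 ln R) with mean resultant length R = I1(kappa)/I0(kappa),
    converted from radians to degrees.  kappa -> inf gives sd -> 0; kappa = 0
    gives +inf (vanishing resultant).
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be >= 0")
    r = _bessel_ratio(kappa)
    with np.errstate(divide="ignore"):
        sd = np.sqrt(-2.0 * np.log(r)) / _DEG
    if sd.ndim == 0:
        return float(sd)
    return sd


def circ_sd_to_kappa(sd, tol=1e-12):
    """Inverse of :func:`kappa_to_circ_sd`, solved numerically.

    Parameters
    ----------
    sd : float
        Circular SD in degrees, > 0.

    Raises
    ------
    ValueError
        If ``sd`` is out of range or the bracketing/rootfinding fails.
    """
    sd = float(sd)
    if not (np.isfinite(sd) and sd > 0):
        raise ValueError("sd must be finite and > 0")

    def f(k):
        return kappa_to_circ_sd(k) - sd

    lo, hi = 1e-10, 1.0
    while f(hi) > 0:
        hi *= 10.0
        if hi > 1e12:
            raise ValueError(f"circ_sd_to_kappa failed to bracket sd={sd}")
    if f(lo) < 0:  # sd larger than achievable at kappa -> 0: no solution
        raise ValueError(f"circ_sd_to_kappa: no kappa >= 0 attains sd={sd}")
    return float(brentq(f, lo, hi, xtol=tol, rtol=8.9e-16))


def circ_mean(angles_deg, weights=None):
    """Circular mean (degrees, signed convention) of a sample of angles."""
    a = np.asarray(angles_deg, dtype=float) * _DEG
    if weights is None:
        c, s = np.mean(np.cos(a)), np.mean(np.sin(a))
    else:
        w = np.asarray(weights, dtype=float)
        c, s = np.sum(w * np.cos(a)) / np.sum(w), np.sum(w * np.sin(a)) / np.sum(w)
    return float(np.arctan2(s, c) / _DEG)


def circ_sd_sample(angles_deg):
    """Sample circular standard deviation in degrees: sqrt(-2 ln R)."""
    a = np.asarray(angles_deg, dtype=float) * _DEG
    r = np.hypot(np.mean(np.cos(a)), np.mean(np.sin(a)))
    if r <= 0:
        return float("inf")
    return float(np.sqrt(-2.0 * np.log(r)) / _DEG)
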