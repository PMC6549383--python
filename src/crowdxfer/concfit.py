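"""Concentration dependence of the soft-attraction component, and
perturbed-virial-expansion utilities.

The soft-attraction component dmu_sa(phi) is fitted to a polynomial through
the origin, dmu_sa = a phi + b phi^2 (+ c phi^3), optionally holding out the
last concentration to test extrapolation. The near-linearity of dmu_sa is
rationalized by a perturbed virial expansion with a hard-sphere reference:

    mu_ex = mu_ref_ex + kT sum_{l>=2} [l/(l-1)] dB_l rho^{l-1}

where dB_l are residual virial coefficients (real minus reference). B2 is a
one-dimensional Mayer-function quadrature; B3 is estimated by Mayer-sampling
Monte Carlo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import integrate


@dataclass(frozen=True)
class PhiSeries:
    """dmu_sa values (kcal/mol) at increasing crowder volume fractions."""

    phi: np.ndarray
    dmu_sa: np.ndarray
    errors: np.ndarray | None = None

    def __post_init__(self):
        phi = np.asarray(self.phi, dtype=float)
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "dmu_sa", np.asarray(self.dmu_sa, dtype=float))
        if self.errors is not None:
            object.__setattr__(self, "errors", np.asarray(self.errors, dtype=float))
        if np.any(np.diff(phi) <= 0) or np.any(phi < 0) or np.any(phi >= 1):
            raise ValueError("phi must be strictly increasing in [0, 1)")


@dataclass
class PolyFit:
    """Polynomial fit through the origin: coefficients for phi, phi^2
    (and phi^3 for a cubic), with covariance."""

    coeffs: np.ndarray
    cov: np.ndarray
    order: int
    prediction: float | None = None   # held-out point prediction
    z_score: float | None = None

    @property
    def a(self) -> float:
        return float(self.coeffs[0])

    @property
    def b(self) -> float:
        return float(self.coeffs[1])

    def __call__(self, phi):
        phi = np.asarray(phi, dtype=float)
        return sum(c * phi ** (k + 1) for k, c in enumerate(self.coeffs))


def fit_phi(series: PhiSeries, order: int = 2,
            holdout_last: bool = False) -> PolyFit:
    """Weighted least squares of dmu_sa against (phi, phi^2[, phi^3]) with
    zero intercept.

    Inverse-variance weights are used when the series carries errors. With
    ``holdout_last`` the last point is excluded from the fit and its
    extrapolated prediction and z-score (prediction minus observation over
    combined uncertainty) are attached to the result.
    """
    if order not in (2, 3):
        raise ValueError("order must be 2 or 3")
    phi, y = series.phi, series.dmu_sa
    err = series.errors
    n_fit = len(phi) - (1 if holdout_last else 0)
    if n_fit < order + 1:
        raise ValueError(f"need >= {order + 1} points, have {n_fit}")
    X = np.column_stack([phi[:n_fit] ** (k + 1) for k in range(order)])
    yy = y[:n_fit]
    if err is not None:
        w = 1.0 / err[:n_fit] ** 2
        sw = np.sqrt(w)
        coeffs, *_ = np.linalg.lstsq(X * sw[:, None], yy * sw, rcond=None)
        xtwx = X.T @ (X * w[:, None])
        cov = np.linalg.inv(xtwx)
    else:
        coeffs, *_ = np.linalg.lstsq(X, yy, rcond=None)
        resid = yy - X @ coeffs
        dof = max(n_fit - order, 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(X.T @ X)
    fit = PolyFit(coeffs, cov, order)
    if holdout_last:
        xs = np.array([phi[-1] ** (k + 1) for k in range(order)])
        pred = float(xs @ coeffs)
        var_pred = float(xs @ cov @ xs)
        var_obs = float(err[-1] ** 2) if err is not None else 0.0
        denom = math.sqrt(var_pred + var_obs)
        fit.prediction = pred
        fit.z_score = (pred - float(y[-1])) / denom if denom > 0 else math.inf
    return fit


def linearity_report(fit: PolyFit, phi_eval: float) -> float:
    """|b phi^2| / |a phi| at ``phi_eval``; inf when the linear term
    vanishes."""
    if fit.order < 2:
        raise ValueError("fit must have order >= 2")
    lin = abs(fit.a * phi_eval)
    quad = abs(fit.b * phi_eval ** 2)
    if lin == 0.0:
        return math.inf if quad > 0 else 0.0
    return quad / lin


# ---------------------------------------------------------------------------
# virial machinery


def lj_potential(r, eps, sigma):
    sr6 = (sigma / np.asarray(r, dtype=float)) ** 6
    return 4.0 * eps * (sr6 ** 2 - sr6)


def mayer_b2(u, kbt: float, r_max: float, points=None) -> float:
    """Second virial coefficient -2 pi int (e^{-u(r)/kT} - 1) r^2 dr for an
    arbitrary pair potential ``u`` by adaptive quadrature; ``points`` marks
    discontinuities (e.g. a hard-sphere diameter)."""

    def integrand(r):
        return (math.exp(-u(r) / kbt) - 1.0) * r * r

    val, _ = integrate.quad(integrand, 0.0, r_max, points=points, limit=400)
    return -2.0 * math.pi * val


def lj_b2(eps: float, sigma: float, kbt: float, r_max_factor: float = 10.0) -> float:
    """Second virial coefficient of a Lennard-Jones fluid by adaptive
    quadrature of the Mayer function, with an analytic r^-6 tail correction
    beyond the cutoff."""
    if eps < 0 or sigma <= 0:
        raise ValueError("eps >= 0 and sigma > 0 required")
    rc = r_max_factor * sigma

    def integrand(r):
        return (math.exp(-lj_potential(r, eps, sigma) / kbt) - 1.0) * r * r

    val = 0.0
    for a, b in ((1e-8, 0.8 * sigma), (0.8 * sigma, 2.5 * sigma),
                 (2.5 * sigma, rc)):
        part, _ = integrate.quad(integrand, a, b, limit=200)
        val += part
    # tail: f ~ -u/kT = 4 eps sigma^6 / (kT r^6)
    tail = 4.0 * eps * sigma ** 6 / (kbt * 3.0 * rc ** 3)
    return -2.0 * math.pi * (val + tail)


def hclj_b2(eps: float, sigma: float, kbt: float,
            r_max_factor: float = 10.0) -> float:
    """B2 of a hard-core Lennard-Jones fluid: impenetrable below sigma, the
    12-6 tail beyond (the same shape as the insertion engine's hard-core +
    LJ potential). As eps -> 0 this reduces exactly to the hard-sphere B2
    of diameter sigma, so residual coefficients against that reference
    vanish with the attraction."""
    if eps < 0 or sigma <= 0:
        raise ValueError("eps >= 0 and sigma > 0 required")
    rc = r_max_factor * sigma

    def integrand(r):
        return (math.exp(-lj_potential(r, eps, sigma) / kbt) - 1.0) * r * r

    val, _ = integrate.quad(integrand, sigma, rc, limit=200)
    tail = 4.0 * eps * sigma ** 6 / (kbt * 3.0 * rc ** 3)
    return hs_b2(sigma) - 2.0 * math.pi * (val + tail)


def hs_b2(d: float) -> float:
    """Hard-sphere second virial coefficient, 2 pi d^3 / 3."""
    return 2.0 * math.pi * d ** 3 / 3.0


def hs_b3(d: float) -> float:
    """Hard-sphere third virial coefficient, 5 pi^2 d^6 / 18."""
    return 5.0 * math.pi ** 2 * d ** 6 / 18.0


@njit(cache=False)
def _mayer_f(r, eps, sigma, kbt, hard_d):
    if hard_d > 0.0 and r < hard_d:
        return -1.0
    if eps == 0.0:
        return 0.0
    if r < 1e-10:
        return -1.0
    sr6 = (sigma / r) ** 6
    arg = -4.0 * eps * (sr6 * sr6 - sr6) / kbt
    if arg < -500.0:
        return -1.0  # deep overlap: effectively hard core
    return math.exp(arg) - 1.0


@njit(cache=False)
def _mayer_b3_kernel(eps, sigma, kbt, rcut, n_samples, seed, hard_d):
    """Mayer-sampling estimate of -(1/3) iint f12 f13 f23 dr2 dr3.

    The positions of particles 2 and 3 relative to particle 1 are drawn
    with radial density proportional to |f(r)| r^2 (isotropic directions),
    which cancels the |f12 f13| magnitudes from the integrand and leaves
    only sign(f12) sign(f13) f23 (4 pi W)^2 per sample — a low-variance
    estimator compared with uniform sampling in a ball."""
    np.random.seed(seed)
    # tabulate the radial weight and its cumulative on [0, rcut]
    m = 4000
    dr = rcut / m
    cdf = np.empty(m)
    total = 0.0
    for i in range(m):
        r = (i + 0.5) * dr
        total += abs(_mayer_f(r, eps, sigma, kbt, hard_d)) * r * r * dr
        cdf[i] = total
    w_norm = total
    if w_norm <= 0.0:
        return 0.0
    for i in range(m):
        cdf[i] /= w_norm
    acc = 0.0
    for _ in range(n_samples):
        # radii by inverse-CDF lookup, directions isotropic
        r12 = (np.searchsorted(cdf, np.random.random()) + 0.5) * dr
        r13 = (np.searchsorted(cdf, np.random.random()) + 0.5) * dr
        # random relative angle between the two directions
        cos_t = 2.0 * np.random.random() - 1.0
        r23sq = r12 * r12 + r13 * r13 - 2.0 * r12 * r13 * cos_t
        r23 = r23sq ** 0.5 if r23sq > 0.0 else 0.0
        f12 = _mayer_f(r12, eps, sigma, kbt, hard_d)
        f13 = _mayer_f(r13, eps, sigma, kbt, hard_d)
        f23 = _mayer_f(r23, eps, sigma, kbt, hard_d)
        s12 = 1.0 if f12 > 0 else (-1.0 if f12 < 0 else 0.0)
        s13 = 1.0 if f13 > 0 else (-1.0 if f13 < 0 else 0.0)
        acc += s12 * s13 * f23
    pref = (4.0 * math.pi * w_norm) ** 2
    return -pref * acc / (3.0 * n_samples)


def mayer_b3(eps: float, sigma: float, kbt: float, n_samples: int = 1_000_000,
             seed: int = 0, rcut_factor: float = 3.0,
             hard_core: bool = False) -> float:
    """Third virial coefficient of a (hard-core) Lennard-Jones fluid by
    Mayer-sampling Monte Carlo (uniform sampling in a ball of radius
    ``rcut_factor*sigma``; the Mayer function is negligible beyond).
    ``hard_core`` makes the potential impenetrable below sigma, matching
    :func:`hclj_b2`."""
    return float(_mayer_b3_kernel(eps, sigma, kbt, rcut_factor * sigma,
                                  n_samples, seed % 2 ** 31,
                                  sigma if hard_core else -1.0))


def mayer_b3_hs(d: float, n_samples: int = 1_000_000, seed: int = 0) -> float:
    """Hard-sphere B3 by the same Mayer-sampling estimator (cross-check
    against the 5 pi^2 d^6/18 closed form)."""
    return float(_mayer_b3_kernel(0.0, d, 1.0, 2.0 * d, n_samples,
                                  seed % 2 ** 31, d))


def perturbed_mu_ex(rho: float, delta_b, kbt: float = 1.0):
    """Per-order contributions kT [l/(l-1)] dB_l rho^{l-1} of the perturbed
    virial expansion; ``delta_b`` lists residual coefficients starting at
    l = 2. Returns (total, list of per-order terms)."""
    terms = []
    for i, db in enumerate(delta_b):
        l = i + 2
        terms.append(kbt * (l / (l - 1.0)) * db * rho ** (l - 1))
    return sum(terms), terms
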