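"""Generalized fundamental measure theory (GFMT) for the excluded-volume
component of the transfer free energy.

The crowders are modeled as hard spheres of radius R_c at number density
rho_c; the test molecule enters through three shape measures: volume v_p,
surface area s_p and integrated mean curvature l_p (obtained by probing the
atomistic structure with a sphere of radius R_c, see
:func:`crowdxfer.structures.parallel_body_measures`). The excluded-volume
component is

    dmu_ev = Pi_c v_p + gamma_c s_p + kappa_c l_p - kT ln(1 - phi)

with the crowder-fluid osmotic pressure Pi_c, surface tension gamma_c and
bending rigidity kappa_c given by scaled-particle-theory closed forms in
phi = V_c rho_c, rho_R = R_c rho_c and rho_S = S_c rho_c:

    Pi_c/kT    = rho_c/(1-phi) + rho_R rho_S/(1-phi)^2 + rho_S^3/(12 pi (1-phi)^3)
    gamma_c/kT = rho_R/(1-phi) + rho_S^2/(8 pi (1-phi)^2)
    kappa_c/kT = rho_S/(1-phi)

R_c is the single free parameter when fitting measured dmu_ev data;
:func:`fit_rc` recomputes the probe-dependent shape measures for each
candidate radius.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .structures import Molecule, ShapeMeasures, parallel_body_measures


@dataclass(frozen=True)
class CrowderSphere:
    """Spherical crowder descriptor; area and volume derive from R_c."""

    r_c: float

    @property
    def s_c(self) -> float:
        return 4.0 * math.pi * self.r_c ** 2

    @property
    def v_c(self) -> float:
        return (4.0 / 3.0) * math.pi * self.r_c ** 3


@dataclass(frozen=True)
class CrowderState:
    """A crowder fluid: sphere descriptor plus number density (Å^-3)."""

    sphere: CrowderSphere
    rho_c: float

    @property
    def phi(self) -> float:
        return self.sphere.v_c * self.rho_c

    @property
    def rho_r(self) -> float:
        return self.sphere.r_c * self.rho_c

    @property
    def rho_s(self) -> float:
        return self.sphere.s_c * self.rho_c

    @classmethod
    def from_phi(cls, r_c: float, phi: float) -> "CrowderState":
        s = CrowderSphere(r_c)
        return cls(s, phi / s.v_c)


@dataclass(frozen=True)
class GFMTThermo:
    """Osmotic pressure (kcal/mol/Å^3), surface tension (kcal/mol/Å^2) and
    bending rigidity (kcal/mol/Å) of the crowder fluid."""

    pi_c: float
    gamma_c: float
    kappa_c: float


def gfmt_thermo(state: CrowderState, kbt: float) -> GFMTThermo:
    """Scaled-particle closed forms for the crowder-fluid thermodynamics."""
    phi = state.phi
    if phi >= 1.0:
        raise ValueError(f"volume fraction {phi} >= 1")
    om = 1.0 - phi
    pi_c = kbt * (state.rho_c / om
                  + state.rho_r * state.rho_s / om ** 2
                  + state.rho_s ** 3 / (12.0 * math.pi * om ** 3))
    gamma_c = kbt * (state.rho_r / om
                     + state.rho_s ** 2 / (8.0 * math.pi * om ** 2))
    kappa_c = kbt * state.rho_s / om
    return GFMTThermo(pi_c, gamma_c, kappa_c)


def gfmt_mu_ev(shape: ShapeMeasures, state: CrowderState, kbt: float) -> float:
    """Excluded-volume transfer free energy (kcal/mol) of a test molecule
    with the given shape measures in the crowder fluid."""
    th = gfmt_thermo(state, kbt)
    return (th.pi_c * shape.v_p + th.gamma_c * shape.s_p
            + th.kappa_c * shape.l_p - kbt * math.log(1.0 - state.phi))


# ---------------------------------------------------------------------------
# R_c fitting


class _ShapeCache:
    def __init__(self, grid_spacing):
        self.grid_spacing = grid_spacing
        self._cache = {}

    def get(self, mol: Molecule, r_c: float) -> ShapeMeasures:
        key = (id(mol), round(r_c, 4))
        if key not in self._cache:
            self._cache[key] = parallel_body_measures(
                mol, r_c, grid_spacing=self.grid_spacing)
        return self._cache[key]


def _golden_section(f, lo, hi, tol):
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


@dataclass
class RcFit:
    """Result of the global crowder-radius fit."""

    r_c: float
    sse: float
    residuals: dict          # (molecule name, row index) -> residual kcal/mol
    multi_minimum: bool
    scan: list               # (r_c, sse) pairs from the coarse scan


def fit_rc(dataset, molecules: dict, kbt: float,
           bracket=(2.0, 50.0), scan_points: int = 33,
           refine_tol: float = 0.01, grid_spacing: float = 0.5,
           weights: str = "none") -> RcFit:
    """Fit the single crowder radius R_c to measured dmu_ev data.

    Parameters
    ----------
    dataset : iterable of (molecule_id, rho_c_or_phi, is_phi, dmu_ev[, err])
        rows; ``is_phi`` selects whether the density column is a volume
        fraction (phi depends on the candidate R_c when a number density is
        given).
    molecules : mapping molecule_id -> Molecule.
    bracket : (lo, hi) search interval for R_c in Å.
    weights : "none" for unweighted least squares, "inverse-variance" to
        weight rows by 1/err^2.

    The objective (sum of squared residuals over all molecules and
    densities, shape measures recomputed per candidate R_c) is scanned on a
    coarse grid over the bracket, then refined by golden section to
    ``refine_tol`` Å. A warning flag is set when the coarse scan shows more
    than one local minimum.
    """
    rows = [tuple(r) for r in dataset]
    if not rows:
        raise ValueError("empty dataset")
    under_determined = len({r[0] for r in rows}) < 2 and len(rows) < 3
    cache = _ShapeCache(grid_spacing)

    def sse(r_c):
        total = 0.0
        for row in rows:
            mol_id, dens, is_phi, dmu = row[:4]
            err = row[4] if len(row) > 4 else None
            state = CrowderState.from_phi(r_c, dens) if is_phi \
                else CrowderState(CrowderSphere(r_c), dens)
            pred = gfmt_mu_ev(cache.get(molecules[mol_id], r_c), state, kbt)
            w = 1.0
            if weights == "inverse-variance" and err:
                w = 1.0 / err ** 2
            total += w * (pred - dmu) ** 2
        return total

    grid = np.linspace(bracket[0], bracket[1], scan_points)
    vals = np.array([sse(r) for r in grid])
    # count interior local minima on the coarse scan
    interior = (vals[1:-1] < vals[:-2]) & (vals[1:-1] <= vals[2:])
    n_min = int(interior.sum()) + int(vals[0] < vals[1]) + int(vals[-1] < vals[-2])
    multi = n_min > 1 or under_determined
    if multi:
        warnings.warn("R_c objective has multiple minima or is "
                      "under-determined; reporting global scan minimum")
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    best = _golden_section(sse, lo, hi, refine_tol) if hi > lo else grid[i]
    residuals = {}
    for k, row in enumerate(rows):
        mol_id, dens, is_phi, dmu = row[:4]
        state = CrowderState.from_phi(best, dens) if is_phi \
            else CrowderState(CrowderSphere(best), dens)
        pred = gfmt_mu_ev(cache.get(molecules[mol_id], best), state, kbt)
        residuals[(mol_id, k)] = pred - dmu
    return RcFit(float(best), float(sse(best)), residuals, multi,
                 list(zip(grid.tolist(), vals.tolist())))
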