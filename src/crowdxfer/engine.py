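"""FFT-accelerated Widom insertion of a rigid test molecule into a crowded
periodic box.

For one test-molecule orientation and one crowder configuration, the
Boltzmann factor of the test-crowder interaction energy is needed at every
point of a cubic grid spanning the box. The interaction is a sum of
pairwise terms

    U_int = U_st + U_na + U_elec,

with a hard-core clash whenever an interatomic distance falls below the sum
of the two hard-core radii, a 12-6 Lennard-Jones attraction
``A_ij/r^12 - B_ij/r^6`` and a Debye-Hückel screened Coulomb term
``332.06 q_i q_j exp(-r/lambda) / (kappa r)`` (kcal/mol with r in Å).

Because every pairwise term depends only on the displacement between a test
atom and a crowder atom, each grid map is a circular cross-correlation of a
test-atom field with a crowder field convolved with a radial kernel, and is
evaluated with FFTs:

* clash counting: per-atom radii are quantized into 0.1 Å bins; for each
  (test bin, crowder bin) pair the number of sub-contact pairs is a
  correlation of a test count map with a crowder count map convolved with a
  hard-ball indicator kernel. A grid point is clash-free iff the total
  count is zero.
* soft energy: pair coefficients factorize geometrically,
  A_ij = sqrt(A_ii A_jj) and B_ij = sqrt(B_ii B_jj), so each power-law sum
  is one correlation of sqrt-coefficient-weighted fields with an r^-12 or
  r^-6 kernel; the electrostatic term factorizes exactly through charges.

Kernels are clamped below the smallest possible hard-core contact distance;
clamped values never contribute because those grid points are clashed. Atom
positions are snapped to the nearest grid node (no spreading), which makes
the FFT maps exactly equal (to FFT round-off) to a direct double sum over
snapped coordinates — the oracle in :func:`direct_insertion_maps`.

The per-sample Boltzmann average factorizes exactly as

    <e^{-U_int/kT}>_R = <e^{-U_st/kT}>_R x <e^{-u_soft/kT}>_1

where <...>_R runs over all grid points (clash-free fraction for the steric
factor) and <...>_1 over clash-free points only. Aggregation over
orientations and configurations averages the Boltzmann factors sample-wise
and converts to free energies; samples without a single clash-free point
are handled by the -kT ln(n_ok/n_total) correction applied to the total and
excluded-volume components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from . import errors as error_stats
from .constants import COULOMB_KCAL, debye_length, kbt
from .crowder_box import CrowderConfiguration
from .structures import Molecule, random_orientation

RADIUS_BIN = 0.1  # Å; hard-core radius quantization for the clash maps


def smooth_size(n: int) -> int:
    """Smallest 5-smooth integer >= n (FFT-friendly grid dimension)."""
    m = n
    while True:
        k = m
        for p in (2, 3, 5):
            while k % p == 0:
                k //= p
        if k == 1:
            return m
        m += 1


@dataclass(frozen=True)
class GridSpec:
    """Cubic periodic grid over the crowder box."""

    box_side: float
    n_points: int

    @property
    def spacing(self) -> float:
        return self.box_side / self.n_points

    @property
    def n_total(self) -> int:
        return self.n_points ** 3

    @classmethod
    def from_spacing(cls, box_side: float, max_spacing: float = 0.6) -> "GridSpec":
        n = smooth_size(int(math.ceil(box_side / max_spacing)))
        return cls(box_side, n)


@dataclass(frozen=True)
class PotentialParams:
    """Interaction-potential parameters.

    Defaults follow the standard protein-crowder setup: 298 K, solvent
    dielectric 78.4, ionic strength 0.15 M, non-polar scale 0.2, electrostatic
    scale 2.0. The Debye length is computed from the ionic strength unless
    given explicitly.
    """

    temperature: float = 298.0
    dielectric: float = 78.4
    ionic_strength: float = 0.15
    scale_nonpolar: float = 0.2
    scale_elec: float = 2.0
    debye: float | None = None

    @property
    def kbt(self) -> float:
        return kbt(self.temperature)

    @property
    def debye_length(self) -> float:
        if self.debye is not None:
            return self.debye
        return debye_length(self.ionic_strength, self.temperature,
                            self.dielectric)


@dataclass
class InsertionMaps:
    """Per-grid-point clash indicator and soft energy for one sample."""

    clash_free: np.ndarray  # bool, (n, n, n)
    u_soft: np.ndarray      # kcal/mol, zero at clashed points
    n_total: int
    n_free: int

    @property
    def clash_free_fraction(self) -> float:
        return self.n_free / self.n_total


@dataclass(frozen=True)
class SampleAverages:
    """Boltzmann-factor averages for one (orientation, configuration)."""

    bf_int: float    # <e^{-U_int/kT}>_R over all grid points
    bf_st: float     # clash-free fraction
    bf_soft: float   # <e^{-u_soft/kT}>_1 over clash-free points (nan if none)
    fully_clashed: bool


@dataclass
class TransferFreeEnergyResult:
    """Transfer free energy and its decomposition, kcal/mol."""

    dmu: float
    dmu_ev: float
    dmu_sa: float
    err_dmu: float
    err_dmu_ev: float
    err_dmu_sa: float
    correction: float
    n_samples: int
    n_fully_clashed: int
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# kernels and fields


def _bin_radius(r: np.ndarray) -> np.ndarray:
    return np.rint(np.asarray(r) / RADIUS_BIN).astype(np.int64)


def _minimage_r(grid: GridSpec) -> np.ndarray:
    # integer squared lattice distances scaled once: bit-identical to the
    # direct-sum oracle's h * sqrt(di^2 + dj^2 + dk^2)
    n, h = grid.n_points, grid.spacing
    i = np.arange(n, dtype=np.int64)
    d = np.minimum(i, n - i)
    m2 = (d[:, None, None] ** 2 + d[None, :, None] ** 2
          + d[None, None, :] ** 2).astype(float)
    return h * np.sqrt(m2)


def _snap(coords: np.ndarray, grid: GridSpec) -> np.ndarray:
    return np.rint(coords / grid.spacing).astype(np.int64) % grid.n_points


def _delta_map(idx: np.ndarray, weights, grid: GridSpec) -> np.ndarray:
    m = np.zeros((grid.n_points,) * 3)
    np.add.at(m, (idx[:, 0], idx[:, 1], idx[:, 2]), weights)
    return m


def _kernel_lj(r: np.ndarray, power: int, r_clamp: float) -> np.ndarray:
    rc = max(r_clamp, 1e-6)
    rr = np.maximum(r, rc)
    return rr ** (-power)


def _kernel_debye(r: np.ndarray, lam: float, r_clamp: float) -> np.ndarray:
    rc = max(r_clamp, 1e-6)
    rr = np.maximum(r, rc)
    return np.exp(-rr / lam) / rr


class CrowderFields:
    """Per-configuration FFT fields, reusable across test orientations.

    The clash kernels depend on the test molecule's radius bins, so the
    cache is keyed by the set of test bins (identical across orientations
    of one test molecule).
    """

    def __init__(self, cfg: CrowderConfiguration, grid: GridSpec,
                 params: PotentialParams, test: Molecule):
        if abs(cfg.box_side - grid.box_side) > 1e-9:
            raise ValueError("grid box side must match configuration")
        self.cfg = cfg
        self.grid = grid
        self.params = params
        coords, radii, lj_a, lj_b, charges = cfg.atoms_flat()
        idx = _snap(coords, grid)
        self.crowder_bins = np.unique(_bin_radius(radii))
        self.test_bins = np.unique(_bin_radius(test.radii))
        # smallest possible contact distance -> kernel clamp radius
        self.r_clamp = (self.test_bins.min() + self.crowder_bins.min()) * RADIUS_BIN
        r = _minimage_r(grid)
        fft = np.fft.rfftn
        cbins = _bin_radius(radii)
        # clash: F[C_c] * F[ball_{t,c}] accumulated per test bin
        self.clash_factors = {}
        for tb in self.test_bins:
            acc = None
            for cb in self.crowder_bins:
                d_contact = (tb + cb) * RADIUS_BIN
                ball = fft((r < d_contact).astype(float))
                cmap = fft(_delta_map(idx[cbins == cb],
                                      np.ones(int((cbins == cb).sum())), grid))
                term = cmap * ball
                acc = term if acc is None else acc + term
            self.clash_factors[int(tb)] = acc
        # soft terms
        self.f_a = fft(_delta_map(idx, np.sqrt(lj_a), grid)) \
            * fft(_kernel_lj(r, 12, self.r_clamp))
        self.f_b = fft(_delta_map(idx, np.sqrt(lj_b), grid)) \
            * fft(_kernel_lj(r, 6, self.r_clamp))
        if np.any(charges != 0.0):
            self.f_q = fft(_delta_map(idx, charges, grid)) \
                * fft(_kernel_debye(r, params.debye_length, self.r_clamp))
        else:
            self.f_q = None


def build_insertion_maps(test_oriented: Molecule, cfg, grid: GridSpec,
                         params: PotentialParams | None = None,
                         soft_terms=("nonpolar", "electrostatic"),
                         fields: CrowderFields | None = None) -> InsertionMaps:
    """Clash indicator and soft-energy maps over all grid positions.

    ``test_oriented`` is used with coordinates relative to its centroid.
    ``fields`` may carry precomputed per-configuration FFTs; otherwise they
    are built here.
    """
    params = params or PotentialParams()
    n = grid.n_points
    if cfg.n_crowders == 0:
        return InsertionMaps(np.ones((n,) * 3, dtype=bool),
                             np.zeros((n,) * 3), n ** 3, n ** 3)
    if fields is None:
        fields = CrowderFields(cfg, grid, params, test_oriented)
    shape = (n,) * 3
    fft, ifft = np.fft.rfftn, np.fft.irfftn
    t = test_oriented
    rel = t.coords - t.centroid
    idx = _snap(rel, grid)
    tbins = _bin_radius(t.radii)
    # clash counts
    acc = None
    for tb in np.unique(tbins):
        sel = tbins == tb
        tmap = fft(_delta_map(idx[sel], np.ones(int(sel.sum())), grid))
        term = np.conj(tmap) * fields.clash_factors[int(tb)]
        acc = term if acc is None else acc + term
    counts = ifft(acc, s=shape, axes=(0, 1, 2))
    clash_free = counts < 0.5
    # soft energy
    e_f = np.zeros_like(acc)
    if "nonpolar" in soft_terms:
        fa = fft(_delta_map(idx, np.sqrt(t.lj_a), grid))
        fb = fft(_delta_map(idx, np.sqrt(t.lj_b), grid))
        e_f += params.scale_nonpolar * (np.conj(fa) * fields.f_a
                                        - np.conj(fb) * fields.f_b)
    if "electrostatic" in soft_terms and fields.f_q is not None \
            and np.any(t.charges != 0.0):
        fq = fft(_delta_map(idx, t.charges, grid))
        e_f += params.scale_elec * (COULOMB_KCAL / params.dielectric) \
            * np.conj(fq) * fields.f_q
    u = ifft(e_f, s=shape, axes=(0, 1, 2))
    u[~clash_free] = 0.0
    return InsertionMaps(clash_free, u, n ** 3, int(clash_free.sum()))


# ---------------------------------------------------------------------------
# direct-sum oracle


@njit(cache=False)
def _direct_maps_kernel(n, h, t_idx, t_bins, t_sa, t_sb, t_q,
                        c_idx, c_bins, c_sa, c_sb, c_q,
                        scale_np, scale_q_pref, lam, r_clamp,
                        use_np, use_q, counts, energy):
    nt = t_idx.shape[0]
    nc = c_idx.shape[0]
    for gi in range(n):
        for gj in range(n):
            for gk in range(n):
                cnt = 0
                e = 0.0
                for a in range(nt):
                    ia = (t_idx[a, 0] + gi) % n
                    ja = (t_idx[a, 1] + gj) % n
                    ka = (t_idx[a, 2] + gk) % n
                    for b in range(nc):
                        di = abs(ia - c_idx[b, 0])
                        dj = abs(ja - c_idx[b, 1])
                        dk = abs(ka - c_idx[b, 2])
                        if di > n - di:
                            di = n - di
                        if dj > n - dj:
                            dj = n - dj
                        if dk > n - dk:
                            dk = n - dk
                        r = h * (di * di + dj * dj + dk * dk) ** 0.5
                        if r < (t_bins[a] + c_bins[b]) * 0.1:
                            cnt += 1
                        rr = r if r > r_clamp else r_clamp
                        if use_np:
                            e += scale_np * (t_sa[a] * c_sa[b] / rr ** 12
                                             - t_sb[a] * c_sb[b] / rr ** 6)
                        if use_q:
                            e += scale_q_pref * t_q[a] * c_q[b] \
                                * math.exp(-rr / lam) / rr
                counts[gi, gj, gk] = cnt
                energy[gi, gj, gk] = e


def direct_insertion_maps(test_oriented: Molecule, cfg, grid: GridSpec,
                          params: PotentialParams | None = None,
                          soft_terms=("nonpolar", "electrostatic")) -> InsertionMaps:
    """Brute-force double-sum evaluation of the insertion maps.

    Uses the same snapped coordinates, quantized radii and clamped kernels
    as the FFT path, so the two must agree to FFT round-off. Independent
    oracle: shares no FFT code with :func:`build_insertion_maps`.
    """
    params = params or PotentialParams()
    n, h = grid.n_points, grid.spacing
    coords, radii, lj_a, lj_b, charges = cfg.atoms_flat()
    c_idx = _snap(coords, grid)
    c_bins = _bin_radius(radii)
    t = test_oriented
    t_idx = _snap(t.coords - t.centroid, grid)
    t_bins = _bin_radius(t.radii)
    r_clamp = max((t_bins.min() + c_bins.min()) * RADIUS_BIN, 1e-6)
    counts = np.zeros((n,) * 3, dtype=np.int64)
    energy = np.zeros((n,) * 3)
    _direct_maps_kernel(
        n, h, t_idx, t_bins.astype(np.float64), np.sqrt(t.lj_a),
        np.sqrt(t.lj_b), t.charges,
        c_idx, c_bins.astype(np.float64), np.sqrt(lj_a), np.sqrt(lj_b),
        charges, params.scale_nonpolar,
        params.scale_elec * COULOMB_KCAL / params.dielectric,
        params.debye_length, r_clamp,
        "nonpolar" in soft_terms, "electrostatic" in soft_terms,
        counts, energy)
    clash_free = counts == 0
    energy[~clash_free] = 0.0
    return InsertionMaps(clash_free, energy, n ** 3, int(clash_free.sum()))


def pairwise_energy(test: Molecule, cfg, params: PotentialParams | None = None,
                    soft_terms=("nonpolar", "electrostatic")):
    """Direct pairwise interaction of ``test`` (at its current coordinates)
    with all crowder atoms under minimum image.

    Returns ``(energy, clash)``: energy in kcal/mol (soft terms only) and a
    flag set when any pair distance is below hard-core contact. This is the
    continuum (non-gridded) reference; the FFT path is compared against
    :func:`direct_insertion_maps`, which applies the same grid snapping.
    """
    params = params or PotentialParams()
    coords, radii, lj_a, lj_b, charges = cfg.atoms_flat()
    L = cfg.box_side
    d = test.coords[:, None, :] - coords[None, :, :]
    d -= L * np.rint(d / L)
    r = np.sqrt((d ** 2).sum(-1))
    contact = test.radii[:, None] + radii[None, :]
    clash = bool(np.any(r < contact))
    e = 0.0
    with np.errstate(divide="ignore"):
        if "nonpolar" in soft_terms:
            a_ij = np.sqrt(np.outer(test.lj_a, lj_a))
            b_ij = np.sqrt(np.outer(test.lj_b, lj_b))
            e += params.scale_nonpolar * float(
                (a_ij / r ** 12 - b_ij / r ** 6).sum())
        if "electrostatic" in soft_terms:
            q_ij = np.outer(test.charges, charges)
            e += params.scale_elec * COULOMB_KCAL / params.dielectric * float(
                (q_ij * np.exp(-r / params.debye_length) / r).sum())
    return e, clash


# ---------------------------------------------------------------------------
# averages and aggregation


def insertion_averages(maps: InsertionMaps,
                       params: PotentialParams | None = None) -> SampleAverages:
    """Boltzmann-factor averages of one sample; the product identity
    bf_int = bf_st * bf_soft holds exactly."""
    params = params or PotentialParams()
    bf_st = maps.n_free / maps.n_total
    if maps.n_free == 0:
        return SampleAverages(0.0, 0.0, float("nan"), True)
    w = np.exp(-maps.u_soft[maps.clash_free] / params.kbt)
    bf_soft = float(w.mean())
    bf_int = float(w.sum() / maps.n_total)
    return SampleAverages(bf_int, bf_st, bf_soft, False)


def aggregate(samples: list[SampleAverages],
              params: PotentialParams | None = None,
              n_boot: int = 1000, seed: int = 0) -> TransferFreeEnergyResult:
    """Combine per-(orientation, configuration) averages into a transfer
    free energy with components and bootstrap errors.

    Boltzmann factors are averaged sample-wise over the non-fully-clashed
    subset; when fully clashed samples exist, -kT ln(n_ok/n_total) is added
    to the total and excluded-volume components. Errors are the mean
    standard deviation of bootstrap resamples of the per-sample free-energy
    series (a sample-to-sample spread, following the bootstrap convention
    of the reference protocol).
    """
    params = params or PotentialParams()
    kT = params.kbt
    n_tot = len(samples)
    ok = [s for s in samples if not s.fully_clashed]
    n_ok = len(ok)
    if n_ok == 0:
        return TransferFreeEnergyResult(
            math.inf, math.inf, float("nan"), math.nan, math.nan, math.nan,
            0.0, n_tot, n_tot, {"note": "all samples fully clashed"})
    bf_int = np.array([s.bf_int for s in ok])
    bf_st = np.array([s.bf_st for s in ok])
    bf_soft = np.array([s.bf_soft for s in ok])
    correction = -kT * math.log(n_ok / n_tot) if n_ok < n_tot else 0.0
    dmu = -kT * math.log(bf_int.mean()) + correction
    dmu_ev = -kT * math.log(bf_st.mean()) + correction
    dmu_sa = -kT * math.log(bf_soft.mean())

    def _err(values):
        if len(values) < 2:
            return math.nan
        return error_stats.bootstrap_error(-kT * np.log(values),
                                           n_boot=n_boot, seed=seed)

    return TransferFreeEnergyResult(
        dmu, dmu_ev, dmu_sa,
        _err(bf_int), _err(bf_st), _err(bf_soft),
        correction, n_tot, n_tot - n_ok,
        {"kbt": kT})


def run_transfer(test: Molecule, cfg_set, n_orientations: int,
                 grid: GridSpec | None = None,
                 params: PotentialParams | None = None,
                 seed: int = 0,
                 soft_terms=("nonpolar", "electrostatic"),
                 orientation_scheme: str = "axis-angle",
                 n_boot: int = 1000,
                 use_fft: bool = True) -> TransferFreeEnergyResult:
    """Full orientation x configuration Widom-insertion loop.

    ``cfg_set`` is a non-empty list of crowder configurations sharing one
    box side. ``use_fft=False`` switches to the direct-sum oracle path
    (identical results, for validation).
    """
    if not cfg_set:
        raise ValueError("cfg_set must be non-empty")
    params = params or PotentialParams()
    if grid is None:
        grid = GridSpec.from_spacing(cfg_set[0].box_side)
    ss = np.random.SeedSequence(seed)
    samples = []
    for cfg in cfg_set:
        fields = CrowderFields(cfg, grid, params, test) if use_fft else None
        for child in ss.spawn(n_orientations):
            rng = np.random.default_rng(child)
            oriented = random_orientation(test, rng, orientation_scheme)
            if use_fft:
                maps = build_insertion_maps(oriented, cfg, grid, params,
                                            soft_terms, fields)
            else:
                maps = direct_insertion_maps(oriented, cfg, grid, params,
                                             soft_terms)
            samples.append(insertion_averages(maps, params))
    result = aggregate(samples, params, n_boot=n_boot, seed=seed)
    result.metadata.update({
        "n_orientations": n_orientations,
        "n_configurations": len(cfg_set),
        "grid_points": grid.n_points,
        "grid_spacing": grid.spacing,
        "seed": seed,
        "soft_terms": list(soft_terms),
        "orientation_scheme": orientation_scheme,
        "fft": use_fft,
    })
    return result


def single_interaction_mu(test: Molecule, cfg_set, n_orientations: int,
                          grid: GridSpec | None = None,
                          params: PotentialParams | None = None,
                          which: str = "nonpolar", seed: int = 0) -> float:
    """Soft component with only one interaction type active (``nonpolar``
    or ``electrostatic``); used to probe the correlation between the two
    soft terms."""
    if which not in ("nonpolar", "electrostatic"):
        raise ValueError("which must be 'nonpolar' or 'electrostatic'")
    res = run_transfer(test, cfg_set, n_orientations, grid, params,
                       seed=seed, soft_terms=(which,))
    return res.dmu_sa
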