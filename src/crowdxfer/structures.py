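"""Molecular structures, interaction-parameter assignment, orientations, and
geometric shape measures.

A :class:`Molecule` is a rigid collection of atoms, each carrying a hard-core
radius, Lennard-Jones self coefficients (A_ii, B_ii) and a partial charge.
Coordinates are in Å, energies in kcal/mol, charges in elementary-charge units.

Shape measures (volume ``v_p``, surface area ``s_p`` and integrated mean
curvature ``l_p``) are extracted from the Steiner expansion of the
parallel-body volume: for a convex body,

    V(R) = v_p + s_p R + 4 pi l_p R^2 + (4/3) pi R^3,

where V(R) is the volume of the set of points within distance R of the body.
For a non-convex atomistic molecule the expansion is fitted locally around the
probe radius of interest, which yields effective measures appropriate to a
probe of that size.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from numba import njit
from scipy.spatial.transform import Rotation


class ParameterError(ValueError):
    """An atom could not be assigned interaction parameters."""


class FormatError(ValueError):
    """The structure file could not be parsed."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: label, position (Å), hard-core radius (Å), LJ self
    coefficients A_ii (kcal Å^12/mol) and B_ii (kcal Å^6/mol), charge (e)."""

    label: str
    position: tuple[float, float, float]
    radius: float
    lj_a: float
    lj_b: float
    charge: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.label}")
        if self.radius <= 0:
            raise ValueError(f"atom {self.label}: radius must be > 0")
        if self.lj_a < 0 or self.lj_b < 0:
            raise ValueError(f"atom {self.label}: LJ coefficients must be >= 0")


class Molecule:
    """Ordered atom collection stored as flat numpy arrays.

    Attributes
    ----------
    name : str
    labels : list of per-atom type labels
    coords : (n, 3) float array, Å
    radii, lj_a, lj_b, charges : (n,) float arrays
    """

    def __init__(self, name, labels, coords, radii, lj_a, lj_b, charges):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError("coords must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords must be finite")
        self.name = name
        self.labels = list(labels)
        self.coords = coords
        self.radii = np.asarray(radii, dtype=float)
        self.lj_a = np.asarray(lj_a, dtype=float)
        self.lj_b = np.asarray(lj_b, dtype=float)
        self.charges = np.asarray(charges, dtype=float)
        n = len(coords)
        for arr, what in ((self.radii, "radii"), (self.lj_a, "lj_a"),
                          (self.lj_b, "lj_b"), (self.charges, "charges")):
            if arr.shape != (n,):
                raise ValueError(f"{what} must have shape ({n},)")
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be > 0")
        if np.any(self.lj_a < 0) or np.any(self.lj_b < 0):
            raise ValueError("LJ coefficients must be >= 0")

    def __len__(self):
        return len(self.coords)

    @property
    def centroid(self) -> np.ndarray:
        """Mean atom position, recomputed on access."""
        return self.coords.mean(axis=0)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [AtomRecord(l, tuple(c), r, a, b, q)
                for l, c, r, a, b, q in zip(self.labels, self.coords,
                                            self.radii, self.lj_a,
                                            self.lj_b, self.charges)]

    def centered(self) -> "Molecule":
        """Copy translated so the centroid sits at the origin."""
        return Molecule(self.name, self.labels, self.coords - self.centroid,
                        self.radii, self.lj_a, self.lj_b, self.charges)

    def translated(self, shift) -> "Molecule":
        return Molecule(self.name, self.labels,
                        self.coords + np.asarray(shift, dtype=float),
                        self.radii, self.lj_a, self.lj_b, self.charges)

    def radius_of_gyration(self) -> float:
        d = self.coords - self.centroid
        return float(np.sqrt((d ** 2).sum(axis=1).mean()))


@dataclass
class ForceFieldTable:
    """Map from atom-type label to (radius, lj_a, lj_b, charge).

    ``element_fallback`` optionally resolves unknown labels through their
    leading element symbol (lenient mode).
    """

    entries: dict[str, tuple[float, float, float, float]]
    lenient: bool = False

    @classmethod
    def from_file(cls, path, lenient: bool = False) -> "ForceFieldTable":
        """Read a whitespace-delimited table: ``type radius lj_a lj_b charge``.

        Lines starting with ``#`` are comments.
        """
        entries = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise FormatError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
            label, *vals = parts
            try:
                r, a, b, q = map(float, vals)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from None
            entries[label] = (r, a, b, q)
        return cls(entries, lenient=lenient)

    @classmethod
    def bundled(cls, lenient: bool = False) -> "ForceFieldTable":
        """The element-keyed table shipped with the package (synthetic but
        physically plausible values; supply your own for production work)."""
        ref = importlib.resources.files("crowdxfer") / "data" / "elements.par"
        with importlib.resources.as_file(ref) as p:
            return cls.from_file(p, lenient=lenient)

    def lookup(self, label: str):
        if label in self.entries:
            return self.entries[label]
        if self.lenient:
            elem = label.strip()[:1].upper()
            if elem in self.entries:
                return self.entries[elem]
        return None


# ---------------------------------------------------------------------------
# structure IO


def _molecule_from_gemmi(st: gemmi.Structure, table: ForceFieldTable) -> Molecule:
    labels, coords, radii, lja, ljb, charges = [], [], [], [], [], []
    missing = []
    seen_altloc = False
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    if atom.altloc not in ("", "A", "\x00"):
                        seen_altloc = True
                        continue
                    label = atom.element.name if atom.element.name else atom.name
                    params = table.lookup(label) or table.lookup(atom.name)
                    if params is None:
                        missing.append(f"{chain.name}/{res.name}/{atom.name}")
                        continue
                    r, a, b, q = params
                    labels.append(label)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    radii.append(r)
                    lja.append(a)
                    ljb.append(b)
                    charges.append(q)
        break  # first model only
    if seen_altloc:
        warnings.warn("alternate locations present; kept first altloc only")
    if missing:
        raise ParameterError(
            "no parameters for atoms: " + ", ".join(missing[:20])
            + ("..." if len(missing) > 20 else ""))
    if not coords:
        raise FormatError("no atoms parsed")
    return Molecule(st.name or "mol", labels, coords, radii, lja, ljb, charges)


def _read_pqr(path, table: ForceFieldTable) -> Molecule:
    """PQR: whitespace-delimited ATOM/HETATM with explicit charge and radius
    in the last two fields; these override the parameter table."""
    labels, coords, radii, lja, ljb, charges = [], [], [], [], [], []
    missing = []
    for line in Path(path).read_text().splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        parts = line.split()
        if len(parts) < 10:
            raise FormatError(f"short PQR record: {line!r}")
        name = parts[2]
        try:
            x, y, z = map(float, parts[-5:-2])
            q, r = float(parts[-2]), float(parts[-1])
        except ValueError as exc:
            raise FormatError(f"bad PQR record {line!r}: {exc}") from None
        elem = name[:1].upper()
        params = table.lookup(name) or table.lookup(elem)
        if params is None:
            # PQR supplies radius and charge; LJ coefficients still need a table
            missing.append(name)
            continue
        _, a, b, _ = params
        labels.append(elem)
        coords.append([x, y, z])
        radii.append(r)
        lja.append(a)
        ljb.append(b)
        charges.append(q)
    if missing:
        raise ParameterError("no LJ parameters for atoms: " + ", ".join(missing[:20]))
    if not coords:
        raise FormatError("no atoms parsed")
    return Molecule(Path(path).stem, labels, coords, radii, lja, ljb, charges)


def read_structure(path, table: ForceFieldTable | None = None) -> Molecule:
    """Read a PDB or PQR file and assign interaction parameters.

    PDB atoms are typed by element and looked up in ``table`` (bundled table
    by default); unknown types raise :class:`ParameterError` naming the atoms
    unless the table is lenient. PQR radius/charge columns override the table.
    """
    path = Path(path)
    if table is None:
        table = ForceFieldTable.bundled()
    if path.suffix.lower() == ".pqr":
        return _read_pqr(path, table)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from None
    st.name = path.stem
    return _molecule_from_gemmi(st, table)


def write_pdb(mol: Molecule, path, *, serial_start: int = 1,
              chain: str = "A", append: bool = False) -> None:
    """Write a Molecule as minimal PDB ATOM records (one residue per file)."""
    lines = []
    for i, (label, xyz) in enumerate(zip(mol.labels, mol.coords)):
        name = (label[:4]).ljust(4)
        lines.append(
            f"ATOM  {serial_start + i:5d} {name} MOL {chain}   1    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
            f"          {label[:2].rjust(2)}")
    lines.append("END")
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# orientations


def random_rotation(rng: np.random.Generator, scheme: str = "axis-angle") -> Rotation:
    """Draw a random rotation.

    ``axis-angle`` picks a uniformly distributed axis and a uniform angle in
    [0, 2pi) — the sampling used to orient crowders here; note this is *not*
    the uniform (Haar) measure on SO(3). ``uniform`` draws Haar-uniform
    rotations via random unit quaternions.
    """
    if scheme == "axis-angle":
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        angle = rng.uniform(0.0, 2.0 * np.pi)
        return Rotation.from_rotvec(angle * v)
    if scheme == "uniform":
        q = rng.standard_normal(4)
        q /= np.linalg.norm(q)
        return Rotation.from_quat(q)
    raise ValueError(f"unknown orientation scheme {scheme!r}")


def random_orientation(mol: Molecule, seed, scheme: str = "axis-angle") -> Molecule:
    """Rigidly rotate ``mol`` about its centroid by a random rotation.

    ``seed`` may be an int or a numpy Generator. Deterministic for a fixed
    integer seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rot = random_rotation(rng, scheme)
    c = mol.centroid
    new_coords = rot.apply(mol.coords - c) + c
    return Molecule(mol.name, mol.labels, new_coords, mol.radii,
                    mol.lj_a, mol.lj_b, mol.charges)


# ---------------------------------------------------------------------------
# shape measures


@njit(cache=False)
def _scanline_volume(coords, r_eff, spacing):
    """Union-of-spheres volume by x-scanlines on a (y, z) grid.

    Each column contributes the exact length of the union of its sphere
    chords, so the estimate is smooth in the inflation radius (only the
    transverse directions are discretized) — essential for the stability
    of the Steiner-expansion fit.
    """
    n = coords.shape[0]
    ylo, yhi = 1e30, -1e30
    zlo, zhi = 1e30, -1e30
    for a in range(n):
        if coords[a, 1] - r_eff[a] < ylo:
            ylo = coords[a, 1] - r_eff[a]
        if coords[a, 1] + r_eff[a] > yhi:
            yhi = coords[a, 1] + r_eff[a]
        if coords[a, 2] - r_eff[a] < zlo:
            zlo = coords[a, 2] - r_eff[a]
        if coords[a, 2] + r_eff[a] > zhi:
            zhi = coords[a, 2] + r_eff[a]
    ny = int((yhi - ylo) / spacing) + 2
    nz = int((zhi - zlo) / spacing) + 2
    lo_x = np.empty(n)
    hi_x = np.empty(n)
    order = np.empty(n, dtype=np.int64)
    total = 0.0
    for iy in range(ny):
        y = ylo + (iy + 0.5) * spacing
        for iz in range(nz):
            z = zlo + (iz + 0.5) * spacing
            m = 0
            for a in range(n):
                dy = y - coords[a, 1]
                dz = z - coords[a, 2]
                w2 = r_eff[a] * r_eff[a] - dy * dy - dz * dz
                if w2 > 0.0:
                    w = w2 ** 0.5
                    lo_x[m] = coords[a, 0] - w
                    hi_x[m] = coords[a, 0] + w
                    m += 1
            if m == 0:
                continue
            # insertion sort intervals by start, then merge
            for i in range(m):
                order[i] = i
            for i in range(1, m):
                j = i
                while j > 0 and lo_x[order[j]] < lo_x[order[j - 1]]:
                    order[j], order[j - 1] = order[j - 1], order[j]
                    j -= 1
            cur_lo = lo_x[order[0]]
            cur_hi = hi_x[order[0]]
            length = 0.0
            for i in range(1, m):
                a = order[i]
                if lo_x[a] <= cur_hi:
                    if hi_x[a] > cur_hi:
                        cur_hi = hi_x[a]
                else:
                    length += cur_hi - cur_lo
                    cur_lo = lo_x[a]
                    cur_hi = hi_x[a]
            length += cur_hi - cur_lo
            total += length
    return total * spacing * spacing


def _union_volume(coords, radii, inflate, spacing):
    """Volume of the union of atom spheres inflated by ``inflate``.

    Transverse sampling runs at half the nominal spacing (the scanline
    direction is exact)."""
    coords = np.ascontiguousarray(coords, dtype=np.float64)
    r_eff = np.ascontiguousarray(radii + inflate, dtype=np.float64)
    return float(_scanline_volume(coords, r_eff, 0.5 * spacing))


def _n_components(coords, radii, inflate):
    """Connected components of the inflated sphere union (union-find).

    Approximates the Euler characteristic of the parallel body, which sets
    the coefficient of the R^3 Steiner term (handles/voids of toy unions
    are neglected)."""
    n = len(coords)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(coords[i] - coords[j]) \
                    < radii[i] + radii[j] + 2.0 * inflate:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    return len({find(i) for i in range(n)})


@dataclass(frozen=True)
class ShapeMeasures:
    """Volume (Å^3), surface area (Å^2) and integrated mean curvature (Å)."""

    v_p: float
    s_p: float
    l_p: float


def parallel_body_measures(mol: Molecule, probe_radius: float,
                           grid_spacing: float = 0.3,
                           n_probe: int = 7,
                           window: float = 0.25) -> ShapeMeasures:
    """Effective shape measures of a molecule for a probe of given radius.

    The parallel-body volume V(R) is computed by voxelization at ``n_probe``
    inflation distances R spanning ``probe_radius`` ± ``window`` (fraction),
    and the Steiner form V(R) = v_p + s_p R + 4 pi l_p R^2 + chi (4/3) pi R^3
    is fitted by least squares with the cubic coefficient fixed at its known
    value (chi = number of connected components of the inflated union, which
    conditions the fit and makes disjoint unions additive). Requires at
    least ~8 voxels across the smallest atom.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be > 0")
    dmin = 2.0 * mol.radii.min()
    if grid_spacing > dmin / 4.0:
        warnings.warn(
            f"grid spacing {grid_spacing} coarse for smallest atom "
            f"(diameter {dmin:.2f}); consider <= {dmin / 8:.3f}")
    R = np.linspace(probe_radius * (1 - window), probe_radius * (1 + window), n_probe)
    V = np.array([_union_volume(mol.coords, mol.radii, r, grid_spacing) for r in R])
    chi = np.array([_n_components(mol.coords, mol.radii, r) for r in R])
    y = V - chi * (4.0 / 3.0) * np.pi * R ** 3
    X = np.column_stack([np.ones_like(R), R, 4.0 * np.pi * R ** 2])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    if not np.all(np.isfinite(coef)):
        raise FloatingPointError("degenerate parallel-body fit")
    v_p, s_p, l_p = (max(0.0, float(c)) for c in coef)
    return ShapeMeasures(v_p, s_p, l_p)


def sphere_measures(radius: float) -> ShapeMeasures:
    """Analytic measures of a single sphere (the l_p of a sphere equals its
    radius)."""
    return ShapeMeasures((4.0 / 3.0) * math.pi * radius ** 3,
                         4.0 * math.pi * radius ** 2,
                         radius)
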