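"""Crowded periodic boxes: replace packed spheres by oriented molecules.

Each sphere of a physical-units :class:`~crowdxfer.packing.SpherePacking` is
replaced, in index order, by a copy of the crowder molecule centered at the
sphere center. Random orientations are drawn repeatedly until the new copy
has no interatomic distance below the clash threshold to any molecule already
placed, periodic images included (minimum-image convention). Molecules are
not wrapped: atoms may protrude past box faces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import AVOGADRO
from .packing import SpherePacking
from .structures import Molecule, random_rotation, write_pdb


class PlacementError(RuntimeError):
    """A sphere exhausted the orientation retry budget."""

    def __init__(self, sphere_index: int, max_retries: int):
        self.sphere_index = sphere_index
        super().__init__(
            f"sphere {sphere_index}: no clash-free orientation in "
            f"{max_retries} retries")


@dataclass
class CrowderConfiguration:
    """One periodic configuration of placed crowder molecules."""

    box_side: float
    crowder: Molecule
    translations: np.ndarray       # (n_placed, 3) sphere centers, Å
    rotations: list                # scipy Rotation per placement
    atom_coords: np.ndarray        # (n_placed * n_atoms, 3) box coordinates
    sphere_radius: float
    seed: int

    @property
    def n_crowders(self) -> int:
        return len(self.translations)

    @property
    def volume_fraction(self) -> float:
        """Volume fraction of the enclosing spheres."""
        return self.n_crowders * (4.0 / 3.0) * np.pi * self.sphere_radius ** 3 \
            / self.box_side ** 3

    def atoms_flat(self):
        """Concatenated per-atom parameter arrays in placement order."""
        n = self.n_crowders
        tile = lambda a: np.tile(a, n)
        return (self.atom_coords, tile(self.crowder.radii),
                tile(self.crowder.lj_a), tile(self.crowder.lj_b),
                tile(self.crowder.charges))

    def min_cross_distance(self) -> float:
        """Exhaustive minimum-image distance between atoms of distinct
        molecules (O(N^2) oracle used by the validity check)."""
        na = len(self.crowder)
        best = np.inf
        for i in range(self.n_crowders):
            for j in range(i + 1, self.n_crowders):
                d = self.atom_coords[i * na:(i + 1) * na, None, :] \
                    - self.atom_coords[None, j * na:(j + 1) * na, :]
                d -= self.box_side * np.rint(d / self.box_side)
                best = min(best, float(np.sqrt((d ** 2).sum(-1)).min()))
        return best

    def to_files(self, pdb_path, meta_path) -> None:
        """Write concatenated PDB plus a JSON sidecar with placements."""
        na = len(self.crowder)
        first = True
        for i in range(self.n_crowders):
            m = Molecule(self.crowder.name, self.crowder.labels,
                         self.atom_coords[i * na:(i + 1) * na],
                         self.crowder.radii, self.crowder.lj_a,
                         self.crowder.lj_b, self.crowder.charges)
            write_pdb(m, pdb_path, serial_start=i * na + 1,
                      chain=chr(ord("A") + i % 26), append=not first)
            first = False
        meta = {
            "box_side": self.box_side,
            "sphere_radius": self.sphere_radius,
            "seed": self.seed,
            "n_crowders": self.n_crowders,
            "translations": self.translations.tolist(),
            "quaternions": [r.as_quat().tolist() for r in self.rotations],
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=1)


def replace_with_molecules(p: SpherePacking, mol: Molecule,
                           clash_threshold: float = 4.0,
                           seed: int = 0,
                           max_retries: int = 10_000) -> CrowderConfiguration:
    """Replace every sphere of a packing (physical units) by an oriented copy
    of ``mol``.

    The molecule is centered on its centroid before each placement. A
    placement is accepted when no atom of the new copy comes within
    ``clash_threshold`` Å of any previously placed atom under the
    minimum-image convention. Deterministic for fixed ``seed``.
    """
    if clash_threshold <= 0:
        raise ValueError("clash_threshold must be > 0")
    L = p.box_side
    base = mol.centered()
    extent = np.sqrt((base.coords ** 2).sum(axis=1)).max()
    if extent > p.radius:
        import warnings
        warnings.warn(
            f"molecule extent {extent:.1f} Å exceeds sphere radius "
            f"{p.radius:.1f} Å; atoms protrude (allowed)")
    rng = np.random.default_rng(seed)
    placed_tree = None
    placed = []
    rotations = []
    for isph, center in enumerate(p.centers):
        accepted = False
        for _try in range(max_retries):
            rot = random_rotation(rng, "axis-angle")
            coords = rot.apply(base.coords) + center
            if placed_tree is None:
                accepted = True
                break
            # wrap query points for the periodic KD-tree
            q = coords % L
            hits = placed_tree.query_ball_point(q, clash_threshold)
            if not any(hits):
                accepted = True
                break
        if not accepted:
            raise PlacementError(isph, max_retries)
        placed.append(coords)
        rotations.append(rot)
        all_atoms = np.concatenate(placed) % L
        placed_tree = cKDTree(all_atoms, boxsize=L)
    atom_coords = np.concatenate(placed)
    return CrowderConfiguration(L, mol, np.array(p.centers, dtype=float),
                                rotations, atom_coords, p.radius, seed)


def mass_concentration(n_molecules: int, molar_mass: float,
                       box_side: float) -> float:
    """Mass concentration in mg/mL of ``n_molecules`` of ``molar_mass``
    (g/mol) in a cubic box of side ``box_side`` Å."""
    if molar_mass <= 0:
        raise ValueError("molar_mass must be > 0")
    volume_litre = box_side ** 3 * 1e-27
    return n_molecules * molar_mass / (AVOGADRO * volume_litre)
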