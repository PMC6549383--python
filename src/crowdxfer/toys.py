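"""Synthetic toy molecules and miniature crowded systems.

Real protein structures are large and externally hosted; these generators
emulate their essential features for testing and demonstration: compact
clusters of atoms with mixed hard-core radii, Lennard-Jones coefficients and
partial charges (neutral, zwitterionic or net-charged). Radii are drawn on a
0.1 Å lattice so that the engine's radius quantization is exact on toys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .crowder_box import CrowderConfiguration, replace_with_molecules
from .packing import SpherePacking, pack_spheres, scale_packing
from .structures import Molecule, write_pdb


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ToyMoleculeSpec:
    """Recipe for a toy molecule."""

    n_atoms: int = 15
    envelope_radius: float = 4.0      # Å
    radius_range: tuple = (1.2, 1.8)  # Å, quantized to 0.1
    charge_scheme: str = "zwitterionic"  # neutral | zwitterionic | net
    net_charge: float = 0.0
    epsilon_range: tuple = (0.1, 0.3)  # kcal/mol LJ well depths
    seed: int = 0


def make_toy_molecule(spec: ToyMoleculeSpec, name: str | None = None) -> Molecule:
    """Generate a compact toy molecule.

    Atoms are placed uniformly inside the envelope sphere with minimum
    separation 0.8x the sum of their radii (rejection sampling, up to 1e5
    attempts). LJ self coefficients follow A_ii = eps (2 r_i)^12,
    B_ii = 2 eps (2 r_i)^6, which puts the pair minimum near hard-core
    contact so attraction is felt by clash-free placements. Charge schemes:
    ``neutral`` (all zero), ``zwitterionic`` (+q/-q pairs, exact zero sum)
    or ``net`` (zwitterionic pattern plus the requested total on atom 0).
    Deterministic for the spec's seed.
    """
    if spec.n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(spec.seed)
    lo_bin = round(spec.radius_range[0] / 0.1)
    hi_bin = round(spec.radius_range[1] / 0.1)
    radii = rng.integers(lo_bin, hi_bin + 1, spec.n_atoms) * 0.1
    coords = []
    for i in range(spec.n_atoms):
        for attempt in range(100_000):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            p = u * spec.envelope_radius * rng.random() ** (1.0 / 3.0)
            ok = all(np.linalg.norm(p - q) >= 0.8 * (radii[i] + radii[j])
                     for j, q in enumerate(coords))
            if ok:
                coords.append(p)
                break
        else:
            raise GenerationError(
                f"cannot place atom {i} of {spec.n_atoms} in envelope "
                f"{spec.envelope_radius} Å")
    coords = np.array(coords)
    eps = rng.uniform(*spec.epsilon_range, spec.n_atoms)
    r0 = 2.0 * radii
    lj_a = eps * r0 ** 12
    lj_b = 2.0 * eps * r0 ** 6
    charges = np.zeros(spec.n_atoms)
    if spec.charge_scheme in ("zwitterionic", "net"):
        mags = rng.integers(1, 6, spec.n_atoms // 2) * 0.1
        for k, q in enumerate(mags):
            charges[2 * k] = q
            charges[2 * k + 1] = -q
        if spec.charge_scheme == "net":
            charges[0] += spec.net_charge
    elif spec.charge_scheme != "neutral":
        raise ValueError(f"unknown charge scheme {spec.charge_scheme!r}")
    return Molecule(name or f"toy{spec.seed}", ["C"] * spec.n_atoms, coords,
                    radii, lj_a, lj_b, charges)


@dataclass
class MiniSystem:
    """In-memory miniature crowded system for end-to-end runs."""

    test: Molecule
    crowder: Molecule
    configurations: dict      # phi -> list of CrowderConfiguration
    box_side: float
    sphere_radius: float


def make_test_system(phi_targets, n_configs: int = 2,
                     box_side: float = 36.0,
                     crowder_spec: ToyMoleculeSpec | None = None,
                     test_spec: ToyMoleculeSpec | None = None,
                     clash_threshold: float = 4.0,
                     seed: int = 0,
                     out_dir=None) -> MiniSystem:
    """Build a miniature concentration series.

    The enclosing-sphere radius is fixed at the crowder's extent plus half
    the clash threshold (so neighbouring placements can always succeed),
    and for each target volume fraction the crowder count N is chosen to
    match it: the realized phi values are exactly proportional to N,
    mirroring an arithmetic concentration ladder. Packings are generated in
    the unit box, scaled to ``box_side`` Å and filled with oriented toy
    crowders.

    When ``out_dir`` is given, molecules (PDB), packings and configuration
    sidecars (JSON) plus concatenated-PDB boxes are written there.
    """
    phi_targets = list(phi_targets)
    crowder_spec = crowder_spec or ToyMoleculeSpec(
        n_atoms=12, envelope_radius=3.6, seed=seed + 101)
    test_spec = test_spec or ToyMoleculeSpec(
        n_atoms=10, envelope_radius=3.4, seed=seed + 202)
    crowder = make_toy_molecule(crowder_spec, "crowder")
    test = make_toy_molecule(test_spec, "test")
    system = MiniSystem(test, crowder, {}, box_side, 0.0)
    if not phi_targets:
        return system
    centered = crowder.coords - crowder.centroid
    extent = float(np.sqrt((centered ** 2).sum(axis=1)).max())
    r_phys = extent + clash_threshold / 2.0 + 0.5
    radius_unit = r_phys / box_side
    v_sphere = (4.0 / 3.0) * np.pi * radius_unit ** 3
    system.sphere_radius = r_phys
    ss = np.random.SeedSequence(seed)
    for phi in phi_targets:
        n = max(1, int(round(phi / v_sphere)))
        cfgs = []
        for _rep in range(n_configs):
            s = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31 - 1))
            p = pack_spheres(n, radius_unit, seed=s)
            ps = scale_packing(p, box_side)
            cfgs.append(replace_with_molecules(
                ps, crowder, clash_threshold=clash_threshold, seed=s))
        system.configurations[phi] = cfgs
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_pdb(test, out / "test.pdb")
        write_pdb(crowder, out / "crowder.pdb")
        manifest = {"box_side": box_side, "seed": seed,
                    "phi_targets": phi_targets, "configs": {}}
        for phi, cfgs in system.configurations.items():
            names = []
            for k, cfg in enumerate(cfgs):
                stem = f"config_phi{phi:.3f}_{k}"
                cfg.to_files(out / f"{stem}.pdb", out / f"{stem}.json")
                names.append(stem)
            manifest["configs"][f"{phi:.3f}"] = names
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return system
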