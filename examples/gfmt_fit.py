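"""Predict the excluded-volume component with generalized fundamental
measure theory and recover the crowder radius from data.

Run:  python examples/gfmt_fit.py   (~30 s)
"""

import numpy as np

from crowdxfer import (CrowderState, ToyMoleculeSpec, fit_rc, gfmt_mu_ev,
                       make_toy_molecule, parallel_body_measures)
from crowdxfer.constants import kbt

KT = kbt(298.0)

# three toy "test proteins" and a crowder sphere of radius 8 Å
molecules = {f"m{i}": make_toy_molecule(
    ToyMoleculeSpec(n_atoms=8, envelope_radius=3.0, seed=40 + i), f"m{i}")
    for i in range(3)}
r_true = 8.0

rows = []
for name, mol in molecules.items():
    shape = parallel_body_measures(mol, r_true, grid_spacing=0.3)
    print(f"{name}: v_p = {shape.v_p:7.1f} Å^3, s_p = {shape.s_p:7.1f} Å^2, "
          f"l_p = {shape.l_p:5.2f} Å")
    for phi in np.linspace(0.04, 0.32, 8):
        state = CrowderState.from_phi(r_true, phi)
        rows.append([name, phi, True, gfmt_mu_ev(shape, state, KT)])

fit = fit_rc(rows, molecules, KT, bracket=(3.0, 16.0), grid_spacing=0.3)
print(f"\ncrowder radius fitted to the dmu_ev table: "
      f"R_c = {fit.r_c:.2f} Å (true {r_true} Å)")
# The single free parameter R_c is recovered from 24 synthetic
# molecule x concentration points; shape measures are re-probed at each
# candidate radius, as the probe size enters the parallel-body geometry.
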