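# crowdxfer

Transfer free energies of atomistic test molecules into crowded
macromolecular solutions, computed by FFT-accelerated Widom insertion.

## The problem

A "bystander" macromolecule in a cell changes the thermodynamics of every
protein around it. The controlling quantity is the transfer free energy
Δμ — the free-energy cost of moving a test molecule from dilute solution
into the crowded solution — which equals the crowder contribution to the
test molecule's excess chemical potential. `crowdxfer` computes Δμ for
rigid, atomistic test and crowder molecules interacting through

* hard-core repulsion: a clash whenever an interatomic distance falls below
  the sum of the two hard-core radii,
* non-polar attraction: a 12-6 Lennard-Jones term
  `A_ij/r^12 − B_ij/r^6`,
* screened electrostatics: a Debye–Hückel term
  `332.06 q_i q_j exp(−r/λ)/(κ r)` (kcal/mol, Å, elementary charges).

Widom insertion estimates exp(−Δμ/k_BT) as the average of the Boltzmann
factor exp(−U_int/k_BT) of a fictitious (ghost) insertion over positions
**R**, orientations **Ω** of the test molecule, and crowder configurations
**c**. The average over **R** — millions of grid positions — is done in a
handful of FFTs, because every pairwise term is a cross-correlation of a
test-atom field with a crowder field convolved with a radial kernel.

The per-sample average factorizes exactly into a clash-free fraction and a
soft-interaction average over clash-free points,

    ⟨e^(−U_int/kT)⟩_R = ⟨e^(−U_st/kT)⟩_R · ⟨e^(−(U_na+U_elec)/kT)⟩_1 ,

which decomposes Δμ into an excluded-volume component Δμ_ev (always
positive) and a soft-attraction component Δμ_sa (negative when attraction
dominates). Around the insertion engine the package provides:

* **crowder boxes** — periodic hard-sphere packings (growth + Monte Carlo
  densification, up to volume fraction ≈ 0.66) whose spheres are replaced
  by randomly oriented crowder molecules under a 4 Å interatomic clash rule;
* **GFMT** — generalized fundamental-measure (scaled-particle) prediction
  of Δμ_ev from the test molecule's volume, surface area and integrated
  mean curvature, with a single fitted crowder radius R_c;
* **concentration fits** — quadratic/cubic fits of Δμ_sa through the origin
  vs crowder volume fraction, with hold-out extrapolation, plus a perturbed
  virial expansion (Mayer-function B2 quadrature, Mayer-sampling B3 Monte
  Carlo) that explains the near-linearity of Δμ_sa;
* **error analysis** — the bootstrap spread of per-sample free energies and
  Flyvbjerg–Petersen blocking for correlated series;
* **synthetic fixtures** — seeded toy molecules and miniature crowded
  systems so every stage runs in seconds without external structures.

## Worked example

```
$ python examples/insertion_transfer_energy.py
transfer free energy  dmu    = +0.178 +- 0.012 kcal/mol
excluded volume       dmu_ev = +0.228 +- 0.005 kcal/mol
soft attraction       dmu_sa = -0.049 +- 0.011 kcal/mol
additivity gap               = -0.00001 kcal/mol
```

A toy test molecule is inserted into two crowded configurations (volume
fraction 0.15, 36 Å box) at 20 orientations each. Excluding volume costs
+0.23 kcal/mol; soft attraction wins back −0.05 kcal/mol; the two
components sum to the total to 1e-5 kcal/mol, demonstrating the accuracy
of the decomposition. The other scripts in `examples/` cover packing and
box generation, GFMT prediction and the R_c fit, concentration
extrapolation, the virial expansion, and error estimation, one capability
per script.

A thin CLI mirrors the library for shell use:
`crowdxfer pack | boxgen | conc | insert | gfmt | fitphi | stats |
fixtures` (see `crowdxfer --help`).

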