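# Methods

This note records the models, numerical choices and limitations behind
`crowdxfer`, in the order the pipeline runs.

## Interaction model

Test–crowder interactions are pairwise and implicit-solvent:
`U_int = U_st + U_na + U_elec`. `U_st` is infinite whenever an interatomic
distance is below the sum of the two hard-core radii, else zero. `U_na` is
a 12-6 Lennard-Jones sum `Σ A_ij/r^12 − B_ij/r^6` and `U_elec` a
Debye–Hückel sum `Σ 332.06 q_i q_j e^(−r/λ)/(κ r)` in kcal/mol with r in
Å and charges in elementary units. Defaults: 298 K (k_BT =
0.5922 kcal/mol), dielectric κ = 78.4, ionic strength 0.15 M (λ ≈ 7.85 Å
from the Debye formula, overridable), non-polar scale 0.2 and
electrostatic scale 2.0 — the conventional balance for this class of
protein–crowder model. The model ignores solvent structure, polarization
and flexibility; the test and crowder molecules are rigid single
conformations.

Per-atom LJ coefficients are combined geometrically, `A_ij = √(A_ii A_jj)`
and `B_ij = √(B_ii B_jj)`. This is a deliberate design choice: geometric
combination makes each power-law sum factorizable into a single
correlation of √coefficient-weighted atom fields, which is what lets the
FFT engine evaluate it with one kernel per power. Tables with
non-factorizable pair terms can only be approximated this way; the
deviation knob is the user's own per-atom table. The bundled element table
(`data/elements.par`) is synthetic but physically plausible and carries
zero charges — real charges come from PQR input or a user table.

## FFT insertion engine

The Boltzmann factor is needed at every node of a cubic periodic grid
(default spacing ≤ 0.6 Å; the grid dimension is rounded up to a 5-smooth
integer). Atom positions are snapped to the nearest node — no trilinear
spreading — so that the FFT result is *exactly* (to FFT round-off, ~1e-15
relative) the direct double sum over snapped coordinates. The test suite
exploits this: an independent numba double-sum oracle must agree with the
FFT maps at every grid point, bit-for-bit in the clash flags.

Clash detection: per-atom radii are quantized into 0.1 Å bins; for each
(test-bin, crowder-bin) pair the number of sub-contact pairs at a grid
offset is a correlation of a test count map with a crowder count map
convolved with a hard-ball indicator kernel. All bin pairs accumulate in
Fourier space; a point is clash-free iff the total count is below 0.5
(counts are integers up to FFT noise ~1e-9). The kernel distance grid is
built from integer squared lattice distances scaled once, so the FFT path
and the oracle evaluate the identical float expression — this matters at
contact distances that land exactly on lattice shells.

The r^−12, r^−6 and Debye kernels are clamped below the smallest possible
contact distance (recorded per run); clamped values never contribute
because those offsets are always clashed. Crowder-side FFTs are built once
per configuration and reused across all test orientations.

Averaging follows the exact factorization: per (orientation,
configuration) sample, ⟨e^(−U_int/kT)⟩_R equals the clash-free fraction
times the soft-energy Boltzmann average over clash-free points (an
arithmetic identity in the implementation; asserted to machine precision).
Samples are then averaged with equal weight and converted to free
energies. Samples with *no* clash-free point cannot contribute a
soft-energy average; components are averaged over the usable subset and
the correction −k_BT ln(n_ok/n_total) is added to Δμ and Δμ_ev — this
reconstructs exactly the all-sample average, since fully clashed samples
contribute zero Boltzmann factor.

Errors attached to a run are the bootstrap of the per-sample free-energy
series: the mean standard deviation over resamples, i.e. a
sample-to-sample spread, not a standard error of the mean. The blocking
estimator (below) provides the SE-of-mean view; for independent samples
the two differ by √n. Both conventions are implemented as described and
not conflated.

The axis–angle orientation scheme (uniform random axis, uniform angle in
[0, 2π)) is the default for compatibility with the established sampling
protocol for this method; it is *not* the Haar-uniform measure on
rotations (it over-weights small rotation angles). A Haar-uniform
quaternion scheme is available via `scheme="uniform"`. For the isotropic
averages computed here the difference is a sampling-weight detail, not a
bias in the limit of many orientations.

## Crowder box generation

Packings are generated in a periodic unit box by growing spheres from
random points. Stage 1 grows the radius at a steady rate, resolving
overlaps by pushing pairs apart; this alone reaches volume fractions
≈ 0.55. Stage 2 is a hard-sphere Monte Carlo ratchet: single-particle
moves with overlap rejection, with the common radius raised to half the
minimum pair distance after every cycle. The thermal motion lets the
configuration partially order, reaching φ = 0.658 at N = 48 (beyond random
close packing). Because success above RCP depends on the growth history,
a jammed attempt restarts from fresh seeded positions (up to 20 restarts;
typical total time 0.2–15 s at the densest condition). After reaching the
target radius the box is equilibrated by a few hundred fixed-radius MC
sweeps so that sub-jamming packings sample the equilibrium hard-sphere
fluid — this matters for the fundamental-measure cross-validation, which
assumes an equilibrium reference fluid. Every emitted packing passes an
exhaustive O(N²) minimum-image overlap check.

Spheres are replaced by molecule copies one at a time, in index order:
the copy is centred on the sphere, orientations are redrawn until no
interatomic distance to previously placed molecules (minimum image,
periodic KD-tree) is below the clash threshold (default 4.0 Å, up to
10,000 retries per sphere). Molecules are not wrapped; protruding atoms
are handled by the image convention.

## Shape measures and GFMT

The excluded-volume component is predicted by the scaled-particle /
fundamental-measure closed forms for an atomistic solute in a hard-sphere
fluid (see `gfmt.py` docstrings for the three thermodynamic functions).
One printed source renders the surface-tension relation as γ_c/T; it is
implemented as γ_c/k_BT, the only dimensionally consistent reading.

The test molecule enters through (v_p, s_p, l_p), extracted from the
parallel-body volume V(R): V is evaluated at 7 inflation radii spanning
the probe radius ±25 % and fitted to the Steiner form with the cubic
coefficient fixed at χ(4π/3), where χ is the number of connected
components of the inflated union (union-find over atom spheres; handles
and voids are neglected, adequate for compact molecules). Fixing the cubic
term conditions the fit; counting components makes disjoint unions
exactly additive. V(R) itself is computed by x-scanlines on a transverse
(y, z) grid at half the nominal spacing: each column contributes the exact
length of the union of its sphere chords. The scanline estimate is smooth
in R — unlike voxel counting, whose lattice jitter is amplified ~100× by
the narrow-window Steiner fit; this was the decisive numerical choice in
this module (single-sphere measures are recovered to ~1 % at 0.25 Å
nominal spacing).

`fit_rc` fits the single free parameter R_c by least squares over all
molecules and concentrations, recomputing shape measures per candidate
radius (probe size enters the geometry; results are cached per
(molecule, R_c)). The objective is scanned coarsely over the bracket
(default (2, 50) Å, an explicit parameter) and refined by golden section
to 0.01 Å; multiple scan minima or an under-determined dataset raise a
warning and return the global scan minimum. Unweighted residuals are the
default; inverse-variance weighting is available.

## Concentration fits and the virial expansion

Δμ_sa(φ) is fitted through the origin to aφ + bφ² (optionally + cφ³) by
(weighted) least squares; with `holdout_last` the final concentration is
predicted by extrapolation and reported with a z-score against the
combined prediction/observation uncertainty. `linearity_report` gives the
quadratic-to-linear term ratio at a chosen φ.

The near-linearity is rationalized by a perturbed virial expansion with a
hard-sphere reference: μ_ex − μ_ref = k_BT Σ_{l≥2} [l/(l−1)] ΔB_l ρ^{l−1},
the chemical-potential image of the residual pressure series (the
pressure↔chemical-potential route identity is verified symbolically for
truncations l ≤ 4). The model fluid for the demonstration is hard-core
Lennard-Jones — impenetrable below σ with the 12-6 tail beyond — matching
the insertion engine's potential shape; its residual coefficients vanish
as ε → 0 against a hard-sphere reference of diameter σ. B2 is an adaptive
Mayer-function quadrature with an analytic r^−6 tail beyond 10σ; B3 is
Mayer-sampling Monte Carlo with radii drawn from a density ∝ |f(r)| r²
(inverse-CDF lookup), which removes the sampling-volume² factor from the
variance (≈ 4 % relative at 4×10⁵ samples; the hard-sphere closed form is
reproduced to 0.1 % at 5×10⁵). First-order dominance holds for
ε/k_BT ≤ 1 and ρσ³ ≤ 0.5.

## Error estimators

`bootstrap_error` returns the mean of the standard deviations (ddof = 1)
of with-replacement resamples — by construction a data σ. The constant
series short-circuits to exactly 0. `blocking_error` halves the series
into successive generations of pair averages and returns the square root
of the variance-of-the-mean at the first generation whose change to the
next is within its own uncertainty √(2/(n−1))·estimate; if no plateau
appears before the block count drops below 15, the maximum over
generations is returned with a warning. Calibration on iid normals and an
AR(1) series with autocorrelation 0.9 (inflation √(1.9/0.1) ≈ 4.36) is
part of the test suite.

## Synthetic systems and what the tests show

Toy molecules are compact seeded clusters (default 10–15 atoms, envelope
3–4 Å) with hard-core radii on a 0.1 Å lattice — so the engine's radius
quantization is exact on them — zwitterionic or net charges summing
exactly to the target, and LJ wells placed near hard-core contact so that
clash-free placements feel the attraction. Miniature crowded systems use
a sphere radius equal to the crowder extent plus half the clash threshold,
and choose the crowder count per target volume fraction, making realized
φ exactly proportional to N. Default test problem sizes — 36 Å boxes,
48³–64³ grids, tens of orientations, 8 configurations for the hard-sphere
cross-check — were chosen so the whole suite runs in a couple of minutes
on one core while leaving each assertion's sampling error well inside its
tolerance.

Toys emulate the geometry and charge mixture of globular proteins but not
residue topology, hydration, flexibility, or realistic force-field
parameters; passing tests validate the estimator machinery (exactness of
the FFT evaluation, the decomposition identity, theory cross-checks,
calibrated error bars), not the biophysical accuracy of any particular
parameter table on real proteins.

## Known limitations

* Energies are evaluated on snapped coordinates; spreading is not
  implemented beyond the oracle-exact snapping mode.
* Geometric-mean LJ combination cannot reproduce arbitrary published pair
  tables exactly.
* GFMT treats crowders as monodisperse spheres; no mixtures.
* The packing stage is practical to φ ≈ 0.66 for N ≲ 10²; it is not an
  event-driven collision integrator, only contract-equivalent to one.
* Fully clashed samples carry no soft-energy information; at conditions
  where most samples are fully clashed, Δμ_sa rests on few samples and the
  concentration extrapolation is the recommended route.
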