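# Synthetic element-keyed interaction parameter table (crowdxfer bundled default).
# Values are physically plausible placeholders, NOT a published force field:
# hard-core radii ~0.8x van der Waals, 12-6 coefficients from A = eps*rmin^12,
# B = 2*eps*rmin^6 with per-element well depths, charges zero (supply a PQR
# file or your own table for real partial charges).
# columns: type  radius(A)  lj_a(kcal A^12/mol)  lj_b(kcal A^6/mol)  charge(e)
H   0.96   8.0e3    3.0e1   0.0
C   1.36   2.52e6   1.23e3  0.0
N   1.24   1.26e6   8.0e2   0.0
O   1.22   1.05e6   7.4e2   0.0
S   1.60   5.2e6    2.2e3   0.0
P   1.60   5.2e6    2.2e3   0.0
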