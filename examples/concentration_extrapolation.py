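"""Fit the soft-attraction component against crowder volume fraction and
extrapolate to an unseen concentration.

Run:  python examples/concentration_extrapolation.py
"""

import numpy as np

from crowdxfer import PhiSeries, fit_phi, linearity_report

rng = np.random.default_rng(1)
phi = np.linspace(0.04, 0.32, 8)
truth = -3.0 * phi + 0.5 * phi ** 2           # kcal/mol
noisy = truth + rng.normal(0.0, 0.02, len(phi))
series = PhiSeries(phi, noisy, errors=np.full(len(phi), 0.02))

fit = fit_phi(series, order=2, holdout_last=True)
print(f"fit through origin: a = {fit.a:+.3f}, b = {fit.b:+.3f} kcal/mol")
print(f"extrapolated value at phi = {phi[-1]:.2f}: {fit.prediction:+.3f} "
      f"(observed {noisy[-1]:+.3f}, z = {fit.z_score:+.2f})")
print(f"quadratic/linear term ratio at phi = 0.30: "
      f"{linearity_report(fit, 0.30):.3f}")
# A small ratio means the concentration dependence is nearly linear, so
# low-concentration runs extrapolate reliably to crowded conditions where
# direct insertion becomes expensive.
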