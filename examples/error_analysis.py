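"""Bootstrap and Flyvbjerg-Petersen blocking error estimates for a
correlated sample series.

Run:  python examples/error_analysis.py
"""

import numpy as np

from crowdxfer import blocking_error, bootstrap_error

rng = np.random.default_rng(0)
n, rho = 8192, 0.9
x = np.empty(n)
x[0] = rng.standard_normal()
innov = rng.standard_normal(n) * np.sqrt(1 - rho ** 2)
for i in range(1, n):
    x[i] = rho * x[i - 1] + innov[i]

boot = bootstrap_error(x, n_boot=5000, seed=1)
block, curve = blocking_error(x)
naive = x.std(ddof=1) / np.sqrt(n)

print(f"bootstrap (sample sigma):        {boot:.4f}")
print(f"naive standard error of mean:    {naive:.4f}")
print(f"blocking standard error of mean: {block:.4f}")
print(f"blocking inflation vs naive:     {block / naive:.2f} "
      f"(theory sqrt(1.9/0.1) = {np.sqrt(19):.2f})")
# The bootstrap reports the spread of individual samples; blocking keeps
# halving the series into block averages until correlations die out, so
# its estimate of the error of the mean is honest for correlated data.
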