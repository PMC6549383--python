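"""Error estimators for per-sample Monte Carlo series.

Two procedures: a bootstrap that reports the mean standard deviation over
resamples (a sample-to-sample spread), and Flyvbjerg-Petersen blocking,
which estimates the standard error of the mean of a correlated series by
repeated pairwise averaging until the variance-of-the-mean estimate
plateaus. Note the two live on different scales: for iid data of length n,
blocking ~ bootstrap / sqrt(n).
"""

from __future__ import annotations

import math
import warnings

import numpy as np


def bootstrap_error(series, n_boot: int = 10_000, seed: int = 0,
                    chunk: int = 200) -> float:
    """Mean of the standard deviations (ddof=1) of ``n_boot`` bootstrap
    resamples of ``series`` (each resample the same size, drawn with
    replacement). Deterministic for fixed ``seed``."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("series must be 1-D with length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if np.all(x == x[0]):
        return 0.0
    rng = np.random.default_rng(seed)
    n = len(x)
    total = 0.0
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(m, n))
        total += float(x[idx].std(axis=1, ddof=1).sum())
        done += m
    return total / n_boot


def blocking_error(series, min_blocks: int = 15):
    """Flyvbjerg-Petersen blocking estimate of the standard error of the
    mean of a (possibly autocorrelated) series.

    Successive generations replace pairs of neighbours by their average
    (odd leftover dropped); each generation's variance-of-the-mean is
    var(x, ddof=1)/n_g. The plateau is the first generation whose change to
    the next is within the estimate's own uncertainty
    sqrt(2/(n_g - 1)) * estimate; if no plateau is found before the block
    count drops below ``min_blocks``, the maximum over generations is
    returned with a warning.

    Returns ``(error, curve)`` where ``curve`` is the per-generation
    variance-of-the-mean estimates.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 2 * min_blocks:
        raise ValueError(f"series must be 1-D with length >= {2 * min_blocks}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    curve = []
    while len(x) >= min_blocks:
        n = len(x)
        curve.append(x.var(ddof=1) / n)
        if n // 2 < min_blocks:
            break
        x = 0.5 * (x[: 2 * (n // 2) : 2] + x[1: 2 * (n // 2): 2])
    curve = np.asarray(curve)
    ng = len(series)
    for g in range(len(curve) - 1):
        unc = math.sqrt(2.0 / max(ng - 1, 1)) * curve[g]
        if abs(curve[g + 1] - curve[g]) <= unc:
            return math.sqrt(curve[g + 1]), curve
        ng //= 2
    warnings.warn("no blocking plateau found; returning maximum estimate")
    return math.sqrt(curve.max()), curve
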