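"""Small statistical utilities: a dip-style unimodality test and significance tiers."""

from __future__ import annotations

import numpy as np


def _lower_hull_maxdev(xs: np.ndarray, fs: np.ndarray) -> float:
    """Max vertical deviation of the points above their lower convex hull."""
    m = len(xs)
    if m < 3:
        return 0.0
    hull = [0]
    for i in range(1, m):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            # drop b if it lies on or above segment a->i
            if (fs[b] - fs[a]) * (xs[i] - xs[a]) >= (fs[i] - fs[a]) * (xs[b] - xs[a]):
                hull.pop()
            else:
                break
        hull.append(i)
    hx = xs[hull]
    hf = fs[hull]
    interp = np.interp(xs, hx, hf)
    return float(np.max(fs - interp))


def dip_statistic(x: np.ndarray, n_modes: int = 50) -> float:
    """Dip-style departure of a sample's ECDF from the nearest unimodal CDF.

    For each candidate mode the ECDF must be convex to the left and concave
    to the right; the sup-distance to the best such fit is half the maximal
    deviation from the convex minorant (left) / concave majorant (right).
    The statistic is the minimum over candidate modes (quantile-spaced, at
    most ``n_modes``) of the larger of the two half-deviations.  The null
    distribution is obtained by Monte Carlo (see :func:`dip_test`), so only
    internal consistency of the formula matters.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 4 or x[0] == x[-1]:
        return 0.0
    fs = (np.arange(n) + 0.5) / n
    ks = np.unique(np.linspace(1, n - 2, min(n_modes, n - 2)).astype(int))
    best = np.inf
    for k in ks:
        left = _lower_hull_maxdev(x[: k + 1], fs[: k + 1]) / 2.0
        right = _lower_hull_maxdev(x[k:], -fs[k:]) / 2.0
        best = min(best, max(left, right))
    return float(best)


def dip_test(x: np.ndarray, n_boot: int = 200, seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo test of unimodality based on :func:`dip_statistic`.

    The null is simulated from uniform samples of the same size (the
    least-favourable unimodal case).  Returns ``(dip, pvalue)``; small p
    rejects unimodality.
    """
    x = np.asarray(x, dtype=float)
    d = dip_statistic(x)
    rng = np.random.default_rng(seed)
    null = np.array([dip_statistic(rng.uniform(size=len(x))) for _ in range(n_boot)])
    p = (1.0 + float(np.sum(null >= d))) / (n_boot + 1.0)
    return d, p


def significance_tier(p: float) -> str:
    """Map a p-value to the figure-legend significance tier.

    ``NS`` for p > 0.05, ``*`` for p < 0.01, ``**`` for p < 1e-10, ``****``
    for p < 2.2e-16.  The tier scheme leaves 0.01 <= p <= 0.05 unnamed; it is
    reported as the NS-adjacent tier ``ns*``.
    """
    if p < 2.2e-16:
        return "****"
    if p < 1e-10:
        return "**"
    if p < 0.01:
        return "*"
    if p > 0.05:
        return "NS"
    return "ns*"
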