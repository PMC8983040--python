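"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: the circle
oracle is a zooming grid search over the centre with the radius in closed
form, and the chi-square p-value oracle is the closed-form df=3 survival
function.
"""

import math

import numpy as np


def brute_force_circle(points, n_grid=41, n_zoom=4):
    """Geometric least-squares circle by nested grid search over the centre.

    For a fixed centre the optimal radius is the mean point distance; the
    centre minimizing sum((|p - c| - r)^2) is found by zooming grids.
    Returns (cx, cy, r).
    """
    pts = np.asarray(points, dtype=float)
    c = pts.mean(axis=0)
    span = max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1]), 1.0)
    for _ in range(n_zoom):
        xs = np.linspace(c[0] - span, c[0] + span, n_grid)
        ys = np.linspace(c[1] - span, c[1] + span, n_grid)
        best = (np.inf, c, 0.0)
        for cx in xs:
            for cy in ys:
                d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
                r = d.mean()
                sse = float(np.sum((d - r) ** 2))
                if sse < best[0]:
                    best = (sse, np.array([cx, cy]), r)
        c = best[1]
        span *= 2.5 / (n_grid - 1)
    return float(c[0]), float(c[1]), float(best[2])


def chi2_sf_df3(x: float) -> float:
    """Closed-form survival function of chi-square with 3 degrees of freedom:
    S(x) = 2 * (1 - Phi(sqrt(x))) + sqrt(2 x / pi) * exp(-x / 2)."""
    if x <= 0:
        return 1.0
    phi = 0.5 * (1.0 + math.erf(math.sqrt(x) / math.sqrt(2.0)))
    return 2.0 * (1.0 - phi) + math.sqrt(2.0 * x / math.pi) * math.exp(-x / 2.0)


def exact_quadrant_chi2_power(probs, n: int, alpha: float = 0.05) -> float:
    """Exact power of the quadrant chi-square by full multinomial enumeration."""
    from math import exp, lgamma

    from scipy import stats as sps

    p = np.asarray(probs, dtype=float)
    crit = sps.chi2.isf(alpha, 3)
    lp = np.log(p)
    lgn = lgamma(n + 1)
    e = n / 4.0
    power = 0.0
    for c1 in range(n + 1):
        for c2 in range(n - c1 + 1):
            for c3 in range(n - c1 - c2 + 1):
                c4 = n - c1 - c2 - c3
                c = (c1, c2, c3, c4)
                chi2 = sum((ci - e) ** 2 / e for ci in c)
                if chi2 > crit:
                    ll = lgn - sum(lgamma(ci + 1) for ci in c) + sum(
                        ci * lpi for ci, lpi in zip(c, lp))
                    power += exp(ll)
    return float(power)


def circular_resultant_null_p99(n: int, reps: int = 3000, seed: int = 0) -> float:
    """99th percentile of the mean resultant length of n uniform angles."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 2 * np.pi, size=(reps, n))
    r = np.hypot(np.cos(a).mean(axis=1), np.sin(a).mean(axis=1))
    return float(np.quantile(r, 0.99))
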