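"""Independent oracles used by the tests.

Everything here is deliberately naive — explicit loops and exact rational
arithmetic — and shares no code with the implementation it checks.
"""

from fractions import Fraction
from math import comb, log

import numpy as np


def kapur_criterion(hist, t) -> float:
    """Two-class entropy sum at threshold t, by explicit loops."""
    hist = np.asarray(hist, dtype=float)
    w0 = hist[: t + 1].sum()
    w1 = hist.sum() - w0
    if w0 == 0 or w1 == 0:
        return -np.inf
    h = 0.0
    for c, w in [(c, w0) for c in hist[: t + 1]] + [(c, w1) for c in hist[t + 1 :]]:
        if c > 0:
            h -= (c / w) * log(c / w)
    return h


def kapur_bruteforce(hist) -> int:
    """Exhaustive-search maximum of the two-class entropy-sum criterion."""
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    best_t, best_crit = None, -np.inf
    for t in range(hist.size - 1):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        h0 = 0.0
        for c in hist[: t + 1]:
            if c > 0:
                q = c / w0
                h0 -= q * log(q)
        h1 = 0.0
        for c in hist[t + 1 :]:
            if c > 0:
                q = c / w1
                h1 -= q * log(q)
        if h0 + h1 > best_crit:
            best_crit, best_t = h0 + h1, t
    return best_t


def binomial_minlike_exact(k: int, n: int, p0: Fraction) -> float:
    """Two-sided minimum-likelihood binomial p-value in exact arithmetic."""
    q0 = 1 - p0
    pmf = [comb(n, j) * p0**j * q0 ** (n - j) for j in range(n + 1)]
    p_obs = pmf[k]
    return float(min(sum(p for p in pmf if p <= p_obs), Fraction(1)))


def fisher_minlike_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided minimum-likelihood Fisher p-value in exact arithmetic."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = comb(n, c1)
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)
    pmf = {
        x: Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom) for x in range(lo, hi + 1)
    }
    p_obs = pmf[a]
    return float(min(sum(p for p in pmf.values() if p <= p_obs), Fraction(1)))


def uniform_ellipse_major_fraction_mc(a: float, b: float, n: int, seed: int) -> float:
    """Monte-Carlo fraction of uniform ellipse points within 45 deg of the major axis."""
    rng = np.random.default_rng(seed)
    hits = total = 0
    while total < n:
        m = min(n - total, 200_000)
        x = rng.uniform(-a, a, m)
        y = rng.uniform(-b, b, m)
        inside = (x / a) ** 2 + (y / b) ** 2 <= 1.0
        x, y = x[inside], y[inside]
        theta = np.degrees(np.arctan2(y, x)) % 180.0
        hits += int(((theta <= 45.0) | (theta >= 135.0)).sum())
        total += int(inside.sum())
    return hits / total
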