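"""Random-positioning null models and the study's statistical tests.

The axial-orientation analysis needs the probability that a *randomly*
positioned territory classifies as major-parallel.  Three nulls are
provided and reported side by side:

* ``naive`` — p_major = 0.5 (the angle itself uniform on [0, 180));
* ``ellipse_corrected`` — territory centroid uniform over the
  moment-equivalent ellipse.  The probability that such a point lies
  within 45 degrees (central angle) of the major-axis line has the closed
  form ``p = (2/pi) * arctan(a/b)``: the elliptical sector from polar
  angle 0 to phi has area (ab/2)*t with parametric angle
  t = arctan((a/b) tan phi), and the within-45-degree region is two
  opposite 90-degree sectors.  This corrects for the greater run of the
  major axis in elongated nuclei.
* ``empirical_mask`` — Monte-Carlo over the actual segmented mask pixels,
  for masks that are far from elliptical.

Exact tests use the minimum-likelihood two-sided convention (sum the
probabilities of all outcomes no more likely than the observed one), the
convention of mainstream biostatistics software, so p-values here are
directly comparable with typical published values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats as sps

from .errors import DataError, UserError
from .morphometry import NuclearShape
from .segment import NuclearMask


@dataclass
class AxialNull:
    p_major: float
    model: Literal["naive", "ellipse_corrected", "empirical_mask"]
    parameters: dict = field(default_factory=dict)
    se: float | None = None


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    n: int


NAIVE_NULL = AxialNull(p_major=0.5, model="naive")


def expected_major_fraction_ellipse(a: float, b: float) -> AxialNull:
    """Closed-form random-positioning null for an ellipse with semi-axes a >= b."""
    if not (a >= b > 0):
        raise UserError("require a >= b > 0")
    p = float(2.0 / np.pi * np.arctan(a / b))
    return AxialNull(p_major=p, model="ellipse_corrected", parameters={"a": a, "b": b})


def expected_major_fraction_mask(
    mask: NuclearMask | np.ndarray,
    shape: NuclearShape,
    n_mc: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> AxialNull:
    """Monte-Carlo random-positioning null over the actual mask pixels.

    Samples ``n_mc`` points uniformly over the area of the mask (a random
    pixel plus uniform jitter within it, so the mask is treated as a region
    rather than a lattice), classifies each centroid direction against the
    measured major axis, and returns the major-parallel fraction with its
    binomial standard error.
    """
    if n_mc < 100:
        raise UserError("n_mc must be >= 100")
    pixels = mask.pixels if isinstance(mask, NuclearMask) else np.asarray(mask)
    rows, cols = np.nonzero(pixels)
    if rows.size == 0:
        raise UserError("empty mask")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, rows.size, size=n_mc)
    jitter = rng.uniform(-0.5, 0.5, size=(2, n_mc))
    dx = cols[idx] + jitter[0] - shape.centroid_xy[0]
    dy = rows[idx] + jitter[1] - shape.centroid_xy[1]
    keep = (dx != 0) | (dy != 0)
    theta = np.mod(
        np.degrees(np.arctan2(-dy[keep], dx[keep])) - shape.orientation_deg, 180.0
    )
    hits = (theta <= 45.0) | (theta >= 135.0)
    p = float(hits.mean())
    return AxialNull(
        p_major=p,
        model="empirical_mask",
        parameters={"n_mc": n_mc},
        se=float(np.sqrt(p * (1 - p) / hits.size)),
    )


def expected_cell_class_probability(
    p_major: float, scheme: Literal["normal", "tumor"], n: int
) -> float:
    """Null probability of the per-cell class under independent positioning.

    normal (n must be 2): P(both_minor) = (1 - p_major)^2.
    tumor: P(at least ceil(n/2) of n territories major-parallel), binomial.
    """
    if not 0 < p_major < 1:
        raise UserError("p_major must be in (0, 1)")
    if scheme == "normal":
        if n != 2:
            raise UserError("normal scheme requires n = 2")
        return float((1.0 - p_major) ** 2)
    if scheme == "tumor":
        if n < 1:
            raise UserError("n must be >= 1")
        k = int(np.ceil(n / 2))
        return float(sps.binom.sf(k - 1, n, p_major))
    raise UserError(f"unknown scheme {scheme!r}")


_TIE_REL_TOL = 1e-12  # absorbs float noise when detecting equally likely outcomes


def _snap_unit(p: float) -> float:
    """Clamp a p-value to [0, 1], snapping float dust below an exact 1."""
    if p > 1.0 - _TIE_REL_TOL:
        return 1.0
    return max(p, 0.0)


def binomial_obs_vs_expected(k: int, n: int, p0: float) -> TestResult:
    """Exact two-sided binomial test (minimum-likelihood tail).

    The p-value sums P(X = j) over every j whose probability does not
    exceed P(X = k), capped at 1 — the observed-vs-expected count test of
    mainstream biostatistics software.
    """
    if not (0 <= k <= n) or n < 1:
        raise UserError("require 0 <= k <= n, n >= 1")
    if not 0 < p0 < 1:
        raise UserError("p0 must be in (0, 1)")
    pmf = sps.binom.pmf(np.arange(n + 1), n, p0)
    p = float(pmf[pmf <= pmf[k] * (1.0 + _TIE_REL_TOL)].sum())
    return TestResult(
        statistic=k / n, p_value=_snap_unit(p), test_name="binomial", n=n
    )


def fisher_exact_2x2(table: np.ndarray) -> TestResult:
    """Fisher's exact test on a 2x2 table, two-sided (minimum-likelihood).

    Sums the hypergeometric probabilities of every table with the observed
    margins that is no more likely than the observed one.  The statistic is
    the sample odds ratio (inf when only the off-diagonal is empty, nan for
    a degenerate margin).
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise UserError("table must be 2x2")
    if np.any(table < 0):
        raise UserError("counts must be nonnegative")
    total = int(table.sum())
    if total == 0:
        raise UserError("table total must be > 0")
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    r1, c1 = a + b, a + c
    support = np.arange(max(0, c1 - (c + d)), min(r1, c1) + 1)
    pmf = sps.hypergeom.pmf(support, total, r1, c1)
    p_obs = sps.hypergeom.pmf(a, total, r1, c1)
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_REL_TOL)].sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.divide(a * d, b * c) if b * c else (np.inf if a * d else np.nan)
    return TestResult(
        statistic=float(odds), p_value=_snap_unit(p), test_name="fisher_exact", n=total
    )


def welch_t(group_a: np.ndarray, group_b: np.ndarray) -> TestResult:
    """Two-tailed t-test with Welch's correction (unequal variances)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise UserError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise DataError("zero variance in both groups")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(
        statistic=float(t), p_value=float(p), test_name="welch_t", n=a.size + b.size
    )


def coefficient_of_variation(values: np.ndarray) -> float:
    """Sample standard deviation divided by the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise UserError("need n >= 2")
    mean = v.mean()
    if mean == 0:
        raise DataError("zero mean; CV undefined")
    return float(np.std(v, ddof=1) / mean)


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (off by default in the pipeline)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (p.size - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
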