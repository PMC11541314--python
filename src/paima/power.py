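"""Dichotomous case-control power and sample size.

Design: ``n`` cases and ``m * n`` controls; exposure probability ``p0``
in controls; odds ratio ``psi`` so that the case exposure probability is
``p1 = psi p0 / (1 + p0 (psi - 1))``; two-sided Fisher exact test at
level ``alpha`` (one-sided available).

Two power evaluations are returned:

* ``power_exact`` — full enumeration: the exposed counts are
  X ~ Bin(m n, p0) in controls and Y ~ Bin(n, p1) in cases, and the power
  is the joint probability of all (x, y) tables rejected by the
  two-sided Fisher exact test ("sum of small p" convention, as in R's
  ``fisher.test``).  Binomial tails below a mass cutoff are truncated for
  large designs; the truncated mass bounds the error and is reported.
* ``power_cc`` — the continuity-corrected two-proportion normal
  approximation (Casagrande-Pike-Smith / Fleiss), the closed form used by
  the classical PS-style calculators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

_TAIL_EPS = 1e-13  # binomial support truncation for the enumeration
_PVAL_SLOP = 1.0 + 1e-7  # two-sided "small p" comparison tolerance


@dataclass(frozen=True)
class PowerDesign:
    """Parameters of the dichotomous case-control design."""

    alpha: float
    p0: float
    psi: float
    n: int
    m: float = 1.0
    sided: str = "two"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must be in (0, 1)")
        if self.psi <= 0:
            raise ValueError("psi (odds ratio) must be positive")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.m <= 0:
            raise ValueError("m must be positive")
        if self.sided not in ("two", "one"):
            raise ValueError("sided must be 'two' or 'one'")

    @property
    def n_controls(self) -> int:
        exact = self.n * self.m
        rounded = int(round(exact))
        if abs(exact - rounded) > 1e-9:
            log.warning("n*m = %s is not an integer; rounding to %d controls", exact, rounded)
        return rounded


@dataclass(frozen=True)
class PowerResult:
    """Implied case exposure probability and the two power evaluations."""

    p1: float
    power_exact: float | None
    power_cc: float
    truncation_error: float | None = None

    def to_dict(self) -> dict:
        return {
            "p1": self.p1,
            "power_exact": self.power_exact,
            "power_cc": self.power_cc,
            "truncation_error": self.truncation_error,
        }


def implied_p1(p0: float, psi: float) -> float:
    """Case exposure probability implied by control exposure and odds ratio."""
    return psi * p0 / (1.0 + p0 * (psi - 1.0))


def _binom_window(n: int, p: float) -> tuple[int, int]:
    """Support window holding all but ~_TAIL_EPS of a binomial's mass."""
    lo = int(stats.binom.ppf(_TAIL_EPS, n, p))
    hi = int(stats.binom.ppf(1.0 - _TAIL_EPS, n, p))
    return max(lo - 2, 0), min(hi + 2, n)


def _fisher_rejection(n1: int, n0: int, k: int, alpha: float, sided: str) -> np.ndarray:
    """Boolean rejection mask over y = max(0, k - n0) .. min(n1, k).

    Conditional on k total exposed, Y | k is hypergeometric; the
    two-sided Fisher p-value of an observed y is the sum of all outcome
    probabilities not exceeding its own.
    """
    ylo, yhi = max(0, k - n0), min(n1, k)
    ys = np.arange(ylo, yhi + 1)
    pmf = stats.hypergeom.pmf(ys, n1 + n0, n1, k)
    if sided == "one":
        # greater-alternative one-sided test (psi > 1 direction)
        pvals = np.cumsum(pmf[::-1])[::-1]
    else:
        order = np.argsort(pmf, kind="mergesort")
        sorted_cum = np.cumsum(pmf[order])
        # p-value of y = mass of all outcomes with pmf <= pmf(y) (with slop)
        pvals = np.empty_like(pmf)
        sorted_pmf = pmf[order]
        idx = np.searchsorted(sorted_pmf, pmf * _PVAL_SLOP, side="right") - 1
        pvals = sorted_cum[idx]
    return pvals <= alpha


def power(design: PowerDesign, exact: bool = True) -> PowerResult:
    """Evaluate the design's power (exact enumeration + normal approximation)."""
    p1 = implied_p1(design.p0, design.psi)
    cc = _power_cc(design, p1)
    if not exact:
        return PowerResult(p1=p1, power_exact=None, power_cc=cc)

    n1, n0 = design.n, design.n_controls
    ylo, yhi = _binom_window(n1, p1)
    xlo, xhi = _binom_window(n0, design.p0)
    py = stats.binom.pmf(np.arange(n1 + 1), n1, p1)
    px = stats.binom.pmf(np.arange(n0 + 1), n0, design.p0)
    total_power = 0.0
    covered = 0.0
    for k in range(ylo + xlo, yhi + xhi + 1):
        reject = _fisher_rejection(n1, n0, k, design.alpha, design.sided)
        ys_all = np.arange(max(0, k - n0), min(n1, k) + 1)
        window = (ys_all >= ylo) & (ys_all <= yhi) & (k - ys_all >= xlo) & (k - ys_all <= xhi)
        ys = ys_all[window]
        joint = py[ys] * px[k - ys]
        covered += joint.sum()
        total_power += joint[reject[window]].sum()
    truncation = max(0.0, 1.0 - covered)
    return PowerResult(
        p1=p1,
        power_exact=float(total_power),
        power_cc=cc,
        truncation_error=float(truncation),
    )


def _power_cc(design: PowerDesign, p1: float) -> float:
    """Continuity-corrected two-proportion normal approximation."""
    n1, n0 = design.n, design.n_controls
    p0 = design.p0
    pbar = (n1 * p1 + n0 * p0) / (n1 + n0)
    se0 = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n0))
    se1 = np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0)
    cc = 0.5 * (1 / n1 + 1 / n0)
    z_alpha = stats.norm.ppf(1 - design.alpha / (2 if design.sided == "two" else 1))
    delta = abs(p1 - p0)
    z = (delta - cc - z_alpha * se0) / se1
    return float(stats.norm.cdf(z))


def sample_size(
    alpha: float,
    p0: float,
    psi: float,
    target_power: float,
    m: float = 1.0,
    sided: str = "two",
    n_max: int = 100_000,
) -> int:
    """Smallest case count n whose exact power reaches ``target_power``.

    Bisects the monotone normal approximation for a bracket, then walks
    the exact enumeration (which is not exactly monotone in n for an
    exact test) to the smallest qualifying n.
    """
    if not alpha < target_power < 1:
        raise ValueError("target power must lie in (alpha, 1)")

    def cc_power(n: int) -> float:
        return power(PowerDesign(alpha, p0, psi, max(n, 2), m, sided), exact=False).power_cc

    lo, hi = 2, 4
    while cc_power(hi) < target_power:
        hi *= 2
        if hi > n_max:
            raise ValueError("design cannot reach the target power within n_max")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if cc_power(mid) >= target_power:
            hi = mid
        else:
            lo = mid

    def exact_power(n: int) -> float:
        return power(PowerDesign(alpha, p0, psi, max(n, 2), m, sided)).power_exact

    n = hi
    # walk down while still powered, then up if the bracket fell short
    while n > 2 and exact_power(n - 1) >= target_power:
        n -= 1
    while exact_power(n) < target_power:
        n += 1
        if n > n_max:
            raise ValueError("design cannot reach the target power within n_max")
    return n
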