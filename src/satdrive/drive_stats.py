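"""Meiotic drive strength (k) with viability correction, and exact tests.

In a Segregation Distorter (SD) system, drive strength *k* is the
proportion of offspring of a heterozygous SD/+ father that inherit the SD
chromosome: k = 0.5 is Mendelian transmission, k = 1.0 is perfect drive.
Raw counts confound drive with differential viability of SD-bearing
offspring, so each male test cross is paired with a reciprocal cross
through a heterozygous SD/+ mother, in which transmission is Mendelian and
any departure of the SD:+ ratio from 1:1 estimates relative viability.
The correction rescales the male cross's SD count by that viability factor
before recomputing the proportion.

Drive sensitivity between two genotypes is compared with Fisher's exact
test on the 2x2 table of (SD, +) offspring counts, two-sided by the
probability-mass rule (summing hypergeometric probabilities of all tables
no more probable than the observed one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CrossCounts:
    """Offspring counts for a male test cross and optional reciprocal cross."""

    male_sd: int
    male_plus: int
    reciprocal_sd: int | None = None
    reciprocal_plus: int | None = None
    line_id: str = ""

    def __post_init__(self) -> None:
        for v in (self.male_sd, self.male_plus, self.reciprocal_sd, self.reciprocal_plus):
            if v is not None and v < 0:
                raise ValueError("offspring counts must be non-negative")


@dataclass(frozen=True)
class DriveEstimate:
    k_raw: float
    viability: float
    k_corrected: float
    ci_low: float
    ci_high: float
    n: int


def viability_factor(reciprocal: tuple[int, int] | None) -> float:
    """Relative viability of SD-bearing offspring from the reciprocal cross.

    ``v = n_SD / n_plus`` of the female (Mendelian-transmission) cross;
    1.0 when no reciprocal cross is available.
    """
    if reciprocal is None:
        return 1.0
    n_sd, n_plus = reciprocal
    if n_plus <= 0:
        raise ValueError("reciprocal cross has no wild-type offspring; correction undefined")
    if n_sd <= 0:
        raise ValueError("reciprocal cross has no SD offspring; correction undefined")
    return n_sd / n_plus


def clopper_pearson(successes: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for a proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    lo = stats.beta.ppf(alpha / 2, successes, n - successes + 1) if successes > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes) if successes < n else 1.0
    return float(lo), float(hi)


def k_value(male: tuple[int, int], v: float = 1.0, alpha: float = 0.05) -> DriveEstimate:
    """Viability-corrected drive strength from a male test cross.

    ``k_raw = n_SD / (n_SD + n_plus)``; the corrected value rescales the SD
    count by 1/v, so ``k_corrected = (n_SD/v) / (n_SD/v + n_plus)``.  With
    v = 1 the correction is the identity.  The Clopper-Pearson confidence
    interval is computed on the raw counts (reported alongside, not
    corrected).
    """
    n_sd, n_plus = male
    n = n_sd + n_plus
    if n <= 0:
        raise ValueError("male cross must have offspring")
    if v <= 0:
        raise ValueError("viability factor must be positive")
    k_raw = n_sd / n
    adj = n_sd / v
    k_corr = adj / (adj + n_plus)
    lo, hi = clopper_pearson(n_sd, n, alpha)
    return DriveEstimate(
        k_raw=k_raw, viability=v, k_corrected=k_corr, ci_low=lo, ci_high=hi, n=n
    )


def estimate_drive(cross: CrossCounts, alpha: float = 0.05) -> DriveEstimate:
    """Convenience: viability factor from the reciprocal cross, then k."""
    recip = (
        (cross.reciprocal_sd, cross.reciprocal_plus)
        if cross.reciprocal_sd is not None and cross.reciprocal_plus is not None
        else None
    )
    return k_value((cross.male_sd, cross.male_plus), viability_factor(recip), alpha)


def drive_test(counts_a: tuple[int, int], counts_b: tuple[int, int]) -> float:
    """Two-sided Fisher's exact test comparing two (SD, +) offspring tables.

    P-value by the probability-mass rule: the sum, over all tables with the
    observed margins, of hypergeometric probabilities not exceeding that of
    the observed table (a relative tolerance of 1e-10 guards floating-point
    ties).  Degenerate margins (an empty row or column) yield p = 1.
    """
    a, b = counts_a
    c, d = counts_b
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        warnings.warn("drive_test: degenerate table margin, p = 1", stacklevel=2)
        return 1.0
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1 + 1e-10)].sum())
    return min(p, 1.0)
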