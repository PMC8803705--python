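"""Elementary inferential machinery: t-tests, Holm correction, Fisher exact.

These are implemented from first principles (with the t distribution taken
from scipy) so that every reported p-value has an auditable computation:
Welch's t with Welch–Satterthwaite degrees of freedom, the paired t-test on
differences, the Bonferroni–Holm step-down adjustment, and the two-sided
Fisher exact test by full hypergeometric enumeration under the
point-probability rule (sum the probabilities of all tables with the same
margins that are no more probable than the observed one).

Mixed-model analyses (site-season × Tₐ interactions and Tukey-adjusted
marginal means) are deliberately not re-implemented; ``model_ready_table``
exports the tidy per-animal-per-bin data those models consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

WELCH = "WELCH"
PAIRED = "PAIRED"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | None
    p: float
    comparison: str = ""
    adjusted_p: float | None = None
    odds_ratio: float | None = None


def welch_or_paired_t(
    x: Sequence[float], y: Sequence[float], mode: str = WELCH, comparison: str = ""
) -> TestResult:
    """Two-sided t-test: Welch (unequal variances) or paired on differences.

    Degenerate zero-variance input with equal means returns t = 0, p = 1 by
    convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if mode == PAIRED:
        if len(x) != len(y):
            raise ValueError("paired test requires equal-length samples")
        d = x - y
        n = len(d)
        if n < 2:
            raise ValueError("need at least 2 pairs")
        sd = d.std(ddof=1)
        if sd == 0:
            p = 1.0 if d.mean() == 0 else 0.0
            return TestResult(statistic=0.0 if d.mean() == 0 else math.inf,
                              df=float(n - 1), p=p, comparison=comparison)
        t = d.mean() / (sd / math.sqrt(n))
        df = float(n - 1)
    elif mode == WELCH:
        if len(x) < 2 or len(y) < 2:
            raise ValueError("need at least 2 observations per sample")
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        nx, ny = len(x), len(y)
        se2 = vx / nx + vy / ny
        if se2 == 0:
            p = 1.0 if x.mean() == y.mean() else 0.0
            return TestResult(statistic=0.0 if p == 1.0 else math.inf,
                              df=float(nx + ny - 2), p=p, comparison=comparison)
        t = (x.mean() - y.mean()) / math.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    else:
        raise ValueError("mode must be WELCH or PAIRED")
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p=float(min(1.0, p)),
                      comparison=comparison)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Bonferroni–Holm step-down adjustment, order-preserving.

    Sort ascending, multiply the i-th smallest by (m − i), enforce a
    monotone cumulative maximum, cap at 1, and restore the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    adjusted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _log_hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    """log P(A = a) for a 2×2 table with margins (r1, r2; c1, ·)."""
    lg = math.lgamma
    def lchoose(n, k):
        return lg(n + 1) - lg(k + 1) - lg(n - k + 1)
    n = r1 + r2
    return lchoose(r1, a) + lchoose(r2, c1 - a) - lchoose(n, c1)


def fisher_exact_two_sided(
    a: int, b: int, c: int, d: int, comparison: str = ""
) -> TestResult:
    """Two-sided Fisher exact test by the point-probability rule.

    Enumerates every table sharing the observed margins and sums the
    probabilities of those no more probable than the observed table (a tiny
    relative tolerance absorbs floating-point ties).  Degenerate margins
    (an empty row or column) give p = 1.  The reported odds ratio is the
    sample odds ratio ad/bc (inf or nan when undefined).
    """
    counts = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in counts):
        raise ValueError("counts must be non-negative integers")
    a, b, c, d = (int(x) for x in counts)
    r1, r2, c1 = a + b, c + d, a + c
    if b * c == 0:
        oratio = math.inf if a * d > 0 else math.nan
    else:
        oratio = (a * d) / (b * c)
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return TestResult(statistic=math.nan, df=None, p=1.0,
                          comparison=comparison, odds_ratio=oratio)
    lp_obs = _log_hypergeom_pmf(a, r1, r2, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = 0.0
    for k in range(lo, hi + 1):
        lp = _log_hypergeom_pmf(k, r1, r2, c1)
        if lp <= lp_obs + 1e-7:
            total += math.exp(lp)
    return TestResult(statistic=math.nan, df=None, p=float(min(1.0, total)),
                      comparison=comparison, odds_ratio=oratio)


def model_ready_table(
    bin_table: pd.DataFrame, animals: pd.DataFrame
) -> pd.DataFrame:
    """Tidy per-animal-per-bin table for external mixed-model fitting.

    Joins the Tₐ-binned per-animal state means with the animal records
    (sex, body condition) so a formula such as
    ``mr ~ site_season * ta_bin + sex + smi + (1 | animal_id)`` can be fit
    directly in a dedicated mixed-model package.
    """
    cols = [c for c in ("animal_id", "sex", "smi", "bm_g", "forearm_mm") if c in animals]
    return bin_table.merge(animals[cols], on="animal_id", how="left")
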