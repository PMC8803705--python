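"""Circular statistics for torpor entry and arousal timing.

Times of day live on a circle (23:55 and 00:05 are 10 min apart), so bout
timing is summarised with the circular mean ± circular standard deviation,
uniformity is assessed with Rayleigh's test, and two groups are compared
with the Watson two-sample U² test.  Clock times map to angles anchored at
local midnight: θ = 2π · minutes / 1440.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

TWO_PI = 2.0 * math.pi

#: Asymptotic critical values for the two-sample Watson U² statistic.
WATSON_U2_CRITICAL = {0.10: 0.152, 0.05: 0.187, 0.01: 0.268, 0.001: 0.385}

#: Smallest per-sample size for which the tabulated critical values apply.
WATSON_MIN_N = 8


def times_to_angles(minutes_of_day: Sequence[float]) -> np.ndarray:
    """Map minutes past local midnight to radians on [0, 2π)."""
    return (TWO_PI * np.asarray(minutes_of_day, dtype=float) / 1440.0) % TWO_PI


def angles_to_minutes(angles: Sequence[float]) -> np.ndarray:
    """Inverse of :func:`times_to_angles`."""
    return (np.asarray(angles, dtype=float) % TWO_PI) * 1440.0 / TWO_PI


@dataclass(frozen=True)
class CircularSummary:
    mean_angle: float  # radians in [0, 2π); nan when r == 0
    sd_rad: float
    r: float

    @property
    def mean_minutes(self) -> float:
        return float(angles_to_minutes(self.mean_angle)) if not math.isnan(self.mean_angle) else math.nan

    @property
    def sd_minutes(self) -> float:
        return self.sd_rad * 1440.0 / TWO_PI


def circular_mean_sd(angles: Sequence[float]) -> CircularSummary:
    """Circular mean, circular SD (√(−2 ln r)) and resultant length r.

    With r = 0 (perfectly balanced sample) the mean direction is undefined
    and reported as NaN with infinite SD.
    """
    a = np.asarray(angles, dtype=float)
    if a.size < 1:
        raise ValueError("need at least one angle")
    c = float(np.cos(a).mean())
    s = float(np.sin(a).mean())
    r = math.hypot(c, s)
    if r < 1e-12:
        return CircularSummary(mean_angle=math.nan, sd_rad=math.inf, r=0.0)
    mean = math.atan2(s, c) % TWO_PI
    # guard against r marginally above 1 from rounding
    sd = math.sqrt(max(0.0, -2.0 * math.log(min(r, 1.0))))
    return CircularSummary(mean_angle=mean, sd_rad=sd, r=r)


def circular_sd_alt(r: float) -> float:
    """Alternative angular deviation √(2(1 − r)) (radians)."""
    return math.sqrt(max(0.0, 2.0 * (1.0 - r)))


@dataclass(frozen=True)
class RayleighResult:
    r: float
    z: float
    p: float
    n: int


def rayleigh_test(angles: Sequence[float]) -> RayleighResult:
    """Rayleigh test of circular uniformity.

    z = n·r²; the p-value uses the standard series approximation

        p = exp(−z)·[1 + (2z − z²)/(4n) − (24z − 132z² + 76z³ − 9z⁴)/(288n²)]

    clipped to [0, 1].
    """
    a = np.asarray(angles, dtype=float)
    n = a.size
    if n < 3:
        raise ValueError("Rayleigh test needs at least 3 angles")
    r = circular_mean_sd(a).r
    z = n * r * r
    p = math.exp(-z) * (
        1.0
        + (2.0 * z - z * z) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n * n)
    )
    return RayleighResult(r=r, z=z, p=min(1.0, max(0.0, p)), n=n)


def _watson_u2_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Watson U² from pooled empirical CDFs, ties handled by shared atoms.

    With distinct pooled values v_i carrying counts (a_i, b_i), weights
    w_i = (a_i + b_i)/N and CDF differences d_i = F_a(v_i) − F_b(v_i):

        U² = (n_a·n_b / N) · [Σ w_i d_i² − (Σ w_i d_i)²]

    which reduces to the classical unweighted form when there are no ties
    and is the midrank convention otherwise.
    """
    na, nb = len(a), len(b)
    n = na + nb
    pooled = np.concatenate([a, b])
    labels = np.concatenate([np.zeros(na), np.ones(nb)])
    order = np.argsort(pooled, kind="stable")
    pooled, labels = pooled[order], labels[order]
    vals, start = np.unique(pooled, return_index=True)
    counts_a = np.add.reduceat((labels == 0).astype(float), start)
    counts_b = np.add.reduceat((labels == 1).astype(float), start)
    fa = np.cumsum(counts_a) / na
    fb = np.cumsum(counts_b) / nb
    w = (counts_a + counts_b) / n
    d = fa - fb
    dbar = float(np.sum(w * d))
    return float(na * nb / n * (np.sum(w * d * d) - dbar * dbar))


@dataclass(frozen=True)
class WatsonResult:
    u2: float
    n_a: int
    n_b: int
    p_upper_bound: float | None  # smallest tabulated alpha exceeded, else None
    p_permutation: float | None = None

    def significant(self, alpha: float = 0.05) -> bool:
        if self.p_permutation is not None:
            return self.p_permutation <= alpha
        return self.u2 > WATSON_U2_CRITICAL[alpha]


def watson_two_sample(
    a: Sequence[float],
    b: Sequence[float],
    method: str = "table",
    n_permutations: int = 9999,
    seed: int | None = None,
) -> WatsonResult:
    """Watson two-sample U² test for a common circular distribution.

    ``method='table'`` compares U² with the standard asymptotic critical
    values (needs ≥ 8 observations per sample); ``method='permutation'``
    estimates a p-value by seeded label shuffling and has no minimum n.
    The statistic is invariant under a common rotation of all angles.
    """
    aa = np.asarray(a, dtype=float) % TWO_PI
    bb = np.asarray(b, dtype=float) % TWO_PI
    u2 = _watson_u2_statistic(aa, bb)
    if method == "table":
        if len(aa) < WATSON_MIN_N or len(bb) < WATSON_MIN_N:
            raise ValueError(
                f"tabulated critical values need n ≥ {WATSON_MIN_N} per sample; "
                "use method='permutation'"
            )
        p_bound = None
        for alpha in sorted(WATSON_U2_CRITICAL):  # most stringent first
            if u2 > WATSON_U2_CRITICAL[alpha]:
                p_bound = alpha
                break
        return WatsonResult(u2=u2, n_a=len(aa), n_b=len(bb), p_upper_bound=p_bound)
    if method != "permutation":
        raise ValueError("method must be 'table' or 'permutation'")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([aa, bb])
    na = len(aa)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if _watson_u2_statistic(perm[:na], perm[na:]) >= u2:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return WatsonResult(
        u2=u2, n_a=len(aa), n_b=len(bb), p_upper_bound=None, p_permutation=p
    )
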