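"""Occurrence-count distribution of a non-clumpable motif.

For a non-clumpable motif ``S`` of length ``m`` in a random text of
length ``n``, the probability of exactly ``j`` occurrences is

    P(j, m, n) = P(S)^j * sum over configurations prod_y P(S_{0, d_y})

where the sum runs over all weak compositions ``d_1 + ... + d_{j+1} =
n - m j`` of the text left free between the ``j`` placements, and
``P(S_{0,d})`` is the probability a text of length ``d`` avoids the
motif, obeying the linear recurrence

    P(S_{0,n}) = P(S_{0,n-1}) - P(S) * P(S_{0,n-m}),   P(S_{0,n}) = 1 for n < m.

The number of configurations is the binomial ``C(n + j(1-m), n - mj)``.
Direct summation is O(n^j); the production path instead exploits that
the ratio ``R = P(S_{0,n+1}) / P(S_{0,n})`` converges geometrically, so
past a convergence index ``n_eps`` every avoidance probability is
``P(S_{0,n_eps}) * R^(d - n_eps)`` and the whole sum collapses to

    P(j, m, n) ~ P(S)^j * R^(n - mj - n_eps (j+1))
                 * P(S_{0,n_eps})^(j+1) * C(n + j(1-m), n - mj).

All production arithmetic is carried in log space (log-gamma binomials)
so genome lengths in the millions and counts in the hundreds never
overflow; exponentiated probabilities are clamped to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
from scipy.special import gammaln

from .background import (
    BackgroundModel,
    MotifQuery,
    is_clumpable,
    motif_probability,
    stationary_occurrence_probability,
    validate_motif,
)

__all__ = [
    "DistributionConfig",
    "ZeroOccurrenceSeries",
    "CountDistribution",
    "zero_occurrence_series",
    "configuration_count_log",
    "exact_distribution_enumeration",
    "approx_log_probability",
    "count_distribution",
    "expected_count",
    "tail_pvalue",
    "ConvergenceError",
    "NumericalInstabilityError",
    "DegenerateMotifError",
    "ClumpableMotifError",
    "EnumerationGuardError",
]


class ConvergenceError(RuntimeError):
    """Ratio of the zero-occurrence series failed to stabilise within the
    iteration cap; carries the last observed ratio gap."""

    def __init__(self, message: str, last_gap: float | None = None):
        super().__init__(message)
        self.last_gap = last_gap


class NumericalInstabilityError(RuntimeError):
    """The recurrence produced a value outside [0, 1]."""


class DegenerateMotifError(ValueError):
    """Motif probability is 0 or 1; the count distribution is degenerate."""


class ClumpableMotifError(ValueError):
    """The formula requires a non-clumpable motif; route clumpable
    queries through their surrogate first."""


class EnumerationGuardError(RuntimeError):
    """Reference-path enumeration would exceed its tractability guard."""


@dataclass(frozen=True)
class DistributionConfig:
    """Tunable precision parameters.

    ``epsilon`` is both the ratio-convergence tolerance and the count
    cut-off level; ``j_max`` caps the number of counts evaluated;
    ``n_eps_cap`` bounds the convergence iterations.
    """

    epsilon: float = 1e-7
    j_max: int = 500
    n_eps_cap: int = 1_000_000

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon < 1e-2):
            raise ValueError(f"epsilon must be in (0, 1e-2), got {self.epsilon}")
        if self.j_max < 1:
            raise ValueError("j_max must be >= 1")


@dataclass(frozen=True)
class ZeroOccurrenceSeries:
    """The avoidance-probability series with its converged ratio.

    ``values[d]`` is P(S_{0,d}) for d = 0 .. n_epsilon; ``ratio`` is R,
    ``achieved_tolerance`` the final gap between consecutive ratios.
    """

    values: np.ndarray
    ratio: float
    n_epsilon: int
    achieved_tolerance: float
    motif_prob: float

    def avoidance_probability(self, d: int) -> float:
        """P(S_{0,d}), extrapolated geometrically past ``n_epsilon``."""
        if d <= self.n_epsilon:
            return float(self.values[d])
        return float(self.values[self.n_epsilon] * self.ratio ** (d - self.n_epsilon))


def zero_occurrence_series(
    P_S: float, m: int, config: DistributionConfig | None = None
) -> ZeroOccurrenceSeries:
    """Iterate the avoidance recurrence until its ratio stabilises.

    Terminates at the first index ``n`` where the gap between
    consecutive ratios ``p_n/p_{n-1}`` drops to ``epsilon`` or below;
    raises :class:`ConvergenceError` if ``n_eps_cap`` iterations pass
    without stabilisation and :class:`NumericalInstabilityError` if any
    value leaves [0, 1] (the recurrence is unstable for large P(S)).
    """
    config = config or DistributionConfig()
    if not (0.0 < P_S < 1.0):
        raise DegenerateMotifError(f"P(S) must be in (0, 1), got {P_S}")
    if m < 1:
        raise ValueError("motif length must be >= 1")

    values = [1.0] * m
    values.append(1.0 - P_S)  # p_m
    prev_ratio = values[m] / values[m - 1]
    n = m
    gap = math.inf
    while True:
        n += 1
        if n - m > config.n_eps_cap:
            raise ConvergenceError(
                f"ratio gap {gap:.3e} after {config.n_eps_cap} iterations "
                f"(epsilon={config.epsilon})",
                last_gap=gap,
            )
        p = values[n - 1] - P_S * values[n - m]
        if not (0.0 < p <= 1.0):
            raise NumericalInstabilityError(
                f"avoidance probability left (0, 1] at n={n} (P(S)={P_S}, m={m})"
            )
        values.append(p)
        ratio = p / values[n - 1]
        gap = abs(ratio - prev_ratio)
        if gap <= config.epsilon:
            return ZeroOccurrenceSeries(
                np.asarray(values), ratio, n, gap, P_S
            )
        prev_ratio = ratio


def configuration_count_log(n: int, m: int, j: int) -> float:
    """log of the number of placement configurations
    ``C(n + j(1-m), n - mj)``: the ways j non-overlapping length-m
    placements split n - mj free positions into j + 1 segments.

    Returns ``-inf`` when ``n - mj < 0`` (more placements than fit).
    Computed via log-gamma so n in the millions never overflows.
    """
    if n < 0 or m < 0 or j < 0:
        raise ValueError("n, m, j must be nonnegative")
    t = n - m * j
    if t < 0:
        return -math.inf
    top = n + j * (1 - m)  # = t + j
    return float(gammaln(top + 1) - gammaln(t + 1) - gammaln(j + 1))


def _compositions(total: int, parts: int) -> Iterator[tuple[int, ...]]:
    """Weak compositions of ``total`` into ``parts`` nonnegative parts."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first, *rest)


#: maximum number of compositions the reference path will enumerate
_ENUMERATION_GUARD = 10_000_000


def exact_distribution_enumeration(
    model: BackgroundModel, motif: "MotifQuery | str", n: int, j: int
) -> float:
    """Reference path: the exact P(j, m, n) by literal summation over all
    segment-length configurations.  Exponential in j — used to validate
    the production approximation at small n, never in production.
    """
    seq = motif.sequence if isinstance(motif, MotifQuery) else validate_motif(motif, model)
    if is_clumpable(seq):
        raise ClumpableMotifError(f"{seq!r} is clumpable; the formula does not apply")
    m = len(seq)
    t = n - m * j
    if t < 0:
        return 0.0
    if math.comb(t + j, j) > _ENUMERATION_GUARD:
        raise EnumerationGuardError(
            f"{math.comb(t + j, j)} configurations exceed the enumeration guard"
        )
    P_S = motif_probability(model, seq)
    if j > 0 and P_S == 0.0:
        return 0.0
    # exact avoidance series up to the longest possible segment
    series = [1.0] * max(m, t + 1)
    for d in range(m, t + 1):
        series[d] = series[d - 1] - P_S * series[d - m]
    total = math.fsum(
        math.prod(series[d] for d in comp) for comp in _compositions(t, j + 1)
    )
    return P_S**j * total


def approx_log_probability(
    P_S: float, series: ZeroOccurrenceSeries, n: int, m: int, j: int
) -> float:
    """log P(j, m, n) from the collapsed geometric-ratio formula.

    The R exponent ``n - mj - n_eps (j+1)`` may be negative when the
    free segments are shorter on average than the convergence index;
    the geometric extrapolation is then run backwards, which small-n
    oracle checks show stays within the advertised tolerance.
    Returns ``-inf`` for structurally impossible counts (``n - mj < 0``).
    """
    t = n - m * j
    if t < 0:
        return -math.inf
    lc = configuration_count_log(n, m, j)
    ne = series.n_epsilon
    return (
        j * math.log(P_S)
        + (t - ne * (j + 1)) * math.log(series.ratio)
        + (j + 1) * math.log(series.values[ne])
        + lc
    )


@dataclass
class CountDistribution:
    """P(j) for j = 0 .. J with truncation/normalisation diagnostics."""

    motif: MotifQuery
    n: int
    probs: dict[int, float]
    J: int
    truncated: bool
    normalization_residual: float
    expected_count: float
    mode_short_circuited: bool
    series: ZeroOccurrenceSeries | None = None

    def as_array(self) -> np.ndarray:
        out = np.zeros(self.J + 1)
        for j, p in self.probs.items():
            out[j] = p
        return out


def expected_count(model: BackgroundModel, motif: "MotifQuery | str", n: int) -> float:
    """Expected number of occurrences, ``(n - m + 1) * P(start)`` over
    the n - m + 1 possible start positions (0 when the motif is longer
    than the text)."""
    seq = motif.sequence if isinstance(motif, MotifQuery) else validate_motif(motif, model)
    positions = max(0, n - len(seq) + 1)
    return positions * stationary_occurrence_probability(model, seq)


def count_distribution(
    model: BackgroundModel,
    motif: "MotifQuery | str",
    n: int,
    config: DistributionConfig | None = None,
) -> CountDistribution:
    """Full occurrence-count distribution of a non-clumpable motif.

    Short-circuits to a single P(0) mass when the feasibility inequality
    ``(n - m + 1) log(1 - P(S)) > log(1 - epsilon)`` guarantees
    P(0) > 1 - epsilon; otherwise evaluates the collapsed formula for
    j = 0, 1, ... stopping once P(j) < epsilon *and* j is past the
    distribution's mode (epsilon alone would stop at j = 0 for large n),
    or at ``min(j_max, floor(n/m))``.  Counts beyond floor(n/m) are
    structurally zero.  If the computed masses sum above 1 (by the
    approximation error) they are rescaled so the stored distribution is
    a sub-probability vector.
    """
    config = config or DistributionConfig()
    if isinstance(motif, str):
        motif = MotifQuery.from_sequence(motif, model)
    if motif.clumpable:
        raise ClumpableMotifError(
            f"{motif.sequence!r} is clumpable; analyse its surrogate instead"
        )
    seq = motif.sequence
    m = motif.m
    e_count = expected_count(model, motif, n)

    if n < m:
        return CountDistribution(
            motif, n, {0: 1.0}, 0, False, 0.0, 0.0, False, None
        )

    P_S = motif_probability(model, seq)
    if P_S == 0.0:
        raise DegenerateMotifError(
            f"P(S) = 0 for {seq!r} (zero-frequency symbol); distribution is "
            "degenerate at j = 0"
        )
    if P_S >= 1.0:
        raise DegenerateMotifError(f"P(S) = 1 for {seq!r}")

    # feasibility short-circuit: P(0) provably exceeds 1 - epsilon
    log_p0_bound = (n - m + 1) * math.log1p(-P_S)
    if log_p0_bound > math.log1p(-config.epsilon):
        p0 = math.exp(log_p0_bound)
        return CountDistribution(
            motif, n, {0: p0}, 0, False, 1.0 - p0, e_count, True, None
        )

    series = zero_occurrence_series(P_S, m, config)
    j_hi = min(config.j_max, n // m)
    mode_guard = math.ceil(e_count)
    probs: dict[int, float] = {}
    stopped_early = False
    for j in range(j_hi + 1):
        lp = approx_log_probability(P_S, series, n, m, j)
        p = 0.0 if lp == -math.inf else min(1.0, math.exp(lp))
        if math.isnan(p) or p < 0.0:
            raise NumericalInstabilityError(
                f"invalid probability at j={j} for {seq!r}"
            )
        probs[j] = p
        if p < config.epsilon and j > mode_guard:
            stopped_early = True
            break

    truncated = (not stopped_early) and j_hi < n // m
    total = math.fsum(probs.values())
    if total > 1.0:
        probs = {j: p / total for j, p in probs.items()}
        total = math.fsum(probs.values())
    residual = 1.0 - total
    J = max(probs)
    return CountDistribution(
        motif, n, probs, J, truncated, residual, e_count, False, series
    )


def tail_pvalue(dist: CountDistribution, observed: int) -> tuple[float, float]:
    """Exact tail p-values under the computed distribution.

    ``p_ge`` (enrichment) is 1 minus the mass strictly below ``observed``
    so a tiny upper tail never suffers cancellation; any truncation
    residual is thereby included in ``p_ge`` as an upper bound.
    ``p_le`` (depletion) is the mass at or below ``observed``.
    """
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    below = math.fsum(p for j, p in dist.probs.items() if j < observed)
    p_ge = min(1.0, max(0.0, 1.0 - below))
    p_le = min(1.0, math.fsum(p for j, p in dist.probs.items() if j <= observed))
    return p_ge, p_le
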