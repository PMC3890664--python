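"""Tolerance-interval statistics and the diagnosability/gap criteria.

Two families of tolerance computations support species delimitation on
morphology:

* **Normal tolerance intervals** (two-sided, Howe k2 factor) estimate
  the range of a continuous character containing a proportion P of the
  population with confidence 1 - alpha.  A *gap* between two taxa is
  non-overlap of their intervals.
* **Binomial tolerance bounds** (one-sided, Wilson score) estimate, for
  a binary character fixed in the observed samples, how many individuals
  of a future sample of size m could still carry the unseen alternative
  state.  A *fixed difference* is disjointness of the observed state
  sets; the binomial bound is its statistical caveat.

Chi-square and normal quantiles are exact numerical inversions
(:mod:`scipy.stats`), not series approximations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .datatypes import CharacterMatrix, ContinuousSummary, ToleranceConfig, ValidationError

__all__ = [
    "ToleranceInterval",
    "BinomialToleranceBound",
    "DiscreteDiagnosis",
    "howe_k",
    "normal_ti",
    "wilson_bound",
    "binomial_tolerance_bound",
    "diagnose_discrete",
    "detect_gap",
]


@dataclass(frozen=True)
class ToleranceInterval:
    lower: float
    upper: float
    k: float
    config: ToleranceConfig

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValidationError("tolerance interval with lower > upper")


@dataclass(frozen=True)
class BinomialToleranceBound:
    """One-sided binomial tolerance bound.

    ``p_bound`` is the Wilson confidence bound on the true state
    proportion; ``count_bound`` the tolerance bound on how many of a
    future sample of size m carry the state (content P of that future
    sample's distribution).
    """

    x: int
    n: int
    m: int
    p_bound: float
    count_bound: int
    config: ToleranceConfig

    @property
    def proportion_bound(self) -> float:
        return self.count_bound / self.m


@dataclass(frozen=True)
class DiscreteDiagnosis:
    """Result of the fixed-difference test for one character and taxon pair.

    ``fixed_difference`` is None when the character could not be assessed
    (no scored individuals in one of the taxa).  ``caveat_bounds`` maps
    each taxon to the tolerance-bounded proportion of a future sample
    that may carry the alternative (unobserved) state; populated only
    when the difference is fixed.
    """

    character: str
    state_sets: dict
    fixed_difference: Optional[bool]
    caveat_bounds: dict


def howe_k(n: int, config: ToleranceConfig) -> float:
    """Howe two-sided normal tolerance factor k2.

    k = z_{(1+P)/2} * sqrt((n-1) * (1 + 1/n) / chi2_{alpha, n-1}) where
    chi2_{alpha, n-1} is the lower alpha-quantile of chi-square with
    n - 1 degrees of freedom.  Monotonically decreasing in n, with limit
    z_{(1+P)/2} as n grows.
    """
    if n < 2:
        raise ValidationError(f"howe_k needs n >= 2, got {n}")
    if config.side != "two-sided":
        raise ValidationError("howe_k is defined for two-sided configs")
    z = stats.norm.ppf((1.0 + config.content) / 2.0)
    chi2 = stats.chi2.ppf(config.alpha, n - 1)
    return float(z * np.sqrt((n - 1) * (1.0 + 1.0 / n) / chi2))


def normal_ti(summary: ContinuousSummary, config: ToleranceConfig) -> ToleranceInterval:
    """Two-sided normal tolerance interval mean +/- k * sd (Howe method)."""
    k = howe_k(summary.n, config)
    half = k * summary.sd
    return ToleranceInterval(
        lower=summary.mean - half, upper=summary.mean + half, k=k, config=config
    )


def wilson_bound(x: int, n: int, confidence: float, direction: str) -> float:
    """One-sided Wilson score confidence bound on a binomial proportion.

    Uses z at the confidence quantile (one-sided alpha directly, not
    alpha/2).  ``lower(x, n) == 1 - upper(n - x, n)``.
    """
    if n <= 0:
        raise ValidationError("wilson_bound needs n >= 1")
    if not 0 <= x <= n:
        raise ValidationError(f"x must be in [0, n], got x={x}, n={n}")
    if direction not in ("lower", "upper"):
        raise ValidationError(f"direction must be lower or upper, got {direction!r}")
    z = stats.norm.ppf(confidence)
    phat = x / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    bound = center + half if direction == "upper" else center - half
    return float(min(1.0, max(0.0, bound)))


def _count_upper(m: int, p: float, content: float) -> int:
    """Smallest c with BinomCDF(c; m, p) >= content."""
    c = int(stats.binom.ppf(content, m, p)) if p > 0 else 0
    c = max(0, min(m, c))
    while c > 0 and stats.binom.cdf(c - 1, m, p) >= content:
        c -= 1
    while stats.binom.cdf(c, m, p) < content and c < m:
        c += 1
    return c


def _count_lower(m: int, p: float, content: float) -> int:
    """Largest c with P(X >= c) = 1 - CDF(c-1; m, p) >= content."""
    c = int(stats.binom.ppf(1.0 - content, m, p))
    c = max(0, min(m, c))
    while c < m and stats.binom.cdf(c, m, p) <= 1.0 - content:
        c += 1
    while c > 0 and stats.binom.cdf(c - 1, m, p) > 1.0 - content:
        c -= 1
    return c


def binomial_tolerance_bound(
    x: int, n: int, m: int, config: ToleranceConfig, direction: str
) -> BinomialToleranceBound:
    """One-sided binomial tolerance bound (Wilson score method).

    From x of n observed individuals with the focal state, bound the
    number of a future sample of size m carrying that state: the Wilson
    ``direction`` confidence bound on the proportion feeds an exact
    binomial quantile at content P.
    """
    if m < 1:
        raise ValidationError("future-sample size m must be >= 1")
    if config.side != "one-sided":
        raise ValidationError("binomial tolerance bounds are one-sided")
    p = wilson_bound(x, n, config.confidence, direction)
    if direction == "upper":
        count = _count_upper(m, p, config.content)
    else:
        count = _count_lower(m, p, config.content)
    return BinomialToleranceBound(x=x, n=n, m=m, p_bound=p, count_bound=count, config=config)


def diagnose_discrete(
    matrix: CharacterMatrix,
    taxon_a: str,
    taxon_b: str,
    character: str,
    config: Optional[ToleranceConfig] = None,
    m: Optional[int] = None,
) -> DiscreteDiagnosis:
    """Test a binary character for a fixed difference between two taxa.

    The difference is *fixed* iff the observed state sets are disjoint
    and both non-empty.  When fixed, each taxon gets a caveat bound: the
    tolerance-bounded proportion of a future sample (size ``m``,
    defaulting to that taxon's own n) that may carry the alternative,
    never-observed state, from ``binomial_tolerance_bound(x=0, n, m,
    upper)``.  Returns ``fixed_difference=None`` (not assessed) when a
    taxon has no scored individuals.
    """
    if config is None:
        config = ToleranceConfig(side="one-sided")
    elif config.side != "one-sided":
        config = ToleranceConfig(config.content, config.confidence, "one-sided")
    states = {t: matrix.states(t, character) for t in (taxon_a, taxon_b)}
    sets = {t: set(np.unique(s)) for t, s in states.items()}
    if any(len(s) == 0 for s in sets.values()):
        return DiscreteDiagnosis(character, sets, None, {})
    fixed = bool(sets[taxon_a].isdisjoint(sets[taxon_b]))
    caveats: dict = {}
    if fixed:
        for t in (taxon_a, taxon_b):
            n = len(states[t])
            bound = binomial_tolerance_bound(0, n, m or n, config, "upper")
            caveats[t] = bound.proportion_bound
    return DiscreteDiagnosis(character, sets, fixed, caveats)


def detect_gap(ti_a: ToleranceInterval, ti_b: ToleranceInterval) -> bool:
    """True iff the two closed intervals are disjoint.

    Touching endpoints count as overlap (conservative: no gap).
    """
    return bool(ti_a.upper < ti_b.lower or ti_b.upper < ti_a.lower)


def tolerance_table(summaries, config: ToleranceConfig):
    """Long-format DataFrame of tolerance intervals for a set of summaries.

    Columns: taxon, character, mean, sd, n, k, lower, upper, plus a
    ``display`` column holding the "lower-upper" string rounded to one
    decimal (half away from zero) as printed in descriptive tables.
    """
    import pandas as pd

    def round1(v: float) -> float:
        return float(np.floor(abs(v) * 10 + 0.5) / 10 * np.sign(v))

    rows = []
    for s in summaries:
        ti = normal_ti(s, config)
        rows.append(
            {
                "taxon": s.taxon,
                "character": s.character,
                "mean": s.mean,
                "sd": s.sd,
                "n": s.n,
                "k": ti.k,
                "lower": ti.lower,
                "upper": ti.upper,
                "display": f"{round1(ti.lower):.1f}-{round1(ti.upper):.1f}",
            }
        )
    return pd.DataFrame(rows)
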