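"""Pool-representation depth simulation.

Pooled sequencing observes reads, not individuals: at a given position, a
read depth of ``d`` over a pool of ``n`` individuals samples individuals
with replacement, so only some pool members contribute.  This module
quantifies, by Monte-Carlo resampling, how many distinct individuals a given
depth represents, and derives the minimum depth at which a required fraction
of the pool is represented with high confidence.  It is the justification
for the pipeline's default minimum read-depth filter of 25: for a pool of
25 individuals, depth 25 represents at least half the pool (13 individuals)
at the lower end of the central 95% interval.

Reads are assumed uniform over individuals (equal DNA contribution); the
expected number of distinct individuals then has the classical occupancy
closed form ``n * (1 - (1 - 1/n)**d)``, which the tests use as an
independent check of the simulation.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = ["RepresentationSummary", "sample_distinct", "representation_summary",
           "min_depth_for_representation", "expected_distinct"]

_QUANTILE_PROBS = (0.025, 0.05, 0.25, 0.5, 0.75, 0.95, 0.975)


@dataclasses.dataclass(frozen=True)
class RepresentationSummary:
    """Monte-Carlo summary of distinct-individual counts at one depth."""
    n_pool: int
    depth: int
    n_reps: int
    mean_distinct: float
    #: lower bound of the central 95% interval (2.5% empirical quantile) or,
    #: with tail="lower", the one-sided 5% quantile
    lower95: int
    quantiles: dict[float, int]

    def __post_init__(self):
        upper = min(self.n_pool, self.depth)
        if not (1 <= self.lower95 <= upper):
            raise ValueError("lower95 outside feasible range")
        if not (self.lower95 <= self.mean_distinct <= upper):
            raise ValueError("mean outside feasible range")


def expected_distinct(n_pool: int, depth: int) -> float:
    """Closed-form expected number of distinct individuals hit."""
    return n_pool * (1.0 - (1.0 - 1.0 / n_pool) ** depth)


def sample_distinct(n_pool: int, depth: int,
                    rng: np.random.Generator) -> int:
    """Draw ``depth`` reads uniformly over individuals; count distinct ones."""
    if n_pool < 1 or depth < 1:
        raise ValueError("n_pool and depth must be positive")
    return int(np.unique(rng.integers(0, n_pool, size=depth)).size)


def _distinct_counts(n_pool: int, depth: int, n_reps: int,
                     rng: np.random.Generator,
                     chunk: int = 100_000) -> np.ndarray:
    """Vectorised distinct-count draws, chunked to bound memory."""
    dtype = np.int8 if n_pool <= 127 else (np.int16 if n_pool <= 32767
                                           else np.int64)
    out = np.empty(n_reps, dtype=np.int64)
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        draws = rng.integers(0, n_pool, size=(m, depth), dtype=dtype)
        draws.sort(axis=1)
        out[done:done + m] = 1 + (np.diff(draws, axis=1) != 0).sum(axis=1)
        done += m
    return out


def representation_summary(n_pool: int, depth: int, n_reps: int = 1_000_000,
                           seed: int = 0,
                           tail: str = "central") -> RepresentationSummary:
    """Monte-Carlo distribution of distinct individuals represented.

    ``tail`` selects how the lower 95% confidence limit is read: "central"
    (default) takes the 2.5% quantile of the simulated distribution, i.e.
    the lower bound of the central 95% interval; "lower" takes the one-sided
    5% quantile.  For a pool of 25 at depth 25 both give 13.
    """
    if n_pool < 1 or depth < 1 or n_reps < 1:
        raise ValueError("n_pool, depth and n_reps must be positive")
    if tail not in ("central", "lower"):
        raise ValueError("tail must be 'central' or 'lower'")
    rng = np.random.default_rng(seed)
    counts = _distinct_counts(n_pool, depth, n_reps, rng)
    quantiles = {p: int(np.quantile(counts, p, method="inverted_cdf"))
                 for p in _QUANTILE_PROBS}
    lower = quantiles[0.025] if tail == "central" else quantiles[0.05]
    return RepresentationSummary(
        n_pool=n_pool, depth=depth, n_reps=n_reps,
        mean_distinct=float(counts.mean()), lower95=lower,
        quantiles=quantiles)


def min_depth_for_representation(n_pool: int, fraction: float = 0.5,
                                 confidence: float = 0.95,
                                 n_reps: int = 100_000,
                                 seed: int = 0,
                                 tail: str = "central",
                                 max_depth: int = 10_000) -> int:
    """Smallest depth whose lower-tail quantile represents the target fraction.

    Searches depth upward (doubling then bisection) for the smallest depth at
    which the lower (1-confidence) limit of the distinct-count distribution
    reaches ``ceil(fraction * n_pool)`` individuals.  Each candidate depth is
    evaluated with its own deterministic sub-seed so the search and a linear
    brute-force scan agree exactly.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    target = math.ceil(fraction * n_pool)
    if target > n_pool:
        raise ValueError("requested fraction exceeds pool size")

    def ok(depth: int) -> bool:
        summary = representation_summary(
            n_pool, depth, n_reps=n_reps, seed=seed + depth, tail=tail)
        return summary.lower95 >= target

    lo, hi = target, None  # need at least `target` reads to hit target individuals
    depth = max(lo, 1)
    while depth <= max_depth:
        if ok(depth):
            hi = depth
            break
        lo, depth = depth + 1, depth * 2
    if hi is None:
        raise ValueError(f"no depth <= {max_depth} reaches the target")
    while lo < hi:
        mid = (lo + hi) // 2
        if ok(mid):
            hi = mid
        else:
            lo = mid + 1
    return hi
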