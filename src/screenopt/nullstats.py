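"""Empirical null distribution of random-classifier enrichment.

Because hundreds to thousands of docking models are tested per target, an
apparently good enrichment can arise by chance.  This module simulates the
conditional distribution of normalized LogAUC produced by a uniformly
random ranking of ``n_pos`` positives among ``round(ratio * n_pos)``
negatives, applies the Bonferroni correction for the number of models
tested, and derives the significance threshold a single tested model must
exceed to reject the null hypothesis that all observed enrichments are
random.

The mean of the null tends to 0 as class sizes grow, but for the small
positive counts typical of retrospective datasets the distribution is
wide and strongly skewed, which is why the threshold is conditioned on
the positive count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from screenopt.enrichment import DEFAULT_LAMBDA, normalized_logauc_from_ranks

__all__ = [
    "NullDistribution",
    "SignificanceConfig",
    "simulate_null",
    "exhaustive_null",
    "bonferroni",
    "significance_threshold",
]


@dataclass(frozen=True)
class NullDistribution:
    """Sorted normalized-LogAUC samples of a random classifier at fixed class shape."""

    n_pos: int
    ratio: float
    reps: int
    samples: np.ndarray  # sorted ascending
    seed: int
    exhaustive: bool = False

    def __post_init__(self) -> None:
        s = np.sort(np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "samples", s)
        if s.size != self.reps:
            raise ValueError("sample count must equal reps")

    @property
    def n_neg(self) -> int:
        return int(round(self.ratio * self.n_pos))

    def cdf(self, value: float) -> float:
        """Empirical P(sample <= value)."""
        return float(np.searchsorted(self.samples, value, side="right") / self.samples.size)

    def sf(self, value: float) -> float:
        """Empirical P(sample >= value) — the p-value of an observed enrichment."""
        return float(
            (self.samples.size - np.searchsorted(self.samples, value, side="left"))
            / self.samples.size
        )


@dataclass(frozen=True)
class SignificanceConfig:
    """Desired family-wise error rate and number of tests performed."""

    p_value: float = 0.01
    n_tests: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must be in (0, 1]")
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")

    @property
    def corrected_p(self) -> float:
        return bonferroni(self.p_value, self.n_tests)


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-corrected significance level: min(1, p / n_tests).

    Dividing the desired p-value by the number of tests controls the
    family-wise error rate; e.g. p = 0.01 over 1000 tests becomes 1e-5.
    The correction assumes independent tests and is strictly conservative
    for the positively dependent tests produced by nearby points in
    parameter space.
    """
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return min(1.0, p / n_tests)


def _null_key(n_pos: int, ratio: float, reps: int, seed: int) -> str:
    return f"null_n{n_pos}_r{ratio:g}_reps{reps}_seed{seed}.txt"


def simulate_null(
    n_pos: int,
    ratio: float = 50.0,
    reps: int = 100_000,
    seed: int = 0,
    lam: float = DEFAULT_LAMBDA,
    cache_dir: str | Path | None = None,
) -> NullDistribution:
    """Simulate the null distribution of normalized LogAUC for random rankings.

    Each replicate places ``n_pos`` positives uniformly at random among
    ``round(ratio * n_pos)`` negatives and scores the resulting ranking.
    Deterministic under the seed.  With ``cache_dir`` set, sorted samples
    are persisted to a text file keyed by (n_pos, ratio, reps, seed) and
    reloaded on subsequent calls.
    """
    if n_pos < 1:
        raise ValueError("n_pos must be >= 1")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n_neg = int(round(ratio * n_pos))
    if n_neg < 1:
        raise ValueError("ratio too small: no negatives")

    cache_path = None
    if cache_dir is not None:
        cache_path = Path(cache_dir) / _null_key(n_pos, ratio, reps, seed)
        if cache_path.exists():
            samples = np.loadtxt(cache_path, ndmin=1)
            return NullDistribution(n_pos=n_pos, ratio=ratio, reps=reps, samples=samples, seed=seed)

    rng = np.random.default_rng(seed)
    total = n_pos + n_neg
    samples = np.empty(reps)
    offsets = np.arange(n_pos)
    for i in range(reps):
        pos_ranks = np.sort(rng.choice(total, size=n_pos, replace=False))
        samples[i] = normalized_logauc_from_ranks(pos_ranks - offsets, n_neg, lam)
    samples.sort()

    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        np.savetxt(cache_path, samples)
    return NullDistribution(n_pos=n_pos, ratio=ratio, reps=reps, samples=samples, seed=seed)


def exhaustive_null(
    n_pos: int, ratio: float, lam: float = DEFAULT_LAMBDA
) -> NullDistribution:
    """Exact permutation null: every placement of positives among negatives.

    Enumerates all C(n_pos + n_neg, n_pos) equally likely position sets;
    feasible only for small datasets.  Serves as the exact reference the
    Monte-Carlo simulator must converge to.
    """
    n_neg = int(round(ratio * n_pos))
    total = n_pos + n_neg
    offsets = np.arange(n_pos)
    values = [
        normalized_logauc_from_ranks(np.array(combo) - offsets, n_neg, lam)
        for combo in itertools.combinations(range(total), n_pos)
    ]
    samples = np.sort(np.array(values))
    return NullDistribution(
        n_pos=n_pos,
        ratio=ratio,
        reps=samples.size,
        samples=samples,
        seed=-1,
        exhaustive=True,
    )


def significance_threshold(dist: NullDistribution, cfg: SignificanceConfig) -> float:
    """Enrichment a model must reach to reject the null at the corrected level.

    Returns the empirical (1 - p/n_tests) quantile of the null samples
    using the conservative 'higher' interpolation, so the rejection rule
    never exceeds its nominal error rate.  A model whose criterion value
    is >= the threshold rejects the null; a single such model suffices.
    """
    corrected = cfg.corrected_p
    if not dist.exhaustive and corrected < 1.0 / dist.reps:
        raise ValueError(
            f"corrected p = {corrected:g} is below 1/reps = {1.0 / dist.reps:g}; "
            "the empirical quantile is unreliable — rerun simulate_null with more reps"
        )
    return float(np.quantile(dist.samples, 1.0 - corrected, method="higher"))
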