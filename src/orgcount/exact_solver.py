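"""Exact limiting distribution of the four-process model.

At equilibrium the probability flux from state ``n`` to ``n + 1`` must equal
the reverse flux (detailed balance between adjacent states of a birth-death
chain):

    (k_de_novo + k_fission * n) * f_n = (gamma + k_fusion * n) * (n + 1) * f_{n+1}

which gives the term-ratio recurrence

    f_{n+1} = (k_de_novo + k_fission * n) / ((gamma + k_fusion * n) * (n + 1)) * f_n

The solver seeds the recurrence with an arbitrary first term, runs it
forward until the tail is provably negligible, and normalises.  The
normalised result is independent of the seed term.  All terms are
accumulated in log space, so parameter sets whose unnormalised terms would
overflow or underflow double precision are handled transparently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.special import logsumexp

from .errors import RegimeError, TruncationError
from .model_core import ModelRates, RegimeReason, classify_regime

__all__ = [
    "CountDistribution",
    "StationaryStats",
    "stationary_distribution",
    "distribution_stats",
    "stationarity_residual",
]

DEFAULT_TAIL_TOLERANCE = 1e-12
DEFAULT_N_CAP = 100_000


@dataclass(frozen=True)
class CountDistribution:
    """A probability distribution over organelle number ``n``.

    ``probabilities[i]`` is the probability of ``n = support_min + i``.
    ``tail_bound`` bounds the probability mass beyond the retained support.
    """

    support_min: int
    probabilities: np.ndarray
    tail_bound: float = 0.0

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", probs)
        if probs.ndim != 1 or probs.size == 0:
            raise ValueError("probabilities must be a non-empty 1-D sequence")
        if (probs < 0).any():
            raise ValueError("probabilities must be non-negative")

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.support_min, self.support_min + self.probabilities.size)

    @property
    def n_max(self) -> int:
        return self.support_min + self.probabilities.size - 1

    def pmf(self, n: int) -> float:
        """Probability of exactly ``n`` organelles (0 outside the retained
        support)."""
        i = n - self.support_min
        if 0 <= i < self.probabilities.size:
            return float(self.probabilities[i])
        return 0.0

    @classmethod
    def from_counts(cls, counts: np.ndarray, support_min: int = 0) -> "CountDistribution":
        """Empirical distribution from a histogram of cell counts."""
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError("histogram is empty")
        return cls(support_min, counts / total, tail_bound=0.0)

    # -- I/O --------------------------------------------------------------

    def to_tsv(self, path: Union[str, Path], rates: Optional[ModelRates] = None) -> None:
        from . import __version__

        lines = [f"# orgcount {__version__} stationary distribution\n"]
        if rates is not None:
            lines.append(
                "# rates: "
                f"k_de_novo={rates.k_de_novo!r} k_fission={rates.k_fission!r} "
                f"gamma={rates.gamma!r} k_fusion={rates.k_fusion!r}\n"
            )
        lines.append(f"# tail_bound: {self.tail_bound!r}\n")
        lines.append("n\tprobability\n")
        for n, p in zip(self.support, self.probabilities):
            lines.append(f"{n}\t{float(p)!r}\n")
        Path(path).write_text("".join(lines))

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "CountDistribution":
        support = []
        probs = []
        tail_bound = 0.0
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# tail_bound:"):
                    tail_bound = float(line.split(":", 1)[1])
                continue
            if line.startswith("n\t"):
                continue
            n_str, p_str = line.split("\t")
            support.append(int(n_str))
            probs.append(float(p_str))
        if not support:
            raise ValueError(f"no distribution rows found in {path}")
        if support != list(range(support[0], support[0] + len(support))):
            raise ValueError("support must be contiguous")
        return cls(support[0], np.asarray(probs), tail_bound=tail_bound)


@dataclass(frozen=True)
class StationaryStats:
    """Mean, variance and Fano factor (variance/mean) of a count
    distribution.  ``fano`` is NaN with ``fano_defined=False`` when the mean
    is zero — the ratio has no value there."""

    mean: float
    variance: float
    fano: float
    fano_defined: bool = True


def _point_mass(n: int) -> CountDistribution:
    return CountDistribution(n, np.array([1.0]), tail_bound=0.0)


def stationary_distribution(
    rates: ModelRates,
    tail_tolerance: float = DEFAULT_TAIL_TOLERANCE,
    n_cap: Optional[int] = None,
) -> CountDistribution:
    """Exact limiting distribution by the detailed-balance recurrence.

    Parameters
    ----------
    rates
        Model rate constants; must admit a limiting distribution
        (see :func:`orgcount.model_core.classify_regime`).
    tail_tolerance
        Upper bound on the probability mass allowed beyond the retained
        support.  The recurrence is extended until the running term drops
        below ``tail_tolerance * 1e-3`` of the retained mass *and* the term
        ratio has fallen below 1 (past the mode), so that the discarded tail
        is bounded by a geometric series.
    n_cap
        Hard cap on the support size (default 100,000).  Hitting the cap
        before the tail criterion raises :class:`TruncationError`.

    Raises
    ------
    RegimeError
        If the rates have no limiting distribution.
    TruncationError
        If the tail criterion is not reached within ``n_cap`` states.
    """
    if tail_tolerance <= 0 or tail_tolerance >= 1:
        raise ValueError("tail_tolerance must be in (0, 1)")
    cap = DEFAULT_N_CAP if n_cap is None else int(n_cap)

    regime = classify_regime(rates)
    if not regime.has_limiting_distribution:
        raise RegimeError(
            "no limiting distribution: "
            f"{regime.reason.value} (k_fission={rates.k_fission} >= "
            f"gamma={rates.gamma} with k_fusion=0 lets the organelle number "
            "grow without bound)"
        )
    if regime.reason is RegimeReason.ABSORBED_AT_ZERO:
        # without de novo synthesis, decay empties every cell eventually
        return _point_mass(0)

    kd, kf, g, ku = rates.k_de_novo, rates.k_fission, rates.gamma, rates.k_fusion
    n = regime.support_min
    log_terms = [0.0]  # arbitrary seed term f_{support_min} = 1
    log_total = 0.0
    ratio = math.inf
    while True:
        numerator = kd + kf * n
        denominator = (g + ku * n) * (n + 1)
        if numerator == 0.0:
            ratio = 0.0
            break  # chain cannot leave [support_min, n]; tail is exactly 0
        ratio = numerator / denominator
        log_next = log_terms[-1] + math.log(ratio)
        rel_term = math.exp(log_next - log_total)
        if ratio < 1.0 and rel_term < tail_tolerance * 1e-3:
            break
        if len(log_terms) >= cap:
            retained = 1.0 / (1.0 + rel_term / max(1.0 - ratio, 1e-16)) if ratio < 1 else 0.0
            raise TruncationError(
                f"support cap {cap} reached before the tail criterion "
                f"(term ratio {ratio:.4g} at n={n + 1}); "
                "raise n_cap or loosen tail_tolerance",
                accumulated_mass=retained,
                n_cap=cap,
            )
        log_terms.append(log_next)
        log_total = np.logaddexp(log_total, log_next)
        n += 1

    log_arr = np.asarray(log_terms)
    log_norm = logsumexp(log_arr)
    probs = np.exp(log_arr - log_norm)
    if ratio > 0.0:
        # mass beyond n_max bounded by the geometric series with the final
        # (sub-unit, still decreasing) term ratio
        last_rel = math.exp(log_arr[-1] - log_norm)
        tail_bound = last_rel * ratio / (1.0 - ratio)
    else:
        tail_bound = 0.0
    return CountDistribution(regime.support_min, probs, tail_bound=tail_bound)


def distribution_stats(dist: CountDistribution) -> StationaryStats:
    """Mean, variance and Fano factor of a (normalised) count distribution."""
    probs = dist.probabilities
    total = probs.sum()
    if total <= 0:
        raise ValueError("distribution has no mass")
    p = probs / total
    n = dist.support.astype(float)
    mean = float(n @ p)
    variance = float((n * n) @ p - mean * mean)
    variance = max(variance, 0.0)  # guard tiny negative round-off
    if mean > 0:
        return StationaryStats(mean, variance, variance / mean, True)
    return StationaryStats(mean, variance, math.nan, False)


def stationarity_residual(dist: CountDistribution, rates: ModelRates) -> float:
    """Maximum detailed-balance flux imbalance over adjacent state pairs.

    For each adjacent pair ``(n, n + 1)`` the up-flux is
    ``(k_de_novo + k_fission n) f_n`` and the down-flux is
    ``(gamma + k_fusion n) (n + 1) f_{n+1}``; the residual is the largest
    absolute difference.  Solver output satisfies this to round-off by
    construction; for an empirical histogram the residual measures distance
    from stationarity (in probability per unit time).
    """
    probs = dist.probabilities
    total = probs.sum()
    if total <= 0:
        raise ValueError("distribution has no mass")
    p = probs / total
    n = dist.support.astype(float)[:-1]
    up = (rates.k_de_novo + rates.k_fission * n) * p[:-1]
    down = (rates.gamma + rates.k_fusion * n) * (n + 1) * p[1:]
    if up.size == 0:
        return 0.0
    return float(np.abs(up - down).max())
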