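"""Stochastic simulation of single cells and cell ensembles.

Two schemes are provided:

* ``EVENT_DRIVEN`` — exact stochastic simulation: the waiting time to the
  next event is exponential with rate equal to the summed propensities, and
  the event type is drawn proportionally to the four propensities.
* ``FIXED_STEP`` — the discrete-time scheme implied by the first-order
  event probabilities: at each step of length ``dt`` one uniform variate is
  compared against the cumulative per-process probabilities
  ``k_de_novo*dt``, ``k_fission*n*dt``, ``gamma*n*dt``,
  ``k_fusion*n*(n-1)*dt``; at most one event fires per step.  The default
  step of 0.0001 time units keeps the per-step event probability small so
  the multi-event error is second order in ``dt``.

Both schemes are exactly reproducible from a seed.  Ensembles derive one
child seed per cell from the master seed with a counter-based split, so the
ensemble is reproducible regardless of execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .errors import DivergenceError
from .exact_solver import CountDistribution, StationaryStats
from .model_core import ModelRates, classify_regime

__all__ = [
    "Scheme",
    "SimulationConfig",
    "Trajectory",
    "EnsembleSnapshot",
    "simulate_trajectory",
    "simulate_ensemble",
    "time_average_stats",
]

DEFAULT_DT = 0.0001
DEFAULT_DIVERGENCE_CAP = 1_000_000


class Scheme(str, Enum):
    FIXED_STEP = "FIXED_STEP"
    EVENT_DRIVEN = "EVENT_DRIVEN"


@dataclass(frozen=True)
class SimulationConfig:
    rates: ModelRates
    n0: int = 0
    t_end: float = 10.0
    seed: int = 0
    scheme: Scheme = Scheme.EVENT_DRIVEN
    dt: Optional[float] = None
    divergence_cap: int = DEFAULT_DIVERGENCE_CAP

    def __post_init__(self) -> None:
        if self.n0 < 0:
            raise ValueError("n0 must be >= 0")
        if self.t_end < 0:
            raise ValueError("t_end must be >= 0")
        scheme = Scheme(self.scheme)
        object.__setattr__(self, "scheme", scheme)
        if scheme is Scheme.FIXED_STEP:
            dt = DEFAULT_DT if self.dt is None else self.dt
            if not dt > 0:
                raise ValueError("dt must be > 0 for the fixed-step scheme")
            object.__setattr__(self, "dt", dt)


@dataclass(frozen=True)
class Trajectory:
    """A single-cell time course: the count changes by exactly +-1 at each
    recorded event time; ``times[0] = 0`` carries the initial count and the
    final entry records the state at ``t_end``."""

    times: np.ndarray
    counts: np.ndarray
    config: SimulationConfig

    def count_at(self, t: float) -> int:
        """Organelle count at time ``t`` (right-continuous)."""
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        return int(self.counts[max(i, 0)])

    def to_tsv(self, path: Union[str, Path]) -> None:
        from . import __version__

        r = self.config.rates
        lines = [
            f"# orgcount {__version__} trajectory\n",
            f"# rates: k_de_novo={r.k_de_novo!r} k_fission={r.k_fission!r} "
            f"gamma={r.gamma!r} k_fusion={r.k_fusion!r}\n",
            f"# n0={self.config.n0} t_end={self.config.t_end!r} "
            f"seed={self.config.seed} scheme={self.config.scheme.value}\n",
            "time\tcount\n",
        ]
        lines.extend(f"{float(t)!r}\t{int(c)}\n" for t, c in zip(self.times, self.counts))
        Path(path).write_text("".join(lines))


@dataclass(frozen=True)
class EnsembleSnapshot:
    """Histogram of organelle counts over an ensemble of cells observed at
    a single time ``tau``."""

    tau: float
    counts: np.ndarray  # counts[n] = number of cells with n organelles
    n_cells: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.sum() != self.n_cells:
            raise ValueError("histogram total must equal the number of cells")

    def to_distribution(self) -> CountDistribution:
        return CountDistribution.from_counts(self.counts, support_min=0)

    def to_tsv(self, path: Union[str, Path], config: Optional[SimulationConfig] = None) -> None:
        from . import __version__

        lines = [f"# orgcount {__version__} ensemble snapshot\n"]
        if config is not None:
            r = config.rates
            lines.append(
                f"# rates: k_de_novo={r.k_de_novo!r} k_fission={r.k_fission!r} "
                f"gamma={r.gamma!r} k_fusion={r.k_fusion!r}\n"
            )
            lines.append(f"# n0={config.n0} seed={config.seed} scheme={config.scheme.value}\n")
        lines.append(f"# tau={self.tau!r} n_cells={self.n_cells}\n")
        lines.append("n\tcells\n")
        lines.extend(f"{n}\t{c}\n" for n, c in enumerate(self.counts))
        Path(path).write_text("".join(lines))


def _propensities(rates: ModelRates, n: int) -> tuple[float, float, float, float]:
    return (
        rates.k_de_novo,
        rates.k_fission * n,
        rates.gamma * n,
        rates.k_fusion * n * (n - 1),
    )


_DELTAS = (1, 1, -1, -1)  # de novo, fission, decay, fusion


def _divergence_error(config: SimulationConfig, t: float, n: int) -> DivergenceError:
    regime = classify_regime(config.rates)
    verdict = (
        "no limiting distribution exists for these rates "
        f"(classify_regime: {regime.reason.value})"
        if not regime.has_limiting_distribution
        else f"classify_regime reports {regime.reason.value}; the cap may simply be too low"
    )
    return DivergenceError(
        f"organelle count exceeded the divergence cap "
        f"{config.divergence_cap} at t={t:.6g}; {verdict}",
        time=t,
        count=n,
    )


def _run_event_driven(config: SimulationConfig, rng: np.random.Generator, record: bool):
    rates = config.rates
    t, n = 0.0, config.n0
    times, counts = [0.0], [n]
    while True:
        a = _propensities(rates, n)
        total = a[0] + a[1] + a[2] + a[3]
        if total == 0.0:
            break
        t_next = t + rng.exponential(1.0 / total)
        if t_next > config.t_end:
            break
        t = t_next
        u = rng.random() * total
        if u < a[0]:
            n += 1
        elif u < a[0] + a[1]:
            n += 1
        elif u < a[0] + a[1] + a[2]:
            n -= 1
        else:
            n -= 1
        if n > config.divergence_cap:
            raise _divergence_error(config, t, n)
        if record:
            times.append(t)
            counts.append(n)
    return times, counts, n


def _run_fixed_step(config: SimulationConfig, rng: np.random.Generator, record: bool):
    """Literal fixed-step scheme: one uniform per step against the four
    cumulative probabilities.  Uniforms are drawn in blocks and scanned for
    the first event-triggering step, which preserves the per-step stream
    while avoiding a Python loop over every step."""
    rates = config.rates
    dt = config.dt
    n_steps_total = int(math.floor(config.t_end / dt + 1e-9))
    step = 0
    n = config.n0
    times, counts = [0.0], [n]
    while step < n_steps_total:
        p = _propensities(rates, n)
        p_total = (p[0] + p[1] + p[2] + p[3]) * dt
        if p_total == 0.0:
            break
        if p_total >= 1.0:
            raise ValueError(
                f"per-step event probability {p_total:.3g} >= 1 at n={n}; "
                "reduce dt"
            )
        remaining = n_steps_total - step
        # block sized so one block almost always contains the next event
        block = min(remaining, max(64, int(4.0 / p_total)))
        fired = False
        while not fired and step < n_steps_total:
            block = min(block, n_steps_total - step)
            u = rng.random(block)
            hits = np.nonzero(u < p_total)[0]
            if hits.size == 0:
                step += block
                continue
            k = int(hits[0])
            step += k + 1
            v = u[k]  # reuse the triggering uniform for the event type
            if v < p[0] * dt:
                n += 1
            elif v < (p[0] + p[1]) * dt:
                n += 1
            elif v < (p[0] + p[1] + p[2]) * dt:
                n -= 1
            else:
                n -= 1
            fired = True
        if not fired:
            break
        if n > config.divergence_cap:
            raise _divergence_error(config, step * dt, n)
        if record:
            times.append(step * dt)
            counts.append(n)
    return times, counts, n


def _run(config: SimulationConfig, rng: np.random.Generator, record: bool):
    if config.scheme is Scheme.EVENT_DRIVEN:
        return _run_event_driven(config, rng, record)
    return _run_fixed_step(config, rng, record)


def simulate_trajectory(config: SimulationConfig) -> Trajectory:
    """Simulate one cell and return its full event-resolved time course.

    Identical config and seed reproduce the trajectory exactly.  If the
    count exceeds ``config.divergence_cap`` a :class:`DivergenceError` is
    raised, annotated with the regime classification of the rates.
    """
    rng = np.random.default_rng(config.seed)
    times, counts, n_final = _run(config, rng, record=True)
    if not times or times[-1] != config.t_end:
        times = times + [config.t_end]
        counts = counts + [n_final]
    return Trajectory(np.asarray(times), np.asarray(counts, dtype=np.int64), config)


def simulate_ensemble(
    config: SimulationConfig, n_cells: int, tau: float
) -> EnsembleSnapshot:
    """Simulate ``n_cells`` independent cells from ``config`` and histogram
    their organelle counts at observation time ``tau``.

    Per-cell seeds are spawned from ``config.seed`` with
    ``numpy.random.SeedSequence``, so the snapshot is reproducible and
    independent of the order in which cells are run.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    cell_config = replace(config, t_end=tau)
    children = np.random.SeedSequence(config.seed).spawn(n_cells)
    finals = np.empty(n_cells, dtype=np.int64)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        _, _, n_final = _run(cell_config, rng, record=False)
        finals[i] = n_final
    hist = np.bincount(finals)
    return EnsembleSnapshot(tau=tau, counts=hist, n_cells=n_cells)


def time_average_stats(
    trajectory: Trajectory, burn_in_fraction: float = 0.2
) -> StationaryStats:
    """Time-weighted mean, variance and Fano factor of a trajectory after
    discarding an initial burn-in window (default: the first 20% of the
    run, enough for the chain to forget its arbitrary starting count when
    the run is long compared with the relaxation time)."""
    if not 0 <= burn_in_fraction < 1:
        raise ValueError("burn_in_fraction must be in [0, 1)")
    t_start = burn_in_fraction * trajectory.config.t_end
    times = trajectory.times
    counts = trajectory.counts.astype(float)
    t_end = trajectory.config.t_end
    # piecewise-constant integral over [t_start, t_end]
    starts = np.maximum(times, t_start)
    ends = np.append(times[1:], t_end)
    ends = np.maximum(ends, t_start)
    widths = np.clip(ends - starts, 0.0, None)
    total = widths.sum()
    if total <= 0:
        raise ValueError("burn-in leaves no observation window")
    w = widths / total
    mean = float(counts @ w)
    variance = max(float((counts * counts) @ w - mean * mean), 0.0)
    if mean > 0:
        return StationaryStats(mean, variance, variance / mean, True)
    return StationaryStats(mean, variance, math.nan, False)
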