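"""Moment-based inference for the {de novo, fission; decay} model.

Everything here follows from the model's exact moment identities.  Writing
``F`` for the Fano factor and ``<n>`` for the equilibrium mean:

* production decomposition — total production splits into an absolute de
  novo rate ``k_de_novo`` and an absolute fission rate ``k_fission * <n>``;
  at equilibrium their fractions depend on ``F`` alone:
  ``de_novo_fraction = 1/F``, ``fission_fraction = (F - 1)/F``;
* rate inversion — an observed ``(<n>, F)`` pair determines the rate ratios
  ``k_fission/gamma = 1 - 1/F`` and ``k_de_novo/gamma = <n>/F``;
* knockout prediction — setting ``k_fission = 0`` changes the equilibrium
  mean from ``k_de_novo/(gamma - k_fission)`` to ``k_de_novo/gamma``, a
  relative drop of exactly ``k_fission/gamma``.

These identities require ``k_fusion = 0`` and ``F >= 1``; a Fano factor
below 1 is outside the model (it suggests fusion, a detection floor, or a
non-equilibrium population) and is reported as such rather than projected
onto the boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import OutOfModelError
from .model_core import ModelRates

__all__ = [
    "ProductionDecomposition",
    "InferredRates",
    "ObservedMoments",
    "decompose_production",
    "invert_rates",
    "knockout_prediction",
    "observed_moments",
    "read_histogram",
    "estimate_rates_from_histogram",
]


@dataclass(frozen=True)
class ProductionDecomposition:
    """Split of total organelle production into de novo and fission parts.

    Fractions always sum to 1; absolute rates are present only when the
    decomposition was computed from rates and a mean, not from a bare Fano
    factor."""

    de_novo_fraction: float
    fission_fraction: float
    de_novo_rate: Optional[float] = None
    fission_rate: Optional[float] = None

    @property
    def de_novo_percent(self) -> int:
        """De novo share rounded to the nearest whole percent."""
        return round(100.0 * self.de_novo_fraction)

    @property
    def fission_percent(self) -> int:
        return round(100.0 * self.fission_fraction)


@dataclass(frozen=True)
class InferredRates:
    """Rate ratios inferred from an observed (mean, Fano) pair.

    Only ratios to the decay rate are identifiable from a single
    equilibrium snapshot; the absolute time scale is not."""

    k_de_novo_over_gamma: float
    k_fission_over_gamma: float

    def to_rates(self, gamma: float = 1.0) -> ModelRates:
        return ModelRates(
            k_de_novo=self.k_de_novo_over_gamma * gamma,
            k_fission=self.k_fission_over_gamma * gamma,
            gamma=gamma,
            k_fusion=0.0,
        )


@dataclass(frozen=True)
class ObservedMoments:
    mean: float
    variance: float
    fano: float
    n_cells: int
    fano_defined: bool = True
    mean_ci: Optional[Tuple[float, float]] = None
    fano_ci: Optional[Tuple[float, float]] = None


def _check_fano(fano: float, tolerance: float) -> float:
    if math.isnan(fano):
        raise OutOfModelError("Fano factor is undefined (mean 0)")
    if fano < 1.0:
        if fano >= 1.0 - tolerance:
            warnings.warn(
                f"Fano factor {fano:.4g} is below 1 but within tolerance "
                f"{tolerance:.3g}; clamping to 1",
                stacklevel=3,
            )
            return 1.0
        raise OutOfModelError(
            f"Fano factor {fano:.4g} < 1 is unattainable in the "
            "{de novo, fission; decay} model; it suggests fusion, "
            "undercounting, or a non-equilibrium population"
        )
    return fano


def decompose_production(
    fano: float,
    mean: Optional[float] = None,
    rates: Optional[ModelRates] = None,
    tolerance: float = 0.0,
) -> ProductionDecomposition:
    """Fraction of total production due to de novo synthesis vs fission.

    At equilibrium the de novo fraction is ``1/F`` and the fission fraction
    ``(F - 1)/F``.  If ``rates`` (or ``mean`` alongside inferred rates) are
    supplied, the absolute rates ``k_de_novo`` and ``k_fission * mean`` are
    attached as well.

    ``tolerance`` accepts Fano factors slightly below 1 (sampling noise)
    by clamping them to 1 with a warning; by default the check is strict.
    """
    fano = _check_fano(fano, tolerance)
    de_novo_fraction = 1.0 / fano
    fission_fraction = 1.0 - de_novo_fraction
    de_novo_rate = fission_rate = None
    if rates is not None:
        de_novo_rate = rates.k_de_novo
        if mean is None:
            from .closed_forms import peroxisome_mean

            mean = peroxisome_mean(rates)
        fission_rate = rates.k_fission * mean
    return ProductionDecomposition(
        de_novo_fraction, fission_fraction, de_novo_rate, fission_rate
    )


def invert_rates(mean: float, fano: float, tolerance: float = 0.0) -> InferredRates:
    """Invert the exact moment formulas: from an observed equilibrium mean
    and Fano factor, recover ``k_fission/gamma = 1 - 1/F`` and
    ``k_de_novo/gamma = mean/F``.

    The inversion is exact: applying the forward mean and Fano formulas to
    the result reproduces the observations to machine precision.
    """
    if not mean > 0:
        raise OutOfModelError(f"mean must be > 0, got {mean!r}")
    fano = _check_fano(fano, tolerance)
    return InferredRates(
        k_de_novo_over_gamma=mean / fano,
        k_fission_over_gamma=1.0 - 1.0 / fano,
    )


def knockout_prediction(inferred: InferredRates) -> float:
    """Percent drop in the equilibrium mean when fission is deleted
    (``k_fission -> 0``), predicted from the exact mean formula.

    The full-model mean is ``k_de_novo/(gamma - k_fission)`` and the
    knockout mean ``k_de_novo/gamma``, so the relative drop is exactly
    ``k_fission/gamma``.
    """
    return 100.0 * inferred.k_fission_over_gamma


def _histogram_arrays(
    histogram: Union[Mapping[int, int], Sequence[int], np.ndarray],
) -> Tuple[np.ndarray, np.ndarray]:
    """Normalise histogram input to (values, counts) arrays.

    Accepts a mapping {n: cells} or a dense array where index = n.
    """
    if isinstance(histogram, Mapping):
        values = np.asarray(sorted(histogram), dtype=np.int64)
        counts = np.asarray([histogram[v] for v in values], dtype=np.int64)
    else:
        counts = np.asarray(histogram, dtype=np.int64)
        values = np.arange(counts.size, dtype=np.int64)
    if (values < 0).any():
        raise ValueError("organelle counts must be non-negative integers")
    if (counts < 0).any():
        raise ValueError("cell counts must be non-negative")
    return values, counts


def _moments_from_hist(values: np.ndarray, counts: np.ndarray) -> Tuple[float, float]:
    total = counts.sum()
    mean = float(values @ counts) / total
    # unbiased sample variance (n - 1 denominator)
    ss = float(counts @ (values.astype(float) - mean) ** 2)
    variance = ss / (total - 1)
    return mean, variance


def observed_moments(
    histogram: Union[Mapping[int, int], Sequence[int], np.ndarray],
    bootstrap_reps: int = 0,
    seed: Optional[int] = None,
    ci_level: float = 0.95,
) -> ObservedMoments:
    """Sample mean, unbiased variance and Fano factor of an observed
    organelle-count histogram, with optional percentile-bootstrap
    confidence intervals (resampling cells).
    """
    values, counts = _histogram_arrays(histogram)
    total = int(counts.sum())
    if total < 2:
        raise ValueError("need at least 2 cells to estimate a variance")
    mean, variance = _moments_from_hist(values, counts)
    if mean > 0:
        fano, fano_defined = variance / mean, True
    else:
        fano, fano_defined = math.nan, False

    mean_ci = fano_ci = None
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        p = counts / total
        boot_means = np.empty(bootstrap_reps)
        boot_fanos = np.full(bootstrap_reps, np.nan)
        for b in range(bootstrap_reps):
            resampled = rng.multinomial(total, p)
            m, v = _moments_from_hist(values, resampled)
            boot_means[b] = m
            if m > 0:
                boot_fanos[b] = v / m
        lo, hi = (1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100
        mean_ci = tuple(np.percentile(boot_means, [lo, hi]))
        ok = ~np.isnan(boot_fanos)
        if ok.any():
            fano_ci = tuple(np.percentile(boot_fanos[ok], [lo, hi]))
    return ObservedMoments(mean, variance, fano, total, fano_defined, mean_ci, fano_ci)


def estimate_rates_from_histogram(
    histogram: Union[Mapping[int, int], Sequence[int], np.ndarray],
    bootstrap_reps: int = 0,
    seed: Optional[int] = None,
    tolerance: float = 0.0,
) -> Tuple[InferredRates, Optional[Tuple[float, float]]]:
    """Invert observed moments to rate ratios, with optional bootstrap
    standard errors.

    Returns ``(inferred, standard_errors)`` where ``standard_errors`` is a
    ``(se_k_de_novo_over_gamma, se_k_fission_over_gamma)`` pair from
    resampling cells (None when ``bootstrap_reps == 0``).  Bootstrap
    replicates whose Fano factor falls below 1 are clamped to the Poisson
    boundary, where the fission ratio is 0.
    """
    values, counts = _histogram_arrays(histogram)
    total = int(counts.sum())
    mean, variance = _moments_from_hist(values, counts)
    inferred = invert_rates(mean, variance / mean, tolerance=tolerance)
    if bootstrap_reps <= 0:
        return inferred, None
    rng = np.random.default_rng(seed)
    p = counts / total
    kd = np.empty(bootstrap_reps)
    kf = np.empty(bootstrap_reps)
    for b in range(bootstrap_reps):
        resampled = rng.multinomial(total, p)
        m, v = _moments_from_hist(values, resampled)
        fano = max(v / m, 1.0)
        kd[b] = m / fano
        kf[b] = 1.0 - 1.0 / fano
    return inferred, (float(kd.std(ddof=1)), float(kf.std(ddof=1)))


def read_histogram(path: Union[str, Path]) -> dict[int, int]:
    """Read an organelle-count histogram from plain text.

    Two layouts are auto-detected: one integer count per line (one cell per
    line), or two-column ``n<TAB or whitespace>cells`` rows.  Comment lines
    starting with ``#`` and a ``n  cells`` header row are ignored.
    """
    hist: dict[int, int] = {}
    per_cell: list[int] = []
    two_column = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fields[0].lower() in ("n", "count") and not fields[0].isdigit():
            continue  # header row
        if two_column is None:
            two_column = len(fields) == 2
        if len(fields) != (2 if two_column else 1):
            raise ValueError(f"inconsistent histogram row: {raw!r}")
        if two_column:
            n, cells = int(fields[0]), int(fields[1])
            if n < 0 or cells < 0:
                raise ValueError(f"negative value in histogram row: {raw!r}")
            hist[n] = hist.get(n, 0) + cells
        else:
            n = int(fields[0])
            if n < 0:
                raise ValueError(f"negative count in histogram row: {raw!r}")
            per_cell.append(n)
    if two_column is None:
        raise ValueError(f"no histogram rows found in {path}")
    if not two_column:
        for n in per_cell:
            hist[n] = hist.get(n, 0) + 1
    return dict(sorted(hist.items()))
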