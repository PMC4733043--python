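"""Closed-form limiting laws of the sub-models, with exact moments.

Three sub-models of the four-process system have named limiting
distributions, read off directly from the detailed-balance term ratio:

* ``{de novo; decay}`` (the Golgi-style model) — Poisson with
  ``lam = k_de_novo / gamma``.
* ``{fission; fusion}`` (the vacuole-style model) — zero-truncated Poisson
  with ``lam = k_fission / k_fusion`` on support ``n >= 1``.
* ``{de novo, fission; decay}`` (the peroxisome model) — negative binomial
  with ``r = k_de_novo / k_fission`` and ``p = k_fission / gamma``.

A *shifted* Poisson (``n - 1 ~ Poisson(lam)``) is also provided: it is NOT a
limiting law of any sub-model, but it was previously reported as the
vacuole distribution and its Fano-versus-mean curve is the standard foil
for the zero-truncated Poisson.

The peroxisome model's exact moments are::

    <n>        = k_de_novo / (gamma - k_fission)
    sigma2/<n> = gamma / (gamma - k_fission)
               = 1 + k_fission * <n> / k_de_novo

valid for all parameter values with ``k_fission < gamma``; both diverge as
``k_fission`` approaches ``gamma``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .errors import RegimeError
from .model_core import ModelRates

__all__ = [
    "Family",
    "ClosedFormSpec",
    "FanoMeanCurve",
    "closed_form_pmf",
    "family_moments",
    "peroxisome_mean",
    "peroxisome_fano",
    "fano_from_contributions",
    "fano_mean_curve",
]


class Family(str, Enum):
    POISSON = "POISSON"
    TRUNCATED_POISSON = "TRUNCATED_POISSON"
    SHIFTED_POISSON = "SHIFTED_POISSON"
    NEGATIVE_BINOMIAL = "NEGATIVE_BINOMIAL"


@dataclass(frozen=True)
class ClosedFormSpec:
    """A limiting-law family plus its shape parameters.

    ``lam`` is used by the three Poisson-type families; the negative
    binomial uses ``r`` (shape) and ``p`` (its term ratio, in ``(0, 1)``),
    with pmf proportional to ``Gamma(r + n) / (Gamma(r) n!) * p**n``.
    """

    family: Family
    lam: float = math.nan
    r: float = math.nan
    p: float = math.nan

    def __post_init__(self) -> None:
        if self.family is Family.NEGATIVE_BINOMIAL:
            if not (self.r > 0 and 0 < self.p < 1):
                raise ValueError(
                    f"negative binomial needs r > 0 and 0 < p < 1, "
                    f"got r={self.r!r}, p={self.p!r}"
                )
        else:
            if not self.lam > 0:
                raise ValueError(f"{self.family.value} needs lam > 0, got {self.lam!r}")

    @property
    def support_min(self) -> int:
        if self.family in (Family.TRUNCATED_POISSON, Family.SHIFTED_POISSON):
            return 1
        return 0

    @classmethod
    def from_rates(cls, rates: ModelRates) -> "ClosedFormSpec":
        """Identify the closed-form law of a sub-model from its rates.

        Raises ``ValueError`` if the active processes do not match one of
        the three solvable sub-models.
        """
        kd, kf, g, ku = rates.k_de_novo, rates.k_fission, rates.gamma, rates.k_fusion
        if ku == 0 and kf == 0 and kd > 0 and g > 0:
            return cls(Family.POISSON, lam=kd / g)
        if kd == 0 and g == 0 and kf > 0 and ku > 0:
            return cls(Family.TRUNCATED_POISSON, lam=kf / ku)
        if ku == 0 and kd > 0 and kf > 0 and g > 0:
            if kf >= g:
                raise RegimeError(
                    "negative binomial requires k_fission < gamma; "
                    f"got k_fission={kf}, gamma={g}"
                )
            return cls(Family.NEGATIVE_BINOMIAL, r=kd / kf, p=kf / g)
        raise ValueError(
            "active processes do not form a {de novo; decay}, "
            "{fission; fusion} or {de novo, fission; decay} sub-model"
        )


def closed_form_pmf(spec: ClosedFormSpec, n) -> np.ndarray | float:
    """Probability mass at organelle number ``n`` (scalar or array).

    ``n`` below the family's support minimum returns 0.
    """
    n_arr = np.asarray(n)
    fam = spec.family
    if fam is Family.POISSON:
        out = stats.poisson.pmf(n_arr, spec.lam)
    elif fam is Family.TRUNCATED_POISSON:
        # Poisson conditioned on n >= 1
        out = np.where(
            n_arr >= 1,
            stats.poisson.pmf(n_arr, spec.lam) / (1.0 - math.exp(-spec.lam)),
            0.0,
        )
    elif fam is Family.SHIFTED_POISSON:
        out = np.where(n_arr >= 1, stats.poisson.pmf(n_arr - 1, spec.lam), 0.0)
    elif fam is Family.NEGATIVE_BINOMIAL:
        # scipy parameterises by the complementary probability
        out = stats.nbinom.pmf(n_arr, spec.r, 1.0 - spec.p)
    else:  # pragma: no cover
        raise ValueError(f"unknown family {fam!r}")
    if np.isscalar(n):
        return float(out)
    return out


def family_moments(spec: ClosedFormSpec) -> Tuple[float, float, float]:
    """Exact (mean, variance, fano) of a closed-form family.

    Zero-truncated Poisson: mean ``mu = lam / (1 - exp(-lam))``,
    Fano ``1 + lam - mu``.  Shifted Poisson: mean ``1 + lam``, variance
    ``lam``, Fano ``lam / (1 + lam)``.  Negative binomial: mean
    ``r p / (1 - p)``, Fano ``1 / (1 - p)``.
    """
    fam = spec.family
    if fam is Family.POISSON:
        return spec.lam, spec.lam, 1.0
    if fam is Family.TRUNCATED_POISSON:
        mu = spec.lam / (1.0 - math.exp(-spec.lam))
        fano = 1.0 + spec.lam - mu
        return mu, fano * mu, fano
    if fam is Family.SHIFTED_POISSON:
        mean = 1.0 + spec.lam
        return mean, spec.lam, spec.lam / mean
    if fam is Family.NEGATIVE_BINOMIAL:
        mean = spec.r * spec.p / (1.0 - spec.p)
        fano = 1.0 / (1.0 - spec.p)
        return mean, fano * mean, fano
    raise ValueError(f"unknown family {fam!r}")  # pragma: no cover


def _require_peroxisome_regime(rates: ModelRates) -> None:
    if rates.k_fusion != 0:
        raise RegimeError("exact mean/Fano formulas hold only for k_fusion = 0")
    if rates.k_fission >= rates.gamma:
        raise RegimeError(
            f"mean and Fano factor diverge for k_fission={rates.k_fission} >= "
            f"gamma={rates.gamma}"
        )


def peroxisome_mean(rates: ModelRates) -> float:
    """Exact equilibrium mean of the {de novo, fission; decay} model:
    ``k_de_novo / (gamma - k_fission)``."""
    _require_peroxisome_regime(rates)
    return rates.k_de_novo / (rates.gamma - rates.k_fission)


def peroxisome_fano(rates: ModelRates) -> float:
    """Exact equilibrium Fano factor of the {de novo, fission; decay}
    model: ``gamma / (gamma - k_fission)``.  Exact for all parameter values
    in the convergent regime, not a fluctuation-dissipation approximation."""
    _require_peroxisome_regime(rates)
    return rates.gamma / (rates.gamma - rates.k_fission)


def fano_from_contributions(mean: float, rates: ModelRates) -> float:
    """Fano factor written in terms of the two production rates:
    ``1 + k_fission * mean / k_de_novo``.

    Equals :func:`peroxisome_fano` when ``mean`` is the equilibrium mean;
    the two production terms it compares are the absolute de novo rate
    ``k_de_novo`` and the absolute fission rate ``k_fission * mean``.
    """
    if rates.k_de_novo <= 0:
        raise ValueError("k_de_novo must be > 0 for the contribution form")
    return 1.0 + rates.k_fission * mean / rates.k_de_novo


@dataclass(frozen=True)
class FanoMeanCurve:
    """A family's (mean, Fano) locus swept over its shape parameter."""

    family: Family
    sweep: np.ndarray
    means: np.ndarray
    fanos: np.ndarray

    def to_tsv(self, path: Union[str, Path]) -> None:
        from . import __version__

        lines = [
            f"# orgcount {__version__} fano-mean curve\n",
            f"# family: {self.family.value}\n",
            "sweep_value\tmean\tfano\n",
        ]
        for s, m, f in zip(self.sweep, self.means, self.fanos):
            lines.append(f"{float(s)!r}\t{float(m)!r}\t{float(f)!r}\n")
        Path(path).write_text("".join(lines))


def fano_mean_curve(
    family: Family,
    sweep: Sequence[float],
    r: float = math.nan,
) -> FanoMeanCurve:
    """Exact (mean, Fano) pairs along a sweep of the family's shape
    parameter.

    For the Poisson-type families the sweep is over ``lam``; for the
    negative binomial it is over ``p`` at fixed shape ``r``.  Means must
    come out strictly increasing, which they do for any increasing sweep.
    """
    sweep_arr = np.asarray(list(sweep), dtype=float)
    if sweep_arr.size == 0:
        raise ValueError("sweep must be non-empty")
    specs = [
        ClosedFormSpec(family, lam=s)
        if family is not Family.NEGATIVE_BINOMIAL
        else ClosedFormSpec(family, r=r, p=s)
        for s in sweep_arr
    ]
    moments = [family_moments(spec) for spec in specs]
    means = np.array([m[0] for m in moments])
    fanos = np.array([m[2] for m in moments])
    if not np.all(np.diff(means) > 0):
        raise ValueError("sweep must produce strictly increasing means")
    return FanoMeanCurve(family, sweep_arr, means, fanos)
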