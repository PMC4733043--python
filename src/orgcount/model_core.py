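"""Core definition of the four-process organelle copy-number model.

A cell carries an integer number ``n`` of organelles.  Four elementary
processes change ``n`` by one organelle at a time:

==========  ==============================  ==========  =================
process     rate in a cell with n           changes n   interpretation
==========  ==============================  ==========  =================
de novo     ``k_de_novo``                   +1          synthesis from
                                                        precursor material
fission     ``k_fission * n``               +1          one organelle
                                                        splits in two
decay       ``gamma * n``                   -1          degradation /
                                                        loss of identity
fusion      ``k_fusion * n * (n - 1)``      -1          two organelles
                                                        merge
==========  ==============================  ==========  =================

This is a birth-death chain on the non-negative integers: de novo synthesis
is an immigration term, fission a per-capita birth, decay a per-capita
death, and fusion a pairwise (quadratic) loss.  Time units are arbitrary;
only rate ratios matter for the equilibrium behaviour.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from enum import Enum
from pathlib import Path
from typing import Mapping, Union

__all__ = [
    "ModelRates",
    "ProcessEventProbabilities",
    "RegimeReason",
    "RegimeClassification",
    "PROCESS_NAMES",
    "event_probabilities",
    "population_process_rate",
    "classify_regime",
]

PROCESS_NAMES = ("de_novo", "fission", "decay", "fusion")


@dataclass(frozen=True)
class ModelRates:
    """The four non-negative rate constants of a model instance.

    Parameters
    ----------
    k_de_novo : float
        De novo synthesis rate, events per unit time, independent of ``n``.
    k_fission : float
        Fission rate per organelle per unit time.
    gamma : float
        Decay rate per organelle per unit time.
    k_fusion : float
        Fusion rate per ordered organelle pair per unit time; the propensity
        in a cell with ``n`` organelles is ``k_fusion * n * (n - 1)``.
    """

    k_de_novo: float = 0.0
    k_fission: float = 0.0
    gamma: float = 0.0
    k_fusion: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_de_novo", "k_fission", "gamma", "k_fusion"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")

    def scaled(self, factor: float) -> "ModelRates":
        """Return a copy with every rate multiplied by ``factor``.

        Uniform scaling changes only the time unit, not the limiting
        distribution.
        """
        if factor <= 0:
            raise ValueError("scale factor must be > 0")
        return ModelRates(
            self.k_de_novo * factor,
            self.k_fission * factor,
            self.gamma * factor,
            self.k_fusion * factor,
        )

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ModelRates":
        known = {k: float(v) for k, v in mapping.items()
                 if k in ("k_de_novo", "k_fission", "gamma", "k_fusion")}
        unknown = set(mapping) - set(known)
        if unknown:
            raise ValueError(f"unknown rate keys: {sorted(unknown)}")
        return cls(**known)

    @classmethod
    def from_json(cls, text: str) -> "ModelRates":
        return cls.from_mapping(json.loads(text))

    def to_config(self, path: Union[str, Path]) -> None:
        """Write a flat ``key = value`` config file; full float precision."""
        lines = [f"{k} = {v!r}\n" for k, v in self.to_dict().items()]
        Path(path).write_text("".join(lines))

    @classmethod
    def from_config(cls, path: Union[str, Path]) -> "ModelRates":
        """Read a flat ``key = value`` config file written by :meth:`to_config`."""
        mapping = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            mapping[key] = float(value)
        return cls.from_mapping(mapping)


@dataclass(frozen=True)
class ProcessEventProbabilities:
    """First-order probabilities of each process firing in a window ``dt``
    for one cell with ``n`` organelles."""

    de_novo: float
    fission: float
    decay: float
    fusion: float

    @property
    def total(self) -> float:
        return self.de_novo + self.fission + self.decay + self.fusion


class RegimeReason(str, Enum):
    """Why a parameter set does or does not admit a limiting distribution."""

    STANDARD = "STANDARD"
    FISSION_EXCEEDS_DECAY = "FISSION_EXCEEDS_DECAY"
    ABSORBED_AT_ZERO = "ABSORBED_AT_ZERO"
    FUSION_REGULARISED = "FUSION_REGULARISED"
    NO_LOSS_PROCESS = "NO_LOSS_PROCESS"


@dataclass(frozen=True)
class RegimeClassification:
    has_limiting_distribution: bool
    support_min: int
    reason: RegimeReason


def event_probabilities(rates: ModelRates, n: int, dt: float) -> ProcessEventProbabilities:
    """Per-process probabilities of one event in the next ``dt`` for a cell
    with ``n`` organelles.

    These are first-order (linear in ``dt``) probabilities: the caller must
    choose ``dt`` small enough that their sum is well below 1.  A warning is
    raised when the summed probability exceeds 0.1 and an error when it
    exceeds 1; no clamping is performed.
    """
    if not isinstance(n, (int,)) or isinstance(n, bool):
        if not (isinstance(n, float) and n.is_integer()):
            raise ValueError(f"n must be a non-negative integer, got {n!r}")
        n = int(n)
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if not (dt > 0):
        raise ValueError(f"dt must be > 0, got {dt!r}")
    probs = ProcessEventProbabilities(
        de_novo=rates.k_de_novo * dt,
        fission=rates.k_fission * n * dt,
        decay=rates.gamma * n * dt,
        fusion=rates.k_fusion * n * (n - 1) * dt,
    )
    if probs.total > 1:
        raise ValueError(
            f"summed event probability {probs.total:.3g} exceeds 1 at n={n}; "
            "reduce dt"
        )
    if probs.total > 0.1:
        warnings.warn(
            f"summed event probability {probs.total:.3g} exceeds 0.1 at n={n}; "
            "first-order-in-dt probabilities are inaccurate at this step size",
            stacklevel=2,
        )
    return probs


def population_process_rate(
    rates: ModelRates, n: int, f_n: float, N: float, process: str
) -> float:
    """Rate (cells per unit time) at which cells with ``n`` organelles in a
    sample of ``N`` cells undergo the named process.

    ``f_n`` is the fraction of cells currently holding ``n`` organelles, so
    the rate is the single-cell propensity times ``f_n * N``.
    """
    if not 0 <= f_n <= 1:
        raise ValueError(f"f_n must be in [0, 1], got {f_n!r}")
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N!r}")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n!r}")
    per_cell = {
        "de_novo": rates.k_de_novo,
        "fission": rates.k_fission * n,
        "decay": rates.gamma * n,
        "fusion": rates.k_fusion * n * (n - 1),
    }
    try:
        propensity = per_cell[process]
    except KeyError:
        raise ValueError(
            f"unknown process {process!r}; expected one of {PROCESS_NAMES}"
        ) from None
    return propensity * f_n * N


def classify_regime(rates: ModelRates) -> RegimeClassification:
    """Decide whether the rates admit a limiting distribution and on which
    support it lives.

    Without fusion, fission is a per-capita production term competing with
    per-capita decay: if ``k_fission >= gamma`` (and fission is active) the
    organelle number grows without bound and no limiting distribution
    exists.  The boundary case ``k_fission == gamma`` is included in the
    divergent class because the mean and Fano factor both diverge there and
    the recurrence produces a non-normalisable sequence.

    Quadratic fusion loss always dominates linear fission gain at large
    ``n``, so any ``k_fusion > 0`` restores a limiting distribution.

    Special supports:

    * ``k_de_novo == 0`` with ``gamma > 0``: state 0 is absorbing and
      reachable, so the unique limiting law is the point mass at 0.
    * ``k_de_novo == 0`` with ``gamma == 0`` and ``k_fission > 0``: state 0
      is unreachable from ``n >= 1`` (the pure fission/fusion model); the
      recurrence runs on ``n >= 1``.
    """
    kd, kf, g, ku = rates.k_de_novo, rates.k_fission, rates.gamma, rates.k_fusion
    if ku == 0 and kf > 0 and kf >= g:
        return RegimeClassification(False, 0, RegimeReason.FISSION_EXCEEDS_DECAY)
    if kd > 0 and g == 0 and ku == 0:
        # pure immigration (kf == 0 here, else caught above): n only grows
        return RegimeClassification(False, 0, RegimeReason.NO_LOSS_PROCESS)
    if kd == 0 and g > 0:
        return RegimeClassification(True, 0, RegimeReason.ABSORBED_AT_ZERO)
    if kd == 0 and g == 0 and kf > 0:
        # reachable: ku > 0 here, else caught by the divergence branch above
        return RegimeClassification(True, 1, RegimeReason.FUSION_REGULARISED)
    if ku > 0 and kf >= g and kf > 0:
        return RegimeClassification(True, 0, RegimeReason.FUSION_REGULARISED)
    return RegimeClassification(True, 0, RegimeReason.STANDARD)
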