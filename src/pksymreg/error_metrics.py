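"""Observation-prediction error measures and the population training loss.

Per-sample errors are the (absolute) logarithmic error LE/ALE = (|)ln(Cobs/
Cpred)(|) and the (absolute) percent prediction error PE/APE.  Per-individual
errors take the median over that individual's samples (even counts: mean of
the two central order statistics); the population loss J_ALE is the
unweighted mean of the per-individual MdALE values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._exceptions import DomainError
from .pk_model import ConcentrationSeries

__all__ = [
    "SampleErrors",
    "IndividualError",
    "PopulationLoss",
    "log_error",
    "prediction_error",
    "sample_errors",
    "individual_medians",
    "population_loss",
    "clinical_bounds",
    "median_and_weights",
]


@dataclass(frozen=True)
class SampleErrors:
    le: float
    ale: float
    pe: float  # %
    ape: float  # %


@dataclass(frozen=True)
class IndividualError:
    individual_id: str
    md_ale: float
    md_le: float
    md_ape: float  # %
    md_pe: float  # %
    n_obs: int


@dataclass(frozen=True)
class PopulationLoss:
    j_ale: float
    n_individuals: int


def log_error(c_obs: float, c_pred: float) -> float:
    """ln(Cobs/Cpred); both concentrations must be strictly positive."""
    if c_obs <= 0 or c_pred <= 0:
        raise DomainError(
            f"log error requires positive concentrations, got obs={c_obs}, "
            f"pred={c_pred}"
        )
    return math.log(c_obs / c_pred)


def prediction_error(c_obs: float, c_pred: float) -> float:
    """Percent prediction error; defined as exactly 0 when Cpred == 0."""
    if c_obs < 0 or c_pred < 0:
        raise DomainError("concentrations must be non-negative")
    if c_pred == 0:
        return 0.0
    return 100.0 * (c_obs - c_pred) / c_pred


def sample_errors(c_obs: float, c_pred: float) -> SampleErrors:
    le = log_error(c_obs, c_pred)
    pe = prediction_error(c_obs, c_pred)
    return SampleErrors(le=le, ale=abs(le), pe=pe, ape=abs(pe))


def _median(values: np.ndarray) -> float:
    # mean-of-central-pair for even counts (numpy's convention, made explicit)
    return float(np.median(values))


def median_and_weights(values: np.ndarray) -> tuple[float, np.ndarray]:
    """Median plus its subgradient weights over the input samples.

    Odd count: weight 1 on the middle order statistic.  Even count: 0.5 on
    each of the two central order statistics.  All other samples get zero —
    the median is locally independent of them.
    """
    values = np.asarray(values, dtype=float)
    m = values.size
    if m == 0:
        raise DomainError("median of an empty sample set")
    order = np.argsort(values, kind="stable")
    w = np.zeros(m)
    if m % 2 == 1:
        w[order[m // 2]] = 1.0
    else:
        w[order[m // 2 - 1]] = 0.5
        w[order[m // 2]] = 0.5
    return float(w @ values), w


def individual_medians(
    obs: ConcentrationSeries,
    pred: ConcentrationSeries,
    individual_id: str = "",
) -> IndividualError:
    """Per-individual medians of ALE/LE/APE/PE over shared sample times."""
    if len(obs) == 0:
        raise DomainError("individual has no observations")
    if len(obs) != len(pred) or not np.allclose(obs.times, pred.times):
        raise DomainError("observed and predicted series must share times")
    le = np.array([log_error(o, p) for o, p in zip(obs.values, pred.values)])
    pe = np.array(
        [prediction_error(o, p) for o, p in zip(obs.values, pred.values)]
    )
    return IndividualError(
        individual_id=individual_id,
        md_ale=_median(np.abs(le)),
        md_le=_median(le),
        md_ape=_median(np.abs(pe)),
        md_pe=_median(pe),
        n_obs=len(obs),
    )


def population_loss(individual_errors: Sequence[IndividualError]) -> PopulationLoss:
    """J_ALE: unweighted mean of MdALE over individuals."""
    if len(individual_errors) == 0:
        raise DomainError("population loss of an empty population")
    j = float(np.mean([e.md_ale for e in individual_errors]))
    return PopulationLoss(j_ale=j, n_individuals=len(individual_errors))


def clinical_bounds() -> tuple[float, float]:
    """(bias bound on MdLE, accuracy bound on MdALE).

    The clinically acceptable upper limits of 20 % on |MdPE| and 40 % on
    MdAPE convert to the log scale as ln(1.20) and ln(1.40); both are
    rounded to two decimals for reporting, giving (0.18, 0.34).
    """
    return round(math.log(1.20), 2), round(math.log(1.40), 2)
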