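"""Epidemiological sensitization indices for contact haptens.

Two indices condense published patch-test prevalence data into a binary
sensitizer call for each substance:

* **eOR** (estimated odds ratio) — ``Me_ACD / Me_gen``, the ratio of the
  median sensitization rate among allergic-contact-dermatitis (ACD)
  patients to the median rate in the general population.  ``eOR >= 3``
  classifies a substance as sensitizing, by analogy with the stimulation
  index threshold of the murine local lymph node assay.  When the
  general-population median is zero and the patient median is positive,
  the ratio is undefined; such substances are flagged :data:`NOT_CALCULABLE`
  and coded as sensitizers (a positive patient signal with zero background
  is treated as maximal concern).

* **eAR** (estimated attributable risk) — ``Me_ACD − Me_gen`` in
  percentage points, interpretable as the excess sensitization prevalence
  attributable to clinical exposure.  ``eAR >= 1`` (one percentage point)
  classifies a substance as sensitizing, by analogy with the inclusion
  criterion for baseline patch-test series.

Both medians are plain sample medians of the rates reported across the
published studies retained for a substance.  All rates are percentages in
[0, 100].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

__all__ = [
    "NOT_CALCULABLE",
    "NotCalculable",
    "PrevalenceRecord",
    "IndexResult",
    "EOR_THRESHOLD",
    "EAR_THRESHOLD",
    "median_prevalence",
    "compute_eor",
    "compute_ear",
    "classify_eor",
    "classify_ear",
    "evaluate_record",
    "round_half_away",
]

#: Sensitizer threshold on the estimated odds ratio (inclusive).
EOR_THRESHOLD = 3.0
#: Sensitizer threshold on the estimated attributable risk, in % points.
EAR_THRESHOLD = 1.0


class NotCalculable:
    """Typed sentinel for an eOR whose denominator median is zero.

    Deliberately not a float (``inf`` would silently flow through
    arithmetic); downstream code must branch on it explicitly.
    """

    _instance = None

    def __new__(cls) -> "NotCalculable":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NOT_CALCULABLE"


NOT_CALCULABLE = NotCalculable()

EorValue = Union[float, NotCalculable]


def _check_rates(rates: Sequence[float], name: str) -> None:
    for r in rates:
        if not (0.0 <= float(r) <= 100.0) or not math.isfinite(float(r)):
            raise ValueError(f"{name}: rate {r!r} outside [0, 100]")


@dataclass(frozen=True)
class PrevalenceRecord:
    """Raw prevalence data for one patch-tested substance.

    Parameters
    ----------
    substance_name:
        Identifier as printed in the source table.
    rates_acd:
        Reported sensitization rates (%) among patch-test-positive ACD
        patients, one value per retained study.  Must be non-empty for a
        usable record.
    rates_gen:
        Reported rates (%) in the general population.  May be empty when a
        median is supplied externally.
    """

    substance_name: str
    rates_acd: tuple = ()
    rates_gen: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates_acd", tuple(float(r) for r in self.rates_acd))
        object.__setattr__(self, "rates_gen", tuple(float(r) for r in self.rates_gen))
        _check_rates(self.rates_acd, self.substance_name)
        _check_rates(self.rates_gen, self.substance_name)


@dataclass(frozen=True)
class IndexResult:
    """Computed indices and binary calls for one substance."""

    substance_name: str
    me_acd: float
    me_gen: float
    eor: EorValue
    ear: float
    label_eor: int
    label_ear: int

    def __post_init__(self) -> None:
        if self.label_eor not in (0, 1) or self.label_ear not in (0, 1):
            raise ValueError("labels must be 0/1")
        if not (-100.0 <= self.ear <= 100.0):
            raise ValueError(f"eAR {self.ear} outside [-100, 100]")


def median_prevalence(rates: Sequence[float]) -> float:
    """Sample median of reported prevalence rates (percentages).

    Mean of the two central order statistics for even-length input.

    Raises
    ------
    ValueError
        If ``rates`` is empty (no usable epidemiological data) or any
        value lies outside [0, 100].
    """
    if len(rates) == 0:
        raise ValueError("no usable epidemiological data: empty rate list")
    _check_rates(rates, "median_prevalence")
    ordered = sorted(float(r) for r in rates)
    n = len(ordered)
    mid = n // 2
    if n % 2:
        return ordered[mid]
    return (ordered[mid - 1] + ordered[mid]) / 2.0


def compute_eor(me_acd: float, me_gen: float) -> EorValue:
    """Estimated odds ratio ``Me_ACD / Me_gen``.

    Returns :data:`NOT_CALCULABLE` when the general-population median is
    zero but the patient median is positive.

    Raises
    ------
    ValueError
        If either median is negative, or both are zero (the index carries
        no information and the record is unusable).
    """
    if me_acd < 0 or me_gen < 0:
        raise ValueError("medians must be non-negative")
    if me_acd == 0 and me_gen == 0:
        raise ValueError("eOR undefined: both medians are zero")
    if me_gen == 0:
        return NOT_CALCULABLE
    return me_acd / me_gen


def compute_ear(me_acd: float, me_gen: float) -> float:
    """Estimated attributable risk ``Me_ACD − Me_gen`` in % points."""
    if not (0.0 <= me_acd <= 100.0) or not (0.0 <= me_gen <= 100.0):
        raise ValueError("medians must be percentages in [0, 100]")
    return me_acd - me_gen


def _at_least(value: float, threshold: float) -> bool:
    # the inputs are ratios/differences of 2-decimal percentages, so a
    # relative guard keeps exact-boundary cases (0.30/0.10) on the
    # sensitizer side despite binary-float roundoff
    return value >= threshold or math.isclose(value, threshold, rel_tol=1e-12, abs_tol=1e-12)


def classify_eor(eor: EorValue) -> int:
    """1 (sensitizer) iff ``eOR >= 3`` or the eOR is not calculable."""
    if isinstance(eor, NotCalculable):
        return 1
    return 1 if _at_least(eor, EOR_THRESHOLD) else 0


def classify_ear(ear: float) -> int:
    """1 (sensitizer) iff ``eAR >= 1`` percentage point."""
    return 1 if _at_least(ear, EAR_THRESHOLD) else 0


def evaluate_record(record: PrevalenceRecord) -> IndexResult:
    """Medians, both indices and both labels for one substance."""
    me_acd = median_prevalence(record.rates_acd)
    me_gen = median_prevalence(record.rates_gen) if record.rates_gen else 0.0
    eor = compute_eor(me_acd, me_gen)
    ear = compute_ear(me_acd, me_gen)
    return IndexResult(
        substance_name=record.substance_name,
        me_acd=me_acd,
        me_gen=me_gen,
        eor=eor,
        ear=ear,
        label_eor=classify_eor(eor),
        label_ear=classify_ear(ear),
    )


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of the source tables).

    ``round()`` uses banker's rounding, which disagrees with the printed
    indices on exact .xx5 ties.
    """
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
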