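"""Pollen viability and quantity statistics.

Pollen quality is scored as a nonviable-to-total ratio from Lugol-stained
grains counted in three fixed-area fields of view per individual; pollen
quantity as grains/microliter from three hemacytometer counts (count times a
chamber conversion factor).  Genotype summaries report the mean of
per-individual averages, with the standard deviation taken over all raw
measurements (sample sd, n-1) — the convention of the published tables.
Group comparisons (e.g. SaFX carriers vs non-carriers) use a two-sample
t-test, Welch by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps


class MeasurementError(ValueError):
    pass


@dataclass(frozen=True)
class PollenSample:
    """Triplicate pollen measurements for one individual.

    ``field_counts``: three (viable, nonviable) grain counts, one per field
    of view.  ``hemacytometer_counts``: three raw chamber counts, converted
    to grains/microliter by ``chamber_factor``.
    """

    accession: str
    genotype: str  # haploid slash notation
    field_counts: Optional[tuple[tuple[int, int], ...]] = None
    hemacytometer_counts: Optional[tuple[float, ...]] = None
    chamber_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.field_counts is not None and len(self.field_counts) != 3:
            raise MeasurementError(
                f"{self.accession}: exactly 3 field counts required"
            )
        if self.hemacytometer_counts is not None \
                and len(self.hemacytometer_counts) != 3:
            raise MeasurementError(
                f"{self.accession}: exactly 3 hemacytometer counts required"
            )


def field_nonviable_percents(sample: PollenSample) -> list[float]:
    """Per-field percent nonviable pollen."""
    if sample.field_counts is None:
        raise MeasurementError(f"{sample.accession}: no field counts")
    out = []
    for i, (viable, nonviable) in enumerate(sample.field_counts):
        total = viable + nonviable
        if total <= 0:
            raise MeasurementError(
                f"{sample.accession}: field {i + 1} has no counted pollen"
            )
        out.append(100.0 * nonviable / total)
    return out


def nonviable_percent(sample: PollenSample) -> float:
    """Mean percent nonviable pollen over the three fields of view."""
    percents = field_nonviable_percents(sample)
    return sum(percents) / len(percents)


def pollen_concentration(sample: PollenSample) -> float:
    """Mean pollen concentration (grains/microliter) over three chamber
    counts, each scaled by the chamber conversion factor."""
    if sample.hemacytometer_counts is None:
        raise MeasurementError(f"{sample.accession}: no hemacytometer counts")
    if sample.chamber_factor <= 0:
        raise MeasurementError("chamber conversion factor must be positive")
    vals = [c * sample.chamber_factor for c in sample.hemacytometer_counts]
    return sum(vals) / len(vals)


@dataclass(frozen=True)
class GenotypeSummary:
    genotype: str
    mean: float     # mean of per-individual averages
    sd: Optional[float]  # sample sd over all raw measurements (None if < 2)
    n_individuals: int
    n_measurements: int


def genotype_summary(values_by_genotype: Mapping[str, Sequence[Sequence[float]]]
                     ) -> dict[str, GenotypeSummary]:
    """Summarise a quantity per genotype.

    Input maps genotype -> list of per-individual raw triplicates (any
    per-individual measurement lists).  The mean is taken over per-individual
    averages; the sd over the pooled raw measurements with n-1 degrees of
    freedom.
    """
    out = {}
    for genotype, individuals in values_by_genotype.items():
        if not individuals:
            continue
        per_ind = [sum(v) / len(v) for v in individuals]
        raw = [x for v in individuals for x in v]
        sd = float(np.std(raw, ddof=1)) if len(raw) > 1 else None
        out[genotype] = GenotypeSummary(
            genotype=genotype,
            mean=sum(per_ind) / len(per_ind),
            sd=sd,
            n_individuals=len(individuals),
            n_measurements=len(raw),
        )
    return out


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: str
    diagnostic: str = ""


def two_sample_t(group_a: Sequence[float], group_b: Sequence[float],
                 variant: str = "welch") -> TTestResult:
    """Two-sided two-sample t-test (Welch by default, Student optional)."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise MeasurementError("each group needs n >= 2 for a t-test")
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            df = (len(a) + len(b) - 2)
            return TTestResult(0.0, df, 1.0, variant,
                               "zero variance in both groups, equal means")
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return TTestResult(float(res.statistic), float(res.df),
                       float(res.pvalue), variant)
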