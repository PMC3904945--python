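"""Genotype panels, allele-type frequency tables and two-locus genotype
distributions.

Accessions are grouped into the study's ten populations: the cultivated
groups *indica*, *aus* and *japonica*; the US weedy-rice groups SH (straw
hull), BHA1/BHA2 (black hull awned), MX (weed x crop hybrids) and BRH
(SH x BHA hybrids); wild *O. rufipogon*/*O. nivara*; and outgroup species.
Wild accessions are outcrossing and carry two alleles per locus (diploid
convention); all other groups are treated as haploid inbred lines except for
rare heterozygotes, which contribute both alleles.

Frequency rows follow the published table conventions: percentages are
integers (round-half-up), denominators count non-missing alleles only, and at
*s5* the wide-compatibility deletion allele *s5-n* is tabulated as an
indica-type allele with a separate "wc" percentage computed among indica-type
alleles only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from ._util import round_half_up
from .loci import ALLELE_ENUM, LOCUS_NAMES, AlleleCall

GROUPS = ("indica", "aus", "japonica", "SH", "BHA1", "BHA2", "MX", "BRH",
          "wild", "outgroup")

# Table-1 display convention: at s5 the wc (s5-n) alleles are folded into the
# indica-type row, with the deletion reported as a share of indica-type.
_DISPLAY_GROUPING: dict[str, dict[str, tuple[str, ...]]] = {
    "s5": {"s5-i": ("s5-i", "s5-n"), "s5-j": ("s5-j",)},
}
_WC_TYPES: dict[str, tuple[str, ...]] = {"s5": ("s5-n",)}
_WC_BASE: dict[str, tuple[str, ...]] = {"s5": ("s5-i", "s5-n")}


class PanelError(ValueError):
    pass


@dataclass
class GenotypeRecord:
    """Per-accession typed alleles across loci.

    ``calls[locus]`` holds one AlleleCall for haploid records and two for
    diploid (wild) or heterozygous records.
    """

    accession: str
    group: str
    calls: dict[str, tuple[AlleleCall, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise PanelError(f"unknown group label {self.group!r}")

    @property
    def ploidy_convention(self) -> str:
        return "diploid" if self.group == "wild" else "haploid"

    def alleles(self, locus: str) -> tuple[AlleleCall, ...]:
        return self.calls.get(locus, ())

    def typed_alleles(self, locus: str) -> tuple[str, ...]:
        """Non-missing allele-type labels at a locus."""
        return tuple(c.allele_type for c in self.alleles(locus)
                     if not c.missing and c.allele_type is not None)


def build_panel(metadata: Iterable[tuple[str, str]],
                calls: Iterable[tuple[str, AlleleCall]]) -> list[GenotypeRecord]:
    """Assemble GenotypeRecords from a sample table and typed allele calls.

    ``metadata`` yields (accession, group) pairs; ``calls`` yields
    (accession, AlleleCall) pairs.  Duplicate accessions, unknown groups and
    calls referencing absent accessions are rejected.
    """
    records: dict[str, GenotypeRecord] = {}
    for accession, group in metadata:
        if accession in records:
            raise PanelError(f"duplicate accession id {accession!r}")
        records[accession] = GenotypeRecord(accession=accession, group=group)
    for accession, call in calls:
        if accession not in records:
            raise PanelError(f"call references unknown accession {accession!r}")
        rec = records[accession]
        rec.calls[call.locus] = rec.calls.get(call.locus, ()) + (call,)
    return list(records.values())


@dataclass(frozen=True)
class FrequencyRow:
    """One population x locus row of the allele-type frequency table."""

    locus: str
    group: str
    counts: Mapping[str, int]            # display type -> allele count
    percents: Mapping[str, int]          # round-half-up integer percents
    exact_percents: Mapping[str, float]  # un-rounded percentages
    alleles_sampled: int
    wc_percent: Optional[int] = None     # % of indica-type alleles with the wc deletion
    wc_exact_percent: Optional[float] = None
    empty: bool = False


def _display_types(locus: str) -> dict[str, tuple[str, ...]]:
    if locus in _DISPLAY_GROUPING:
        return dict(_DISPLAY_GROUPING[locus])
    return {t: (t,) for t in ALLELE_ENUM[locus]}


def allele_type_frequencies(panel: Sequence[GenotypeRecord], locus: str,
                            group: str) -> FrequencyRow:
    """Tabulate allele-type percentages for one locus in one group.

    Missing calls are excluded from the denominator.  A group with no typed
    alleles yields an explicit empty row rather than zero percentages.
    """
    if locus not in LOCUS_NAMES:
        raise PanelError(f"unknown locus {locus!r}")
    if group not in GROUPS:
        raise PanelError(f"unknown group {group!r}")
    raw: dict[str, int] = {t: 0 for t in ALLELE_ENUM[locus]}
    for rec in panel:
        if rec.group != group:
            continue
        for atype in rec.typed_alleles(locus):
            raw[atype] += 1
    total = sum(raw.values())
    display = _display_types(locus)
    if total == 0:
        return FrequencyRow(locus, group, {k: 0 for k in display}, {}, {},
                            alleles_sampled=0, empty=True)
    counts = {label: sum(raw[t] for t in members)
              for label, members in display.items()}
    exact = {label: 100.0 * c / total for label, c in counts.items()}
    percents = {label: round_half_up(p) for label, p in exact.items()}
    wc_percent = wc_exact = None
    if locus in _WC_TYPES:
        base = sum(raw[t] for t in _WC_BASE[locus])
        wc = sum(raw[t] for t in _WC_TYPES[locus])
        if base > 0:
            wc_exact = 100.0 * wc / base
            wc_percent = round_half_up(wc_exact)
    return FrequencyRow(locus, group, counts, percents, exact,
                        alleles_sampled=total, wc_percent=wc_percent,
                        wc_exact_percent=wc_exact)


@dataclass(frozen=True)
class GenotypeDistribution:
    """Joint genotype classes at a two-gene system within one group."""

    loci: tuple[str, str]
    group: str
    counts: Mapping[str, int]      # genotype class string -> individuals
    percents: Mapping[str, int]
    n_individuals: int
    n_excluded: int


def genotype_distribution(panel: Sequence[GenotypeRecord],
                          locus_pair: tuple[str, str],
                          group: str) -> GenotypeDistribution:
    """Count joint genotypes at a two-locus system (DPL1+DPL2 or SaM+SaF).

    Individuals haploid at both loci are listed in haploid format
    (``DPL1-N+/DPL2-K+``); heterozygous/diploid individuals are written out in
    full (``SaM+X/SaM-//SaFX/SaF-``).  Individuals missing either locus are
    excluded and tallied separately.
    """
    la, lb = locus_pair
    if {la, lb} not in ({"DPL1", "DPL2"}, {"SaM", "SaF"}):
        raise PanelError(f"unsupported locus pair {locus_pair!r}")
    counts: dict[str, int] = {}
    n_inc = n_exc = 0
    for rec in panel:
        if rec.group != group:
            continue
        a = rec.typed_alleles(la)
        b = rec.typed_alleles(lb)
        if not a or not b:
            if rec.alleles(la) or rec.alleles(lb):
                n_exc += 1
            continue
        if len(a) == 1 and len(b) == 1:
            label = f"{a[0]}/{b[0]}"
        else:
            aa = "/".join(sorted(a * (2 // len(a))))
            bb = "/".join(sorted(b * (2 // len(b))))
            label = f"{aa}//{bb}"
        counts[label] = counts.get(label, 0) + 1
        n_inc += 1
    percents = {k: round_half_up(100.0 * v / n_inc) for k, v in counts.items()} \
        if n_inc else {}
    return GenotypeDistribution((la, lb), group, counts, percents, n_inc, n_exc)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_panel_tsv(panel: Sequence[GenotypeRecord], path) -> None:
    """Write a panel as TSV (accession, group, locus, allele_1, allele_2)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["accession", "group", "locus", "allele_1", "allele_2"])
        for rec in panel:
            for locus in LOCUS_NAMES:
                calls = rec.alleles(locus)
                if not calls:
                    continue
                labels = [c.allele_type if not c.missing and c.allele_type
                          else "missing" for c in calls]
                while len(labels) < 2:
                    labels.append("")
                w.writerow([rec.accession, rec.group, locus, *labels[:2]])


def read_panel_tsv(path) -> list[GenotypeRecord]:
    """Read a panel TSV written by :func:`write_panel_tsv`."""
    records: dict[str, GenotypeRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            acc, group, locus = row["accession"], row["group"], row["locus"]
            rec = records.setdefault(acc, GenotypeRecord(acc, group))
            for col in ("allele_1", "allele_2"):
                label = (row.get(col) or "").strip()
                if not label:
                    continue
                if label == "missing":
                    call = AlleleCall(locus, None, missing=True)
                else:
                    call = AlleleCall(locus, label)
                rec.calls[locus] = rec.calls.get(locus, ()) + (call,)
    return list(records.values())
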