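"""Bateson-Dobzhansky-Muller sterility rules and cross-fertility prediction.

Three epistatic systems reduce fertility in indica x japonica rice hybrids:

* **Sa** (pollen): an F1 that is functionally heterozygous at *SaM*
  (one functional *SaM+*, one functional *SaM-*) and carries at least one
  functional *SaF+* allele aborts the *SaM-*-bearing microspores —
  male semi-sterility, ~50% viable pollen.  Alleles on the *SaFX* deletion
  background (*SaFX*, *SaM+X*, *SaM-X*) produce no functional product, so
  crosses involving them escape the interaction (the wide-compatibility
  hypothesis this package models; switchable to an abstaining mode).
* **s5** (embryo sac): the *s5-i*/*s5-j* heterodimer aborts embryo sacs,
  reducing spikelet fertility by 46%; any *s5-n* (136-bp deletion null)
  allele restores compatibility.
* **DPL** (pollen): *DPL1* and *DPL2* are duplicate pollen genes on
  chromosomes 1 and 6; a gamete carrying non-functional alleles at both
  (*DPL1-K-* and *DPL2-N-*) is non-viable.  Gametes are enumerated under
  independent assortment.

Per-system viable fractions are combined multiplicatively into one relative
fertility scalar — a modeling assumption (the systems act on different
chromosomes and different gametophyte stages), reported alongside the
per-system verdicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Optional, Sequence

from .loci import ALLELE_ENUM

SA_EFFECT = 0.5          # viable-pollen fraction lost in Sa semi-sterility
S5_REDUCTION = 0.46      # spikelet-fertility reduction of the i/j heterodimer

SYSTEMS = ("Sa", "s5", "DPL")

COMPATIBLE = "compatible"
SEMI_STERILE = "semi-sterile"
UNKNOWN = "unknown"


class GenotypeError(ValueError):
    pass


def _check_allele(locus: str, allele: str) -> str:
    if allele not in ALLELE_ENUM[locus]:
        raise GenotypeError(f"unknown {locus} allele label {allele!r}")
    return allele


@dataclass(frozen=True)
class SystemVerdict:
    system: str
    verdict: str                 # compatible | semi-sterile | unknown
    viable_fraction: Optional[float]
    mechanism: str               # pollen | embryo-sac
    rationale: str


@dataclass(frozen=True)
class CrossPrediction:
    parent_a: str
    parent_b: str
    f1: Mapping[str, tuple[str, str]]      # locus -> diploid genotype
    verdicts: tuple[SystemVerdict, ...]
    combined_fertility: Optional[float]    # product over evaluated systems
    unevaluated: tuple[str, ...] = ()      # systems lacking genotypes


# ---------------------------------------------------------------------------
# F1 formation
# ---------------------------------------------------------------------------

ParentGenotype = Mapping[str, Sequence[str]]  # locus -> 1 (haploid/inbred) or 2 alleles


def f1_genotype(parent_a: ParentGenotype, parent_b: ParentGenotype,
                loci: Optional[Sequence[str]] = None
                ) -> dict[str, Optional[tuple[str, str]]]:
    """Form the F1 diploid genotype: one allele from each parent per locus.

    Single-allele (inbred, hence homozygous) parents transmit their allele
    deterministically; a heterozygous parent transmits its first listed
    allele (use :func:`predict_cross` to average over parental gametes).
    A locus missing in either parent is returned as None — unpredictable —
    without blocking the other loci.  Symmetric up to allele order.
    """
    if loci is None:
        loci = sorted(set(parent_a) | set(parent_b))
    out: dict[str, Optional[tuple[str, str]]] = {}
    for locus in loci:
        a, b = parent_a.get(locus), parent_b.get(locus)
        if not a or not b:
            out[locus] = None
            continue
        out[locus] = (_check_allele(locus, a[0]), _check_allele(locus, b[0]))
    return out


# ---------------------------------------------------------------------------
# Per-system rules
# ---------------------------------------------------------------------------

def _functional_sam(allele: str) -> Optional[str]:
    """Functional product class of a SaM allele: '+', '-' or None (null)."""
    return {"SaM+": "+", "SaM-": "-"}.get(allele)


def evaluate_sa(sam: tuple[str, str], saf: tuple[str, str],
                effect: float = SA_EFFECT,
                x_mode: str = "null") -> SystemVerdict:
    """Sa pollen-killer rule.

    Semi-sterile iff the F1 is functionally heterozygous at SaM (one
    functional SaM+ and one functional SaM-) and carries >= 1 functional
    SaF+.  X-background alleles (SaFX, SaM+X, SaM-X) contribute no
    functional product under ``x_mode="null"`` (default); under
    ``x_mode="unknown"`` any cross involving an X allele abstains.
    """
    for a in sam:
        _check_allele("SaM", a)
    for a in saf:
        _check_allele("SaF", a)
    has_x = any(a in ("SaM+X", "SaM-X") for a in sam) or "SaFX" in saf
    if has_x and x_mode == "unknown":
        return SystemVerdict("Sa", UNKNOWN, None, "pollen",
                             "X allele present; effect treated as unknown")
    products = {_functional_sam(a) for a in sam} - {None}
    het = products == {"+", "-"}
    saf_plus = any(a == "SaF+" for a in saf)
    if het and saf_plus:
        return SystemVerdict(
            "Sa", SEMI_STERILE, 1.0 - effect, "pollen",
            "functional SaM heterozygote with a functional SaF+: "
            "selective abortion of SaM- microspores",
        )
    reason = ("X alleles are nulls; no functional SaM heterozygote + SaF+ "
              "interaction" if has_x else
              "no functional SaM heterozygote with SaF+")
    return SystemVerdict("Sa", COMPATIBLE, 1.0, "pollen", reason)


def evaluate_s5(genotype: tuple[str, str],
                reduction: float = S5_REDUCTION) -> SystemVerdict:
    """s5 embryo-sac rule: the i/j heterodimer reduces spikelet fertility by
    ``reduction``; any s5-n (null) allele restores full compatibility."""
    for a in genotype:
        _check_allele("s5", a)
    if set(genotype) == {"s5-i", "s5-j"}:
        return SystemVerdict(
            "s5", SEMI_STERILE, 1.0 - reduction, "embryo-sac",
            "s5-i/s5-j heterodimer causes embryo-sac abortion",
        )
    reason = ("wide-compatibility s5-n allele present"
              if "s5-n" in genotype else "no i/j heterodimer")
    return SystemVerdict("s5", COMPATIBLE, 1.0, "embryo-sac", reason)


def evaluate_dpl(dpl1: tuple[str, str], dpl2: tuple[str, str]) -> SystemVerdict:
    """DPL duplicate-gene rule by gamete enumeration.

    The loci assort independently (chromosomes 1 and 6); the four equifrequent
    gametes are enumerated and a gamete is dead iff it carries DPL1-K- and
    DPL2-N-.  Viable fraction = 1 - dead/4.
    """
    for a in dpl1:
        _check_allele("DPL1", a)
    for a in dpl2:
        _check_allele("DPL2", a)
    gametes = list(product(dpl1, dpl2))
    dead = sum(1 for g1, g2 in gametes if g1 == "DPL1-K-" and g2 == "DPL2-N-")
    frac = 1.0 - dead / len(gametes)
    verdict = COMPATIBLE if dead == 0 else SEMI_STERILE
    return SystemVerdict(
        "DPL", verdict, frac, "pollen",
        f"{dead}/4 gametes carry the dead DPL1-K- & DPL2-N- combination",
    )


# ---------------------------------------------------------------------------
# Cross prediction
# ---------------------------------------------------------------------------

def _gametes(parent: ParentGenotype, locus: str) -> list[str]:
    alleles = parent.get(locus) or []
    return [_check_allele(locus, a) for a in alleles]


def _evaluate_f1(f1: Mapping[str, Optional[tuple[str, str]]],
                 sa_effect: float, s5_reduction: float,
                 x_mode: str) -> tuple[list[SystemVerdict], list[str]]:
    verdicts: list[SystemVerdict] = []
    missing: list[str] = []
    if f1.get("SaM") and f1.get("SaF"):
        verdicts.append(evaluate_sa(f1["SaM"], f1["SaF"],
                                    effect=sa_effect, x_mode=x_mode))
    else:
        missing.append("Sa")
    if f1.get("s5"):
        verdicts.append(evaluate_s5(f1["s5"], reduction=s5_reduction))
    else:
        missing.append("s5")
    if f1.get("DPL1") and f1.get("DPL2"):
        verdicts.append(evaluate_dpl(f1["DPL1"], f1["DPL2"]))
    else:
        missing.append("DPL")
    return verdicts, missing


def predict_cross(parent_a: ParentGenotype, parent_b: ParentGenotype,
                  name_a: str = "A", name_b: str = "B",
                  sa_effect: float = SA_EFFECT,
                  s5_reduction: float = S5_REDUCTION,
                  x_mode: str = "null") -> CrossPrediction:
    """Predict the (in)compatibility consequences of a cross.

    Heterozygous parents are handled by enumerating parental gamete
    combinations per locus and averaging each system's viable fraction over
    the equifrequent F1s.  Combined relative fertility is the product of the
    per-system viable fractions (modeling assumption; see module docstring).
    Symmetric in the parents.  Systems with a locus untyped in either parent
    are reported as unevaluated, never silently dropped.
    """
    loci = sorted(set(parent_a) | set(parent_b))
    # representative F1 (first gametes) for reporting
    f1_repr = f1_genotype(parent_a, parent_b, loci)

    # enumerate F1s per system over parental gamete combinations
    def combos(locus: str) -> list[tuple[str, str]]:
        ga, gb = _gametes(parent_a, locus), _gametes(parent_b, locus)
        return [(x, y) for x in ga for y in gb]

    verdict_sets: dict[str, list[SystemVerdict]] = {s: [] for s in SYSTEMS}
    missing: list[str] = []

    sam_c, saf_c = combos("SaM"), combos("SaF")
    if sam_c and saf_c:
        for sam in sam_c:
            for saf in saf_c:
                verdict_sets["Sa"].append(
                    evaluate_sa(sam, saf, effect=sa_effect, x_mode=x_mode))
    else:
        missing.append("Sa")
    s5_c = combos("s5")
    if s5_c:
        for g in s5_c:
            verdict_sets["s5"].append(evaluate_s5(g, reduction=s5_reduction))
    else:
        missing.append("s5")
    d1_c, d2_c = combos("DPL1"), combos("DPL2")
    if d1_c and d2_c:
        for d1 in d1_c:
            for d2 in d2_c:
                verdict_sets["DPL"].append(evaluate_dpl(d1, d2))
    else:
        missing.append("DPL")

    summary: list[SystemVerdict] = []
    combined: Optional[float] = 1.0
    any_known = False
    for system in SYSTEMS:
        vs = verdict_sets[system]
        if not vs:
            continue
        fracs = [v.viable_fraction for v in vs]
        if any(f is None for f in fracs):
            summary.append(SystemVerdict(system, UNKNOWN, None,
                                         vs[0].mechanism, vs[0].rationale))
            combined = None
            continue
        mean = sum(fracs) / len(fracs)
        verdict = COMPATIBLE if mean >= 1.0 else SEMI_STERILE
        summary.append(SystemVerdict(system, verdict, mean, vs[0].mechanism,
                                     vs[0].rationale))
        if combined is not None:
            combined *= mean
            any_known = True
    if not any_known and combined is not None:
        combined = None if not summary else combined

    return CrossPrediction(
        parent_a=name_a, parent_b=name_b,
        f1={k: v for k, v in f1_repr.items() if v is not None},
        verdicts=tuple(summary),
        combined_fertility=combined,
        unevaluated=tuple(missing),
    )


# ---------------------------------------------------------------------------
# Population-level barrier matrix
# ---------------------------------------------------------------------------

def _record_genotype(record) -> dict[str, tuple[str, ...]]:
    """Per-locus allele tuples of a GenotypeRecord, non-missing only."""
    out = {}
    for locus in ALLELE_ENUM:
        alleles = record.typed_alleles(locus)
        if alleles:
            out[locus] = alleles
    return out


@dataclass(frozen=True)
class BarrierCell:
    group_a: str
    group_b: str
    mean_fertility: Optional[float]
    n_crosses: int
    n_skipped_systems: int


def population_barrier_matrix(panel, groups: Optional[Sequence[str]] = None,
                              **kwargs) -> dict[tuple[str, str], BarrierCell]:
    """Expected compatibility for every ordered group pair.

    Each cell is the mean combined predicted fertility over all individual x
    individual crosses between the two groups (an individual may be crossed
    with itself across identical groups).  Crosses where no system could be
    evaluated contribute nothing; per-cross skipped systems are counted.
    Empty groups yield undefined (None) cells.
    """
    from .panel import GROUPS

    if groups is None:
        groups = [g for g in GROUPS if any(r.group == g for r in panel)]
    by_group = {g: [r for r in panel if r.group == g] for g in groups}
    out: dict[tuple[str, str], BarrierCell] = {}
    genotypes = {r.accession: _record_genotype(r) for r in panel}
    for ga in groups:
        for gb in groups:
            recs_a, recs_b = by_group[ga], by_group[gb]
            if not recs_a or not recs_b:
                out[(ga, gb)] = BarrierCell(ga, gb, None, 0, 0)
                continue
            ferts = []
            skipped = 0
            for ra in recs_a:
                for rb in recs_b:
                    pred = predict_cross(genotypes[ra.accession],
                                         genotypes[rb.accession],
                                         ra.accession, rb.accession, **kwargs)
                    skipped += len(pred.unevaluated)
                    if pred.combined_fertility is not None:
                        ferts.append(pred.combined_fertility)
            mean = sum(ferts) / len(ferts) if ferts else None
            out[(ga, gb)] = BarrierCell(ga, gb, mean,
                                        len(recs_a) * len(recs_b), skipped)
    return out


# ---------------------------------------------------------------------------
# Genotype-string parsing (CLI surface)
# ---------------------------------------------------------------------------

def parse_genotype_string(text: str) -> dict[str, tuple[str, ...]]:
    """Parse the haploid slash notation, e.g.
    ``"SaM+X/SaFX;s5-n;DPL1-N+;DPL2-K+"``.

    Fields are ';'-separated; within a field, '/' separates alleles (each
    assigned to its locus by label), so two alleles of the same locus denote
    a heterozygote.
    """
    out: dict[str, list[str]] = {}
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        for allele in chunk.split("/"):
            allele = allele.strip()
            locus = next((l for l, en in ALLELE_ENUM.items() if allele in en),
                         None)
            if locus is None:
                raise GenotypeError(f"unrecognised allele label {allele!r}")
            out.setdefault(locus, []).append(allele)
    for locus, alleles in out.items():
        if len(alleles) > 2:
            raise GenotypeError(f"more than two {locus} alleles supplied")
    return {l: tuple(a) for l, a in out.items()}
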