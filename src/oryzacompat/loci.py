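"""Definitions and classification of the five rice hybrid-incompatibility loci.

Three hybrid sterility systems operate between the *indica* and *japonica*
subspecies of Asian rice (*Oryza sativa*): the embryo-sac system at *s5*
(chromosome 6), the duplicate pollen-lethality system at *DPL1*/*DPL2*
(chromosomes 1 and 6), and the two-gene pollen-killer system at the *Sa*
locus (*SaM* + *SaF*, chromosome 1).  Each locus carries a small number of
diagnostic polymorphisms that separate indica-like from japonica-like
functional allele types, plus — at *s5* and *Sa* — loss-of-function deletions
that behave as wide-compatibility (null) alleles:

* ``s5``   — two CDS SNPs (symbols C282A, C877T) separate *s5-i* from *s5-j*;
  a 136-bp deletion in the N-terminus produces the non-functional
  wide-compatibility allele *s5-n*.
* ``DPL1`` — a 517-bp insertion 204 bp downstream of the start codon knocks
  the gene out (*K-*); alleles without it are functional (*N+*).
* ``DPL2`` — the CDS SNP A434G distinguishes the functional indica allele
  (*K+*, A) from the non-functional japonica allele (*N-*, G).
* ``SaM``  — a G-to-T polymorphism in the fifth intron separates *SaM+*
  (indica) from the truncated *SaM-* (japonica).
* ``SaF``  — a C-to-T transition at CDS position 287 separates *SaF+*
  (indica) from *SaF-* (japonica); the 8,628-bp *SaFX* deletion removes the
  entire gene (and the first four exons of *SaM*), so *SaM* alleles on a
  *SaFX* background are re-labelled *SaM+X* / *SaM-X*.

Published diagnostic symbols are coding-sequence positions; operationally
every diagnostic is addressed by a 1-based alignment column within the
package's amplicon frame, with the CDS symbol retained as an annotation.
All spans are 1-based, end-exclusive.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from ._util import DNA, GAP, MISSING, as_pairs, check_aligned

LOCUS_NAMES = ("s5", "DPL1", "DPL2", "SaM", "SaF")

ALLELE_ENUM: dict[str, tuple[str, ...]] = {
    "s5": ("s5-i", "s5-j", "s5-n"),
    "DPL1": ("DPL1-N+", "DPL1-K-"),
    "DPL2": ("DPL2-K+", "DPL2-N-"),
    "SaM": ("SaM+", "SaM-", "SaM+X", "SaM-X"),
    "SaF": ("SaF+", "SaF-", "SaFX"),
}


class LocusConfigError(ValueError):
    """Raised for invalid locus configuration input."""


class AssayConflictError(ValueError):
    """Raised when complementary presence/absence assays both succeed."""


@dataclass(frozen=True)
class DiagnosticPolymorphism:
    """One diagnostic site (SNP or indel) at a locus.

    ``column`` is the 1-based alignment column of a SNP; for an indel the
    diagnostic occupies ``span`` (1-based, end-exclusive columns) and its
    states are ``"present"``/``"absent"``.  ``state_labels`` maps each
    observable state to its contribution to the allele type (e.g. ``"i"`` or
    ``"j"`` for the two s5 SNPs, or a full label for single-site loci).
    ``cds_symbol`` keeps the published coding-sequence symbol (C282A, A434G,
    ...) as an annotation; it plays no computational role.
    """

    name: str
    kind: str  # "SNP" | "indel"
    column: Optional[int] = None
    span: Optional[tuple[int, int]] = None
    ref_state: str = ""
    alt_state: str = ""
    state_labels: Mapping[str, str] = field(default_factory=dict)
    cds_symbol: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("SNP", "indel"):
            raise LocusConfigError(f"unknown diagnostic kind {self.kind!r}")
        if self.kind == "SNP":
            if self.column is None or self.column < 1:
                raise LocusConfigError(f"SNP {self.name}: position must be >= 1")
            if self.ref_state == self.alt_state:
                raise LocusConfigError(f"SNP {self.name}: ref == alt state")
        else:
            if self.span is None or self.span[1] <= self.span[0]:
                raise LocusConfigError(f"indel {self.name}: invalid span")


@dataclass(frozen=True)
class DeletionSignature:
    """A deletion allele definition.

    ``detection_mode`` is either ``"sequence-gap"`` (the deletion appears as a
    gap run inside the amplicon alignment, as for s5-n) or
    ``"complementary-primer-amplification"`` (the deletion removes the whole
    amplicon and is typed by a presence/absence primer pair, as for SaFX).
    ``replace_label`` sets the allele type outright when the deletion is
    present; ``overlay_map`` instead rewrites a SNP-derived base type (the
    SaM+ -> SaM+X convention).  ``breakpoints`` are 1-based end-exclusive
    genomic coordinates when known.
    """

    name: str
    length: int
    detection_mode: str
    span: Optional[tuple[int, int]] = None  # alignment columns for sequence-gap
    breakpoints: Optional[tuple[int, int]] = None
    collateral: str = ""
    replace_label: Optional[str] = None
    overlay_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.breakpoints is not None:
            start, end = self.breakpoints
            if end - start != self.length:
                raise LocusConfigError(
                    f"deletion {self.name}: breakpoints span {end - start} bp "
                    f"but declared length is {self.length}"
                )
        if self.span is not None and self.span[1] - self.span[0] != self.length:
            raise LocusConfigError(
                f"deletion {self.name}: alignment span does not match length"
            )


@dataclass(frozen=True)
class LocusDefinition:
    name: str
    chromosome: str
    amplicon_length: int
    amplicon_anchor: str
    diagnostics: tuple[DiagnosticPolymorphism, ...]
    deletion_defs: tuple[DeletionSignature, ...]
    # maps tuple of diagnostic states (in `diagnostics` order) -> allele type
    allele_type_map: Mapping[tuple[str, ...], str]

    def __post_init__(self) -> None:
        if self.name not in LOCUS_NAMES:
            raise LocusConfigError(f"unknown locus name {self.name!r}")
        if not self.diagnostics and not self.deletion_defs:
            raise LocusConfigError(f"locus {self.name}: no diagnostics defined")
        cols = [d.column for d in self.diagnostics if d.column is not None]
        if len(cols) != len(set(cols)):
            raise LocusConfigError(
                f"locus {self.name}: overlapping diagnostics at the same position"
            )
        for d in self.diagnostics:
            if d.column is not None and not (1 <= d.column <= self.amplicon_length):
                raise LocusConfigError(
                    f"locus {self.name}: diagnostic {d.name} at column {d.column} "
                    f"outside amplicon of length {self.amplicon_length}"
                )

    @property
    def allele_types(self) -> tuple[str, ...]:
        return ALLELE_ENUM[self.name]


@dataclass(frozen=True)
class AlleleCall:
    """A typed allele for one accession at one locus.

    ``evidence`` records the observed diagnostic-state vector and deletion
    flags; ``missing`` marks amplification failure / undecidable evidence and
    excludes the call from frequency denominators; ``conflict`` flags
    contradictory evidence (e.g. the two s5 SNPs disagreeing, or a gap with a
    positive amplification), which is surfaced rather than silently resolved.
    """

    locus: str
    allele_type: Optional[str]
    evidence: Mapping[str, str] = field(default_factory=dict)
    haplotype_id: Optional[int] = None
    missing: bool = False
    conflict: bool = False

    def __post_init__(self) -> None:
        if self.allele_type is not None and self.allele_type not in ALLELE_ENUM[self.locus]:
            raise ValueError(
                f"allele type {self.allele_type!r} not valid for locus {self.locus}"
            )


@dataclass(frozen=True)
class ObservedStates:
    """Raw observations for one allele: SNP/indel states plus deletion flags.

    ``states`` maps diagnostic name -> observed state ('A', 'C', ..., 'N' for
    unreadable, '-' for gap; 'present'/'absent' for indel diagnostics).
    ``deletions`` maps deletion-signature name -> True/False/None (unknown).
    ``amplified`` is False when the whole amplicon failed to amplify.
    """

    states: Mapping[str, str] = field(default_factory=dict)
    deletions: Mapping[str, Optional[bool]] = field(default_factory=dict)
    amplified: bool = True


# ---------------------------------------------------------------------------
# Built-in locus definitions
# ---------------------------------------------------------------------------

_SAFX = dict(
    name="SaFX",
    length=8628,
    detection_mode="complementary-primer-amplification",
    breakpoints=(22_371_187, 22_379_815),
    collateral="entire SaF, partial Os01g39660, first four exons (1,240 bp) of SaM",
)


def _builtin_definitions() -> dict[str, LocusDefinition]:
    s5 = LocusDefinition(
        name="s5",
        chromosome="6",
        amplicon_length=1897,
        amplicon_anchor="949 bp downstream of the start codon (exon 2) to 1016 bp past the stop codon",
        diagnostics=(
            DiagnosticPolymorphism(
                name="s5_snp282", kind="SNP", column=282, ref_state="C",
                alt_state="A", state_labels={"C": "j", "A": "i"},
                cds_symbol="C282A",
            ),
            DiagnosticPolymorphism(
                name="s5_snp877", kind="SNP", column=877, ref_state="C",
                alt_state="T", state_labels={"C": "j", "T": "i"},
                cds_symbol="C877T",
            ),
        ),
        deletion_defs=(
            DeletionSignature(
                name="s5n_del", length=136, detection_mode="sequence-gap",
                span=(1201, 1337), collateral="N-terminal coding sequence",
                replace_label="s5-n",
            ),
        ),
        allele_type_map={("A", "T"): "s5-i", ("C", "C"): "s5-j"},
    )
    dpl1 = LocusDefinition(
        name="DPL1",
        chromosome="1",
        amplicon_length=900,
        amplicon_anchor="start codon through downstream flank; insertion 204 bp into CDS",
        diagnostics=(
            DiagnosticPolymorphism(
                name="dpl1_ins517", kind="indel", span=(205, 722),
                ref_state="absent", alt_state="present",
                state_labels={"absent": "DPL1-N+", "present": "DPL1-K-"},
                cds_symbol="+517bp@204",
            ),
        ),
        deletion_defs=(),
        allele_type_map={("absent",): "DPL1-N+", ("present",): "DPL1-K-"},
    )
    dpl2 = LocusDefinition(
        name="DPL2",
        chromosome="6",
        amplicon_length=499,
        amplicon_anchor="16 bp into exon 1 through 19 bp into exon 2",
        diagnostics=(
            DiagnosticPolymorphism(
                name="dpl2_snp434", kind="SNP", column=434, ref_state="A",
                alt_state="G", state_labels={"A": "DPL2-K+", "G": "DPL2-N-"},
                cds_symbol="A434G",
            ),
        ),
        deletion_defs=(),
        allele_type_map={("A",): "DPL2-K+", ("G",): "DPL2-N-"},
    )
    sam = LocusDefinition(
        name="SaM",
        chromosome="1",
        amplicon_length=634,
        amplicon_anchor="4 bp into exon 4 through 44 bp downstream of exon 5",
        diagnostics=(
            DiagnosticPolymorphism(
                name="sam_intron5_gt", kind="SNP", column=410, ref_state="G",
                alt_state="T", state_labels={"G": "SaM+", "T": "SaM-"},
                cds_symbol="intron5 G>T",
            ),
        ),
        deletion_defs=(
            DeletionSignature(
                overlay_map={"SaM+": "SaM+X", "SaM-": "SaM-X"}, **_SAFX
            ),
        ),
        allele_type_map={("G",): "SaM+", ("T",): "SaM-"},
    )
    saf = LocusDefinition(
        name="SaF",
        chromosome="1",
        amplicon_length=1300,
        amplicon_anchor="674 bp into exon 1 through 357 bp into exon 3",
        diagnostics=(
            DiagnosticPolymorphism(
                name="saf_snp287", kind="SNP", column=287, ref_state="C",
                alt_state="T", state_labels={"C": "SaF+", "T": "SaF-"},
                cds_symbol="C287T",
            ),
        ),
        deletion_defs=(
            DeletionSignature(replace_label="SaFX", **_SAFX),
        ),
        allele_type_map={("C",): "SaF+", ("T",): "SaF-"},
    )
    return {d.name: d for d in (s5, dpl1, dpl2, sam, saf)}


def load_locus_definitions(config=None) -> list[LocusDefinition]:
    """Return the five built-in locus definitions, optionally overridden.

    ``config`` may be None (defaults), a path to a JSON file, or a parsed
    mapping ``{locus_name: {overrides}}``; recognised override keys are
    ``amplicon_length`` and per-diagnostic ``column`` (keyed by diagnostic
    name).  Unknown locus names are rejected by name.
    """
    defs = _builtin_definitions()
    if config is None:
        return [defs[n] for n in LOCUS_NAMES]
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = json.load(fh)
    if not isinstance(config, Mapping):
        raise LocusConfigError("locus config must be a mapping of locus blocks")
    for name, block in config.items():
        if name not in defs:
            raise LocusConfigError(f"unknown locus {name!r} in config")
        base = defs[name]
        length = block.get("amplicon_length", base.amplicon_length)
        columns = block.get("columns", {})
        new_diags = []
        for d in base.diagnostics:
            if d.name in columns:
                d = DiagnosticPolymorphism(
                    name=d.name, kind=d.kind, column=int(columns[d.name]),
                    span=d.span, ref_state=d.ref_state, alt_state=d.alt_state,
                    state_labels=d.state_labels, cds_symbol=d.cds_symbol,
                )
            new_diags.append(d)
        defs[name] = LocusDefinition(
            name=base.name, chromosome=base.chromosome, amplicon_length=length,
            amplicon_anchor=base.amplicon_anchor, diagnostics=tuple(new_diags),
            deletion_defs=base.deletion_defs, allele_type_map=base.allele_type_map,
        )
    return [defs[n] for n in LOCUS_NAMES]


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

_VALID_SNP_STATES = DNA | {GAP, MISSING}


def classify_allele(locus_def: LocusDefinition, observed: ObservedStates) -> AlleleCall:
    """Map observed diagnostic states and deletion flags to an allele type.

    Deterministic, pure.  Deletion signatures take precedence over SNP-defined
    types (s5-n over s5-i/j; the SaFX overlay turns SaM+/- into SaM+X/-X).
    An 'N' at a required diagnostic yields a missing call unless a deletion
    signature already decides the type; contradictory evidence (both states of
    a complementary assay, or disagreeing s5 SNPs) is flagged as a conflict.
    """
    evidence = {**{k: str(v) for k, v in observed.states.items()},
                **{k: str(v) for k, v in observed.deletions.items()}}

    if not observed.amplified and not any(observed.deletions.values()):
        return AlleleCall(locus_def.name, None, evidence, missing=True)

    # Deletion precedence: replacement first.
    for sig in locus_def.deletion_defs:
        present = observed.deletions.get(sig.name)
        if present and sig.replace_label is not None:
            if sig.detection_mode == "sequence-gap" and observed.amplified is False:
                pass  # gap deletions live inside an amplified amplicon
            return AlleleCall(locus_def.name, sig.replace_label, evidence)

    # SNP/indel state vector.
    states = []
    for diag in locus_def.diagnostics:
        state = str(observed.states.get(diag.name, MISSING)).upper()
        if diag.kind == "SNP":
            if state not in _VALID_SNP_STATES:
                raise ValueError(
                    f"invalid state {state!r} at diagnostic {diag.name}"
                )
        elif state not in ("PRESENT", "ABSENT", MISSING):
            raise ValueError(f"invalid state {state!r} at diagnostic {diag.name}")
        states.append(state.lower() if diag.kind == "indel" else state)

    key = tuple(states)
    base_type = locus_def.allele_type_map.get(key)
    if base_type is None:
        known = [s for s in states if s not in (MISSING, GAP)]
        if len(known) < len(states):
            # partially missing: decisive only if every completion agrees
            candidates = {
                label for sv, label in locus_def.allele_type_map.items()
                if all(o in (MISSING, GAP) or o == e for o, e in zip(states, sv))
            }
            if len(candidates) == 1:
                base_type = candidates.pop()
            else:
                return AlleleCall(locus_def.name, None, evidence, missing=True)
        else:
            # fully observed but off-map: disagreeing diagnostics (recombinant)
            return AlleleCall(locus_def.name, None, evidence,
                              missing=True, conflict=True)

    # Deletion overlay (SaM +X/-X re-assignment).
    for sig in locus_def.deletion_defs:
        if observed.deletions.get(sig.name) and sig.overlay_map:
            overlaid = sig.overlay_map.get(base_type)
            if overlaid is None:
                return AlleleCall(locus_def.name, None, evidence,
                                  missing=True, conflict=True)
            return AlleleCall(locus_def.name, overlaid, evidence)

    return AlleleCall(locus_def.name, base_type, evidence)


def states_from_sequence(locus_def: LocusDefinition, seq: str) -> ObservedStates:
    """Extract diagnostic states and sequence-gap deletion flags from one
    aligned sequence in the locus's amplicon frame."""
    seq = seq.upper()
    if len(seq) != locus_def.amplicon_length:
        raise ValueError(
            f"sequence length {len(seq)} != amplicon length "
            f"{locus_def.amplicon_length} for locus {locus_def.name}"
        )
    states: dict[str, str] = {}
    for diag in locus_def.diagnostics:
        if diag.kind == "SNP":
            states[diag.name] = seq[diag.column - 1]
        else:
            start, end = diag.span
            chunk = seq[start - 1:end - 1]
            if all(c == GAP for c in chunk):
                states[diag.name] = "absent"
            elif GAP not in chunk:
                states[diag.name] = "present"
            else:
                states[diag.name] = MISSING
    deletions: dict[str, Optional[bool]] = {}
    for sig in locus_def.deletion_defs:
        if sig.detection_mode == "sequence-gap" and sig.span is not None:
            start, end = sig.span
            chunk = seq[start - 1:end - 1]
            deletions[sig.name] = all(c == GAP for c in chunk)
        else:
            deletions[sig.name] = None
    return ObservedStates(states=states, deletions=deletions)


def classify_sequence(locus_def: LocusDefinition, seq: str,
                      deletions: Optional[Mapping[str, Optional[bool]]] = None
                      ) -> AlleleCall:
    """Convenience wrapper: extract states from an aligned sequence and
    classify, with optional externally assayed deletion flags merged in."""
    obs = states_from_sequence(locus_def, seq)
    if deletions:
        merged = dict(obs.deletions)
        merged.update(deletions)
        obs = ObservedStates(states=obs.states, deletions=merged)
    return classify_allele(locus_def, obs)


# ---------------------------------------------------------------------------
# SaFX complementary-primer assay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SafxResult:
    status: str  # "present" | "absent" | "missing"
    span: Optional[int] = None


def detect_safx(saf_outcome: Optional[str] = None,
                safdel_outcome: Optional[str] = None,
                breakpoints: Optional[tuple[int, int]] = None) -> SafxResult:
    """Call the SaFX deletion from the complementary primer assay.

    The SaF primer set amplifies only when the deletion is absent; the SaFdel
    set only when it is present.  Outcomes are ``"success"``/``"fail"``/None.
    Both succeeding is contradictory and raises; both failing (the
    occasionally observed unexplained failure mode) yields a missing call.  When genomic breakpoints are
    supplied (1-based, end-exclusive), the deletion span is end - start.
    """
    if saf_outcome is None and safdel_outcome is None and breakpoints is None:
        raise ValueError("no evidence supplied to detect_safx")
    span = None
    if breakpoints is not None:
        start, end = breakpoints
        if end <= start:
            raise ValueError("breakpoints must satisfy end > start")
        span = end - start
    if saf_outcome == "success" and safdel_outcome == "success":
        raise AssayConflictError(
            "both SaF and SaFdel primer sets amplified; complementary assay conflict"
        )
    if saf_outcome == "success":
        return SafxResult("absent", span)
    if safdel_outcome == "success":
        return SafxResult("present", span)
    if saf_outcome == "fail" and safdel_outcome == "fail":
        return SafxResult("missing", span)
    if breakpoints is not None and saf_outcome is None and safdel_outcome is None:
        return SafxResult("present", span)
    return SafxResult("missing", span)


# ---------------------------------------------------------------------------
# Haplotype enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Haplotype:
    haplotype_id: int
    sequence: str
    members: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.members)


def enumerate_haplotypes(alignment, reference_id: Optional[str] = None
                         ) -> list[Haplotype]:
    """Collapse identical aligned sequences (indels included as characters)
    into numbered haplotypes.

    The reference sequence (the Nipponbare convention) receives haplotype id
    1; the remaining haplotypes are numbered by descending count, ties broken
    by first appearance in input order.  Counts partition the input: they sum
    to the number of sequences.
    """
    pairs = as_pairs(alignment)
    check_aligned(pairs)
    groups: dict[str, list[str]] = {}
    order: dict[str, int] = {}
    for idx, (name, seq) in enumerate(pairs):
        groups.setdefault(seq, []).append(name)
        order.setdefault(seq, idx)

    ref_seq = None
    if reference_id is not None:
        for name, seq in pairs:
            if name == reference_id:
                ref_seq = seq
                break
        if ref_seq is None:
            raise ValueError(f"reference {reference_id!r} not in alignment")

    ranked = sorted(
        (seq for seq in groups if seq != ref_seq),
        key=lambda s: (-len(groups[s]), order[s]),
    )
    haplotypes = []
    next_id = 1
    if ref_seq is not None:
        haplotypes.append(Haplotype(1, ref_seq, tuple(groups[ref_seq])))
        next_id = 2
    for seq in ranked:
        haplotypes.append(Haplotype(next_id, seq, tuple(groups[seq])))
        next_id += 1
    return haplotypes
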