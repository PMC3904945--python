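"""Synthetic aligned haplotype panels, genotype tables and pollen datasets.

The generator emulates the structure of a diagnostic-locus resequencing
study: per-population panels of aligned amplicon haplotypes whose diagnostic
columns encode a known allele type (including the 136-bp s5 deletion, the
517-bp DPL1 insertion and the whole-amplicon SaFX absence with its
complementary-primer signature), neutral SNP variation added only at
non-diagnostic columns so truth labels can never be corrupted, optional
haplotype-count targets, whole-locus amplification failures as the missing
data mechanism, and noisy triplicate pollen measurements.  Every record
carries ground truth, and all output is byte-deterministic under the spec
seed.

The generator targets marginal summaries (allele-type counts, segregating
sites, haplotype counts) — not coalescent realism: there is no recombination,
no mutation-rate heterogeneity and no genealogical correlation structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from ._util import DNA, GAP
from .loci import (ALLELE_ENUM, LocusDefinition, load_locus_definitions)
from .panel import GROUPS, GenotypeRecord
from .phenotype import PollenSample

_BASES = np.array(list("ACGT"))


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class LocusSim:
    """Simulation spec for one locus.

    ``counts`` maps group -> {allele_type: n alleles}.  ``target_s`` is the
    desired number of segregating sites (achieved within +-10%; diagnostic
    columns that happen to segregate count toward it).  ``n_haplotypes``
    optionally requests an exact number of distinct sequences.
    ``missing_rate`` is the per-allele probability of a whole-locus
    amplification failure.
    """

    counts: Mapping[str, Mapping[str, int]]
    target_s: int = 0
    n_haplotypes: Optional[int] = None
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for group, per_type in self.counts.items():
            if group not in GROUPS:
                raise SpecError(f"unknown group {group!r}")
            for t, n in per_type.items():
                if n < 0:
                    raise SpecError(f"negative count for {group}/{t}")
                if all(t not in enum for enum in ALLELE_ENUM.values()):
                    raise SpecError(f"unknown allele type {t!r}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise SpecError("missing_rate must be in [0, 1]")


@dataclass(frozen=True)
class PanelSpec:
    """Full simulation spec: per-locus specs plus the mandatory seed."""

    loci: Mapping[str, LocusSim]
    seed: int

    def __post_init__(self) -> None:
        for name in self.loci:
            if name not in ALLELE_ENUM:
                raise SpecError(f"unknown locus {name!r}")


@dataclass(frozen=True)
class AlleleTruth:
    sequence_id: str
    accession: str
    group: str
    locus: str
    allele_type: str
    missing: bool = False      # amplification failure
    safx: bool = False         # allele sits on the SaFX deletion background


@dataclass(frozen=True)
class SimulatedAlignment:
    locus: str
    records: tuple[tuple[str, str], ...]   # (sequence_id, aligned sequence)
    truth: tuple[AlleleTruth, ...]         # includes unaligned (missing/SaFX) alleles
    amplification: tuple[tuple[str, str, str, str], ...]
    # rows: (accession, locus, primer_set, outcome)


def _rng_for(spec_seed: int, locus: str, stream: int = 0) -> np.random.Generator:
    # stable locus hash (Python's str hash is salted per process)
    locus_key = int.from_bytes(locus.encode(), "big") % (2**31)
    return np.random.default_rng(
        np.random.SeedSequence([spec_seed, locus_key, stream]))


def _blocked_columns(locus_def: LocusDefinition) -> set[int]:
    """0-based columns reserved for diagnostics/indel spans."""
    blocked: set[int] = set()
    for d in locus_def.diagnostics:
        if d.column is not None:
            blocked.add(d.column - 1)
        if d.span is not None:
            blocked.update(range(d.span[0] - 1, d.span[1] - 1))
    for s in locus_def.deletion_defs:
        if s.span is not None:
            blocked.update(range(s.span[0] - 1, s.span[1] - 1))
    return blocked


def _template_for_type(locus_def: LocusDefinition, base: np.ndarray,
                       allele_type: str) -> Optional[np.ndarray]:
    """Aligned template carrying the diagnostic states of one allele type.

    Returns None when the type has no amplicon sequence at all (SaFX, and the
    X-suffixed SaM types are handled by the caller since their amplicon is
    still present).
    """
    if allele_type == "SaFX":
        return None
    seq = base.copy()
    # which SNP-state vector does this type (or its base type) require?
    target = allele_type
    for sig in locus_def.deletion_defs:
        inverse = {v: k for k, v in sig.overlay_map.items()}
        target = inverse.get(target, target)
        if sig.replace_label == allele_type and sig.span is not None:
            # sequence-gap deletion (s5-n): indica SNP background + gap run
            target = {"s5-n": "s5-i"}.get(allele_type, target)
    state_vec = None
    for sv, label in locus_def.allele_type_map.items():
        if label == target:
            state_vec = sv
            break
    if state_vec is None:
        raise SpecError(f"no diagnostic state vector yields {allele_type!r}")
    for diag, state in zip(locus_def.diagnostics, state_vec):
        if diag.kind == "SNP":
            seq[diag.column - 1] = state
        else:
            start, end = diag.span
            if state == "absent":
                seq[start - 1:end - 1] = GAP
    for sig in locus_def.deletion_defs:
        if sig.replace_label == allele_type and sig.span is not None:
            start, end = sig.span
            seq[start - 1:end - 1] = GAP
    return seq


def generate_alignment(spec: PanelSpec, locus: str,
                       locus_def: Optional[LocusDefinition] = None
                       ) -> SimulatedAlignment:
    """Generate one locus's aligned panel with full ground truth.

    Sequences for SaFX alleles (and amplification failures) are absent from
    the alignment and appear only in the truth and amplification tables,
    mirroring the real assay.  Neutral SNPs are placed only at non-diagnostic
    columns; haplotype-count targets are met by giving sub-cohorts private
    marker columns.
    """
    if locus not in spec.loci:
        raise SpecError(f"locus {locus!r} not in spec")
    sim = spec.loci[locus]
    if locus_def is None:
        locus_def = next(d for d in load_locus_definitions() if d.name == locus)
    length = locus_def.amplicon_length
    blocked = _blocked_columns(locus_def)
    free_cols = [c for c in range(length) if c not in blocked]

    rng = _rng_for(spec.seed, locus)
    base = _BASES[rng.integers(0, 4, size=length)]

    # --- allele cohort bookkeeping -------------------------------------
    entries: list[AlleleTruth] = []
    seqs: dict[str, Optional[np.ndarray]] = {}
    amplification: list[tuple[str, str, str, str]] = []
    for group in GROUPS:
        per_type = sim.counts.get(group, {})
        allele_idx = 0
        for allele_type in ALLELE_ENUM[locus]:
            n = per_type.get(allele_type, 0)
            if allele_type not in ALLELE_ENUM[locus]:
                raise SpecError(f"{allele_type!r} not an allele of {locus}")
            for _ in range(n):
                if group == "wild":
                    accession = f"{group}{allele_idx // 2:03d}"
                    sid = f"{accession}_{'ab'[allele_idx % 2]}"
                else:
                    accession = f"{group}{allele_idx:03d}"
                    sid = accession
                allele_idx += 1
                missing = bool(rng.random() < sim.missing_rate)
                safx = allele_type in ("SaFX", "SaM+X", "SaM-X")
                entries.append(AlleleTruth(sid, accession, group, locus,
                                           allele_type, missing=missing,
                                           safx=safx))

    for e in entries:
        if e.missing:
            amplification.append((e.accession, locus, f"{locus}_primers", "fail"))
            seqs[e.sequence_id] = None
            continue
        template = _template_for_type(locus_def, base, e.allele_type) \
            if e.allele_type != "SaFX" else None
        if e.allele_type == "SaFX":
            amplification.append((e.accession, "SaF", "SaF_primers", "fail"))
            amplification.append((e.accession, "SaF", "SaFdel_primers", "success"))
            seqs[e.sequence_id] = None
            continue
        if e.safx:  # SaM+X / SaM-X: amplicon present, deletion assay positive
            amplification.append((e.accession, "SaF", "SaF_primers", "fail"))
            amplification.append((e.accession, "SaF", "SaFdel_primers", "success"))
        seqs[e.sequence_id] = template.copy()

    aligned_ids = [e.sequence_id for e in entries if seqs[e.sequence_id] is not None]

    # --- haplotype grouping --------------------------------------------
    # Haplotype identity is controlled at group granularity: every sequence
    # belongs to a haplo-group (an allele-type cohort, possibly split to meet
    # a haplotype target); mutations are applied uniformly within a group, so
    # distinct groups stay distinct and group members stay identical.
    cohorts: dict[str, list[str]] = {}
    for e in entries:
        if seqs[e.sequence_id] is not None:
            cohorts.setdefault(e.allele_type, []).append(e.sequence_id)
    hgroups: list[list[str]] = [list(m) for m in cohorts.values()]
    if sim.n_haplotypes is not None and aligned_ids:
        extra = sim.n_haplotypes - len(hgroups)
        if extra < 0 or sim.n_haplotypes > len(aligned_ids):
            raise SpecError(
                f"cannot realise {sim.n_haplotypes} haplotypes with "
                f"{len(aligned_ids)} sequences in {len(hgroups)} "
                "allele-type cohorts"
            )
        carved: list[list[str]] = []
        while extra > 0:
            donor = max(hgroups, key=len)
            if len(donor) <= 1:
                raise SpecError("not enough sequences to realise haplotype target")
            carved.append([donor.pop()])
            extra -= 1
        if len(carved) > len(free_cols):
            raise SpecError("haplotype target exceeds available columns")
        # a private marker column makes each carved subgroup distinct
        for members in carved:
            col = free_cols.pop(rng.integers(0, len(free_cols)))
            ref = base[col]
            alt = rng.permutation([b for b in "ACGT" if b != ref])[0]
            for sid in members:
                seqs[sid][col] = alt
        hgroups.extend(carved)

    # --- neutral variation toward target S -----------------------------
    # diagnostic + marker columns that segregate already count toward S
    def current_s() -> int:
        mat = np.array([seqs[sid] for sid in aligned_ids])
        s = 0
        for col in range(length):
            states = set(mat[:, col])
            if GAP in states:
                continue
            if len(states & set("ACGT")) >= 2:
                s += 1
        return s

    if sim.target_s > 0 and len(aligned_ids) >= 2:
        have = current_s()
        need = sim.target_s - have
        if need > len(free_cols):
            raise SpecError(
                f"target S={sim.target_s} exceeds available free columns"
            )
        # mutate whole haplo-groups when a haplotype target must be preserved,
        # individual sequences otherwise
        units = hgroups if sim.n_haplotypes is not None \
            else [[sid] for sid in aligned_ids]
        for _ in range(max(0, need)):
            col = free_cols.pop(rng.integers(0, len(free_cols)))
            ref = base[col]
            alt = rng.permutation([b for b in "ACGT" if b != ref])[0]
            k = int(rng.integers(1, len(units))) if len(units) > 1 else 1
            chosen = rng.choice(len(units), size=k, replace=False)
            for idx in chosen:
                for sid in units[idx]:
                    if seqs[sid][col] != GAP:
                        seqs[sid][col] = alt
            # guarantee polymorphism even if choice hit gap-only carriers
            if all(seqs[sid][col] != alt for sid in aligned_ids) or \
                    all(seqs[sid][col] in (alt, GAP) for sid in aligned_ids):
                unit = units[int(rng.integers(0, len(units)))]
                for sid in unit:
                    if seqs[sid][col] != GAP:
                        seqs[sid][col] = base[col] if all(
                            seqs[s2][col] in (alt, GAP) for s2 in aligned_ids
                        ) else alt

    records = tuple((sid, "".join(seqs[sid])) for sid in aligned_ids)
    return SimulatedAlignment(locus=locus, records=records,
                              truth=tuple(entries),
                              amplification=tuple(amplification))


# ---------------------------------------------------------------------------
# Panels from printed marginal counts
# ---------------------------------------------------------------------------

def generate_panel_from_marginals(counts: Mapping[str, Mapping[str, Mapping[str, int]]],
                                  seed: int) -> list[GenotypeRecord]:
    """Build a GenotypeRecord panel realising exact allele-type counts.

    ``counts`` maps group -> locus -> {allele_type: n alleles}.  Haploid
    groups get one allele per individual per locus; the wild group's alleles
    are paired into diploid individuals.  Frequency tabling on the output
    reproduces the implied percentages exactly.
    """
    from .loci import AlleleCall

    rng = np.random.default_rng(seed)
    panel: list[GenotypeRecord] = []
    for group, per_locus in counts.items():
        if group not in GROUPS:
            raise SpecError(f"unknown group {group!r}")
        # allele lists per locus, shuffled deterministically
        allele_lists: dict[str, list[str]] = {}
        for locus, per_type in per_locus.items():
            if locus not in ALLELE_ENUM:
                raise SpecError(f"unknown locus {locus!r}")
            alleles: list[str] = []
            for t, n in per_type.items():
                if t not in ALLELE_ENUM[locus]:
                    raise SpecError(f"{t!r} is not a {locus} allele type")
                if n < 0:
                    raise SpecError(f"negative count for {group}/{locus}/{t}")
                alleles.extend([t] * n)
            rng.shuffle(alleles)
            allele_lists[locus] = alleles
        per_individual = 2 if group == "wild" else 1
        n_ind = max((-(-len(v) // per_individual) for v in allele_lists.values()),
                    default=0)
        records = [GenotypeRecord(f"{group}{i:03d}", group) for i in range(n_ind)]
        for locus, alleles in allele_lists.items():
            for j, allele in enumerate(alleles):
                rec = records[j // per_individual]
                call = AlleleCall(locus, allele)
                rec.calls[locus] = rec.calls.get(locus, ()) + (call,)
        panel.extend(records)
    return panel


# ---------------------------------------------------------------------------
# Pollen datasets
# ---------------------------------------------------------------------------

def generate_pollen_dataset(effects: Mapping[str, float], noise_sd: float,
                            n_per_genotype: int, seed: int,
                            field_total: int = 1000,
                            concentrations: Optional[Mapping[str, float]] = None
                            ) -> tuple[list[PollenSample], dict[str, float]]:
    """Simulate triplicate pollen measurements around true genotype means.

    ``effects`` maps genotype -> true mean percent nonviable pollen; each of
    ``n_per_genotype`` individuals gets three fields of view whose percent
    nonviable is drawn N(mean, noise_sd), truncated to [0, 100], and encoded
    as integer grain counts out of ``field_total`` grains per field (so with
    ``noise_sd=0`` means with <= 1 decimal place are recovered exactly).
    Optional ``concentrations`` adds triplicate hemacytometer counts the same
    way.  Returns the samples and the truth map.
    """
    for g, e in effects.items():
        if not 0.0 <= e <= 100.0:
            raise SpecError(f"effect for {g!r} outside [0, 100]")
    if noise_sd < 0:
        raise SpecError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    samples: list[PollenSample] = []
    for genotype in sorted(effects):
        mean = effects[genotype]
        for i in range(n_per_genotype):
            fields = []
            for _ in range(3):
                p = float(np.clip(rng.normal(mean, noise_sd) if noise_sd > 0
                                  else mean, 0.0, 100.0))
                nonviable = int(round(p * field_total / 100.0))
                fields.append((field_total - nonviable, nonviable))
            hema = None
            if concentrations and genotype in concentrations:
                cmean = concentrations[genotype]
                hema = tuple(
                    float(max(0.0, rng.normal(cmean, noise_sd)
                              if noise_sd > 0 else cmean))
                    for _ in range(3))
            samples.append(PollenSample(
                accession=f"{_slug(genotype)}_{i:02d}", genotype=genotype,
                field_counts=tuple(fields), hemacytometer_counts=hema))
    return samples, dict(effects)


def _slug(genotype: str) -> str:
    return (genotype.replace("/", "_").replace("+", "p")
            .replace("-", "m"))


# ---------------------------------------------------------------------------
# File emission (FASTA / TSV / truth JSON)
# ---------------------------------------------------------------------------

def write_simulation(spec: PanelSpec, out_dir) -> dict[str, str]:
    """Emit FASTA per locus, a metadata TSV, an amplification TSV and a truth
    JSON for a full panel spec.  Byte-deterministic under the spec seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    meta: dict[str, str] = {}
    truth_all: list[dict] = []
    amp_rows: list[tuple[str, str, str, str]] = []
    for locus in spec.loci:
        sim = generate_alignment(spec, locus)
        fasta = out / f"{locus}.aln.fasta"
        with open(fasta, "w") as fh:
            for sid, seq in sim.records:
                fh.write(f">{sid}\n{seq}\n")
        paths[f"alignment_{locus}"] = str(fasta)
        for e in sim.truth:
            meta.setdefault(e.accession, e.group)
            truth_all.append({
                "sequence_id": e.sequence_id, "accession": e.accession,
                "group": e.group, "locus": e.locus,
                "allele_type": e.allele_type, "missing": e.missing,
                "safx": e.safx,
            })
        amp_rows.extend(sim.amplification)
    meta_path = out / "metadata.tsv"
    with open(meta_path, "w") as fh:
        fh.write("accession\tgroup\n")
        for acc in sorted(meta):
            fh.write(f"{acc}\t{meta[acc]}\n")
    paths["metadata"] = str(meta_path)
    amp_path = out / "amplification.tsv"
    with open(amp_path, "w") as fh:
        fh.write("accession\tlocus\tprimer_set\toutcome\n")
        for row in sorted(set(amp_rows)):
            fh.write("\t".join(row) + "\n")
    paths["amplification"] = str(amp_path)
    truth_path = out / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump({"seed": spec.seed, "alleles": truth_all}, fh, indent=1,
                  sort_keys=True)
    paths["truth"] = str(truth_path)
    return paths
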