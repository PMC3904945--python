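"""Per-locus diversity statistics and haplotype-subtraction phasing.

Implements the classic frequency-spectrum summaries for a gapped multiple
sequence alignment — segregating sites S, average pairwise nucleotide
diversity pi (Nei & Li), Watterson's theta, and Tajima's D — together with
indel-event counting and Clark's haplotype-subtraction method for phasing
heterozygotes against haplotypes known from homozygotes.

Gap handling follows the DnaSP convention: alignment columns containing any
gap are excluded from S, from theta's site denominator and from the
complete-deletion forms of pi; pi defaults to pairwise deletion (each pair of
sequences compared over its own gap-free sites) and is switchable.  Tajima's
D uses the complete-deletion pi so that it is computed on the same set of
sites as S.  D is undefined (None) when fewer than four sequences are
available or when S = 0, and is rendered as "n/a" in tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

from ._util import DNA, GAP, as_pairs, check_aligned


class AlignmentError(ValueError):
    pass


def _columns(pairs: list[tuple[str, str]]) -> Iterable[tuple[str, ...]]:
    return zip(*(seq for _, seq in pairs))


def _gap_free_columns(pairs: list[tuple[str, str]]) -> list[tuple[str, ...]]:
    """Columns where every sequence has an unambiguous A/C/G/T base."""
    return [col for col in _columns(pairs) if all(c in DNA for c in col)]


def segregating_sites(alignment) -> int:
    """Number of polymorphic gap-free columns (S).

    A column counts as segregating when it carries >= 2 distinct states among
    {A, C, G, T}; any column containing a gap or ambiguous base is excluded.
    """
    pairs = as_pairs(alignment)
    if len(pairs) < 2:
        raise AlignmentError("segregating sites require >= 2 sequences")
    check_aligned(pairs)
    return sum(1 for col in _gap_free_columns(pairs) if len(set(col)) >= 2)


def _pairwise_diffs(a: str, b: str) -> tuple[int, int]:
    """(differences, comparable sites) over positions where both are A/C/G/T."""
    diffs = comp = 0
    for x, y in zip(a, b):
        if x in DNA and y in DNA:
            comp += 1
            if x != y:
                diffs += 1
    return diffs, comp


def nucleotide_diversity(alignment, gap_mode: str = "pairwise") -> Optional[float]:
    """Average pairwise nucleotide diversity per site (pi).

    ``gap_mode="pairwise"`` (default) compares each sequence pair over its own
    gap-free sites; ``"complete"`` restricts all pairs to columns gap-free in
    every sequence.  Returns None when no pair has comparable sites.
    """
    pairs = as_pairs(alignment)
    if len(pairs) < 2:
        raise AlignmentError("pi requires >= 2 sequences")
    check_aligned(pairs)
    if gap_mode == "complete":
        kept = _gap_free_columns(pairs)
        seqs = ["".join(col[i] for col in kept) for i in range(len(pairs))]
    elif gap_mode == "pairwise":
        seqs = [seq for _, seq in pairs]
    else:
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    per_pair = []
    for a, b in combinations(seqs, 2):
        diffs, comp = _pairwise_diffs(a, b)
        if comp > 0:
            per_pair.append(diffs / comp)
    if not per_pair:
        return None
    return sum(per_pair) / (len(pairs) * (len(pairs) - 1) / 2)


def harmonic_number(n: int) -> float:
    """a1 = sum_{i=1}^{n} 1/i."""
    return sum(1.0 / i for i in range(1, n + 1))


def watterson_theta(alignment) -> Optional[float]:
    """Watterson's estimator per site: theta_W = S / (a1 * L).

    a1 = sum_{i=1}^{n-1} 1/i and L is the gap-free alignment length.  Returns
    None when no gap-free sites exist.
    """
    pairs = as_pairs(alignment)
    if len(pairs) < 2:
        raise AlignmentError("theta_W requires >= 2 sequences")
    check_aligned(pairs)
    kept = _gap_free_columns(pairs)
    if not kept:
        return None
    s = sum(1 for col in kept if len(set(col)) >= 2)
    a1 = harmonic_number(len(pairs) - 1)
    return s / (a1 * len(kept))


def tajima_constants(n: int) -> dict[str, float]:
    """The constants of Tajima's variance normalisation for sample size n."""
    a1 = harmonic_number(n - 1)
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(alignment, min_n: int = 4) -> Optional[float]:
    """Tajima's D, or None when undefined.

    D = (pi_total - S/a1) / sqrt(e1*S + e2*S*(S-1)), where pi_total is the
    mean number of pairwise differences over gap-free columns.  Undefined
    (None, rendered "n/a") when n < ``min_n`` or S = 0.
    """
    pairs = as_pairs(alignment)
    check_aligned(pairs)
    n = len(pairs)
    if n < min_n:
        return None
    kept = _gap_free_columns(pairs)
    seqs = ["".join(col[i] for col in kept) for i in range(n)]
    s = sum(1 for col in kept if len(set(col)) >= 2)
    if s == 0:
        return None
    pi_total = sum(_pairwise_diffs(a, b)[0] for a, b in combinations(seqs, 2))
    pi_total /= n * (n - 1) / 2
    k = tajima_constants(n)
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    return (pi_total - s / k["a1"]) / math.sqrt(var)


def count_indels(alignment) -> int:
    """Number of distinct indel events in a gapped alignment.

    A contiguous gap run is identified by its (start, end) column span;
    identical spans shared across sequences count as one event, spans with
    different boundaries count separately.
    """
    pairs = as_pairs(alignment)
    check_aligned(pairs)
    events: set[tuple[int, int]] = set()
    for _, seq in pairs:
        start = None
        for i, c in enumerate(seq):
            if c == GAP and start is None:
                start = i
            elif c != GAP and start is not None:
                events.add((start, i))
                start = None
        if start is not None:
            events.add((start, len(seq)))
    return len(events)


@dataclass(frozen=True)
class DiversityStats:
    """Summary-statistic bundle for one group x locus alignment."""

    group: str
    locus: str
    n: int
    S: int
    pi: Optional[float]
    theta_w: Optional[float]
    tajima_d: Optional[float]
    n_haplotypes: int
    n_indels: int


def diversity_stats(alignment, group: str = "", locus: str = "",
                    gap_mode: str = "pairwise") -> DiversityStats:
    """Compute the full statistic bundle for one alignment."""
    from .loci import enumerate_haplotypes

    pairs = as_pairs(alignment)
    return DiversityStats(
        group=group, locus=locus, n=len(pairs),
        S=segregating_sites(pairs),
        pi=nucleotide_diversity(pairs, gap_mode=gap_mode),
        theta_w=watterson_theta(pairs),
        tajima_d=tajimas_d(pairs),
        n_haplotypes=len(enumerate_haplotypes(pairs)),
        n_indels=count_indels(pairs),
    )


# ---------------------------------------------------------------------------
# Clark haplotype-subtraction phasing
# ---------------------------------------------------------------------------

Genotype = tuple[tuple[str, ...], ...]  # per-site sorted state tuples


def genotype_from_haplotypes(h1: str, h2: str) -> Genotype:
    """Collapse two haplotypes into an unphased site-wise genotype."""
    if len(h1) != len(h2):
        raise ValueError("haplotype length mismatch")
    return tuple(tuple(sorted({a, b})) for a, b in zip(h1.upper(), h2.upper()))


def _is_homozygous(g: Genotype) -> bool:
    return all(len(site) == 1 for site in g)


def _haplotype_of_homozygote(g: Genotype) -> str:
    return "".join(site[0] for site in g)


def _compatible(hap: str, g: Genotype) -> bool:
    return all(h in site for h, site in zip(hap, g))


def _complement(hap: str, g: Genotype) -> str:
    out = []
    for h, site in zip(hap, g):
        if len(site) == 1:
            out.append(site[0])
        else:
            a, b = site
            out.append(b if h == a else a)
    return "".join(out)


@dataclass(frozen=True)
class PhasedPair:
    accession: str
    haplotype_a: str
    haplotype_b: str
    resolved_by: Optional[str]  # known-haplotype sequence used for subtraction


@dataclass(frozen=True)
class PhasingResult:
    phased: tuple[PhasedPair, ...]
    unresolved: tuple[str, ...]  # accessions left unphased
    known_haplotypes: tuple[str, ...]
    diagnostic: str = ""


def clark_phase(genotypes: Sequence[tuple[str, Genotype]],
                known_haplotypes: Iterable[str] = ()) -> PhasingResult:
    """Phase heterozygotes by iterative haplotype subtraction.

    Homozygotes are resolved first (each contributes one known haplotype);
    each heterozygote compatible with a known haplotype is split into that
    haplotype and its site-wise complement, which joins the known set.
    Iteration continues while new haplotypes appear; heterozygotes in input
    order (order-dependence is inherent to the method).  Records that no
    known haplotype can resolve are flagged unresolved, never guessed.
    """
    known: list[str] = list(dict.fromkeys(known_haplotypes))
    phased: list[PhasedPair] = []
    pending: list[tuple[str, Genotype]] = []
    for accession, g in genotypes:
        if _is_homozygous(g):
            hap = _haplotype_of_homozygote(g)
            phased.append(PhasedPair(accession, hap, hap, resolved_by=None))
            if hap not in known:
                known.append(hap)
        else:
            pending.append((accession, g))

    diagnostic = ""
    if pending and not known:
        diagnostic = "no homozygote seed available; all heterozygotes unresolved"

    progress = True
    while progress and pending:
        progress = False
        still: list[tuple[str, Genotype]] = []
        for accession, g in pending:
            hit = next((h for h in known if _compatible(h, g)), None)
            if hit is None:
                still.append((accession, g))
                continue
            comp = _complement(hit, g)
            phased.append(PhasedPair(accession, hit, comp, resolved_by=hit))
            if comp not in known:
                known.append(comp)
            progress = True
        pending = still

    return PhasingResult(
        phased=tuple(phased),
        unresolved=tuple(acc for acc, _ in pending),
        known_haplotypes=tuple(known),
        diagnostic=diagnostic,
    )
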