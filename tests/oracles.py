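"""Independent brute-force oracles used to cross-check the package.

These deliberately take different computational routes from the library:
diversity statistics are computed from per-column allele-count spectra
rather than sequence-pair loops, and Tajima's D is evaluated from its
published constant definitions with no shared code.
"""

from __future__ import annotations

import math
from itertools import combinations

DNA = set("ACGT")


def gap_free_columns(seqs: list[str]) -> list[str]:
    return ["".join(col) for col in zip(*seqs)
            if all(c in DNA for c in col)]


def oracle_S(seqs: list[str]) -> int:
    return sum(1 for col in gap_free_columns(seqs) if len(set(col)) > 1)


def oracle_pi_per_site(seqs: list[str]) -> float:
    """Mean pairwise diversity from column frequency spectra
    (complete-deletion; equals pairwise-deletion on gap-free input)."""
    cols = gap_free_columns(seqs)
    n = len(seqs)
    npairs = n * (n - 1) / 2
    total = 0.0
    for col in cols:
        same = sum(col.count(b) * (col.count(b) - 1) / 2 for b in set(col))
        total += 1.0 - same / npairs
    return total / len(cols) if cols else float("nan")


def oracle_theta_per_site(seqs: list[str]) -> float:
    cols = gap_free_columns(seqs)
    a1 = sum(1.0 / i for i in range(1, len(seqs)))
    return oracle_S(seqs) / (a1 * len(cols)) if cols else float("nan")


def oracle_tajimas_d(seqs: list[str]):
    n = len(seqs)
    if n < 4:
        return None
    s = oracle_S(seqs)
    if s == 0:
        return None
    cols = gap_free_columns(seqs)
    npairs = n * (n - 1) / 2
    pi_total = sum(
        1.0 - sum(col.count(b) * (col.count(b) - 1) / 2 for b in set(col)) / npairs
        for col in cols)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (pi_total - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def oracle_dpl_viable_fraction(dpl1: tuple[str, str], dpl2: tuple[str, str]) -> float:
    """Gamete-enumeration brute force for the duplicate-pollen-gene rule."""
    viable = total = 0
    for g1 in dpl1:
        for g2 in dpl2:
            total += 1
            if not (g1 == "DPL1-K-" and g2 == "DPL2-N-"):
                viable += 1
    return viable / total


def random_alignment(rng, n_max=8, length_max=50, gapped=False) -> list[str]:
    n = int(rng.integers(2, n_max + 1))
    length = int(rng.integers(2, length_max + 1))
    bases = "ACGT-" if gapped else "ACGT"
    probs = [0.225, 0.225, 0.225, 0.225, 0.1] if gapped else [0.25] * 4
    # low per-column diversity so alignments look sequence-like
    out = []
    anchor = [bases[int(rng.integers(0, 4))] for _ in range(length)]
    for _ in range(n):
        seq = []
        for j in range(length):
            if rng.random() < 0.7:
                seq.append(anchor[j])
            else:
                seq.append(rng.choice(list(bases), p=probs))
        out.append("".join(seq))
    return out
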