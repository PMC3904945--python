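import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from oryzacompat import LocusSim, PanelSpec, load_locus_definitions


@pytest.fixture(scope="session")
def locus_defs():
    return {d.name: d for d in load_locus_definitions()}


@pytest.fixture(scope="session")
def s5_def(locus_defs):
    return locus_defs["s5"]


def make_s5_sequence(locus_def, allele_type: str, base: str = "A") -> str:
    """Minimal aligned s5 amplicon carrying one allele type's diagnostics."""
    seq = [base] * locus_def.amplicon_length
    states = {"s5-i": ("A", "T"), "s5-j": ("C", "C"), "s5-n": ("A", "T")}[allele_type]
    seq[281], seq[876] = states
    if allele_type == "s5-n":
        for i in range(1200, 1336):
            seq[i] = "-"
    return "".join(seq)


@pytest.fixture(scope="session")
def table1_counts():
    """Allele counts reconstructed from the published frequency table's
    denominators and percentages (exact prose fractions where printed)."""
    return {
        "japonica": {"s5": {"s5-j": 5, "s5-i": 3}},
        "wild": {"s5": {"s5-i": 25, "s5-n": 4, "s5-j": 1},
                 "SaM": {"SaM+": 25, "SaM+X": 6, "SaM-": 7}},
    }


@pytest.fixture(scope="session")
def mixed_panel_spec():
    """A small multi-locus panel with coherent SaFX backgrounds."""
    counts = {
        "s5": {"indica": {"s5-i": 6}, "aus": {"s5-n": 3},
               "japonica": {"s5-j": 5, "s5-i": 3},
               "SH": {"s5-n": 12, "s5-i": 2},
               "wild": {"s5-i": 25, "s5-n": 4, "s5-j": 1}},
        "DPL1": {"indica": {"DPL1-K-": 4, "DPL1-N+": 2},
                 "japonica": {"DPL1-N+": 11, "DPL1-K-": 3},
                 "SH": {"DPL1-N+": 11},
                 "wild": {"DPL1-K-": 14, "DPL1-N+": 18}},
        "DPL2": {"indica": {"DPL2-K+": 4},
                 "japonica": {"DPL2-K+": 11, "DPL2-N-": 2},
                 "SH": {"DPL2-K+": 13}, "wild": {"DPL2-K+": 28}},
        "SaM": {"indica": {"SaM+": 8, "SaM-": 1},
                "japonica": {"SaM-": 9, "SaM+": 1},
                "SH": {"SaM+": 1, "SaM+X": 12, "SaM-X": 1},
                "wild": {"SaM+": 25, "SaM-": 7, "SaM+X": 6}},
        "SaF": {"indica": {"SaF+": 7, "SaF-": 2},
                "japonica": {"SaF-": 8},
                "SH": {"SaF-": 1, "SaFX": 13},
                "wild": {"SaF+": 17, "SaF-": 13, "SaFX": 6}},
    }
    return PanelSpec(
        loci={l: LocusSim(counts=c, target_s=10) for l, c in counts.items()},
        seed=20260920,
    )
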