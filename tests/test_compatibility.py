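"""Sterility rules, cross prediction and the population barrier matrix."""

from itertools import product

import pytest

from oryzacompat import (
    evaluate_dpl,
    evaluate_s5,
    evaluate_sa,
    f1_genotype,
    generate_panel_from_marginals,
    parse_genotype_string,
    population_barrier_matrix,
    predict_cross,
)
from oryzacompat.compatibility import COMPATIBLE, SEMI_STERILE, UNKNOWN, GenotypeError

from oracles import oracle_dpl_viable_fraction

SH_TYPICAL = {"s5": ("s5-n",), "DPL1": ("DPL1-N+",), "DPL2": ("DPL2-K+",),
              "SaM": ("SaM+X",), "SaF": ("SaFX",)}
US_JAPONICA = {"s5": ("s5-j",), "DPL1": ("DPL1-N+",), "DPL2": ("DPL2-K+",),
               "SaM": ("SaM-",), "SaF": ("SaF-",)}
INDICA_TYPICAL = {"s5": ("s5-i",), "DPL1": ("DPL1-K-",), "DPL2": ("DPL2-K+",),
                  "SaM": ("SaM+",), "SaF": ("SaF+",)}


class TestF1:
    def test_table2_cross_one(self):
        f1 = f1_genotype({"SaM": ("SaM+X",), "SaF": ("SaFX",)},
                         {"SaM": ("SaM-",), "SaF": ("SaF-",)})
        assert f1["SaM"] == ("SaM+X", "SaM-")
        assert f1["SaF"] == ("SaFX", "SaF-")

    def test_selfing_homozygote(self):
        f1 = f1_genotype({"s5": ("s5-i",)}, {"s5": ("s5-i",)})
        assert f1["s5"] == ("s5-i", "s5-i")

    def test_wide_compat_heterozygote(self):
        f1 = f1_genotype({"s5": ("s5-i",)}, {"s5": ("s5-n",)})
        assert set(f1["s5"]) == {"s5-i", "s5-n"}

    def test_missing_locus_marked_unpredictable(self):
        f1 = f1_genotype({"s5": ("s5-i",)}, {"SaM": ("SaM+",)})
        assert f1["s5"] is None and f1["SaM"] is None


class TestSaRule:
    def test_classic_heterozygote_with_saf_plus_is_semisterile(self):
        v = evaluate_sa(("SaM+", "SaM-"), ("SaF+", "SaF-"))
        assert v.verdict == SEMI_STERILE and v.viable_fraction == 0.5

    def test_safx_hybrid_is_compatible(self):
        v = evaluate_sa(("SaM+X", "SaM-"), ("SaF+", "SaFX"))
        assert v.verdict == COMPATIBLE and v.viable_fraction == 1.0

    def test_no_heterozygote_no_effect(self):
        v = evaluate_sa(("SaM-", "SaM-"), ("SaF-", "SaF-"))
        assert v.verdict == COMPATIBLE

    def test_heterozygote_without_saf_plus_is_compatible(self):
        v = evaluate_sa(("SaM+", "SaM-"), ("SaF-", "SaF-"))
        assert v.verdict == COMPATIBLE

    def test_unknown_mode_abstains_for_x_alleles(self):
        v = evaluate_sa(("SaM+X", "SaM-"), ("SaF+", "SaFX"), x_mode="unknown")
        assert v.verdict == UNKNOWN and v.viable_fraction is None

    def test_unknown_allele_rejected(self):
        with pytest.raises(GenotypeError):
            evaluate_sa(("SaM?", "SaM-"), ("SaF-", "SaF-"))


class TestS5Rule:
    def test_ij_heterodimer_reduces_fertility_46_percent(self):
        v = evaluate_s5(("s5-i", "s5-j"))
        assert v.verdict == SEMI_STERILE
        assert v.viable_fraction == pytest.approx(0.54)

    @pytest.mark.parametrize("genotype", [
        ("s5-n", "s5-j"), ("s5-n", "s5-i"), ("s5-i", "s5-i"), ("s5-n", "s5-n")])
    def test_everything_else_compatible(self, genotype):
        v = evaluate_s5(genotype)
        assert v.verdict == COMPATIBLE and v.viable_fraction == 1.0


class TestDPLRule:
    def test_double_heterozygote_loses_quarter_of_gametes(self):
        v = evaluate_dpl(("DPL1-K-", "DPL1-N+"), ("DPL2-K+", "DPL2-N-"))
        assert v.viable_fraction == 0.75

    def test_functional_dpl1_homozygote_fully_viable(self):
        v = evaluate_dpl(("DPL1-N+", "DPL1-N+"), ("DPL2-N-", "DPL2-N-"))
        assert v.viable_fraction == 1.0

    def test_double_null_homozygote_dead(self):
        v = evaluate_dpl(("DPL1-K-", "DPL1-K-"), ("DPL2-N-", "DPL2-N-"))
        assert v.viable_fraction == 0.0

    def test_equals_gamete_enumeration_for_all_nine_classes(self):
        """Exhaustive brute force over all 3x3 diploid two-locus classes."""
        d1_classes = [("DPL1-N+", "DPL1-N+"), ("DPL1-N+", "DPL1-K-"),
                      ("DPL1-K-", "DPL1-K-")]
        d2_classes = [("DPL2-K+", "DPL2-K+"), ("DPL2-K+", "DPL2-N-"),
                      ("DPL2-N-", "DPL2-N-")]
        for d1, d2 in product(d1_classes, d2_classes):
            assert evaluate_dpl(d1, d2).viable_fraction == \
                oracle_dpl_viable_fraction(d1, d2)


class TestPredictCross:
    def test_sh_weed_by_us_japonica_fully_compatible(self):
        pred = predict_cross(SH_TYPICAL, US_JAPONICA)
        assert pred.combined_fertility == 1.0
        assert all(v.verdict == COMPATIBLE for v in pred.verdicts)

    def test_indica_japonica_semisterile_at_sa_and_s5(self):
        pred = predict_cross(INDICA_TYPICAL, US_JAPONICA)
        by_system = {v.system: v for v in pred.verdicts}
        assert by_system["Sa"].verdict == SEMI_STERILE
        assert by_system["s5"].verdict == SEMI_STERILE
        assert pred.combined_fertility == pytest.approx(0.5 * 0.54)

    def test_self_cross_fully_compatible(self):
        for parent in (SH_TYPICAL, US_JAPONICA, INDICA_TYPICAL):
            assert predict_cross(parent, parent).combined_fertility == 1.0

    def test_symmetric_in_parents(self):
        a = predict_cross(INDICA_TYPICAL, US_JAPONICA)
        b = predict_cross(US_JAPONICA, INDICA_TYPICAL)
        assert a.combined_fertility == b.combined_fertility
        assert {(v.system, v.verdict) for v in a.verdicts} == \
            {(v.system, v.verdict) for v in b.verdicts}

    def test_replacing_alleles_by_nulls_never_decreases_fertility(self):
        nulls = {"s5-i": "s5-n", "s5-j": "s5-n", "SaF+": "SaFX", "SaF-": "SaFX",
                 "SaM+": "SaM+X", "SaM-": "SaM-X"}
        base = predict_cross(INDICA_TYPICAL, US_JAPONICA).combined_fertility
        for locus in ("s5", "SaF", "SaM"):
            for parent in (INDICA_TYPICAL, US_JAPONICA):
                modified = dict(parent)
                modified[locus] = tuple(nulls.get(a, a) for a in parent[locus])
                other = US_JAPONICA if parent is INDICA_TYPICAL else INDICA_TYPICAL
                f = predict_cross(modified, other).combined_fertility
                assert f >= base

    def test_heterozygous_parent_averages_over_gametes(self):
        het = {"s5": ("s5-i", "s5-n")}
        jap = {"s5": ("s5-j",)}
        pred = predict_cross(het, jap)
        # half the F1s are i/j (0.54), half n/j (1.0)
        s5 = next(v for v in pred.verdicts if v.system == "s5")
        assert s5.viable_fraction == pytest.approx(0.77)

    def test_untyped_system_reported_not_silent(self):
        pred = predict_cross({"s5": ("s5-i",)}, {"s5": ("s5-j",)})
        assert set(pred.unevaluated) == {"Sa", "DPL"}


class TestGenotypeStrings:
    def test_haploid_slash_notation_round_trip(self):
        g = parse_genotype_string("SaM+X/SaFX;s5-n;DPL1-N+;DPL2-K+")
        assert g == {"SaM": ("SaM+X",), "SaF": ("SaFX",), "s5": ("s5-n",),
                     "DPL1": ("DPL1-N+",), "DPL2": ("DPL2-K+",)}

    def test_heterozygote_notation(self):
        g = parse_genotype_string("SaM+/SaM-")
        assert g == {"SaM": ("SaM+", "SaM-")}

    def test_bad_label_rejected(self):
        with pytest.raises(GenotypeError):
            parse_genotype_string("SaM*/SaF-")


class TestBarrierMatrix:
    def test_wide_compatibility_group_crosses_freely(self):
        counts = {
            "SH": {"s5": {"s5-n": 4}, "SaM": {"SaM+X": 4}, "SaF": {"SaFX": 4},
                   "DPL1": {"DPL1-N+": 4}, "DPL2": {"DPL2-K+": 4}},
            "japonica": {"s5": {"s5-j": 4}, "SaM": {"SaM-": 4},
                         "SaF": {"SaF-": 4}, "DPL1": {"DPL1-N+": 4},
                         "DPL2": {"DPL2-K+": 4}},
        }
        panel = generate_panel_from_marginals(counts, seed=0)
        matrix = population_barrier_matrix(panel)
        assert matrix[("SH", "japonica")].mean_fertility == 1.0

    def test_identical_monomorphic_groups(self):
        counts = {
            "BHA1": {"s5": {"s5-i": 3}},
            "BHA2": {"s5": {"s5-i": 3}},
        }
        panel = generate_panel_from_marginals(counts, seed=0)
        matrix = population_barrier_matrix(panel)
        assert matrix[("BHA1", "BHA2")].mean_fertility == 1.0

    def test_sa_incompatible_groups_below_one(self):
        counts = {
            "BHA2": {"SaM": {"SaM+": 3}, "SaF": {"SaF+": 3}},
            "japonica": {"SaM": {"SaM-": 3}, "SaF": {"SaF-": 3}},
        }
        panel = generate_panel_from_marginals(counts, seed=0)
        matrix = population_barrier_matrix(panel)
        cell = matrix[("BHA2", "japonica")]
        assert cell.mean_fertility == pytest.approx(0.5)

    def test_empty_group_yields_undefined_cells(self):
        counts = {"SH": {"s5": {"s5-n": 2}}}
        panel = generate_panel_from_marginals(counts, seed=0)
        matrix = population_barrier_matrix(panel, groups=("SH", "MX"))
        assert matrix[("SH", "MX")].mean_fertility is None
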