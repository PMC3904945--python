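"""K2P distances, neighbor joining and bootstrap supports."""

import math
from itertools import combinations

import numpy as np
import pytest

from oryzacompat import (
    DistanceMatrix,
    SaturationError,
    bipartitions,
    bootstrap_supports,
    k2p_distance,
    k2p_matrix,
    nj_tree,
)


class TestK2P:
    def test_identical_sequences(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_transitions_only_closed_form(self):
        # 10 transitions in 100 sites: P=0.1, Q=0 -> -0.5 ln(0.8)
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        assert k2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.8))

    def test_saturation_raises(self):
        a = "A" * 10
        b = "G" * 6 + "C" * 4  # P=0.6, Q=0.4 -> 1-2P-Q < 0
        with pytest.raises(SaturationError):
            k2p_distance(a, b)

    def test_symmetry_and_gap_exclusion(self):
        a, b = "ACG-ACGT", "ACGTAC-A"
        assert k2p_distance(a, b) == k2p_distance(b, a)
        # only 6 shared non-gap sites, 1 transversion... recompute: site 7 T/A
        assert k2p_distance(a, b) > 0

    def test_monotone_in_transition_proportion(self):
        def d(k):
            return k2p_distance("A" * 100, "G" * k + "A" * (100 - k))
        vals = [d(k) for k in range(0, 30, 5)]
        assert all(x < y for x, y in zip(vals, vals[1:]))


def _additive_matrix_4taxa(split, lengths):
    """Distances on the quartet tree ((A,B),(C,D)) re-labelled by `split`."""
    (a, b), (c, d) = split
    la, lb, lc, ld, lm = lengths
    labels = sorted([a, b, c, d])
    dist = {
        frozenset((a, b)): la + lb,
        frozenset((c, d)): lc + ld,
        frozenset((a, c)): la + lm + lc,
        frozenset((a, d)): la + lm + ld,
        frozenset((b, c)): lb + lm + lc,
        frozenset((b, d)): lb + lm + ld,
    }
    m = np.zeros((4, 4))
    for i, j in combinations(range(4), 2):
        m[i, j] = m[j, i] = dist[frozenset((labels[i], labels[j]))]
    return DistanceMatrix(tuple(labels), m)


class TestNJ:
    def test_three_taxa_unique_topology(self):
        m = DistanceMatrix(("A", "B", "C"),
                           np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float))
        tree = nj_tree(m)
        assert tree.leaf_names() == {"A", "B", "C"}
        assert bipartitions(tree) == set()

    @pytest.mark.parametrize("split", [
        (("A", "B"), ("C", "D")),
        (("A", "C"), ("B", "D")),
        (("A", "D"), ("B", "C")),
    ])
    def test_all_four_taxon_splits_recovered(self, split):
        rng = np.random.default_rng(11)
        for _ in range(25):
            lengths = rng.uniform(0.05, 1.0, size=5)
            tree = nj_tree(_additive_matrix_4taxa(split, lengths))
            expected = frozenset(
                split[0] if "A" not in split[0] else split[1])
            assert bipartitions(tree) == {expected}

    @staticmethod
    def _tree_distances(tree):
        """Leaf-to-leaf path lengths of an unrooted tree."""
        # edge sets per leaf: root-to-leaf edge lists; distance = symmetric diff
        paths: dict[str, tuple] = {}

        def walk(node, acc):
            acc = acc + ((id(node), node.length),)
            if node.is_leaf:
                paths[node.name] = acc
                return
            for c in node.children:
                walk(c, acc)

        for c in tree.children:
            walk(c, ())
        out = {}
        for a, b in combinations(sorted(paths), 2):
            ea, eb = dict(paths[a]), dict(paths[b])
            shared = set(ea) & set(eb)
            out[(a, b)] = sum(v for k, v in ea.items() if k not in shared) + \
                sum(v for k, v in eb.items() if k not in shared)
        return out

    def test_additive_path_lengths_recovered(self):
        split = (("A", "B"), ("C", "D"))
        m = _additive_matrix_4taxa(split, (0.1, 0.2, 0.3, 0.4, 0.25))
        tree = nj_tree(m)
        dists = self._tree_distances(tree)
        idx = {l: i for i, l in enumerate(m.labels)}
        for (a, b), d in dists.items():
            assert d == pytest.approx(m.values[idx[a], idx[b]], abs=1e-9)

    def test_ultrametric_five_taxon_generating_topology(self):
        # ((A,B),(C,D),E) with clock-like depths
        labels = ("A", "B", "C", "D", "E")
        m = np.array([
            [0.0, 0.2, 0.6, 0.6, 1.0],
            [0.2, 0.0, 0.6, 0.6, 1.0],
            [0.6, 0.6, 0.0, 0.2, 1.0],
            [0.6, 0.6, 0.2, 0.0, 1.0],
            [1.0, 1.0, 1.0, 1.0, 0.0],
        ])
        tree = nj_tree(DistanceMatrix(labels, m))
        assert bipartitions(tree) == {frozenset("CD"), frozenset("CDE")}

    def test_matches_independent_nj_implementation(self):
        """Same splits as scikit-bio's neighbor joining on random matrices."""
        import skbio
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            labels = tuple(f"t{i}" for i in range(n))
            # random additive-ish symmetric matrix
            base = rng.uniform(0.1, 1.0, size=(n, n))
            m = (base + base.T) / 2
            np.fill_diagonal(m, 0.0)
            mine = nj_tree(DistanceMatrix(labels, m))
            theirs = skbio_nj(skbio.DistanceMatrix(m, labels))
            all_leaves = frozenset(labels)
            ref = min(labels)
            their_bips = set()
            for node in theirs.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if ref in side:
                    side = all_leaves - side
                if 1 < len(side) < n - 1:
                    their_bips.add(side)
            assert bipartitions(mine) == their_bips

    def test_non_symmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B"), np.array([[0, 1], [2, 0]], float))


class TestBootstrap:
    @staticmethod
    def _two_clade_alignment(rng, n_per_clade=4, length=300, divergence=0.25):
        anchor1 = rng.choice(list("ACGT"), size=length)
        anchor2 = anchor1.copy()
        flip = rng.random(length) < divergence
        subst = {"A": "G", "G": "A", "C": "T", "T": "C"}
        anchor2[flip] = [subst[b] for b in anchor2[flip]]
        seqs = []
        for c, anchor in (("x", anchor1), ("y", anchor2)):
            for i in range(n_per_clade):
                s = anchor.copy()
                jitter = rng.random(length) < 0.01
                s[jitter] = rng.choice(list("ACGT"), size=int(jitter.sum()))
                seqs.append((f"{c}{i}", "".join(s)))
        return seqs

    def test_separating_edge_gets_high_support(self):
        rng = np.random.default_rng(2024)
        aln = self._two_clade_alignment(rng)
        st = bootstrap_supports(aln, b=100, seed=7)
        clade = frozenset(f"y{i}" for i in range(4))
        assert st.supports.get(clade, 0.0) >= 90

    def test_b1_supports_are_zero_or_hundred(self):
        rng = np.random.default_rng(1)
        aln = self._two_clade_alignment(rng)
        st = bootstrap_supports(aln, b=1, seed=0)
        assert set(st.supports.values()) <= {0.0, 100.0}

    def test_fixed_seed_is_deterministic(self):
        rng = np.random.default_rng(5)
        aln = self._two_clade_alignment(rng)
        a = bootstrap_supports(aln, b=25, seed=123)
        b = bootstrap_supports(aln, b=25, seed=123)
        assert a.supports == b.supports
        assert a.newick() == b.newick()

    def test_supports_bounded_and_low_values_hidden(self):
        rng = np.random.default_rng(8)
        aln = self._two_clade_alignment(rng, divergence=0.02)
        st = bootstrap_supports(aln, b=30, seed=1)
        assert all(0.0 <= v <= 100.0 for v in st.supports.values())
        newick = st.newick(min_support=50)
        for v in st.supports.values():
            if 0 < v < 50:
                assert f"){int(round(v))}:" not in newick or v >= 50
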