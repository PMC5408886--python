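import itertools
import math

import numpy as np
import pytest

from allosite.errors import InputError, UndefinedDistanceError
from allosite.phylogeny import (
    DistanceMatrix,
    Tree,
    distance_matrix,
    family_coherence,
    pairwise_distance,
    read_distance_csv,
    read_newick,
    to_newick,
    upgma,
    write_distance_csv,
)


class TestPairwiseDistance:
    def test_identical_sequences_are_zero(self):
        for model in ("p_distance", "poisson"):
            assert pairwise_distance("ACDEFG", "ACDEFG", model) == 0.0

    def test_poisson_closed_form(self):
        # one mismatch in ten columns: p = 0.1, d = -ln(0.9)
        d = pairwise_distance("A" * 10, "A" * 9 + "C", "poisson")
        assert abs(d - 0.1053605) < 1e-5

    def test_gap_columns_excluded(self):
        # gapped column dropped in both: 1 mismatch of 4 compared
        assert pairwise_distance("AC-DE", "AC-DF", "p_distance") == 0.25
        assert pairwise_distance("ACGDE", "AC-DE", "p_distance") == 0.0

    def test_brute_force_column_scan(self):
        rng = np.random.default_rng(3)
        aas = "ACDEFGHIKLMNPQRSTVWY-"
        for _ in range(20):
            a = "".join(rng.choice(list(aas), 60))
            b = "".join(rng.choice(list(aas), 60))
            compared = [(x, y) for x, y in zip(a, b) if "-" not in (x, y)]
            if not compared:
                continue
            p = sum(x != y for x, y in compared) / len(compared)
            assert pairwise_distance(a, b, "p_distance") == pytest.approx(p)

    def test_poisson_dominates_p_distance(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = "".join(rng.choice(list("ACDE"), 40))
            b = "".join(rng.choice(list("ACDE"), 40))
            p = pairwise_distance(a, b, "p_distance")
            q = pairwise_distance(a, b, "poisson")
            assert q >= p
            assert (q == p) == (p == 0.0)

    def test_cap_with_warning(self):
        with pytest.warns(UserWarning, match="capped"):
            d = pairwise_distance("A" * 50, "C" * 50, "poisson")
        assert d == pytest.approx(-math.log1p(-0.95))

    def test_no_comparable_columns(self):
        with pytest.raises(UndefinedDistanceError):
            pairwise_distance("--A", "AA-", "p_distance")


def _naive_upgma(taxa, d0):
    """Independent definitional UPGMA: cluster distances recomputed as the
    plain mean over all original cross pairs at every step."""
    clusters = [frozenset([t]) for t in taxa]
    heights = {c: 0.0 for c in clusters}
    children = {}
    index = {t: i for i, t in enumerate(taxa)}

    def cdist(c1, c2):
        return sum(d0[index[a]][index[b]] for a in c1 for b in c2) / (len(c1) * len(c2))

    while len(clusters) > 1:
        best = None
        for c1, c2 in itertools.combinations(clusters, 2):
            key = (cdist(c1, c2), tuple(sorted((min(c1), min(c2)))))
            if best is None or key < best[0]:
                best = (key, c1, c2)
        (dmin, _), c1, c2 = best
        merged = c1 | c2
        heights[merged] = dmin / 2.0
        children[merged] = (c1, c2)
        clusters = [c for c in clusters if c not in (c1, c2)] + [merged]
    return clusters[0], heights, children


def _canonical(node):
    """Order-independent form of our TreeNode: nested sorted tuples."""
    if node.is_leaf:
        return (node.name, 0.0)
    subs = sorted((_canonical(c) for c in node.children), key=repr)
    return (tuple(subs), round(node.height, 9))


def _canonical_naive(cluster, heights, children):
    if len(cluster) == 1:
        return (next(iter(cluster)), 0.0)
    c1, c2 = children[cluster]
    subs = sorted([
        _canonical_naive(c1, heights, children),
        _canonical_naive(c2, heights, children),
    ], key=repr)
    return (tuple(subs), round(heights[cluster], 9))


class TestUpgma:
    def test_hand_executed_three_taxa(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.0]]))
        tree = upgma(dm)
        root = tree.root
        assert root.height == pytest.approx(2.0)
        inner = next(c for c in root.children if not c.is_leaf)
        assert inner.height == pytest.approx(1.0)
        assert inner.leaf_names() == frozenset({"A", "B"})

    def test_equal_distances_tie_break_deterministic(self):
        taxa = ["D", "B", "C", "A"]
        d = np.full((4, 4), 3.0)
        np.fill_diagonal(d, 0.0)
        tree = upgma(DistanceMatrix(taxa, d))
        # first merge must be the lexicographically smallest pair (A, B)
        first = min(
            (n for n in tree.root.walk() if not n.is_leaf), key=lambda n: n.height
        )
        assert {"A", "B"} <= set(first.leaf_names())
        for node in tree.root.walk():
            if not node.is_leaf:
                assert node.height == pytest.approx(1.5)

    def test_oracle_equivalence_random_matrices(self):
        rng = np.random.default_rng(12)
        for trial in range(100):
            n = int(rng.integers(4, 9))
            taxa = [f"T{chr(65 + i)}" for i in range(n)]
            d = np.round(rng.uniform(0.1, 2.0, (n, n)), 3)
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            tree = upgma(DistanceMatrix(taxa, d))
            cluster, heights, children = _naive_upgma(taxa, d.tolist())
            assert _canonical(tree.root) == _canonical_naive(cluster, heights, children)

    def test_ultrametricity(self):
        rng = np.random.default_rng(13)
        n = 8
        taxa = [f"X{i}" for i in range(n)]
        d = rng.uniform(0.5, 3.0, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = upgma(DistanceMatrix(taxa, d))
        root_h = tree.root.height
        leaf_depths = []

        def walk(node, dist):
            if node.is_leaf:
                leaf_depths.append(dist)
            for c in node.children:
                walk(c, dist + (node.height - c.height))

        walk(tree.root, 0.0)
        assert all(abs(x - root_h) < 1e-9 for x in leaf_depths)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(14)
        n = 6
        taxa = [f"P{i}" for i in range(n)]
        d = rng.uniform(0.2, 2.0, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        ref = _canonical(upgma(DistanceMatrix(taxa, d)).root)
        for _ in range(5):
            perm = rng.permutation(n)
            taxa_p = [taxa[i] for i in perm]
            d_p = d[np.ix_(perm, perm)]
            assert _canonical(upgma(DistanceMatrix(taxa_p, d_p)).root) == ref

    def test_single_taxon_rejected(self):
        with pytest.raises(InputError):
            upgma(DistanceMatrix(["A"], np.zeros((1, 1))))


class TestNewickAndCsv:
    def test_newick_round_trip(self):
        rng = np.random.default_rng(15)
        n = 7
        taxa = [f"N{i}" for i in range(n)]
        d = rng.uniform(0.3, 2.5, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = upgma(DistanceMatrix(taxa, d))
        back = read_newick(to_newick(tree))

        def rounded(node, digits=7):
            if node.is_leaf:
                return (node.name, 0.0)
            subs = sorted((rounded(c, digits) for c in node.children), key=repr)
            return (tuple(subs), round(node.height, digits))

        # serialized branch lengths carry 9 decimals; heights are sums of a
        # few of them, so agreement is to well under 1e-7
        assert rounded(back.root) == rounded(tree.root)

    def test_distance_csv_round_trip(self, tmp_path):
        aln = {"A": "ACDEFG", "B": "ACDFFG", "C": "QWDEFG"}
        dm = distance_matrix(aln, "poisson")
        path = tmp_path / "dm.csv"
        write_distance_csv(dm, path)
        back = read_distance_csv(path)
        assert back.taxa == dm.taxa
        assert np.allclose(back.d, dm.d, atol=1e-9)


class TestFamilyCoherence:
    def _block_alignment(self, swap=False):
        """Two-family block alignment; optionally swap one leaf across blocks."""
        rng = np.random.default_rng(16)
        base1 = rng.choice(list("ACDEFGHIKL"), 60)
        base2 = rng.choice(list("MNPQRSTVWY"), 60)
        aln, fams = {}, {}
        for i in range(4):
            seq = base1.copy()
            idx = rng.choice(60, 3, replace=False)
            seq[idx] = "W"
            aln[f"A{i}"] = "".join(seq)
            fams[f"A{i}"] = "famA"
        for i in range(4):
            seq = base2.copy()
            idx = rng.choice(60, 3, replace=False)
            seq[idx] = "A"
            aln[f"B{i}"] = "".join(seq)
            fams[f"B{i}"] = "famB"
        if swap:
            aln["A3"], aln["B3"] = aln["B3"], aln["A3"]
        return aln, fams

    def test_block_structure_gives_all_coherent(self):
        aln, fams = self._block_alignment()
        tree = upgma(distance_matrix(aln, "p_distance"))
        assert all(family_coherence(tree, fams).values())

    def test_single_swap_breaks_both_involved_families(self):
        aln, fams = self._block_alignment(swap=True)
        tree = upgma(distance_matrix(aln, "p_distance"))
        coherent = family_coherence(tree, fams)
        assert not coherent["famA"] and not coherent["famB"]

    def test_regrouped_orphan_tracks_its_neighbours(self):
        """An orphan receptor generated inside another family's block groups
        with that family, and the coherence report reflects it."""
        aln, fams = self._block_alignment()
        # the orphan's sequence is a famB-like sequence
        aln["ORPHAN"] = aln["B0"][:-1] + ("A" if aln["B0"][-1] != "A" else "C")
        fams["ORPHAN"] = "orphan"
        tree = upgma(distance_matrix(aln, "p_distance"))
        coherent = family_coherence(tree, fams)
        assert coherent["famA"]
        assert not coherent["famB"]      # the orphan nests inside famB's clade
        assert coherent["orphan"]        # a single leaf is trivially a clade

    def test_missing_family_assignment_rejected(self):
        aln, fams = self._block_alignment()
        tree = upgma(distance_matrix(aln, "p_distance"))
        del fams["A0"]
        with pytest.raises(InputError):
            family_coherence(tree, fams)
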