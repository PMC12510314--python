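"""Complete deletion, Poisson distances, neighbor joining and bootstrap."""

import numpy as np
import pytest

from seedvigor.phylogeny import (
    ProteinAlignment,
    bipartitions,
    bootstrap_tree,
    complete_deletion,
    distance_matrix,
    nj,
    poisson_distance,
)

AA = list("ACDEFGHIKLMNPQRSTVWY")


def random_additive_matrix(n_taxa, rng):
    """Distances synthesized from a random binary tree with random branch
    lengths; returns (matrix, labels, set of true bipartitions)."""
    nodes = [{"leaves": {f"T{i}"}, "id": i} for i in range(n_taxa)]
    dist = {(f"T{i}", f"T{i}"): 0.0 for i in range(n_taxa)}
    leaf_depth = {f"T{i}": 0.0 for i in range(n_taxa)}
    # distances via repeated agglomeration of random pairs
    D = np.zeros((n_taxa, n_taxa))
    labels = [f"T{i}" for i in range(n_taxa)]
    # build tree as nested sets with branch lengths
    import itertools

    active = [({f"T{i}"}, {f"T{i}": 0.0}) for i in range(n_taxa)]
    splits = []
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        (si, di) = active.pop(j)
        (sj, dj) = active.pop(i)
        li, lj = rng.uniform(0.05, 0.5, 2)
        merged_set = si | sj
        merged_d = {k: v + li for k, v in di.items()}
        merged_d.update({k: v + lj for k, v in dj.items()})
        for a in si:
            for b in sj:
                D[labels.index(a), labels.index(b)] = D[labels.index(b), labels.index(a)] = (
                    di[a] + li + dj[b] + lj
                )
        if 1 < len(merged_set) < n_taxa - 1:
            splits.append(frozenset(merged_set))
        active.append((merged_set, merged_d))
    (sa, da), (sb, db) = active
    l_root = rng.uniform(0.05, 0.5)
    for a in sa:
        for b in sb:
            D[labels.index(a), labels.index(b)] = D[labels.index(b), labels.index(a)] = (
                da[a] + db[b] + l_root
            )
    ref = min(labels)
    canon = {s if ref not in s else frozenset(set(labels) - s) for s in splits}
    return D, labels, canon


class TestCompleteDeletion:
    def test_gap_free_identity(self):
        aln = ProteinAlignment(["a", "b"], ["ACDEF", "ACDEG"])
        out = complete_deletion(aln)
        assert out.seqs == aln.seqs

    def test_single_gap_drops_column_for_all(self):
        aln = ProteinAlignment(["a", "b"], ["AC-EF", "ACDEG"])
        out = complete_deletion(aln)
        assert out.seqs == ["ACEF", "ACEG"]

    def test_crafted_alignment_against_column_scan(self, rng):
        n, L = 5, 10
        cols = [[rng.choice(AA) for _ in range(n)] for _ in range(L)]
        for j in rng.choice(L, 4, replace=False):
            cols[j][int(rng.integers(n))] = rng.choice(["-", "X"])
        seqs = ["".join(cols[j][i] for j in range(L)) for i in range(n)]
        out = complete_deletion(ProteinAlignment([f"t{i}" for i in range(n)], seqs))
        expected_cols = [j for j in range(L) if all(c in set(AA) for c in cols[j])]
        assert out.n_sites == len(expected_cols) == 6

    def test_all_ambiguous_rejected(self):
        with pytest.raises(ValueError):
            complete_deletion(ProteinAlignment(["a", "b"], ["-A", "A-"]))


class TestPoissonDistance:
    def test_identical_zero(self):
        assert poisson_distance("ACDEF", "ACDEF") == 0.0

    def test_closed_form(self):
        a = "A" * 10
        b = "C" + "A" * 9  # p = 0.1
        assert poisson_distance(a, b) == pytest.approx(-np.log(0.9))

    def test_correction_inflates(self, rng):
        for _ in range(20):
            L = 50
            a = "".join(rng.choice(AA, L))
            b = list(a)
            k = int(rng.integers(1, 20))
            for i in rng.choice(L, k, replace=False):
                b[i] = rng.choice(AA)
            b = "".join(b)
            p = sum(x != y for x, y in zip(a, b)) / L
            if p < 1:
                assert poisson_distance(a, b) >= p

    def test_saturation_rejected(self):
        with pytest.raises(ValueError):
            poisson_distance("AAAA", "CCCC")


class TestNeighborJoining:
    def test_known_four_taxon_tree_recovered(self):
        # tree ((A:1,B:2):3,C:4,D:5) -> additive distances
        D = np.array(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float
        )
        tree = nj(D, list("ABCD"))
        bip = bipartitions(tree.root, set("ABCD"))
        assert frozenset("CD") in bip or frozenset("AB") in bip
        # branch lengths: leaf edges recovered exactly
        lengths = {leaf.name: leaf.length for leaf in tree.root.leaves()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 4.0, "D": 5.0})

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = nj(D, list("ABC"))
        lengths = {leaf.name: leaf.length for leaf in tree.root.leaves()}
        assert lengths["A"] == pytest.approx(0.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_random_additive_trees_exact(self, n_taxa, rng):
        for _ in range(5):
            D, labels, true_splits = random_additive_matrix(n_taxa, rng)
            tree = nj(D, labels)
            got = set(bipartitions(tree.root, set(labels)))
            assert got == true_splits
            # path lengths reproduce the input matrix
            reD = _tree_distances(tree, labels)
            assert np.allclose(reD, D, atol=1e-9)

    def test_matches_dendropy_topology(self, rng):
        dendropy = pytest.importorskip("dendropy")
        n = 7
        D, labels, _ = random_additive_matrix(n, rng)
        noisy = D + rng.uniform(0, 0.01, D.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        mine = set(bipartitions(nj(noisy, labels).root, set(labels)))
        # dendropy NJ as independent oracle
        csv = "," + ",".join(labels) + "\n"
        for i, lab in enumerate(labels):
            csv += lab + "," + ",".join(f"{x:.8f}" for x in noisy[i]) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv)
        )
        dtree = pdm.nj_tree()
        ref = min(labels)
        theirs = set()
        for edge in dtree.preorder_edge_iter():
            if edge.head_node and not edge.head_node.is_leaf() and edge.head_node.parent_node:
                side = {t.taxon.label for t in edge.head_node.leaf_iter()}
                if 1 < len(side) < n - 1:
                    theirs.add(
                        frozenset(side) if ref not in side else frozenset(set(labels) - side)
                    )
        assert mine == theirs

    def test_nan_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError):
            nj(D, list("ABC"))


def _tree_distances(tree, labels):
    """Leaf-to-leaf path lengths via bipartition-free traversal."""
    paths = {}

    def walk(node, acc):
        acc = acc + [node]
        if node.is_leaf:
            paths[node.name] = acc
        for c in node.children:
            walk(c, acc)

    walk(tree.root, [])
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa, pb = paths[labels[i]], paths[labels[j]]
            common = 0
            for x, y in zip(pa, pb):
                if x is y:
                    common += 1
                else:
                    break
            d = sum(nd.length for nd in pa[common:]) + sum(nd.length for nd in pb[common:])
            D[i, j] = D[j, i] = d
    return D


def simulate_two_clade_alignment(rng, n_per_clade=5, L=300, clade_muts=60, tip_muts=8):
    anc = rng.choice(AA, L)

    def mutate(s, k):
        s = s.copy()
        for i in rng.choice(L, k, replace=False):
            s[i] = rng.choice(AA)
        return s

    clades = [mutate(anc, clade_muts), mutate(anc, clade_muts)]
    names, seqs = [], []
    for c, base in zip("AB", clades):
        for i in range(n_per_clade):
            names.append(f"{c}{i}")
            seqs.append("".join(mutate(base, tip_muts)))
    return ProteinAlignment(names, seqs)


class TestBootstrap:
    def test_single_replicate_supports_binary(self, rng):
        aln = simulate_two_clade_alignment(rng)
        tree = bootstrap_tree(aln, B=1, collapse_below=0.0, seed=1)
        sups = [n.support for n in _internal_nodes(tree.root) if n.support is not None]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_deep_split_gets_full_support(self, rng):
        aln = simulate_two_clade_alignment(rng)
        tree = bootstrap_tree(aln, B=200, collapse_below=50.0, seed=2)
        bip = tree.bipartitions()
        deep = frozenset(f"B{i}" for i in range(5))
        assert deep in bip
        assert bip[deep].support >= 95.0

    def test_star_data_collapses(self, rng):
        # taxa mutated independently from one ancestor: no internal structure
        anc = rng.choice(AA, 200)
        seqs = []
        for i in range(8):
            s = anc.copy()
            for j in rng.choice(200, 30, replace=False):
                s[j] = rng.choice(AA)
            seqs.append("".join(s))
        aln = ProteinAlignment([f"t{i}" for i in range(8)], seqs)
        full = bootstrap_tree(aln, B=100, collapse_below=0.0, seed=3)
        collapsed = bootstrap_tree(aln, B=100, collapse_below=50.0, seed=3)
        n_full = len(list(_internal_nodes(full.root)))
        n_coll = len(list(_internal_nodes(collapsed.root)))
        assert n_coll < n_full

    def test_supports_invariant_to_taxon_order(self, rng):
        aln = simulate_two_clade_alignment(rng, n_per_clade=4, L=200)
        perm = rng.permutation(aln.n_taxa)
        aln2 = ProteinAlignment(
            [aln.names[i] for i in perm], [aln.seqs[i] for i in perm]
        )
        t1 = bootstrap_tree(aln, B=100, collapse_below=0.0, seed=4)
        t2 = bootstrap_tree(aln2, B=100, collapse_below=0.0, seed=4)
        deep = frozenset(f"B{i}" for i in range(4))
        assert t1.bipartitions()[deep].support >= 90
        assert t2.bipartitions()[deep].support >= 90

    def test_newick_roundtrips_through_dendropy(self, rng):
        dendropy = pytest.importorskip("dendropy")
        aln = simulate_two_clade_alignment(rng, n_per_clade=3, L=150)
        tree = bootstrap_tree(aln, B=50, seed=5)
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == set(aln.names)


def _internal_nodes(node):
    if not node.is_leaf:
        yield node
        for c in node.children:
            yield from _internal_nodes(c)
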