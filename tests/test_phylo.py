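"""Concatenated matrices, p-distances, NJ, and topology comparison."""
import itertools

import numpy as np
import pytest

from psyllomito.alignment import MultipleAlignment
from psyllomito.phylo import (DistanceMatrix, Node, PhyloTree, build_matrix,
                              nj_tree, p_distance, parse_newick,
                              robinson_foulds, same_topology,
                              strip_third_positions)
from psyllomito.simulate import (EvolutionSpec, GenomeSpec, evolve_panel,
                                 generate_genome)


def test_third_position_stripping_hand_example():
    aln = MultipleAlignment(["x"], ["ATGGAA"])
    assert strip_third_positions(aln).rows == ["ATGA"]


def test_stripping_rejects_non_codon_matrix():
    with pytest.raises(ValueError, match="codon"):
        strip_third_positions(MultipleAlignment(["x"], ["ATGGA"]))


def test_p_distance_hand_count():
    a = "ACGTACGTACGT"
    b = "TCGTACGAACGA"      # 3 differences over 12 valid sites
    d = p_distance(MultipleAlignment(["a", "b"], [a, b]), mode="nt")
    assert d.get("a", "b") == pytest.approx(0.25)


def test_p_distance_matches_column_scan_oracle():
    rng = np.random.default_rng(17)
    rows = ["".join(rng.choice(list("ACGT-"), 120,
                               p=[.24, .24, .24, .23, .05]))
            for _ in range(4)]
    aln = MultipleAlignment(list("abcd"), rows)
    d = p_distance(aln, mode="nt")
    for (i, x), (j, y) in itertools.combinations(enumerate("abcd"), 2):
        diff = valid = 0
        for p, q in zip(rows[i], rows[j]):
            if p in "ACGT" and q in "ACGT":
                valid += 1
                diff += p != q
        assert d.get(x, y) == pytest.approx(diff / valid)


def test_identical_rows_have_zero_distance():
    aln = MultipleAlignment(["a", "b"], ["ACGTAA", "ACGTAA"])
    assert p_distance(aln, mode="nt").get("a", "b") == 0.0


# ---------------------------------------------------------------------------
# neighbour joining

def _tree_distances(newick):
    """Leaf-to-leaf path lengths of a branch-length newick tree."""
    tree = parse_newick(newick)
    leaves = sorted(tree.leaf_names)

    def paths(node, acc):
        if node.is_leaf():
            return {node.name: acc + (node.branch_length or 0)}
        out = {}
        for c in node.children:
            out.update(paths(c, acc + (node.branch_length or 0)))
        return out

    # distance via recursive LCA decomposition
    def dmat(node):
        if node.is_leaf():
            return {node.name: node.branch_length or 0}, {}
        depth_maps, dists = [], {}
        for c in node.children:
            dm, dd = dmat(c)
            dists.update(dd)
            depth_maps.append(dm)
        for m1, m2 in itertools.combinations(depth_maps, 2):
            for l1 in m1:
                for l2 in m2:
                    dists[frozenset((l1, l2))] = m1[l1] + m2[l2]
        merged = {}
        for m in depth_maps:
            for l, v in m.items():
                merged[l] = v + (node.branch_length or 0)
        return merged, dists
    _, dists = dmat(tree.root)
    D = np.zeros((len(leaves), len(leaves)))
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            if i != j:
                D[i, j] = dists[frozenset((a, b))]
    return DistanceMatrix(leaves, D)


def test_nj_recovers_four_taxon_additive_tree_exactly():
    src = "((A:2,B:3):1,C:4,D:5);"
    d = _tree_distances(src)
    tree = nj_tree(d)
    assert same_topology(tree, parse_newick("((A,B),C,D);"))
    # branch lengths recovered exactly for an additive matrix
    lengths = {}
    def walk(n):
        for c in n.children:
            if c.is_leaf():
                lengths[c.name] = c.branch_length
            walk(c)
    walk(tree.root)
    assert lengths == {"A": pytest.approx(2), "B": pytest.approx(3),
                       "C": pytest.approx(4), "D": pytest.approx(5)}


def test_nj_three_taxa_star():
    d = DistanceMatrix(list("ABC"), np.array([[0, 2, 3], [2, 0, 4],
                                              [3, 4, 0.0]]))
    tree = nj_tree(d)
    assert len(tree.root.children) == 3
    assert tree.leaf_names == frozenset("ABC")


def _random_additive_tree(rng, n_leaves):
    names = [f"L{i}" for i in range(n_leaves)]
    nodes = [Node(name=x, branch_length=float(rng.uniform(0.5, 3)))
             for x in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        merged = Node(children=[b, a],
                      branch_length=float(rng.uniform(0.5, 3)))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    tree = PhyloTree(Node(children=nodes))
    return tree


def test_nj_exact_recovery_on_random_additive_matrices():
    rng = np.random.default_rng(18)
    for _ in range(20):
        n = int(rng.integers(4, 11))
        truth = _random_additive_tree(rng, n)
        d = _tree_distances(truth.newick())
        assert same_topology(nj_tree(d), truth)


def test_nj_matches_dendropy_oracle_on_random_matrices():
    dendropy = pytest.importorskip("dendropy")
    rng = np.random.default_rng(19)
    for _ in range(8):
        n = int(rng.integers(5, 9))
        labels = [f"t{i}" for i in range(n)]
        M = rng.uniform(0.1, 1.0, size=(n, n))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0.0)
        mine = nj_tree(DistanceMatrix(labels, M))
        csv = "," + ",".join(labels) + "\n" + "\n".join(
            labels[i] + "," + ",".join(str(M[i, j]) for j in range(n))
            for i in range(n))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv))
        theirs_newick = pdm.nj_tree().as_string(schema="newick",
                                                suppress_rooting=True)
        theirs = parse_newick(theirs_newick.strip())
        assert robinson_foulds(mine, theirs) == 0


def test_rf_matches_dendropy_oracle_on_random_tree_pairs():
    dendropy = pytest.importorskip("dendropy")
    from dendropy.calculate import treecompare
    rng = np.random.default_rng(20)
    for _ in range(8):
        n = int(rng.integers(4, 9))
        t1 = _random_additive_tree(rng, n)
        t2 = _random_additive_tree(rng, n)
        mine = robinson_foulds(t1, t2)
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=t1.newick(), schema="newick",
                               taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=t2.newick(), schema="newick",
                               taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        assert mine == treecompare.symmetric_difference(d1, d2)


def test_same_topology_examples():
    a = parse_newick("((A,B),(C,D));")
    b = parse_newick("((A,C),(B,D));")
    assert same_topology(a, parse_newick("((B,A),(D,C));"))
    assert not same_topology(a, b)
    with pytest.raises(ValueError, match="leaf sets differ"):
        robinson_foulds(a, parse_newick("((A,B),(C,E));"))


# ---------------------------------------------------------------------------
# the concatenated matrix

def test_identical_genomes_give_zero_distances(genome):
    m = build_matrix([genome, genome], taxa=["x", "y"])
    d = p_distance(m, "nt12")
    assert d.get("x", "y") == 0.0


def test_block_arithmetic_invariants(phylo_panel):
    panel, _ = phylo_panel
    m = build_matrix(panel)
    assert m.block_order[:3] == ["nad2", "cox1", "cox2"]
    nt = m.concatenated("nt")
    nt12 = m.concatenated("nt12")
    assert nt.n_cols % 3 == 0
    assert nt12.n_cols == 2 * nt.n_cols // 3
    for gene, block in m.gene_blocks.items():
        assert block.n_cols % 3 == 0


def test_missing_gene_raises(genome):
    import copy
    crippled = copy.deepcopy(genome)
    crippled.features = [f for f in crippled.features if f.name != "cox2"]
    with pytest.raises(ValueError, match="cox2"):
        build_matrix([genome, crippled], taxa=["a", "b"])


def test_nt12_nj_recovery_stays_high_under_saturation():
    """Third positions evolved to saturation: nt12 NJ still recovers the
    generating topology nearly always."""
    mini_order = (("cox1", "J", "PCG"), ("nad5", "N", "PCG"))
    mini_table = {"cox1": ("ATG", "TAA", 303), "nad5": ("ATT", "TAA", 303)}
    ref = parse_newick("((BC,PS),(CC,PV),(CQ,AA));")

    def tree():
        return Node(children=[
            Node(branch_length=0.03, children=[
                Node(name="BC", branch_length=0.05),
                Node(name="PS", branch_length=0.05)]),
            Node(branch_length=0.03, children=[
                Node(name="CC", branch_length=0.05),
                Node(name="PV", branch_length=0.05)]),
            Node(branch_length=0.05, children=[
                Node(name="CQ", branch_length=0.5),
                Node(name="AA", branch_length=0.55)]),
        ])

    wins = 0
    trials = 40
    for trial in range(trials):
        g = generate_genome(GenomeSpec(gene_order=mini_order,
                                       pcg_table=mini_table, overlaps={},
                                       control_region_length=80,
                                       primer_pair=None, seed=100 + trial))
        spec = EvolutionSpec(tree=tree(), default_gene_rate=1.0,
                             noncoding_rate=0.0,
                             position_weights=(0.35, 0.35, 2.3),
                             seed=200 + trial)
        panel, _ = evolve_panel(g, spec)
        rows = ["".join(p.get(gene).sense_sequence(p.sequence)
                        for gene in ("cox1", "nad5")) for p in panel]
        aln = MultipleAlignment([p.metadata["accession"] for p in panel],
                                rows)
        t = nj_tree(p_distance(strip_third_positions(aln), mode="nt"))
        wins += robinson_foulds(t, ref) == 0
    assert wins >= 0.9 * trials
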