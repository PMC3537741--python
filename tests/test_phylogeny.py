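"""Tests for distance matrices, neighbour joining, bootstrap and group calling."""

import dendropy
import numpy as np
import pytest

from gliafam import phylogeny as phy
from gliafam import simulate
from gliafam.ng86 import jukes_cantor


def test_filter_by_length_boundary():
    aln = {
        "short": "A" * 599 + "-" * 301,
        "exact": "A" * 600 + "-" * 300,
        "gaps": "-" * 900,
        "full": "A" * 900,
    }
    kept = phy.filter_by_length(aln, 600)
    assert set(kept) == {"exact", "full"}
    with pytest.raises(ValueError):
        phy.filter_by_length({"a": "----"}, 600)


def test_jc_distance_matrix_values():
    a = "A" * 100
    b = "A" * 70 + "C" * 30  # 30 diffs / 100 sites
    c = "A" * 50 + "G" * 50
    D = phy.jc_distance_matrix({"a": a, "b": b, "c": c})
    i, j = D.labels.index("a"), D.labels.index("b")
    assert D.values[i, i] == 0.0
    assert D.values[i, j] == pytest.approx(0.3831, abs=5e-5)
    assert D.values[i, j] == pytest.approx(jukes_cantor(0.30), abs=1e-12)


def test_jc_distance_pairwise_deletion_and_saturation():
    aln = {
        "a": "AAAAACCCCC",
        "b": "AAAAA-----",  # gap columns dropped only for pairs with 'b'
        "c": "TTTTTGGGGG",  # saturated vs 'a'
    }
    D = phy.jc_distance_matrix(aln)
    la = D.labels.index("a")
    lb = D.labels.index("b")
    lc = D.labels.index("c")
    assert D.values[la, lb] == 0.0
    assert np.isnan(D.values[la, lc])
    assert D.has_missing


def test_nj_four_taxon_textbook_case():
    labels = ["A", "B", "C", "D"]
    D = np.array(
        [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], dtype=float
    )
    tree = phy.neighbor_joining(phy.DistanceMatrix(labels, D))
    splits = {
        frozenset(lf.taxon.label for lf in nd.leaf_iter())
        for nd in tree.preorder_node_iter()
        if not nd.is_leaf() and nd is not tree.seed_node
    }
    assert frozenset("AB") in splits or frozenset("CD") in splits


def test_nj_errors_on_missing_entries():
    D = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
    with pytest.raises(ValueError, match="missing"):
        phy.neighbor_joining(phy.DistanceMatrix(["a", "b", "c"], D))


def _random_additive_case(n_taxa, rng):
    tns = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        taxon_namespace=tns, rng=rng,
    )
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = rng.uniform(0.1, 1.0)
    pdm = tree.phylogenetic_distance_matrix()
    labels = [t.label for t in tns]
    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(n_taxa):
            if i != j:
                D[i, j] = pdm.distance(tns[i], tns[j])
    return tree, labels, D


def rf_distance(true_tree, est_tree):
    est = dendropy.Tree.get(
        data=est_tree.as_string(schema="newick"),
        schema="newick",
        taxon_namespace=true_tree.taxon_namespace,
    )
    t = true_tree.clone(depth=1)
    t.deroot()
    t.encode_bipartitions()
    est.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t, est)


def test_nj_recovers_random_additive_trees():
    import random

    rng = random.Random(13)
    for _ in range(20):
        true_tree, labels, D = _random_additive_case(8, rng)
        est = phy.neighbor_joining(phy.DistanceMatrix(labels, D))
        assert rf_distance(true_tree, est) == 0


def test_nj_agrees_with_independent_implementation():
    """Cross-check topology against scikit-bio's neighbour joining."""
    import io
    import random

    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    rng = random.Random(3)
    true_tree, labels, D = _random_additive_case(7, rng)
    ours = phy.neighbor_joining(phy.DistanceMatrix(labels, D))
    theirs = skbio_nj(SkbioDM(D, ids=labels))
    buf = io.StringIO()
    theirs.write(buf)
    theirs_dp = dendropy.Tree.get(
        data=buf.getvalue(), schema="newick",
        taxon_namespace=true_tree.taxon_namespace,
    )
    ours_dp = dendropy.Tree.get(
        data=ours.as_string(schema="newick"), schema="newick",
        taxon_namespace=true_tree.taxon_namespace,
    )
    theirs_dp.encode_bipartitions()
    ours_dp.encode_bipartitions()
    assert dendropy.calculate.treecompare.symmetric_difference(ours_dp, theirs_dp) == 0


def test_nj_input_order_invariance():
    import random

    rng = random.Random(21)
    _, labels, D = _random_additive_case(8, rng)
    t1 = phy.neighbor_joining(phy.DistanceMatrix(labels, D))
    perm = list(range(len(labels)))[::-1]
    t2 = phy.neighbor_joining(
        phy.DistanceMatrix([labels[i] for i in perm], D[np.ix_(perm, perm)])
    )
    tns = dendropy.TaxonNamespace(labels)
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=tns)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=tns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    assert dendropy.calculate.treecompare.symmetric_difference(a, b) == 0


@pytest.fixture(scope="module")
def two_clade_alignment():
    rng = np.random.default_rng(17)
    anc = simulate.random_coding_sequence(250, rng)
    clade1 = simulate.evolve_codon_star(anc, 4, 0.02, 0.02, rng)
    far = simulate.evolve_codon_star(anc, 1, 0.25, 0.25, rng)[0]
    clade2 = simulate.evolve_codon_star(far, 4, 0.02, 0.02, rng)
    aln = {f"a{i}": s for i, s in enumerate(clade1)}
    aln.update({f"b{i}": s for i, s in enumerate(clade2)})
    return aln


def test_bootstrap_support_separated_clades(two_clade_alignment):
    tree, supports = phy.bootstrap_support(two_clade_alignment, n_reps=100, seed=4)
    side = frozenset(k for k in two_clade_alignment if k.startswith("b"))
    assert supports.get(side, 0.0) >= 0.99


def test_bootstrap_single_rep_and_order_invariance(two_clade_alignment):
    _, s1 = phy.bootstrap_support(two_clade_alignment, n_reps=1, seed=9)
    assert set(s1.values()) <= {0.0, 1.0}
    permuted = dict(reversed(list(two_clade_alignment.items())))
    _, s2 = phy.bootstrap_support(permuted, n_reps=50, seed=9)
    _, s3 = phy.bootstrap_support(two_clade_alignment, n_reps=50, seed=9)
    assert s2 == s3
    with pytest.raises(ValueError):
        phy.bootstrap_support(two_clade_alignment, n_reps=0, seed=1)


def test_call_groups_no_supported_splits(two_clade_alignment):
    tree, supports = phy.bootstrap_support(two_clade_alignment, n_reps=20, seed=5)
    asg = phy.call_groups(tree, {}, {"a0"}, 0.84)  # no supports at all
    assert asg.groups == {}
    assert asg.ungrouped  # everything unassigned
    over = phy.call_groups(tree, supports, {"a0"}, 1.01)  # unattainable
    assert over.groups == {}
    with pytest.raises(ValueError, match="outgroup"):
        phy.call_groups(tree, supports, {"zz"}, 0.84)


def test_call_groups_threshold_refinement(pipeline_result):
    """Groups called at a stricter threshold nest inside groups called at a
    looser one (laminar refinement)."""
    tree, supports = pipeline_result.tree, pipeline_result.supports
    og = pipeline_result.assignment.outgroup_ids
    loose = phy.call_groups(tree, supports, og, 0.70)
    strict = phy.call_groups(tree, supports, og, 0.95)
    for members in strict.groups.values():
        assert any(members <= big for big in loose.groups.values())


def test_protein_distance_matrix():
    aln = {"a": "MKTLL", "b": "MKTLV", "c": "MXTL-"}
    D = phy.p_distance_matrix(aln)
    ia, ib, ic = (D.labels.index(k) for k in ("a", "b", "c"))
    assert D.values[ia, ib] == pytest.approx(0.2)
    assert D.values[ia, ic] == pytest.approx(0.0)  # X and gap excluded
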