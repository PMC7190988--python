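import math
import random

import numpy as np
import pytest

import oracles
from synphylo.treebuild import (DistanceMatrix, bootstrap_support, build_me,
                                build_ml, build_mp, build_nj, build_upgma,
                                fitch_score, log_likelihood,
                                ols_branch_lengths, pairwise_distance)
from synphylo.trees import tree_from_newick, unrooted_splits


def _tree_distances(tree):
    """Leaf-pair path-length matrix of a dendropy tree."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    m = np.zeros((len(labels), len(labels)))
    tax = {t.label: t for t in tree.taxon_namespace}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                m[i, j] = pdm.patristic_distance(tax[a], tax[b])
    return labels, m


# ---------------------------------------------------------------------------
# distances


def test_pairwise_distance_closed_forms():
    rows = {"a": "AAAAAAAAAA", "b": "AACCAAAAAA"}
    d = pairwise_distance(rows, "p")
    assert d.matrix[0, 1] == pytest.approx(0.2)
    jc = pairwise_distance(rows, "jc")
    assert jc.matrix[0, 1] == pytest.approx(-0.75 * math.log(1 - 0.8 / 3),
                                            abs=1e-5)
    assert jc.matrix[0, 1] == pytest.approx(0.23262, abs=1e-5)
    same = pairwise_distance({"a": "ACGT", "b": "ACGT"}, "p")
    assert same.matrix[0, 1] == 0


def test_pairwise_distance_saturation_flagged():
    rows = {"a": "AAAA", "b": "CCCC"}
    d = pairwise_distance(rows, "jc")
    assert d.saturated[0, 1]
    assert np.isnan(d.matrix[0, 1])
    capped = d.capped()
    assert np.isfinite(capped.matrix[0, 1])


def test_pairwise_deletion_of_gap_columns():
    rows = {"a": "AC-TAC", "b": "ACGTNC"}
    d = pairwise_distance(rows, "p")
    assert d.matrix[0, 1] == 0.0  # only 4 comparable, all matching


# ---------------------------------------------------------------------------
# NJ / UPGMA / ME


def test_nj_four_taxon_additive():
    labels = ["A", "B", "C", "D"]
    m = np.array([[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]],
                 dtype=float)
    tree = build_nj(DistanceMatrix(labels, m))
    assert unrooted_splits(tree) == {frozenset({"C", "D"})}
    _, got = _tree_distances(tree)
    assert np.allclose(got, m)


def test_nj_three_taxon_closed_form():
    m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    tree = build_nj(DistanceMatrix(["A", "B", "C"], m))
    lengths = {leaf.taxon.label: leaf.edge.length
               for leaf in tree.leaf_node_iter()}
    assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
    assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
    assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)


def test_nj_recovers_random_additive_trees():
    """NJ is consistent on additive matrices (up to 8 taxa)."""
    for seed in range(8):
        rng = random.Random(seed)
        n = rng.randint(4, 8)
        labels = [f"t{i}" for i in range(n)]
        topo = oracles.random_topology(labels, rng)
        labs, m = oracles.additive_matrix(topo, rng)
        tree = build_nj(DistanceMatrix(labs, m))
        assert unrooted_splits(tree) == \
            oracles.nested_splits(topo, frozenset(labels))
        _, got = _tree_distances(tree)
        assert np.allclose(got, m, atol=1e-9)


def test_upgma_textbook_case():
    m = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
    tree = build_upgma(DistanceMatrix(["A", "B", "C"], m))
    newick = tree.as_string(schema="newick").strip()
    assert "(A:1.0,B:1.0):1.0" in newick and "C:2.0" in newick


def test_upgma_recovers_random_ultrametric_trees():
    for seed in range(8):
        rng = random.Random(100 + seed)
        labels = [f"t{i}" for i in range(rng.randint(3, 8))]
        labs, m = oracles.random_ultrametric(labels, rng)
        tree = build_upgma(DistanceMatrix(labs, m))
        _, got = _tree_distances(tree)
        assert np.allclose(got, m, atol=1e-9)


def test_upgma_equal_distance_tie_policy():
    m = np.ones((4, 4)) - np.eye(4)
    tree = build_upgma(DistanceMatrix(["D", "C", "B", "A"], m))
    # lexicographic tie-break joins A+B first
    splits = {frozenset(leaf.taxon.label for leaf in nd.leaf_iter())
              for nd in tree.preorder_internal_node_iter()}
    assert frozenset({"A", "B"}) in splits


def test_nj_equals_upgma_on_ultrametric_input():
    rng = random.Random(7)
    labs, m = oracles.random_ultrametric(["a", "b", "c", "d", "e"], rng)
    nj = build_nj(DistanceMatrix(labs, m))
    up = build_upgma(DistanceMatrix(labs, m))
    assert unrooted_splits(nj) == unrooted_splits(up)


def test_me_on_additive_matrix_matches_truth():
    rng = random.Random(3)
    labels = [f"t{i}" for i in range(6)]
    topo = oracles.random_topology(labels, rng)
    labs, m = oracles.additive_matrix(topo, rng)
    tree = build_me(DistanceMatrix(labs, m))
    assert unrooted_splits(tree) == \
        oracles.nested_splits(topo, frozenset(labels))
    # OLS on the true topology reproduces the generating distances exactly
    _, got = _tree_distances(tree)
    assert np.allclose(got, m, atol=1e-8)


def test_me_total_length_not_above_nj():
    rng = np.random.default_rng(12)
    for _ in range(5):
        labels = [f"t{i}" for i in range(5)]
        m = rng.uniform(0.2, 1.0, (5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        D = DistanceMatrix(labels, m)
        nj = build_nj(D)
        nj_total = ols_branch_lengths(nj, D)
        me = build_me(D)
        me_total = sum(nd.edge.length for nd in me.preorder_node_iter()
                       if nd.edge.length is not None)
        assert me_total <= nj_total + 1e-9


# ---------------------------------------------------------------------------
# parsimony


def test_fitch_single_column_cases():
    tree = tree_from_newick("((A,B),(C,D));")
    assert fitch_score(tree, {"A": "A", "B": "A", "C": "C", "D": "C"}) == 1
    assert fitch_score(tree, {"A": "A", "B": "A", "C": "A", "D": "A"}) == 0
    with pytest.raises(ValueError, match="missing"):
        fitch_score(tree, {"A": "A", "B": "A", "C": "A"})


def test_fitch_matches_bruteforce_assignment_oracle():
    rng = np.random.default_rng(21)
    for n in (4, 5, 6):
        labels = [f"t{i}" for i in range(n)]
        topo = oracles.random_topology(labels, random.Random(n))
        rows = {lab: "".join(rng.choice(list("ACGT"), 15)) for lab in labels}
        newick = _nested_to_newick(topo) + ";"
        tree = tree_from_newick(newick)
        assert fitch_score(tree, rows) == \
            oracles.brute_force_parsimony(topo, rows)


def _nested_to_newick(t):
    if isinstance(t, str):
        return t
    return "(" + ",".join(_nested_to_newick(c) for c in t) + ")"


def test_mp_recovers_supported_split():
    rows = {"A": "AAAAAGGGGG", "B": "AAAAAGGGGG",
            "C": "CCCCCGGGGG", "D": "CCCCCGGGGG"}
    tree = build_mp(rows)
    assert unrooted_splits(tree) == {frozenset({"C", "D"})}
    assert tree.parsimony_score == 5


def test_mp_invariant_alignment_all_cooptimal():
    rows = {k: "AAAA" for k in "ABCD"}
    tree = build_mp(rows)
    assert tree.parsimony_score == 0
    assert tree.co_optimal_count == 3


def test_mp_score_equals_exhaustive_minimum_six_taxa():
    rng = np.random.default_rng(33)
    labels = [f"t{i}" for i in range(6)]
    rows = {lab: "".join(rng.choice(list("ACGT"), 12)) for lab in labels}
    tree = build_mp(rows, max_exhaustive=7)
    best = min(oracles.brute_force_parsimony(t, rows)
               for t in oracles.enumerate_topologies(labels))
    assert tree.parsimony_score == best


# ---------------------------------------------------------------------------
# likelihood


def test_loglik_two_leaf_closed_form():
    t = 0.07
    tree = tree_from_newick(f"(A:{t/2},B:{t/2});")
    lnl = log_likelihood(tree, {"A": "A", "B": "A"}, model="jc")
    expect = math.log(0.25 * (0.25 + 0.75 * math.exp(-4 * t / 3)))
    assert lnl == pytest.approx(expect, abs=1e-9)
    # zero-length limit: a single shared site approaches ln(1/4)
    tree0 = tree_from_newick("(A:1e-9,B:1e-9);")
    assert log_likelihood(tree0, {"A": "C", "B": "C"}) == \
        pytest.approx(math.log(0.25), abs=1e-6)


def test_loglik_matches_state_enumeration():
    rng = np.random.default_rng(8)
    nested = (("A", "B"), ("C", "D"))
    blens = {"A": 0.1, "B": 0.3, "C": 0.2, "D": 0.15,
             id(nested[0]): 0.12, id(nested[1]): 0.05}
    rows = {lab: "".join(rng.choice(list("ACGT"), 10)) for lab in "ABCD"}
    expect = oracles.enumeration_loglik(nested, blens, rows)
    newick = "((A:0.1,B:0.3):0.12,(C:0.2,D:0.15):0.05);"
    lnl = log_likelihood(tree_from_newick(newick), rows)
    assert lnl == pytest.approx(expect, abs=1e-9)


def test_loglik_gap_treated_as_missing():
    tree = tree_from_newick("(A:0.1,B:0.1);")
    with_gap = log_likelihood(tree, {"A": "AC", "B": "A-"})
    only_first = log_likelihood(tree, {"A": "A", "B": "A"})
    assert with_gap == pytest.approx(only_first + math.log(0.25), abs=1e-9)


def test_leaf_order_never_changes_results():
    rng = np.random.default_rng(4)
    rows = {lab: "".join(rng.choice(list("ACGT"), 30)) for lab in "ABCDE"}
    perm = {k: rows[k] for k in ("D", "B", "E", "A", "C")}
    d1 = pairwise_distance(rows, "p").capped()
    d2 = pairwise_distance(perm, "p").capped()
    assert unrooted_splits(build_nj(d1)) == unrooted_splits(build_nj(d2))
    assert unrooted_splits(build_upgma(d1)) == unrooted_splits(build_upgma(d2))
    t1, t2 = build_mp(rows), build_mp(perm)
    assert t1.parsimony_score == t2.parsimony_score
    tree = tree_from_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1,E:0.1);")
    assert log_likelihood(tree, rows) == pytest.approx(
        log_likelihood(tree, perm), abs=1e-12)


def test_ml_recovers_strong_signal():
    from synphylo.simulate import SimulationConfig, evolve_codon_sequences
    hits = 0
    for rep in range(8):
        true = tree_from_newick(
            "((A:0.05,B:0.05):0.3,(C:0.05,D:0.05):0.3);", rooted=True)
        cfg = SimulationConfig(n_groups=1, seq_len_codons=100, seed=0)
        seqs = evolve_codon_sequences(true, cfg, seed=40 + rep)
        tree = build_ml(seqs)
        hits += unrooted_splits(tree) == {frozenset({"C", "D"})}
    assert hits >= 7


def test_ml_optimizer_not_below_true_lengths():
    rng = np.random.default_rng(2)
    rows = {lab: "".join(rng.choice(list("ACGT"), 60)) for lab in "ABCD"}
    tree = build_ml(rows)
    true = tree_from_newick("((A:0.2,B:0.2):0.1,C:0.2,D:0.2);")
    assert tree.log_likelihood >= log_likelihood(true, rows) - 1e-6


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_support_basics():
    rows = {"A": "AAAAAGGGGGCC", "B": "AAAAAGGGGGCC",
            "C": "CCCCCGGGGGAA", "D": "CCCCCGGGGGAA"}
    one = bootstrap_support(rows, "nj", n_reps=1, seed=0, codon_blocks=False)
    sups = [nd.support for nd in one.preorder_internal_node_iter()
            if getattr(nd, "support", None) is not None]
    assert all(s in (0.0, 100.0) for s in sups)
    a = bootstrap_support(rows, "nj", n_reps=30, seed=5, codon_blocks=False)
    b = bootstrap_support(rows, "nj", n_reps=30, seed=5, codon_blocks=False)
    sa = [nd.support for nd in a.preorder_internal_node_iter()
          if getattr(nd, "support", None) is not None]
    sb = [nd.support for nd in b.preorder_internal_node_iter()
          if getattr(nd, "support", None) is not None]
    assert sa == sb
    assert all(s >= 95 for s in sa)  # clean signal
    with pytest.raises(ValueError):
        bootstrap_support(rows, "nj", n_reps=0)
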