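import numpy as np
import pandas as pd
import pytest

from synphylo.conformance import (ConformanceRecord, classify_conformance,
                                  copy_number_from_hits,
                                  group_agreement_classes, root_by_outgroup,
                                  stratify_by_copy_number, summarize_methods)
from synphylo.groups import SyntenicGroup, build_expected_tree
from synphylo.trees import clade_sets, tree_from_newick


@pytest.fixture()
def expected3():
    return build_expected_tree(SyntenicGroup("g", "V", "T", ["G1", "G2", "G3"]))


def _rec(gid, method, conforms):
    return ConformanceRecord(gid, method, conforms,
                             escape_pattern=frozenset() if conforms
                             else frozenset({"x"}))


# ---------------------------------------------------------------------------
# rooting


def test_root_by_outgroup_basic():
    tree = tree_from_newick("((G1:1,G2:1):1,(T:1,V:2):1);")
    rooted = root_by_outgroup(tree, "V")
    root_children = rooted.seed_node.child_nodes()
    labs = {c.taxon.label for c in root_children if c.is_leaf()}
    assert labs == {"V"}
    # midpoint of the outgroup's pendant edge
    v = rooted.find_node_with_taxon_label("V")
    assert v.edge.length == pytest.approx(1.0)
    assert frozenset({"G1", "G2"}) in clade_sets(rooted, nontrivial=False)


def test_root_by_outgroup_idempotent():
    tree = tree_from_newick("(V:1,(T:1,(G1:1,G2:1):1):1);", rooted=True)
    rooted = root_by_outgroup(tree, "V")
    again = root_by_outgroup(rooted, "V")
    assert clade_sets(rooted, nontrivial=False) == \
        clade_sets(again, nontrivial=False)


def test_root_by_outgroup_missing_label():
    tree = tree_from_newick("(A:1,B:1,C:1);")
    with pytest.raises(ValueError, match="Vx"):
        root_by_outgroup(tree, "Vx")


# ---------------------------------------------------------------------------
# classification


def test_conforming_tree(expected3):
    tree = tree_from_newick("(V,(T,(G1,(G2,G3))));")
    rec = classify_conformance(tree, expected3)
    assert rec.conforms and rec.escape_pattern == frozenset()


def test_escaped_cotton_detected(expected3):
    tree = tree_from_newick("(V,(G1,(T,(G2,G3))));")
    rec = classify_conformance(tree, expected3)
    assert not rec.conforms
    assert rec.escape_pattern == frozenset({"G1"})


def test_expected_tree_conforms_to_itself():
    for n in (2, 3, 5):
        group = SyntenicGroup("g", "V", "T", [f"G{i}" for i in range(n)])
        et = build_expected_tree(group)
        assert classify_conformance(et.tree, et).conforms


def test_classification_invariances(expected3):
    """Branch lengths, child rotation and leaf order never change the verdict."""
    variants = ["(V,(T,(G1,(G2,G3))));",
                "(V:9,(T:0.1,(G1:5,(G3:1,G2:1):0.01):2):3);",
                "(((G2,G3),G1),T,V);",
                "((T,(G1,(G2,G3))),V);"]
    for nwk in variants:
        assert classify_conformance(tree_from_newick(nwk), expected3).conforms


def test_cotton_polytomy_counts_as_conforming(expected3):
    tree = tree_from_newick("(V,(T,(G1,G2,G3)));")
    assert classify_conformance(tree, expected3).conforms


def test_leafset_mismatch_errors(expected3):
    with pytest.raises(ValueError, match="leaf sets"):
        classify_conformance(tree_from_newick("(V,(T,(G1,G2)));"), expected3)


# ---------------------------------------------------------------------------
# summaries


def test_method_summary_percentages():
    recs = []
    for m, c in [("ml", 111), ("nj", 97), ("me", 106), ("upgma", 6),
                 ("mp", 87)]:
        recs += [_rec(f"g{i}", m, i < c) for i in range(662)]
    s = summarize_methods(recs, method_subset=("ml", "nj", "me", "mp"))
    assert s.percentages == {"ml": 16.8, "nj": 14.7, "me": 16.0,
                             "upgma": 0.9, "mp": 13.1}
    assert s.subset_average == 15.2
    assert s.best_method == "ml"
    assert s.best_complement == 83.2
    with pytest.raises(ValueError):
        summarize_methods([])


def test_agreement_classes_counts_and_styles():
    recs = []
    methods = ("ml", "nj", "me", "upgma", "mp")
    for i in range(662):
        if i < 5:
            verdicts = [True] * 5
        elif i < 662 - 503:
            verdicts = [True, True, False, False, True]
        else:
            verdicts = [False] * 5
        recs += [_rec(f"g{i}", m, v) for m, v in zip(methods, verdicts)]
    cls = group_agreement_classes(recs)
    assert cls["counts"] == {"all_conform": 5, "all_nonconform": 503,
                             "mixed": 154}
    assert cls["percentages"]["all_conform"] == 0.76
    assert cls["percentages"]["all_nonconform"] == 76


def test_agreement_single_group_and_incomplete_coverage():
    recs = [_rec("g1", m, True) for m in ("nj", "ml")]
    cls = group_agreement_classes(recs)
    assert cls["counts"] == {"all_conform": 1, "all_nonconform": 0, "mixed": 0}
    recs.append(_rec("g2", "nj", True))
    with pytest.raises(ValueError, match="lacks records"):
        group_agreement_classes(recs)


# ---------------------------------------------------------------------------
# copy numbers


def _hits_df(rows):
    df = pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue"])
    for col in ["pident", "length", "mismatch", "gapopen", "qstart", "qend",
                "sstart", "send", "bitscore"]:
        df[col] = 0
    return df


def test_copy_number_threshold_filter():
    df = _hits_df([("q1", "s1", 1e-30), ("q1", "s2", 1e-10),
                   ("q1", "s3", 1e-3)])
    assert copy_number_from_hits(df, 1e-20) == {"q1": 1}
    assert copy_number_from_hits(df, 1e-5) == {"q1": 2}


def test_copy_number_self_hits_and_duplicates():
    df = _hits_df([("q1", "q1", 0.0), ("q1", "s1", 1e-40),
                   ("q1", "s1", 1e-35)])
    assert copy_number_from_hits(df, 1e-20) == {"q1": 1}


def test_copy_number_malformed_rows_skipped(caplog):
    df = _hits_df([("q1", "s1", 1e-40), ("q1", "s2", "bogus")])
    assert copy_number_from_hits(df, 1e-20) == {"q1": 1}
    assert "skipped" in caplog.text


def test_stratification_bins_half_open():
    recs = [_rec("a", "nj", True), _rec("b", "nj", True),
            _rec("c", "nj", False)]
    counts = {"a": 4, "b": 5, "c": 60}
    table = stratify_by_copy_number(recs, counts)
    assert table.loc["nj", "[0, 5)"] == 100.0
    assert table.loc["nj", "[5, 10)"] == 100.0
    assert table.loc["nj", "[50, inf)"] == 0.0
    assert np.isnan(table.loc["nj", "[10, 20)"])
    with pytest.raises(ValueError, match="missing"):
        stratify_by_copy_number(recs, {"a": 1})
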