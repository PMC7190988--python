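"""Classify reconstructed gene trees against the expected topology.

A reconstructed tree *conforms* when, after rooting on the grape outgroup,
every constraint bipartition of the expected tree is present as a clade —
for the default three-species template this reduces to the cotton paralogs
forming one clade (equivalently, cacao being sister to all cottons).
Classification looks only at topology: branch lengths, child rotation and
bootstrap supports never change the verdict (supports are carried along in
the record for sensitivity analyses).

Also provides the reporting operations: per-method conformance summaries,
group-level agreement classes, and stratification of conformance by
whole-genome homolog copy number from a BLAST-style hit table.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from ._fmt import adaptive_percent, percent, round_half_up
from .groups import ExpectedTree
from .trees import root_by_outgroup

logger = logging.getLogger(__name__)

__all__ = [
    "ConformanceRecord", "MethodSummary", "root_by_outgroup",
    "classify_conformance", "summarize_methods", "group_agreement_classes",
    "copy_number_from_hits", "stratify_by_copy_number", "BLAST6_COLUMNS",
]

BLAST6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                  "gapopen", "qstart", "qend", "sstart", "send",
                  "evalue", "bitscore"]


@dataclass
class ConformanceRecord:
    group_id: str
    method: str
    conforms: bool
    aligner: str = ""
    escape_pattern: frozenset = frozenset()
    support: float | None = None  # bootstrap % of the confirmed/violated split

    def __post_init__(self):
        assert self.conforms == (len(self.escape_pattern) == 0)


def _clade_map(tree: dendropy.Tree) -> dict:
    """node -> frozenset of leaf labels, postorder."""
    sets = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset([node.taxon.label])
        else:
            sets[node] = frozenset().union(*(sets[c] for c in node.child_nodes()))
    return sets


def classify_conformance(tree: dendropy.Tree, expected: ExpectedTree,
                         cotton_genes=None, method: str = "",
                         aligner: str = "") -> ConformanceRecord:
    """Compare one reconstructed tree to its expected topology.

    The tree is rooted on the expected tree's outgroup (the leaf attached
    directly to its root) before clade comparison.  When non-conforming,
    ``escape_pattern`` lists the cotton genes outside the maximal
    cotton-only clade (plurality rule; ties resolved toward the
    lexicographically smaller label set).
    """
    exp_sets = _clade_map(expected.tree)
    exp_leaves = exp_sets[expected.tree.seed_node]
    outgroup = next(lab for child in expected.tree.seed_node.child_nodes()
                    if child.is_leaf()
                    for lab in [child.taxon.label])
    obs_leaves = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    if obs_leaves != exp_leaves:
        raise ValueError("leaf sets of reconstructed and expected trees differ")
    rooted = root_by_outgroup(tree, outgroup)
    clades = _clade_map(rooted)
    clade_sets = set(clades.values())
    conforms = all(c in clade_sets for c in expected.constraint_bipartitions)
    if cotton_genes is None:
        cotton_genes = frozenset().union(*expected.constraint_bipartitions) \
            if expected.constraint_bipartitions else frozenset()
    cotton = frozenset(cotton_genes)
    escape: frozenset = frozenset()
    if not conforms:
        # plurality cotton-only clade; ties -> lexicographically smaller set
        candidates = [s for s in clade_sets if s and s <= cotton]
        best_size = max((len(s) for s in candidates), default=0)
        tied = sorted((s for s in candidates if len(s) == best_size),
                      key=lambda s: sorted(s))
        best = tied[0] if tied else frozenset()
        escape = cotton - best
        if not escape:
            # cotton monophyly holds but a template-resolved constraint
            # fails; record the genes of the first missing constraint
            missing = next(c for c in sorted(
                expected.constraint_bipartitions, key=lambda s: sorted(s))
                if c not in clade_sets)
            escape = frozenset(missing)
    support = None
    if conforms and cotton in clade_sets:
        for node, s in clades.items():
            if s == cotton and getattr(node, "support", None) is not None:
                support = node.support
    return ConformanceRecord(group_id=expected.group_id, method=method,
                             aligner=aligner, conforms=conforms,
                             escape_pattern=escape, support=support)


@dataclass
class MethodSummary:
    counts: dict                 # method -> conforming count
    total: int
    percentages: dict            # method -> % (1 decimal, half-up)
    nonconforming_percentages: dict = field(default_factory=dict)
    subset: tuple = ()
    subset_average: float | None = None

    @property
    def best_method(self) -> str:
        return max(self.percentages, key=lambda m: (self.percentages[m], m))

    @property
    def best_complement(self) -> float:
        """Share of trees not conforming even under the best method."""
        return round_half_up(100.0 - self.percentages[self.best_method], 1)


def summarize_methods(records, method_subset=None) -> MethodSummary:
    """Per-method conforming counts and percentages (1 decimal, half-up).

    ``method_subset`` additionally averages the *printed* (rounded)
    per-method percentages over the named methods.
    """
    records = list(records)
    if not records:
        raise ValueError("no conformance records")
    methods = sorted({r.method for r in records})
    counts, totals, percentages = {}, {}, {}
    for m in methods:
        recs = [r for r in records if r.method == m]
        counts[m] = sum(r.conforms for r in recs)
        totals[m] = len(recs)
        percentages[m] = percent(counts[m], totals[m], 1)
    total = totals[methods[0]]
    if len(set(totals.values())) > 1:
        logger.warning("methods cover different group counts: %s", totals)
    noncf = {m: round_half_up(100.0 - percentages[m], 1) for m in methods}
    subset_avg = None
    subset = tuple(method_subset) if method_subset else ()
    if subset:
        missing = set(subset) - set(methods)
        if missing:
            raise ValueError(f"subset methods absent from records: {sorted(missing)}")
        subset_avg = round_half_up(
            float(np.mean([percentages[m] for m in subset])), 1)
    return MethodSummary(counts=counts, total=total, percentages=percentages,
                         nonconforming_percentages=noncf, subset=subset,
                         subset_average=subset_avg)


def group_agreement_classes(records, method_set=None) -> dict:
    """Group-level agreement over a method set.

    Returns counts and printed-style percentages of groups whose trees all
    conform, all fail, or are mixed.  Every group must have exactly one
    record per method in the set.
    """
    records = list(records)
    methods = set(method_set) if method_set else {r.method for r in records}
    by_group: dict[str, dict] = {}
    for r in records:
        if r.method in methods:
            by_group.setdefault(r.group_id, {})[r.method] = r.conforms
    counts = {"all_conform": 0, "all_nonconform": 0, "mixed": 0}
    for gid, verdicts in by_group.items():
        if set(verdicts) != methods:
            raise ValueError(f"group {gid} lacks records for some methods")
        vals = set(verdicts.values())
        if vals == {True}:
            counts["all_conform"] += 1
        elif vals == {False}:
            counts["all_nonconform"] += 1
        else:
            counts["mixed"] += 1
    n = len(by_group)
    if n == 0:
        raise ValueError("no groups covered by the requested methods")
    pct = {k: adaptive_percent(v, n) for k, v in counts.items()}
    return {"methods": tuple(sorted(methods)), "n_groups": n,
            "counts": counts, "percentages": pct}


def copy_number_from_hits(hit_table, evalue_cutoff: float) -> dict:
    """Distinct-subject homolog counts per query from BLAST outfmt-6 hits.

    Self-hits (query == subject) are excluded; duplicate query-subject rows
    count once; malformed rows are skipped (count logged).
    """
    if isinstance(hit_table, pd.DataFrame):
        df = hit_table.copy()
    else:
        df = pd.read_csv(hit_table, sep="\t", header=None,
                         names=BLAST6_COLUMNS, dtype=str,
                         comment="#")
    n0 = len(df)
    df["evalue"] = pd.to_numeric(df["evalue"], errors="coerce")
    df = df.dropna(subset=["qseqid", "sseqid", "evalue"])
    skipped = n0 - len(df)
    if skipped:
        logger.warning("skipped %d malformed hit rows", skipped)
    df = df[(df["evalue"] < evalue_cutoff) & (df["qseqid"] != df["sseqid"])]
    return df.groupby("qseqid")["sseqid"].nunique().to_dict()


DEFAULT_BIN_EDGES = (0, 5, 10, 20, 50, np.inf)


def stratify_by_copy_number(records, counts: dict,
                            bin_edges=DEFAULT_BIN_EDGES) -> pd.DataFrame:
    """Per-copy-number-bin, per-method conformance percentages.

    ``counts`` maps group id to whole-genome homolog copy number; bins are
    half-open [lo, hi).  Returns a DataFrame (rows methods, columns bins)
    of percentages (1 decimal, half-up); empty cells are NaN.
    """
    records = list(records)
    missing = {r.group_id for r in records} - set(counts)
    if missing:
        raise ValueError(f"copy count missing for groups: {sorted(missing)[:5]}")
    edges = list(bin_edges)
    labels = [f"[{int(lo)}, {int(hi) if np.isfinite(hi) else 'inf'})"
              for lo, hi in zip(edges[:-1], edges[1:])]

    def bin_of(c):
        for lab, (lo, hi) in zip(labels, zip(edges[:-1], edges[1:])):
            if lo <= c < hi:
                return lab
        raise ValueError(f"copy count {c} outside bins")

    methods = sorted({r.method for r in records})
    table = pd.DataFrame(index=methods, columns=labels, dtype=float)
    for m in methods:
        for lab in labels:
            recs = [r for r in records
                    if r.method == m and bin_of(counts[r.group_id]) == lab]
            if recs:
                table.loc[m, lab] = percent(sum(r.conforms for r in recs),
                                            len(recs), 1)
    return table
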