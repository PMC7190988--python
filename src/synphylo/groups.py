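"""Collinear homolog groups and their collinearity-derived expected trees.

A syntenic group is the unit of analysis: one grape gene (outgroup), one
cacao ortholog and two or more cotton paralogs occupying collinear positions
in the three genomes.  Because the duplication (the cotton decaploidy) and
speciation events that produced the group are known, the group implies an
*expected* topology independent of any sequence data: grape outside, cacao
sister to a clade containing every cotton paralog, with the cotton-internal
structure left unresolved (a polytomy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .trees import clade_sets, tree_from_newick

logger = logging.getLogger(__name__)

GRAPE_TAG = "Vv"
CACAO_TAG = "Tc"
DEFAULT_TEMPLATE = "(VV,(TC,COTTON_POLYTOMY));"

__all__ = [
    "SyntenicGroup", "ExpectedTree", "read_group_table", "filter_groups",
    "build_expected_tree", "DEFAULT_TEMPLATE",
]


@dataclass
class SyntenicGroup:
    """One collinear homolog group: 1 grape + 1 cacao + >=2 cotton genes."""

    group_id: str
    grape_gene: str
    cacao_gene: str
    cotton_genes: list[str]
    cotton_tags: list[str] = field(default_factory=list)
    positions: dict = field(default_factory=dict)  # gene id -> (chrom, pos)

    def __post_init__(self):
        if not self.cotton_tags:
            self.cotton_tags = ["Gr"] * len(self.cotton_genes)
        if len(self.cotton_tags) != len(self.cotton_genes):
            raise ValueError("cotton_tags must parallel cotton_genes")
        self.validate()

    def validate(self) -> None:
        if not self.grape_gene or not self.cacao_gene:
            raise ValueError(f"group {self.group_id}: missing grape or cacao gene")
        if len(self.cotton_genes) < 2:
            raise ValueError(f"group {self.group_id}: needs >=2 cotton genes")
        ids = self.all_genes()
        if len(set(ids)) != len(ids):
            raise ValueError(f"group {self.group_id}: duplicate gene ids")

    def all_genes(self) -> list[str]:
        return [self.grape_gene, self.cacao_gene, *self.cotton_genes]

    @property
    def n_cotton(self) -> int:
        return len(self.cotton_genes)


@dataclass
class ExpectedTree:
    """Rooted expected topology plus the splits that define conformance."""

    tree: dendropy.Tree
    constraint_bipartitions: set[frozenset]
    group_id: str = ""


def read_group_table(path) -> list[SyntenicGroup]:
    """Read a group table TSV (group_id, species, gene_id[, chrom, pos]).

    Malformed rows and invalid groups are logged (with 1-based data line
    numbers for rows) and skipped; the function never raises on bad data,
    only on a missing file or missing required columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"group_id", "species", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"group table missing columns: {sorted(missing)}")
    if df.empty:
        logger.warning("group table %s is empty", path)
        return []

    bad_rows = df[sorted(required)].isna().any(axis=1)
    for idx in df.index[bad_rows]:
        logger.warning("group table row %d: missing field, skipped", idx + 1)
    df = df[~bad_rows]

    groups: list[SyntenicGroup] = []
    seen_ids: set[str] = set()
    for gid, sub in df.groupby("group_id", sort=False):
        grape = list(sub.loc[sub["species"] == GRAPE_TAG, "gene_id"])
        cacao = list(sub.loc[sub["species"] == CACAO_TAG, "gene_id"])
        cotton = sub[~sub["species"].isin([GRAPE_TAG, CACAO_TAG])]
        if len(grape) != 1 or len(cacao) != 1:
            logger.warning("group %s rejected: needs exactly one %s and one %s gene",
                           gid, GRAPE_TAG, CACAO_TAG)
            continue
        genes = grape + cacao + list(cotton["gene_id"])
        if seen_ids.intersection(genes):
            logger.warning("group %s rejected: gene id reused across groups", gid)
            continue
        positions = {}
        if {"chrom", "pos"}.issubset(sub.columns):
            for _, row in sub.iterrows():
                if pd.notna(row.get("chrom")) and pd.notna(row.get("pos")):
                    positions[row["gene_id"]] = (row["chrom"], float(row["pos"]))
        try:
            group = SyntenicGroup(
                group_id=str(gid), grape_gene=grape[0], cacao_gene=cacao[0],
                cotton_genes=list(cotton["gene_id"]),
                cotton_tags=list(cotton["species"]),
                positions=positions,
            )
        except ValueError as exc:
            logger.warning("group %s rejected: %s", gid, exc)
            continue
        seen_ids.update(genes)
        groups.append(group)
    return groups


def filter_groups(groups: list[SyntenicGroup], min_cotton: int) -> list[SyntenicGroup]:
    """Keep groups with at least ``min_cotton`` cotton paralogs, order preserved."""
    if min_cotton < 1:
        raise ValueError("min_cotton must be >= 1")
    return [g for g in groups if g.n_cotton >= min_cotton]


def _placeholder_genes(placeholder: str, group: SyntenicGroup) -> list[str]:
    """Genes a template leaf placeholder expands to, or [] when unknown."""
    tag = placeholder.upper()
    if tag == "VV":
        return [group.grape_gene]
    if tag == "TC":
        return [group.cacao_gene]
    if tag in ("COTTON_POLYTOMY", "COTTON"):
        return list(group.cotton_genes)
    return [g for g, t in zip(group.cotton_genes, group.cotton_tags)
            if t.upper() == tag]


def build_expected_tree(group: SyntenicGroup,
                        template: str | None = None) -> ExpectedTree:
    """Instantiate the expected topology for a group from a Newick template.

    Template leaves are species placeholders (VV, TC, COTTON_POLYTOMY, or a
    cotton subgenome tag such as AA / AD-AT); a placeholder matching several
    genes expands to a polytomy of those genes.  The default template is the
    three-species decaploidy topology ``(VV,(TC,COTTON_POLYTOMY));``.

    The constraint bipartitions are every non-trivial clade of the expanded
    template; for the default template that is exactly the cotton clade.
    """
    template = template or DEFAULT_TEMPLATE
    tree = tree_from_newick(template, rooted=True)

    covered: set[str] = set()
    for leaf in list(tree.leaf_node_iter()):
        genes = _placeholder_genes(leaf.taxon.label, group)
        if not genes:
            raise ValueError(
                f"template placeholder {leaf.taxon.label!r} matches no gene "
                f"in group {group.group_id}")
        covered.update(genes)
        tns = tree.taxon_namespace
        if len(genes) == 1:
            leaf.taxon = tns.new_taxon(genes[0])
        else:
            leaf.taxon = None
            for gene in genes:
                leaf.new_child(taxon=tns.new_taxon(gene), edge_length=None)
    missing = set(group.all_genes()) - covered
    if missing:
        tags = sorted({t for g, t in zip(group.cotton_genes, group.cotton_tags)
                       if g in missing})
        raise ValueError(
            f"group {group.group_id}: species tag(s) {tags} not covered by template")
    tree.is_rooted = True
    constraints = clade_sets(tree, nontrivial=True)
    return ExpectedTree(tree=tree, constraint_bipartitions=constraints,
                        group_id=group.group_id)
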