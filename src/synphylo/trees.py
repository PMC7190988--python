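"""Thin helpers over dendropy trees.

Trees throughout the package are ``dendropy.Tree`` objects; these functions
centralise Newick I/O (underscores preserved), leaf-set/bipartition
extraction and outgroup rooting so that inference, conformance testing and
simulation all speak the same dialect.
"""

from __future__ import annotations

import dendropy

__all__ = [
    "tree_from_newick",
    "to_newick",
    "leaf_labels",
    "clade_sets",
    "unrooted_splits",
    "root_by_outgroup",
    "build_star_tree",
]


def tree_from_newick(newick: str, rooted: bool | None = None) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    if rooted is not None:
        tree.is_rooted = rooted
    return tree


def to_newick(tree: dendropy.Tree, **kwargs) -> str:
    return tree.as_string(
        schema="newick", unquoted_underscores=True,
        suppress_rooting=kwargs.pop("suppress_rooting", True), **kwargs
    ).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _node_leafsets(tree: dendropy.Tree) -> dict:
    sets = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*(sets[c] for c in node.child_nodes()))
            sets[node] = s
    return sets


def clade_sets(tree: dendropy.Tree, nontrivial: bool = True) -> set[frozenset]:
    """Leaf-label sets of the clades of a rooted tree.

    With ``nontrivial`` only clades with 2 <= size <= n-2 leaves are
    returned (single leaves and complements of single leaves carry no
    topological information once the root is fixed by an outgroup).
    """
    sets = _node_leafsets(tree)
    n = len(sets[tree.seed_node])
    out = set()
    for node, s in sets.items():
        if node is tree.seed_node:
            continue
        if nontrivial and not (2 <= len(s) <= n - 2):
            continue
        out.add(s)
    return out


def unrooted_splits(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions of the tree read as unrooted.

    Each split is normalised to the side *not* containing the
    lexicographically smallest leaf label, so sets compare across
    differently rooted representations of the same topology.
    """
    sets = _node_leafsets(tree)
    all_leaves = sets[tree.seed_node]
    ref = min(all_leaves)
    n = len(all_leaves)
    out = set()
    for node, s in sets.items():
        side = all_leaves - s if ref in s else s
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def root_by_outgroup(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    """Root a (copy of the) tree on the outgroup leaf's pendant edge.

    The root is placed at the midpoint of that edge; all other
    relationships are preserved.  Raises ``ValueError`` when the label is
    absent.
    """
    tree = tree.clone(depth=1)
    node = tree.find_node_with_taxon_label(outgroup_label)
    if node is None:
        raise ValueError(f"outgroup label {outgroup_label!r} not found in tree")
    # already rooted directly above the outgroup: nothing to do
    root_children = tree.seed_node.child_nodes()
    if len(root_children) == 2 and node in root_children:
        tree.is_rooted = True
        return tree
    length = node.edge.length
    halves = (length / 2.0, length / 2.0) if length is not None else (None, None)
    tree.reroot_at_edge(node.edge, length1=halves[0], length2=halves[1],
                        suppress_unifurcations=True)
    tree.is_rooted = True
    return tree


def build_star_tree(labels, branch_length: float | None = None) -> dendropy.Tree:
    """Star (single polytomy) tree over the given leaf labels."""
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    for lab in labels:
        taxon = tns.new_taxon(lab)
        tree.seed_node.new_child(taxon=taxon, edge_length=branch_length)
    tree.is_rooted = True
    return tree
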