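"""From-scratch implementations of the five tree-construction methods.

Distance methods (NJ, UPGMA, ME) work from a pairwise distance matrix;
character methods (MP, ML) work directly on the alignment.  All methods are
bit-deterministic: every tie is broken toward the lexicographically
smallest leaf label (or first enumeration order), and all searches are
plain hill climbs with documented tolerances.

Alignments are passed as ``{label: row}`` mappings (or any object with a
``.rows`` attribute, such as ``CodonAlignment``); trees are dendropy trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar, nnls

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix", "pairwise_distance", "build_nj", "build_upgma",
    "build_me", "fitch_score", "build_mp", "log_likelihood", "build_ml",
    "bootstrap_support", "build_tree",
]

_MISSING_CHARS = set("-.?*")
_NUC_ALPHABET = set("ACGT")


def _as_rows(aln) -> dict:
    rows = getattr(aln, "rows", aln)
    if not isinstance(rows, dict):
        raise TypeError("alignment must be a {label: row} mapping or have .rows")
    return rows


def _is_nucleotide(rows: dict) -> bool:
    chars = set("".join(rows.values()).upper()) - _MISSING_CHARS - {"N"}
    return chars <= _NUC_ALPHABET


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with saturation flags."""

    labels: list[str]
    matrix: np.ndarray
    model: str = "p"
    saturated: np.ndarray = field(default=None)  # bool matrix; True -> nan entry

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if self.saturated is None:
            self.saturated = np.zeros((n, n), dtype=bool)
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.matrix) < 0:
                logger.warning("negative distances clamped to 0")
                self.matrix = np.maximum(self.matrix, 0.0)

    def capped(self, factor: float = 1.5) -> "DistanceMatrix":
        """Copy with saturated (nan) entries replaced by factor * max finite."""
        m = self.matrix.copy()
        if np.isnan(m).any():
            cap = np.nanmax(m) * factor if np.isfinite(np.nanmax(m)) else 1.0
            m[np.isnan(m)] = cap
        return DistanceMatrix(list(self.labels), m, self.model,
                              self.saturated.copy())


def pairwise_distance(aln, model: str = "p") -> DistanceMatrix:
    """p-distance / Poisson / Jukes-Cantor distances with pairwise deletion.

    Columns where either sequence has a gap or ambiguity character are
    skipped for that pair.  Entries beyond the model's domain (p >= 3/4 for
    JC and Poisson p >= 1) are set to nan and flagged saturated.
    """
    if model not in ("p", "poisson", "jc"):
        raise ValueError(f"unknown distance model {model!r}")
    rows = _as_rows(aln)
    labels = list(rows)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    seqs = [rows[lab].upper() for lab in labels]
    arrs = [np.frombuffer(s.encode(), dtype="S1") for s in seqs]
    missing = _MISSING_CHARS | ({"N"} if _is_nucleotide(rows) else {"X"})
    valid = [~np.isin(a, [c.encode() for c in missing]) for a in arrs]
    n = len(labels)
    mat = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns for pair {labels[i]}, {labels[j]}")
            p = float((arrs[i][ok] != arrs[j][ok]).sum()) / m
            if model == "p":
                d = p
            elif model == "poisson":
                d = -np.log(1.0 - p) if p < 1.0 else np.nan
            else:  # jc
                d = -0.75 * np.log(1.0 - 4.0 * p / 3.0) if p < 0.75 else np.nan
            mat[i, j] = mat[j, i] = d
            if np.isnan(d):
                sat[i, j] = sat[j, i] = True
                logger.warning("saturated distance for pair %s, %s",
                               labels[i], labels[j])
    return DistanceMatrix(labels, mat, model, sat)


# ---------------------------------------------------------------------------
# agglomerative methods


def _dist_dicts(D: DistanceMatrix) -> dict:
    d = {}
    for i, a in enumerate(D.labels):
        for j, b in enumerate(D.labels):
            if i < j:
                key = (min(a, b), max(a, b))
                d[key] = D.matrix[i, j]
    return d


def _get(d, a, b):
    return d[(a, b) if a < b else (b, a)]


def _set(d, a, b, v):
    d[(a, b) if a < b else (b, a)] = v


def build_nj(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    Ties in the Q criterion are broken by the lexicographically smallest
    (cluster, cluster) key pair; negative branch lengths are clamped to 0
    (count stored on the tree as ``n_clamped_branches``).
    """
    if len(D.labels) < 3:
        raise ValueError("NJ needs at least 3 taxa")
    if np.isnan(D.matrix).any():
        raise ValueError("distance matrix contains saturated entries; "
                         "use .capped() first")
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = {lab: dendropy.Node(taxon=tns.new_taxon(lab))
             for lab in sorted(D.labels)}
    d = _dist_dicts(D)
    active = sorted(D.labels)  # cluster keys = min leaf label in cluster
    clamped = 0

    def clamp(x):
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        rsum = {a: sum(_get(d, a, b) for b in active if b != a) for a in active}
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                a, b = active[ai], active[aj]
                q = (r - 2) * _get(d, a, b) - rsum[a] - rsum[b]
                if best is None or q < best[0] - 1e-15:
                    best = (q, a, b)
        _, a, b = best
        dab = _get(d, a, b)
        la = 0.5 * dab + (rsum[a] - rsum[b]) / (2.0 * (r - 2))
        lb = dab - la
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        nodes[a].edge.length = clamp(la)
        parent.add_child(nodes[b])
        nodes[b].edge.length = clamp(lb)
        new_key = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (_get(d, a, c) + _get(d, b, c) - dab)
            _set(d, new_key, c, duc)
        active = sorted(set(active) - {a, b} | {new_key})
        nodes[new_key] = parent

    a, b, c = active
    dab, dac, dbc = _get(d, a, b), _get(d, a, c), _get(d, b, c)
    center = tree.seed_node
    for key, length in ((a, 0.5 * (dab + dac - dbc)),
                        (b, 0.5 * (dab + dbc - dac)),
                        (c, 0.5 * (dac + dbc - dab))):
        center.add_child(nodes[key])
        nodes[key].edge.length = clamp(length)
    tree.is_rooted = False
    tree.n_clamped_branches = clamped
    if clamped:
        logger.warning("NJ clamped %d negative branch length(s) to 0", clamped)
    return tree


def build_upgma(D: DistanceMatrix) -> dendropy.Tree:
    """Size-weighted average-linkage agglomeration; rooted ultrametric tree.

    Node height = cluster distance / 2; ties broken lexicographically.
    """
    if len(D.labels) < 2:
        raise ValueError("UPGMA needs at least 2 taxa")
    if np.isnan(D.matrix).any():
        raise ValueError("distance matrix contains saturated entries; "
                         "use .capped() first")
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = {lab: dendropy.Node(taxon=tns.new_taxon(lab))
             for lab in sorted(D.labels)}
    heights = {lab: 0.0 for lab in D.labels}
    sizes = {lab: 1 for lab in D.labels}
    d = _dist_dicts(D)
    active = sorted(D.labels)
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                a, b = active[ai], active[aj]
                v = _get(d, a, b)
                if best is None or v < best[0] - 1e-15:
                    best = (v, a, b)
        v, a, b = best
        parent = dendropy.Node()
        h = v / 2.0
        for key in (a, b):
            parent.add_child(nodes[key])
            nodes[key].edge.length = max(h - heights[key], 0.0)
        new_key = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            duc = (sizes[a] * _get(d, a, c) + sizes[b] * _get(d, b, c)) \
                / (sizes[a] + sizes[b])
            _set(d, new_key, c, duc)
        sizes[new_key] = sizes[a] + sizes[b]
        heights[new_key] = h
        nodes[new_key] = parent
        active = sorted(set(active) - {a, b} | {new_key})
    root = nodes[active[0]]
    tree.seed_node = root
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# NNI machinery (shared by ME, MP, ML searches)


def _internal_child_nodes(tree):
    return [nd for nd in tree.preorder_node_iter()
            if nd is not tree.seed_node and not nd.is_leaf()]


def _nni_swap_pairs(tree):
    """Child-node pairs whose exchange performs each NNI move.

    For the internal edge above node v (parent u), the four subtrees are
    v's two children (a, b) and u's other neighborhood; exchanging a or b
    with u's first other child realises the two alternative topologies.
    """
    pairs = []
    for v in _internal_child_nodes(tree):
        u = v.parent_node
        others = [c for c in u.child_nodes() if c is not v]
        if not others:
            continue
        x = others[0]
        ch = v.child_nodes()
        if len(ch) != 2:
            continue
        pairs.append((ch[0], x))
        pairs.append((ch[1], x))
    return pairs


def _swap_nodes(n1, n2):
    p1, p2 = n1.parent_node, n2.parent_node
    i1 = p1.child_nodes().index(n1)
    i2 = p2.child_nodes().index(n2)
    p1.remove_child(n1)
    p2.remove_child(n2)
    p1.insert_child(i1, n2)
    p2.insert_child(i2, n1)


# ---------------------------------------------------------------------------
# minimum evolution


def _edge_nodes(tree):
    return [nd for nd in tree.preorder_node_iter() if nd is not tree.seed_node]


def ols_branch_lengths(tree: dendropy.Tree, D: DistanceMatrix) -> float:
    """Fit non-negative OLS branch lengths for a fixed topology in place.

    Returns the total tree length (sum of fitted branch lengths).
    """
    idx = {lab: i for i, lab in enumerate(D.labels)}
    edges = _edge_nodes(tree)
    leafsets = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = frozenset([node.taxon.label])
        else:
            leafsets[node] = frozenset().union(
                *(leafsets[c] for c in node.child_nodes()))
    pairs = [(a, b) for i, a in enumerate(D.labels)
             for b in D.labels[i + 1:]]
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([D.matrix[idx[a], idx[b]] for a, b in pairs])
    for e, node in enumerate(edges):
        s = leafsets[node]
        for p, (a, b) in enumerate(pairs):
            if (a in s) != (b in s):
                A[p, e] = 1.0
    x, _ = nnls(A, y)
    for e, node in enumerate(edges):
        node.edge.length = float(x[e])
    return float(x.sum())


def build_me(D: DistanceMatrix) -> dendropy.Tree:
    """Minimum evolution: NJ start, OLS lengths, NNI descent on total length."""
    tree = build_nj(D)
    if len(D.labels) < 4:
        return tree
    best = ols_branch_lengths(tree, D)
    improved = True
    while improved:
        improved = False
        for n1, n2 in _nni_swap_pairs(tree):
            _swap_nodes(n1, n2)
            total = ols_branch_lengths(tree, D)
            if total < best - 1e-12:
                best = total
                improved = True
                break
            _swap_nodes(n1, n2)
            ols_branch_lengths(tree, D)
    return tree


# ---------------------------------------------------------------------------
# parsimony


def _compress_columns(rows: dict) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Unique columns + weights.  Returns (labels, columns array, weights)."""
    labels = list(rows)
    mat = np.array([list(rows[lab]) for lab in labels])
    cols, weights = np.unique(mat, axis=1, return_counts=True)
    return labels, cols, weights


def _char_masks(cols: np.ndarray, labels: list[str], nucleotide: bool) -> dict:
    """Per-leaf bitmask arrays over compressed columns; missing -> all bits."""
    chars = sorted(set(cols.ravel().tolist()))
    missing = _MISSING_CHARS | ({"N", "n"} if nucleotide else {"X", "x"})
    symbols = [c for c in chars if c.upper() not in missing and c not in missing]
    canon = sorted({c.upper() for c in symbols})
    if len(canon) > 32:
        raise ValueError("alphabet too large for parsimony bitmasks")
    bit = {c: np.uint32(1 << i) for i, c in enumerate(canon)}
    full = np.uint32((1 << len(canon)) - 1) if canon else np.uint32(1)
    masks = {}
    for i, lab in enumerate(labels):
        row = cols[i]
        m = np.empty(cols.shape[1], dtype=np.uint32)
        for j, ch in enumerate(row):
            m[j] = bit.get(ch.upper(), full)
        masks[lab] = m
    return masks


def _nested_from_tree(tree: dendropy.Tree):
    def rec(node):
        if node.is_leaf():
            return node.taxon.label
        return tuple(rec(c) for c in node.child_nodes())
    return rec(tree.seed_node)


def _binarise_root(nested):
    """((c1,c2),c3) form for a 3-child root; parsimony is rooting-invariant."""
    if isinstance(nested, tuple) and len(nested) == 3:
        return ((nested[0], nested[1]), nested[2])
    return nested


def _fitch_on_nested(nested, masks: dict, weights: np.ndarray) -> int:
    total = 0

    def rec(node):
        nonlocal total
        if isinstance(node, str):
            return masks[node]
        acc = rec(node[0])
        for child in node[1:]:
            m = rec(child)
            inter = acc & m
            disjoint = inter == 0
            total += int(weights[disjoint].sum())
            acc = np.where(disjoint, acc | m, inter)
        return acc

    rec(_binarise_root(nested))
    return total


def fitch_score(tree: dendropy.Tree, aln) -> int:
    """Fitch small-parsimony count summed over columns; gaps are missing."""
    rows = _as_rows(aln)
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = labels - set(rows)
    if missing:
        raise ValueError(f"leaves missing from alignment: {sorted(missing)}")
    sub = {lab: rows[lab] for lab in rows if lab in labels}
    labs, cols, weights = _compress_columns(sub)
    masks = _char_masks(cols, labs, _is_nucleotide(sub))
    return _fitch_on_nested(_nested_from_tree(tree), masks, weights)


def _enumerate_nested(labels: list[str]):
    """All unrooted leaf-labeled topologies as nested tuples (3-child root)."""
    trees = [tuple(labels[:3])]
    for x in labels[3:]:
        nxt = []
        for t in trees:
            nxt.extend(_insert_leaf(t, x))
        trees = nxt
    return trees


def _insert_leaf(tree: tuple, x: str):
    out = []
    for i, child in enumerate(tree):
        out.append(tree[:i] + ((child, x),) + tree[i + 1:])
        if isinstance(child, tuple):
            for sub in _insert_leaf(child, x):
                out.append(tree[:i] + (sub,) + tree[i + 1:])
    return out


def _tree_from_nested(nested, tns=None) -> dendropy.Tree:
    tns = tns or dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)

    def rec(node, parent):
        if isinstance(node, str):
            parent.new_child(taxon=tns.require_taxon(label=node))
        else:
            child = parent.new_child()
            for sub in node:
                rec(sub, child)

    for sub in nested:
        rec(sub, tree.seed_node)
    tree.is_rooted = False
    return tree


def build_mp(aln, max_exhaustive: int = 7) -> dendropy.Tree:
    """Maximum parsimony tree.

    Exhaustive search over all unrooted topologies when the taxon count is
    at most ``max_exhaustive`` (first minimal tree in enumeration order is
    returned and the co-optimal count recorded); otherwise NJ start plus
    NNI hill climbing.  The result carries ``parsimony_score`` and, for
    exhaustive searches, ``co_optimal_count`` attributes; branch lengths
    are left unset (parsimony estimates none).
    """
    rows = _as_rows(aln)
    if len(rows) < 4:
        raise ValueError("MP needs at least 4 taxa")
    labs, cols, weights = _compress_columns(rows)
    masks = _char_masks(cols, labs, _is_nucleotide(rows))
    labels = sorted(rows)
    if len(labels) <= max_exhaustive:
        best_tree, best_score, n_opt = None, None, 0
        for nested in _enumerate_nested(labels):
            score = _fitch_on_nested(nested, masks, weights)
            if best_score is None or score < best_score:
                best_tree, best_score, n_opt = nested, score, 1
            elif score == best_score:
                n_opt += 1
        tree = _tree_from_nested(best_tree)
        tree.parsimony_score = best_score
        tree.co_optimal_count = n_opt
        return tree
    D = pairwise_distance(rows, "p")
    tree = build_nj(D.capped())
    best = _fitch_on_nested(_nested_from_tree(tree), masks, weights)
    improved = True
    while improved:
        improved = False
        for n1, n2 in _nni_swap_pairs(tree):
            _swap_nodes(n1, n2)
            score = _fitch_on_nested(_nested_from_tree(tree), masks, weights)
            if score < best:
                best = score
                improved = True
                break
            _swap_nodes(n1, n2)
    for node in _edge_nodes(tree):
        node.edge.length = None
    tree.parsimony_score = best
    tree.co_optimal_count = None
    return tree


# ---------------------------------------------------------------------------
# likelihood


_NUC_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _nuc_rate_matrix(model: str, kappa: float) -> np.ndarray:
    q = np.ones((4, 4))
    if model == "hky":
        for i in range(4):
            for j in range(4):
                pur = (i in (0, 2), j in (0, 2))
                if i != j and pur[0] == pur[1]:
                    q[i, j] = kappa
    elif model != "jc":
        raise ValueError(f"unknown nucleotide model {model!r}")
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -np.mean(np.diag(q))
    return q / rate


def _nuc_probs(q: np.ndarray, t: float) -> np.ndarray:
    evals, evecs = np.linalg.eigh(q)
    p = (evecs * np.exp(evals * t)) @ evecs.T
    np.maximum(p, 0.0, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _leaf_partials(cols: np.ndarray, labels: list[str]) -> dict:
    partials = {}
    for i, lab in enumerate(labels):
        m = np.ones((cols.shape[1], 4))
        for j, ch in enumerate(cols[i]):
            k = _NUC_INDEX.get(ch.upper())
            if k is not None:
                m[j] = 0.0
                m[j, k] = 1.0
        partials[lab] = m
    return partials


def log_likelihood(tree: dendropy.Tree, aln, model: str = "jc",
                   kappa: float = 2.0) -> float:
    """Felsenstein-pruning log likelihood of a nucleotide alignment.

    Gap/ambiguity cells contribute partial likelihood 1 in every state.
    Equal base frequencies; branch lengths must be set on every edge.
    """
    rows = _as_rows(aln)
    labs, cols, weights = _compress_columns(rows)
    leaf_p = _leaf_partials(cols, labs)
    q = _nuc_rate_matrix(model, kappa)
    ncols = cols.shape[1]
    logscale = np.zeros(ncols)
    partials = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            partials[node] = leaf_p[node.taxon.label]
            continue
        acc = np.ones((ncols, 4))
        for child in node.child_nodes():
            t = child.edge.length
            if t is None:
                raise ValueError("every branch needs a length for likelihood")
            p = _nuc_probs(q, max(t, 0.0))
            acc *= partials[child] @ p.T
        mx = acc.max(axis=1)
        mx[mx == 0] = 1.0
        logscale += np.log(mx)
        partials[node] = acc / mx[:, None]
    site = partials[tree.seed_node].mean(axis=1)  # pi = 1/4
    return float(np.sum(weights * (np.log(site) + logscale)))


def _optimize_branch_lengths(tree, rows, model, kappa, sweeps=2):
    for _ in range(sweeps):
        for node in _edge_nodes(tree):
            def f(t, node=node):
                node.edge.length = t
                return -log_likelihood(tree, rows, model, kappa)
            res = minimize_scalar(f, bounds=(1e-9, 10.0), method="bounded",
                                  options={"xatol": 1e-6})
            node.edge.length = float(res.x)
    return log_likelihood(tree, rows, model, kappa)


def build_ml(aln, model: str = "jc", kappa: float = 2.0,
             search: str = "nni") -> dendropy.Tree:
    """Maximum-likelihood tree: NJ start, scalar branch-length optimisation
    to 1e-6, NNI accepted when lnL improves by more than 1e-8."""
    rows = _as_rows(aln)
    if len(rows) < 3:
        raise ValueError("ML needs at least 3 taxa")
    D = pairwise_distance(rows, "jc").capped()
    tree = build_nj(D)
    for node in _edge_nodes(tree):
        if node.edge.length is None or node.edge.length <= 0:
            node.edge.length = 1e-6
    best = _optimize_branch_lengths(tree, rows, model, kappa)
    if search == "nni":
        improved = True
        while improved:
            improved = False
            for n1, n2 in _nni_swap_pairs(tree):
                saved = {nd: nd.edge.length for nd in _edge_nodes(tree)}
                _swap_nodes(n1, n2)
                lnl = _optimize_branch_lengths(tree, rows, model, kappa,
                                               sweeps=1)
                if lnl > best + 1e-8:
                    best = _optimize_branch_lengths(tree, rows, model, kappa)
                    improved = True
                    break
                _swap_nodes(n1, n2)
                for nd, ln in saved.items():
                    nd.edge.length = ln
    tree.log_likelihood = best
    return tree


# ---------------------------------------------------------------------------
# dispatch + bootstrap


def build_tree(aln, method: str, dist_model: str = "jc", **kwargs) -> dendropy.Tree:
    """Build a tree from an alignment with one of nj/upgma/me/mp/ml."""
    method = method.lower()
    if method in ("nj", "upgma", "me"):
        rows = _as_rows(aln)
        model = dist_model if _is_nucleotide(rows) else "poisson"
        D = pairwise_distance(rows, model).capped()
        return {"nj": build_nj, "upgma": build_upgma, "me": build_me}[method](D)
    if method == "mp":
        return build_mp(aln, **kwargs)
    if method == "ml":
        return build_ml(aln, **kwargs)
    raise ValueError(f"unknown method {method!r}")


def bootstrap_support(aln, method: str, n_reps: int = 1000, seed: int = 0,
                      codon_blocks: bool | None = None,
                      **kwargs) -> dendropy.Tree:
    """Bootstrap supports (%) on the point-estimate tree's bipartitions.

    Columns are resampled with replacement; codon alignments are resampled
    in codon-triplet blocks to preserve frame (auto-detected from a
    ``codon`` attribute on the alignment or column count divisible by 3 for
    nucleotide data when ``codon_blocks`` is None).
    """
    from .trees import unrooted_splits

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = _as_rows(aln)
    ncol = len(next(iter(rows.values())))
    if codon_blocks is None:
        codon_blocks = bool(getattr(aln, "is_codon", False)) or (
            _is_nucleotide(rows) and ncol % 3 == 0)
    point = build_tree(aln, method, **kwargs)
    target_splits = unrooted_splits(point)
    counts = {s: 0 for s in target_splits}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        if codon_blocks:
            picks = rng.integers(0, ncol // 3, size=ncol // 3)
            idx = (picks[:, None] * 3 + np.arange(3)).ravel()
        else:
            idx = rng.integers(0, ncol, size=ncol)
        rep_rows = {lab: "".join(np.array(list(row))[idx])
                    for lab, row in rows.items()}
        rep_tree = build_tree(rep_rows, method, **kwargs)
        rep_splits = unrooted_splits(rep_tree)
        for s in target_splits:
            if s in rep_splits:
                counts[s] += 1
    # annotate internal nodes of the point tree
    all_leaves = frozenset(lab for lab in rows)
    ref = min(all_leaves)
    leafsets = {}
    for node in point.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = frozenset([node.taxon.label])
        else:
            leafsets[node] = frozenset().union(
                *(leafsets[c] for c in node.child_nodes()))
            side = leafsets[node]
            norm = all_leaves - side if ref in side else side
            if norm in counts:
                node.support = 100.0 * counts[norm] / n_reps
                node.label = f"{node.support:g}"
    return point
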