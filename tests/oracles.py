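"""Independent brute-force oracles used by the test suite.

Everything here is implemented from first principles (enumeration, closed
forms, Biopython's genetic code) without touching the package's own
algorithmic code paths, so agreement between the two is meaningful.
"""

from __future__ import annotations

import itertools
import math
import random

import numpy as np
from Bio.Seq import Seq
from scipy.linalg import expm

# ---------------------------------------------------------------------------
# Nei-Gojobori by direct per-codon enumeration


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def ng_syn_sites(codon: str) -> float:
    aa = _aa(codon)
    s = 0.0
    for pos in range(3):
        for n in "ACGT":
            if n == codon[pos]:
                continue
            alt = codon[:pos] + n + codon[pos + 1:]
            if _aa(alt) == aa and _aa(alt) != "*":
                s += 1.0 / 3.0
    return s


def ng_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    valid, blocked = [], []
    for order in itertools.permutations(diff):
        cur, sd, nd, stop = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _aa(nxt) == "*":
                stop = True
            if _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if stop else valid).append((sd, nd))
    paths = valid or blocked
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def ng_kaks(seq1: str, seq2: str) -> tuple[float, float]:
    """(dS, dN) by direct enumeration with Jukes-Cantor correction."""
    s_sites = 0.0
    sd = nd = 0.0
    n_codons = 0
    for k in range(len(seq1) // 3):
        c1, c2 = seq1[3 * k: 3 * k + 3], seq2[3 * k: 3 * k + 3]
        if set(c1 + c2) - set("ACGT") or _aa(c1) == "*" or _aa(c2) == "*":
            continue
        n_codons += 1
        s_sites += 0.5 * (ng_syn_sites(c1) + ng_syn_sites(c2))
        a, b = ng_pair_differences(c1, c2)
        sd += a
        nd += b
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0

    def jc(p):
        return -0.75 * math.log(1 - 4 * p / 3) if p < 0.75 else float("nan")

    return jc(ps), jc(pn)


# ---------------------------------------------------------------------------
# random additive / ultrametric trees as (topology splits, distance matrix)


def random_topology(labels: list[str], rng: random.Random):
    """Random unrooted binary topology as nested tuples (3-child root)."""
    tree = tuple(labels[:3])

    def edges(t):
        out = []
        for i, c in enumerate(t):
            out.append((t, i))
            if isinstance(c, tuple):
                out.extend(edges(c))
        return out

    def replace(t, target, idx, new):
        if t is target:
            return t[:idx] + (new,) + t[idx + 1:]
        return tuple(replace(c, target, idx, new) if isinstance(c, tuple) else c
                     for c in t)

    for lab in labels[3:]:
        es = edges(tree)
        t, i = es[rng.randrange(len(es))]
        tree = replace(tree, t, i, (t[i], lab))
    return tree


def nested_splits(tree, all_labels: frozenset) -> set[frozenset]:
    """Non-trivial unrooted splits, normalised away from the min label."""
    ref = min(all_labels)
    out = set()

    def leafset(t):
        if isinstance(t, str):
            return frozenset([t])
        return frozenset().union(*(leafset(c) for c in t))

    def rec(t):
        for c in t:
            s = leafset(c)
            side = all_labels - s if ref in s else s
            if 2 <= len(side) <= len(all_labels) - 2:
                out.add(side)
            if isinstance(c, tuple):
                rec(c)

    rec(tree)
    return out


def additive_matrix(tree, rng: random.Random, lo=0.1, hi=1.0):
    """Leaf-pair path distances for random branch lengths on a nested tree."""
    dist: dict[str, dict[str, float]] = {}

    def rec(t):
        # returns {leaf: distance to this node}
        if isinstance(t, str):
            return {t: 0.0}
        below = []
        for c in t:
            d = rec(c)
            ln = rng.uniform(lo, hi)
            below.append({leaf: v + ln for leaf, v in d.items()})
        for i in range(len(below)):
            for j in range(i + 1, len(below)):
                for a, da in below[i].items():
                    for b, db in below[j].items():
                        dist.setdefault(a, {})[b] = da + db
                        dist.setdefault(b, {})[a] = da + db
        merged = {}
        for d in below:
            merged.update(d)
        return merged

    rec(tree)
    labels = sorted(dist)
    m = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                m[i, j] = dist[a][b]
    return labels, m


def random_ultrametric(labels: list[str], rng: random.Random):
    """Random ultrametric matrix via random sequential coalescence."""
    clusters = [(frozenset([lab]), 0.0) for lab in labels]
    dist: dict[frozenset, float] = {}
    height = 0.0
    while len(clusters) > 1:
        height += rng.uniform(0.1, 1.0)
        i, j = sorted(rng.sample(range(len(clusters)), 2))
        (a, _), (b, _) = clusters[i], clusters[j]
        for x in a:
            for y in b:
                dist[frozenset([x, y])] = 2.0 * height
        clusters[i] = (a | b, height)
        clusters.pop(j)
    m = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                m[i, j] = dist[frozenset([a, b])]
    return labels, m


# ---------------------------------------------------------------------------
# parsimony by exhaustive internal-state assignment


def enumerate_topologies(labels: list[str]):
    trees = [tuple(labels[:3])]
    for lab in labels[3:]:
        nxt = []
        for t in trees:
            nxt.extend(_insert(t, lab))
        trees = nxt
    return trees


def _insert(tree, lab):
    out = []
    for i, c in enumerate(tree):
        out.append(tree[:i] + ((c, lab),) + tree[i + 1:])
        if isinstance(c, tuple):
            for sub in _insert(c, lab):
                out.append(tree[:i] + (sub,) + tree[i + 1:])
    return out


def brute_force_column_score(tree, states: dict) -> int:
    """Minimum substitutions for one column by assigning every internal
    node every observed state (missing leaves excluded)."""
    observed = sorted({s for s in states.values() if s is not None})
    if not observed:
        return 0

    internals = []

    def collect(t):
        if isinstance(t, tuple):
            internals.append(t)
            for c in t:
                collect(c)

    collect(tree)

    def edges_cost(assign):
        cost = 0

        def rec(t, parent_state):
            nonlocal cost
            if isinstance(t, str):
                s = states.get(t)
                if s is not None and s != parent_state:
                    cost += 1
                return
            my = assign[id(t)]
            if parent_state is not None and my != parent_state:
                cost += 1
            for c in t:
                rec(c, my)

        root_state = assign[id(tree)]
        for c in tree:
            rec(c, root_state)
        return cost

    best = None
    for combo in itertools.product(observed, repeat=len(internals)):
        assign = {id(t): s for t, s in zip(internals, combo)}
        cost = edges_cost(assign)
        if best is None or cost < best:
            best = cost
    return best


def brute_force_parsimony(tree, rows: dict) -> int:
    ncol = len(next(iter(rows.values())))
    total = 0
    for k in range(ncol):
        states = {}
        for lab, row in rows.items():
            ch = row[k].upper()
            states[lab] = ch if ch in "ACGT" else None
        total += brute_force_column_score(tree, states)
    return total


# ---------------------------------------------------------------------------
# likelihood by explicit state enumeration (JC, scipy expm)


_jc_cache: dict = {}


def jc_p_matrix(t: float) -> np.ndarray:
    if t not in _jc_cache:
        q = np.full((4, 4), 1.0 / 3.0)
        np.fill_diagonal(q, -1.0)
        _jc_cache[t] = expm(q * t)
    return _jc_cache[t]


def enumeration_loglik(newick_nested, blens: dict, rows: dict) -> float:
    """JC log-likelihood by summing over all internal-state combinations.

    ``newick_nested`` is a nested-tuple tree; ``blens`` maps id(subtree) or
    leaf label to branch length (edge above that node).
    """
    internals = []

    def collect(t):
        if isinstance(t, tuple):
            internals.append(t)
            for c in t:
                collect(c)

    for c in newick_nested:
        collect(c)

    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    ncol = len(next(iter(rows.values())))
    total = 0.0
    for k in range(ncol):
        site_lik = 0.0
        for root_state in range(4):
            for combo in itertools.product(range(4), repeat=len(internals)):
                assign = {id(t): s for t, s in zip(internals, combo)}

                def prob(t, parent_state):
                    key = t if isinstance(t, str) else id(t)
                    p_mat = jc_p_matrix(blens[key])
                    if isinstance(t, str):
                        ch = rows[t][k].upper()
                        if ch not in idx:
                            return 1.0  # missing: marginalise
                        return p_mat[parent_state, idx[ch]]
                    my = assign[id(t)]
                    val = p_mat[parent_state, my]
                    for c in t:
                        val *= prob(c, my)
                    return val

                term = 0.25
                for c in newick_nested:
                    term *= prob(c, root_state)
                site_lik += term
        total += math.log(site_lik)
    return total
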