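"""Shared codon-level machinery.

Standard genetic code tables, Nei-Gojobori site/difference counting tables
(precomputed over all 61x61 sense-codon pairs, with multi-hit codons averaged
over stop-free minimal substitution pathways), and the Goldman-Yang one-ratio
codon rate matrix used both to simulate sequences and to fit codon models.

All rate matrices use equal codon frequencies (1/61) and are scaled so that
branch lengths are expected substitutions per codon.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

import numpy as np
from Bio.Data import CodonTable

NUCS = "TCAG"
_table = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS = tuple(sorted(_table.stop_codons))
SENSE_CODONS = tuple(
    sorted(c for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
           if c not in _table.stop_codons)
)
N_SENSE = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_TO_AA = dict(_table.forward_table)

_PURINES = {"A", "G"}


def is_transition(n1: str, n2: str) -> bool:
    """A<->G or C<->T interchange."""
    return n1 != n2 and ((n1 in _PURINES) == (n2 in _PURINES))


def translate_codon(codon: str) -> str:
    """One-letter amino acid; '*' for stop, 'X' for ambiguous."""
    if codon in CODON_TO_AA:
        return CODON_TO_AA[codon]
    if codon in _table.stop_codons:
        return "*"
    return "X"


def synonymous_fraction(codon: str) -> float:
    """Nei-Gojobori synonymous site count s for one codon.

    At each position, the fraction of the three possible single-nucleotide
    changes that are synonymous; changes to stop codons count as
    nonsynonymous.  Sums over the three positions, so s in [0, 3].
    """
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for n in "ACGT":
            if n == codon[pos]:
                continue
            alt = codon[:pos] + n + codon[pos + 1:]
            if CODON_TO_AA.get(alt) == aa:
                syn += 1
        s += syn / 3.0
    return s


SYN_SITES = np.array([synonymous_fraction(c) for c in SENSE_CODONS])


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences between two codons.

    Enumerates every ordering of the single-nucleotide steps from c1 to c2,
    drops orderings that pass through a stop codon, and averages the
    syn/nonsyn step classification over the remaining pathways with equal
    weights.  If every pathway is blocked by a stop (cannot happen between
    sense codons differing at <=2 positions; possible at 3), all pathways
    are used.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _table.stop_codons:
                through_stop = True
            aa_cur = translate_codon(cur)
            aa_nxt = translate_codon(nxt)
            if aa_cur == aa_nxt:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if through_stop else valid).append((sd, nd))
    paths = valid if valid else blocked
    sd_mean = sum(p[0] for p in paths) / len(paths)
    nd_mean = sum(p[1] for p in paths) / len(paths)
    return sd_mean, nd_mean


@lru_cache(maxsize=1)
def ng_difference_tables() -> tuple[np.ndarray, np.ndarray]:
    """(Sd, Nd) contribution tables over all sense-codon pairs, 61x61."""
    sd = np.zeros((N_SENSE, N_SENSE))
    nd = np.zeros((N_SENSE, N_SENSE))
    for i, c1 in enumerate(SENSE_CODONS):
        for j, c2 in enumerate(SENSE_CODONS):
            if i < j:
                s, n = _pathway_counts(c1, c2)
                sd[i, j] = sd[j, i] = s
                nd[i, j] = nd[j, i] = n
    return sd, nd


@lru_cache(maxsize=1)
def _gy_structure() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Masks over single-step codon pairs: (single, transition, synonymous)."""
    single = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    ts = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    syn = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    for i, c1 in enumerate(SENSE_CODONS):
        for j, c2 in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [p for p in range(3) if c1[p] != c2[p]]
            if len(diff) != 1:
                continue
            single[i, j] = True
            p = diff[0]
            ts[i, j] = is_transition(c1[p], c2[p])
            syn[i, j] = CODON_TO_AA[c1] == CODON_TO_AA[c2]
    return single, ts, syn


def gy_rate_matrix(kappa: float, omega: float) -> np.ndarray:
    """Goldman-Yang one-ratio rate matrix, equal codon frequencies.

    q_ij = 0 for multi-step changes; otherwise proportional to kappa for
    transitions, omega for nonsynonymous changes.  Scaled so the expected
    number of substitutions per codon per unit branch length is 1.  With
    equal frequencies the matrix is symmetric.
    """
    single, ts, syn = _gy_structure()
    q = np.where(single, 1.0, 0.0)
    q = np.where(single & ts, q * kappa, q)
    q = np.where(single & ~syn, q * omega, q)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -np.mean(np.diag(q))  # pi_i = 1/61
    return q / rate


def codon_transition_probs(q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t) via symmetric eigendecomposition."""
    evals, evecs = np.linalg.eigh(q)
    p = (evecs * np.exp(evals * t)) @ evecs.T
    np.maximum(p, 0.0, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


class CodonPropagator:
    """Reusable transition-probability factory for one (kappa, omega)."""

    def __init__(self, kappa: float, omega: float):
        self.kappa = kappa
        self.omega = omega
        q = gy_rate_matrix(kappa, omega)
        self._evals, self._evecs = np.linalg.eigh(q)

    def probs(self, t: float) -> np.ndarray:
        p = (self._evecs * np.exp(self._evals * t)) @ self._evecs.T
        np.maximum(p, 0.0, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


def encode_codons(cds: str) -> np.ndarray:
    """CDS string -> array of sense-codon indices; -1 for gap/ambiguous/stop."""
    n = len(cds) // 3
    out = np.empty(n, dtype=np.int64)
    for k in range(n):
        out[k] = CODON_INDEX.get(cds[3 * k: 3 * k + 3], -1)
    return out


def decode_codons(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)
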