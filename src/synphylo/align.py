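"""Codon-aware multiple alignment.

CDS rows are translated to protein, aligned progressively (k-mer distance
guide tree, profile-profile Needleman-Wunsch with affine gaps and BLOSUM62),
and back-translated so the codon alignment stays in frame: every gap run has
length divisible by 3 and degapping a row reproduces its input CDS exactly.

Two parameter presets emulate the common aligner defaults:
``clustalw-like`` (gap open 10, extend 0.2) and ``muscle-like``
(gap open 12, extend 1).  A pass-through reader accepts externally produced
FASTA alignments for users who prefer the original tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

from ._codon import translate_codon
from .treebuild import DistanceMatrix, build_upgma

__all__ = [
    "CodonAlignment", "translate_cds", "progressive_align", "backtranslate",
    "align_group_cds", "PRESETS", "read_fasta", "write_fasta", "write_phylip",
]

PRESETS = {
    "clustalw-like": {"gap_open": 10.0, "gap_extend": 0.2},
    "muscle-like": {"gap_open": 12.0, "gap_extend": 1.0},
}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_AA_ALPHABET = _BLOSUM62.alphabet  # includes X and *
_AA_INDEX = {a: i for i, a in enumerate(_AA_ALPHABET)}
_SCORE = np.array(_BLOSUM62)


@dataclass
class CodonAlignment:
    """In-frame aligned CDS rows (gaps as '-'), column count divisible by 3."""

    rows: dict = field(default_factory=dict)  # gene id -> aligned CDS
    is_codon: bool = True

    def __post_init__(self):
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have equal length")
        if lengths and next(iter(lengths)) % 3:
            raise ValueError("alignment length must be divisible by 3")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def degapped(self, label: str) -> str:
        return self.rows[label].replace("-", "")

    def gap_mask(self) -> np.ndarray:
        """Per-column True when any row has a gap."""
        mat = np.array([list(r) for r in self.rows.values()])
        return (mat == "-").any(axis=0)


def translate_cds(cds: str) -> str:
    """Standard-code translation; N-codons -> 'X'; trailing stop trimmed."""
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    bad = set(cds) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected characters in CDS: {sorted(bad)}")
    aas = []
    n = len(cds) // 3
    for k in range(n):
        aa = translate_codon(cds[3 * k: 3 * k + 3])
        if aa == "*":
            if k == n - 1:
                break  # trailing stop trimmed
            raise ValueError(f"internal stop codon at codon {k + 1}")
        aas.append(aa)
    return "".join(aas)


def _kmer_distance_matrix(proteins: dict, k: int = 3) -> DistanceMatrix:
    labels = sorted(proteins)
    kmers = {}
    for lab in labels:
        s = proteins[lab]
        kk = min(k, max(len(s), 1))
        kmers[lab] = {s[i:i + kk] for i in range(max(len(s) - kk + 1, 1))}
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = len(kmers[labels[i]] & kmers[labels[j]])
            denom = min(len(kmers[labels[i]]), len(kmers[labels[j]])) or 1
            m[i, j] = m[j, i] = 1.0 - shared / denom
    return DistanceMatrix(labels, m, "kmer")


def _profile_counts(rows: list[str]) -> np.ndarray:
    ncol = len(rows[0])
    counts = np.zeros((ncol, len(_AA_ALPHABET)))
    for row in rows:
        for j, ch in enumerate(row):
            idx = _AA_INDEX.get(ch.upper())
            if idx is not None:
                counts[j, idx] += 1
    return counts


def _align_profiles(rows_a, rows_b, gap_open, gap_extend):
    """Affine-gap Needleman-Wunsch between two profiles.

    Column score is the mean BLOSUM62 score over residue pairs (gap cells
    contribute 0).  Traceback ties break toward the diagonal, then up.
    """
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    na, nb = ca.shape[0], cb.shape[0]
    denom = len(rows_a) * len(rows_b)
    S = (ca @ _SCORE @ cb.T) / denom
    NEG = -1e30
    M = np.full((na + 1, nb + 1), NEG)
    X = np.full((na + 1, nb + 1), NEG)  # gap in B (consume A column)
    Y = np.full((na + 1, nb + 1), NEG)  # gap in A
    ptr_m = np.zeros((na + 1, nb + 1), dtype=np.int8)  # 0=M 1=X 2=Y
    ptr_x = np.zeros((na + 1, nb + 1), dtype=np.int8)
    ptr_y = np.zeros((na + 1, nb + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, na + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
        ptr_x[i, 0] = 0 if i == 1 else 1
    for j in range(1, nb + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
        ptr_y[0, j] = 0 if j == 1 else 2
    for i in range(1, na + 1):
        Si = S[i - 1]
        for j in range(1, nb + 1):
            cand = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(cand))  # ties -> lowest index: M, then X, then Y
            M[i, j] = Si[j - 1] + cand[k]
            ptr_m[i, j] = k
            open_x = M[i - 1, j] - gap_open
            ext_x = X[i - 1, j] - gap_extend
            if open_x >= ext_x:
                X[i, j], ptr_x[i, j] = open_x, 0
            else:
                X[i, j], ptr_x[i, j] = ext_x, 1
            open_y = M[i, j - 1] - gap_open
            ext_y = Y[i, j - 1] - gap_extend
            if open_y >= ext_y:
                Y[i, j], ptr_y[i, j] = open_y, 0
            else:
                Y[i, j], ptr_y[i, j] = ext_y, 2
    # traceback; end-state ties prefer M (diagonal), then X (up)
    i, j = na, nb
    state = int(np.argmax((M[i, j], X[i, j], Y[i, j])))
    ops = []
    while i > 0 or j > 0:
        if state == 0:
            ops.append("D")
            state = int(ptr_m[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append("U")
            state = int(ptr_x[i, j])
            i -= 1
        else:
            ops.append("L")
            state = int(ptr_y[i, j])
            j -= 1
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    pa = pb = 0
    for op in ops:
        if op in ("D", "U"):
            for r, row in enumerate(rows_a):
                out_a[r] += row[pa]
            pa += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += "-"
        if op in ("D", "L"):
            for r, row in enumerate(rows_b):
                out_b[r] += row[pb]
            pb += 1
        else:
            for r in range(len(rows_b)):
                out_b[r] += "-"
    return out_a, out_b


def progressive_align(proteins: dict, gap_open: float = 10.0,
                      gap_extend: float = 0.2,
                      preset: str | None = None) -> dict:
    """Progressive protein alignment; returns {label: aligned row}.

    Guide tree from 3-mer distances + UPGMA; profiles merged postorder with
    affine-gap Needleman-Wunsch.  Deterministic for fixed inputs, invariant
    (up to row order) to input order; output keeps the input row order.
    """
    if preset is not None:
        params = PRESETS[preset]
        gap_open, gap_extend = params["gap_open"], params["gap_extend"]
    if any(len(s) == 0 for s in proteins.values()):
        raise ValueError("empty sequence cannot be aligned")
    if len(proteins) < 2:
        raise ValueError("need at least 2 sequences")
    if len(set(map(len, proteins.values()))) == 1 and len(set(proteins.values())) == 1:
        return dict(proteins)
    guide = build_upgma(_kmer_distance_matrix(proteins))

    def merge(node):
        if node.is_leaf():
            lab = node.taxon.label
            return [lab], [proteins[lab]]
        children = [merge(c) for c in node.child_nodes()]
        labs, rows = children[0]
        for labs_b, rows_b in children[1:]:
            rows, rows_b = _align_profiles(rows, rows_b, gap_open, gap_extend)
            labs = labs + labs_b
            rows = rows + rows_b
        return labs, rows

    labs, rows = merge(guide.seed_node)
    aligned = dict(zip(labs, rows))
    return {lab: aligned[lab] for lab in proteins}


def backtranslate(protein_aln: dict, cds_map: dict) -> CodonAlignment:
    """Back-translate an aligned protein set onto its CDS; '-' -> '---'."""
    rows = {}
    for lab, prow in protein_aln.items():
        cds = cds_map[lab].upper()
        if translate_cds(cds) != prow.replace("-", ""):
            raise ValueError(f"protein row for {lab} does not translate its CDS")
        out = []
        pos = 0
        for ch in prow:
            if ch == "-":
                out.append("---")
            else:
                out.append(cds[pos:pos + 3])
                pos += 3
        rows[lab] = "".join(out)
    return CodonAlignment(rows=rows)


def align_group_cds(cds_map: dict, preset: str = "clustalw-like") -> CodonAlignment:
    """translate -> progressive protein alignment -> back-translation."""
    proteins = {lab: translate_cds(cds) for lab, cds in cds_map.items()}
    paln = progressive_align(proteins, preset=preset)
    trimmed = {lab: cds[:3 * len(proteins[lab])] for lab, cds in cds_map.items()}
    return backtranslate(paln, trimmed)


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(rows: dict, path) -> None:
    with open(path, "w") as fh:
        for lab, seq in rows.items():
            fh.write(f">{lab}\n{seq}\n")


def write_phylip(rows: dict, path) -> None:
    """Relaxed PHYLIP (name, two spaces, sequence)."""
    n = len(rows)
    ncol = len(next(iter(rows.values())))
    with open(path, "w") as fh:
        fh.write(f" {n} {ncol}\n")
        for lab, seq in rows.items():
            fh.write(f"{lab}  {seq}\n")
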