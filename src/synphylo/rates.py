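"""Nei-Gojobori Ka/Ks estimation and relative-rate statistics.

Implements the original (1986) Nei-Gojobori method: synonymous site counts
as the average of the two sequences' per-codon synonymous fractions,
multi-difference codons averaged over all minimal substitution pathways with
equal weights (pathways through stop codons excluded), and Jukes-Cantor
correction d = -(3/4) ln(1 - 4p/3).

On top of the pairwise distances sit the relative rate-difference ratios
used to quantify how much faster the cotton paralogs evolve than their
cacao ortholog, all measured against the shared grape outgroup:

    R_A   = [mean_i Ks(cotton_i, grape) - Ks(cacao, grape)] / Ks(cacao, grape)
    R_Max = [max_i  Ks(cotton_i, grape) - Ks(cacao, grape)] / Ks(cacao, grape)
    R_Min = [min_i  Ks(cotton_i, grape) - Ks(cacao, grape)] / Ks(cacao, grape)

plus a Welch t-test for elevation of cotton-grape over cacao-grape Ks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._codon import SYN_SITES, encode_codons, ng_difference_tables
from ._fmt import round_half_up

__all__ = [
    "KaKsResult", "RateRecord", "nei_gojobori", "relative_rate_ratios",
    "rate_record_for_group", "ks_elevation_test", "summarize_rates",
]

SATURATION_P = 0.75


@dataclass
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float  # Ks; nan when saturated
    dN: float  # Ka; nan when saturated
    n_codons: int
    saturated_s: bool = False
    saturated_n: bool = False

    @property
    def omega(self) -> float:
        """dN/dS; nan when dS is 0 or either distance is saturated."""
        if self.saturated_s or self.saturated_n or not self.dS:
            return math.nan
        return self.dN / self.dS


def _jc_correct(p: float) -> tuple[float, bool]:
    if p >= SATURATION_P:
        return math.nan, True
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


def nei_gojobori(seq1: str, seq2: str) -> KaKsResult:
    """Pairwise Ka/Ks for two equal-length, in-frame (aligned) CDS rows.

    Codons containing a gap, ambiguity or stop in either sequence are
    dropped pairwise.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must have equal length")
    if len(seq1) % 3:
        raise ValueError("sequence length must be divisible by 3")
    c1 = encode_codons(seq1.upper())
    c2 = encode_codons(seq2.upper())
    keep = (c1 >= 0) & (c2 >= 0)
    c1, c2 = c1[keep], c2[keep]
    n_codons = int(keep.sum())
    if n_codons == 0:
        raise ValueError("no comparable codons after pairwise deletion")
    s = 0.5 * (SYN_SITES[c1].sum() + SYN_SITES[c2].sum())
    n = 3.0 * n_codons - s
    sd_tab, nd_tab = ng_difference_tables()
    sd = float(sd_tab[c1, c2].sum())
    nd = float(nd_tab[c1, c2].sum())
    ps = sd / s if s > 0 else 0.0
    pn = nd / n if n > 0 else 0.0
    ds, sat_s = _jc_correct(ps)
    dn, sat_n = _jc_correct(pn)
    return KaKsResult(S=s, N=n, Sd=sd, Nd=nd, pS=ps, pN=pn, dS=ds, dN=dn,
                      n_codons=n_codons, saturated_s=sat_s, saturated_n=sat_n)


@dataclass
class RateRecord:
    """Per-group relative-rate ratios against the cacao-grape baseline."""

    group_id: str
    tc_vv: float                     # Ks(cacao, grape)
    gr_vv_list: list = field(default_factory=list)  # Ks(cotton_i, grape)
    r_a: float = math.nan
    r_max: float = math.nan
    r_min: float = math.nan
    defined: bool = False


def relative_rate_ratios(tc_vv: float, gr_vv_list,
                         group_id: str = "") -> RateRecord:
    """R_A / R_Max / R_Min from one cacao-grape Ks and >=1 cotton-grape Ks."""
    gr = [g for g in gr_vv_list if np.isfinite(g)]
    rec = RateRecord(group_id=group_id, tc_vv=tc_vv, gr_vv_list=list(gr))
    if not gr or not np.isfinite(tc_vv) or tc_vv <= 0:
        return rec
    rec.r_a = (float(np.mean(gr)) - tc_vv) / tc_vv
    rec.r_max = (max(gr) - tc_vv) / tc_vv
    rec.r_min = (min(gr) - tc_vv) / tc_vv
    rec.defined = True
    return rec


def rate_record_for_group(group, sequences: dict) -> RateRecord:
    """Ks-based rate record for one syntenic group.

    ``sequences`` maps gene id to aligned (or equal-length) CDS rows.
    Saturated cotton-grape pairs are dropped from the ratio computation.
    """
    grape = sequences[group.grape_gene]
    tc = nei_gojobori(sequences[group.cacao_gene], grape)
    gr_list = []
    for gene in group.cotton_genes:
        res = nei_gojobori(sequences[gene], grape)
        if not res.saturated_s:
            gr_list.append(res.dS)
    tc_vv = math.nan if tc.saturated_s else tc.dS
    return relative_rate_ratios(tc_vv, gr_list, group_id=group.group_id)


@dataclass
class ElevationTest:
    t: float
    p_one_sided: float
    p_two_sided: float
    mean_cotton: float
    mean_cacao: float


def ks_elevation_test(cotton_grape_ks, cacao_grape_ks) -> ElevationTest:
    """Welch t-test of elevated cotton-grape Ks over cacao-grape Ks.

    One-sided alternative is "cotton > cacao"; the two-sided p is reported
    alongside because the sidedness convention differs between studies.
    """
    a = np.asarray([x for x in cotton_grape_ks if np.isfinite(x)], dtype=float)
    b = np.asarray([x for x in cacao_grape_ks if np.isfinite(x)], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 finite values")
    res_g = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    res_2 = stats.ttest_ind(a, b, equal_var=False)
    return ElevationTest(t=float(res_g.statistic),
                         p_one_sided=float(res_g.pvalue),
                         p_two_sided=float(res_2.pvalue),
                         mean_cotton=float(a.mean()),
                         mean_cacao=float(b.mean()))


def summarize_rates(records: list[RateRecord]) -> pd.DataFrame:
    """Per-stratum relative-rate table, strata by cotton paralog count.

    Rows: Numbers (group count), Average (mean R_A), Max (max R_Max),
    Min (min R_Min); ratio rows as percentages rounded half-up to 1 decimal.
    Undefined records are skipped.
    """
    strata: dict[int, list[RateRecord]] = {}
    for rec in records:
        if rec.defined:
            strata.setdefault(len(rec.gr_vv_list), []).append(rec)
    cols = {}
    for k in sorted(strata):
        recs = strata[k]
        cols[f"{k}Gr"] = {
            "Numbers": len(recs),
            "Average": round_half_up(100 * float(np.mean([r.r_a for r in recs])), 1),
            "Max": round_half_up(100 * max(r.r_max for r in recs), 1),
            "Min": round_half_up(100 * min(r.r_min for r in recs), 1),
        }
    return pd.DataFrame(cols, index=["Numbers", "Average", "Max", "Min"])
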