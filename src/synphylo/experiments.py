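"""Reproduction experiments: parameter recovery, mechanism and calibration.

These procedures tie the whole package together: they generate data with the
simulator, run the inference/audit machinery, and return the summary numbers
a reader needs to judge whether the implementation behaves as the underlying
theory predicts.  They are used both by the test suite and by the
acceptance script.

Two experiments use a *rapid-radiation* branch-length scenario (cotton stem
0.02 substitutions/codon) rather than the simulator defaults: topology
distortion by rate heterogeneity is only observable when the internal branch
separating cacao from the cotton clade is short relative to the rate noise,
which is exactly the regime the decaploidy polytomy represents.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .conformance import classify_conformance
from .groups import SyntenicGroup, build_expected_tree
from .rates import ks_elevation_test, rate_record_for_group
from .selection import (CodonModelSpec, branch_omega_report, fit_codon_model,
                        likelihood_ratio_test)
from .simulate import (SimulationConfig, _build_true_tree,
                       evolve_codon_sequences, evolve_heterogeneous_sequences,
                       multiplier_mean_for_elevation, simulate_group_set)
from .treebuild import build_tree

#: Rapid-radiation scenario: very short cacao/cotton-clade separating branch
#: (misplacement experiment: distortion must be near-certain).
RADIATION_BRANCH_LENGTHS = {
    "grape_stem": 0.20,
    "malvales_stem": 0.15,
    "cacao_stem": 0.30,
    "cotton_stem": 0.02,
    "cotton_tip": 0.28,
}

#: Trend scenario: stem short enough that rate variance can break cotton
#: monophyly, long enough that the zero-variance baseline mostly resolves.
TREND_BRANCH_LENGTHS = {
    "grape_stem": 0.20,
    "malvales_stem": 0.15,
    "cacao_stem": 0.30,
    "cotton_stem": 0.05,
    "cotton_tip": 0.25,
}

#: Lognormal sigma (log-scale spread) levels for the variance trend.
VARIANCE_SIGMA_LEVELS = (0.0, 0.3, 0.6, 0.9, 1.2)


def m0_omega_recovery(n_reps: int = 20, seq_len: int = 500,
                      true_omega: float = 0.3, seed: int = 0) -> list[float]:
    """Refit the one-ratio model on its own simulations (6 taxa)."""
    out = []
    for rep in range(n_reps):
        cfg = SimulationConfig(n_groups=1, seq_len_codons=seq_len,
                               omega=true_omega,
                               copy_number_probs=(0.0, 1.0, 0.0),  # 4 cottons
                               rate_multiplier_mean=1.0,
                               rate_multiplier_sd=0.0,
                               seed=seed * 1000 + rep)
        sg = simulate_group_set(cfg)[0]
        fit = fit_codon_model(sg.true_tree, sg.sequences,
                              CodonModelSpec("M0"))
        out.append(fit.omega)
    return out


def rate_elevation_recovery(target_r_a: float = 0.15, n_groups: int = 200,
                            seq_len: int = 300, sd: float = 0.5,
                            seed: int = 0) -> dict:
    """Tune the mean tip multiplier for a chosen mean R_A and re-measure it."""
    mean_mult = multiplier_mean_for_elevation(target_r_a)
    cfg = SimulationConfig(n_groups=n_groups, seq_len_codons=seq_len,
                           rate_multiplier_mean=mean_mult,
                           rate_multiplier_sd=sd, seed=seed)
    records = [rate_record_for_group(sg.group, sg.sequences)
               for sg in simulate_group_set(cfg)]
    r_a = [r.r_a for r in records if r.defined]
    return {"target_percent": 100 * target_r_a,
            "mean_multiplier": mean_mult,
            "recovered_percent": 100 * float(np.mean(r_a)),
            "n_groups": len(r_a),
            "records": records}


def variance_nonconformance_trend(n_groups_per_level: int = 100,
                                  seq_len: int = 300,
                                  levels=VARIANCE_SIGMA_LEVELS,
                                  median_multiplier: float = 1.0,
                                  method: str = "nj",
                                  seed: int = 0) -> dict:
    """Non-conformance percentage as cotton rate-multiplier variance grows.

    The multiplier distribution is widened on the log scale (sigma levels)
    while its *median* is held fixed, so the typical branch length does not
    drift with the variance level; returns per-level percentages and the
    Spearman correlation between sigma and non-conformance.
    """
    percentages = []
    for i, sigma in enumerate(levels):
        mean = median_multiplier * math.exp(sigma ** 2 / 2.0)
        sd = mean * math.sqrt(math.expm1(sigma ** 2))
        cfg = SimulationConfig(n_groups=n_groups_per_level,
                               seq_len_codons=seq_len,
                               branch_lengths=dict(TREND_BRANCH_LENGTHS),
                               rate_multiplier_mean=mean,
                               rate_multiplier_sd=sd,
                               seed=seed * 100 + i)
        bad = 0
        for sg in simulate_group_set(cfg):
            expected = build_expected_tree(sg.group)
            tree = build_tree(sg.sequences, method)
            rec = classify_conformance(tree, expected,
                                       cotton_genes=sg.group.cotton_genes)
            bad += not rec.conforms
        percentages.append(100.0 * bad / n_groups_per_level)
    rho = float(stats.spearmanr(levels, percentages).statistic)
    return {"levels": list(levels), "nonconformance_percent": percentages,
            "spearman_rho": rho}


def misplacement_overassessment(n_reps: int = 20, seq_len: int = 500,
                                multipliers=(8.0, 3.0, 1.0, 1.0, 1.0),
                                seed: int = 0) -> dict:
    """Free-ratio omega > 1 branch counts: expected vs distorted topology.

    Each replicate simulates one group in the rapid-radiation scenario with
    strongly unbalanced cotton tip rates, reconstructs the NJ tree, and
    keeps the replicate only when the tree misplaces at least one paralog
    (non-conforming).  Both topologies are then fitted with the free-ratio
    branch model and the numbers of branches with omega > 1 are compared.
    """
    counts_expected, counts_reconstructed = [], []
    attempt = 0
    while len(counts_expected) < n_reps and attempt < 20 * n_reps:
        attempt += 1
        cfg = SimulationConfig(n_groups=1, seq_len_codons=seq_len,
                               branch_lengths=dict(RADIATION_BRANCH_LENGTHS),
                               seed=seed * 10000 + attempt)
        cottons = [f"Gr_x_{i}" for i in range(1, len(multipliers) + 1)]
        group = SyntenicGroup("mis", "Vv_x", "Tc_x", cottons)
        mult = dict(zip(cottons, multipliers))
        true_tree = _build_true_tree(group, cfg, mult)
        seqs = evolve_codon_sequences(true_tree, cfg,
                                      seed=seed * 10000 + attempt)
        expected = build_expected_tree(group)
        recon = build_tree(seqs, "nj")
        rec = classify_conformance(recon, expected,
                                   cotton_genes=group.cotton_genes)
        if rec.conforms:
            continue
        spec = CodonModelSpec("branch_free")
        fit_e = fit_codon_model(expected.tree, seqs, spec)
        fit_r = fit_codon_model(recon, seqs, spec)
        counts_expected.append(len(branch_omega_report(fit_e)))
        counts_reconstructed.append(len(branch_omega_report(fit_r)))
    ce = np.array(counts_expected)
    cr = np.array(counts_reconstructed)
    return {"n_reps": len(ce),
            "counts_expected": ce.tolist(),
            "counts_reconstructed": cr.tolist(),
            "n_reconstructed_ge": int((cr >= ce).sum()),
            "n_reconstructed_gt": int((cr > ce).sum()),
            "n_reconstructed_lt": int((cr < ce).sum())}


def ks_test_type1_calibration(n_reps: int = 500, groups_per_sample: int = 12,
                              seq_len: int = 100, alpha: float = 0.05,
                              seed: int = 0) -> dict:
    """Type-I rate of the Ks-elevation test on equal-rate simulations.

    Each replicate draws two *independent* sets of groups (the samples must
    not share grape lineages, or the two-sample test becomes conservative)
    and tests cotton-grape vs cacao-grape Ks at level alpha.
    """
    rejections = 0
    for rep in range(n_reps):
        cfg = SimulationConfig(n_groups=2 * groups_per_sample,
                               seq_len_codons=seq_len,
                               rate_multiplier_mean=1.0,
                               rate_multiplier_sd=0.0,
                               seed=seed * 1000 + rep)
        records = [rate_record_for_group(sg.group, sg.sequences)
                   for sg in simulate_group_set(cfg)]
        cotton = [float(np.mean(r.gr_vv_list))
                  for r in records[:groups_per_sample] if r.defined]
        cacao = [r.tc_vv for r in records[groups_per_sample:] if r.defined]
        res = ks_elevation_test(cotton, cacao)
        rejections += res.p_one_sided < alpha
    return {"n_reps": n_reps, "alpha": alpha,
            "rejection_rate": rejections / n_reps}


def m7_m8_lrt_calibration(n_reps: int = 100, seq_len: int = 100,
                          beta_p: float = 0.8, beta_q: float = 1.5,
                          alpha: float = 0.05, seed: int = 0) -> dict:
    """M7-vs-M8 LRT rejection rate on data simulated under the M7 null.

    Site omegas are drawn from beta(p, q); both models are fitted with
    branch lengths fixed at the generating values (M8 warm-started from the
    M7 optimum).  The chi-square df=2 reference is conservative at this
    boundary null, so the rate should sit below alpha.
    """
    group = SyntenicGroup("cal", "Vv_x", "Tc_x", ["Gr_x_1", "Gr_x_2"])
    cfg = SimulationConfig(n_groups=1, seq_len_codons=seq_len, seed=0)
    tree = _build_true_tree(group, cfg, {g: 1.0 for g in group.cotton_genes})
    rng = np.random.default_rng(seed)
    rejections = 0
    for rep in range(n_reps):
        omegas = np.clip(stats.beta.rvs(beta_p, beta_q, size=seq_len,
                                        random_state=rng), 1e-4, 1 - 1e-6)
        seqs = evolve_heterogeneous_sequences(tree, cfg.kappa, omegas,
                                              seed=int(rng.integers(2**31)))
        f7 = fit_codon_model(tree, seqs,
                             CodonModelSpec("M7", fix_branch_lengths=True))
        f8 = fit_codon_model(tree, seqs, CodonModelSpec(
            "M8", fix_branch_lengths=True,
            init_beta=(f7.beta_p, f7.beta_q),
            init_p0=0.995, init_omega_s=1.001))
        _, p = likelihood_ratio_test(f7, f8, df=2)
        rejections += p < alpha
    return {"n_reps": n_reps, "alpha": alpha,
            "rejection_rate": rejections / n_reps}
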