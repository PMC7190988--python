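import math

import numpy as np
import pytest
from scipy import stats
from scipy.linalg import expm

from synphylo._codon import CODON_INDEX, SENSE_CODONS, is_transition, \
    translate_codon
from synphylo.selection import (CodonModelSpec, branch_omega_report,
                                codon_log_likelihood,
                                compare_topology_inference, fit_codon_model,
                                likelihood_ratio_test, neb_site_posteriors)
from synphylo.selection import _CodonEngine, _class_structure
from synphylo.simulate import (SimulationConfig, evolve_codon_sequences,
                               evolve_heterogeneous_sequences,
                               simulate_group_set)
from synphylo.trees import tree_from_newick


@pytest.fixture(scope="module")
def m0_data():
    """One simulated group (5 taxa, 200 codons) under omega=0.3."""
    cfg = SimulationConfig(n_groups=1, seq_len_codons=200, seed=13,
                           rate_multiplier_mean=1.0, rate_multiplier_sd=0.0)
    sg = simulate_group_set(cfg)[0]
    return sg.true_tree, sg.sequences


@pytest.fixture(scope="module")
def m7_m8_fits(m0_data):
    tree, seqs = m0_data
    f7 = fit_codon_model(tree, seqs, CodonModelSpec("M7",
                                                    fix_branch_lengths=True))
    f8 = fit_codon_model(tree, seqs, CodonModelSpec(
        "M8", fix_branch_lengths=True, init_beta=(f7.beta_p, f7.beta_q),
        init_p0=0.995, init_omega_s=1.001))
    return f7, f8


def _oracle_gy_loglik(c1, c2, t1, t2, kappa, omega):
    """Two-leaf, one-codon log-likelihood by explicit 61x61 enumeration,
    built independently from Biopython's code table and scipy expm."""
    n = len(SENSE_CODONS)
    q = np.zeros((n, n))
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            diff = [k for k in range(3) if a[k] != b[k]]
            if len(diff) != 1:
                continue
            rate = 1.0
            if is_transition(a[diff[0]], b[diff[0]]):
                rate *= kappa
            if translate_codon(a) != translate_codon(b):
                rate *= omega
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    q /= -np.mean(np.diag(q))
    p1, p2 = expm(q * t1), expm(q * t2)
    i, j = CODON_INDEX[c1], CODON_INDEX[c2]
    return math.log(sum(p1[r, i] * p2[r, j] for r in range(n)) / n)


@pytest.mark.parametrize("kappa,omega", [(1.0, 1.0), (2.0, 0.3)])
def test_codon_likelihood_matches_pair_enumeration(kappa, omega):
    tree = tree_from_newick("(A:0.2,B:0.4);", rooted=True)
    for c1, c2 in [("ATG", "ATG"), ("TTT", "TTC"), ("AAA", "GGG")]:
        got = codon_log_likelihood(tree, {"A": c1, "B": c2}, kappa, omega)
        want = _oracle_gy_loglik(c1, c2, 0.2, 0.4, kappa, omega)
        assert got == pytest.approx(want, abs=1e-9)


def test_m0_parameter_recovery(m0_data):
    tree, seqs = m0_data
    fit = fit_codon_model(tree, seqs, CodonModelSpec("M0"))
    assert fit.converged
    assert 0.2 <= fit.omega <= 0.45
    assert 1.2 <= fit.kappa <= 3.2


def test_m8_reduces_to_m7_when_positive_class_empty(m0_data):
    """In the p1 -> 0 limit the M8 likelihood equals the M7 likelihood."""
    tree, seqs = m0_data
    engine = _CodonEngine(tree, seqs)
    blens = engine.init_blens
    theta7 = np.log([0.7, 1.8])
    om7, pr7 = _class_structure(CodonModelSpec("M7"), theta7)
    lnl7, _, _ = engine.mixture_loglik(2.0, om7, pr7, blens)
    # M8 with p0 -> 1 (logit 18) and the same beta
    theta8 = np.array([math.log(0.7), math.log(1.8), 18.0, math.log(0.5)])
    om8, pr8 = _class_structure(CodonModelSpec("M8"), theta8)
    lnl8, _, _ = engine.mixture_loglik(2.0, om8, pr8, blens)
    assert lnl8 == pytest.approx(lnl7, abs=1e-4)


def test_added_parameters_never_decrease_lnl(m0_data, m7_m8_fits):
    tree, seqs = m0_data
    f7, f8 = m7_m8_fits
    assert f8.lnl >= f7.lnl - 1e-4
    f0 = fit_codon_model(tree, seqs, CodonModelSpec("M0",
                                                    fix_branch_lengths=True))
    f1 = fit_codon_model(tree, seqs, CodonModelSpec("M1",
                                                    fix_branch_lengths=True))
    assert f1.lnl >= f0.lnl - 1e-4


def test_likelihood_ratio_test_chi_square():
    from synphylo.selection import CodonModelFit
    null = CodonModelFit(spec=CodonModelSpec("M7"), lnl=-100.0, kappa=2.0)
    alt = CodonModelFit(spec=CodonModelSpec("M8"), lnl=-100.0, kappa=2.0)
    assert likelihood_ratio_test(null, alt, 2) == (0.0, 1.0)
    alt.lnl = -100.0 + 5.99 / 2
    stat, p = likelihood_ratio_test(null, alt, 2)
    assert stat == pytest.approx(5.99)
    assert p == pytest.approx(stats.chi2.sf(5.99, 2), abs=1e-12)
    assert p == pytest.approx(0.050, abs=5e-4)
    alt.lnl = -101.0
    with pytest.raises(ValueError, match="optimizer"):
        likelihood_ratio_test(null, alt, 2)


def test_site_posteriors_normalised(m7_m8_fits):
    f7, f8 = m7_m8_fits
    for fit in (f7, f8):
        sums = fit.site_posteriors.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)


def test_neb_empty_without_positive_mass(m7_m8_fits):
    f7, _ = m7_m8_fits
    assert neb_site_posteriors(f7) == []  # M7 has no omega > 1 class


def test_neb_flags_simulated_positive_site():
    """A single site evolved under omega=5 amid omega=0.1 background gets
    the highest positive-class posterior."""
    tree = tree_from_newick(
        "((A:0.3,B:0.3):0.2,(C:0.3,D:0.3):0.2,(E:0.3,F:0.3):0.2);",
        rooted=True)
    omegas = np.full(150, 0.1)
    omegas[7] = 5.0
    seqs = evolve_heterogeneous_sequences(tree, 2.0, omegas, seed=3)
    fit = fit_codon_model(tree, seqs, CodonModelSpec(
        "M8", fix_branch_lengths=True))
    from synphylo.selection import positive_site_mass
    mass = positive_site_mass(fit)
    assert int(np.argmax(mass)) == 7


def test_branch_report_and_type_errors(m0_data, m7_m8_fits):
    tree, seqs = m0_data
    fit = fit_codon_model(tree, seqs, CodonModelSpec(
        "branch_free", fix_branch_lengths=True))
    assert branch_omega_report(fit, threshold=math.inf) == []
    low = branch_omega_report(fit, threshold=0.0)
    assert low == sorted(low, key=lambda kv: -kv[1])
    with pytest.raises(TypeError):
        branch_omega_report(m7_m8_fits[0])
    with pytest.raises(TypeError):
        neb_site_posteriors(fit)


def test_two_ratio_foreground_matches_background_truth(m0_data):
    """When foreground and background share the true omega, the two
    estimates agree to within estimation noise."""
    tree, seqs = m0_data
    fg = (list(seqs)[-1],)
    fit = fit_codon_model(tree, seqs, CodonModelSpec(
        "branch_two_ratio", foreground=fg, fix_branch_lengths=True))
    omegas = set(round(v, 6) for v in fit.branch_omegas.values())
    assert len(omegas) == 2
    lo, hi = sorted(omegas)
    assert 0.1 <= lo and hi <= 1.0


def test_compare_topology_identical_fits(m0_data):
    tree, seqs = m0_data
    fit = fit_codon_model(tree, seqs, CodonModelSpec(
        "branch_free", fix_branch_lengths=True))
    rep = compare_topology_inference(fit, fit)
    assert rep["verdict"] == "equal"
    assert rep["branch_jaccard"] == 1.0  # both flag sets empty -> 1
    assert rep["n_branches_expected"] == rep["n_branches_reconstructed"]


def test_site_posteriors_invariant_to_site_order(m0_data):
    tree, seqs = m0_data
    perm = np.random.default_rng(0).permutation(200)
    shuffled = {lab: "".join(s[3 * i: 3 * i + 3] for i in perm)
                for lab, s in seqs.items()}
    spec = CodonModelSpec("M1", fix_branch_lengths=True)
    f1 = fit_codon_model(tree, seqs, spec)
    f2 = fit_codon_model(tree, shuffled, spec)
    assert f1.lnl == pytest.approx(f2.lnl, abs=1e-6)
    assert np.allclose(f1.site_posteriors[perm], f2.site_posteriors,
                       atol=1e-6)
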