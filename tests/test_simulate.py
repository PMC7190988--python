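import numpy as np
import pytest

from synphylo._codon import STOP_CODONS
from synphylo.rates import nei_gojobori
from synphylo.simulate import (SimulationConfig, evolve_codon_sequences,
                               sample_copy_numbers, simulate_group_set)
from synphylo.trees import tree_from_newick


def test_copy_numbers_degenerate_and_reproducible():
    assert sample_copy_numbers(10, (1, 0, 0), seed=1) == [3] * 10
    a = sample_copy_numbers(50, (0.5, 0.3, 0.2), seed=7)
    b = sample_copy_numbers(50, (0.5, 0.3, 0.2), seed=7)
    assert a == b
    with pytest.raises(ValueError):
        sample_copy_numbers(10, (0.5, 0.3, 0.1), seed=1)


def test_copy_number_mixture_matches_probabilities():
    probs = (0.814, 0.165, 0.021)
    draws = np.array(sample_copy_numbers(10000, probs, seed=3))
    for k, p in zip((3, 4, 5), probs):
        frac = float(np.mean(draws == k))
        se = np.sqrt(p * (1 - p) / 10000)
        assert abs(frac - p) <= 3 * se


def test_simulation_is_deterministic():
    cfg = dict(n_groups=3, seq_len_codons=40, seed=9)
    a = simulate_group_set(SimulationConfig(**cfg))
    b = simulate_group_set(SimulationConfig(**cfg))
    for ga, gb in zip(a, b):
        assert ga.sequences == gb.sequences
        assert ga.per_branch_multiplier == gb.per_branch_multiplier


def test_structural_contract(small_group_set):
    for sg in small_group_set:
        g = sg.group
        assert 3 <= g.n_cotton <= 5
        assert set(sg.sequences) == set(g.all_genes())
        lengths = {len(s) for s in sg.sequences.values()}
        assert lengths == {150 * 3}


def test_no_internal_stop_codons(small_group_set):
    for sg in small_group_set:
        for seq in sg.sequences.values():
            codons = {seq[i:i + 3] for i in range(0, len(seq), 3)}
            assert not codons & set(STOP_CODONS)


def test_unit_multipliers_when_sd_zero():
    cfg = SimulationConfig(n_groups=4, seq_len_codons=10, seed=1,
                           rate_multiplier_mean=1.0, rate_multiplier_sd=0.0)
    for sg in simulate_group_set(cfg):
        assert all(m == pytest.approx(1.0)
                   for m in sg.per_branch_multiplier.values())


def test_zero_branch_lengths_freeze_sequences():
    cfg = SimulationConfig(n_groups=1, seq_len_codons=30, seed=5,
                           branch_lengths={k: 0.0 for k in
                                           ("grape_stem", "malvales_stem",
                                            "cacao_stem", "cotton_stem",
                                            "cotton_tip")},
                           rate_multiplier_mean=1.0, rate_multiplier_sd=0.0)
    sg = simulate_group_set(cfg)[0]
    assert len(set(sg.sequences.values())) == 1


def test_neutral_omega_gives_unit_dnds():
    """With omega = 1 the estimated dN/dS between two leaves is ~1.

    Run without transition bias and at modest divergence, where the
    Nei-Gojobori counting is close to unbiased (with kappa > 1 or at high
    divergence the estimator is known to sit a few percent below truth).
    """
    tree = tree_from_newick("(A:0.05,B:0.05);", rooted=True)
    cfg = SimulationConfig(n_groups=1, seq_len_codons=500, omega=1.0,
                           kappa=1.0, seed=0)
    ratios = []
    for rep in range(20):
        seqs = evolve_codon_sequences(tree, cfg, seed=100 + rep)
        res = nei_gojobori(seqs["A"], seqs["B"])
        ratios.append(res.dN / res.dS)
    mean = np.mean(ratios)
    ci = 1.96 * np.std(ratios, ddof=1) / np.sqrt(len(ratios))
    assert mean - ci <= 1.0 <= mean + ci


def test_rate_multiplier_orders_divergence():
    """A 2x-multiplied tip accumulates more mismatches than a 1x tip."""
    wins = 0
    for rep in range(20):
        tree = tree_from_newick("(R:0.001,FAST:0.4,SLOW:0.2);", rooted=True)
        cfg = SimulationConfig(n_groups=1, seq_len_codons=300, seed=0)
        seqs = evolve_codon_sequences(tree, cfg, seed=500 + rep)

        def pdist(a, b):
            return np.mean([x != y for x, y in zip(seqs[a], seqs[b])])

        wins += pdist("FAST", "R") > pdist("SLOW", "R")
    assert wins >= 18


def test_rate_neutrality_under_clock():
    """Equal multipliers + equal tip depths: cotton-grape Ks matches
    cacao-grape Ks on average (within 2 SE over 200 groups)."""
    cfg = SimulationConfig(n_groups=200, seq_len_codons=100, seed=11,
                           rate_multiplier_mean=1.0, rate_multiplier_sd=0.0)
    diffs = []
    for sg in simulate_group_set(cfg):
        grape = sg.sequences[sg.group.grape_gene]
        tc = nei_gojobori(sg.sequences[sg.group.cacao_gene], grape).dS
        gr = np.mean([nei_gojobori(sg.sequences[g], grape).dS
                      for g in sg.group.cotton_genes])
        diffs.append(gr - tc)
    mean = np.mean(diffs)
    se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
    assert abs(mean) <= 2 * se


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_groups=0)
    with pytest.raises(ValueError):
        SimulationConfig(copy_number_probs=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        SimulationConfig(branch_lengths={"grape_stem": -0.1})
    with pytest.raises(ValueError):
        SimulationConfig(rate_multiplier_mean=0.0)
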