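"""Synthetic collinear homolog groups with codon sequences.

Emulates the statistical structure of the real three-genome dataset so every
pipeline stage is testable without genome downloads: each group has one
grape outgroup gene, one cacao ortholog and 3-5 cotton paralogs (mixture
0.814 / 0.165 / 0.021), the true tree instantiates the decaploidy topology
(grape, (cacao, (cotton polytomy))), and sequences evolve under a one-ratio
Goldman-Yang codon model with equal codon frequencies.  Cotton tip branches
receive independent lognormal rate multipliers, reproducing the elevated and
unbalanced evolutionary rates of the duplicated copies (observed mean
relative rate elevation of roughly 9-18% over the cacao baseline).

No indels are simulated by default, so the simulated sequences are already
an exact codon alignment; an optional per-tip codon deletion rate exercises
the aligner when wanted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from ._codon import N_SENSE, SENSE_CODONS, CodonPropagator, decode_codons
from .groups import SyntenicGroup

__all__ = [
    "SimulationConfig", "SimulatedGroup", "sample_copy_numbers",
    "evolve_codon_sequences", "simulate_group_set",
    "multiplier_mean_for_elevation", "write_group_set",
]

#: Branch roles of the decaploidy template tree, expected substitutions/codon.
#: Chosen so tip depths are equal when every rate multiplier is 1
#: (cacao_stem == cotton_stem + cotton_tip), i.e. a strict molecular clock
#: holds in the absence of rate elevation.
DEFAULT_BRANCH_LENGTHS = {
    "grape_stem": 0.20,
    "malvales_stem": 0.15,
    "cacao_stem": 0.30,
    "cotton_stem": 0.10,
    "cotton_tip": 0.20,
}


@dataclass
class SimulationConfig:
    """Study-condition parameters for one simulated group set."""

    n_groups: int = 100
    copy_number_probs: tuple = (0.814, 0.165, 0.021)  # P(3), P(4), P(5)
    seq_len_codons: int = 300
    kappa: float = 2.0
    omega: float = 0.3
    branch_lengths: dict = field(
        default_factory=lambda: dict(DEFAULT_BRANCH_LENGTHS))
    rate_multiplier_mean: float = 1.5
    rate_multiplier_sd: float = 0.5
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        probs = np.asarray(self.copy_number_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("copy_number_probs must be 3 non-negative values summing to 1")
        if self.seq_len_codons < 1:
            raise ValueError("seq_len_codons must be >= 1")
        if self.kappa <= 0 or self.omega <= 0:
            raise ValueError("kappa and omega must be > 0")
        missing = set(DEFAULT_BRANCH_LENGTHS) - set(self.branch_lengths)
        if missing:
            raise ValueError(f"branch_lengths missing roles: {sorted(missing)}")
        if any(v < 0 for v in self.branch_lengths.values()):
            raise ValueError("branch lengths must be >= 0")
        if self.rate_multiplier_mean <= 0 or self.rate_multiplier_sd < 0:
            raise ValueError("rate multiplier mean must be > 0 and sd >= 0")
        if not 0 <= self.indel_rate < 1:
            raise ValueError("indel_rate must be in [0, 1)")


@dataclass
class SimulatedGroup:
    group: SyntenicGroup
    true_tree: dendropy.Tree
    sequences: dict          # gene id -> CDS string
    per_branch_multiplier: dict  # branch name (tip label or role) -> factor


def multiplier_mean_for_elevation(target_r_a: float,
                                  branch_lengths: dict | None = None) -> float:
    """Mean cotton-tip rate multiplier giving a chosen mean rate elevation.

    The relative rate-difference ratio R_A compares cotton-grape to
    cacao-grape distances; under the template tree it equals
    ``tip * (m - 1) / (grape_stem + malvales_stem + cacao_stem)`` for a mean
    multiplier m, so the inversion is closed-form.
    """
    bl = branch_lengths or DEFAULT_BRANCH_LENGTHS
    baseline = bl["grape_stem"] + bl["malvales_stem"] + bl["cacao_stem"]
    return 1.0 + target_r_a * baseline / bl["cotton_tip"]


def sample_copy_numbers(n_groups: int, probs, seed: int) -> list[int]:
    """Draw cotton paralog counts in {3,4,5} from the copy-number mixture."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (3,) or (probs < 0).any() or abs(probs.sum() - 1) > 1e-9:
        raise ValueError("probs must be 3 non-negative values summing to 1")
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    rng = np.random.default_rng(seed)
    return list(rng.choice([3, 4, 5], size=n_groups, p=probs / probs.sum()))


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _build_true_tree(group: SyntenicGroup, config: SimulationConfig,
                     multipliers: dict) -> dendropy.Tree:
    """Decaploidy template tree with effective (multiplier-scaled) lengths."""
    bl = config.branch_lengths
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    root.new_child(taxon=tns.new_taxon(group.grape_gene),
                   edge_length=bl["grape_stem"])
    malvales = root.new_child(edge_length=bl["malvales_stem"])
    malvales.new_child(taxon=tns.new_taxon(group.cacao_gene),
                       edge_length=bl["cacao_stem"])
    cotton = malvales.new_child(edge_length=bl["cotton_stem"])
    for gene in group.cotton_genes:
        cotton.new_child(taxon=tns.new_taxon(gene),
                         edge_length=bl["cotton_tip"] * multipliers[gene])
    tree.is_rooted = True
    return tree


def evolve_codon_sequences(true_tree: dendropy.Tree, config: SimulationConfig,
                           seed: int) -> dict:
    """Evolve a CDS down a rooted tree under the one-ratio codon model.

    The root sequence is uniform over the 61 sense codons; each branch
    applies ``expm(Q * t)`` with t the branch's (already multiplier-scaled)
    length.  Stop codons are excluded from the state space, so simulated
    sequences never contain in-frame stops.  Returns gap-free CDS strings
    keyed by leaf label.
    """
    rng = np.random.default_rng(seed)
    prop = CodonPropagator(config.kappa, config.omega)
    n = config.seq_len_codons
    root_states = rng.integers(0, N_SENSE, size=n)
    states = {true_tree.seed_node: root_states}
    sequences: dict[str, str] = {}
    for node in true_tree.preorder_node_iter():
        if node is not true_tree.seed_node:
            t = node.edge.length
            if t is None or t < 0:
                raise ValueError("every branch needs a non-negative length")
            parent_states = states[node.parent_node]
            if t == 0:
                child_states = parent_states.copy()
            else:
                cum = np.cumsum(prop.probs(t), axis=1)
                u = rng.random(n)
                child_states = (cum[parent_states] < u[:, None]).sum(axis=1)
                np.clip(child_states, 0, N_SENSE - 1, out=child_states)
            states[node] = child_states
        if node.is_leaf():
            sequences[node.taxon.label] = decode_codons(states[node])
    if not sequences:
        raise ValueError("tree has no leaves")
    return sequences


def evolve_heterogeneous_sequences(true_tree: dendropy.Tree, kappa: float,
                                   site_omegas, seed: int) -> dict:
    """Evolve a CDS with a per-site omega (site-class models).

    ``site_omegas`` gives one dN/dS value per codon site; sites sharing a
    value evolve under one propagator.  Used to generate data under beta
    site models for likelihood-ratio calibration.
    """
    site_omegas = np.asarray(site_omegas, dtype=float)
    if (site_omegas <= 0).any():
        raise ValueError("site omegas must be > 0")
    rng = np.random.default_rng(seed)
    n = len(site_omegas)
    unique = np.unique(site_omegas)
    props = {w: CodonPropagator(kappa, float(w)) for w in unique}
    root_states = rng.integers(0, N_SENSE, size=n)
    states = {true_tree.seed_node: root_states}
    sequences: dict[str, str] = {}
    for node in true_tree.preorder_node_iter():
        if node is not true_tree.seed_node:
            t = node.edge.length
            if t is None or t < 0:
                raise ValueError("every branch needs a non-negative length")
            parent_states = states[node.parent_node]
            child_states = parent_states.copy()
            if t > 0:
                u = rng.random(n)
                for w in unique:
                    sel = site_omegas == w
                    cum = np.cumsum(props[w].probs(t), axis=1)
                    child_states[sel] = (
                        cum[parent_states[sel]] < u[sel, None]).sum(axis=1)
                np.clip(child_states, 0, N_SENSE - 1, out=child_states)
            states[node] = child_states
        if node.is_leaf():
            sequences[node.taxon.label] = decode_codons(states[node])
    return sequences


def _apply_indels(sequences: dict, group: SyntenicGroup, rate: float,
                  rng: np.random.Generator) -> dict:
    """Delete one random codon from a cotton CDS with probability ``rate``."""
    out = dict(sequences)
    for gene in group.cotton_genes:
        if rng.random() < rate:
            seq = out[gene]
            k = rng.integers(0, len(seq) // 3)
            out[gene] = seq[:3 * k] + seq[3 * (k + 1):]
    return out


def simulate_group_set(config: SimulationConfig) -> list[SimulatedGroup]:
    """Generate ``config.n_groups`` simulated collinear homolog groups."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    copy_numbers = sample_copy_numbers(
        config.n_groups, config.copy_number_probs,
        seed=int(rng.integers(2**31)))
    mu, sigma = _lognormal_params(config.rate_multiplier_mean,
                                  config.rate_multiplier_sd)
    out: list[SimulatedGroup] = []
    for i, k in enumerate(copy_numbers, start=1):
        gid = f"g{i:04d}"
        group = SyntenicGroup(
            group_id=gid,
            grape_gene=f"Vv_{gid}",
            cacao_gene=f"Tc_{gid}",
            cotton_genes=[f"Gr_{gid}_{j}" for j in range(1, k + 1)],
        )
        if sigma == 0:
            draws = np.full(k, math.exp(mu))
        else:
            draws = rng.lognormal(mean=mu, sigma=sigma, size=k)
        multipliers = {g: float(m) for g, m in zip(group.cotton_genes, draws)}
        tree = _build_true_tree(group, config, multipliers)
        seqs = evolve_codon_sequences(tree, config,
                                      seed=int(rng.integers(2**31)))
        if config.indel_rate > 0:
            seqs = _apply_indels(seqs, group, config.indel_rate, rng)
        per_branch = {"grape_stem": 1.0, "malvales_stem": 1.0,
                      "cacao_stem": 1.0, "cotton_stem": 1.0, **multipliers}
        out.append(SimulatedGroup(group=group, true_tree=tree,
                                  sequences=seqs,
                                  per_branch_multiplier=per_branch))
    return out


def write_group_set(groups: list[SimulatedGroup], outdir,
                    config: SimulationConfig | None = None,
                    combined_fasta: bool = True) -> None:
    """Write FASTA, group-table TSV, true-tree Newick and a config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = ["group_id\tspecies\tgene_id"]
    fasta_lines: list[str] = []
    newicks: list[str] = []
    for sg in groups:
        g = sg.group
        rows.append(f"{g.group_id}\tVv\t{g.grape_gene}")
        rows.append(f"{g.group_id}\tTc\t{g.cacao_gene}")
        for gene, tag in zip(g.cotton_genes, g.cotton_tags):
            rows.append(f"{g.group_id}\t{tag}\t{gene}")
        for gene in g.all_genes():
            fasta_lines.append(f">{gene}")
            fasta_lines.append(sg.sequences[gene])
        newicks.append(sg.true_tree.as_string(
            schema="newick", unquoted_underscores=True).strip())
    (outdir / "groups.tsv").write_text("\n".join(rows) + "\n")
    (outdir / "sequences.fasta").write_text("\n".join(fasta_lines) + "\n")
    (outdir / "true_trees.nwk").write_text("\n".join(newicks) + "\n")
    if config is not None:
        echo = asdict(config)
        echo["copy_number_probs"] = list(config.copy_number_probs)
        (outdir / "config.json").write_text(json.dumps(echo, indent=2) + "\n")
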