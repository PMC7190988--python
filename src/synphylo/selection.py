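"""Codon-model selection inference (branch and site models).

Implements a Goldman-Yang codon substitution framework with equal codon
frequencies (1/61) over the 61 sense codons: the one-ratio model M0, the
nearly-neutral two-class site model M1 (classes omega0 < 1 and omega = 1),
the beta site models M7 (beta-distributed omega on (0,1), K = 10
equal-probability classes, class omega at the bin median) and M8 (beta plus
one extra class with omega_s >= 1), and branch models with two or free
per-branch omega ratios.  Likelihoods are computed by Felsenstein pruning
over sense-codon states with per-pattern scaling; parameters are maximised
with bounded quasi-Newton search (L-BFGS-B, omega in [1e-4, 99], kappa in
[0.1, 50]).  Branch lengths are re-estimated under each fit unless the spec
asks for them to be held fixed.

Positive-selection site identification uses naive empirical Bayes (NEB):
the posterior of site class k at site s is p_k L_s(omega_k) / sum_j p_j
L_s(omega_j).  Bayes empirical Bayes is out of scope; every report states
the method used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import stats
from scipy.optimize import minimize
from scipy.special import logsumexp

from ._codon import N_SENSE, CodonPropagator, encode_codons

__all__ = [
    "CodonModelSpec", "CodonModelFit", "fit_codon_model",
    "codon_log_likelihood", "likelihood_ratio_test", "neb_site_posteriors",
    "branch_omega_report", "compare_topology_inference",
]

SITE_MODELS = ("M0", "M1", "M7", "M8")
BRANCH_MODELS = ("branch_two_ratio", "branch_free")

_KAPPA_BOUNDS = (0.1, 50.0)
_OMEGA_BOUNDS = (1e-4, 99.0)
_BLEN_BOUNDS = (1e-6, 15.0)


@dataclass
class CodonModelSpec:
    model: str
    n_classes: int = 10                 # K for beta discretisation
    foreground: tuple = ()              # labels / clade frozensets (two-ratio)
    fix_branch_lengths: bool = False
    init_kappa: float = 2.0
    init_omega: float = 0.4
    init_beta: tuple = (0.8, 1.5)       # starting beta(p, q) for M7/M8
    init_p0: float = 0.9                # M8 starting beta-class weight
    init_omega_s: float = 1.5           # M8 starting positive-class omega

    def __post_init__(self):
        if self.model not in SITE_MODELS + BRANCH_MODELS:
            raise ValueError(f"unknown codon model {self.model!r}")
        if self.model in ("M7", "M8") and self.n_classes < 3:
            raise ValueError("beta models need at least 3 site classes")
        if self.model == "branch_two_ratio" and not self.foreground:
            raise ValueError("two-ratio model needs foreground branches")


@dataclass
class CodonModelFit:
    spec: CodonModelSpec
    lnl: float
    kappa: float
    omega: float | None = None                  # M0 global omega
    branch_omegas: dict = field(default_factory=dict)  # edge key -> omega
    class_omegas: np.ndarray | None = None
    class_props: np.ndarray | None = None
    beta_p: float | None = None
    beta_q: float | None = None
    omega_s: float | None = None                # M8 positive class omega
    p0: float | None = None
    site_posteriors: np.ndarray | None = None   # (nsites, K)
    branch_lengths: dict = field(default_factory=dict)  # edge key -> length
    converged: bool = True
    n_evaluations: int = 0
    n_sites: int = 0
    notes: str = ""

    @property
    def is_site_model(self) -> bool:
        return self.spec.model in SITE_MODELS


# ---------------------------------------------------------------------------
# likelihood engine


def _propagator(kappa: float, omega: float,
                cache: dict) -> CodonPropagator:
    key = (round(kappa, 12), round(omega, 12))
    if key not in cache:
        if len(cache) > 256:
            cache.clear()
        cache[key] = CodonPropagator(kappa, omega)
    return cache[key]


class _CodonEngine:
    """Pattern-compressed pruning likelihood for one tree + codon alignment."""

    def __init__(self, tree: dendropy.Tree, aln):
        rows = getattr(aln, "rows", aln)
        self.tree = tree.clone(depth=1)
        # the likelihood is invariant to root placement (reversible model);
        # a bifurcating root would leave the two root-adjacent branch
        # lengths and omegas confounded, so work on the unrooted tree
        if len(self.tree.seed_node.child_nodes()) == 2:
            self.tree.deroot()
        self.leaves = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if set(self.leaves) != set(rows):
            raise ValueError("tree leaves and alignment rows differ")
        codes = np.stack([encode_codons(rows[lab].upper())
                          for lab in self.leaves])
        patterns, inverse, weights = np.unique(
            codes, axis=1, return_inverse=True, return_counts=True)
        self.patterns = patterns            # (ntaxa, npat)
        self.pattern_of_site = inverse
        self.weights = weights.astype(float)
        self.n_sites = codes.shape[1]
        self.npat = patterns.shape[1]
        # postorder node/edge bookkeeping; edges keyed by clade leafset
        self.postorder = list(self.tree.postorder_node_iter())
        self.edges = [nd for nd in self.postorder
                      if nd is not self.tree.seed_node]
        leafsets = {}
        for nd in self.postorder:
            if nd.is_leaf():
                leafsets[nd] = frozenset([nd.taxon.label])
            else:
                leafsets[nd] = frozenset().union(
                    *(leafsets[c] for c in nd.child_nodes()))
        all_leaves = frozenset(self.leaves)
        ref = min(all_leaves)
        # edges keyed by their unrooted split (side without the reference
        # leaf) so keys are comparable across differently rooted topologies
        self.edge_keys = [
            (all_leaves - leafsets[nd]) if ref in leafsets[nd]
            else leafsets[nd]
            for nd in self.edges]
        self._all_leaves, self._ref = all_leaves, ref
        self.init_blens = np.array(
            [nd.edge.length if nd.edge.length else 0.05 for nd in self.edges])
        # leaf partials per pattern
        self._leaf_partials = {}
        for i, lab in enumerate(self.leaves):
            part = np.zeros((self.npat, N_SENSE))
            codes_i = self.patterns[i]
            miss = codes_i < 0
            part[np.arange(self.npat), np.where(miss, 0, codes_i)] = 1.0
            part[miss] = 1.0
            self._leaf_partials[lab] = part
        self._cache: dict = {}

    def class_site_loglik(self, kappa: float, omega, blens) -> np.ndarray:
        """Per-pattern log-likelihood for one omega class.

        ``omega`` is either a scalar (same on all branches) or an array per
        edge (branch models).
        """
        omegas = np.broadcast_to(np.asarray(omega, dtype=float),
                                 (len(self.edges),))
        edge_index = {nd: i for i, nd in enumerate(self.edges)}
        partials = {}
        logscale = np.zeros(self.npat)
        for node in self.postorder:
            if node.is_leaf():
                partials[node] = self._leaf_partials[node.taxon.label]
                continue
            acc = np.ones((self.npat, N_SENSE))
            for child in node.child_nodes():
                e = edge_index[child]
                prop = _propagator(kappa, float(omegas[e]), self._cache)
                p = prop.probs(max(float(blens[e]), 1e-9))
                acc *= partials[child] @ p.T
            mx = acc.max(axis=1)
            mx[mx <= 0] = 1.0
            logscale += np.log(mx)
            partials[node] = acc / mx[:, None]
        site = partials[self.postorder[-1]].mean(axis=1)  # pi = 1/61
        site[site <= 0] = 1e-300
        return np.log(site) + logscale

    def mixture_loglik(self, kappa, class_omegas, class_props, blens,
                       return_parts=False):
        parts = np.stack([self.class_site_loglik(kappa, w, blens)
                          for w in class_omegas])
        logp = np.log(np.maximum(np.asarray(class_props), 1e-300))
        site = logsumexp(parts + logp[:, None], axis=0)
        lnl = float(np.sum(self.weights * site))
        if return_parts:
            return lnl, parts, site
        return lnl, None, None

    def expand(self, per_pattern: np.ndarray) -> np.ndarray:
        return per_pattern[..., self.pattern_of_site]


# ---------------------------------------------------------------------------
# parameterisations


def _logit(p):
    p = min(max(p, 1e-9), 1 - 1e-9)
    return math.log(p / (1 - p))


def _sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


def _beta_class_omegas(p: float, q: float, k: int) -> np.ndarray:
    quantiles = (2 * np.arange(k) + 1) / (2.0 * k)
    w = stats.beta.ppf(quantiles, p, q)
    return np.clip(w, 1e-6, 1 - 1e-6)


def _class_structure(spec: CodonModelSpec, theta: np.ndarray):
    """(class_omegas, class_props) from model-specific parameters."""
    m = spec.model
    if m == "M0":
        return np.array([math.exp(theta[0])]), np.array([1.0])
    if m == "M1":
        w0 = _sigmoid(theta[0]) * (1 - 1e-6)
        p0 = _sigmoid(theta[1])
        return np.array([w0, 1.0]), np.array([p0, 1.0 - p0])
    if m == "M7":
        p, q = math.exp(theta[0]), math.exp(theta[1])
        k = spec.n_classes
        return _beta_class_omegas(p, q, k), np.full(k, 1.0 / k)
    if m == "M8":
        p, q = math.exp(theta[0]), math.exp(theta[1])
        p0 = _sigmoid(theta[2])
        ws = 1.0 + math.exp(theta[3])
        k = spec.n_classes
        omegas = np.append(_beta_class_omegas(p, q, k), ws)
        props = np.append(np.full(k, p0 / k), 1.0 - p0)
        return omegas, props
    raise AssertionError(m)


_N_THETA = {"M0": 1, "M1": 2, "M7": 2, "M8": 4}

_THETA_INIT = {
    "M0": lambda spec: [math.log(spec.init_omega)],
    "M1": lambda spec: [_logit(0.3), _logit(0.7)],
    "M7": lambda spec: [math.log(spec.init_beta[0]),
                        math.log(spec.init_beta[1])],
    "M8": lambda spec: [math.log(spec.init_beta[0]),
                        math.log(spec.init_beta[1]), _logit(spec.init_p0),
                        math.log(max(spec.init_omega_s - 1.0, 1e-6))],
}

_THETA_BOUNDS = {
    "M0": [(math.log(_OMEGA_BOUNDS[0]), math.log(_OMEGA_BOUNDS[1]))],
    "M1": [(-12, 12), (-12, 12)],
    "M7": [(math.log(0.005), math.log(99.0))] * 2,
    "M8": [(math.log(0.005), math.log(99.0))] * 2
          + [(-12, 12), (math.log(1e-6), math.log(98.0))],
}


def _foreground_mask(engine: _CodonEngine, foreground) -> np.ndarray:
    mask = np.zeros(len(engine.edges), dtype=bool)
    wanted = []
    for item in foreground:
        s = frozenset([item]) if isinstance(item, str) else frozenset(item)
        if engine._ref in s:
            s = engine._all_leaves - s
        wanted.append(s)
    for i, key in enumerate(engine.edge_keys):
        if key in wanted:
            mask[i] = True
    if mask.sum() != len(set(wanted)):
        raise ValueError("some foreground branches not found in tree")
    return mask


# ---------------------------------------------------------------------------
# fitting


def fit_codon_model(tree: dendropy.Tree, aln,
                    spec: CodonModelSpec) -> CodonModelFit:
    """Maximum-likelihood fit of a codon model on a fixed topology.

    Branch lengths are re-estimated jointly with the model parameters
    unless ``spec.fix_branch_lengths`` (then the input tree's lengths are
    used as-is).  Non-convergence is flagged on the returned fit, never
    raised.
    """
    engine = _CodonEngine(tree, aln)
    m = spec.model
    log_kappa0 = math.log(spec.init_kappa)
    if m in SITE_MODELS:
        theta0 = list(_THETA_INIT[m](spec))
        theta_bounds = list(_THETA_BOUNDS[m])
    elif m == "branch_two_ratio":
        theta0 = [math.log(spec.init_omega)] * 2
        theta_bounds = [_THETA_BOUNDS["M0"][0]] * 2
        fg_mask = _foreground_mask(engine, spec.foreground)
    else:  # branch_free
        theta0 = [math.log(spec.init_omega)] * len(engine.edges)
        theta_bounds = [_THETA_BOUNDS["M0"][0]] * len(engine.edges)

    x0 = [log_kappa0] + theta0
    bounds = [(math.log(_KAPPA_BOUNDS[0]), math.log(_KAPPA_BOUNDS[1]))] \
        + theta_bounds
    free_blens = not spec.fix_branch_lengths
    blens0 = np.clip(engine.init_blens, *_BLEN_BOUNDS)
    if free_blens:
        x0 = x0 + list(np.log(blens0))
        bounds += [(math.log(_BLEN_BOUNDS[0]), math.log(_BLEN_BOUNDS[1]))] \
            * len(engine.edges)
    n_theta = len(theta0)
    evals = [0]

    def unpack(x):
        kappa = math.exp(x[0])
        theta = np.asarray(x[1:1 + n_theta])
        blens = np.exp(x[1 + n_theta:]) if free_blens else blens0
        return kappa, theta, blens

    def negloglik(x):
        evals[0] += 1
        kappa, theta, blens = unpack(x)
        if m in SITE_MODELS:
            omegas, props = _class_structure(spec, theta)
            lnl, _, _ = engine.mixture_loglik(kappa, omegas, props, blens)
        else:
            if m == "branch_two_ratio":
                per_edge = np.where(fg_mask, math.exp(theta[1]),
                                    math.exp(theta[0]))
            else:
                per_edge = np.exp(theta)
            site = engine.class_site_loglik(kappa, per_edge, blens)
            lnl = float(np.sum(engine.weights * site))
        if not np.isfinite(lnl):
            return 1e12
        return -lnl

    res = minimize(negloglik, np.array(x0), method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-10, "maxfun": 20000})
    kappa, theta, blens = unpack(res.x)
    fit = CodonModelFit(spec=spec, lnl=-float(res.fun), kappa=kappa,
                        converged=bool(res.success),
                        n_evaluations=evals[0], n_sites=engine.n_sites,
                        branch_lengths=dict(
                            zip(engine.edge_keys, map(float, blens))))
    if m in SITE_MODELS:
        omegas, props = _class_structure(spec, theta)
        fit.class_omegas, fit.class_props = omegas, props
        _, parts, site = engine.mixture_loglik(kappa, omegas, props, blens,
                                               return_parts=True)
        post = np.exp(parts + np.log(np.maximum(props, 1e-300))[:, None]
                      - site[None, :])
        fit.site_posteriors = engine.expand(post).T  # (nsites, K)
        if m == "M0":
            fit.omega = float(omegas[0])
        elif m == "M1":
            fit.p0 = float(props[0])
        else:
            fit.beta_p = float(math.exp(theta[0]))
            fit.beta_q = float(math.exp(theta[1]))
            if m == "M8":
                fit.p0 = float(_sigmoid(theta[2]))
                fit.omega_s = float(omegas[-1])
    else:
        if m == "branch_two_ratio":
            per_edge = np.where(fg_mask, math.exp(theta[1]),
                                math.exp(theta[0]))
        else:
            per_edge = np.exp(theta)
        fit.branch_omegas = dict(zip(engine.edge_keys, map(float, per_edge)))
    if m == "M1":
        fit.notes = ("M1 = nearly-neutral two-class model (omega0 < 1 free, "
                     "omega1 = 1); the pairing with M0 is not strictly nested")
    return fit


def codon_log_likelihood(tree: dendropy.Tree, aln, kappa: float,
                         omega: float) -> float:
    """One-ratio (M0) codon log-likelihood at fixed parameters.

    Uses the tree's own branch lengths; no optimisation.
    """
    engine = _CodonEngine(tree, aln)
    site = engine.class_site_loglik(kappa, omega, engine.init_blens)
    return float(np.sum(engine.weights * site))


def likelihood_ratio_test(fit_null: CodonModelFit, fit_alt: CodonModelFit,
                          df: int) -> tuple[float, float]:
    """2*(lnL_alt - lnL_null) against chi-square with ``df`` degrees.

    Slightly negative statistics within optimizer tolerance are clamped to
    0; larger negative values indicate an optimisation failure and raise.
    """
    stat = 2.0 * (fit_alt.lnl - fit_null.lnl)
    if stat < -1e-2:
        raise ValueError(
            f"alternative lnL below null by {-stat/2:.4g}: optimizer failure")
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, p


def neb_site_posteriors(fit: CodonModelFit, threshold: float = 0.95) -> list:
    """Sites whose NEB posterior mass on omega > 1 classes exceeds threshold.

    Returns (site index, posterior) pairs sorted by site; empty with a note
    when the model has no class allowing positive selection.
    """
    if not fit.is_site_model or fit.site_posteriors is None:
        raise TypeError("NEB requires a fitted site-class model")
    positive = fit.class_omegas > 1.0
    if not positive.any() or (fit.class_props[positive] <= 1e-12).all():
        return []
    mass = fit.site_posteriors[:, positive].sum(axis=1)
    return [(int(i), float(mass[i])) for i in np.where(mass > threshold)[0]]


def positive_site_mass(fit: CodonModelFit) -> np.ndarray:
    """Per-site NEB posterior mass on omega > 1 classes (zeros if none)."""
    if fit.site_posteriors is None:
        raise TypeError("fit has no site posteriors")
    positive = fit.class_omegas > 1.0
    if not positive.any():
        return np.zeros(fit.site_posteriors.shape[0])
    return fit.site_posteriors[:, positive].sum(axis=1)


def branch_omega_report(fit: CodonModelFit, threshold: float = 1.0) -> list:
    """Branches with omega above threshold, sorted by descending omega."""
    if fit.is_site_model:
        raise TypeError("branch report requires a branch-model fit")
    hits = [(key, w) for key, w in fit.branch_omegas.items() if w > threshold]
    return sorted(hits, key=lambda kv: (-kv[1], sorted(kv[0])))


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0  # convention: two empty flag sets agree perfectly
    return len(a & b) / len(a | b)


def compare_topology_inference(fit_expected: CodonModelFit,
                               fit_reconstructed: CodonModelFit,
                               threshold: float = 1.0,
                               site_threshold: float = 0.95) -> dict:
    """Quantify how the reconstructed topology shifts selection inference.

    For branch-model fits: counts of omega > threshold branches under each
    topology and the Jaccard overlap of the flagged branches' leaf sets.
    For site-model fits: overlap of NEB-flagged sites.  The verdict says
    whether the reconstructed topology over-, under- or equally assesses
    positive selection relative to the expected one.
    """
    if fit_expected.n_sites != fit_reconstructed.n_sites:
        raise ValueError("fits are not on the same alignment")
    if fit_expected.is_site_model != fit_reconstructed.is_site_model:
        raise ValueError("fits are from different model families")
    report: dict = {"delta_lnl": fit_reconstructed.lnl - fit_expected.lnl,
                    "method": "NEB"}
    if fit_expected.is_site_model:
        sites_e = {i for i, _ in neb_site_posteriors(fit_expected, site_threshold)}
        sites_r = {i for i, _ in neb_site_posteriors(fit_reconstructed,
                                                     site_threshold)}
        report.update(n_sites_expected=len(sites_e),
                      n_sites_reconstructed=len(sites_r),
                      site_jaccard=_jaccard(sites_e, sites_r))
        ce, cr = len(sites_e), len(sites_r)
    else:
        fe = branch_omega_report(fit_expected, threshold)
        fr = branch_omega_report(fit_reconstructed, threshold)
        keys_e = {k for k, _ in fe}
        keys_r = {k for k, _ in fr}
        report.update(n_branches_expected=len(fe),
                      n_branches_reconstructed=len(fr),
                      branch_jaccard=_jaccard(keys_e, keys_r),
                      flagged_expected=fe, flagged_reconstructed=fr)
        ce, cr = len(fe), len(fr)
    report["verdict"] = ("over" if cr > ce else "under" if cr < ce
                         else "equal")
    return report
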