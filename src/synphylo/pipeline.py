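"""End-to-end orchestration: data -> alignment -> trees -> audit tables.

One run takes a set of syntenic groups (simulated or read from files),
aligns each group's CDS, infers trees with the requested methods, classifies
every tree against the collinearity-derived expected topology, computes the
relative-rate statistics, optionally runs the selection comparison, and
emits the aggregate report bundle (per-method conformance table, group
agreement classes, per-stratum rate table, Ks-elevation test, manifest).

One group's failure never aborts the run: failures are recorded in the
manifest with the stage and message, and the group is dropped from the
aggregates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .align import CodonAlignment, align_group_cds, read_fasta
from .conformance import (classify_conformance, copy_number_from_hits,
                          group_agreement_classes, stratify_by_copy_number,
                          summarize_methods)
from .groups import build_expected_tree, read_group_table
from .rates import ks_elevation_test, rate_record_for_group, summarize_rates
from .simulate import SimulationConfig, simulate_group_set
from .treebuild import bootstrap_support, build_tree
from .trees import to_newick

logger = logging.getLogger(__name__)

ALL_METHODS = ("ml", "nj", "me", "upgma", "mp")
NON_UPGMA = ("ml", "nj", "me", "mp")


@dataclass
class PipelineConfig:
    mode: str = "simulate"                       # simulate | files
    simulation: SimulationConfig | None = None
    fasta_path: str | None = None
    groups_path: str | None = None
    hits_path: str | None = None
    template: str | None = None
    methods: tuple = ALL_METHODS
    aligners: tuple = ("clustalw-like",)
    bootstrap_reps: int = 0
    min_cotton: int = 2
    evalue_cutoffs: tuple = (1e-5, 1e-20)
    bin_edges: tuple = (0, 5, 10, 20, 50, np.inf)
    skip_alignment: bool | None = None           # None -> auto
    run_selection: bool = False
    seed: int = 0

    def __post_init__(self):
        if not self.methods:
            raise ValueError("method list must be non-empty")
        if any(c <= 0 for c in self.evalue_cutoffs):
            raise ValueError("E-value cutoffs must be > 0")
        if self.mode not in ("simulate", "files"):
            raise ValueError("mode must be 'simulate' or 'files'")


@dataclass
class PipelineResult:
    records: list = field(default_factory=list)       # ConformanceRecord
    rate_records: list = field(default_factory=list)  # RateRecord
    trees: dict = field(default_factory=dict)         # (gid, aligner, method) -> newick
    method_summaries: dict = field(default_factory=dict)   # aligner -> MethodSummary
    agreement: dict = field(default_factory=dict)
    rate_table = None
    elevation_test = None
    copy_stratification: dict = field(default_factory=dict)
    selection_reports: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _load_groups(config: PipelineConfig):
    """Returns (groups, sequences-by-gene) for either input mode."""
    if config.mode == "simulate":
        sim = config.simulation or SimulationConfig(seed=config.seed)
        simulated = simulate_group_set(sim)
        seqs = {}
        for sg in simulated:
            seqs.update(sg.sequences)
        return [sg.group for sg in simulated], seqs
    groups = read_group_table(config.groups_path)
    seqs = read_fasta(config.fasta_path)
    return groups, seqs


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    result = PipelineResult()
    failures: list[dict] = []
    groups, all_seqs = _load_groups(config)
    groups = [g for g in groups if g.n_cotton >= config.min_cotton]
    skip_alignment = config.skip_alignment
    if skip_alignment is None:
        sim = config.simulation
        skip_alignment = (config.mode == "simulate"
                          and (sim is None or sim.indel_rate == 0))

    for group in groups:
        try:
            cds = {gid: all_seqs[gid] for gid in group.all_genes()}
        except KeyError as exc:
            failures.append({"group": group.group_id, "stage": "input",
                             "error": f"missing sequence {exc}"})
            continue
        try:
            expected = build_expected_tree(group, template=config.template)
        except ValueError as exc:
            failures.append({"group": group.group_id, "stage": "expected_tree",
                             "error": str(exc)})
            continue
        ok = True
        for aligner in config.aligners:
            try:
                if skip_alignment:
                    aln = CodonAlignment(rows=dict(cds))
                else:
                    aln = align_group_cds(cds, preset=aligner)
            except Exception as exc:
                failures.append({"group": group.group_id, "stage": "align",
                                 "aligner": aligner, "error": str(exc)})
                ok = False
                continue
            for method in config.methods:
                try:
                    if config.bootstrap_reps > 0:
                        tree = bootstrap_support(
                            aln, method, n_reps=config.bootstrap_reps,
                            seed=config.seed)
                    else:
                        tree = build_tree(aln, method)
                    rec = classify_conformance(
                        tree, expected, cotton_genes=group.cotton_genes,
                        method=method, aligner=aligner)
                    result.records.append(rec)
                    result.trees[(group.group_id, aligner, method)] = \
                        to_newick(tree)
                except Exception as exc:
                    failures.append({"group": group.group_id, "stage": "infer",
                                     "aligner": aligner, "method": method,
                                     "error": str(exc)})
                    ok = False
        if ok:
            try:
                first = config.aligners[0]
                aln = CodonAlignment(rows=dict(cds)) if skip_alignment \
                    else align_group_cds(cds, preset=first)
                result.rate_records.append(
                    rate_record_for_group(group, aln.rows))
            except Exception as exc:
                failures.append({"group": group.group_id, "stage": "rates",
                                 "error": str(exc)})

    # aggregates: drop groups with any failure from the tables
    failed_ids = {f["group"] for f in failures}
    clean = [r for r in result.records if r.group_id not in failed_ids]
    for aligner in config.aligners:
        recs = [r for r in clean if r.aligner == aligner]
        if recs:
            subset = tuple(m for m in NON_UPGMA if m in config.methods)
            result.method_summaries[aligner] = summarize_methods(
                recs, method_subset=subset or None)
            try:
                result.agreement[aligner] = {
                    "all": group_agreement_classes(recs),
                }
                if subset and set(subset) != set(config.methods):
                    result.agreement[aligner]["non_upgma"] = \
                        group_agreement_classes(recs, method_set=subset)
            except ValueError as exc:
                logger.warning("agreement classes unavailable: %s", exc)
    defined = [r for r in result.rate_records
               if r.defined and r.group_id not in failed_ids]
    if defined:
        result.rate_table = summarize_rates(defined)
        cotton_ks = [k for r in defined for k in r.gr_vv_list]
        cacao_ks = [r.tc_vv for r in defined]
        if len(cotton_ks) >= 2 and len(cacao_ks) >= 2:
            result.elevation_test = ks_elevation_test(cotton_ks, cacao_ks)
    if config.hits_path:
        for cutoff in config.evalue_cutoffs:
            counts = copy_number_from_hits(config.hits_path, cutoff)
            grape_counts = {}
            for g in groups:
                if g.grape_gene in counts:
                    grape_counts[g.group_id] = counts[g.grape_gene]
            usable = [r for r in clean if r.group_id in grape_counts]
            if usable:
                result.copy_stratification[cutoff] = stratify_by_copy_number(
                    usable, grape_counts, bin_edges=config.bin_edges)

    result.manifest = {
        "seed": config.seed,
        "mode": config.mode,
        "methods": list(config.methods),
        "aligners": list(config.aligners),
        "n_groups_input": len(groups),
        "n_groups_ok": len({r.group_id for r in clean}),
        "n_failures": len(failures),
        "failures": failures,
        "skip_alignment": bool(skip_alignment),
    }
    return result


def write_reports(result: PipelineResult, outdir, force: bool = False) -> list:
    """Write TSV/JSON aggregate tables, Newick trees and the manifest.

    Returns the list of written paths.  Existing files are replaced only
    with ``force``; writes go to a temp name then atomic-rename.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def emit(name: str, text: str):
        path = outdir / name
        if path.exists() and not force:
            raise FileExistsError(f"{path} exists (use force=True)")
        tmp = path.with_suffix(path.suffix + ".tmp")
        tmp.write_text(text)
        tmp.replace(path)
        written.append(path)

    # per-method conformance (Table-1 analog)
    lines = ["aligner\tmethod\tconforming\ttotal\tpercentage"]
    for aligner, summ in result.method_summaries.items():
        for m in sorted(summ.counts):
            lines.append(f"{aligner}\t{m}\t{summ.counts[m]}\t{summ.total}"
                         f"\t{summ.percentages[m]}")
    emit("method_conformance.tsv", "\n".join(lines) + "\n")

    agreement = {
        aligner: {name: {"methods": list(cls["methods"]),
                         "n_groups": cls["n_groups"],
                         "counts": cls["counts"],
                         "percentages": cls["percentages"]}
                  for name, cls in sets.items()}
        for aligner, sets in result.agreement.items()}
    emit("agreement_classes.json", json.dumps(agreement, indent=2) + "\n")

    if result.rate_table is not None:
        emit("rate_table.tsv", result.rate_table.to_csv(sep="\t"))
    if result.elevation_test is not None:
        emit("ks_elevation.json", json.dumps(asdict(result.elevation_test),
                                             indent=2) + "\n")
    for cutoff, table in result.copy_stratification.items():
        emit(f"copy_stratification_{cutoff:g}.tsv", table.to_csv(sep="\t"))

    nwk = [f"{gid}\t{aligner}\t{method}\t{newick}"
           for (gid, aligner, method), newick in sorted(result.trees.items())]
    emit("trees.tsv", "\n".join(nwk) + ("\n" if nwk else ""))

    records = ["group_id\taligner\tmethod\tconforms\tescape_pattern\tsupport"]
    for r in result.records:
        esc = ",".join(sorted(r.escape_pattern))
        records.append(f"{r.group_id}\t{r.aligner}\t{r.method}\t"
                       f"{int(r.conforms)}\t{esc}\t"
                       f"{'' if r.support is None else r.support}")
    emit("conformance_records.tsv", "\n".join(records) + "\n")
    emit("manifest.json", json.dumps(result.manifest, indent=2) + "\n")
    return written
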