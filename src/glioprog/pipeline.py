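"""End-to-end orchestration of the analysis stages on a cohort directory.

``run_all`` executes the stages in dependency order — simulate (or load)
-> variant filtering / copy number / structural variants -> TAD
integration and gene-set activity -> survival endpoints — writing every
output under the run directory and returning a report with per-stage
record counts, a full parameter echo, and a checksummed output manifest
(identical config + seed implies identical checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cna, genesets, io, simulate, sv, survival, tad, variants

log = logging.getLogger("glioprog")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "glioprog_run"
    # simulation
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    # variant filtering
    min_support: int = 3
    min_vaf: float = 0.10
    heterogeneity_alpha: float = 0.01
    # copy number; 200-fold decimation suits genome-scale tracks, 10 the
    # simulated toy chromosomes (hundreds of kb)
    window_size: int = 1000
    decimation_factor: int = 10
    # structural variants
    sv_min_support: int = 5
    sv_recurrence_cap: float = 0.30
    sv_af_threshold: float = 0.2
    sv_match_radius: int = 200
    # TAD integration
    fc_threshold: float = 1.0
    min_patients: int = 2
    expression_min_count: int = 15
    expression_min_samples: int = 2
    # gene sets
    correlation_threshold: float = 0.4
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Run every stage on a freshly simulated cohort; returns the report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = io.ensure_dir(config.outdir)
    report: dict = {
        "parameters": dataclasses.asdict(config),
        "stages": {},
        "manifest": {},
    }

    sim_config = simulate.SimulationConfig(
        seed=config.seed, window_size=config.window_size, **config.simulation
    )
    log.info("simulating cohort (seed=%d)", config.seed)
    cohort = simulate.simulate_cohort(sim_config)
    genome = cohort.genome
    genome.to_fasta(outdir / "reference.fa")
    io.write_vcf(cohort.variant_table, outdir / "variants.vcf")
    io.write_germline_db(cohort.germline_db, outdir / "germline_db.tsv")
    io.write_tads_bed(cohort.tads, outdir / "tads.bed")
    genes = simulate.gene_annotations(cohort.gene_table)
    io.write_genes_bed(genes, outdir / "genes.bed")
    expr = simulate.expression_matrix(cohort)
    io.write_expression_tsv(expr, outdir / "expression.tsv")
    for name, obs in cohort.samples.items():
        io.write_bedpe(obs.junctions, outdir / f"{name}.sv.bedpe")
    report["stages"]["simulate"] = {
        "n_samples": len(cohort.samples),
        "n_variant_rows": len(cohort.variant_table),
        "n_genes": len(cohort.gene_table),
    }

    # --- variant filtering
    filt = variants.SomaticFilterConfig(
        min_support=config.min_support,
        min_vaf=config.min_vaf,
        heterogeneity_alpha=config.heterogeneity_alpha,
        germline_db=cohort.germline_db,
    )
    retained, provenance = variants.filter_somatic(cohort.variant_table, filt)
    io.write_variant_tsv(cohort.variant_table, outdir / "variants.all.tsv", provenance)
    io.write_variant_tsv(retained, outdir / "variants.retained.tsv")
    spectrum, n_excluded = variants.trinucleotide_spectrum(retained, genome)
    spectrum.rename("count").to_csv(outdir / "spectrum.tsv", sep="\t", index_label="class")
    report["stages"]["variant_filtering"] = {
        "n_input": len(cohort.variant_table),
        "n_retained": len(retained),
        "n_spectrum_excluded": n_excluded,
        "rejected_by_gate": provenance.value_counts().drop("retained", errors="ignore").to_dict(),
    }

    # --- copy number per sample (vs the simulated reference sample)
    decim = max(1, config.decimation_factor)
    n_segments = {}
    for name, obs in cohort.samples.items():
        ratio = cna.coverage_log_ratio(obs.coverage, cohort.reference_coverage)
        decimated = cna.median_decimate(ratio, decim)
        io.write_bedgraph(decimated, outdir / f"{name}.log2.bedgraph")
        segments = cna.call_segments(decimated)
        io.write_segments_bed(segments, outdir / f"{name}.segments.bed")
        n_segments[name] = sum(1 for s in segments if s[3] != "neutral")
    report["stages"]["copy_number"] = {
        "decimation_factor": decim,
        "non_neutral_segments": n_segments,
    }

    # --- structural variants
    n_cohort = len(cohort.samples)
    all_junctions = [j for obs in cohort.samples.values() for j in obs.junctions]
    kept = sv.filter_junctions(
        all_junctions,
        n_cohort_samples=n_cohort,
        min_support=config.sv_min_support,
        recurrence_cap=config.sv_recurrence_cap,
        match_radius=config.sv_match_radius,
    )
    by_sample: dict[str, list] = {name: [] for name in cohort.samples}
    for j in kept:
        by_sample[j.sample].append(j)
    summaries = {}
    grade4_unique: dict[str, list] = {}
    for patient, (pre_name, post_name) in cohort.pairs.items():
        pre_j, post_j = by_sample[pre_name], by_sample[post_name]
        for name, own, other in ((pre_name, pre_j, post_j), (post_name, post_j, pre_j)):
            calls = [
                sv.clonality(
                    j, other,
                    af_threshold=config.sv_af_threshold,
                    match_radius=config.sv_match_radius,
                )
                for j in own
            ]
            homologies = [sv.microhomology(j, genome) for j in own]
            summaries[name] = sv.sv_summary(own, calls, homologies)
        grade4_unique[patient] = tad.grade4_unique_junctions(
            post_j, pre_j, match_radius=config.sv_match_radius
        )
    with open(outdir / "sv_summary.json", "w") as fh:
        json.dump(summaries, fh, indent=2)
    report["stages"]["structural_variants"] = {
        "n_input": len(all_junctions),
        "n_after_filters": len(kept),
        "mean_clonal_per_sample": float(
            np.mean([s["n_clonal"] for s in summaries.values()])
        ),
    }

    # --- TAD integration
    grade_groups = {
        name: ("grade_4" if name.endswith("b") else "grade_2_3")
        for name in cohort.samples
    }
    expressed = tad.expressed_filter(
        expr, grade_groups,
        min_count=config.expression_min_count,
        min_samples=config.expression_min_samples,
    )
    fold_changes = tad.progression_fold_change(expr, cohort.pairs)
    reports = tad.recurrent_tad_genes(
        grade4_unique, cohort.tads, genes, fold_changes,
        expressed_genes=expressed,
        fc_threshold=config.fc_threshold,
        min_patients=config.min_patients,
    )
    pd.DataFrame(
        [
            {
                "gene": r.gene,
                "direction": r.direction,
                "n_supporting": len(r.supporting_patients),
                "patients": ",".join(r.supporting_patients),
                "expression_only": ",".join(r.expression_only_patients),
            }
            for r in reports
        ],
        columns=["gene", "direction", "n_supporting", "patients", "expression_only"],
    ).to_csv(outdir / "tad_genes.tsv", sep="\t", index=False)
    report["stages"]["tad_integration"] = {"n_reported_genes": len(reports)}

    # --- gene-set activity
    normalized = genesets.log_normalize(expr)
    program_sets = [
        genesets.GeneSet(
            name=program,
            members=list(cohort.gene_table.index[cohort.gene_table["program"] == program]),
            provenance="simulated program",
        )
        for program in sorted(cohort.config.program_shift)
    ]
    scores = {}
    for gene_set in program_sets:
        core = genesets.correlation_filter(
            normalized, gene_set, threshold=config.correlation_threshold
        )
        activity = genesets.activity_zscore(normalized, core)
        scores[gene_set.name] = activity
        scores[f"{gene_set.name}.scaled"] = genesets.scale_unit(activity)
    pd.DataFrame(scores).to_csv(outdir / "geneset_activity.tsv", sep="\t", index_label="sample")
    report["stages"]["geneset_activity"] = {
        "sets": {s.name: len(s.members) for s in program_sets}
    }

    # --- survival
    surv_config = simulate.SurvivalConfig(seed=config.seed)
    timelines = simulate.simulate_survival_cohort(surv_config)
    survival.timelines_to_frame(timelines).to_csv(
        outdir / "timelines.tsv", sep="\t", index=False
    )
    endpoint_counts = {}
    for endpoint in survival.ENDPOINTS:
        table = survival.endpoint_table(timelines, endpoint)
        table.to_csv(outdir / f"endpoint_{endpoint}.tsv", sep="\t", index=False)
        endpoint_counts[endpoint] = int(table["event"].sum())
    report["stages"]["survival"] = {
        "n_patients": len(timelines),
        "events_per_endpoint": endpoint_counts,
    }

    for path in sorted(outdir.iterdir()):
        if path.is_file() and path.name != "report.json":
            report["manifest"][path.name] = _checksum(path)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    log.info("run complete: %d outputs in %s", len(report["manifest"]), outdir)
    return report
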