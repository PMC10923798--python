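"""Orchestration: simulate -> scan -> mktest -> geneflow -> isolation.

``run_pipeline`` executes the full analysis on either a simulated bundle or
files on disk, writes per-stage tables, and consolidates a report JSON.
Stage results are cached by an input checksum so an unchanged rerun skips
recomputation. All randomness flows from ``RunConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import eco_geo_stats as eco
from . import geneflow_recomb as gfr
from . import io_formats as io
from . import popgen_scan as pg
from . import selection_mk as mk
from . import synthetic_data as syn

log = logging.getLogger("contiscan")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    sim: syn.SimConfig | None = None
    # file inputs (used when sim is None)
    alignment_fasta: str | None = None
    vcf: str | None = None
    genes_gff: str | None = None
    recomb_gff: str | None = None
    metadata_tsv: str | None = None
    ani_tsv: str | None = None
    tree_nwk: str | None = None
    reference_fasta: str | None = None
    # analysis parameters
    window_size: int = 50_000
    window_step: int = 12_500
    neutral_window_size: int = 10_000
    neutral_window_step: int = 2_500
    outlier_q: float = 0.99
    alpha: float = 0.05
    n_perm: int = 9_999
    signal_perm: int = 999
    stage_thresholds: tuple[float, float] = gfr.DEFAULT_STAGE_THRESHOLDS
    geneflow_mode: str = "union"


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    message: str


def validate_inputs(
    aln: io.SnpAlignment,
    metadata: io.SampleMetadata | None = None,
    events: list[io.RecombEvent] | None = None,
    tree=None,
    ani: io.AniMatrix | None = None,
) -> list[ValidationIssue]:
    """Cross-check sample-ID consistency across inputs (report-only)."""
    issues: list[ValidationIssue] = []
    base = set(aln.sample_ids)
    if metadata is not None:
        ids = metadata.sample_ids
        if len(set(ids)) != len(ids):
            issues.append(ValidationIssue("error", "duplicate sample id in metadata"))
        for s in sorted(base - set(ids)):
            issues.append(ValidationIssue("warning", f"missing-in-metadata: {s}"))
        for s in sorted(set(ids) - base):
            issues.append(ValidationIssue("warning", f"extra-in-metadata: {s}"))
    if events is not None:
        carriers = set().union(*(e.carriers for e in events)) if events else set()
        for s in sorted(carriers - base):
            issues.append(ValidationIssue("warning", f"unknown-carrier: {s}"))
    if tree is not None:
        tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
        for s in sorted(base - tips):
            issues.append(ValidationIssue("warning", f"missing-in-tree: {s}"))
    if ani is not None:
        for s in sorted(base - set(ani.sample_ids)):
            issues.append(ValidationIssue("warning", f"missing-in-ani: {s}"))
    return issues


def _load_inputs(cfg: RunConfig):
    if cfg.sim is not None:
        bundle = syn.simulate_continuum(cfg.sim)
        import dendropy

        tree = dendropy.Tree.get(data=bundle.tree_newick, schema="newick",
                                 preserve_underscores=True)
        return (bundle.alignment, bundle.reference, bundle.genes,
                bundle.events, bundle.metadata, bundle.ani, tree, bundle.truth)
    if cfg.alignment_fasta:
        aln, _, reference = io.read_fasta_alignment(cfg.alignment_fasta)
    elif cfg.vcf:
        aln, _ = io.read_snp_vcf(cfg.vcf)
        reference = None
        if cfg.reference_fasta:
            from Bio import SeqIO

            reference = str(next(SeqIO.parse(cfg.reference_fasta, "fasta")).seq)
    else:
        raise ValueError("need either sim config, alignment_fasta or vcf")
    genes = io.read_gene_gff(cfg.genes_gff)[0] if cfg.genes_gff else []
    events = (
        io.read_recomb_gff(cfg.recomb_gff, aln.sample_ids, strict=False)
        if cfg.recomb_gff else []
    )
    metadata = io.read_metadata(cfg.metadata_tsv) if cfg.metadata_tsv else None
    ani = io.read_ani_matrix(cfg.ani_tsv) if cfg.ani_tsv else None
    tree = io.read_tree(cfg.tree_nwk) if cfg.tree_nwk else None
    return aln, reference, genes, events, metadata, ani, tree, None


def _windows_table(records: list[pg.WindowStatRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict[str, Any] = {"start": r.start, "end": r.end}
        for lin, d in r.per_lineage.items():
            for k, v in d.items():
                row[f"{lin}:{k}"] = v
        for (a, b), d in r.per_pair.items():
            for k, v in d.items():
                row[f"{a}|{b}:{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def _cache_key(cfg: RunConfig) -> str:
    d = dataclasses.asdict(cfg)
    d.pop("outdir", None)  # the key identifies inputs, not their destination
    for key in ("alignment_fasta", "vcf", "genes_gff", "recomb_gff",
                "metadata_tsv", "ani_tsv", "tree_nwk", "reference_fasta"):
        path = d.get(key)
        if path and Path(path).exists():
            d[key + "_sha"] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return hashlib.sha256(
        json.dumps(d, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(cfg: RunConfig, use_cache: bool = True) -> dict:
    """Run every stage in dependency order and write a consolidated report.

    Returns the report dict; artifacts land in ``cfg.outdir``. A stage
    failure aborts with a stage-labeled error and leaves a FAILED marker.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    key = _cache_key(cfg)
    report_path = outdir / "report.json"
    if use_cache and report_path.exists():
        prior = json.loads(report_path.read_text())
        if prior.get("cache_key") == key:
            log.info("cache hit; skipping recomputation")
            return prior

    report: dict[str, Any] = {"seed": cfg.seed, "cache_key": key, "stages": {}}
    stage = "load"
    try:
        t0 = time.time()
        aln, reference, genes, events, metadata, ani, tree, truth = \
            _load_inputs(cfg)
        lineage_map = metadata.lineage_map() if metadata else {}
        issues = validate_inputs(aln, metadata, events, tree, ani)
        report["validation"] = [dataclasses.asdict(i) for i in issues]
        report["stages"]["load"] = {
            "seconds": round(time.time() - t0, 3),
            "n_samples": aln.n_samples, "n_snps": aln.n_sites,
        }
        log.info("load: %d samples, %d SNPs", aln.n_samples, aln.n_sites)

        stage = "scan"
        t0 = time.time()
        specs = {
            "diversity": pg.WindowSpec(cfg.window_size, cfg.window_step),
            "neutrality": pg.WindowSpec(cfg.neutral_window_size,
                                        cfg.neutral_window_step),
        }
        scans = pg.scan_genome(aln, lineage_map, specs)
        div = scans["diversity"]
        neu = scans["neutrality"]
        _windows_table(div).to_csv(outdir / "windows_diversity.tsv",
                                   sep="\t", index=False, float_format="%.6g")
        _windows_table(neu).to_csv(outdir / "windows_neutrality.tsv",
                                   sep="\t", index=False, float_format="%.6g")
        lineages = sorted({v for v in lineage_map.values()}) if lineage_map else []
        per_lin = {}
        for lin in lineages:
            if not div or lin not in div[0].per_lineage:
                continue
            pi = float(np.nanmean([r.per_lineage[lin]["pi"] for r in div]))
            d_vals = [r.per_lineage[lin]["tajima_d"] for r in neu]
            f_vals = [r.per_lineage[lin]["fu_f"] for r in neu]
            entry = {
                "mean_pi": pi,
                "mean_tajima_d": float(np.nanmean(d_vals)),
                "mean_fu_f": float(np.nanmean(f_vals)),
            }
            finite = [v for v in d_vals if np.isfinite(v)]
            if len(finite) >= 2 and np.ptp(finite) > 0:
                entry["tajima_departure"] = pg.neutrality_departure_test(d_vals)
            per_lin[lin] = entry
        per_pair = {}
        if div:
            for pair in div[0].per_pair:
                per_pair["|".join(pair)] = {
                    "mean_fst": float(np.nanmean(
                        [r.per_pair[pair]["fst"] for r in div])),
                    "mean_dxy": float(np.nanmean(
                        [r.per_pair[pair]["dxy"] for r in div])),
                }
        regions = pg.outlier_regions(div, q=cfg.outlier_q, genes=genes) \
            if per_pair else []
        pd.DataFrame([
            {"start": r.start, "end": r.end, "mean_fst": r.mean_fst,
             "mean_dxy": r.mean_dxy, "genes": ",".join(r.gene_ids)}
            for r in regions
        ]).to_csv(outdir / "outlier_regions.tsv", sep="\t", index=False,
                  float_format="%.6g")
        report["per_lineage"] = per_lin
        report["per_pair"] = per_pair
        report["outlier_regions"] = [
            {"start": r.start, "end": r.end, "genes": r.gene_ids}
            for r in regions
        ]
        report["stages"]["scan"] = {"seconds": round(time.time() - t0, 3),
                                    "n_windows": len(div)}
        log.info("scan: %d diversity windows, %d regions", len(div), len(regions))

        stage = "mktest"
        t0 = time.time()
        mk_summary: dict[str, Any] = {}
        if genes and reference is not None and lineage_map:
            mk_res = mk.genomewide_mk(genes, aln, lineage_map, reference,
                                      alpha=cfg.alpha, outlier_regions=regions)
            rows = []
            for lin, results in mk_res.items():
                for r in results:
                    rows.append({"lineage": lin, **dataclasses.asdict(r)})
            pd.DataFrame(rows).to_csv(outdir / "mk_results.tsv", sep="\t",
                                      index=False, float_format="%.6g")
            positive = sorted({
                r.gene_id for results in mk_res.values() for r in results
                if r.selection_class == "positive"
            })
            negative = sorted({
                r.gene_id for results in mk_res.values() for r in results
                if r.selection_class == "negative"
            })
            candidates = sorted({
                r.gene_id for results in mk_res.values() for r in results
                if r.selection_class == "positive" and r.in_outlier_region
            })
            mk_summary = {
                "n_positive": len(positive), "n_negative": len(negative),
                "positive_genes": positive, "candidate_genes": candidates,
            }
        report["mk"] = mk_summary
        report["stages"]["mktest"] = {"seconds": round(time.time() - t0, 3)}

        stage = "geneflow"
        t0 = time.time()
        gf_summary: dict[str, Any] = {}
        if events and lineage_map:
            matrix = gfr.geneflow_fractions(events, lineage_map,
                                            aln.genome_length,
                                            mode=cfg.geneflow_mode)
            summed = gfr.geneflow_fractions(events, lineage_map,
                                            aln.genome_length, mode="summed")
            stages_up = gfr.upcel_stages(
                matrix if cfg.geneflow_mode == "union" else
                gfr.geneflow_fractions(events, lineage_map, aln.genome_length,
                                       mode="union"),
                thresholds=cfg.stage_thresholds,
            )
            strains = gfr.all_strain_recomb_params(events, aln, lineage_map)
            pd.DataFrame([dataclasses.asdict(s) for s in strains]).to_csv(
                outdir / "strain_recomb.tsv", sep="\t", index=False,
                float_format="%.6g")
            pd.DataFrame([
                {"pair": "|".join(u.pair), "p_div": u.p_div, "stage": u.stage}
                for u in stages_up
            ]).to_csv(outdir / "upcel_stages.tsv", sep="\t", index=False,
                      float_format="%.6g")
            gf_summary = {
                "fraction_within": matrix.fraction_within,
                "fraction_between": {
                    "|".join(k): v for k, v in matrix.fraction_between.items()
                },
                "fraction_between_summed": {
                    "|".join(k): v for k, v in summed.fraction_between.items()
                },
                "upcel": [
                    {"pair": "|".join(u.pair), "p_div": u.p_div,
                     "stage": u.stage} for u in stages_up
                ],
                "mean_rm": float(np.nanmean([s.rm for s in strains])),
                "mean_rho_theta": float(np.nanmean(
                    [s.rho_theta for s in strains])),
            }
        report["geneflow"] = gf_summary
        report["stages"]["geneflow"] = {"seconds": round(time.time() - t0, 3)}

        stage = "isolation"
        t0 = time.time()
        iso: dict[str, Any] = {}
        if ani is not None and metadata is not None:
            gen_d = eco.genetic_distance_matrix(ani)
            geo_d = eco.geo_distance_matrix(metadata)
            m = eco.mantel_test(gen_d, geo_d, n_perm=cfg.n_perm, seed=cfg.seed)
            iso["mantel_geo"] = {"r": m.r, "p": m.p, "n_perm": m.n_perm}
            env_cols = metadata.env_columns()
            if env_cols:
                env_d = eco.env_distance_matrix(metadata)
                me = eco.mantel_test(gen_d, env_d, n_perm=cfg.n_perm,
                                     seed=cfg.seed + 1)
                iso["mantel_env"] = {"r": me.r, "p": me.p, "n_perm": me.n_perm}
            iso["ani_clusters"] = len(set(
                eco.ani_cluster(ani, threshold=95.0).values()))
            if "hgt_count" in metadata.table.columns:
                h = eco.hgt_per_mb(metadata)
                iso["hgt"] = {"spearman_rho": h["spearman_rho"],
                              "pearson_r": h["pearson_r"]}
            if tree is not None and env_cols:
                sig = eco.phylogenetic_signal(
                    tree, metadata.table[env_cols], n_perm=cfg.signal_perm,
                    seed=cfg.seed)
                iso["signal"] = [dataclasses.asdict(s) for s in sig]
                pd.DataFrame(iso["signal"]).to_csv(
                    outdir / "phylo_signal.tsv", sep="\t", index=False,
                    float_format="%.6g")
        report["isolation"] = iso
        report["stages"]["isolation"] = {"seconds": round(time.time() - t0, 3)}

        if truth is not None:
            tr = {"island": truth.island,
                  "selected_genes": truth.selected_genes}
            if truth.island and regions:
                best = max(
                    pg.jaccard_interval(truth.island, (r.start, r.end))
                    for r in regions
                )
                tr["island_best_jaccard"] = best
            report["truth_comparison"] = tr
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report_path.write_text(json.dumps(report, indent=1, sort_keys=True,
                                      default=str) + "\n")
    return report
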