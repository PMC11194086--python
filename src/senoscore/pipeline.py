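"""End-to-end orchestration of the analysis stages from a single config.

Stages run in order simulate -> qc -> recover -> rank -> signatures ->
classify -> de (+ bootstrap) -> enrichment -> chromatin; every inter-stage
product is written to (and read back from) declared files under the output
directory, and a provenance record captures the full config, software
version, per-file checksums and stage timings, sufficient to re-run any
stage bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import yaml

from . import __version__, chromatin, de, enrichment, qc, recovery, signature, syndata
from . import io as sio

logger = logging.getLogger(__name__)

STAGES = [
    "simulate", "qc", "recover", "rank", "signatures",
    "classify", "de", "enrichment", "chromatin",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def default_config(out_dir="pipeline_out", seed: int = 0) -> dict:
    """A small, fast demo configuration exercising every stage."""
    return {
        "seed": seed,
        "out_dir": str(out_dir),
        "stages": {name: True for name in STAGES},
        "sim": {"n_cells": 500, "n_genes": 600, "depth_lognormal": (6.9, 0.35),
                "mito_shift": 1.2,
                "module_sizes": {"maturation": 60, "isg": 30, "sasp": 20},
                "module_loadings": {"maturation": 0.9, "isg": 0.6, "sasp": 0.0}},
        "landscape": {"n_promoter_sites": 8, "n_intervening_sites": 10,
                      "n_boundary_sites": 8, "n_other_sites": 6,
                      "n_extra_promoters": 6, "n_extra_enhancers": 6,
                      "n_inactive_tss": 8, "n_null_regions": 50},
        "intensity": {"n_cells": 500},
        "qc": {"profile": "tenx", "min_ex": 3.5, "min_frac": 0.02},
        "recover": {"n_components": 20, "ridge": 1e-2},
        "signature": {"N": 100, "n_bins": 25, "n_ctrl": 100},
        "classify": {"upper_pct": 70.0, "lower_pct": 30.0},
        "de": {"padj_max": 0.05, "min_fc": 1.0, "n_cycles": 150, "n_cells": 200},
        "enrichment": {"n_perm": 200, "weight_p": 1.0, "min_overlap": 5},
        "chromatin": {"pvalue_max": 1e-4, "padj_max": 0.05, "min_fc": 1.5},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = default_config(cfg.get("out_dir", "pipeline_out"), cfg.get("seed", 0))
    for key, value in cfg.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            base[key].update(value)
        else:
            base[key] = value
    return base


def _read_counts(fix: Path) -> qc.CountMatrix:
    counts = scipy.io.mmread(fix / "counts.mtx").tocsr()
    genes = pd.read_csv(fix / "features.tsv", sep="\t", header=None)[0].to_numpy()
    cells = pd.read_csv(fix / "barcodes.tsv", sep="\t", header=None)[0].to_numpy()
    meta = pd.read_csv(fix / "cell_meta.tsv", sep="\t", index_col=0)
    return qc.CountMatrix(counts=counts, gene_names=genes, cell_ids=cells, cell_meta=meta)


def run_pipeline(config: dict) -> dict:
    """Execute the enabled stages; return the provenance record."""
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    fix = out / "fixtures"
    seed = int(config["seed"])
    stages_on = config["stages"]
    provenance: dict = {
        "version": __version__,
        "config": config,
        "stages": {},
    }

    def _record(stage: str, t0: float, outputs: list[Path]) -> None:
        provenance["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": {p.name: sio.sha256_file(p) for p in outputs if p.exists()},
        }

    try:
        if stages_on.get("simulate"):
            t0 = time.time()
            sim_cfg = syndata.SimConfig(seed=seed, **config.get("sim", {}))
            pop = syndata.generate_cell_population(sim_cfg)
            land_cfg = syndata.LandscapeConfig(seed=seed + 1, **config.get("landscape", {}))
            land = syndata.generate_regulatory_landscape(land_cfg)
            img_cfg = syndata.IntensityConfig(seed=seed + 2, **config.get("intensity", {}))
            table = syndata.generate_intensity_table(img_cfg)
            syndata.write_fixtures(pop, land, table, fix)
            _record("simulate", t0, list(fix.iterdir()))

        ex_file = out / "ex.tsv"
        if stages_on.get("qc"):
            t0 = time.time()
            counts = _read_counts(fix)
            metrics = qc.compute_cell_qc(counts)
            metrics.to_csv(out / "cell_qc.tsv", sep="\t")
            kept = qc.filter_cells(counts, metrics, config["qc"]["profile"])
            if kept.counts.shape[1] == 0:
                raise PipelineError("qc", "no cells passed the filter")
            ex = qc.transform_ex(kept)
            ex = qc.filter_genes(ex, config["qc"]["min_ex"], config["qc"]["min_frac"])
            ex.to_frame().to_csv(ex_file, sep="\t")
            kept_genes = pd.Series(ex.gene_names)
            kept_genes.to_csv(out / "kept_genes.tsv", sep="\t", header=False, index=False)
            pd.Series(ex.cell_ids).to_csv(out / "kept_cells.tsv", sep="\t",
                                          header=False, index=False)
            _record("qc", t0, [out / "cell_qc.tsv", ex_file])

        rec_file = out / "recovered.tsv"
        rel_file = out / "reliability.tsv"
        if stages_on.get("recover"):
            t0 = time.time()
            counts = _read_counts(fix)
            kept_cells = pd.read_csv(out / "kept_cells.tsv", sep="\t", header=None)[0]
            kept_genes = pd.read_csv(out / "kept_genes.tsv", sep="\t", header=None)[0]
            sub = counts.subset(
                gene_mask=np.isin(counts.gene_names, kept_genes),
                cell_mask=np.isin(counts.cell_ids, kept_cells),
            )
            rec = recovery.recover_expression(sub, **config.get("recover", {}))
            rec.to_frame().to_csv(rec_file, sep="\t")
            pd.Series(rec.reliability, index=rec.gene_names, name="w").to_csv(
                rel_file, sep="\t")
            _record("recover", t0, [rec_file, rel_file])

        rank_file = out / "ranking.tsv"
        marker = config.get("marker", "CDKN2A")
        if stages_on.get("rank"):
            t0 = time.time()
            lam = pd.read_csv(rec_file, sep="\t", index_col=0)
            w = pd.read_csv(rel_file, sep="\t", index_col=0)["w"]
            rec = recovery.RecoveredExpression(
                lambda_hat=lam.to_numpy(), prior_mean=lam.to_numpy(),
                prior_dispersion=np.zeros(len(lam)), cell_size=np.ones(lam.shape[1]),
                posterior_var=np.zeros_like(lam.to_numpy()),
                reliability=w.reindex(lam.index).to_numpy(),
                gene_names=lam.index.to_numpy(), cell_ids=lam.columns.to_numpy(),
            )
            ranking = recovery.rank_genes_by_marker(rec, marker)
            ranking.table.to_csv(rank_file, sep="\t")
            _record("rank", t0, [rank_file])

        scores_file = out / "scores.tsv"
        if stages_on.get("signatures"):
            t0 = time.time()
            table = pd.read_csv(rank_file, sep="\t", index_col=0)
            ranking = recovery.GeneCorrelationRanking(marker=marker, table=table)
            lam = pd.read_csv(rec_file, sep="\t", index_col=0)
            es = qc.scale_genes(np.log2(lam + 1.0), lam.index.to_numpy(),
                                lam.columns.to_numpy())
            sig_cfg = config["signature"]
            sig = signature.build_marker_signature(ranking, sig_cfg["N"])
            ex = pd.read_csv(ex_file, sep="\t", index_col=0)
            means = ex.mean(axis=1)
            ctrl = signature.match_control_genes(
                sig, means, sig_cfg["n_bins"], sig_cfg["n_ctrl"], seed=seed)
            vectors = [signature.score_modules(es, sig, ctrl)]
            modules = sio.read_gmt(fix / "modules.gmt")
            for name, genes in modules.items():
                present = [g for g in genes if g in lam.index]
                if len(present) < 5:
                    continue
                msig = signature.GeneSignature(name=name, genes=present, source="external")
                mctrl = signature.match_control_genes(
                    msig, means, sig_cfg["n_bins"], sig_cfg["n_ctrl"], seed=seed)
                vectors.append(signature.score_modules(es, msig, mctrl))
            frame = pd.concat([v.scores for v in vectors], axis=1)
            frame.to_csv(scores_file, sep="\t")
            if len(vectors) >= 2:
                corr = signature.correlate_signatures(vectors)
                corr.R.to_csv(out / "signature_correlations.tsv", sep="\t")
            _record("signatures", t0, [scores_file, out / "signature_correlations.tsv"])

        labels_file = out / "labels.tsv"
        if stages_on.get("classify"):
            t0 = time.time()
            lam = pd.read_csv(rec_file, sep="\t", index_col=0)
            if marker not in lam.index:
                raise PipelineError("classify", f"marker {marker} missing")
            labels = signature.classify_cells_by_value(
                lam.loc[marker], config["classify"]["upper_pct"],
                config["classify"]["lower_pct"])
            labels.labels.rename("label").to_csv(labels_file, sep="\t")
            _record("classify", t0, [labels_file])

        de_file = out / "de.tsv"
        land_de_file = out / "landscape_de.tsv"
        if stages_on.get("de"):
            t0 = time.time()
            ex = pd.read_csv(ex_file, sep="\t", index_col=0)
            lab = pd.read_csv(labels_file, sep="\t", index_col=0)["label"]
            labels = signature.CellClassLabels(
                labels=lab, upper_threshold=np.nan, lower_threshold=np.nan,
                upper_pct=config["classify"]["upper_pct"],
                lower_pct=config["classify"]["lower_pct"])
            meta = pd.read_csv(fix / "cell_meta.tsv", sep="\t", index_col=0)
            fit = de.fit_hurdle(ex, labels, covariates=meta)
            result = de.test_de(fit, config["de"]["padj_max"], config["de"]["min_fc"])
            ci = de.bootstrap_log2fc(ex, labels, config["de"]["n_cycles"],
                                     config["de"]["n_cells"], seed=seed)
            merged = result.table.join(ci.table[["ci_low", "ci_high"]])
            merged.to_csv(de_file, sep="\t")
            # differential call on the landscape's planted expression counts
            gcounts = pd.read_csv(fix / "gene_counts.tsv", sep="\t", index_col=0)
            gcond = pd.read_csv(fix / "region_condition.tsv", sep="\t", index_col=0)[
                "condition"]
            gres = chromatin.differential_region_test(
                gcounts, gcond, config["chromatin"]["padj_max"],
                config["chromatin"]["min_fc"])
            gres.table.to_csv(land_de_file, sep="\t")
            _record("de", t0, [de_file, land_de_file])

        if stages_on.get("enrichment"):
            t0 = time.time()
            table = pd.read_csv(rank_file, sep="\t", index_col=0)
            ranked = enrichment.RankedGeneList.from_series(table["r_adj"])
            sets = sio.read_gmt(fix / "modules.gmt")
            enr_cfg = config["enrichment"]
            gsea = enrichment.gsea_preranked(
                ranked, sets, enr_cfg["weight_p"], enr_cfg["n_perm"], seed=seed,
                min_overlap=enr_cfg["min_overlap"])
            gsea.table.to_csv(out / "gsea.tsv", sep="\t")
            de_table = pd.read_csv(de_file, sep="\t", index_col=0)
            hits = de_table.index[
                de_table["significant"].fillna(False) & (de_table["log2fc"] > 0)
            ].tolist()
            if hits:
                ora = enrichment.ora_hypergeometric(
                    hits, sets, de_table.index.tolist())
                ora.table.to_csv(out / "ora.tsv", sep="\t")
            _record("enrichment", t0, [out / "gsea.tsv", out / "ora.tsv"])

        if stages_on.get("chromatin"):
            t0 = time.time()
            tss = pd.read_csv(fix / "tss.tsv", sep="\t")
            peaks = {m: sio.read_bed(fix / f"peaks_{m}.bed")
                     for m in ["H3K27ac", "H3K4me1", "H3K4me3", "ATAC", "CTCF"]}
            with open(fix / "truth.json") as fh:
                chrom_sizes = json.load(fh)["chrom_sizes"]
            promoters = chromatin.call_active_promoters(
                tss, peaks, chrom_sizes=chrom_sizes)
            promoters.to_csv(out / "promoters.tsv", sep="\t", index=False)
            enhancers = chromatin.call_enhancers(
                peaks["H3K27ac"], peaks["H3K4me1"],
                chromatin.promoter_windows(promoters))
            enhancers = chromatin.link_nearest_gene(enhancers, tss)
            enhancers.to_csv(out / "enhancers.tsv", sep="\t", index=False)

            counts = pd.read_csv(fix / "region_counts.tsv", sep="\t", index_col=0)
            cond = pd.read_csv(fix / "region_condition.tsv", sep="\t", index_col=0)[
                "condition"]
            diff = chromatin.differential_region_test(
                counts, cond, config["chromatin"]["padj_max"],
                config["chromatin"]["min_fc"])
            diff.table.to_csv(out / "diffbind.tsv", sep="\t")

            seqs = sio.read_fasta(fix / "ctcf_sequences.fasta")
            _, pfm = sio.read_jaspar_pfm(fix / "ctcf_pwm.jaspar")
            pwm = chromatin.PWM.from_counts(pfm)
            motif = chromatin.scan_pwm(seqs, pwm, config["chromatin"]["pvalue_max"])
            motif.to_csv(out / "motif_scan.tsv", sep="\t")

            sites = sio.read_bed(fix / "ctcf_sites.bed")
            passed = motif.index[motif["passed"]]
            sites = sites[sites["name"].isin(passed)].reset_index(drop=True)
            tads = sio.read_bed(fix / "tad_boundaries.bed")
            catalog = chromatin.categorize_ctcf_sites(
                sites, promoters, enhancers, tss, tads)
            catalog.to_csv(out / "ctcf_catalog.tsv", sep="\t")

            if not land_de_file.exists():
                raise PipelineError(
                    "chromatin",
                    "missing DE result: the boundary-upregulation test needs "
                    "the de stage output")
            gres = pd.read_csv(land_de_file, sep="\t", index_col=0)
            upregulated = set(gres.index[gres["class"] == "increased"])
            universe = set(gres.index)
            change = diff.table["log2fc"].reindex(catalog.index)
            try:
                btest = chromatin.boundary_upregulation_test(
                    catalog, change, upregulated, universe)
            except ValueError as err:
                btest = {"p": np.nan, "note": str(err)}
            with open(out / "boundary_test.json", "w") as fh:
                json.dump(btest, fh, indent=2)
            _record("chromatin", t0, [
                out / "promoters.tsv", out / "enhancers.tsv", out / "diffbind.tsv",
                out / "motif_scan.tsv", out / "ctcf_catalog.tsv",
                out / "boundary_test.json"])
    except PipelineError:
        raise
    except Exception as err:
        stage = [s for s in STAGES if s not in provenance["stages"]]
        raise PipelineError(stage[0] if stage else "unknown", str(err)) from err

    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)
    return provenance
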