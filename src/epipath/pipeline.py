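"""End-to-end pipeline: QC -> pairwise scan -> dosage refinement ->
locus mapping -> haplotype windows -> pathway enrichment.

Each stage writes one TSV into the output directory plus a JSON manifest
recording parameters, seed, row counts, and wall time.  Existing stage
outputs are reused on rerun unless ``force`` is set.  TSV numbers use
6-significant-digit formatting so identical runs are byte-identical.
"""
from __future__ import annotations

import json
import logging
import time
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import epistasis, haplotype, locus_mapping, pathway
from .config import PipelineConfig
from .genotype_io import (GenotypeMatrix, QCThresholds, read_plink_binary,
                          read_plink_text, qc_filter)

__all__ = ["run_pipeline", "load_genotypes", "write_tsv"]

logger = logging.getLogger(__name__)

STAGES = ("qc", "scan", "refine", "map", "haplotype", "gsea")


def _fmt(x) -> str:
    if isinstance(x, float):
        return "nan" if np.isnan(x) else f"{x:.6g}"
    return str(x)


def write_tsv(df: pd.DataFrame, path: Path) -> int:
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")
    return len(df)


def load_genotypes(prefix: str) -> GenotypeMatrix:
    """Load ``prefix``.bed/.bim/.fam if present, else ``prefix``.ped/.map."""
    p = Path(prefix)
    if p.with_suffix(".bed").exists():
        return read_plink_binary(p.with_suffix(".bed"), p.with_suffix(".bim"),
                                 p.with_suffix(".fam"))
    if p.with_suffix(".ped").exists():
        return read_plink_text(p.with_suffix(".ped"), p.with_suffix(".map"))
    raise FileNotFoundError(f"no genotype files found at prefix {prefix!r}")


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "epipath",
        "version": _pkg_version("epipath"),
        "seed": config.seed,
        "parameters": {
            "qc": config.qc, "scan": config.scan,
            "haplotype": config.haplotype, "gsea": config.gsea,
        },
        "stages": {},
    }

    def record(stage: str, path: Path | None, n_rows: int, t0: float,
               reused: bool = False, note: str | None = None) -> None:
        manifest["stages"][stage] = {
            "output": path.name if path else None,
            "n_rows": n_rows,
            "wall_time_s": round(time.monotonic() - t0, 3),
            "reused": reused,
            **({"note": note} if note else {}),
        }

    # --- qc -----------------------------------------------------------------
    t0 = time.monotonic()
    matrix = load_genotypes(config.genotypes)
    thresholds = QCThresholds(
        maf_min=config.qc["maf_min"],
        hwe_p_min=config.qc["hwe_p_min"],
        max_missing_per_snp=config.qc["max_missing"],
    )
    matrix = qc_filter(matrix, thresholds)
    qc_path = out_dir / "qc_variants.tsv"
    qc_df = pd.DataFrame(
        [(v.snp_id, v.chrom, v.pos_bp, v.allele_a1, v.allele_a2, v.maf)
         for v in matrix.variants],
        columns=["snp_id", "chrom", "pos_bp", "a1", "a2", "maf"],
    )
    write_tsv(qc_df, qc_path)
    record("qc", qc_path, len(qc_df), t0)

    # --- scan ---------------------------------------------------------------
    t0 = time.monotonic()
    scan_path = out_dir / "scan_pairs.tsv"
    scan_cfg = epistasis.ScanConfig(
        p_screen=config.scan["p_screen"], alpha=config.scan["alpha"],
        min_maf=config.qc["maf_min"],
    )
    if scan_path.exists() and not force:
        scan_df = pd.read_csv(scan_path, sep="\t")
        n_planned = epistasis.n_pairs(matrix.n_variants)
        record("scan", scan_path, len(scan_df), t0, reused=True)
    else:
        result = epistasis.pairwise_scan(matrix, scan_cfg)
        chrom_of = {v.snp_id: v.chrom for v in matrix.variants}
        scan_df = pd.DataFrame(
            [(s.snp1_id, chrom_of[s.snp1_id], s.snp2_id, chrom_of[s.snp2_id],
              s.z, s.p_z, s.beta_int, s.p_dosage, s.n_used)
             for s in result.interactions],
            columns=["snp1", "chr1", "snp2", "chr2", "z", "p_z",
                     "beta_int", "p_dosage", "n_used"],
        )
        write_tsv(scan_df, scan_path)
        n_planned = result.n_tests_planned
        record("scan", scan_path, len(scan_df), t0,
               note=f"tests planned {n_planned}, skipped {result.n_skipped}")
    manifest["n_tests_planned"] = int(n_planned)
    manifest["bonferroni_threshold"] = epistasis.bonferroni_threshold(
        scan_cfg.alpha, n_planned)

    # --- refine -------------------------------------------------------------
    t0 = time.monotonic()
    refine_path = out_dir / "refined_pairs.tsv"
    screened = scan_df[scan_df["p_z"] < scan_cfg.p_screen].copy()
    write_tsv(screened, refine_path)
    record("refine", refine_path, len(screened), t0)

    # --- map ----------------------------------------------------------------
    t0 = time.monotonic()
    map_path = out_dir / "locus_pairs.tsv"
    pairs: list[locus_mapping.LocusPair] = []
    if config.annotation:
        annotation = locus_mapping.read_bed4(config.annotation)
        interactions = [
            epistasis.InteractionStat(r.snp1, r.snp2, float(r.z), float(r.p_z))
            for r in screened.itertuples(index=False)
        ]
        variants = {v.snp_id: v for v in matrix.variants}
        pairs = locus_mapping.apply_exclusion_criteria(
            interactions, variants, annotation)
        map_df = pd.DataFrame(
            [(p.locus1_id, p.locus2_id, len(p.supporting_interactions),
              p.distinct_snps1, p.distinct_snps2, p.best_p) for p in pairs],
            columns=["locus1", "locus2", "n_support", "n_snps1", "n_snps2",
                     "best_p"],
        )
        write_tsv(map_df, map_path)
        record("map", map_path, len(map_df), t0)
    else:
        record("map", None, 0, t0, note="no annotation supplied; skipped")

    # --- haplotype ----------------------------------------------------------
    t0 = time.monotonic()
    hap_path = out_dir / "haplotypes.tsv"
    hap_rows = []
    if pairs:
        top = pairs[0]
        pos_of = {v.snp_id: v.pos_bp for v in matrix.variants}
        for side_snps in _locus_side_snps(top, matrix):
            side_snps.sort(key=lambda s: pos_of[s])
            if len(side_snps) < 2:
                continue
            sizes = [s for s in config.haplotype["window_sizes"]
                     if s <= len(side_snps)]
            if not sizes:
                continue
            for window in haplotype.sliding_windows(side_snps, sizes):
                tc = haplotype.em_haplotype_frequencies(matrix, window, "cases")
                tk = haplotype.em_haplotype_frequencies(matrix, window, "controls")
                tests = haplotype.haplotype_case_control_test(
                    tc, tk, int(matrix.case_mask.sum()),
                    int(matrix.control_mask.sum()))
                for t in tests:
                    hap_rows.append(("|".join(window), t.haplotype,
                                     t.freq_cases, t.freq_controls,
                                     t.chi2, t.df, t.p))
    hap_df = pd.DataFrame(
        hap_rows, columns=["window", "haplotype", "f_a", "f_u", "chi2", "df", "p"])
    write_tsv(hap_df, hap_path)
    record("haplotype", hap_path, len(hap_df), t0,
           note=None if pairs else "no locus pair retained; empty output")

    # --- gsea ---------------------------------------------------------------
    t0 = time.monotonic()
    gsea_path = out_dir / "pathways.tsv"
    if config.gene_sets and config.annotation and config.gsea["n_perm"] > 0:
        gene_sets = pathway.read_gmt(config.gene_sets)
        annotation = locus_mapping.read_bed4(config.annotation)
        covered = {
            g.gene_id for g in pathway.gene_level_stats(
                matrix, annotation, flank=config.gsea["flank"])
        }
        gene_sets = pathway.filter_gene_sets(
            gene_sets, covered, config.gsea["min_size"], config.gsea["max_size"])
        results = pathway.gsea_permutation_test(
            matrix, annotation, gene_sets,
            n_perm=config.gsea["n_perm"], seed=config.seed,
            flank=config.gsea["flank"])
        gsea_df = pd.DataFrame(
            [(r.set_id, r.n_members, r.es, r.nes, r.empirical_p, r.fdr, r.fwer)
             for r in results],
            columns=["set_id", "n_members", "es", "nes", "empirical_p",
                     "fdr", "fwer"],
        )
        write_tsv(gsea_df, gsea_path)
        record("gsea", gsea_path, len(gsea_df), t0)
    else:
        record("gsea", None, 0, t0,
               note="no gene sets/annotation or n_perm=0; skipped")

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %s", manifest_path)
    return manifest


def _locus_side_snps(pair: locus_mapping.LocusPair,
                     matrix: GenotypeMatrix) -> list[list[str]]:
    side1, side2 = set(), set()
    for it in pair.supporting_interactions:
        side1.add(it.snp1_id)
        side2.add(it.snp2_id)
    present = set(v.snp_id for v in matrix.variants)
    return [sorted(side1 & present), sorted(side2 & present)]
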