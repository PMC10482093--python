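"""End-to-end pipeline: score -> fit -> associate -> interact -> gene set
-> PRS -> risk-by-diet grid, with a JSON run manifest.

Inputs come either from files (FFQ/covariate TSVs, ``.raw``/VCF genotypes,
PRS weight TSV, gene-location TSV, GMT) or, when paths are omitted, from
the seeded synthetic cohort generator — in which case PRS weights, gene
locations and gene sets are also synthesized so the run is self-contained.
Outputs are one TSV per stage plus ``manifest.json`` capturing the seed and
a hash of the configuration; a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ngio
from .association import (fit_association, group_association, standardize,
                          tertile_groups)
from .cohort_stats import build_table1
from .genetics import (compute_prs, filter_hits, gene_set_test, gene_test,
                       interaction_records_frame, interaction_scan,
                       map_snps_to_genes, risk_by_diet_grid)
from .hiscom import HiscomModel, select_lambda1
from .plsda import PlsdaModel
from .rfs import indicator_matrix
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger("nutrigen")


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for one pipeline run.

    With all paths ``None`` a synthetic cohort of ``n_subjects`` is drawn
    from ``seed``. Tertile fractions default to the 33.33%/66.6% rank cuts;
    alpha thresholds to 0.05 (scan) and 0.001 (stringent subset); the FDR
    q threshold to 0.1.
    """

    out_dir: str = "results"
    ffq_path: str | None = None
    covariates_path: str | None = None
    phenotype_path: str | None = None
    genotypes_path: str | None = None
    genotype_format: str | None = None
    prs_weights_path: str | None = None
    gene_locations_path: str | None = None
    gmt_path: str | None = None
    seed: int = 0
    n_subjects: int = 1000
    n_snps: int = 50
    lambda1: float | str = 1.0  # numeric, or "auto" for 5-fold CV
    lambda1_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    permutations: int = 0  # 0 disables permutation inference in the pipeline
    tertile_fractions: tuple[float, float] = (0.3333, 0.666)
    alpha: float = 0.05
    alpha_strict: float = 0.001
    fdr_q: float = 0.1
    gene_window_kb: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.tertile_fractions
        if not 0 < lo < hi < 1:
            raise ValueError("tertile fractions must be increasing in (0,1)")
        for a in (self.alpha, self.alpha_strict, self.fdr_q):
            if not 0 < a <= 1:
                raise ValueError("thresholds must lie in (0, 1]")

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _synthesize_aux(cohort, rng: np.random.Generator):
    """Deterministic PRS weights, gene locations and gene sets for a
    self-contained synthetic run (all labelled synthetic)."""
    info = cohort.snp_info
    weights = pd.DataFrame({
        "snp": info.index,
        "effect_allele": info["a1"].to_numpy(),
        "beta": np.round(rng.normal(0.0, 0.1, len(info)), 6),
    })
    genes = []
    snps = list(info.index)
    for gi in range(0, len(snps), 4):  # 4 SNPs per synthetic gene
        block = info.iloc[gi:gi + 4]
        chrom = block["chrom"].iloc[0]
        same = block[block["chrom"] == chrom]
        genes.append({"gene": f"GENE{gi//4+1:03d}", "chrom": chrom,
                      "start": int(same["pos"].min()) - 1000,
                      "end": int(same["pos"].max()) + 1000})
    gene_loc = pd.DataFrame(genes)
    names = list(gene_loc["gene"])
    half = max(1, len(names) // 2)
    sets = {"SET_A": names[:half], "SET_B": names[half:] or names[:1]}
    return weights, gene_loc, sets


def _load_inputs(cfg: PipelineConfig):
    rng = np.random.default_rng(cfg.seed)
    if cfg.ffq_path is None:
        sim = SimulationConfig(n_subjects=cfg.n_subjects, n_snps=cfg.n_snps,
                               seed=cfg.seed)
        cohort = simulate_cohort(sim)
        ffq, cov, y = cohort.ffq, cohort.covariates, cohort.phenotype
        dosages, snp_info = cohort.dosages, cohort.snp_info
        weights, gene_loc, sets = _synthesize_aux(cohort, rng)
        return ffq, cov, y, dosages, snp_info, weights, gene_loc, sets, True
    ffq = ngio.read_tsv(cfg.ffq_path)
    cov = ngio.read_tsv(cfg.covariates_path)
    y = ngio.read_tsv(cfg.phenotype_path).iloc[:, 0]
    dosages, snp_info = ngio.read_genotypes(cfg.genotypes_path,
                                            cfg.genotype_format)
    weights = (ngio.read_prs_weights(cfg.prs_weights_path)
               if cfg.prs_weights_path else None)
    gene_loc = (ngio.read_gene_locations(cfg.gene_locations_path)
                if cfg.gene_locations_path else None)
    sets = ngio.read_gmt(cfg.gmt_path) if cfg.gmt_path else None
    return ffq, cov, y, dosages, snp_info, weights, gene_loc, sets, False


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages in order; returns the results directory.

    Any stage failure aborts with the stage name and cause. Rerunning with
    the same config and seed reproduces every output byte-for-byte.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    manifest: dict = {"seed": config.seed, "config_digest": config.digest(),
                      "stages": []}

    def _log(stage, n_in, n_out, t0):
        logger.info("stage=%s n_in=%d n_out=%d elapsed=%.2fs",
                    stage, n_in, n_out, time.time() - t0)
        manifest["stages"].append({"stage": stage, "n_in": n_in,
                                   "n_out": n_out})

    try:
        t0 = time.time()
        (ffq, cov, y, dosages, snp_info, weights, gene_loc, sets,
         synthetic) = _load_inputs(config)
        manifest["synthetic_inputs"] = synthetic
        _log(stage, len(ffq), len(ffq), t0)

        stage = "score"
        t0 = time.time()
        g = indicator_matrix(ffq)
        rfs = g.sum(axis=1).rename("rfs")
        ngio.write_tsv(rfs.to_frame(), out / "rfs.tsv")
        _log(stage, len(ffq), len(rfs), t0)

        stage = "fit"
        t0 = time.time()
        lam = (select_lambda1(g, y, config.lambda1_grid, seed=config.seed)
               if config.lambda1 == "auto" else float(config.lambda1))
        hres = HiscomModel(y, g).fit(lambda1=lam)
        if config.permutations:
            hres.permutation_test(B=config.permutations, seed=config.seed)
        pres = PlsdaModel(y, g).fit()
        hiscom_rfs = hres.score(g).rename("hiscom_rfs")
        plsda_rfs = pres.score(g).rename("plsda_rfs")
        scores = pd.concat([rfs.astype(float), hiscom_rfs, plsda_rfs], axis=1)
        ngio.write_tsv(scores.round(10), out / "scores.tsv")
        (out / "hiscom_fit.json").write_text(
            json.dumps(hres.to_dict(), indent=1, sort_keys=True))
        (out / "plsda_fit.json").write_text(
            json.dumps(pres.to_dict(), indent=1, sort_keys=True))
        _log(stage, len(g), len(scores), t0)

        stage = "table1"
        t0 = time.time()
        tbl = build_table1(cov, scores, y)
        ngio.write_tsv(tbl, out / "table1.tsv", index=False)
        _log(stage, len(cov), len(tbl), t0)

        stage = "associate"
        t0 = time.time()
        rows = []
        for name in scores.columns:
            r = fit_association(y, scores[name], cov)
            rows.append({"score": name, "term": "per_sd", "or": r.odds_ratio,
                         "l95": r.ci_low, "u95": r.ci_high, "p": r.pvalue})
            groups = tertile_groups(scores[name], config.tertile_fractions)
            for gr in group_association(y, groups, reference="high",
                                        covariates=cov):
                rows.append({"score": name, "term": gr.term,
                             "or": gr.odds_ratio, "l95": gr.ci_low,
                             "u95": gr.ci_high, "p": gr.pvalue})
        assoc = pd.DataFrame(rows)
        ngio.write_tsv(assoc.round(10), out / "association.tsv", index=False)
        _log(stage, len(scores), len(assoc), t0)

        stage = "interact"
        t0 = time.time()
        z = standardize(scores["rfs"])
        records = interaction_scan(y, dosages, z, cov, snp_info=snp_info)
        rec_df = interaction_records_frame(records)
        ngio.write_tsv(rec_df.round(10), out / "interaction_scan.tsv",
                       index=False)
        hits = filter_hits(records, config.alpha)
        _log(stage, dosages.shape[1], len(hits), t0)

        stage = "gene-set"
        t0 = time.time()
        gene_rows, set_df = [], pd.DataFrame()
        if gene_loc is not None:
            gmap = map_snps_to_genes(records, gene_loc, config.gene_window_kb)
            gene_results = []
            for gene, snps in sorted(gmap.items()):
                gres = gene_test(y, dosages[snps], z, cov, gene=gene)
                gene_results.append(gres)
                gene_rows.append({"gene": gene, "n_snps": gres.n_snps,
                                  "p": gres.pvalue})
            ngio.write_tsv(pd.DataFrame(gene_rows).round(10),
                           out / "genes.tsv", index=False)
            if sets and len(gene_results) >= 2:
                set_res = gene_set_test(gene_results, sets)
                set_df = pd.DataFrame([s.__dict__ for s in set_res])
                ngio.write_tsv(set_df.round(10), out / "gene_sets.tsv",
                               index=False)
        _log(stage, len(hits), len(gene_rows), t0)

        stage = "prs"
        t0 = time.time()
        prs_df = pd.DataFrame(index=dosages.index)
        if weights is not None:
            prs, prs_info = compute_prs(dosages, weights, snp_info)
            manifest["prs"] = prs_info
            prs_df = prs.to_frame()
            ngio.write_tsv(prs_df.round(10), out / "prs.tsv")
        _log(stage, dosages.shape[1], len(prs_df), t0)

        stage = "grid"
        t0 = time.time()
        if weights is not None:
            diet = tertile_groups(scores["rfs"], config.tertile_fractions)
            grid = risk_by_diet_grid(y, prs, diet, cov)
            ngio.write_tsv(grid.round(10), out / "risk_diet_grid.tsv",
                           index=False)
            _log(stage, len(prs), len(grid), t0)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return out
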