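"""End-to-end pipeline: simulate/load -> gene test -> selection -> effects.

The stages mirror how the methods are meant to be used on a gene: first a
groupwise Burden (or SKAT) test establishes that the gene harbors associated
variants; only then (configurable gate, default alpha = 0.05) are the
backward-elimination selection and the hierarchical effect model run, and the
per-variant report assembled.  One global seed deterministically spawns
per-stage child seeds so stages can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import assoc, backward_elim, genotype_io, hier_model, mixture, simulate

logger = logging.getLogger("rarecausal")


@dataclass
class RunConfig:
    """Full configuration of one pipeline run (YAML/JSON serializable)."""

    output_dir: str = "rarecausal_run"
    seed: int = 0
    # input: either file paths ...
    genotype_vcf: str | None = None
    genotype_tsv: str | None = None
    phenotype_tsv: str | None = None
    annotation_tsv: str | None = None
    # ... or a simulation block
    simulate: dict | None = None
    # association / gate
    maf_threshold: float = 0.05
    test: str = "burden"
    pvalue_method: str = "moment_match"
    gate_alpha: float | None = 0.05
    # backward elimination
    be_k: int = 10
    be_resamples: int = 2000
    be_weight_column: str | None = None
    # selection
    selection_mode_functional: str = "mixture"
    selection_mode_synonymous: str = "quantile"
    selection_quantile: float = 0.20
    # hierarchical model
    hm_annotation_columns: list[str] = field(default_factory=list)
    hm_tau2_grid: list[float] | None = None
    rank_by: str = "beta"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the analysis configuration (output location excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def _default_pool_slice(sim: dict, seed_pool: int, seed_slice: int):
    pool_cfg = sim.get("pool", {})
    pool = simulate.simulate_haplotypes(
        n_hap=pool_cfg.get("n_hap", 10_000),
        n_sites=pool_cfg.get("n_sites", 10_000),
        region_length=pool_cfg.get("region_length", 1_000_000),
        seed=seed_pool,
    )
    return simulate.draw_region(pool, sim.get("region_width", 10_000), seed=seed_slice)


def _simulate_input(sim: dict, seeds: list[int]):
    dm_name = sim.get("disease_model", "M1")
    dmodel = getattr(simulate.DiseaseModel, dm_name)(
        causal_fraction=sim.get("causal_fraction", 0.2),
        prevalence=sim.get("prevalence", 0.05),
    )
    amodel = simulate.AnnotationModel(ns_s_ratio=sim.get("ns_s_ratio", 1.0))
    pool_slice = _default_pool_slice(sim, seeds[0], seeds[1])
    cohort = simulate.simulate_cohort(
        pool_slice,
        dmodel,
        amodel,
        n_cases=sim.get("n_cases", 1000),
        n_controls=sim.get("n_controls", 1000),
        seed=seeds[2],
    )
    return cohort


def _write_tsv_with_hash(df, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the pipeline and return the output directory."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    config.to_yaml(str(out / "run_config.yaml"))
    seeds = _spawn_seeds(config.seed, 8)
    logger.info("run %s seeds=%s", cfg_hash, seeds)

    # --- input stage -------------------------------------------------------
    cohort = None
    if config.simulate is not None:
        cohort = _simulate_input(config.simulate, seeds[:3])
        gm, pheno, annot = cohort.genotypes, cohort.phenotypes, cohort.annotations
    elif config.genotype_vcf and config.phenotype_tsv and config.annotation_tsv:
        gm = genotype_io.read_vcf(config.genotype_vcf)
        _, pheno, annot = genotype_io.read_tables(
            config.genotype_tsv or config.phenotype_tsv,  # unused genotype TSV slot
            config.phenotype_tsv,
            config.annotation_tsv,
        )
    elif config.genotype_tsv and config.phenotype_tsv and config.annotation_tsv:
        gm, pheno, annot = genotype_io.read_tables(
            config.genotype_tsv, config.phenotype_tsv, config.annotation_tsv
        )
    else:
        raise ValueError("config must provide either input files or a simulate block")

    gm = gm.impute_missing()
    rare = gm.maf <= config.maf_threshold
    if rare.sum() < 2:
        raise RuntimeError("fewer than 2 rare variants after MAF filtering")
    gm_rare = gm.subset(rare)
    logger.info("stage input: %d samples, %d rare variants (of %d)",
                gm.n_individuals, gm_rare.n_variants, gm.n_variants)

    # --- gene-level test ---------------------------------------------------
    null = assoc.fit_null(pheno)
    rho = 1.0 if config.test == "burden" else 0.0
    gene_res = assoc.score_statistic(
        gm_rare, null, assoc.ScoreTestConfig(rho=rho, pvalue_method=config.pvalue_method)
    )
    (out / "gene_test.json").write_text(
        json.dumps(
            {
                "config_hash": cfg_hash,
                "test": config.test,
                "Q": gene_res.Q,
                "pvalue": gene_res.pvalue,
                "n_variants": gene_res.n_variants,
                "eigenvalues": list(map(float, gene_res.eigenvalues)),
            },
            indent=1,
        )
    )
    logger.info("stage gene_test: %s p=%.3g", config.test, gene_res.pvalue)
    if config.gate_alpha is not None and gene_res.pvalue > config.gate_alpha:
        logger.info("gene-level p above gate (%.3g > %.3g); stopping",
                    gene_res.pvalue, config.gate_alpha)
        return out

    # --- backward elimination per stratum ---------------------------------
    is_functional = annot.stratum(gm_rare.variant_ids)
    weights_all = None
    if config.be_weight_column:
        weights_all = annot.scores([config.be_weight_column], gm_rare.variant_ids)[:, 0]
    rc_tables = []
    selected: set[str] = set()
    for label, mask, mode in (
        ("nonsynonymous-like", is_functional, config.selection_mode_functional),
        ("synonymous", ~is_functional, config.selection_mode_synonymous),
    ):
        if mask.sum() < max(config.be_k, 2):
            logger.info("stage select: stratum %s too small (%d variants); skipped",
                        label, int(mask.sum()))
            continue
        g_str = gm_rare.subset(mask)
        cfg_be = backward_elim.BEConfig(
            k=config.be_k,
            n_resamples=config.be_resamples,
            seed=seeds[3] if label == "nonsynonymous-like" else seeds[4],
            test=config.test,
            pvalue_method=config.pvalue_method,
            weights=None if weights_all is None else weights_all[mask],
        )
        rc = backward_elim.resample_return_counts(g_str, null, cfg_be, stratum=label)
        rc_tables.append(rc.table)
        selected |= mixture.select_interesting(rc, mode=mode, q=config.selection_quantile)
    if rc_tables:
        import pandas as pd

        rc_all = pd.concat(rc_tables, ignore_index=True)
        _write_tsv_with_hash(rc_all, out / "return_counts.tsv", cfg_hash)
    logger.info("stage select: %d variants selected", len(selected))

    # --- hierarchical model ------------------------------------------------
    spec = hier_model.SecondStageSpec.from_annotations(
        annot, gm_rare.variant_ids, columns=config.hm_annotation_columns
    )
    fit = hier_model.fit_hierarchical(
        gm_rare,
        pheno,
        spec,
        hier_model.HMConfig(
            tau2_grid=None if config.hm_tau2_grid is None else np.asarray(config.hm_tau2_grid)
        ),
    )
    logger.info("stage fit: tau2_hat=%.4f", fit.tau2_hat)

    rc_map = {}
    for tbl in rc_tables:
        rc_map.update(zip(tbl["variant_id"], tbl["return_count"]))
    rc_vec = np.array([rc_map.get(v, np.nan) for v in gm_rare.variant_ids])
    report = genotype_io.build_results_table(
        gm_rare, pheno, fit.beta_hat, fit.se_beta, rc_vec, annot
    )
    report["selected"] = report["variant_id"].isin(selected).astype(int)
    _write_tsv_with_hash(report, out / "results.tsv", cfg_hash)

    ranked_sel = hier_model.rank_variants(fit, subset=selected or None, by=config.rank_by)
    (out / "selected_ranking.json").write_text(
        json.dumps({"config_hash": cfg_hash, "ranked_selected": ranked_sel}, indent=1)
    )

    # --- evaluation against known truth ------------------------------------
    if cohort is not None:
        from .evaluate import median_causal_rank, topk_causal_count

        causal = set(
            cohort.truth.index[cohort.truth["causal"]]
        ) & set(gm_rare.variant_ids)
        ranking_all = hier_model.rank_variants(fit, by=config.rank_by)
        evaluation = {
            "config_hash": cfg_hash,
            "n_causal_observed": len(causal),
            "median_rank_all": median_causal_rank(ranking_all, causal),
            "median_rank_selected": median_causal_rank(ranked_sel, causal),
            "top10_selected": topk_causal_count(ranked_sel, causal),
        }
        (out / "evaluation.json").write_text(json.dumps(evaluation, indent=1))

    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return out


# ---------------------------------------------------------------------------
# Replicate studies (benchmarking on simulated cohorts)
# ---------------------------------------------------------------------------

def run_simulation_study(
    dmodel,
    amodel,
    n_replicates: int = 50,
    seed: int = 0,
    hm_specs: dict[str, list[str]] | None = None,
    be_stratum: str = "functional",  # "functional" | "synonymous" | None
    selection_mode: str = "mixture",
    selection_q: float = 0.20,
    n_cases: int = 1000,
    n_controls: int = 1000,
    region_width: int = 10_000,
    k: int = 10,
    n_resamples: int = 2000,
    gate_alpha: float | None = 0.05,
    maf_threshold: float = 0.05,
    pool=None,
    calibration_mc_size: int = 50_000,
) -> list[dict]:
    """Simulate replicate cohorts and run selection + effect estimation.

    Analyses are conditional on the gene-level Burden test clearing the gate
    (the procedure is meant to run only on genes already showing association),
    so gated-out cohorts are skipped and further regions drawn until
    ``n_replicates`` analysable replicates accrue.

    Returns one record per replicate with the observed rare variants, truth,
    the stratum return counts and selected set, and a hierarchical-model fit
    per entry of ``hm_specs`` (name -> list of annotation score columns used
    in addition to the non-synonymous indicator).
    """
    from . import evaluate  # noqa: F401  (callers typically need it too)

    hm_specs = {"HM_S": []} if hm_specs is None else hm_specs
    seeds = _spawn_seeds(seed, 3)
    if pool is None:
        pool = simulate.simulate_haplotypes(seed=seeds[0])
    records: list[dict] = []
    attempt = 0
    max_attempts = 20 * n_replicates
    while len(records) < n_replicates and attempt < max_attempts:
        attempt += 1
        region = simulate.draw_region(pool, region_width, seed=seeds[1] + attempt)
        if region.n_sites < 2 * k:
            continue
        cohort = simulate.simulate_cohort(
            region,
            dmodel,
            amodel,
            n_cases=n_cases,
            n_controls=n_controls,
            seed=seeds[2] + attempt,
            calibration_mc_size=calibration_mc_size,
        )
        gm = cohort.genotypes
        rare = gm.maf <= maf_threshold
        if rare.sum() < 2 * k:
            continue
        gm_rare = gm.subset(rare)
        null = assoc.fit_null(cohort.phenotypes)
        if gate_alpha is not None:
            gene_p = assoc.score_statistic(gm_rare, null).pvalue
            if gene_p > gate_alpha:
                continue
        is_functional = cohort.annotations.stratum(gm_rare.variant_ids)
        rec: dict = {
            "variant_ids": list(gm_rare.variant_ids),
            "true_beta": cohort.true_beta(gm_rare.variant_ids),
            "causal": cohort.causal_mask(gm_rare.variant_ids),
            "functional": is_functional,
            "seed": seeds[2] + attempt,
        }
        if be_stratum is not None:
            mask = is_functional if be_stratum == "functional" else ~is_functional
            if mask.sum() < max(k, 10):
                continue
            rct = backward_elim.resample_return_counts(
                gm_rare.subset(mask),
                null,
                backward_elim.BEConfig(k=k, n_resamples=n_resamples, seed=rec["seed"]),
                stratum=be_stratum,
            )
            rec["rc"] = dict(zip(rct.variant_ids, rct.return_count))
            rec["selected"] = mixture.select_interesting(
                rct, mode=selection_mode, q=selection_q
            )
        rec["fits"] = {}
        for name, columns in hm_specs.items():
            spec = hier_model.SecondStageSpec.from_annotations(
                cohort.annotations, gm_rare.variant_ids, columns=columns
            )
            rec["fits"][name] = hier_model.fit_hierarchical(
                gm_rare, cohort.phenotypes, spec
            )
        records.append(rec)
    if len(records) < n_replicates:
        raise RuntimeError(
            f"only {len(records)} analysable replicates after {attempt} attempts"
        )
    return records


def rc_ranking(record: dict) -> list[str]:
    """Selected variants ranked by descending return count (ties by id)."""
    items = sorted(
        ((vid, record["rc"][vid]) for vid in record["selected"]),
        key=lambda t: (-t[1], t[0]),
    )
    return [vid for vid, _ in items]
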