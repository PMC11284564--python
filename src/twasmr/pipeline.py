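"""End-to-end synthetic vignette: meta-analysis -> model training -> TWAS ->
gene-level MR -> bidirectional trait MR -> PheWAS.

The vignette mirrors the analysis flow of a TWAS + MR study of a disease
trait: two GWAS sub-cohorts are meta-analysed, expression prediction models
are trained on a separate expression cohort drawn from the same population,
gene-disease associations are tested from summary statistics, significant
genes go to three-method MR, the disease trait is tested bidirectionally
against a second trait with locus-restricted and locus-excluded instrument
sets, and the top gene is scanned against a phenotype catalog.

Every stage writes plain TSV plus a provenance record; a fixed seed
reproduces every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._stats import ols_scan
from .gwas import LdReferencePanel, meta_analyse, write_summary_stats
from .models import (
    TrainingConfig,
    make_folds,
    regress_out_covariates,
    select_best_model,
    train_cross_tissue,
    train_elastic_net,
    train_similarity_weighted,
    write_weight_db,
)
from .mr import InsufficientInstruments, Locus, bidirectional_mr, build_instruments, run_methods
from .phewas import PhenotypeCatalog, phewas_scan
from .simulate import (
    SimulationConfig,
    default_similarity,
    gene_annotation,
    make_gwas_summary,
    simulate_case_control,
    simulate_expression,
    simulate_genotypes,
    simulate_trait_pair,
    SimulatedStudy,
)
from .twas import twas_scan

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")


@dataclass
class RunConfig:
    """Thresholds, cohort sizes and method list for one pipeline run."""

    out_dir: str = "twasmr_run"
    seed: int = 0
    n_gwas: int = 6000
    n_train: int = 300
    simulation: SimulationConfig = field(default_factory=lambda: SimulationConfig(
        n_variants=300, ld_block_size=5, n_genes=10, heritability=0.5,
        causal_fraction=0.2, gene_effect=0.8,
    ))
    training: TrainingConfig = field(default_factory=TrainingConfig)
    frameworks: tuple[str, ...] = ("elastic_net", "cross_tissue_group", "similarity_weighted")
    mr_methods: tuple[str, ...] = ("ivw", "wme", "egger")
    gwas_p_threshold: float = 5e-8
    eqtl_p_threshold: float = 1e-5
    r2_threshold: float = 0.01
    clump_window_bp: int = 250_000
    cis_window_bp: int = 1_000_000
    fdr_threshold: float = 0.10
    # BH family size for the TWAS stage.  The vignette simulates a handful
    # of genes as a stand-in for a transcriptome-wide scan (~10k imputable
    # genes), so the FDR is assessed against the configured family size;
    # set to None to correct only across the genes actually tested.
    m_total: int | None = 10_000
    trait_b_effect: float = 0.5

    def __post_init__(self) -> None:
        for name in ("gwas_p_threshold", "eqtl_p_threshold", "r2_threshold",
                     "clump_window_bp", "cis_window_bp", "fdr_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Flat key: value config file; nested simulation/training keys use
        a ``simulation.`` / ``training.`` prefix."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_kwargs = {k.split(".", 1)[1]: v for k, v in raw.items() if k.startswith("simulation.")}
        train_kwargs = {k.split(".", 1)[1]: v for k, v in raw.items() if k.startswith("training.")}
        top = {k: v for k, v in raw.items() if "." not in k}
        for key in ("frameworks", "mr_methods"):
            if key in top and isinstance(top[key], str):
                top[key] = tuple(top[key].split(","))
        cfg = cls(**top)
        if sim_kwargs:
            cfg.simulation = replace(cfg.simulation, **sim_kwargs)
        if train_kwargs:
            cfg.training = replace(cfg.training, **train_kwargs)
        return cfg


def _tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _mr_rows(direction: str, result: dict) -> list[dict]:
    rows = []
    if result["refused"]:
        rows.append({
            "direction": direction, "method": "none", "estimate": np.nan, "se": np.nan,
            "or": np.nan, "ci_low": np.nan, "ci_high": np.nan, "pvalue": np.nan,
            "n_iv": result["n_iv"], "intercept": np.nan, "intercept_p": np.nan,
            "status": "refused: " + result.get("reason", ""),
        })
        return rows
    for method, est in result["estimates"].items():
        lo, hi = est.ci()
        rows.append({
            "direction": direction, "method": method, "estimate": est.estimate,
            "se": est.se, "or": est.odds_ratio, "ci_low": float(np.exp(lo)),
            "ci_high": float(np.exp(hi)), "pvalue": est.pvalue, "n_iv": est.n_iv,
            "intercept": est.egger_intercept if est.egger_intercept is not None else np.nan,
            "intercept_p": est.intercept_p if est.intercept_p is not None else np.nan,
            "status": "ok",
        })
    return rows


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a dict of in-memory results and writes
    TSV outputs plus provenance under ``config.out_dir``.

    A stage failure raises :class:`PipelineError` naming the stage; outputs
    of completed stages are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def note(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    results: dict = {}
    stage = "setup"
    try:
        # ---- simulate one population, split into expression + GWAS cohorts
        stage = "simulate"
        n_total = config.n_train + config.n_gwas
        sim = replace(config.simulation, n_samples=n_total, seed=config.seed)
        rng = np.random.default_rng(config.seed)
        dosages, variants = simulate_genotypes(sim, rng)
        genes = gene_annotation(sim, variants)
        similarity = default_similarity(sim.n_tissues)
        expr, covars, gvals, truth = simulate_expression(
            dosages, variants, genes, sim, similarity, rng
        )
        train_rows = np.arange(config.n_train)
        gwas_rows = np.arange(config.n_train, n_total)
        ci = sim.causal_gene_index
        pool = np.arange(int(genes["window_lo"].iat[ci]), int(genes["window_hi"].iat[ci]))
        y_a, invalid, direct = simulate_case_control(
            gvals[gwas_rows, ci], dosages[gwas_rows], variants, sim, rng,
            pleiotropy_pool=pool,
        )
        truth.invalid_iv_ids = invalid
        truth.direct_effects = direct
        note(f"simulated {n_total} samples x {sim.n_variants} variants, "
             f"{len(genes)} genes; causal gene {truth.causal_gene} "
             f"(effect {sim.gene_effect}); GWAS prevalence {y_a.mean():.3f}")
        _tsv(variants, out / "variants.tsv")
        _tsv(genes, out / "genes.tsv")
        truth_json = {
            "causal_gene": truth.causal_gene,
            "true_gene_effect": truth.true_gene_effect,
            "invalid_iv_ids": truth.invalid_iv_ids,
        }
        (out / "ground_truth.json").write_text(json.dumps(truth_json, indent=2))

        # ---- stage: per-study GWAS + fixed-effect meta-analysis
        stage = "meta"
        half = len(gwas_rows) // 2
        study1 = make_gwas_summary(dosages[gwas_rows[:half]], y_a[:half], variants)
        study2 = make_gwas_summary(dosages[gwas_rows[half:]], y_a[half:], variants)
        meta = meta_analyse([study1, study2])
        write_summary_stats(study1, out / "sumstats_study1.tsv")
        write_summary_stats(study2, out / "sumstats_study2.tsv")
        write_summary_stats(meta, out / "sumstats_meta.tsv")
        n_sig = int((meta["pvalue"] < config.gwas_p_threshold).sum())
        note(f"meta-analysis: {len(meta)} variants, {n_sig} at P < {config.gwas_p_threshold}")
        results["meta"] = meta

        # ---- stage: prediction model training + selection
        stage = "train"
        tissues = list(expr)
        folds = make_folds(config.n_train, config.training.n_folds, config.seed)
        resid = {
            t: regress_out_covariates(expr[t][train_rows], covars[train_rows])
            for t in tissues
        }
        panel_train = LdReferencePanel(variants, dosages=dosages[train_rows])
        selected, all_models = [], []
        pos = variants["pos"].to_numpy()
        for gi, gene in genes.iterrows():
            cis = np.flatnonzero(
                (pos >= gene["gene_start"] - config.cis_window_bp)
                & (pos <= gene["gene_end"] + config.cis_window_bp)
            )
            Xc = dosages[np.ix_(train_rows, cis)]
            cis_variants = variants.iloc[cis].reset_index(drop=True)
            resid_g = {t: resid[t][:, gi] for t in tissues}
            candidates = []
            if "elastic_net" in config.frameworks:
                candidates.append(train_elastic_net(
                    resid_g[tissues[0]], Xc, cis_variants, gene, config.training,
                    tissue=tissues[0], folds=folds,
                ))
            if "cross_tissue_group" in config.frameworks:
                xt = train_cross_tissue(
                    resid_g, Xc, cis_variants, gene, config.training, folds=folds
                )
                candidates.append(xt[tissues[0]])
            if "similarity_weighted" in config.frameworks:
                candidates.append(train_similarity_weighted(
                    resid_g, Xc, cis_variants, gene, similarity, config.training,
                    target_tissue=tissues[0], folds=folds,
                ))
            all_models.extend(candidates)
            best = select_best_model(candidates)
            if best is not None:
                selected.append(best)
        note(f"training: {len(genes)} genes, {len(selected)} imputable "
             f"(cv_r > 0.1 and P < 0.05)")
        write_weight_db(selected, out / "weights.tsv")
        results["models"] = selected

        # ---- stage: summary-statistic TWAS
        stage = "twas"
        panel_gwas = LdReferencePanel(variants, dosages=dosages[gwas_rows])
        m_total = (max(config.m_total, len(selected))
                   if config.m_total is not None else len(selected))
        twas = twas_scan(selected, meta, panel_gwas, m_total=m_total,
                         fdr_threshold=config.fdr_threshold)
        _tsv(twas, out / "twas.tsv")
        sig_genes = twas.loc[twas["significant"], "gene_id"].tolist() if len(twas) else []
        note(f"TWAS: {len(twas)} genes tested, {len(sig_genes)} significant at "
             f"FDR < {config.fdr_threshold}: {sig_genes}")
        results["twas"] = twas

        # ---- stage: gene-level MR (cis eQTL instruments -> disease)
        stage = "gene_mr"
        gene_mr_rows = []
        mr_genes = sig_genes if sig_genes else (
            [twas["gene_id"].iat[0]] if len(twas) else []
        )
        for gene_id in mr_genes:
            gene = genes[genes["gene_id"] == gene_id].iloc[0]
            gi = genes.index[genes["gene_id"] == gene_id][0]
            cis = np.flatnonzero(
                (pos >= gene["gene_start"] - config.cis_window_bp)
                & (pos <= gene["gene_end"] + config.cis_window_bp)
            )
            b, s, p = ols_scan(
                np.asarray(dosages[np.ix_(train_rows, cis)], dtype=float),
                resid[tissues[0]][:, gi],
            )
            eqtl = variants.iloc[cis][
                ["variant_id", "chrom", "pos", "effect_allele", "other_allele"]
            ].copy()
            eqtl["beta"], eqtl["se"], eqtl["pvalue"] = b, s, p
            eqtl["eaf"] = np.asarray(dosages[np.ix_(train_rows, cis)]).mean(axis=0) / 2
            eqtl["n"] = config.n_train
            locus = Locus(gene_id, str(gene["chrom"]), int(gene["gene_start"]),
                          int(gene["gene_end"]), config.cis_window_bp)
            ivs = build_instruments(
                eqtl, meta, panel_gwas, config.eqtl_p_threshold,
                config.r2_threshold, config.clump_window_bp,
                locus=locus, exposure_id=f"{gene_id} expression",
            )
            try:
                ests = run_methods(ivs, config.mr_methods, seed=config.seed)
                for row in _mr_rows(gene_id, {"estimates": ests, "n_iv": ivs.n_iv,
                                              "refused": False}):
                    gene_mr_rows.append(row)
                note(f"gene MR {gene_id}: {ivs.n_iv} IVs")
            except InsufficientInstruments as err:
                gene_mr_rows.append(_mr_rows(gene_id, {"refused": True,
                                                       "n_iv": err.n_iv,
                                                       "reason": str(err)})[0])
                note(f"gene MR {gene_id}: refused ({err})")
        gene_mr = pd.DataFrame(gene_mr_rows)
        _tsv(gene_mr, out / "gene_mr.tsv")
        results["gene_mr"] = gene_mr

        # ---- stage: bidirectional trait MR with locus restriction/exclusion
        stage = "trait_mr"
        y_b, own_idx = simulate_trait_pair(
            SimulatedStudy(sim, dosages[gwas_rows], variants, genes, expr, covars,
                           gvals[gwas_rows], y_a, truth, meta),
            effect_a_on_b=config.trait_b_effect,
        )
        gwas_b = make_gwas_summary(dosages[gwas_rows], y_b, variants)
        write_summary_stats(gwas_b, out / "sumstats_traitB.tsv")
        causal_gene = genes.iloc[ci]
        causal_locus = Locus(truth.causal_gene, str(causal_gene["chrom"]),
                             int(causal_gene["gene_start"]),
                             int(causal_gene["gene_end"]), config.cis_window_bp)
        trait_rows = []
        for tag, kwargs in (
            ("all_snps", {}),
            ("locus_restricted", {"locus": causal_locus}),
            ("locus_excluded", {"exclude_locus": causal_locus}),
        ):
            bi = bidirectional_mr(
                meta, gwas_b, panel_gwas, config.mr_methods,
                config.gwas_p_threshold, config.r2_threshold,
                config.clump_window_bp, seed=config.seed,
                label_a="traitA", label_b="traitB", **kwargs,
            )
            for direction, res in bi.items():
                for row in _mr_rows(f"{tag}:{direction}", res):
                    trait_rows.append(row)
            note(f"trait MR [{tag}]: A->B n_iv={bi['a_to_b']['n_iv']}, "
                 f"B->A n_iv={bi['b_to_a']['n_iv']}")
        trait_mr = pd.DataFrame(trait_rows)
        _tsv(trait_mr, out / "trait_mr.tsv")
        results["trait_mr"] = trait_mr

        # ---- stage: PheWAS of the top gene
        stage = "phewas"
        if selected:
            top_gene = mr_genes[0] if mr_genes else selected[0].gene_id
            model = next(m for m in selected if m.gene_id == top_gene)
            catalog = PhenotypeCatalog()
            catalog.add("008", "trait B (caused downstream)", "endocrine", gwas_b)
            catalog.add("001", "trait A (disease)", "neoplasms", meta)
            perm_rng = np.random.default_rng(config.seed + 11)
            for k in range(3):
                y_perm = perm_rng.permutation(y_a)
                catalog.add(f"90{k}", f"null trait {k}", "other",
                            make_gwas_summary(dosages[gwas_rows], y_perm, variants))
            phw = phewas_scan(model, catalog, panel_gwas)
            _tsv(phw, out / "phewas.tsv")
            note(f"PheWAS of {top_gene}: {len(phw)} phenotypes")
            results["phewas"] = phw
        else:
            note("PheWAS skipped: no imputable gene")

        stage = "provenance"
        prov = {
            "package": "twasmr",
            "version": __version__,
            "seed": config.seed,
            "config": _as_plain(dataclasses.asdict(config)),
        }
        (out / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True))
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001 - annotate with the failing stage
        (out / "run_log.txt").write_text("\n".join(log_lines + [f"FAILED at {stage}: {err}"]) + "\n")
        raise PipelineError(stage, err) from err
    results["log"] = log_lines
    return results


def _as_plain(obj):
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
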