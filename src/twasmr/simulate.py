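"""Synthetic genotype / expression / phenotype generator with known ground truth.

Everything downstream of this module (meta-analysis, prediction-model
training, summary-statistic TWAS, MR, PheWAS) is exercised on data produced
here, so the generator is first-class, seeded, and fully deterministic.

Design in brief
---------------
* Genotypes come in LD blocks.  Within a block the two haplotypes of each
  individual are first-order Markov chains over {0, 1} whose stationary allele
  frequency is the block MAF and whose lag-one autocorrelation is ``ld_rho``.
  Summing the haplotypes gives Hardy-Weinberg genotypes whose correlation is
  exactly ``ld_rho ** |i - j|`` in expectation — the AR(1) target holds on the
  genotype scale in closed form, with no discretization attenuation.  Blocks
  are mutually independent.
* Genes tile the variant panel: each gene owns a contiguous window of
  variants, its gene body sits in the middle of the window, and its cis
  region is +/- 1 Mb of the body.
* Expression for each gene is ``sqrt(h2) * g_std + sqrt(1 - h2) * e`` where
  ``g_std`` is the standardized genetic value from sparse causal cis effects
  and ``e`` is a unit-variance mix of covariate signal (2 PCs + sex) and
  noise.  Cross-tissue effect sharing follows a supplied tissue-similarity
  matrix: per-variant effect vectors across tissues are Gaussian with
  correlation equal to the similarity.
* Case-control phenotypes follow a logistic model
  ``logit P(case) = alpha + gene_effect * g_std + sum direct SNP effects``
  where the direct effects live on a subset of variants (the invalid
  instruments); ``alpha`` is solved for the target prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd
from scipy import optimize, special

from ._stats import logistic_scan, ols_scan

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedStudy",
    "default_similarity",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_case_control",
    "make_gwas_summary",
    "simulate_study",
    "simulate_trait_pair",
    "simulate_iv_summary",
    "scenario_global_null",
    "scenario_gene_mediated",
    "scenario_directional_pleiotropy",
    "scenario_balanced_invalid",
]

# Non-palindromic allele pairs only: simulated records then never hit the
# ambiguous-strand drop rule during harmonization (that rule is exercised by
# dedicated fixtures instead).
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T")]

SUMSTAT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
    "eaf",
    "n",
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    The defaults describe the study conditions the pipeline is exercised
    under: a GWAS cohort of a few thousand samples, common variants in short
    LD blocks, moderately heritable cis-regulated expression in a handful of
    tissues, and a 50%-prevalence case-control design (case oversampling, as
    in a case-control GWAS).
    """

    n_samples: int = 2000
    n_variants: int = 200
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_block_size: int = 5
    ld_rho: float = 0.6
    n_tissues: int = 3
    n_genes: int = 10
    heritability: float = 0.3
    causal_fraction: float = 0.2
    gene_effect: float = 0.0
    pleiotropy_fraction: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.1
    prevalence: float = 0.5
    covariate_share: float = 0.2
    variant_spacing_bp: int = 25_000
    causal_gene_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"maf_range must lie within (0,1), got {self.maf_range}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError(f"ld_rho must lie in [0,1), got {self.ld_rho}")
        if self.n_samples <= 0 or self.n_variants <= 0:
            raise ValueError("n_samples and n_variants must be positive")
        if not (0.0 <= self.heritability <= 1.0):
            raise ValueError("heritability must lie in [0,1]")
        if not (0.0 < self.causal_fraction <= 1.0):
            raise ValueError("causal_fraction must lie in (0,1]")
        if not (0.0 <= self.pleiotropy_fraction <= 1.0):
            raise ValueError("pleiotropy_fraction must lie in [0,1]")
        if not (0.05 < self.prevalence < 0.95):
            raise ValueError("prevalence must lie in (0.05, 0.95)")
        if not (0.0 <= self.covariate_share < 1.0):
            raise ValueError("covariate_share must lie in [0,1)")


@dataclass
class GroundTruth:
    """What the generator actually planted, for assertions downstream.

    ``true_weights`` are on the standardized-dosage scale (effect per SD of
    dosage), matching the scale on which prediction models report weights.
    """

    true_weights: pd.DataFrame  # columns: gene_id, variant_id, tissue, weight
    true_gene_effect: float
    causal_gene: str
    invalid_iv_ids: list[str] = field(default_factory=list)
    direct_effects: dict[str, float] = field(default_factory=dict)


def default_similarity(n_tissues: int, rho: float = 0.8) -> np.ndarray:
    """Exchangeable tissue-similarity matrix with off-diagonal ``rho``."""
    s = np.full((n_tissues, n_tissues), rho, dtype=float)
    np.fill_diagonal(s, 1.0)
    return s


def _check_similarity(similarity: np.ndarray, n_tissues: int) -> np.ndarray:
    s = np.asarray(similarity, dtype=float)
    if s.shape != (n_tissues, n_tissues):
        raise ValueError(f"similarity must be {n_tissues}x{n_tissues}")
    if not np.allclose(s, s.T, atol=1e-12):
        raise ValueError("similarity matrix must be symmetric")
    if not np.allclose(np.diag(s), 1.0, atol=1e-12):
        raise ValueError("similarity matrix must have unit diagonal")
    return s


def tissue_names(n_tissues: int) -> list[str]:
    return ["pancreas"] + [f"tissue_{i}" for i in range(2, n_tissues + 1)]


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw an (n_samples, n_variants) dosage matrix in {0,1,2} plus metadata.

    Variants are laid out on one chromosome at ``variant_spacing_bp``
    intervals; consecutive ``ld_block_size`` variants form an LD block with
    AR(1) genotype correlation ``ld_rho ** lag``; blocks are independent.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_variants
    rho = config.ld_rho
    bs = config.ld_block_size
    lo, hi = config.maf_range

    dosages = np.empty((n, m), dtype=np.int8)
    mafs = np.empty(m)
    start = 0
    while start < m:
        width = min(bs, m - start)
        p = float(rng.uniform(lo, hi))
        haps = np.empty((2 * n, width), dtype=np.int8)
        haps[:, 0] = rng.random(2 * n) < p
        # stationary two-state Markov chain: stay probabilities chosen so the
        # lag-one correlation is exactly rho and the marginal stays p
        p_stay1 = p + rho * (1.0 - p)
        p_from0 = p * (1.0 - rho)
        for j in range(1, width):
            u = rng.random(2 * n)
            prev = haps[:, j - 1] == 1
            haps[:, j] = np.where(prev, u < p_stay1, u < p_from0)
        dosages[:, start : start + width] = haps[:n] + haps[n:]
        mafs[start : start + width] = p
        start += width

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    variants = pd.DataFrame(
        {
            "variant_id": [f"snp_{i:05d}" for i in range(m)],
            "chrom": "1",
            "pos": (np.arange(m) + 1) * config.variant_spacing_bp,
            "effect_allele": [_ALLELE_PAIRS[k][0] for k in pair_idx],
            "other_allele": [_ALLELE_PAIRS[k][1] for k in pair_idx],
            "maf": mafs,
            "block": np.arange(m) // bs,
        }
    )
    return dosages, variants


def gene_annotation(config: SimulationConfig, variants: pd.DataFrame) -> pd.DataFrame:
    """Tile genes across the variant panel (contiguous windows of variants).

    The gene body spans the central third of its window, so each gene has
    flanking cis variants on both sides.
    """
    m = len(variants)
    g = config.n_genes
    if g <= 0 or g > m:
        raise ValueError("n_genes must lie in [1, n_variants]")
    bounds = np.linspace(0, m, g + 1).astype(int)
    rows = []
    pos = variants["pos"].to_numpy()
    for i in range(g):
        w0, w1 = bounds[i], bounds[i + 1]
        body0 = w0 + (w1 - w0) // 3
        body1 = w0 + 2 * (w1 - w0) // 3
        body1 = max(body1, body0)
        rows.append(
            {
                "gene_id": f"GENE{i + 1:02d}",
                "chrom": "1",
                "gene_start": int(pos[body0]),
                "gene_end": int(pos[min(body1, m - 1)]),
                "window_lo": int(w0),
                "window_hi": int(w1),
            }
        )
    return pd.DataFrame(rows)


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def simulate_expression(
    dosages: np.ndarray,
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    config: SimulationConfig,
    similarity: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray, GroundTruth]:
    """Simulate per-tissue expression matrices with sparse cis genetics.

    Returns
    -------
    expression : dict tissue -> (n_samples, n_genes) matrix
    covariates : (n_samples, 3) matrix (pc1, pc2, sex)
    genetic_values : (n_samples, n_genes) standardized genetic values in the
        first (target) tissue — the mediator used by the phenotype model
    truth : GroundTruth with standardized-scale effective weights
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    T = config.n_tissues
    if similarity is None:
        similarity = default_similarity(T)
    S = _check_similarity(similarity, T)
    n = dosages.shape[0]
    G = len(genes)
    h2 = config.heritability

    # matrix-normal column factor: effect vectors across tissues have
    # correlation equal to the similarity matrix
    evals, evecs = np.linalg.eigh(S)
    A = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))

    covariates = np.column_stack(
        [rng.standard_normal(n), rng.standard_normal(n), rng.integers(0, 2, n).astype(float)]
    )
    Xstd = _standardize(np.asarray(dosages, dtype=float))

    tissues = tissue_names(T)
    expr = {t: np.empty((n, G)) for t in tissues}
    genetic_values = np.empty((n, G))
    weight_rows = []
    for gi, gene in genes.iterrows():
        w0, w1 = int(gene["window_lo"]), int(gene["window_hi"])
        width = w1 - w0
        k = max(1, int(round(config.causal_fraction * width)))
        causal = np.sort(rng.choice(np.arange(w0, w1), size=min(k, width), replace=False))
        raw = rng.standard_normal((len(causal), T)) @ A.T  # (k, T)

        gamma = rng.standard_normal(3)
        cov_signal = covariates @ gamma
        cov_sd = cov_signal.std()
        cov_signal = cov_signal / (cov_sd if cov_sd > 0 else 1.0)

        for ti, t in enumerate(tissues):
            gval = Xstd[:, causal] @ raw[:, ti]
            sd = gval.std()
            if h2 > 0 and sd > 0:
                g_std = gval / sd
                eff = raw[:, ti] * np.sqrt(h2) / sd
            else:
                g_std = np.zeros(n)
                eff = np.zeros(len(causal))
            noise = rng.standard_normal(n)
            env = (
                np.sqrt(config.covariate_share) * cov_signal
                + np.sqrt(1.0 - config.covariate_share) * noise
            )
            expr[t][:, gi] = np.sqrt(h2) * g_std + np.sqrt(1.0 - h2) * env
            if ti == 0:
                genetic_values[:, gi] = g_std
            for ci, vidx in enumerate(causal):
                weight_rows.append(
                    {
                        "gene_id": gene["gene_id"],
                        "variant_id": variants["variant_id"].iat[vidx],
                        "tissue": t,
                        "weight": eff[ci],
                    }
                )

    truth = GroundTruth(
        true_weights=pd.DataFrame(weight_rows),
        true_gene_effect=config.gene_effect,
        causal_gene=genes["gene_id"].iat[config.causal_gene_index],
    )
    return expr, covariates, genetic_values, truth


def simulate_case_control(
    genetic_value: np.ndarray,
    dosages: np.ndarray,
    variants: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    pleiotropy_pool: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str], dict[str, float]]:
    """Binary phenotype from a logistic liability on the gene's genetic value.

    ``pleiotropy_pool`` optionally restricts which variant indices may carry
    direct (horizontally pleiotropic) effects; by default all variants are
    eligible.  Returns (phenotype, invalid_iv_ids, direct_effects).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n, m = dosages.shape
    if not np.isfinite(config.gene_effect):
        raise ValueError("gene_effect must be finite")
    g = np.asarray(genetic_value, dtype=float)
    eta = config.gene_effect * g

    invalid_ids: list[str] = []
    direct: dict[str, float] = {}
    if config.pleiotropy_fraction > 0:
        pool = np.arange(m) if pleiotropy_pool is None else np.asarray(pleiotropy_pool)
        k = max(1, int(round(config.pleiotropy_fraction * len(pool))))
        chosen = np.sort(rng.choice(pool, size=min(k, len(pool)), replace=False))
        deltas = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=len(chosen))
        Xstd = _standardize(np.asarray(dosages[:, chosen], dtype=float))
        eta = eta + Xstd @ deltas
        invalid_ids = [variants["variant_id"].iat[i] for i in chosen]
        direct = dict(zip(invalid_ids, deltas.tolist()))

    def mean_prev(alpha: float) -> float:
        return float(special.expit(alpha + eta).mean()) - config.prevalence

    alpha = optimize.brentq(mean_prev, -30.0, 30.0)
    y = (rng.random(n) < special.expit(alpha + eta)).astype(np.int8)
    if y.min() == y.max():
        raise RuntimeError(
            f"degenerate phenotype: all samples are {'cases' if y[0] else 'controls'} "
            f"(alpha={alpha:.3f}, linear-predictor sd={eta.std():.3f})"
        )
    return y, invalid_ids, direct


def make_gwas_summary(
    dosages: np.ndarray, phenotype: np.ndarray, variants: pd.DataFrame
) -> pd.DataFrame:
    """Per-variant marginal association scan -> GWAS summary-statistic table.

    Binary phenotypes get Wald statistics from per-variant logistic
    regression (beta on the log-odds scale); quantitative phenotypes get OLS
    slopes with t-test p-values.  Monomorphic variants are kept in the table
    with NaN statistics (flagged, never silently dropped).
    """
    y = np.asarray(phenotype)
    X = np.asarray(dosages, dtype=float)
    uniq = np.unique(y)
    if uniq.size <= 2 and np.isin(uniq, (0, 1)).all():
        beta, se, pval = logistic_scan(X, y.astype(float))
    else:
        beta, se, pval = ols_scan(X, y.astype(float))
    out = variants[["variant_id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["pvalue"] = pval
    out["eaf"] = X.mean(axis=0) / 2.0
    out["n"] = X.shape[0]
    return out.reset_index(drop=True)


@dataclass
class SimulatedStudy:
    """One fully simulated study: genotypes through GWAS summary statistics."""

    config: SimulationConfig
    dosages: np.ndarray
    variants: pd.DataFrame
    genes: pd.DataFrame
    expression: dict[str, np.ndarray]
    covariates: np.ndarray
    genetic_values: np.ndarray
    phenotype: np.ndarray
    truth: GroundTruth
    gwas: pd.DataFrame


def simulate_study(
    config: SimulationConfig, similarity: np.ndarray | None = None
) -> SimulatedStudy:
    """End-to-end draw: genotypes -> expression -> phenotype -> GWAS table.

    The phenotype is mediated by the causal gene's standardized genetic value
    in the first (target) tissue; direct pleiotropic variant effects, if
    requested, are drawn from the causal gene's cis window so they act as
    invalid instruments downstream.
    """
    rng = np.random.default_rng(config.seed)
    dosages, variants = simulate_genotypes(config, rng)
    genes = gene_annotation(config, variants)
    expr, covars, genetic_values, truth = simulate_expression(
        dosages, variants, genes, config, similarity, rng
    )
    ci = config.causal_gene_index
    pool = np.arange(int(genes["window_lo"].iat[ci]), int(genes["window_hi"].iat[ci]))
    y, invalid, direct = simulate_case_control(
        genetic_values[:, ci], dosages, variants, config, rng, pleiotropy_pool=pool
    )
    truth.invalid_iv_ids = invalid
    truth.direct_effects = direct
    gwas = make_gwas_summary(dosages, y, variants)
    return SimulatedStudy(
        config=config,
        dosages=dosages,
        variants=variants,
        genes=genes,
        expression=expr,
        covariates=covars,
        genetic_values=genetic_values,
        phenotype=y,
        truth=truth,
        gwas=gwas,
    )


# --- scenario presets -------------------------------------------------------


def scenario_global_null(seed: int = 0, **overrides) -> SimulationConfig:
    """No gene effect, no pleiotropy: every downstream P-value is null."""
    return replace(SimulationConfig(seed=seed), gene_effect=0.0, pleiotropy_fraction=0.0, **overrides)


def scenario_gene_mediated(seed: int = 0, gene_effect: float = 0.8, **overrides) -> SimulationConfig:
    """Vertical pleiotropy: phenotype caused by the gene's expression."""
    return replace(
        SimulationConfig(seed=seed),
        gene_effect=gene_effect,
        heritability=0.5,
        pleiotropy_fraction=0.0,
        **overrides,
    )


def scenario_directional_pleiotropy(
    seed: int = 0, mean: float = 0.15, sd: float = 0.05, fraction: float = 0.3, **overrides
) -> SimulationConfig:
    """Invalid instruments with a common directional direct effect (Egger)."""
    return replace(
        SimulationConfig(seed=seed),
        gene_effect=0.5,
        heritability=0.5,
        pleiotropy_fraction=fraction,
        pleiotropy_mean=mean,
        pleiotropy_sd=sd,
        **overrides,
    )


def scenario_balanced_invalid(
    seed: int = 0, fraction: float = 0.2, sd: float = 0.3, **overrides
) -> SimulationConfig:
    """Balanced (zero-mean) invalid instruments at 20% or 40% (WME regime)."""
    return replace(
        SimulationConfig(seed=seed),
        gene_effect=0.5,
        heritability=0.5,
        pleiotropy_fraction=fraction,
        pleiotropy_mean=0.0,
        pleiotropy_sd=sd,
        **overrides,
    )


# --- direct instrument-level simulation (for MR calibration studies) --------


def simulate_iv_summary(
    n_iv: int,
    n_invalid: int,
    theta: float,
    seed: int,
    gamma_range: tuple[float, float] = (0.1, 0.3),
    delta_mean: float = 0.5,
    delta_sd: float = 0.0,
    n_exposure: int = 20_000,
    n_outcome: int = 50_000,
) -> pd.DataFrame:
    """Draw harmonized instrument-level summary statistics directly.

    Standard two-sample MR simulation on standardized variants: true exposure
    effects ``gamma_j ~ U(gamma_range)``, observed ``beta_exp_j ~ N(gamma_j,
    1/sqrt(n_exposure))``; outcome effects ``theta * gamma_j`` plus, for the
    first ``n_invalid`` instruments, a direct effect ``N(delta_mean,
    delta_sd)``; observed ``beta_out_j ~ N(., 1/sqrt(n_outcome))``.  Returns a
    harmonized instrument table ready for the MR estimators.
    """
    if not 0 <= n_invalid <= n_iv:
        raise ValueError("n_invalid must lie in [0, n_iv]")
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(*gamma_range, size=n_iv)
    se_exp = np.full(n_iv, 1.0 / np.sqrt(n_exposure))
    se_out = np.full(n_iv, 1.0 / np.sqrt(n_outcome))
    direct = np.zeros(n_iv)
    if n_invalid:
        direct[:n_invalid] = rng.normal(delta_mean, delta_sd, size=n_invalid)
    beta_exp = gamma + rng.normal(0.0, se_exp)
    beta_out = theta * gamma + direct + rng.normal(0.0, se_out)
    return pd.DataFrame(
        {
            "variant_id": [f"iv_{j:03d}" for j in range(n_iv)],
            "chrom": "1",
            "pos": (np.arange(n_iv) + 1) * 1_000_000,
            "beta_exp": beta_exp,
            "se_exp": se_exp,
            "beta_out": beta_out,
            "se_out": se_out,
            "invalid": direct != 0.0,
        }
    )


def simulate_trait_pair(
    study: SimulatedStudy,
    effect_a_on_b: float,
    n_own_variants: int = 15,
    own_effect: float = 0.3,
    prevalence_b: float = 0.5,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a second binary trait B causally downstream of trait A.

    B's liability is ``effect_a_on_b`` times A's (centered) liability signal
    plus B-specific genetic effects on ``n_own_variants`` variants spread
    across blocks far from A's causal locus, so that B has instruments of its
    own and the reverse (B -> A) MR is genuinely null.

    Returns (phenotype_b, own_variant_indices).
    """
    cfg = study.config
    n = study.dosages.shape[0]
    rng = np.random.default_rng(cfg.seed + 7 if seed is None else seed)
    g = study.genetic_values[:, cfg.causal_gene_index]
    eta_a = cfg.gene_effect * g  # A's genetic liability signal

    ci = cfg.causal_gene_index
    lo = int(study.genes["window_lo"].iat[ci])
    hi = int(study.genes["window_hi"].iat[ci])
    far = np.array(
        [
            i
            for i in range(cfg.n_variants)
            if i < lo - 2 * cfg.ld_block_size or i >= hi + 2 * cfg.ld_block_size
        ]
    )
    # one variant per block, spread out, so B's instruments are independent
    blocks = study.variants["block"].to_numpy()
    chosen: list[int] = []
    for b in np.unique(blocks[far]):
        members = far[blocks[far] == b]
        chosen.append(int(rng.choice(members)))
        if len(chosen) >= n_own_variants:
            break
    own = np.array(sorted(chosen))
    signs = rng.choice([-1.0, 1.0], size=len(own))
    Xstd = _standardize(np.asarray(study.dosages[:, own], dtype=float))
    eta_b = effect_a_on_b * (eta_a - eta_a.mean()) + Xstd @ (own_effect * signs)

    def mean_prev(alpha: float) -> float:
        return float(special.expit(alpha + eta_b).mean()) - prevalence_b

    alpha = optimize.brentq(mean_prev, -30.0, 30.0)
    y_b = (rng.random(n) < special.expit(alpha + eta_b)).astype(np.int8)
    return y_b, own
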