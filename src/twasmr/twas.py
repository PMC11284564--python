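"""Summary-statistic gene-level association (S-PrediXcan-style).

The gene z-score combines per-variant GWAS z-scores with prediction-model
weights and an LD reference panel:

    z_g = sum_l a_l sigma_l z_l / sigma_g,
    sigma_g^2 = sum_{l,l'} a_l a_l' sigma_l sigma_l' rho_ll',

where a_l are the model weights on the raw-dosage scale, sigma_l the panel
dosage SDs and rho the panel correlations.  Model weights stored on the
standardized-dosage scale (this package's convention) are converted with
a_l = w_l / sigma_l before applying the formula.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import LdReferencePanel
from .models import ExpressionModel

logger = logging.getLogger(__name__)

__all__ = [
    "TwasResult",
    "NoOverlappingVariants",
    "z_to_p",
    "bh_adjust",
    "or_ci_from_beta_z",
    "summary_twas",
    "twas_scan",
]


class NoOverlappingVariants(RuntimeError):
    """No model variant is present in both the GWAS table and the LD panel."""


@dataclass
class TwasResult:
    gene_id: str
    zscore: float
    beta_g: float
    se_g: float
    pvalue: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    n_model_snps: int
    coverage: float
    low_coverage: bool
    fdr_adjusted_p: float = float("nan")


def z_to_p(z, log: bool = False) -> np.ndarray | float:
    """Two-sided normal tail probability, accurate for extreme z.

    Uses the survival function directly (no 1 - CDF cancellation).  A double
    cannot represent P below ~5e-324, so for |z| beyond ~38.5 the plain
    probability underflows; ``log=True`` returns ln(P) instead, which is
    finite and strictly decreasing for arbitrarily large |z|.
    """
    z = np.asarray(z, dtype=float)
    if log:
        p = np.log(2.0) + stats.norm.logsf(np.abs(z))
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))
    return float(p) if p.ndim == 0 else p


def bh_adjust(pvalues, m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m_total`` is the total number of tests (>= the number of supplied
    p-values); when the supplied list is a significant subset of a larger
    family — e.g. the printed top genes out of all genes tested — passing
    the family size reproduces the published FDR values for the top ranks.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    k = len(p)
    m = k if m_total is None else int(m_total)
    if m < k:
        raise ValueError(f"m_total ({m}) smaller than number of p-values ({k})")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, k + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(k)
    out[order] = adj
    return out


def or_ci_from_beta_z(
    odds_ratio: float | None = None,
    z: float | None = None,
    beta: float | None = None,
    conf: float = 0.95,
) -> tuple[float, float, float]:
    """Odds ratio with its Wald confidence interval from (OR or beta) and z.

    beta = ln(OR); SE = beta / z; CI = exp(beta +/- z_crit * SE).  A unit OR
    gives a degenerate (1, 1) interval, which is flagged with a warning;
    z = 0 is an error (the SE is undefined).
    """
    if (odds_ratio is None) == (beta is None):
        raise ValueError("provide exactly one of odds_ratio or beta")
    if z is None or z == 0:
        raise ValueError("z must be nonzero to recover the standard error")
    b = np.log(odds_ratio) if beta is None else beta
    se = b / z
    if se < 0:
        raise ValueError("sign of z inconsistent with sign of the effect")
    if se == 0:
        logger.warning("degenerate confidence interval: OR = 1 gives zero-width CI")
    zc = stats.norm.ppf(0.5 + conf / 2.0)
    return float(np.exp(b)), float(np.exp(b - zc * se)), float(np.exp(b + zc * se))


def summary_twas(
    model: ExpressionModel,
    gwas: pd.DataFrame,
    panel: LdReferencePanel,
    weights_standardized: bool = True,
    coverage_warn: float = 0.8,
) -> TwasResult:
    """Gene-level association from model weights + GWAS z-scores + LD.

    Model variants absent from the GWAS table are dropped and the retained
    weight fraction (by absolute weight) is reported as ``coverage``; genes
    below ``coverage_warn`` are flagged.  Raises
    :class:`NoOverlappingVariants` when nothing overlaps, and ValueError for
    an inconsistent (non-positive-variance) LD configuration.
    """
    merged = model.weights.merge(
        gwas, on="variant_id", suffixes=("", "_gwas"), how="inner"
    ).dropna(subset=["beta", "se"])
    total_wt = float(np.abs(model.weights["weight"]).sum())
    if len(merged) == 0 or total_wt == 0:
        raise NoOverlappingVariants(
            f"gene {model.gene_id}: no model variant with usable GWAS statistics"
        )
    # align the GWAS effect allele to the model's effect allele
    flip = merged["effect_allele_gwas"] == merged["other_allele"]
    same = merged["effect_allele_gwas"] == merged["effect_allele"]
    merged = merged[flip | same]
    if len(merged) == 0:
        raise NoOverlappingVariants(f"gene {model.gene_id}: allele sets incompatible")
    sign = np.where(merged["effect_allele_gwas"] == merged["effect_allele"], 1.0, -1.0)
    beta_l = merged["beta"].to_numpy() * sign
    se_l = merged["se"].to_numpy()
    z_l = beta_l / se_l
    w = merged["weight"].to_numpy()
    coverage = float(np.abs(w).sum() / total_wt)

    ids = merged["variant_id"].tolist()
    sigma = panel.sd(ids)
    rho = panel.corr_matrix(ids)
    a = w / np.where(sigma > 0, sigma, np.inf) if weights_standardized else w
    var_g = float(a * sigma @ rho @ (a * sigma))
    if var_g <= 0:
        raise ValueError(
            f"gene {model.gene_id}: non-positive predicted-expression variance "
            f"({var_g:.3e}) — inconsistent LD panel"
        )
    sigma_g = np.sqrt(var_g)
    z_g = float((a * sigma * z_l).sum() / sigma_g)
    beta_g = float((a * sigma**2 * beta_l).sum() / var_g)
    se_g = beta_g / z_g if z_g != 0 else float("nan")
    p = z_to_p(z_g)
    if z_g != 0:
        or_, lo, hi = or_ci_from_beta_z(beta=beta_g, z=z_g)
    else:
        or_, lo, hi = float(np.exp(beta_g)), float("nan"), float("nan")
    low_cov = coverage < coverage_warn
    if low_cov:
        logger.warning(
            "gene %s: only %.0f%% of model weight covered by the GWAS",
            model.gene_id,
            100 * coverage,
        )
    return TwasResult(
        gene_id=model.gene_id,
        zscore=z_g,
        beta_g=beta_g,
        se_g=se_g,
        pvalue=p,
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        n_model_snps=len(merged),
        coverage=coverage,
        low_coverage=low_cov,
    )


def twas_scan(
    models: list[ExpressionModel],
    gwas: pd.DataFrame,
    panel: LdReferencePanel,
    m_total: int | None = None,
    fdr_threshold: float = 0.10,
) -> pd.DataFrame:
    """TWAS over a set of gene models, with BH FDR across the scan.

    Genes with no overlapping variants are skipped (recorded in
    ``df.attrs["skipped"]``).  ``significant`` marks FDR < ``fdr_threshold``.
    """
    rows, skipped = [], []
    for m in models:
        try:
            r = summary_twas(m, gwas, panel)
        except NoOverlappingVariants as err:
            skipped.append({"gene_id": m.gene_id, "reason": str(err)})
            continue
        rows.append(
            {
                "gene_id": r.gene_id,
                "region": f"{m.chrom}:{m.gene_start}-{m.gene_end}",
                "r2": m.cv_r**2,
                "or": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "zscore": r.zscore,
                "pvalue": r.pvalue,
                "n_model_snps": r.n_model_snps,
                "coverage": r.coverage,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = bh_adjust(df["pvalue"].to_numpy(), m_total or len(df))
        df["significant"] = df["fdr"] < fdr_threshold
        df = df.sort_values("pvalue", kind="mergesort").reset_index(drop=True)
    df.attrs["skipped"] = skipped
    return df
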