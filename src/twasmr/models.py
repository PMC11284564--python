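"""Cis expression prediction models: elastic net, cross-tissue sparse-group
lasso, and similarity-weighted (sample-reweighted) elastic net.

All three frameworks share the same seeded cross-validation folds so their
out-of-fold performance estimates are directly comparable, and all report
weights on the standardized-dosage scale (effect per SD of dosage).  A gene
is *imputable* when the best model's out-of-fold Pearson correlation exceeds
0.1 with P < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet

from ._stats import pearson_corr_pvalue

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "ExpressionModel",
    "make_folds",
    "regress_out_covariates",
    "train_elastic_net",
    "train_cross_tissue",
    "train_similarity_weighted",
    "select_best_model",
    "write_weight_db",
    "read_weight_db",
]

FRAMEWORK_ORDER = {"elastic_net": 0, "cross_tissue_group": 1, "similarity_weighted": 2}

IMPUTABLE_R = 0.1
IMPUTABLE_P = 0.05


@dataclass
class TrainingConfig:
    """Hyper-parameters shared by the three training frameworks.

    ``n_lambda`` log-spaced penalties are generated from the data-dependent
    lambda_max (smallest penalty giving the all-zero model) down
    ``lambda_min_ratio`` orders; the cross-tissue framework uses its own
    small (lambda1, lambda2) grid with the SAME pair in every fold.
    """

    cis_window_bp: int = 1_000_000
    n_folds: int = 5
    alpha_mixing: float = 0.5
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-4
    lambda1_fracs: tuple[float, ...] = (0.5, 0.2, 0.05, 0.01)
    lambda2_fracs: tuple[float, ...] = (0.5, 0.1, 0.0)
    similarity_power_grid: tuple[float, ...] = (1.0, 4.0, 16.0)
    max_iter: int = 5000
    tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not (0.0 < self.alpha_mixing <= 1.0):
            raise ValueError("alpha_mixing must lie in (0,1]")


@dataclass
class ExpressionModel:
    """Per-gene, per-tissue SNP weights with cross-validated performance.

    ``weights`` is a DataFrame with columns variant_id, chrom, pos,
    effect_allele, other_allele, weight (standardized-dosage scale; zero
    weights are not stored).
    """

    gene_id: str
    gene_start: int
    gene_end: int
    chrom: str
    tissue: str
    framework: str
    weights: pd.DataFrame
    cv_r: float
    cv_p: float
    converged: bool = True
    extra: dict = field(default_factory=dict)

    @property
    def imputable(self) -> bool:
        return self.cv_r > IMPUTABLE_R and self.cv_p < IMPUTABLE_P

    @property
    def n_snps(self) -> int:
        return len(self.weights)


def make_folds(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Fold labels from a seeded permutation; shared across frameworks."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[perm] = np.arange(n) % n_folds
    return folds


def regress_out_covariates(expression: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residualize expression on covariates (plus intercept) by OLS projection.

    With zero covariates this reduces to centering.  Rank-deficient
    covariate matrices are rejected with the offending columns listed.
    """
    Y = np.atleast_2d(np.asarray(expression, dtype=float))
    if Y.shape[0] == 1 and np.asarray(expression).ndim == 1:
        Y = Y.T
    n = Y.shape[0]
    C = np.asarray(covariates, dtype=float).reshape(n, -1)
    design = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = []
        cols = [np.ones(n)]
        for j in range(C.shape[1]):
            trial = np.column_stack(cols + [C[:, j]])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                cols.append(C[:, j])
            else:
                bad.append(j)
        raise ValueError(f"covariate matrix is rank deficient; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ coef
    return resid if np.asarray(expression).ndim > 1 else resid.ravel()


def expression_pcs(expression: np.ndarray, k: int = 5) -> np.ndarray:
    """Top-k principal components of an (samples x genes) expression matrix.

    Used as hidden-confounder surrogates alongside the measured covariates.
    """
    X = np.asarray(expression, dtype=float)
    X = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    k = min(k, len(s))
    return u[:, :k] * s[:k]


# --- shared weighted elastic-net core ---------------------------------------


def _lambda_grid(Xs: np.ndarray, yc: np.ndarray, w: np.ndarray, config: TrainingConfig):
    grad = np.abs(Xs.T @ (w * yc)) / w.sum()
    lam_max = float(grad.max()) / config.alpha_mixing
    if lam_max <= 0:
        lam_max = 1e-3
    return np.logspace(
        np.log10(lam_max), np.log10(lam_max * config.lambda_min_ratio), config.n_lambda
    )


def _weighted_enet_cv(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None,
    donor_folds: np.ndarray,
    eval_mask: np.ndarray,
    config: TrainingConfig,
):
    """Weighted elastic net with penalty chosen by (donor-split) CV.

    Returns (weights_on_standardized_scale, cv_r, cv_p, chosen_lambda,
    oof_predictions_over_eval_rows).  ``eval_mask`` restricts both the CV
    loss and the performance estimate to the rows of interest (the target
    tissue when samples from several tissues are stacked).
    """
    n = X.shape[0]
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    keep = w > 0
    X, y, w, donor_folds, eval_mask = (
        X[keep],
        y[keep],
        w[keep],
        donor_folds[keep],
        eval_mask[keep],
    )
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    informative = sd > 0
    sd_safe = np.where(informative, sd, 1.0)
    Xs = (X - mu) / sd_safe
    Xs[:, ~informative] = 0.0
    yc = y - y.mean()
    lambdas = _lambda_grid(Xs, yc, w, config)

    oof = np.full((len(lambdas), int(eval_mask.sum())), np.nan)
    y_eval = y[eval_mask]
    eval_rows = np.flatnonzero(eval_mask)
    eval_pos = {r: i for i, r in enumerate(eval_rows)}
    for fold in np.unique(donor_folds):
        tr = donor_folds != fold
        te = (~tr) & eval_mask
        if te.sum() == 0 or tr.sum() < 3:
            continue
        model = ElasticNet(
            l1_ratio=config.alpha_mixing,
            fit_intercept=True,
            max_iter=config.max_iter,
            tol=config.tol,
            warm_start=True,
        )
        for li, lam in enumerate(lambdas):
            model.set_params(alpha=lam)
            model.fit(Xs[tr], y[tr], sample_weight=w[tr])
            pred = model.predict(Xs[te])
            cols = [eval_pos[r] for r in np.flatnonzero(te)]
            oof[li, cols] = pred

    w_eval = w[eval_mask]
    with np.errstate(invalid="ignore"):
        mse = np.nansum(w_eval * (oof - y_eval) ** 2, axis=1)
    n_seen = np.isfinite(oof).sum(axis=1)
    mse = np.where(n_seen > 0, mse / np.maximum(n_seen, 1), np.inf)
    best = int(np.argmin(mse))
    lam = float(lambdas[best])

    final = ElasticNet(
        alpha=lam,
        l1_ratio=config.alpha_mixing,
        fit_intercept=True,
        max_iter=config.max_iter,
        tol=config.tol,
    )
    final.fit(Xs, y, sample_weight=w)
    beta = final.coef_.copy()
    beta[~informative] = 0.0

    oof_best = oof[best]
    ok = np.isfinite(oof_best)
    if ok.sum() >= 3 and np.any(beta != 0):
        cv_r, cv_p = pearson_corr_pvalue(oof_best[ok], y_eval[ok])
    else:
        cv_r, cv_p = 0.0, 1.0
    return beta, float(cv_r), float(cv_p), lam, oof_best


def _model_from_beta(beta, cis_variants, gene, tissue, framework, cv_r, cv_p, **extra):
    nz = np.flatnonzero(beta)
    weights = cis_variants.iloc[nz][
        ["variant_id", "chrom", "pos", "effect_allele", "other_allele"]
    ].copy()
    weights["weight"] = beta[nz]
    return ExpressionModel(
        gene_id=gene["gene_id"],
        gene_start=int(gene["gene_start"]),
        gene_end=int(gene["gene_end"]),
        chrom=str(gene["chrom"]),
        tissue=tissue,
        framework=framework,
        weights=weights.reset_index(drop=True),
        cv_r=cv_r,
        cv_p=cv_p,
        extra=extra,
    )


def train_elastic_net(
    residuals: np.ndarray,
    cis_dosages: np.ndarray,
    cis_variants: pd.DataFrame,
    gene: pd.Series | dict,
    config: TrainingConfig,
    tissue: str = "pancreas",
    folds: np.ndarray | None = None,
) -> ExpressionModel:
    """Single-tissue elastic net with the penalty chosen by k-fold CV.

    An all-zero fit is not an error: the model is returned with cv_r = 0 and
    flagged non-imputable.
    """
    n = cis_dosages.shape[0]
    if n < 2 * config.n_folds:
        raise ValueError(f"need at least {2 * config.n_folds} samples, got {n}")
    if folds is None:
        folds = make_folds(n, config.n_folds, config.seed)
    beta, cv_r, cv_p, lam, _ = _weighted_enet_cv(
        np.asarray(cis_dosages, dtype=float),
        np.asarray(residuals, dtype=float),
        None,
        folds,
        np.ones(n, dtype=bool),
        config,
    )
    return _model_from_beta(
        beta, cis_variants, gene, tissue, "elastic_net", cv_r, cv_p, chosen_lambda=lam
    )


# --- cross-tissue sparse-group lasso ----------------------------------------


def _sgl_objective(B, Xs_list, ys, lam1, lam2):
    loss = 0.0
    for t, (Xs, y) in enumerate(zip(Xs_list, ys)):
        r = y - Xs @ B[:, t]
        loss += 0.5 * float(r @ r) / len(y)
    return loss + lam1 * float(np.abs(B).sum()) + lam2 * float(
        np.linalg.norm(B, axis=1).sum()
    )


def _sgl_fit(Xs_list, ys, lam1, lam2, max_iter, tol):
    """Proximal-gradient (ISTA) solver for the sparse-group-lasso objective.

    The loss is separable across tissues; the prox of the composite penalty
    (per-entry soft threshold, then per-SNP group shrinkage) is applied
    jointly.  Fixed step 1/L with L the largest per-tissue Lipschitz
    constant guarantees monotone descent.
    """
    p = Xs_list[0].shape[1]
    T = len(Xs_list)
    L = max(
        float(np.linalg.eigvalsh(Xs.T @ Xs / len(y)).max()) if Xs.size else 1.0
        for Xs, y in zip(Xs_list, ys)
    )
    L = max(L, 1e-8)
    step = 1.0 / L
    B = np.zeros((p, T))
    obj = _sgl_objective(B, Xs_list, ys, lam1, lam2)
    trace = [obj]
    converged = False
    for _ in range(max_iter):
        G = np.empty_like(B)
        for t, (Xs, y) in enumerate(zip(Xs_list, ys)):
            G[:, t] = Xs.T @ (Xs @ B[:, t] - y) / len(y)
        Z = B - step * G
        Z = np.sign(Z) * np.maximum(np.abs(Z) - step * lam1, 0.0)
        norms = np.linalg.norm(Z, axis=1)
        scale = np.where(norms > 0, np.maximum(0.0, 1.0 - step * lam2 / np.maximum(norms, 1e-300)), 0.0)
        B_new = Z * scale[:, None]
        obj_new = _sgl_objective(B_new, Xs_list, ys, lam1, lam2)
        trace.append(obj_new)
        if abs(obj - obj_new) <= tol * max(1.0, abs(obj)):
            B = B_new
            converged = True
            break
        B, obj = B_new, obj_new
    return B, converged, trace


def train_cross_tissue(
    residuals_per_tissue: dict[str, np.ndarray],
    cis_dosages: np.ndarray,
    cis_variants: pd.DataFrame,
    gene: pd.Series | dict,
    config: TrainingConfig,
    folds: np.ndarray | None = None,
) -> dict[str, ExpressionModel]:
    """Joint multi-tissue fit with lasso + group-lasso (per-SNP) penalties.

    Minimizes  sum_t (1/2 n_t) ||y_t - X_t b_t||^2
             + lambda1 * sum_{j,t} |b_jt| + lambda2 * sum_j ||b_j.||_2,
    with one (lambda1, lambda2) pair — selected by CV on the pooled
    out-of-fold loss — used in every fold.  Returns one model per tissue.
    """
    tissues = list(residuals_per_tissue)
    n = cis_dosages.shape[0]
    if folds is None:
        folds = make_folds(n, config.n_folds, config.seed)
    X = np.asarray(cis_dosages, dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    informative = sd > 0
    Xs = (X - mu) / np.where(informative, sd, 1.0)
    Xs[:, ~informative] = 0.0
    ys = {t: np.asarray(residuals_per_tissue[t], dtype=float) for t in tissues}
    yc = {t: ys[t] - ys[t].mean() for t in tissues}

    lam1_max = max(float(np.abs(Xs.T @ yc[t]).max()) / n for t in tissues)
    lam2_max = float(
        np.linalg.norm(np.column_stack([Xs.T @ yc[t] / n for t in tissues]), axis=1).max()
    )
    grid = [
        (lam1_max * f1, lam2_max * f2)
        for f1 in config.lambda1_fracs
        for f2 in config.lambda2_fracs
    ]

    best_pair, best_mse, best_oof = None, np.inf, None
    for lam1, lam2 in grid:
        oof = {t: np.full(n, np.nan) for t in tissues}
        for fold in np.unique(folds):
            tr = folds != fold
            B, _, _ = _sgl_fit(
                [Xs[tr]] * len(tissues),
                [yc[t][tr] - yc[t][tr].mean() for t in tissues],
                lam1,
                lam2,
                config.max_iter,
                config.tol,
            )
            for ti, t in enumerate(tissues):
                icept = yc[t][tr].mean() - (Xs[tr] @ B[:, ti]).mean()
                oof[t][~tr] = Xs[~tr] @ B[:, ti] + icept
        mse = float(
            np.mean([np.nanmean((oof[t] - yc[t]) ** 2) for t in tissues])
        )
        if mse < best_mse:
            best_pair, best_mse, best_oof = (lam1, lam2), mse, oof

    lam1, lam2 = best_pair
    B, converged, _ = _sgl_fit(
        [Xs] * len(tissues), [yc[t] for t in tissues], lam1, lam2, config.max_iter, config.tol
    )
    if not converged:
        logger.warning(
            "cross-tissue fit for %s did not converge in %d iterations",
            dict(gene).get("gene_id", "?"),
            config.max_iter,
        )
    out = {}
    for ti, t in enumerate(tissues):
        beta = B[:, ti].copy()
        beta[~informative] = 0.0
        pred = best_oof[t]
        ok = np.isfinite(pred)
        if ok.sum() >= 3 and np.any(beta != 0):
            cv_r, cv_p = pearson_corr_pvalue(pred[ok], yc[t][ok])
        else:
            cv_r, cv_p = 0.0, 1.0
        model = _model_from_beta(
            beta,
            cis_variants,
            gene,
            t,
            "cross_tissue_group",
            cv_r,
            cv_p,
            lambda1=lam1,
            lambda2=lam2,
        )
        model.converged = converged
        out[t] = model
    return out


def train_similarity_weighted(
    residuals_per_tissue: dict[str, np.ndarray],
    cis_dosages: np.ndarray,
    cis_variants: pd.DataFrame,
    gene: pd.Series | dict,
    similarity: np.ndarray,
    config: TrainingConfig,
    target_tissue: str | None = None,
    folds: np.ndarray | None = None,
) -> ExpressionModel:
    """Similarity-weighted elastic net for one target tissue.

    All tissues' samples are stacked; samples from tissue t get weight
    ``similarity(target, t) ** p`` with the exponent p chosen by CV in the
    target tissue.  CV folds are split by donor, so no donor contributes to
    both the training and the test side of a fold.
    """
    tissues = list(residuals_per_tissue)
    if target_tissue is None:
        target_tissue = tissues[0]
    ti_target = tissues.index(target_tissue)
    S = np.asarray(similarity, dtype=float)
    if not np.allclose(S, S.T, atol=1e-12) or not np.allclose(np.diag(S), 1.0, atol=1e-12):
        raise ValueError("similarity matrix must be symmetric with unit diagonal")
    if (S < 0).any() or (S > 1).any():
        raise ValueError("similarity entries must lie in [0,1]")

    n = cis_dosages.shape[0]
    if folds is None:
        folds = make_folds(n, config.n_folds, config.seed)
    X = np.asarray(cis_dosages, dtype=float)
    Xstack = np.vstack([X] * len(tissues))
    ystack = np.concatenate([np.asarray(residuals_per_tissue[t], dtype=float) for t in tissues])
    donor_folds = np.tile(folds, len(tissues))
    eval_mask = np.zeros(n * len(tissues), dtype=bool)
    eval_mask[ti_target * n : (ti_target + 1) * n] = True

    best = None
    for power in config.similarity_power_grid:
        sw = np.concatenate(
            [np.full(n, float(S[ti_target, ti]) ** power) for ti in range(len(tissues))]
        )
        beta, cv_r, cv_p, lam, _ = _weighted_enet_cv(
            Xstack, ystack, sw, donor_folds, eval_mask, config
        )
        if best is None or cv_r > best[1]:
            best = (beta, cv_r, cv_p, lam, power)
    beta, cv_r, cv_p, lam, power = best
    return _model_from_beta(
        beta,
        cis_variants,
        gene,
        target_tissue,
        "similarity_weighted",
        cv_r,
        cv_p,
        chosen_lambda=lam,
        similarity_power=power,
    )


def select_best_model(models: list[ExpressionModel]) -> ExpressionModel | None:
    """Pick the candidate with the highest cv_r; None if it is not imputable.

    Exact ties in cv_r are broken by a fixed framework order
    (elastic_net < cross_tissue_group < similarity_weighted).
    """
    if not models:
        raise ValueError("select_best_model requires at least one candidate")
    best = sorted(models, key=lambda m: (-m.cv_r, FRAMEWORK_ORDER[m.framework]))[0]
    return best if best.imputable else None


# --- weight DB I/O ----------------------------------------------------------

_DB_COLUMNS = [
    "gene_id",
    "gene_start",
    "gene_end",
    "tissue",
    "framework",
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "weight",
    "cv_r",
    "cv_p",
]


def write_weight_db(models: list[ExpressionModel], path) -> None:
    rows = []
    for m in models:
        for _, w in m.weights.iterrows():
            rows.append(
                {
                    "gene_id": m.gene_id,
                    "gene_start": m.gene_start,
                    "gene_end": m.gene_end,
                    "tissue": m.tissue,
                    "framework": m.framework,
                    "variant_id": w["variant_id"],
                    "chrom": w["chrom"],
                    "pos": int(w["pos"]),
                    "effect_allele": w["effect_allele"],
                    "other_allele": w["other_allele"],
                    "weight": w["weight"],
                    "cv_r": m.cv_r,
                    "cv_p": m.cv_p,
                }
            )
    pd.DataFrame(rows, columns=_DB_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_weight_db(path) -> list[ExpressionModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    models = []
    for (gene_id, tissue, framework), grp in df.groupby(
        ["gene_id", "tissue", "framework"], sort=False
    ):
        first = grp.iloc[0]
        models.append(
            ExpressionModel(
                gene_id=gene_id,
                gene_start=int(first["gene_start"]),
                gene_end=int(first["gene_end"]),
                chrom=str(first["chrom"]),
                tissue=tissue,
                framework=framework,
                weights=grp[
                    ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "weight"]
                ].reset_index(drop=True),
                cv_r=float(first["cv_r"]),
                cv_p=float(first["cv_p"]),
            )
        )
    return models
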