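"""Two-sample Mendelian randomization with pleiotropy-robust estimators.

Instrument selection follows the standard summary-statistics recipe: take
exposure-associated variants (P < 5e-8), LD-clump them to pairwise
r^2 < 0.01 within 250 kb, optionally restrict to (or exclude) the cis locus
of a gene (gene body +/- 1 Mb), and harmonize against the outcome GWAS.
Estimation is refused with fewer than three independent instruments.

Estimators: per-IV Wald ratios, inverse-variance weighting (IVW), the
weighted median (consistent while < 50% of instrument weight is invalid),
MR-Egger regression (intercept = average directional pleiotropy), and a
heterogeneity-penalized estimator that gives each instrument its own
L1-shrunk direct-effect term (the per-IV heterogeneity idea behind MR-JTI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import LdReferencePanel, clump, harmonize

logger = logging.getLogger(__name__)

__all__ = [
    "InstrumentSet",
    "MrEstimate",
    "InsufficientInstruments",
    "Locus",
    "build_instruments",
    "wald_ratios",
    "ivw",
    "weighted_median",
    "egger",
    "het_penalized",
    "bidirectional_mr",
    "run_methods",
]

MIN_INSTRUMENTS = 3


class InsufficientInstruments(RuntimeError):
    """Fewer than the required number of independent instruments survive."""

    def __init__(self, n: int, context: str = ""):
        self.n_iv = n
        msg = f"only {n} independent instrument(s) available (need >= {MIN_INSTRUMENTS})"
        super().__init__(msg + (f" [{context}]" if context else ""))


@dataclass(frozen=True)
class Locus:
    """A gene locus: the cis window is the gene body +/- window_bp (inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    window_bp: int = 1_000_000

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and (
            self.start - self.window_bp <= pos <= self.end + self.window_bp
        )


@dataclass
class InstrumentSet:
    """Harmonized, clumped exposure/outcome effect pairs."""

    exposure_id: str
    table: pd.DataFrame  # variant_id, chrom, pos, beta_exp, se_exp, beta_out, se_out

    @property
    def n_iv(self) -> int:
        return len(self.table)

    def require(self, context: str = "") -> None:
        if self.n_iv < MIN_INSTRUMENTS:
            raise InsufficientInstruments(self.n_iv, context or self.exposure_id)


@dataclass
class MrEstimate:
    method: str
    estimate: float  # log-OR per exposure unit
    se: float
    pvalue: float
    n_iv: int
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    bootstrap_seed: int | None = None
    converged: bool = True

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate))

    def ci(self, conf: float = 0.95) -> tuple[float, float]:
        zc = stats.norm.ppf(0.5 + conf / 2.0)
        return self.estimate - zc * self.se, self.estimate + zc * self.se


def _normal_p(est: float, se: float) -> float:
    if se == 0 or not np.isfinite(se):
        return float("nan")
    return float(2.0 * stats.norm.sf(abs(est) / se))


def build_instruments(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    panel: LdReferencePanel,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.01,
    window_bp: int = 250_000,
    locus: Locus | None = None,
    exclude_locus: Locus | None = None,
    exposure_id: str = "exposure",
) -> InstrumentSet:
    """Clump + (optional) locus filter + harmonize -> instrument table.

    The locus filter keeps variants within ``locus.window_bp`` of the gene
    body (inclusive on both boundaries); ``exclude_locus`` removes them
    instead.  Estimation with < 3 surviving IVs is refused by the
    estimators, not here, so callers can report the surviving count.
    """
    candidates = exposure
    if locus is not None:
        keep = [
            locus.contains(str(r["chrom"]), int(r["pos"])) for _, r in candidates.iterrows()
        ]
        candidates = candidates[np.array(keep, dtype=bool)]
    if exclude_locus is not None:
        keep = [
            not exclude_locus.contains(str(r["chrom"]), int(r["pos"]))
            for _, r in candidates.iterrows()
        ]
        candidates = candidates[np.array(keep, dtype=bool)]
    clumped = clump(candidates, panel, p_threshold, r2_threshold, window_bp)
    if len(clumped) == 0:
        return InstrumentSet(exposure_id, pd.DataFrame(
            columns=["variant_id", "chrom", "pos", "beta_exp", "se_exp", "beta_out", "se_out"]
        ))
    harmonized, _ = harmonize(clumped, outcome)
    table = harmonized[
        ["variant_id", "chrom", "pos", "beta_exp", "se_exp", "beta_out", "se_out"]
    ].reset_index(drop=True)
    logger.info("%s: %d independent instruments after clumping/harmonization",
                exposure_id, len(table))
    return InstrumentSet(exposure_id, table)


def wald_ratios(iv_set: InstrumentSet) -> pd.DataFrame:
    """Per-IV causal ratios theta_j = beta_out_j / beta_exp_j.

    First-order SE (se_out / |beta_exp|); instruments with a zero exposure
    effect are excluded with a reason recorded in ``attrs["excluded"]``.
    """
    t = iv_set.table
    nonzero = t["beta_exp"] != 0
    excluded = [
        {"variant_id": v, "reason": "zero exposure effect"}
        for v in t.loc[~nonzero, "variant_id"]
    ]
    t = t[nonzero]
    out = pd.DataFrame(
        {
            "variant_id": t["variant_id"],
            "theta": t["beta_out"] / t["beta_exp"],
            "se": (t["se_out"] / t["beta_exp"].abs()),
        }
    ).reset_index(drop=True)
    out.attrs["excluded"] = excluded
    return out


def ivw(iv_set: InstrumentSet) -> MrEstimate:
    """Inverse-variance-weighted mean of the Wald ratios.

    Equivalent to weighted least squares of beta_out on beta_exp through the
    origin with weights 1/se_out^2 (fixed-effect IVW).
    """
    iv_set.require("ivw")
    ratios = wald_ratios(iv_set)
    w = 1.0 / ratios["se"].to_numpy() ** 2
    theta = ratios["theta"].to_numpy()
    est = float((w * theta).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    return MrEstimate("ivw", est, se, _normal_p(est, se), iv_set.n_iv)


def _weighted_median(theta: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(theta, kind="mergesort")
    th = theta[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w  # Bowden's mid-point convention
    if 0.5 <= cum[0]:
        return float(th[0])
    if 0.5 >= cum[-1]:
        return float(th[-1])
    return float(np.interp(0.5, cum, th))


def weighted_median(
    iv_set: InstrumentSet, n_boot: int = 1000, seed: int = 0
) -> MrEstimate:
    """Weighted median of the Wald ratios (robust to <50% invalid weight).

    The SE is the standard deviation of the estimate over ``n_boot``
    parametric-bootstrap resamples in which each beta_exp_j and beta_out_j
    is redrawn from a normal centered at its observed value.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100 for a stable bootstrap SE")
    iv_set.require("weighted_median")
    ratios = wald_ratios(iv_set)
    theta = ratios["theta"].to_numpy()
    w = 1.0 / ratios["se"].to_numpy() ** 2
    est = _weighted_median(theta, w)

    t = iv_set.table[iv_set.table["beta_exp"] != 0]
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    be, se_e = t["beta_exp"].to_numpy(), t["se_exp"].to_numpy()
    bo, se_o = t["beta_out"].to_numpy(), t["se_out"].to_numpy()
    for b in range(n_boot):
        bexp = rng.normal(be, se_e)
        bout = rng.normal(bo, se_o)
        ok = bexp != 0
        th = bout[ok] / bexp[ok]
        wt = (np.abs(bexp[ok]) / se_o[ok]) ** 2
        boots[b] = _weighted_median(th, wt)
    se = float(boots.std(ddof=1))
    return MrEstimate(
        "wme", est, se, _normal_p(est, se), iv_set.n_iv, bootstrap_seed=seed
    )


def egger(iv_set: InstrumentSet) -> MrEstimate:
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    Exposure effects are first oriented non-negative (flipping both betas of
    an IV leaves its ratio unchanged); the slope is the causal estimate and
    the intercept estimates the average directional pleiotropy, with its own
    normal test.
    """
    iv_set.require("egger")
    t = iv_set.table
    sign = np.where(t["beta_exp"].to_numpy() >= 0, 1.0, -1.0)
    x = t["beta_exp"].to_numpy() * sign
    y = t["beta_out"].to_numpy() * sign
    w = 1.0 / t["se_out"].to_numpy() ** 2
    X = np.column_stack([np.ones_like(x), x])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ y)
    resid = y - X @ coef
    dof = len(x) - 2
    # scale the covariance by the residual dispersion, floored at 1
    # (multiplicative random-effects convention)
    phi = max(float((w * resid**2).sum() / dof), 1.0) if dof > 0 else 1.0
    cov = np.linalg.inv(xtwx) * phi
    slope, icept = float(coef[1]), float(coef[0])
    se_slope, se_icept = float(np.sqrt(cov[1, 1])), float(np.sqrt(cov[0, 0]))
    return MrEstimate(
        "egger",
        slope,
        se_slope,
        _normal_p(slope, se_slope),
        iv_set.n_iv,
        egger_intercept=icept,
        intercept_se=se_icept,
        intercept_p=_normal_p(icept, se_icept),
    )


def _het_fit(x, y, w, lam, max_iter=500, tol=1e-10):
    """Alternating minimization of
    sum_j w_j/2 (y_j - theta x_j - phi_j)^2 + lam sum_j |phi_j|."""
    phi = np.zeros_like(y)
    theta = float((w * x * y).sum() / (w * x * x).sum())
    for _ in range(max_iter):
        r = y - theta * x
        phi_new = np.sign(r) * np.maximum(np.abs(r) - lam / w, 0.0)
        theta_new = float((w * x * (y - phi_new)).sum() / (w * x * x).sum())
        if abs(theta_new - theta) < tol and np.abs(phi_new - phi).max() < tol:
            theta, phi = theta_new, phi_new
            return theta, phi, True
        theta, phi = theta_new, phi_new
    return theta, phi, False


def het_penalized(
    iv_set: InstrumentSet,
    seed: int = 0,
    n_boot: int = 200,
    n_lambda: int = 20,
    cv_folds: int = 5,
) -> MrEstimate:
    """Heterogeneity-penalized causal estimate (per-IV direct-effect terms).

    Each instrument gets its own direct-effect parameter phi_j, shrunk by an
    L1 penalty whose strength is chosen by cross-validation over instruments
    (held-out instruments are predicted by the causal term alone); the
    causal coefficient theta itself is never penalized.  Valid instruments
    keep phi_j = 0 and the estimate reduces to IVW; outlying instruments
    absorb their own heterogeneity instead of biasing theta.  The SE comes
    from a parametric bootstrap.
    """
    iv_set.require("het_penalized")
    t = iv_set.table[iv_set.table["beta_exp"] != 0]
    x = t["beta_exp"].to_numpy()
    y = t["beta_out"].to_numpy()
    w = 1.0 / t["se_out"].to_numpy() ** 2
    m = len(x)

    theta0 = float((w * x * y).sum() / (w * x * x).sum())
    lam_max = float(np.max(w * np.abs(y - theta0 * x)))
    lam_max = max(lam_max, 1e-12)
    lambdas = np.logspace(np.log10(lam_max * 1.5), np.log10(lam_max * 1e-3), n_lambda)

    rng = np.random.default_rng(seed)
    folds = rng.permutation(m) % min(cv_folds, m)
    cv_err = np.zeros(n_lambda)
    for k in np.unique(folds):
        tr = folds != k
        if tr.sum() < 2:
            continue
        for li, lam in enumerate(lambdas):
            th, _, _ = _het_fit(x[tr], y[tr], w[tr], lam)
            cv_err[li] += float((w[~tr] * (y[~tr] - th * x[~tr]) ** 2).sum())
    best = int(np.argmin(cv_err))
    lam = float(lambdas[best])
    theta, phi, converged = _het_fit(x, y, w, lam)
    if not converged:
        logger.warning("het_penalized did not converge at lambda=%.3g", lam)

    se_e = t["se_exp"].to_numpy()
    se_o = t["se_out"].to_numpy()
    boots = np.empty(n_boot)
    for b in range(n_boot):
        xb = rng.normal(x, se_e)
        yb = rng.normal(y, se_o)
        ok = xb != 0
        if ok.sum() < 2:
            boots[b] = np.nan
            continue
        th_b, _, _ = _het_fit(xb[ok], yb[ok], w[ok], lam)
        boots[b] = th_b
    se = float(np.nanstd(boots, ddof=1))
    est = MrEstimate(
        "het_penalized",
        float(theta),
        se,
        _normal_p(float(theta), se),
        iv_set.n_iv,
        bootstrap_seed=seed,
        converged=converged,
    )
    return est


_METHODS = {
    "ivw": lambda ivs, seed: ivw(ivs),
    "wme": lambda ivs, seed: weighted_median(ivs, seed=seed),
    "egger": lambda ivs, seed: egger(ivs),
    "het": lambda ivs, seed: het_penalized(ivs, seed=seed),
}


def run_methods(
    iv_set: InstrumentSet, methods: tuple[str, ...] = ("ivw", "wme", "egger"), seed: int = 0
) -> dict[str, MrEstimate]:
    iv_set.require()
    return {m: _METHODS[m](iv_set, seed) for m in methods}


def bidirectional_mr(
    gwas_a: pd.DataFrame,
    gwas_b: pd.DataFrame,
    panel: LdReferencePanel,
    methods: tuple[str, ...] = ("ivw", "wme", "egger"),
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.01,
    window_bp: int = 250_000,
    locus: Locus | None = None,
    exclude_locus: Locus | None = None,
    seed: int = 0,
    label_a: str = "traitA",
    label_b: str = "traitB",
) -> dict[str, dict]:
    """Run A -> B and B -> A MR with every requested method.

    Each direction reports either the method estimates or a refusal record
    with the surviving instrument count.  Locus restriction/exclusion is
    applied to the exposure's instrument selection in both directions.
    """
    out: dict[str, dict] = {}
    for key, exp, outc, lab in (
        ("a_to_b", gwas_a, gwas_b, label_a),
        ("b_to_a", gwas_b, gwas_a, label_b),
    ):
        ivs = build_instruments(
            exp,
            outc,
            panel,
            p_threshold,
            r2_threshold,
            window_bp,
            locus=locus,
            exclude_locus=exclude_locus,
            exposure_id=lab,
        )
        try:
            est = run_methods(ivs, methods, seed)
            out[key] = {"estimates": est, "n_iv": ivs.n_iv, "refused": False}
        except InsufficientInstruments as err:
            out[key] = {"estimates": {}, "n_iv": err.n_iv, "refused": True,
                        "reason": str(err)}
    return out
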