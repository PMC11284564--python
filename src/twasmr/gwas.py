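"""GWAS summary-statistic data model, I/O, meta-analysis, harmonization, LD.

Summary statistics live in pandas DataFrames with the fixed column set
``SUMSTAT_COLUMNS`` (variant_id, chrom, pos, effect_allele, other_allele,
beta, se, pvalue, eaf, n).  For binary traits ``beta`` is a log odds ratio.
Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import SUMSTAT_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "Variant",
    "LdReferencePanel",
    "read_summary_stats",
    "write_summary_stats",
    "meta_fixed_effect",
    "meta_analyse",
    "harmonize",
    "clump",
    "SUMSTAT_COLUMNS",
]

_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP with an explicit effect-allele orientation."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"position must be positive, got {self.pos}")
        if self.effect_allele not in _BASES or self.other_allele not in _BASES:
            raise ValueError(
                f"alleles must be single nucleotides in ACGT, got "
                f"{self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele must differ")

    @property
    def is_palindromic(self) -> bool:
        return _COMPLEMENT[self.effect_allele] == self.other_allele


# --- I/O --------------------------------------------------------------------

_NUMERIC = {"pos": int, "beta": float, "se": float, "pvalue": float, "eaf": float, "n": float}


def read_summary_stats(path) -> pd.DataFrame:
    """Read a GWAS summary TSV, rejecting malformed rows individually.

    Missing required columns raise :class:`ValueError`.  Rows with
    non-numeric fields or ``se <= 0`` are dropped; each rejection is logged
    and recorded (with its 1-based file line number and a reason) in
    ``df.attrs["rejected"]``.  NaN-statistic rows (e.g. monomorphic variants)
    are kept, flagged in ``df.attrs["flagged_missing"]``.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SUMSTAT_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"summary-statistics file {path} is missing columns: {missing}")

    rejected: list[dict] = []
    keep = np.ones(len(raw), dtype=bool)
    parsed = raw[SUMSTAT_COLUMNS].copy()
    for col, typ in _NUMERIC.items():
        vals = pd.to_numeric(parsed[col], errors="coerce")
        bad = vals.isna() & parsed[col].notna() & (parsed[col].str.lower() != "nan")
        for i in np.flatnonzero(bad.to_numpy()):
            rejected.append(
                {"line": i + 2, "reason": f"non-numeric {col}: {parsed[col].iat[i]!r}"}
            )
        keep &= ~bad.to_numpy()
        parsed[col] = vals
    bad_se = (parsed["se"] <= 0).to_numpy() & keep
    for i in np.flatnonzero(bad_se):
        rejected.append({"line": i + 2, "reason": f"se <= 0 ({parsed['se'].iat[i]})"})
    keep &= ~bad_se

    df = parsed[keep].reset_index(drop=True)
    df["pos"] = df["pos"].astype(int)
    df["n"] = df["n"].astype(float)
    for rec in rejected:
        logger.warning("rejected row at line %d of %s: %s", rec["line"], path, rec["reason"])
    df.attrs["rejected"] = rejected
    df.attrs["flagged_missing"] = df.index[df["beta"].isna()].tolist()
    return df


def write_summary_stats(df: pd.DataFrame, path) -> None:
    """Write a summary-statistic table as TSV (round-trips to >=10 digits)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# --- fixed-effect meta-analysis ---------------------------------------------


def meta_fixed_effect(records: pd.DataFrame | list) -> pd.Series:
    """Inverse-variance fixed-effect meta-analysis of one variant across studies.

    All rows must refer to the same variant with identical allele
    orientation (harmonize first).  The combined effect is the
    inverse-variance weighted mean, combined SE = (sum of weights)^-1/2, and
    the p-value comes from the combined z.  Cochran's Q and I^2 are reported
    alongside but do not alter the estimate.
    """
    df = pd.DataFrame(records)
    if len(df) == 0:
        raise ValueError("meta_fixed_effect requires at least one study")
    for col in ("variant_id", "effect_allele", "other_allele"):
        if df[col].nunique() != 1:
            raise ValueError(
                f"cannot meta-analyse: studies disagree on {col}: {sorted(df[col].unique())}"
            )
    if (df["se"] <= 0).any():
        raise ValueError("all standard errors must be positive")
    w = 1.0 / df["se"].to_numpy() ** 2
    beta = float((w * df["beta"].to_numpy()).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = beta / se
    q = float((w * (df["beta"].to_numpy() - beta) ** 2).sum())
    dfree = len(df) - 1
    i2 = max(0.0, (q - dfree) / q) if q > 0 and dfree > 0 else 0.0
    n = float(df["n"].sum())
    eaf = float((df["eaf"].to_numpy() * df["n"].to_numpy()).sum() / n)
    out = df.iloc[0][["variant_id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["pvalue"] = float(2.0 * stats.norm.sf(abs(z)))
    out["eaf"] = eaf
    out["n"] = n
    out["het_q"] = q
    out["het_i2"] = i2
    return out


def meta_analyse(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Variant-wise fixed-effect meta-analysis of several study tables.

    Variants are matched on variant_id; a variant present in only a subset
    of studies is combined over that subset.  Rows with missing statistics
    are excluded per variant; a variant with no usable row in any study is
    emitted with NaN statistics.
    """
    stacked = pd.concat(tables, ignore_index=True)
    rows = []
    for vid, grp in stacked.groupby("variant_id", sort=False):
        usable = grp.dropna(subset=["beta", "se"])
        usable = usable[usable["se"] > 0]
        if len(usable) == 0:
            row = grp.iloc[0][SUMSTAT_COLUMNS].copy()
            row[["beta", "se", "pvalue"]] = np.nan
            rows.append(row)
        else:
            rows.append(meta_fixed_effect(usable))
    out = pd.DataFrame(rows).reset_index(drop=True)
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


# --- allele harmonization ---------------------------------------------------


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_band: tuple[float, float] = (0.4, 0.6),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align outcome records to the exposure's effect-allele orientation.

    Variants are matched on (chrom, pos).  If the outcome's alleles are
    swapped relative to the exposure (directly or on the opposite strand),
    the outcome beta is sign-flipped and its eaf complemented.  Palindromic
    variants (A/T or C/G) whose exposure eaf falls inside
    ``palindromic_band`` are dropped as strand-ambiguous.  Incompatible
    allele sets are excluded with a reason code.

    Returns (harmonized, exclusions); ``harmonized`` has columns
    variant_id/chrom/pos/effect_allele/other_allele/beta_exp/se_exp/
    pvalue_exp/eaf_exp/beta_out/se_out/pvalue_out/eaf_out; ``exclusions``
    has variant_id and reason.
    """
    merged = exposure.merge(
        outcome, on=["chrom", "pos"], suffixes=("_exp", "_out"), how="inner"
    )
    rows, excl = [], []
    for _, r in merged.iterrows():
        ea_x, oa_x = r["effect_allele_exp"], r["other_allele_exp"]
        ea_y, oa_y = r["effect_allele_out"], r["other_allele_out"]
        palindromic = _COMPLEMENT[ea_x] == oa_x
        if palindromic and palindromic_band[0] < r["eaf_exp"] < palindromic_band[1]:
            excl.append({"variant_id": r["variant_id_exp"], "reason": "palindromic-ambiguous"})
            continue
        flip_y = None
        if (ea_y, oa_y) == (ea_x, oa_x):
            flip_y = False
        elif (ea_y, oa_y) == (oa_x, ea_x):
            flip_y = True
        elif not palindromic:
            cx, cox = _COMPLEMENT[ea_x], _COMPLEMENT[oa_x]
            if (ea_y, oa_y) == (cx, cox):
                flip_y = False
            elif (ea_y, oa_y) == (cox, cx):
                flip_y = True
        if flip_y is None:
            excl.append({"variant_id": r["variant_id_exp"], "reason": "allele-mismatch"})
            continue
        beta_out = -r["beta_out"] if flip_y else r["beta_out"]
        eaf_out = 1.0 - r["eaf_out"] if flip_y else r["eaf_out"]
        rows.append(
            {
                "variant_id": r["variant_id_exp"],
                "chrom": r["chrom"],
                "pos": r["pos"],
                "effect_allele": ea_x,
                "other_allele": oa_x,
                "beta_exp": r["beta_exp"],
                "se_exp": r["se_exp"],
                "pvalue_exp": r["pvalue_exp"],
                "eaf_exp": r["eaf_exp"],
                "beta_out": beta_out,
                "se_out": r["se_out"],
                "pvalue_out": r["pvalue_out"],
                "eaf_out": eaf_out,
            }
        )
    harmonized = pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "chrom",
            "pos",
            "effect_allele",
            "other_allele",
            "beta_exp",
            "se_exp",
            "pvalue_exp",
            "eaf_exp",
            "beta_out",
            "se_out",
            "pvalue_out",
            "eaf_out",
        ],
    )
    exclusions = pd.DataFrame(excl, columns=["variant_id", "reason"])
    for rec in excl:
        logger.info("harmonize: dropped %s (%s)", rec["variant_id"], rec["reason"])
    return harmonized, exclusions


# --- LD reference panel -----------------------------------------------------


class LdReferencePanel:
    """Genotype dosages (or a precomputed correlation matrix) for LD queries.

    Supplies the pairwise dosage correlations rho and the per-variant dosage
    standard deviations sigma used by the summary TWAS variance and by
    clumping r^2.
    """

    def __init__(
        self,
        variants: pd.DataFrame,
        dosages: np.ndarray | None = None,
        corr: np.ndarray | None = None,
        sd: np.ndarray | None = None,
    ):
        self.variants = variants.reset_index(drop=True)
        self._index = {v: i for i, v in enumerate(self.variants["variant_id"])}
        if dosages is not None:
            self._dosages = np.asarray(dosages, dtype=float)
            self._corr = None
            self._sd = self._dosages.std(axis=0, ddof=1)
        elif corr is not None:
            corr = np.asarray(corr, dtype=float)
            if corr.shape != (len(self.variants),) * 2:
                raise ValueError("correlation matrix shape does not match variants")
            if not np.allclose(corr, corr.T, atol=1e-8):
                raise ValueError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
                raise ValueError("correlation matrix must have unit diagonal")
            if sd is None:
                raise ValueError("per-variant dosage SDs required with a correlation matrix")
            self._dosages = None
            self._corr = corr
            self._sd = np.asarray(sd, dtype=float)
        else:
            raise ValueError("provide either dosages or a correlation matrix")

    @classmethod
    def from_dosage_file(cls, variants_path, dosage_path) -> "LdReferencePanel":
        variants = pd.read_csv(variants_path, sep="\t", dtype={"chrom": str})
        dosages = np.loadtxt(dosage_path, delimiter="\t")
        if dosages.ndim == 1:
            dosages = dosages[:, None]
        return cls(variants, dosages=dosages)

    def _cols(self, variant_ids) -> np.ndarray:
        try:
            return np.array([self._index[v] for v in variant_ids])
        except KeyError as err:
            raise KeyError(f"variant {err.args[0]!r} not present in LD panel") from None

    def sd(self, variant_ids) -> np.ndarray:
        """Dosage standard deviations (ddof=1) for the requested variants."""
        return self._sd[self._cols(variant_ids)]

    def corr_matrix(self, variant_ids) -> np.ndarray:
        idx = self._cols(variant_ids)
        if len(idx) == 1:
            return np.ones((1, 1))
        if self._corr is not None:
            return self._corr[np.ix_(idx, idx)]
        sub = self._dosages[:, idx]
        sd = sub.std(axis=0)
        if (sd == 0).any():
            # monomorphic in panel: correlation undefined, treat as independent
            r = np.eye(len(idx))
            ok = sd > 0
            if ok.sum() > 1:
                r[np.ix_(ok, ok)] = np.corrcoef(sub[:, ok], rowvar=False)
            return r
        return np.corrcoef(sub, rowvar=False)

    def r2(self, v1: str, v2: str) -> float:
        """Squared Pearson correlation of the two variants' dosage vectors."""
        if v1 == v2:
            return 1.0
        r = self.corr_matrix([v1, v2])[0, 1]
        return float(r * r)


# --- LD clumping ------------------------------------------------------------


def clump(
    records: pd.DataFrame,
    panel: LdReferencePanel,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.01,
    window_bp: int = 250_000,
) -> pd.DataFrame:
    """Greedy P-value-ordered LD clumping of a summary-statistic table.

    Variants with P < ``p_threshold`` are visited in ascending P (ties
    broken by chrom, then position); a variant is accepted iff its r^2 with
    every already-accepted variant within ``window_bp`` (center-to-center,
    inclusive, same chromosome) is below ``r2_threshold``.  Returns the
    accepted subset of ``records`` sorted by genomic position; empty input
    or no passing variant yields an empty frame.
    """
    passing = records.dropna(subset=["pvalue"])
    passing = passing[passing["pvalue"] < p_threshold]
    if len(passing) == 0:
        return records.iloc[0:0].copy()
    passing = passing.sort_values(["pvalue", "chrom", "pos"], kind="mergesort")
    accepted: list[int] = []
    for idx, row in passing.iterrows():
        ok = True
        for j in accepted:
            prev = records.loc[j]
            if prev["chrom"] != row["chrom"]:
                continue
            if abs(int(prev["pos"]) - int(row["pos"])) > window_bp:
                continue
            if panel.r2(prev["variant_id"], row["variant_id"]) >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(idx)
    out = records.loc[accepted].sort_values(["chrom", "pos"], kind="mergesort")
    return out.reset_index(drop=True)
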