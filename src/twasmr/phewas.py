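"""Phenome-wide scan of one gene's predicted expression across a phecode
catalog of GWAS summary statistics."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gwas import LdReferencePanel, read_summary_stats
from .models import ExpressionModel
from .twas import NoOverlappingVariants, bh_adjust, summary_twas

__all__ = ["PhenotypeCatalog", "phewas_scan", "read_catalog"]


@dataclass
class PhenotypeCatalog:
    """Per-phecode GWAS summary tables with display labels and categories."""

    entries: list[dict] = field(default_factory=list)

    def add(self, phecode: str, label: str, category: str, gwas: pd.DataFrame) -> None:
        if any(e["phecode"] == phecode for e in self.entries):
            raise ValueError(f"duplicate phecode {phecode!r} in catalog")
        self.entries.append(
            {"phecode": phecode, "label": label, "category": category, "gwas": gwas}
        )

    def __len__(self) -> int:
        return len(self.entries)


def read_catalog(manifest_path) -> PhenotypeCatalog:
    """Load a catalog from a manifest TSV: phecode, label, category, path.

    Paths are resolved relative to the manifest's directory.
    """
    manifest = pd.read_csv(manifest_path, sep="\t", dtype=str)
    base = Path(manifest_path).parent
    cat = PhenotypeCatalog()
    for _, row in manifest.iterrows():
        cat.add(
            row["phecode"],
            row["label"],
            row["category"],
            read_summary_stats(base / row["path"]),
        )
    return cat


def phewas_scan(
    model: ExpressionModel,
    catalog: PhenotypeCatalog,
    panel: LdReferencePanel,
    significance_threshold: float = 0.05,
) -> pd.DataFrame:
    """One summary TWAS per catalog phenotype, BH-adjusted within the scan.

    Phenotypes with no overlapping variants are reported in
    ``df.attrs["skipped"]``.  Rows come back sorted by p-value with a
    ``direction`` column (sign of the z-score).
    """
    if len(catalog) == 0:
        raise ValueError("phenotype catalog is empty")
    rows, skipped = [], []
    for entry in catalog.entries:
        try:
            r = summary_twas(model, entry["gwas"], panel)
        except NoOverlappingVariants as err:
            skipped.append({"phecode": entry["phecode"], "reason": str(err)})
            continue
        rows.append(
            {
                "gene_id": model.gene_id,
                "phecode": entry["phecode"],
                "label": entry["label"],
                "category": entry["category"],
                "zscore": r.zscore,
                "pvalue": r.pvalue,
                "direction": "+" if r.zscore >= 0 else "-",
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["adjusted_p"] = bh_adjust(df["pvalue"].to_numpy())
        df["significant"] = df["adjusted_p"] < significance_threshold
        df = df.sort_values(["pvalue", "phecode"], kind="mergesort").reset_index(drop=True)
    df.attrs["skipped"] = skipped
    return df
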