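import numpy as np
import pandas as pd
import pytest

from twasmr.gwas import LdReferencePanel
from twasmr.simulate import SUMSTAT_COLUMNS


@pytest.fixture(scope="session")
def independent_panel():
    """A reference panel of mutually independent common variants."""
    rng = np.random.default_rng(42)
    m = 30
    dosages = rng.binomial(2, 0.3, size=(4000, m)).astype(float)
    variants = pd.DataFrame(
        {
            "variant_id": [f"pv_{i:03d}" for i in range(m)],
            "chrom": "1",
            "pos": (np.arange(m) + 1) * 100_000,
            "effect_allele": "A",
            "other_allele": "G",
        }
    )
    return LdReferencePanel(variants, dosages=dosages)


def sumstat_frame(rows):
    """Build a summary-statistic table from dicts with defaults filled in."""
    defaults = {
        "chrom": "1",
        "effect_allele": "A",
        "other_allele": "G",
        "beta": 0.1,
        "se": 0.05,
        "pvalue": 0.04,
        "eaf": 0.3,
        "n": 1000,
    }
    full = []
    if not rows:
        return pd.DataFrame(columns=SUMSTAT_COLUMNS)
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec.setdefault("variant_id", f"v{i}")
        rec.setdefault("pos", (i + 1) * 1000)
        rec.update(row)
        full.append(rec)
    return pd.DataFrame(full)[SUMSTAT_COLUMNS]
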