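"""Summary-stat I/O, fixed-effect meta-analysis, harmonization, LD, clumping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from twasmr.gwas import (
    LdReferencePanel,
    Variant,
    clump,
    harmonize,
    meta_fixed_effect,
    read_summary_stats,
    write_summary_stats,
)
from twasmr.simulate import SimulationConfig, make_gwas_summary, simulate_genotypes

from conftest import sumstat_frame


# --- Variant ----------------------------------------------------------------


def test_variant_validation():
    Variant("rs1", "1", 100, "A", "G")
    with pytest.raises(ValueError):
        Variant("rs1", "1", 0, "A", "G")
    with pytest.raises(ValueError):
        Variant("rs1", "1", 100, "A", "A")
    with pytest.raises(ValueError):
        Variant("rs1", "1", 100, "N", "G")


# --- I/O --------------------------------------------------------------------


def test_read_exact_values(tmp_path):
    df = sumstat_frame([
        {"variant_id": "a", "beta": 0.123456, "se": 0.01, "pvalue": 1e-5},
        {"variant_id": "b", "beta": -0.2, "se": 0.02, "pvalue": 0.5},
        {"variant_id": "c", "beta": 0.0, "se": 0.03, "pvalue": 1.0},
    ])
    path = tmp_path / "s.tsv"
    write_summary_stats(df, path)
    back = read_summary_stats(path)
    assert len(back) == 3
    assert back["beta"].tolist() == pytest.approx([0.123456, -0.2, 0.0])
    assert back["variant_id"].tolist() == ["a", "b", "c"]


def test_bad_rows_rejected_with_line_numbers(tmp_path):
    df = sumstat_frame([
        {"variant_id": "a"},
        {"variant_id": "b", "se": 0.0},
        {"variant_id": "c", "beta": "oops"},
        {"variant_id": "d"},
    ])
    path = tmp_path / "s.tsv"
    df.to_csv(path, sep="\t", index=False)
    back = read_summary_stats(path)
    assert back["variant_id"].tolist() == ["a", "d"]
    report = {r["line"]: r["reason"] for r in back.attrs["rejected"]}
    assert 3 in report and "se" in report[3]
    assert 4 in report and "beta" in report[4]


def test_missing_column_raises(tmp_path):
    df = sumstat_frame([{"variant_id": "a"}]).drop(columns=["eaf"])
    path = tmp_path / "s.tsv"
    df.to_csv(path, sep="\t", index=False)
    with pytest.raises(ValueError, match="eaf"):
        read_summary_stats(path)


def test_round_trip_thousand_records(tmp_path):
    cfg = SimulationConfig(n_samples=500, n_variants=1000, seed=21)
    rng = np.random.default_rng(21)
    d, v = simulate_genotypes(cfg, rng)
    y = rng.standard_normal(500)
    df = make_gwas_summary(d, y, v)
    path = tmp_path / "s.tsv"
    write_summary_stats(df, path)
    back = read_summary_stats(path)
    for col in ("beta", "se", "pvalue", "eaf"):
        a, b = df[col].to_numpy(), back[col].to_numpy()
        ok = np.isfinite(a)
        assert np.nanmax(np.abs((a[ok] - b[ok]) / a[ok])) < 1e-6


# --- meta-analysis ----------------------------------------------------------


def test_meta_single_study_identity():
    df = sumstat_frame([{"variant_id": "a", "beta": 0.25, "se": 0.07}])
    out = meta_fixed_effect(df)
    assert out["beta"] == pytest.approx(0.25)
    assert out["se"] == pytest.approx(0.07)


def test_meta_identical_studies_shrink_se_by_sqrt_k():
    for k in (2, 4, 9):
        df = sumstat_frame([{"variant_id": "a", "pos": 5, "beta": 0.2, "se": 0.1}] * k)
        out = meta_fixed_effect(df)
        assert out["beta"] == pytest.approx(0.2)
        assert out["se"] == pytest.approx(0.1 / np.sqrt(k))


def test_meta_hand_computed_weighted_mean():
    # weights 1/0.1^2 = 100 and 1/0.2^2 = 25:
    # beta = (0.1*100 + 0.3*25) / 125 = 0.14, se = 125^-0.5 = 0.08944
    df = sumstat_frame([
        {"variant_id": "a", "pos": 5, "beta": 0.1, "se": 0.1},
        {"variant_id": "a", "pos": 5, "beta": 0.3, "se": 0.2},
    ])
    out = meta_fixed_effect(df)
    assert out["beta"] == pytest.approx(0.14)
    assert out["se"] == pytest.approx(0.08944, abs=1e-5)


def test_meta_requires_consistent_alleles():
    df = sumstat_frame([
        {"variant_id": "a", "pos": 5},
        {"variant_id": "a", "pos": 5, "effect_allele": "G", "other_allele": "A"},
    ])
    with pytest.raises(ValueError, match="disagree"):
        meta_fixed_effect(df)
    with pytest.raises(ValueError, match="at least one"):
        meta_fixed_effect(sumstat_frame([]))


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    st.lists(
        st.tuples(
            st.floats(-1, 1, allow_nan=False),
            st.floats(0.01, 1, allow_nan=False),
        ),
        min_size=1,
        max_size=6,
    ),
    st.randoms(use_true_random=False),
)
def test_meta_order_invariant_and_se_bounded(studies, rnd):
    rows = [
        {"variant_id": "a", "pos": 5, "beta": b, "se": s, "n": 100} for b, s in studies
    ]
    out1 = meta_fixed_effect(sumstat_frame(rows))
    shuffled = rows[:]
    rnd.shuffle(shuffled)
    out2 = meta_fixed_effect(sumstat_frame(shuffled))
    assert out1["beta"] == pytest.approx(out2["beta"], rel=1e-12)
    assert out1["se"] == pytest.approx(out2["se"], rel=1e-12)
    assert out1["se"] <= min(s for _, s in studies) + 1e-12


# --- harmonization ----------------------------------------------------------


def test_harmonize_identical_orientation_unchanged():
    exp = sumstat_frame([{"variant_id": "a", "beta": 0.1}])
    out = sumstat_frame([{"variant_id": "a", "beta": 0.3}])
    h, excl = harmonize(exp, out)
    assert len(h) == 1 and len(excl) == 0
    assert h["beta_out"].iat[0] == pytest.approx(0.3)


def test_harmonize_swapped_alleles_flip_sign_and_eaf():
    exp = sumstat_frame([{"variant_id": "a", "beta": 0.1, "eaf": 0.3}])
    out = sumstat_frame([
        {"variant_id": "a", "effect_allele": "G", "other_allele": "A",
         "beta": 0.3, "eaf": 0.7}
    ])
    h, _ = harmonize(exp, out)
    assert h["beta_out"].iat[0] == pytest.approx(-0.3)
    assert h["eaf_out"].iat[0] == pytest.approx(0.3)


def test_harmonize_palindromic_ambiguous_dropped():
    exp = sumstat_frame([
        {"variant_id": "a", "effect_allele": "A", "other_allele": "T", "eaf": 0.5}
    ])
    out = sumstat_frame([
        {"variant_id": "a", "effect_allele": "A", "other_allele": "T", "eaf": 0.5}
    ])
    h, excl = harmonize(exp, out)
    assert len(h) == 0
    assert excl["reason"].iat[0] == "palindromic-ambiguous"


def test_harmonize_incompatible_alleles_excluded():
    exp = sumstat_frame([{"variant_id": "a"}])
    out = sumstat_frame([
        {"variant_id": "a", "effect_allele": "A", "other_allele": "C"}
    ])
    h, excl = harmonize(exp, out)
    assert len(h) == 0
    assert excl["reason"].iat[0] == "allele-mismatch"


def test_harmonize_is_idempotent():
    exp = sumstat_frame([
        {"variant_id": "a", "beta": 0.1, "eaf": 0.2},
        {"variant_id": "b", "pos": 2000, "beta": -0.4, "eaf": 0.8},
    ])
    out = sumstat_frame([
        {"variant_id": "a", "effect_allele": "G", "other_allele": "A",
         "beta": 0.3, "eaf": 0.7},
        {"variant_id": "b", "pos": 2000, "beta": 0.2, "eaf": 0.6},
    ])
    h1, _ = harmonize(exp, out)
    out_aligned = h1.rename(
        columns={"beta_out": "beta", "se_out": "se", "pvalue_out": "pvalue",
                 "eaf_out": "eaf"}
    )
    out_aligned["n"] = 1000
    h2, _ = harmonize(exp, out_aligned)
    assert np.allclose(h1["beta_out"], h2["beta_out"])
    assert np.allclose(h1["eaf_out"], h2["eaf_out"])


# --- LD panel ---------------------------------------------------------------


def test_r2_of_variant_with_itself_is_one(independent_panel):
    assert independent_panel.r2("pv_000", "pv_000") == 1.0


def test_r2_duplicated_dosage_column():
    rng = np.random.default_rng(0)
    x = rng.binomial(2, 0.4, 500).astype(float)
    variants = pd.DataFrame(
        {"variant_id": ["a", "b"], "chrom": "1", "pos": [1, 2],
         "effect_allele": "A", "other_allele": "G"}
    )
    panel = LdReferencePanel(variants, dosages=np.column_stack([x, x]))
    assert panel.r2("a", "b") == pytest.approx(1.0)


def test_r2_independent_variants_mostly_below_threshold():
    cfg = SimulationConfig(n_samples=5000, n_variants=40, ld_rho=0.0, seed=33)
    d, v = simulate_genotypes(cfg)
    panel = LdReferencePanel(v, dosages=d)
    ids = v["variant_id"].tolist()
    r2s = [panel.r2(ids[i], ids[j]) for i in range(40) for j in range(i + 1, 40)]
    assert np.mean(np.array(r2s) < 0.01) >= 0.95


def test_missing_variant_raises(independent_panel):
    with pytest.raises(KeyError, match="nope"):
        independent_panel.r2("pv_000", "nope")


def test_precomputed_correlation_panel_matches_dosage_panel(independent_panel):
    ids = ["pv_000", "pv_001", "pv_002"]
    corr_panel = LdReferencePanel(
        independent_panel.variants,
        corr=independent_panel.corr_matrix(independent_panel.variants["variant_id"]),
        sd=independent_panel.sd(independent_panel.variants["variant_id"]),
    )
    assert np.allclose(
        corr_panel.corr_matrix(ids), independent_panel.corr_matrix(ids), atol=1e-12
    )


# --- clumping ---------------------------------------------------------------


def _clump_panel():
    rng = np.random.default_rng(1)
    x1 = rng.standard_normal(2000)
    x2 = 0.7 * x1 + 0.71 * rng.standard_normal(2000)  # r^2 ~ 0.5 with x1
    x3 = rng.standard_normal(2000)
    variants = pd.DataFrame(
        {"variant_id": ["v1", "v2", "v3"], "chrom": "1",
         "pos": [100_000, 150_000, 200_000],
         "effect_allele": "A", "other_allele": "G"}
    )
    return LdReferencePanel(variants, dosages=np.column_stack([x1, x2, x3]))


def test_clump_single_passing_variant():
    panel = _clump_panel()
    recs = sumstat_frame([
        {"variant_id": "v1", "pos": 100_000, "pvalue": 1e-10},
        {"variant_id": "v2", "pos": 150_000, "pvalue": 0.5},
    ])
    out = clump(recs, panel)
    assert out["variant_id"].tolist() == ["v1"]


def test_clump_greedy_keeps_independent_pair():
    panel = _clump_panel()
    recs = sumstat_frame([
        {"variant_id": "v1", "pos": 100_000, "pvalue": 1e-10},
        {"variant_id": "v2", "pos": 150_000, "pvalue": 1e-9},
        {"variant_id": "v3", "pos": 200_000, "pvalue": 1e-8 * 0.99},
    ])
    out = clump(recs, panel)
    assert out["variant_id"].tolist() == ["v1", "v3"]


def test_clump_nothing_passes_threshold():
    panel = _clump_panel()
    recs = sumstat_frame([
        {"variant_id": "v1", "pos": 100_000, "pvalue": 1e-6},
        {"variant_id": "v3", "pos": 200_000, "pvalue": 1e-7},
    ])
    assert len(clump(recs, panel)) == 0


def test_clump_outside_window_ignores_ld():
    rng = np.random.default_rng(2)
    x1 = rng.standard_normal(2000)
    variants = pd.DataFrame(
        {"variant_id": ["a", "b"], "chrom": "1", "pos": [100_000, 500_000],
         "effect_allele": "A", "other_allele": "G"}
    )
    panel = LdReferencePanel(variants, dosages=np.column_stack([x1, x1]))
    recs = sumstat_frame([
        {"variant_id": "a", "pos": 100_000, "pvalue": 1e-10},
        {"variant_id": "b", "pos": 500_000, "pvalue": 1e-9},
    ])
    # perfect LD but 400 kb apart: both kept under the 250 kb window
    assert len(clump(recs, panel)) == 2


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_clump_output_pairwise_independent_within_window(seed):
    cfg = SimulationConfig(n_samples=3000, n_variants=60, ld_rho=0.85,
                           ld_block_size=6, seed=seed)
    d, v = simulate_genotypes(cfg)
    rng = np.random.default_rng(seed)
    panel = LdReferencePanel(v, dosages=d)
    recs = v[["variant_id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    recs["beta"], recs["se"], recs["n"] = 0.1, 0.01, 1000
    recs["eaf"] = 0.3
    recs["pvalue"] = 10.0 ** rng.uniform(-12, -6, len(v))
    out = clump(recs, panel)
    assert set(out["variant_id"]) <= set(recs["variant_id"])
    ids, pos = out["variant_id"].tolist(), out["pos"].tolist()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if abs(pos[i] - pos[j]) <= 250_000:
                assert panel.r2(ids[i], ids[j]) < 0.01
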