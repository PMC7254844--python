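"""Summary-statistics I/O, harmonization and LD-filtering behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from progbias.sumstats import (
    LDReference,
    SumStatsFormatError,
    filter_records,
    harmonize,
    ld_clump,
    ld_prune,
    read_sumstats,
    validate_sumstats,
    write_sumstats,
)
from conftest import make_sumstats


# ---------------------------------------------------------------------- I/O


def test_roundtrip(tmp_path):
    df = make_sumstats(5)
    path = tmp_path / "ss.tsv"
    write_sumstats(df, path)
    back = read_sumstats(path)
    pd.testing.assert_frame_equal(back, df, check_dtype=False, atol=1e-12)


def test_invalid_rows_dropped():
    df = make_sumstats(3)
    df.loc[1, "SE"] = 0.0
    clean, n_dropped = validate_sumstats(df)
    assert n_dropped == 1
    assert list(clean["SNP"]) == ["rs1", "rs3"]


def test_or_column_converted(tmp_path):
    df = make_sumstats(3).drop(columns=["BETA"])
    df["OR"] = [1.5, 0.8, 1.0]
    path = tmp_path / "or.tsv"
    df.to_csv(path, sep="\t", index=False)
    back = read_sumstats(path)
    np.testing.assert_allclose(back["BETA"], np.log([1.5, 0.8, 1.0]))


def test_column_map(tmp_path):
    df = make_sumstats(2).rename(columns={"SNP": "rsid", "BETA": "effect"})
    path = tmp_path / "alt.tsv"
    df.to_csv(path, sep="\t", index=False)
    back = read_sumstats(path, column_map={"rsid": "SNP", "effect": "BETA"})
    assert list(back["SNP"]) == ["rs1", "rs2"]


def test_missing_column_names_offender(tmp_path):
    df = make_sumstats(2).drop(columns=["SE"])
    path = tmp_path / "bad.tsv"
    df.to_csv(path, sep="\t", index=False)
    with pytest.raises(SumStatsFormatError, match="SE"):
        read_sumstats(path)


# ------------------------------------------------------------- harmonization


def test_harmonize_identical_alleles_unchanged():
    a = make_sumstats(4)
    b = a.copy()
    merged, report = harmonize(a, b)
    np.testing.assert_allclose(merged["BETA_b"], merged["BETA"])
    assert report["n_flipped"] == 0
    assert report["n_dropped_palindromic"] == 0


def test_harmonize_swapped_alleles_flips_sign():
    a = make_sumstats(1, ea="A", oa="G")
    a.loc[0, ["BETA", "EAF"]] = [0.10, 0.3]
    b = a.copy()
    b.loc[0, ["EA", "OA"]] = ["G", "A"]
    b.loc[0, "EAF"] = 0.7
    merged, report = harmonize(a, b)
    assert report["n_flipped"] == 1
    assert merged["BETA_b"][0] == pytest.approx(-0.10)
    assert merged["EAF_b"][0] == pytest.approx(0.3)


def test_harmonize_strand_flip_resolved():
    a = make_sumstats(1, ea="A", oa="G")
    b = a.copy()
    b.loc[0, ["EA", "OA"]] = ["T", "C"]  # same variant, opposite strand
    merged, report = harmonize(a, b)
    assert report["n_strand_flipped"] == 1
    assert merged["BETA_b"][0] == pytest.approx(merged["BETA"][0])


def test_palindromic_ambiguous_dropped():
    a = make_sumstats(1, ea="A", oa="T")
    a.loc[0, "EAF"] = 0.5
    b = a.copy()
    merged, report = harmonize(a, b)
    assert merged.empty
    assert report["n_dropped_palindromic"] == 1


def test_palindromic_clear_frequency_kept():
    a = make_sumstats(1, ea="G", oa="C")
    a.loc[0, "EAF"] = 0.1
    b = a.copy()
    merged, _ = harmonize(a, b)
    assert len(merged) == 1
    assert merged["BETA_b"][0] == pytest.approx(merged["BETA"][0])


@given(st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_harmonize_self_involution(seed):
    """Harmonizing a non-palindromic table against itself: no flips, no drops."""
    a = make_sumstats(8, seed=seed, ea="A", oa="G")
    merged, report = harmonize(a, a)
    assert len(merged) == len(a)
    assert report["n_flipped"] == 0
    assert report["n_dropped_mismatch"] == 0
    np.testing.assert_allclose(merged["BETA_b"], merged["BETA"])


def test_irreconcilable_alleles_dropped():
    a = make_sumstats(1, ea="A", oa="G")
    b = a.copy()
    b.loc[0, ["EA", "OA"]] = ["A", "C"]
    merged, report = harmonize(a, b)
    assert merged.empty
    assert report["n_dropped_mismatch"] == 1


# --------------------------------------------------------------------- LD


def table_ld(pairs):
    rows = [{"SNP_A": a, "SNP_B": b, "R2": r} for (a, b), r in pairs.items()]
    return LDReference.from_table(pd.DataFrame(rows))


def test_ld_reference_basics():
    ld = table_ld({("rs1", "rs2"): 0.5})
    assert ld.r2("rs1", "rs1") == 1.0
    assert ld.r2("rs2", "rs1") == 0.5  # symmetric
    assert ld.r2("rs1", "rs99") == 0.0  # missing -> independent


def test_ld_reference_rejects_bad_r2():
    with pytest.raises(ValueError):
        table_ld({("a", "b"): 1.5})


def test_clump_three_snp_example():
    df = make_sumstats(3, p=[1e-8, 1e-7, 1e-6])
    ld = table_ld({("rs1", "rs2"): 0.5, ("rs1", "rs3"): 0.05})
    out = ld_clump(df, ld, r2_max=0.2, window_bp=250_000)
    assert list(out["SNP"]) == ["rs1", "rs3"]


def test_clump_window_scoped_to_chromosome():
    df = pd.concat(
        [make_sumstats(1, chrom=1, p=[1e-8]), make_sumstats(1, chrom=2, p=[1e-7])]
    ).reset_index(drop=True)
    ld = table_ld({("rs1", "rs1"): 1.0})  # same ids on both chromosomes
    out = ld_clump(df, ld, r2_max=0.2, window_bp=250_000)
    assert len(out) == 2


def test_clump_empty_input():
    df = make_sumstats(0)
    assert ld_clump(df, table_ld({}), 0.2, 250_000).empty


def test_prune_pairwise_examples():
    df = make_sumstats(2, bp_step=1_000)
    ld = table_ld({("rs1", "rs2"): 0.5})
    out = ld_prune(df, ld, window_bp=250_000, step_snps=5, r2_max=0.1)
    assert list(out["SNP"]) == ["rs1"]  # later-position member dropped

    ld_low = table_ld({("rs1", "rs2"): 0.05})
    assert len(ld_prune(df, ld_low, 250_000, 5, 0.1)) == 2  # intact


def clump_oracle(df, ld, r2_max, window_bp):
    kept = []
    for _, row in df.sort_values(["P", "BP"]).iterrows():
        if all(
            row["CHR"] != k["CHR"]
            or abs(row["BP"] - k["BP"]) > window_bp
            or ld.r2(row["SNP"], k["SNP"]) < r2_max
            for k in kept
        ):
            kept.append(row)
    return sorted(k["SNP"] for k in kept)


def prune_oracle(df, ld, r2_max, window_bp):
    kept = []
    for _, row in df.sort_values(["CHR", "BP"]).iterrows():
        if all(
            row["CHR"] != k["CHR"]
            or abs(row["BP"] - k["BP"]) > window_bp
            or ld.r2(row["SNP"], k["SNP"]) < r2_max
            for k in kept
        ):
            kept.append(row)
    return sorted(k["SNP"] for k in kept)


def random_instance(seed, max_snps=50):
    r = np.random.default_rng(seed)
    m = int(r.integers(3, max_snps + 1))
    df = make_sumstats(m, seed=seed, bp_step=0)
    df["BP"] = np.sort(r.integers(1, 600_000, m))
    df["CHR"] = r.integers(1, 3, m)
    pairs = {}
    ids = df["SNP"].to_list()
    for i in range(m):
        for j in range(i + 1, m):
            if r.random() < 0.3:
                pairs[(ids[i], ids[j])] = float(r.random())
    return df, table_ld(pairs)


@pytest.mark.parametrize("seed", range(12))
def test_clump_and_prune_match_oracles(seed):
    df, ld = random_instance(seed)
    out = ld_clump(df, ld, r2_max=0.2, window_bp=100_000)
    assert sorted(out["SNP"]) == clump_oracle(df, ld, 0.2, 100_000)
    out = ld_prune(df, ld, window_bp=100_000, step_snps=5, r2_max=0.1)
    assert sorted(out["SNP"]) == prune_oracle(df, ld, 0.1, 100_000)


@pytest.mark.parametrize("seed", range(6))
def test_clump_output_mutually_compatible(seed):
    """Post-hoc invariant: every retained pair within the window has r2 < r2_max."""
    df, ld = random_instance(seed)
    out = ld_clump(df, ld, r2_max=0.2, window_bp=100_000)
    assert set(out["SNP"]) <= set(df["SNP"])
    for i, a in out.iterrows():
        for j, b in out.iterrows():
            if i < j and a["CHR"] == b["CHR"] and abs(a["BP"] - b["BP"]) <= 100_000:
                assert ld.r2(a["SNP"], b["SNP"]) < 0.2


# ------------------------------------------------------------------ filters


def test_filter_strict_inequalities():
    df = make_sumstats(3)
    df["INFO"] = [0.99, 0.995, 1.0]
    assert len(filter_records(df, info_min=0.99)) == 2

    df["P"] = [0.049, 0.05, 0.5]
    assert len(filter_records(df, p_max=0.05)) == 1

    pd.testing.assert_frame_equal(filter_records(df), df)


def test_filter_absent_field_errors():
    df = make_sumstats(2).drop(columns=["INFO"])
    with pytest.raises(ValueError, match="INFO"):
        filter_records(df, info_min=0.9)
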