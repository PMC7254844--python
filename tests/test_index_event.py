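"""Slope estimators, I2_GX, beta adjustment, IVW, and the orchestrated correction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from progbias.index_event import (
    CorrectionConfig,
    adjust_prognosis,
    correct_and_estimate,
    i2_gx,
    ivw,
    pair_and_filter,
    slope_hedges_olkin,
    slope_naive,
    slope_simex,
)
from progbias.sumstats import LDReference
from conftest import make_sumstats


def make_pairs(k=50, slope=-0.3, se1=0.02, se2=0.05, tau=0.1, seed=0, noisy_b1=True):
    """Paired effects with a known generative cross-SNP slope."""
    rng = np.random.default_rng(seed)
    b1_true = rng.normal(0, tau, k)
    b1 = b1_true + (rng.normal(0, se1, k) if noisy_b1 and se1 > 0 else 0.0)
    b2 = slope * b1_true + rng.normal(0, se2, k)
    return pd.DataFrame(
        {"SNP": [f"rs{i + 1}" for i in range(k)],
         "beta_inc": b1, "se_inc": np.full(k, se1),
         "p_inc": np.full(k, 0.01),
         "beta_prog": b2, "se_prog": np.full(k, se2)}
    )


# ------------------------------------------------------------ pairing


def test_pair_and_filter_composition():
    """10 shared SNPs, 2 failing INFO, 2 pruned away -> 6 pairs."""
    inc = make_sumstats(10, bp_step=1_000)
    prog = make_sumstats(10, bp_step=1_000, seed=1)
    inc.loc[[8, 9], "INFO"] = 0.5
    ld = LDReference.from_table(pd.DataFrame(
        {"SNP_A": ["rs1", "rs3"], "SNP_B": ["rs2", "rs4"], "R2": [0.9, 0.8]}))
    pairs = pair_and_filter(inc, prog, ld=ld, info_min=0.99, prune_params=(250_000, 5, 0.1))
    assert len(pairs) == 6
    assert {"rs2", "rs4", "rs9", "rs10"}.isdisjoint(set(pairs["SNP"]))


def test_pair_p_inc_subset():
    inc = make_sumstats(4, p=[0.01, 0.2, 0.03, 0.9])
    prog = make_sumstats(4, seed=1)
    pairs = pair_and_filter(inc, prog, ld=None, info_min=None, prune_params=None,
                            p_inc_max=0.05)
    assert set(pairs["SNP"]) == {"rs1", "rs3"}


def test_pair_disjoint_tables_error():
    inc = make_sumstats(3)
    prog = make_sumstats(3, seed=1)
    prog["SNP"] = ["rsX", "rsY", "rsZ"]
    with pytest.raises(ValueError, match="no shared"):
        pair_and_filter(inc, prog)


# ------------------------------------------------------------ naive slope


def test_naive_slope_exact_on_noiseless_line():
    pairs = make_pairs(k=10, slope=0.5, se1=0.0, se2=0.0, noisy_b1=False)
    pairs["beta_prog"] = 0.5 * pairs["beta_inc"]
    est = slope_naive(pairs)
    assert est.value == pytest.approx(0.5, abs=1e-12)


def test_naive_slope_matches_ols_oracle():
    pairs = make_pairs(seed=3)
    est = slope_naive(pairs)
    X = sm.add_constant(pairs["beta_inc"].to_numpy())
    ref = sm.OLS(pairs["beta_prog"].to_numpy(), X).fit()
    assert est.value == pytest.approx(ref.params[1], abs=1e-10)
    assert est.se == pytest.approx(ref.bse[1], abs=1e-10)


def test_naive_slope_attenuated_by_measurement_error():
    """Averaged over replicates, |naive slope| < |generative slope| when beta1 is noisy."""
    vals = [slope_naive(make_pairs(k=200, se1=0.08, seed=s)).value for s in range(40)]
    assert np.mean(vals) > -0.3  # attenuated toward zero from below


def test_zero_variance_errors():
    pairs = make_pairs(k=5)
    pairs["beta_inc"] = 0.1
    with pytest.raises(ValueError):
        slope_naive(pairs)


# ------------------------------------------------------- Hedges-Olkin


def test_hedges_olkin_equals_naive_without_measurement_error():
    pairs = make_pairs(k=30, se1=0.0, seed=1)
    assert slope_hedges_olkin(pairs).value == pytest.approx(slope_naive(pairs).value, abs=1e-12)


def test_hedges_olkin_matches_direct_formula():
    pairs = make_pairs(seed=5)
    b1 = pairs["beta_inc"].to_numpy()
    b2 = pairs["beta_prog"].to_numpy()
    s1 = pairs["se_inc"].to_numpy()
    expected = np.cov(b1, b2, ddof=1)[0, 1] / (np.var(b1, ddof=1) - np.mean(s1**2))
    assert slope_hedges_olkin(pairs).value == pytest.approx(expected, abs=1e-10)


def test_hedges_olkin_recovers_generative_slope():
    vals = [slope_hedges_olkin(make_pairs(k=300, seed=s)).value for s in range(60)]
    mc_se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(np.mean(vals) - (-0.3)) < 3 * mc_se


def test_hedges_olkin_noise_dominated_errors():
    pairs = make_pairs(k=20, tau=0.001, se1=0.5, seed=2)
    with pytest.raises(ValueError, match="noise"):
        slope_hedges_olkin(pairs)


# ---------------------------------------------------------------- SIMEX


def test_simex_equals_naive_without_measurement_error():
    pairs = make_pairs(k=30, se1=0.0, seed=4)
    est = slope_simex(pairs, n_sim=50, seed=0)
    naive = slope_naive(pairs).value
    assert est.value == pytest.approx(naive, abs=1e-6)
    assert np.allclose(est.diagnostics["mean_slopes"], naive, atol=1e-9)


def test_simex_attenuation_monotone_in_lambda():
    pairs = make_pairs(k=400, se1=0.05, seed=6)
    est = slope_simex(pairs, n_sim=400, seed=1)
    mags = np.abs(est.diagnostics["mean_slopes"])
    assert np.all(np.diff(mags) <= 1e-3)  # |slope| shrinks as noise is added


def test_simex_deterministic_under_seed():
    pairs = make_pairs(seed=7)
    a = slope_simex(pairs, n_sim=100, seed=42)
    b = slope_simex(pairs, n_sim=100, seed=42)
    assert a.value == b.value
    assert a.se == b.se


def test_simex_and_hedges_olkin_agree_on_clean_data():
    pairs = make_pairs(k=500, seed=8)
    ho = slope_hedges_olkin(pairs)
    sx = slope_simex(pairs, n_sim=300, seed=0)
    joint = np.hypot(ho.se, sx.se) + 1e-6
    assert abs(ho.value - sx.value) < 3 * max(joint, 0.03)


def test_simex_lambda_grid_validation():
    with pytest.raises(ValueError):
        slope_simex(make_pairs(), lambda_grid=(0.0, 3.0))


# ---------------------------------------------------------------- I2_GX


def test_i2_zero_for_identical_effects():
    pairs = make_pairs(k=5)
    pairs["beta_inc"] = 0.2
    pairs["se_inc"] = 0.01
    i2, diag = i2_gx(pairs)
    assert i2 == 0.0
    assert diag["Q"] == pytest.approx(0.0)


def test_i2_hand_oracle():
    pairs = pd.DataFrame({"beta_inc": [0.1, 0.2, 0.3], "se_inc": [0.01] * 3,
                          "beta_prog": 0.0, "se_prog": 0.1})
    i2, diag = i2_gx(pairs)
    assert diag["Q"] == pytest.approx(200.0, abs=1e-10)
    assert i2 == pytest.approx(0.99, abs=1e-10)


def test_i2_scale_invariant():
    pairs = make_pairs(seed=9)
    i2a, _ = i2_gx(pairs)
    scaled = pairs.assign(beta_inc=pairs["beta_inc"] * 7, se_inc=pairs["se_inc"] * 7)
    i2b, _ = i2_gx(scaled)
    assert i2a == pytest.approx(i2b, abs=1e-12)


# ----------------------------------------------------------- adjustment


def test_adjust_zero_slope_is_identity():
    pairs = make_pairs(seed=10)
    adj = adjust_prognosis(pairs, 0.0)
    np.testing.assert_allclose(adj["BETA"], pairs["beta_prog"], atol=1e-15)
    np.testing.assert_allclose(adj["SE"], pairs["se_prog"], atol=1e-15)


def test_adjust_arithmetic():
    pairs = pd.DataFrame({"SNP": ["rs1"], "beta_inc": [0.20], "se_inc": [0.04],
                          "beta_prog": [0.10], "se_prog": [0.03]})
    adj = adjust_prognosis(pairs, 0.05)
    assert adj["BETA"][0] == pytest.approx(0.09, abs=1e-12)
    adj2 = adjust_prognosis(pairs, 0.5)
    assert adj2["SE"][0] == pytest.approx(np.sqrt(0.0009 + 0.0004), abs=1e-10)


def test_adjust_linearity_in_slope():
    """Adjusting by b1 then b2 equals one pass with b1 + b2 (betas exactly)."""
    pairs = make_pairs(seed=11)
    once = adjust_prognosis(pairs, 0.12 + 0.3)
    step1 = adjust_prognosis(pairs, 0.12)
    tmp = pairs.assign(beta_prog=step1["BETA"].to_numpy())
    twice = adjust_prognosis(tmp, 0.3)
    np.testing.assert_allclose(twice["BETA"], once["BETA"], atol=1e-15)


# ----------------------------------------------------------------- IVW


def test_ivw_single_instrument_wald_ratio():
    pairs = pd.DataFrame({"SNP": ["rs1"], "beta_inc": [0.2], "se_inc": [0.01],
                          "beta_prog": [0.06], "se_prog": [0.05]})
    res = ivw(pairs)
    assert res.beta == pytest.approx(0.06 / 0.2, abs=1e-12)
    assert res.se == pytest.approx(0.05 / 0.2, abs=1e-12)


def test_ivw_matches_weighted_regression_oracle():
    pairs = make_pairs(seed=12)
    res = ivw(pairs)
    w = 1 / pairs["se_prog"] ** 2
    ref = sm.WLS(pairs["beta_prog"], pairs[["beta_inc"]], weights=w).fit()
    assert res.beta == pytest.approx(ref.params.iloc[0], abs=1e-10)
    # fixed-effect SE: the oracle's SE with dispersion pinned at 1
    assert res.se == pytest.approx(ref.bse.iloc[0] / np.sqrt(ref.scale), abs=1e-10)


def test_ivw_recovers_causal_effect():
    rng = np.random.default_rng(0)
    vals = []
    for s in range(100):
        b1 = rng.uniform(0.05, 0.15, 50)
        pairs = pd.DataFrame({"SNP": [f"rs{i}" for i in range(50)],
                              "beta_inc": b1 + rng.normal(0, 0.005, 50),
                              "se_inc": 0.005,
                              "beta_prog": 0.3 * b1 + rng.normal(0, 0.05, 50),
                              "se_prog": 0.05})
        vals.append(ivw(pairs).beta)
    mc_se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(np.mean(vals) - 0.3) < 3 * mc_se


def test_ivw_no_strength_errors():
    pairs = make_pairs(k=5)
    pairs["beta_inc"] = 0.0
    with pytest.raises(ValueError, match="instrument"):
        ivw(pairs)


# ----------------------------------------------------------- orchestration


def _sumstats_pair(k=40, seed=0):
    rng = np.random.default_rng(seed)
    inc = make_sumstats(k, bp_step=400_000, seed=seed)
    inc["BETA"] = rng.normal(0, 0.1, k)
    inc["SE"] = 0.02
    inc["P"] = np.minimum(rng.uniform(1e-10, 0.04, k), 1.0)
    prog = inc.copy()
    prog["BETA"] = -0.25 * inc["BETA"] + rng.normal(0, 0.05, k)
    prog["SE"] = 0.05
    return inc, prog


def test_corrected_equals_raw_minus_slope_in_unadjusted_mode():
    inc, prog = _sumstats_pair()
    cc = CorrectionConfig(info_min=None, p_inc_max=None, slope_method="hedges_olkin",
                          instruments=list(inc["SNP"]), ivw_weights="unadjusted")
    rep = correct_and_estimate(inc, prog, None, cc)
    assert rep.corrected.beta == pytest.approx(rep.raw.beta - rep.slope.value, abs=1e-10)


def test_correction_report_counts_and_diagnostics():
    inc, prog = _sumstats_pair(seed=1)
    cc = CorrectionConfig(info_min=None, p_inc_max=0.05, slope_method="simex",
                          simex_n_sim=100, instruments=list(inc["SNP"][:10]))
    rep = correct_and_estimate(inc, prog, None, cc)
    assert rep.counts["n_instruments"] == 10
    assert 0 <= rep.i2_gx < 1
    assert rep.slope.method == "simex"
    d = rep.to_dict()
    assert set(d) == {"raw", "slope", "i2_gx", "corrected", "counts"}


def test_unknown_slope_method_errors():
    inc, prog = _sumstats_pair()
    cc = CorrectionConfig(slope_method="bogus", instruments=list(inc["SNP"]))
    with pytest.raises(ValueError, match="slope method"):
        correct_and_estimate(inc, prog, None, cc)
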