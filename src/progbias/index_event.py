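"""Index-event (collider) bias correction for case-only GWAS.

Conditioning on an index event induces spurious associations between the
event's causes; in case-only prognosis GWAS this shows up as a systematic
cross-SNP regression of prognosis effects (beta2) on incidence effects
(beta1).  The correction estimates that slope b, subtracts b * beta1 from
each prognosis effect, and re-estimates the score-prognosis relationship by
fixed-effect inverse-variance weighting.

Because beta1 is itself estimated with error, the naive least-squares slope
is attenuated.  Two de-attenuating estimators are provided:

* Hedges-Olkin:  b = cov(beta1, beta2) / (var(beta1) - mean(se1^2)),
  removing the estimation-error variance from the denominator.
* SIMEX: re-estimate the naive slope after adding extra noise of variance
  lambda * se1^2 per SNP, for a grid of lambda >= 0, then extrapolate the
  trend back to lambda = -1 (no measurement error).

The I2_GX statistic quantifies how much variation in beta1 is signal rather
than noise (low values warn that slope estimates are strongly attenuated and
SIMEX may fail to converge; restricting to SNPs nominally associated with
incidence is the standard remedy and is supported natively).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDReference, harmonize, ld_prune

__all__ = [
    "SlopeEstimate",
    "IVWResult",
    "CorrectionConfig",
    "CorrectionReport",
    "pair_and_filter",
    "slope_naive",
    "slope_hedges_olkin",
    "slope_simex",
    "i2_gx",
    "adjust_prognosis",
    "ivw",
    "correct_and_estimate",
]

Z975 = 1.959964

PAIR_COLUMNS = ["SNP", "CHR", "BP", "EA", "OA", "EAF",
                "beta_inc", "se_inc", "p_inc", "info_inc",
                "beta_prog", "se_prog", "p_prog", "info_prog"]


@dataclass
class SlopeEstimate:
    method: str  # naive | hedges_olkin | simex
    value: float
    se: float
    n_snps: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def ci95(self) -> tuple:
        return (self.value - Z975 * self.se, self.value + Z975 * self.se)


@dataclass
class IVWResult:
    beta: float
    se: float
    n_instruments: int
    corrected: bool = False

    @property
    def p(self) -> float:
        return float(2 * stats.norm.sf(abs(self.beta / self.se)))

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple:
        return (float(np.exp(self.beta - Z975 * self.se)), float(np.exp(self.beta + Z975 * self.se)))


# ---------------------------------------------------------------------------


def pair_and_filter(
    inc_records: pd.DataFrame,
    prog_records: pd.DataFrame,
    ld: LDReference | None = None,
    info_min: float | None = 0.99,
    prune_params: tuple | None = (250_000, 5, 0.1),
    p_inc_max: float | None = None,
) -> pd.DataFrame:
    """Harmonized, INFO-filtered, LD-pruned incidence/prognosis effect pairs.

    The optional ``p_inc_max`` subset (SNPs nominally associated with the
    index trait) is applied last, for slope estimation.
    """
    merged, _ = harmonize(inc_records, prog_records)
    if merged.empty:
        raise ValueError("no shared variants between incidence and prognosis tables")
    if info_min is not None:
        ok = pd.Series(True, index=merged.index)
        if "INFO" in merged.columns:
            ok &= merged["INFO"].fillna(1.0) > info_min
        if "INFO_b" in merged.columns:
            ok &= merged["INFO_b"].fillna(1.0) > info_min
        merged = merged.loc[ok]
    if ld is not None and prune_params is not None:
        window_bp, step_snps, r2_max = prune_params
        merged = ld_prune(merged, ld, window_bp=window_bp, step_snps=step_snps, r2_max=r2_max)
    if p_inc_max is not None:
        merged = merged[merged["P"] < p_inc_max]
    if merged.empty:
        raise ValueError("no variant pairs survive filtering")
    pairs = pd.DataFrame(
        {
            "SNP": merged["SNP"],
            "CHR": merged.get("CHR"),
            "BP": merged.get("BP"),
            "EA": merged.get("EA"),
            "OA": merged.get("OA"),
            "EAF": merged.get("EAF"),
            "beta_inc": merged["BETA"],
            "se_inc": merged["SE"],
            "p_inc": merged["P"],
            "info_inc": merged.get("INFO"),
            "beta_prog": merged["BETA_b"],
            "se_prog": merged["SE_b"],
            "p_prog": merged.get("P_b"),
            "info_prog": merged.get("INFO_b"),
        }
    ).reset_index(drop=True)
    return pairs


def _check_pairs(pairs: pd.DataFrame, min_n: int = 3) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if len(pairs) < min_n:
        raise ValueError(f"need at least {min_n} SNP pairs, got {len(pairs)}")
    b1 = pairs["beta_inc"].to_numpy(dtype=float)
    b2 = pairs["beta_prog"].to_numpy(dtype=float)
    s1 = pairs["se_inc"].to_numpy(dtype=float)
    s2 = pairs["se_prog"].to_numpy(dtype=float)
    return b1, b2, s1, s2


def _ols_slope(b1: np.ndarray, b2: np.ndarray, intercept: bool = True):
    """Least-squares slope of b2 on b1 with its classical SE."""
    if intercept:
        x = b1 - b1.mean()
        y = b2 - b2.mean()
        dof = b1.size - 2
    else:
        x, y = b1, b2
        dof = b1.size - 1
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("zero variance in incidence effects")
    slope = float(x @ y) / sxx
    resid = y - slope * x
    se = np.sqrt(float(resid @ resid) / max(dof, 1) / sxx)
    return slope, float(se)


def slope_naive(pairs: pd.DataFrame, intercept: bool = True) -> SlopeEstimate:
    """Unweighted least squares of prognosis effects on incidence effects."""
    b1, b2, _, _ = _check_pairs(pairs)
    slope, se = _ols_slope(b1, b2, intercept=intercept)
    return SlopeEstimate(method="naive", value=slope, se=se, n_snps=b1.size,
                         diagnostics={"intercept": intercept})


def slope_hedges_olkin(pairs: pd.DataFrame, intercept: bool = True) -> SlopeEstimate:
    """Regression-dilution-corrected slope.

    The naive denominator var(beta1) overstates the spread of true incidence
    effects by the mean squared estimation error; subtracting mean(se1^2)
    de-attenuates the slope.  The SE is a leave-one-out jackknife.
    """
    b1, b2, s1, _ = _check_pairs(pairs)
    k = b1.size

    def _ho(b1, b2, s1):
        n = b1.size
        if intercept:
            cov = np.cov(b1, b2, ddof=1)[0, 1]
            var = b1.var(ddof=1)
        else:
            cov = float(b1 @ b2) / n
            var = float(b1 @ b1) / n
        denom = var - np.mean(s1**2)
        if denom <= 0:
            raise ValueError("incidence effects dominated by noise (denominator <= 0)")
        return cov / denom

    est = _ho(b1, b2, s1)

    # vectorized leave-one-out jackknife
    loo = np.empty(k)
    idx = np.arange(k)
    for i in range(k):
        m = idx != i
        loo[i] = _ho(b1[m], b2[m], s1[m])
    se = float(np.sqrt((k - 1) / k * np.sum((loo - loo.mean()) ** 2)))
    return SlopeEstimate(
        method="hedges_olkin", value=float(est), se=se, n_snps=k,
        diagnostics={"intercept": intercept, "mean_se1_sq": float(np.mean(s1**2)),
                     "var_beta1": float(b1.var(ddof=1))},
    )


def slope_simex(
    pairs: pd.DataFrame,
    lambda_grid: tuple = (0.0, 0.5, 1.0, 1.5, 2.0),
    n_sim: int = 1000,
    seed: int = 0,
    intercept: bool = True,
) -> SlopeEstimate:
    """Simulation-extrapolation slope.

    For each lambda > 0, the naive slope is averaged over ``n_sim`` replicates
    of beta1 + N(0, lambda * se1^2); a quadratic in lambda is then
    extrapolated to lambda = -1.  The SE propagates the Monte-Carlo spread of
    the per-lambda means through the (linear) extrapolation; per-lambda
    variances are exposed in the diagnostics as a convergence check.
    """
    b1, b2, s1, _ = _check_pairs(pairs)
    lams = np.asarray(sorted(set(float(l) for l in lambda_grid)), dtype=float)
    if lams.min() < 0 or lams.max() > 2:
        raise ValueError("lambda grid must lie within [0, 2]")
    if 0.0 not in lams:
        lams = np.concatenate([[0.0], lams])
    rng = np.random.default_rng(seed)

    if intercept:
        def slopes_of(B1):  # B1: (r, k)
            xc = B1 - B1.mean(axis=1, keepdims=True)
            yc = b2 - b2.mean()
            return (xc @ yc) / np.einsum("rk,rk->r", xc, xc)
    else:
        def slopes_of(B1):
            return (B1 @ b2) / np.einsum("rk,rk->r", B1, B1)

    naive, _ = _ols_slope(b1, b2, intercept=intercept)
    means = np.empty(lams.size)
    mean_vars = np.zeros(lams.size)
    rep_sd = np.zeros(lams.size)
    for i, lam in enumerate(lams):
        if lam == 0:
            means[i] = naive
            continue
        noise = rng.standard_normal((n_sim, b1.size)) * (np.sqrt(lam) * s1)[None, :]
        reps = slopes_of(b1[None, :] + noise)
        if not np.all(np.isfinite(reps)):
            raise ValueError(f"non-finite replicate slopes at lambda={lam}")
        means[i] = reps.mean()
        rep_sd[i] = reps.std(ddof=1)
        mean_vars[i] = rep_sd[i] ** 2 / n_sim

    # quadratic extrapolation to lambda = -1; the fitted value is linear in
    # the per-lambda means, so their MC variances propagate exactly
    A = np.vander(lams, 3, increasing=True)  # [1, lam, lam^2]
    coef, *_ = np.linalg.lstsq(A, means, rcond=None)
    proj = np.linalg.pinv(A)  # (3, L)
    g = np.array([1.0, -1.0, 1.0]) @ proj  # value at lambda=-1 as g @ means
    value = float(np.array([1.0, -1.0, 1.0]) @ coef)
    se = float(np.sqrt(np.sum(g**2 * mean_vars)))
    return SlopeEstimate(
        method="simex", value=value, se=se, n_snps=b1.size,
        diagnostics={
            "lambda_grid": lams.tolist(),
            "mean_slopes": means.tolist(),
            "replicate_sd": rep_sd.tolist(),
            "quadratic_coef": coef.tolist(),
            "n_sim": n_sim,
            "intercept": intercept,
        },
    )


def i2_gx(pairs: pd.DataFrame) -> tuple[float, dict]:
    """Signal share of variation in the incidence effects.

    Q = sum_j (beta1_j - weighted mean)^2 / se1_j^2 with inverse-variance
    weights; I2 = max(0, (Q - (k - 1)) / Q).  Values near 1 indicate the
    incidence effects are measured nearly without error; low values warn of
    regression-dilution-driven attenuation.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 SNP pairs for I2_GX")
    b1 = pairs["beta_inc"].to_numpy(dtype=float)
    s1 = pairs["se_inc"].to_numpy(dtype=float)
    w = 1.0 / s1**2
    bw = float(np.sum(w * b1) / np.sum(w))
    q = float(np.sum((b1 - bw) ** 2 * w))
    k = b1.size
    i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    return i2, {"Q": q, "k": k, "weighted_mean": bw}


def adjust_prognosis(
    pairs: pd.DataFrame,
    slope: SlopeEstimate | float,
    include_slope_variance: bool = False,
) -> pd.DataFrame:
    """Remove the index-event bias component from each prognosis effect.

    beta2_adj = beta2 - b * beta1;  se_adj = sqrt(se2^2 + b^2 * se1^2),
    optionally adding var(b) * beta1^2 when ``include_slope_variance``.
    Returns a summary-statistics table (BETA/SE/P refer to adjusted prognosis).
    """
    b = slope.value if isinstance(slope, SlopeEstimate) else float(slope)
    b_var = (slope.se**2 if isinstance(slope, SlopeEstimate) else 0.0) if include_slope_variance else 0.0
    if not np.isfinite(b):
        raise ValueError("slope estimate is not finite")
    b1 = pairs["beta_inc"].to_numpy(dtype=float)
    s1 = pairs["se_inc"].to_numpy(dtype=float)
    b2 = pairs["beta_prog"].to_numpy(dtype=float)
    s2 = pairs["se_prog"].to_numpy(dtype=float)
    beta_adj = b2 - b * b1
    se_adj = np.sqrt(s2**2 + b**2 * s1**2 + b_var * b1**2)
    out = pairs[[c for c in ("SNP", "CHR", "BP", "EA", "OA", "EAF") if c in pairs.columns]].copy()
    out["BETA"] = beta_adj
    out["SE"] = se_adj
    out["P"] = 2 * stats.norm.sf(np.abs(beta_adj / se_adj))
    out["INFO"] = pairs["info_prog"].to_numpy() if "info_prog" in pairs.columns else 1.0
    return out


def ivw(
    pairs: pd.DataFrame,
    instruments: list | None = None,
    corrected: bool = False,
    beta_prog_col: str = "beta_prog",
    se_prog_col: str = "se_prog",
) -> IVWResult:
    """Fixed-effect inverse-variance-weighted estimate.

    beta = sum w beta1 beta2 / sum w beta1^2 with w = 1/se2^2 — the weighted
    regression of outcome effects on exposure effects through the origin,
    with SE = 1/sqrt(sum w beta1^2) (dispersion fixed at 1).  With a single
    instrument this is the Wald ratio beta2/beta1 with SE se2/|beta1|.
    """
    sub = pairs if instruments is None else pairs[pairs["SNP"].isin(set(instruments))]
    if len(sub) < 1:
        raise ValueError("no instruments available")
    b1 = sub["beta_inc"].to_numpy(dtype=float)
    b2 = sub[beta_prog_col].to_numpy(dtype=float)
    s2 = sub[se_prog_col].to_numpy(dtype=float)
    w = 1.0 / s2**2
    denom = float(np.sum(w * b1**2))
    if denom == 0:
        raise ValueError("no instrument strength: all incidence effects zero")
    beta = float(np.sum(w * b1 * b2)) / denom
    se = 1.0 / np.sqrt(denom)
    return IVWResult(beta=beta, se=float(se), n_instruments=len(sub), corrected=corrected)


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class CorrectionConfig:
    info_min: float | None = 0.99
    prune_window_bp: int = 250_000
    prune_step_snps: int = 5
    prune_r2_max: float = 0.1
    p_inc_max: float | None = 0.05  # slope-estimation subset
    slope_method: str = "simex"  # simex | hedges_olkin | naive
    slope_intercept: bool = True
    simex_lambdas: tuple = (0.0, 0.5, 1.0, 1.5, 2.0)
    simex_n_sim: int = 1000
    simex_seed: int = 0
    instruments: list | None = None  # explicit SNP list for IVW, never inferred
    ivw_weights: str = "adjusted"  # adjusted | unadjusted prognosis SEs
    include_slope_variance: bool = False


@dataclass
class CorrectionReport:
    raw: IVWResult
    slope: SlopeEstimate
    corrected: IVWResult
    i2_gx: float
    counts: dict
    adjusted: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "raw": {"beta": self.raw.beta, "se": self.raw.se, "or": self.raw.or_,
                    "ci95": self.raw.ci95, "p": self.raw.p,
                    "n_instruments": self.raw.n_instruments},
            "slope": {"method": self.slope.method, "value": self.slope.value,
                      "se": self.slope.se, "ci95": self.slope.ci95,
                      "n_snps": self.slope.n_snps,
                      "naive": self.slope.diagnostics.get("slope_naive"),
                      "hedges_olkin": self.slope.diagnostics.get(
                          "slope_hedges_olkin",
                          self.slope.value if self.slope.method == "hedges_olkin" else None)},
            "i2_gx": self.i2_gx,
            "corrected": {"beta": self.corrected.beta, "se": self.corrected.se,
                          "or": self.corrected.or_, "ci95": self.corrected.ci95,
                          "p": self.corrected.p,
                          "n_instruments": self.corrected.n_instruments},
            "counts": self.counts,
        }


def correct_and_estimate(
    inc_records: pd.DataFrame,
    prog_records: pd.DataFrame,
    ld: LDReference | None,
    config: CorrectionConfig,
) -> CorrectionReport:
    """Full pipeline: pair/filter, slope, I2_GX, adjustment, IVW before/after.

    The slope is estimated on the (optionally incidence-P-restricted) pruned
    pair set; the IVW uses the explicit ``config.instruments`` list (a
    stricter, independent SNP list by design).
    """
    all_pairs = pair_and_filter(
        inc_records, prog_records, ld=ld, info_min=config.info_min,
        prune_params=(config.prune_window_bp, config.prune_step_snps, config.prune_r2_max),
        p_inc_max=None,
    )
    slope_pairs = all_pairs if config.p_inc_max is None else (
        all_pairs[all_pairs["p_inc"] < config.p_inc_max].reset_index(drop=True)
    )
    if config.slope_method == "simex":
        slope = slope_simex(slope_pairs, lambda_grid=config.simex_lambdas,
                            n_sim=config.simex_n_sim, seed=config.simex_seed,
                            intercept=config.slope_intercept)
    elif config.slope_method == "hedges_olkin":
        slope = slope_hedges_olkin(slope_pairs, intercept=config.slope_intercept)
    elif config.slope_method == "naive":
        slope = slope_naive(slope_pairs, intercept=config.slope_intercept)
    else:
        raise ValueError(f"unknown slope method {config.slope_method!r}")
    i2, i2_diag = i2_gx(slope_pairs)
    slope.diagnostics["i2_gx"] = i2
    # the two cheap estimators are always reported alongside for comparison
    slope.diagnostics["slope_naive"] = slope_naive(slope_pairs, intercept=config.slope_intercept).value
    if config.slope_method != "hedges_olkin":
        try:
            slope.diagnostics["slope_hedges_olkin"] = slope_hedges_olkin(
                slope_pairs, intercept=config.slope_intercept).value
        except ValueError:
            slope.diagnostics["slope_hedges_olkin"] = float("nan")

    instruments = config.instruments
    inst_pairs = all_pairs if instruments is None else (
        all_pairs[all_pairs["SNP"].isin(set(instruments))].reset_index(drop=True)
    )
    if inst_pairs.empty:
        raise ValueError("no instruments present in the paired table")
    raw = ivw(inst_pairs, corrected=False)

    adjusted = adjust_prognosis(all_pairs, slope,
                                include_slope_variance=config.include_slope_variance)
    adj_pairs = inst_pairs.copy()
    adj_map = adjusted.set_index("SNP")
    adj_pairs["beta_adj"] = adj_pairs["SNP"].map(adj_map["BETA"])
    if config.ivw_weights == "adjusted":
        adj_pairs["se_adj"] = adj_pairs["SNP"].map(adj_map["SE"])
    elif config.ivw_weights == "unadjusted":
        adj_pairs["se_adj"] = adj_pairs["se_prog"]
    else:
        raise ValueError(f"unknown ivw_weights mode {config.ivw_weights!r}")
    corrected = ivw(adj_pairs, corrected=True,
                    beta_prog_col="beta_adj", se_prog_col="se_adj")

    counts = {
        "n_pairs": len(all_pairs),
        "n_slope_snps": len(slope_pairs),
        "n_instruments": len(inst_pairs),
        "i2_gx_Q": i2_diag["Q"],
    }
    return CorrectionReport(raw=raw, slope=slope, corrected=corrected,
                            i2_gx=i2, counts=counts, adjusted=adjusted)
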