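"""Synthetic cohorts with a built-in index-event-bias structure.

The generative model is a liability-threshold model for disease onset with an
unmeasured shared risk factor and survival-dependent recruitment:

* liability  L = sum_j beta_j (g_j - 2 f_j) + U + covariate effects + eps,
  eps ~ N(0,1); an individual is a prevalent case iff L > threshold.
* U ~ N(0, var_shared_factor) is an unmeasured factor raising both disease
  risk and post-disease mortality; conditioning on case status makes case
  status a collider between the genetic score and U, inducing a spurious
  inverse genetic association with prognosis among cases.
* Recruitment: cases survive into the study with probability decreasing in
  liability (higher-liability cases are more likely to have died before
  enrolment), a second selection channel for the same bias.
* Prognosis: a binary fixed-horizon death outcome for every recruited
  individual (among cases this is the case-only prognosis outcome), plus a
  follow-up disease-onset outcome among the disease-free stratum.

Two GWAS emulators provide the two-sample design: an external case-control
incidence GWAS on a freshly drawn sample, and a case-only prognosis GWAS on
the recruited cases.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .glm import fit_logistic_per_snp

__all__ = [
    "SimConfig",
    "Cohort",
    "stage_rng",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_incidence",
    "apply_recruitment",
    "simulate_prognosis",
    "gwas_incidence",
    "gwas_prognosis",
    "predicted_liability_sd",
    "predicted_prevalence",
]

AGE_RANGE = (40.0, 69.0)  # recruitment window, years
_AGE_MEAN = sum(AGE_RANGE) / 2
_AGE_VAR = (AGE_RANGE[1] - AGE_RANGE[0]) ** 2 / 12
_BMI_MEAN, _BMI_SD = 27.0, 4.0
_SEX_P, _SMOKE_P = 0.5, 0.45
_ALLELE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]


def _default_covariate_effects() -> dict:
    # per-unit liability effects (age per year, BMI per kg/m2) and prognosis
    # log-odds effects; magnitudes chosen to give covariates a visible but
    # minority share of liability variance
    return {
        "age": {"incidence": 0.035, "prognosis": 0.04},
        "sex": {"incidence": 0.10, "prognosis": 0.20},
        "bmi": {"incidence": 0.02, "prognosis": 0.01},
        "smoking": {"incidence": 0.15, "prognosis": 0.30},
    }


@dataclass
class SimConfig:
    """Generative parameters for one synthetic study.

    With ``allele_freqs``/``beta_incidence`` left as None they are drawn
    deterministically from ``seed``: frequencies uniform on ``maf_range`` and
    incidence effects Gaussian, rescaled so the genetic liability variance is
    exactly ``var_genetic``.  ``incidence_threshold=None`` places the
    liability cutoff at the Gaussian quantile giving ``target_prevalence``.
    """

    n_individuals: int = 200_000
    n_snps: int = 100
    seed: int = 0
    allele_freqs: list | None = None
    maf_range: tuple = (0.1, 0.9)
    beta_incidence: list | None = None
    var_genetic: float = 0.3
    beta_prognosis_direct: list | float = 0.0
    var_shared_factor: float = 0.5
    shared_prognosis_effect: float = 1.2  # log-odds of death per unit U
    incidence_threshold: float | None = None
    # prevalence chosen so that survival selection leaves ~5000 recruited cases
    # out of 200 000, the scaled-down two-subsample design
    target_prevalence: float = 0.045
    incidence_model: str = "probit"  # or "logistic"
    survival_coefficient: float = 0.5  # recruitment logit drop per SD liability (cases)
    recruitment_base_rate: float = 0.8
    prognosis_base_rate: float = 0.20
    onset_base_rate: float = 0.05  # follow-up disease onset, disease-free stratum
    onset_scale: float = 0.6  # log-odds of onset per unit liability
    covariate_effects: dict = field(default_factory=_default_covariate_effects)
    prior_mi_fraction: float = 0.55  # cases with MI history (subtype labelling)
    ld_rho: float = 0.0  # adjacent-SNP haplotype correlation within a block
    ld_block_size: int = 10
    gwas_n_cases: int = 15_000
    gwas_n_controls: int = 15_000

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.var_shared_factor < 0 or self.var_genetic < 0:
            raise ValueError("variances must be >= 0")
        if self.allele_freqs is not None:
            f = np.asarray(self.allele_freqs, dtype=float)
            if np.any((f <= 0) | (f >= 1)):
                raise ValueError("allele frequencies must lie in (0, 1)")
        if self.incidence_model not in ("probit", "logistic"):
            raise ValueError(f"unknown incidence model {self.incidence_model!r}")

    # --- resolved generative quantities -----------------------------------

    def freqs(self) -> np.ndarray:
        if self.allele_freqs is not None:
            return np.asarray(self.allele_freqs, dtype=float)
        rng = stage_rng(self.seed, "params")
        return rng.uniform(*self.maf_range, size=self.n_snps)

    def betas_incidence(self) -> np.ndarray:
        if self.beta_incidence is not None:
            return np.asarray(self.beta_incidence, dtype=float)
        rng = stage_rng(self.seed, "params")
        rng.uniform(*self.maf_range, size=self.n_snps)  # keep stream aligned with freqs()
        f = self.freqs()
        raw = rng.standard_normal(self.n_snps)
        var = np.sum(raw**2 * 2 * f * (1 - f))
        if var == 0 or self.var_genetic == 0:
            return np.zeros(self.n_snps)
        return raw * np.sqrt(self.var_genetic / var)

    def betas_prognosis_direct(self) -> np.ndarray:
        b = self.beta_prognosis_direct
        if np.isscalar(b):
            return np.full(self.n_snps, float(b))
        return np.asarray(b, dtype=float)

    def threshold(self) -> float:
        if self.incidence_threshold is not None:
            return float(self.incidence_threshold)
        return float(predicted_liability_sd(self) * stats.norm.isf(self.target_prevalence))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator: one master seed, named substreams."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())]))


def predicted_liability_sd(config: SimConfig) -> float:
    ce = config.covariate_effects
    cov_var = (
        ce["age"]["incidence"] ** 2 * _AGE_VAR
        + ce["sex"]["incidence"] ** 2 * _SEX_P * (1 - _SEX_P)
        + ce["bmi"]["incidence"] ** 2 * _BMI_SD**2
        + ce["smoking"]["incidence"] ** 2 * _SMOKE_P * (1 - _SMOKE_P)
    )
    total = config.var_genetic + config.var_shared_factor + cov_var + 1.0
    if config.beta_incidence is not None:
        f = config.freqs()
        b = np.asarray(config.beta_incidence, dtype=float)
        total = np.sum(b**2 * 2 * f * (1 - f)) + config.var_shared_factor + cov_var + 1.0
    return float(np.sqrt(total))


def predicted_prevalence(config: SimConfig) -> float:
    """Gaussian-tail prediction for the configured threshold (probit model)."""
    return float(stats.norm.sf(config.threshold() / predicted_liability_sd(config)))


# ---------------------------------------------------------------------------
# cohort container


@dataclass
class Cohort:
    """Individual-level synthetic data plus retained ground truth."""

    genotypes: np.ndarray  # (n, m) dosages in [0, 2]
    variants: pd.DataFrame  # SNP CHR BP A1 A2 FREQ (A1 = counted allele)
    age: np.ndarray
    sex: np.ndarray
    covariates: pd.DataFrame  # bmi, smoking
    shared_factor: np.ndarray  # U, unmeasured
    true_liability: np.ndarray | None = None
    incident_case: np.ndarray | None = None
    recruited: np.ndarray | None = None
    prognosis_outcomes: pd.DataFrame | None = None  # death, incident_disease
    prior_mi: np.ndarray | None = None
    config: SimConfig | None = None

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    def genotype_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.genotypes, columns=self.variants["SNP"].to_list())

    def counted_alleles(self) -> dict:
        return dict(zip(self.variants["SNP"], self.variants["A1"]))

    def true_raw_score(self) -> np.ndarray:
        """Genetic liability component (validation only)."""
        return self.genotypes @ self.config.betas_incidence()

    def to_frame(self) -> pd.DataFrame:
        df = self.genotype_frame()
        df["age"] = self.age
        df["sex"] = self.sex
        for c in self.covariates.columns:
            df[c] = self.covariates[c].to_numpy()
        if self.incident_case is not None:
            df["incident_case"] = self.incident_case.astype(int)
        if self.recruited is not None:
            df["recruited"] = self.recruited.astype(int)
        if self.prognosis_outcomes is not None:
            for c in self.prognosis_outcomes.columns:
                df[c] = self.prognosis_outcomes[c].to_numpy()
        if self.prior_mi is not None:
            df["prior_mi"] = self.prior_mi
        df["true_liability"] = self.true_liability
        df["shared_factor"] = self.shared_factor
        return df

    def write(self, table_path, sidecar_path) -> None:
        self.to_frame().to_csv(table_path, sep="\t", index=False, float_format="%.6g")
        side = {
            "config": asdict(self.config),
            "variants": self.variants.to_dict(orient="list"),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(side, fh, default=float)


# ---------------------------------------------------------------------------
# simulation stages


def _variant_table(config: SimConfig) -> pd.DataFrame:
    rng = stage_rng(config.seed, "variants")
    f = config.freqs()
    m = config.n_snps
    block = max(int(config.ld_block_size), 1)
    block_idx = np.arange(m) // block
    within = np.arange(m) % block
    bp = 1 + block_idx * 1_000_000 + within * 20_000
    pairs = [_ALLELE_PAIRS[k] for k in rng.integers(0, len(_ALLELE_PAIRS), size=m)]
    return pd.DataFrame(
        {
            "SNP": [f"rs{j + 1}" for j in range(m)],
            "CHR": np.ones(m, dtype=int),
            "BP": bp.astype(int),
            "A1": [p[0] for p in pairs],
            "A2": [p[1] for p in pairs],
            "FREQ": f,
        }
    )


def _draw_genotypes(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    f = config.freqs()
    m = config.n_snps
    if config.ld_rho <= 0:
        return rng.binomial(2, f[None, :], size=(n, m)).astype(np.float64)
    # block-AR(1) latent Gaussians per haplotype, thresholded at the allele
    # frequency quantile: induces positive dosage correlation within blocks
    rho = config.ld_rho
    block = max(int(config.ld_block_size), 1)
    thr = stats.norm.isf(f)
    dosage = np.zeros((n, m))
    for _hap in range(2):
        z = rng.standard_normal((n, m))
        for j in range(1, m):
            if j % block != 0:
                z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * z[:, j]
        dosage += (z > thr[None, :]).astype(float)
    return dosage


def simulate_genotypes(config: SimConfig) -> np.ndarray:
    """Dosage matrix (n x m): independent binomial(2, f_j), or block-LD draws."""
    return _draw_genotypes(config, config.n_individuals, stage_rng(config.seed, "genotypes"))


def _draw_people(config: SimConfig, n: int, rng: np.random.Generator) -> dict:
    """Genotypes, covariates, shared factor and liability for n individuals."""
    g = _draw_genotypes(config, n, rng)
    age = rng.uniform(*AGE_RANGE, size=n)
    sex = (rng.random(n) < _SEX_P).astype(float)
    bmi = rng.normal(_BMI_MEAN, _BMI_SD, size=n)
    smoking = (rng.random(n) < _SMOKE_P).astype(float)
    u = rng.normal(0.0, np.sqrt(config.var_shared_factor), size=n)
    eps = rng.standard_normal(n)
    f = config.freqs()
    b = config.betas_incidence()
    ce = config.covariate_effects
    lin = (
        (g - 2 * f[None, :]) @ b
        + u
        + ce["age"]["incidence"] * (age - _AGE_MEAN)
        + ce["sex"]["incidence"] * (sex - _SEX_P)
        + ce["bmi"]["incidence"] * (bmi - _BMI_MEAN)
        + ce["smoking"]["incidence"] * (smoking - _SMOKE_P)
    )
    if config.incidence_model == "probit":
        liability = lin + eps
        case = liability > config.threshold()
    else:
        liability = lin
        case = rng.random(n) < 1 / (1 + np.exp(-(lin - config.threshold())))
    return {
        "genotypes": g,
        "age": age,
        "sex": sex,
        "bmi": bmi,
        "smoking": smoking,
        "shared_factor": u,
        "liability": liability,
        "case": case,
    }


def simulate_incidence(config: SimConfig) -> Cohort:
    """Base cohort with liability and prevalent-case indicator."""
    rng = stage_rng(config.seed, "cohort")
    d = _draw_people(config, config.n_individuals, rng)
    return Cohort(
        genotypes=d["genotypes"],
        variants=_variant_table(config),
        age=d["age"],
        sex=d["sex"],
        covariates=pd.DataFrame({"bmi": d["bmi"], "smoking": d["smoking"]}),
        shared_factor=d["shared_factor"],
        true_liability=d["liability"],
        incident_case=d["case"],
        config=config,
    )


def apply_recruitment(cohort: Cohort, config: SimConfig | None = None) -> Cohort:
    """Survival-dependent selection into the study.

    Cases are recruited with probability decreasing in standardized liability
    (slope ``survival_coefficient`` on the logit scale); the disease-free are
    all recruited.  With a positive coefficient the mean genetic score of
    recruited cases falls below that of all cases.
    """
    config = config or cohort.config
    if cohort.incident_case is None:
        raise RuntimeError("incidence must be simulated before recruitment")
    rng = stage_rng(config.seed, "recruitment")
    n = cohort.n
    z = cohort.true_liability / predicted_liability_sd(config)
    if config.recruitment_base_rate >= 1.0 and config.survival_coefficient == 0:
        p_case = np.ones(n)
    else:
        rate = min(config.recruitment_base_rate, 1 - 1e-12)
        base = np.log(rate / (1 - rate))
        p_case = 1 / (1 + np.exp(-(base - config.survival_coefficient * z)))
    p = np.where(cohort.incident_case, p_case, 1.0)
    cohort.recruited = rng.random(n) < p
    return cohort


def simulate_prognosis(cohort: Cohort, config: SimConfig | None = None) -> Cohort:
    """Fixed-horizon binary outcomes for the recruited sample.

    ``death``: logit = base + direct genetic effects + shared-factor and
    covariate effects, for every recruited individual (among cases this is the
    case-only prognosis outcome).  ``incident_disease``: follow-up disease
    onset among recruited non-cases, driven by the incidence liability.
    """
    config = config or cohort.config
    if cohort.recruited is None:
        raise RuntimeError("recruitment must be applied before prognosis")
    if not (cohort.recruited & cohort.incident_case).any():
        raise RuntimeError("empty case stratum: no recruited cases")
    rng = stage_rng(config.seed, "prognosis")
    n = cohort.n
    f = config.freqs()
    ce = config.covariate_effects
    lin = (
        np.log(config.prognosis_base_rate / (1 - config.prognosis_base_rate))
        + (cohort.genotypes - 2 * f[None, :]) @ config.betas_prognosis_direct()
        + config.shared_prognosis_effect * cohort.shared_factor
        + ce["age"]["prognosis"] * (cohort.age - _AGE_MEAN)
        + ce["sex"]["prognosis"] * (cohort.sex - _SEX_P)
        + ce["bmi"]["prognosis"] * (cohort.covariates["bmi"].to_numpy() - _BMI_MEAN)
        + ce["smoking"]["prognosis"] * (cohort.covariates["smoking"].to_numpy() - _SMOKE_P)
    )
    death = np.where(
        cohort.recruited, (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(float), np.nan
    )

    onset_lin = (
        np.log(config.onset_base_rate / (1 - config.onset_base_rate))
        + config.onset_scale * cohort.true_liability
    )
    free = cohort.recruited & ~cohort.incident_case
    onset = np.full(n, np.nan)
    onset[free] = (rng.random(free.sum()) < 1 / (1 + np.exp(-onset_lin[free]))).astype(float)

    cohort.prognosis_outcomes = pd.DataFrame({"death": death, "incident_disease": onset})

    mi = np.full(n, np.nan)
    case_idx = np.where(cohort.incident_case)[0]
    mi[case_idx] = (rng.random(case_idx.size) < config.prior_mi_fraction).astype(float)
    cohort.prior_mi = mi
    return cohort


def simulate_cohort(config: SimConfig) -> Cohort:
    """All stages: incidence, recruitment, prognosis."""
    cohort = simulate_incidence(config)
    apply_recruitment(cohort, config)
    simulate_prognosis(cohort, config)
    return cohort


# ---------------------------------------------------------------------------
# GWAS emulators


def _sumstats_from_fits(fits: pd.DataFrame, variants: pd.DataFrame, eaf: np.ndarray,
                        drop_failed: bool = True) -> pd.DataFrame:
    out = variants[["SNP", "CHR", "BP", "A1", "A2"]].rename(
        columns={"A1": "EA", "A2": "OA"}
    ).copy()
    out["EAF"] = eaf
    out["BETA"] = fits["beta"].to_numpy()
    out["SE"] = fits["se"].to_numpy()
    out["P"] = fits["p"].to_numpy()
    out["INFO"] = 1.0
    if drop_failed:
        bad = ~fits["converged"].to_numpy()
        if bad.any():
            import logging

            logging.getLogger(__name__).warning(
                "dropping %d variant(s) with failed/degenerate fits", int(bad.sum())
            )
        out = out.loc[~bad].reset_index(drop=True)
    return out[["SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P", "INFO"]]


def gwas_incidence(config: SimConfig, n_cases: int | None = None,
                   n_controls: int | None = None) -> pd.DataFrame:
    """External incidence GWAS on a fresh case-control sample (two-sample design).

    Cases and controls are accumulated by rejection sampling from the same
    generative model, then each SNP is fit with a logistic model of case
    status on dosage, age and sex.  INFO is 1.0 for simulated data.
    """
    n_cases = n_cases or config.gwas_n_cases
    n_controls = n_controls or config.gwas_n_controls
    rng = stage_rng(config.seed, "gwas_incidence")
    got_ca, got_co = [], []
    need_ca, need_co = n_cases, n_controls
    guard = 0
    while (need_ca > 0 or need_co > 0) and guard < 1000:
        guard += 1
        chunk = int(min(400_000, max(50_000, need_ca / max(predicted_prevalence(config), 1e-4))))
        d = _draw_people(config, chunk, rng)
        ca = d["case"]
        if need_ca > 0:
            idx = np.where(ca)[0][:need_ca]
            got_ca.append({k: v[idx] for k, v in d.items() if isinstance(v, np.ndarray)})
            need_ca -= idx.size
        if need_co > 0:
            idx = np.where(~ca)[0][:need_co]
            got_co.append({k: v[idx] for k, v in d.items() if isinstance(v, np.ndarray)})
            need_co -= idx.size
    parts = got_ca + got_co
    g = np.vstack([p["genotypes"] for p in parts])
    age = np.concatenate([p["age"] for p in parts])
    sex = np.concatenate([p["sex"] for p in parts])
    y = np.concatenate([p["case"].astype(float) for p in parts])
    variants = _variant_table(config)
    fits = fit_logistic_per_snp(g, np.column_stack([age, sex]), y, snp_ids=variants["SNP"])
    return _sumstats_from_fits(fits, variants, g.mean(axis=0) / 2)


def gwas_prognosis(cohort: Cohort, config: SimConfig | None = None,
                   outcome: str = "death") -> pd.DataFrame:
    """Case-only prognosis GWAS: logistic outcome ~ dosage + age + sex among recruited cases."""
    config = config or cohort.config
    if cohort.prognosis_outcomes is None:
        raise RuntimeError("prognosis must be simulated first")
    mask = cohort.recruited & cohort.incident_case
    if not mask.any():
        raise RuntimeError("empty case stratum: no recruited cases")
    y = cohort.prognosis_outcomes[outcome].to_numpy()[mask]
    if np.nanmin(y) == np.nanmax(y):
        raise ValueError("degenerate outcome: single class among recruited cases")
    g = cohort.genotypes[mask]
    covs = np.column_stack([cohort.age[mask], cohort.sex[mask]])
    fits = fit_logistic_per_snp(g, covs, y, snp_ids=cohort.variants["SNP"])
    return _sumstats_from_fits(fits, cohort.variants, g.mean(axis=0) / 2)
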