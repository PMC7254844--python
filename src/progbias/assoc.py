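"""Case-stratified association estimates, heterogeneity testing, covariate profiles.

Effect estimates are per standard deviation of the polygenic score (pass a
standardized score), fitted by maximum-likelihood logistic (binary outcomes)
or ordinary least squares (continuous covariates) via statsmodels.  Between-
stratum heterogeneity uses the two-sample z test on the log-odds scale,
z = (b1 - b2) / sqrt(se1^2 + se2^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssocEstimate",
    "HeterogeneityResult",
    "fit_outcome_assoc",
    "heterogeneity_test",
    "ci_to_se",
    "quintile_profile",
    "stratify",
]

Z975 = 1.959964  # two-sided 95% normal quantile


@dataclass
class AssocEstimate:
    stratum: str
    outcome: str
    beta: float
    se: float
    p: float
    n: int
    model: str = "logistic"
    covariates: list = field(default_factory=list)

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple:
        return (float(np.exp(self.beta - Z975 * self.se)), float(np.exp(self.beta + Z975 * self.se)))


@dataclass
class HeterogeneityResult:
    z: float
    p: float


class SeparationError(RuntimeError):
    pass


def fit_outcome_assoc(
    score: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    stratum: str = "all",
    outcome_name: str = "outcome",
    model: str = "logistic",
) -> AssocEstimate:
    """Fit outcome ~ score (+ covariates) and report the score coefficient.

    Rows with a missing outcome are excluded.  Binary outcomes must have both
    classes present; perfect separation raises naming the stratum/outcome.
    """
    score = np.asarray(score, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    mask = np.isfinite(outcome) & np.isfinite(score)
    cov_names: list = []
    if covariates is not None:
        C = pd.DataFrame(covariates)
        cov_names = [str(c) for c in C.columns]
        C = C.to_numpy(dtype=float)
        mask &= np.isfinite(C).all(axis=1)
        X = np.column_stack([np.ones(mask.sum()), score[mask], C[mask]])
    else:
        X = np.column_stack([np.ones(mask.sum()), score[mask]])
    y = outcome[mask]
    if model == "logistic":
        if np.unique(y).size < 2:
            raise ValueError(f"single-class outcome {outcome_name!r} in stratum {stratum!r}")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:
            raise SeparationError(
                f"logistic fit failed for {outcome_name!r} in stratum {stratum!r}: {exc}"
            ) from exc
        if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 50:
            raise SeparationError(
                f"perfect separation suspected for {outcome_name!r} in stratum {stratum!r}"
            )
    elif model == "linear":
        res = sm.OLS(y, X).fit()
    else:
        raise ValueError(f"unknown model {model!r}")
    beta, se = float(res.params[1]), float(res.bse[1])
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return AssocEstimate(
        stratum=stratum, outcome=outcome_name, beta=beta, se=se, p=p,
        n=int(mask.sum()), model=model, covariates=cov_names,
    )


def heterogeneity_test(a: AssocEstimate, b: AssocEstimate) -> HeterogeneityResult:
    """Two-sample z test for a difference between independent effect estimates."""
    if a.outcome != b.outcome:
        raise ValueError(f"mismatched outcomes: {a.outcome!r} vs {b.outcome!r}")
    z = (a.beta - b.beta) / np.hypot(a.se, b.se)
    return HeterogeneityResult(z=float(z), p=float(2 * stats.norm.sf(abs(z))))


def ci_to_se(or_point: float, ci95: tuple) -> float:
    """Recover the log-scale SE from a printed OR and symmetric 95% CI."""
    lo, hi = ci95
    if lo <= 0 or hi <= 0 or hi < lo:
        raise ValueError("CI bounds must be positive with lower <= upper")
    return float((np.log(hi) - np.log(lo)) / (2 * Z975))


def quintile_profile(
    score: np.ndarray,
    covariate: np.ndarray,
    adjust: pd.DataFrame | np.ndarray | None = None,
    quantiles: tuple = (0.2, 0.4, 0.6, 0.8),
    method: str = "model",
) -> pd.Series:
    """Covariate value at score quantiles (default 20/40/60/80%).

    ``method='model'``: linear fit of covariate on score (plus adjustment
    covariates held at their means), evaluated at the empirical score
    quantiles.  Binary covariates use the same linear fit for presentation,
    so predictions may fall outside [0, 1].  ``method='bin_means'``: raw mean
    within quantile bins whose upper edges are the requested quantiles.
    """
    score = np.asarray(score, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    mask = np.isfinite(score) & np.isfinite(covariate)
    score, covariate = score[mask], covariate[mask]
    qs = np.quantile(score, quantiles)
    if np.unique(covariate).size == 1:
        import logging

        logging.getLogger(__name__).warning("constant covariate: profile is flat")
        return pd.Series(covariate[0], index=list(quantiles))
    if method == "bin_means":
        edges = np.concatenate([[-np.inf], qs])
        out = [covariate[(score > lo) & (score <= hi)].mean() for lo, hi in zip(edges[:-1], edges[1:])]
        return pd.Series(out, index=list(quantiles))
    if method != "model":
        raise ValueError(f"unknown method {method!r}")
    if adjust is not None:
        C = pd.DataFrame(adjust).to_numpy(dtype=float)[mask]
        X = np.column_stack([np.ones(score.size), score, C])
        res = sm.OLS(covariate, X).fit()
        pred = res.params[0] + res.params[1] * qs + C.mean(axis=0) @ res.params[2:]
    else:
        X = np.column_stack([np.ones(score.size), score])
        res = sm.OLS(covariate, X).fit()
        pred = res.params[0] + res.params[1] * qs
    return pd.Series(pred, index=list(quantiles))


def stratify(cohort, scheme: str = "case_control") -> np.ndarray:
    """Stratum labels for each individual.

    ``case_control``: {'case', 'disease-free'} from the prevalent-case flag.
    ``cad_subtype``: cases split by MI history into {'CADMI', 'CADnoMI'};
    non-cases keep 'disease-free'.  Labels always partition the sample.
    """
    case = np.asarray(cohort.incident_case, dtype=bool)
    if scheme == "case_control":
        return np.where(case, "case", "disease-free")
    if scheme == "cad_subtype":
        labels = np.where(case, "CADnoMI", "disease-free").astype(object)
        mi = getattr(cohort, "prior_mi", None)
        if mi is not None:
            mi = np.asarray(mi, dtype=float)
            labels[case & (mi == 1)] = "CADMI"
        return np.asarray(labels, dtype=str)
    raise ValueError(f"unknown stratification scheme {scheme!r}")
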