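"""End-to-end simulation studies: configuration, orchestration, fixtures.

A study run simulates a cohort and an external incidence GWAS, builds the
polygenic score, produces the stratified association tables (the Table-1 /
Table-2 analogues), runs the case-only prognosis GWAS and the index-event
bias correction, and emits a single JSON-serializable report.  One master
seed is expanded into per-stage child seeds by hashing the stage name into a
seed sequence, so any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, synth
from .index_event import CorrectionConfig, correct_and_estimate
from .prs import PRSModel, build_prs_model, score_individuals, standardize_score
from .sumstats import LDReference, ld_clump, filter_records
from .synth import Cohort, SimConfig, stage_rng

log = logging.getLogger(__name__)

__all__ = [
    "PRSParams",
    "CorrectionParams",
    "RunConfig",
    "derive_child_seed",
    "run_simulation_study",
    "generate_fixtures",
]


def derive_child_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2^31) from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PRSParams:
    p_threshold: float = 5e-6
    r2_max: float = 0.2
    window_bp: int = 250_000
    use_true_weights: bool = False  # scaled runs: skip GWAS-based model building


@dataclass
class CorrectionParams:
    info_min: float | None = 0.99
    prune_window_bp: int = 250_000
    prune_step_snps: int = 5
    prune_r2_max: float = 0.1
    p_inc_max: float | None = 0.05
    slope_method: str = "simex"
    slope_intercept: bool = True
    simex_lambdas: list = field(default_factory=lambda: [0.0, 0.5, 1.0, 1.5, 2.0])
    simex_n_sim: int = 1000
    instrument_p_threshold: float = 5e-8  # genome-wide significant instrument list
    instrument_r2_max: float = 0.2
    ivw_weights: str = "adjusted"
    include_slope_variance: bool = False


@dataclass
class RunConfig:
    """One study: master seed plus per-stage parameter blocks.

    Defaults equal the headline analysis settings: PRS inclusion P < 5e-6
    with R2 < 0.2 / 250 kb clumping, pairing with INFO > 0.99 and
    (250 kb, 5 SNP, r2 = 0.1) pruning, slope estimation on the P < 0.05
    incidence subset.
    """

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    prs: PRSParams = field(default_factory=PRSParams)
    correction: CorrectionParams = field(default_factory=CorrectionParams)
    ld_panel_size: int = 500
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return json.loads(json.dumps(d, default=float))  # normalize tuples etc.

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = SimConfig(**{k: (tuple(v) if k == "maf_range" else v)
                           for k, v in d.pop("sim", {}).items()})
        prs = PRSParams(**d.pop("prs", {}))
        corr = CorrectionParams(**d.pop("correction", {}))
        return cls(sim=sim, prs=prs, correction=corr, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _with_child_seeds(config: RunConfig) -> RunConfig:
    cfg = dataclasses.replace(config)
    cfg.sim = dataclasses.replace(config.sim, seed=derive_child_seed(config.seed, "simulation"))
    return cfg


def _estimate_row(est: assoc.AssocEstimate) -> dict:
    return {
        "stratum": est.stratum, "outcome": est.outcome, "n": est.n,
        "beta": est.beta, "se": est.se, "p": est.p,
        "or": est.or_, "ci_low": est.ci95[0], "ci_high": est.ci95[1],
    }


def run_simulation_study(
    config: RunConfig,
    stages: tuple = ("simulate", "associate", "correct"),
) -> dict:
    """Run the study and return the report dict (optionally writing artifacts)."""
    config = _with_child_seeds(config)
    sim = config.sim
    report: dict = {"config": config.to_dict(), "stages": list(stages)}

    cohort = synth.simulate_cohort(sim)
    case = cohort.incident_case & cohort.recruited
    free = ~cohort.incident_case & cohort.recruited
    report["cohort"] = {
        "n": cohort.n,
        "n_cases": int(cohort.incident_case.sum()),
        "n_recruited_cases": int(case.sum()),
        "n_disease_free": int(free.sum()),
        "prevalence": float(cohort.incident_case.mean()),
        "predicted_prevalence": synth.predicted_prevalence(sim),
    }

    # LD reference panel: an external genotype sample, as with a public
    # reference panel standing in for the GWAS population
    panel_g = synth._draw_genotypes(sim, config.ld_panel_size, stage_rng(sim.seed, "ld_panel"))
    ld = LDReference.from_panel(pd.DataFrame(panel_g, columns=cohort.variants["SNP"].to_list()))

    inc_sumstats = synth.gwas_incidence(sim)
    report["n_inc_snps"] = len(inc_sumstats)

    if config.prs.use_true_weights:
        entries = cohort.variants.rename(columns={"A1": "EA", "FREQ": "EAF"})[["SNP", "EA", "EAF"]]
        entries = entries.assign(WEIGHT=sim.betas_incidence())
        model = PRSModel(entries=entries, provenance={"source": "true_weights"})
    else:
        model = build_prs_model(
            inc_sumstats, p_threshold=config.prs.p_threshold, ld=ld,
            r2_max=config.prs.r2_max, window_bp=config.prs.window_bp,
        )
    raw_score = score_individuals(cohort.genotype_frame(), model, cohort.counted_alleles())
    score = standardize_score(raw_score)  # pooled SD: one unit for all strata
    report["prs"] = {"n_snps": len(model), "provenance": model.provenance}

    results = report
    if "associate" in stages:
        covs = pd.DataFrame({"age": cohort.age, "sex": cohort.sex})
        death = cohort.prognosis_outcomes["death"].to_numpy()
        onset = cohort.prognosis_outcomes["incident_disease"].to_numpy()

        rows = []
        ests = {}
        for stratum, mask in (("disease-free", free), ("case", case)):
            est = assoc.fit_outcome_assoc(score[mask], death[mask], covs[mask],
                                          stratum=stratum, outcome_name="death")
            ests[("death", stratum)] = est
            rows.append(_estimate_row(est))
        est_onset = assoc.fit_outcome_assoc(score[free], onset[free], covs[free],
                                            stratum="disease-free",
                                            outcome_name="incident_disease")
        rows.append(_estimate_row(est_onset))
        het = assoc.heterogeneity_test(ests[("death", "disease-free")], ests[("death", "case")])
        results["table1"] = {
            "rows": rows,
            "heterogeneity_death": {"z": het.z, "p": het.p},
        }

        # case-subtype sensitivity split (random MI-history labels)
        labels = assoc.stratify(cohort, "cad_subtype")
        sub_ests = {}
        for sub in ("CADMI", "CADnoMI"):
            m = (labels == sub) & cohort.recruited
            if m.sum() > 50 and np.unique(death[m & np.isfinite(death)]).size == 2:
                sub_ests[sub] = assoc.fit_outcome_assoc(
                    score[m], death[m], covs[m], stratum=sub, outcome_name="death")
        if len(sub_ests) == 2:
            h = assoc.heterogeneity_test(sub_ests["CADMI"], sub_ests["CADnoMI"])
            results["subtype"] = {
                "rows": [_estimate_row(e) for e in sub_ests.values()],
                "heterogeneity_death": {"z": h.z, "p": h.p},
            }

        # Table-2 analogue: covariate values at score quintiles per stratum
        profile_defs = {
            "age": (cohort.age, None),
            "sex": (cohort.sex, None),
            "bmi": (cohort.covariates["bmi"].to_numpy(), covs),
            "smoking": (cohort.covariates["smoking"].to_numpy(), covs),
        }
        table2 = {}
        for name, (values, adj) in profile_defs.items():
            per_stratum = {}
            for stratum, mask in (("disease-free", free), ("case", case)):
                adj_m = adj[mask] if adj is not None else None
                prof = assoc.quintile_profile(score[mask], values[mask], adjust=adj_m)
                per_stratum[stratum] = {str(q): float(v) for q, v in prof.items()}
            table2[name] = per_stratum
        results["table2"] = table2

    if "correct" in stages:
        prog_sumstats = synth.gwas_prognosis(cohort, sim)
        report["n_prog_snps"] = len(prog_sumstats)

        gw = filter_records(inc_sumstats, p_max=config.correction.instrument_p_threshold)
        if gw.empty:
            raise RuntimeError("stage 'correct': no genome-wide-significant instruments")
        instruments = ld_clump(gw, ld, r2_max=config.correction.instrument_r2_max,
                               window_bp=config.prs.window_bp)["SNP"].to_list()

        cc = CorrectionConfig(
            info_min=config.correction.info_min,
            prune_window_bp=config.correction.prune_window_bp,
            prune_step_snps=config.correction.prune_step_snps,
            prune_r2_max=config.correction.prune_r2_max,
            p_inc_max=config.correction.p_inc_max,
            slope_method=config.correction.slope_method,
            slope_intercept=config.correction.slope_intercept,
            simex_lambdas=tuple(config.correction.simex_lambdas),
            simex_n_sim=config.correction.simex_n_sim,
            simex_seed=derive_child_seed(config.seed, "simex"),
            instruments=instruments,
            ivw_weights=config.correction.ivw_weights,
            include_slope_variance=config.correction.include_slope_variance,
        )
        correction = correct_and_estimate(inc_sumstats, prog_sumstats, ld, cc)
        results["correction"] = correction.to_dict()

        if config.out_dir:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            from .sumstats import write_sumstats

            write_sumstats(inc_sumstats, out / "sumstats_incidence.tsv")
            write_sumstats(prog_sumstats, out / "sumstats_prognosis.tsv")
            write_sumstats(correction.adjusted, out / "sumstats_prognosis_adjusted.tsv")
            model.write(out / "prs_model.tsv", out / "prs_model.json")

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if "table1" in results:
            pd.DataFrame(results["table1"]["rows"]).to_csv(
                out / "table1_associations.tsv", sep="\t", index=False)
        with open(out / "study_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report


# ---------------------------------------------------------------------------
# fixtures


def fixture_sim_config(seed: int = 7) -> SimConfig:
    """Scaled-down generative settings with an exaggerated bias structure,
    small enough for unit tests but large enough to show the collider sign."""
    return SimConfig(
        n_individuals=2_000,
        n_snps=50,
        seed=seed,
        var_genetic=0.4,
        var_shared_factor=0.8,
        shared_prognosis_effect=1.5,
        target_prevalence=0.20,
        survival_coefficient=0.8,
        recruitment_base_rate=0.8,
        prognosis_base_rate=0.25,
        onset_base_rate=0.08,
        ld_rho=0.35,
        ld_block_size=5,
        gwas_n_cases=1_500,
        gwas_n_controls=1_500,
    )


def generate_fixtures(seed: int = 7) -> dict:
    """Small deterministic datasets shared by the test suite.

    Returns a dict with a 2000-person cohort, the paired 50-SNP incidence /
    prognosis summary statistics, and a 20-SNP LD panel (200 individuals);
    variants outside the panel exercise the missing-variant r2=0 rule.
    """
    cfg = fixture_sim_config(seed)
    cohort = synth.simulate_cohort(cfg)
    inc = synth.gwas_incidence(cfg)
    prog = synth.gwas_prognosis(cohort, cfg)
    panel_g = synth._draw_genotypes(cfg, 200, stage_rng(cfg.seed, "fixture_panel"))[:, :20]
    panel = pd.DataFrame(panel_g, columns=cohort.variants["SNP"].to_list()[:20])
    return {
        "config": cfg,
        "cohort": cohort,
        "sumstats_inc": inc,
        "sumstats_prog": prog,
        "ld_panel": panel,
    }
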