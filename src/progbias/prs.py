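"""Polygenic score construction and scoring.

A score is defined by a list of (variant, effect allele, weight) entries,
with weights equal to the per-allele log-odds from an incidence GWAS after
P-value thresholding and LD clumping.  Individuals are scored as the
weighted sum of effect-allele dosages; the score is reported per standard
deviation of the pooled (unstratified) sample so that case and control
effect estimates share a unit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import LDReference, filter_records, ld_clump

__all__ = ["PRSModel", "build_prs_model", "score_individuals", "standardize_score"]


@dataclass
class PRSModel:
    """Variant weights defining a polygenic score.

    ``entries`` has columns SNP, EA, WEIGHT and optionally EAF (used to impute
    missing dosages as 2*eaf).  ``provenance`` records the thresholds used.
    """

    entries: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.entries["SNP"].duplicated().any():
            raise ValueError("duplicate variant ids in PRS model")
        if not np.isfinite(self.entries["WEIGHT"]).all():
            raise ValueError("non-finite weight in PRS model")

    def __len__(self) -> int:
        return len(self.entries)

    def write(self, tsv_path, json_path=None) -> None:
        cols = ["SNP", "EA", "WEIGHT"] + (["EAF"] if "EAF" in self.entries.columns else [])
        self.entries[cols].to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.provenance, fh, indent=2, default=float)

    @classmethod
    def read(cls, tsv_path, json_path=None) -> "PRSModel":
        entries = pd.read_csv(tsv_path, sep="\t")
        prov = {}
        if json_path is not None:
            with open(json_path) as fh:
                prov = json.load(fh)
        return cls(entries=entries, provenance=prov)


def build_prs_model(
    records: pd.DataFrame,
    p_threshold: float = 5e-6,
    ld: LDReference | None = None,
    r2_max: float = 0.2,
    window_bp: int = 250_000,
) -> PRSModel:
    """P-value threshold then LD-clump; weights are the surviving GWAS betas."""
    survivors = filter_records(records, p_max=p_threshold)
    if ld is not None:
        survivors = ld_clump(survivors, ld, r2_max=r2_max, window_bp=window_bp)
    if survivors.empty:
        raise ValueError("empty model: no variants survive thresholding/clumping")
    entries = survivors.rename(columns={"BETA": "WEIGHT"})[
        ["SNP", "EA", "WEIGHT"] + (["EAF"] if "EAF" in survivors.columns else [])
    ].reset_index(drop=True)
    prov = {
        "p_threshold": p_threshold,
        "r2_max": r2_max if ld is not None else None,
        "window_bp": window_bp if ld is not None else None,
        "n_input": len(records),
        "n_selected": len(entries),
    }
    return PRSModel(entries=entries, provenance=prov)


def score_individuals(
    genotypes: pd.DataFrame,
    model: PRSModel,
    counted_alleles: dict | pd.Series,
    other_alleles: dict | pd.Series | None = None,
) -> np.ndarray:
    """Weighted effect-allele dosage sum per individual.

    ``genotypes`` holds one dosage column (0-2) per variant; ``counted_alleles``
    maps each column to the allele its dosage counts.  Entries whose effect
    allele is the column's other allele are re-oriented (dosage -> 2 - dosage).
    Missing dosages are imputed with 2*eaf when the model carries an EAF,
    otherwise with the column mean.
    """
    counted = dict(counted_alleles)
    other = dict(other_alleles) if other_alleles is not None else {}
    missing = [s for s in model.entries["SNP"] if s not in genotypes.columns]
    if missing:
        raise KeyError(f"model variants absent from genotypes: {missing}")
    score = np.zeros(len(genotypes))
    has_eaf = "EAF" in model.entries.columns
    for row in model.entries.itertuples(index=False):
        d = genotypes[row.SNP].to_numpy(dtype=float)
        flip = False
        if row.EA != counted[row.SNP]:
            if other and other.get(row.SNP) not in (None, row.EA):
                raise ValueError(f"allele mismatch for {row.SNP}: {row.EA} not in panel alleles")
            flip = True
        if np.isnan(d).any():
            eaf = getattr(row, "EAF", np.nan) if has_eaf else np.nan
            if np.isfinite(eaf):
                fill = 2 * (1 - eaf) if flip else 2 * eaf
            else:
                fill = np.nanmean(d)
            d = np.where(np.isnan(d), fill, d)
        if flip:
            d = 2.0 - d
        score += row.WEIGHT * d
    return score


def standardize_score(scores: np.ndarray) -> np.ndarray:
    """Center and scale to unit sample SD (n-1 denominator); idempotent."""
    x = np.asarray(scores, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot standardize constant scores")
    return (x - x.mean()) / sd
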