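#!/usr/bin/env python
"""Build the polygenic score from the external incidence GWAS.

Simulates the independent case-control incidence GWAS (the external
summary-statistics source of the two-sample design), applies the P < 5e-6
inclusion threshold and R2 < 0.2 / 250 kb LD clumping against a 500-sample
reference panel, and writes the resulting score model and the summary
statistics to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from progbias import synth
from progbias.pipeline import RunConfig, derive_child_seed
from progbias.prs import build_prs_model
from progbias.sumstats import LDReference, write_sumstats
from progbias.synth import stage_rng

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()

    cfg = RunConfig(seed=args.seed)
    sim = cfg.sim.__class__(**{**cfg.sim.__dict__,
                               "seed": derive_child_seed(args.seed, "simulation")})

    inc = synth.gwas_incidence(sim)
    panel_g = synth._draw_genotypes(sim, cfg.ld_panel_size, stage_rng(sim.seed, "ld_panel"))
    variants = synth._variant_table(sim)
    ld = LDReference.from_panel(pd.DataFrame(panel_g, columns=variants["SNP"].to_list()))

    model = build_prs_model(inc, p_threshold=cfg.prs.p_threshold, ld=ld,
                            r2_max=cfg.prs.r2_max, window_bp=cfg.prs.window_bp)

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    write_sumstats(inc, out / "02_sumstats_incidence.tsv")
    model.write(out / "02_prs_model.tsv", out / "02_prs_model.json")

    print(f"incidence GWAS: {len(inc)} SNPs "
          f"({sim.gwas_n_cases} cases / {sim.gwas_n_controls} controls)")
    print(f"score model: {len(model)} SNPs survive P < {cfg.prs.p_threshold:g} "
          f"and clumping (r2 < {cfg.prs.r2_max}, {cfg.prs.window_bp // 1000} kb)")


if __name__ == "__main__":
    main()
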