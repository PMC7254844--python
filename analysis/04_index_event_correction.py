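#!/usr/bin/env python
"""Index-event bias correction on the simulated two-sample summary statistics.

Runs the full study including the correction stage: pairs the external
incidence GWAS with the case-only mortality GWAS, prunes and filters, fits
the bias slope (SIMEX by default, Hedges-Olkin and naive alongside),
computes I2_GX, adjusts the prognosis effects, and reports the IVW estimate
of genetic disease liability on mortality before and after correction.
With zero direct genetic prognosis effects the raw IVW OR is spuriously
protective; the corrected CI should cover the null.
"""

import argparse
import json
from pathlib import Path

from progbias.pipeline import RunConfig, run_simulation_study

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--slope-method", default="simex",
                    choices=["simex", "hedges_olkin", "naive"])
    args = ap.parse_args()

    cfg = RunConfig(seed=args.seed)
    cfg.correction.slope_method = args.slope_method
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    cfg.out_dir = str(out / "04_correction")
    report = run_simulation_study(cfg)

    corr = report["correction"]
    with open(out / "04_correction_report.json", "w") as fh:
        json.dump(corr, fh, indent=2, default=float)

    s = corr["slope"]
    print(f"paired SNPs: {corr['counts']['n_pairs']}  "
          f"slope set (P<{cfg.correction.p_inc_max}): {corr['counts']['n_slope_snps']}  "
          f"instruments: {corr['counts']['n_instruments']}")
    print(f"bias slope ({s['method']}): {s['value']:.4f} "
          f"(95% CI {s['ci95'][0]:.4f}, {s['ci95'][1]:.4f}); "
          f"naive {s['naive']:.4f}; Hedges-Olkin {s['hedges_olkin']:.4f}")
    print(f"I2_GX: {100 * corr['i2_gx']:.1f}%")
    for key in ("raw", "corrected"):
        r = corr[key]
        print(f"IVW {key:>9}: OR {r['or']:.3f} "
              f"(95% CI {r['ci95'][0]:.3f}, {r['ci95'][1]:.3f})  P={r['p']:.2g}")


if __name__ == "__main__":
    main()
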