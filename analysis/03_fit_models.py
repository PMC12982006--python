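#!/usr/bin/env python
"""Standardized facility-level models for the four ACS balancing metrics.

Fits one OLS model per outcome (coverage, overtreatment, timing, overall use)
on the facility profiles, plus the sensitivity variant that rebuilds the
pipeline after dropping abruption and Grade-1-cesarean pregnancies. Writes
coefficient tables (standardized and per-natural-unit, with VIFs) and forest
plots under results/. Pass --facility-table to model an externally supplied
facility-level aggregate table instead of the synthetic registry (only the
columns it carries are usable as covariates).
"""

import argparse
from pathlib import Path

import acsbalance as ab
from acsbalance import metrics as fm, models

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20201)
    ap.add_argument("--facility-table", type=Path, default=None)
    ap.add_argument("--no-plots", action="store_true")
    args = ap.parse_args()

    if args.facility_table is not None:
        profiles = fm.read_facility_table(args.facility_table)
        covs = ["n_total", "n_lt34"]
        fits = models.run_analysis_suite(profiles, covariates=covs)
        sens = None
    else:
        reg = ab.generate_registry(ab.RegistryConfig(seed=args.seed))
        retained, _ = ab.apply_exclusions(reg.records)
        profiles, _ = ab.profiles_from_records(reg.records, reg.attributes)
        fits = models.run_analysis_suite(profiles)
        sens = models.run_analysis_suite(
            profiles, sensitivity=True, records=retained, attributes=reg.attributes
        )

    RESULTS.mkdir(exist_ok=True)
    models.suite_table(fits).to_csv(RESULTS / "model_fits.tsv", sep="\t", index=False)
    if sens is not None:
        models.suite_table(sens).to_csv(
            RESULTS / "model_fits_sensitivity.tsv", sep="\t", index=False
        )

    for outcome, fit in fits.items():
        sig = fit.table[fit.table["significant"]]
        print(f"\n{outcome} (n={fit.n}, R²={fit.r_squared:.2f}, max VIF "
              f"{fit.table['vif'].max():.2f})")
        if len(sig):
            for cov, row in sig.iterrows():
                print(f"  {cov}: {row['coef']:+.1f} pp/SD "
                      f"[{row['ci_low']:.1f}, {row['ci_high']:.1f}]")
        else:
            print("  no covariate with CI excluding zero")
        if not args.no_plots:
            models.forest_plot(fit, RESULTS / f"forest_{outcome}.png")

    print(f"\nwrote model tables{'' if args.no_plots else ' and forest plots'} "
          f"under {RESULTS}")


if __name__ == "__main__":
    main()
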