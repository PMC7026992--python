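"""Goodness-of-fit diagnostics for the fitted population model.

Computes observed-vs-predicted regression, bias (mean prediction error) and
imprecision (bias-adjusted mean squared prediction error) from MAP-Bayesian
individual predictions, NPDE summaries, and 1000-replicate VPC bands for both
study arms, with the fraction of observations inside the 5th-95th band.
Writes tables to results/diagnostics/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from meropk import pk_core
from meropk.cli import load_subjects
from meropk.datasets import load_regimen
from meropk.estimation import (
    ErrorModel,
    PopulationModel,
    bias_imprecision,
    npde,
    obs_pred_regression,
    population_predictions,
    vpc,
)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "diagnostics"
SEED = 1


def main() -> None:
    subjects = load_subjects(
        ROOT / "results/trial/obs.csv", ROOT / "results/trial/dosing.csv"
    )
    blob = json.loads((ROOT / "results/fit/fit.json").read_text())
    model = PopulationModel(
        support=np.asarray(blob["support"]),
        weights=np.asarray(blob["weights"]),
        gamma=blob["gamma"],
    )
    error = ErrorModel()
    OUT.mkdir(parents=True, exist_ok=True)

    table = population_predictions(model, subjects, mode="map")
    table.to_csv(OUT / "obs_pred.csv", index=False)
    report = {}
    for analyte, rows in table.groupby("analyte"):
        bias, imprecision = bias_imprecision(rows["observed"], rows["predicted"])
        intercept, slope, r2 = obs_pred_regression(rows["observed"], rows["predicted"])
        report[analyte] = {
            "bias_mg_L": bias, "imprecision_mg2_L2": imprecision,
            "intercept": intercept, "slope": slope, "r2": r2,
        }
        print(f"{analyte}: bias {bias:.3f} mg/L, imprecision {imprecision:.3f}, "
              f"slope {slope:.3f}, R^2 {r2:.3f}")

    values = npde(model, subjects, n_sim=1000, seed=SEED, error=error)
    report["npde"] = {"mean": float(values.mean()), "variance": float(values.var())}
    print(f"NPDE: mean {values.mean():.3f}, variance {values.var():.3f}")

    grid = pk_core.default_grid(72.0, step=0.5)
    coverage_rows = []
    for arm, regimen, maint in (
        ("1g_q8h", "2g_ld_1g_q8h_ci", 1000.0),
        ("2g_q8h", "2g_ld_2g_q8h_ci", 2000.0),
    ):
        bands = vpc(model, load_regimen(regimen), grid, n_sim=1000, seed=SEED, error=error)
        pd.DataFrame(
            {"time_h": bands.times, "p5": bands.p5, "p50": bands.p50, "p95": bands.p95}
        ).to_csv(OUT / f"vpc_{arm}.csv", index=False)
        arm_subjects = [s for s in subjects if s.schedule.events[1][2] == maint]
        times = np.concatenate([s.times[s.analytes == "plasma"] for s in arm_subjects])
        vals = np.concatenate([s.values[s.analytes == "plasma"] for s in arm_subjects])
        cov = bands.coverage(times, vals)
        coverage_rows.append({"arm": arm, "fraction_in_5_95_band": cov})
        print(f"VPC {arm}: {100*cov:.1f}% of plasma observations inside the 5th-95th band")
    pd.DataFrame(coverage_rows).to_csv(OUT / "vpc_coverage.csv", index=False)
    (OUT / "summary.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
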