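"""Discriminant models: backward-stepwise selection over the five linear
measurements (partial-F enter 3.84 / remove 2.71) and the fixed wing+bill
model, with resubstitution accuracies from Mahalanobis classification.
Writes results/model_stepwise.json, results/model_wing_bill.json and
results/model_accuracies.csv."""

import argparse
import json
from pathlib import Path

import pandas as pd

from cormorant_sexing import backward_stepwise, fit_lda, resubstitution_accuracy
from cormorant_sexing.cli_report import read_morphometrics_csv

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    argparse.ArgumentParser().parse_args()
    csv = RESULTS / "simulated_population.csv"
    if not csv.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    sample = read_morphometrics_csv(csv)

    step_model, trace = backward_stepwise(sample)
    (RESULTS / "model_stepwise.json").write_text(step_model.to_json())
    print("stepwise selected:", ", ".join(step_model.variables))
    for t in trace:
        print(f"  {t['direction']} {t['variable']}: partial F = {t['F']:.2f}, "
              f"lambda -> {t['lambda']:.3f}")

    keep = ~sample.data[["wing_length", "bill_length"]].isna().any(axis=1)
    fixed = fit_lda(sample.data.loc[keep],
                    variables=("wing_length", "bill_length"))
    (RESULTS / "model_wing_bill.json").write_text(fixed.to_json())
    eq = " + ".join(f"{c:.3f}*{v}" for c, v in
                    zip(fixed.coefficients, fixed.variables))
    print(f"wing+bill equation: D = {eq} {fixed.constant:+.3f}")

    rows = []
    for name, model in (("stepwise", step_model), ("wing_bill", fixed)):
        acc = resubstitution_accuracy(model, sample)
        rows.append({"model": name, "variables": "+".join(model.variables),
                     "wilks_lambda": round(model.wilks_lambda, 4), **acc})
        print(f"{name}: males {acc['male_pct']:.1f}%, "
              f"females {acc['female_pct']:.1f}%, "
              f"overall {acc['overall_pct']:.1f}% correctly sexed")
    pd.DataFrame(rows).to_csv(RESULTS / "model_accuracies.csv", index=False)


if __name__ == "__main__":
    main()
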