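"""Grey-zone thresholds on the wing+bill discriminant scores (1% per-sex
error target) and cross-validation of the shipped Greece and Netherlands
equations plus our fitted rule. Writes results/greyzone.csv and
results/cross_validation.csv."""

import argparse
from pathlib import Path

import pandas as pd

from cormorant_sexing import (
    PRESETS,
    cross_validate_rules,
    derive_greyzone,
)
from cormorant_sexing.cli_report import read_morphometrics_csv
from cormorant_sexing.discriminant_analysis import DiscriminantModel

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    argparse.ArgumentParser().parse_args()
    sample = read_morphometrics_csv(RESULTS / "simulated_population.csv")
    model = DiscriminantModel.from_json(
        (RESULTS / "model_wing_bill.json").read_text()
    )

    keep = ~sample.data[list(model.variables)].isna().any(axis=1)
    scores = model.score(sample.data.loc[keep])
    sexes = sample.data.loc[keep, "sex"].to_numpy()
    rep = derive_greyzone(scores[sexes == "M"], scores[sexes == "F"])
    pd.DataFrame([{
        "t_F": rep.t_F, "t_M": rep.t_M,
        "male_misclassified_pct": rep.male_misclassified_pct,
        "female_misclassified_pct": rep.female_misclassified_pct,
        "unsexed_pct": rep.unsexed_pct,
    }]).round(3).to_csv(RESULTS / "greyzone.csv", index=False)
    print(f"grey zone for 1% per-sex error: D in [{rep.t_F:.3f}, {rep.t_M:.3f}]"
          f" leaves {rep.unsexed_pct:.0f}% of birds unsexed")

    rules = [PRESETS["greece"], PRESETS["netherlands"],
             model.to_rule("fitted_wing_bill")]
    table = cross_validate_rules(rules, sample)
    table.round(1).to_csv(RESULTS / "cross_validation.csv", index=False)
    print(table.round(1).to_string(index=False))


if __name__ == "__main__":
    main()
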