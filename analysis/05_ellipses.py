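"""95% prediction ellipses per sex for the two most dimorphic bill traits
(bill length x minimum bill depth) and the fraction of each sex inside the
overlap region. Writes results/ellipse_overlap.csv; the optional figure
goes under scratch/ (pass --plot)."""

import argparse
from pathlib import Path

import pandas as pd

from cormorant_sexing import overlap_membership, prediction_ellipse
from cormorant_sexing.cli_report import read_morphometrics_csv

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
TRAITS = ["bill_length", "min_bill_depth"]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--plot", action="store_true")
    args = ap.parse_args()
    sample = read_morphometrics_csv(RESULTS / "simulated_population.csv")

    pts, ell = {}, {}
    for sex in ("M", "F"):
        sub = sample.sex_subset(sex)[TRAITS].dropna().to_numpy()
        pts[sex] = sub
        ell[sex] = prediction_ellipse(sub)
    rows = []
    for sex in ("M", "F"):
        frac = 100 * overlap_membership(ell["M"], ell["F"], pts[sex])
        rows.append({"sex": sex, "n": len(pts[sex]),
                     "inside_overlap_pct": round(frac, 1)})
        print(f"{sex}: {frac:.0f}% of birds inside the overlap of the "
              "two 95% prediction ellipses")
    pd.DataFrame(rows).to_csv(RESULTS / "ellipse_overlap.csv", index=False)

    if args.plot:
        from cormorant_sexing.prediction_ellipse import plot_ellipses

        scratch = ROOT / "scratch"
        scratch.mkdir(exist_ok=True)
        plot_ellipses(
            {"males": ell["M"], "females": ell["F"]},
            {"M": pts["M"], "F": pts["F"]},
            path=scratch / "ellipse_overlap.png",
            xlabel="bill length [mm]", ylabel="minimum bill depth [mm]",
        )
        print(f"figure written to {scratch / 'ellipse_overlap.png'}")


if __name__ == "__main__":
    main()
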