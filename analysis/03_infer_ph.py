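"""Infer medium pH trajectories from the BCECF channels.

Background-subtracts each dye-loaded well against its BCECF-free sister
replicate, forms the F490/F440 ratio, and inverts the calibration curve.
Prints the agreement with the generating pH per condition.
"""

import argparse
from pathlib import Path

import pandas as pd

from strainpheno import pipeline, plates

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    sim = args.out / "sim"
    path = pipeline.infer_ph(sim / "plate.csv", sim / "layout.csv",
                             sim / "calibration.csv", args.out / "ph")
    traj = pd.read_csv(path, sep="\t")
    layout = {w.well: w for w in plates.read_layout_csv(sim / "layout.csv")}
    traj["target"] = traj.well.map(
        lambda w: layout[w].condition_value if layout[w].condition_type == "pH" else 6.9
    )
    err = (traj.ph - traj.target).abs()
    print(f"{traj.well.nunique()} BCECF wells; max |pH error| = {err.max():.2e}; "
          f"{traj.in_range.mean():.1%} of points inside the calibration range")


if __name__ == "__main__":
    main()
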