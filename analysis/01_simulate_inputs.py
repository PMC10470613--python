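"""Generate the synthetic study inputs.

Writes a characterization plate (OD600 + BCECF channels for every strain
in quadruplicate across the eight pH/osmolality conditions, with sterile
controls), the per-experiment pH calibration, and the ground-truth growth
parameters that later stages should recover.
"""

import argparse
from pathlib import Path

from strainpheno import pipeline

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    paths = pipeline.simulate_study_plate(args.out / "sim", args.seed)
    print(f"simulated plate inputs (seed {args.seed}):")
    for name, path in paths.items():
        print(f"  {name}: {path}")


if __name__ == "__main__":
    main()
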