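#!/usr/bin/env python
"""Simulate the demo screen: two replicate plates of the bundled layout.

Writes per-well ground-truth bookkeeping (designed mean log YAP/TAZ ratio,
multinucleation, cell counts) and the plate maps under results/simulated/.
Field images are written as multi-page TIFFs only with --save-images, to
keep the results tree small.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from morphoscreen.imageio import write_field, write_labels
from morphoscreen.pipeline import demo_layout
from morphoscreen.plate import PlateLayout, write_plate_map
from morphoscreen.synth import PlateSimSpec, WellEffect, simulate_plate


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-cells", type=int, default=40)
    ap.add_argument("--out", type=Path, default=Path("results/simulated"))
    ap.add_argument("--save-images", action="store_true")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    layout = demo_layout(8)
    samples = [w.well for w in layout.by_role("sample")]
    effects = {
        samples[0]: WellEffect(log_ratio_shift=0.4),
        samples[1]: WellEffect(
            multinucleate_fraction=0.45,
            mixture={"spindly": 0.10, "large_spread": 0.45, "triangular": 0.10,
                     "fan": 0.10, "small_round": 0.25},
        ),
    }
    for pi, plate_id in enumerate(("1A", "1B")):
        pseed = int(np.random.SeedSequence([args.seed, pi]).generate_state(1)[0] % 2**31)
        spec = PlateSimSpec(
            layout=PlateLayout(wells=layout.wells, plate_id=plate_id),
            n_cells=args.n_cells, effects=effects, rng_seed=pseed,
        )
        truths = []
        for well, img, gt, truth in simulate_plate(spec):
            truths.append(truth)
            if args.save_images:
                img_dir = args.out / plate_id
                img_dir.mkdir(exist_ok=True)
                write_field(img_dir / f"{well}_field.tif", img)
                write_labels(img_dir / f"{well}_cells.tif", gt.cells)
                write_labels(img_dir / f"{well}_nuclei.tif", gt.nuclei)
        truth_df = pd.DataFrame(truths)
        truth_df.to_csv(args.out / f"well_truth_{plate_id}.tsv", sep="\t", index=False)
        write_plate_map(spec.layout, args.out / f"plate_map_{plate_id}.csv")
        mocks = truth_df[truth_df.role == "mock"]
        lats = truth_df[truth_df.role == "control_lats1"]
        print(
            f"plate {plate_id}: {len(truth_df)} wells; designed LATS1-like "
            f"log-ratio shift = "
            f"{lats.true_mean_log_ratio.mean() - mocks.true_mean_log_ratio.mean():+.3f}"
        )
    print(f"ground truth written under {args.out}")


if __name__ == "__main__":
    main()
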