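#!/usr/bin/env python
"""Hit selection on the profiled screen.

Reads the per-plate well tables from 02, plate-normalises, computes
control-referenced Z-scores against the mock wells, calls hits at
|Z| >= 1.5 on the shape proportions, YAP/TAZ ratio and total YAP/TAZ, and
fits the density-dependence regression on the dilution wells.  Writes
results/hits.csv and results/density_fit.txt.
"""

import argparse
from pathlib import Path

import pandas as pd

from morphoscreen.config import Config
from morphoscreen.pipeline import HIT_FEATURES
from morphoscreen.screen import (
    call_hits,
    density_regression,
    plate_normalise,
    zscore_to_controls,
)
from morphoscreen.tables import read_feature_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--profiles", type=Path, default=Path("results/profiles"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    cfg = Config()

    tables = [
        read_feature_table(p) for p in sorted(args.profiles.glob("well_table_*.tsv"))
    ]
    combined = pd.concat(tables, ignore_index=True)
    z = zscore_to_controls(plate_normalise(combined, cfg.screen))
    feats = [f for f in HIT_FEATURES if f in combined.columns]
    hits = call_hits(
        z, combined, feats, threshold=cfg.screen.hit_threshold,
        fold_feature_map={"yap_ratio_nuc_ring_log10": "yap_ratio_nuc_ring"},
    )
    hits.to_csv(args.out / "hits.csv", index=False)
    called = hits[hits["hit"]]
    print(f"{len(called)} hit calls of {len(hits)} well-feature pairs")
    for feat, grp in called.groupby("feature"):
        top = grp.iloc[0]
        print(
            f"  top {feat}: {top.gene or top.well} Z={top.z:+.2f} "
            f"fold={top.fold_change:.2f}"
        )

    dil = combined[combined["role"] == "dilution"]
    if dil["cells_plated"].nunique() >= 3:
        fit = density_regression(dil["cells_plated"], dil["yap_ratio_nuc_ring_log10"])
        with open(args.out / "density_fit.txt", "w") as fh:
            fh.write(
                f"slope\t{fit.slope}\nintercept\t{fit.intercept}\n"
                f"r\t{fit.r_value}\np\t{fit.p_value}\nn\t{fit.n}\n"
            )
        print(
            f"density regression: slope {fit.slope:+.2e} per plated cell "
            f"(p = {fit.p_value:.3f}, n = {fit.n})"
        )


if __name__ == "__main__":
    main()
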