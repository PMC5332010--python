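#!/usr/bin/env python
"""Screen quality control.

Replicate-plate correlation (diagonal vs off-diagonal of the well-by-well
correlation matrix), siRNA-reproducibility distributions against a
feature-randomised null, and Z' factors for each positive-control readout.
Reads the profiled well tables from 02; writes results/qc_summary.txt.
"""

import argparse
from pathlib import Path

import pandas as pd

from morphoscreen.features import REGISTRY_NAMES
from morphoscreen.pipeline import CONTROL_READOUTS
from morphoscreen.qc import replicate_correlation, sirna_reproducibility, zprime
from morphoscreen.tables import read_feature_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--profiles", type=Path, default=Path("results/profiles"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    paths = sorted(args.profiles.glob("well_table_*.tsv"))
    tables = {p.stem.split("_")[-1]: read_feature_table(p) for p in paths}
    lines = []

    if len(tables) >= 2:
        (pa, a), (pb, b) = list(tables.items())[:2]
        feats = [c for c in REGISTRY_NAMES if c in a.columns and a[c].notna().all()]
        rep = replicate_correlation(a, b, feats)
        lines += [
            f"replicate_pair\t{pa}/{pb}",
            f"replicate_median_diagonal\t{rep.median_diagonal:.4f}",
            f"replicate_median_off_diagonal\t{rep.median_off_diagonal:.4f}",
            f"replicate_welch_p\t{rep.p_value:.3e}",
        ]
        print(
            f"replicate plates {pa}/{pb}: diagonal median "
            f"{rep.median_diagonal:.3f} vs null {rep.median_off_diagonal:.3f} "
            f"(Welch p = {rep.p_value:.2e})"
        )

    combined = pd.concat(tables.values(), ignore_index=True)
    # technical replicates: same well across replicate plates
    feats = [c for c in REGISTRY_NAMES if c in combined.columns]
    rr = sirna_reproducibility(
        combined.dropna(subset=feats), seed=args.seed,
        group_column="well", feature_columns=feats,
    )
    lines += [
        f"sirna_positive_median\t{rr.median_positive:.4f}",
        f"sirna_null_median\t{rr.median_null:.4f}",
        f"sirna_positive_skew\t{rr.skew_positive:.4f}",
        f"sirna_null_skew\t{rr.skew_null:.4f}",
    ]
    print(
        f"siRNA reproducibility: positive median {rr.median_positive:.3f} "
        f"(skew {rr.skew_positive:+.2f}), null median {rr.median_null:.3f}"
    )

    mock = combined[combined["role"] == "mock"]
    for role, feat in CONTROL_READOUTS.items():
        pos = combined[combined["role"] == role][feat].dropna()
        neg = mock[feat].dropna()
        if len(pos) >= 3 and len(neg) >= 3:
            z, band = zprime(pos, neg)
            lines.append(f"zprime_{role}\t{z:.3f}\t{band}")
            print(f"Z' {role} on {feat}: {z:.3f} ({band})")

    (args.out / "qc_summary.txt").write_text("\n".join(lines) + "\n")


if __name__ == "__main__":
    main()
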