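#!/usr/bin/env python
"""Shape-classifier validation: proportion recovery over the simplex.

Trains the five-way linear classifier on rendered reference cells, then
classifies held-out populations drawn from mixtures spanning the 5-class
simplex and reports the worst absolute proportion error per mixture.
Writes results/shape_recovery.tsv.
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1]))

from morphoscreen.features import SHAPE_CLASSES  # noqa: E402
from morphoscreen.pipeline import mixture_population_table, training_table  # noqa: E402
from morphoscreen.shape_classify import classify, train  # noqa: E402
from tests.test_acceptance import SIMPLEX_MIXTURES  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-per-mixture", type=int, default=1000)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    mseed = int(np.random.SeedSequence([args.seed, 3]).generate_state(1)[0] % 2**31)
    table, labels = training_table(300, mseed)
    model = train(table, labels)
    print(f"training accuracy: {model.training_accuracy['overall']:.3f}")

    rows = []
    for mi, weights in enumerate(SIMPLEX_MIXTURES):
        t, truth = mixture_population_table(
            weights, n_cells=args.n_per_mixture,
            seed=int(np.random.SeedSequence([args.seed, 100 + mi]).generate_state(1)[0] % 2**31),
        )
        pred = classify(model, t)["shape_class"]
        worst = max(
            abs(float((pred == c).mean()) - float((truth == c).mean()))
            for c in SHAPE_CLASSES
        )
        desc = ", ".join(f"{c}={w:.2f}" for c, w in weights.items())
        rows.append({"mixture": desc, "n": len(t), "max_abs_proportion_error": worst})
        print(f"mixture {mi + 1} ({desc}): max |error| = {worst:.3f}")
    df = pd.DataFrame(rows)
    df.to_csv(args.out / "shape_recovery.tsv", sep="\t", index=False)
    print(f"overall worst error: {df.max_abs_proportion_error.max():.3f}")


if __name__ == "__main__":
    main()
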