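"""Feature-level screen simulation.

Direct simulation of well-averaged feature tables, bypassing the image
pipeline.  This is the generator used for screen-statistics and QC
validation, where hundreds of wells and replicate plates are needed: each
well carries a latent biological feature vector shared across replicate
plates, plus independent technical noise, so the within-well (replicate)
correlation is controlled exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def simulate_replicate_plates(
    n_wells: int,
    n_features: int,
    within_well_correlation: float,
    seed: int,
    plates: tuple[str, str] = ("A", "B"),
) -> dict[str, pd.DataFrame]:
    """Two replicate plates whose well feature vectors share a latent part.

    observed = sqrt(rho) * latent_well + sqrt(1-rho) * noise, so the
    expected Pearson correlation between replicate wells is ``rho`` while
    distinct wells are independent.
    """
    if not 0 <= within_well_correlation <= 1:
        raise ValueError("correlation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rho = within_well_correlation
    latent = rng.standard_normal((n_wells, n_features))
    wells = [f"W{i + 1:03d}" for i in range(n_wells)]
    out = {}
    for p in plates:
        noise = rng.standard_normal((n_wells, n_features))
        obs = np.sqrt(rho) * latent + np.sqrt(1 - rho) * noise
        df = pd.DataFrame(obs, columns=[f"f{j + 1:03d}" for j in range(n_features)])
        df.insert(0, "well", wells)
        out[p] = df
    return out


def simulate_sirna_replicates(
    n_sirnas: int,
    n_features: int,
    replicate_correlation: float,
    seed: int,
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Well table with ``n_replicates`` technical replicates per siRNA."""
    rng = np.random.default_rng(seed)
    rho = replicate_correlation
    rows = []
    for i in range(n_sirnas):
        latent = rng.standard_normal(n_features)
        for r in range(n_replicates):
            noise = rng.standard_normal(n_features)
            obs = np.sqrt(rho) * latent + np.sqrt(1 - rho) * noise
            rows.append([f"siRNA{i + 1:03d}", r + 1, *obs])
    cols = ["sirna", "replicate"] + [f"f{j + 1:03d}" for j in range(n_features)]
    return pd.DataFrame(rows, columns=cols)


def simulate_null_screen(
    n_plates: int,
    wells_per_plate: int,
    n_features: int,
    n_controls_per_plate: int,
    seed: int,
    spikes: dict[tuple[int, int], dict[int, float]] | None = None,
) -> pd.DataFrame:
    """Null screen table: every well i.i.d. Gaussian per feature, with
    optional spiked effects.

    ``spikes`` maps (plate index, well index) -> {feature index: shift in
    control-sd units}.  Plates get their own additive offset and scale per
    feature, which plate normalisation must remove.
    """
    rng = np.random.default_rng(seed)
    rows = []
    feat_cols = [f"f{j + 1:03d}" for j in range(n_features)]
    for p in range(n_plates):
        offset = rng.normal(0, 2, n_features)
        scale = rng.uniform(0.5, 2.0, n_features)
        for w in range(wells_per_plate):
            x = rng.standard_normal(n_features)
            if spikes and (p, w) in spikes:
                for j, shift in spikes[(p, w)].items():
                    x[j] += shift
            obs = offset + scale * x
            role = "mock" if w < n_controls_per_plate else "sample"
            rows.append([f"P{p + 1}", f"W{w + 1:03d}", role, *obs])
    return pd.DataFrame(rows, columns=["plate", "well", "role"] + feat_cols)


def simulate_dilution_curve(
    densities: list[int],
    slope: float,
    intercept: float,
    noise_sd: float,
    seed: int,
    n_per_density: int = 2,
) -> pd.DataFrame:
    """Dilution-series wells with YAP/TAZ ratio linear in plated density."""
    rng = np.random.default_rng(seed)
    rows = []
    for d in densities:
        for _ in range(n_per_density):
            y = intercept + slope * d + rng.normal(0, noise_sd)
            rows.append([d, y])
    return pd.DataFrame(rows, columns=["cells_plated", "yap_ratio"])
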