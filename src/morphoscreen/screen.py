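"""Screen statistics: plate normalisation, control-referenced Z-scores,
threshold hit calling and the density-dependence regression.

The published order of operations is followed: raw per-plate well tables
are normalised plate-wise (z-scaling by plate mean and sd, with a robust
median/MAD variant), normalised values are pooled per screen, and Z-scores
are computed against the pooled control-well mean and sd.  A well is a hit
for a feature when |Z| >= 1.5.  Fold changes are computed on the raw scale
against the raw control mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ScreenConfig

log = logging.getLogger(__name__)

META_COLUMNS = ("plate", "well", "role", "gene", "cells_plated")


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def plate_normalise(
    table: pd.DataFrame, config: ScreenConfig | None = None
) -> pd.DataFrame:
    """Plate-wise z-scaling of every feature column.

    Features with zero variance on a plate are skipped (left missing) with
    a warning.  Normalising an already-normalised plate is a no-op up to
    float tolerance.
    """
    cfg = config or ScreenConfig()
    feats = _feature_columns(table)
    out = table.copy()
    for plate, idx in table.groupby("plate").groups.items():
        sub = table.loc[idx, feats]
        if len(idx) < 2:
            raise ValueError(f"plate {plate} has fewer than 2 wells")
        if cfg.robust:
            center = sub.median()
            scale = (sub - center).abs().median() * 1.4826
        else:
            center = sub.mean()
            scale = sub.std(ddof=0)
        bad = ~(scale > 0)
        if bad.any():
            log.warning(
                "plate %s: %d constant features skipped (e.g. %s)",
                plate,
                int(bad.sum()),
                list(scale.index[bad])[:3],
            )
        scale = scale.where(~bad)
        out.loc[idx, feats] = ((sub - center) / scale).to_numpy()
    return out


def zscore_to_controls(
    table: pd.DataFrame,
    control_roles: tuple[str, ...] = ("mock",),
    min_controls: int = 3,
) -> pd.DataFrame:
    """Z-scores of every well against the screen's pooled control wells."""
    feats = _feature_columns(table)
    ctrl = table[table["role"].isin(control_roles)]
    if len(ctrl) < min_controls:
        raise ValueError(
            f"need >= {min_controls} control wells, found {len(ctrl)}"
        )
    mu = ctrl[feats].mean()
    sd = ctrl[feats].std(ddof=1)
    bad = ~(sd > 0)
    if bad.any():
        log.warning("%d features with zero control sd skipped", int(bad.sum()))
    sd = sd.where(~bad)
    out = table.copy()
    out.loc[:, feats] = ((table[feats] - mu) / sd).to_numpy()
    return out


@dataclass
class HitCall:
    gene: str
    well: str
    feature: str
    z: float
    fold_change: float
    hit: bool
    direction: str


def call_hits(
    zscores: pd.DataFrame,
    raw: pd.DataFrame,
    features: list[str],
    threshold: float = 1.5,
    control_roles: tuple[str, ...] = ("mock",),
    fold_feature_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Hit table: a well is a hit for a feature when |Z| >= threshold.

    Fold change = raw well value / raw control mean; ``fold_feature_map``
    redirects the fold computation of a feature to a companion column
    (e.g. the unlogged ratio for a log-scale feature).  Control and
    dilution wells are excluded from calling.  Rows are ranked by |Z| per
    feature.
    """
    fold_feature_map = fold_feature_map or {}
    fold_cols = {f: fold_feature_map.get(f, f) for f in features}
    ctrl = raw[raw["role"].isin(control_roles)]
    ctrl_mean = {f: ctrl[c].mean() for f, c in fold_cols.items() if c in raw.columns}
    callable_rows = ~zscores["role"].isin([*control_roles, "dilution"])
    rows = []
    for feat in features:
        for _, r in zscores[callable_rows].iterrows():
            z = r[feat]
            if not np.isfinite(z):
                continue
            raw_val = raw.loc[r.name, fold_cols[feat]]
            fc = raw_val / ctrl_mean[feat] if ctrl_mean.get(feat) else np.nan
            rows.append(
                {
                    "gene": r.get("gene", ""),
                    "well": r["well"],
                    "plate": r.get("plate", ""),
                    "feature": feat,
                    "z": float(z),
                    "fold_change": float(fc) if np.isfinite(fc) else np.nan,
                    "hit": bool(abs(z) >= threshold),
                    "direction": "up" if z > 0 else "down",
                }
            )
    hits = pd.DataFrame(
        rows,
        columns=["gene", "well", "plate", "feature", "z", "fold_change", "hit", "direction"],
    )
    if len(hits):
        hits["abs_z"] = hits["z"].abs()
        hits = (
            hits.sort_values(["feature", "abs_z"], ascending=[True, False])
            .drop(columns="abs_z")
            .reset_index(drop=True)
        )
    return hits


@dataclass
class DensityFit:
    slope: float
    intercept: float
    r_value: float
    p_value: float
    stderr: float
    intercept_stderr: float
    n: int

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        t = stats.t.ppf(0.5 + level / 2, self.n - 2)
        return self.slope - t * self.stderr, self.slope + t * self.stderr


def density_regression(
    cells_plated: np.ndarray | pd.Series, yap_ratio: np.ndarray | pd.Series
) -> DensityFit:
    """OLS of the well YAP/TAZ ratio on plated cell density."""
    x = np.asarray(cells_plated, dtype=float)
    y = np.asarray(yap_ratio, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct plated densities")
    res = stats.linregress(x, y)
    return DensityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_value=float(res.rvalue),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
        intercept_stderr=float(res.intercept_stderr),
        n=int(x.size),
    )
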