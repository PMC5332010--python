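"""Screen quality control: replicate-plate correlation, siRNA
reproducibility with a randomised null, and the Z' factor.

Replicate-plate reproducibility: well-averaged feature vectors are z-scored
per plate, every well on plate A is correlated (Pearson) against every well
on plate B, and the matrix diagonal (replicate wells) is compared to the
off-diagonal (null) by Welch's two-sample t-test.

Z' = 1 - 3(sigma_p + sigma_n)/|mu_p - mu_n|; above 0.3 is acceptable and
0.5-1.0 desirable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class CorrelationReport:
    matrix: np.ndarray  # wells(A) x wells(B) Pearson correlations
    diagonal: np.ndarray
    off_diagonal: np.ndarray
    t_statistic: float
    p_value: float
    excluded_wells: list[str] = field(default_factory=list)

    @property
    def median_diagonal(self) -> float:
        return float(np.median(self.diagonal))

    @property
    def median_off_diagonal(self) -> float:
        return float(np.median(self.off_diagonal))


def _zscore_features(df: pd.DataFrame, feats: list[str]) -> np.ndarray:
    X = df[feats].to_numpy(dtype=float)
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd[sd == 0] = np.nan
    return (X - mu) / sd


def replicate_correlation(
    plate_a: pd.DataFrame, plate_b: pd.DataFrame, feature_columns: list[str] | None = None
) -> CorrelationReport:
    """Correlation matrix between well feature vectors of duplicate plates."""
    if feature_columns is None:
        feature_columns = [c for c in plate_a.columns if c != "well"]
    a = plate_a.set_index("well")
    b = plate_b.set_index("well")
    if set(a.index) != set(b.index):
        raise ValueError("plates must share the same well set")
    b = b.loc[a.index]
    Za = _zscore_features(a.reset_index(), feature_columns)
    Zb = _zscore_features(b.reset_index(), feature_columns)
    # drop wells with constant (zero-variance) feature vectors
    ok_a = np.nanstd(Za, axis=1) > 0
    ok_b = np.nanstd(Zb, axis=1) > 0
    ok = ok_a & ok_b
    excluded = list(a.index[~ok])
    if excluded:
        log.warning("excluding %d constant wells: %s", len(excluded), excluded[:5])
    Za, Zb = Za[ok], Zb[ok]
    # row-standardise, then the correlation matrix is a scaled dot product
    Za = (Za - Za.mean(axis=1, keepdims=True)) / Za.std(axis=1, keepdims=True)
    Zb = (Zb - Zb.mean(axis=1, keepdims=True)) / Zb.std(axis=1, keepdims=True)
    M = Za @ Zb.T / Za.shape[1]
    diag = np.diag(M)
    off = M[~np.eye(M.shape[0], dtype=bool)]
    t, p = stats.ttest_ind(diag, off, equal_var=False)
    return CorrelationReport(
        matrix=M,
        diagonal=diag,
        off_diagonal=off,
        t_statistic=float(t),
        p_value=float(p),
        excluded_wells=excluded,
    )


@dataclass
class ReproducibilityReport:
    positive: np.ndarray
    null: np.ndarray
    n_skipped: int
    t_statistic: float
    p_value: float

    @property
    def median_positive(self) -> float:
        return float(np.median(self.positive)) if self.positive.size else np.nan

    @property
    def median_null(self) -> float:
        return float(np.median(self.null)) if self.null.size else np.nan

    @property
    def skew_positive(self) -> float:
        return float(stats.skew(self.positive, bias=False)) if self.positive.size > 2 else np.nan

    @property
    def skew_null(self) -> float:
        return float(stats.skew(self.null, bias=False)) if self.null.size > 2 else np.nan


def _pairwise_correlations(groups: list[np.ndarray]) -> np.ndarray:
    out = []
    for X in groups:
        for i in range(len(X)):
            for j in range(i + 1, len(X)):
                a, b = X[i], X[j]
                sa, sb = a.std(), b.std()
                if sa > 0 and sb > 0:
                    out.append(float(np.corrcoef(a, b)[0, 1]))
    return np.array(out)


def sirna_reproducibility(
    table: pd.DataFrame,
    seed: int,
    group_column: str = "sirna",
    feature_columns: list[str] | None = None,
    standardise: bool = True,
) -> ReproducibilityReport:
    """Replicate-correlation distribution vs a feature-randomised null.

    Positive: Pearson correlations between technical-replicate wells of the
    same siRNA.  Null: the same computation after permuting whole feature
    vectors across wells (preserving within-vector covariance), seeded.
    siRNAs lacking replicates are skipped and counted.  Features are
    z-scored across wells first (``standardise``), without which raw
    mixed-unit features make every pair of wells correlate.
    """
    if feature_columns is None:
        feature_columns = [
            c for c in table.columns if c not in (group_column, "well", "replicate", "plate")
        ]
    X = table[feature_columns].to_numpy(dtype=float)
    if standardise:
        mu = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0)
        sd[sd == 0] = np.nan
        X = (X - mu) / sd
        X = X[:, np.isfinite(sd)]
    groups = []
    n_skipped = 0
    sizes = []
    for _, idx in table.groupby(group_column).groups.items():
        if len(idx) < 2:
            n_skipped += 1
            continue
        groups.append(X[table.index.get_indexer(idx)])
        sizes.append(len(idx))
    if not groups:
        log.warning("no siRNA has >= 2 technical replicates")
        return ReproducibilityReport(
            positive=np.array([]), null=np.array([]), n_skipped=n_skipped,
            t_statistic=np.nan, p_value=np.nan,
        )
    positive = _pairwise_correlations(groups)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(X.shape[0])
    Xp = X[perm]
    start = 0
    null_groups = []
    for s in sizes:
        null_groups.append(Xp[start : start + s])
        start += s
    null = _pairwise_correlations(null_groups)
    t, p = stats.ttest_ind(positive, null, equal_var=False)
    return ReproducibilityReport(
        positive=positive, null=null, n_skipped=n_skipped,
        t_statistic=float(t), p_value=float(p),
    )


#: Published quality bands for the Z' factor.
ZPRIME_ACCEPTABLE = 0.3
ZPRIME_DESIRABLE = 0.5


def zprime_from_stats(mu_p: float, sd_p: float, mu_n: float, sd_n: float) -> float:
    """Closed-form Z' from control means and standard deviations."""
    if mu_p == mu_n:
        return float("nan")
    return 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)


def zprime(
    positive: np.ndarray | pd.Series, negative: np.ndarray | pd.Series, min_wells: int = 3
) -> tuple[float, str]:
    """Z' factor of a positive/negative control pair, with its quality band.

    Returns (value, band) where band is "desirable" (0.5-1.0),
    "acceptable" (>0.3), or "failing"; identical control means give
    (nan, "undefined").
    """
    p = np.asarray(positive, dtype=float)
    n = np.asarray(negative, dtype=float)
    p, n = p[np.isfinite(p)], n[np.isfinite(n)]
    if p.size < min_wells or n.size < min_wells:
        raise ValueError(f"need >= {min_wells} wells per control arm")
    mu_p, mu_n = p.mean(), n.mean()
    if mu_p == mu_n:
        log.warning("identical control means; Z' undefined")
        return float("nan"), "undefined"
    z = 1.0 - 3.0 * (p.std(ddof=1) + n.std(ddof=1)) / abs(mu_p - mu_n)
    if z >= ZPRIME_DESIRABLE:
        band = "desirable"
    elif z > ZPRIME_ACCEPTABLE:
        band = "acceptable"
    else:
        band = "failing"
    return float(z), band
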