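"""Five-way linear shape classification.

A regularised one-vs-rest linear discriminant (ridge classifier) on
z-standardised registry features assigns every cell to exactly one of the
five reference shapes; ties break by fixed class order.  A multinomial
logistic model is available through the configuration.  Models serialise to
a plain-text key-value artifact and round-trip bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, RidgeClassifier

from .config import ClassifyConfig
from .features.registry import REGISTRY_NAMES, SHAPE_CLASSES

log = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"


@dataclass
class ShapeModel:
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    mean: np.ndarray  # per-feature standardisation mean
    sd: np.ndarray  # per-feature standardisation sd
    coef: np.ndarray  # (n_classes, n_features) on standardised features
    intercept: np.ndarray  # (n_classes,)
    training_accuracy: dict[str, float] | None = None

    def scores(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mean) / self.sd
        return Z @ self.coef.T + self.intercept

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"classes\t{','.join(self.classes)}\n")
            fh.write(f"features\t{','.join(self.feature_names)}\n")
            for key, arr in (
                ("mean", self.mean),
                ("sd", self.sd),
                ("intercept", self.intercept),
            ):
                fh.write(key + "\t" + ",".join(repr(float(v)) for v in arr) + "\n")
            for i, cls in enumerate(self.classes):
                fh.write(
                    f"coef:{cls}\t" + ",".join(repr(float(v)) for v in self.coef[i]) + "\n"
                )

    @classmethod
    def load(cls, path) -> "ShapeModel":
        kv: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                key, val = line.rstrip("\n").split("\t", 1)
                kv[key] = val
        classes = tuple(kv["classes"].split(","))
        feats = tuple(kv["features"].split(","))
        parse = lambda s: np.array([float(v) for v in s.split(",")])  # noqa: E731
        coef = np.vstack([parse(kv[f"coef:{c}"]) for c in classes])
        return cls(
            classes=classes,
            feature_names=feats,
            mean=parse(kv["mean"]),
            sd=parse(kv["sd"]),
            coef=coef,
            intercept=parse(kv["intercept"]),
        )


def _design_matrix(
    table: pd.DataFrame, feature_names: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    X = table[list(feature_names)].to_numpy(dtype=float)
    missing = ~np.isfinite(X)
    return X, missing


def train(
    table: pd.DataFrame,
    labels: pd.Series,
    config: ClassifyConfig | None = None,
    feature_names: tuple[str, ...] | None = None,
    min_per_class: int = 20,
) -> ShapeModel:
    """Fit the shape model on a labelled per-cell feature table.

    Requires every reference class to be present with at least
    ``min_per_class`` cells; constant (degenerate) features are dropped
    with a warning.
    """
    cfg = config or ClassifyConfig()
    feature_names = feature_names or REGISTRY_NAMES
    counts = labels.value_counts()
    missing_classes = [c for c in SHAPE_CLASSES if counts.get(c, 0) < min_per_class]
    if missing_classes:
        raise ValueError(
            f"classes absent or below {min_per_class} cells: {missing_classes}"
        )
    X, miss = _design_matrix(table, feature_names)
    col_mean = np.nanmean(np.where(miss, np.nan, X), axis=0)
    X = np.where(miss, col_mean[None, :], X)
    sd = X.std(axis=0)
    keep = sd > 1e-12
    if not keep.all():
        dropped = [f for f, k in zip(feature_names, keep) if not k]
        log.warning("dropping %d constant features (e.g. %s)", len(dropped), dropped[:3])
    feats = tuple(f for f, k in zip(feature_names, keep) if k)
    X = X[:, keep]
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    Z = (X - mean) / sd
    y = labels.to_numpy()
    if cfg.model == "ridge":
        clf = RidgeClassifier(alpha=cfg.alpha)
    elif cfg.model == "logistic":
        clf = LogisticRegression(C=1.0 / max(cfg.alpha, 1e-12), max_iter=2000)
    else:
        raise ValueError(f"unknown classifier model {cfg.model!r}")
    clf.fit(Z, y)
    # reorder to the canonical class order
    order = [list(clf.classes_).index(c) for c in SHAPE_CLASSES]
    coef = clf.coef_[order]
    intercept = clf.intercept_[order]
    model = ShapeModel(
        classes=SHAPE_CLASSES,
        feature_names=feats,
        mean=mean,
        sd=sd,
        coef=coef,
        intercept=intercept,
    )
    pred = classify(model, table)["shape_class"]
    acc = {
        c: float((pred[y == c] == c).mean()) for c in SHAPE_CLASSES
    }
    acc["overall"] = float((pred.to_numpy() == y).mean())
    model.training_accuracy = acc
    return model


def classify(
    model: ShapeModel,
    table: pd.DataFrame,
    confidence_threshold: float | None = None,
) -> pd.DataFrame:
    """Assign each cell exactly one shape label (argmax of linear scores).

    Missing features are imputed with the training means and the cell is
    flagged.  Ties break toward the earlier class in the canonical order.
    With ``confidence_threshold`` (off by default: every cell is classified
    once), cells whose top score falls below it are labelled unclassified.
    """
    X, miss = _design_matrix(table, model.feature_names)
    X = np.where(miss, model.mean[None, :], X)
    S = model.scores(X)
    idx = np.argmax(S, axis=1)  # first max wins: fixed-order tie-break
    labels = np.array(model.classes)[idx]
    if confidence_threshold is not None:
        labels = np.where(
            S[np.arange(len(idx)), idx] >= confidence_threshold, labels, UNCLASSIFIED
        )
    flagged = miss.any(axis=1)
    out = pd.DataFrame(
        {
            "shape_class": labels,
            "score": S[np.arange(len(idx)), idx],
            "imputed": flagged,
        },
        index=table.index,
    )
    return out


def shape_counts(labels: pd.Series, well: str | None = None) -> pd.Series:
    """Exact per-well tabulation of shape labels, plus proportions."""
    n = len(labels)
    counts = labels.value_counts()
    out: dict[str, float] = {}
    for cls in SHAPE_CLASSES:
        out[f"shape_n_{cls}"] = float(counts.get(cls, 0))
    out["shape_n_unclassified"] = float(counts.get(UNCLASSIFIED, 0))
    total = sum(out.values())
    assert total == n, "shape counts must sum to n_cells"
    for cls in SHAPE_CLASSES:
        out[f"shape_frac_{cls}"] = out[f"shape_n_{cls}"] / n if n else np.nan
    out["n_cells"] = float(n)
    s = pd.Series(out)
    if well is not None:
        s["well"] = well
    return s
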