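"""Cell-type assignment: marker gating, probabilistic classification, fallback.

The labeling strategy mirrors common practice for multiplexed tissue data:

1. confidently gate immune cells with ordered marker-threshold rules
   (CD11b/Ly6G for neutrophils vs other myeloid cells; CD3 with CD8a or CD4
   for T cells);
2. train a regularized multinomial logistic classifier on the gated cells
   (log1p intensities, standardized by training-set statistics);
3. classify the remaining cells, assigning the highest-probability class —
   unless that probability falls below a threshold, in which case the cell
   is labeled a tumor cell (the dominant "none of the above" population).

Gated labels are never overwritten by the classifier.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.linear_model import LogisticRegression

from .synthetic import CELL_TYPES, PANEL

__all__ = [
    "GatePredicate",
    "GateRule",
    "GatingRules",
    "ClassifierModel",
    "default_gating_rules",
    "rules_from_marker_model",
    "gate_cells",
    "train_classifier",
    "classify_ungated",
    "assign_cell_types",
]

UNGATED = "ungated"
TUMOR = "tumor"
GATE_TARGETS = ("neutrophil", "myeloid", "cd8t", "cd4t")


@dataclass(frozen=True)
class GatePredicate:
    marker: str
    comparator: str  # ">=" or "<"
    threshold: float

    def evaluate(self, values: np.ndarray) -> np.ndarray:
        if self.comparator == ">=":
            return values >= self.threshold
        if self.comparator == "<":
            return values < self.threshold
        raise ValueError(f"unknown comparator {self.comparator!r}")


@dataclass(frozen=True)
class GateRule:
    label: str
    predicates: tuple[GatePredicate, ...]


@dataclass
class GatingRules:
    """Ordered gate rules; a cell takes the first matching rule's label."""

    rules: tuple[GateRule, ...]

    def __post_init__(self):
        labels = [r.label for r in self.rules]
        if len(set(labels)) != len(labels):
            raise ValueError("exactly one rule per target label")
        for r in self.rules:
            if r.label not in GATE_TARGETS:
                raise ValueError(f"unknown gate target {r.label!r}")
            for p in r.predicates:
                if p.threshold < 0:
                    raise ValueError("gate thresholds must be >= 0")

    @property
    def markers(self) -> set[str]:
        return {p.marker for r in self.rules for p in r.predicates}

    def to_yaml(self, path) -> None:
        doc = [{"label": r.label,
                "predicates": [{"marker": p.marker, "comparator": p.comparator,
                                "threshold": float(p.threshold)}
                               for p in r.predicates]}
               for r in self.rules]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GatingRules":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(tuple(
            GateRule(label=r["label"],
                     predicates=tuple(GatePredicate(p["marker"], p["comparator"],
                                                    float(p["threshold"]))
                                      for p in r["predicates"]))
            for r in doc))


def rules_from_marker_model(marker_model, hi_type_by_marker=None) -> GatingRules:
    """Derive gate thresholds from a generator-style marker model.

    The threshold for each gate marker is the geometric midpoint between
    its positive and negative populations' log-means.
    """
    def midpoint(marker: str, pos_type: str, neg_type: str) -> float:
        mu_pos = marker_model[marker][pos_type][0]
        mu_neg = marker_model[marker][neg_type][0]
        return math.exp(0.5 * (mu_pos + mu_neg))

    t_cd11b = midpoint("CD11b", "neutrophil", "tumor")
    t_ly6g = midpoint("Ly6G", "neutrophil", "tumor")
    t_cd3 = midpoint("CD3", "cd4t", "tumor")
    t_cd4 = midpoint("CD4", "cd4t", "tumor")
    t_cd8 = midpoint("CD8a", "cd8t", "tumor")
    return GatingRules((
        GateRule("neutrophil", (GatePredicate("CD11b", ">=", t_cd11b),
                                GatePredicate("Ly6G", ">=", t_ly6g))),
        GateRule("myeloid", (GatePredicate("CD11b", ">=", t_cd11b),
                             GatePredicate("Ly6G", "<", t_ly6g))),
        GateRule("cd8t", (GatePredicate("CD3", ">=", t_cd3),
                          GatePredicate("CD8a", ">=", t_cd8))),
        GateRule("cd4t", (GatePredicate("CD3", ">=", t_cd3),
                          GatePredicate("CD4", ">=", t_cd4))),
    ))


def default_gating_rules() -> GatingRules:
    from .synthetic import default_marker_model
    return rules_from_marker_model(default_marker_model())


def tumor_seed_threshold_from_model(marker_model,
                                    marker: str = "E-Cadherin") -> float:
    """Epithelial-marker threshold for seeding tumor-candidate training cells.

    Geometric midpoint between the tumor-positive and immune-negative
    log-means of the marker (by default E-Cadherin, the panel's epithelial
    marker).
    """
    mu_pos = marker_model[marker]["tumor"][0]
    mu_neg = marker_model[marker]["myeloid"][0]
    return math.exp(0.5 * (mu_pos + mu_neg))


def gate_cells(cells: pd.DataFrame, rules: GatingRules) -> pd.Series:
    """Apply ordered gates; cells matching no rule are ``"ungated"``."""
    missing = rules.markers - set(cells.columns)
    if missing:
        raise KeyError(f"missing marker columns: {sorted(missing)}")
    labels = pd.Series(UNGATED, index=cells.index, dtype=object, name="gated_label")
    unassigned = np.ones(len(cells), dtype=bool)
    for rule in rules.rules:
        match = np.ones(len(cells), dtype=bool)
        for p in rule.predicates:
            match &= p.evaluate(cells[p.marker].to_numpy())
        hit = match & unassigned
        labels.iloc[np.flatnonzero(hit)] = rule.label
        unassigned &= ~match
    return labels


@dataclass
class ClassifierModel:
    """Multinomial logistic classifier on standardized log1p intensities.

    Parameters are stored explicitly so the model can be serialized to JSON
    and evaluated without the fitting library.
    """

    features: tuple[str, ...]
    classes: tuple[str, ...]
    coef: np.ndarray            # (n_classes, n_features)
    intercept: np.ndarray       # (n_classes,)
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    seed: int
    probability_threshold: float
    regularization_c: float = 1.0
    version: str = "1"

    def _design(self, cells: pd.DataFrame) -> np.ndarray:
        missing = set(self.features) - set(cells.columns)
        if missing:
            raise KeyError(f"feature columns missing from table: {sorted(missing)}")
        x = np.log1p(cells.loc[:, list(self.features)].to_numpy(dtype=float))
        return (x - self.scaler_mean) / self.scaler_scale

    def predict_proba(self, cells: pd.DataFrame) -> pd.DataFrame:
        z = self._design(cells) @ self.coef.T + self.intercept
        z -= z.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        return pd.DataFrame(p, index=cells.index, columns=list(self.classes))

    def to_json(self, path) -> None:
        doc = {
            "version": self.version,
            "features": list(self.features),
            "classes": list(self.classes),
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "seed": self.seed,
            "probability_threshold": self.probability_threshold,
            "regularization_c": self.regularization_c,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(features=tuple(doc["features"]), classes=tuple(doc["classes"]),
                   coef=np.array(doc["coef"]), intercept=np.array(doc["intercept"]),
                   scaler_mean=np.array(doc["scaler_mean"]),
                   scaler_scale=np.array(doc["scaler_scale"]),
                   seed=int(doc["seed"]),
                   probability_threshold=float(doc["probability_threshold"]),
                   regularization_c=float(doc.get("regularization_c", 1.0)),
                   version=str(doc.get("version", "1")))


def train_classifier(cells: pd.DataFrame, labels: pd.Series,
                     features=None, seed: int = 0,
                     probability_threshold: float = 0.5,
                     regularization_c: float = 1.0) -> ClassifierModel:
    """Fit the multinomial classifier on gated (confidently labeled) cells.

    Requires at least two classes with >= 5 cells each.  Deterministic for
    fixed inputs and seed (L-BFGS on a convex objective; the seed is
    recorded for provenance).
    """
    if features is None:
        features = [c for c in cells.columns if c in PANEL]
    labels = labels.astype(str)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need >= 2 classes to train")
    small = counts[counts < 5]
    if len(small):
        raise ValueError(f"classes with < 5 cells: {dict(small)}")
    if not 0 < probability_threshold <= 1:
        raise ValueError("probability_threshold must be in (0, 1]")

    x = np.log1p(cells.loc[:, list(features)].to_numpy(dtype=float))
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    xs = (x - mean) / scale
    classes = tuple(sorted(counts.index))
    clf = LogisticRegression(C=regularization_c, max_iter=2000,
                             random_state=seed)
    clf.fit(xs, labels.to_numpy())
    # sklearn orders classes lexicographically already; assert and keep
    assert tuple(clf.classes_) == classes
    coef, intercept = clf.coef_, clf.intercept_
    if coef.shape[0] == 1:  # binary case: expand to per-class rows
        coef = np.vstack([-coef[0], coef[0]])
        intercept = np.array([-intercept[0], intercept[0]])
    return ClassifierModel(features=tuple(features), classes=classes,
                           coef=coef, intercept=intercept,
                           scaler_mean=mean, scaler_scale=scale,
                           seed=seed, probability_threshold=probability_threshold,
                           regularization_c=regularization_c)


def classify_ungated(model: ClassifierModel, cells: pd.DataFrame) -> pd.Series:
    """Label ungated cells: argmax class, or tumor if max probability is low.

    Probability ties are broken by the fixed (alphabetical) class order.
    """
    if len(cells) == 0:
        return pd.Series(dtype=object, name="final_label")
    proba = model.predict_proba(cells)
    best = proba.to_numpy().argmax(axis=1)  # first (alphabetical) wins ties
    maxp = proba.to_numpy()[np.arange(len(proba)), best]
    labels = np.array([model.classes[i] for i in best], dtype=object)
    labels[maxp < model.probability_threshold] = TUMOR
    return pd.Series(labels, index=cells.index, name="final_label")


def assign_cell_types(cells: pd.DataFrame, rules: GatingRules | None = None,
                      seed: int = 0, probability_threshold: float = 0.5,
                      regularization_c: float = 1.0,
                      features=None,
                      tumor_seed_marker: str | None = "E-Cadherin",
                      tumor_seed_threshold: float | None = None):
    """Full labeling pipeline: gate, train on gated, classify the rest.

    A discriminative classifier trained only on the gated immune classes
    cannot recognize "none of the above" cells — far from every class, its
    softmax still commits confidently to one of them.  The training set is
    therefore seeded with high-confidence tumor candidates: ungated cells
    whose epithelial marker (``tumor_seed_marker``) exceeds a threshold
    (positive/negative midpoint of the default marker model when not
    given).  The low-probability fallback to tumor remains in force for
    genuinely ambiguous cells.  Set ``tumor_seed_marker=None`` for the pure
    immune-class classifier with fallback only.

    Returns ``(final_labels, gated_labels, model)``; ``final_labels`` has
    exactly one label per cell and never overwrites a gated label.
    """
    if rules is None:
        rules = default_gating_rules()
    gated = gate_cells(cells, rules)
    final = gated.copy().rename("final_label")
    is_gated = gated != UNGATED
    train_labels = gated.loc[is_gated]
    train_cells = cells.loc[is_gated]
    if tumor_seed_marker is not None:
        if tumor_seed_threshold is None:
            from .synthetic import default_marker_model
            tumor_seed_threshold = tumor_seed_threshold_from_model(
                default_marker_model(), tumor_seed_marker)
        candidate = (~is_gated) & (cells[tumor_seed_marker] >= tumor_seed_threshold)
        if candidate.sum() >= 5:
            train_cells = pd.concat([train_cells, cells.loc[candidate]])
            train_labels = pd.concat([train_labels,
                                      pd.Series(TUMOR, index=cells.index[candidate])])
    model = train_classifier(train_cells, train_labels,
                             features=features, seed=seed,
                             probability_threshold=probability_threshold,
                             regularization_c=regularization_c)
    if (~is_gated).any():
        final.loc[~is_gated] = classify_ungated(model, cells.loc[~is_gated])
    return final, gated, model
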