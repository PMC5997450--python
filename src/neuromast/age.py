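"""Post-mitotic age classification of hair cells.

Hair cells pass through three behaviourally distinct stages after the
division that produces them: 0-5 h (anteroposterior rearrangement of the
sibling pair), 5-15 h (dynamic basal projections seeking innervation), and
>15 h (ribbon synaptogenesis essentially complete).  Specimens without
long time-lapse preimaging lack direct age information, so ages are
assigned from four morphometric features — total traced membrane area,
cell volume, total ribbon-synapse volume, and apical surface area — by a
classification tree trained on the preimaged cells (70 % train / 30 %
test, random split).

The tree is a plain binary CART with axis-aligned thresholds minimizing
Gini impurity, implemented here directly so the trained model is fully
inspectable and serializable to JSON.  Training is deterministic given the
data, the split seed and the hyperparameters; only the train/test split is
randomized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import GeometryConfig, apical_contact_area
from .model import HairCell, NeuromastConnectome

FEATURE_NAMES = ("cell_area", "cell_volume", "ribbon_volume_total",
                 "apical_contact_area")


@dataclass
class AgeFeatures:
    cell_area: float              # nm^2, traced membrane area
    cell_volume: float            # nm^3, sum of polygon areas x thickness
    ribbon_volume_total: float    # nm^3; 0 for nascent cells
    apical_contact_area: float    # nm^2 at the epithelial surface

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


def extract_features(haircell: HairCell | str, conn: NeuromastConnectome,
                     geometry_config: GeometryConfig | None = None) -> AgeFeatures:
    """Morphometric features of one traced hair cell.

    Volume is the per-section polygon area integrated over the section
    thickness; membrane area is the perimeter integrated the same way.
    """
    config = geometry_config or GeometryConfig()
    cid = haircell if isinstance(haircell, str) else haircell.cell_id
    traces = conn.traces.get(cid)
    if not traces:
        raise ValueError(f"cell {cid} has no contour traces")
    thickness = config.section_thickness
    cell_area = sum(tr.perimeter for tr in traces) * thickness
    cell_volume = sum(tr.area for tr in traces) * thickness
    ribbon_volume = sum(r.volume_nm3 for r in conn.ribbons_of_cell(cid))
    apical = apical_contact_area(cid, conn, config)
    return AgeFeatures(cell_area, cell_volume, ribbon_volume, apical)


# ---------------------------------------------------------------------------
# CART
# ---------------------------------------------------------------------------

def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p * p).sum())


def _best_split(X: np.ndarray, y: np.ndarray, n_classes: int,
                min_leaf: int) -> tuple[int, float] | None:
    """Best (feature, threshold) by weighted Gini; deterministic tie-break on
    lowest feature index then lowest threshold."""
    n, d = X.shape
    parent_counts = np.bincount(y, minlength=n_classes)
    best = None
    best_score = _gini(parent_counts) - 1e-12  # must strictly improve
    for f in range(d):
        order = np.argsort(X[:, f], kind="stable")
        xs, ys = X[order, f], y[order]
        left = np.zeros(n_classes, dtype=float)
        right = parent_counts.astype(float).copy()
        for i in range(n - 1):
            left[ys[i]] += 1
            right[ys[i]] -= 1
            if xs[i] == xs[i + 1]:
                continue
            nl, nr = i + 1, n - i - 1
            if nl < min_leaf or nr < min_leaf:
                continue
            score = (nl * _gini(left) + nr * _gini(right)) / n
            if score < best_score - 1e-12:
                best_score = score
                best = (f, float((xs[i] + xs[i + 1]) / 2.0))
    return best


def _grow(X: np.ndarray, y: np.ndarray, n_classes: int, depth: int,
          max_depth: int, min_leaf: int) -> dict:
    counts = np.bincount(y, minlength=n_classes)
    leaf = {"leaf": True, "class": int(np.argmax(counts)),
            "counts": counts.tolist()}
    if depth >= max_depth or len(y) < 2 * min_leaf or counts.max() == len(y):
        return leaf
    split = _best_split(X, y, n_classes, min_leaf)
    if split is None:
        return leaf
    f, thr = split
    mask = X[:, f] <= thr
    return {"leaf": False, "feature": int(f), "threshold": thr,
            "counts": counts.tolist(),
            "left": _grow(X[mask], y[mask], n_classes, depth + 1, max_depth, min_leaf),
            "right": _grow(X[~mask], y[~mask], n_classes, depth + 1, max_depth, min_leaf)}


@dataclass
class AgeModel:
    """A trained classification tree plus its label vocabulary."""

    tree: dict
    classes: list[str]
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    max_depth: int = 3
    min_leaf: int = 3
    split_fraction: float = 0.7
    seed: int = 0
    test_accuracy: float = float("nan")

    def _predict_row(self, x: np.ndarray) -> int:
        node = self.tree
        while not node["leaf"]:
            node = node["left"] if x[node["feature"]] <= node["threshold"] else node["right"]
        return node["class"]

    def predict(self, X: np.ndarray | Sequence[Sequence[float]]) -> list[str]:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return [self.classes[self._predict_row(row)] for row in X]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"tree": self.tree, "classes": self.classes,
                   "feature_names": self.feature_names,
                   "max_depth": self.max_depth, "min_leaf": self.min_leaf,
                   "split_fraction": self.split_fraction, "seed": self.seed,
                   "test_accuracy": self.test_accuracy}
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AgeModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(tree=payload["tree"], classes=payload["classes"],
                   feature_names=payload["feature_names"],
                   max_depth=payload["max_depth"], min_leaf=payload["min_leaf"],
                   split_fraction=payload["split_fraction"], seed=payload["seed"],
                   test_accuracy=payload["test_accuracy"])


def train_tree(features: np.ndarray | Sequence[AgeFeatures],
               labels: Sequence[str],
               split_fraction: float = 0.7, seed: int = 0,
               max_depth: int = 3, min_leaf: int = 3) -> AgeModel:
    """Train a CART age classifier with a random train/test split.

    The split (``split_fraction`` of cells to training, stratification-free
    as in small-cohort practice) is the only randomized step.  Raises if
    any class present in the labels is absent from the training split.
    """
    if isinstance(features, (list, tuple)) and features and isinstance(features[0], AgeFeatures):
        X = np.vstack([f.as_array() for f in features])
    else:
        X = np.asarray(features, dtype=float)
    labels = list(labels)
    if len(labels) != len(X):
        raise ValueError("features and labels disagree in length")
    classes = sorted(set(labels))
    y = np.array([classes.index(l) for l in labels])

    rng = np.random.default_rng(seed)
    n = len(y)
    n_train = max(int(round(split_fraction * n)), 1)
    perm = rng.permutation(n)
    train_idx, test_idx = perm[:n_train], perm[n_train:]

    train_classes = set(y[train_idx].tolist())
    missing = [classes[c] for c in range(len(classes)) if c not in train_classes]
    if missing:
        raise ValueError(f"classes absent from training split: {missing}")

    tree = _grow(X[train_idx], y[train_idx], len(classes), 0, max_depth, min_leaf)
    model = AgeModel(tree=tree, classes=classes, max_depth=max_depth,
                     min_leaf=min_leaf, split_fraction=split_fraction, seed=seed)
    if len(test_idx):
        pred = model.predict(X[test_idx])
        truth = [classes[c] for c in y[test_idx]]
        model.test_accuracy = float(np.mean([p == t for p, t in zip(pred, truth)]))
    return model


def predict_age_class(model: AgeModel,
                      features: AgeFeatures | np.ndarray | Sequence[float]) -> str:
    """Deterministic class for one cell's features."""
    x = features.as_array() if isinstance(features, AgeFeatures) else np.asarray(features, float)
    return model.predict(x[None, :])[0]


def classify_unaged_cells(conn: NeuromastConnectome, model: AgeModel,
                          geometry_config: GeometryConfig | None = None) -> dict[str, str]:
    """Assign age classes to cells lacking preimaging; sets age_source."""
    out: dict[str, str] = {}
    for hc in conn.haircells.values():
        if hc.age_class != "unknown":
            continue
        feats = extract_features(hc, conn, geometry_config)
        hc.age_class = predict_age_class(model, feats)
        hc.age_source = "classified"
        out[hc.cell_id] = hc.age_class
    return out
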