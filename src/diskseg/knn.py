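"""Supervised k-nearest-neighbour labelling of candidate regions.

Separates true intervertebral-disk regions from the over-segmentation
background (vertebral bodies, soft tissue) using the eight texture features.
Features are z-standardized with the training set's location/scale; queries
use Euclidean distance in the standardized space and an odd ``k`` so a
majority vote can never tie.  Distance ties are broken by training-row
order, which makes classification fully deterministic.

Classification applies to sagittal regions only — coronal candidates are
matched later by anatomical (centroid) correspondence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence

import numpy as np

from .features import FEATURE_NAMES, feature_matrix
from .volume import Region2D

DISK = "disk"
BACKGROUND = "background"


@dataclass
class KnnModel:
    """Frozen training state of the classifier."""

    training_features: np.ndarray  # standardized, (n, 8)
    training_labels: List[str]
    k: int
    loc: np.ndarray = field(default_factory=lambda: np.zeros(len(FEATURE_NAMES)))
    scale: np.ndarray = field(default_factory=lambda: np.ones(len(FEATURE_NAMES)))

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.loc) / self.scale

    def predict(self, X: np.ndarray) -> List[str]:
        """Majority-vote labels for raw (unstandardized) feature rows."""
        Z = self.standardize(np.atleast_2d(X))
        out: List[str] = []
        labels = np.asarray(self.training_labels)
        for z in Z:
            d = np.linalg.norm(self.training_features - z, axis=1)
            order = np.argsort(d, kind="stable")[: self.k]  # ties: row order
            votes = labels[order]
            disk_votes = int(np.sum(votes == DISK))
            out.append(DISK if disk_votes * 2 > self.k else BACKGROUND)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "feature_names": list(FEATURE_NAMES),
                "loc": self.loc.tolist(),
                "scale": self.scale.tolist(),
                "training_features": self.training_features.tolist(),
                "training_labels": list(self.training_labels),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "KnnModel":
        d = json.loads(text)
        return cls(
            training_features=np.asarray(d["training_features"], dtype=float),
            training_labels=list(d["training_labels"]),
            k=int(d["k"]),
            loc=np.asarray(d["loc"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
        )


def train_knn_arrays(X: np.ndarray, labels: Sequence[str], k: int) -> KnnModel:
    """Train from a raw feature matrix and label list."""
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    if k < 1 or k % 2 == 0:
        raise ValueError("k must be an odd positive integer")
    if k > len(labels):
        raise ValueError("k cannot exceed the number of training samples")
    classes = set(labels)
    if not {DISK, BACKGROUND} <= classes or len(classes) != 2:
        raise ValueError("training set must contain both 'disk' and 'background'")
    loc = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)  # constant features pass through
    return KnnModel(
        training_features=(X - loc) / scale,
        training_labels=labels,
        k=k,
        loc=loc,
        scale=scale,
    )


def train_knn(regions: Iterable[Region2D], k: int = 5) -> KnnModel:
    """Train from labeled regions whose features are already computed."""
    regions = list(regions)
    X = feature_matrix(regions)
    return train_knn_arrays(X, [r.label for r in regions], k)


def classify_regions(model: KnnModel, regions: Iterable[Region2D]) -> List[Region2D]:
    """Set ``label`` on each region from its feature vector.  In place."""
    regions = list(regions)
    if not regions:
        return regions
    X = feature_matrix(regions)
    for region, label in zip(regions, model.predict(X)):
        region.label = label
    return regions
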