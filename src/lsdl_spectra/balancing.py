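"""SMOTE oversampling of the feature table to stated per-class targets.

Synthetic rows are convex combinations ``x + u * (x_nn - x)`` with
``u ~ Uniform(0, 1)`` between a real class member and one of its k nearest
same-class neighbors (Euclidean distance in feature space). Real rows are
never modified or removed; synthetic rows are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .errors import ValidationError
from .features import FeatureMatrix

__all__ = ["BalanceSpec", "smote_balance"]


@dataclass(frozen=True)
class BalanceSpec:
    k_neighbors: int = 5
    target_per_class: int | str = "majority"
    seed: int = 0

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValidationError("k_neighbors must be >= 1")
        if isinstance(self.target_per_class, str) and self.target_per_class != "majority":
            raise ValidationError("target_per_class must be an int or 'majority'")


def smote_balance(features: FeatureMatrix, spec: BalanceSpec) -> FeatureMatrix:
    """Oversample each class up to the target count.

    ``target_per_class='majority'`` raises every class to the largest real
    class size; an integer target may exceed the majority size (both classes
    are then oversampled). Targets below an existing class size are rejected
    — no undersampling.
    """
    if not np.all(np.isfinite(features.X)):
        raise ValidationError("feature matrix contains missing values; SMOTE "
                              "requires complete numeric rows")
    labels = features.labels.astype(str)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValidationError(f"SMOTE here expects binary labels, got {list(classes)}")
    target = (
        int(counts.max())
        if spec.target_per_class == "majority"
        else int(spec.target_per_class)
    )
    for cls, cnt in zip(classes, counts):
        if target < cnt:
            raise ValidationError(
                f"target {target} below existing size {cnt} of class {cls!r}; "
                "undersampling is not supported"
            )

    rng = np.random.default_rng(spec.seed)
    new_rows, new_labels, new_ids = [], [], []
    for cls, cnt in zip(classes, counts):
        n_new = target - int(cnt)
        if n_new == 0:
            continue
        if cnt < spec.k_neighbors + 1:
            raise ValidationError(
                f"class {cls!r} has {cnt} samples, fewer than k_neighbors+1="
                f"{spec.k_neighbors + 1}; use a smaller k_neighbors"
            )
        rows = features.X[labels == cls]
        nn = NearestNeighbors(n_neighbors=spec.k_neighbors + 1).fit(rows)
        # drop the self-neighbor in column 0
        neigh = nn.kneighbors(rows, return_distance=False)[:, 1:]
        base_idx = rng.integers(0, len(rows), size=n_new)
        pick = rng.integers(0, spec.k_neighbors, size=n_new)
        u = rng.uniform(0.0, 1.0, size=n_new)
        for j, (bi, pj, uj) in enumerate(zip(base_idx, pick, u)):
            x = rows[bi]
            x_nn = rows[neigh[bi, pj]]
            new_rows.append(x + uj * (x_nn - x))
            new_labels.append(cls)
            new_ids.append(f"smote-{cls}-{j:03d}")

    if not new_rows:
        return features
    X = np.vstack([features.X, np.vstack(new_rows)])
    return FeatureMatrix(
        X=X,
        feature_names=features.feature_names,
        labels=np.concatenate([features.labels, np.array(new_labels, dtype=object)]),
        sample_ids=np.concatenate([features.sample_ids, np.array(new_ids, dtype=object)]),
        is_synthetic=np.concatenate(
            [features.is_synthetic, np.ones(len(new_rows), dtype=bool)]
        ),
    )
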