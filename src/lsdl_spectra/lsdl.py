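"""Amplitude-threshold series decomposition with an embedded threshold learner.

A *scheme* is a direction (``upper``/``lower``) plus an amplitude level; the
decomposition of a signal retains exactly the samples on the scheme's side of
the level, in original order. The learner scans candidate levels on a
coarse-to-fine grid, scoring each by a normalized Euclidean distance between
the two class centroids in feature space, and keeps the global argmax. The
learned scheme is then applied uniformly to every signal from the same source.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateInputError, SearchFailureError, ValidationError
from .features import FeatureConfig, FeatureMatrix, extract_features
from .spectra_io import SpectraDataset, Spectrum

logger = logging.getLogger(__name__)

DIRECTIONS = ("upper", "lower")

__all__ = [
    "ThresholdScheme",
    "SubSignal",
    "ClassSeparationStats",
    "Candidate",
    "LSDLModel",
    "decompose",
    "performance_index",
    "threshold_search",
    "apply_model",
    "permutation_null_max_j",
]


@dataclass(frozen=True)
class ThresholdScheme:
    """Direction + amplitude level defining one amplitude band."""

    direction: str
    level: float
    iteration: int = 1

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"direction must be one of {DIRECTIONS}")
        if not np.isfinite(self.level):
            raise ValidationError("threshold level must be finite")
        if self.iteration < 1:
            raise ValidationError("iteration index starts at 1")


@dataclass
class SubSignal:
    """Samples of one signal retained by a threshold scheme, order preserved."""

    parent_id: str
    retained: np.ndarray
    scheme: ThresholdScheme | None = None
    meets_min: bool = True

    def __post_init__(self):
        self.retained = np.asarray(self.retained, dtype=float).ravel()

    @property
    def retained_count(self) -> int:
        return int(self.retained.size)

    def __len__(self) -> int:
        return self.retained_count


@dataclass
class ClassSeparationStats:
    """Normalized Euclidean distance between class centroids.

    ``j = ed / sigma_m`` where ``ed`` is the Euclidean distance between the
    per-class centroids of the (pooled-standardized) feature matrix and
    ``sigma_m`` is the mean per-feature standard deviation of the pooled data.
    """

    p: np.ndarray
    q: np.ndarray
    per_feature_sd: np.ndarray
    sigma_m: float
    ed: float
    j: float


@dataclass
class Candidate:
    """One evaluated (direction, iteration, level) during the search."""

    direction: str
    iteration: int
    level: float
    j: float | None
    reason: str | None = None  # set when j is None ("n/a")

    @property
    def feasible(self) -> bool:
        return self.j is not None


@dataclass
class LSDLModel:
    """Learned decomposition parameters for one signal source."""

    scheme: ThresholdScheme
    candidates: list[Candidate]
    min_samples: int
    feature_config_id: str
    # transient cache used by the permutation null; never serialized
    candidate_features: dict | None = field(default=None, repr=False)

    def search_table(self) -> dict[str, list[dict]]:
        """Per-direction, per-iteration best level and J ('n/a' when absent)."""
        table: dict[str, list[dict]] = {}
        iterations = sorted({c.iteration for c in self.candidates})
        for direction in DIRECTIONS:
            rows = []
            for it in iterations:
                cands = [
                    c
                    for c in self.candidates
                    if c.direction == direction and c.iteration == it and c.feasible
                ]
                if cands:
                    best = max(cands, key=lambda c: c.j)
                    rows.append(
                        {"iteration": it, "level": best.level, "j": best.j}
                    )
                else:
                    reasons = {
                        c.reason
                        for c in self.candidates
                        if c.direction == direction and c.iteration == it
                    }
                    rows.append(
                        {
                            "iteration": it,
                            "level": "n/a",
                            "j": "n/a",
                            "reason": "; ".join(sorted(r for r in reasons if r))
                            or "no feasible candidate",
                        }
                    )
            table[direction] = rows
        return table

    def to_dict(self) -> dict:
        return {
            "scheme": {
                "direction": self.scheme.direction,
                "level": self.scheme.level,
                "iteration": self.scheme.iteration,
            },
            "min_samples": self.min_samples,
            "feature_config_id": self.feature_config_id,
            "search_table": self.search_table(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "LSDLModel":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        scheme = ThresholdScheme(**doc["scheme"])
        return cls(
            scheme=scheme,
            candidates=[Candidate(scheme.direction, scheme.iteration, scheme.level, 0.0)],
            min_samples=int(doc["min_samples"]),
            feature_config_id=doc["feature_config_id"],
        )


# ---------------------------------------------------------------------------


def decompose(signal: Spectrum | np.ndarray, scheme: ThresholdScheme) -> SubSignal:
    """Retain the samples on the scheme's side of the level (order kept)."""
    if hasattr(signal, "intensities"):
        x = signal.intensities
        pid = signal.sample_id
    else:
        x = np.asarray(signal, dtype=float).ravel()
        pid = "array"
    if scheme.direction == "upper":
        mask = x >= scheme.level
    else:
        mask = x <= scheme.level
    return SubSignal(parent_id=pid, retained=x[mask], scheme=scheme)


def performance_index(
    features_a: np.ndarray, features_b: np.ndarray
) -> ClassSeparationStats:
    """Normalized Euclidean distance between two class centroids.

    Each feature column is standardized to zero mean / unit variance on the
    pooled two-class data (n-1 convention) before centroids are taken, so the
    index is invariant to per-feature scaling.
    """
    a = np.atleast_2d(np.asarray(features_a, dtype=float))
    b = np.atleast_2d(np.asarray(features_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValidationError("feature matrices must share columns")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValidationError("need at least 2 samples per class")
    pooled = np.vstack([a, b])
    if not np.all(np.isfinite(pooled)):
        raise DegenerateInputError("non-finite feature values")
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=1)
    if np.any(sd == 0):
        dead = [str(i) for i in np.flatnonzero(sd == 0)]
        raise DegenerateInputError(
            f"constant feature column(s) {','.join(dead)}: index undefined"
        )
    za = (a - mu) / sd
    zb = (b - mu) / sd
    zpooled = np.vstack([za, zb])
    p = za.mean(axis=0)
    q = zb.mean(axis=0)
    per_feature_sd = zpooled.std(axis=0, ddof=1)
    sigma_m = float(per_feature_sd.mean())
    ed = float(np.linalg.norm(p - q))
    return ClassSeparationStats(
        p=p, q=q, per_feature_sd=per_feature_sd, sigma_m=sigma_m, ed=ed, j=ed / sigma_m
    )


# ---------------------------------------------------------------------------
# threshold search
# ---------------------------------------------------------------------------


def _retained_counts(sorted_rows: list[np.ndarray], direction: str, level: float) -> np.ndarray:
    # sorted_rows[i] is spectrum i's intensities sorted ascending
    counts = np.empty(len(sorted_rows), dtype=int)
    for i, sx in enumerate(sorted_rows):
        k = np.searchsorted(sx, level, side="left")
        counts[i] = sx.size - k if direction == "upper" else np.searchsorted(
            sx, level, side="right"
        )
    return counts


def _class_split(labels: Sequence[str]) -> tuple[str, str]:
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValidationError(f"need exactly two classes, got {uniq}")
    return uniq[0], uniq[1]


def _evaluate_candidate(
    dataset: SpectraDataset,
    direction: str,
    level: float,
    iteration: int,
    config: FeatureConfig,
    min_samples: int,
    sorted_rows: list[np.ndarray],
    cache: dict,
) -> Candidate:
    counts = _retained_counts(sorted_rows, direction, level)
    if counts.min() < min_samples:
        return Candidate(
            direction,
            iteration,
            level,
            None,
            reason=f"insufficient samples (min retained {int(counts.min())} < {min_samples})",
        )
    key = (direction, round(float(level), 12))
    if key in cache:
        feats = cache[key]
    else:
        scheme = ThresholdScheme(direction, level, iteration)
        rows = []
        for s in dataset:
            sub = decompose(s, scheme)
            fv = extract_features(sub, config)
            if fv.missing:
                return Candidate(
                    direction,
                    iteration,
                    level,
                    None,
                    reason=f"degenerate feature(s) {sorted(fv.missing)} in {s.sample_id}",
                )
            rows.append(fv.as_array())
        feats = np.vstack(rows)
        cache[key] = feats
    la, lb = _class_split([s.label for s in dataset])
    labels = np.array([s.label for s in dataset])
    try:
        stats = performance_index(feats[labels == la], feats[labels == lb])
    except DegenerateInputError as exc:
        return Candidate(direction, iteration, level, None, reason=str(exc))
    return Candidate(direction, iteration, level, stats.j)


def threshold_search(
    training: SpectraDataset,
    feature_config: FeatureConfig | None = None,
    n_iterations: int = 4,
    levels_per_iteration: int = 16,
    min_samples: int = 8,
    keep_features: bool = False,
) -> LSDLModel:
    """Coarse-to-fine scan of amplitude levels maximizing the performance index.

    Iteration 1 scans ``levels_per_iteration`` equally spaced levels across
    the pooled amplitude range for each direction; each later iteration
    re-scans an interval of half the previous width centered on that
    direction's incumbent best level. Candidates leaving any signal with
    fewer than ``min_samples`` retained are recorded "n/a". Ties in J break
    toward the lower iteration, then toward ``upper``.
    """
    if feature_config is None:
        feature_config = FeatureConfig(reduced_after_lsdl=True)
    if len(training) < 4:
        raise ValidationError("threshold search needs at least 4 training spectra")
    _class_split([s.label for s in training])  # validates two classes
    mat = training.intensity_matrix()
    lo, hi = float(mat.min()), float(mat.max())
    if hi <= lo:
        raise ValidationError("degenerate amplitude range")
    sorted_rows = [np.sort(s.intensities) for s in training]
    cache: dict = {}
    candidates: list[Candidate] = []

    for direction in DIRECTIONS:
        incumbent: Candidate | None = None
        for it in range(1, n_iterations + 1):
            if it == 1:
                levels = np.linspace(lo, hi, levels_per_iteration)
            else:
                if incumbent is None:
                    break  # nothing to refine around; earlier n/a rows stand
                width = (hi - lo) / (2 ** (it - 1))
                center = incumbent.level
                levels = np.linspace(
                    max(lo, center - width / 2), min(hi, center + width / 2),
                    levels_per_iteration,
                )
            for level in levels:
                cand = _evaluate_candidate(
                    training, direction, float(level), it, feature_config,
                    min_samples, sorted_rows, cache,
                )
                candidates.append(cand)
                if cand.feasible and (incumbent is None or cand.j > incumbent.j):
                    incumbent = cand

    feasible = [c for c in candidates if c.feasible]
    if not feasible:
        raise SearchFailureError(
            f"no candidate level left every signal with >= {min_samples} samples"
        )
    # argmax J; ties -> lower iteration, then 'upper' first
    best = max(
        feasible,
        key=lambda c: (c.j, -c.iteration, c.direction == "upper"),
    )
    model = LSDLModel(
        scheme=ThresholdScheme(best.direction, best.level, best.iteration),
        candidates=candidates,
        min_samples=min_samples,
        feature_config_id=feature_config.config_id,
    )
    if keep_features:
        model.candidate_features = {
            "cache": cache,
            "labels": np.array([s.label for s in training]),
            "levels": [(c.direction, round(float(c.level), 12)) for c in feasible],
        }
    return model


def apply_model(
    model: LSDLModel, dataset: SpectraDataset | Iterable[Spectrum]
) -> list[SubSignal]:
    """Decompose every spectrum with the learned scheme (order preserved)."""
    subs: list[SubSignal] = []
    n_flagged = 0
    for s in dataset:
        sub = decompose(s, model.scheme)
        if sub.retained_count < model.min_samples:
            sub.meets_min = False
            n_flagged += 1
        subs.append(sub)
    if n_flagged:
        logger.warning(
            "%d/%d signals retained fewer than min_samples=%d under the learned "
            "scheme and are flagged for downstream exclusion",
            n_flagged, len(subs), model.min_samples,
        )
    return subs


def permutation_null_max_j(
    model: LSDLModel, n_permutations: int = 200, seed: int = 0
) -> tuple[float, np.ndarray, float]:
    """Permutation calibration of the search's best J.

    Re-uses the candidate feature matrices cached during a
    ``threshold_search(..., keep_features=True)`` run (features do not depend
    on labels, so only the index needs recomputation) and returns

    ``(observed_max_j, null_max_j_distribution, p_value)``

    where the null distribution is the max-over-candidates J under label
    permutation — a maxT-style correction for scanning many levels.
    """
    if not model.candidate_features:
        raise ValidationError("run threshold_search with keep_features=True first")
    cache = model.candidate_features["cache"]
    labels = model.candidate_features["labels"]
    keys = sorted(set(model.candidate_features["levels"]))
    la, lb = _class_split(list(labels))

    def max_j(lbls: np.ndarray) -> float:
        best = 0.0
        for key in keys:
            feats = cache[key]
            try:
                stats = performance_index(feats[lbls == la], feats[lbls == lb])
            except DegenerateInputError:
                continue
            best = max(best, stats.j)
        return best

    observed = max_j(labels)
    rng = np.random.default_rng(seed)
    null = np.array(
        [max_j(rng.permutation(labels)) for _ in range(n_permutations)]
    )
    p = float((1 + np.sum(null >= observed)) / (1 + n_permutations))
    return observed, null, p
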