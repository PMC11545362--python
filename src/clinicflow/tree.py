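"""Attendance-risk model: entropy, information gain and a decision tree.

The tree is induced from scratch by greedy recursive partitioning on
categorical (or pre-binned numeric) patient features — age bracket,
gender, district, travel-time bin, past-behaviour bin — choosing at each
node the feature with maximal information gain

    IG(D, f) = H(labels of D) - sum_v |D_v|/|D| * H(labels of D_v)

where ``H`` is Shannon entropy in bits and ``D_v`` the rows with feature
value ``v``. Categorical features split multiway, one child per observed
value. Interpretability is the point: shallow trees with explicit
if-else paths, not an ensemble.

Leaf class frequencies are Laplace-smoothed (+1 per class) at prediction
time so no probability is ever exactly zero and downstream risk ranking
has a strict order. Ties between equally informative features break by
schema order, making fitted trees reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .domain import PatientProfile
from .errors import FitError, SchemaError, UndefinedEntropyError, UpdateError

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSES_3",
    "CLASSES_BINARY",
    "LabeledDataset",
    "RiskProfile",
    "TreeNode",
    "NoShowModel",
    "entropy",
    "information_gain",
    "fit_tree",
    "predict_risk",
    "incremental_update",
    "build_training_data",
    "profile_features",
]

#: Default label set: cancellations and no-shows are distinct outcomes.
CLASSES_3: tuple[str, ...] = ("realized", "canceled", "no_show")
#: Binarized alternative for show / not-show scoring.
CLASSES_BINARY: tuple[str, ...] = ("show", "not_show")

_EPS = 1e-12


def entropy(class_counts: Sequence[float]) -> float:
    """Shannon entropy in bits of a class-count vector.

    A pure set has entropy 0; a balanced binary set has entropy 1.

    Raises
    ------
    UndefinedEntropyError
        If every count is zero (no distribution to measure).
    """
    counts = np.asarray(class_counts, dtype=float)
    if counts.size == 0 or counts.sum() <= 0:
        raise UndefinedEntropyError("entropy undefined for an empty class distribution")
    if (counts < 0).any():
        raise ValueError("class counts must be non-negative")
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


@dataclass
class LabeledDataset:
    """Feature table plus outcome labels for risk-model fitting.

    ``features`` holds categorical columns only (numeric features are
    binned before they get here); column order is the schema order used
    for deterministic tie-breaking.
    """

    features: pd.DataFrame
    labels: np.ndarray
    classes: tuple[str, ...] = CLASSES_3

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.features) != len(self.labels):
            raise SchemaError(
                f"{len(self.features)} feature rows vs {len(self.labels)} labels"
            )
        unknown = set(self.labels) - set(self.classes)
        if unknown:
            raise SchemaError(f"labels outside the class set: {sorted(unknown)}")

    @property
    def schema(self) -> list[str]:
        return list(self.features.columns)

    def __len__(self) -> int:
        return len(self.labels)

    def class_counts(self, labels: Optional[np.ndarray] = None) -> np.ndarray:
        lab = self.labels if labels is None else labels
        return np.array([(lab == c).sum() for c in self.classes], dtype=int)


def information_gain(data: LabeledDataset, feature: str) -> float:
    """Entropy reduction achieved by splitting ``data`` on ``feature``.

    Always in ``[0, H(labels)]``; zero for a constant feature.
    """
    if feature not in data.features.columns:
        raise SchemaError(f"unknown feature {feature!r}; schema is {data.schema}")
    if len(data) == 0:
        raise FitError("information gain undefined on an empty dataset")
    total = entropy(data.class_counts())
    n = len(data)
    weighted = 0.0
    for _, idx in data.features.groupby(feature, observed=True, sort=True).indices.items():
        sub = data.labels[idx]
        weighted += (len(sub) / n) * entropy(data.class_counts(sub))
    return max(0.0, total - weighted)


@dataclass
class RiskProfile:
    """Predicted outcome probabilities for one patient."""

    patient_id: str
    p_attend: float
    p_cancel: float
    p_noshow: float
    high_risk: bool

    def __post_init__(self) -> None:
        total = self.p_attend + self.p_cancel + self.p_noshow
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {total}")


@dataclass
class TreeNode:
    """One node of the fitted tree; a leaf iff ``feature`` is None."""

    counts: dict[str, int]
    feature: Optional[str] = None
    children: dict[str, "TreeNode"] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def majority_child(self) -> "TreeNode":
        return max(self.children.values(), key=lambda c: (c.n,))

    def to_dict(self) -> dict:
        d: dict = {"counts": self.counts}
        if not self.is_leaf:
            d["feature"] = self.feature
            d["children"] = {v: c.to_dict() for v, c in self.children.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(counts={k: int(v) for k, v in d["counts"].items()})
        if "feature" in d:
            node.feature = d["feature"]
            node.children = {v: cls.from_dict(c) for v, c in d["children"].items()}
        return node


@dataclass
class NoShowModel:
    """A fitted attendance-risk tree with its schema and training window.

    ``version`` increments on every refit through
    :func:`incremental_update`; the retained window (up to
    ``window_length`` most recent rows) is what a refit sees.
    """

    tree: TreeNode
    schema: list[str]
    classes: tuple[str, ...]
    min_leaf: int
    max_depth: int
    trained_on: int
    version: int = 1
    window_length: int = 50_000
    travel_bin_edges: Optional[list[float]] = None
    _window: Optional[LabeledDataset] = field(default=None, repr=False)
    _warned: set = field(default_factory=set, repr=False)
    #: cancel : no-show ratio used to split "not_show" mass in binary mode
    not_show_split: tuple[float, float] = (0.5, 0.5)

    def predict_risk(
        self, profile: PatientProfile, high_risk_threshold: float = 0.6
    ) -> RiskProfile:
        return predict_risk(self, profile, high_risk_threshold=high_risk_threshold)

    def update(self, new_rows: LabeledDataset) -> "NoShowModel":
        return incremental_update(self, new_rows)

    # -- serialization ------------------------------------------------
    def to_json(self) -> str:
        """Serialize the fitted tree (prediction state only, no window)."""
        return json.dumps(
            {
                "tree": self.tree.to_dict(),
                "schema": self.schema,
                "classes": list(self.classes),
                "min_leaf": self.min_leaf,
                "max_depth": self.max_depth,
                "trained_on": self.trained_on,
                "version": self.version,
                "window_length": self.window_length,
                "travel_bin_edges": self.travel_bin_edges,
                "not_show_split": list(self.not_show_split),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NoShowModel":
        d = json.loads(text)
        return cls(
            tree=TreeNode.from_dict(d["tree"]),
            schema=list(d["schema"]),
            classes=tuple(d["classes"]),
            min_leaf=int(d["min_leaf"]),
            max_depth=int(d["max_depth"]),
            trained_on=int(d["trained_on"]),
            version=int(d["version"]),
            window_length=int(d["window_length"]),
            travel_bin_edges=d.get("travel_bin_edges"),
            not_show_split=tuple(d.get("not_show_split", (0.5, 0.5))),
        )


def _grow(
    features: pd.DataFrame,
    labels: np.ndarray,
    classes: tuple[str, ...],
    min_leaf: int,
    max_depth: int,
    depth: int,
) -> TreeNode:
    counts = {c: int((labels == c).sum()) for c in classes}
    node = TreeNode(counts=counts)
    n = len(labels)
    nonzero = [c for c in classes if counts[c] > 0]
    if depth >= max_depth or len(nonzero) <= 1 or n < 2 * min_leaf:
        return node

    base = entropy(list(counts.values()))
    best_feature = None
    best_gain = _EPS
    best_groups = None
    for feat in features.columns:  # schema order breaks ties deterministically
        groups = features.groupby(feat, observed=True, sort=True).indices
        if len(groups) < 2:
            continue
        if any(len(idx) < min_leaf for idx in groups.values()):
            continue
        weighted = 0.0
        for idx in groups.values():
            sub = labels[idx]
            weighted += (len(sub) / n) * entropy([(sub == c).sum() for c in classes])
        gain = base - weighted
        if gain > best_gain + _EPS:
            best_feature, best_gain, best_groups = feat, gain, groups
    if best_feature is None:
        return node

    node.feature = best_feature
    for value, idx in sorted(best_groups.items(), key=lambda kv: str(kv[0])):
        child = _grow(
            features.iloc[idx].reset_index(drop=True),
            labels[idx],
            classes,
            min_leaf,
            max_depth,
            depth + 1,
        )
        node.children[str(value)] = child
    return node


def fit_tree(
    data: LabeledDataset,
    min_leaf: int = 5,
    max_depth: int = 6,
    window_length: int = 50_000,
    travel_bin_edges: Optional[list[float]] = None,
) -> NoShowModel:
    """Induce a risk tree by greedy information-gain partitioning.

    Splitting stops at purity, at ``max_depth``, or when no split keeps
    every child at ``min_leaf`` rows or more.
    """
    if len(data) == 0:
        raise FitError("cannot fit a tree on an empty dataset")
    if min_leaf < 1:
        raise ValueError("min_leaf must be >= 1")
    root = _grow(
        data.features.reset_index(drop=True),
        data.labels,
        data.classes,
        min_leaf,
        max_depth,
        depth=0,
    )
    # base cancel:no-show ratio, used only when labels are binarized
    split = (0.5, 0.5)
    if data.classes == CLASSES_3:
        nc = (data.labels == "canceled").sum()
        nn = (data.labels == "no_show").sum()
        if nc + nn > 0:
            split = (nc / (nc + nn), nn / (nc + nn))
    return NoShowModel(
        tree=root,
        schema=data.schema,
        classes=data.classes,
        min_leaf=min_leaf,
        max_depth=max_depth,
        trained_on=len(data),
        version=1,
        window_length=window_length,
        travel_bin_edges=travel_bin_edges,
        _window=data,
        not_show_split=split,
    )


def _route(model: NoShowModel, feats: Mapping[str, str]) -> TreeNode:
    node = model.tree
    while not node.is_leaf:
        value = str(feats.get(node.feature, ""))
        child = node.children.get(value)
        if child is None:
            if (node.feature, value) not in model._warned:
                model._warned.add((node.feature, value))
                logger.warning(
                    "feature %r value %r unseen in training; routing via majority child",
                    node.feature,
                    value,
                )
            child = node.majority_child()
        node = child
    return node


def _leaf_probs(model: NoShowModel, leaf: TreeNode) -> dict[str, float]:
    k = len(model.classes)
    n = leaf.n
    return {c: (leaf.counts.get(c, 0) + 1) / (n + k) for c in model.classes}


def predict_risk(
    model: NoShowModel,
    profile: PatientProfile,
    high_risk_threshold: float = 0.6,
) -> RiskProfile:
    """Route a patient down the tree and return smoothed outcome probabilities.

    Values unseen in training are routed through the majority child (and
    logged) rather than raising: a live scheduler must always produce a
    risk estimate.
    """
    feats = profile_features(profile, travel_bin_edges=model.travel_bin_edges)
    leaf = _route(model, feats)
    probs = _leaf_probs(model, leaf)
    if model.classes == CLASSES_BINARY:
        p_attend = probs["show"]
        w_cancel, w_noshow = model.not_show_split
        p_cancel = probs["not_show"] * w_cancel
        p_noshow = probs["not_show"] * w_noshow
    else:
        p_attend = probs["realized"]
        p_cancel = probs["canceled"]
        p_noshow = probs["no_show"]
    return RiskProfile(
        patient_id=profile.patient_id,
        p_attend=p_attend,
        p_cancel=p_cancel,
        p_noshow=p_noshow,
        high_risk=p_attend < high_risk_threshold,
    )


def incremental_update(model: NoShowModel, new_rows: LabeledDataset) -> NoShowModel:
    """Refit on a sliding window of retained + new rows (continuous learning).

    An empty update returns the model unchanged (same version). Two
    sequential updates are equivalent to one update with the
    concatenated rows, window permitting.
    """
    if len(new_rows) == 0:
        return model
    if model._window is None:
        raise UpdateError("model carries no training window; refit from scratch instead")
    if new_rows.schema != model.schema or new_rows.classes != model.classes:
        raise UpdateError(
            f"schema mismatch: model {model.schema}/{model.classes} "
            f"vs update {new_rows.schema}/{new_rows.classes}"
        )
    feats = pd.concat(
        [model._window.features, new_rows.features], ignore_index=True
    ).iloc[-model.window_length :]
    labels = np.concatenate([model._window.labels, new_rows.labels])[
        -model.window_length :
    ]
    combined = LabeledDataset(
        features=feats.reset_index(drop=True), labels=labels, classes=model.classes
    )
    refit = fit_tree(
        combined,
        min_leaf=model.min_leaf,
        max_depth=model.max_depth,
        window_length=model.window_length,
        travel_bin_edges=model.travel_bin_edges,
    )
    refit.version = model.version + 1
    return refit


# ---------------------------------------------------------------------
# Feature engineering: profiles -> categorical rows
# ---------------------------------------------------------------------

_BEHAVIOR_LABELS = ("none", "reliable", "mixed", "unreliable")


def _behavior_bin(profile: PatientProfile) -> str:
    if profile.n_past == 0:
        return "none"
    miss = (profile.n_canceled + profile.n_noshow) / profile.n_past
    if miss <= 0.25:
        return "reliable"
    if miss <= 0.5:
        return "mixed"
    return "unreliable"


def _travel_bin(travel: Optional[float], edges: Optional[list[float]]) -> str:
    if travel is None or edges is None:
        return "missing"
    return f"t{int(np.searchsorted(edges, travel, side='right'))}"


def profile_features(
    profile: PatientProfile, travel_bin_edges: Optional[list[float]] = None
) -> dict[str, str]:
    """Categorical feature row for one patient, matching the training schema."""
    return {
        "age_bracket": profile.age_bracket,
        "gender": profile.gender,
        "district": profile.district,
        "travel_bin": _travel_bin(profile.travel_time_min, travel_bin_edges),
        "past_behavior": _behavior_bin(profile),
    }


def build_training_data(
    profiles: Iterable[PatientProfile],
    statuses: Iterable[str],
    binary: bool = False,
    travel_bins: int = 4,
    feature_names: Optional[Sequence[str]] = None,
) -> tuple[LabeledDataset, Optional[list[float]]]:
    """Assemble a labeled dataset from patient profiles and outcomes.

    Numeric travel time is binned at population quantiles into
    ``travel_bins`` categories (edges returned for reuse at prediction
    time). ``feature_names`` restricts the schema, in the given order.
    Returns ``(dataset, travel_bin_edges)``.
    """
    profiles = list(profiles)
    statuses = [str(s) for s in statuses]
    if len(profiles) != len(statuses):
        raise SchemaError(f"{len(profiles)} profiles vs {len(statuses)} statuses")
    travels = [p.travel_time_min for p in profiles if p.travel_time_min is not None]
    edges: Optional[list[float]] = None
    if travels and travel_bins > 1:
        qs = np.quantile(travels, np.linspace(0, 1, travel_bins + 1)[1:-1])
        edges = sorted(set(float(q) for q in qs))
    rows = [profile_features(p, travel_bin_edges=edges) for p in profiles]
    features = pd.DataFrame(rows)
    if feature_names is not None:
        missing = set(feature_names) - set(features.columns)
        if missing:
            raise SchemaError(f"unknown feature names: {sorted(missing)}")
        features = features[list(feature_names)]
    if binary:
        labels = np.array(
            ["show" if s == "realized" else "not_show" for s in statuses], dtype=object
        )
        classes = CLASSES_BINARY
    else:
        labels = np.array(statuses, dtype=object)
        classes = CLASSES_3
    return LabeledDataset(features=features, labels=labels, classes=classes), edges
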