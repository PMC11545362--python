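"""Logistic-form attendance scorer fitted by IRLS.

An alternative to the decision tree behind the same risk contract: a
linear score on one-hot encoded binned features passed through the
logistic link, fitted by iteratively reweighted least squares with a
small ridge term for stability on separable or sparse designs. Predicts
p(show); the complementary mass is split between cancellation and
no-show by the training base ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .domain import PatientProfile
from .errors import FitError
from .tree import LabeledDataset, RiskProfile, profile_features

__all__ = ["LogisticScorer", "fit_logistic"]


@dataclass
class LogisticScorer:
    """Fitted logistic attendance scorer over one-hot categorical features."""

    coef: np.ndarray
    columns: list[str]
    schema: list[str]
    not_show_split: tuple[float, float]
    travel_bin_edges: Optional[list[float]] = None
    n_iter: int = 0
    trained_on: int = 0
    version: int = 1
    _levels: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def _design_row(self, feats: dict[str, str]) -> np.ndarray:
        x = np.zeros(len(self.columns))
        x[0] = 1.0  # intercept
        for name, value in feats.items():
            col = f"{name}={value}"
            if col in self._col_index:
                x[self._col_index[col]] = 1.0
        return x

    @property
    def _col_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.columns)}

    def predict_risk(
        self, profile: PatientProfile, high_risk_threshold: float = 0.6
    ) -> RiskProfile:
        feats = profile_features(profile, travel_bin_edges=self.travel_bin_edges)
        eta = float(self._design_row(feats) @ self.coef)
        p_attend = 1.0 / (1.0 + np.exp(-eta))
        w_cancel, w_noshow = self.not_show_split
        rest = 1.0 - p_attend
        return RiskProfile(
            patient_id=profile.patient_id,
            p_attend=p_attend,
            p_cancel=rest * w_cancel,
            p_noshow=rest * w_noshow,
            high_risk=p_attend < high_risk_threshold,
        )


def _one_hot(features: pd.DataFrame) -> tuple[np.ndarray, list[str], dict[str, list[str]]]:
    cols = ["intercept"]
    levels: dict[str, list[str]] = {}
    blocks = [np.ones((len(features), 1))]
    for name in features.columns:
        lv = sorted(features[name].astype(str).unique())
        levels[name] = lv
        for v in lv[1:]:  # drop first level as reference
            cols.append(f"{name}={v}")
            blocks.append((features[name].astype(str) == v).to_numpy()[:, None].astype(float))
    return np.hstack(blocks), cols, levels


def fit_logistic(
    data: LabeledDataset,
    max_iter: int = 50,
    tol: float = 1e-8,
    ridge: float = 1e-6,
    travel_bin_edges: Optional[list[float]] = None,
) -> LogisticScorer:
    """Fit p(show) by IRLS on the binned feature design.

    Three-class labels are binarized (realized -> show). Converges when
    the coefficient step drops below ``tol``.
    """
    if len(data) == 0:
        raise FitError("cannot fit a scorer on an empty dataset")
    y = np.array([1.0 if s in ("realized", "show") else 0.0 for s in data.labels])
    if y.min() == y.max():
        raise FitError("labels are constant; logistic fit is degenerate")
    X, cols, levels = _one_hot(data.features)
    beta = np.zeros(X.shape[1])
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        A = XtW @ X + ridge * np.eye(X.shape[1])
        new = np.linalg.solve(A, XtW @ z)
        step = float(np.max(np.abs(new - beta)))
        beta = new
        if step < tol:
            break
    nc = sum(1 for s in data.labels if s == "canceled")
    nn = sum(1 for s in data.labels if s == "no_show")
    split = (nc / (nc + nn), nn / (nc + nn)) if nc + nn > 0 else (0.5, 0.5)
    return LogisticScorer(
        coef=beta,
        columns=cols,
        schema=data.schema,
        not_show_split=split,
        travel_bin_edges=travel_bin_edges,
        n_iter=n_iter,
        trained_on=len(data),
        _levels=levels,
    )
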