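"""Episignature SVM training and MVP (methylation variant pathogenicity) scoring.

A linear-kernel, balanced-class-weight support vector machine is trained on
the beta values of the signature probes; its signed decision values are
mapped to a calibrated probability — the MVP score — by Platt's sigmoid
``mvp = 1 / (1 + exp(A*d + B))`` with ``(A, B)`` fit on 3-fold
cross-validated decision values, so the calibration never sees a decision
value produced by a model trained on the same sample.

Clinical calls use two strict cutoffs: MVP > 0.5 is *positive* (the
episignature is present), MVP < 0.25 is *negative*, and anything in between
(including the boundary values themselves) is *inconclusive*.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dmp import ProbeSet
from .exceptions import ArgumentError, ScoringError, SplitError, TrainingError

#: samples strictly above this MVP carry the episignature
POSITIVE_CUTOFF = 0.5
#: samples strictly below this MVP do not carry the episignature
NEGATIVE_CUTOFF = 0.25

#: sample-sheet groups forming the negative class during training
NEGATIVE_GROUPS = ("control", "other_disorder")


# ---------------------------------------------------------------------------
# train/test split


def split_train_test(sheet: pd.DataFrame, fraction: float = 0.75, seed: int = 0):
    """Stratified train/test partition of a sample sheet.

    Each group label contributes ``floor(fraction * n)`` samples (at least 1
    when the group has >= 2) to training and the rest to test.  Deterministic
    under ``seed``.
    """
    if not 0.0 < fraction < 1.0:
        raise ArgumentError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for grp in sorted(sheet["group"].dropna().unique()):
        ids = sorted(sheet.loc[sheet["group"] == grp, "sample_id"])
        if len(ids) < 2:
            raise SplitError(f"group {grp!r} has {len(ids)} sample(s); need >= 2 to split")
        perm = rng.permutation(len(ids))
        n_train = max(1, int(math.floor(fraction * len(ids))))
        n_train = min(n_train, len(ids) - 1)  # test side keeps >= 1
        train_ids.extend(ids[i] for i in perm[:n_train])
        test_ids.extend(ids[i] for i in perm[n_train:])
    return sorted(train_ids), sorted(test_ids)


# ---------------------------------------------------------------------------
# Platt sigmoid calibration


def fit_platt(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit ``(A, B)`` of ``P(y=1|d) = 1 / (1 + exp(A*d + B))``.

    Uses Platt's regularised targets ``(N+ + 1)/(N+ + 2)`` and
    ``1/(N- + 2)`` so separable decision values still give a finite map.
    """
    d = np.asarray(decision, dtype=float)
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise TrainingError("calibration needs both classes")
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params):
        a, b = params
        f = a * d + b
        # t*f + log(1 + exp(-f)) computed stably for both signs of f
        return float(np.sum(t * f + np.logaddexp(0.0, -f)))

    def grad(params):
        a, b = params
        p = 1.0 / (1.0 + np.exp(np.clip(a * d + b, -500, 500)))
        gcom = t - p
        return np.array([float(np.sum(gcom * d)), float(np.sum(gcom))])

    x0 = np.array([0.0, math.log((n_neg + 1.0) / (n_pos + 1.0))])
    res = minimize(nll, x0, jac=grad, method="BFGS", options={"maxiter": 200, "gtol": 1e-10})
    return float(res.x[0]), float(res.x[1])


# ---------------------------------------------------------------------------
# the trained classifier


@dataclass
class TrainedClassifier:
    """Linear SVM plus Platt calibration, fully described by its numbers so
    re-scoring is exact and serialisable."""

    probe_ids: list[str]
    weights: np.ndarray
    intercept: float
    platt_a: float
    platt_b: float
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)
    seed: int = 0

    def decision_values(self, beta: pd.DataFrame) -> pd.Series:
        """Signed decision value per sample (columns of ``beta``)."""
        missing = [p for p in self.probe_ids if p not in beta.index]
        if missing:
            raise ScoringError(
                f"{len(missing)} signature probes missing from input "
                f"(first: {missing[:5]})",
                missing=missing,
            )
        if beta.loc[self.probe_ids].isna().to_numpy().any():
            bad = beta.loc[self.probe_ids].isna().any(axis=1)
            raise ScoringError(
                "missing values on signature probes", missing=bad[bad].index.tolist()
            )
        x = beta.loc[self.probe_ids].to_numpy().T  # samples x probes
        return pd.Series(x @ self.weights + self.intercept, index=beta.columns)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "probe_ids": self.probe_ids,
                    "weights": self.weights.tolist(),
                    "intercept": self.intercept,
                    "platt_a": self.platt_a,
                    "platt_b": self.platt_b,
                    "train_ids": self.train_ids,
                    "test_ids": self.test_ids,
                    "seed": self.seed,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "TrainedClassifier":
        with open(path) as fh:
            data = json.load(fh)
        data["weights"] = np.asarray(data["weights"], dtype=float)
        return cls(**data)


def train_svm(
    beta: pd.DataFrame,
    probe_set: ProbeSet,
    sheet: pd.DataFrame,
    c: float = 1.0,
    seed: int = 0,
    test_ids: list[str] | None = None,
) -> TrainedClassifier:
    """Train the episignature SVM on the samples of ``sheet``.

    Positive class = ``case`` samples; negative class = controls together
    with other-disorder samples when present.  Features are the beta values
    of ``probe_set`` in its stored order.  ``(A, B)`` of the Platt map are
    fit on 3-fold cross-validated decision values.
    """
    labelled = sheet[sheet["group"].isin(("case",) + NEGATIVE_GROUPS)]
    ids = labelled["sample_id"].tolist()
    y = (labelled["group"] == "case").astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise TrainingError("training labels contain a single class")
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise TrainingError("need >= 2 samples per class")
    missing = [p for p in probe_set.probe_ids if p not in beta.index]
    if missing:
        raise ScoringError(f"signature probes missing from training matrix: {missing[:5]}",
                           missing=missing)
    x = beta.loc[probe_set.probe_ids, ids].to_numpy().T  # samples x probes

    svm = SVC(kernel="linear", C=c, class_weight="balanced")
    svm.fit(x, y)

    # cross-validated decision values for calibration
    n_splits = min(3, (y == 1).sum(), (y == 0).sum())
    cv_decision = np.empty(len(y))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for tr, te in skf.split(x, y):
        fold = SVC(kernel="linear", C=c, class_weight="balanced")
        fold.fit(x[tr], y[tr])
        cv_decision[te] = fold.decision_function(x[te])
    a, b = fit_platt(cv_decision, y)

    return TrainedClassifier(
        probe_ids=list(probe_set.probe_ids),
        weights=svm.coef_.ravel().copy(),
        intercept=float(svm.intercept_[0]),
        platt_a=a,
        platt_b=b,
        train_ids=ids,
        test_ids=list(test_ids or []),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# scoring and calls


def mvp_from_decision(decision, a: float, b: float):
    """Platt map ``mvp = 1 / (1 + exp(A*d + B))``, numerically stable."""
    f = np.clip(a * np.asarray(decision, dtype=float) + b, -500, 500)
    return 1.0 / (1.0 + np.exp(f))


def mvp_score(classifier: TrainedClassifier, beta: pd.DataFrame) -> pd.Series:
    """MVP score in (0, 1) for every sample column of ``beta``."""
    d = classifier.decision_values(beta)
    return pd.Series(
        mvp_from_decision(d.to_numpy(), classifier.platt_a, classifier.platt_b),
        index=d.index,
        name="mvp",
    )


def classify_call(mvp: float) -> str:
    """Categorical call at the clinical cutoffs (strict inequalities)."""
    if not 0.0 <= mvp <= 1.0:
        raise ArgumentError(f"mvp must be in [0, 1], got {mvp}")
    if mvp > POSITIVE_CUTOFF:
        return "positive"
    if mvp < NEGATIVE_CUTOFF:
        return "negative"
    return "inconclusive"


def mvp_report(classifier: TrainedClassifier, beta: pd.DataFrame) -> pd.DataFrame:
    """Score samples and attach the categorical call."""
    scores = mvp_score(classifier, beta)
    return pd.DataFrame(
        {
            "sample_id": scores.index,
            "mvp": scores.to_numpy(),
            "call": [classify_call(v) for v in scores],
        }
    )


def assess_specificity(
    classifier: TrainedClassifier, beta: pd.DataFrame, negative_ids: list[str]
) -> float:
    """Percent of true-negative samples with MVP below the negative cutoff."""
    if not negative_ids:
        raise ArgumentError("held-out negative set is empty")
    scores = mvp_score(classifier, beta[list(negative_ids)])
    return 100.0 * float((scores < NEGATIVE_CUTOFF).sum()) / len(negative_ids)
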