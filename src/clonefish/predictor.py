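"""Relapse risk prediction from per-sample chromosome-gain percentages.

A Random-Forest/Gini-importance ranking (leave-one-out cross-validated)
identifies the chromosomes whose gain rates separate favorable (CR) from
unfavorable (REL) outcome; two-chromosome threshold rules are then fitted
as depth-2 decision trees.  The deployed rule is the two-step
chr18 → chr10 classifier: a sample with < 40% chromosome-18 gains is
unfavorable; otherwise < 40% chromosome-10 gains is unfavorable; otherwise
favorable.  Robustness is quantified by a noise-injection stress test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import LeaveOneOut
from sklearn.tree import DecisionTreeClassifier

from .clonality import TrisomyProfile

__all__ = [
    "PredictorConfig",
    "RiskCall",
    "StressTestResult",
    "gini_importance_loocv",
    "evaluate_pair_rules",
    "chr18_chr10_rule",
    "classification_report",
    "stress_test",
]

FAVORABLE = "favorable"
UNFAVORABLE = "unfavorable"


@dataclass(frozen=True)
class PredictorConfig:
    """Thresholds and model settings for the risk predictor.

    The boundary policy is strict-greater for favorable: a sample exactly
    at 40/40 is called unfavorable unless ``strict_favorable=False``.
    """

    threshold_18: float = 40.0
    threshold_10: float = 40.0
    strict_favorable: bool = True
    n_trees: int = 500
    seed: int = 0
    loocv: bool = True

    def __post_init__(self) -> None:
        for t in (self.threshold_18, self.threshold_10):
            if not 0 < t < 100:
                raise ValueError("thresholds must lie in (0, 100)")


@dataclass(frozen=True)
class RiskCall:
    label: str  # favorable | unfavorable
    rule_trace: str
    features: Dict[str, float]


@dataclass
class StressTestResult:
    """Mean correctly/incorrectly classified patients per noise level."""

    levels: Tuple[float, ...]
    mean_correct: Tuple[float, ...]
    mean_misclassified: Tuple[float, ...]
    reps: int
    seed: int
    n_patients: int

    def __post_init__(self) -> None:
        for c, m in zip(self.mean_correct, self.mean_misclassified):
            if not np.isclose(c + m, self.n_patients):
                raise ValueError("correct + misclassified must equal cohort size")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "noise_level": self.levels,
                "mean_correct": self.mean_correct,
                "mean_misclassified": self.mean_misclassified,
            }
        )


def _check_features(features: pd.DataFrame, labels: Sequence[str]) -> np.ndarray:
    y = np.asarray(labels)
    if len(features) != len(y):
        raise ValueError("features and labels have different lengths")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need samples from both outcome classes")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"need >= 2 samples per class, got {counts}")
    return y


def gini_importance_loocv(
    features: pd.DataFrame,
    labels: Sequence[str],
    config: PredictorConfig = PredictorConfig(),
) -> Tuple[pd.DataFrame, List[str]]:
    """Leave-one-out Random-Forest Gini importances.

    For each held-out sample a forest is trained on the remaining samples;
    the per-feature mean-decrease-in-impurity importances are collected
    across folds.  Returns the fold x feature importance table and the
    feature names ranked by median importance (descending).
    """
    y = _check_features(features, labels)
    X = features.to_numpy(dtype=float)
    rows = []
    splits = LeaveOneOut().split(X) if config.loocv else [(np.arange(len(X)), None)]
    for train_idx, _ in splits:
        forest = RandomForestClassifier(
            n_estimators=config.n_trees, random_state=config.seed
        )
        forest.fit(X[train_idx], y[train_idx])
        rows.append(forest.feature_importances_)
    imp = pd.DataFrame(rows, columns=list(features.columns))
    ranking = imp.median(axis=0).sort_values(ascending=False).index.tolist()
    return imp, ranking


def _fit_two_threshold_rule(
    x1: np.ndarray, x2: np.ndarray, y_binary: np.ndarray
) -> Tuple[float, float, float]:
    """Empirical-risk-minimizing axis-aligned two-threshold rule.

    Searches all candidate threshold pairs (midpoints of consecutive
    observed values) and all sign orientations for the conjunction rule
    ``(±x1 > ±t1) ∧ (±x2 > ±t2)`` (label polarity free, so disjunctions are
    covered by complement).  Because accuracy plateaus over intervals of
    indistinguishable thresholds, the reported (t1, t2) is the centroid of
    the near-optimal set (within one misclassified sample of the optimum) —
    a lower-variance estimate of the plateau centre than any single
    maximizer.
    """
    def midpoints(x: np.ndarray) -> np.ndarray:
        xs = np.unique(x)
        if len(xs) < 2:
            return xs
        return (xs[:-1] + xs[1:]) / 2.0

    c1, c2 = midpoints(x1), midpoints(x2)
    n = len(y_binary)
    best_acc, best_t1, best_t2 = -1.0, float(c1[0]), float(c2[0])
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            M2 = (s2 * x2)[None, :] > (s2 * c2)[:, None]
            accs = np.empty((len(c1), len(c2)))
            for i, t1 in enumerate(c1):
                pred = ((s1 * x1) > (s1 * t1))[None, :] & M2
                agree = (pred == y_binary[None, :]).mean(axis=1)
                accs[i] = np.maximum(agree, 1.0 - agree)  # free label polarity
            top = accs.max()
            if top > best_acc:
                best_acc = top
                ii, jj = np.where(accs >= top - 1.0 / n - 1e-12)
                best_t1, best_t2 = float(c1[ii].mean()), float(c2[jj].mean())
    return best_t1, best_t2, best_acc


def evaluate_pair_rules(
    features: pd.DataFrame,
    labels: Sequence[str],
    pairs: Sequence[Tuple[str, str]],
    config: PredictorConfig = PredictorConfig(),
) -> pd.DataFrame:
    """Fit depth-2 threshold rules for candidate chromosome pairs.

    Each pair is scored by leave-one-out accuracy of a depth-2 decision
    tree; the reported thresholds come from an exhaustive accuracy-
    maximizing two-threshold refit on the full data (plateau-centred, see
    :func:`_fit_two_threshold_rule`), which is less variable than the
    greedy tree's split points.
    """
    y = _check_features(features, labels)
    rows = []
    for f1, f2 in pairs:
        X = features[[f1, f2]].to_numpy(dtype=float)
        correct = 0
        for train_idx, test_idx in LeaveOneOut().split(X):
            tree = DecisionTreeClassifier(max_depth=2, random_state=config.seed)
            tree.fit(X[train_idx], y[train_idx])
            correct += int(tree.predict(X[test_idx])[0] == y[test_idx][0])
        y_bin = (y == np.unique(y)[0])
        t1, t2, _ = _fit_two_threshold_rule(X[:, 0], X[:, 1], y_bin)
        rows.append((f"{f1}-{f2}", f1, f2, t1, t2, correct / len(X)))
    return pd.DataFrame(
        rows,
        columns=["pair", "feature_1", "feature_2", "threshold_1", "threshold_2",
                 "loocv_accuracy"],
    ).sort_values("loocv_accuracy", ascending=False, ignore_index=True)


def _get_features(
    profile: Union[TrisomyProfile, Mapping[str, float], pd.Series]
) -> Dict[str, float]:
    if isinstance(profile, TrisomyProfile):
        return {"18": profile.pct_gain("18"), "10": profile.pct_gain("10")}
    d = dict(profile)
    for key in ("18", "10"):
        if key not in d:
            raise ValueError(f"missing chromosome-{key} gain percentage")
    return {"18": float(d["18"]), "10": float(d["10"])}


def chr18_chr10_rule(
    profile: Union[TrisomyProfile, Mapping[str, float], pd.Series],
    config: PredictorConfig = PredictorConfig(),
) -> RiskCall:
    """Two-step chr18 → chr10 threshold rule."""
    feats = _get_features(profile)
    p18, p10 = feats["18"], feats["10"]

    def above(value: float, threshold: float) -> bool:
        return value > threshold if config.strict_favorable else value >= threshold

    if not above(p18, config.threshold_18):
        return RiskCall(
            UNFAVORABLE,
            f"step1: %+18 = {p18:.4g} <= {config.threshold_18:g}",
            feats,
        )
    if not above(p10, config.threshold_10):
        return RiskCall(
            UNFAVORABLE,
            f"step2: %+10 = {p10:.4g} <= {config.threshold_10:g}",
            feats,
        )
    return RiskCall(
        FAVORABLE,
        f"%+18 = {p18:.4g} and %+10 = {p10:.4g} both > threshold",
        feats,
    )


def classification_report(
    calls: Sequence[Union[RiskCall, str]],
    outcomes: Sequence[str],
) -> Dict[str, object]:
    """Confusion counts plus overall and per-class accuracies (%).

    ``outcomes`` uses the same favorable/unfavorable labels as the calls.
    """
    pred = [c.label if isinstance(c, RiskCall) else str(c) for c in calls]
    if len(pred) != len(outcomes):
        raise ValueError("calls and outcomes have different lengths")
    truth = [str(o) for o in outcomes]
    confusion = {
        (t, p): sum(1 for ti, pi in zip(truth, pred) if (ti, pi) == (t, p))
        for t in (FAVORABLE, UNFAVORABLE)
        for p in (FAVORABLE, UNFAVORABLE)
    }
    n = len(truth)
    correct = sum(1 for t, p in zip(truth, pred) if t == p)

    def class_acc(cls: str) -> float:
        total = sum(1 for t in truth if t == cls)
        if total == 0:
            return float("nan")
        hit = sum(1 for t, p in zip(truth, pred) if t == cls and p == cls)
        return 100.0 * hit / total

    return {
        "n": n,
        "confusion": confusion,
        "overall_accuracy": 100.0 * correct / n,
        "favorable_accuracy": class_acc(FAVORABLE),
        "unfavorable_accuracy": class_acc(UNFAVORABLE),
    }


def stress_test(
    classifier: Callable[[Mapping[str, float]], Union[RiskCall, str]],
    features: pd.DataFrame,
    labels: Sequence[str],
    noise_levels: Sequence[float] = (0, 5, 10, 15, 20, 25, 30),
    reps: int = 100,
    seed: int = 0,
) -> StressTestResult:
    """Noise-injection robustness test for a deterministic classifier.

    For each noise level L and repetition, every feature value x is
    perturbed to clip(x ± u, 0, 100) with u ~ Uniform(0, L) and an
    independent random sign, then reclassified; the mean number of
    correctly and incorrectly classified patients over the repetitions is
    reported per level.  At L = 0 the counts equal the noiseless confusion
    exactly.
    """
    if any(level < 0 for level in noise_levels):
        raise ValueError("noise levels must be non-negative")
    X = features.to_numpy(dtype=float)
    cols = list(features.columns)
    y = [str(v) for v in labels]
    if len(y) != len(X):
        raise ValueError("features and labels have different lengths")
    rng = np.random.default_rng(seed)

    mean_correct, mean_wrong = [], []
    for level in noise_levels:
        corrects = np.empty(reps)
        for rep in range(reps):
            u = rng.uniform(0.0, level, size=X.shape) if level > 0 else np.zeros(X.shape)
            sign = rng.choice((-1.0, 1.0), size=X.shape)
            Xp = np.clip(X + sign * u, 0.0, 100.0)
            n_ok = 0
            for i in range(len(Xp)):
                call = classifier(dict(zip(cols, Xp[i])))
                pred = call.label if isinstance(call, RiskCall) else str(call)
                n_ok += int(pred == y[i])
            corrects[rep] = n_ok
        mean_correct.append(float(corrects.mean()))
        mean_wrong.append(float(len(X) - corrects.mean()))
    return StressTestResult(
        levels=tuple(float(v) for v in noise_levels),
        mean_correct=tuple(mean_correct),
        mean_misclassified=tuple(mean_wrong),
        reps=reps,
        seed=seed,
        n_patients=len(X),
    )
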