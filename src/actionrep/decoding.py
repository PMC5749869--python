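"""Action decoding from model features.

A Gaussian-kernel regularized-least-squares (RLS) classifier with one-vs-all
target coding is trained on feature vectors of clips at one viewpoint and
evaluated on clips of a held-out actor, either at the same viewpoint
(viewpoint-match protocol) or the opposite one (viewpoint-mismatch protocol,
the invariant-recognition test). The kernel aperture and the l2
regularization strength are selected by leave-one-out (LOO) cross-validation
on the training set using the closed-form LOO residual of regularized least
squares; accuracy is per-class recall averaged with equal class weight, and
the experiment reports mean and standard error over the leave-one-actor-out
splits.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .synthetic import DatasetIndex

__all__ = [
    "ClassifierSpec",
    "RLSClassifier",
    "ExperimentResult",
    "fit_rls",
    "evaluate",
    "run_experiment",
    "significance_tests",
    "static_features",
]

log = logging.getLogger(__name__)

_LAMBDA_FLOOR = 1e-10


@dataclass
class ClassifierSpec:
    """Hyperparameter grids and (after fitting) the LOO-selected values.

    ``aperture_grid`` entries are multiples of the median pairwise training
    distance (the median heuristic); ``lambda_grid`` is the l2 regularization
    grid. Ties in LOO error are broken toward larger regularization, then
    larger aperture.
    """

    aperture_grid: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
    lambda_grid: tuple[float, ...] = tuple(float(10.0**e) for e in np.linspace(-6, 2, 9))
    selected: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.aperture_grid or not self.lambda_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if min(self.aperture_grid) <= 0 or min(self.lambda_grid) <= 0:
            raise ValueError("grid values must be positive")


@dataclass
class RLSClassifier:
    X: np.ndarray  # standardized training features
    alpha: np.ndarray  # dual coefficients, (n, n_classes)
    classes: np.ndarray
    aperture: float
    lam: float
    mean: np.ndarray
    std: np.ndarray
    loo_error: float

    def _kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        d2 = cdist(A, B, "sqeuclidean")
        return np.exp(-d2 / (2.0 * self.aperture**2))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, float) - self.mean) / self.std
        return self._kernel(Xs, self.X) @ self.alpha

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        # argmax returns the lowest class id on ties
        return self.classes[np.argmax(scores, axis=1)]


def fit_rls(
    features: np.ndarray,
    labels: Sequence,
    spec: ClassifierSpec | None = None,
) -> RLSClassifier:
    """Fit a Gaussian-kernel RLS classifier with LOO hyperparameter selection.

    Features are z-scored per dimension (fit on the training data). For each
    (aperture, lambda) pair the LOO prediction for sample i is obtained in
    closed form from H = K (K + n*lambda*I)^{-1}:

        f_i^{loo} = (f_i - H_ii * y_i) / (1 - H_ii)

    and the pair minimizing the LOO classification error is selected, ties
    broken toward larger lambda, then larger aperture.
    """
    spec = spec or ClassifierSpec()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("features must be (n, d) with one label per row")
    classes, y_idx = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    counts = np.bincount(y_idx)
    if counts.min() < 2:
        raise ValueError("need >= 2 samples per class for leave-one-out selection")
    n = X.shape[0]

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Xs = (X - mean) / std

    Y = -np.ones((n, len(classes)))
    Y[np.arange(n), y_idx] = 1.0

    d2 = cdist(Xs, Xs, "sqeuclidean")
    off = d2[~np.eye(n, dtype=bool)]
    med = math.sqrt(np.median(off)) if off.size and np.median(off) > 0 else 1.0

    best = None  # (error, lam, aperture, Hdiag-free alphas recomputed later)
    for ap_mult in spec.aperture_grid:
        aperture = ap_mult * med
        K = np.exp(-d2 / (2.0 * aperture**2))
        evals, Q = np.linalg.eigh(K)
        QtY = Q.T @ Y
        for lam in spec.lambda_grid:
            shrink = evals / (evals + n * lam)  # eigenvalues of H
            H_diag = (Q**2) @ shrink
            denom = 1.0 - H_diag
            if np.any(denom <= 1e-12):
                log.warning("singular LOO system at lambda=%g; applying floor", lam)
                denom = np.maximum(denom, _LAMBDA_FLOOR)
            F = Q @ (shrink[:, None] * QtY)  # F = H Y
            F_loo = (F - H_diag[:, None] * Y) / denom[:, None]
            err = float(np.mean(np.argmax(F_loo, axis=1) != y_idx))
            cand = (err, lam, aperture)
            if best is None or _prefer(cand, best):
                best = cand
    err, lam, aperture = best
    K = np.exp(-d2 / (2.0 * aperture**2))
    alpha = np.linalg.solve(K + n * lam * np.eye(n), Y)
    fitted_spec = ClassifierSpec(spec.aperture_grid, spec.lambda_grid,
                                 selected=(aperture, lam))
    clf = RLSClassifier(Xs, alpha, classes, aperture, lam, mean, std, err)
    clf.spec = fitted_spec
    return clf


def _prefer(cand: tuple, best: tuple) -> bool:
    """Lower LOO error wins; ties prefer larger lambda, then larger aperture."""
    if not math.isclose(cand[0], best[0], abs_tol=1e-12):
        return cand[0] < best[0]
    if not math.isclose(cand[1], best[1], rel_tol=1e-9):
        return cand[1] > best[1]
    return cand[2] > best[2]


def evaluate(clf: RLSClassifier, features: np.ndarray, labels: Sequence) -> dict:
    """Per-class recall and its equal-weight average.

    Classes absent from the test set are excluded (and logged).
    """
    y = np.asarray(labels)
    test_classes = set(np.unique(y).tolist())
    train_classes = set(clf.classes.tolist())
    if not test_classes <= train_classes:
        raise ValueError(
            f"test classes {sorted(test_classes - train_classes)} never seen in training"
        )
    pred = clf.predict(features)
    per_class = {}
    for c in clf.classes:
        mask = y == c
        if not mask.any():
            log.info("class %r absent from the test set; excluded from the mean", c)
            continue
        key = c.item() if hasattr(c, "item") else c
        per_class[key] = float(np.mean(pred[mask] == c))
    return {"per_class": per_class,
            "mean": float(np.mean(list(per_class.values())))}


# ---------------------------------------------------------------------------
# experiment protocols
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Leave-one-actor-out accuracies for one model under one protocol."""

    protocol: str
    viewpoints: tuple[float, float]
    split_accuracies: list[float]  # one per test actor, averaged over train views
    per_split: list[dict]  # detail: per train view, per class
    test_actors: list[int]

    @property
    def mean(self) -> float:
        return float(np.mean(self.split_accuracies))

    @property
    def se(self) -> float:
        a = np.asarray(self.split_accuracies)
        return float(a.std(ddof=1) / math.sqrt(len(a))) if len(a) > 1 else 0.0

    def summary(self) -> str:
        return (f"{self.protocol} protocol, views {self.viewpoints}: "
                f"accuracy {self.mean:.3f} +/- {self.se:.3f} SE over "
                f"{len(self.split_accuracies)} leave-one-actor-out splits")

    def to_dict(self) -> dict:
        return {"protocol": self.protocol, "viewpoints": list(self.viewpoints),
                "split_accuracies": self.split_accuracies,
                "mean": self.mean, "se": self.se,
                "test_actors": self.test_actors, "detail": self.per_split}


def static_features(F: np.ndarray) -> Callable:
    """Wrap a fixed feature matrix as an embedding-independent feature source."""
    F = np.asarray(F, dtype=float)

    def _fn(embedding_actors):
        return F

    return _fn


def run_experiment(
    feature_fn: Callable | np.ndarray,
    index: DatasetIndex,
    protocol: str,
    viewpoints: tuple[float, float],
    spec: ClassifierSpec | None = None,
) -> ExperimentResult:
    """Leave-one-actor-out decoding under the match or mismatch protocol.

    ``feature_fn(embedding_actors) -> (n_clips, d)`` returns features for all
    clips in ``index`` computed from a model whose templates come only from
    the embedding actors; pass an array (or :func:`static_features`) for
    embedding-independent features. For each choice of test actor the
    training set is the embedding actors' clips at the training viewpoint and
    the test set is the test actor's clips at the test viewpoint — the same
    viewpoint under ``match``, the opposite under ``mismatch`` — with the
    split accuracy averaged over the two choices of training viewpoint.
    """
    if protocol not in ("match", "mismatch"):
        raise ValueError(f"unknown protocol {protocol!r}")
    vA, vB = viewpoints
    views = set(index.labels("viewpoint").tolist())
    if vA not in views or vB not in views or vA == vB:
        raise ValueError(f"viewpoints {viewpoints} not available in the dataset ({sorted(views)})")
    actors = sorted(set(index.labels("actor").tolist()))
    if len(actors) < 2:
        raise ValueError("need >= 2 actors for leave-one-actor-out splits")
    actor_arr = index.labels("actor")
    view_arr = index.labels("viewpoint")
    action_arr = index.labels("action")

    split_acc, per_split = [], []
    for test_actor in actors:
        embedding = tuple(a for a in actors if a != test_actor)
        F = feature_fn(embedding) if callable(feature_fn) else np.asarray(feature_fn)
        if F.shape[0] != len(index):
            raise ValueError("feature matrix rows must align with the dataset index")
        view_results = {}
        for train_view in (vA, vB):
            test_view = train_view if protocol == "match" else (vB if train_view == vA else vA)
            tr = (actor_arr != test_actor) & (view_arr == train_view)
            te = (actor_arr == test_actor) & (view_arr == test_view)
            if not (tr.any() and te.any()):
                raise ValueError("empty training or test set for split")
            assert not (tr & te).any(), "train/test overlap"
            assert test_actor not in embedding, "test actor leaked into the embedding set"
            clf = fit_rls(F[tr], action_arr[tr], spec)
            view_results[train_view] = evaluate(clf, F[te], action_arr[te])
        acc = float(np.mean([r["mean"] for r in view_results.values()]))
        split_acc.append(acc)
        per_split.append({
            "test_actor": int(test_actor),
            "by_train_view": {str(v): r for v, r in view_results.items()},
        })
    return ExperimentResult(protocol, (vA, vB), split_acc, per_split,
                            [int(a) for a in actors])


def significance_tests(
    results_by_model: dict[str, ExperimentResult],
    learned_models: Sequence[str] = (),
    alpha: float = 0.05,
) -> dict:
    """Group one-way ANOVA (fixed vs learned) and pairwise paired t-tests.

    Pairwise tests run over the per-split accuracies with a Bonferroni
    adjusted threshold at family level ``alpha``.
    """
    names = list(results_by_model)
    lengths = {len(r.split_accuracies) for r in results_by_model.values()}
    if len(lengths) != 1:
        raise ValueError("all models must share the same split structure")
    report: dict = {"pairwise": {}, "alpha": alpha}
    fixed = [results_by_model[n].split_accuracies for n in names if n not in learned_models]
    learned = [results_by_model[n].split_accuracies for n in names if n in learned_models]
    if fixed and learned:
        F, p = stats.f_oneway(np.concatenate(fixed), np.concatenate(learned))
        report["group_anova"] = {"F": float(F), "p": float(p),
                                 "significant": bool(p < alpha)}
    m = len(names) * (len(names) - 1) // 2
    report["bonferroni_factor"] = m
    from .rsa import _paired_test  # same paired machinery, same fast paths

    for a, b in itertools.combinations(names, 2):
        report["pairwise"][f"{a} vs {b}"] = _paired_test(
            np.asarray(results_by_model[a].split_accuracies),
            np.asarray(results_by_model[b].split_accuracies),
            alpha / max(m, 1))
    return report
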