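"""Leave-one-subject-out (LOSO) decoding of behavior and group status.

Two protocols operate on amygdala connectivity features:

* ``loso_behavior_prediction`` — per fold, the group-difference map is
  recomputed on the n-1 training subjects, the two reference clusters are
  redefined as the suprathreshold components with maximal overlap, four mean-z
  features (left/right amygdala x two clusters) are extracted, and an OLS
  model fitted on the training subjects predicts the held-out subject's
  behavioral score (d' or CV); the Pearson r between predicted and observed
  scores across all subjects measures prediction.

* ``loso_classify`` — a Gaussian naive Bayes classifier over seed-to-parcel
  Fisher-z features; per fold the N features with greatest between-group
  separation (absolute pooled-variance t on the training rows only) are
  selected, with N swept from 1 to the feature budget.  Accuracy, sensitivity
  and specificity are tracked per N; significance of the best model comes
  from a label-shuffling permutation test.

Feature selection, cluster redefinition and classifier fitting never touch
the held-out subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .clusters import Cluster, adjacency_structure, extract_clusters
from .connectivity import group_difference_map

__all__ = [
    "FeatureMatrix",
    "LosoRegressionResult",
    "ClassificationResult",
    "PermutationResult",
    "rank_features",
    "nb_fit_predict",
    "loso_classify",
    "classification_metrics",
    "permutation_test",
    "permutation_pvalue",
    "loso_behavior_prediction",
]

_VAR_FLOOR = 1e-9


@dataclass
class FeatureMatrix:
    """Subjects x features Fisher-z values with per-feature metadata.

    For a 116-parcel atlas with left and right amygdala seeds the expected
    layout is 2 x 116 = 232 features named ``{seed}_parcel{id:03d}``.
    """

    values: np.ndarray
    feature_names: list[str]
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match the feature axis")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class LosoRegressionResult:
    predicted: np.ndarray
    observed: np.ndarray
    r: float
    p: float
    fold_cluster_sizes: list[dict]


@dataclass
class ClassificationResult:
    n_values: np.ndarray
    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    best_n: int
    confusion: dict  # tp, fn, tn, fp at best_n
    metrics: dict  # accuracy/sensitivity/specificity/dor at best_n
    predictions_best_n: np.ndarray = field(repr=False, default=None)


@dataclass
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    p: float
    n_perm: int
    seed: int


def rank_features(train_X: np.ndarray, train_y: np.ndarray, n: int) -> np.ndarray:
    """Indices of the N features with greatest between-group separation.

    Separation is the absolute pooled-variance two-sample t statistic on the
    training rows; ties break toward the lower feature index.  Pooled
    variance is floored at 1e-9 for degenerate features.
    """
    X = np.asarray(train_X, float)
    y = np.asarray(train_y, int)
    if not 1 <= n <= X.shape[1]:
        raise ValueError("N must be between 1 and the feature count")
    g1, g0 = X[y == 1], X[y == 0]
    n1, n0 = len(g1), len(g0)
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 training subjects per class")
    sp2 = ((n1 - 1) * g1.var(axis=0, ddof=1) + (n0 - 1) * g0.var(axis=0, ddof=1)) / (n1 + n0 - 2)
    sp2 = np.maximum(sp2, _VAR_FLOOR)
    t = (g1.mean(axis=0) - g0.mean(axis=0)) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    order = np.argsort(-np.abs(t), kind="stable")  # stable => lower index first on ties
    return order[:n]


def _nb_params(train_X: np.ndarray, train_y: np.ndarray):
    classes = np.unique(train_y)
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    means, variances, priors = [], [], []
    for c in classes:
        rows = train_X[train_y == c]
        if len(rows) < 2:
            raise ValueError(f"need at least 2 training subjects in class {c}")
        means.append(rows.mean(axis=0))
        variances.append(np.maximum(rows.var(axis=0, ddof=0), _VAR_FLOOR))
        priors.append(len(rows) / len(train_X))
    return classes, np.array(means), np.array(variances), np.array(priors)


def nb_fit_predict(train_X: np.ndarray, train_y: np.ndarray,
                   test_x: np.ndarray) -> tuple[int, np.ndarray]:
    """Gaussian naive Bayes: diagonal-covariance fit, single-point prediction.

    Class priors are the empirical training proportions; per-class feature
    variances use the maximum-likelihood estimate floored at 1e-9.  The
    posterior is proportional to prior x product of univariate normal
    densities.  Prediction ties break toward the class with the larger prior,
    then class 0.  Returns (label, posteriors over classes in sorted order).
    """
    train_X = np.asarray(train_X, float)
    train_y = np.asarray(train_y, int)
    test_x = np.asarray(test_x, float)
    classes, means, variances, priors = _nb_params(train_X, train_y)
    log_post = (np.log(priors)
                + np.sum(stats.norm.logpdf(test_x[None, :], means, np.sqrt(variances)), axis=1))
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()
    best = np.flatnonzero(post == post.max())
    if len(best) > 1:  # tie: larger prior, then class 0 (classes sorted ascending)
        best = best[np.lexsort((classes[best], -priors[best]))]
    return int(classes[best[0]]), post


def classification_metrics(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Accuracy, sensitivity, specificity and diagnostic odds ratio.

    DOR = (TP*TN)/(FP*FN); when any cell is zero all four cells get the
    Haldane +0.5 correction so the ratio stays finite.
    """
    for v in (tp, fn, tn, fp):
        if v < 0 or v != int(v):
            raise ValueError("confusion counts must be nonnegative integers")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("need at least one positive and one negative subject")
    total = tp + fn + tn + fp
    if min(tp, fn, tn, fp) == 0:
        h = 0.5
        dor = ((tp + h) * (tn + h)) / ((fp + h) * (fn + h))
    else:
        dor = (tp * tn) / (fp * fn)
    return {
        "accuracy": (tp + tn) / total,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "dor": dor,
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
    }


def _loso_predictions(X: np.ndarray, y: np.ndarray, n_values: np.ndarray) -> np.ndarray:
    """Held-out predictions for every subject at every feature-count N.

    Returns an array (len(n_values), n_subjects).  The per-fold feature
    ranking is computed once and reused across N (the top-N sets are nested).
    """
    n_subj = len(y)
    preds = np.empty((len(n_values), n_subj), int)
    max_n = int(max(n_values))
    for i in range(n_subj):
        tr = np.ones(n_subj, bool)
        tr[i] = False
        Xtr, ytr = X[tr], y[tr]
        ranked = rank_features(Xtr, ytr, max_n)
        for j, n in enumerate(n_values):
            sel = ranked[:n]
            preds[j, i], _ = nb_fit_predict(Xtr[:, sel], ytr, X[i, sel])
    return preds


def loso_classify(features: FeatureMatrix | np.ndarray, labels: np.ndarray,
                  n_range: np.ndarray | range | None = None) -> ClassificationResult:
    """LOSO naive-Bayes classification across a sweep of feature counts.

    For each N in ``n_range`` (default 1..min(n_features, n_subjects)): per
    fold, rank features on the training rows, fit the classifier on the top N
    and predict the held-out subject.  ``best_n`` is the smallest N attaining
    the maximal overall accuracy; the confusion counts and diagnostic odds
    ratio are reported at that N.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = np.asarray(labels, int)
    n_subj, n_feat = X.shape
    if n_range is None:
        n_range = range(1, min(n_feat, n_subj) + 1)
    n_values = np.asarray(list(n_range), int)
    if n_values.min() < 1 or n_values.max() > min(n_feat, n_subj):
        raise ValueError("n_range must lie within [1, min(n_features, n_subjects)]")

    preds = _loso_predictions(X, y, n_values)
    acc = (preds == y).mean(axis=1)
    sens = np.array([(p[y == 1] == 1).mean() for p in preds])
    spec = np.array([(p[y == 0] == 0).mean() for p in preds])

    best_idx = int(np.argmax(acc))  # argmax returns the first (smallest N) maximum
    best_n = int(n_values[best_idx])
    pb = preds[best_idx]
    tp = int(np.sum((pb == 1) & (y == 1)))
    fn = int(np.sum((pb == 0) & (y == 1)))
    tn = int(np.sum((pb == 0) & (y == 0)))
    fp = int(np.sum((pb == 1) & (y == 0)))
    metrics = classification_metrics(tp, fn, tn, fp)
    return ClassificationResult(
        n_values=n_values, accuracy=acc, sensitivity=sens, specificity=spec,
        best_n=best_n, confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
        metrics=metrics, predictions_best_n=pb,
    )


def permutation_pvalue(null_accuracies: np.ndarray, observed: float) -> float:
    """Proportion of null accuracies >= the observed accuracy (no +1 term)."""
    null_accuracies = np.asarray(null_accuracies, float)
    return float(np.mean(null_accuracies >= observed))


def permutation_test(features: FeatureMatrix | np.ndarray, labels: np.ndarray,
                     n_features: int, n_perm: int = 1000, seed: int = 0) -> PermutationResult:
    """Label-shuffling null for the fixed-N LOSO classification accuracy.

    Each iteration shuffles the group labels once and repeats the complete
    LOSO fold structure at the fixed feature count; p is the proportion of
    null accuracies equal to or exceeding the observed accuracy.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = np.asarray(labels, int)
    n_values = np.array([n_features])
    observed = float((_loso_predictions(X, y, n_values)[0] == y).mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        null[b] = (_loso_predictions(X, y_perm, n_values)[0] == y_perm).mean()
    return PermutationResult(observed_accuracy=observed, null_accuracies=null,
                             p=permutation_pvalue(null, observed), n_perm=n_perm, seed=seed)


def _match_cluster(components: list[Cluster], reference: Cluster) -> np.ndarray:
    """Training-fold mask for a reference cluster: maximal-overlap component.

    Components of the reference's sign are scanned for the largest voxel
    overlap with the reference mask; with no overlapping component the
    reference mask itself is the fallback.
    """
    best, best_ov = None, 0
    for comp in components:
        if comp.sign != reference.sign:
            continue
        ov = int(np.logical_and(comp.mask, reference.mask).sum())
        if ov > best_ov:
            best, best_ov = comp, ov
    return best.mask if best is not None else reference.mask


def loso_behavior_prediction(zmaps_bilateral: np.ndarray,
                             zmaps_by_seed: dict[str, np.ndarray],
                             labels: np.ndarray, behavior: np.ndarray,
                             reference_clusters: list[Cluster],
                             nominal_p: float = 0.01,
                             adjacency: str = "face",
                             mask: np.ndarray | None = None) -> LosoRegressionResult:
    """LOSO multiple regression of behavior on per-fold-redefined cluster features.

    ``zmaps_bilateral`` is (n_subjects, X, Y, Z): each subject's bilateral-seed
    Fisher-z map, used to redefine the clusters per fold.  ``zmaps_by_seed``
    maps seed names (e.g. left/right amygdala) to same-shaped arrays from
    which the mean-z features are extracted — 2 seeds x 2 clusters = 4
    features.  Per fold the group-difference map is recomputed on the
    training subjects only, thresholded two-sidedly at ``nominal_p``, and
    each reference cluster is redefined as the same-sign component with
    maximal overlap (falling back to the reference mask when none overlaps).
    """
    zb = np.asarray(zmaps_bilateral, float)
    y = np.asarray(behavior, float)
    labels = np.asarray(labels, int)
    n_subj = zb.shape[0]
    grid_shape = zb.shape[1:]
    if not np.isfinite(y).all():
        raise ValueError("behavior must be finite")
    seeds = sorted(zmaps_by_seed)
    flat_bilateral = zb.reshape(n_subj, -1)
    flat_by_seed = {s: np.asarray(zmaps_by_seed[s], float).reshape(n_subj, -1) for s in seeds}

    predicted = np.empty(n_subj)
    fold_sizes: list[dict] = []
    for i in range(n_subj):
        tr = np.ones(n_subj, bool)
        tr[i] = False
        if len(np.unique(labels[tr])) < 2 or min(np.bincount(labels[tr])) < 2:
            raise ValueError(f"fold {i} leaves a group empty or singleton")
        diff = group_difference_map(flat_bilateral[tr], labels[tr])
        tcrit = diff.threshold_value(nominal_p)
        comps = extract_clusters(diff.stat.reshape(grid_shape), tcrit,
                                 min_cluster_size=1, adjacency=adjacency, mask=mask)
        masks = [_match_cluster(comps, ref) for ref in reference_clusters]
        fold_sizes.append({f"cluster{j}": int(m.sum()) for j, m in enumerate(masks)})

        feats = np.column_stack([
            flat_by_seed[s][:, m.ravel()].mean(axis=1) for s in seeds for m in masks
        ])
        Xtr = np.column_stack([np.ones(tr.sum()), feats[tr]])
        beta, *_ = np.linalg.lstsq(Xtr, y[tr], rcond=None)
        predicted[i] = np.concatenate([[1.0], feats[i]]) @ beta

    r, p = stats.pearsonr(predicted, y)
    return LosoRegressionResult(predicted=predicted, observed=y, r=float(r), p=float(p),
                                fold_cluster_sizes=fold_sizes)
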