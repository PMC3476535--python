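"""Single-trial decoding of contraction type from masked spectrogram features.

Normalized trial spectrograms are reduced by block-averaging (factor 10 in
time and frequency), significant time-frequency points are selected per
condition with the same bootstrap used for display masking, and the dB
values at the union of significant points form the feature vector for a
4-way linear naive-Bayes classifier (isometric/isotonic x high/low effort).
Accuracy is estimated with stratified 10-fold cross-validation, and
per-fold confusion counts are pooled into a grand-average normalized
confusion matrix whose 16 cells sum to 100%.

Feature selection runs inside each training fold by default, so the test
fold never informs the mask.  ``paper_mode=True`` instead selects features
once per subject on all trials before cross-validation, matching the
simpler historical protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .spectro import bootstrap_mask

__all__ = [
    "PooledGaussianNB",
    "ConfusionMatrix",
    "reduce_resolution",
    "select_features",
    "build_features",
    "crossvalidate",
    "aggregate_confusion",
]


# --- resolution reduction -------------------------------------------------

def reduce_resolution(values: np.ndarray, factor: int = 10) -> np.ndarray:
    """Block-mean a (time, frequency) map by ``factor`` along both axes.

    Trailing blocks smaller than ``factor`` are averaged over the cells
    available.  Works on stacks: reduction applies to the last two axes.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    v = np.asarray(values, dtype=float)

    def reduce_axis(x: np.ndarray, axis: int) -> np.ndarray:
        n = x.shape[axis]
        edges = np.arange(0, n, factor)
        sums = np.add.reduceat(x, edges, axis=axis)
        counts = np.diff(np.append(edges, n))
        shape = [1] * x.ndim
        shape[axis] = len(counts)
        return sums / counts.reshape(shape)

    return reduce_axis(reduce_axis(v, -2), -1)


# --- naive Bayes ----------------------------------------------------------

class PooledGaussianNB(ClassifierMixin, BaseEstimator):
    """Gaussian naive Bayes with per-feature variance pooled across classes.

    Pooling the within-class variances makes the log-posterior differences
    linear in the features (the quadratic terms cancel), i.e. this is the
    "linear naive Bayes" construction: a diagonal-covariance linear
    discriminant with naive (independent-feature) likelihoods.  With
    ``pooled=False`` it reduces to ordinary Gaussian naive Bayes with
    per-class variances (quadratic boundaries).

    Variances are floored at ``var_floor_frac`` times the overall feature
    variance to keep log-likelihoods finite on degenerate features.
    """

    def __init__(self, pooled: bool = True, var_floor_frac: float = 1e-6,
                 priors: np.ndarray | None = None):
        self.pooled = pooled
        self.var_floor_frac = var_floor_frac
        self.priors = priors

    def fit(self, X: np.ndarray, y) -> "PooledGaussianNB":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_features) matching y")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        n, p = X.shape
        self.theta_ = np.empty((n_classes, p))
        within = np.empty((n_classes, p))
        counts = np.bincount(y_idx, minlength=n_classes)
        if np.any(counts == 0):
            raise ValueError("every class needs at least one sample")
        for k in range(n_classes):
            Xk = X[y_idx == k]
            self.theta_[k] = Xk.mean(axis=0)
            within[k] = ((Xk - self.theta_[k]) ** 2).sum(axis=0)
        floor = self.var_floor_frac * X.var(axis=0) + 1e-12
        if self.pooled:
            pooled_var = within.sum(axis=0) / n
            self.var_ = np.tile(np.maximum(pooled_var, floor), (n_classes, 1))
        else:
            self.var_ = np.maximum(within / counts[:, None], floor)
        if self.priors is not None:
            pr = np.asarray(self.priors, dtype=float)
            if len(pr) != n_classes or not np.isclose(pr.sum(), 1.0):
                raise ValueError("priors must match classes and sum to 1")
            self.class_prior_ = pr
        else:
            self.class_prior_ = counts / n
        self.n_features_in_ = p
        return self

    def _joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        jll = np.empty((X.shape[0], len(self.classes_)))
        for k in range(len(self.classes_)):
            diff2 = (X - self.theta_[k]) ** 2
            jll[:, k] = (np.log(self.class_prior_[k])
                         - 0.5 * np.sum(np.log(2 * np.pi * self.var_[k]))
                         - 0.5 * np.sum(diff2 / self.var_[k], axis=1))
        return jll

    def predict_log_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "theta_")
        jll = self._joint_log_likelihood(X)
        norm = np.logaddexp.reduce(jll, axis=1, keepdims=True)
        return jll - norm

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.exp(self.predict_log_proba(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "theta_")
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


# --- feature selection ----------------------------------------------------

@dataclass
class FeatureSpec:
    """Selected (cluster, time-bin, freq-bin) coordinates on the reduced grid."""

    points: list  # list of (cluster_index, t_idx, f_idx)

    def __len__(self) -> int:
        return len(self.points)


def select_features(reduced_specs: np.ndarray, labels: np.ndarray,
                    baseline_cols: np.ndarray, alpha: float = 0.05,
                    n_boot: int = 200, seed: int | None = 0) -> np.ndarray:
    """Union over conditions of bootstrap-significant reduced-grid points.

    ``reduced_specs`` is (n_trials, n_t, n_f); ``labels`` the 4-way condition
    of each trial; ``baseline_cols`` the time-bin indices of the baseline on
    the reduced grid.  Returns a boolean (n_t, n_f) selection mask.
    """
    reduced_specs = np.asarray(reduced_specs, dtype=float)
    union = np.zeros(reduced_specs.shape[1:], dtype=bool)
    for j, cond in enumerate(np.unique(labels)):
        sel = reduced_specs[np.asarray(labels) == cond]
        res = bootstrap_mask(sel, baseline_cols=baseline_cols, alpha=alpha,
                             n_boot=n_boot, seed=None if seed is None else seed + j)
        union |= res.mask
    return union


def build_features(trial_specs_by_cluster, labels, baseline_cols,
                   alpha: float = 0.05, n_boot: int = 200,
                   seed: int | None = 0, trial_indices=None):
    """Feature matrix from significance-selected reduced spectrogram points.

    ``trial_specs_by_cluster`` is a sequence of (n_trials, n_t, n_f) arrays,
    one per component cluster.  Selection uses the trials in
    ``trial_indices`` (default: all), so cross-validation can restrict the
    mask to the training fold.  Returns ``(X, spec)`` where ``X`` is
    (n_trials, n_features) over *all* trials and ``spec`` a
    :class:`FeatureSpec`.
    """
    labels = np.asarray(labels)
    if trial_indices is None:
        trial_indices = np.arange(len(labels))
    points = []
    cols = []
    for ci, specs in enumerate(trial_specs_by_cluster):
        specs = np.asarray(specs, dtype=float)
        mask = select_features(specs[trial_indices], labels[trial_indices],
                               baseline_cols, alpha=alpha, n_boot=n_boot,
                               seed=None if seed is None else seed + 1000 * ci)
        tt, ff = np.nonzero(mask)
        points.extend((ci, int(t), int(f)) for t, f in zip(tt, ff))
        cols.append(specs[:, tt, ff])
    X = np.concatenate(cols, axis=1) if cols else np.empty((len(labels), 0))
    if X.shape[1] == 0:
        raise ValueError(
            "no significant time-frequency points selected; lower alpha or "
            "increase the effect size / number of trials")
    return X, FeatureSpec(points=points)


# --- cross-validation -----------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Counts plus the normalized (percent-of-all-trials) confusion matrix."""

    classes: np.ndarray
    counts: np.ndarray

    @property
    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        return 100.0 * self.counts / total if total else self.counts.astype(float)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.normalized) / 100.0)


def _confusion_counts(classes, y_true, y_pred) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[idx[t], idx[p]] += 1
    return counts


def crossvalidate(trial_specs_by_cluster, labels, baseline_cols, k: int = 10,
                  seed: int = 0, alpha: float = 0.05, n_boot: int = 200,
                  paper_mode: bool = False, pooled: bool = True):
    """Stratified k-fold cross-validation of the masked-feature classifier.

    Returns a list of per-fold :class:`ConfusionMatrix`.  By default the
    significance mask is recomputed from each training fold (leakage-free);
    ``paper_mode=True`` computes it once from all trials.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    counts = np.bincount(np.searchsorted(classes, labels))
    if counts.min() < k:
        raise ValueError(f"every class needs >= {k} trials for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    if paper_mode:
        X_all, _ = build_features(trial_specs_by_cluster, labels, baseline_cols,
                                  alpha=alpha, n_boot=n_boot, seed=seed)
    for fold_i, (train, test) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        if paper_mode:
            X = X_all
        else:
            X, _ = build_features(trial_specs_by_cluster, labels, baseline_cols,
                                  alpha=alpha, n_boot=n_boot,
                                  seed=seed + 17 * fold_i, trial_indices=train)
        clf = PooledGaussianNB(pooled=pooled).fit(X[train], labels[train])
        pred = clf.predict(X[test])
        folds.append(ConfusionMatrix(classes=classes,
                                     counts=_confusion_counts(classes, labels[test], pred)))
    return folds


def aggregate_confusion(matrices) -> ConfusionMatrix:
    """Pool per-fold/per-subject confusion counts into a grand average.

    Counts are summed and then normalized so the 16 cells sum to 100%; row
    sums therefore reflect class prevalence in the protocol.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no confusion matrices to aggregate")
    classes = matrices[0].classes
    for m in matrices:
        if not np.array_equal(m.classes, classes):
            raise ValueError("confusion matrices have mismatched class sets")
    total = np.sum([m.counts for m in matrices], axis=0)
    return ConfusionMatrix(classes=classes, counts=total)
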