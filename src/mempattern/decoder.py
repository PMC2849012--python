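"""Multiclass linear SVM decoding under nested leave-one-trial-out CV.

The classifier is a soft-margin linear SVM with fixed regularization C = 1,
extended to more than two classes by one-vs-one voting.  The outer
cross-validation is leave-one-trial-out (k equals the number of trials); the
searchlight feature selection is recomputed inside every outer training fold
so the held-out trial never influences which voxels are used — the nested
scheme that avoids double dipping.  Chance level is estimated by rerunning
the full nested pipeline on label permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _svm
from .design import ROIMask
from .preprocess import PatternSet

__all__ = [
    "ClassifierConfig",
    "BinarySVM",
    "LinearModel",
    "CVScheme",
    "DecodingResult",
    "PermutationResult",
    "train_binary_svm",
    "train_multiclass",
    "make_loto_scheme",
    "cross_validate_decoding",
    "permutation_chance",
    "empirical_p",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Linear SVM settings; C = 1 is the study's fixed hyperparameter.

    ``class_weight='balanced'`` rescales each class's misclassification cost
    so both classes of every pairwise problem carry equal total cost.  Under
    leave-one-trial-out CV the training set is always short exactly one trial
    of the tested class; on signal-free data an unweighted SVM then drifts
    toward the majority classes and votes *against* the held-out trial's
    class, depressing null accuracy below theoretical chance.  Balancing
    removes that bias while leaving the average cost at C.
    """

    C: float = 1.0
    multiclass: str = "one_vs_one"
    class_weight: str = "balanced"  # "balanced" | "none"
    tol: float = 1e-4
    max_iter: int = 50_000

    def __post_init__(self) -> None:
        if self.C <= 0 or self.tol <= 0:
            raise ValueError("C and tol must be positive")
        if self.multiclass != "one_vs_one":
            raise ValueError("only one_vs_one multiclass is supported")
        if self.class_weight not in ("balanced", "none"):
            raise ValueError("class_weight must be 'balanced' or 'none'")

    @property
    def balanced(self) -> bool:
        return self.class_weight == "balanced"


@dataclass(frozen=True)
class BinarySVM:
    """A fitted binary linear decision function sign(x . w + b)."""

    w: np.ndarray
    b: float
    converged: bool
    n_iter: int

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.w + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, 1, -1)


@dataclass(frozen=True)
class LinearModel:
    """One-vs-one multiclass linear SVM.

    ``weights[p]`` / ``biases[p]`` belong to class pair ``pairs[p] = (a, b)``
    (original labels, a < b); a positive decision votes for ``a``.
    """

    classes: np.ndarray
    pairs: np.ndarray
    weights: np.ndarray  # (n_pairs, n_features)
    biases: np.ndarray  # (n_pairs,)
    converged: np.ndarray  # (n_pairs,) bool

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """Pairwise signed decision values, shape (n_samples, n_pairs)."""
        return np.asarray(X) @ self.weights.T + self.biases

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Majority vote; ties by largest summed signed margin, then lowest
        class id."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        Wb = np.hstack([self.weights, self.biases[:, None]])
        codes = _svm.vote_predict(
            np.ascontiguousarray(Wb), np.ascontiguousarray(X), self.n_classes
        )
        return self.classes[codes]


def train_binary_svm(X: np.ndarray, y: np.ndarray, cfg: ClassifierConfig | None = None) -> BinarySVM:
    """Fit the binary soft-margin linear SVM (objective 0.5||w||^2 + C*hinge).

    ``y`` must contain both +1 and -1.  Non-convergence within
    ``cfg.max_iter`` sweeps is flagged on the result and warned about, never
    silent.
    """
    cfg = cfg or ClassifierConfig()
    X = np.ascontiguousarray(np.atleast_2d(X), dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    if not (np.any(y > 0) and np.any(y < 0)):
        raise ValueError("both classes (+1/-1) must be present")
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ValueError("binary labels must be +/-1")
    Xb = np.hstack([X, np.ones((X.shape[0], 1))])
    Cvec = np.full(len(y), cfg.C)
    if cfg.balanced:
        n_pos = int(np.sum(y > 0))
        n_neg = len(y) - n_pos
        Cvec[y > 0] = cfg.C * len(y) / (2.0 * n_pos)
        Cvec[y < 0] = cfg.C * len(y) / (2.0 * n_neg)
    w, n_iter, ok = _svm.dcd_fit(Xb, y, Cvec, cfg.tol, cfg.max_iter)
    if not ok:
        warnings.warn(
            f"binary SVM did not converge within {cfg.max_iter} sweeps "
            f"(tol={cfg.tol})",
            RuntimeWarning,
        )
    return BinarySVM(w=w[:-1].copy(), b=float(w[-1]), converged=bool(ok), n_iter=int(n_iter))


def train_multiclass(
    X: np.ndarray, y: np.ndarray, cfg: ClassifierConfig | None = None
) -> LinearModel:
    """One binary SVM per unordered class pair, trained on the pair's trials."""
    cfg = cfg or ClassifierConfig()
    X = np.ascontiguousarray(np.atleast_2d(X), dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes present")
    codes = np.searchsorted(classes, y).astype(np.int64)
    W, conv = _svm.fit_pairs(
        X, codes, len(classes), cfg.C, cfg.balanced, cfg.tol, cfg.max_iter
    )
    if not conv.all():
        warnings.warn("one or more pairwise SVMs did not converge", RuntimeWarning)
    pairs = np.array(
        [(classes[a], classes[b]) for a in range(len(classes)) for b in range(a + 1, len(classes))]
    )
    return LinearModel(
        classes=classes,
        pairs=pairs,
        weights=W[:, :-1].copy(),
        biases=W[:, -1].copy(),
        converged=conv.copy(),
    )


@dataclass(frozen=True)
class CVScheme:
    """List of (train_indices, test_indices) folds partitioning the trials."""

    folds: tuple[tuple[np.ndarray, np.ndarray], ...]
    k: int


def make_loto_scheme(patterns: PatternSet) -> CVScheme:
    """Leave-one-trial-out: k equals the number of trials; fold i tests
    trial i and trains on all the others."""
    n = patterns.n_trials
    n_classes = len(patterns.classes)
    if n < n_classes + 1:
        raise ValueError(
            f"need at least {n_classes + 1} trials for leave-one-trial-out"
        )
    folds = tuple(
        (np.delete(np.arange(n), i), np.array([i]))
        for i in range(n)
    )
    return CVScheme(folds=folds, k=n)


@dataclass(frozen=True)
class DecodingResult:
    accuracy: float
    y_true: np.ndarray
    y_pred: np.ndarray
    confusion: np.ndarray  # rows = true class, cols = predicted
    classes: np.ndarray
    fold_selections: tuple  # per outer fold: (n_sel, 3) voxel arrays
    final_map: object  # InformationMap from all-trials scoring (mapping only)
    n_select: int

    def confusion_ok(self) -> bool:
        return bool(
            np.isclose(self.accuracy, np.trace(self.confusion) / self.confusion.sum())
        )


def _zscore_train_test(Xtr: np.ndarray, Xte: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature z-scoring using training statistics only."""
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (Xtr - mu) / sd, (Xte - mu) / sd


def cross_validate_decoding(
    patterns: PatternSet,
    mask: ROIMask,
    sl_spec=None,
    n_select: int = 100,
    cfg: ClassifierConfig | None = None,
    *,
    inner_folds: int = 5,
    selection: str = "nested",
    compute_final_map: bool = True,
    subject_id: int | None = None,
) -> DecodingResult:
    """Nested leave-one-trial-out decoding with per-fold feature selection.

    For each outer fold the searchlight scoring and top-``n_select``
    selection are computed on the training trials only; the SVM is then
    trained on the selected voxels (z-scored with training statistics) and
    the held-out trial is predicted.  ``selection='whole'`` instead selects
    once on all trials — a deliberately leaky test mode whose optimistic
    bias the test suite documents; never use it for reported accuracy.

    The returned ``final_map`` is the selection computed on *all* trials and
    is for anatomical mapping only, never for accuracy.
    """
    from .searchlight import (
        SearchlightSpec,
        build_information_map,
        neighborhood_table,
        score_searchlights,
    )

    sl_spec = sl_spec or SearchlightSpec()
    cfg = cfg or ClassifierConfig()
    if selection not in ("nested", "whole"):
        raise ValueError("selection must be 'nested' or 'whole'")
    scheme = make_loto_scheme(patterns)
    classes = patterns.classes
    table = neighborhood_table(mask, sl_spec)

    whole_cols: np.ndarray | None = None
    if selection == "whole":
        scores_all = score_searchlights(
            patterns, mask, sl_spec, inner_folds=inner_folds, cfg=cfg, _table=table
        )
        imap = build_information_map(scores_all, n_select, subject_id=subject_id)
        whole_cols = _map_columns(imap, patterns)

    y_true = patterns.labels
    y_pred = np.empty_like(y_true)
    fold_selections = []
    for train_idx, test_idx in scheme.folds:
        train = patterns.subset(train_idx)
        if selection == "nested":
            scores = score_searchlights(
                train, mask, sl_spec, inner_folds=inner_folds, cfg=cfg, _table=table
            )
            imap = build_information_map(scores, n_select, subject_id=subject_id)
            cols = _map_columns(imap, patterns)
        else:
            cols = whole_cols
        fold_selections.append(patterns.voxel_index[cols])
        Xtr, Xte = _zscore_train_test(
            patterns.matrix[np.ix_(train_idx, cols)],
            patterns.matrix[np.ix_(test_idx, cols)],
        )
        model = train_multiclass(Xtr, y_true[train_idx], cfg)
        y_pred[test_idx] = model.predict(Xte)

    accuracy = float(np.mean(y_pred == y_true))
    k = len(classes)
    confusion = np.zeros((k, k), dtype=np.int64)
    code = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        confusion[code[t], code[p]] += 1

    final_map = None
    if compute_final_map:
        scores_all = score_searchlights(
            patterns, mask, sl_spec, inner_folds=inner_folds, cfg=cfg, _table=table
        )
        final_map = build_information_map(scores_all, n_select, subject_id=subject_id)

    return DecodingResult(
        accuracy=accuracy,
        y_true=y_true.copy(),
        y_pred=y_pred,
        confusion=confusion,
        classes=classes,
        fold_selections=tuple(fold_selections),
        final_map=final_map,
        n_select=n_select,
    )


def _map_columns(imap, patterns: PatternSet) -> np.ndarray:
    """Column indices (into the PatternSet) of an InformationMap's voxels."""
    lookup = {tuple(v): j for j, v in enumerate(patterns.voxel_index)}
    return np.array(sorted(lookup[tuple(v)] for v in imap.selected), dtype=np.int64)


def empirical_p(observed: float, null_accuracies: np.ndarray) -> float:
    """p = (1 + #{null >= observed}) / (n_perm + 1)."""
    null_accuracies = np.asarray(null_accuracies)
    return float((1 + np.sum(null_accuracies >= observed)) / (len(null_accuracies) + 1))


@dataclass(frozen=True)
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float


def permutation_chance(
    patterns: PatternSet,
    mask: ROIMask,
    sl_spec=None,
    n_select: int = 100,
    cfg: ClassifierConfig | None = None,
    *,
    inner_folds: int = 5,
    n_perm: int = 20,
    seed: int = 0,
    run_observed: bool = True,
) -> PermutationResult:
    """Null distribution of the full nested pipeline under label permutation.

    Labels are permuted within condition (cued labels among cued trials, free
    among free), the complete nested searchlight + SVM leave-one-trial-out
    pipeline is rerun per permutation, and the empirical p-value is
    ``(1 + #{null >= observed}) / (n_perm + 1)``.  With ``run_observed=False``
    the observed accuracy is skipped (NaN) — useful when only the null
    distribution itself is of interest.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    def _run(ps: PatternSet) -> float:
        res = cross_validate_decoding(
            ps,
            mask,
            sl_spec,
            n_select,
            cfg,
            inner_folds=inner_folds,
            selection="nested",
            compute_final_map=False,
        )
        return res.accuracy

    observed = _run(patterns) if run_observed else float("nan")
    conditions = patterns.conditions
    null = np.empty(n_perm)
    for p in range(n_perm):
        labels = patterns.labels.copy()
        for cond in np.unique(conditions):
            idx = np.flatnonzero(conditions == cond)
            labels[idx] = labels[idx[rng.permutation(len(idx))]]
        null[p] = _run(patterns.with_labels(labels))
    pval = empirical_p(observed, null) if run_observed else float("nan")
    return PermutationResult(
        observed_accuracy=observed, null_accuracies=null, p_value=pval
    )
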