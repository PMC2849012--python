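"""Searchlight feature selection: score every ROI voxel by how well its local
neighborhood decodes the memories, then keep the top scorers.

A searchlight visits each ROI voxel in turn, restricts the pattern matrix to
the voxels within a small radius (the neighborhood never leaves the mask),
and records the inner cross-validated accuracy of the multiclass linear SVM
on that neighborhood.  The subject's "information map" is the set of voxels
with the highest scores — the voxels carrying the most episodic information.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import _svm
from .decoder import ClassifierConfig
from .design import ROIMask
from .preprocess import PatternSet

__all__ = [
    "SearchlightSpec",
    "ScoreMap",
    "InformationMap",
    "neighborhood",
    "neighborhood_table",
    "score_searchlights",
    "build_information_map",
    "DEFAULT_N_SELECT",
]

#: default size of the information map (top-scoring voxels kept per ROI).
DEFAULT_N_SELECT = 100


@dataclass(frozen=True)
class SearchlightSpec:
    """Neighborhood geometry: radius-1 chebyshev is the 27-voxel cube."""

    radius_vox: int = 1
    metric: str = "chebyshev"
    min_neighborhood: int = 9

    def __post_init__(self) -> None:
        if self.radius_vox < 0:
            raise ValueError("radius_vox must be >= 0")
        if self.metric not in ("chebyshev", "euclidean"):
            raise ValueError("metric must be 'chebyshev' or 'euclidean'")
        if self.min_neighborhood < 1:
            raise ValueError("min_neighborhood must be >= 1")

    def offsets(self) -> np.ndarray:
        """All integer offsets within the radius, lexicographic order."""
        r = self.radius_vox
        offs = []
        for d in product(range(-r, r + 1), repeat=3):
            if self.metric == "euclidean" and sum(x * x for x in d) > r * r:
                continue
            offs.append(d)
        return np.array(offs, dtype=np.int64)


def neighborhood(
    mask: ROIMask, center: tuple[int, int, int], spec: SearchlightSpec
) -> np.ndarray:
    """Mask voxels within the searchlight radius of ``center`` (inclusive),
    lexicographically ordered.  ``center`` must itself be in the mask."""
    if not mask.contains(center):
        raise ValueError(f"center {center} is not in mask {mask.name!r}")
    in_mask = {tuple(v) for v in mask.voxels}
    c = np.asarray(center)
    out = [tuple(c + o) for o in spec.offsets() if tuple(c + o) in in_mask]
    return np.array(sorted(out), dtype=np.int64)


def neighborhood_table(mask: ROIMask, spec: SearchlightSpec):
    """Neighborhood column indices for every mask voxel (CSR-style).

    Returns ``(cols, offsets)``: the neighborhood of voxel ``v`` (row index
    into ``mask.voxels``) is ``cols[offsets[v]:offsets[v+1]]``, holding
    column indices into the mask's voxel order.
    """
    index = {tuple(v): j for j, v in enumerate(mask.voxels)}
    offs = spec.offsets()
    cols: list[int] = []
    offsets = np.zeros(mask.n_voxels + 1, dtype=np.int64)
    for j, v in enumerate(mask.voxels):
        hits = sorted(
            index[t] for o in offs if (t := tuple(v + o)) in index
        )
        cols.extend(hits)
        offsets[j + 1] = len(cols)
    return np.array(cols, dtype=np.int64), offsets


@dataclass(frozen=True)
class ScoreMap:
    """Inner-CV accuracy per ROI voxel, aligned with ``mask.voxels``."""

    scores: np.ndarray
    mask: ROIMask
    spec: SearchlightSpec
    n_inner_folds: int

    def __post_init__(self) -> None:
        if len(self.scores) != self.mask.n_voxels:
            raise ValueError("one score per ROI voxel required")
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError("scores must lie in [0, 1]")

    def to_dense(self) -> np.ndarray:
        out = np.zeros(self.mask.grid_shape, dtype=np.float64)
        vx = self.mask.voxels
        out[vx[:, 0], vx[:, 1], vx[:, 2]] = self.scores
        return out


@dataclass(frozen=True)
class InformationMap:
    """The selected most-informative voxels of one subject's ROI."""

    selected: np.ndarray  # (n, 3), lex-sorted
    n_select: int
    roi_name: str
    grid_shape: tuple[int, int, int]
    subject_id: int | None = None

    @property
    def selected_set(self) -> set[tuple[int, int, int]]:
        return {tuple(v) for v in self.selected}

    def to_dense(self) -> np.ndarray:
        out = np.zeros(self.grid_shape, dtype=np.uint8)
        s = self.selected
        out[s[:, 0], s[:, 1], s[:, 2]] = 1
        return out


def score_searchlights(
    patterns: PatternSet,
    mask: ROIMask,
    spec: SearchlightSpec | None = None,
    *,
    inner_folds: int = 5,
    cfg: ClassifierConfig | None = None,
    _table=None,
) -> ScoreMap:
    """Score every ROI voxel by its neighborhood's inner-CV decodability.

    The inner loop is stratified ``inner_folds``-fold cross-validation of the
    one-vs-one linear SVM, with per-voxel z-scoring computed from each inner
    training fold only.  Neighborhoods smaller than ``spec.min_neighborhood``
    score 0.
    """
    spec = spec or SearchlightSpec()
    cfg = cfg or ClassifierConfig()
    if patterns.n_voxels != mask.n_voxels or not np.array_equal(
        patterns.voxel_index, mask.voxels
    ):
        raise ValueError("patterns are not aligned with this mask's voxels")
    if inner_folds < 2:
        raise ValueError("inner_folds must be >= 2")
    if patterns.n_trials < inner_folds:
        raise ValueError("fewer trials than inner folds")
    classes, codes = np.unique(patterns.labels, return_inverse=True)
    counts = np.bincount(codes)
    if counts.min() < inner_folds:
        raise ValueError(
            f"every class needs >= {inner_folds} trials for stratified "
            f"{inner_folds}-fold inner CV (have {counts.min()})"
        )
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=False)
    tr_all: list[np.ndarray] = []
    te_all: list[np.ndarray] = []
    for tr, te in skf.split(np.zeros(len(codes)), codes):
        tr_all.append(tr)
        te_all.append(te)
    fold_train = np.concatenate(tr_all).astype(np.int64)
    fold_test = np.concatenate(te_all).astype(np.int64)
    fold_train_off = np.cumsum([0] + [len(a) for a in tr_all]).astype(np.int64)
    fold_test_off = np.cumsum([0] + [len(a) for a in te_all]).astype(np.int64)

    cols, offsets = _table if _table is not None else neighborhood_table(mask, spec)
    X = np.ascontiguousarray(patterns.matrix, dtype=np.float64)
    correct, tested = _svm.score_searchlights_kernel(
        X,
        codes.astype(np.int64),
        len(classes),
        fold_train,
        fold_train_off,
        fold_test,
        fold_test_off,
        cols,
        offsets,
        spec.min_neighborhood,
        cfg.C,
        cfg.balanced,
        cfg.tol,
        cfg.max_iter,
    )
    scores = correct / np.maximum(tested, 1)
    return ScoreMap(scores=scores, mask=mask, spec=spec, n_inner_folds=inner_folds)


def build_information_map(
    scores: ScoreMap,
    n_select: int = DEFAULT_N_SELECT,
    *,
    subject_id: int | None = None,
) -> InformationMap:
    """Keep the ``n_select`` highest-scoring voxels (clipped to the ROI size);
    ties break toward the lexicographically first voxel, so the selection is
    deterministic."""
    if n_select < 1:
        raise ValueError("n_select must be >= 1")
    n = min(n_select, scores.mask.n_voxels)
    # voxels are lex-sorted, so a stable sort on -score realizes the tie rule
    order = np.argsort(-scores.scores, kind="stable")[:n]
    selected = scores.mask.voxels[np.sort(order)]
    return InformationMap(
        selected=selected,
        n_select=n_select,
        roi_name=scores.mask.name,
        grid_shape=scores.mask.grid_shape,
        subject_id=subject_id,
    )
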