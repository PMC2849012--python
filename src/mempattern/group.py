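"""Group-level aggregation: frequency heat maps and voxelwise binomial tests.

Subject information maps on a common grid are summed into an integer
frequency map (how many subjects selected each voxel, at most the number of
subjects).  Each voxel's count is then compared against a Binomial(n, p0)
null — p0 being the probability that a voxel would be selected by chance in
one subject — via the inclusive upper tail P(X >= k), computed by exact
summation of the mass function.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .searchlight import InformationMap

__all__ = [
    "HeatMap",
    "PMap",
    "aggregate_heat_map",
    "binomial_voxel_pvalues",
    "binomial_tail",
    "threshold_map",
    "resample_information_map",
]


@dataclass(frozen=True)
class HeatMap:
    """Voxelwise count of subject maps containing each voxel."""

    counts: np.ndarray  # 3D int
    n_subjects: int

    def __post_init__(self) -> None:
        if self.counts.min() < 0 or self.counts.max() > self.n_subjects:
            raise ValueError("counts must lie in [0, n_subjects]")


@dataclass(frozen=True)
class PMap:
    """Upper-tail binomial p-value per voxel for the heat map's counts."""

    p: np.ndarray  # 3D float in (0, 1]
    p0: float
    n_subjects: int


def aggregate_heat_map(maps: list[InformationMap]) -> HeatMap:
    """Sum subject information maps into a frequency heat map.

    All maps must share one grid (synthetic cohorts do by construction; use
    :func:`resample_information_map` first for externally aligned maps).
    """
    if not maps:
        raise ValueError("need at least one information map")
    grid = maps[0].grid_shape
    for m in maps:
        if m.grid_shape != grid:
            raise ValueError(
                f"grid mismatch: {m.grid_shape} vs {grid}; resample to a "
                "common grid first"
            )
    counts = np.zeros(grid, dtype=np.int64)
    for m in maps:
        counts += m.to_dense().astype(np.int64)
    return HeatMap(counts=counts, n_subjects=len(maps))


def binomial_tail(k: int, n: int, p0: float) -> float:
    """Inclusive upper tail P(X >= k) for X ~ Binomial(n, p0), summed term by
    term from the exact mass function."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly between 0 and 1")
    k = max(int(k), 0)
    if k > n:
        return 0.0
    total = 0.0
    for j in range(k, n + 1):
        total += comb(n, j) * p0**j * (1.0 - p0) ** (n - j)
    return min(total, 1.0)


def binomial_voxel_pvalues(heat: HeatMap, p0: float) -> PMap:
    """Upper-tail binomial p-value for every voxel's frequency count."""
    n = heat.n_subjects
    tails = np.array([binomial_tail(k, n, p0) for k in range(n + 1)])
    return PMap(p=tails[heat.counts], p0=float(p0), n_subjects=n)


def threshold_map(
    pmap: PMap,
    alpha: float,
    *,
    bonferroni: bool = False,
    n_tests: int | None = None,
) -> np.ndarray:
    """Voxels with p strictly below ``alpha`` (uncorrected by default).

    With ``bonferroni=True`` the threshold becomes ``alpha / n_tests``;
    ``n_tests`` must then be given (typically the number of ROI voxels).
    Returns a lex-sorted (m, 3) voxel index array.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    thresh = alpha
    if bonferroni:
        if n_tests is None or n_tests < 1:
            raise ValueError("bonferroni correction requires n_tests >= 1")
        thresh = alpha / n_tests
    return np.argwhere(pmap.p < thresh)


def resample_information_map(
    imap: InformationMap,
    source_affine: np.ndarray,
    target_affine: np.ndarray,
    target_shape: tuple[int, int, int],
) -> InformationMap:
    """Nearest-neighbor affine resampling of a binary map onto another grid.

    This is the only spatial-normalization contract provided: voxel indices
    are mapped through ``source_affine`` to world coordinates and back
    through ``target_affine``; out-of-grid voxels are dropped.  Nonlinear
    stereotactic warping is out of scope.
    """
    src = np.asarray(source_affine, dtype=np.float64)
    tgt = np.asarray(target_affine, dtype=np.float64)
    if src.shape != (4, 4) or tgt.shape != (4, 4):
        raise ValueError("affines must be 4x4 matrices")
    hom = np.hstack([imap.selected, np.ones((len(imap.selected), 1))])
    world = hom @ src.T
    tgt_idx = np.rint(world @ np.linalg.inv(tgt).T[:, :3]).astype(np.int64)
    inside = np.all((tgt_idx >= 0) & (tgt_idx < np.asarray(target_shape)), axis=1)
    uniq = np.unique(tgt_idx[inside], axis=0)
    return InformationMap(
        selected=uniq,
        n_select=imap.n_select,
        roi_name=imap.roi_name,
        grid_shape=tuple(target_shape),
        subject_id=imap.subject_id,
    )
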