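"""Time-series preprocessing: linear detrend, hemodynamic onset shift, trial patterns.

The decoding pipeline never models the hemodynamic response explicitly.  Instead,
each trial's multivoxel response pattern is taken as the mean of a short window of
volumes starting a fixed number of volumes after trial onset (the hemodynamic
delay), after removing a first-order polynomial trend fitted to the whole run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import detrend as _scipy_detrend

from .design import ROIMask, TrialDesign

__all__ = [
    "BOLDRun",
    "PatternSet",
    "linear_detrend",
    "shift_onsets",
    "extract_trial_patterns",
]

#: Repetition time of the emulated acquisition, seconds per volume.
DEFAULT_TR_S = 3.5


@dataclass(frozen=True)
class BOLDRun:
    """A single 4D voxel time-series on a regular grid.

    Parameters
    ----------
    data
        Array of shape ``(x, y, z, n_volumes)``.
    tr_s
        Repetition time in seconds (time between successive volumes).
    """

    data: np.ndarray
    tr_s: float = DEFAULT_TR_S

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError(f"BOLDRun.data must be 4D, got shape {self.data.shape}")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class PatternSet:
    """Trial-by-voxel feature matrix tied to an ROI mask.

    ``matrix[i, j]`` is trial *i*'s response at voxel ``voxel_index[j]``.
    Column order follows ``voxel_index`` (lexicographically sorted voxel
    coordinates, matching :attr:`ROIMask.voxels`).
    """

    matrix: np.ndarray
    labels: np.ndarray
    conditions: np.ndarray
    voxel_index: np.ndarray
    mask_name: str = ""

    def __post_init__(self) -> None:
        n, v = self.matrix.shape
        if len(self.labels) != n or len(self.conditions) != n:
            raise ValueError("labels/conditions length must equal the number of trials")
        if len(self.voxel_index) != v:
            raise ValueError("voxel_index length must equal the number of columns")

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset(self, index: np.ndarray) -> "PatternSet":
        """Row subset (trial selection); keeps the voxel space unchanged."""
        index = np.asarray(index)
        return PatternSet(
            matrix=self.matrix[index],
            labels=self.labels[index],
            conditions=self.conditions[index],
            voxel_index=self.voxel_index,
            mask_name=self.mask_name,
        )

    def filter_condition(self, condition: str) -> "PatternSet":
        """Restrict to one retrieval mode: ``'cued'``, ``'free'`` or ``'both'``."""
        if condition == "both":
            return self
        if condition not in ("cued", "free"):
            raise ValueError(f"unknown condition {condition!r}")
        return self.subset(np.flatnonzero(self.conditions == condition))

    def with_labels(self, labels: np.ndarray) -> "PatternSet":
        return replace(self, labels=np.asarray(labels))


def linear_detrend(run: BOLDRun) -> BOLDRun:
    """Remove a first-order polynomial (intercept + slope) from every voxel.

    The linear drift is fitted by ordinary least squares to the whole run and
    subtracted from the voxel intensities, so each residual series has zero
    mean and zero least-squares slope.  Idempotent up to floating-point noise.
    """
    if run.n_volumes < 2:
        raise ValueError("linear detrend requires at least 2 volumes")
    if not np.all(np.isfinite(run.data)):
        raise ValueError("run contains non-finite values")
    out = _scipy_detrend(np.asarray(run.data, dtype=np.float64), axis=-1, type="linear")
    return BOLDRun(data=out, tr_s=run.tr_s)


def shift_onsets(
    design: TrialDesign, delay_volumes: int, *, window_volumes: int = 1
) -> TrialDesign:
    """Shift every trial onset later by ``delay_volumes`` volumes.

    This accounts for the lag of the hemodynamic response relative to the
    cognitive event: the pattern window should cover volumes in which the
    BOLD signal actually reflects the trial.

    Raises if any shifted onset plus the pattern window would run past the
    end of the run.
    """
    if delay_volumes < 0:
        raise ValueError("delay_volumes must be >= 0")
    if window_volumes < 1:
        raise ValueError("window_volumes must be >= 1")
    shifted = design.with_onsets(design.onsets + delay_volumes)
    last_needed = int(shifted.onsets.max()) + window_volumes if shifted.n_trials else 0
    if last_needed > design.n_volumes:
        raise ValueError(
            f"shift by {delay_volumes} volumes pushes a trial window past the run "
            f"end (needs {last_needed} volumes, run has {design.n_volumes})"
        )
    return shifted


def extract_trial_patterns(
    run: BOLDRun,
    design: TrialDesign,
    mask: ROIMask,
    window_volumes: int = 2,
) -> PatternSet:
    """One pattern vector per trial: the window mean over mask voxels.

    Row *i* is the mean of ``window_volumes`` consecutive volumes starting at
    trial *i*'s (already shifted) onset, restricted to the mask voxels in
    lexicographic order.  Intervals are half-open: ``[onset, onset + window)``.
    """
    if window_volumes < 1:
        raise ValueError("window_volumes must be >= 1")
    if mask.n_voxels == 0:
        raise ValueError("empty ROI mask")
    if run.grid_shape != mask.grid_shape:
        raise ValueError(
            f"run grid {run.grid_shape} != mask grid {mask.grid_shape}"
        )
    onsets = design.onsets
    if design.n_trials and int(onsets.max()) + window_volumes > run.n_volumes:
        raise ValueError("trial window runs past the end of the run")
    vx = mask.voxels
    roi_series = run.data[vx[:, 0], vx[:, 1], vx[:, 2], :]  # (n_vox, n_vol)
    rows = np.empty((design.n_trials, mask.n_voxels), dtype=np.float64)
    for i, onset in enumerate(onsets):
        rows[i] = roi_series[:, onset : onset + window_volumes].mean(axis=1)
    return PatternSet(
        matrix=rows,
        labels=design.labels.copy(),
        conditions=design.conditions.copy(),
        voxel_index=vx.copy(),
        mask_name=mask.name,
    )
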