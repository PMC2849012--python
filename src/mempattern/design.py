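"""Trial designs and ROI masks.

The emulated experiment has two blocks in one continuous run: a cued-recall
block in which each of ``n_classes`` episodic memories is probed a fixed
number of times in pseudorandom order (never the same memory twice in a row),
then a rest gap, then a free-recall block in which the participant chooses
which memory to recall on each trial.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DesignConfig",
    "Trial",
    "TrialDesign",
    "ROIMask",
    "EllipsoidSpec",
    "generate_trial_design",
    "generate_roi_masks",
]

CUED = "cued"
FREE = "free"


@dataclass(frozen=True)
class DesignConfig:
    """Trial-design parameters.

    Defaults reproduce the study layout: 3 memories, 7 cued repetitions each
    (21 cued trials), 30 free-recall trials.
    """

    n_classes: int = 3
    cued_reps_per_class: int = 7
    free_trials: int = 30
    #: onset-to-onset spacing within a block, in volumes.
    inter_trial_volumes: int = 6
    #: gap between the cued and free blocks, in volumes (~30 s at TR 3.5 s).
    rest_gap_volumes: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.cued_reps_per_class < 1:
            raise ValueError("cued_reps_per_class must be >= 1")
        if self.free_trials < self.n_classes:
            raise ValueError("free_trials must be >= n_classes (each memory sampled)")
        if self.inter_trial_volumes < 1 or self.rest_gap_volumes < 0:
            raise ValueError("volume counts must be positive")


@dataclass(frozen=True)
class Trial:
    onset_volume: int
    condition: str  # "cued" | "free"
    label: int  # 1..n_classes


@dataclass(frozen=True)
class TrialDesign:
    """Ordered trial list for one run."""

    trials: tuple[Trial, ...]
    n_volumes: int

    def __post_init__(self) -> None:
        onsets = self.onsets
        if len(onsets) and not np.all(np.diff(onsets) > 0):
            raise ValueError("trial onsets must be strictly increasing")
        if len(onsets) and (onsets[0] < 0 or onsets[-1] >= self.n_volumes):
            raise ValueError("trial onsets must lie within the run")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([t.onset_volume for t in self.trials], dtype=np.int64)

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.trials], dtype=np.int64)

    @property
    def conditions(self) -> np.ndarray:
        return np.array([t.condition for t in self.trials], dtype=object)

    def with_onsets(self, onsets: np.ndarray) -> "TrialDesign":
        trials = tuple(
            replace(t, onset_volume=int(o)) for t, o in zip(self.trials, onsets)
        )
        return replace(self, trials=trials)

    def filter_condition(self, condition: str) -> "TrialDesign":
        if condition == "both":
            return self
        trials = tuple(t for t in self.trials if t.condition == condition)
        return replace(self, trials=trials)


def _sequence_without_repeats(
    counts: np.ndarray, rng: np.random.Generator, max_restarts: int = 10_000
) -> list[int]:
    """Pseudorandom label sequence with given per-class counts and no two equal
    labels adjacent.  Sequential sampling with restart on dead ends."""
    n_classes = len(counts)
    total = int(counts.sum())
    # a class needed more than ceil(total/2) times cannot avoid self-adjacency
    if counts.max() > (total + 1) // 2:
        raise ValueError(
            "infeasible design: one class has too many repetitions to avoid "
            "immediate repeats"
        )
    for _ in range(max_restarts):
        remaining = counts.copy()
        seq: list[int] = []
        prev = -1
        ok = True
        for _pos in range(total):
            avail = [c for c in range(n_classes) if remaining[c] > 0 and c != prev]
            if not avail:
                ok = False
                break
            c = int(rng.choice(avail))
            seq.append(c + 1)  # class ids are 1-based
            remaining[c] -= 1
            prev = c
        if ok:
            return seq
    raise ValueError("could not build a no-repeat sequence (infeasible design?)")


def generate_trial_design(cfg: DesignConfig) -> TrialDesign:
    """Build the two-block design: cued block (balanced, no immediate label
    repeats), rest gap, then free-recall block (uniform labels, every class
    sampled at least once).  Deterministic for a fixed ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    counts = np.full(cfg.n_classes, cfg.cued_reps_per_class, dtype=np.int64)
    cued_labels = _sequence_without_repeats(counts, rng)

    while True:  # free-recall choices: uniform, but each memory visited
        free_labels = rng.integers(1, cfg.n_classes + 1, size=cfg.free_trials)
        if len(np.unique(free_labels)) == cfg.n_classes:
            break

    step = cfg.inter_trial_volumes
    trials: list[Trial] = []
    onset = 0
    for lab in cued_labels:
        trials.append(Trial(onset, CUED, int(lab)))
        onset += step
    onset += cfg.rest_gap_volumes
    for lab in free_labels:
        trials.append(Trial(onset, FREE, int(lab)))
        onset += step
    # the final inter-trial interval is the tail margin for delay + window
    n_volumes = onset
    return TrialDesign(trials=tuple(trials), n_volumes=n_volumes)


@dataclass(frozen=True)
class ROIMask:
    """A set of voxels on a regular 3D grid.

    ``voxels`` is an ``(n, 3)`` integer array in lexicographic order; this
    order defines the column order of every :class:`PatternSet` extracted
    from the mask.
    """

    grid_shape: tuple[int, int, int]
    voxels: np.ndarray
    voxel_size_mm: float = 1.5
    name: str = "ROI"

    def __post_init__(self) -> None:
        vx = np.asarray(self.voxels, dtype=np.int64)
        if vx.ndim != 2 or vx.shape[1] != 3 or vx.shape[0] == 0:
            raise ValueError("voxels must be a non-empty (n, 3) index array")
        if np.any(vx < 0) or np.any(vx >= np.asarray(self.grid_shape)):
            raise ValueError("mask voxels outside the grid")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        order = np.lexsort((vx[:, 2], vx[:, 1], vx[:, 0]))
        object.__setattr__(self, "voxels", vx[order])

    @property
    def n_voxels(self) -> int:
        return self.voxels.shape[0]

    def contains(self, index: tuple[int, int, int]) -> bool:
        return bool(np.any(np.all(self.voxels == np.asarray(index), axis=1)))

    def to_dense(self) -> np.ndarray:
        """0/1 volume of the mask on its grid."""
        out = np.zeros(self.grid_shape, dtype=np.uint8)
        out[self.voxels[:, 0], self.voxels[:, 1], self.voxels[:, 2]] = 1
        return out

    @classmethod
    def from_dense(
        cls, volume: np.ndarray, voxel_size_mm: float = 1.5, name: str = "ROI"
    ) -> "ROIMask":
        vx = np.argwhere(volume > 0)
        return cls(tuple(volume.shape), vx, voxel_size_mm, name)


@dataclass(frozen=True)
class EllipsoidSpec:
    """Axis-aligned discrete ellipsoid: voxels v with sum(((v-c)/r)^2) <= 1."""

    name: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ValueError("ellipsoid radii must be positive")


def generate_roi_masks(
    grid_shape: tuple[int, int, int],
    specs: list[EllipsoidSpec],
    voxel_size_mm: float = 1.5,
) -> list[ROIMask]:
    """Deterministic disjoint ellipsoidal masks (e.g. HC / EC / PHG analogs).

    Raises if an ellipsoid reaches outside the grid or if two masks overlap.
    """
    grid = np.asarray(grid_shape)
    masks: list[ROIMask] = []
    claimed: set[tuple[int, int, int]] = set()
    for spec in specs:
        c = np.asarray(spec.center, dtype=np.float64)
        r = np.asarray(spec.radii, dtype=np.float64)
        if np.any(c - r < -0.5) or np.any(c + r > grid - 0.5):
            raise ValueError(f"ROI {spec.name!r} exceeds the grid {grid_shape}")
        lo = np.maximum(np.floor(c - r).astype(int), 0)
        hi = np.minimum(np.ceil(c + r).astype(int), grid - 1)
        vox: list[tuple[int, int, int]] = []
        for x in range(lo[0], hi[0] + 1):
            for y in range(lo[1], hi[1] + 1):
                for z in range(lo[2], hi[2] + 1):
                    d = (np.array([x, y, z]) - c) / r
                    if float(d @ d) <= 1.0:
                        vox.append((x, y, z))
        overlap = claimed.intersection(vox)
        if overlap:
            raise ValueError(
                f"ROI {spec.name!r} overlaps a previous mask at {sorted(overlap)[:3]}..."
            )
        claimed.update(vox)
        masks.append(
            ROIMask(
                grid_shape=tuple(grid_shape),
                voxels=np.array(vox, dtype=np.int64),
                voxel_size_mm=voxel_size_mm,
                name=spec.name,
            )
        )
    return masks
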