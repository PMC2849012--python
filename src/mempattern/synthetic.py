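"""Synthetic BOLD pattern simulation.

Each subject's run is baseline + per-voxel linear drift + i.i.d. Gaussian
noise over the whole grid; on top of that, every trial adds its memory's
multivoxel amplitude pattern over a small set of spatially clustered
"informative" voxels, in a boxcar window starting a fixed hemodynamic delay
after trial onset.  The boxcar (rather than a convolved hemodynamic response)
is deliberate: the decoding pipeline only ever consumes window averages, so a
boxcar keeps the recovery oracles exact.

Class patterns are random sign patterns (+/- effect_size per informative
voxel), pairwise distinct whenever the effect size is positive; their
expected pairwise correlation is zero, so discriminability scales with
``effect_size / noise_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import (
    CUED,
    DesignConfig,
    EllipsoidSpec,
    ROIMask,
    TrialDesign,
    generate_roi_masks,
    generate_trial_design,
)
from .preprocess import BOLDRun

__all__ = [
    "SignalConfig",
    "GroundTruth",
    "SubjectData",
    "Cohort",
    "synthesize_run",
    "generate_cohort",
    "draw_informative_voxels",
    "default_roi_specs",
    "DEMO_GRID_SHAPE",
]

#: Grid used by the bundled demo/cohort presets (1.5 mm isotropic voxels).
DEMO_GRID_SHAPE: tuple[int, int, int] = (20, 20, 20)


@dataclass(frozen=True)
class SignalConfig:
    """Parameters of the implanted multivoxel signal.

    ``effect_size`` is the per-voxel pattern amplitude in the same arbitrary
    units as ``noise_sd``; the default 3.0 is a deliberately strong,
    well-recoverable signal, while 0.0 gives a pure-noise (null) subject.
    """

    n_informative_clusters: int = 2
    cluster_radius_vox: float = 1.0  # euclidean, in voxels
    effect_size: float = 3.0
    noise_sd: float = 1.0
    drift_slope: float = 0.02  # intensity units per volume
    hemodynamic_delay_volumes: int = 2  # 7 s at TR 3.5 s
    pattern_window_volumes: int = 2
    baseline: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_informative_clusters < 1:
            raise ValueError("need at least one informative cluster")
        if self.hemodynamic_delay_volumes < 0 or self.pattern_window_volumes < 1:
            raise ValueError("invalid window parameters")


@dataclass(frozen=True)
class GroundTruth:
    """Which voxels carry signal, and each memory's amplitude pattern.

    ``class_patterns[k]`` is the amplitude vector of class ``k + 1`` over
    ``informative_voxels`` (lexicographic voxel order).
    """

    informative_voxels: np.ndarray  # (m, 3) int, lex-sorted
    class_patterns: np.ndarray  # (n_classes, m)

    @property
    def informative_set(self) -> set[tuple[int, int, int]]:
        return {tuple(v) for v in self.informative_voxels}


@dataclass(frozen=True)
class SubjectData:
    subject_id: int
    design: TrialDesign
    run: BOLDRun
    truths: dict[str, GroundTruth]  # per ROI name


@dataclass(frozen=True)
class Cohort:
    grid_shape: tuple[int, int, int]
    masks: list[ROIMask]
    subjects: list[SubjectData]


def default_roi_specs(grid_shape: tuple[int, int, int] = DEMO_GRID_SHAPE):
    """Three disjoint medial-temporal-lobe ROI analogs on the demo grid.

    Sizes are scaled-down stand-ins (the real structures hold thousands of
    1.5 mm voxels): HC is the largest, EC the smallest.
    """
    if grid_shape != DEMO_GRID_SHAPE:
        scale = np.asarray(grid_shape) / np.asarray(DEMO_GRID_SHAPE)
    else:
        scale = np.ones(3)

    def _s(center, radii):
        return (
            tuple(np.asarray(center) * scale),
            tuple(np.maximum(np.asarray(radii) * scale, 1.0)),
        )

    hc = _s((6.0, 10.0, 10.0), (3.0, 4.0, 3.0))
    ec = _s((14.0, 5.0, 9.0), (2.0, 2.5, 2.0))
    phg = _s((14.0, 14.0, 10.0), (2.5, 3.0, 2.5))
    return [
        EllipsoidSpec("HC", hc[0], hc[1]),
        EllipsoidSpec("EC", ec[0], ec[1]),
        EllipsoidSpec("PHG", phg[0], phg[1]),
    ]


def draw_informative_voxels(
    mask: ROIMask, cfg: SignalConfig, rng: np.random.Generator
) -> np.ndarray:
    """Cluster centers drawn uniformly from the ROI (without replacement);
    the informative set is the union of euclidean balls around the centers,
    clipped to the ROI.  Returns a lex-sorted (m, 3) array."""
    n = min(cfg.n_informative_clusters, mask.n_voxels)
    centers = mask.voxels[rng.choice(mask.n_voxels, size=n, replace=False)]
    keep = np.zeros(mask.n_voxels, dtype=bool)
    for c in centers:
        d2 = ((mask.voxels - c) ** 2).sum(axis=1)
        keep |= d2 <= cfg.cluster_radius_vox**2
    return mask.voxels[keep]


def _draw_class_patterns(
    n_classes: int, n_voxels: int, cfg: SignalConfig, rng: np.random.Generator
) -> np.ndarray:
    if cfg.effect_size == 0.0:
        return np.zeros((n_classes, n_voxels))
    for _ in range(1000):
        signs = rng.choice([-1.0, 1.0], size=(n_classes, n_voxels))
        distinct = all(
            not np.array_equal(signs[a], signs[b])
            for a in range(n_classes)
            for b in range(a + 1, n_classes)
        )
        if distinct:
            return signs * cfg.effect_size
    raise ValueError(
        "could not draw pairwise-distinct class patterns (too few informative voxels)"
    )


def _base_run(
    n_volumes: int,
    grid_shape: tuple[int, int, int],
    cfg: SignalConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    t = np.arange(n_volumes, dtype=np.float64)
    data = rng.normal(0.0, cfg.noise_sd, size=(*grid_shape, n_volumes))
    data += cfg.baseline + cfg.drift_slope * t
    return data


def _implant(
    data: np.ndarray, design: TrialDesign, truth: GroundTruth, cfg: SignalConfig
) -> None:
    """Add each trial's class pattern over the informative voxels, in the
    boxcar window ``[onset + delay, onset + delay + window)``."""
    n_volumes = data.shape[3]
    vx = truth.informative_voxels
    for trial in design.trials:
        start = trial.onset_volume + cfg.hemodynamic_delay_volumes
        stop = start + cfg.pattern_window_volumes
        if stop > n_volumes:
            raise ValueError(
                f"trial at volume {trial.onset_volume}: signal window "
                f"[{start}, {stop}) overruns the run ({n_volumes} volumes)"
            )
        pattern = truth.class_patterns[trial.label - 1]
        data[vx[:, 0], vx[:, 1], vx[:, 2], start:stop] += pattern[:, None]


def synthesize_run(
    design: TrialDesign,
    mask: ROIMask,
    cfg: SignalConfig,
    *,
    informative_voxels: np.ndarray | None = None,
    tr_s: float = 3.5,
) -> tuple[BOLDRun, GroundTruth]:
    """One subject's run with signal implanted in a single ROI.

    ``informative_voxels`` may be supplied (e.g. shared across a cohort);
    otherwise clusters are drawn from ``cfg.seed``.  Bit-identical for
    identical inputs.
    """
    rng = np.random.default_rng(cfg.seed)
    if informative_voxels is None:
        informative_voxels = draw_informative_voxels(mask, cfg, rng)
    else:
        informative_voxels = np.asarray(informative_voxels, dtype=np.int64)
        mask_set = {tuple(v) for v in mask.voxels}
        if not all(tuple(v) in mask_set for v in informative_voxels):
            raise ValueError("informative voxels must lie inside the ROI")
    n_classes = int(design.labels.max())
    patterns = _draw_class_patterns(n_classes, len(informative_voxels), cfg, rng)
    truth = GroundTruth(informative_voxels=informative_voxels, class_patterns=patterns)
    data = _base_run(design.n_volumes, mask.grid_shape, cfg, rng)
    _implant(data, design, truth, cfg)
    return BOLDRun(data=data, tr_s=tr_s), truth


def generate_cohort(
    n_subjects: int,
    design_cfg: DesignConfig,
    signal_cfg: SignalConfig,
    masks: list[ROIMask] | None = None,
    *,
    master_seed: int = 0,
    shared_clusters: bool = True,
    grid_shape: tuple[int, int, int] = DEMO_GRID_SHAPE,
    tr_s: float = 3.5,
) -> Cohort:
    """Independent subject datasets on one grid with shared ROI geometry.

    Per-subject seeds are ``master_seed + subject_index`` so any subject can
    be regenerated in isolation.  With ``shared_clusters`` the informative
    voxel sets are drawn once (from ``master_seed``) and shared by every
    subject — group overlap is then maximal; otherwise each subject draws
    independent clusters from the same uniform spatial prior over the ROI.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if masks is None:
        masks = generate_roi_masks(grid_shape, default_roi_specs(grid_shape))
    for m in masks:
        if m.grid_shape != tuple(grid_shape):
            raise ValueError("all masks must share the cohort grid")

    shared: dict[str, np.ndarray] = {}
    if shared_clusters:
        shared_rng = np.random.default_rng(master_seed)
        for m in masks:
            shared[m.name] = draw_informative_voxels(m, signal_cfg, shared_rng)

    subjects: list[SubjectData] = []
    for s in range(n_subjects):
        seed = master_seed + s
        rng = np.random.default_rng(seed)
        design = generate_trial_design(
            DesignConfig(
                n_classes=design_cfg.n_classes,
                cued_reps_per_class=design_cfg.cued_reps_per_class,
                free_trials=design_cfg.free_trials,
                inter_trial_volumes=design_cfg.inter_trial_volumes,
                rest_gap_volumes=design_cfg.rest_gap_volumes,
                seed=seed,
            )
        )
        n_classes = design_cfg.n_classes
        data = _base_run(design.n_volumes, tuple(grid_shape), signal_cfg, rng)
        truths: dict[str, GroundTruth] = {}
        for m in masks:
            if shared_clusters:
                informative = shared[m.name]
            else:
                informative = draw_informative_voxels(m, signal_cfg, rng)
            patterns = _draw_class_patterns(n_classes, len(informative), signal_cfg, rng)
            truth = GroundTruth(informative_voxels=informative, class_patterns=patterns)
            _implant(data, design, truth, signal_cfg)
            truths[m.name] = truth
        subjects.append(
            SubjectData(
                subject_id=s,
                design=design,
                run=BOLDRun(data=data, tr_s=tr_s),
                truths=truths,
            )
        )
    return Cohort(grid_shape=tuple(grid_shape), masks=list(masks), subjects=subjects)
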