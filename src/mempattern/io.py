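"""File formats: NIfTI volumes, TSV designs and pattern tables, JSON results.

Internally everything is 0-based voxel indices; the NIfTI affine is the only
world-coordinate authority.  Masks and binary maps are written as integer
volumes, runs and score maps as float32.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import ROIMask, Trial, TrialDesign
from .preprocess import BOLDRun, PatternSet

__all__ = [
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "write_run",
    "read_run",
    "write_design_tsv",
    "read_design_tsv",
    "write_patterns_tsv",
    "write_result_json",
]


def default_affine(voxel_size_mm: float = 1.5) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine)."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # noqa: BLE001 - surface the parse failure
        raise ValueError(f"could not read NIfTI volume {path}: {exc}") from exc
    return data, img.affine


def write_volume(
    data: np.ndarray, affine: np.ndarray, path: str | Path, dtype=None
) -> None:
    if dtype is not None:
        data = np.asarray(data, dtype=dtype)
    img = nib.Nifti1Image(data, np.asarray(affine, dtype=np.float64))
    nib.save(img, str(path))


def write_mask(mask: ROIMask, path: str | Path) -> None:
    write_volume(mask.to_dense(), default_affine(mask.voxel_size_mm), path, dtype=np.uint8)


def read_mask(path: str | Path, name: str = "ROI") -> ROIMask:
    data, affine = read_volume(path)
    voxel_size = float(np.abs(affine[0, 0])) or 1.5
    return ROIMask.from_dense(np.asarray(data), voxel_size_mm=voxel_size, name=name)


def write_run(run: BOLDRun, path: str | Path, voxel_size_mm: float = 1.5) -> None:
    write_volume(run.data, default_affine(voxel_size_mm), path, dtype=np.float32)


def read_run(path: str | Path, tr_s: float = 3.5) -> BOLDRun:
    data, _ = read_volume(path)
    return BOLDRun(data=np.asarray(data, dtype=np.float64), tr_s=tr_s)


def write_design_tsv(design: TrialDesign, path: str | Path) -> None:
    """TSV with onset_volume / condition / label columns; the run length is
    kept in a leading comment line so the file round-trips."""
    df = pd.DataFrame(
        {
            "onset_volume": design.onsets,
            "condition": design.conditions,
            "label": design.labels,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# n_volumes: {design.n_volumes}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_design_tsv(path: str | Path) -> TrialDesign:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# n_volumes:"):
            raise ValueError(f"{path}: missing '# n_volumes:' header line")
        n_volumes = int(first.split(":")[1])
        df = pd.read_csv(fh, sep="\t")
    required = {"onset_volume", "condition", "label"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: design TSV needs columns {sorted(required)}")
    trials = tuple(
        Trial(int(r.onset_volume), str(r.condition), int(r.label))
        for r in df.itertuples()
    )
    return TrialDesign(trials=trials, n_volumes=n_volumes)


def write_patterns_tsv(patterns: PatternSet, path: str | Path) -> None:
    cols = {"label": patterns.labels, "condition": patterns.conditions}
    for j, v in enumerate(patterns.voxel_index):
        cols[f"v{v[0]}_{v[1]}_{v[2]}"] = patterns.matrix[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_result_json(result, path: str | Path, extra: dict | None = None) -> None:
    """Serialize a DecodingResult (accuracy, confusion, per-trial table)."""
    payload = {
        "accuracy": result.accuracy,
        "classes": [int(c) for c in result.classes],
        "confusion": result.confusion.tolist(),
        "trials": [
            {"true": int(t), "predicted": int(p)}
            for t, p in zip(result.y_true, result.y_pred)
        ],
        "n_select": result.n_select,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))
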