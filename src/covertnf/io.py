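"""File formats: TSV ROI runs, JSONL feedback logs, NIfTI grids, YAML specs.

ROI runs are written as plain TSV (columns ``tr_index``, ``target1``,
``target2``, ``control``) with a JSON sidecar holding the run metadata, so
the time series stay readable by any table tool.  Voxel grids and masks go
through nibabel as NIfTI; cohort specs round-trip through YAML.  All readers
raise position-specific errors on malformed input.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import yaml

from covertnf.cohort import CohortSpec, RoiRun
from covertnf.feedback import FeedbackLog

_RUN_COLUMNS = ("tr_index", "target1", "target2", "control")


class ParseError(ValueError):
    """Malformed input file; message names the file and line."""


def write_roi_run(run: RoiRun, tsv_path: str | Path) -> Path:
    """Write one run as TSV plus a ``.json`` metadata sidecar."""
    tsv_path = Path(tsv_path)
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(_RUN_COLUMNS) + "\n")
        for t, row in enumerate(run.series):
            fh.write(f"{t}\t{row[0]:.10g}\t{row[1]:.10g}\t{row[2]:.10g}\n")
    sidecar = tsv_path.with_suffix(".json")
    meta = {
        "subject_id": run.subject_id,
        "day": run.day,
        "run_index": run.run_index,
        "run_type": run.run_type,
        "n_tr": run.n_tr,
    }
    sidecar.write_text(json.dumps(meta, indent=2) + "\n")
    return tsv_path


def read_roi_run(tsv_path: str | Path) -> RoiRun:
    """Read a TSV run and its sidecar back into a :class:`RoiRun`."""
    tsv_path = Path(tsv_path)
    rows: list[list[float]] = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _RUN_COLUMNS:
            raise ParseError(f"{tsv_path}:1: expected header {_RUN_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ParseError(
                    f"{tsv_path}:{lineno}: expected 4 tab-separated fields, got {len(parts)}"
                )
            try:
                idx = int(parts[0])
                vals = [float(p) for p in parts[1:]]
            except ValueError as exc:
                raise ParseError(f"{tsv_path}:{lineno}: {exc}") from None
            if idx != lineno - 2:
                raise ParseError(
                    f"{tsv_path}:{lineno}: tr_index {idx} out of order (expected {lineno - 2})"
                )
            rows.append(vals)
    sidecar = tsv_path.with_suffix(".json")
    if not sidecar.exists():
        raise ParseError(f"{sidecar}: metadata sidecar missing")
    meta = json.loads(sidecar.read_text())
    return RoiRun(
        subject_id=meta["subject_id"],
        day=meta["day"],
        run_index=int(meta["run_index"]),
        run_type=meta["run_type"],
        series=np.array(rows, dtype=float),
    )


def write_feedback_log(log: FeedbackLog, jsonl_path: str | Path) -> Path:
    """One decision per JSONL line, plus a ``.summary.json`` next to it."""
    jsonl_path = Path(jsonl_path)
    with open(jsonl_path, "w") as fh:
        for d in log.decisions:
            fh.write(json.dumps(asdict(d)) + "\n")
    summary = {
        "subject_id": log.subject_id,
        "day": log.day,
        "run_index": log.run_index,
        "n_decisions": len(log.decisions),
        "pieces_revealed": log.pieces_revealed,
        "boards_completed": log.boards_completed,
        "fired_fraction": log.fired_fraction,
    }
    Path(str(jsonl_path) + ".summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return jsonl_path


def write_nifti(
    data: np.ndarray, path: str | Path, voxel_size_mm: float = 3.2
) -> Path:
    """Write a 3-D/4-D array as NIfTI with an isotropic diagonal affine."""
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    nib.save(img, str(path))
    return Path(path)


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Return (data, affine) from a NIfTI file."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def spec_to_yaml(spec: CohortSpec, path: str | Path) -> Path:
    d = asdict(spec)
    d["baseline_corr"] = np.asarray(spec.baseline_corr).tolist()
    d["day_deltas"] = {k: list(v) for k, v in spec.day_deltas.items()}
    d["runs_per_day"] = dict(spec.runs_per_day)
    d["days"] = list(spec.days)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
    return Path(path)


def spec_from_yaml(path: str | Path) -> CohortSpec:
    d = yaml.safe_load(Path(path).read_text())
    d["baseline_corr"] = np.asarray(d["baseline_corr"], dtype=float)
    d["day_deltas"] = {k: tuple(v) for k, v in d["day_deltas"].items()}
    d["days"] = tuple(d["days"])
    return CohortSpec(**d)


def write_cohort(cohort_runs: Sequence[RoiRun], out_dir: str | Path) -> list[Path]:
    """One directory per subject/day; run files named by type and index."""
    out_dir = Path(out_dir)
    paths = []
    for run in cohort_runs:
        d = out_dir / run.subject_id / run.day
        d.mkdir(parents=True, exist_ok=True)
        paths.append(write_roi_run(run, d / f"{run.run_type}_{run.run_index:02d}.tsv"))
    return paths


def read_cohort(root: str | Path) -> list[RoiRun]:
    root = Path(root)
    return [read_roi_run(p) for p in sorted(root.rglob("*.tsv"))]
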