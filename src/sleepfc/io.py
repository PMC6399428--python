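"""File-format adapters.

Plain-text dialects used across the pipeline:

* ROI series: TSV, volumes x ROIs, header row of ROI names.
* Motion parameters: whitespace-delimited 6-column text, no header
  (the SPM ``rp_*.txt`` dialect).
* Respiration: 2-column CSV ``time_s,signal`` with header.
* State labels: TSV ``volume_index<TAB>label``.
* Cohort manifest: CSV with subject_id, group and file-path columns.
* Connectivity matrices: R x R TSV with ROI-name header/index plus a
  JSON metadata sidecar.
* Voxel data: NIfTI-1 with the TR recorded in the header; label maps as
  integer NIfTI plus a JSON sidecar mapping code -> ROI name.

Every writer/reader pair round-trips values to full precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .connectivity import ConnectivityMatrix
from .core import (MotionParams, RespirationTrace, RoiTimeSeriesSet, State,
                   StateLabels, state_to_code, code_to_state)
from .groupstats import GroupComparisonResult
from .synthdata import SyntheticCohortConfig, SyntheticSubject

__all__ = [
    "read_roi_tsv", "write_roi_tsv", "read_motion_txt", "write_motion_txt",
    "read_respiration_csv", "write_respiration_csv", "read_labels_tsv",
    "write_labels_tsv", "read_manifest", "write_manifest",
    "read_nifti_4d", "write_nifti_4d", "read_label_map", "write_label_map",
    "read_connectivity_tsv", "write_connectivity_tsv",
    "write_comparison_tsv", "read_comparison_tsv",
    "read_cohort_config", "write_cohort_config", "write_subject_files",
]

_FLOAT_FMT = "%.17g"


def write_roi_tsv(ts: RoiTimeSeriesSet, path: str | Path) -> None:
    df = pd.DataFrame(ts.values, columns=ts.roi_labels)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_roi_tsv(path: str | Path, tr_seconds: float) -> RoiTimeSeriesSet:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected >= 2 ROI columns")
    values = df.to_numpy(dtype=float)
    return RoiTimeSeriesSet(values, tr_seconds, [str(c) for c in df.columns])


def write_motion_txt(motion: MotionParams, path: str | Path) -> None:
    np.savetxt(path, motion.values, fmt=_FLOAT_FMT, delimiter="  ")


def read_motion_txt(path: str | Path) -> MotionParams:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(
                    f"{path}, line {lineno}: expected 6 motion columns, "
                    f"found {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(
                    f"{path}, line {lineno}: non-numeric cell") from exc
    if not rows:
        raise ValueError(f"{path}: empty motion file")
    return MotionParams(np.array(rows))


def write_respiration_csv(trace: RespirationTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "signal": trace.signal}).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def read_respiration_csv(path: str | Path) -> RespirationTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "signal"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    fs = 1.0 / float(np.median(np.diff(t)))
    return RespirationTrace(t, df["signal"].to_numpy(dtype=float), fs)


def write_labels_tsv(labels: StateLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("volume_index\tlabel\n")
        for i, code in enumerate(labels.codes):
            fh.write(f"{i}\t{code_to_state(code).value}\n")


def read_labels_tsv(path: str | Path, tr_seconds: float) -> StateLabels:
    df = pd.read_csv(path, sep="\t")
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing 'label' column")
    codes = np.array([state_to_code(State(v)) for v in df["label"]],
                     dtype=np.int8)
    return StateLabels(codes, tr_seconds)


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: manifest missing column {col!r}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{path}: duplicate subject ids {dupes}")
    bad = set(df["group"]) - {"control", "lesion"}
    if bad:
        raise ValueError(f"{path}: unknown groups {sorted(bad)}")
    return df


def write_nifti_4d(data: np.ndarray, path: str | Path,
                   tr_seconds: float | None = None,
                   affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    if tr_seconds is not None and data.ndim == 4:
        zooms = list(img.header.get_zooms())
        zooms[3] = tr_seconds
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def read_nifti_4d(path: str | Path) -> tuple[np.ndarray, float | None]:
    """Returns (data, tr_seconds from the header or None)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    tr = None
    if data.ndim == 4:
        zooms = img.header.get_zooms()
        if len(zooms) >= 4 and zooms[3] > 0:
            tr = float(zooms[3])
    return data, tr


def write_label_map(label_map: np.ndarray, roi_labels: list[str],
                    path: str | Path,
                    affine: np.ndarray | None = None) -> None:
    """Integer NIfTI plus a JSON sidecar mapping code -> ROI name."""
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(label_map, dtype=np.int16), affine)
    nib.save(img, str(path))
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "")
                   + ".json")
    sidecar.write_text(json.dumps(
        {str(i + 1): name for i, name in enumerate(roi_labels)}, indent=1))


def read_label_map(path: str | Path) -> tuple[np.ndarray, dict[str, int]]:
    """Returns (integer map, name -> code mapping from the sidecar)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(int)
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "")
                   + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"label-map sidecar {sidecar} not found")
    code_to_name = json.loads(sidecar.read_text())
    return data, {name: int(code) for code, name in code_to_name.items()}


def write_connectivity_tsv(matrix: ConnectivityMatrix,
                           path: str | Path) -> None:
    df = pd.DataFrame(matrix.z, index=matrix.roi_labels,
                      columns=matrix.roi_labels)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    meta = {"state": matrix.state.value, "subject_id": matrix.subject_id,
            "n_windows_used": matrix.n_windows_used}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_connectivity_tsv(path: str | Path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    meta_path = Path(str(path) + ".json")
    meta = (json.loads(meta_path.read_text()) if meta_path.exists()
            else {"state": State.WHOLE_SCAN.value, "subject_id": "",
                  "n_windows_used": 0})
    return ConnectivityMatrix(df.to_numpy(dtype=float),
                              [str(c) for c in df.columns],
                              State(meta["state"]),
                              subject_id=meta.get("subject_id", ""),
                              n_windows_used=meta.get("n_windows_used", 0))


def write_comparison_tsv(result: GroupComparisonResult,
                         path: str | Path) -> None:
    result.table.to_csv(path, sep="\t", index=False,
                        float_format=_FLOAT_FMT)
    meta = {"state": result.state.value, "n_a": result.n_a,
            "n_b": result.n_b, "alpha": result.alpha,
            "roi_labels": result.roi_labels}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_comparison_tsv(path: str | Path) -> GroupComparisonResult:
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta = json.loads(Path(str(path) + ".json").read_text())
    return GroupComparisonResult(table, meta["roi_labels"],
                                 State(meta["state"]), meta["n_a"],
                                 meta["n_b"], meta["alpha"])


def write_cohort_config(cfg: SyntheticCohortConfig, path: str | Path) -> None:
    d = dataclasses.asdict(cfg)
    d["sigma_rem"] = np.asarray(d["sigma_rem"]).tolist()
    d["sigma_nrem"] = np.asarray(d["sigma_nrem"]).tolist()
    d["effect_edges"] = [list(e) for e in d["effect_edges"]]
    text = (json.dumps(d, indent=1) if str(path).endswith(".json")
            else yaml.safe_dump(d, sort_keys=False))
    Path(path).write_text(text)


def read_cohort_config(path: str | Path) -> SyntheticCohortConfig:
    text = Path(path).read_text()
    d = (json.loads(text) if str(path).endswith(".json")
         else yaml.safe_load(text))
    if d.get("sigma_rem") is not None:
        d["sigma_rem"] = np.asarray(d["sigma_rem"], dtype=float)
    if d.get("sigma_nrem") is not None:
        d["sigma_nrem"] = np.asarray(d["sigma_nrem"], dtype=float)
    d["effect_edges"] = [tuple(e) for e in d.get("effect_edges", [])]
    return SyntheticCohortConfig(**d)


def write_subject_files(subject: SyntheticSubject,
                        out_dir: str | Path) -> dict[str, str]:
    """Write one subject's ROI TSV, motion text, respiration CSV and
    true-state labels; returns the manifest path entries."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = subject.subject_id
    paths = {
        "roi_ts_path": str(out / f"{sid}_roi.tsv"),
        "motion_path": str(out / f"rp_{sid}.txt"),
        "respiration_path": str(out / f"{sid}_resp.csv"),
        "true_labels_path": str(out / f"{sid}_true_labels.tsv"),
    }
    write_roi_tsv(subject.roi_ts, paths["roi_ts_path"])
    write_motion_txt(subject.motion, paths["motion_path"])
    write_respiration_csv(subject.respiration, paths["respiration_path"])
    write_labels_tsv(subject.true_states, paths["true_labels_path"])
    return paths
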