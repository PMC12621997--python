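"""File formats: trajectory CSV, multi-page TIFF stacks with YAML sidecars.

Trajectory CSV schema (one row per structure per frame, UTF-8, header
required)::

    embryo_id,condition,stage,frame,t_s,structure,x_um,y_um,z_um

Stacks are written as multi-page TIFF in TCZYX page order with a sidecar
YAML (same stem, ``.yaml``) recording calibration — voxel sizes, frame
interval, channel names, onset frame, origin — and the path of the
embedded ground-truth trajectory CSV when one is written.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import ImageStack4D
from .records import EmbryoRecord, PointTrack, STRUCTURES

TRAJECTORY_COLUMNS = [
    "embryo_id", "condition", "stage", "frame", "t_s", "structure",
    "x_um", "y_um", "z_um",
]


class SchemaError(ValueError):
    pass


def records_to_frame(records: list[EmbryoRecord]) -> pd.DataFrame:
    """Flatten records into the trajectory CSV schema."""
    rows = []
    for rec in records:
        for s in STRUCTURES:
            tr = rec.tracks[s]
            for f, (t, xyz) in enumerate(zip(tr.t, tr.xyz)):
                rows.append(
                    (rec.embryo_id, rec.condition, rec.stage, f, t, s, *xyz)
                )
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


def write_trajectories(records: list[EmbryoRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_trajectories(path, embryo_lengths: dict[str, float] | None = None
                      ) -> list[EmbryoRecord]:
    """Read and validate a trajectory CSV into records.

    Malformed content is reported with the offending structure or line;
    an optional ``embryo_lengths`` map attaches AP-axis lengths by
    embryo_id.

    Raises
    ------
    SchemaError
        Missing columns, missing structures, non-monotone time, or
        unparseable numeric fields.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in ("t_s", "x_um", "y_um", "z_um"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            lines = (df.index[bad] + 2).tolist()[:5]
            raise SchemaError(f"{path}: non-numeric {col} at line(s) {lines}")
        df[col] = pd.to_numeric(df[col])

    records = []
    for embryo_id, g in df.groupby("embryo_id", sort=False):
        tracks = {}
        for s in STRUCTURES:
            gs = g[g["structure"] == s].sort_values("frame")
            if gs.empty:
                raise SchemaError(f"{path}: embryo {embryo_id} missing structure {s!r}")
            t = gs["t_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise SchemaError(
                    f"{path}: embryo {embryo_id} structure {s}: non-monotone time"
                )
            tracks[s] = PointTrack(s, t, gs[["x_um", "y_um", "z_um"]].to_numpy())
        records.append(
            EmbryoRecord(
                embryo_id=str(embryo_id),
                condition=str(g["condition"].iloc[0]),
                stage=str(g["stage"].iloc[0]),
                tracks=tracks,
                embryo_length=(embryo_lengths or {}).get(str(embryo_id)),
            )
        )
    if not records:
        raise SchemaError(f"{path}: no embryos found")
    return records


def write_stack(stack: ImageStack4D, path, write_truth: bool = True) -> Path:
    """Write TIFF pages in TCZYX order plus a YAML calibration sidecar."""
    path = Path(path)
    tifffile.imwrite(
        path,
        stack.data.astype(np.float32),
        photometric="minisblack",
        metadata={"axes": "TCZYX"},
    )
    sidecar = {
        "axes": "TCZYX",
        "shape": list(stack.data.shape),
        "voxel_size_um": {"xy": float(stack.voxel_size[0]),
                          "z": float(stack.voxel_size[1])},
        "frame_interval_s": float(stack.frame_interval),
        "psf_sigma_um": float(stack.psf_sigma),
        "origin_um": [float(v) for v in stack.origin],
        "onset_frame": int(stack.onset_frame),
        "channel_names": list(stack.channel_names),
    }
    if write_truth and stack.truth is not None:
        truth_path = path.with_suffix(".truth.csv")
        write_trajectories([stack.truth], truth_path)
        sidecar["truth_csv"] = truth_path.name
        if stack.truth.embryo_length is not None:
            sidecar["embryo_length_um"] = stack.truth.embryo_length
    yaml_path = path.with_suffix(".yaml")
    yaml_path.write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return yaml_path


def read_stack(path) -> ImageStack4D:
    """Read a TIFF + sidecar pair back into an ImageStack4D."""
    path = Path(path)
    sidecar = yaml.safe_load(path.with_suffix(".yaml").read_text())
    data = tifffile.imread(path).reshape(sidecar["shape"]).astype(float)
    truth = None
    if "truth_csv" in sidecar:
        lengths = None
        if "embryo_length_um" in sidecar:
            recs = read_trajectories(path.parent / sidecar["truth_csv"])
            lengths = {r.embryo_id: sidecar["embryo_length_um"] for r in recs}
        truth = read_trajectories(path.parent / sidecar["truth_csv"], lengths)[0]
    return ImageStack4D(
        data=data,
        voxel_size=(
            sidecar["voxel_size_um"]["xy"], sidecar["voxel_size_um"]["z"]
        ),
        frame_interval=sidecar["frame_interval_s"],
        psf_sigma=sidecar["psf_sigma_um"],
        origin=tuple(sidecar["origin_um"]),
        onset_frame=sidecar["onset_frame"],
        truth=truth,
        channel_names=tuple(sidecar["channel_names"]),
    )


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=str))
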