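"""Detection, onset calling and linking on synthetic 3D+t stacks.

Replaces interactive surface-based tracking with a deterministic algorithm:
per frame and channel the background-subtracted volume is thresholded
(Otsu by default), 26-connected components below a voxel-count floor are
discarded, and intensity-weighted centroids are computed in micrometres
(never in voxels — Z anisotropy is handled by the calibration).  Anaphase
onset is the first frame where the chromosome channel splits into two
masses separated by more than a minimum distance and stays split for a
minimum number of consecutive frames.  Tracks are formed by frame-to-frame
nearest-neighbour assignment within a gate, identities fixed at onset by
axial order (the anterior pole is the lower-x pole, each chromosome set is
assigned to its nearer pole).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .imaging import ImageStack4D
from .records import EmbryoRecord, PointTrack


@dataclass
class Detection:
    """One segmented object: centroid (μm), total intensity, voxel count."""

    xyz: np.ndarray
    intensity: float
    voxels: int


@dataclass
class DetectionSet:
    """Detections of one channel in one frame."""

    frame: int
    channel: str
    detections: list[Detection] = field(default_factory=list)
    flagged: bool = False  # True when no component cleared the threshold

    def __len__(self) -> int:
        return len(self.detections)

    def positions(self) -> np.ndarray:
        if not self.detections:
            return np.empty((0, 3))
        return np.vstack([d.xyz for d in self.detections])


class OnsetNotFoundError(RuntimeError):
    pass


class TrackLostError(RuntimeError):
    pass


def segment_structures(
    stack: ImageStack4D,
    frame: int,
    channel: str,
    threshold: float | str = "otsu",
    min_voxels: int = 3,
) -> DetectionSet:
    """Segment one frame of one channel into centroided objects.

    The volume background (median intensity) is subtracted before
    thresholding and centroiding.  The pole channel keeps the two
    highest-intensity components, the chromosome channel the one or two
    largest.  A frame with no component above threshold is returned empty
    and flagged, not raised.
    """
    if not 0 <= frame < stack.n_frames:
        raise IndexError(f"frame {frame} out of range")
    ci = stack.channel_names.index(channel)
    vol = stack.data[frame, ci].astype(float)
    bg = float(np.median(vol))
    vol = np.clip(vol - bg, 0.0, None)

    if threshold == "otsu":
        thr = float(threshold_otsu(vol)) if vol.max() > 0 else np.inf
    else:
        thr = float(threshold)
    mask = vol > thr
    out = DetectionSet(frame=frame, channel=channel)
    if not mask.any():
        out.flagged = True
        return out

    lbl = label(mask, connectivity=3)  # 26-connectivity in 3D
    dets: list[Detection] = []
    for region in regionprops(lbl, intensity_image=vol):
        if region.num_pixels < min_voxels:
            continue
        # centroid over the component's bounding box padded by 2 voxels:
        # including the sub-threshold skirt suppresses truncation bias
        lo = np.maximum(np.array(region.bbox[:3]) - 2, 0)
        hi = np.minimum(np.array(region.bbox[3:]) + 2, vol.shape)
        box = vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        coords = np.indices(box.shape).reshape(3, -1).T + lo
        weights = box.ravel()
        centroid_vox = (coords * weights[:, None]).sum(0) / weights.sum()
        dets.append(
            Detection(
                xyz=stack.voxel_to_um(centroid_vox),
                intensity=float(weights.sum()),
                voxels=int(region.num_pixels),
            )
        )
    if not dets:
        out.flagged = True
        return out
    if channel == "poles":
        dets = sorted(dets, key=lambda d: -d.intensity)[:2]
    else:
        dets = sorted(dets, key=lambda d: -d.voxels)[:2]
    out.detections = dets
    return out


def detect_channel(
    stack: ImageStack4D, channel: str, **kwargs
) -> list[DetectionSet]:
    """Segment every frame of one channel."""
    return [
        segment_structures(stack, f, channel, **kwargs)
        for f in range(stack.n_frames)
    ]


def detect_anaphase_onset(
    chromosome_detections: list[DetectionSet],
    min_split: float = 1.0,
    min_persist: int = 2,
    manual: int | None = None,
) -> int:
    """First frame where the chromosome mass is split into two.

    A frame qualifies when two chromosome components are present with
    centroid separation above ``min_split`` μm; onset is the first frame
    starting a run of at least ``min_persist`` consecutive qualifying
    frames (one-frame transients are excluded).  A ``manual`` frame index
    takes precedence over detection.
    """
    if manual is not None:
        return int(manual)
    if len(chromosome_detections) < 3:
        raise ValueError("need at least 3 frames to call anaphase onset")
    qualifies = []
    for ds in chromosome_detections:
        if len(ds) >= 2:
            p = ds.positions()
            sep = float(np.linalg.norm(p[0] - p[1]))
            qualifies.append(sep > min_split)
        else:
            qualifies.append(False)
    for f in range(len(qualifies) - min_persist + 1):
        if all(qualifies[f : f + min_persist]):
            return f
    raise OnsetNotFoundError("onset not found: chromosome mass never splits")


def _assign(
    prev: np.ndarray, dets: DetectionSet, max_step: float
) -> tuple[dict[int, int], list[str]]:
    """Gated assignment of previous positions (rows) to detections.

    Returns {track_index: detection_index} for pairs within the gate, plus
    tie-break log messages.  Ties at equal distance are broken toward the
    higher-intensity detection; assignment is injective.
    """
    flags: list[str] = []
    pos = dets.positions()
    if pos.shape[0] == 0:
        return {}, flags
    dist = np.linalg.norm(prev[:, None, :] - pos[None, :, :], axis=2)
    # deterministic tie-break: among equidistant candidates prefer higher
    # intensity, encoded as an infinitesimal cost discount
    inten = np.array([d.intensity for d in dets.detections])
    rank = np.argsort(np.argsort(-inten))  # 0 = brightest
    for i in range(dist.shape[0]):
        row = dist[i]
        eq = np.isclose(row[:, None], row[None, :], rtol=0, atol=1e-12)
        if np.any(eq & ~np.eye(len(row), dtype=bool)):
            flags.append(
                f"frame {dets.frame}: equidistant candidates for track {i}; "
                "tie broken by intensity"
            )
    cost = dist + rank[None, :] * 1e-9
    rows, cols = linear_sum_assignment(cost)
    return {int(r): int(c) for r, c in zip(rows, cols)
            if dist[r, c] <= max_step}, flags


def link_tracks(
    pole_detections: list[DetectionSet],
    chromosome_detections: list[DetectionSet],
    onset_frame: int,
    frame_interval: float,
    max_step: float = 3.0,
    embryo_length: float | None = None,
    embryo_id: str = "tracked",
    condition: str = "unknown",
    stage: str = "unknown",
    polarity: str = "ap",
) -> tuple[EmbryoRecord, dict]:
    """Link per-frame detections into an onset-registered EmbryoRecord.

    Identities at onset: ``pole_A`` is the lower-x pole, ``chr_A`` the
    chromosome set nearer ``pole_A``.  Frames after onset are linked by
    gated nearest-neighbour assignment; a single missing frame is filled by
    linear interpolation and flagged, a longer loss raises
    :class:`TrackLostError` naming the structure and frame.  Pre-onset
    frames carry the unsplit chromosome mass in both chromosome tracks.
    Times are rebased so onset = 0 s.
    """
    n_frames = len(pole_detections)
    if len(pole_detections[onset_frame]) < 2:
        raise TrackLostError(f"fewer than 2 poles detected at onset frame {onset_frame}")
    if len(chromosome_detections[onset_frame]) < 2:
        raise TrackLostError(
            f"fewer than 2 chromosome sets detected at onset frame {onset_frame}"
        )
    flags: list[str] = []
    if polarity == "arbitrary":
        flags.append("arbitrary-polarity")

    poles0 = pole_detections[onset_frame].positions()
    order = np.argsort(poles0[:, 0])
    init = {"pole_A": poles0[order[0]], "pole_P": poles0[order[1]]}
    chrom0 = chromosome_detections[onset_frame].positions()
    d_to_a = np.linalg.norm(chrom0 - init["pole_A"], axis=1)
    ca = int(np.argmin(d_to_a))
    init["chr_A"] = chrom0[ca]
    init["chr_P"] = chrom0[1 - ca]

    pos = {s: np.full((n_frames, 3), np.nan) for s in init}
    for s, p in init.items():
        pos[s][onset_frame] = p

    def link_channel(structures, detections, direction):
        frames = (
            range(onset_frame + 1, n_frames)
            if direction > 0
            else range(onset_frame - 1, -1, -1)
        )
        last_seen = {s: onset_frame for s in structures}
        for f in frames:
            prev = np.vstack([pos[s][f - direction] for s in structures])
            # carry a predicted position through a 1-frame gap
            for i, s in enumerate(structures):
                if np.any(np.isnan(prev[i])):
                    prev[i] = pos[s][last_seen[s]]
            match, tie_flags = _assign(prev, detections[f], max_step)
            flags.extend(tie_flags)
            dpos = detections[f].positions()
            for i, s in enumerate(structures):
                if i in match:
                    pos[s][f] = dpos[match[i]]
                    last_seen[s] = f
                else:
                    if abs(f - last_seen[s]) > 1:
                        raise TrackLostError(
                            f"track lost: {s} missing for more than 1 frame "
                            f"from frame {last_seen[s] + direction}"
                        )

    link_channel(["pole_A", "pole_P"], pole_detections, +1)
    link_channel(["pole_A", "pole_P"], pole_detections, -1)
    link_channel(["chr_A", "chr_P"], chromosome_detections, +1)

    # pre-onset frames: the unsplit chromosome mass stands in for both sets
    for f in range(onset_frame):
        ds = chromosome_detections[f]
        if len(ds) >= 1:
            plate = ds.positions()[int(np.argmax([d.voxels for d in ds.detections]))]
            pos["chr_A"][f] = plate
            pos["chr_P"][f] = plate
        else:
            flags.append(f"frame {f}: no pre-onset chromosome mass detected")

    # interpolate single-frame gaps, flag them; fail on longer gaps
    t = (np.arange(n_frames) - onset_frame) * frame_interval
    keep = np.ones(n_frames, dtype=bool)
    for s in pos:
        missing = np.flatnonzero(np.isnan(pos[s][:, 0]))
        for f in missing:
            if f == 0 or f == n_frames - 1:
                keep[f] = False  # unfillable edge frame: drop it
                flags.append(f"frame {f}: {s} missing at sequence edge; frame dropped")
                continue
            lo, hi = f - 1, f + 1
            if np.any(np.isnan(pos[s][lo])) or np.any(np.isnan(pos[s][hi])):
                raise TrackLostError(
                    f"track lost: {s} missing for more than 1 frame at frame {f}"
                )
            w = (t[f] - t[lo]) / (t[hi] - t[lo])
            pos[s][f] = (1 - w) * pos[s][lo] + w * pos[s][hi]
            flags.append(f"frame {f}: {s} gap filled by linear interpolation")

    tracks = {
        s: PointTrack(s, t[keep], pos[s][keep]) for s in pos
    }
    record = EmbryoRecord(
        embryo_id=embryo_id,
        condition=condition,
        stage=stage,
        tracks=tracks,
        embryo_length=embryo_length,
        flags=flags,
    )
    report = {
        "onset_frame": int(onset_frame),
        "n_frames": int(n_frames),
        "max_step_um": max_step,
        "flags": flags,
    }
    return record, report


def track_stack(
    stack: ImageStack4D,
    onset: int | str = "auto",
    threshold: float | str = "otsu",
    min_voxels: int = 3,
    min_split: float = 1.0,
    max_step: float = 3.0,
    embryo_id: str = "tracked",
    condition: str = "unknown",
    stage: str = "unknown",
    polarity: str = "ap",
) -> tuple[EmbryoRecord, dict]:
    """Full detection → onset → linking pipeline on one stack."""
    pole_dets = detect_channel(stack, "poles", threshold=threshold,
                               min_voxels=min_voxels)
    chrom_dets = detect_channel(stack, "chromosomes", threshold=threshold,
                                min_voxels=min_voxels)
    onset_frame = detect_anaphase_onset(
        chrom_dets, min_split=min_split,
        manual=None if onset == "auto" else int(onset),
    )
    embryo_length = (
        stack.truth.embryo_length if stack.truth is not None else None
    )
    record, report = link_tracks(
        pole_dets,
        chrom_dets,
        onset_frame,
        stack.frame_interval,
        max_step=max_step,
        embryo_length=embryo_length,
        embryo_id=embryo_id,
        condition=condition,
        stage=stage,
        polarity=polarity,
    )
    report["threshold"] = threshold
    report["min_split_um"] = min_split
    return record, report
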