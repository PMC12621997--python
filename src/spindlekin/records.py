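"""Core trajectory containers.

An embryo's anaphase is described by four point tracks in 3D — the two
spindle poles and the two segregating chromosome sets — sampled on a shared
time grid registered so that t = 0 s is anaphase onset.  The
antero-posterior (AP) axis is the x axis with the anterior cortex at x = 0;
all positions are in micrometres and all times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

STRUCTURES = ("pole_A", "pole_P", "chr_A", "chr_P")

#: label swap used when mirroring a record along the AP axis
_MIRROR = {"pole_A": "pole_P", "pole_P": "pole_A", "chr_A": "chr_P", "chr_P": "chr_A"}


@dataclass
class PointTrack:
    """One structure's positions over time.

    Parameters
    ----------
    structure_id : str
        One of ``pole_A``, ``pole_P``, ``chr_A``, ``chr_P``.
    t : ndarray, shape (n,)
        Sample times in seconds, strictly increasing. Negative times are
        pre-onset frames.
    xyz : ndarray, shape (n, 3)
        Positions in micrometres, finite.
    """

    structure_id: str
    t: np.ndarray
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.structure_id not in STRUCTURES:
            raise ValueError(f"unknown structure_id {self.structure_id!r}")
        if self.t.ndim != 1 or self.xyz.shape != (self.t.size, 3):
            raise ValueError("t must be (n,) and xyz (n, 3)")
        if self.t.size and not np.all(np.diff(self.t) > 0):
            raise ValueError(f"{self.structure_id}: time must be strictly increasing")
        if not (np.isfinite(self.t).all() and np.isfinite(self.xyz).all()):
            raise ValueError(f"{self.structure_id}: non-finite sample")

    @property
    def x(self) -> np.ndarray:
        """Axial (AP) coordinates."""
        return self.xyz[:, 0]

    def at(self, t: float, atol: float = 1e-9) -> np.ndarray:
        """Position at time ``t`` (exact grid match within ``atol``)."""
        i = np.flatnonzero(np.isclose(self.t, t, rtol=0.0, atol=atol))
        if i.size == 0:
            raise KeyError(f"time {t} s not on the grid of {self.structure_id}")
        return self.xyz[int(i[0])]


@dataclass
class EmbryoRecord:
    """Four time-registered tracks plus condition/stage metadata.

    Invariants enforced at construction: the four tracks share one strictly
    increasing time grid containing t = 0 (anaphase onset); at onset the
    anterior pole sits at lower x than the posterior pole and both
    chromosome sets lie between the poles along the spindle axis.
    """

    embryo_id: str
    condition: str
    stage: str
    tracks: dict[str, PointTrack]
    embryo_length: float | None = None
    t_onset_index: int = 0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [s for s in STRUCTURES if s not in self.tracks]
        if missing:
            raise ValueError(f"missing tracks: {missing}")
        t0 = self.tracks["pole_A"].t
        for s in STRUCTURES[1:]:
            if not np.array_equal(self.tracks[s].t, t0):
                raise ValueError("tracks do not share one time grid")
        onset = np.flatnonzero(np.isclose(t0, 0.0))
        if onset.size != 1:
            raise ValueError("time grid must contain t = 0 (anaphase onset)")
        self.t_onset_index = int(onset[0])
        i = self.t_onset_index
        xa = self.tracks["pole_A"].x[i]
        xp = self.tracks["pole_P"].x[i]
        if not xa < xp:
            raise ValueError("at onset pole_A must be anterior (lower x) to pole_P")
        # projection of both chromosome sets onto the pole-pole axis must
        # fall strictly between the poles at onset
        pa = self.tracks["pole_A"].xyz[i]
        pp = self.tracks["pole_P"].xyz[i]
        axis = pp - pa
        span = float(axis @ axis)
        for s in ("chr_A", "chr_P"):
            u = float((self.tracks[s].xyz[i] - pa) @ axis) / span
            if not 0.0 < u < 1.0:
                raise ValueError(f"{s} not between the poles at onset")
        if self.embryo_length is not None and self.embryo_length <= 0:
            raise ValueError("embryo_length must be positive")

    @property
    def t(self) -> np.ndarray:
        """Shared time grid (seconds from anaphase onset)."""
        return self.tracks["pole_A"].t

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    def post_onset(self) -> "EmbryoRecord":
        """Copy restricted to t >= 0."""
        keep = self.t >= 0
        tracks = {
            s: PointTrack(s, tr.t[keep], tr.xyz[keep]) for s, tr in self.tracks.items()
        }
        return replace(self, tracks=tracks, t_onset_index=0)


def mirror_record(record: EmbryoRecord) -> EmbryoRecord:
    """Reflect a record through the AP midplane and swap A/P labels.

    x -> embryo_length - x (or reflection about the recorded axial midrange
    when embryo_length is unknown), anterior structures relabelled
    posterior and vice versa.  All pairwise distances are preserved, so the
    kinematics of the mirrored record equal those of the original with the
    anterior and posterior series exchanged.
    """
    if record.embryo_length is not None:
        ref = record.embryo_length
    else:
        allx = np.concatenate([tr.x for tr in record.tracks.values()])
        ref = float(allx.min() + allx.max())
    tracks = {}
    for s, tr in record.tracks.items():
        xyz = tr.xyz.copy()
        xyz[:, 0] = ref - xyz[:, 0]
        tracks[_MIRROR[s]] = PointTrack(_MIRROR[s], tr.t.copy(), xyz)
    return replace(record, tracks=tracks, flags=list(record.flags) + ["mirrored"])
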