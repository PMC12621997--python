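"""Kinematic statistics of anaphase chromosome segregation.

All distances are full 3D Euclidean distances between tracked centres:

* ``PP``   pole-to-pole distance (spindle length);
* ``CC``   distance between the two segregating chromosome sets
           (chromosome segregation);
* ``CP_A``/``CP_P``  distance from each chromosome set to its own pole.

Onset-referenced deltas subtract the value at anaphase onset (AO, t = 0):
``ΔPP(t) = PP(t) − PP(0)`` and likewise for CP and CC.  Windowed velocities
are finite differences of CP over fixed windows, by default (0, 50) s and
(50, 100) s; a negative velocity is poleward movement (anaphase A), a
positive one anti-poleward.  The relative contribution of chromosome
displacement to segregation at time t is

    contribution(t) = (ΔCC(t) − ΔPP(t)) / CC(t) × 100   [percent]

the share of segregation not explained by pole separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import EmbryoRecord

EARLY_WINDOW = (0.0, 50.0)
LATE_WINDOW = (50.0, 100.0)


def euclidean_distance(a, b) -> float:
    """3D Euclidean distance between two points in μm."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite coordinates")
    return float(np.linalg.norm(a - b))


@dataclass
class KinematicsSeries:
    """Per-timepoint distances and onset-referenced deltas for one embryo."""

    embryo_id: str
    condition: str
    stage: str
    t: np.ndarray  # s, >= 0
    pp: np.ndarray
    cc: np.ndarray
    cp_a: np.ndarray
    cp_p: np.ndarray
    dpp: np.ndarray = field(init=False)
    dcc: np.ndarray = field(init=False)
    dcp_a: np.ndarray = field(init=False)
    dcp_p: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not np.isclose(self.t[0], 0.0):
            raise ValueError("series must start at anaphase onset (t = 0)")
        self.dpp = self.pp - self.pp[0]
        self.dcc = self.cc - self.cc[0]
        self.dcp_a = self.cp_a - self.cp_a[0]
        self.dcp_p = self.cp_p - self.cp_p[0]

    def value_at(self, name: str, t: float) -> float:
        """Series ``name`` at grid time ``t`` (nearest sample within half a
        frame; the substitution is warned about)."""
        arr = getattr(self, name)
        i = int(np.argmin(np.abs(self.t - t)))
        if not np.isclose(self.t[i], t):
            half = 0.5 * float(np.median(np.diff(self.t)))
            if abs(self.t[i] - t) > half + 1e-9:
                raise KeyError(f"time {t} s beyond half a frame from the grid")
            warnings.warn(
                f"{name}: using nearest sample t={self.t[i]} s for requested {t} s",
                stacklevel=2,
            )
        return float(arr[i])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table, one row per timepoint × variable."""
        wide = pd.DataFrame(
            {
                "t_s": self.t,
                "PP": self.pp,
                "CC": self.cc,
                "CP_A": self.cp_a,
                "CP_P": self.cp_p,
                "dPP": self.dpp,
                "dCC": self.dcc,
                "dCP_A": self.dcp_a,
                "dCP_P": self.dcp_p,
            }
        )
        out = wide.melt(id_vars="t_s", var_name="variable", value_name="value_um")
        out.insert(0, "embryo_id", self.embryo_id)
        out.insert(1, "condition", self.condition)
        out.insert(2, "stage", self.stage)
        return out


@dataclass
class VelocitySummary:
    """Early/late chromosome-to-pole velocities per spindle half."""

    v_early_A: float
    v_early_P: float
    v_late_A: float
    v_late_P: float

    def directions(self) -> dict[str, str]:
        return {
            k: classify_direction(getattr(self, k))
            for k in ("v_early_A", "v_early_P", "v_late_A", "v_late_P")
        }


def compute_kinematics(record: EmbryoRecord) -> KinematicsSeries:
    """All distance and delta series for one onset-registered record.

    Only t >= 0 samples enter the series; pre-onset frames (unsplit
    chromosome mass) are excluded.
    """
    rec = record.post_onset()
    tr = rec.tracks
    pp = np.linalg.norm(tr["pole_A"].xyz - tr["pole_P"].xyz, axis=1)
    cc = np.linalg.norm(tr["chr_A"].xyz - tr["chr_P"].xyz, axis=1)
    cp_a = np.linalg.norm(tr["chr_A"].xyz - tr["pole_A"].xyz, axis=1)
    cp_p = np.linalg.norm(tr["chr_P"].xyz - tr["pole_P"].xyz, axis=1)
    return KinematicsSeries(
        embryo_id=rec.embryo_id,
        condition=rec.condition,
        stage=rec.stage,
        t=rec.t,
        pp=pp,
        cc=cc,
        cp_a=cp_a,
        cp_p=cp_p,
    )


def window_velocity(
    series: KinematicsSeries, side: str, t0: float = 0.0, t1: float = 50.0
) -> float:
    """(CP(t1) − CP(t0)) / (t1 − t0) in μm/s for side ``'A'`` or ``'P'``."""
    if side not in ("A", "P"):
        raise ValueError("side must be 'A' or 'P'")
    if not t0 < t1:
        raise ValueError("t0 must be < t1")
    if t1 > series.t[-1] + 0.5 * float(np.median(np.diff(series.t))):
        raise ValueError(f"t1 = {t1} s beyond series extent ({series.t[-1]} s)")
    name = "cp_a" if side == "A" else "cp_p"
    return (series.value_at(name, t1) - series.value_at(name, t0)) / (t1 - t0)


def velocity_summary(series: KinematicsSeries) -> VelocitySummary:
    """Early (0–50 s) and late (50–100 s) velocities for both halves."""
    return VelocitySummary(
        v_early_A=window_velocity(series, "A", *EARLY_WINDOW),
        v_early_P=window_velocity(series, "P", *EARLY_WINDOW),
        v_late_A=window_velocity(series, "A", *LATE_WINDOW),
        v_late_P=window_velocity(series, "P", *LATE_WINDOW),
    )


def classify_direction(v: float) -> str:
    """Sign-based direction of chromosome-to-pole movement.

    Negative → ``poleward`` (anaphase A), positive → ``anti-poleward``,
    exactly zero → ``static``.
    """
    if not np.isfinite(v):
        raise ValueError("velocity must be finite")
    if v < 0:
        return "poleward"
    if v > 0:
        return "anti-poleward"
    return "static"


def contribution(series: KinematicsSeries, t: float) -> float:
    """Relative contribution of chromosome displacement to segregation, %.

    ``(ΔCC(t) − ΔPP(t)) / CC(t) × 100`` for t > 0.  For colinear noiseless
    motion this equals ``−(ΔCP_A + ΔCP_P)/CC × 100``.
    """
    if t <= 0:
        raise ValueError("contribution is defined for t > 0 only")
    cc = series.value_at("cc", t)
    if cc <= 0:
        raise ValueError(f"CC({t}) = {cc}: contribution undefined")
    return (series.value_at("dcc", t) - series.value_at("dpp", t)) / cc * 100.0


def contribution_series(series: KinematicsSeries) -> pd.DataFrame:
    """Contribution at every grid time t > 0 with CC(t) > 0."""
    mask = (series.t > 0) & (series.cc > 0)
    vals = (series.dcc[mask] - series.dpp[mask]) / series.cc[mask] * 100.0
    return pd.DataFrame({"t_s": series.t[mask], "contribution_pct": vals})


def relative_pole_position(record: EmbryoRecord, structure: str, t: float) -> float:
    """Axial pole position as % of the AP axis (anterior cortex 0%,
    posterior cortex 100%), clamped to [0, 100] with a warning."""
    if record.embryo_length is None:
        raise ValueError("embryo_length required for relative pole position")
    if structure not in ("pole_A", "pole_P"):
        raise ValueError("structure must be pole_A or pole_P")
    x = record.tracks[structure].at(t)[0]
    pct = x / record.embryo_length * 100.0
    if pct < 0.0 or pct > 100.0:
        warnings.warn(
            f"{structure} at {pct:.1f}% lies outside the embryo; clamped",
            stacklevel=2,
        )
        pct = min(max(pct, 0.0), 100.0)
    return pct


def spindle_length_at_onset(series: KinematicsSeries) -> float:
    """PP(0), μm."""
    return float(series.pp[0])


def group_average(
    series_list: list[KinematicsSeries],
    variable: str,
    grid_dt: float = 10.0,
) -> pd.DataFrame:
    """Pointwise group mean of one variable with a 95% t-based CI.

    Series on mixed grids (10 s / 20 s acquisitions) are first linearly
    interpolated onto a common ``grid_dt`` grid spanning the shortest
    series.  Columns: ``t_s, mean, ci_low, ci_high, n``.  With a single
    series the CI is NaN (flagged undefined).
    """
    if not series_list:
        raise ValueError("empty input")
    t_max = min(s.t[-1] for s in series_list)
    grid = np.arange(0.0, t_max + 0.5 * grid_dt, grid_dt)
    vals = np.vstack(
        [np.interp(grid, s.t, getattr(s, variable)) for s in series_list]
    )
    n = vals.shape[0]
    mean = vals.mean(axis=0)
    if n == 1:
        ci = np.full_like(mean, np.nan)
    else:
        sem = vals.std(axis=0, ddof=1) / np.sqrt(n)
        ci = sps.t.ppf(0.975, n - 1) * sem
    return pd.DataFrame(
        {"t_s": grid, "mean": mean, "ci_low": mean - ci, "ci_high": mean + ci,
         "n": n}
    )


def summarize_embryo(series: KinematicsSeries) -> dict:
    """Per-embryo summary row: windowed velocities with direction labels,
    contribution at 100 s, spindle length at onset, and the displacement/
    separation pair used in stage scatter plots."""
    vs = velocity_summary(series)
    dirs = vs.directions()
    out = {
        "embryo_id": series.embryo_id,
        "condition": series.condition,
        "stage": series.stage,
        "pp_onset_um": spindle_length_at_onset(series),
        "v_early_A": vs.v_early_A,
        "v_early_P": vs.v_early_P,
        "v_late_A": vs.v_late_A,
        "v_late_P": vs.v_late_P,
        "dir_early_A": dirs["v_early_A"],
        "dir_early_P": dirs["v_early_P"],
        "dir_late_A": dirs["v_late_A"],
        "dir_late_P": dirs["v_late_P"],
        "contribution_100s_pct": contribution(series, 100.0),
        "dpp_100s_um": series.value_at("dpp", 100.0),
        "dcp_100s_um": 0.5
        * (series.value_at("dcp_a", 100.0) + series.value_at("dcp_p", 100.0)),
    }
    # poleward extent: positive magnitude of poleward displacement at 100 s
    out["poleward_extent_100s_um"] = -out["dcp_100s_um"] * 2.0
    return out


def summarize_cohort(series_list: list[KinematicsSeries]) -> pd.DataFrame:
    """Summary table over a cohort, one row per embryo."""
    return pd.DataFrame([summarize_embryo(s) for s in series_list])
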