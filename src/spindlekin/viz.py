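"""Bespoke anaphase graphics: color-coded displacement graphs and
composite kymographs.

The color-coded graph renders, per timepoint, each half-spindle's
chromosome displacement ΔCP as a colored band spanning pole to chromosome:
a diverging palette anchored at +0.5 μm anti-poleward (dark blue) and
−2.0 μm poleward (dark red), with a near-white midpoint at ΔCP = 0.  The
two chromosome sets are drawn as vertical black lines, anterior measured
from the left edge and posterior from the right; the uncropped row width
equals the spindle length at anaphase onset, and rows are stacked
top-to-bottom as a kymograph.  The asymmetric anchors make the mapping
piecewise-linear about zero.

The composite kymograph shows two per-pole-aligned kymographs (axial
intensity profiles with the anterior or posterior pole held at a fixed
column), each cropped at the chromosome midpoint at anaphase onset, joined
side by side — chromosome displacement is then visible as motion relative
to the fixed pole columns, with pole separation factored out.

Both renderers are deterministic: identical inputs give pixel-identical
images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging import ImageStack4D
from .kinematics import KinematicsSeries
from .records import EmbryoRecord

BLACK = np.zeros(3)


@dataclass
class ColorGraphSpec:
    """Rendering parameters of a color-coded displacement graph."""

    t_range: tuple[float, float] = (0.0, 100.0)
    row_interval: float | None = None  # s; None = the series' own grid
    anchor_anti: float = 0.5  # μm anti-poleward mapped to the blue anchor
    anchor_pole: float = -2.0  # μm poleward mapped to the red anchor
    crop_width: float = 10.0  # μm, centre crop of the final image
    px_per_um: float = 10.0
    row_scale: int = 6  # vertical repetition per row, cosmetic
    line_width_px: int = 2
    color_anti: tuple = (0.08, 0.12, 0.45)  # dark blue
    color_mid: tuple = (0.96, 0.96, 0.96)  # near-white at ΔCP = 0
    color_pole: tuple = (0.62, 0.07, 0.07)  # dark red

    def __post_init__(self) -> None:
        if not self.anchor_anti > 0 > self.anchor_pole:
            raise ValueError("anchors must satisfy anchor_anti > 0 > anchor_pole")
        if self.crop_width is not None and self.crop_width <= 0:
            raise ValueError("crop_width must be positive")


def map_dcp_color(dcp: float, spec: ColorGraphSpec | None = None) -> np.ndarray:
    """Map a ΔCP value (μm) to an RGB triple in [0, 1].

    Piecewise-linear through the midpoint color at ΔCP = 0; values beyond
    an anchor clamp to that anchor's color.
    """
    spec = spec or ColorGraphSpec()
    if not np.isfinite(dcp):
        raise ValueError("dcp must be finite")
    mid = np.asarray(spec.color_mid, dtype=float)
    if dcp >= 0:
        f = min(dcp / spec.anchor_anti, 1.0)
        target = np.asarray(spec.color_anti, dtype=float)
    else:
        f = min(dcp / spec.anchor_pole, 1.0)
        target = np.asarray(spec.color_pole, dtype=float)
    return (1.0 - f) * mid + f * target


def render_color_graph(
    series: KinematicsSeries, spec: ColorGraphSpec | None = None
) -> tuple[np.ndarray, dict]:
    """Render one embryo's color-coded displacement graph.

    Returns the uint8 RGB image and a geometry sidecar (row times, width,
    crop bounds, anchors, flags) for downstream assertions.
    """
    spec = spec or ColorGraphSpec()
    t0, t1 = spec.t_range
    if series.t[-1] + 1e-9 < t1:
        raise ValueError(f"series ends at {series.t[-1]} s, before t_range end {t1} s")
    dt = spec.row_interval or float(np.median(np.diff(series.t)))
    times = np.arange(t0, t1 + 0.5 * dt, dt)

    px = spec.px_per_um
    width_um = float(series.pp[0])  # uncropped width = spindle length at onset
    w = int(round(width_um * px))
    lw = spec.line_width_px
    flags: list[str] = []

    rows = np.empty((times.size, w, 3))
    for r, t in enumerate(times):
        cp_a = series.value_at("cp_a", t)
        cp_p = series.value_at("cp_p", t)
        dcp_a = series.value_at("dcp_a", t)
        dcp_p = series.value_at("dcp_p", t)
        if cp_a + cp_p > width_um:
            flags.append(f"row t={t:g}s: CP_A + CP_P exceeds PP(0); row clipped")
        row = np.ones((w, 3))  # white between the lines
        # anterior: band from the left edge to the black line at CP_A
        a0 = int(round(cp_a * px - lw / 2))
        row[: max(a0, 0)] = map_dcp_color(dcp_a, spec)
        row[max(a0, 0) : max(min(a0 + lw, w), 0)] = BLACK
        # posterior: same construction measured from the right edge
        b0 = int(round(cp_p * px - lw / 2))
        row[w - max(b0, 0) :] = map_dcp_color(dcp_p, spec)
        row[w - max(min(b0 + lw, w), 0) : w - max(b0, 0)] = BLACK
        rows[r] = row

    crop_lo, crop_hi = 0, w
    if spec.crop_width is not None:
        cw = int(round(spec.crop_width * px))
        if cw >= w:
            if cw > w:
                flags.append("crop_width exceeds spindle length at onset; not cropped")
        else:
            if (w - cw) % 2:  # keep the crop mirror-symmetric
                cw += 1
            crop_lo = (w - cw) // 2
            crop_hi = crop_lo + cw
    rows = rows[:, crop_lo:crop_hi]

    image = np.repeat(rows, spec.row_scale, axis=0)
    image = (np.clip(image, 0, 1) * 255).round().astype(np.uint8)
    geometry = {
        "row_times_s": times.tolist(),
        "n_rows": int(times.size),
        "width_um": width_um,
        "width_px_uncropped": w,
        "crop_px": [crop_lo, crop_hi],
        "anchors_um": [spec.anchor_anti, spec.anchor_pole],
        "px_per_um": px,
        "row_scale": spec.row_scale,
        "flags": flags,
    }
    return image, geometry


def _axial_frame(record: EmbryoRecord, t: float):
    """Pole positions, axis direction, and projected structure coordinates."""
    pa = record.tracks["pole_A"].at(t)
    pp = record.tracks["pole_P"].at(t)
    e = (pp - pa) / np.linalg.norm(pp - pa)
    s = {
        name: float((record.tracks[name].at(t) - pa) @ e)
        for name in record.tracks
    }
    return pa, e, s


def _bump(u: np.ndarray, centre: float, sigma: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((u - centre) / sigma) ** 2)


def render_composite_kymograph(
    source: EmbryoRecord | ImageStack4D,
    interval: float = 20.0,
    t_range: tuple[float, float] = (0.0, 100.0),
    px_per_um: float = 10.0,
    margin_um: float = 2.0,
    row_scale: int = 6,
) -> tuple[np.ndarray, dict]:
    """Composite kymograph with the spindle poles held at fixed columns.

    Left panel: axial intensity profile aligned on the anterior pole,
    cropped at the chromosome midpoint at anaphase onset.  Right panel: the
    same aligned on the posterior pole.  Image sources use max-Z-projected
    intensity sampled along the pole–pole line (per frame); trajectory
    sources draw the same geometry schematically.

    Returns a uint8 grayscale image and a geometry sidecar whose
    ``onset_midpoint_um`` is the axial chromosome midpoint at t = 0 (the
    crop position of both panels).
    """
    if isinstance(source, ImageStack4D):
        if source.truth is None:
            raise ValueError("image source requires embedded truth for alignment")
        record = source.truth
        stack = source
    else:
        record = source
        stack = None
    if record.t_onset_index is None or not np.any(np.isclose(record.t, 0.0)):
        raise ValueError("source is not registered to anaphase onset")

    t0, t1 = t_range
    t1 = min(t1, float(record.t[-1]))
    times = [t for t in np.arange(t0, t1 + 0.5 * interval, interval)
             if np.any(np.isclose(record.t, t))]
    if not times:
        raise ValueError("no record timepoints fall in t_range at this interval")

    _, _, s0 = _axial_frame(record, 0.0)
    mid0 = 0.5 * (s0["chr_A"] + s0["chr_P"])  # from pole_A along the axis, μm
    pp0 = s0["pole_P"]

    step = 1.0 / px_per_um
    # left panel: axial coordinate u measured from pole_A, −margin .. mid0
    u_left = np.arange(-margin_um, mid0 + 0.5 * step, step)
    # right panel: coordinate w measured from pole_P (negative inside the
    # spindle), mid0 − PP(0) .. +margin
    u_right = np.arange(mid0 - pp0, margin_um + 0.5 * step, step)

    def profile(t: float, u: np.ndarray, anchor: str) -> np.ndarray:
        pa, e, s = _axial_frame(record, t)
        offset = 0.0 if anchor == "pole_A" else s["pole_P"]
        su = u + offset  # axial position from pole_A
        if stack is None:
            out = _bump(su, s["pole_A"], 0.35, 1.0) + _bump(su, s["pole_P"], 0.35, 1.0)
            out += _bump(su, s["chr_A"], 0.6, 0.8) + _bump(su, s["chr_P"], 0.6, 0.8)
            return out
        f = int(np.argmin(np.abs(record.t - t)))
        proj = stack.data[f].sum(axis=0).max(axis=0)  # channels+Z collapsed -> (Y, X)
        pts = pa[None, :] + su[:, None] * e[None, :]
        vox = stack.um_to_voxel(pts)  # (z, y, x)
        return ndimage.map_coordinates(
            proj, [vox[:, 1], vox[:, 2]], order=1, mode="constant", cval=0.0
        )

    left = np.vstack([profile(t, u_left, "pole_A") for t in times])
    right = np.vstack([profile(t, u_right, "pole_P") for t in times])
    panel = np.hstack([left, right])
    panel = panel / panel.max() if panel.max() > 0 else panel
    image = np.repeat((panel * 255).round().astype(np.uint8), row_scale, axis=0)

    geometry = {
        "row_times_s": list(map(float, times)),
        "n_rows": len(times),
        "onset_midpoint_um": float(
            0.5 * (record.tracks["chr_A"].at(0.0)[0] + record.tracks["chr_P"].at(0.0)[0])
        ),
        "onset_midpoint_from_pole_A_um": float(mid0),
        "left_panel_px": int(u_left.size),
        "right_panel_px": int(u_right.size),
        "interval_s": float(interval),
        "px_per_um": px_per_um,
    }
    return image, geometry


def save_png(image: np.ndarray, path) -> None:
    """Write an image array as PNG (grayscale or RGB)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    plt.imsave(path, image, cmap="gray" if image.ndim == 2 else None)
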