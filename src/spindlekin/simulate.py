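"""Ground-truth trajectory generator.

Simulates the four tracked structures of one dividing blastomere: the two
spindle poles separate along the AP (x) axis at constant signed speeds from
an initial separation ``L0`` (anaphase B), and each chromosome set follows
its pole at a chromosome-to-pole distance obeying the biphasic law

    CP(t) = CP(0) + r_early * min(t, t_switch) + r_late * max(0, t - t_switch)

with negative rates meaning poleward movement (anaphase A).  Frames before
anaphase onset carry a single unsplit chromosome mass at the spindle
centre, represented by coincident ``chr_A``/``chr_P`` samples.  Isotropic
Gaussian noise of the requested standard deviation is added to every
coordinate.  Given the same (spec, seed) the output is bitwise
reproducible.
"""

from __future__ import annotations

import numpy as np

from .conditions import ConditionSpec
from .records import EmbryoRecord, PointTrack

#: lateral (y) and axial-depth (z) plane of the simulated spindle, μm.
#: y is placed relative to the embryo width, z at the mid focal plane of a
#: default 4-section acquisition with 2 μm steps.
_Z0 = 3.0


def cp_distance(spec: ConditionSpec, side: str, t: np.ndarray | float) -> np.ndarray:
    """Closed-form chromosome-to-pole distance at time ``t >= 0``."""
    t = np.asarray(t, dtype=float)
    early, late = spec.dcp_rates(side)
    s = spec.switch_smoothing
    if s > 0.0:
        # smooth logistic blend of the two linear phases (optional)
        u = (t - spec.t_switch) / s
        ramp = s * np.logaddexp(0.0, u)  # smooth max(0, t - t_switch)
        early_part = t - ramp
    else:
        early_part = np.minimum(t, spec.t_switch)
        ramp = np.maximum(0.0, t - spec.t_switch)
    return spec.cp0_effective + early * early_part + late * ramp


def simulate_embryo(
    spec: ConditionSpec,
    seed: int | None = None,
    embryo_id: str | None = None,
    stage: str | None = None,
) -> EmbryoRecord:
    """Simulate one embryo under ``spec``.

    Parameters
    ----------
    spec : ConditionSpec
        Condition parameters (validated at construction).
    seed : int, optional
        Overrides ``spec.seed`` for the noise stream.

    Returns
    -------
    EmbryoRecord
        Four tracks on the grid ``-pre_onset_frames*dt .. duration`` step
        ``dt``, registered so t = 0 is anaphase onset.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    dt = spec.dt
    n_pre = spec.pre_onset_frames
    t_post = np.arange(0.0, spec.duration + 0.5 * dt, dt)
    t = np.concatenate([-dt * np.arange(n_pre, 0, -1), t_post])

    centre = spec.embryo_length / 2.0
    y0 = spec.embryo_length * 0.25
    xa0 = centre - spec.L0 / 2.0
    xp0 = centre + spec.L0 / 2.0

    # poles hold their metaphase position before onset, then move at
    # constant speed
    tpos = np.maximum(t, 0.0)
    x_pa = xa0 + spec.pole_speed_A * tpos
    x_pp = xp0 + spec.pole_speed_P * tpos

    cp_a = cp_distance(spec, "A", t_post)
    cp_p = cp_distance(spec, "P", t_post)
    x_ca = np.empty_like(t)
    x_cp = np.empty_like(t)
    # unsplit metaphase plate at the spindle centre
    x_ca[:n_pre] = centre
    x_cp[:n_pre] = centre
    x_ca[n_pre:] = x_pa[n_pre:] + cp_a
    x_cp[n_pre:] = x_pp[n_pre:] - cp_p

    def track(structure: str, x: np.ndarray) -> PointTrack:
        xyz = np.column_stack([x, np.full_like(x, y0), np.full_like(x, _Z0)])
        if spec.noise_sd > 0:
            xyz = xyz + rng.normal(0.0, spec.noise_sd, size=xyz.shape)
        return PointTrack(structure, t, xyz)

    tracks = {
        "pole_A": track("pole_A", x_pa),
        "pole_P": track("pole_P", x_pp),
        "chr_A": track("chr_A", x_ca),
        "chr_P": track("chr_P", x_cp),
    }
    return EmbryoRecord(
        embryo_id=embryo_id or f"{spec.name}-s{seed}",
        condition=spec.name,
        stage=stage or spec.name,
        tracks=tracks,
        embryo_length=spec.embryo_length,
    )


def simulate_cohort(
    spec: ConditionSpec, n: int, seed: int = 0
) -> list[EmbryoRecord]:
    """Simulate ``n`` embryos with per-embryo seeds derived from ``seed``."""
    ss = np.random.SeedSequence(seed)
    return [
        simulate_embryo(spec, seed=int(s.generate_state(1)[0] % (2**31)),
                        embryo_id=f"{spec.name}-{i:03d}")
        for i, s in enumerate(ss.spawn(n))
    ]
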