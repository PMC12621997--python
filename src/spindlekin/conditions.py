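"""Condition presets for the synthetic anaphase generator.

Each preset encodes, as generator parameters, the qualitative kinematic
phenotype of one experimental condition: signed axial pole speeds (anaphase
B), biphasic chromosome-to-pole displacement rates per half-spindle
(anaphase A and its late anti-poleward reversal), the 50 s phase switch,
spindle length at onset, and noise.  The published study reports no numeric
rates, so the values below are free parameters of the generator chosen once
to reproduce the orderings seen experimentally:

* the 1-cell control is biphasic and asymmetric — poleward displacement in
  the first 50 s, faster on the anterior half, then a slower anti-poleward
  drift;
* polarity perturbations symmetrize the two halves (``par2-like`` static
  chromosomes with weak pole separation, ``par3-like`` control-like but
  symmetric, ``gpr12-like`` slow sustained poleward movement with weak pole
  separation);
* midzone loss (``spd1-like``, ``ablation-like``) gives faster pole
  separation with fast, sustained poleward displacement;
* ``klp7-gpr12-like`` abolishes poleward displacement almost entirely,
  ``klp18-gpr12-like`` exaggerates it;
* the ``stage-N`` series shrinks the spindle with each cleavage round while
  the relative contribution of chromosome displacement to segregation rises
  from roughly 9% (1-cell) to roughly 49% (64-cell);
* ``ems-dissociated-like`` shows prolonged poleward movement with no
  anti-poleward reversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

#: default ratio of onset chromosome-to-pole distance to spindle length;
#: 5 μm for a 14 μm 1-cell spindle
_CP0_RATIO = 5.0 / 14.0


@dataclass(frozen=True)
class ConditionSpec:
    """Parameters of one simulated condition.

    Signs follow the axis convention: AP axis = x, anterior at x = 0.
    ``pole_speed_A``/``pole_speed_P`` are signed axial speeds (μm/s); pole
    separation increases when ``pole_speed_P - pole_speed_A > 0``.  The
    ``dcp_rate_*`` values are chromosome-to-pole distance rates (μm/s);
    negative means poleward movement (anaphase A), positive anti-poleward.
    """

    name: str
    L0: float  # spindle length at anaphase onset, μm
    embryo_length: float  # AP-axis length, μm
    pole_speed_A: float  # μm/s
    pole_speed_P: float  # μm/s
    dcp_rate_early_A: float  # μm/s, 0..t_switch
    dcp_rate_early_P: float
    dcp_rate_late_A: float  # μm/s, t_switch..duration
    dcp_rate_late_P: float
    t_switch: float = 50.0  # s, early/late phase boundary
    pre_onset_frames: int = 5
    noise_sd: float = 0.05  # μm, isotropic positional noise
    duration: float = 150.0  # s of tracked anaphase
    dt: float = 10.0  # s frame interval
    seed: int = 0
    cp0: float | None = None  # onset CP distance, μm; default 5/14 * L0
    switch_smoothing: float = 0.0  # s; 0 = sharp piecewise-linear switch

    def __post_init__(self) -> None:
        if self.L0 <= 0:
            raise ValueError("L0 must be positive")
        if self.embryo_length < self.L0:
            raise ValueError("embryo_length must be >= L0")
        if self.dt not in (10.0, 20.0):
            raise ValueError("dt must be 10 or 20 s")
        if self.duration < 100.0:
            raise ValueError("duration must be >= 100 s")
        if not 0.0 < self.t_switch < self.duration:
            raise ValueError("t_switch must lie inside (0, duration)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.pre_onset_frames < 0:
            raise ValueError("pre_onset_frames must be non-negative")
        if self.switch_smoothing < 0:
            raise ValueError("switch_smoothing must be non-negative")
        cp0 = self.cp0 if self.cp0 is not None else _CP0_RATIO * self.L0
        if not 0.0 < 2 * cp0 < self.L0 + 2 * cp0:  # cp0 positive
            raise ValueError("cp0 must be positive")
        if self.L0 - 2 * cp0 <= 0:
            raise ValueError("chromosome sets must start between the poles (2*cp0 < L0)")

    @property
    def cp0_effective(self) -> float:
        return self.cp0 if self.cp0 is not None else _CP0_RATIO * self.L0

    def dcp_rates(self, side: str) -> tuple[float, float]:
        """(early, late) ΔCP rate for side ``'A'`` or ``'P'``."""
        if side == "A":
            return self.dcp_rate_early_A, self.dcp_rate_late_A
        if side == "P":
            return self.dcp_rate_early_P, self.dcp_rate_late_P
        raise ValueError("side must be 'A' or 'P'")

    def to_dict(self) -> dict:
        return asdict(self)


def _spec(name, L0, embryo_length, vA, vP, eA, eP, lA, lP, **kw) -> ConditionSpec:
    return ConditionSpec(
        name=name,
        L0=L0,
        embryo_length=embryo_length,
        pole_speed_A=vA,
        pole_speed_P=vP,
        dcp_rate_early_A=eA,
        dcp_rate_early_P=eP,
        dcp_rate_late_A=lA,
        dcp_rate_late_P=lP,
        **kw,
    )


def _stage_spec(stage: int, L0: float, sep_rate: float, extent: float) -> ConditionSpec:
    """Stage preset from spindle length, pole-separation rate and the total
    poleward displacement extent (both sides, μm, at 100 s)."""
    late = 0.004  # μm/s, mild anti-poleward drift in late anaphase
    # per-side displacement at 100 s = 50*early + 50*late; anterior carries 55%
    e_a = -(0.55 * extent + 50 * late) / 50.0
    e_p = -(0.45 * extent + 50 * late) / 50.0
    return _spec(
        f"stage-{stage}",
        L0,
        round(50.0 * L0 / 14.0, 1),
        -sep_rate / 2,
        sep_rate / 2,
        e_a,
        e_p,
        late,
        late,
    )


_CONTROL = _spec("control-1cell", 14.0, 50.0, -0.02, 0.04, -0.024, -0.012, 0.010, 0.006)

# stage: (L0 μm, pole separation rate μm/s, poleward extent μm at 100 s)
_STAGES = {
    2: (12.0, 0.050, 1.3),
    4: (10.0, 0.040, 1.6),
    8: (8.5, 0.032, 1.9),
    16: (7.0, 0.026, 2.2),
    32: (6.0, 0.020, 2.5),
    64: (5.0, 0.015, 2.8),
}

PRESETS: dict[str, ConditionSpec] = {
    "control-1cell": _CONTROL,
    "stage-1": replace(_CONTROL, name="stage-1"),
    # polarity loss: symmetric halves
    "par2-like": _spec("par2-like", 14.0, 50.0, -0.020, 0.020, 0.0, 0.0, 0.0, 0.0),
    "par3-like": _spec("par3-like", 14.0, 50.0, -0.030, 0.030, -0.018, -0.018, 0.008, 0.008),
    "gpr12-like": _spec("gpr12-like", 14.0, 50.0, -0.015, 0.015, -0.015, -0.015, -0.008, -0.008),
    # midzone loss: fast poles, fast sustained poleward displacement
    "spd1-like": _spec("spd1-like", 14.0, 50.0, -0.040, 0.040, -0.035, -0.035, -0.015, -0.015),
    "ablation-like": _spec("ablation-like", 14.0, 50.0, -0.038, 0.038, -0.032, -0.032, -0.014, -0.014),
    # kinesin screen on the gpr-1/2 background
    "klp7-gpr12-like": _spec("klp7-gpr12-like", 14.0, 50.0, -0.018, 0.018, 0.0, 0.0, 0.0, 0.0),
    "klp18-gpr12-like": _spec("klp18-gpr12-like", 14.0, 50.0, -0.012, 0.012, -0.028, -0.028, -0.015, -0.015),
    # dissociated EMS blastomere: prolonged poleward, no reversal
    "ems-dissociated-like": _spec("ems-dissociated-like", 10.0, 36.0, -0.015, 0.015, -0.018, -0.018, -0.008, -0.008),
}
PRESETS.update({f"stage-{s}": _stage_spec(s, *p) for s, p in _STAGES.items()})

#: stage presets ordered by cleavage round (1-cell first)
STAGE_PRESETS = ["stage-1"] + [f"stage-{s}" for s in _STAGES]


def make_condition(name: str, overrides: dict | None = None) -> ConditionSpec:
    """Look up a preset by name, optionally overriding parameters.

    Overrides win over preset defaults; the returned spec is re-validated.

    Raises
    ------
    KeyError
        Unknown preset name.
    ValueError
        An override violates a :class:`ConditionSpec` invariant.
    """
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    spec = PRESETS[name]
    if overrides:
        unknown = set(overrides) - set(spec.to_dict())
        if unknown:
            raise ValueError(f"unknown ConditionSpec parameters: {sorted(unknown)}")
        spec = replace(spec, **{k: v for k, v in overrides.items()})
    return spec
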