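# Methods

## The measurement problem

During anaphase, sister chromatids separate through two superimposed
motions: the spindle poles move apart (anaphase B) and each chromosome set
moves relative to its own pole (anaphase A when poleward).  In early
*C. elegans* embryos the two can be decomposed from 4D (3D + time)
tracking of four structures — the two spindle poles and the two
segregating chromosome sets.  `spindlekin` implements that decomposition:
a synthetic-data generator that produces trajectories (and optionally
two-channel image stacks) with the statistical structure the analysis
assumes, a tracker that turns stacks back into trajectories, the kinematic
statistics, the two bespoke visualizations used in this literature
(composite kymographs and color-coded displacement graphs), and the
nonparametric group statistics.

## Kinematic model and statistics

All distances are full 3D Euclidean distances between structure centres,
in micrometres:

* `PP(t)` — pole-to-pole distance (spindle length),
* `CC(t)` — distance between the two chromosome sets (chromosome
  segregation),
* `CP_A(t)`, `CP_P(t)` — chromosome-set-to-own-pole distance on the
  anterior and posterior half-spindle.

Time is measured in seconds from anaphase onset (AO, the frame where the
chromosome mass splits); every series is onset-referenced:
`ΔPP(t) = PP(t) − PP(0)`, `ΔCP(t) = CP(t) − CP(0)`,
`ΔCC(t) = CC(t) − CC(0)`.  `ΔCC` is defined here by analogy with the other
deltas — it is the only definition that makes the contribution statistic
below dimensionally and sign-consistent with "the difference between pole
separation and chromosome segregation".

Windowed velocities are finite differences of `CP` over fixed windows,
`v = (CP(t₁) − CP(t₀)) / (t₁ − t₀)`, with default windows (0, 50) s (early
anaphase) and (50, 100) s (late anaphase).  The sign is the direction
label: negative = poleward (anaphase A), positive = anti-poleward, zero =
static.

The relative contribution of chromosome displacement to segregation at
time t > 0 is

    contribution(t) = (ΔCC(t) − ΔPP(t)) / CC(t) × 100   [percent]

For exactly colinear, noiseless motion the identity
`ΔCC = ΔPP − ΔCP_A − ΔCP_P` holds, so the contribution equals
`−(ΔCP_A + ΔCP_P)/CC × 100`; with real (noisy, non-colinear) data the two
differ slightly and the printed formula is authoritative.  Contribution is
computed **per embryo and then averaged** across a group; the alternative
(evaluating the formula on group-mean series) is available via
`group_average` composition but is not the default, since the per-embryo
route keeps the statistic paired with per-embryo covariates.

Auxiliary readouts: spindle length at onset is `PP(0)`; relative pole
position is the axial coordinate as a percentage of the AP axis (anterior
cortex 0 %, posterior cortex 100 %), clamped with a warning outside that
range.

Group means carry 95 % confidence intervals using the Student-t quantile
(`mean ± t₀.₉₇₅,ₙ₋₁ · SEM`) rather than 1.96, because typical group sizes
are 13–55 embryos.  Mixed 10 s / 20 s acquisitions are linearly
interpolated onto a common 10 s grid before group statistics; per-embryo
outputs keep their native grid.

## Synthetic-data generator

The generator is a kinematic, not mechanistic, model: it encodes *what the
structures do*, not the forces that make them do it (no cortical force
generators, microtubule dynamics, or tension model).

Per condition (`ConditionSpec`):

* Poles separate along the AP (x) axis at constant signed speeds from an
  initial separation `L0`; the anterior pole sits at lower x.
* Each chromosome set follows its pole at a chromosome-to-pole distance
  obeying a biphasic piecewise-linear law
  `CP(t) = CP(0) + r_early·min(t, t_switch) + r_late·max(0, t − t_switch)`
  with `t_switch = 50 s`, matching the early/late analysis windows.
  Whether the real reversal is abrupt or gradual is not established; the
  sharp switch is an assumption, and a logistic smoothing option
  (`switch_smoothing`, seconds) is provided but off by default.
* Frames before onset (default 5) carry a single unsplit chromosome mass
  at the spindle centre, so onset detection is exercised.
* Isotropic Gaussian noise of `noise_sd` (default 0.05 μm) is added to
  every coordinate — the simplest model consistent with centroid-based
  tracking error.

No numeric kinematic rates are published for these conditions, so preset
values are free parameters chosen once to reproduce the qualitative
phenotypes and orderings of the experimental literature and then frozen:

| preset | phenotype encoded |
|---|---|
| `control-1cell` | biphasic, asymmetric: early rates −0.024/−0.012 μm/s (anterior/posterior, poleward), late +0.010/+0.006 (anti-poleward); poles −0.02/+0.04 μm/s; `L0` 14 μm |
| `par2-like` | symmetrized, static chromosomes, weak pole separation |
| `par3-like` | symmetrized but control-like biphasic displacement |
| `gpr12-like` | symmetric slow sustained poleward movement, weak pole separation |
| `spd1-like`, `ablation-like` | fast pole separation with fast sustained poleward displacement (midzone loss) |
| `klp7-gpr12-like` | poleward displacement abolished (rates 0) |
| `klp18-gpr12-like` | exaggerated poleward displacement, reduced pole separation |
| `stage-2 … stage-64` | `L0` shrinking 12 → 5 μm, pole-separation rate 0.050 → 0.015 μm/s, total poleward extent at 100 s growing 1.3 → 2.8 μm — the contribution at 100 s then rises from ≈13 % to ≈49 % across stages, ≈9 % at the 1-cell stage |
| `ems-dissociated-like` | prolonged poleward movement without the anti-poleward reversal |

The onset chromosome-to-pole distance defaults to `(5/14)·L0` (5 μm for
the 14 μm 1-cell spindle) unless `cp0` is set.

What the generator does **not** emulate: spindle rotation/oscillation,
photobleaching and focus drift, chromosome-arm resolution, metaphase-plate
congression dynamics, or any force balance.  Tests passing on these data
therefore validate the measurement chain (formulas, detection, linking,
registration, statistics), not biological discovery: they show the
pipeline recovers known inputs under the stated noise model.

## Image rendering and tracking

Rendering emulates a spinning-disk acquisition (default 4 Z-sections
2 μm apart, one volume per 10 s; 0.4 μm/px laterally): poles are isotropic
Gaussian foci (lateral σ 0.4 μm, axial 2.5×), chromosome masses are
anisotropic Gaussians elongated perpendicular to the spindle axis
(σ = 0.6 × 1.5 × 0.8 μm), over a constant background with Poisson shot
noise.  The generating record stays embedded as ground truth.

Tracking is deliberately simple and fully parameterized:

* **Detection** — per frame and channel: median background subtraction,
  Otsu threshold (or a fixed value), 26-connected component labelling,
  components under 3 voxels discarded, intensity-weighted centroid in μm
  computed over the component's bounding box padded by 2 voxels (including
  the sub-threshold skirt suppresses threshold-truncation bias to
  ≪ 0.25 voxel).  All distances are computed in micrometres so the 2 μm Z
  step never distorts geometry.  The pole channel keeps the two brightest
  components, the chromosome channel the one or two largest.  Empty frames
  are flagged, not fatal.
* **Onset** — first frame at which two chromosome components are separated
  by > 1 μm and remain so for ≥ 2 consecutive frames (one-frame transients
  rejected); a manual frame index overrides.
* **Linking** — gated (3 μm per step) nearest-neighbour assignment solved
  as a 2×k linear assignment per channel; identities fixed at onset by
  axial order (anterior pole = lower x; each chromosome set to its nearer
  pole).  Equidistant candidates tie-break toward the brighter detection,
  logged.  One-frame gaps are filled by linear interpolation and flagged;
  longer losses abort naming the structure and first missing frame.  In
  cells without a meaningful AP axis (dissociated blastomeres) the same
  x-axis rule applies and the record carries an `arbitrary-polarity` flag.

## Visualizations

**Color-coded graph** — one row per timepoint (default 0–100 s), row
width = `PP(0)` at 10 px/μm.  The anterior chromosome set is a vertical
black line at `CP_A(t)` from the left edge, the posterior at `CP_P(t)`
from the right; the band between pole edge and line is filled with the
color of that side's `ΔCP(t)`, and the region between the lines is white
(the segregation signal).  The palette is a diverging piecewise-linear
map, anchored at +0.5 μm anti-poleward (dark blue, RGB 0.08/0.12/0.45)
and −2.0 μm poleward (dark red, 0.62/0.07/0.07) through a near-white
midpoint at ΔCP = 0 — the asymmetric anchors give two linear segments
about zero; exact hues are a package choice (only the endpoint semantics
are established) and are exposed in `ColorGraphSpec`.  The final image is
centre-cropped to a common width (default 10 μm) for cross-condition
comparison; the crop is kept mirror-symmetric (even margin) so mirrored
records render to exactly mirrored pixels.  Pole-to-chromosome band fill
was chosen over a fixed-width band, consistent with reading the white gap
as the segregation driven by displacement.

**Composite kymograph** — per timepoint (default every 20 s), the axial
intensity profile along the pole–pole line (max-Z projection, bilinear
sampling for image sources; Gaussian marks at the projected structure
positions for trajectory sources).  The left panel translates each row so
the anterior pole sits at a fixed column, the right panel likewise for the
posterior pole; each panel is cropped at the axial position of the
chromosome midpoint at onset and the panels are joined side by side.  With
pole motion factored out, chromosome displacement appears as motion of the
chromosome marks toward/away from the fixed pole columns.

Both renderers are deterministic (no hidden randomness): identical inputs
give pixel-identical images, asserted in tests.

## Group statistics

Two-sided throughout (one- vs two-sidedness is not stated per comparison
in this literature; two-sided is the conservative default).

* **Mann–Whitney U** — exact by full enumeration of the C(n, n₁) label
  assignments when the combined n ≤ 20 (valid with ties, using midranks),
  normal approximation with tie correction (scipy) otherwise.
* **Kruskal–Wallis + Dunn** — scipy's H statistic; Dunn pairwise z-tests
  on pooled mean ranks with tie correction, adjusted by multiplying each
  raw p by the number of comparisons (Bonferroni-style, capped at 1).
  This is the adjustment most commercial packages label "Dunn's
  correction"; other variants (Holm, Šidák) would order identically and
  the variant is isolated in one function argument.
* **Spearman ρ** — scipy's tie-aware statistic; exact permutation p by
  full enumeration for n ≤ 9, t-approximation otherwise.  Constant input
  is an error.

The stage-series scatter relates pole separation `ΔPP(100 s)` to the
*extent* of poleward displacement, reported as `−(ΔCP_A + ΔCP_P)` so that
larger values mean more anaphase A.  With that sign convention the
expected inverse relationship (small spindles: little pole separation,
much displacement) appears as a negative rank correlation, matching how
the displacement-versus-separation relationship is described in this
literature.

## Numerical choices and degenerate inputs

* Exact-grid lookups use `np.isclose`; a requested time off-grid by less
  than half a frame resolves to the nearest sample with a warning, beyond
  that it is an error.
* `contribution` is undefined at t ≤ 0 and where `CC = 0` (errors).
* Records must contain t = 0, have the anterior pole at lower x at onset,
  and both chromosome sets strictly between the poles (projected onto the
  spindle axis) — violated invariants raise at construction.
* Mann–Whitney on two identical constant samples returns p = 1 with a
  warning instead of failing.
* Mirroring a record (x → L − x, A↔P relabel) is an exact symmetry of all
  kinematics up to floating-point rounding (≤ 1e-12 μm on distances).

## Problem sizes

The test suite and the acceptance script size their simulations for
desk-scale runs: velocity-recovery cohorts of 100 embryos
(trajectory-only), 20 rendered stacks of 64 × 64 × 8 voxels × 21 frames
for tracking recovery, 2,000 null simulations at n = 16 per group for the
type-I-error calibration, and 8–16 embryos per preset for the phenotype
orderings.  These sizes give stable medians and rates while keeping the
whole suite under a minute of compute.

## Known limitations

* The generator's piecewise-linear law cannot produce curvature within a
  phase; velocity windows aligned to the switch recover rates exactly,
  which is a best case relative to real data.
* Tracking assumes exactly 2 + 2 structures and separable channels; it
  does not handle pole/chromosome marker bleed-through, spindle rotation
  out of the sampled Z range, or more than one dividing cell per field.
* The contribution statistic is undefined before segregation begins and is
  noisy where `CC` is small; early-timepoint group means should be read
  with that in mind.
* Preset parameter values are plausible encodings of published qualitative
  phenotypes, not fitted quantities; conclusions about real embryos
  require re-estimating them from real tracks.
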