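# spindlekin

Anaphase A/B decomposition of mitotic spindle kinematics in early
*C. elegans* embryos.

During anaphase, the two sets of sister chromatids separate through two
superimposed motions: the spindle poles move apart (**anaphase B**), and
each chromosome set moves relative to its own pole (**anaphase A** when
that motion is poleward).  Given 4D tracks of the two spindle poles and
the two segregating chromosome sets, `spindlekin` decomposes overall
chromosome segregation into these components.  It is aimed at
cell-division labs quantifying live-imaging experiments, and at anyone who
needs a tested, scriptable replacement for interactive spindle-tracking
workflows.

With `PP`, `CC` and `CP` the 3D Euclidean pole–pole,
chromosome–chromosome and chromosome-to-own-pole distances, and t = 0 at
anaphase onset (AO), the package computes:

- onset-referenced deltas ΔPP(t) = PP(t) − PP(AO), ΔCP(t) = CP(t) − CP(AO),
  ΔCC(t) = CC(t) − CC(AO);
- windowed velocities v = (CP(t₁) − CP(t₀))/(t₁ − t₀) over early (0–50 s)
  and late (50–100 s) anaphase, with sign-based direction labels
  (v < 0 poleward, v > 0 anti-poleward);
- the relative contribution of chromosome displacement to segregation,
  (ΔCC − ΔPP)(t) / CC(t) × 100 [%];
- group means with 95 % t-based confidence intervals, Mann–Whitney,
  Kruskal–Wallis with Dunn's post-hoc, and Spearman correlation;
- composite kymographs (pole positions held fixed) and color-coded
  ΔCP graphs (diverging palette anchored at +0.5 μm anti-poleward /
  −2.0 μm poleward).

Because raw microscopy for this problem is rarely shareable, the package
ships a first-class synthetic generator: condition presets (polarity loss,
midzone loss, kinesin depletions, cleavage stages 1–64, dissociated
blastomeres) produce ground-truth trajectories with the biphasic,
anterior/posterior-asymmetric displacement structure of the real system,
and an optional renderer turns them into two-channel 3D+t TIFF stacks
(point-like pole foci, elongated chromosome masses, Poisson noise) so the
tracking stage is testable end to end.

## Worked example

```python
import spindlekin as sk

spec = sk.make_condition("control-1cell", {"noise_sd": 0.0})
record = sk.simulate_embryo(spec, seed=0)
series = sk.compute_kinematics(record)

print(f"spindle length at onset : {sk.spindle_length_at_onset(series):.1f} um")
print(f"pole separation  dPP(100s) : {series.value_at('dpp', 100):+.2f} um")
print(f"displacement  dCP_A(100s) : {series.value_at('dcp_a', 100):+.2f} um")
print(f"displacement  dCP_P(100s) : {series.value_at('dcp_p', 100):+.2f} um")
vs = sk.velocity_summary(series)
print(f"early velocities (A, P) : {vs.v_early_A:+.3f}, {vs.v_early_P:+.3f} um/s "
      f"({vs.directions()['v_early_A']})")
print(f"late velocities  (A, P) : {vs.v_late_A:+.3f}, {vs.v_late_P:+.3f} um/s "
      f"({vs.directions()['v_late_A']})")
print(f"contribution of displacement to segregation at 100 s : "
      f"{sk.contribution(series, 100):.1f} %")
```

prints

```
spindle length at onset : 14.0 um
pole separation  dPP(100s) : +6.00 um
displacement  dCP_A(100s) : -0.70 um
displacement  dCP_P(100s) : -0.30 um
early velocities (A, P) : -0.024, -0.012 um/s (poleward)
late velocities  (A, P) : +0.010, +0.006 um/s (anti-poleward)
contribution of displacement to segregation at 100 s : 9.1 %
```

Read: over the first 100 s of anaphase the poles separate by 6 μm while
both chromosome sets first move 1.2/0.6 μm toward their poles (anterior
faster — the hallmark asymmetry of the polarized zygote) and then drift
back; net, about 9 % of chromosome segregation in this control condition
is chromosome displacement rather than pole separation.  Under the
`stage-64` preset the same readout rises to ≈ 49 %.

The same flows are available from a shell:

```sh
spindlekin simulate -p control-1cell --n 10 --seed 1 --out run/
spindlekin render --traj run/trajectories_control-1cell.csv --out run/stacks/
spindlekin track --stack run/stacks/control-1cell-000.tif --out run/tracked.csv
spindlekin analyze --traj run/trajectories_control-1cell.csv --out run/analysis/
spindlekin plot color-graph --traj run/tracked.csv --out run/cg.png
spindlekin stats --summary run/analysis/summary.csv --out run/stats.json
spindlekin run --config config.yaml   # full pipeline from YAML
```

## Layout

```
src/spindlekin/
  conditions.py   condition presets and parameter validation
  simulate.py     ground-truth trajectory generator
  imaging.py      two-channel 3D+t renderer
  tracking.py     detection, onset calling, linking
  kinematics.py   distance/velocity/contribution statistics
  viz.py          color-coded graphs, composite kymographs
  stats.py        Mann–Whitney, Kruskal–Wallis + Dunn, Spearman
  io.py           trajectory CSV, TIFF + YAML sidecar
  pipeline.py     end-to-end run with manifest
  cli.py          `spindlekin` command
docs/methods.md   model, parameter and design documentation
```
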