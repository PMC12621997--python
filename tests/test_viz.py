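import numpy as np
import pytest

import spindlekin as sk
from spindlekin.records import PointTrack
from spindlekin.viz import ColorGraphSpec, map_dcp_color


@pytest.fixture
def spec():
    return ColorGraphSpec()


class TestColorMapping:
    def test_anchor_values_map_exactly(self, spec):
        assert np.allclose(map_dcp_color(0.5, spec), spec.color_anti)
        assert np.allclose(map_dcp_color(-2.0, spec), spec.color_pole)

    def test_zero_maps_to_midpoint(self, spec):
        assert np.allclose(map_dcp_color(0.0, spec), spec.color_mid)

    def test_values_beyond_anchors_clamp(self, spec):
        assert np.allclose(map_dcp_color(3.0, spec), spec.color_anti)
        assert np.allclose(map_dcp_color(-9.0, spec), spec.color_pole)

    def test_componentwise_monotone_between_anchors(self, spec):
        """Colors along each arm progress monotonically from midpoint to
        anchor, and distinct ΔCP values map to distinct colors."""
        for lo, hi in ((0.0, spec.anchor_anti), (spec.anchor_pole, 0.0)):
            vals = np.linspace(lo, hi, 25)
            cols = np.array([map_dcp_color(v, spec) for v in vals])
            diffs = np.diff(cols, axis=0)
            for c in range(3):
                assert np.all(diffs[:, c] >= -1e-12) or np.all(diffs[:, c] <= 1e-12)
            assert all(
                not np.allclose(cols[i], cols[i + 1]) for i in range(len(cols) - 1)
            )

    def test_non_finite_rejected(self, spec):
        with pytest.raises(ValueError):
            map_dcp_color(np.nan, spec)

    def test_invalid_anchor_ordering_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            ColorGraphSpec(anchor_anti=-0.5)


class TestColorGraph:
    def test_row_count_matches_timepoints(self, worked_series, spec):
        img, geo = sk.render_color_graph(worked_series, spec)
        assert geo["n_rows"] == 11  # 0..100 s inclusive at 10 s
        assert img.shape[0] == 11 * spec.row_scale

    def test_uncropped_width_is_onset_spindle_length(self, worked_series):
        s = ColorGraphSpec(crop_width=None)
        img, geo = sk.render_color_graph(worked_series, s)
        assert geo["width_um"] == pytest.approx(14.0)
        assert img.shape[1] == round(14.0 * s.px_per_um)

    def test_pure_anaphase_b_bands_are_midpoint_colored(self, spec):
        t = np.arange(0.0, 101.0, 10.0)
        xa, xp = 2.0 - 0.02 * t, 16.0 + 0.04 * t
        z = np.zeros_like(t)
        tr = lambda n, x: PointTrack(n, t, np.column_stack([x, z, z]))
        rec = sk.EmbryoRecord(
            "b", "c", "s",
            {
                "pole_A": tr("pole_A", xa),
                "pole_P": tr("pole_P", xp),
                "chr_A": tr("chr_A", xa + 5.0),
                "chr_P": tr("chr_P", xp - 5.0),
            },
        )
        series = sk.compute_kinematics(rec)
        img, geo = sk.render_color_graph(series, ColorGraphSpec(crop_width=None))
        mid = np.round(np.array(ColorGraphSpec().color_mid) * 255).astype(np.uint8)
        # leftmost and rightmost columns carry the band color at every row
        assert np.all(img[:, 0] == mid)
        assert np.all(img[:, -1] == mid)
        # black chromosome lines are vertical: same columns black in every row
        black_cols = np.where((img == 0).all(axis=2).all(axis=0))[0]
        assert black_cols.size >= 2 * ColorGraphSpec().line_width_px

    def test_control_lines_converge_then_return(self, control_record_noiseless):
        series = sk.compute_kinematics(control_record_noiseless)
        img, geo = sk.render_color_graph(series, ColorGraphSpec(crop_width=None))
        # CP_A shrinks through early anaphase (line moves toward the pole
        # edge) then grows again; read line position per row
        scale = ColorGraphSpec().row_scale
        rows = img[::scale]
        line_pos = []
        for r in rows:
            blacks = np.where((r == 0).all(axis=1))[0]
            line_pos.append(blacks.min())
        assert line_pos[5] < line_pos[0]  # poleward by 50 s
        assert line_pos[10] > line_pos[5]  # anti-poleward after

    def test_mirrored_record_mirrors_image_pixel_exact(
        self, control_record_noiseless, spec
    ):
        series = sk.compute_kinematics(control_record_noiseless)
        mirrored = sk.compute_kinematics(sk.mirror_record(control_record_noiseless))
        img, _ = sk.render_color_graph(series, spec)
        img_m, _ = sk.render_color_graph(mirrored, spec)
        assert np.array_equal(img_m, img[:, ::-1])

    def test_rerender_pixel_identical(self, worked_series, spec):
        a, _ = sk.render_color_graph(worked_series, spec)
        b, _ = sk.render_color_graph(worked_series, spec)
        assert np.array_equal(a, b)

    def test_short_series_rejected(self, worked_record):
        series = sk.compute_kinematics(worked_record)
        with pytest.raises(ValueError, match="before t_range"):
            sk.render_color_graph(series, ColorGraphSpec(t_range=(0, 200)))


class TestCompositeKymograph:
    def test_crop_column_is_onset_chromosome_midpoint(self, worked_record):
        img, geo = sk.render_composite_kymograph(worked_record)
        truth_mid = 0.5 * (
            worked_record.tracks["chr_A"].at(0.0)[0]
            + worked_record.tracks["chr_P"].at(0.0)[0]
        )
        assert geo["onset_midpoint_um"] == pytest.approx(truth_mid, abs=1e-12)

    def test_stationary_record_panels_mirror(self):
        t = np.arange(0.0, 101.0, 10.0)
        z = np.zeros_like(t)
        tr = lambda n, x: PointTrack(n, t, np.column_stack([np.full_like(t, x), z, z]))
        rec = sk.EmbryoRecord(
            "s", "c", "s",
            {
                "pole_A": tr("pole_A", 2.0),
                "pole_P": tr("pole_P", 16.0),
                "chr_A": tr("chr_A", 7.0),
                "chr_P": tr("chr_P", 11.0),
            },
        )
        img, geo = sk.render_composite_kymograph(rec)
        left = img[:, : geo["left_panel_px"]].astype(int)
        right = img[:, geo["left_panel_px"] :].astype(int)
        assert left.shape == right.shape
        assert np.max(np.abs(left - right[:, ::-1])) <= 1  # uint8 rounding

    def test_row_count_and_interval(self, control_record_noiseless):
        img, geo = sk.render_composite_kymograph(
            control_record_noiseless, interval=20.0
        )
        assert geo["n_rows"] == 6  # 0, 20, ..., 100 s
        assert geo["interval_s"] == 20.0

    def test_chromosomes_approach_fixed_pole_early(self, control_record_noiseless):
        """With poles held fixed, the chromosome mark moves toward the pole
        column during early anaphase (the composite's whole point)."""
        img, geo = sk.render_composite_kymograph(
            control_record_noiseless, interval=10.0, row_scale=1
        )
        rec = control_record_noiseless
        # distance of chr_A from pole_A shrinks over rows 0..5
        cp = [
            np.linalg.norm(rec.tracks["chr_A"].at(t) - rec.tracks["pole_A"].at(t))
            for t in (0.0, 50.0)
        ]
        assert cp[1] < cp[0]
        # and the schematic image reflects it: brightest chromosome pixel in
        # the left panel moves left between row 0 and row 5
        left = img[:, : geo["left_panel_px"]]
        margin_px = int(2.0 * geo["px_per_um"])
        peak0 = margin_px + np.argmax(left[0, margin_px + 10 :])
        peak5 = margin_px + np.argmax(left[5, margin_px + 10 :])
        assert peak5 < peak0

    def test_image_and_trajectory_sources_agree_on_geometry(
        self, control_record_noiseless, control_stack_noiseless
    ):
        _, g1 = sk.render_composite_kymograph(control_record_noiseless)
        _, g2 = sk.render_composite_kymograph(control_stack_noiseless)
        assert g1["onset_midpoint_um"] == pytest.approx(g2["onset_midpoint_um"])
        assert g1["left_panel_px"] == g2["left_panel_px"]

    def test_rerender_pixel_identical(self, control_stack_noiseless):
        a, _ = sk.render_composite_kymograph(control_stack_noiseless)
        b, _ = sk.render_composite_kymograph(control_stack_noiseless)
        assert np.array_equal(a, b)

    def test_unregistered_source_rejected(self, worked_record):
        shifted = {
            s: PointTrack(s, tr.t + 5.0, tr.xyz)
            for s, tr in worked_record.tracks.items()
        }
        with pytest.raises(ValueError):
            rec = sk.EmbryoRecord("e", "c", "s", shifted)
            sk.render_composite_kymograph(rec)
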