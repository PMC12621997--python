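import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spindlekin as sk
from spindlekin.records import PointTrack

finite = st.floats(-100, 100, allow_nan=False)
point = st.tuples(finite, finite, finite)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ((0, 0, 0), (3, 4, 0), 5.0),
        ((1, 1, 1), (1, 1, 1), 0.0),
        ((0, 0, 0), (1, 2, 2), 3.0),
    ],
)
def test_euclidean_distance_examples(a, b, expected):
    assert sk.euclidean_distance(a, b) == pytest.approx(expected, abs=1e-12)


@settings(max_examples=50, derandomize=True)
@given(a=point, b=point)
def test_euclidean_distance_symmetric_nonnegative(a, b):
    d = sk.euclidean_distance(a, b)
    assert d >= 0
    assert d == pytest.approx(sk.euclidean_distance(b, a), abs=1e-12)


def test_euclidean_distance_rejects_non_finite():
    with pytest.raises(ValueError):
        sk.euclidean_distance((0, 0, 0), (np.nan, 0, 0))


class TestWorkedRecord:
    """Hand-evaluated distance and delta series on the colinear record."""

    def test_distances_and_deltas(self, worked_series):
        s = worked_series
        assert s.pp[0] == pytest.approx(14.0, abs=1e-9)
        assert s.value_at("pp", 100) == pytest.approx(20.0, abs=1e-9)
        assert s.value_at("dpp", 100) == pytest.approx(6.0, abs=1e-9)
        assert s.value_at("dcp_a", 100) == pytest.approx(-1.0, abs=1e-9)
        assert s.value_at("dcp_p", 100) == pytest.approx(-1.0, abs=1e-9)
        assert s.value_at("cc", 100) == pytest.approx(12.0, abs=1e-9)
        assert s.value_at("dcc", 100) == pytest.approx(8.0, abs=1e-9)

    def test_all_deltas_zero_at_onset(self, worked_series):
        s = worked_series
        for name in ("dpp", "dcc", "dcp_a", "dcp_p"):
            assert getattr(s, name)[0] == 0.0

    def test_contribution(self, worked_series):
        assert sk.contribution(worked_series, 100) == pytest.approx(
            (8.0 - 6.0) / 12.0 * 100.0, abs=1e-9
        )

    def test_early_velocity_poleward(self, worked_series):
        v = sk.window_velocity(worked_series, "A", 0, 50)
        assert v == pytest.approx(-0.02, abs=1e-9)
        assert sk.classify_direction(v) == "poleward"

    def test_spindle_length_at_onset(self, worked_series):
        assert sk.spindle_length_at_onset(worked_series) == pytest.approx(14.0)

    def test_translation_invariance(self, worked_record):
        shift = np.array([10.0, -3.0, 2.0])
        tracks = {
            s: PointTrack(s, tr.t, tr.xyz + shift)
            for s, tr in worked_record.tracks.items()
        }
        moved = sk.EmbryoRecord("e", "c", "s", tracks)
        a = sk.compute_kinematics(worked_record)
        b = sk.compute_kinematics(moved)
        for name in ("pp", "cc", "cp_a", "cp_p"):
            assert np.allclose(getattr(a, name), getattr(b, name), atol=1e-12)


@pytest.mark.parametrize(
    "cp_breakpoints, window, expected",
    [
        ((5.0, 4.0, 4.0), (0.0, 50.0), -0.02),
        ((4.0, 4.0, 4.0), (50.0, 100.0), 0.0),
        ((5.0, 4.0, 4.5), (50.0, 100.0), 0.01),
    ],
)
def test_window_velocity_formula(cp_breakpoints, window, expected):
    t = np.arange(0.0, 101.0, 10.0)
    cp = np.interp(t, [0.0, 50.0, 100.0], cp_breakpoints)
    series = sk.KinematicsSeries(
        "e", "c", "s", t,
        pp=np.full_like(t, 20.0),
        cc=20.0 - 2 * cp,
        cp_a=cp,
        cp_p=cp,
    )
    assert sk.window_velocity(series, "A", *window) == pytest.approx(
        expected, abs=1e-12
    )


def test_window_velocity_beyond_extent_errors(worked_series):
    with pytest.raises(ValueError, match="beyond series extent"):
        sk.window_velocity(worked_series, "A", 100, 150)


@pytest.mark.parametrize(
    "v, label",
    [(-0.02, "poleward"), (0.01, "anti-poleward"), (0.0, "static")],
)
def test_classify_direction(v, label):
    assert sk.classify_direction(v) == label


def test_contribution_requires_positive_time(worked_series):
    with pytest.raises(ValueError, match="t > 0"):
        sk.contribution(worked_series, 0.0)


def test_contribution_zero_for_pure_anaphase_b():
    """When chromosomes ride the poles (ΔCP = 0), ΔCC = ΔPP and the
    contribution vanishes at every timepoint."""
    t = np.arange(0.0, 101.0, 10.0)
    xa = 2.0 - 0.02 * t
    xp = 16.0 + 0.04 * t
    z = np.zeros_like(t)

    def track(name, x):
        return PointTrack(name, t, np.column_stack([x, z, z]))

    rec = sk.EmbryoRecord(
        "b", "c", "s",
        {
            "pole_A": track("pole_A", xa),
            "pole_P": track("pole_P", xp),
            "chr_A": track("chr_A", xa + 5.0),
            "chr_P": track("chr_P", xp - 5.0),
        },
    )
    series = sk.compute_kinematics(rec)
    for t_q in series.t[1:]:
        assert sk.contribution(series, t_q) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("preset", sorted(sk.PRESETS))
def test_decomposition_identity_all_presets(preset):
    """Colinear noiseless: ΔCC = ΔPP − ΔCP_A − ΔCP_P, and the contribution
    plus the pole-separation share equals the total segregation share."""
    spec = sk.make_condition(preset, {"noise_sd": 0.0})
    series = sk.compute_kinematics(sk.simulate_embryo(spec, seed=0))
    assert np.allclose(
        series.dcc, series.dpp - series.dcp_a - series.dcp_p, atol=1e-9
    )
    for t in series.t[1:]:
        cc = series.value_at("cc", t)
        lhs = sk.contribution(series, t) + series.value_at("dpp", t) / cc * 100
        rhs = series.value_at("dcc", t) / cc * 100
        assert lhs == pytest.approx(rhs, abs=1e-9)


def test_relative_pole_position():
    rec = sk.simulate_embryo(sk.make_condition("control-1cell", {"noise_sd": 0.0}))
    assert rec.embryo_length == 50.0
    pct = sk.relative_pole_position(rec, "pole_A", 0.0)
    assert pct == pytest.approx((25.0 - 7.0) / 50.0 * 100.0)
    # end-member conventions: anterior cortex 0%, posterior cortex 100%
    assert 0.0 <= pct <= 100.0
    rec_nolen = sk.EmbryoRecord(
        "e", "c", "s", rec.tracks, embryo_length=None
    )
    with pytest.raises(ValueError, match="embryo_length"):
        sk.relative_pole_position(rec_nolen, "pole_A", 0.0)


def test_group_average_trivial_cases():
    spec = sk.make_condition("control-1cell", {"noise_sd": 0.0})
    s = sk.compute_kinematics(sk.simulate_embryo(spec, seed=0))
    out = sk.group_average([s, s, s], "dcp_a")
    assert np.allclose(out["ci_high"] - out["ci_low"], 0.0, atol=1e-12)

    # {0 everywhere} and {2 everywhere} -> mean 1
    t = np.arange(0.0, 101.0, 10.0)
    mk = lambda off: sk.KinematicsSeries(
        "e", "c", "s", t, pp=np.full_like(t, 10.0) + off,
        cc=np.full_like(t, 4.0), cp_a=np.full_like(t, 3.0),
        cp_p=np.full_like(t, 3.0),
    )
    out = sk.group_average([mk(0.0), mk(2.0)], "pp")
    assert np.allclose(out["mean"], 11.0)


def test_group_average_single_series_ci_undefined():
    spec = sk.make_condition("control-1cell", {"noise_sd": 0.0})
    s = sk.compute_kinematics(sk.simulate_embryo(spec, seed=0))
    out = sk.group_average([s], "dcp_a")
    assert out["ci_low"].isna().all()
    with pytest.raises(ValueError, match="empty"):
        sk.group_average([], "dcp_a")


def test_group_average_mixed_grids_harmonized():
    """10 s and 20 s acquisitions are interpolated onto one grid."""
    s10 = sk.compute_kinematics(
        sk.simulate_embryo(sk.make_condition("control-1cell", {"noise_sd": 0.0}))
    )
    s20 = sk.compute_kinematics(
        sk.simulate_embryo(
            sk.make_condition("control-1cell", {"noise_sd": 0.0, "dt": 20.0})
        )
    )
    out = sk.group_average([s10, s20], "dpp", grid_dt=10.0)
    assert np.allclose(np.diff(out["t_s"]), 10.0)
    assert np.allclose(out["mean"], np.interp(out["t_s"], s10.t, s10.dpp), atol=1e-9)


def test_group_mean_ci_covers_generator_truth():
    """95% CI of the cohort mean ΔCP_A(50) covers the generator value in at
    least 90% of 20 repetitions (50 noisy embryos each)."""
    spec = sk.make_condition("control-1cell")  # default noise
    truth = spec.dcp_rate_early_A * 50.0
    hits = 0
    for rep in range(20):
        series = [
            sk.compute_kinematics(r)
            for r in sk.simulate_cohort(spec, 50, seed=1000 + rep)
        ]
        out = sk.group_average(series, "dcp_a")
        row = out[np.isclose(out["t_s"], 50.0)].iloc[0]
        hits += row["ci_low"] <= truth <= row["ci_high"]
    assert hits >= 18


def test_velocity_recovery_noiseless_exact_and_noisy_close():
    spec0 = sk.make_condition("control-1cell", {"noise_sd": 0.0})
    s = sk.compute_kinematics(sk.simulate_embryo(spec0, seed=0))
    assert sk.window_velocity(s, "A", 0, 50) == pytest.approx(
        spec0.dcp_rate_early_A, abs=1e-9
    )
    assert sk.window_velocity(s, "P", 50, 100) == pytest.approx(
        spec0.dcp_rate_late_P, abs=1e-9
    )

    spec = sk.make_condition("control-1cell", {"noise_sd": 0.1})
    errs = []
    for rec in sk.simulate_cohort(spec, 100, seed=0):
        ser = sk.compute_kinematics(rec)
        errs.append(abs(sk.window_velocity(ser, "A", 0, 50) - spec.dcp_rate_early_A))
        errs.append(abs(sk.window_velocity(ser, "P", 0, 50) - spec.dcp_rate_early_P))
    assert np.median(errs) < 0.005


def test_summarize_cohort_columns():
    spec = sk.make_condition("control-1cell")
    series = [sk.compute_kinematics(r) for r in sk.simulate_cohort(spec, 3, seed=0)]
    df = sk.summarize_cohort(series)
    assert len(df) == 3
    for col in ("v_early_A", "dir_early_A", "contribution_100s_pct",
                "pp_onset_um", "dpp_100s_um", "poleward_extent_100s_um"):
        assert col in df.columns
    assert (df["dir_early_A"] == "poleward").all()
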