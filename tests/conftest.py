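import numpy as np
import pytest

import spindlekin as sk
from spindlekin.records import EmbryoRecord, PointTrack


def build_worked_record() -> EmbryoRecord:
    """Hand-built colinear record with known kinematics.

    Poles start 14 μm apart (x = 2 and 16) and end 20 μm apart (x = 0 and
    20) at t = 100 s; each chromosome-to-pole distance shrinks linearly
    from 5 μm to 4 μm during the first 50 s and then holds.  Every
    downstream value is hand-computable: ΔPP(100) = 6, ΔCP = −1 per side,
    CC 4 → 12 so ΔCC = 8, contribution(100) = (8 − 6)/12 × 100 = 16.667%,
    early velocity −0.02 μm/s.
    """
    t = np.arange(0.0, 101.0, 10.0)
    xa = 2.0 - 0.02 * t
    xp = 16.0 + 0.04 * t
    cp = 5.0 - 0.02 * np.minimum(t, 50.0)
    z = np.zeros_like(t)

    def track(name, x):
        return PointTrack(name, t, np.column_stack([x, z, z]))

    return EmbryoRecord(
        embryo_id="worked",
        condition="worked",
        stage="1-cell",
        tracks={
            "pole_A": track("pole_A", xa),
            "pole_P": track("pole_P", xp),
            "chr_A": track("chr_A", xa + cp),
            "chr_P": track("chr_P", xp - cp),
        },
        embryo_length=22.0,
    )


@pytest.fixture
def worked_record() -> EmbryoRecord:
    return build_worked_record()


@pytest.fixture
def worked_series(worked_record):
    return sk.compute_kinematics(worked_record)


@pytest.fixture(scope="session")
def control_spec_noiseless():
    return sk.make_condition("control-1cell", {"noise_sd": 0.0})


@pytest.fixture(scope="session")
def control_record_noiseless(control_spec_noiseless):
    return sk.simulate_embryo(control_spec_noiseless, seed=0)


@pytest.fixture(scope="session")
def control_stack_noiseless(control_record_noiseless):
    return sk.render_stack(
        control_record_noiseless, z_planes=8, poisson=False
    )
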