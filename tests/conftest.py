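import pytest

import roctscan as r
from roctscan.geometry import DOWNWARD_ROTATION, PixelResolution, ProbePose
from roctscan.oct_simulation import make_layered_kidney, make_letter_phantom


@pytest.fixture
def probe():
    """Desk-scale probe: 64x100 px, 3.2 mm lateral / 2 mm axial FOV."""
    return r.ProbeSpec(
        width_px=64,
        height_px=100,
        alpha_res=PixelResolution(lateral=0.05, axial=0.02, elevational=0.03),
    )


@pytest.fixture
def flat_sample():
    """Flat noiseless tissue at altitude 0 with uniform extinction 1.5/mm."""
    return make_layered_kidney((40.0, 40.0), 0.0, [(5.0, 1.5)])


def downward_pose(x=0.0, y=0.0, z=0.0, timestamp=0.0):
    return ProbePose.from_rt(DOWNWARD_ROTATION, (x, y, z), timestamp=timestamp)


@pytest.fixture
def small_plan():
    return r.ScanPlan(x_st=1.0, y_st=3.0, z_st=8.0, L=2.0, W=6.0, W_ol=0.8, W_OCT=3.2)


@pytest.fixture(scope="session")
def phantom_scan():
    """Three-scanline noiseless scan of a square-glyph phantom, reused widely."""
    # extrusion must stay below the NSD headroom (0.25 * H_OCT = 0.5 mm) so
    # the glyph top never rises above the image origin mid-scan
    sample = make_letter_phantom(
        footprint=(10.0, 10.0),
        letters=[{"rect": (2.0, 3.5, 3.0, 2.0)}],
        extrusion_height=0.4,
        pitch=0.05,
        mu_t=1.5,
    )
    probe = r.ProbeSpec(
        width_px=64,
        height_px=100,
        alpha_res=PixelResolution(lateral=0.05, axial=0.02, elevational=0.03),
    )
    plan = r.ScanPlan(x_st=0.5, y_st=2.5, z_st=8.0, L=6.0, W=6.0, W_ol=0.8, W_OCT=3.2)
    cfg = r.ScanConfig()
    log = r.run_scan(sample, plan, cfg, probe=probe)
    return {"sample": sample, "probe": probe, "plan": plan, "cfg": cfg, "log": log}
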