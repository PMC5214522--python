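import numpy as np
import pytest

from stampede.protocol import MotionBlock, StimulusTimeline, build_standard_timeline
from stampede.simulate import (
    ArenaGeometry,
    ImagingParams,
    TrajectorySet,
    get_preset,
    render_frames,
    run_trial,
)


@pytest.fixture(scope="session")
def standard_timeline():
    return build_standard_timeline()


@pytest.fixture(scope="session")
def arena():
    return ArenaGeometry()


def make_two_fly_trajectories(seed_a=1, seed_b=2, duration_s=60.0, fps=25.0):
    """Two random-walk flies confined to opposite halves of the tube, so
    they stay far apart (well-separated closed-loop fixture)."""
    half = ArenaGeometry(length_mm=70.0)
    tl = StimulusTimeline.from_blocks([MotionBlock(-1, duration_s, 25.0)])
    null = get_preset("null")
    a = run_trial(tl, null, arena=half, fps=fps, seed=seed_a)
    b = run_trial(tl, null, arena=half, fps=fps, seed=seed_b)
    x = np.vstack([a.x_mm[0], b.x_mm[0] + 82.0])
    y = np.vstack([a.y_mm[0], b.y_mm[0]])
    return TrajectorySet(
        t_s=a.t_s, x_mm=x, y_mm=y, fps=fps, fly_ids=(0, 1), arena=ArenaGeometry()
    )


@pytest.fixture(scope="session")
def two_fly_scene():
    """Noise-free rendered video of two well-separated flies plus its
    ground truth."""
    trajs = make_two_fly_trajectories(duration_s=20.0)
    stack = render_frames(trajs, ImagingParams(noise_sigma=0.0))
    return trajs, stack
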