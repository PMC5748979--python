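import numpy as np
import pytest

from centrotrack import simgen
from centrotrack.spots import ImageStack


def render_single_spot(position_um, n_x=32, n_y=32, n_z=15, noise="none",
                       amplitude=500.0, background=10.0, seed=0,
                       frame_interval=40.0) -> ImageStack:
    """One static spot rendered through the standard optics."""
    optics = simgen.OpticsParams(n_x=n_x, n_y=n_y, n_z=n_z,
                                 noise_model=noise, spot_amplitude=amplitude,
                                 background=background, seed=seed)
    truth = simgen.SyntheticTruth(
        positions=np.asarray(position_um, dtype=float).reshape(1, 1, 3),
        separation=np.array([0.0]),
        frame_interval=frame_interval,
        completion_frame=None, motorized_onset_frame=None,
        anaphase_onset_frame=0)
    return simgen.render_stack(truth, optics)


@pytest.fixture
def single_spot_stack():
    """Noiseless spot at an off-grid position inside a small volume."""
    pos = np.array([2.11, 1.57, 3.60])
    return render_single_spot(pos), pos


@pytest.fixture
def clustering_truth():
    """Noiseless clustering pair: onset at frame 0, completion at frame 23."""
    params = simgen.MotionParams(
        mean_separation_search=7.5, sd_search=0.0, onset_separation=7.5,
        motorized_duration=900.0, frame_interval=40.0, final_separation=1.5,
        n_frames=40, cluster=True, seed=11)
    return simgen.simulate_pair(params)
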