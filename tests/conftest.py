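import numpy as np
import pytest

from penlaws.io import TrialRecording
from penlaws.synthetic import MotorProfile


def make_trial(t, x, y, pen_down=None, game="copy", item="circle",
               modality="spontaneous", geometry_id=None, **kw):
    """Hand-rolled trial with sensible metadata defaults."""
    t = np.asarray(t, dtype=float)
    pen = np.ones(len(t), dtype=bool) if pen_down is None else np.asarray(pen_down, bool)
    if game == "tunnel" and modality == "spontaneous":
        modality = None
    return TrialRecording(subject_id=kw.pop("subject_id", "s1"),
                          group=kw.pop("group", "primary"), game=game,
                          item=item, t=t, x=np.asarray(x, float),
                          y=np.asarray(y, float), pen_down=pen,
                          modality=modality, geometry_id=geometry_id, **kw)


@pytest.fixture
def constant_velocity_trial():
    """Straight pen-down line at exactly 120 mm/s, 50 Hz, 4 s."""
    t = np.arange(201) * 0.02
    return make_trial(t, 120.0 * t, np.zeros_like(t))


@pytest.fixture
def noiseless_profile():
    return MotorProfile(lateral_noise_sd=0.0, fraction_noise_sd=0.0,
                        mt_noise_sd=0.0)
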