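import numpy as np
import pytest

from dissofit import DissolutionProfile, two_stage_schedule


@pytest.fixture
def schedule():
    return two_stage_schedule()


def make_profile(times, release, fid="P", replicate=None, stages=()):
    return DissolutionProfile(
        formulation_id=fid,
        times=np.asarray(times, dtype=float),
        release=np.asarray(release, dtype=float),
        stages=stages,
        replicate_id=replicate,
    )


@pytest.fixture
def profile_factory():
    return make_profile
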