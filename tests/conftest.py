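import numpy as np
import pytest

from meahazard.io_formats import ScoringConfig, SpikeTrain, WellRecording


@pytest.fixture
def cfg():
    return ScoringConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_train(eid, timestamps):
    return SpikeTrain(eid, np.asarray(timestamps, dtype=float))


def make_recording(trains, duration_s=1800.0, well_id="A1", phase="baseline"):
    """trains: mapping electrode id -> timestamp sequence."""
    return WellRecording(
        well_id=well_id,
        phase=phase,
        trains={eid: make_train(eid, ts) for eid, ts in trains.items()},
        duration_s=duration_s,
    )


def poisson_train(rng, rate_hz, duration_s):
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


@pytest.fixture
def poisson_well(rng):
    """16 electrodes of independent 1 Hz Poisson firing over 1800 s."""
    trains = {
        f"e{i:02d}": poisson_train(rng, 1.0, 1800.0) for i in range(1, 17)
    }
    return make_recording(trains)
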