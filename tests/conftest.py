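import io

import numpy as np
import pandas as pd
import pytest

from foragescale.telemetry import Track


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(xy, dt=60.0, individual_id="t1", **kw) -> Track:
    """Planar track from an (n, 2) array with uniform time steps (seconds)."""
    xy = np.asarray(xy, dtype=float)
    return Track(
        individual_id=individual_id,
        t=dt * np.arange(xy.shape[0], dtype=float),
        start_time=pd.Timestamp("2020-01-01", tz="UTC"),
        x=xy[:, 0],
        y=xy[:, 1],
        **kw,
    )


def random_walk_track(rng, n=20, step=100.0, dt=60.0) -> Track:
    steps = rng.normal(scale=step, size=(n - 1, 2))
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return make_track(xy, dt=dt)


def csv_buffer(text: str) -> io.StringIO:
    return io.StringIO(text)
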