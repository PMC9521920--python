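import numpy as np
import pandas as pd
import pytest

from elkdemog import synth


@pytest.fixture(scope="session")
def station_daily() -> pd.DataFrame:
    """A 72-year synthetic daily weather record at subpolar defaults."""
    return synth.simulate_daily_weather(synth.WeatherConfig(), seed=3)


def make_daily(start: str, end: str, **columns) -> pd.DataFrame:
    """Small hand-built daily frame; scalar column values are broadcast."""
    idx = pd.date_range(start, end, freq="D")
    data = {}
    for name, value in columns.items():
        data[name] = np.broadcast_to(np.asarray(value, dtype=float), len(idx)).copy()
    return pd.DataFrame(data, index=idx)
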