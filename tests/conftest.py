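import numpy as np
import pandas as pd
import pytest

import endoair as ea


@pytest.fixture(scope="session")
def dataset():
    """A moderate synthetic campaign: April–September, full network."""
    return ea.simulate_dataset(n_days=160, start_date="2002-04-01", seed=7)


@pytest.fixture(scope="session")
def landscape():
    return ea.gen_landscape()


@pytest.fixture(scope="session")
def dry_snapshot(dataset):
    return ea.snapshot(dataset.conc, "endotoxin", "dry")


@pytest.fixture(scope="session")
def sites(dataset):
    return dataset.landscape.sites


def constant_wind(n_hours, speed=5.0, direction=315.0, rh=40.0,
                  start="2002-06-01"):
    """Hourly met frame with constant wind/humidity."""
    ts = pd.date_range(start, periods=n_hours, freq="h")
    return pd.DataFrame({
        "timestamp": ts,
        "ws": np.full(n_hours, speed),
        "wd": np.full(n_hours, direction),
        "rh": np.full(n_hours, rh),
        "temp": np.full(n_hours, 25.0),
    })
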