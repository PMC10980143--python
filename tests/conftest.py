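import numpy as np
import pytest

from wristgait.synthetic import generate_labeled_cohort_windows


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_window(rng):
    return rng.normal(size=(3, 300))


@pytest.fixture(scope="session")
def labeled_windows():
    """Small labeled window pool (4 synthetic subjects, 10 min each)."""
    return generate_labeled_cohort_windows(4, duration_s=600.0, seed=3)


@pytest.fixture
def accel_csv(tmp_path):
    """Factory writing a time/x/y/z CSV and returning its path."""

    def _write(n=600, fs=60.0, name="rec.csv", nan_rows=(), drop_cols=(),
               shuffle_time=False):
        t = np.arange(n) / fs
        if shuffle_time and n > 2:
            t[1], t[2] = t[2], t[1]
        gen = np.random.default_rng(7)
        cols = {"time": t, "x": gen.normal(size=n), "y": gen.normal(size=n),
                "z": gen.normal(size=n)}
        for c in drop_cols:
            cols.pop(c)
        for r in nan_rows:
            cols["x"][r] = np.nan
        import pandas as pd

        path = tmp_path / name
        pd.DataFrame(cols).to_csv(path, index=False)
        return path

    return _write
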