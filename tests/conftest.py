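import numpy as np
import pytest

from fontanstress.synthetic import CyclePhysioParams


def make_params(**overrides) -> CyclePhysioParams:
    """A well-behaved reference cycle; any field can be overridden.

    E and A fill volumes are rebalanced to the stroke volume unless both are
    given explicitly.
    """
    base = dict(
        edv=100.0,
        esv=50.0,
        e_fill_volume=35.0,
        a_fill_volume=15.0,
        systole_fraction=0.38,
        e_peak_time_frac=0.2,
        e_width_frac=0.4,
        a_onset_frac=0.7,
        a_width_frac=0.3,
        heart_rate=75.0,
        a_min_volume=30.0,
    )
    base.update(overrides)
    if "e_fill_volume" not in overrides and "a_fill_volume" in overrides:
        base["e_fill_volume"] = base["edv"] - base["esv"] - base["a_fill_volume"]
    if "a_fill_volume" not in overrides and "e_fill_volume" in overrides:
        base["a_fill_volume"] = base["edv"] - base["esv"] - base["e_fill_volume"]
    return CyclePhysioParams.closed_loop(**base)


@pytest.fixture
def params() -> CyclePhysioParams:
    return make_params()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
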