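import numpy as np
import pytest

import vo2fit as v


@pytest.fixture
def bi_truth():
    return dict(v.DEFAULT_TRUTHS["bi_td"])


@pytest.fixture
def bi_spec():
    return v.get_model("bi_td")


@pytest.fixture
def bi_series_clean(bi_truth):
    series, _ = v.generate_series(v.GeneratorConfig(model="bi_td"))
    return series


@pytest.fixture
def bi_series_noisy():
    series, _ = v.generate_series(
        v.GeneratorConfig(model="bi_td", noise_sd=2.0, seed=42)
    )
    return series


@pytest.fixture
def noisy_flat_series():
    """Stationary noisy signal around 30 mL·kg⁻¹·min⁻¹."""
    rng = np.random.default_rng(0)
    vo2 = 30.0 + rng.normal(0.0, 1.0, 200)
    return v.BreathSeries(np.arange(200.0), np.maximum(vo2, 0.0))
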