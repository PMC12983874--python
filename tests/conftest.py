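import numpy as np
import pytest

from vacalib import CauseMap, FitSettings, PairedCauseCounts, make_cause_map


@pytest.fixture(scope="session")
def cm2() -> CauseMap:
    return make_cause_map(["cause_1", "cause_2"])


@pytest.fixture(scope="session")
def cm3() -> CauseMap:
    return make_cause_map(["a", "b", "c"])


@pytest.fixture(scope="session")
def cm3_other() -> CauseMap:
    return make_cause_map(["a", "b", "other"], other_label="other")


def fast_fit_settings(seed: int, **kw) -> FitSettings:
    """Reduced-size sampler settings for module-level tests."""
    defaults = dict(n_steps=1200, n_burn=700, n_draws=500,
                    check_diagnostics=False)
    defaults.update(kw)
    return FitSettings(seed=seed, **defaults)


@pytest.fixture(scope="session")
def paired_2x2(cm2) -> PairedCauseCounts:
    counts = np.array([[[900, 100], [300, 700]]])
    return PairedCauseCounts(cm2, ("site_a",), counts)
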