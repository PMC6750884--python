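import numpy as np
import pandas as pd
import pytest

from twostage import ModelSpec, Params, resolve_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_trials():
    """Three-trial probe session used by the hand-walked lag-logic checks."""
    rows = [
        dict(subject="r1", session=0, phase="probe", trial=0, a1="L", s2="S2",
             a2="R", outcome=1, transition="common", aborted=0, rt=np.nan),
        dict(subject="r1", session=0, phase="probe", trial=1, a1="L", s2="S1",
             a2="R", outcome=0, transition="rare", aborted=0, rt=np.nan),
        dict(subject="r1", session=0, phase="probe", trial=2, a1="R", s2="S1",
             a2="L", outcome=0, transition="common", aborted=0, rt=np.nan),
    ]
    return pd.DataFrame(rows)


def random_params(spec: ModelSpec, rng: np.random.Generator) -> Params:
    """Random free-parameter draw with full support coverage, for property tests."""
    values = {}
    for name in spec.free_params():
        if name in ("beta1", "beta2"):
            values[name] = float(rng.uniform(0.0, 8.0))
        elif name == "b_disc":
            values[name] = float(rng.normal(0.0, 2.0))
        elif name == "eps":
            values[name] = float(rng.uniform(0.0, 0.49))
        else:
            values[name] = float(rng.uniform(0.0, 1.0))
    return resolve_params(spec, values)
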