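import numpy as np
import pandas as pd
import pytest

from crcgrs.simulate import simulate_event_times


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def exp_survival_data():
    """n=2000 exponential event times (rate 0.1), no censoring mechanism
    beyond a distant horizon."""
    t, e = simulate_event_times(
        np.zeros(2000), shape=1.0, scale=10.0,
        censor_horizon=500.0, dropout_rate=0.0, seed=77,
    )
    return t, e


@pytest.fixture
def small_weights():
    return pd.DataFrame(
        {
            "snp_id": ["rs1", "rs2"],
            "effect_allele": ["A", "G"],
            "log_or": [0.1, -0.2],
        }
    )


@pytest.fixture
def small_dosages():
    return pd.DataFrame(
        {"rs1": [1.0], "rs2": [2.0]}, index=pd.Index(["P1"], name="participant_id")
    )


def brute_force_concordance(time, event, score):
    """O(n^2) pair enumeration oracle for Harrell's C."""
    n = len(time)
    num = den = 0.0
    for i in range(n):
        if not event[i]:
            continue
        for j in range(n):
            if i == j:
                continue
            comparable = time[j] > time[i] or (time[j] == time[i] and not event[j])
            if not comparable:
                continue
            den += 1.0
            if score[i] > score[j]:
                num += 1.0
            elif score[i] == score[j]:
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den
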