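import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mptsource as mp
from mptsource.fit import FrequencyTable
from mptsource.models import category_probabilities, condition_parameter

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Published aggregated estimates used as realistic generating values.
WAKE_5A = {"D": 0.60, "d": 0.48, "a": 0.44, "b": 0.25, "g": 0.47}
SLEEP_5A = {"D": 0.65, "d": 0.63, "a": 0.48, "b": 0.20, "g": 0.64}


def joint_theta(wake, sleep):
    theta = {condition_parameter(k, "wake"): v for k, v in wake.items()}
    theta.update({condition_parameter(k, "sleep"): v for k, v in sleep.items()})
    return theta


def multinomial_table(model, theta, totals, rng):
    """Aggregated table sampled from a model; ``totals`` maps tree name to N."""
    probs = category_probabilities(model, theta)
    records = []
    for tree in model.trees:
        draws = rng.multinomial(int(totals[tree.name]), probs[tree.label])
        for cat, k in zip(tree.categories, draws):
            records.append(("ALL", tree.condition, tree.name, cat, float(k)))
    return FrequencyTable(
        pd.DataFrame(records, columns=["participant", "condition", "tree", "category", "count"]),
        aggregated=True,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def joint_5a():
    return mp.build_2htsm("5a")


@pytest.fixture
def table2_theta():
    return joint_theta(WAKE_5A, SLEEP_5A)
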