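import numpy as np
import pandas as pd
import pytest

from lcarisk.cohort import Cohort, DEFAULT_LEVELS


def make_cohort(
    indicators: dict[str, list[str]],
    levels: dict[str, list[str]] | None = None,
    time=None,
    event=None,
    **extra,
) -> Cohort:
    """Build a small validated-shape cohort directly from column lists."""
    n = len(next(iter(indicators.values())))
    if levels is None:
        levels = {k: sorted(set(v)) for k, v in indicators.items()}
    df = pd.DataFrame({"patient_id": [f"P{i}" for i in range(n)]})
    for k, v in indicators.items():
        df[k] = v
    df["time_months"] = np.ones(n) if time is None else np.asarray(time, float)
    df["event"] = np.zeros(n, int) if event is None else np.asarray(event, int)
    for k, v in extra.items():
        df[k] = v
    return Cohort(data=df, levels=levels)


@pytest.fixture
def two_item_toy():
    """6-row cohort with two binary indicators (positive association)."""
    return make_cohort(
        {
            "a": ["x", "x", "x", "y", "y", "y"],
            "b": ["u", "u", "v", "u", "v", "v"],
        }
    )


@pytest.fixture(scope="session")
def separated_two_class_config():
    """Well-separated 2-class generator used by recovery/selection tests."""
    from lcarisk.synthetic import GeneratorConfig

    item_response = {
        name: np.array([[0.9] + [0.1 / (m - 1)] * (m - 1),
                        [0.1 / (m - 1)] * (m - 1) + [0.9]])
        for name, m in ((k, len(v)) for k, v in DEFAULT_LEVELS.items())
    }
    cfg = GeneratorConfig(
        n_patients=2000,
        class_prevalence=np.array([0.6, 0.4]),
        item_response=item_response,
        cause_hr=np.array([[1.0, 1.0], [1.5, 0.5]]),
        seed=42,
    )
    cfg.validate()
    return cfg
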