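import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sf36mode.scoring import SCALE_ORDER, ScoringSpec
from sf36mode.simulate import SimulationConfig, simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def spec() -> ScoringSpec:
    return ScoringSpec.default()


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 400-subject cohort from the default generator, fixed seed."""
    cfg = SimulationConfig.default().with_(n_per_arm=200)
    return simulate_cohort(cfg, seed=42)


@pytest.fixture(scope="session")
def responders(small_cohort) -> pd.DataFrame:
    return small_cohort[small_cohort["responder"] == 1].set_index("id")


def random_questionnaires(rng: np.random.Generator, n: int, spec: ScoringSpec,
                          missing_rate: float = 0.15) -> pd.DataFrame:
    """Uniformly random admissible answers with independent missingness."""
    cols = {}
    for item_id, table in spec.recode_tables.items():
        codes = np.array(sorted(table))
        vals = codes[rng.integers(0, len(codes), size=n)].astype(float)
        vals[rng.random(n) < missing_rate] = np.nan
        cols[f"item_{item_id}"] = pd.array(vals, dtype="Int64")
    return pd.DataFrame(cols)
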