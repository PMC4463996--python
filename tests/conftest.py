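import numpy as np
import pytest

from dietq.model import ScoringConfig
from dietq.scoring import IntakeSummary
from dietq.synthetic import demo_composition


@pytest.fixture(scope="session")
def composition():
    return demo_composition()


@pytest.fixture(scope="session")
def config():
    return ScoringConfig()


def make_random_summary(rng: np.random.Generator, sex: str | None = None) -> IntakeSummary:
    """A random but structurally valid IntakeSummary for fuzzing the rubric."""
    veg_all = ["green_veg", "orange_veg", "legumes", "starchy_veg", "other_veg"]
    fruit_all = ["pome", "citrus", "berries", "stone", "tropical"]
    n_veg = int(rng.integers(0, 6))
    n_fruit = int(rng.integers(0, 6))
    return IntakeSummary(
        participant_id="fuzz",
        sex=sex or ("male" if rng.random() < 0.5 else "female"),
        group_serves={
            "vegetables": float(rng.uniform(0, 12)),
            "fruit": float(rng.uniform(0, 6)),
            "grains": float(rng.uniform(0, 12)),
            "meat_alt": float(rng.uniform(0, 8)),
            "dairy_alt": float(rng.uniform(0, 6)),
        },
        wholegrain_prop=float(rng.uniform(0, 1)),
        lowfat_prop=float(rng.uniform(0, 1)),
        veg_subgroups=frozenset(rng.choice(veg_all, size=n_veg, replace=False).tolist()),
        fruit_subgroups=frozenset(rng.choice(fruit_all, size=n_fruit, replace=False).tolist()),
        sat_fat_pct_e=float(rng.uniform(0, 30)),
        total_sugars_pct_e=float(rng.uniform(0, 50)),
        sodium_mg_day=float(rng.uniform(0, 8000)),
        alcohol_g_day=float(rng.uniform(0, 80)),
        discretionary_pct_e=float(rng.uniform(0, 90)),
        water_prop=float(rng.uniform(0, 1)),
        energy_kj_day=float(rng.uniform(500, 20000)),
        energy_defined=True,
    )
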