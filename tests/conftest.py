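import numpy as np
import pandas as pd
import pytest

from phenosel.simulate import SimulationConfig, generate_fitness, generate_traits


def truth_to_seasons(truth: pd.DataFrame) -> pd.DataFrame:
    """Turn a simulation truth table into a plant-season analysis table.

    Bypasses the census/phenology observation layer: the true trait values
    are used directly, with volume = exp(ln_size) and fitness = seed count.
    """
    df = truth.rename(columns={"ffd": "first_flowering_day"}).copy()
    df["development_time"] = df["first_flowering_day"] - df["leaf_out_day"]
    df["aboveground_volume"] = np.exp(df["ln_size"])
    df["fitness_intact_seeds"] = df["seed_count"].astype(float)
    return df


@pytest.fixture
def make_seasons():
    """Factory: simulate traits + fitness and return an analysis table."""

    def _make(**kwargs) -> pd.DataFrame:
        cfg = SimulationConfig(**kwargs)
        traits = generate_traits(cfg)
        truth = generate_fitness(traits, cfg)
        return truth_to_seasons(truth)

    return _make


@pytest.fixture
def quiet_clamp():
    """Suppress the fitness-surface clamp warning inside a test."""
    import warnings

    from phenosel.simulate import ClampWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ClampWarning)
        yield
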