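import numpy as np
import pandas as pd
import pytest

from phthalburden import SynthConfig, generate_cohort_dyads


def attach_truth_exposure(dyads: pd.DataFrame, groups=("DEHP",)) -> pd.DataFrame:
    """Expose the generator's latent group exposures under the column names
    the model layer expects, bypassing the measurement pipeline."""
    out = dyads.copy()
    for g in groups:
        out[f"log10_pregnancy_average_{g}"] = out[f"true_log10_{g}"]
    return out


@pytest.fixture(scope="session")
def small_cohorts():
    """Six cohorts x 120 dyads with full urine tables: big enough for the
    processing chain, small enough to run in seconds."""
    cfg = SynthConfig(n_cohorts=6, dyads_per_cohort=120, seed=42)
    return generate_cohort_dyads(cfg)


@pytest.fixture(scope="session")
def population_dyads():
    """A 5000-dyad population (no urine) for marginal-calibration checks."""
    cfg = SynthConfig(n_cohorts=13, dyads_per_cohort=385, include_urine=False, seed=2024)
    dyads, _ = generate_cohort_dyads(cfg)
    return dyads
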