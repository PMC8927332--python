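from pathlib import Path

import pandas as pd
import pytest

from combatkit import (
    BatchEffectSpec,
    CovariateSpec,
    SimulationSpec,
    simulate,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixture_features() -> pd.DataFrame:
    return pd.read_csv(DATA_DIR / "combat_fixture_features.csv", index_col=0)


@pytest.fixture(scope="session")
def fixture_metadata() -> pd.DataFrame:
    return pd.read_csv(DATA_DIR / "combat_fixture_metadata.csv", index_col=0)


@pytest.fixture(scope="session")
def fixture_reference() -> pd.DataFrame:
    """Harmonized fixture output frozen from an independent reference
    ComBat implementation (Bioconductor sva, parametric priors)."""
    return pd.read_csv(DATA_DIR / "combat_fixture_reference_harmonized.csv", index_col=0)


@pytest.fixture(scope="session")
def shifted_dataset():
    """200 x 50 dataset with a strong 2-level location/scale batch effect and
    a protected binary covariate; ground truth attached."""
    spec = SimulationSpec(
        n_samples=200,
        n_features=50,
        batch_effects=(
            BatchEffectSpec("scanner", location_sd=1.5, scale_range=(0.7, 1.4)),
        ),
        covariates=(CovariateSpec("histology", effect_size=1.5, affected_fraction=0.4),),
        seed=424242,
    )
    return simulate(spec)
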