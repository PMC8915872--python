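import pandas as pd
import pytest

from inhalttc.synth import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def messy_dataset():
    """Mid-size synthetic dataset with outliers, ambiguous rows and
    profiler disagreement, shared across integration tests."""
    config = SyntheticConfig(
        n_substances=300,
        outlier_rate=0.04,
        ambiguous_rate=0.05,
        profiler_disagreement_rate=0.15,
        seed=20240915,
    )
    return generate_dataset(config)


@pytest.fixture()
def tiny_records():
    """Handful of handwritten study rows covering every filter branch."""
    return pd.DataFrame(
        [
            # kept: inhalation NOAEC rodent chronic
            ("S1", "chronic", 120, "days", "inhalation", "NOAEC", 5.0, "mg/m3", "Rat"),
            # dropped: oral route
            ("S1", "chronic", 120, "days", "oral", "NOAEL", 5.0, "mg/m3", "Rat"),
            # dropped: LOAEL type
            ("S1", "chronic", 120, "days", "inhalation", "LOAEL", 5.0, "mg/m3", "Rat"),
            # dropped: dog
            ("S1", "chronic", 120, "days", "inhalation", "NOAEC", 5.0, "mg/m3", "dog"),
            # kept: ppm with known MW
            ("S2", "subchronic", 90, "days", "inhalation", "NOEC", 10.0, "ppm", "mice"),
        ],
        columns=[
            "substance_id",
            "study_type",
            "study_duration_value",
            "study_duration_units",
            "exposure_route",
            "toxval_type",
            "toxval_numeric",
            "toxval_units",
            "species",
        ],
    )


@pytest.fixture()
def tiny_substances():
    return pd.DataFrame(
        {"substance_id": ["S1", "S2"], "mw": [100.0, 48.90]}
    )
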