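import hypothesis
import numpy as np
import pandas as pd
import pytest

from carbrisk import datasets, simulate

hypothesis.settings.register_profile(
    "ci", hypothesis.settings(derandomize=True, max_examples=50))
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_bundle():
    return datasets.study_fixture(seed=7)


@pytest.fixture(scope="session")
def residue_table(fixture_bundle):
    """One simulated survey (55 samples x 14 pesticides)."""
    return simulate.generate_residue_table(fixture_bundle.residue_spec)


@pytest.fixture(scope="session")
def large_residue_table():
    """Large survey for sampling-error checks on detection frequencies."""
    spec = datasets.residue_sim_spec(n_samples=20_000, seed=11)
    return simulate.generate_residue_table(spec)


def printed_counts_table() -> pd.DataFrame:
    """Deterministic residue table realising the survey's printed counts.

    Per pesticide: the printed number of detects among 55 samples, of which
    the printed number exceed the MRL.  Detected concentrations are placed
    just inside/outside the MRL so only the counts matter.
    """
    rows = []
    for row in datasets.SURVEY_ROWS:
        mrl = row.mrl
        for i in range(datasets.N_SAMPLES):
            sid = f"S{i + 1:03d}"
            if i < row.n_above_mrl:
                rows.append((sid, row.pesticide, mrl * 1.5, 1))
            elif i < row.n_detected:
                rows.append((sid, row.pesticide, mrl * 0.5, 1))
            else:
                rows.append((sid, row.pesticide, np.nan, 0))
    return pd.DataFrame(rows, columns=list(
        ("sample_id", "pesticide", "concentration_ug_per_kg", "detected")))


@pytest.fixture(scope="session")
def printed_counts():
    return printed_counts_table()
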