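import numpy as np
import pandas as pd
import pytest

import matsig as ms


@pytest.fixture(scope="session")
def design():
    return ms.default_design()


@pytest.fixture(scope="session")
def small_design():
    """A miniature but structurally complete design for fast end-to-end runs."""
    return ms.StudyDesign(
        materials=("wood", "metal", "fabric"),
        attributes=("glossy", "hard", "rough"),
        segments_per_material=8,
        n_sets=2,
        raters_per_cell=4,
        repetitions=3,
    )


@pytest.fixture(scope="session")
def small_truth(small_design):
    rng = np.random.default_rng(42)
    mu = pd.DataFrame(
        rng.uniform(25, 75, (small_design.n_materials, small_design.n_attributes)),
        index=list(small_design.materials), columns=list(small_design.attributes),
    )
    return ms.GroundTruth(mu=mu, sigma_taste=6.0, sigma_noise=5.0, sigma_stim=8.0)


@pytest.fixture(scope="session")
def small_records(small_design, small_truth):
    return ms.simulate_ratings(small_design, small_truth, seed=11,
                               spammer_fraction=0.0)


@pytest.fixture(scope="session")
def default_run(design):
    """One full-scale simulated experiment, shared across tests."""
    truth = ms.default_truth(design)
    records = ms.simulate_ratings(design, truth, seed=7)
    kept, excluded = ms.exclude_fast_raters(records)
    means = ms.stimulus_means(kept, design)
    return {"truth": truth, "records": records, "kept": kept,
            "excluded": excluded, "means": means}
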