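import warnings

import pytest

from laterality.pipeline import RunConfig, run_full_report
from laterality.scoring import filter_min_counts, score_table
from laterality.simulate import default_paper_like_config, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (counts, latent truth), fixed seed."""
    return simulate_cohort(default_paper_like_config(seed=0))


@pytest.fixture(scope="session")
def scored_session1(default_cohort):
    counts, _ = default_cohort
    s1 = counts[counts["session"] == 1]
    kept, _ = filter_min_counts(s1)
    return score_table(kept)


@pytest.fixture(scope="session")
def default_bundle(default_cohort):
    counts, _ = default_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_full_report(counts, RunConfig(seed=0))
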