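import numpy as np
import pytest

from probioscreen import marker_screen, synthetic_genomes as sg
from probioscreen.pipeline import VALIDATION_MARKERS
from probioscreen.sequence_confirmation import confirm_hits


@pytest.fixture(scope="session")
def cohort():
    """The study-condition cohort: 3 species x 12 genomes, ~150 genes each,
    with planted markers (exact/diverged/decoy), bacteriocins and safety genes."""
    return sg.simulate_cohort(sg.CohortConfig(seed=11))


@pytest.fixture(scope="session")
def panel():
    return marker_screen.load_panel()


@pytest.fixture(scope="session")
def cohort_hits(cohort, panel):
    return marker_screen.screen_cohort(cohort.records, panel)


@pytest.fixture(scope="session")
def validation_reference_db():
    return sg.reference_db(list(VALIDATION_MARKERS))


@pytest.fixture(scope="session")
def validation_outcomes(cohort, cohort_hits, validation_reference_db):
    candidates = [h for h in cohort_hits if h.marker_id in validation_reference_db]
    return confirm_hits(candidates, cohort.records, validation_reference_db)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
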