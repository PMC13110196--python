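import logging

import numpy as np
import pandas as pd
import pytest

from spotter.study import COLUMNS, Study
from spotter.synth import ParameterSpec, SynthConfig, fig1_fixture, generate_study

logging.getLogger("spotter").setLevel(logging.ERROR)
logging.getLogger("py.warnings").setLevel(logging.ERROR)


def make_study(subject_visits: dict[str, dict[int, float]],
               sites: dict[str, str] | None = None,
               parameter: str = "ALT") -> Study:
    """Build a study from {subject: {visit: value}} with optional site mapping."""
    rows = []
    for subject, visits in subject_visits.items():
        site = (sites or {}).get(subject, "SITE1")
        for visit, value in visits.items():
            rows.append((subject, site, "C1", "R1", parameter,
                         visit, True, False, value))
    return Study(pd.DataFrame(rows, columns=COLUMNS))


@pytest.fixture(scope="session")
def fig1():
    return fig1_fixture()


@pytest.fixture(scope="session")
def small_study():
    """8 sites x 8 subjects x 6 visits, one parameter, no site signal."""
    cfg = SynthConfig(
        n_sites=8, subjects_per_site=8, n_visits=6,
        parameters=(ParameterSpec("ALT", 30.0, 8.0, 0.2, 5.0),),
        missing_rate=0.0, staggered_fraction=0.0,
        unscheduled_rate=0.0, screen_failure_rate=0.0, seed=42,
    )
    return generate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
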