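import numpy as np
import pandas as pd
import pytest

from intentgap.survey_io import Cohort, SurveyLayout
from intentgap.synthetic import default_calibration, generate_cohort


@pytest.fixture(scope="session")
def layout() -> SurveyLayout:
    return SurveyLayout.default()


@pytest.fixture(scope="session")
def default_config():
    """Default generator configuration (latent model cached for the session)."""
    cfg = default_calibration()
    cfg.latent_model()
    return cfg


@pytest.fixture(scope="session")
def cohort144(default_config) -> Cohort:
    """One default synthetic cohort (176 starters, 144 completers)."""
    return generate_cohort(default_config, seed=7)


def make_cohort(values: dict, layout: SurveyLayout, dk: dict | None = None) -> Cohort:
    """Build a cohort from {participant: {item: value}} with optional DK cells."""
    frame = pd.DataFrame.from_dict(values, orient="index", dtype=float)
    mask = pd.DataFrame(False, index=frame.index, columns=frame.columns)
    for pid, items in (dk or {}).items():
        for item in items:
            mask.at[pid, item] = True
            frame.at[pid, item] = np.nan
    return Cohort(values=frame, dont_know=mask, layout=layout)


@pytest.fixture()
def tiny_layout() -> SurveyLayout:
    """Single-item-per-construct layout for hand-computable fixtures."""
    return SurveyLayout.default(items_per_construct=1)


@pytest.fixture()
def filled_record(tiny_layout):
    """One fully answered record on the single-item layout (all zeros)."""
    return {item: 0 for item in tiny_layout.item_names}
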