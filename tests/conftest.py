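import logging

import numpy as np
import pandas as pd
import pytest

from famtrack.core_data import CohortMetadata, FeatureTable, TaxonomyMap, rarefy
from famtrack.source_tracking import EMConfig, track_cohort
from famtrack.synthetic_cohort import CohortConfig, generate_cohort

logging.getLogger("famtrack").setLevel(logging.ERROR)

#: Rarefaction depth used throughout the default analysis.
DEPTH = 7115


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort: 24 households, 3 niches, planted signals."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def rarefied_tables(cohort):
    return {n: rarefy(t, DEPTH, seed=1).table for n, t in cohort.tables.items()}


@pytest.fixture(scope="session")
def tracking_raw(cohort):
    """Source tracking on the full-depth tables (every source present)."""
    return track_cohort(cohort.tables, cohort.metadata, EMConfig(seed=5))


@pytest.fixture(scope="session")
def tracking_rarefied(cohort, rarefied_tables):
    """Source tracking on rarefied tables (the pipeline default)."""
    return track_cohort(rarefied_tables, cohort.metadata, EMConfig(seed=5))


@pytest.fixture()
def tiny_table():
    return FeatureTable(
        pd.DataFrame(
            [[5, 3, 0], [0, 2, 8], [1, 1, 1]],
            index=["s1", "s2", "s3"],
            columns=["a1", "a2", "a3"],
        )
    )


@pytest.fixture()
def tiny_taxonomy():
    return TaxonomyMap(
        {
            "a1": ("Bacteria", "P1", "C1", "O1", "FamA", "g1"),
            "a2": ("Bacteria", "P1", "C1", "O1", "FamA", "g2"),
            "a3": ("Bacteria", "P2", "C2", "O2", "FamB", "g3"),
        }
    )


@pytest.fixture()
def tiny_metadata():
    samples = pd.DataFrame(
        {
            "subject_id": ["H1_C1", "H1_M", "H1_F"],
            "household": ["H1", "H1", "H1"],
            "role": ["C", "M", "F"],
            "niche": ["gut", "gut", "gut"],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    subjects = pd.DataFrame(
        {
            "household": ["H1", "H1", "H1"],
            "role": ["C", "M", "F"],
            "age": [4.0, 33.0, 35.0],
            "sex": ["F", "F", "M"],
            "family_time": [np.nan, 10.0, 8.0],
        },
        index=pd.Index(["H1_C1", "H1_M", "H1_F"], name="subject_id"),
    )
    return CohortMetadata(samples=samples, subjects=subjects)


#: 4-leaf worked tree used for hand-computed UniFrac values.
WORKED_TREE = "((A:1,B:1):1,(C:1,D:1):1);"
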