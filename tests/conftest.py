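import numpy as np
import pandas as pd
import pytest

from faersignal.ingest import AnalysisDataset
from faersignal.synthetic import SyntheticConfig, generate


def make_dataset(records_rows, events_rows, pt_soc_map=None) -> AnalysisDataset:
    """Assemble an AnalysisDataset directly from row dicts (test helper)."""
    defaults = {"sex": "unknown", "age_group": "unknown", "report_year": 2022,
                "serious": False, "is_focal": True, "onset_days": np.nan,
                "weight_kg": np.nan, "age_years": np.nan,
                "country": "US", "reporter": "consumer",
                "outcomes": frozenset()}
    records = pd.DataFrame([{**defaults, **row} for row in records_rows])
    events = pd.DataFrame(events_rows, columns=["case_id", "pt", "is_focal"])
    events["soc"] = pd.NA
    return AnalysisDataset(records=records, events=events,
                           pt_soc_map=dict(pt_soc_map or {}))


@pytest.fixture(scope="session")
def small_corpus():
    """A small synthetic corpus with one strongly implanted signal."""
    config = SyntheticConfig(n_background_reports=4000, n_focal_reports=300,
                             implanted_rr={"ARIA-E": 50.0}, seed=7)
    return config, generate(config)
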