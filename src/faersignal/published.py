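"""Published summary statistics for aducanumab in FAERS (January 2004 - June 2024).

These constants transcribe the printed tables of the published FAERS
surveillance analysis of aducanumab: the database margins, the demographic
breakdown of the 510 deduplicated case reports, the preferred-term (PT)
disproportionality table of the 27 significant signals, and the system-organ
class (SOC) event distribution.  They serve two purposes:

* as inputs to :func:`faersignal.contingency.reconstruct_from_published`,
  which rebuilds the underlying 2x2 tables from printed (count, ROR) pairs
  and the database margins, and
* as calibration targets for :func:`faersignal.synthetic.aducanumab_profile`.

MedDRA itself is licensed and not bundled; PT and SOC strings below are the
printed labels only.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

# -- database margins ---------------------------------------------------------

TOTAL_REPORTS = 510          # deduplicated aducanumab reports (demographics)
TOTAL_EVENTS = 1095          # aducanumab drug-event pairs (signal analysis)
DEMO_RECORDS = 18_278_243    # DEMO rows in the full corpus
DRUG_RECORDS = 66_418_951    # DRUG rows in the full corpus
REAC_RECORDS = 54_336_884    # REAC rows in the full corpus (grand total N)

SURVEILLANCE_YEARS = (2004, 2024)

# -- demographics (counts out of 510 reports) ---------------------------------

SEX_COUNTS = {"female": 254, "male": 227, "unknown": 29}

AGE_GROUP_COUNTS = {
    "<18": 0, "18-44": 0, "45-64": 29, "65-74": 117, ">=75": 166,
    "unknown": 198,
}

REPORT_YEAR_COUNTS = {
    2016: 18, 2018: 1, 2019: 2, 2021: 18, 2022: 224, 2023: 199, 2024: 48,
}

REPORTER_COUNTS = {
    "consumer": 212, "other/not-specified": 3, "pharmacist": 120,
    "physician": 175,
}

COUNTRY_COUNTS = {
    "US": 473, "JP": 10, "CA": 5, "FR": 4, "CH": 4, "other": 14,
}

SEVERITY_COUNTS = {"serious": 258, "non-serious": 252}

# FAERS outcome codes: DE death, LT life-threatening, HO hospitalization,
# DS disability, CA congenital anomaly, RI required intervention, OT other.
OUTCOME_COUNTS = {"LT": 8, "HO": 121, "DS": 2, "DE": 29, "CA": 0, "RI": 2,
                  "OT": 135}

ONSET_BIN_COUNTS = {
    "0-30": 25, "31-60": 18, "61-90": 21, "91-120": 33,
    "121-150": 23, "151-180": 39, "181-360": 43, ">360": 15,
}
ONSET_N = 217                 # reports with a computable time to onset
ONSET_MEDIAN_DAYS = 146.0
ONSET_IQR_DAYS = (80.0, 195.0)

WEIGHT_KG = {
    "n": 170, "missing": 340, "mean": 71.49, "sd": 16.36,
    "median": 69.62, "q1": 60.80, "q3": 80.30, "min": 34.20, "max": 132.00,
}


class PtSignalRow(NamedTuple):
    """One printed PT-level disproportionality row."""

    term: str
    n: int
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    chi2: float
    ic: float
    ic_minus_2sd: float
    ebgm: float
    ebgm05: float


#: The 27 preferred terms meeting all five signal criteria, with the printed
#: statistics (ROR with 95% CI, PRR with chi-square, IC with IC-2SD, EBGM
#: with EBGM05).
PT_SIGNALS: tuple[PtSignalRow, ...] = tuple(PtSignalRow(*row) for row in [
    ("ARIA-E", 141, 53538.3, 42177.8, 67958.6, 46644.4, 3390009, 14.55, 6.83, 24044.0, 18942.0),
    ("ARIA-H", 100, 38187.9, 29358.2, 49673.2, 34700.5, 2041938, 14.32, 6.30, 20420.9, 15699.2),
    ("Headache", 41, 3.77, 2.76, 5.15, 3.66, 80.25, 1.87, 1.33, 3.66, 2.68),
    ("Confusional state", 35, 12.42, 8.87, 17.39, 12.05, 355.56, 3.59, 2.71, 12.05, 8.60),
    ("Cerebral haemorrhage", 27, 42.86, 29.25, 62.81, 41.83, 1075.76, 5.39, 3.54, 41.79, 28.52),
    ("Fall", 23, 3.95, 2.61, 5.97, 3.89, 49.58, 1.96, 1.20, 3.89, 2.57),
    ("Superficial siderosis of CNS", 22, 35937.4, 20741.2, 62267.2, 35215.4, 453124, 14.33, 3.80, 20598.1, 11888.2),
    ("Dementia Alzheimer's type", 21, 128.36, 83.30, 197.79, 125.91, 2596.15, 6.97, 3.61, 125.60, 81.51),
    ("Seizure", 20, 6.56, 4.21, 10.21, 6.46, 92.50, 2.69, 1.72, 6.46, 4.15),
    ("Amyloid related imaging abnormalities", 17, 17487.2, 10039.7, 30459.3, 17215.7, 217258, 13.64, 3.40, 12781.6, 7338.13),
    ("Cognitive disorder", 13, 16.05, 9.29, 27.73, 15.87, 181.19, 3.99, 2.17, 15.86, 9.18),
    ("Brain oedema", 13, 59.01, 34.14, 101.99, 58.32, 731.68, 5.86, 2.74, 58.25, 33.70),
    ("Memory impairment", 12, 4.89, 2.77, 8.63, 4.84, 36.68, 2.28, 1.10, 4.84, 2.74),
    ("Atrial fibrillation", 11, 6.35, 3.50, 11.50, 6.29, 49.06, 2.65, 1.29, 6.29, 3.47),
    ("Subarachnoid haemorrhage", 9, 48.94, 25.39, 94.34, 48.54, 418.73, 5.60, 2.16, 48.50, 25.16),
    ("Head injury", 8, 14.43, 7.20, 28.93, 14.33, 99.25, 3.84, 1.56, 14.33, 7.15),
    ("Cerebral microhaemorrhage", 7, 1493.95, 702.77, 3175.87, 1484.41, 10075.5, 10.49, 1.95, 1441.32, 678.01),
    ("Transient ischaemic attack", 5, 8.02, 3.33, 19.31, 7.99, 30.57, 3.00, 0.70, 7.99, 3.32),
    ("Mental status changes", 5, 10.00, 4.15, 24.07, 9.96, 40.30, 3.32, 0.82, 9.95, 4.13),
    ("Aphasia", 4, 7.20, 2.70, 19.22, 7.18, 21.28, 2.84, 0.39, 7.18, 2.69),
    ("Disorientation", 4, 5.49, 2.06, 14.66, 5.48, 14.64, 2.45, 0.24, 5.47, 2.05),
    ("Subdural haematoma", 3, 11.44, 3.68, 35.52, 11.41, 28.48, 3.51, 0.22, 11.40, 3.67),
    ("Skin cancer", 3, 7.94, 2.56, 24.67, 7.92, 18.15, 2.99, 0.09, 7.92, 2.55),
    ("Posterior reversible encephalopathy syndrome", 3, 17.14, 5.52, 53.22, 17.09, 45.44, 4.09, 0.32, 17.09, 5.50),
    ("Cerebral infarction", 3, 6.76, 2.18, 20.98, 6.74, 14.67, 2.75, 0.02, 6.74, 2.17),
    ("Haemorrhage intracranial", 3, 10.71, 3.45, 33.27, 10.69, 26.34, 3.42, 0.20, 10.68, 3.44),
    ("Ischaemic stroke", 3, 9.32, 3.00, 28.93, 9.29, 22.20, 3.22, 0.15, 9.29, 2.99),
])

#: SOC-level event counts (event counting unit; shares of the 1095 events).
SOC_EVENT_COUNTS = {
    "Nervous system disorders": 583,
    "Injury, poisoning and procedural complications": 84,
    "Psychiatric disorders": 83,
    "General disorders and administration site conditions": 75,
    "Gastrointestinal disorders": 39,
}

#: SOC-level case counts (report counting unit), all 22 printed SOCs.
SOC_CASE_COUNTS = {
    "Nervous system disorders": 352,
    "Injury, poisoning and procedural complications": 63,
    "Psychiatric disorders": 58,
    "General disorders and administration site conditions": 53,
    "Gastrointestinal disorders": 36,
    "Infections and infestations": 28,
    "Investigations": 20,
    "Cardiac disorders": 20,
    "Musculoskeletal and connective tissue disorders": 18,
    "Neoplasms benign, malignant and unspecified (incl cysts and polyps)": 16,
    "Skin and subcutaneous tissue disorders": 15,
    "Metabolism and nutrition disorders": 15,
    "Vascular disorders": 15,
    "Renal and urinary disorders": 13,
    "Respiratory, thoracic and mediastinal disorders": 10,
    "Eye disorders": 9,
    "Ear and labyrinth disorders": 7,
    "Hepatobiliary disorders": 3,
    "Blood and lymphatic system disorders": 3,
    "Product issues": 2,
    "Immune system disorders": 1,
    "Reproductive system and breast disorders": 1,
}

_ONSET_BIN_MID = {
    "0-30": 15.0, "31-60": 45.5, "61-90": 75.5, "91-120": 105.5,
    "121-150": 135.5, "151-180": 165.5, "181-360": 270.5, ">360": 450.0,
}


def _fill(column: list, counts: dict, total: int) -> None:
    """Assign category values to the first sum(counts) slots, in order."""
    pos = 0
    for value, n in counts.items():
        for _ in range(n):
            column[pos] = value
            pos += 1
    if pos > total:
        raise ValueError("counts exceed total")


def demographic_records() -> pd.DataFrame:
    """Record set whose per-column marginal counts equal the printed Table.

    Columns are filled independently (the published table reports marginals
    only, not the joint distribution), so any per-column tally reproduces the
    printed counts exactly while cross-tabulations are arbitrary.  Weight is
    left missing throughout: the printed weight summary cannot be inverted
    into individual values.
    """
    n = TOTAL_REPORTS
    frame = pd.DataFrame({"case_id": [f"P{i:04d}" for i in range(n)]})
    for name, counts, fill_rest in [
        ("sex", SEX_COUNTS, None),
        ("age_group", AGE_GROUP_COUNTS, None),
        ("reporter", REPORTER_COUNTS, "other/not-specified"),
        ("country", COUNTRY_COUNTS, "other"),
        ("serious", SEVERITY_COUNTS, None),
    ]:
        col = [fill_rest] * n
        _fill(col, counts, n)
        frame[name] = col
    year_col: list = [pd.NA] * n
    _fill(year_col, REPORT_YEAR_COUNTS, n)
    frame["report_year"] = pd.array(year_col, dtype="Int64")
    frame["serious"] = frame["serious"] == "serious"
    # outcomes are multi-valued; each code marks its count of records from
    # the top so per-code tallies match the printed rows
    outcome_sets: list[set] = [set() for _ in range(n)]
    for code, count in OUTCOME_COUNTS.items():
        for i in range(count):
            outcome_sets[i].add(code)
    frame["outcomes"] = outcome_sets
    onset: list = [np.nan] * n
    _fill(onset, {_ONSET_BIN_MID[k]: v for k, v in ONSET_BIN_COUNTS.items()}, n)
    frame["onset_days"] = onset
    frame["age_years"] = np.nan
    frame["weight_kg"] = np.nan
    frame["is_focal"] = True
    return frame


def signal_table_inputs() -> pd.DataFrame:
    """The printed (term, n, ROR) triples used for table reconstruction."""
    return pd.DataFrame(
        [(r.term, r.n, r.ror) for r in PT_SIGNALS],
        columns=["term", "a", "ror"],
    )
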