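"""Readers and record assembly for FAERS-style quarterly flat files.

FAERS quarterly extracts are "$"-delimited ASCII tables with a header row:
DEMO (one row per report version), DRUG (one row per reported drug), REAC
(one row per reported reaction, coded as a MedDRA preferred term) and THER
(therapy dates).  This module parses those tables (several header vintages,
optionally gzipped), deduplicates report versions down to one record per
case, identifies the cases where a focal drug was the primary suspect, and
joins everything into an analysis-ready :class:`AnalysisDataset`.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (ConfigurationError, EmptyInputError, SchemaError,
                     ValidationError)

logger = logging.getLogger(__name__)

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "THER")

#: Age groups used throughout (printed-table convention; upper bounds
#: inclusive as counted, e.g. 64.9 years falls in "45-64", 65 in "65-74").
AGE_GROUPS = ("<18", "18-44", "45-64", "65-74", ">=75")
AGE_UNKNOWN = "unknown"

#: AGE_COD conversion factors to years.
AGE_UNIT_YEARS = {
    "yr": 1.0, "year": 1.0, "years": 1.0,
    "dec": 10.0, "decade": 10.0,
    "mon": 1.0 / 12.0, "month": 1.0 / 12.0,
    "wk": 1.0 / 52.18, "week": 1.0 / 52.18,
    "dy": 1.0 / 365.25, "day": 1.0 / 365.25,
}

_REQUIRED_COLUMNS = {
    "DEMO": {"primaryid", "caseid"},
    "DRUG": {"primaryid", "caseid", "drugname", "role_cod"},
    "REAC": {"primaryid", "caseid", "pt"},
    "THER": {"primaryid", "caseid", "start_dt"},
}

# union over the FAERS vintages we accept, plus the synthetic dialect's
# extension columns (serious, outc_cod, event_dt on REAC)
_KNOWN_COLUMNS = {
    "DEMO": _REQUIRED_COLUMNS["DEMO"] | {
        "caseversion", "i_f_code", "i_f_cod", "event_dt", "mfr_dt",
        "init_fda_dt", "fda_dt", "rept_cod", "auth_num", "mfr_num",
        "mfr_sndr", "lit_ref", "age", "age_cod", "age_grp", "sex",
        "gndr_cod", "e_sub", "wt", "wt_cod", "rept_dt", "to_mfr",
        "occp_cod", "reporter_country", "occr_country", "occp_cod_num",
        "death_dt", "confid", "serious", "outc_cod",
    },
    "DRUG": _REQUIRED_COLUMNS["DRUG"] | {
        "drug_seq", "val_vbm", "prod_ai", "route", "dose_vbm",
        "cum_dose_chr", "cum_dose_unit", "dechal", "rechal", "lot_num",
        "lot_nbr", "exp_dt", "nda_num", "dose_amt", "dose_unit",
        "dose_form", "dose_freq",
    },
    "REAC": _REQUIRED_COLUMNS["REAC"] | {"drug_rec_act", "event_dt"},
    "THER": _REQUIRED_COLUMNS["THER"] | {
        "dsg_drug_seq", "drug_seq", "end_dt", "dur", "dur_cod",
    },
}

_NUMERIC_COLUMNS = {
    "DEMO": ("caseversion", "event_dt", "fda_dt", "init_fda_dt", "age", "wt"),
    "DRUG": ("drug_seq",),
    "REAC": ("event_dt",),
    "THER": ("dsg_drug_seq", "drug_seq", "start_dt", "end_dt", "dur"),
}

_OCCP_MAP = {"CN": "consumer", "MD": "physician", "PH": "pharmacist"}

OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")


@dataclass(frozen=True)
class ReportRecord:
    """One deduplicated safety report."""

    case_id: str
    version_key: tuple
    sex: str = AGE_UNKNOWN
    age_years: float | None = None
    age_group: str = AGE_UNKNOWN
    weight_kg: float | None = None
    country: str = ""
    reporter: str = "other/not-specified"
    report_year: int | None = None
    serious: bool = False
    outcomes: frozenset = frozenset()


@dataclass(frozen=True)
class DrugEntry:
    case_id: str
    drug_name: str
    role: str            # PS, SS, C or I
    therapy_start: int | None = None


@dataclass(frozen=True)
class ReactionEntry:
    case_id: str
    pt: str
    event_date: int | None = None


@dataclass
class AnalysisDataset:
    """Joined, deduplicated corpus ready for disproportionality analysis.

    ``records`` has one row per case (focal and background) with demographic
    fields plus ``is_focal`` and ``onset_days``; ``events`` has one row per
    reaction with ``case_id``, ``pt``, ``soc`` and ``is_focal``.
    """

    records: pd.DataFrame
    events: pd.DataFrame
    pt_soc_map: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def focal_case_ids(self) -> set:
        return set(self.records.loc[self.records["is_focal"], "case_id"])

    def subset(self, case_mask: pd.Series) -> "AnalysisDataset":
        """Restrict records (and their events) to ``case_mask`` rows."""
        records = self.records.loc[case_mask].reset_index(drop=True)
        keep = set(records["case_id"])
        events = self.events.loc[self.events["case_id"].isin(keep)]
        return AnalysisDataset(records, events.reset_index(drop=True),
                               self.pt_soc_map, dict(self.meta))


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt", encoding="utf-8", errors="replace")
    return open(path, "r", encoding="utf-8", errors="replace")


def read_faers_table(path, table_kind: str) -> pd.DataFrame:
    """Parse one "$"-delimited FAERS table into a string-typed DataFrame.

    Column names are normalized to lower case; ``gndr_cod`` is renamed to
    ``sex`` (older vintages).  Rows with the wrong field count are retained
    (padded or truncated) and counted; numeric fields that fail to parse are
    set to missing and counted.  The total count is exposed as
    ``df.attrs["n_malformed"]`` and logged.

    Raises :class:`SchemaError` for an unrecognized header and
    :class:`EmptyInputError` for an empty file.
    """
    table_kind = table_kind.upper()
    if table_kind not in TABLE_KINDS:
        raise ConfigurationError(f"unknown table kind: {table_kind!r}")
    path = Path(path)
    with _open_text(path) as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise EmptyInputError(f"{path}: empty {table_kind} file")
        header = [c.strip().lower() for c in header_line.rstrip("\n\r").split("$")]
        unknown = [c for c in header if c not in _KNOWN_COLUMNS[table_kind]]
        missing = _REQUIRED_COLUMNS[table_kind] - set(header)
        if unknown or missing:
            raise SchemaError(
                f"{path}: header does not match any known {table_kind} layout"
                f" (unmatched columns: {sorted(unknown)};"
                f" missing required: {sorted(missing)})")
        ncol = len(header)
        rows: list[list[str]] = []
        n_malformed = 0
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n\r").split("$")
            if len(fields) != ncol:
                n_malformed += 1
                logger.warning("%s:%d: expected %d fields, got %d (row kept)",
                               path, lineno, ncol, len(fields))
                fields = (fields + [""] * ncol)[:ncol]
            rows.append(fields)
    frame = pd.DataFrame(rows, columns=header, dtype="string")
    frame = frame.replace("", pd.NA)
    if "gndr_cod" in frame.columns and "sex" not in frame.columns:
        frame = frame.rename(columns={"gndr_cod": "sex"})
    for col in _NUMERIC_COLUMNS[table_kind]:
        if col in frame.columns:
            parsed = pd.to_numeric(frame[col], errors="coerce")
            bad = int((frame[col].notna() & parsed.isna()).sum())
            if bad:
                n_malformed += bad
                logger.warning("%s: %d unparseable %r values set to missing",
                               path, bad, col)
            frame[col] = parsed
    frame.attrs["table_kind"] = table_kind
    frame.attrs["n_malformed"] = n_malformed
    logger.info("%s: %d rows, %d malformed fields/rows", path, len(frame),
                n_malformed)
    return frame


def load_faers_dir(directory, suffix: str = ".txt") -> dict[str, pd.DataFrame]:
    """Read DEMO/DRUG/REAC/THER files named ``<KIND><suffix>[.gz]``."""
    directory = Path(directory)
    tables = {}
    for kind in TABLE_KINDS:
        for candidate in (directory / f"{kind}{suffix}",
                          directory / f"{kind}{suffix}.gz"):
            if candidate.exists():
                tables[kind] = read_faers_table(candidate, kind)
                break
    if "DEMO" not in tables:
        raise EmptyInputError(f"{directory}: no DEMO table found")
    return tables


def deduplicate(records: pd.DataFrame, case_col: str = "caseid",
                version_cols: Iterable[str] = ("fda_dt", "primaryid")) -> pd.DataFrame:
    """Keep the latest version of every case.

    FAERS republishes a case whenever a follow-up arrives; standard practice
    keeps the most recent version, ordered here by the sortable version key
    (FDA receipt date, primary id).  Output is sorted by case id, one row per
    case.  Idempotent.
    """
    if records.empty:
        return records.copy()
    version_cols = [c for c in version_cols if c in records.columns]
    ordered = records.sort_values([case_col, *version_cols], kind="mergesort",
                                  na_position="first")
    latest = ordered.groupby(case_col, sort=True).tail(1)
    return latest.sort_values(case_col, kind="mergesort").reset_index(drop=True)


def filter_focal_drug(drug_entries: pd.DataFrame, dictionary: Iterable[str],
                      role_filter: Iterable[str] = ("PS",),
                      case_col: str = "caseid") -> set:
    """Case ids with >=1 drug row matching the dictionary and role filter.

    Matching is case-insensitive substring against ``drugname`` (and
    ``prod_ai`` when present): FAERS drug names are free text with salt and
    biosimilar suffixes, so exact matching would undercount.
    """
    patterns = [p.strip().lower() for p in dictionary if p and p.strip()]
    if not patterns:
        raise ConfigurationError("focal-drug dictionary is empty")
    roles = {r.upper() for r in role_filter}
    frame = drug_entries
    name = frame["drugname"].astype("string").str.lower().fillna("")
    hit = name.str.contains(patterns[0], regex=False)
    for pat in patterns[1:]:
        hit |= name.str.contains(pat, regex=False)
    if "prod_ai" in frame.columns:
        ai = frame["prod_ai"].astype("string").str.lower().fillna("")
        for pat in patterns:
            hit |= ai.str.contains(pat, regex=False)
    role_ok = frame["role_cod"].astype("string").str.upper().isin(roles)
    return set(frame.loc[hit & role_ok, case_col].astype(str))


def assign_age_group(age_value, age_unit="yr") -> str:
    """Convert an (age, unit) pair to years and bin it.

    Units follow FAERS AGE_COD (YR, DEC, MON, WK, DY); a missing unit is
    taken as years.  Missing age maps to ``"unknown"``; negative age raises
    :class:`ValidationError`.
    """
    if age_value is None or (isinstance(age_value, float) and np.isnan(age_value)) \
            or age_value is pd.NA:
        return AGE_UNKNOWN
    unit = "yr" if age_unit is None or age_unit is pd.NA or str(age_unit).strip() == "" \
        else str(age_unit).strip().lower()
    if unit not in AGE_UNIT_YEARS:
        raise ValidationError(f"unknown age unit: {age_unit!r}")
    years = float(age_value) * AGE_UNIT_YEARS[unit]
    if years < 0:
        raise ValidationError(f"negative age: {age_value!r} {age_unit!r}")
    return age_group_from_years(years)


def age_group_from_years(years: float) -> str:
    if np.isnan(years):
        return AGE_UNKNOWN
    if years < 18:
        return "<18"
    if years < 45:
        return "18-44"
    if years < 65:
        return "45-64"
    if years < 75:
        return "65-74"
    return ">=75"


def read_pt_soc_map(path) -> dict[str, str]:
    """Read a 2-column ``pt,soc`` CSV into a dict (PT keys lower-cased).

    A MedDRA stand-in: each PT must map to exactly one SOC.
    """
    frame = pd.read_csv(path)
    cols = [c.strip().lower() for c in frame.columns]
    frame.columns = cols
    if "pt" not in cols or "soc" not in cols:
        raise SchemaError(f"{path}: expected columns pt,soc, got {cols}")
    mapping: dict[str, str] = {}
    for pt, soc in zip(frame["pt"], frame["soc"]):
        key = str(pt).strip().lower()
        if key in mapping and mapping[key] != str(soc).strip():
            raise ValidationError(f"PT {pt!r} maps to more than one SOC")
        mapping[key] = str(soc).strip()
    return mapping


def _yyyymmdd_to_datetime(series: pd.Series) -> pd.Series:
    as_int = pd.to_numeric(series, errors="coerce")
    return pd.to_datetime(as_int.astype("Int64").astype("string"),
                          format="%Y%m%d", errors="coerce")


def build_dataset(tables: Mapping[str, pd.DataFrame],
                  focal_dictionary: Iterable[str],
                  pt_soc_map: Mapping[str, str] | None = None,
                  role_filter: Iterable[str] = ("PS",),
                  year_range: tuple[int, int] | None = None) -> AnalysisDataset:
    """Deduplicate, join and annotate the four FAERS tables.

    Drug and reaction rows are restricted to each case's retained (latest)
    report version.  ``onset_days`` is the difference between the case-level
    event date and the earliest therapy start date of the focal drug;
    negative values are retained here and excluded (with a count) by
    :func:`faersignal.signals.compute_onset`.
    """
    demo = deduplicate(tables["DEMO"])
    if demo.empty:
        raise EmptyInputError("DEMO table has no rows")
    keep_pid = set(demo["primaryid"].astype(str))

    def _latest(kind: str) -> pd.DataFrame:
        frame = tables.get(kind)
        if frame is None or frame.empty:
            return pd.DataFrame(columns=_REQUIRED_COLUMNS.get(kind, set()))
        return frame.loc[frame["primaryid"].astype(str).isin(keep_pid)]

    drug = _latest("DRUG")
    reac = _latest("REAC")
    ther = _latest("THER")

    focal_ids = filter_focal_drug(drug, focal_dictionary, role_filter) \
        if len(drug) else set()

    records = pd.DataFrame({"case_id": demo["caseid"].astype(str)})
    records["primaryid"] = demo["primaryid"].astype(str)
    sex = demo.get("sex", pd.Series(pd.NA, index=demo.index)).astype("string").str.upper()
    records["sex"] = sex.map({"F": "female", "M": "male"}).fillna(AGE_UNKNOWN)
    age = pd.to_numeric(demo.get("age"), errors="coerce")
    unit = demo.get("age_cod", pd.Series(pd.NA, index=demo.index))
    factors = unit.astype("string").str.strip().str.lower().map(AGE_UNIT_YEARS)
    factors = factors.fillna(1.0).to_numpy(dtype=float)
    age_years = age.to_numpy(dtype=float) * factors
    age_years = np.where(age_years < 0, np.nan, age_years)
    records["age_years"] = age_years
    records["age_group"] = [age_group_from_years(v) for v in age_years]
    wt = pd.to_numeric(demo.get("wt"), errors="coerce").to_numpy(dtype=float)
    wt_cod = demo.get("wt_cod", pd.Series(pd.NA, index=demo.index))
    lbs = wt_cod.astype("string").str.upper().isin(["LBS", "LB"]).to_numpy()
    records["weight_kg"] = np.where(lbs, wt * 0.45359237, wt)
    records["country"] = demo.get("reporter_country",
                                  pd.Series(pd.NA, index=demo.index)) \
        .astype("string").fillna("").str.strip()
    occp = demo.get("occp_cod", pd.Series(pd.NA, index=demo.index)) \
        .astype("string").str.upper()
    records["reporter"] = occp.map(_OCCP_MAP).fillna("other/not-specified")
    fda = pd.to_numeric(demo.get("fda_dt"), errors="coerce")
    records["report_year"] = (fda // 10000).astype("Int64")
    if "outc_cod" in demo.columns:
        records["outcomes"] = [
            frozenset(s.strip().upper() for s in str(v).split(",") if s.strip())
            if pd.notna(v) else frozenset()
            for v in demo["outc_cod"]
        ]
    else:
        records["outcomes"] = [frozenset()] * len(demo)
    if "serious" in demo.columns:
        records["serious"] = demo["serious"].astype("string").str.upper() \
            .isin(["Y", "YES", "1"]).to_numpy()
    else:
        serious_codes = {"DE", "LT", "HO", "DS", "CA", "RI"}
        records["serious"] = [bool(o & serious_codes) for o in records["outcomes"]]
    records["is_focal"] = records["case_id"].isin(focal_ids).to_numpy()

    # onset: earliest focal-drug therapy start vs case-level event date
    event_dt = _yyyymmdd_to_datetime(demo.get("event_dt",
                                              pd.Series(pd.NA, index=demo.index)))
    event_by_case = pd.Series(event_dt.values, index=records["case_id"]).dropna()
    onset = pd.Series(np.nan, index=records["case_id"], dtype=float)
    if len(ther) and "start_dt" in ther.columns:
        tt = ther.copy()
        tt["case_id"] = tt["caseid"].astype(str)
        tt = tt[tt["case_id"].isin(focal_ids)]
        tt["start"] = _yyyymmdd_to_datetime(tt["start_dt"])
        starts = tt.dropna(subset=["start"]).groupby("case_id")["start"].min()
        common = starts.index.intersection(event_by_case.index)
        onset.loc[common] = (event_by_case.loc[common] - starts.loc[common]) \
            .dt.days.astype(float)
    records["onset_days"] = onset.to_numpy()

    pt_soc = {str(k).strip().lower(): str(v) for k, v in (pt_soc_map or {}).items()}
    if len(reac):
        events = pd.DataFrame({
            "case_id": reac["caseid"].astype(str),
            "pt": reac["pt"].astype("string").str.strip(),
        })
        events = events.dropna(subset=["pt"]).reset_index(drop=True)
    else:
        events = pd.DataFrame(columns=["case_id", "pt"])
    events["soc"] = events["pt"].str.lower().map(pt_soc) if len(events) else \
        pd.Series(dtype="string")
    events["is_focal"] = events["case_id"].isin(focal_ids).to_numpy() \
        if len(events) else np.array([], dtype=bool)

    if year_range is not None:
        lo, hi = year_range
        year_ok = records["report_year"].between(lo, hi) | records["report_year"].isna()
        records = records.loc[year_ok].reset_index(drop=True)
        keep = set(records["case_id"])
        events = events.loc[events["case_id"].isin(keep)].reset_index(drop=True)

    meta = {
        "n_cases": int(len(records)),
        "n_focal_cases": int(records["is_focal"].sum()),
        "n_events": int(len(events)),
        "n_focal_events": int(events["is_focal"].sum()) if len(events) else 0,
        "role_filter": tuple(role_filter),
    }
    logger.info("dataset: %(n_cases)d cases (%(n_focal_cases)d focal), "
                "%(n_events)d events (%(n_focal_events)d focal)", meta)
    return AnalysisDataset(records=records, events=events, pt_soc_map=pt_soc,
                           meta=meta)
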