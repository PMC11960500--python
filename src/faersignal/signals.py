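"""Joint signal criteria, stratified/temporal/onset analyses, demographics.

A drug-event pair is flagged as a safety signal only when all five of the
conventional criteria hold simultaneously:

    case count a >= 3,
    lower bound of the ROR 95% CI > 1,
    PRR >= 2 with chi-square >= 4,
    IC - 2SD > 0,
    EBGM05 > 2.

Boundary semantics are frozen exactly as written: the count, PRR and
chi-square thresholds are inclusive, the three interval bounds strict.  An
undefined statistic (NaN) fails its criterion.  No multiple-testing
adjustment is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .contingency import ContingencyTable, build_tables
from .disprop import (DUMOUCHEL_INIT, MgpsPrior, SignalStatistics,
                      compute_bcpnn_ic, compute_ebgm, compute_prr_chi2,
                      compute_ror, fit_mgps_prior)
from .errors import FittingError
from .ingest import AnalysisDataset

logger = logging.getLogger(__name__)

ONSET_BINS: tuple[tuple[float, float], ...] = (
    (0, 30), (31, 60), (61, 90), (91, 120), (121, 150), (151, 180),
    (181, 360), (361, float("inf")),
)
ONSET_BIN_LABELS = ("0-30", "31-60", "61-90", "91-120", "121-150",
                    "151-180", "181-360", ">360")


@dataclass(frozen=True)
class Criteria:
    """Thresholds of the five-way joint signal test (printed defaults)."""

    min_count: int = 3
    ror_ci_low: float = 1.0       # strict >
    min_prr: float = 2.0          # inclusive >=
    min_chi2: float = 4.0         # inclusive >=
    min_ic_minus_2sd: float = 0.0  # strict >
    min_ebgm05: float = 2.0       # strict >


@dataclass(frozen=True)
class SignalDecision:
    term: str
    a: int
    statistics: SignalStatistics
    count_ok: bool
    ror_ok: bool
    prr_ok: bool
    ic_ok: bool
    ebgm_ok: bool

    @property
    def significant(self) -> bool:
        return (self.count_ok and self.ror_ok and self.prr_ok
                and self.ic_ok and self.ebgm_ok)


@dataclass(frozen=True)
class StratumSpec:
    """A subgroup filter: any combination of sex, age group, period and
    seriousness; ``None`` leaves that axis unrestricted."""

    sex: str | None = None
    age_group: str | None = None
    period: tuple[int, int] | None = None
    serious: bool | None = None

    @property
    def label(self) -> str:
        parts = []
        if self.sex is not None:
            parts.append(f"sex={self.sex}")
        if self.age_group is not None:
            parts.append(f"age={self.age_group}")
        if self.period is not None:
            parts.append(f"period={self.period[0]}-{self.period[1]}")
        if self.serious is not None:
            parts.append("serious" if self.serious else "non-serious")
        return ",".join(parts) if parts else "all"


@dataclass(frozen=True)
class OnsetSummary:
    n: int
    median_days: float
    q1_days: float
    q3_days: float
    bin_counts: Mapping[str, int]
    n_negative_excluded: int = 0
    n_missing: int = 0

    def to_dict(self) -> dict:
        return {
            "n": self.n, "median_days": self.median_days,
            "q1_days": self.q1_days, "q3_days": self.q3_days,
            "bin_counts": dict(self.bin_counts),
            "n_negative_excluded": self.n_negative_excluded,
            "n_missing": self.n_missing,
        }


def _ok(value: float, threshold: float, strict: bool) -> bool:
    if value is None or np.isnan(value):
        return False
    return value > threshold if strict else value >= threshold


def evaluate_criteria(decisions_input: Iterable[tuple[str, int, SignalStatistics]],
                      criteria: Criteria = Criteria()) -> list[SignalDecision]:
    """Apply the five-way joint criteria to (term, count, statistics) rows."""
    out = []
    for term, a, s in decisions_input:
        out.append(SignalDecision(
            term=term, a=int(a), statistics=s,
            count_ok=a >= criteria.min_count,
            ror_ok=_ok(s.ror_low, criteria.ror_ci_low, strict=True),
            prr_ok=(_ok(s.prr, criteria.min_prr, strict=False)
                    and _ok(s.chi2, criteria.min_chi2, strict=False)),
            ic_ok=_ok(s.ic_minus_2sd, criteria.min_ic_minus_2sd, strict=True),
            ebgm_ok=_ok(s.ebgm05, criteria.min_ebgm05, strict=True),
        ))
    return out


def decisions_to_frame(decisions: Iterable[SignalDecision]) -> pd.DataFrame:
    rows = []
    for dec in decisions:
        s = dec.statistics
        rows.append({
            "term": dec.term, "a": dec.a, "ror": s.ror, "ror_low": s.ror_low,
            "ror_high": s.ror_high, "prr": s.prr, "chi2": s.chi2, "ic": s.ic,
            "ic_minus_2sd": s.ic_minus_2sd, "ebgm": s.ebgm,
            "ebgm05": s.ebgm05, "rr": s.rr, "count_ok": dec.count_ok,
            "ror_ok": dec.ror_ok, "prr_ok": dec.prr_ok, "ic_ok": dec.ic_ok,
            "ebgm_ok": dec.ebgm_ok, "significant": dec.significant,
        })
    return pd.DataFrame(rows)


def compute_statistics_table(tables: Sequence[tuple[str, ContingencyTable]],
                             prior: MgpsPrior | None = None,
                             ic_estimator: str = "mc",
                             n_draws: int = 100_000,
                             seed: int = 0) -> pd.DataFrame:
    """One row of counts plus all statistics per term.

    When ``prior`` is None and at least 10 tables are available, the MGPS
    prior is fitted to this corpus's (a, E) pairs; with fewer tables the
    canonical DuMouchel prior is used as-is.  Per-term Monte-Carlo IC draws
    use independent substreams spawned from ``seed``.
    """
    if prior is None:
        try:
            prior = fit_mgps_prior([t for _, t in tables], rng=seed)
        except FittingError:
            prior = MgpsPrior(*DUMOUCHEL_INIT)
    streams = np.random.SeedSequence(seed).spawn(len(tables))
    rows = []
    for (term, table), stream in zip(tables, streams):
        ror, lo, hi = compute_ror(table)
        prr, chi2 = compute_prr_chi2(table)
        ic, ic2sd = compute_bcpnn_ic(table, estimator=ic_estimator,
                                     n_draws=n_draws,
                                     rng=np.random.default_rng(stream))
        ebgm, ebgm05, rr = compute_ebgm(table, prior)
        rows.append({"term": term, "a": table.a, "b": table.b, "c": table.c,
                     "d": table.d, "ror": ror, "ror_low": lo, "ror_high": hi,
                     "prr": prr, "chi2": chi2, "ic": ic,
                     "ic_minus_2sd": ic2sd, "ebgm": ebgm, "ebgm05": ebgm05,
                     "rr": rr})
    frame = pd.DataFrame(rows, columns=["term", "a", "b", "c", "d", "ror",
                                        "ror_low", "ror_high", "prr", "chi2",
                                        "ic", "ic_minus_2sd", "ebgm",
                                        "ebgm05", "rr"])
    frame.attrs["prior"] = prior
    return frame


def _stratum_mask(records: pd.DataFrame, stratum: StratumSpec) -> pd.Series:
    mask = pd.Series(True, index=records.index)
    if stratum.sex is not None:
        mask &= records["sex"] == stratum.sex
    if stratum.age_group is not None:
        mask &= records["age_group"] == stratum.age_group
    if stratum.period is not None:
        lo, hi = stratum.period
        mask &= records["report_year"].between(lo, hi).fillna(False)
    if stratum.serious is not None:
        mask &= records["serious"] == stratum.serious
    return mask


def run_stratified(dataset: AnalysisDataset, strata: Sequence[StratumSpec],
                   level: str = "PT", unit: str = "event",
                   criteria: Criteria = Criteria(),
                   **stats_kwargs) -> dict[str, pd.DataFrame]:
    """Recompute all statistics within each subgroup.

    The comparator margin is restricted to the same stratum (focal and
    background records alike), the standard subgroup-disproportionality
    convention that removes stratum-level confounding.  Terms with a < 3
    are retained and flagged ``low_count``; an empty stratum yields an
    empty frame with a warning.
    """
    out: dict[str, pd.DataFrame] = {}
    for stratum in strata:
        mask = _stratum_mask(dataset.records, stratum)
        sub = dataset.subset(mask)
        if sub.records.empty:
            logger.warning("stratum %s matches no records", stratum.label)
            out[stratum.label] = pd.DataFrame()
            continue
        tables = build_tables(sub.events, sub.focal_case_ids, level=level,
                              pt_soc_map=sub.pt_soc_map, unit=unit)
        tables = [(t, tab) for t, tab in tables if tab.a > 0]
        frame = compute_statistics_table(tables, **stats_kwargs)
        frame.insert(1, "stratum", stratum.label)
        frame["low_count"] = frame["a"] < criteria.min_count
        out[stratum.label] = frame
    return out


def forest_frame(stratified: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Forest-plot export: term, stratum, ror, ci bounds, count."""
    frames = [f[["term", "stratum", "ror", "ror_low", "ror_high", "a"]]
              for f in stratified.values() if not f.empty]
    if not frames:
        return pd.DataFrame(columns=["term", "stratum", "ror", "ror_low",
                                     "ror_high", "a"])
    return pd.concat(frames, ignore_index=True)


def run_temporal(dataset: AnalysisDataset, period_edges: Sequence[int],
                 level: str = "PT", unit: str = "event",
                 cumulative: bool = True, ic_estimator: str = "mc",
                 n_draws: int = 100_000, seed: int = 0) -> pd.DataFrame:
    """IC and IC-2SD per term for each surveillance period.

    ``cumulative=True`` (default) computes each period's statistics on all
    reports received up to and including that year, matching the
    progressive-accumulation reading of surveillance heat maps; with
    ``cumulative=False`` each period stands alone.  Terms absent from a
    period (a = 0) carry NaN missing markers.  Returns a tidy frame
    (term, period, a, ic, ic_minus_2sd).
    """
    edges = sorted(int(e) for e in period_edges)
    if not edges:
        raise ValueError("period_edges must be non-empty")
    all_terms = _term_index(dataset, level)
    rows = []
    prev = None
    streams = np.random.SeedSequence(seed).spawn(len(edges))
    for edge, stream in zip(edges, streams):
        year = dataset.records["report_year"]
        mask = year.le(edge).fillna(False)
        if not cumulative and prev is not None:
            mask &= year.gt(prev).fillna(False)
        prev = edge
        sub = dataset.subset(mask)
        tables = dict(build_tables(sub.events, sub.focal_case_ids,
                                   level=level, pt_soc_map=sub.pt_soc_map,
                                   unit=unit))
        term_streams = stream.spawn(len(all_terms))
        for term, tstream in zip(all_terms, term_streams):
            table = tables.get(term)
            if table is None or table.a == 0:
                rows.append({"term": term, "period": edge, "a": 0,
                             "ic": np.nan, "ic_minus_2sd": np.nan})
                continue
            ic, ic2sd = compute_bcpnn_ic(table, estimator=ic_estimator,
                                         n_draws=n_draws,
                                         rng=np.random.default_rng(tstream))
            rows.append({"term": term, "period": edge, "a": table.a,
                         "ic": ic, "ic_minus_2sd": ic2sd})
    return pd.DataFrame(rows)


def _term_index(dataset: AnalysisDataset, level: str) -> list[str]:
    tables = build_tables(dataset.events, dataset.focal_case_ids, level=level,
                          pt_soc_map=dataset.pt_soc_map, unit="event")
    return [term for term, table in tables if table.a > 0]


def temporal_matrix(tidy: pd.DataFrame, value: str = "ic_minus_2sd") -> pd.DataFrame:
    """Pivot the tidy temporal frame into a term x period matrix."""
    return tidy.pivot(index="term", columns="period", values=value)


def compute_onset(dataset: AnalysisDataset | pd.DataFrame,
                  bins: Sequence[tuple[float, float]] = ONSET_BINS,
                  labels: Sequence[str] = ONSET_BIN_LABELS) -> OnsetSummary:
    """Median/IQR and binned distribution of days from therapy start to event.

    Quantiles use linear interpolation; bins are inclusive on both printed
    endpoints (31-60 means 31 <= d <= 60) with day 0 in the first bin.
    Records without a computable onset are excluded; negative onsets
    (event before therapy start, usually a date-entry error) are excluded
    and counted separately.
    """
    records = dataset.records if isinstance(dataset, AnalysisDataset) else dataset
    days = pd.to_numeric(records["onset_days"], errors="coerce")
    n_missing = int(days.isna().sum())
    present = days.dropna().to_numpy(dtype=float)
    negative = present < 0
    n_negative = int(negative.sum())
    if n_negative:
        logger.warning("%d negative onset values excluded", n_negative)
    valid = np.sort(present[~negative])
    counts = {}
    for (lo, hi), label in zip(bins, labels):
        counts[label] = int(((valid >= lo) & (valid <= hi)).sum())
    if valid.size == 0:
        return OnsetSummary(n=0, median_days=float("nan"),
                            q1_days=float("nan"), q3_days=float("nan"),
                            bin_counts=counts, n_negative_excluded=n_negative,
                            n_missing=n_missing)
    q1, med, q3 = np.quantile(valid, [0.25, 0.5, 0.75])  # linear (type 7)
    return OnsetSummary(n=int(valid.size), median_days=float(med),
                        q1_days=float(q1), q3_days=float(q3),
                        bin_counts=counts, n_negative_excluded=n_negative,
                        n_missing=n_missing)


def summarize_demographics(records: pd.DataFrame | AnalysisDataset,
                           top_countries: int = 5) -> pd.DataFrame:
    """Tidy descriptive summary (section, category, n, pct).

    Percentages are out of all records, unknowns included, matching the
    convention of published FAERS demographic tables.  Sections: sex, age
    group, reporting year, reporter occupation, country (top N), severity,
    outcomes, onset bins and weight summary statistics (the latter carry
    NaN percentages).
    """
    if isinstance(records, AnalysisDataset):
        records = records.records
    total = len(records)
    rows: list[dict] = []

    def add_counts(section: str, counts: Mapping, order: Sequence | None = None):
        keys = order if order is not None else list(counts.keys())
        for key in keys:
            n = int(counts.get(key, 0))
            rows.append({"section": section, "category": str(key), "n": n,
                         "pct": 100.0 * n / total if total else float("nan")})

    add_counts("sex", records["sex"].value_counts().to_dict(),
               order=["female", "male", "unknown"])
    from .ingest import AGE_GROUPS, AGE_UNKNOWN
    add_counts("age_group", records["age_group"].value_counts().to_dict(),
               order=[*AGE_GROUPS, AGE_UNKNOWN])
    years = records["report_year"].dropna().astype(int).value_counts().sort_index()
    add_counts("report_year", years.to_dict())
    add_counts("reporter", records["reporter"].value_counts().to_dict())
    countries = records["country"].astype(str).value_counts()
    add_counts("country", countries.head(top_countries).to_dict())
    serious = records["serious"].astype(bool)
    add_counts("severity", {"serious": int(serious.sum()),
                            "non-serious": int((~serious).sum())})
    if "outcomes" in records.columns:
        from .ingest import OUTCOME_CODES
        outcome_counts = {code: int(sum(code in (o or ())
                                        for o in records["outcomes"]))
                          for code in OUTCOME_CODES}
        add_counts("outcome", outcome_counts, order=list(OUTCOME_CODES))
    if "onset_days" in records.columns:
        onset = compute_onset(records)
        add_counts("onset_days", onset.bin_counts, order=list(ONSET_BIN_LABELS))
    if "weight_kg" in records.columns:
        wt = pd.to_numeric(records["weight_kg"], errors="coerce").dropna()
        stats_rows = {
            "n": float(wt.size), "missing": float(total - wt.size),
            "mean": wt.mean(), "sd": wt.std(ddof=1),
            "median": wt.median(),
            "q1": wt.quantile(0.25), "q3": wt.quantile(0.75),
            "min": wt.min(), "max": wt.max(),
        }
        for key, value in stats_rows.items():
            rows.append({"section": "weight_kg", "category": key,
                         "n": value, "pct": float("nan")})
    return pd.DataFrame(rows, columns=["section", "category", "n", "pct"])


def event_shares(term_counts: Mapping[str, int] | pd.Series,
                 total: int | None = None) -> pd.DataFrame:
    """Share of each term among all reported events, as n and percent."""
    items = dict(term_counts)
    denom = total if total is not None else sum(items.values())
    frame = pd.DataFrame(
        [(term, int(n), 100.0 * n / denom) for term, n in items.items()],
        columns=["term", "n", "pct"])
    return frame.sort_values("n", ascending=False, kind="mergesort") \
        .reset_index(drop=True)
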