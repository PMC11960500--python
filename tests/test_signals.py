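"""Joint criteria, stratified/temporal/onset analyses and demographics."""

import math

import numpy as np
import pandas as pd
import pytest

from faersignal import published
from faersignal.contingency import build_tables
from faersignal.disprop import SignalStatistics
from faersignal.ingest import build_dataset
from faersignal.signals import (StratumSpec, compute_onset,
                                compute_statistics_table, evaluate_criteria,
                                event_shares, run_stratified, run_temporal,
                                summarize_demographics)
from faersignal.synthetic import (SyntheticConfig, default_pt_soc_map,
                                  generate)

from conftest import make_dataset


def stats(ror=10.0, ror_low=5.0, ror_high=20.0, prr=10.0, chi2=100.0,
          ic=3.0, ic_minus_2sd=1.0, ebgm=10.0, ebgm05=5.0, rr=10.0):
    return SignalStatistics(ror, ror_low, ror_high, prr, chi2, ic,
                            ic_minus_2sd, ebgm, ebgm05, rr)


class TestCriteria:
    def test_printed_aria_e_row_is_significant(self):
        s = stats(ror=53538.3, ror_low=42177.8, ror_high=67958.6,
                  prr=46644.4, chi2=3390009, ic=14.55, ic_minus_2sd=6.83,
                  ebgm=24044.0, ebgm05=18942.0)
        [decision] = evaluate_criteria([("ARIA-E", 141, s)])
        assert decision.significant

    def test_count_rule_overrides_strong_statistics(self):
        [decision] = evaluate_criteria([("x", 2, stats())])
        assert decision.count_ok is False
        assert not decision.significant

    def test_boundary_semantics_frozen(self):
        # inclusive thresholds at a, PRR, chi2; strict at the three bounds
        s = stats(ror_low=1.0, prr=2.0, chi2=4.0, ic_minus_2sd=0.0,
                  ebgm05=2.0)
        [decision] = evaluate_criteria([("x", 3, s)])
        assert decision.count_ok and decision.prr_ok
        assert not decision.ror_ok
        assert not decision.ic_ok
        assert not decision.ebgm_ok
        assert not decision.significant

    def test_undefined_statistics_fail_their_flag(self):
        s = stats(ror_low=math.nan, ic_minus_2sd=math.nan)
        [decision] = evaluate_criteria([("x", 10, s)])
        assert not decision.ror_ok and not decision.ic_ok

    def test_monotone_in_count(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            s = stats(ror_low=rng.uniform(0.5, 2), prr=rng.uniform(1, 3),
                      chi2=rng.uniform(0, 8), ic_minus_2sd=rng.uniform(-1, 1),
                      ebgm05=rng.uniform(1, 3))
            flags = [evaluate_criteria([("x", a, s)])[0].significant
                     for a in range(0, 8)]
            assert flags == sorted(flags)   # never True -> False as a grows


class TestStratified:
    @staticmethod
    def _dataset(seed=0, implanted=None, n_bg=4000, n_focal=300):
        config = SyntheticConfig(n_background_reports=n_bg,
                                 n_focal_reports=n_focal,
                                 implanted_rr=implanted or {}, seed=seed)
        return build_dataset(generate(config), ("aducanumab", "aduhelm"),
                             default_pt_soc_map())

    def test_all_records_stratum_equals_unstratified(self):
        dataset = self._dataset(seed=3)
        tables = build_tables(dataset.events, dataset.focal_case_ids)
        tables = [(t, tab) for t, tab in tables if tab.a > 0]
        full = compute_statistics_table(tables, n_draws=5000, seed=9)
        out = run_stratified(dataset, [StratumSpec()], n_draws=5000, seed=9)
        strat = out["all"].drop(columns=["stratum", "low_count"])
        pd.testing.assert_frame_equal(strat, full)

    def test_disjoint_strata_partition_counts(self):
        dataset = self._dataset(seed=4)
        strata = [StratumSpec(sex=s) for s in ("female", "male", "unknown")]
        out = run_stratified(dataset, strata, n_draws=2000, seed=1)
        summed = pd.concat(out.values()).groupby("term")["a"].sum()
        tables = dict(build_tables(dataset.events, dataset.focal_case_ids))
        for term, total in summed.items():
            assert total == tables[term].a

    def test_empty_stratum_warns_and_returns_empty(self, caplog):
        dataset = self._dataset(seed=5)
        out = run_stratified(dataset, [StratumSpec(age_group="<18",
                                                   sex="female",
                                                   period=(1990, 1991))],
                             n_draws=1000)
        [frame] = out.values()
        assert frame.empty

    def test_shared_effect_gives_overlapping_sex_cis(self):
        # same implanted relative risk in both sexes: the male and female
        # CIs for the implanted term should overlap in nearly all replicates
        overlap = 0
        n_rep = 20
        for seed in range(n_rep):
            dataset = self._dataset(seed=100 + seed,
                                    implanted={"ARIA-E": 30.0},
                                    n_bg=3000, n_focal=250)
            out = run_stratified(dataset,
                                 [StratumSpec(sex="female"),
                                  StratumSpec(sex="male")],
                                 n_draws=1000, seed=seed)
            rows = {label: frame.set_index("term")
                    for label, frame in out.items()}
            try:
                f = rows["sex=female"].loc["ARIA-E"]
                m = rows["sex=male"].loc["ARIA-E"]
            except KeyError:
                continue
            if f.ror_low <= m.ror_high and m.ror_low <= f.ror_high:
                overlap += 1
        assert overlap >= int(0.9 * n_rep)


class TestTemporal:
    @staticmethod
    def _yearly_dataset():
        # focal reports of one term double each year (1, 2, 4, 8) over a
        # flat focal and background stream, so its cumulative observed/
        # expected ratio — hence IC — grows period over period
        records, events = [], []

        def add(prefix, year, term, count, focal):
            for k in range(count):
                cid = f"{prefix}{year}{term[:2]}{k}"
                records.append({"case_id": cid, "report_year": year,
                                "is_focal": focal})
                events.append((cid, term, focal))

        for i, year in enumerate(range(2019, 2023)):
            add("F", year, "ARIA-E", 2 ** i, True)
            add("F", year, "Nausea", 10, True)
            add("B", year, "ARIA-E", 10, False)
            add("B", year, "Nausea", 90, False)
        return make_dataset(records, events)

    def test_cumulative_ic_non_decreasing_for_growing_signal(self):
        dataset = self._yearly_dataset()
        tidy = run_temporal(dataset, [2019, 2020, 2021, 2022],
                            ic_estimator="gamma")
        ics = tidy[tidy["term"] == "ARIA-E"].sort_values("period")["ic"]
        diffs = np.diff(ics.to_numpy())
        assert (diffs >= -1e-9).all()

    def test_period_before_first_report_is_missing(self):
        dataset = self._yearly_dataset()
        tidy = run_temporal(dataset, [2018, 2022], ic_estimator="gamma")
        first = tidy[tidy["period"] == 2018]
        assert (first["a"] == 0).all()
        assert first["ic"].isna().all()

    def test_single_year_stream_constant_after_that_year(self):
        records = [{"case_id": f"F{k}", "report_year": 2021} for k in range(6)]
        events = [(f"F{k}", "ARIA-E" if k < 4 else "Nausea", True)
                  for k in range(6)]
        records += [{"case_id": f"B{k}", "report_year": 2021,
                     "is_focal": False} for k in range(30)]
        events += [(f"B{k}", "Nausea", False) for k in range(30)]
        dataset = make_dataset(records, events)
        tidy = run_temporal(dataset, [2021, 2022, 2023],
                            ic_estimator="gamma")
        by_period = tidy.pivot(index="term", columns="period", values="ic")
        assert by_period[2021].equals(by_period[2022])
        assert by_period[2021].equals(by_period[2023])

    def test_final_cumulative_period_equals_full_analysis(self):
        dataset = self._yearly_dataset()
        tidy = run_temporal(dataset, [2022], ic_estimator="gamma")
        tables = build_tables(dataset.events, dataset.focal_case_ids)
        from faersignal.disprop import compute_bcpnn_ic
        for term, table in tables:
            if table.a == 0:
                continue
            ic, _ = compute_bcpnn_ic(table, estimator="gamma")
            row = tidy[(tidy["term"] == term) & (tidy["period"] == 2022)]
            assert row["ic"].iloc[0] == pytest.approx(ic, rel=1e-12)


class TestOnset:
    def test_median_of_three(self):
        records = [{"case_id": f"C{i}", "onset_days": d}
                   for i, d in enumerate([1, 2, 3])]
        summary = compute_onset(make_dataset(records, []))
        assert summary.median_days == 2.0

    def test_bin_assignment(self):
        records = [{"case_id": f"C{i}", "onset_days": d}
                   for i, d in enumerate([15, 45, 400])]
        summary = compute_onset(make_dataset(records, []))
        assert summary.bin_counts["0-30"] == 1
        assert summary.bin_counts["31-60"] == 1
        assert summary.bin_counts[">360"] == 1
        assert summary.n == 3

    def test_inclusive_bin_endpoints_and_day_zero(self):
        records = [{"case_id": f"C{i}", "onset_days": d}
                   for i, d in enumerate([0, 30, 31, 60, 360, 361])]
        summary = compute_onset(make_dataset(records, []))
        assert summary.bin_counts["0-30"] == 2
        assert summary.bin_counts["31-60"] == 2
        assert summary.bin_counts["181-360"] == 1
        assert summary.bin_counts[">360"] == 1

    def test_negative_onsets_excluded_with_count(self):
        records = [{"case_id": f"C{i}", "onset_days": d}
                   for i, d in enumerate([-5, 10, 20, np.nan])]
        summary = compute_onset(make_dataset(records, []))
        assert summary.n == 2
        assert summary.n_negative_excluded == 1
        assert summary.n_missing == 1

    def test_generator_onsets_recover_published_bins(self):
        # ~217 onsets drawn from the calibrated onset distribution per
        # replicate; seed-averaged bin proportions stay within 3 points of
        # the published histogram
        from faersignal.synthetic import aducanumab_profile
        profile = aducanumab_profile()
        lows = np.array([b[0] for b in profile.onset_bins])
        highs = np.array([b[1] if np.isfinite(b[1]) else 720.0
                          for b in profile.onset_bins])
        probs = np.array([b[2] for b in profile.onset_bins])
        target = {k: v / published.ONSET_N
                  for k, v in published.ONSET_BIN_COUNTS.items()}
        sums = {k: 0.0 for k in target}
        n_rep = 50
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            idx = rng.choice(len(lows), size=published.ONSET_N, p=probs)
            days = np.floor(rng.uniform(lows[idx], highs[idx] + 1.0))
            records = [{"case_id": f"C{i}", "onset_days": d}
                       for i, d in enumerate(days)]
            summary = compute_onset(make_dataset(records, []))
            for k in sums:
                sums[k] += summary.bin_counts[k] / summary.n
        for k, expected in target.items():
            assert sums[k] / n_rep == pytest.approx(expected, abs=0.03), k

    def test_full_generator_path_onset_bins_match_profile(self):
        # end-to-end: generate -> ingest -> compute_onset reproduces the
        # calibrated bin proportions on a pooled sample
        from faersignal.synthetic import aducanumab_profile, generate
        config = aducanumab_profile(seed=77, n_background_reports=0)
        dataset = build_dataset(generate(config), ("aducanumab", "aduhelm"),
                                default_pt_soc_map())
        summary = compute_onset(dataset.subset(dataset.records["is_focal"]))
        assert summary.n > 150
        for k, count in published.ONSET_BIN_COUNTS.items():
            assert summary.bin_counts[k] / summary.n == pytest.approx(
                count / published.ONSET_N, abs=0.08), k


class TestDemographics:
    def test_published_counts_reproduce_published_percentages(self):
        frame = summarize_demographics(published.demographic_records())
        sex = frame[frame["section"] == "sex"].set_index("category")
        assert sex.loc["female", "pct"] == pytest.approx(49.80, abs=0.005)
        assert sex.loc["male", "pct"] == pytest.approx(44.51, abs=0.005)
        assert sex.loc["unknown", "pct"] == pytest.approx(5.69, abs=0.005)

    def test_single_record_is_hundred_percent(self):
        records = pd.DataFrame([{
            "case_id": "C1", "sex": "female", "age_group": "65-74",
            "report_year": 2022, "reporter": "physician", "country": "US",
            "serious": True, "outcomes": frozenset({"HO"}),
            "onset_days": 100.0, "weight_kg": 70.0,
        }])
        frame = summarize_demographics(records)
        sex = frame[frame["section"] == "sex"].set_index("category")
        assert sex.loc["female", "pct"] == 100.0

    def test_planted_counts_match_hand_ratios(self):
        rng = np.random.default_rng(42)
        n = 510
        sexes = ["female"] * 200 + ["male"] * 250 + ["unknown"] * 60
        rng.shuffle(sexes)
        records = pd.DataFrame({
            "case_id": [f"C{i}" for i in range(n)], "sex": sexes,
            "age_group": ["65-74"] * n, "report_year": [2022] * n,
            "reporter": ["consumer"] * n, "country": ["US"] * n,
            "serious": [False] * n, "outcomes": [frozenset()] * n,
            "onset_days": [np.nan] * n, "weight_kg": [np.nan] * n,
        })
        frame = summarize_demographics(records)
        sex = frame[frame["section"] == "sex"].set_index("category")
        assert sex.loc["female", "pct"] == pytest.approx(round(100 * 200 / 510, 2), abs=0.005)
        assert sex.loc["male", "pct"] == pytest.approx(round(100 * 250 / 510, 2), abs=0.005)


class TestEventShares:
    def test_published_event_shares(self):
        counts = {r.term: r.n for r in published.PT_SIGNALS}
        frame = event_shares(counts, total=published.TOTAL_EVENTS)
        aria_e = frame.set_index("term").loc["ARIA-E"]
        assert aria_e["pct"] == pytest.approx(12.88, abs=0.005)

    def test_default_total_is_sum(self):
        frame = event_shares({"x": 3, "y": 1})
        assert frame.set_index("term").loc["x", "pct"] == 75.0
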