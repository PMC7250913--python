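"""Record assembly, Nelson–Aalen, normalization and quartile analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neurosurv.design import ExperimentDesign, HazardModel, ReporterDynamics
from neurosurv import simulate as sim
from neurosurv import survival as surv


def _records(times, events, group="g", well="w", plate="p"):
    n = len(times)
    return pd.DataFrame({
        "neuron_id": range(n), "time": times, "event": events,
        "group": group, "well": well, "plate": plate,
    })


class TestNelsonAalen:
    def test_three_neuron_hand_computation(self):
        # deaths at 24 and 48, censored at 72: H(24)=1/3, H(48)=1/3+1/2=5/6
        rec = _records([24.0, 48.0, 72.0], [True, True, False])
        na = surv.nelson_aalen(rec)
        assert na.loc[na["time"] == 24.0, "H"].iloc[0] == pytest.approx(1 / 3)
        assert na.loc[na["time"] == 48.0, "H"].iloc[0] == pytest.approx(5 / 6)

    def test_no_events_returns_zero_hazard(self):
        rec = _records([72.0, 72.0], [False, False])
        na = surv.nelson_aalen(rec)
        assert len(na) == 0  # step function identically zero

    def test_all_die_together_gives_unit_hazard(self):
        rec = _records([24.0] * 7, [True] * 7)
        na = surv.nelson_aalen(rec)
        assert na["H"].iloc[-1] == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_naive_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 30))
        times = rng.integers(1, 8, n) * 24.0
        events = rng.binomial(1, 0.6, n).astype(bool)
        rec = _records(times, events)
        na = surv.nelson_aalen(rec)
        # naive oracle: loop over event times, loop over subjects
        for _, row in na.iterrows():
            h = 0.0
            for ti in sorted(set(times[events])):
                if ti > row["time"]:
                    break
                d = sum(1 for t, e in zip(times, events) if t == ti and e)
                r = sum(1 for t in times if t >= ti)
                h += d / r
            assert row["H"] == pytest.approx(h)

    def test_monotone_hazard_and_variance(self):
        rng = np.random.default_rng(1)
        rec = _records(rng.integers(1, 6, 200) * 24.0,
                       rng.binomial(1, 0.5, 200).astype(bool))
        na = surv.nelson_aalen(rec)
        assert (na["H"].diff().dropna() >= 0).all()
        assert (na["var"].diff().dropna() >= 0).all()


class TestRecords:
    def test_event_coding_and_censoring(self):
        fates = pd.DataFrame({
            "track_id": [0, 1], "plate": [0, 0], "well": [0, 0], "field": [0, 0],
            "survival_time_h": [120.0, 48.0], "died": [False, True],
        })
        layout = pd.DataFrame({"plate": [0], "well": [0], "group": ["ctrl"]})
        rec = surv.build_survival_records(fates, layout, 120.0)
        alive = rec[rec["neuron_id"] == 0].iloc[0]
        dead = rec[rec["neuron_id"] == 1].iloc[0]
        assert alive["time"] == 120.0 and not alive["event"]
        assert dead["time"] == 48.0 and dead["event"]

    def test_zero_time_neurons_dropped_with_warning(self):
        fates = pd.DataFrame({
            "track_id": [0, 1], "plate": 0, "well": 0, "field": 0,
            "survival_time_h": [0.0, 120.0], "died": [True, False],
        })
        layout = pd.DataFrame({"plate": [0], "well": [0], "group": ["g"]})
        with pytest.warns(UserWarning, match="never confirmed alive"):
            rec = surv.build_survival_records(fates, layout, 120.0)
        assert len(rec) == 1

    def test_unmapped_well_and_negative_time_rejected(self):
        fates = pd.DataFrame({
            "track_id": [0], "plate": [0], "well": [3], "field": [0],
            "survival_time_h": [24.0], "died": [True],
        })
        layout = pd.DataFrame({"plate": [0], "well": [0], "group": ["g"]})
        with pytest.raises(surv.LayoutError):
            surv.build_survival_records(fates, layout, 120.0)
        bad = fates.assign(well=0, survival_time_h=-1.0)
        with pytest.raises(surv.DataError):
            surv.build_survival_records(bad, layout, 120.0)

    def test_reporter_columns_attached_per_time(self):
        fates = pd.DataFrame({
            "track_id": [0, 1], "plate": 0, "well": 0, "field": 0,
            "survival_time_h": [120.0, 120.0], "died": False,
        })
        layout = pd.DataFrame({"plate": [0], "well": [0], "group": ["g"]})
        reporter = pd.DataFrame({
            "track_id": [0, 0, 1], "time_h": [0.0, 24.0, 24.0],
            "mean_green": [5.0, 7.0, 9.0],
        })
        rec = surv.build_survival_records(fates, layout, 120.0, reporter=reporter)
        assert rec.loc[rec["neuron_id"] == 0, "green_24h"].iloc[0] == 7.0
        assert rec.loc[rec["neuron_id"] == 1, "green_24h"].iloc[0] == 9.0

    def test_eligible_count_matches_alive_at_reference(self):
        d = ExperimentDesign(plates=1, wells_per_plate=4, fields_per_well=1,
                             neurons_per_field=150,
                             group_of_well={w: "g" for w in range(4)},
                             end_of_followup=120.0)
        truth = sim.simulate_fates(d, HazardModel(scale=100.0), seed=42,
                                   place=False)
        rec = surv.records_from_truth(truth)
        qa = surv.assign_quartiles(rec, 24.0)
        n_alive_24 = (rec["time"] >= 24.0).sum()
        assert len(qa.labels) == n_alive_24


class TestNormalize:
    def _series(self):
        return pd.DataFrame({
            "group": ["ctrl"] * 4 + ["mut"] * 4,
            "time_h": [24.0, 24.0, 48.0, 48.0] * 2,
            "mean_green": [2.0, 4.0, 5.0, 6.0, 9.0, 9.0, 12.0, 12.0],
        })

    def test_control_reference_maps_to_one(self):
        out = surv.normalize_reporter(self._series(), "ctrl", 24.0)
        at_ref = out[(out["group"] == "ctrl") & (out["time_h"] == 24.0)]
        assert at_ref["mean_green"].mean() == pytest.approx(1.0)

    def test_scale_invariance(self):
        s = self._series()
        a = surv.normalize_reporter(s, "ctrl", 24.0)
        s2 = s.assign(mean_green=s["mean_green"] * 2)
        b = surv.normalize_reporter(s2, "ctrl", 24.0)
        np.testing.assert_allclose(a["mean_green"], b["mean_green"])

    def test_programmed_elevation_recovered(self):
        out = surv.normalize_reporter(self._series(), "ctrl", 24.0)
        mut24 = out[(out["group"] == "mut") & (out["time_h"] == 24.0)]
        assert mut24["mean_green"].mean() == pytest.approx(3.0)

    def test_nonpositive_control_rejected(self):
        s = self._series()
        s.loc[s["group"] == "ctrl", "mean_green"] = 0.0
        with pytest.raises(surv.DataError):
            surv.normalize_reporter(s, "ctrl", 24.0)


class TestQuartiles:
    def _rec_with_green(self, values, times=None):
        n = len(values)
        rec = _records(times if times is not None else [120.0] * n, [False] * n)
        rec["green_24h"] = values
        return rec

    def test_uniform_split(self):
        qa = surv.assign_quartiles(self._rec_with_green(list(range(1, 9))), 24.0)
        assert (qa.counts() == 2).all()

    def test_ties_go_to_lower_quartile(self):
        qa = surv.assign_quartiles(self._rec_with_green([1.0, 1.0, 1.0, 2.0]), 24.0)
        assert (qa.labels[:3] == "Q1").all()

    def test_degenerate_distribution_warns_all_q1(self):
        with pytest.warns(UserWarning, match="degenerate"):
            qa = surv.assign_quartiles(self._rec_with_green([3.0] * 6), 24.0)
        assert (qa.labels == "Q1").all()

    def test_too_few_measured_rejected(self):
        with pytest.raises(surv.AssignmentError):
            surv.assign_quartiles(self._rec_with_green([1.0, 2.0, 3.0]), 24.0)

    def test_dead_before_reference_excluded(self):
        rec = self._rec_with_green([1, 2, 3, 4, 5], times=[12.0] + [120.0] * 4)
        rec.loc[0, "event"] = True
        qa = surv.assign_quartiles(rec, 24.0)
        assert 0 not in qa.labels.index

    def test_quartile_sizes_on_simulated_cohort(self):
        d = ExperimentDesign(plates=1, wells_per_plate=1, fields_per_well=1,
                             neurons_per_field=523, group_of_well={0: "g"},
                             end_of_followup=120.0)
        truth = sim.simulate_fates(d, HazardModel.constant_rate(0.0), seed=2,
                                   place=False)
        rec = surv.records_from_truth(truth)
        qa = surv.assign_quartiles(rec, 24.0)
        counts = qa.counts()
        assert counts.sum() == 523
        assert counts.max() - counts.min() <= 1

    def test_quartile_model_reference_row_and_truncation(self):
        d = ExperimentDesign(plates=2, wells_per_plate=4, fields_per_well=1,
                             neurons_per_field=80,
                             group_of_well={w: "g" for w in range(4)},
                             end_of_followup=120.0)
        truth = sim.simulate_fates(d, HazardModel(scale=100.0), seed=3,
                                   place=False)
        rec = surv.records_from_truth(truth)
        qa = surv.assign_quartiles(rec, 24.0)
        fit = surv.quartile_hazard_model(rec, qa)
        table = fit.hr_table()
        ref = table[table["term"] == "quartile[Q1]"]
        assert len(ref) == 1 and ref["hr"].iloc[0] == 1.0
        # left truncation: every fitted record entered at the reference time
        assert (fit._entry == 24.0).all()
        assert (fit._time > 24.0).all()

    def test_empty_quartile_named_in_error(self):
        rec = self._rec_with_green([1, 2, 3, 4, 5, 6, 7, 8],
                                   times=[120.0] * 6 + [20.0, 20.0])
        rec.loc[[6, 7], "event"] = True
        rec.loc[[6, 7], "time"] = 20.0
        qa = surv.assign_quartiles(self._rec_with_green([1, 2, 3, 4, 5, 6, 7, 8]),
                                   24.0)
        # force Q4 to vanish after truncation
        rec2 = self._rec_with_green([1, 2, 3, 4, 5, 6, 7, 8])
        rec2.loc[rec2["green_24h"] > 6, "time"] = 24.0
        qa2 = surv.assign_quartiles(rec2, 24.0)
        with pytest.raises(surv.ModelError, match="Q4"):
            surv.quartile_hazard_model(rec2, qa2)

    def test_group_adjustment_adds_group_term(self):
        d = ExperimentDesign(plates=1, wells_per_plate=2, fields_per_well=1,
                             neurons_per_field=200,
                             group_of_well={0: "ctrl", 1: "mut"},
                             end_of_followup=120.0)
        hm = HazardModel(scale=100.0, group_log_hr={"mut": 1.0})
        truth = sim.simulate_fates(d, hm, seed=4, place=False)
        rec = surv.records_from_truth(truth)
        qa = surv.assign_quartiles(rec, 24.0)
        fit = surv.quartile_hazard_model(rec, qa, adjust_by_group=True)
        assert "group[mut]" in fit.terms
        assert fit.reference.get("group") == "ctrl"
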