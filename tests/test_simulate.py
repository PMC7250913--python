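"""Fate simulation and rendering: closed-form checks against the
programmed hazard model, signal conservation, and file round-trips."""

import numpy as np
import pandas as pd
import pytest

from neurosurv.design import (
    ConfigurationError,
    ExperimentDesign,
    HazardModel,
    ImagingModel,
    ReporterDynamics,
)
from neurosurv import simulate as sim
from neurosurv.simulate import FATE_COLUMNS, TRAJ_COLUMNS, GroundTruth, PlacementError


def _flat_design(n, end=960.0, groups=None, wells=1):
    groups = groups or {w: "g" for w in range(wells)}
    return ExperimentDesign(plates=1, wells_per_plate=wells, fields_per_well=1,
                            neurons_per_field=n, group_of_well=groups,
                            frame_interval=24.0, end_of_followup=end)


class TestFates:
    def test_zero_hazard_censors_everyone(self):
        d = _flat_design(200, end=120.0)
        truth = sim.simulate_fates(d, HazardModel.constant_rate(0.0), seed=1,
                                   place=False)
        assert truth.fates["censored"].all()
        assert truth.fates["death_time_h"].isna().all()

    def test_exponential_median_matches_closed_form(self):
        # rate 0.01/h => median ln2/0.01 = 69.3 h; horizon long enough that
        # censoring is negligible (exp(-9.6) of neurons)
        d = _flat_design(10_000)
        truth = sim.simulate_fates(d, HazardModel.constant_rate(0.01), seed=2,
                                   place=False)
        med = np.nanmedian(truth.fates["death_time_h"])
        assert med == pytest.approx(np.log(2) / 0.01, rel=0.05)

    def test_exponential_survival_curve_within_mc_error(self):
        lam, n = 0.01, 10_000
        d = _flat_design(n, end=480.0)
        truth = sim.simulate_fates(d, HazardModel.constant_rate(lam), seed=3,
                                   place=False)
        death = truth.fates["death_time_h"].to_numpy()
        censored = truth.fates["censored"].to_numpy()
        for t in d.frame_times[1:]:
            p = np.exp(-lam * t)
            alive = (censored | (death > t)).mean()
            se = np.sqrt(p * (1 - p) / n)
            assert abs(alive - p) < 3 * se

    def test_group_hazard_ratio_reflected_in_event_counts(self):
        # beta_B - beta_A = ln 2 with constant baseline: the implied hazard
        # ratio from first-interval death fractions is 2
        d = ExperimentDesign(plates=1, wells_per_plate=2, fields_per_well=1,
                             neurons_per_field=5000,
                             group_of_well={0: "A", 1: "B"},
                             frame_interval=24.0, end_of_followup=120.0)
        hm = HazardModel.constant_rate(0.005, group_log_hr={"B": np.log(2)})
        truth = sim.simulate_fates(d, hm, seed=4, place=False)
        f = truth.fates
        p = {g: ((~sub["censored"]) & (sub["death_time_h"] <= 24)).mean()
             for g, sub in f.groupby("group")}
        ratio = np.log(1 - p["B"]) / np.log(1 - p["A"])
        assert ratio == pytest.approx(2.0, abs=0.3)

    def test_same_seed_bitwise_different_seed_differs(self):
        d = _flat_design(150, end=120.0)
        hm = HazardModel()
        a = sim.simulate_fates(d, hm, seed=7, place=False)
        b = sim.simulate_fates(d, hm, seed=7, place=False)
        pd.testing.assert_frame_equal(a.fates, b.fates)
        pd.testing.assert_frame_equal(a.trajectories, b.trajectories)
        c = sim.simulate_fates(d, hm, seed=8, place=False)
        assert sorted(a.fates["death_time_h"].dropna()) != \
            sorted(c.fates["death_time_h"].dropna())

    def test_unknown_group_and_negative_rate_rejected(self):
        d = _flat_design(5, end=120.0)
        with pytest.raises(ConfigurationError):
            sim.simulate_fates(d, HazardModel(group_log_hr={"nope": 1.0}), seed=1)
        with pytest.raises(ConfigurationError):
            HazardModel.constant_rate(-0.1)
        with pytest.raises(ConfigurationError):
            HazardModel(shape=-1.0)

    def test_trajectories_stop_at_death(self):
        d = _flat_design(300, end=120.0)
        truth = sim.simulate_fates(d, HazardModel(scale=80.0), seed=9, place=False)
        merged = truth.trajectories.merge(truth.fates, on="neuron_id")
        dead = merged[~merged["censored"]]
        assert (dead["time_h"] < dead["death_time_h"]).all()
        # censored neurons have a row at every frame
        n_cens = truth.fates["censored"].sum()
        full = truth.trajectories.groupby("neuron_id").size() == d.n_frames
        assert full.sum() >= n_cens

    def test_reporter_surge_precedes_death_in_responders(self):
        rep = ReporterDynamics(surge_fold=2.0, surge_lead_h=48.0,
                               responder_fraction=1.0, cell_sd_log=1e-6)
        d = _flat_design(400, end=120.0)
        hm = HazardModel(scale=80.0, reporter=rep)
        truth = sim.simulate_fates(d, hm, seed=10, place=False)
        merged = truth.trajectories.merge(truth.fates, on="neuron_id")
        dead = merged[~merged["censored"]]
        late = dead[dead["time_h"] >= dead["death_time_h"] - 1e-9]  # none exist
        assert len(late) == 0
        # last observed green of a dying responder exceeds its first green
        last = dead.sort_values("time_h").groupby("neuron_id").last()
        first = dead.sort_values("time_h").groupby("neuron_id").first()
        close_to_death = (last["death_time_h"] - last["time_h"] < 24.0) \
            & (last["time_h"] > first["time_h"])
        rises = (last["green_true"] / first["green_true"])[close_to_death]
        if len(rises) >= 10:
            assert (rises > 1.0).mean() > 0.95


class TestRender:
    def test_empty_field_is_exact_background(self, clean_imaging):
        d = _flat_design(1, end=120.0)
        empty = GroundTruth(fates=pd.DataFrame(columns=FATE_COLUMNS),
                            trajectories=pd.DataFrame(columns=TRAJ_COLUMNS),
                            design=d)
        st = sim.render_movie(empty, clean_imaging, seed=1,
                              plate=0, well=0, field=0)
        assert (st.red == clean_imaging.background_level).all()
        assert (st.green == clean_imaging.background_level).all()

    @staticmethod
    def _one_neuron_truth(intensity=5000.0, x=100.3, y=60.7, end=24.0):
        d = ExperimentDesign(plates=1, wells_per_plate=1, fields_per_well=1,
                             neurons_per_field=1, group_of_well={0: "g"},
                             frame_interval=24.0, end_of_followup=end)
        n_frames = d.n_frames
        fates = pd.DataFrame([{
            "neuron_id": 0, "plate": 0, "well": 0, "field": 0, "group": "g",
            "x": x, "y": y, "death_time_h": np.nan, "censored": True,
        }])
        traj = pd.DataFrame({
            "neuron_id": 0, "frame": range(n_frames),
            "time_h": d.frame_times, "red_true": intensity,
            "green_true": intensity / 2,
        })
        return GroundTruth(fates=fates, trajectories=traj, design=d)

    def test_single_blob_geometry_and_integral(self):
        im = ImagingModel(poisson_noise=False, read_noise_sd=0.0,
                          background_level=0.0, photobleach_rate=0.0)
        truth = self._one_neuron_truth()
        st = sim.render_movie(truth, im, seed=1, plate=0, well=0, field=0)
        frame = st.red[0]
        iy, ix = np.unravel_index(np.argmax(frame), frame.shape)
        assert abs(ix - 100.3) <= 0.5 and abs(iy - 60.7) <= 0.5
        assert frame.sum() == pytest.approx(5000.0, rel=0.01)
        # 6-sigma window captures the integral to 0.5%
        s = im.psf_sigma
        win = frame[int(60.7 - 6 * s):int(60.7 + 6 * s) + 1,
                    int(100.3 - 6 * s):int(100.3 + 6 * s) + 1]
        assert win.sum() == pytest.approx(5000.0, rel=0.005)

    def test_signal_conservation_before_noise(self, small_truth, clean_imaging):
        combos = small_truth.fates[["plate", "well", "field"]].drop_duplicates()
        p, w, f = combos.iloc[0]
        st = sim.render_movie(small_truth, clean_imaging, seed=2,
                              plate=p, well=w, field=f)
        traj = small_truth.field_truth(p, w, f).trajectories
        for t_idx in range(st.red.shape[0]):
            expected = traj[traj["frame"] == t_idx]["red_true"].sum() * \
                (1 - clean_imaging.photobleach_rate) ** t_idx
            measured = (st.red[t_idx] - clean_imaging.background_level).sum()
            assert measured == pytest.approx(expected, rel=0.01)

    def test_dead_neurons_absent_after_death(self, small_truth, clean_imaging):
        f = small_truth.fates
        dead = f[~f["censored"]]
        if len(dead) == 0:
            pytest.skip("no deaths at this seed")
        row = dead.iloc[0]
        st = sim.render_movie(small_truth, clean_imaging, seed=3,
                              plate=row["plate"], well=row["well"],
                              field=row["field"])
        times = small_truth.design.frame_times
        first_gone = int(np.searchsorted(times, row["death_time_h"], "left"))
        x, y = int(round(row["x"])), int(round(row["y"]))
        for t_idx in range(first_gone, len(times)):
            patch = st.red[t_idx, max(y - 2, 0):y + 3, max(x - 2, 0):x + 3]
            assert (patch == clean_imaging.background_level).all()

    def test_overlapping_centers_rejected(self, clean_imaging):
        truth = self._one_neuron_truth()
        f2 = truth.fates.copy()
        f2.loc[1] = f2.loc[0]
        f2.loc[1, "neuron_id"] = 1
        f2.loc[1, "x"] += 2.0  # << min_separation
        t2 = pd.concat([truth.trajectories,
                        truth.trajectories.assign(neuron_id=1)], ignore_index=True)
        bad = GroundTruth(fates=f2, trajectories=t2, design=truth.design)
        with pytest.raises(PlacementError):
            sim.render_movie(bad, clean_imaging, seed=1, plate=0, well=0, field=0)

    def test_seeded_rendering_is_deterministic(self, small_truth):
        im = ImagingModel()
        kw = dict(plate=0, well=0, field=0, seed=5)
        a = sim.render_movie(small_truth, im, **kw)
        b = sim.render_movie(small_truth, im, **kw)
        assert np.array_equal(a.red, b.red) and np.array_equal(a.green, b.green)


class TestTables:
    def test_truth_round_trip(self, small_truth, tmp_path):
        sim.write_truth_tables(small_truth, tmp_path)
        back = sim.read_truth_tables(tmp_path, small_truth.design)
        f0 = small_truth.fates.reset_index(drop=True)
        f1 = back.fates
        for col in ("neuron_id", "plate", "well", "field", "group", "censored"):
            assert (f0[col] == f1[col]).all()
        for col in ("x", "y", "death_time_h"):
            np.testing.assert_allclose(f0[col], f1[col], rtol=0, atol=1e-12)
        assert len(back.trajectories) == len(small_truth.trajectories)

    def test_empty_truth_writes_header_only(self, tmp_path):
        d = _flat_design(1, end=120.0)
        empty = GroundTruth(fates=pd.DataFrame(columns=FATE_COLUMNS),
                            trajectories=pd.DataFrame(columns=TRAJ_COLUMNS),
                            design=d)
        fp, tp = sim.write_truth_tables(empty, tmp_path)
        assert fp.read_text().strip() == ",".join(FATE_COLUMNS)
        back = sim.read_truth_tables(tmp_path, d)
        assert len(back.fates) == 0

    def test_row_counts_match_neuron_and_frame_counts(self):
        d = _flat_design(1000, end=120.0)
        truth = sim.simulate_fates(d, HazardModel.constant_rate(0.0), seed=1,
                                   place=False)
        assert len(truth.fates) == 1000
        assert len(truth.trajectories) == 1000 * d.n_frames

    def test_movie_round_trip_both_dialects(self, small_truth, clean_imaging,
                                            tmp_path):
        st = sim.render_movie(small_truth, clean_imaging, seed=1,
                              plate=0, well=0, field=0)
        sim.write_movie(st, tmp_path)
        back = sim.read_movie(tmp_path, 0, 0, 0)
        np.testing.assert_allclose(back.red, np.round(st.red), atol=0)
        sim.write_movie(st, tmp_path / "combined", combined=True)
        back2 = sim.read_movie(tmp_path / "combined", 0, 0, 0)
        np.testing.assert_allclose(back2.green, np.round(st.green), atol=0)


def test_gamma_for_quartile_hr_inverts_tail_means():
    from scipy import stats
    g = sim.gamma_for_quartile_hr(2.0)
    q = stats.norm.ppf(0.75)
    tail_mean = stats.norm.pdf(q) / 0.25
    assert np.exp(g * 2 * tail_mean) == pytest.approx(2.0, rel=1e-9)
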