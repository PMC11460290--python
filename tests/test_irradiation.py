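"""Cell assembly: dose-targeted sampling, cross-track DSBs, time stamps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cellsim.irradiation import (
    assemble_cell_sdd,
    assign_time_stamps,
    recombine_cross_track_dsb,
)
from cellsim.library import build_library
from cellsim.lu177 import DoseRateModel, IncidentSpectrum
from cellsim.sdd import records_to_frame, pair_ssb_records
from tests.test_sdd import _record

from conftest import make_manual_ensemble, make_manual_library


def _mono_incident(energy=100.0):
    return IncidentSpectrum(energies_kev=np.array([energy]), weights=np.array([1.0]))


class TestAssembly:
    def test_single_track_library_stops_after_one_track(self, genome, rng):
        dep = 0.01 / genome.specific_energy_gy_per_ev
        ens = make_manual_ensemble(100.0, [dep], [2], genome)
        lib = make_manual_library([ens], genome)
        exp = assemble_cell_sdd(lib, _mono_incident(), 0.01, rng)
        assert exp.n_tracks == 1
        assert exp.realized_dose_gy == pytest.approx(0.01)
        assert exp.dsb_count == 2

    def test_wald_identity_for_track_count(self, genome):
        """E[number of tracks] ~ target dose x k, and the overshoot is less
        than one maximal track z (first-crossing stopping rule)."""
        lib = build_library(tracks_per_energy=500, seed=8, model=genome, energies=[100.0])
        z = lib.ensemble(100.0).z_gy
        k = 1.0 / z.mean()
        target = 0.5
        counts, overshoot = [], []
        rng = np.random.default_rng(99)
        for _ in range(300):
            exp = assemble_cell_sdd(lib, _mono_incident(), target, rng, batch_size=256)
            counts.append(exp.n_tracks)
            overshoot.append(exp.realized_dose_gy - target)
            assert exp.realized_dose_gy >= target
        mean_n = np.mean(counts)
        expected_n = target * k
        assert abs(mean_n - expected_n) < 4 * np.std(counts) / np.sqrt(300) + 1.0
        assert max(overshoot) < z.max()

    def test_superposition_linearity_of_dsb_yield(self, genome):
        """Pooled DSBs per unit dose over many cells reproduce the sampled
        library's realized yield: superposition neither adds nor loses
        damage."""
        lib = build_library(tracks_per_energy=2000, seed=10, model=genome, energies=[100.0])
        ens = lib.ensemble(100.0)
        lib_yield = ens.dsb_per_track.sum() / ens.z_gy.sum()
        rng = np.random.default_rng(5)
        target = 0.5
        dsbs, doses = [], []
        for _ in range(200):
            exp = assemble_cell_sdd(lib, _mono_incident(), target, rng, batch_size=1024)
            dsbs.append(exp.dsb_count)
            doses.append(exp.realized_dose_gy)
        y = np.sum(dsbs) / np.sum(doses)
        # resampling error of ~sum(dsbs) draws with replacement
        se = np.sqrt(np.sum(dsbs)) / np.sum(doses)
        assert y == pytest.approx(lib_yield, abs=4 * se)

    def test_records_track_ids_match_tracks_table(self, genome, rng):
        lib = build_library(tracks_per_energy=200, seed=2, model=genome, energies=[10.0])
        exp = assemble_cell_sdd(lib, _mono_incident(10.0), 0.05, rng)
        assert set(exp.merged_records["track_id"]) <= set(exp.tracks["track_id"])
        # draw-order ids are dense
        assert exp.tracks["track_id"].tolist() == list(range(exp.n_tracks))


class TestRecombination:
    def test_no_cross_track_proximity_is_identity(self, genome):
        frame = records_to_frame(
            [_record(bp=100, cls="SSB", strand=1, track=0),
             _record(bp=5000, cls="SSB", strand=2, track=1)]
        )
        out = recombine_cross_track_dsb(frame, genome)
        pd.testing.assert_frame_equal(out, frame)

    def test_cross_track_pair_becomes_dsb(self, genome):
        frame = records_to_frame(
            [_record(bp=100, cls="SSB", strand=1, track=0, time=1.0),
             _record(bp=105, cls="SSB", strand=2, track=1, time=2.5)]
        )
        out = recombine_cross_track_dsb(frame, genome)
        assert list(out["classification"]) == ["DSB"]
        assert out["time_h"].iloc[0] == 2.5  # DSB exists once both strands broke

    def test_same_track_pairs_left_alone(self, genome):
        frame = records_to_frame(
            [_record(bp=100, cls="SSB", strand=1, track=3),
             _record(bp=105, cls="SSB", strand=2, track=3)]
        )
        out = recombine_cross_track_dsb(frame, genome)
        assert list(out["classification"]) == ["SSB", "SSB"]

    def test_idempotent_and_conserves_breaks(self, genome, rng):
        recs = [
            _record(
                bp=int(rng.integers(0, 500)),
                cls="SSB",
                strand=int(rng.integers(1, 3)),
                track=int(rng.integers(0, 10)),
            )
            for _ in range(60)
        ]
        frame = records_to_frame(recs)
        once = recombine_cross_track_dsb(frame, genome)
        twice = recombine_cross_track_dsb(once, genome)
        pd.testing.assert_frame_equal(once, twice)
        assert (
            once["breaks_strand1"].sum() + once["breaks_strand2"].sum()
            == frame["breaks_strand1"].sum() + frame["breaks_strand2"].sum()
        )

    def test_matches_brute_force_all_pairs_oracle(self, rng, genome):
        """DSB count after recombination equals an independent O(n^2)
        greedy leftmost-first pairing over cross-track opposite strands."""
        for trial in range(10):
            items = [
                (
                    int(rng.integers(0, 300)),
                    int(rng.integers(1, 3)),
                    int(rng.integers(0, 6)),
                )
                for _ in range(40)
            ]
            frame = records_to_frame(
                [_record(bp=b, cls="SSB", strand=s, track=t) for b, s, t in items]
            )
            out = recombine_cross_track_dsb(frame, genome)
            # oracle
            srt = sorted(range(len(items)), key=lambda i: (items[i][0], i))
            used = [False] * len(items)
            n_dsb = 0
            for a in range(len(srt)):
                i = srt[a]
                if used[i]:
                    continue
                for b in range(a + 1, len(srt)):
                    j = srt[b]
                    if items[j][0] - items[i][0] > 10:
                        break
                    if used[j] or items[j][1] == items[i][1] or items[j][2] == items[i][2]:
                        continue
                    used[i] = used[j] = True
                    n_dsb += 1
                    break
            assert int((out["classification"] == "DSB").sum()) == n_dsb


class TestTimeStamps:
    def _exposure(self, genome, rng, n_tracks=1000):
        dep = 0.001 / genome.specific_energy_gy_per_ev
        ens = make_manual_ensemble(100.0, [dep] * 4, [1] * 4, genome)
        lib = make_manual_library([ens], genome)
        return assemble_cell_sdd(lib, _mono_incident(), n_tracks * 0.001 - 5e-4, rng)

    def test_no_decay_limit_is_homogeneous_poisson(self, genome, rng):
        exp = self._exposure(genome, rng)
        model = DoseRateModel(
            initial_dose_rate_gy_h=1.0, decay_constant_per_h=0.0,
            track_rate_constant_per_gy=100.0,
        )
        stamped = assign_time_stamps(exp, model, rng=rng)
        gaps = np.diff(np.concatenate([[0.0], stamped.tracks["time_h"].to_numpy()]))
        n = len(gaps)
        assert gaps.mean() == pytest.approx(1.0 / 100.0, abs=4 / 100.0 / np.sqrt(n))
        _, p = stats.kstest(gaps * 100.0, "expon")
        assert p > 0.001

    def test_expected_arrivals_match_integrated_rate(self, genome):
        """Arrivals in [0, T] average to N0 (1 - e^(-λT)) / λ."""
        model = DoseRateModel(
            initial_dose_rate_gy_h=1.0, decay_constant_per_h=0.05,
            track_rate_constant_per_gy=200.0,
        )
        lam, n0 = 0.05, 200.0
        T = 5.0
        expected = n0 * (1 - np.exp(-lam * T)) / lam
        counts = []
        rng = np.random.default_rng(3)
        for _ in range(100):
            exp = self._exposure(genome, rng, n_tracks=1500)
            stamped = assign_time_stamps(exp, model, rng=rng)
            counts.append((stamped.tracks["time_h"].to_numpy() <= T).sum())
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 4 * se + 1

    def test_time_rescaling_gives_unit_exponential_gaps(self, genome, rng):
        """Transforming NHPP arrivals by the integrated rate must yield
        unit-rate exponential inter-arrival gaps (KS test)."""
        model = DoseRateModel(
            initial_dose_rate_gy_h=1.0, decay_constant_per_h=0.2,
            track_rate_constant_per_gy=500.0,
        )
        exp = self._exposure(genome, rng, n_tracks=2000)
        stamped = assign_time_stamps(exp, model, rng=rng)
        t = stamped.tracks["time_h"].to_numpy()
        lam, n0 = 0.2, 500.0
        big_lambda = n0 * (1 - np.exp(-lam * t)) / lam
        gaps = np.diff(np.concatenate([[0.0], big_lambda]))
        _, p = stats.kstest(gaps, "expon")
        assert p > 0.001

    def test_recursion_first_interval(self, genome, rng):
        exp = self._exposure(genome, rng, n_tracks=50)
        model = DoseRateModel(
            initial_dose_rate_gy_h=0.67, track_rate_constant_per_gy=1000.0
        )
        stamped = assign_time_stamps(exp, model, mode="recursion")
        assert stamped.tracks["time_h"].iloc[0] == pytest.approx(1.0 / 670.0)
        # intervals grow as the activity decays
        gaps = np.diff(stamped.tracks["time_h"].to_numpy())
        assert (np.diff(gaps) > 0).all()

    def test_recursion_literal_shrinks_intervals(self, genome, rng):
        exp = self._exposure(genome, rng, n_tracks=50)
        model = DoseRateModel(
            initial_dose_rate_gy_h=0.67, track_rate_constant_per_gy=1000.0
        )
        stamped = assign_time_stamps(exp, model, mode="recursion_literal")
        gaps = np.diff(stamped.tracks["time_h"].to_numpy())
        assert (np.diff(gaps) < 0).all()

    def test_records_inherit_track_times_monotonically(self, genome, rng):
        lib = build_library(tracks_per_energy=100, seed=4, model=genome, energies=[10.0])
        exp = assemble_cell_sdd(lib, _mono_incident(10.0), 0.2, rng)
        model = DoseRateModel(initial_dose_rate_gy_h=0.67, track_rate_constant_per_gy=800.0)
        stamped = assign_time_stamps(exp, model, rng=rng)
        times = stamped.merged_records["time_h"].to_numpy()
        assert (np.diff(times) >= 0).all()
        lookup = stamped.tracks.set_index("track_id")["time_h"]
        got = stamped.merged_records["track_id"].map(lookup).to_numpy()
        np.testing.assert_allclose(times, got)

    def test_more_tracks_than_process_can_deliver_errors(self, genome, rng):
        exp = self._exposure(genome, rng, n_tracks=1000)
        model = DoseRateModel(
            initial_dose_rate_gy_h=0.1, decay_constant_per_h=1.0,
            track_rate_constant_per_gy=100.0,
        )  # N0/lambda = 10 expected arrivals, ever
        with pytest.raises(ValueError, match="achievable|deliver"):
            assign_time_stamps(exp, model, rng=rng)
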