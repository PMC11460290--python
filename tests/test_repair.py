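"""NHEJ kinetics: exponential limit, conservation, master-equation oracle."""

from functools import lru_cache

import numpy as np
import pandas as pd
import pytest

from cellsim.repair import (
    AberrationCounts,
    RepairParams,
    RepairState,
    classify_aberrations,
    residual_dsbs,
    simulate_repair,
)
from cellsim.sdd import records_to_frame
from tests.test_sdd import _record


def _acute_dsbs(n, rng, radius=4.0, times=None, chroms=None):
    """Frame of n acute DSB records at random positions in a sphere."""
    recs = []
    for i in range(n):
        v = rng.normal(size=3)
        pos = tuple(v / np.linalg.norm(v) * radius * rng.random() ** (1 / 3))
        recs.append(
            _record(
                chrom=int(chroms[i]) if chroms is not None else int(rng.integers(1, 4)),
                bp=int(rng.integers(0, 100_000)),
                cls="DSB",
                time=0.0 if times is None else float(times[i]),
                track=i,
                pos=pos,
            )
        )
    return records_to_frame(recs)


class TestPureRepairLimit:
    def test_exponential_decay_of_open_breaks(self, rng):
        """With misrepair off, open(t) = N0 e^(-mu t) in expectation."""
        n0, mu, reps = 150, 2.0, 60
        params = RepairParams(repair_rate_per_h=mu, misrepair_scale=0.0)
        t_check = [0.5, 1.0, 2.0]
        opens = np.zeros((reps, len(t_check)))
        frame = _acute_dsbs(n0, rng)
        for r in range(reps):
            res = simulate_repair(frame, params, 4.0, rng, grid_times=[0] + t_check + [4.0])
            for j, t in enumerate(t_check):
                traj = res.trajectory
                opens[r, j] = traj.loc[traj["time_h"] == t, "open"].iloc[0]
        for j, t in enumerate(t_check):
            p = np.exp(-mu * t)
            se = np.sqrt(n0 * p * (1 - p) / reps)
            assert abs(opens[:, j].mean() - n0 * p) < 4 * se + 0.5

    def test_quasi_steady_state_under_constant_production(self, rng):
        """Constant production at rate P with misrepair off settles to
        open ~ P/mu (birth-death balance)."""
        mu, P, T = 2.0, 40.0, 12.0
        params = RepairParams(repair_rate_per_h=mu, misrepair_scale=0.0)
        n = int(P * T)
        times = np.sort(rng.uniform(0, T, n))  # Poisson-process arrivals given count
        frame = _acute_dsbs(n, rng, times=times)
        grid = np.arange(0.0, T + 0.25, 0.25)
        vals = []
        for _ in range(5):
            res = simulate_repair(frame, params, T, rng, grid_times=grid)
            traj = res.trajectory
            sel = traj["time_h"] >= 6.0
            vals.append(traj.loc[sel, "open"].mean())
        assert np.mean(vals) == pytest.approx(P / mu, rel=0.15)


def test_count_conservation_on_every_grid_row(rng):
    params = RepairParams(misrepair_scale=5.0, interaction_sigma_um=3.0)
    frame = _acute_dsbs(80, rng)
    res = simulate_repair(frame, params, 6.0, rng)
    traj = res.trajectory
    assert (
        traj["produced"] == traj["open"] + traj["repaired"] + traj["misrepaired"]
    ).all()
    c = res.state.counts
    assert c["produced"] == c["open"] + c["repaired"] + c["misrepaired"] == 80


def test_status_partner_symmetry(rng):
    params = RepairParams(misrepair_scale=20.0, interaction_sigma_um=5.0)
    frame = _acute_dsbs(40, rng)
    res = simulate_repair(frame, params, 10.0, rng)
    b = res.state.breaks
    mis = b[b["status"] == "misrepaired"]
    for row in mis.itertuples(index=False):
        assert b["partner"].iloc[row.partner] == row.id


class TestMasterEquationOracle:
    @staticmethod
    def _final_misrepair_distribution(weights, mu, eta):
        """Exact distribution of the final misrepaired count for an acute
        set of breaks, via the embedded jump chain over subsets.

        ``weights[i][j]`` is the Gaussian kernel between breaks i and j.
        Time drops out of the absorbing final-count distribution, so the
        recursion over open subsets is exact.
        """
        n = len(weights)

        @lru_cache(maxsize=None)
        def dist(open_set):
            if not open_set:
                return {0: 1.0}
            items = sorted(open_set)
            pair_rates = {}
            for a in range(len(items)):
                for b in range(a + 1, len(items)):
                    i, j = items[a], items[b]
                    pair_rates[(i, j)] = mu * eta * weights[i][j]
            total = mu * len(items) + sum(pair_rates.values())
            out = {}
            for i in items:
                sub = dist(frozenset(open_set - {i}))
                w = mu / total
                for k, p in sub.items():
                    out[k] = out.get(k, 0.0) + w * p
            for (i, j), rate in pair_rates.items():
                sub = dist(frozenset(open_set - {i, j}))
                w = rate / total
                for k, p in sub.items():
                    out[k + 2] = out.get(k + 2, 0.0) + w * p
            return out

        return dist(frozenset(range(n)))

    def test_small_instance_matches_exact_distribution(self, rng):
        """KMC final misrepair counts on a 5-break instance match the
        exhaustive master-equation (jump-chain) oracle in total variation."""
        n, mu, eta, sigma = 5, 1.0, 4.0, 1.0
        frame = _acute_dsbs(n, rng, radius=1.5)
        pos = frame[["x_um", "y_um", "z_um"]].to_numpy()
        weights = [
            [float(np.exp(-np.sum((pos[i] - pos[j]) ** 2) / (2 * sigma**2))) for j in range(n)]
            for i in range(n)
        ]
        exact = self._final_misrepair_distribution(
            tuple(tuple(w) for w in weights), mu, eta
        )
        params = RepairParams(
            repair_rate_per_h=mu, misrepair_scale=eta, interaction_sigma_um=sigma
        )
        reps = 4000
        counts = np.zeros(n + 1)
        for _ in range(reps):
            res = simulate_repair(frame, params, 200.0, rng)
            counts[res.state.counts["misrepaired"]] += 1
        empirical = counts / reps
        tv = 0.5 * sum(
            abs(empirical[k] - exact.get(k, 0.0)) for k in range(n + 1)
        )
        assert tv < 0.05


def test_misrepair_fraction_increases_with_acute_dose(rng):
    params = RepairParams()
    fracs = []
    for n in (25, 75, 225):
        mis = 0
        for _ in range(20):
            frame = _acute_dsbs(n, rng, radius=4.0)
            res = simulate_repair(frame, params, 50.0, rng)
            mis += res.state.counts["misrepaired"]
        fracs.append(mis / (20 * n))
    assert fracs[0] < fracs[1] < fracs[2]


def test_acute_1gy_misrepair_fraction_is_a_few_percent(rng):
    """Default eta: an acute ~1 Gy insult (about 48 DSBs) misrepairs on
    the order of a few percent of its breaks."""
    params = RepairParams()
    mis = tot = 0
    for _ in range(40):
        frame = _acute_dsbs(48, rng, radius=4.6)
        res = simulate_repair(frame, params, 50.0, rng)
        mis += res.state.counts["misrepaired"]
        tot += 48
    assert 0.005 < mis / tot < 0.10


class TestResidualAndAberrations:
    def test_background_added_to_open_count(self, rng):
        params = RepairParams()
        frame = _acute_dsbs(10, rng)
        res = simulate_repair(frame, params, 60.0, rng)
        assert residual_dsbs(res.trajectory, 60.0, params) == pytest.approx(4.8)
        none = RepairParams(background_foci=0.0)
        assert residual_dsbs(res.trajectory, 60.0, none) == 0.0

    def test_no_misrepairs_means_zero_aberrations(self, rng, genome):
        params = RepairParams(misrepair_scale=0.0)
        frame = _acute_dsbs(20, rng)
        res = simulate_repair(frame, params, 30.0, rng)
        ab = classify_aberrations(res.state, genome)
        assert ab == AberrationCounts(0, 0, 0.0)

    def test_inter_intra_split_matches_partner_list(self, rng, genome):
        params = RepairParams(misrepair_scale=50.0, interaction_sigma_um=10.0)
        frame = _acute_dsbs(30, rng, chroms=rng.integers(1, 4, 30))
        res = simulate_repair(frame, params, 100.0, rng)
        ab = classify_aberrations(res.state, genome, lethal_fraction=0.5)
        b = res.state.breaks
        inter = intra = 0
        seen = set()
        for row in b[b["status"] == "misrepaired"].itertuples(index=False):
            key = frozenset((row.id, row.partner))
            if key in seen:
                continue
            seen.add(key)
            if b["chromosome"].iloc[row.partner] == row.chromosome:
                intra += 1
            else:
                inter += 1
        assert (ab.inter_chromosome_misrepairs, ab.intra_chromosome_misrepairs) == (inter, intra)
        assert ab.lethal_estimate == inter * 0.5
        assert ab.inter_chromosome_misrepairs + ab.intra_chromosome_misrepairs > 0

    def test_two_breaks_on_different_chromosomes_inter(self, genome):
        breaks = pd.DataFrame(
            {
                "id": [0, 1],
                "chromosome": [1, 2],
                "bp_position": [10, 20],
                "x_um": [0.0, 0.1],
                "y_um": [0.0, 0.0],
                "z_um": [0.0, 0.0],
                "birth_time_h": [0.0, 0.0],
                "status": pd.Categorical(
                    ["misrepaired", "misrepaired"],
                    categories=["open", "repaired", "misrepaired"],
                ),
                "partner": [1, 0],
            }
        )
        state = RepairState(breaks=breaks, clock_h=1.0)
        ab = classify_aberrations(state, genome)
        assert ab.inter_chromosome_misrepairs == 1
        assert ab.intra_chromosome_misrepairs == 0


def test_unstamped_extended_delivery_rejected(rng):
    frame = _acute_dsbs(5, rng)
    with pytest.raises(ValueError, match="time stamp|assign_time_stamps"):
        simulate_repair(frame, RepairParams(), 48.0, rng, expected_delivery_h=48.0)


def test_hr_and_mmej_pathways_refused():
    with pytest.raises(NotImplementedError):
        RepairParams(hr_enabled=True)
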