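import numpy as np
import pandas as pd
import pytest

from cellsim.genome import GenomeModel, build_default_genome
from cellsim.library import EnergyEnsemble, SETLibrary, YieldCalibration, build_energy_grid


@pytest.fixture(scope="session")
def genome():
    return build_default_genome()


@pytest.fixture(scope="session")
def small_genome():
    """Two-chromosome toy nucleus for fast placement tests."""
    return build_default_genome(
        chromosome_count=2, total_bp=2_000_000, voxel_count=200
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_manual_ensemble(energy_kev, deposits_ev, dsb_counts, model):
    """Handcraft an ensemble with the given per-track deposit and DSB count.

    All DSBs are placed at distinct loci on chromosome 1; used as a fully
    controlled input for estimator and dose-assembly tests.
    """
    deposits = np.asarray(deposits_ev, dtype=float)
    dsb_counts = np.asarray(dsb_counts, dtype=np.int64)
    n = len(deposits)
    total = int(dsb_counts.sum())
    track = np.repeat(np.arange(n, dtype=np.int32), dsb_counts)
    bp = (1000 * np.arange(total, dtype=np.int64)) % model.chromosome_lengths[0]
    chrom = np.ones(total, dtype=np.int32)
    from cellsim.genome import locus_to_position

    pos = locus_to_position(model, chrom, bp) if total else np.empty((0, 3))
    offsets = np.concatenate([[0], np.cumsum(dsb_counts)]).astype(np.int64)
    return EnergyEnsemble(
        energy_kev=float(energy_kev),
        deposit_ev=deposits,
        z_gy=deposits * model.specific_energy_gy_per_ev,
        rec_track=track,
        rec_chrom=chrom,
        rec_bp=bp,
        rec_pos=pos,
        rec_bd=np.zeros(total, dtype=np.int16),
        rec_b1=np.ones(total, dtype=np.int16),
        rec_b2=np.ones(total, dtype=np.int16),
        rec_direct=np.zeros(total, dtype=bool),
        rec_class=np.full(total, 2, dtype=np.int8),
        rec_site_energy_ev=np.full(total, np.nan, dtype=np.float32),
        track_offsets=offsets,
    )


def make_manual_library(ensembles, model, calibration=None):
    return SETLibrary(
        grid=build_energy_grid(),
        calibration=calibration or YieldCalibration(),
        model=model,
        ensembles={float(e.energy_kev): e for e in ensembles},
        seed=0,
        tracks_per_energy=max(e.n_tracks for e in ensembles),
    )
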