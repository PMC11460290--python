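"""Per-cell irradiation history assembly.

One cell's exposure is built in three moves:

1. *Dose-targeted superposition*: draw incident energies from the
   nucleus-entry spectrum, snap each to the nearest library grid energy,
   draw a pre-calculated track uniformly from that ensemble, and accumulate
   specific energy until the running total first crosses the target dose
   (the overshoot is kept and reported as the realized dose).
2. *Cross-track DSB re-evaluation*: single-strand breaks contributed by
   different tracks can cooperate to form a DSB; superposition makes this
   possible even though each track was classified in isolation.
3. *Decay-aware time stamps*: each track receives an arrival time.  The
   default model is the exact nonhomogeneous Poisson process with rate
   N0_dot * e^(-λt) sampled by inversion of the integrated rate; the
   deterministic interval recursion (first interval 1/N0_dot, subsequent
   intervals stretched by the decay factor) is available as a comparison
   mode, in both sign conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import sdd
from .genome import GenomeModel
from .library import SETLibrary
from .lu177 import DoseRateModel, IncidentSpectrum

TIME_MODES = ("nhpp", "recursion", "recursion_literal")


@dataclass(eq=False)
class CellExposure:
    """One cell's assembled dose history.

    ``tracks`` has one row per sampled track in draw order (track_id,
    energy_kev, z_gy, time_h; time is NaN until stamped); ``merged_records``
    is the superimposed damage in the SDD frame schema with track ids
    matching ``tracks``.
    """

    target_dose_gy: float
    realized_dose_gy: float
    tracks: pd.DataFrame
    merged_records: pd.DataFrame
    time_stamped: bool = False

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    @property
    def dsb_count(self) -> int:
        return int((self.merged_records["classification"] == "DSB").sum())


def assemble_cell_sdd(
    library: SETLibrary,
    incident: IncidentSpectrum,
    target_dose_gy: float,
    rng: np.random.Generator,
    batch_size: int = 8192,
) -> CellExposure:
    """Sample and superimpose library tracks until the target dose is crossed.

    Sampling stops at the first crossing of ``target_dose_gy``; the realized
    dose therefore exceeds the target by less than one track's specific
    energy.  Merged records get fresh sequential track ids in draw order.
    """
    if target_dose_gy <= 0:
        raise ValueError("target dose must be positive")
    flat = library.flat_view()
    energies = flat["energies"]
    n_per = flat["n_tracks"]
    starts = flat["starts"]
    z_flat = flat["z_flat"]
    if (n_per == 0).any():
        bad = energies[np.argmax(n_per == 0)]
        raise ValueError(f"empty ensemble at {bad} keV")
    mids = 0.5 * (energies[:-1] + energies[1:])

    g_parts, t_parts, z_parts = [], [], []
    total = 0.0
    while True:
        e_in = incident.sample(rng, size=batch_size)
        gidx = np.searchsorted(mids, e_in)
        tidx = rng.integers(0, n_per[gidx])
        z = z_flat[starts[gidx] + tidx]
        cum = total + np.cumsum(z)
        crossed = np.flatnonzero(cum >= target_dose_gy)
        if len(crossed):
            stop = int(crossed[0]) + 1
            g_parts.append(gidx[:stop])
            t_parts.append(tidx[:stop])
            z_parts.append(z[:stop])
            total = float(cum[stop - 1])
            break
        g_parts.append(gidx)
        t_parts.append(tidx)
        z_parts.append(z)
        total = float(cum[-1])

    gidx = np.concatenate(g_parts)
    tidx = np.concatenate(t_parts)
    z = np.concatenate(z_parts)
    n = len(gidx)

    tracks = pd.DataFrame(
        {
            "track_id": np.arange(n, dtype=np.int64),
            "energy_kev": energies[gidx],
            "z_gy": z,
            "time_h": np.full(n, np.nan),
        }
    )

    # Gather damage records per ensemble (CSR), then restore draw order.
    cols: dict[str, list] = {k: [] for k in (
        "track_id", "chromosome", "bp_position", "x", "y", "z",
        "bd", "b1", "b2", "direct", "cls",
    )}
    draw_pos = np.arange(n, dtype=np.int64)
    for g in np.unique(gidx):
        ens = library.ensemble(float(energies[g]))
        sel = gidx == g
        tids = tidx[sel]
        new_ids = draw_pos[sel]
        st = ens.track_offsets[tids]
        en = ens.track_offsets[tids + 1]
        lengths = (en - st).astype(np.int64)
        tot = int(lengths.sum())
        if tot == 0:
            continue
        cum = np.cumsum(lengths)
        ridx = np.arange(tot) - np.repeat(cum - lengths, lengths) + np.repeat(st, lengths)
        cols["track_id"].append(np.repeat(new_ids, lengths))
        cols["chromosome"].append(ens.rec_chrom[ridx].astype(np.int64))
        cols["bp_position"].append(ens.rec_bp[ridx])
        cols["x"].append(ens.rec_pos[ridx, 0])
        cols["y"].append(ens.rec_pos[ridx, 1])
        cols["z"].append(ens.rec_pos[ridx, 2])
        cols["bd"].append(ens.rec_bd[ridx].astype(np.int64))
        cols["b1"].append(ens.rec_b1[ridx].astype(np.int64))
        cols["b2"].append(ens.rec_b2[ridx].astype(np.int64))
        cols["direct"].append(ens.rec_direct[ridx])
        cols["cls"].append(ens.rec_class[ridx])

    if cols["track_id"]:
        cat = {k: np.concatenate(v) for k, v in cols.items()}
        order = np.argsort(cat["track_id"], kind="stable")
        merged = pd.DataFrame(
            {
                "track_id": cat["track_id"][order],
                "time_h": np.zeros(len(order)),
                "chromosome": cat["chromosome"][order],
                "bp_position": cat["bp_position"][order],
                "x_um": cat["x"][order],
                "y_um": cat["y"][order],
                "z_um": cat["z"][order],
                "base_damages": cat["bd"][order],
                "breaks_strand1": cat["b1"][order],
                "breaks_strand2": cat["b2"][order],
                "cause": pd.Categorical.from_codes(
                    np.where(cat["direct"][order], 0, 1), categories=list(sdd.CAUSES)
                ),
                "classification": pd.Categorical.from_codes(
                    cat["cls"][order], categories=list(sdd.CLASSIFICATIONS)
                ),
            }
        )
    else:
        merged = sdd.empty_records_frame()

    return CellExposure(
        target_dose_gy=float(target_dose_gy),
        realized_dose_gy=total,
        tracks=tracks,
        merged_records=merged,
    )


def recombine_cross_track_dsb(
    merged_records: pd.DataFrame,
    genome: GenomeModel,
    max_sep: int = 10,
) -> pd.DataFrame:
    """Re-pair opposite-strand SSBs from *different* tracks into DSBs.

    Within-track pairing already happened at generation time, so only
    cross-track cooperation remains.  Idempotent; strand-break totals are
    conserved exactly.
    """
    return sdd.pair_ssb_records(merged_records, max_sep=max_sep, track_scope="different")


def _nhpp_arrival_times(
    n: int, rate0_per_h: float, lam_per_h: float, rng: np.random.Generator
) -> np.ndarray:
    """First ``n`` arrivals of an NHPP with rate rate0 * e^(-λt), by inversion."""
    cum = np.cumsum(rng.exponential(1.0, n))
    if lam_per_h == 0.0:
        return cum / rate0_per_h
    limit = rate0_per_h / lam_per_h  # finite total expectation of the process
    if cum[-1] >= limit:
        achievable = int(np.searchsorted(cum, limit))
        raise ValueError(
            f"requested {n} tracks but the decaying process can only deliver "
            f"about {achievable} (N0/lambda = {limit:.1f})"
        )
    return -np.log1p(-lam_per_h * cum / rate0_per_h) / lam_per_h


def _recursion_arrival_times(n: int, rate0_per_h: float, lam_per_h: float, sign: float) -> np.ndarray:
    """Deterministic interval recursion: TS1 = 1/N0, next interval scaled by e^(±λ·interval)."""
    intervals = np.empty(n)
    dt = 1.0 / rate0_per_h
    for i in range(n):
        intervals[i] = dt
        dt = dt * np.exp(sign * lam_per_h * dt)
    return np.cumsum(intervals)


def assign_time_stamps(
    exposure: CellExposure,
    dose_rate_model: DoseRateModel,
    mode: str = "nhpp",
    rng: np.random.Generator | None = None,
) -> CellExposure:
    """Stamp every track (and its records) with a decay-aware arrival time.

    Modes: ``nhpp`` (default, exact nonhomogeneous-Poisson inversion),
    ``recursion`` (deterministic intervals growing as the activity
    decays) and ``recursion_literal`` (the same recursion with the
    opposite sign, under which intervals shrink).
    """
    if mode not in TIME_MODES:
        raise ValueError(f"mode must be one of {TIME_MODES}")
    n = exposure.n_tracks
    rate0 = dose_rate_model.initial_track_rate_per_h
    if rate0 <= 0:
        raise ValueError("initial track rate must be positive")
    lam = dose_rate_model.decay_constant_per_h
    if n == 0:
        return replace(exposure, time_stamped=True)
    if mode == "nhpp":
        if rng is None:
            raise ValueError("nhpp mode needs an rng")
        times = _nhpp_arrival_times(n, rate0, lam, rng)
    else:
        times = _recursion_arrival_times(n, rate0, lam, +1.0 if mode == "recursion" else -1.0)

    tracks = exposure.tracks.copy()
    tracks["time_h"] = times
    merged = exposure.merged_records.copy()
    if not merged.empty:
        merged["time_h"] = times[merged["track_id"].to_numpy()]
    return replace(exposure, tracks=tracks, merged_records=merged, time_stamped=True)


def exposure_header(genome: GenomeModel, time_stamped: bool, description: str = "") -> sdd.SDDHeader:
    """SDD header matching a cell exposure built on the given genome."""
    return sdd.SDDHeader(
        source_description=description or "superimposed cell exposure",
        scoring_volume_radius_um=genome.nucleus_radius_um,
        chromosome_count=genome.chromosome_count,
        chromosome_lengths=tuple(int(v) for v in genome.chromosome_lengths),
        time_field_present=time_stamped,
    )


def write_exposure(exposure: CellExposure, genome: GenomeModel, destination) -> None:
    """Write the (optionally time-stamped) cell SDD file."""
    header = exposure_header(genome, exposure.time_stamped)
    sdd.write_sdd(header, exposure.merged_records, destination)
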