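"""Population orchestration: many independent cell replicates.

Runs the full pipeline per cell — decay-integrated target dose, dose-
targeted track superposition, cross-track DSB re-evaluation, decay-aware
time stamps, NHEJ kinetics — with a strict seed discipline: one base seed;
cell *i* uses generator seed ``base_seed + i``, so any cell can be replayed
in isolation and populations are embarrassingly parallel in principle.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import build_default_genome
from .irradiation import (
    assemble_cell_sdd,
    assign_time_stamps,
    recombine_cross_track_dsb,
    write_exposure,
)
from .library import SETLibrary, YieldCalibration, build_library, load_library
from .lu177 import (
    BetaSpectrum,
    InVitroGeometry,
    IncidentSpectrum,
    cumulative_dose,
    dose_rate_model_for_activity,
    incident_spectrum,
)
from .repair import RepairParams, classify_aberrations, residual_dsbs, simulate_repair

_ENDPOINT_COLUMNS = [
    "cell",
    "seed",
    "target_dose_gy",
    "realized_dose_gy",
    "n_tracks",
    "produced_dsbs",
    "repaired",
    "misrepaired",
    "resolved_fraction",
    "production_rate_per_h",
    "residual_24h",
    "residual_48h",
    "residual_72h",
    "inter_misrepairs",
    "intra_misrepairs",
    "lethal_estimate",
]


@dataclass
class SimulationConfig:
    """Everything needed to reproduce a population run."""

    activity_mbq_per_ml: float = 10.0
    incubation_hours: float = 48.0
    n_cells: int = 50
    base_seed: int = 0
    tracks_per_energy: int = 500
    incident_samples: int = 100_000
    calibration: YieldCalibration = field(default_factory=YieldCalibration)
    repair: RepairParams = field(default_factory=RepairParams)
    time_mode: str = "nhpp"
    cross_track_recombination: bool = True
    report_times: tuple = (24.0, 48.0, 72.0)
    library_dir: str | None = None
    output_dir: str | None = None
    write_cell_sdd: bool = False

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.incubation_hours <= 0:
            raise ValueError("incubation_hours must be positive")


@dataclass(eq=False)
class PopulationSummary:
    """Per-cell endpoint table plus population means and standard errors."""

    config: SimulationConfig
    per_cell: pd.DataFrame
    dose_rate_model: object

    def aggregate(self) -> pd.DataFrame:
        numeric = self.per_cell.drop(columns=["cell", "seed"])
        mean = numeric.mean()
        se = numeric.std(ddof=1) / np.sqrt(len(numeric)) if len(numeric) > 1 else numeric.mean() * 0.0
        return pd.DataFrame({"mean": mean, "se": se})

    @property
    def mean_production_rate_per_h(self) -> float:
        return float(self.per_cell["production_rate_per_h"].mean())

    @property
    def resolved_fraction(self) -> float:
        """Population-pooled fraction of produced DSBs resolved by the end."""
        produced = self.per_cell["produced_dsbs"].sum()
        resolved = (self.per_cell["repaired"] + self.per_cell["misrepaired"]).sum()
        return float(resolved / produced) if produced else float("nan")


def _prepare_inputs(config: SimulationConfig, library, incident):
    if library is None:
        if config.library_dir:
            library = load_library(config.library_dir)
        else:
            library = build_library(
                calibration=config.calibration,
                tracks_per_energy=config.tracks_per_energy,
                seed=config.base_seed,
            )
    if incident is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.base_seed, 982451653]))
        incident = incident_spectrum(
            BetaSpectrum(), InVitroGeometry(), config.incident_samples, rng
        )
    return library, incident


def run_population(
    config: SimulationConfig,
    library: SETLibrary | None = None,
    incident: IncidentSpectrum | None = None,
    progress: bool = False,
) -> PopulationSummary:
    """Run ``n_cells`` independent replicates and aggregate their endpoints.

    Deterministic given the config (and any supplied library/incident
    spectrum).  If an output directory is configured, per-cell rows are
    flushed as they complete, so a failed run keeps its partial results;
    a stage failure aborts with the cell index and stage name.
    """
    library, incident = _prepare_inputs(config, library, incident)
    genome = library.model
    dose_model = dose_rate_model_for_activity(
        config.activity_mbq_per_ml, library, incident
    )
    hours = float(config.incubation_hours)
    target_dose = cumulative_dose(dose_model, hours)

    out_dir = Path(config.output_dir) if config.output_dir else None
    writer = None
    fh = None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        fh = open(out_dir / "cells.csv", "w", newline="", encoding="utf-8")
        writer = csv.writer(fh)
        writer.writerow(_ENDPOINT_COLUMNS)

    rows = []
    try:
        for i in range(config.n_cells):
            seed = config.base_seed + i
            rng = np.random.default_rng(seed)
            stage = "assemble"
            try:
                exposure = assemble_cell_sdd(library, incident, target_dose, rng)
                if config.cross_track_recombination:
                    stage = "recombine"
                    exposure.merged_records = recombine_cross_track_dsb(
                        exposure.merged_records, genome
                    )
                stage = "time_stamps"
                exposure = assign_time_stamps(
                    exposure, dose_model, mode=config.time_mode, rng=rng
                )
                stage = "repair"
                last_arrival = (
                    float(exposure.tracks["time_h"].iloc[-1]) if exposure.n_tracks else 0.0
                )
                horizon = max(hours, last_arrival)
                grid = np.unique(
                    np.concatenate(
                        [
                            np.arange(0.0, np.floor(horizon) + 1),
                            [t for t in config.report_times if t <= horizon],
                            [horizon],
                        ]
                    )
                )
                result = simulate_repair(
                    exposure.merged_records,
                    config.repair,
                    horizon,
                    rng,
                    grid_times=grid,
                    expected_delivery_h=hours,
                )
                stage = "endpoints"
                counts = result.state.counts
                produced = counts["produced"]
                resolved = counts["repaired"] + counts["misrepaired"]
                window = min(24.0, hours)
                births = result.state.breaks["birth_time_h"].to_numpy()
                rate = float((births <= window).sum() / window)
                residuals = {}
                for t in (24.0, 48.0, 72.0):
                    key = f"residual_{int(t)}h"
                    residuals[key] = (
                        residual_dsbs(result.trajectory, t, config.repair)
                        if t <= horizon and produced
                        else (config.repair.background_foci if t <= horizon else np.nan)
                    )
                ab = classify_aberrations(
                    result.state, genome, config.repair.lethal_fraction
                )
                if config.write_cell_sdd and out_dir is not None:
                    write_exposure(exposure, genome, out_dir / f"cell_{i:04d}.sdd")
            except Exception as exc:
                raise RuntimeError(f"cell {i} failed in stage '{stage}': {exc}") from exc

            row = {
                "cell": i,
                "seed": seed,
                "target_dose_gy": target_dose,
                "realized_dose_gy": exposure.realized_dose_gy,
                "n_tracks": exposure.n_tracks,
                "produced_dsbs": produced,
                "repaired": counts["repaired"],
                "misrepaired": counts["misrepaired"],
                "resolved_fraction": resolved / produced if produced else np.nan,
                "production_rate_per_h": rate,
                **residuals,
                "inter_misrepairs": ab.inter_chromosome_misrepairs,
                "intra_misrepairs": ab.intra_chromosome_misrepairs,
                "lethal_estimate": ab.lethal_estimate,
            }
            rows.append(row)
            if writer is not None:
                writer.writerow([row[c] for c in _ENDPOINT_COLUMNS])
                fh.flush()
            if progress:
                print(f"cell {i + 1}/{config.n_cells}: "
                      f"{produced} DSBs, {row['resolved_fraction']:.3f} resolved")
    finally:
        if fh is not None:
            fh.close()

    per_cell = pd.DataFrame(rows, columns=_ENDPOINT_COLUMNS)
    summary = PopulationSummary(
        config=config, per_cell=per_cell, dose_rate_model=dose_model
    )
    if out_dir is not None:
        summary.aggregate().to_csv(out_dir / "summary.csv")
    return summary


def convergence_report(
    summary: PopulationSummary,
    tolerance: float = 0.01,
    endpoints=("produced_dsbs", "resolved_fraction", "misrepaired"),
) -> tuple[bool, dict]:
    """Check whether every tracked endpoint's relative SE is below tolerance.

    Returns ``(converged, {endpoint: relative_se})``; an endpoint with zero
    mean and zero spread counts as converged.
    """
    if len(summary.per_cell) < 2:
        raise ValueError("need at least 2 cells to assess convergence")
    rel = {}
    for name in endpoints:
        vals = summary.per_cell[name].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        mean = vals.mean()
        if se == 0.0:
            rel[name] = 0.0
        elif mean == 0.0:
            rel[name] = np.inf
        else:
            rel[name] = float(abs(se / mean))
    converged = all(v < tolerance for v in rel.values())
    return converged, rel
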