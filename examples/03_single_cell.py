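"""One cell, end to end: superposition, time stamps, repair, SDD file.

Assembles a single cell's 48 h exposure at 10 MBq/ml from a pre-calculated
track library, re-evaluates cross-track DSBs, stamps each track with a
decay-aware arrival time, writes the time-stamped SDD file, and runs the
NHEJ kinetics to the end of incubation.
"""

import numpy as np

from cellsim import (
    BetaSpectrum,
    InVitroGeometry,
    RepairParams,
    assemble_cell_sdd,
    assign_time_stamps,
    build_default_genome,
    build_library,
    cumulative_dose,
    dose_rate_model_for_activity,
    incident_spectrum,
    recombine_cross_track_dsb,
    residual_dsbs,
    simulate_repair,
    write_exposure,
)

rng = np.random.default_rng(42)
genome = build_default_genome()
library = build_library(tracks_per_energy=400, seed=42, model=genome)
incident = incident_spectrum(BetaSpectrum(), InVitroGeometry(), 60_000, rng)
dose_model = dose_rate_model_for_activity(10.0, library, incident)

target = cumulative_dose(dose_model, 48.0)
exposure = assemble_cell_sdd(library, incident, target, rng)
exposure.merged_records = recombine_cross_track_dsb(exposure.merged_records, genome)
exposure = assign_time_stamps(exposure, dose_model, rng=rng)
print(f"target dose {target:.2f} Gy -> realized {exposure.realized_dose_gy:.2f} Gy "
      f"from {exposure.n_tracks} tracks")
print(f"damage records: {len(exposure.merged_records)} "
      f"({exposure.dsb_count} DSBs)")

write_exposure(exposure, genome, "scratch_cell.sdd")
print("time-stamped SDD file written to scratch_cell.sdd")

params = RepairParams()
horizon = max(48.0, float(exposure.tracks["time_h"].iloc[-1]))
result = simulate_repair(exposure.merged_records, params, horizon, rng)
counts = result.state.counts
res48 = residual_dsbs(result.trajectory, 48.0, params)
print(f"by 48 h: {counts['repaired']} repaired, {counts['misrepaired']} misrepaired, "
      f"{counts['open']} open")
print(f"residual DSBs at 48 h (incl. {params.background_foci} background foci): "
      f"{res48:.1f}")
print("\nAlthough ~1400 DSBs are produced, fast NHEJ keeps only ~10 open at any")
print("time, so the residual count stays near the experimental foci background.")
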