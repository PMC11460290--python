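# Methods

This note documents the models inside `cellsim`, the choices made where the
design was genuinely open, and what the package's tests do and do not
demonstrate about real data.

## Pipeline

Each simulated cell passes through three stages:

1. **Dose-targeted superposition.** Incident electron energies are drawn
   from the nucleus-entry spectrum, snapped to the nearest library grid
   energy, and a pre-calculated track is drawn uniformly from that energy's
   ensemble. Specific energies accumulate until the running total first
   crosses the target dose; the overshoot (always less than one track's
   specific energy) is kept and reported as the realized dose. Merged
   records receive fresh, dense track ids in draw order.
2. **Cross-track DSB re-evaluation.** Tracks are classified in isolation
   when generated, so opposite-strand single-strand breaks from *different*
   tracks that land within 10 bp are re-paired into DSBs after
   superposition. At the doses studied this contributes only a few DSBs per
   cell; a flag disables it.
3. **Decay-aware time stamps and repair.** Track arrival times follow a
   nonhomogeneous Poisson process (below); every record inherits its
   track's time, and the time-stamped DSBs drive the NHEJ kinetics.

Populations repeat this per cell with seed `base_seed + i`, making every
cell replayable in isolation.

## Nucleus and genome model

A G0/G1 fibroblast-like nucleus: water sphere of diameter 9.3 µm
(mass 4.21e-13 kg, so 1 MeV deposited ≈ 0.38 Gy of specific energy),
46 chromosomes, 6.08 Gbp, 14,328 voxels. Constants describing chromatin
fibers (15,150 bp, 51 nucleosomes, 120 nm × 37.1 nm) are carried as
metadata; the simulation never transports particles through chromatin
geometry.

Choices made here:

* **Chromosome lengths** are an equal integer partition of 6.08 Gbp; real
  karyotype lengths are not needed because damage placement is uniform over
  the genome and only chromosome *identity* enters aberration bookkeeping.
* **Territories** are contiguous blocks of lattice voxels (lexicographic
  sweep of the sphere). Space only enters the model through misrepair
  distances, for which territory-scale positions suffice; no attempt is
  made to reproduce space-filling-curve chromatin folding.
* **Locus→position map**: a locus indexes a voxel within its territory and
  receives a sub-voxel jitter hashed deterministically from (chromosome,
  bp), so positions are reproducible without storing coordinates per bp.
  Boundary voxels are radially clipped to keep every position inside the
  nucleus.

## Synthetic track library

Production libraries of single-electron-track SDD data come from full
track-structure physics/chemistry codes. This package generates them with a
calibrated stochastic emulator instead, preserving every downstream
contract (SDD records in, endpoint kinetics out) at desk scale:

* **Energy grid**: 1–20 keV in 1 keV steps, to 100 keV in 5 keV steps, to
  500 keV in 10 keV steps, to 1 MeV in 25 keV steps — 96 energies.
* **Per-track deposit**: mean = min(E, S(E)·4r/3) with S from an embedded
  22-point ESTAR-like collision stopping-power table for water (log-log
  interpolated) and 4r/3 = 6.2 µm the mean isotropic chord of the nucleus
  sphere. Around that mean, deposits are gamma-distributed with shape 2
  (configurable), clipped at the incident energy; energies whose chord mean
  reaches the incident energy deposit it in full (the track stops inside).
  The deposit therefore *rises* with energy through the full-absorption
  regime and then *decreases* with the stopping power toward a high-energy
  plateau — the physical behaviour for a fixed-size target.
* **Lesion counts**: DSBs are Poisson with mean z·y(E); y(E) is piecewise
  linear through (1, 80), (10, 80), (40, 47.5), (1000, 47.5) keV→DSB/Gy.
  Behaviour below the 10 keV peak is held at the peak (not constrained by
  the validation data; configurable). SSB and base-damage counts use
  configurable ratios SSB:DSB = 25 and BD:SSB = 3 — literature-typical
  values, explicitly assumptions, as the benchmarks constrain only DSBs.
* **Provenance labels**: each lesion is direct with probability 0.3 (direct
  sites carry an energy drawn above the 17.5 eV threshold) or
  •OH-mediated indirect otherwise; the 17.5 eV and 0.4 constants are
  recorded in every SDD header. Their observable consequences — the yield
  curve and the direct fraction — are the calibration targets.
* **Classification**: a DSB is two opposite-strand breaks within 10 bp
  (inclusive). One greedy left-to-right pairing routine implements this
  everywhere (generation, file validation, cross-track re-evaluation), so
  brute-force re-classification of any generated track reproduces its
  stored classifications exactly. A DSB is stored as a single damage-site
  record; the intra-pair bp offset is below the dialect's resolution.

Estimators: yield = ΣDSB/Σz over an ensemble with a track-bootstrap
standard error; an ensemble holding ~10,000 DSBs estimates its yield to
≈1% relative SE.

## SDD dialect

Header of `key: value` lines closed by `***EndOfHeader***` (unknown keys
preserved verbatim), then one record per line:
`track_id,time_h,chromosome,bp_position,x;y;z,bd;sb1;sb2,cause,class`.
Chromosomes are 1-based, bp offsets 0-based, times in hours, positions in
µm from the nucleus centre. Floats serialize with shortest round-trip
repr, so write→read→write is byte-identical — the property the round-trip
tests pin down. The reader rejects malformed lines with their line number
rather than skipping them. Only this dialect (plus its own output) is
supported; parsing arbitrary third-party SDD files is out of scope.

## ¹⁷⁷Lu source

* **Beta spectra**: allowed shape p·W·(Q−E)² per branch, branches
  (498 keV, 0.79), (385 keV, 0.09), (176 keV, 0.12), half-life 6.647 d —
  RADAR/ICRP-107-typical constants. No Coulomb correction (the shape is
  used only to seed the degraded arrival spectrum); Auger electrons and
  photons are excluded (negligible yield / no nucleus dose here).
* **Incident spectrum**: emission points uniform in the medium+cytoplasm
  volume (outer radius 1.8 mm ≈ the 498 keV range), isotropic directions;
  an electron whose straight path meets the nucleus arrives with the
  residual energy left after continuous slowing down along the path
  (ranges integrated from the same stopping-power table). Importance
  sampling (radius uniform, direction forced into the nucleus cone, with
  analytic weights) makes this tractable; the weighted spectrum was
  verified against a brute-force analogue sampler.
* **Dose rate**: the 0.67 Gy/h at 10 MBq/ml anchor is a calibrated
  constant (it already contains the one-half flask-attachment exposure
  factor, applied exactly once); activity scales it linearly. Cumulative
  dose is Ḋ₀(1−e^{−λT})/λ. The track-rate constant k is the reciprocal of
  the spectrum-weighted mean specific energy per track; Ṅ₀ = kḊ₀ is
  ≈ 1,040 tracks/Gy × 0.67 Gy/h ≈ 700 tracks/h at 10 MBq/ml.
* **Known bias**: straight-path slowing-down transport has no scattering
  or straggling, so the arrival spectrum carries more weight below
  ~40 keV than full transport would. Since those arrivals combine larger
  specific energy with higher DSB yield, the spectrum-weighted effective
  yield comes out near 51 DSB/Gy rather than the ~48 the plateau would
  give, and the simulated DSB production rate at 10 MBq/ml
  (~32 DSB/cell/h over the first 24 h) sits correspondingly high. This is
  a property of the transport surrogate, not of the superposition method.

## Time stamps

Default: exact inversion of the integrated rate Λ(t) = Ṅ₀(1−e^{−λt})/λ —
unit-exponential cumulative sums E_i map to arrivals
t_i = −ln(1−λE_i/Ṅ₀)/λ. The process can deliver at most Ṅ₀/λ tracks in
expectation; requesting more raises an error naming the achievable count.
λ = 0 reduces exactly to a homogeneous Poisson process. A deterministic
interval recursion (first interval 1/Ṅ₀, each subsequent interval scaled
by e^{+λ·interval}) is available for comparison; with the opposite
(literal) sign the intervals *shrink* while the activity decays, which
contradicts the decaying dose rate — both sign conventions are exposed,
the growing-interval form being the default of the recursion mode.

## NHEJ kinetics

Open DSBs rejoin correctly at rate μ; each unordered pair of coexisting
open DSBs misrejoins at rate μ·η·exp(−r²/2σ²). Events are simulated by
exact exponential competition (kinetic Monte Carlo); the reporting grid is
independent of event times, and produced = open + repaired + misrepaired
holds exactly at every reported time.

Defaults and their reasoning:

* μ = 2.0 h⁻¹ — fast-NHEJ half-time ≈ 21 min, the G0/G1 repair scale.
* σ = 0.5 µm — chromosome-territory interaction range.
* η = 0.15 — set so that an acute ~1 Gy insult (≈48 DSBs) misrepairs a few
  percent of its breaks, the literature scale for this endpoint. η was
  fixed from this acute-dose consideration, not fitted to any time course.
* background_foci = 4.8 per cell — experimental γH2AX background added to
  residual counts.
* Misrepair pairs whole DSBs, not individual break ends — a documented
  simplification; partner bookkeeping is symmetric, and misrepaired pairs
  split into inter-/intra-chromosome exchanges with a flat, explicitly
  assumed lethality fraction (0.5) on inter-chromosome events.
* HR and MMEJ are deliberately absent (NHEJ dominates in G0/G1); enabling
  them raises `NotImplementedError` rather than silently ignoring flags.

Numerical notes: pairwise kernels are recomputed per event (the open set
stays ~15 breaks under protracted delivery, so exactness is cheaper than
bookkeeping); simultaneous arrivals from one track are inserted
back-to-back; trajectories record right-continuously at grid times.

## Problem sizes

Desk-scale defaults were chosen so a laptop-class single core runs the
whole pipeline comfortably: libraries of 500–1,000 tracks per energy
(hundreds of thousands at production scale would only narrow ensemble
statistics), 80,000 importance-sampled emissions for the incident
spectrum, and 50-cell populations for the in-vitro benchmark (≈30,000
tracks and ≈150,000 damage records per 48 h cell; ≈10 s per 50-cell
population). Estimator ensembles are sized by their statistical targets,
e.g. ~33,000 tracks at 10 keV for a ~10,000-DSB yield estimate.

## What the synthetic generator does and does not emulate

The generator reproduces the *statistical* structure the downstream method
consumes: energy-resolved DSB yields, direct/indirect labels, lesion
ratios, genomic uniformity, Poisson track-level dispersion, and specific
energies consistent with nucleus-crossing electrons. It does not emulate
event-by-event energy-deposition clustering, chemical-stage radical
diffusion, damage complexity classes, or spatial correlation of lesions
along a track (each lesion is placed at an independent uniform locus).
Consequently, passing tests demonstrate correctness of the superposition,
time-stamping and kinetic machinery under calibrated damage statistics —
not fidelity of any individual track's microdosimetric pattern.

## Known limitations

* Straight-path CSDA incident transport (see the bias note above).
* Misrepair kinetics use three exposed parameters with literature-scale
  defaults; absolute residual/misrepair magnitudes are approximate, and
  comparisons against measured foci time courses should treat them as
  order-of-magnitude.
* Spatial superposition is genomic/territorial only; tracks do not carry
  their own spatial geometry into the merged cell.
* Cell-cycle progression, HR/MMEJ pathways, radioactive daughters and
  photon/Auger dose are out of scope.
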