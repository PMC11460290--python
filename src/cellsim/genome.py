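"""Reference G0/G1 nucleus and genome model.

The damage-induction and repair stages never re-transport particles through
explicit chromatin geometry; the nucleus enters the simulation only through

* its mass (converting per-track energy deposits into specific energy, Gy),
* chromosome bookkeeping (uniform genomic placement of lesions), and
* a coarse locus -> space map (misrepair interaction distances).

The model is a 9.3 um diameter water sphere containing 46 chromosomes and
6.08 Gbp of DNA arranged in 14,328 chromatin-fiber voxels.  Chromosome
territories are contiguous blocks of lattice voxels; within a territory, loci
map deterministically to a voxel plus a hashed sub-voxel jitter, so positions
are reproducible without storing per-bp coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WATER_DENSITY_KG_M3 = 1000.0
EV_TO_JOULE = 1.602176634e-19

# Nominal G0/G1 fibroblast nucleus constants (kept as metadata even where the
# simulation does not consume them, e.g. fiber geometry).
NUCLEUS_DIAMETER_UM = 9.3
CHROMOSOME_COUNT = 46
TOTAL_BP = 6_080_000_000
VOXEL_COUNT = 14_328
FIBER_BP = 15_150
FIBER_LENGTH_NM = 120.0
FIBER_RADIUS_NM = 37.1
NUCLEOSOMES_PER_FIBER = 51


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finalizer on uint64 arrays (stateless, reproducible)."""
    x = x.astype(np.uint64, copy=True)
    x += np.uint64(0x9E3779B97F4A7C15)
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))


@dataclass(frozen=True, eq=False)
class GenomeModel:
    """Voxelized spherical nucleus with contiguous chromosome territories.

    Attributes
    ----------
    chromosome_lengths
        bp per chromosome (1-based chromosome ids elsewhere); sums to
        ``total_bp`` exactly.
    voxel_centers
        ``(n_voxels, 3)`` lattice voxel centers, um, nucleus-centered.
    chromosome_voxel_start
        ``(n_chromosomes + 1,)`` slice bounds into ``voxel_centers`` giving
        each chromosome's contiguous territory.
    """

    nucleus_diameter_um: float
    chromosome_lengths: np.ndarray
    voxel_centers: np.ndarray
    chromosome_voxel_start: np.ndarray
    voxel_spacing_um: float
    fiber_bp: int = FIBER_BP
    fiber_length_nm: float = FIBER_LENGTH_NM
    fiber_radius_nm: float = FIBER_RADIUS_NM
    nucleosomes_per_fiber: int = NUCLEOSOMES_PER_FIBER
    _cum_lengths: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        lengths = np.asarray(self.chromosome_lengths, dtype=np.int64)
        if (lengths <= 0).any():
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(self, "chromosome_lengths", lengths)
        object.__setattr__(self, "_cum_lengths", np.cumsum(lengths))
        r = self.nucleus_radius_um
        if (np.linalg.norm(self.voxel_centers, axis=1) > r).any():
            raise ValueError("voxel centers must lie inside the nucleus sphere")

    # -- derived constants -------------------------------------------------
    @property
    def nucleus_radius_um(self) -> float:
        return self.nucleus_diameter_um / 2.0

    @property
    def chromosome_count(self) -> int:
        return len(self.chromosome_lengths)

    @property
    def total_bp(self) -> int:
        return int(self._cum_lengths[-1])

    @property
    def voxel_count(self) -> int:
        return len(self.voxel_centers)

    @property
    def nucleus_volume_m3(self) -> float:
        return (np.pi / 6.0) * (self.nucleus_diameter_um * 1e-6) ** 3

    @property
    def nucleus_mass_kg(self) -> float:
        """Mass of the water-equivalent nucleus sphere."""
        return WATER_DENSITY_KG_M3 * self.nucleus_volume_m3

    @property
    def specific_energy_gy_per_ev(self) -> float:
        """Specific energy z per eV deposited in the nucleus (Gy/eV)."""
        return EV_TO_JOULE / self.nucleus_mass_kg


def build_default_genome(
    nucleus_diameter_um: float = NUCLEUS_DIAMETER_UM,
    chromosome_count: int = CHROMOSOME_COUNT,
    total_bp: int = TOTAL_BP,
    voxel_count: int = VOXEL_COUNT,
) -> GenomeModel:
    """Construct the default 46-chromosome, 6.08 Gbp, 14,328-voxel nucleus.

    Chromosome lengths are an equal integer partition of ``total_bp`` (real
    karyotype lengths are not needed by the method; the partition is exact so
    genome-wide sampling stays uniform).  Voxels are the ``voxel_count``
    lattice points closest to the center of a cubic lattice clipped to the
    sphere, ordered lexicographically and split into contiguous chromosome
    territories proportional to chromosome length.
    """
    base, extra = divmod(total_bp, chromosome_count)
    lengths = np.full(chromosome_count, base, dtype=np.int64)
    lengths[:extra] += 1

    radius = nucleus_diameter_um / 2.0
    # Lattice spacing slightly below the equal-volume value so that at least
    # voxel_count points fall strictly inside the sphere.
    nominal = ((np.pi / 6.0) * nucleus_diameter_um**3 / voxel_count) ** (1.0 / 3.0)
    spacing = 0.97 * nominal
    while True:  # shrink until the clipped lattice holds enough points
        m = int(np.ceil(radius / spacing))
        axis = np.arange(-m, m + 1) * spacing
        gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        d2 = np.einsum("ij,ij->i", pts, pts)
        inside = d2 < radius**2
        if inside.sum() >= voxel_count:
            pts, d2 = pts[inside], d2[inside]
            break
        spacing *= 0.9
    del gx, gy, gz
    # Keep the voxel_count closest points; deterministic lexicographic tie-break.
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], d2))
    pts = pts[order[:voxel_count]]
    # Territory layout: lexicographic sweep gives contiguous slabs.
    pts = pts[np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))]

    cum_bp = np.concatenate([[0], np.cumsum(lengths)])
    starts = np.round(cum_bp / total_bp * voxel_count).astype(np.int64)
    starts[-1] = voxel_count

    return GenomeModel(
        nucleus_diameter_um=nucleus_diameter_um,
        chromosome_lengths=lengths,
        voxel_centers=pts,
        chromosome_voxel_start=starts,
        voxel_spacing_um=spacing,
    )


def sample_genomic_locus(model: GenomeModel, rng: np.random.Generator, size=None):
    """Sample loci uniformly over the genome.

    Returns ``(chromosome, bp_position)`` with 1-based chromosome ids and
    0-based bp offsets; chromosome choice is implicitly proportional to its
    length because the draw is uniform over genome-wide bp.
    """
    g = rng.integers(0, model.total_bp, size=size)
    idx = np.searchsorted(model._cum_lengths, g, side="right")
    prev = np.where(idx > 0, model._cum_lengths[idx - 1], 0)
    chrom = idx + 1
    bp = g - prev
    if size is None:
        return int(chrom), int(bp)
    return chrom.astype(np.int64), bp.astype(np.int64)


def locus_to_position(model: GenomeModel, chromosome, bp_position) -> np.ndarray:
    """Deterministic map from a genomic locus to a spatial point (um).

    The locus indexes a voxel within its chromosome territory; a sub-voxel
    jitter hashed from ``(chromosome, bp_position)`` spreads loci inside the
    voxel cube.  Positions are always inside the nucleus sphere (boundary
    voxels are radially clipped).

    Accepts scalars or equal-length arrays; returns ``(3,)`` or ``(n, 3)``.
    """
    chrom = np.asarray(chromosome, dtype=np.int64)
    bp = np.asarray(bp_position, dtype=np.int64)
    scalar = chrom.ndim == 0
    chrom, bp = np.atleast_1d(chrom), np.atleast_1d(bp)

    if ((chrom < 1) | (chrom > model.chromosome_count)).any():
        raise ValueError("chromosome id out of range")
    lengths = model.chromosome_lengths[chrom - 1]
    if ((bp < 0) | (bp >= lengths)).any():
        raise ValueError("bp position out of range for chromosome")

    start = model.chromosome_voxel_start[chrom - 1]
    nvox = model.chromosome_voxel_start[chrom] - start
    local = (bp * nvox) // lengths
    centers = model.voxel_centers[start + local]

    key = chrom.astype(np.uint64) * np.uint64(0xD1B54A32D192ED03) + bp.astype(np.uint64)
    jitter = np.empty((len(key), 3))
    for k in range(3):
        salt = np.uint64((k * 0x9E3779B97F4A7C15) % 2**64)
        h = _splitmix64(key + salt)
        jitter[:, k] = (h / np.float64(2**64)) - 0.5
    pos = centers + jitter * model.voxel_spacing_um

    r = np.linalg.norm(pos, axis=1)
    rmax = model.nucleus_radius_um * (1.0 - 1e-9)
    over = r > rmax
    if over.any():
        pos[over] *= (rmax / r[over])[:, None]
    return pos[0] if scalar else pos
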