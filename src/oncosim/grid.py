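"""Voxel lattice, compartmental tumor state and geometric observables.

The tumor is discretized into cubic voxels ("geometrical cells", 1 or 8 mm^3).
Each voxel holds a real-valued occupancy vector over a dense compartment index
covering the stem/progenitor hierarchy (cycling phases + G0 for the stem and
each LIMP generation), terminally differentiated cells, dying cells (apoptotic
and necrotic age bins) and treatment-hit ("doomed") cells traversing their
rudimentary cycles.  Counts are mean-field (fractional cells are allowed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VoxelGrid",
    "CompartmentIndex",
    "GCState",
    "make_phantom",
    "tumor_volume",
    "center_of_mass",
    "com_distance",
    "save_nifti",
    "load_nifti",
]

#: cells per mm^3 of fully packed tumor tissue
DEFAULT_CELL_DENSITY = 1.0e6

#: a voxel counts as tumor-occupied above this many cells (total, living + dead)
DEFAULT_OCCUPANCY_FLOOR = 10.0

PHASES = ("G1", "S", "G2", "M")

#: default split of the cell-cycle duration T_c over the four cycling phases
DEFAULT_PHASE_FRACTIONS = {"G1": 0.40, "S": 0.30, "G2": 0.20, "M": 0.10}


@dataclass(frozen=True)
class VoxelGrid:
    """Regular cubic-voxel lattice.

    Physical coordinates are voxel centers; voxel indices are 0-based and all
    distances are in mm.
    """

    nx: int
    ny: int
    nz: int
    voxel_edge_mm: float = 1.0
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("grid dimensions must be positive")
        if self.voxel_edge_mm <= 0:
            raise ValueError("voxel edge must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def n_voxels(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_edge_mm ** 3

    def voxel_centers(self) -> np.ndarray:
        """(n_voxels, 3) array of voxel-center coordinates in mm."""
        ax = [
            self.origin_mm[d] + (np.arange(self.shape[d]) + 0.5) * self.voxel_edge_mm
            for d in range(3)
        ]
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)


class CompartmentIndex:
    """Dense, stable index of all cell compartments for one parameter set.

    Layout (contiguous blocks, in order):
      for each lineage (STEM, LIMP_1 .. LIMP_N):
          cycle block  -- G1,S,G2,M age bins of width dt (shift-by-one aging)
          G0 slot      -- single memoryless quiescent compartment
      DIFF slot
      APOP bins (T_A / dt)
      NECR bins (T_N / dt)
      per chemo drug: HIT block (rudimentary cycles, ends at the drug's death phase)
      HIT_RADIO block (rud_divisions_radio full rudimentary cycles)

    G0 is a single compartment with an exponential (memoryless) exit at mean
    residence time T_G0; this matches the population-kinetics growth-rate
    relation used throughout the package, whose quiescence-return term is the
    Laplace transform of an exponential dwell time.
    """

    def __init__(
        self,
        dt: float,
        T_c: float,
        T_A: float,
        T_N: float,
        n_limp: int,
        phase_fractions: dict[str, float] | None = None,
        drugs: dict[str, str] | None = None,
        rud_divisions_chemo: int = 1,
        rud_divisions_radio: int = 2,
    ):
        if dt <= 0:
            raise ValueError("dt must be positive")
        phase_fractions = dict(phase_fractions or DEFAULT_PHASE_FRACTIONS)
        if abs(sum(phase_fractions[p] for p in PHASES) - 1.0) > 1e-9:
            raise ValueError("phase fractions must sum to 1")
        self.dt = float(dt)
        self.n_limp = int(n_limp)
        if self.n_limp < 1:
            raise ValueError("N_LIMP must be >= 1")
        self.drugs = dict(drugs or {})
        for drug, phase in self.drugs.items():
            if phase not in PHASES:
                raise ValueError(f"unknown death phase {phase!r} for drug {drug!r}")

        self.phase_bins = {
            p: int(round(phase_fractions[p] * T_c / dt)) for p in PHASES
        }
        if min(self.phase_bins.values()) < 1:
            raise ValueError("dt larger than the smallest cell-cycle phase")
        self.n_cycle_bins = sum(self.phase_bins.values())
        if self.n_cycle_bins < 1:
            raise ValueError("dt larger than the cell cycle")
        #: effective cycle duration after discretization (== n_cycle_bins * dt)
        self.T_c_eff = self.n_cycle_bins * self.dt
        self.n_apop_bins = max(1, int(round(T_A / dt)))
        self.n_necr_bins = max(1, int(round(T_N / dt)))
        self.T_A_eff = self.n_apop_bins * self.dt
        self.T_N_eff = self.n_necr_bins * self.dt

        self.lineages = ["STEM"] + [f"LIMP_{k}" for k in range(1, self.n_limp + 1)]
        pos = 0
        self._cycle: dict[str, slice] = {}
        self._g0: dict[str, int] = {}
        for lin in self.lineages:
            self._cycle[lin] = slice(pos, pos + self.n_cycle_bins)
            pos += self.n_cycle_bins
            self._g0[lin] = pos
            pos += 1
        self.diff_index = pos
        pos += 1
        self.apop = slice(pos, pos + self.n_apop_bins)
        pos += self.n_apop_bins
        self.necr = slice(pos, pos + self.n_necr_bins)
        pos += self.n_necr_bins

        # cumulative bin offset at the *end* of each phase within a cycle block
        off, self._phase_end = 0, {}
        self._phase_slice_in_cycle = {}
        for p in PHASES:
            self._phase_slice_in_cycle[p] = slice(off, off + self.phase_bins[p])
            off += self.phase_bins[p]
            self._phase_end[p] = off

        self._hit_chemo: dict[str, slice] = {}
        for drug, death_phase in self.drugs.items():
            length = (max(1, rud_divisions_chemo) - 1) * self.n_cycle_bins
            length += self._phase_end[death_phase]
            self._hit_chemo[drug] = slice(pos, pos + length)
            pos += length
        n_radio = max(1, rud_divisions_radio) * self.n_cycle_bins
        self.hit_radio = slice(pos, pos + n_radio)
        pos += n_radio
        self.n_comp = pos

        self._build_masks()

    def _build_masks(self):
        n = self.n_comp
        cyc = np.zeros(n, bool)
        g0 = np.zeros(n, bool)
        stem = np.zeros(n, bool)
        phase_masks = {p: np.zeros(n, bool) for p in PHASES}
        for lin in self.lineages:
            c = self._cycle[lin]
            cyc[c] = True
            g0[self._g0[lin]] = True
            for p in PHASES:
                sl = self._phase_slice_in_cycle[p]
                phase_masks[p][c.start + sl.start : c.start + sl.stop] = True
        stem[self._cycle["STEM"]] = True
        stem[self._g0["STEM"]] = True
        self.cycling_mask = cyc
        self.g0_mask = g0
        self.stem_mask = stem
        self.phase_masks = phase_masks
        living = cyc | g0
        living[self.diff_index] = True
        self.living_mask = living
        dead = np.zeros(n, bool)
        dead[self.apop] = True
        dead[self.necr] = True
        self.dead_mask = dead
        doomed = np.zeros(n, bool)
        for sl in self._hit_chemo.values():
            doomed[sl] = True
        doomed[self.hit_radio] = True
        self.doomed_mask = doomed
        #: STEM + LIMP living compartments (targets of chemo/radio hits)
        self.hierarchy_mask = cyc | g0

    def cycle_slice(self, lineage: str) -> slice:
        return self._cycle[lineage]

    def g0_index(self, lineage: str) -> int:
        return self._g0[lineage]

    def hit_chemo_slice(self, drug: str) -> slice:
        if drug not in self._hit_chemo:
            raise KeyError(f"no HIT_CHEMO block for drug {drug!r}")
        return self._hit_chemo[drug]


@dataclass
class GCState:
    """Per-voxel occupancy over a :class:`CompartmentIndex`.

    ``data`` has shape (n_comp, n_voxels); ``capacity`` is the maximum cell
    count per voxel (cell density x voxel volume by default).
    """

    grid: VoxelGrid
    index: CompartmentIndex
    data: np.ndarray
    capacity: float
    occupancy_floor: float = DEFAULT_OCCUPANCY_FLOOR

    @classmethod
    def empty(
        cls,
        grid: VoxelGrid,
        index: CompartmentIndex,
        cell_density: float = DEFAULT_CELL_DENSITY,
    ) -> "GCState":
        data = np.zeros((index.n_comp, grid.n_voxels))
        return cls(grid, index, data, capacity=cell_density * grid.voxel_volume_mm3)

    def copy(self) -> "GCState":
        return GCState(
            self.grid, self.index, self.data.copy(), self.capacity, self.occupancy_floor
        )

    # -- aggregate views -----------------------------------------------------
    def totals(self) -> np.ndarray:
        """Total cell count (all compartments) per voxel."""
        return self.data.sum(axis=0)

    def living(self) -> np.ndarray:
        return self.data[self.index.living_mask].sum(axis=0)

    def occupied_mask(self) -> np.ndarray:
        return self.totals() > self.occupancy_floor

    def total_count(self) -> float:
        return float(self.data.sum())

    def stem_count(self) -> float:
        """Total (unhit) cancer-stem-cell count across the tumor."""
        return float(self.data[self.index.stem_mask].sum())

    def category_totals(self) -> dict[str, float]:
        ix = self.index
        d = self.data
        return {
            "cycling": float(d[ix.cycling_mask].sum()),
            "g0": float(d[ix.g0_mask].sum()),
            "diff": float(d[ix.diff_index].sum()),
            "apop": float(d[ix.apop].sum()),
            "necr": float(d[ix.necr].sum()),
            "doomed": float(d[ix.doomed_mask].sum()),
            "stem": self.stem_count(),
        }

    def assert_valid(self):
        if np.isnan(self.data).any():
            raise FloatingPointError("NaN occupancy encountered")
        if (self.data < -1e-6 * max(self.capacity, 1.0)).any():
            raise FloatingPointError("negative occupancy encountered")
        np.clip(self.data, 0.0, None, out=self.data)


def composition_vector(index: CompartmentIndex, composition) -> np.ndarray:
    """Normalize a composition spec to a distribution over compartments.

    ``composition`` is either a full (n_comp,) array or a mapping over the
    category keys G1/S/G2/M (STEM cycle, age bin 0 of the phase), G0 (STEM),
    DIFF, APOP, NECR (age bin 0).
    """
    if isinstance(composition, np.ndarray):
        v = np.asarray(composition, float)
        if v.shape != (index.n_comp,):
            raise ValueError("composition vector has wrong length")
        if (v < 0).any():
            raise ValueError("negative composition fractions")
        s = v.sum()
        if s <= 0:
            raise ValueError("composition sums to zero")
        return v / s
    v = np.zeros(index.n_comp)
    stem_cycle = index.cycle_slice("STEM")
    for key, frac in composition.items():
        if frac < 0:
            raise ValueError("negative composition fractions")
        if key in PHASES:
            v[stem_cycle.start + index._phase_slice_in_cycle[key].start] += frac
        elif key == "G0":
            v[index.g0_index("STEM")] += frac
        elif key == "DIFF":
            v[index.diff_index] += frac
        elif key == "APOP":
            v[index.apop.start] += frac
        elif key == "NECR":
            v[index.necr.start] += frac
        else:
            raise KeyError(f"unknown composition key {key!r}")
    s = v.sum()
    if abs(s - 1.0) > 1e-9:
        raise ValueError("composition fractions must sum to 1")
    return v / s


def make_phantom(
    grid: VoxelGrid,
    index: CompartmentIndex,
    center_mm,
    radii_mm,
    composition,
    fill_fraction: float = 1.0,
    label_tumor: int = 1,
    label_background: int = 0,
    cell_density: float = DEFAULT_CELL_DENSITY,
) -> tuple[GCState, np.ndarray]:
    """Ellipsoidal tumor phantom embedded in a labeled background.

    Voxels whose centers fall inside the ellipsoid receive
    ``capacity * fill_fraction`` cells distributed according to
    ``composition``; the returned label map marks them ``label_tumor``.
    """
    center = np.asarray(center_mm, float)
    radii = np.asarray(radii_mm, float)
    if radii.ndim == 0:
        radii = np.full(3, float(radii))
    if (radii < 0).any():
        raise ValueError("negative radii")
    lo = np.asarray(grid.origin_mm)
    hi = lo + np.array(grid.shape) * grid.voxel_edge_mm
    if (radii > 0).any() and ((center - radii < lo).any() or (center + radii > hi).any()):
        raise ValueError("ellipsoid exceeds grid bounds")

    state = GCState.empty(grid, index, cell_density)
    labels = np.full(grid.n_voxels, label_background, dtype=np.int32)
    if (radii > 0).all():
        centers = grid.voxel_centers()
        r2 = (((centers - center) / radii) ** 2).sum(axis=1)
        inside = r2 <= 1.0
    else:
        inside = np.zeros(grid.n_voxels, bool)
    if inside.any():
        comp = composition_vector(index, composition)
        state.data[:, inside] = comp[:, None] * (state.capacity * fill_fraction)
        labels[inside] = label_tumor
    return state, labels.reshape(grid.shape)


def tumor_volume(state: GCState, grid: VoxelGrid | None = None) -> float:
    """Tumor volume in mm^3: occupied-voxel count x voxel volume."""
    grid = grid or state.grid
    return float(state.occupied_mask().sum()) * grid.voxel_volume_mm3


def center_of_mass(state: GCState, grid: VoxelGrid | None = None) -> np.ndarray:
    """Cell-count-weighted mean of voxel centers, in mm."""
    grid = grid or state.grid
    w = state.totals()
    total = w.sum()
    if total <= 0:
        raise ValueError("center of mass of an empty state")
    return (grid.voxel_centers() * w[:, None]).sum(axis=0) / total


def com_distance(state_a: GCState, state_b: GCState, grid: VoxelGrid | None = None) -> float:
    """Euclidean distance (mm) between the two states' centers of mass."""
    ga = grid or state_a.grid
    gb = grid or state_b.grid
    if ga.shape != gb.shape or ga.voxel_edge_mm != gb.voxel_edge_mm:
        raise ValueError("grid mismatch")
    return float(np.linalg.norm(center_of_mass(state_a, ga) - center_of_mass(state_b, gb)))


# -- NIfTI I/O ---------------------------------------------------------------

def save_nifti(path, volume: np.ndarray, grid: VoxelGrid):
    """Write a per-voxel scalar (or multi-channel) field as a NIfTI volume."""
    import nibabel as nib

    vol = np.asarray(volume)
    if vol.ndim == 1:
        vol = vol.reshape(grid.shape)
    elif vol.ndim == 2 and vol.shape[0] == grid.n_voxels:
        vol = vol.reshape(grid.shape + (vol.shape[1],))
    affine = np.diag([grid.voxel_edge_mm] * 3 + [1.0])
    affine[:3, 3] = grid.origin_mm
    nib.save(nib.Nifti1Image(np.asarray(vol, np.float32), affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, VoxelGrid]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    edge = float(abs(img.affine[0, 0]))
    origin = tuple(float(x) for x in img.affine[:3, 3])
    grid = VoxelGrid(*data.shape[:3], voxel_edge_mm=edge, origin_mm=origin)
    return data, grid
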