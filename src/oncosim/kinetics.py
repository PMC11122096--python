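"""Tumor cell-population kinetics on the voxel lattice.

Mean-field compartmental dynamics of the cancer stem / limited-mitotic-potential
(LIMP) / differentiated (DIFF) hierarchy: cycling with discrete age bins,
reversible quiescence (G0), spontaneous apoptosis and necrosis, instantaneous
chemotherapy hits, linear-quadratic radiotherapy hits, and conservative spatial
redistribution of cells along a least-pressure direction field.

Division bookkeeping follows the population-kinetics growth relation used by
the coupling layer: at every mitosis one daughter re-enters G1 directly (the
renewing daughter) while the additional daughter of a symmetric division (or
the LIMP daughter of an asymmetric one) withdraws to G0 with probability
P_sleep.  With that convention the continuum growth rate of the stem
compartment satisfies

    e^{(a + R_A) T_c} = 1 + P_sym [(1 - P_sleep)
                        + P_sleep (P_G0toG1/T_G0) / (R_A + 1/T_G0 + a)]

exactly in the dt -> 0 limit, which the free-growth tests exploit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .grid import (
    DEFAULT_PHASE_FRACTIONS,
    PHASES,
    CompartmentIndex,
    GCState,
    VoxelGrid,
    tumor_volume,
)

__all__ = [
    "VirtualTumorParameters",
    "TreatmentEvent",
    "TreatmentSchedule",
    "SimulationResult",
    "lq_surviving_fraction",
    "cytokinetic_step",
    "apply_chemo_hit",
    "apply_radio_fraction",
    "redistribute_cells",
    "simulate",
    "growth_fraction",
]

#: drug -> cell-cycle phase in which lethally hit cells die (mechanism of action)
DEFAULT_DRUG_DEATH_PHASES = {"vincristine": "M", "actinomycin": "S"}


@dataclass
class VirtualTumorParameters:
    """One point in the oncosimulator parameter space (one "virtual tumor").

    Durations in hours, rates in h^-1, alpha in Gy^-1, beta in Gy^-2.
    """

    T_c: float = 32.0
    T_G0: float = 96.0
    T_A: float = 12.0
    T_N: float = 48.0
    R_A: float = 1.0e-4
    R_ADiff: float = 3.0e-3
    R_NDiff: float = 3.0e-3
    P_sym: float = 0.2
    P_sleep: float = 0.1
    P_G0toG1: float = 0.1
    N_LIMP: int = 15
    alpha: float = 0.35
    beta: float = 0.035
    dt: float = 1.0
    rud_divisions_chemo: int = 1
    rud_divisions_radio: int = 2
    phase_fractions: dict = field(default_factory=lambda: dict(DEFAULT_PHASE_FRACTIONS))
    phase_radiosensitivity: dict = field(default_factory=dict)  # phase -> multiplier
    drugs: dict = field(default_factory=lambda: dict(DEFAULT_DRUG_DEATH_PHASES))

    def validate(self):
        for name in ("T_c", "T_G0", "T_A", "T_N", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("P_sym", "P_sleep", "P_G0toG1"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("R_A", "R_ADiff", "R_NDiff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.N_LIMP < 1:
            raise ValueError("N_LIMP must be >= 1")
        if abs(sum(self.phase_fractions[p] for p in PHASES) - 1.0) > 1e-9:
            raise ValueError("phase fractions must sum to 1")

    def build_index(self) -> CompartmentIndex:
        self.validate()
        return CompartmentIndex(
            dt=self.dt,
            T_c=self.T_c,
            T_A=self.T_A,
            T_N=self.T_N,
            n_limp=self.N_LIMP,
            phase_fractions=self.phase_fractions,
            drugs=self.drugs,
            rud_divisions_chemo=self.rud_divisions_chemo,
            rud_divisions_radio=self.rud_divisions_radio,
        )

    def with_(self, **kw) -> "VirtualTumorParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class TreatmentEvent:
    time_h: float
    modality: str  # "chemo" | "radio"
    drug: str | None = None
    ckr: float | None = None
    dose_gy: float | None = None
    alpha: float | None = None
    beta: float | None = None

    def __post_init__(self):
        if self.modality not in ("chemo", "radio"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "chemo":
            if self.ckr is None or not 0.0 <= self.ckr <= 1.0:
                raise ValueError("chemo event needs a CKR in [0, 1]")
            if not self.drug:
                raise ValueError("chemo event needs a drug name")
        else:
            if self.dose_gy is None or self.dose_gy < 0:
                raise ValueError("radio event needs a dose >= 0")


@dataclass
class TreatmentSchedule:
    events: list

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: e.time_h)

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)

    @property
    def drug_names(self) -> list[str]:
        return sorted({e.drug for e in self.events if e.modality == "chemo"})

    @property
    def end_time_h(self) -> float:
        return max((e.time_h for e in self.events), default=0.0)

    @classmethod
    def from_yaml(cls, path) -> "TreatmentSchedule":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or []
        if isinstance(raw, dict):
            raw = raw.get("events", [])
        return cls([TreatmentEvent(**ev) for ev in raw])

    def to_yaml(self, path):
        import yaml

        events = []
        for e in self.events:
            d = {"time_h": e.time_h, "modality": e.modality}
            if e.modality == "chemo":
                d.update(drug=e.drug, ckr=e.ckr)
            else:
                d.update(dose_gy=e.dose_gy)
                if e.alpha is not None:
                    d.update(alpha=e.alpha, beta=e.beta)
            events.append(d)
        with open(path, "w") as fh:
            yaml.safe_dump(events, fh, sort_keys=False)


# ---------------------------------------------------------------------------


def lq_surviving_fraction(dose: float, alpha: float, beta: float) -> float:
    """Linear-quadratic surviving fraction S(D) = exp(-(alpha D + beta D^2)).

    The cell kill rate per fraction is 1 - S(D).
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    return math.exp(-(alpha * dose + beta * dose * dose))


def _frac(rate: float, dt: float) -> float:
    """Per-step loss fraction for a continuous rate (unconditionally stable)."""
    return -math.expm1(-rate * dt)


def cytokinetic_step(
    state: GCState,
    params: VirtualTumorParameters,
    psleep_map=None,
) -> GCState:
    """Advance all compartments by one time step dt (in place).

    ``psleep_map`` optionally overrides ``params.P_sleep`` per voxel (shape
    (n_voxels,)); this is how the metabolic coupling regulates quiescence.
    """
    ix = state.index
    d = state.data
    dt = params.dt
    nvox = d.shape[1]

    if psleep_map is None:
        psleep = params.P_sleep
    else:
        psleep = np.asarray(psleep_map, float)
        if np.any((psleep < 0) | (psleep > 1)):
            raise ValueError("psleep_map values must be in [0, 1]")

    apop_in = np.zeros(nvox)
    necr_in = np.zeros(nvox)

    # 1) continuous losses --------------------------------------------------
    fA = _frac(params.R_A, dt)
    if fA > 0:
        hier = ix.hierarchy_mask
        loss = d[hier] * fA
        d[hier] -= loss
        apop_in += loss.sum(axis=0)
    r_sum = params.R_ADiff + params.R_NDiff
    if r_sum > 0:
        f_diff = _frac(r_sum, dt)
        loss = d[ix.diff_index] * f_diff
        d[ix.diff_index] -= loss
        apop_in += loss * (params.R_ADiff / r_sum)
        necr_in += loss * (params.R_NDiff / r_sum)

    # 2) G0 exits (memoryless, mean residence T_G0) -------------------------
    fG0 = _frac(1.0 / params.T_G0, dt)
    g1_in = {lin: np.zeros(nvox) for lin in ix.lineages}
    for lin in ix.lineages:
        g0 = ix.g0_index(lin)
        ex = d[g0] * fG0
        d[g0] -= ex
        g1_in[lin] += params.P_G0toG1 * ex
        necr_in += (1.0 - params.P_G0toG1) * ex

    # 3) mitoses (M-phase last bin, captured before aging) -------------------
    diff_in = np.zeros(nvox)
    dividers = {lin: d[ix.cycle_slice(lin).stop - 1].copy() for lin in ix.lineages}
    m = dividers["STEM"]
    sym = params.P_sym * m
    asym = m - sym
    # renewing daughter (stem) never sleeps; the extra symmetric daughter may
    g1_in["STEM"] += sym + asym + sym * (1.0 - psleep)
    g0_add = {lin: np.zeros(nvox) for lin in ix.lineages}
    g0_add["STEM"] += sym * psleep
    # asymmetric second daughter is LIMP_1
    lin1 = "LIMP_1"
    g1_in[lin1] += asym * (1.0 - psleep)
    g0_add[lin1] += asym * psleep
    for k in range(1, ix.n_limp + 1):
        m = dividers[f"LIMP_{k}"]
        if k < ix.n_limp:
            nxt = f"LIMP_{k + 1}"
            g1_in[nxt] += m + m * (1.0 - psleep)
            g0_add[nxt] += m * psleep
        else:
            diff_in += 2.0 * m  # terminal division: both daughters differentiate

    # 4) doomed-cell progression (exits before shifting) ---------------------
    for drug in ix.drugs:
        sl = ix.hit_chemo_slice(drug)
        apop_in += d[sl.stop - 1]
    necr_in += d[ix.hit_radio.stop - 1]

    # 5) shift all age-binned blocks by one ----------------------------------
    for lin in ix.lineages:
        c = ix.cycle_slice(lin)
        d[c.start + 1 : c.stop] = d[c.start : c.stop - 1]
        d[c.start] = 0.0
    for sl in (ix.apop, ix.necr, ix.hit_radio, *[ix.hit_chemo_slice(g) for g in ix.drugs]):
        if sl.stop - sl.start > 1:
            d[sl.start + 1 : sl.stop] = d[sl.start : sl.stop - 1]
        d[sl.start] = 0.0
        if sl.stop - sl.start == 1:
            # single-bin block: occupants left this step (already routed above
            # for hit blocks; apoptotic/necrotic single bins are cleared)
            pass

    # 6) deposit inflows -----------------------------------------------------
    for lin in ix.lineages:
        c = ix.cycle_slice(lin)
        d[c.start] += g1_in[lin]
        d[ix.g0_index(lin)] += g0_add[lin]
    d[ix.diff_index] += diff_in
    d[ix.apop.start] += apop_in
    d[ix.necr.start] += necr_in

    state.assert_valid()
    return state


def apply_chemo_hit(state: GCState, drug: str, ckr: float) -> GCState:
    """Move a CKR fraction of all stem and LIMP cells (all phases, including
    G0) into the drug's doomed compartment; DIFF and dead cells are unaffected.
    """
    if not 0.0 <= ckr <= 1.0:
        raise ValueError("CKR must be in [0, 1]")
    ix = state.index
    sl = ix.hit_chemo_slice(drug)  # raises for unknown drug
    hier = ix.hierarchy_mask
    hit = state.data[hier] * ckr
    state.data[hier] -= hit
    state.data[sl.start] += hit.sum(axis=0)
    return state


def apply_radio_fraction(
    state: GCState, dose: float, params: VirtualTumorParameters
) -> GCState:
    """Apply one radiotherapy fraction via the LQ model.

    Per phase p the hit fraction is 1 - exp(-(m_p alpha D + m_p beta D^2))
    with multiplier m_p (default 1 for every phase, i.e. equal radiosensitivity
    in all phases).  Hit stem/LIMP cells enter the radiation-doomed block and
    die through necrosis after their rudimentary divisions.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    ix = state.index
    alpha, beta = params.alpha, params.beta
    hit_total = np.zeros(state.data.shape[1])
    phase_groups = dict(ix.phase_masks)
    phase_groups["G0"] = ix.g0_mask
    for phase, mask in phase_groups.items():
        m_p = params.phase_radiosensitivity.get(phase, 1.0)
        kill = 1.0 - math.exp(-(m_p * alpha * dose + m_p * beta * dose * dose))
        take = mask & ix.hierarchy_mask
        hit = state.data[take] * kill
        state.data[take] -= hit
        hit_total += hit.sum(axis=0)
    state.data[ix.hit_radio.start] += hit_total
    return state


# -- spatial redistribution --------------------------------------------------

_NEIGHBOR_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


_NEIGHBOR_CACHE: dict = {}


def _neighbor_ids(grid: VoxelGrid) -> np.ndarray:
    """(n_voxels, 6) flat neighbor ids in fixed x->y->z order; -1 off-grid."""
    cached = _NEIGHBOR_CACHE.get(grid.shape)
    if cached is not None:
        return cached
    nx, ny, nz = grid.shape
    idx = np.arange(grid.n_voxels).reshape(grid.shape)
    out = np.full((grid.n_voxels, 6), -1, dtype=np.int64)
    coords = np.stack(np.unravel_index(np.arange(grid.n_voxels), grid.shape), axis=1)
    for j, off in enumerate(_NEIGHBOR_OFFSETS):
        nb = coords + off
        ok = ((nb >= 0) & (nb < [nx, ny, nz])).all(axis=1)
        out[ok, j] = idx[nb[ok, 0], nb[ok, 1], nb[ok, 2]]
    _NEIGHBOR_CACHE[grid.shape] = out
    return out


def redistribute_cells(
    state: GCState,
    direction: np.ndarray | None = None,
    grid: VoxelGrid | None = None,
    shrink_floor: float = 0.1,
    overflow_tol: float = 1e-9,
    max_passes: int = 200,
) -> GCState:
    """Conservative neighbor-exchange of cells on the lattice.

    Voxels above capacity export their excess to the 6-neighbor best aligned
    with the local least-pressure direction (ties broken in fixed x->y->z
    order); with no usable direction the least-loaded neighbor receives the
    excess.  Tumor voxels below ``shrink_floor * capacity`` donate all cells
    to their most-loaded tumor neighbor.  Total cell count is exactly
    conserved.
    """
    grid = grid or state.grid
    if direction is not None:
        direction = np.asarray(direction, float)
        if direction.shape != (grid.n_voxels, 3):
            direction = direction.reshape(grid.n_voxels, 3)
    nb = _neighbor_ids(grid)
    cap = state.capacity
    d = state.data

    def overload_pass() -> bool:
        totals = d.sum(axis=0)
        over = np.flatnonzero(totals > cap * (1.0 + overflow_tol))
        if over.size == 0:
            return False
        nbs = nb[over]  # (n_over, 6)
        valid = nbs >= 0
        loads = np.where(valid, totals[np.clip(nbs, 0, None)], np.inf)
        # default: least-loaded neighbor (argmin takes the first minimum,
        # i.e. the fixed x->y->z tie-break)
        target = nbs[np.arange(over.size), np.argmin(loads, axis=1)]
        if direction is not None:
            dv = direction[over]
            scores = dv @ _NEIGHBOR_OFFSETS.T  # (n_over, 6)
            occ = np.where(valid, totals[np.clip(nbs, 0, None)], 0.0)
            cand = valid & (scores > 1e-12) & (occ > state.occupancy_floor)
            has_dir = (np.linalg.norm(dv, axis=1) > 0) & cand.any(axis=1)
            best = np.argmax(np.where(cand, scores, -np.inf), axis=1)
            target = np.where(has_dir, nbs[np.arange(over.size), best], target)
        frac = (totals[over] - cap) / totals[over]
        moved = d[:, over] * frac  # (n_comp, n_over)
        d[:, over] -= moved
        np.add.at(d.T, target, moved.T)
        return True

    for _ in range(max_passes):
        if not overload_pass():
            break

    # shrinkage: under-filled tumor voxels collapse into their densest neighbor
    totals = d.sum(axis=0)
    under = np.flatnonzero(
        (totals > state.occupancy_floor) & (totals < shrink_floor * cap)
    )
    for v in under:
        nbs = nb[v]
        valid = nbs >= 0
        loads = np.where(valid, totals[np.clip(nbs, 0, None)], -np.inf)
        j = int(np.argmax(loads))
        target = nbs[j]
        if target < 0 or totals[target] <= totals[v]:
            continue  # isolated or locally densest voxel: nothing to donate to
        d[:, target] += d[:, v]
        d[:, v] = 0.0
        totals[target] += totals[v]
        totals[v] = 0.0

    for _ in range(max_passes):
        if not overload_pass():
            break
    return state


# -- simulation loop ---------------------------------------------------------


@dataclass
class SimulationResult:
    """Time series of compartment totals plus the final lattice state."""

    time_h: np.ndarray
    series: dict
    final_state: GCState
    params: VirtualTumorParameters
    seed: int | None = None

    def frame(self):
        import pandas as pd

        return pd.DataFrame({"time_h": self.time_h, **self.series})

    @property
    def surviving_stem(self) -> float:
        return self.series["stem"][-1]

    def to_csv(self, path):
        self.frame().to_csv(path, index=False)


def growth_fraction(state: GCState) -> float:
    """Fraction of living cells actively cycling: (G1+S+G2+M) / (cycling+G0+DIFF)."""
    ix = state.index
    cyc = float(state.data[ix.cycling_mask].sum())
    living = cyc + float(state.data[ix.g0_mask].sum()) + float(
        state.data[ix.diff_index].sum()
    )
    if living <= 0:
        raise ValueError("growth fraction of an empty state")
    return cyc / living


def simulate(
    initial: GCState,
    params: VirtualTumorParameters,
    schedule: TreatmentSchedule | None = None,
    hooks=None,
    horizon_h: float = 0.0,
    seed: int | None = None,
    exchange_interval_h: float = 24.0,
    record_interval_h: float | None = None,
    redistribute: bool = True,
) -> SimulationResult:
    """Run the oncosimulator loop.

    Per step: pending treatment events are applied instantaneously, a
    cytokinetic step advances the compartments, and (when enabled) cells are
    redistributed along the current direction field.  Every
    ``exchange_interval_h`` the coupling ``hooks`` callable is invoked as
    ``hooks(state, t) -> (psleep_map | None, direction | None)`` and its
    outputs are held constant until the next exchange.
    """
    schedule = schedule or TreatmentSchedule([])
    if horizon_h < schedule.end_time_h:
        raise ValueError("horizon earlier than the last scheduled event")
    state = initial.copy()
    dt = params.dt
    n_steps = int(round(horizon_h / dt))
    record_every = max(1, int(round((record_interval_h or dt) / dt)))
    exchange_every = max(1, int(round(exchange_interval_h / dt)))

    events = list(schedule)
    next_event = 0
    psleep_map = None
    direction = None

    times, rows = [], []

    def record(t):
        cat = state.category_totals()
        living = cat["cycling"] + cat["g0"] + cat["diff"]
        gf = cat["cycling"] / living if living > 0 else np.nan
        times.append(t)
        rows.append(
            {
                **cat,
                "living": living,
                "total": state.total_count(),
                "volume_mm3": tumor_volume(state),
                "growth_fraction": gf,
            }
        )

    record(0.0)
    for step in range(1, n_steps + 1):
        t = step * dt
        if hooks is not None and (step - 1) % exchange_every == 0:
            psleep_map, direction = hooks(state, t - dt)
        while next_event < len(events) and events[next_event].time_h <= t - dt + 1e-9:
            ev = events[next_event]
            if ev.modality == "chemo":
                apply_chemo_hit(state, ev.drug, ev.ckr)
            else:
                p = params
                if ev.alpha is not None:
                    p = params.with_(alpha=ev.alpha, beta=ev.beta if ev.beta is not None else params.beta)
                apply_radio_fraction(state, ev.dose_gy, p)
            next_event += 1
        cytokinetic_step(state, params, psleep_map)
        if redistribute:
            redistribute_cells(state, direction)
        if step % record_every == 0 or step == n_steps:
            record(t)

    series = {k: np.array([r[k] for r in rows]) for k in rows[0]}
    return SimulationResult(np.array(times), series, state, params, seed)
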