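"""Inter-model transformations and the per-exchange orchestration loop.

The glucose field from the transport solve is mapped through the metabolic
phenotype table to a local proliferation rate a, which the oncosimulator does
not use directly: it is translated into the fraction P_sleep of newborn cells
withdrawing to quiescence.  The translation inverts the population growth
relation (stem hierarchy and spontaneous apoptosis ignored: P_sym = 1,
R_A = 0)

    e^{a T_c} = 2 - P_sleep [1 - (P_G0toG1/T_G0) / (a + 1/T_G0)]

so a = ln2/T_c maps to P_sleep = 0 (no withdrawal) and slower local rates map
to larger P_sleep; rates slower than achievable (T_c > ln2/a) give a negative
P_sleep which callers treat as an invalid flag.  The same relation with the
full P_sym and R_A is exposed as a root solve for the population growth rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .grid import GCState
from .kinetics import VirtualTumorParameters
from .mechanics import growth_strain, least_pressure_direction, solve_pressure
from .metabolism import MMKinetics, PhenotypeTable, interpolate_phenotype
from .vasculature import solve_glucose

__all__ = [
    "CouplingConfig",
    "psleep_from_rate",
    "eq7_growth_rate",
    "eq7_root",
    "p_sym_for_target_rate",
    "orchestrate_exchange",
    "make_hooks",
]


def psleep_from_rate(a, T_c: float, T_G0: float, P_G0toG1: float):
    """Quiescence fraction reproducing proliferation rate a (P_sym=1, R_A=0).

    Returns P_sleep = (2 - e^{a T_c}) / (1 - (P_G0toG1/T_G0)/(a + 1/T_G0)).
    Values outside [0, 1] (in particular negative values when T_c > ln2/a)
    are returned as-is and act as the biologically-unrealistic flag.
    """
    a_arr = np.asarray(a, float)
    if T_c <= 0 or T_G0 <= 0:
        raise ValueError("durations must be positive")
    if (np.asarray(a_arr) <= 0).any():
        raise ValueError("proliferation rate must be positive")
    denom = 1.0 - (P_G0toG1 / T_G0) / (a_arr + 1.0 / T_G0)
    if (denom <= 0).any():
        raise ValueError("degenerate quiescence return term")
    out = (2.0 - np.exp(a_arr * T_c)) / denom
    return float(out) if np.isscalar(a) else out


def eq7_root(
    T_c: float,
    T_G0: float,
    R_A: float,
    P_sym: float,
    P_sleep: float,
    P_G0toG1: float,
    tol: float = 1e-12,
) -> float:
    """Population growth rate a solving the stem-hierarchy renewal relation

    e^{(a + R_A) T_c} = 1 + P_sym [(1 - P_sleep)
                        + P_sleep (P_G0toG1/T_G0) / (R_A + 1/T_G0 + a)].
    """
    if P_sym == 0.0:
        return -R_A

    def f(a):
        g = (P_G0toG1 / T_G0) / (R_A + 1.0 / T_G0 + a)
        return math.expm1((a + R_A) * T_c) - P_sym * ((1.0 - P_sleep) + P_sleep * g)

    lo = -R_A
    hi = max(2.0 * math.log(2.0) / T_c, 1e-6)
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("no growth-rate root in bracket")
    return brentq(f, lo, hi, xtol=tol, rtol=8.9e-16)


def eq7_growth_rate(params: VirtualTumorParameters, tol: float = 1e-12) -> float:
    """Growth rate of a virtual tumor's stem compartment (see :func:`eq7_root`)."""
    params.validate()
    return eq7_root(
        params.T_c, params.T_G0, params.R_A, params.P_sym, params.P_sleep,
        params.P_G0toG1, tol,
    )


def p_sym_for_target_rate(
    a_target: float,
    T_c: float,
    T_G0: float,
    R_A: float,
    P_sleep: float,
    P_G0toG1: float,
) -> float:
    """Symmetric-division fraction that makes the renewal relation hit a_target."""
    g = (P_G0toG1 / T_G0) / (R_A + 1.0 / T_G0 + a_target)
    return math.expm1((a_target + R_A) * T_c) / ((1.0 - P_sleep) + P_sleep * g)


@dataclass
class CouplingConfig:
    """Knobs of the inter-model exchange.

    ``c0`` is the biomechanical carrying capacity (cells/voxel); when None the
    oncosimulator's voxel capacity is used.
    """

    exchange_interval_h: float = 24.0
    c0: float | None = None
    kinetics: MMKinetics = field(default_factory=MMKinetics)
    compression_positive: bool = False
    glucose_tol: float = 1e-8
    pressure_tol: float = 1e-8


def orchestrate_exchange(
    state: GCState,
    modules: dict,
    config: CouplingConfig = CouplingConfig(),
    params: VirtualTumorParameters | None = None,
):
    """One full data exchange between the component models.

    ``modules`` may contain:
      - "vasculature": VasculatureParameters
      - "metabolic": PhenotypeTable
      - "biomechanics": (labels array, MechanicalProperties)

    Returns ``(psleep_map, direction)``; either entry is None when the
    corresponding chain is disabled (the simulator then falls back to the
    constant P_sleep / least-loaded-neighbor behavior).  The exchange only
    sets rates and directions; it never changes cell counts.
    """
    grid = state.grid
    psleep_map = None
    direction = None

    if "metabolic" in modules:
        if params is None:
            raise ValueError("metabolic coupling needs the tumor parameters")
        if "vasculature" in modules:
            u = solve_glucose(
                grid,
                state.living(),
                state.occupied_mask(),
                modules["vasculature"],
                tol=config.glucose_tol,
            )
        else:
            u = np.ones(grid.n_voxels)
        table: PhenotypeTable = modules["metabolic"]
        a_map = np.asarray(interpolate_phenotype(table, u), float)
        psleep_map = np.full(grid.n_voxels, params.P_sleep)
        ok = a_map > 0
        if ok.any():
            cand = psleep_from_rate(a_map[ok], params.T_c, params.T_G0, params.P_G0toG1)
            valid = (cand >= 0.0) & (cand <= 1.0)
            sel = np.flatnonzero(ok)[valid]
            psleep_map[sel] = np.asarray(cand)[valid]

    if "biomechanics" in modules:
        labels, props = modules["biomechanics"]
        c0 = config.c0 if config.c0 is not None else state.capacity
        strain = growth_strain(state.totals(), c0)
        p = solve_pressure(
            grid, labels, props, strain,
            tol=config.pressure_tol,
            compression_positive=config.compression_positive,
        )
        direction = least_pressure_direction(p, grid)

    return psleep_map, direction


def make_hooks(modules: dict, config: CouplingConfig, params: VirtualTumorParameters):
    """Wrap :func:`orchestrate_exchange` as a ``simulate`` coupling callback."""

    def hooks(state: GCState, t: float):
        return orchestrate_exchange(state, modules, config, params)

    return hooks
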