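"""End-to-end workflows: single-tumor runs, cohort TCP studies and the
proliferation-profile screening grid.

These functions are thin orchestration over the component modules; every
quantity they report is recomputed from the lattice simulation at run time.
"""

from __future__ import annotations

import importlib.resources as resources
import math
from dataclasses import dataclass

import numpy as np

from .cohort import ParameterRanges, generate_cohort, summarize_outcomes
from .grid import GCState, VoxelGrid, make_phantom
from .kinetics import (
    SimulationResult,
    TreatmentEvent,
    TreatmentSchedule,
    VirtualTumorParameters,
    simulate,
)

__all__ = [
    "fixture_path",
    "PhantomSpec",
    "phantom_for",
    "run_virtual_tumor",
    "run_cohort_study",
    "screen_profiles",
    "WT_PROFILES",
]


def fixture_path(name: str):
    """Path to one of the shipped text fixtures (networks, ranges, schedules)."""
    return resources.files("oncosim.fixtures") / name


@dataclass
class PhantomSpec:
    """Spherical phantom description used by the desk-scale studies."""

    grid_n: int = 7
    voxel_edge_mm: float = 1.0
    radius_mm: float = 2.5
    fill_fraction: float = 1.0

    def build(self, index, composition) -> tuple[GCState, np.ndarray]:
        grid = VoxelGrid(self.grid_n, self.grid_n, self.grid_n, self.voxel_edge_mm)
        center = np.full(3, self.grid_n * self.voxel_edge_mm / 2.0)
        return make_phantom(
            grid, index, center, self.radius_mm, composition,
            fill_fraction=self.fill_fraction,
        )


def phantom_for(member, spec: PhantomSpec) -> GCState:
    """Phantom seeded with a cohort member's steady-state composition."""
    index = member.params.build_index()
    comp = member.record.get("composition")
    if comp is None:
        comp = {"G1": 1.0}
    state, _ = spec.build(index, comp)
    return state


def run_virtual_tumor(
    member,
    schedule: TreatmentSchedule,
    spec: PhantomSpec = PhantomSpec(),
    extra_horizon_h: float = 168.0,
    hooks=None,
    seed: int | None = None,
) -> SimulationResult:
    """Simulate one virtual tumor through a treatment schedule."""
    state = phantom_for(member, spec)
    return simulate(
        state,
        member.params,
        schedule,
        hooks=hooks,
        horizon_h=schedule.end_time_h + extra_horizon_h,
        seed=seed,
    )


def scale_schedule_dose(schedule: TreatmentSchedule, dose_gy: float) -> TreatmentSchedule:
    """Same radio schedule with every fraction set to ``dose_gy``."""
    events = [
        TreatmentEvent(e.time_h, "radio", dose_gy=dose_gy)
        if e.modality == "radio"
        else e
        for e in schedule
    ]
    return TreatmentSchedule(events)


def run_cohort_study(
    ranges: ParameterRanges,
    schedule: TreatmentSchedule,
    n: int = 30,
    seed: int | None = None,
    spec: PhantomSpec = PhantomSpec(),
    base: VirtualTumorParameters | None = None,
    extra_horizon_h: float = 168.0,
    observed_reduction: float | None = None,
):
    """LHS cohort -> per-tumor simulation -> TCP / volume summary.

    Returns (cohort, results, OutcomeSummary).  The Poisson TCP of each
    virtual tumor uses its surviving cancer-stem-cell count at the end of the
    run.
    """
    base = base or VirtualTumorParameters()
    drugs = dict(base.drugs)
    for name in schedule.drug_names:
        drugs.setdefault(name, "M")
    base = base.with_(drugs=drugs)
    cohort = generate_cohort(ranges, n, seed=seed, base=base)
    results = [
        run_virtual_tumor(m, schedule, spec, extra_horizon_h, seed=seed)
        for m in cohort.retained
    ]
    summary = summarize_outcomes(results, observed_reduction) if results else None
    return cohort, results, summary


#: proliferation-profile grid for the Wilms-tumor screening study:
#: doubling times (days) x growth fractions x metabolic proliferation times (h)
WT_PROFILES = {
    "T_d_days": (11.0, 25.0, 40.0),
    "GF": (0.10, 0.25, 0.50),
    "prolif_time_h": (13.1, 20.0, 50.0),
}


def screen_profiles(
    ranges: ParameterRanges,
    schedule: TreatmentSchedule,
    profiles: dict = None,
    n_per_profile: int = 60,
    seed: int | None = None,
    spec: PhantomSpec = PhantomSpec(),
    base: VirtualTumorParameters | None = None,
    observed_reduction: float | None = None,
):
    """Screen proliferation profiles for compatibility with an observed
    volume reduction.

    Every (T_d, GF, proliferation-time) combination gets its own LHS cohort;
    the summary rows report the predicted volume-reduction distribution per
    profile and, when an observation is supplied, the box-whisker
    compatibility flag.
    """
    import pandas as pd

    profiles = profiles or WT_PROFILES
    rows = []
    for td in profiles["T_d_days"]:
        for gf in profiles["GF"]:
            for tp in profiles["prolif_time_h"]:
                r = ParameterRanges(
                    dict(ranges.sample),
                    dict(ranges.fixed),
                    {**ranges.targets, "T_d_days": td, "GF": gf,
                     "prolif_rate": math.log(2.0) / tp},
                    dict(ranges.bounds),
                )
                cohort, results, summary = run_cohort_study(
                    r, schedule, n=n_per_profile, seed=seed, spec=spec,
                    base=base, observed_reduction=observed_reduction,
                )
                row = {
                    "T_d_days": td,
                    "GF": gf,
                    "prolif_time_h": tp,
                    "n_retained": len(cohort.retained),
                }
                if summary is not None:
                    row.update(
                        reduction_median=summary.reduction_median,
                        reduction_q1=summary.reduction_iqr[0],
                        reduction_q3=summary.reduction_iqr[1],
                        compatible=summary.compatible,
                    )
                rows.append(row)
    return pd.DataFrame(rows)
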