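"""Virtual-tumor cohorts: Latin-hypercube sampling, constraint solving,
exclusions, tumor-control probability and outcome summaries.

A "virtual tumor" is one admissible point of the oncosimulator parameter
space.  Free parameters are drawn by Latin hypercube sampling from literature
ranges; the remaining parameters are derived so every virtual tumor
reproduces the same macroscopic proliferation profile: P_sleep from the
metabolic proliferation rate, P_sym from the volume doubling-time target T_d
(via the stem-hierarchy renewal relation), and R_NDiff calibrated by
bisection on cheap aspatial free-growth runs until the growth fraction
matches its target.  Tumors violating composition bounds (stem-cell
frequency, necrotic/apoptotic fractions) or with unphysical derived rates
are excluded with a tagged reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .coupling import psleep_from_rate
from .grid import GCState, VoxelGrid
from .kinetics import SimulationResult, VirtualTumorParameters, cytokinetic_step

__all__ = [
    "ParameterRanges",
    "CohortMember",
    "VirtualCohort",
    "lhs_sample",
    "steady_state_profile",
    "derive_constrained_params",
    "generate_cohort",
    "apply_exclusions",
    "tcp_poisson",
    "equivalent_diameter",
    "doubling_time_from_volumes",
    "OutcomeSummary",
    "summarize_outcomes",
]


@dataclass
class ParameterRanges:
    """Sampled ranges, fixed values, proliferation targets and composition bounds."""

    sample: dict  # name -> (min, max)
    fixed: dict = field(default_factory=dict)
    targets: dict = field(default_factory=dict)  # T_d_days, GF, prolif_rate
    bounds: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, (lo, hi) in self.sample.items():
            if lo > hi:
                raise ValueError(f"range for {name} has min > max")

    @classmethod
    def from_yaml(cls, path) -> "ParameterRanges":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            sample={k: tuple(v) for k, v in raw.get("sample", {}).items()},
            fixed=dict(raw.get("fixed", {})),
            targets=dict(raw.get("targets", {})),
            bounds=dict(raw.get("bounds", {})),
        )


def lhs_sample(ranges: ParameterRanges, n: int, seed: int | None = None) -> list[dict]:
    """n Latin-hypercube points over the sampled dimensions (one point per
    equal-probability stratum per dimension); fixed values are attached as-is.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = list(ranges.sample)
    if not names:
        raise ValueError("no sampled dimensions")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n)
    lo = np.array([ranges.sample[k][0] for k in names])
    hi = np.array([ranges.sample[k][1] for k in names])
    pts = qmc.scale(unit, lo, hi)
    out = []
    for row in pts:
        p = dict(zip(names, row))
        p.update(ranges.fixed)
        if "N_LIMP" in p:
            p["N_LIMP"] = int(round(p["N_LIMP"]))
        out.append(p)
    return out


# -- aspatial steady-state profiling ----------------------------------------


def steady_state_profile(
    params: VirtualTumorParameters,
    relax_factor: float = 4.0,
    fit_fraction: float = 0.4,
) -> dict:
    """Free-growth steady state of a single lattice voxel.

    Runs the cytokinetic dynamics without spatial effects until the
    compartment distribution reaches its exponential steady state, then
    measures the growth fraction, the realized growth rate (log-linear fit of
    living count over the trailing window) and the population composition.
    Returns the normalized compartment distribution for seeding phantoms.
    """
    index = params.build_index()
    grid = VoxelGrid(1, 1, 1, voxel_edge_mm=1.0)
    state = GCState(grid, index, np.zeros((index.n_comp, 1)), capacity=np.inf)
    # seed at the predicted stationary composition; any discrepancy between
    # the closed-form balance and the actual dynamics shows up as drift in
    # the measured rate/fractions, so this run is an independent check
    state.data[:, 0] = 1000.0 * stationary_composition(params, index)["composition"]

    horizon = max(
        relax_factor * params.T_c * 2,
        3.0 * params.T_G0,
        3.0 * params.T_N,
        3.0 * params.T_A,
        600.0,
    )
    n_steps = int(round(horizon / params.dt))
    living_series = np.empty(n_steps)
    for step in range(n_steps):
        cytokinetic_step(state, params)
        living_series[step] = state.living()[0]

    tail = slice(int(n_steps * (1.0 - fit_fraction)), n_steps)
    t = np.arange(n_steps)[tail] * params.dt
    y = np.log(np.maximum(living_series[tail], 1e-300))
    rate = float(np.polyfit(t, y, 1)[0])

    cat = state.category_totals()
    living = cat["cycling"] + cat["g0"] + cat["diff"]
    total = state.total_count()
    dist = state.data[:, 0] / total
    return {
        "growth_rate": rate,
        "doubling_time_days": math.log(2.0) / rate / 24.0 if rate > 0 else math.inf,
        "growth_fraction": cat["cycling"] / living if living > 0 else math.nan,
        "stem_over_living": cat["stem"] / living if living > 0 else math.nan,
        "necrotic_over_total": cat["necr"] / total,
        "apoptotic_over_total": cat["apop"] / total,
        "composition": dist,
    }


# -- discrete stationary balance ---------------------------------------------
#
# In free growth the per-step compartment update is linear, so the population
# settles into an exponential regime x_{t+1} = z x_t.  Because the hierarchy
# is feed-forward (stem -> LIMP generations -> DIFF -> dead pools) every pool
# size along that regime has a closed form once the per-step growth factor z
# of the stem subsystem is known.  With per-step survivals s = e^{-R_A dt},
# sD = e^{-(R_ADiff+R_NDiff) dt}, G0 exit probability f = 1 - e^{-dt/T_G0}
# and n cycle bins, z solves
#
#     (z/s)^n = 1 + P_sym W(z),
#     W(z) = (1 - P_sleep) + P_sleep P_G0toG1 f s / (z - s (1 - f)),
#
# the discrete analogue of the continuous renewal relation (to which it
# converges as dt -> 0).  These closed forms make virtual-tumor derivation
# exact and instantaneous; :func:`steady_state_profile` remains the
# independent simulation-based measurement of the same quantities.


def _discrete_w(z, s, f, p_sleep, p_g0):
    return (1.0 - p_sleep) + p_sleep * p_g0 * f * s / (z - s * (1.0 - f))


def discrete_growth_factor(
    n: int, s: float, f: float, p_sym: float, p_sleep: float, p_g0: float
) -> float:
    """Per-step growth factor z of the stem subsystem (discrete renewal root)."""
    if p_sym == 0.0:
        return s

    def h(z):
        return n * (math.log(z) - math.log(s)) - math.log1p(
            p_sym * _discrete_w(z, s, f, p_sleep, p_g0)
        )

    lo = s * (1.0 - f) + 1e-12
    while h(lo) > 0:  # numerically degenerate; nudge the bracket
        lo = s * (1.0 - f) + (lo - s * (1.0 - f)) * 0.1
    hi = s * (1.0 + p_sym) ** (1.0 / n) + 1e-9
    while h(hi) < 0:
        hi *= 2.0
    from scipy.optimize import brentq

    return brentq(h, lo, hi, xtol=1e-15, rtol=8.9e-16)


def p_sym_for_discrete_factor(
    z: float, n: int, s: float, f: float, p_sleep: float, p_g0: float
) -> float:
    """Symmetric-division fraction making the discrete renewal root equal z."""
    return ((z / s) ** n - 1.0) / _discrete_w(z, s, f, p_sleep, p_g0)


def stationary_composition(params: VirtualTumorParameters, index=None) -> dict:
    """Exact stationary pools and compartment distribution of the discrete
    free-growth dynamics.

    Returns growth rate (ln z / dt), growth fraction, composition fractions
    and the normalized per-compartment distribution vector (for seeding
    phantoms at steady state).
    """
    index = index or params.build_index()
    dt = params.dt
    n = index.n_cycle_bins
    s = math.exp(-params.R_A * dt)
    f = -math.expm1(-dt / params.T_G0)
    sD = math.exp(-(params.R_ADiff + params.R_NDiff) * dt)
    ps, pg = params.P_sleep, params.P_G0toG1
    z = discrete_growth_factor(n, s, f, params.P_sym, ps, pg)
    W = _discrete_w(z, s, f, ps, pg)

    ratio = s / z
    cycle_sum = (1.0 - ratio**n) / (1.0 - ratio) if ratio != 1.0 else float(n)
    g0_denom = z - s * (1.0 - f)

    dist = np.zeros(index.n_comp)
    J = {"STEM": 1.0}
    m_prev = None
    C_tot = G_tot = 0.0
    C_stem = g_stem = 0.0
    for lin in index.lineages:
        if lin == "STEM":
            j_in = 1.0
            sleep_src = params.P_sym  # only the extra symmetric daughter sleeps
        elif lin == "LIMP_1":
            sleep_src = 1.0 - params.P_sym
            j_in = m_prev * sleep_src * W
        else:
            sleep_src = 1.0
            j_in = m_prev * (1.0 + W)
        m_here = j_in * (s**n) / (z**n)
        c0 = j_in / z
        bins = c0 * ratio ** np.arange(n)
        g = sleep_src * m_prev * ps / g0_denom if lin != "STEM" else (
            params.P_sym * ps * m_here / g0_denom
        )
        cyc = index.cycle_slice(lin)
        dist[cyc] = bins
        dist[index.g0_index(lin)] = g
        C_tot += bins.sum()
        G_tot += g
        if lin == "STEM":
            C_stem, g_stem = bins.sum(), g
        m_prev = m_here
        J[lin] = j_in
    J_D = 2.0 * m_prev
    D = J_D / (z - sD) if z > sD else math.inf
    dist[index.diff_index] = D

    wA = params.R_ADiff / (params.R_ADiff + params.R_NDiff) if (
        params.R_ADiff + params.R_NDiff
    ) > 0 else 0.0
    J_A = (1.0 - s) * (C_tot + G_tot) + (1.0 - sD) * wA * D
    J_N = (1.0 - sD) * (1.0 - wA) * D + (1.0 - pg) * s * f * G_tot
    inv = 1.0 / z
    geo_A = (1.0 - inv**index.n_apop_bins) / (1.0 - inv) if z != 1.0 else float(
        index.n_apop_bins
    )
    geo_N = (1.0 - inv**index.n_necr_bins) / (1.0 - inv) if z != 1.0 else float(
        index.n_necr_bins
    )
    dist[index.apop] = (J_A / z) * inv ** np.arange(index.n_apop_bins)
    dist[index.necr] = (J_N / z) * inv ** np.arange(index.n_necr_bins)
    A = dist[index.apop].sum()
    Q = dist[index.necr].sum()

    living = C_tot + G_tot + D
    total = living + A + Q
    rate = math.log(z) / dt
    return {
        "z": z,
        "growth_rate": rate,
        "doubling_time_days": math.log(2.0) / rate / 24.0 if rate > 0 else math.inf,
        "growth_fraction": C_tot / living,
        "stem_over_living": (C_stem + g_stem) / living,
        "necrotic_over_total": Q / total,
        "apoptotic_over_total": A / total,
        "composition": dist / dist.sum(),
        "pools": {"C": C_tot, "G": G_tot, "D": D, "A": A, "N": Q, "J_D": J_D},
    }


@dataclass
class CohortMember:
    params: VirtualTumorParameters
    record: dict
    exclusion: str | None = None

    @property
    def retained(self) -> bool:
        return self.exclusion is None


@dataclass
class VirtualCohort:
    members: list

    @property
    def retained(self) -> list:
        return [m for m in self.members if m.retained]

    def __len__(self):
        return len(self.members)


def derive_constrained_params(
    point: dict,
    targets: dict,
    prolif_rate: float,
    base: VirtualTumorParameters | None = None,
) -> CohortMember:
    """Complete a sampled point into a full virtual tumor.

    ``targets`` needs ``T_d_days`` (volume doubling time) and ``GF`` (growth
    fraction); ``prolif_rate`` is the metabolic proliferation rate a (h^-1)
    at the tumor's glucose level.  P_sleep comes from the metabolic rate
    (renewal-relation inversion over the dt-discretized effective cycle
    length), P_sym from the discrete renewal root at the T_d target, and
    R_NDiff from the exact stationary DIFF-pool balance at the GF target.
    Derivation failures mark the tumor excluded rather than raising.
    """
    if targets.get("T_d_days", 0) <= 0 or not 0 < targets.get("GF", 0) < 1:
        raise ValueError("targets must have positive T_d_days and GF in (0,1)")
    base = base or VirtualTumorParameters()
    fields = {k: v for k, v in point.items() if hasattr(base, k)}
    params = base.with_(**fields)
    params.validate()
    index = params.build_index()
    T_c_eff = index.T_c_eff
    dt = params.dt

    record = dict(point)
    p_sleep = psleep_from_rate(prolif_rate, T_c_eff, params.T_G0, params.P_G0toG1)
    record["P_sleep"] = p_sleep
    if not 0.0 <= p_sleep <= 1.0:
        params = params.with_(P_sleep=min(max(p_sleep, 0.0), 1.0))
        return CohortMember(params, record, exclusion="negative P_sleep"
                            if p_sleep < 0 else "P_sleep > 1")
    params = params.with_(P_sleep=p_sleep)

    a_target = math.log(2.0) / (24.0 * targets["T_d_days"])
    s = math.exp(-params.R_A * dt)
    f = -math.expm1(-dt / params.T_G0)
    z_target = math.exp(a_target * dt)
    p_sym = p_sym_for_discrete_factor(
        z_target, index.n_cycle_bins, s, f, p_sleep, params.P_G0toG1
    )
    record["P_sym"] = p_sym
    if not 0.0 < p_sym <= 1.0:
        params = params.with_(P_sym=min(max(p_sym, 0.0), 1.0))
        return CohortMember(params, record, exclusion="P_sym out of (0, 1]")
    params = params.with_(P_sym=p_sym)

    # GF target -> required DIFF pool -> R_NDiff via the stationary balance
    gf_target = targets["GF"]
    ref = stationary_composition(params.with_(R_NDiff=0.0), index)
    C, G = ref["pools"]["C"], ref["pools"]["G"]
    J_D = ref["pools"]["J_D"]
    D_needed = C * (1.0 / gf_target - 1.0) - G
    record["GF_target"] = gf_target
    if D_needed <= 0:
        return CohortMember(params, record, exclusion="negative R_NDiff")
    sD = z_target - J_D / D_needed
    if sD <= 0:
        return CohortMember(params, record, exclusion="GF target unreachable")
    r_ndiff = -math.log(sD) / dt - params.R_ADiff
    record["R_NDiff"] = r_ndiff
    if r_ndiff < 0:
        return CohortMember(params, record, exclusion="negative R_NDiff")
    params = params.with_(R_NDiff=r_ndiff)

    prof = stationary_composition(params, index)
    record.update(GF=prof["growth_fraction"], **_profile_record(prof))
    return CohortMember(params, record)


def _profile_record(prof: dict) -> dict:
    return {
        "achieved_T_d_days": prof["doubling_time_days"],
        "achieved_growth_rate": prof["growth_rate"],
        "stem_over_living": prof["stem_over_living"],
        "necrotic_over_total": prof["necrotic_over_total"],
        "apoptotic_over_total": prof["apoptotic_over_total"],
        "composition": prof["composition"],
    }


def apply_exclusions(cohort: VirtualCohort, bounds: dict) -> VirtualCohort:
    """Tag tumors violating composition bounds; already-tagged members keep
    their original reason."""
    for m in cohort.members:
        if m.exclusion is not None:
            continue
        r = m.record
        p = m.params
        reason = None
        for name in ("P_sleep", "P_sym", "P_G0toG1"):
            v = getattr(p, name)
            if not 0.0 <= v <= 1.0:
                reason = f"{name} out of [0, 1]"
                break
        if reason is None and (p.R_NDiff < 0 or p.R_ADiff < 0 or p.R_A < 0):
            reason = "negative transition rate"
        if reason is None and "p_sym_max" in bounds and p.P_sym > bounds["p_sym_max"]:
            reason = "P_sym above cap"
        if reason is None and "stem_living" in bounds:
            lo, hi = bounds["stem_living"]
            if not lo <= r.get("stem_over_living", math.nan) <= hi:
                reason = "stem fraction out of range"
        if reason is None and "necrotic_total_max" in bounds:
            if r.get("necrotic_over_total", 0.0) > bounds["necrotic_total_max"]:
                reason = "necrotic fraction above bound"
        if reason is None and "apoptotic_total_max" in bounds:
            if r.get("apoptotic_over_total", 0.0) > bounds["apoptotic_total_max"]:
                reason = "apoptotic fraction above bound"
        m.exclusion = reason
    return cohort


def generate_cohort(
    ranges: ParameterRanges,
    n: int,
    prolif_rate: float | None = None,
    seed: int | None = None,
    base: VirtualTumorParameters | None = None,
) -> VirtualCohort:
    """LHS -> constraint solving -> exclusions, end to end.

    ``prolif_rate`` defaults to ``targets["prolif_rate"]`` (h^-1); the upper
    end of the sampled T_c range is additionally capped at ln2/a, the longest
    cycle compatible with the metabolic proliferation rate.
    """
    targets = dict(ranges.targets)
    a = prolif_rate if prolif_rate is not None else targets.get("prolif_rate")
    if a is None or a <= 0:
        raise ValueError("a positive metabolic proliferation rate is required")
    sample = dict(ranges.sample)
    if "T_c" in sample:
        lo, hi = sample["T_c"]
        cap = math.log(2.0) / a
        sample["T_c"] = (min(lo, cap), min(hi, cap))
    capped = ParameterRanges(sample, ranges.fixed, targets, ranges.bounds)
    members = [
        derive_constrained_params(pt, targets, a, base=base)
        for pt in lhs_sample(capped, n, seed)
    ]
    return apply_exclusions(VirtualCohort(members), ranges.bounds)


# -- outcome metrics ---------------------------------------------------------


def tcp_poisson(n_surviving_csc: float) -> float:
    """Poisson tumor control probability exp(-N) for N surviving clonogens."""
    if n_surviving_csc < 0:
        raise ValueError("surviving clonogen count must be >= 0")
    return math.exp(-n_surviving_csc)


def equivalent_diameter(volume_mm3: float, convention: str = "cbrt") -> float:
    """Equivalent tumor diameter in mm.

    The default cube-root convention d = V^(1/3) treats the voxel edge as the
    length scale; ``convention="sphere"`` gives the sphere-equivalent
    diameter (6V/pi)^(1/3).
    """
    if volume_mm3 < 0:
        raise ValueError("volume must be >= 0")
    if convention == "cbrt":
        return volume_mm3 ** (1.0 / 3.0)
    if convention == "sphere":
        return (6.0 * volume_mm3 / math.pi) ** (1.0 / 3.0)
    raise ValueError(f"unknown convention {convention!r}")


def doubling_time_from_volumes(V1: float, V2: float, dt_days: float) -> float:
    """Volume doubling time T_d = dt ln2 / ln(V2/V1) between two scans.

    Negative results flag a shrinking tumor.
    """
    if V1 <= 0 or V2 <= 0:
        raise ValueError("volumes must be positive")
    if V2 == V1:
        raise ValueError("identical volumes give an undefined doubling time")
    return dt_days * math.log(2.0) / math.log(V2 / V1)


@dataclass
class OutcomeSummary:
    n: int
    volume_median: float
    volume_iqr: tuple
    reduction_median: float | None
    reduction_iqr: tuple | None
    tcp_median: float
    tcp_iqr: tuple
    compatible: bool | None = None


def _quartiles(x: np.ndarray) -> tuple[float, tuple]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), (float(q1), float(q3))


def summarize_outcomes(
    results: list[SimulationResult],
    observed_reduction: float | None = None,
) -> OutcomeSummary:
    """Median/IQR of final volume, volume reduction and Poisson TCP.

    With an observed volume-reduction fraction, the summary flags whether it
    lies within the box-whisker range (1.5 IQR fences clipped to the data).
    """
    if not results:
        raise ValueError("no results to summarize")
    vol = np.array([r.series["volume_mm3"][-1] for r in results])
    v0 = np.array([r.series["volume_mm3"][0] for r in results])
    tcp = np.array([tcp_poisson(r.surviving_stem) for r in results])
    red = 1.0 - vol / v0
    vmed, viqr = _quartiles(vol)
    rmed, riqr = _quartiles(red)
    tmed, tiqr = _quartiles(tcp)
    compatible = None
    if observed_reduction is not None:
        q1, q3 = riqr
        lo_f, hi_f = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        lo = max(lo_f, red.min())
        hi = min(hi_f, red.max())
        compatible = bool(lo <= observed_reduction <= hi)
    return OutcomeSummary(
        n=len(results),
        volume_median=vmed,
        volume_iqr=viqr,
        reduction_median=rmed,
        reduction_iqr=riqr,
        tcp_median=tmed,
        tcp_iqr=tiqr,
        compatible=compatible,
    )
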