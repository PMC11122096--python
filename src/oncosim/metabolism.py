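"""Constraint-based cell metabolism: growth-then-lactate optimization.

Cancer cells are assumed to operate at (near-)optimal growth constrained by
flux balance (Sv = 0), reaction bounds, a Michaelis--Menten glucose-uptake
bound, and a solvent-capacity ("crowding") constraint sum_i a_i |v_i| <=
C_enz limiting total enzyme mass.  The Warburg strategy is a two-step
program: (1) maximize growth to obtain mu*; (2) maximize lactate secretion
subject to mu >= k mu*, lowering k stepwise until the lactate rate clears a
small tolerance.  Sweeping normalized glucose u produces the phenotype table
(growth rate, lactate and uptake per u) consumed by the coupling layer.

Linear programs are solved with scipy's HiGHS interface; every returned
solution is re-verified against the constraint set independently of the
solver.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "MMKinetics",
    "StoichiometricModel",
    "FluxSolution",
    "PhenotypeTable",
    "mm_uptake_bound",
    "fba_max_growth",
    "lactate_strategy",
    "phenotype_sweep",
    "interpolate_phenotype",
]


@dataclass(frozen=True)
class MMKinetics:
    """Michaelis--Menten glucose-uptake kinetics (concentrations in kg/m^3)."""

    vmax: float = 1.2
    Km: float = 0.2704
    Cmax: float = 0.9
    normalized: bool = True


def mm_uptake_bound(
    C: float,
    vmax: float = 1.2,
    Km: float = 0.2704,
    Cmax: float = 0.9,
    normalized: bool = True,
) -> float:
    """Glucose-uptake flux bound v_bound = vmax C / (Km + C).

    In normalized mode (default) the curve is rescaled by (Km + Cmax)/Cmax so
    the bound reaches exactly vmax at the maximum observed tissue
    concentration Cmax.
    """
    if C < 0:
        raise ValueError("concentration must be >= 0")
    raw = vmax * C / (Km + C)
    if not normalized:
        return raw
    if C > Cmax * (1 + 1e-12):
        warnings.warn("concentration above Cmax; uptake bound clamped to vmax")
        return vmax
    return min(vmax, raw * (Km + Cmax) / Cmax)


_TERM = re.compile(r"^\s*(?:(\d+\.?\d*|\.\d+)\s+)?(\S+)\s*$")


def _parse_side(side: str) -> list[tuple[float, str]]:
    side = side.strip()
    if not side:
        return []
    out = []
    for term in side.split("+"):
        m = _TERM.match(term)
        if not m:
            raise ValueError(f"cannot parse stoichiometry term {term!r}")
        coeff = float(m.group(1)) if m.group(1) else 1.0
        out.append((coeff, m.group(2)))
    return out


@dataclass
class StoichiometricModel:
    """A metabolic network with bounds and crowding costs.

    S has one row per metabolite and one column per reaction; exchange
    reactions simply have unbalanced columns (metabolites appear or vanish).
    """

    metabolites: list
    reactions: list
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    crowding: np.ndarray
    C_enz: float
    biomass: str = "BIOMASS"
    lactate: str = "LAC_out"
    glucose_uptake: str = "GLC_up"

    def __post_init__(self):
        m, n = len(self.metabolites), len(self.reactions)
        self.S = np.asarray(self.S, float)
        self.lb = np.asarray(self.lb, float)
        self.ub = np.asarray(self.ub, float)
        self.crowding = np.asarray(self.crowding, float)
        if self.S.shape != (m, n):
            raise ValueError("S dimensions inconsistent with names")
        if (self.lb > self.ub).any():
            raise ValueError("lower bound above upper bound")
        for rxn in (self.biomass, self.lactate, self.glucose_uptake):
            if rxn not in self.reactions:
                raise ValueError(f"designated reaction {rxn!r} missing")
        self._pos = {r: i for i, r in enumerate(self.reactions)}

    def reaction_index(self, name: str) -> int:
        return self._pos[name]

    def with_bounds(self, **bounds) -> "StoichiometricModel":
        """Copy with per-reaction (lb, ub) overrides, e.g. GLC_up=(0, 0.4)."""
        lb, ub = self.lb.copy(), self.ub.copy()
        for rxn, (lo, hi) in bounds.items():
            i = self.reaction_index(rxn)
            lb[i], ub[i] = lo, hi
        return StoichiometricModel(
            self.metabolites, self.reactions, self.S, lb, ub, self.crowding,
            self.C_enz, self.biomass, self.lactate, self.glucose_uptake,
        )

    @classmethod
    def from_tsv(cls, path) -> "StoichiometricModel":
        """Read a reaction table: name, equation, lb, ub, crowding columns.

        ``# key: value`` comment lines set C_enz and the designated biomass,
        lactate and glucose_uptake reactions.
        """
        meta = {"C_enz": 0.078, "biomass": "BIOMASS", "lactate": "LAC_out",
                "glucose_uptake": "GLC_up"}
        names, eqs, lbs, ubs, crowd = [], [], [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                if line.startswith("#"):
                    m = re.match(r"#\s*(\w+)\s*:\s*(\S+)", line)
                    if m:
                        key, val = m.groups()
                        if key in meta:
                            meta[key] = float(val) if key == "C_enz" else val
                    continue
                parts = line.split("\t")
                if parts[0].lower() in ("reaction", "name", "id"):
                    continue
                names.append(parts[0])
                eqs.append(parts[1])
                lbs.append(float(parts[2]))
                ubs.append(float(parts[3]))
                crowd.append(float(parts[4]) if len(parts) > 4 else 0.0)
        mets: list[str] = []
        entries = []
        for j, eq in enumerate(eqs):
            if "->" not in eq:
                raise ValueError(f"reaction {names[j]!r} has no '->'")
            lhs, rhs = eq.split("->")
            for sign, side in ((-1.0, lhs), (1.0, rhs)):
                for coeff, met in _parse_side(side):
                    if met not in mets:
                        mets.append(met)
                    entries.append((mets.index(met), j, sign * coeff))
        S = np.zeros((len(mets), len(names)))
        for i, j, v in entries:
            S[i, j] += v
        return cls(mets, names, S, np.array(lbs), np.array(ubs), np.array(crowd),
                   C_enz=meta["C_enz"], biomass=meta["biomass"],
                   lactate=meta["lactate"], glucose_uptake=meta["glucose_uptake"])


@dataclass
class FluxSolution:
    fluxes: np.ndarray
    mu: float
    lactate: float
    glucose_uptake: float
    achieved_k: float | None = None
    flagged: bool = False

    def verify(self, model: StoichiometricModel, tol: float = 1e-8):
        """Independent post-hoc check of every constraint class."""
        v = self.fluxes
        scale = max(1.0, np.abs(v).max())
        if np.abs(model.S @ v).max() > tol * scale:
            raise AssertionError("flux balance Sv = 0 violated")
        if (v < model.lb - tol * scale).any() or (v > model.ub + tol * scale).any():
            raise AssertionError("flux bounds violated")
        if model.crowding @ np.abs(v) > model.C_enz * (1 + tol) + tol:
            raise AssertionError("solvent-capacity constraint violated")


def _solve_lp(model: StoichiometricModel, objective: np.ndarray,
              extra_A_ub=None, extra_b_ub=None):
    """max objective . v via flux splitting (v = v+ - v-) for |v| crowding."""
    n = len(model.reactions)
    lbp = np.maximum(model.lb, 0.0)
    ubp = np.maximum(model.ub, 0.0)
    lbn = np.maximum(-model.ub, 0.0)
    ubn = np.maximum(-model.lb, 0.0)
    A_eq = np.hstack([model.S, -model.S])
    b_eq = np.zeros(model.S.shape[0])
    rows_ub = [np.concatenate([model.crowding, model.crowding])]
    b_ub = [model.C_enz]
    if extra_A_ub is not None:
        for row, b in zip(extra_A_ub, extra_b_ub):
            rows_ub.append(np.concatenate([row, -row]))
            b_ub.append(b)
    c = -np.concatenate([objective, -objective])
    res = linprog(
        c,
        A_ub=np.array(rows_ub),
        b_ub=np.array(b_ub),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=list(zip(lbp, ubp)) + list(zip(lbn, ubn)),
        method="highs",
    )
    if not res.success:
        kind = "infeasible" if res.status == 2 else (
            "unbounded" if res.status == 3 else "solver failure")
        raise RuntimeError(
            f"LP {kind}: check flux bounds / balance / crowding constraints "
            f"({res.message})"
        )
    return res.x[:n] - res.x[n:]


def fba_max_growth(model: StoichiometricModel) -> FluxSolution:
    """Step 1: maximize the growth (biomass) rate."""
    obj = np.zeros(len(model.reactions))
    obj[model.reaction_index(model.biomass)] = 1.0
    v = _solve_lp(model, obj)
    sol = FluxSolution(
        v,
        mu=v[model.reaction_index(model.biomass)],
        lactate=v[model.reaction_index(model.lactate)],
        glucose_uptake=v[model.reaction_index(model.glucose_uptake)],
    )
    sol.verify(model)
    return sol


def lactate_strategy(
    model: StoichiometricModel,
    k_start: float = 0.99,
    k_step: float = 0.01,
    k_min: float = 0.50,
    lactate_tol: float = 0.01,
) -> FluxSolution:
    """Two-step Warburg optimization: growth first, then lactate.

    Iterates k = k_start, k_start - k_step, ... maximizing lactate subject to
    mu >= k mu* until the lactate secretion rate reaches ``lactate_tol``; if
    no k >= k_min achieves it the k_min solution is returned flagged.
    """
    if not 0.0 < k_start <= 1.0 or k_step <= 0:
        raise ValueError("invalid k schedule")
    best = fba_max_growth(model)
    mu_star = best.mu
    obj = np.zeros(len(model.reactions))
    obj[model.reaction_index(model.lactate)] = 1.0
    growth_row = np.zeros(len(model.reactions))
    growth_row[model.reaction_index(model.biomass)] = -1.0  # -mu <= -k mu*
    k = k_start
    last = None
    while k >= k_min - 1e-12:
        v = _solve_lp(model, obj, extra_A_ub=[growth_row], extra_b_ub=[-k * mu_star])
        last = FluxSolution(
            v,
            mu=v[model.reaction_index(model.biomass)],
            lactate=v[model.reaction_index(model.lactate)],
            glucose_uptake=v[model.reaction_index(model.glucose_uptake)],
            achieved_k=k,
        )
        last.verify(model)
        if last.lactate >= lactate_tol:
            return last
        k = round(k - k_step, 12)
    last.flagged = True
    return last


# -- phenotype table ---------------------------------------------------------


@dataclass
class PhenotypeTable:
    """Metabolic map u -> (growth rate, lactate, glucose uptake).

    ``u`` is the normalized glucose concentration c/cn in [0, 1]; growth
    rates are in h^-1 and the proliferation time is ln 2 / a.
    """

    u: np.ndarray
    growth_rate: np.ndarray
    lactate: np.ndarray = None
    glucose_uptake: np.ndarray = None

    def __post_init__(self):
        self.u = np.asarray(self.u, float)
        order = np.argsort(self.u)
        self.u = self.u[order]
        self.growth_rate = np.asarray(self.growth_rate, float)[order]
        for name in ("lactate", "glucose_uptake"):
            val = getattr(self, name)
            setattr(
                self, name,
                np.asarray(val, float)[order] if val is not None
                else np.full(self.u.size, np.nan),
            )
        if self.u.size == 0:
            raise ValueError("empty phenotype table")
        if (self.growth_rate < 0).any():
            raise ValueError("negative growth rates")

    @property
    def proliferation_time_h(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(2.0) / self.growth_rate

    def frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "u": self.u,
                "growth_rate_per_h": self.growth_rate,
                "proliferation_time_h": self.proliferation_time_h,
                "lactate": self.lactate,
                "glucose_uptake": self.glucose_uptake,
            }
        )

    def to_csv(self, path):
        self.frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PhenotypeTable":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            df["u"].to_numpy(),
            df["growth_rate_per_h"].to_numpy(),
            df.get("lactate"),
            df.get("glucose_uptake"),
        )


def phenotype_sweep(
    model: StoichiometricModel,
    glucose_grid,
    kinetics: MMKinetics = MMKinetics(),
    rate_scale: float = 1.0,
    **strategy_kw,
) -> PhenotypeTable:
    """Run the lactate strategy across normalized glucose levels.

    For each u the glucose-uptake upper bound is set from the MM kinetics at
    concentration u * Cmax.  ``rate_scale`` converts the biomass flux to a
    growth rate in h^-1 (1.0 for the toy network, whose biomass stoichiometry
    is already scaled).
    """
    us, a, lac, upt = [], [], [], []
    for u in glucose_grid:
        if not 0.0 <= u <= 1.0 + 1e-12:
            raise ValueError("normalized glucose must be in [0, 1]")
        bound = mm_uptake_bound(
            u * kinetics.Cmax, kinetics.vmax, kinetics.Km, kinetics.Cmax,
            kinetics.normalized,
        )
        m = model.with_bounds(**{model.glucose_uptake: (0.0, bound)})
        if bound <= 0:
            sol = FluxSolution(np.zeros(len(model.reactions)), 0.0, 0.0, 0.0)
        else:
            sol = lactate_strategy(m, **strategy_kw)
        us.append(u)
        a.append(rate_scale * sol.mu)
        lac.append(sol.lactate)
        upt.append(sol.glucose_uptake)
    return PhenotypeTable(np.array(us), np.array(a), np.array(lac), np.array(upt))


def interpolate_phenotype(table: PhenotypeTable, u) -> np.ndarray | float:
    """Piecewise-linear growth rate a(u), clamped at the table ends."""
    u_arr = np.asarray(u, float)
    if ((u_arr < -1e-12) | (u_arr > 1 + 1e-12)).any():
        raise ValueError("normalized glucose must be in [0, 1]")
    out = np.interp(u_arr, table.u, table.growth_rate)
    return float(out) if np.isscalar(u) or u_arr.ndim == 0 else out
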