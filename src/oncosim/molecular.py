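"""Cell-kill-rate algebra and a generic Boolean-network cell-fate engine.

Cell kill rates (CKR, the fraction of cells lethally hit per administration)
are combined and patient-adjusted on the rate-constant scale: with
CKR = 1 - e^{-kt}, additivity of the rate constants k (rather than of the
CKRs themselves) gives the drug-combination rule, and the ratio of model cell
death probabilities between a patient and a control rescales the literature
rate constant (k_adj / k_lit = ln(1-CKR_adj) / ln(1-CKR_lit)).

The fate engine iterates a threshold Boolean network (synchronous updates,
signed integer weights) to a point or cyclic attractor and classifies the
attractor into a cell fate (progression / apoptosis / senescence).  A hybrid
mode alternates the Boolean step with a user-supplied fast module held at
pseudo-steady state, mirroring the two-time-scale signalling/cell-fate split.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DrugSpec",
    "BooleanNetwork",
    "Attractor",
    "FatePredicates",
    "combine_ckr",
    "adjust_ckr",
    "atm_activation_prob",
    "survival_with_quadratic",
    "find_attractor",
    "hybrid_fate_ensemble",
]

FATES = ("progression", "apoptosis", "senescence")


@dataclass(frozen=True)
class DrugSpec:
    name: str
    ckr_lit: float
    death_phase: str

    def __post_init__(self):
        if not 0.0 <= self.ckr_lit < 1.0:
            raise ValueError("literature CKR must be in [0, 1)")


def combine_ckr(ckrs) -> float:
    """Combined CKR for simultaneous drugs under rate-constant additivity.

    k_i = -ln(1 - CKR_i); the combination is 1 - exp(-sum k_i), i.e. the
    product of the single-agent survival fractions.
    """
    total_k = 0.0
    for c in ckrs:
        if not 0.0 <= c < 1.0:
            raise ValueError("each CKR must be in [0, 1) (CKR=1 has infinite rate)")
        total_k += -math.log1p(-c)
    return -math.expm1(-total_k)


def adjust_ckr(ckr_lit: float, p_patient: float, p_control: float) -> float:
    """Patient-specific CKR from the model cell-death probability ratio.

    r = p_patient / p_control scales the literature rate constant, so
    CKR_adj = 1 - (1 - CKR_lit)^r.
    """
    if not 0.0 < ckr_lit < 1.0:
        raise ValueError("literature CKR must be in (0, 1)")
    if p_control <= 0:
        raise ValueError("control death probability must be positive")
    if p_patient < 0:
        raise ValueError("patient death probability must be >= 0")
    r = p_patient / p_control
    return -math.expm1(r * math.log1p(-ckr_lit))


def atm_activation_prob(alpha: float, dose: float) -> float:
    """Probability that the ATM node stays OFF after a dose D: exp(-alpha D).

    The activation probability of the DNA-damage sensor is 1 - exp(-alpha D);
    only the dose-linear part of the LQ model is representable in the
    discrete damage network.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    return math.exp(-alpha * dose)


def survival_with_quadratic(s_model: float, beta: float, dose: float) -> float:
    """Modify a network-derived survival by the LQ quadratic term exp(-beta D^2)."""
    if not 0.0 <= s_model <= 1.0:
        raise ValueError("survival must be in [0, 1]")
    return s_model * math.exp(-beta * dose * dose)


# -- Boolean network engine --------------------------------------------------


@dataclass
class BooleanNetwork:
    """Threshold Boolean network with signed integer weights.

    Synchronous update: s_i(t+1) = 1 iff sum_j w[j, i] s_j(t) > theta_i.
    """

    nodes: list
    weights: np.ndarray  # (n, n), w[j, i] = effect of node j on node i
    thresholds: np.ndarray  # (n,)

    def __post_init__(self):
        n = len(self.nodes)
        self.weights = np.asarray(self.weights, int)
        self.thresholds = np.asarray(self.thresholds, float)
        if self.weights.shape != (n, n) or self.thresholds.shape != (n,):
            raise ValueError("inconsistent network dimensions")
        self._node_pos = {name: i for i, name in enumerate(self.nodes)}

    def node_index(self, name: str) -> int:
        return self._node_pos[name]

    def step(self, state: np.ndarray) -> np.ndarray:
        return (state @ self.weights > self.thresholds).astype(np.int8)

    @classmethod
    def from_edges(cls, nodes, edges, thresholds=None) -> "BooleanNetwork":
        """Build from (source, target, weight) triples."""
        nodes = list(nodes)
        pos = {name: i for i, name in enumerate(nodes)}
        w = np.zeros((len(nodes), len(nodes)), int)
        for src, dst, weight in edges:
            w[pos[src], pos[dst]] = int(weight)
        if thresholds is None:
            th = np.zeros(len(nodes))
        elif isinstance(thresholds, dict):
            th = np.array([thresholds.get(n, 0.0) for n in nodes], float)
        else:
            th = np.asarray(thresholds, float)
        return cls(nodes, w, th)

    @classmethod
    def from_json(cls, path) -> "BooleanNetwork":
        with open(path) as fh:
            raw = json.load(fh)
        return cls.from_edges(raw["nodes"], raw["edges"], raw.get("thresholds"))

    @classmethod
    def from_tsv(cls, path) -> "BooleanNetwork":
        """Edge list TSV: source<TAB>target<TAB>weight; thresholds default 0."""
        edges, nodes = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                src, dst, w = line.split("\t")[:3]
                edges.append((src, dst, int(w)))
                for n in (src, dst):
                    if n not in nodes:
                        nodes.append(n)
        return cls.from_edges(nodes, edges)


@dataclass
class Attractor:
    kind: str  # "point" | "cyclic"
    states: np.ndarray  # (period, n) binary states in cycle order
    basin_entry_step: int

    @property
    def period(self) -> int:
        return self.states.shape[0]

    def node_on_fraction(self, net: BooleanNetwork, name: str) -> float:
        return float(self.states[:, net.node_index(name)].mean())

    def oscillates(self, net: BooleanNetwork, name: str) -> bool:
        col = self.states[:, net.node_index(name)]
        return bool(col.min() != col.max())


def find_attractor(net: BooleanNetwork, initial_state) -> Attractor:
    """Iterate synchronously with visited-state hashing until a state repeats.

    Terminates in at most 2^n steps (finite state space).
    """
    s = np.asarray(initial_state, np.int8)
    if s.shape != (len(net.nodes),) or not np.isin(s, (0, 1)).all():
        raise ValueError("initial state must be binary with one entry per node")
    seen: dict[bytes, int] = {}
    trajectory = [s]
    step = 0
    while True:
        key = s.tobytes()
        if key in seen:
            start = seen[key]
            cycle = np.array(trajectory[start:-1])
            kind = "point" if cycle.shape[0] == 1 else "cyclic"
            return Attractor(kind, cycle, basin_entry_step=start)
        seen[key] = step
        s = net.step(s)
        trajectory.append(s)
        step += 1


@dataclass
class FatePredicates:
    """Total mapping from attractor features to a cell fate.

    ``rules`` is an ordered list of (fate, predicate(attractor, net) -> bool);
    the first matching rule wins and ``default`` catches everything else so
    the mapping is total.
    """

    rules: list
    default: str = "progression"

    def __post_init__(self):
        for fate, _ in self.rules:
            if fate not in FATES:
                raise ValueError(f"unknown fate {fate!r}")
        if self.default not in FATES:
            raise ValueError(f"unknown fate {self.default!r}")

    def classify(self, attractor: Attractor, net: BooleanNetwork) -> str:
        for fate, pred in self.rules:
            if pred(attractor, net):
                return fate
        return self.default


def hybrid_fate_ensemble(
    net: BooleanNetwork,
    predicates: FatePredicates,
    ensemble,
    fast_module=None,
    interface_nodes=(),
    interface_thresholds=None,
    max_rounds: int = 256,
    seed: int | None = None,
) -> dict:
    """Mean fate probabilities over an ensemble of initial conditions.

    Per ensemble member the fast module (if any) is evaluated at pseudo-steady
    state given the current Boolean state, its interface values are
    discretized by threshold and written into the interface nodes, then one
    synchronous Boolean step is taken; the alternation repeats until the slow
    network reaches an attractor, which is classified into a fate.  With no
    fast module this reduces to plain attractor search.  The mean apoptosis
    probability is the cell-death probability fed to :func:`adjust_ckr`.
    """
    rng = np.random.default_rng(seed)
    del rng  # deterministic synchronous dynamics; kept for interface parity
    iface_idx = [net.node_index(n) for n in interface_nodes]
    if interface_thresholds is None:
        interface_thresholds = np.zeros(len(iface_idx))
    counts = {f: 0 for f in FATES}
    for init in ensemble:
        s = np.asarray(init, np.int8).copy()
        if fast_module is None:
            att = find_attractor(net, s)
        else:
            seen: dict[bytes, int] = {}
            states: list[np.ndarray] = []
            att = None
            for step in range(max_rounds):
                vals = np.asarray(fast_module(s), float)
                s[iface_idx] = (vals > interface_thresholds).astype(np.int8)
                key = s.tobytes()
                if key in seen:
                    cycle = np.array(states[seen[key]:])
                    kind = "point" if cycle.shape[0] == 1 else "cyclic"
                    att = Attractor(kind, cycle, basin_entry_step=seen[key])
                    break
                seen[key] = step
                states.append(s.copy())
                s = net.step(s)
            if att is None:
                raise RuntimeError("hybrid iteration did not converge")
        counts[predicates.classify(att, net)] += 1
    n = sum(counts.values())
    return {f: counts[f] / n for f in FATES}
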