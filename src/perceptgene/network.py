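"""Multilayer perceptgene networks, majority-function design constraints,
and sequestration-programmable weights.

The two-layer soft-majority design is analyzed in a *linear-domain*
piecewise abstraction: layer pre-activations are affine combinations
``Y = sum n_i I_i + B`` of binary inputs, and each activation is piecewise
linear with clamp thresholds (Z = 0 below gamma_L, 1 above gamma_H, linear
between).  The printed eight-row truth table of the 3-input majority
function becomes a set of inequality constraints on the weights and
biases; :func:`majority_constraints` evaluates them row by row with slack,
and :func:`truth_table_equivalence` checks the same table by direct
network evaluation, so the two routes can be cross-validated draw by draw.

Log-domain composition of actual perceptgene units (power-law stage plus
Michaelis-Menten activation) is handled by :class:`NetworkSpec` /
:func:`evaluate_network`; a sequestration (titration) equilibrium that
makes one internal weight inducer-programmable is in
:func:`free_activator` / :func:`apparent_hill`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import least_squares

from .model import PerceptgeneParams, Surface, activation, collective_signal

__all__ = [
    "PiecewisePerceptron",
    "ConstraintReport",
    "NetworkSpec",
    "SequestrationParams",
    "HillFit",
    "evaluate_piecewise",
    "majority_constraints",
    "truth_table_equivalence",
    "evaluate_network",
    "classify_log_midpoint",
    "free_activator",
    "sequestration_dose_response",
    "apparent_hill",
    "MAJORITY_FIXTURE",
    "MAJORITY_GAMMAS",
    "MAJORITY_LEVELS",
    "majority_network_fixture",
    "majority_binary_states",
]


@dataclass(frozen=True)
class PiecewisePerceptron:
    """Linear-domain perceptron with a piecewise-linear clamp activation."""

    weights: tuple[float, ...]
    bias: float
    gamma_low: float
    gamma_high: float

    def __post_init__(self):
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if self.gamma_low >= self.gamma_high:
            raise ValueError(
                f"gamma_low ({self.gamma_low}) must be < gamma_high ({self.gamma_high})"
            )

    def f_activation(self, Y: float) -> float:
        """Clamp interpolation; ties take the clamp value (Z=0 at gamma_L,
        Z=1 at gamma_H)."""
        if Y <= self.gamma_low:
            return 0.0
        if Y >= self.gamma_high:
            return 1.0
        return (Y - self.gamma_low) / (self.gamma_high - self.gamma_low)


def evaluate_piecewise(p: PiecewisePerceptron, inputs) -> tuple[float, float]:
    """Pre-activation Y = sum n_i I_i + B and clamped output Z."""
    inputs = tuple(float(v) for v in inputs)
    if len(inputs) != len(p.weights):
        raise ValueError("input count does not match weight count")
    Y = sum(n * I for n, I in zip(p.weights, inputs)) + p.bias
    return Y, p.f_activation(Y)


@dataclass
class ConstraintReport:
    """Row-by-row satisfaction of the majority-function design constraints.

    ``rows`` maps each constrained input state ('001', '010', ...) to a
    list of (description, satisfied, slack) triples; a row is satisfied
    when all its member inequalities hold (slack >= 0)."""

    rows: dict[str, list[tuple[str, bool, float]]]

    @property
    def row_satisfied(self) -> dict[str, bool]:
        return {k: all(ok for _, ok, _ in v) for k, v in self.rows.items()}

    @property
    def row_slack(self) -> dict[str, float]:
        return {k: min(s for _, _, s in v) for k, v in self.rows.items()}

    @property
    def feasible(self) -> bool:
        return all(self.row_satisfied.values())


def majority_constraints(
    n1: float, n2: float, n3: float, m: float, B1: float, B2: float,
    gamma_l1: float, gamma_h1: float, gamma_l2: float, gamma_h2: float,
) -> ConstraintReport:
    """Evaluate the printed 3-input-majority truth-table constraints.

    Layer 1 takes inputs 1 and 2 (weights n1, n2, bias B1); its output Z1
    enters layer 2 with weight m alongside input 3 (weight n3, bias B2).
    States 000 and 111 are subsumed by 001 and by 110/101/011 for
    non-negative weights.  Slack is the signed margin of each inequality
    (>= 0 means satisfied; clamp ties count as satisfied, matching the
    activation's tie rules)."""
    l1 = PiecewisePerceptron((n1, n2), B1, gamma_l1, gamma_h1)
    fA1 = l1.f_activation
    rows: dict[str, list[tuple[str, bool, float]]] = {}

    def lo(desc, value, gamma):  # value must sit at or below gamma
        return (desc, value <= gamma, gamma - value)

    def hi(desc, value, gamma):  # value must sit at or above gamma
        return (desc, value >= gamma, value - gamma)

    rows["001"] = [
        lo("B1 <= gamma_L1 (Z1 clamps to 0)", B1, gamma_l1),
        lo("B2 + n3 <= gamma_L2", B2 + n3, gamma_l2),
    ]
    for state, nk in (("010", n2), ("100", n1)):
        rows[state] = [
            lo(f"B1 + n_k < gamma_H1 (f_A1 < 1), state {state}", B1 + nk,
               gamma_h1),
            lo("B2 + m*f_A1(B1+n_k) <= gamma_L2",
               B2 + m * fA1(B1 + nk), gamma_l2),
        ]
    for state, nk in (("011", n2), ("101", n1)):
        rows[state] = [
            hi(f"B1 + n_k > gamma_L1 (f_A1 > 0), state {state}", B1 + nk,
               gamma_l1),
            hi("B2 + n3 + m*f_A1(B1+n_k) >= gamma_H2",
               B2 + n3 + m * fA1(B1 + nk), gamma_h2),
        ]
    rows["110"] = [
        hi("B1 + n1 + n2 >= gamma_H1 (Z1 clamps to 1)", B1 + n1 + n2, gamma_h1),
        hi("B2 + m >= gamma_H2", B2 + m, gamma_h2),
    ]
    # strict-inequality rows use non-strict slacks: ties coincide with the
    # clamp conventions (Z=0 at gamma_L, Z=1 at gamma_H) and carry zero slack
    for state in ("011", "101"):
        desc, ok, slack = rows[state][0]
        rows[state][0] = (desc, slack > 0, slack)
    desc, ok, slack = rows["001"][0]
    rows["001"][0] = (desc, slack >= 0, slack)
    for state in ("010", "100"):
        desc, ok, slack = rows[state][0]
        rows[state][0] = (desc, slack > 0, slack)
    return ConstraintReport(rows)


_MAJORITY_STATES = [tuple(int(c) for c in f"{k:03b}") for k in range(8)]


def _majority(state: tuple[int, int, int]) -> int:
    return 1 if sum(state) >= 2 else 0


def truth_table_equivalence(
    n1: float, n2: float, n3: float, m: float, B1: float, B2: float,
    gamma_l1: float, gamma_h1: float, gamma_l2: float, gamma_h2: float,
) -> bool:
    """Exhaustively evaluate the two-layer piecewise network on all 8 states.

    The check enforces the full printed truth table: the output must clamp
    to the exact binary majority value (Y2 at or beyond the layer-2
    thresholds), and the intermediate Z1 column must hold (Z1 = 0 for
    states 00x, Z1 = 1 for 11x, 0 < Z1 for x-high singles feeding an
    active row, Z1 < 1 for singles feeding a suppressed row).  By
    construction this agrees with :func:`majority_constraints` for
    non-negative weights."""
    l1 = PiecewisePerceptron((n1, n2), B1, gamma_l1, gamma_h1)
    for state in _MAJORITY_STATES:
        i1, i2, i3 = state
        Y1, Z1 = evaluate_piecewise(l1, (i1, i2))
        Y2 = n3 * i3 + m * Z1 + B2
        want = _majority(state)
        if want == 1 and Y2 < gamma_h2:
            return False
        if want == 0 and Y2 > gamma_l2:
            return False
        # intermediate-layer truth-table column
        if (i1, i2) == (0, 0) and Z1 != 0.0:
            return False
        if (i1, i2) == (1, 1) and Z1 != 1.0:
            return False
        if i1 + i2 == 1:
            if i3 == 0 and Z1 >= 1.0:
                return False
            if i3 == 1 and Z1 <= 0.0:
                return False
    return True


#: Pinned feasible majority parameter set (found by grid search over
#: (n1, n2, n3, m, B1, B2) in [0, 2]^6 at the gammas below).
MAJORITY_FIXTURE = dict(n1=0.8, n2=0.8, n3=0.8, m=1.6, B1=0.1, B2=0.05)
MAJORITY_GAMMAS = dict(gamma_l1=0.2, gamma_h1=1.6, gamma_l2=0.9, gamma_h2=1.6)


def majority_network_fixture(
    ahl_weight: float = 0.45,
    activation_weight: float = 1.9,
) -> "NetworkSpec":
    """Two-layer log-domain soft-majority network.

    Layer 1 integrates AHL (tunable promoter-variant weight) and IPTG
    (measured weight 0.93) through a steep activation whose Hill weight is
    inducer-tunable; its output (a T7-polymerase-like signal) enters layer
    2 with unit weight alongside aTc (weight 1.05).  Input scales sit at
    the geometric midpoints of the low/high induction ranges used for the
    binary truth states (:func:`majority_binary_states`)."""
    layer1 = PerceptgeneParams(
        input_names=("AHL", "IPTG"),
        weights=(ahl_weight, 0.93),
        input_scales=(0.775, 31.6),
        bias=0.355,
        hill=activation_weight,
        basal=0.01,
    )
    layer2 = PerceptgeneParams(
        input_names=("layer1", "aTc"),
        weights=(1.0, 1.05),
        input_scales=(1.0, 6.1),
        bias=4.0,
        hill=2.0,
        basal=0.01,
    )
    return NetworkSpec(units={"layer1": layer1, "layer2": layer2},
                       external_inputs=("AHL", "IPTG", "aTc"),
                       output="layer2")


#: Low/high induction levels of the three majority inputs.
MAJORITY_LEVELS = {"AHL": (0.1875, 3.0), "IPTG": (7.8125, 125.0),
                   "aTc": (1.5625, 25.0)}


def majority_binary_states() -> list[dict[str, float]]:
    """The eight low/high input combinations, in binary-counting order."""
    states = []
    for k in range(8):
        bits = [(k >> (2 - i)) & 1 for i in range(3)]
        states.append({
            name: MAJORITY_LEVELS[name][bit]
            for name, bit in zip(("AHL", "IPTG", "aTc"), bits)
        })
    return states


@dataclass
class NetworkSpec:
    """A DAG of perceptgene units.

    ``units`` maps a unit name to its :class:`PerceptgeneParams`; each of a
    unit's ``input_names`` must resolve to an external input, another
    unit's output z, or a junction.  ``junctions`` are multiplicative
    complex-formation nodes (e.g. a polymerase-tRNA complex): their value
    is the product of their source signals."""

    units: dict[str, PerceptgeneParams]
    external_inputs: tuple[str, ...]
    output: str
    junctions: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        self.external_inputs = tuple(self.external_inputs)
        self.junctions = {k: tuple(v) for k, v in self.junctions.items()}
        if self.output not in self.units:
            raise ValueError(f"output unit {self.output!r} is not defined")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"network contains a cycle: {cycle}")
        known = set(self.external_inputs) | set(self.units) | set(self.junctions)
        for name, params in self.units.items():
            for src in params.input_names:
                if src not in known:
                    raise ValueError(
                        f"unit {name!r} references unknown input {src!r}"
                    )
        for name, sources in self.junctions.items():
            for src in sources:
                if src not in known:
                    raise ValueError(
                        f"junction {name!r} references unknown source {src!r}"
                    )

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.external_inputs)
        g.add_nodes_from(self.units)
        g.add_nodes_from(self.junctions)
        for name, params in self.units.items():
            for src in params.input_names:
                g.add_edge(src, name)
        for name, sources in self.junctions.items():
            for src in sources:
                g.add_edge(src, name)
        return g


def evaluate_network(spec: NetworkSpec, inputs: dict[str, float],
                     order: list[str] | None = None) -> dict[str, float]:
    """Topologically evaluate every unit; returns all z's plus junctions.

    ``inputs`` supplies external input concentrations (> 0).  The result
    maps each unit name to its output z and each junction to its product
    value; the network output is at ``spec.output``.  The evaluation is
    invariant to the choice of topological order."""
    missing = [n for n in spec.external_inputs if n not in inputs]
    if missing:
        raise ValueError(f"missing external inputs: {missing}")
    values: dict[str, float] = {n: float(inputs[n]) for n in spec.external_inputs}
    if order is None:
        order = list(nx.topological_sort(spec.graph()))
    else:
        pos = {n: i for i, n in enumerate(order)}
        for u, v in spec.graph().edges:
            if pos[u] > pos[v]:
                raise ValueError("supplied order is not topological")
    for node in order:
        if node in values:
            continue
        if node in spec.junctions:
            prod = 1.0
            for src in spec.junctions[node]:
                prod *= values[src]
            values[node] = prod
        elif node in spec.units:
            params = spec.units[node]
            x = [values[src] for src in params.input_names]
            y = collective_signal(params, x)
            values[node] = float(activation(y, params.hill, params.basal))
    return values


def classify_log_midpoint(z: float, basal: float) -> int:
    """Binary classification at half the maximum fold change in log scale.

    The midpoint between basal (log10 beta) and saturation (0) is
    sqrt(beta); outputs at or above it classify as 1."""
    return 1 if z >= math.sqrt(basal) else 0


@dataclass(frozen=True)
class SequestrationParams:
    """1:1 titration of an activator A by a sequestering anti-activator D."""

    activator_total: float
    sequestrator_total: float
    K_AD: float

    def __post_init__(self):
        if self.activator_total < 0 or self.sequestrator_total < 0:
            raise ValueError("total concentrations must be >= 0")
        if self.K_AD <= 0:
            raise ValueError("K_AD must be > 0")


def free_activator(seq: SequestrationParams) -> float:
    """Free activator concentration from the A + D <-> AD equilibrium.

    Positive root of A_free^2 + A_free (D_tot - A_tot + K) - K A_tot = 0;
    lies in [0, A_tot] and decreases in D_tot."""
    A, D, K = seq.activator_total, seq.sequestrator_total, seq.K_AD
    b = D - A + K
    disc = b * b + 4.0 * K * A
    if disc < 0:
        raise ArithmeticError("negative discriminant in titration quadratic")
    root = (-b + math.sqrt(disc)) / 2.0
    return min(max(root, 0.0), A)


def sequestration_dose_response(
    input_grid: np.ndarray,
    sequestrator_total: float,
    *,
    activator_max: float = 10.0,
    input_hill: float = 1.0,
    input_K: float = 1.0,
    K_AD: float = 10.0,
    K_act: float = 1.0,
    hill_act: float = 2.0,
    basal: float = 0.01,
) -> Surface:
    """Dose response of a perceptgene whose activator is titrated.

    The inducer drives total activator expression through a saturating
    stage, A_tot = A_max * (x/K)^h / (1 + (x/K)^h); the anti-activator at
    ``sequestrator_total`` shunts it via :func:`free_activator`; the free
    fraction drives a Hill activation.  Raising the sequestrator pushes
    the activation threshold into the compressive (saturating) part of the
    expression stage, which lowers the apparent Hill coefficient, raises
    the apparent K, and reduces the maximum fold change of the composite
    response — the phenomenology of an inducer-programmable internal
    weight."""
    x = np.asarray(input_grid, dtype=float)
    z = np.empty_like(x)
    for i, xi in enumerate(x.flat):
        u = (xi / input_K) ** input_hill
        a_tot = activator_max * u / (1.0 + u)
        a_free = free_activator(SequestrationParams(a_tot, sequestrator_total, K_AD))
        z.flat[i] = activation(max(a_free, 1e-300) / K_act, hill_act, basal)
    return Surface(inputs={"input": x}, outputs=z, coordinates="linear")


@dataclass
class HillFit:
    """Hill-function fit of a single-input dose response."""

    K_eff: float
    m_eff: float
    basal: float
    r_squared: float
    success: bool
    message: str = ""


def apparent_hill(curve: Surface, basal_bounds=(1e-8, 0.5)) -> HillFit:
    """Least-squares Hill fit z = ((x/K)^m + beta) / (1 + (x/K)^m).

    Fit in log10 output space (fold changes, not absolute differences,
    carry the information in these data); requires >= 6 points."""
    if len(curve.inputs) != 1:
        raise ValueError("apparent_hill requires a single-input dose response")
    (x,) = curve.inputs.values()
    z = curve.mean_output()
    if x.size < 6:
        raise ValueError("need at least 6 dose-response points")
    logz = np.log10(z)

    def model(theta):
        logK, m, logbeta = theta
        ym = (x / 10.0 ** logK) ** m
        return np.log10((ym + 10.0 ** logbeta) / (1.0 + ym))

    def resid(theta):
        return model(theta) - logz

    z0 = max(z.min(), 1e-6)
    theta0 = [math.log10(np.median(x)), 1.0, math.log10(z0)]
    lb = [math.log10(x.min()) - 3, 0.05, math.log10(basal_bounds[0])]
    ub = [math.log10(x.max()) + 3, 10.0, math.log10(basal_bounds[1])]
    theta0 = np.clip(theta0, lb, ub)
    sol = least_squares(resid, theta0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14)
    ss_res = float(np.sum(sol.fun ** 2))
    ss_tot = float(np.sum((logz - logz.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if not sol.success:
        raise RuntimeError(
            f"Hill fit did not converge: {sol.message}; best-so-far "
            f"K={10 ** sol.x[0]:.3g}, m={sol.x[1]:.3g}"
        )
    return HillFit(K_eff=float(10.0 ** sol.x[0]), m_eff=float(sol.x[1]),
                   basal=float(10.0 ** sol.x[2]), r_squared=r2,
                   success=True, message=sol.message)
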