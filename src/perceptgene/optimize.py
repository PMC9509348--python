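"""Logarithmic cost, chain-rule gradient signs, and discrete two-phase
backpropagation over genetic weight libraries.

Gene-circuit weights cannot be tuned continuously: an activation weight is
selected by an inducer concentration from a pre-chosen set, an input
weight by picking one of a few promoter variants.  Optimization therefore
walks a finite grid.  The cost is the logarithmic mean squared error

    <C> = (1/2N) * sum_i (log10(z_Di / z_i))^2

over the N truth-table states, which weighs fold-change errors rather than
absolute ones.  The partial derivative of the cost with respect to any
weight is obtained analytically by the chain rule through the layer
outputs; only its *sign* is used, to move the weight to the adjacent
library value in the descending direction.  The walk alternates phases
(one tunable weight per phase) until a full pass makes no move, every
state reaches its binary target, or a library boundary pins the weight.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np

from .model import collective_signal
from .network import NetworkSpec, classify_log_midpoint, evaluate_network

__all__ = [
    "TruthSpec",
    "WeightLibrary",
    "Trajectory",
    "CostGrid",
    "log_mse_cost",
    "normalize_outputs",
    "NetworkCostEvaluator",
    "gradient_sign",
    "discrete_backprop",
    "exhaustive_cost_surface",
    "sample_count",
    "majority_truth_spec",
    "ARABINOSE_WEIGHT_LIBRARY",
    "LUX_VARIANT_WEIGHT_LIBRARY",
]

#: Tie tolerance: cost differences below this count as a zero gradient.
TIE_TOL = 1e-12


@dataclass(frozen=True)
class TruthSpec:
    """Input states and desired normalized outputs z_D in (0, 1]."""

    states: tuple[dict, ...]
    desired: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(dict(s) for s in self.states))
        object.__setattr__(self, "desired", tuple(float(d) for d in self.desired))
        if len(self.states) < 1:
            raise ValueError("need at least one truth state")
        if len(self.states) != len(self.desired):
            raise ValueError("one desired output per state is required")
        if any(d <= 0 for d in self.desired):
            raise ValueError("desired outputs must be > 0")

    @property
    def batch_size(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class WeightLibrary:
    """Discrete tunable-weight values (inducer levels, promoter variants)."""

    name: str
    values: tuple[float, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) == 0:
            raise ValueError(f"weight library {self.name!r} is empty")
        if any(v <= 0 for v in vals):
            raise ValueError("library values must be > 0")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("library values must be sorted ascending, no duplicates")
        if self.labels is not None and len(self.labels) != len(vals):
            raise ValueError("one label per library value is required")

    def __len__(self) -> int:
        return len(self.values)


#: Activation weights addressable by the six pre-selected Arabinose levels
#: (mM), lowest inducer first.
ARABINOSE_WEIGHT_LIBRARY = WeightLibrary(
    name="P_BAD/AraC",
    values=(0.4, 0.7, 1.0, 1.4, 1.9, 2.5),
    labels=("0.007 mM", "0.015 mM", "0.031 mM", "0.062 mM", "0.125 mM", "0.25 mM"),
)

#: Input weights of the four LuxR-operator promoter variants.
LUX_VARIANT_WEIGHT_LIBRARY = WeightLibrary(
    name="P_lux/AHL",
    values=(0.1, 0.2, 0.27, 0.45),
    labels=("TCTA", "GTTG", "GAGC", "TGGG"),
)


def log_mse_cost(observed, desired) -> float:
    """<C> = (1/2N) sum (log10(z_D / z))^2; zero iff all outputs match."""
    z = np.asarray(observed, dtype=float)
    zd = np.asarray(desired, dtype=float)
    if z.shape != zd.shape:
        raise ValueError("observed and desired lengths differ")
    if np.any(z <= 0) or np.any(zd <= 0):
        raise ValueError("outputs must be > 0 (log domain)")
    return float(np.mean(np.log10(zd / z) ** 2) / 2.0)


def normalize_outputs(raw, basal: float):
    """Scale by the highest level measured and floor at the basal level."""
    raw = np.asarray(raw, dtype=float)
    top = raw.max()
    if top <= 0:
        raise ValueError("all outputs are non-positive; cannot normalize")
    return np.maximum(raw / top, basal)


class NetworkCostEvaluator:
    """Cost of a perceptgene network over a truth table, with analytic
    chain-rule gradients with respect to named tunable weights.

    Weights are addressed as ``"<unit>:w:<input_name>"`` (a power-law input
    weight) or ``"<unit>:hill"`` (the activation weight m of a unit).
    Setting a weight rebuilds the unit parameters; gradients are computed
    by reverse accumulation of d log10 z_out / d weight through the DAG,
    using each layer's evaluated intermediate output.
    """

    def __init__(self, spec: NetworkSpec, truth: TruthSpec):
        self.spec = spec
        self.truth = truth

    # -- weight plumbing ---------------------------------------------------
    def _with_weight(self, spec: NetworkSpec, name: str, value: float) -> NetworkSpec:
        unit_name, kind, *rest = name.split(":")
        if unit_name not in spec.units:
            raise KeyError(f"no unit {unit_name!r} for tunable weight {name!r}")
        params = spec.units[unit_name]
        if kind == "hill":
            new = replace(params, hill=value)
        elif kind == "w":
            (input_name,) = rest
            if input_name not in params.input_names:
                raise KeyError(
                    f"unit {unit_name!r} has no input {input_name!r} "
                    f"(weight {name!r} is not tunable)"
                )
            idx = params.input_names.index(input_name)
            weights = list(params.weights)
            weights[idx] = value
            new = replace(params, weights=tuple(weights))
        else:
            raise KeyError(f"unknown weight kind in {name!r}")
        units = dict(spec.units)
        units[unit_name] = new
        return NetworkSpec(units=units, external_inputs=spec.external_inputs,
                           output=spec.output, junctions=spec.junctions)

    def _apply(self, config: Mapping[str, float]) -> NetworkSpec:
        spec = self.spec
        for name, value in config.items():
            spec = self._with_weight(spec, name, value)
        return spec

    # -- cost and gradient -------------------------------------------------
    def outputs(self, config: Mapping[str, float]) -> np.ndarray:
        spec = self._apply(config)
        return np.array([
            evaluate_network(spec, state)[spec.output] for state in self.truth.states
        ])

    def cost(self, config: Mapping[str, float]) -> float:
        return log_mse_cost(self.outputs(config), self.truth.desired)

    def classified_correct(self, config: Mapping[str, float]) -> bool:
        """Every state on the correct side of the log-midpoint threshold."""
        spec = self._apply(config)
        basal = spec.units[spec.output].basal
        z = self.outputs(config)
        return all(
            classify_log_midpoint(zi, basal) == (1 if zd >= math.sqrt(basal) else 0)
            for zi, zd in zip(z, self.truth.desired)
        )

    def _dlogz_dweight(self, spec: NetworkSpec, state: Mapping[str, float],
                       weight: str) -> float:
        """d log10(z_out) / d w by reverse accumulation over the DAG."""
        values = evaluate_network(spec, state)
        # activation log-log sensitivities S_u = dln z_u / dln y_u
        sens: dict[str, float] = {}
        ys: dict[str, float] = {}
        for name, params in spec.units.items():
            x = [values[src] for src in params.input_names]
            y = float(collective_signal(params, x))
            ys[name] = y
            ym = y ** params.hill
            sens[name] = (params.hill * ym * (1.0 - params.basal)
                          / ((ym + params.basal) * (1.0 + ym)))
        # adjoint[u] = d log z_out / d log value_u
        adjoint: dict[str, float] = {n: 0.0 for n in values}
        adjoint[spec.output] = 1.0
        order = list(nx.topological_sort(spec.graph()))
        for node in reversed(order):
            a = adjoint.get(node, 0.0)
            if a == 0.0:
                continue
            if node in spec.units:
                params = spec.units[node]
                for src, n_w in zip(params.input_names, params.weights):
                    adjoint[src] = adjoint.get(src, 0.0) + a * sens[node] * n_w
            elif node in spec.junctions:
                for src in spec.junctions[node]:
                    adjoint[src] = adjoint.get(src, 0.0) + a
        unit_name, kind, *rest = weight.split(":")
        params = spec.units[unit_name]
        a_unit = adjoint.get(unit_name, 0.0)
        if kind == "hill":
            # d log10 z / dm = S * log10(y) / m
            return a_unit * sens[unit_name] * math.log10(max(ys[unit_name], 1e-300)) \
                / params.hill
        (input_name,) = rest
        idx = params.input_names.index(input_name)
        src = params.input_names[idx]
        K = params.input_scales[idx]
        x = values[src]
        return a_unit * sens[unit_name] * math.log10(x / K)

    def dcost_dweight(self, config: Mapping[str, float], weight: str) -> float:
        """Analytic dC/dw at the given weight configuration."""
        spec = self._apply(config)
        z = self.outputs(config)
        total = 0.0
        for state, zi, zd in zip(self.truth.states, z, self.truth.desired):
            dlz = self._dlogz_dweight(spec, state, weight)
            total += math.log10(zi / zd) * dlz
        return total / self.truth.batch_size


def _neighbors(lib: WeightLibrary, idx: int) -> tuple[int | None, int | None]:
    lo = idx - 1 if idx > 0 else None
    hi = idx + 1 if idx < len(lib) - 1 else None
    return lo, hi


def gradient_sign(
    evaluator,
    weight: str,
    config_idx: Mapping[str, int],
    libraries: Mapping[str, WeightLibrary],
) -> int:
    """Sign of dC/dw at the current library configuration, in {-1, 0, +1}.

    For a :class:`NetworkCostEvaluator` the derivative is computed
    analytically through the chain rule; for a plain cost callable it
    falls back to finite differences over the neighboring library values.
    Cost differences below the tie tolerance report 0."""
    if weight not in libraries:
        raise KeyError(f"weight {weight!r} has no library (not tunable)")
    lib = libraries[weight]
    idx = config_idx[weight]
    values = {n: libraries[n].values[i] for n, i in config_idx.items()}
    if isinstance(evaluator, NetworkCostEvaluator):
        d = evaluator.dcost_dweight(values, weight)
        if abs(d) < TIE_TOL:
            return 0
        return 1 if d > 0 else -1
    # finite-difference fallback over neighboring library values
    cost = _as_cost_fn(evaluator)
    lo, hi = _neighbors(lib, idx)
    c0 = cost(values)
    dlo = dhi = None
    if lo is not None:
        v = dict(values); v[weight] = lib.values[lo]
        dlo = c0 - cost(v)  # positive: moving down decreases... sign bookkeeping below
    if hi is not None:
        v = dict(values); v[weight] = lib.values[hi]
        dhi = cost(v) - c0
    slopes = [d for d in (dlo, dhi) if d is not None]
    if not slopes:
        raise ValueError(f"weight {weight!r} has a single-value library")
    slope = float(np.mean(slopes))
    if abs(slope) < TIE_TOL:
        return 0
    return 1 if slope > 0 else -1


def _as_cost_fn(evaluator) -> Callable[[Mapping[str, float]], float]:
    if isinstance(evaluator, NetworkCostEvaluator):
        return evaluator.cost
    if callable(evaluator):
        return evaluator
    raise TypeError("evaluator must be a NetworkCostEvaluator or a cost callable")


@dataclass
class Trajectory:
    """An optimization path: per-step configuration, cost, and phase."""

    steps: list[tuple[dict[str, float], float, str]] = field(default_factory=list)
    converged: bool = False
    reason: str = ""

    @property
    def costs(self) -> list[float]:
        return [c for _, c, _ in self.steps]

    @property
    def final_config(self) -> dict[str, float]:
        return self.steps[-1][0]

    @property
    def final_cost(self) -> float:
        return self.steps[-1][1]

    @property
    def configurations_visited(self) -> int:
        seen = {tuple(sorted(cfg.items())) for cfg, _, _ in self.steps}
        return len(seen)


def discrete_backprop(
    evaluator,
    libraries: Mapping[str, WeightLibrary],
    start: Mapping[str, int] | str = "lowest",
    phase_order: Sequence[str] | None = None,
    max_passes: int = 10,
    success_predicate: Callable[[Mapping[str, float]], bool] | None = None,
) -> Trajectory:
    """Two-phase coordinate descent over discrete weight libraries.

    Each phase tunes one weight: the weight moves to the adjacent library
    value opposite the gradient sign, accepting only cost-decreasing moves,
    until the sign is 0, a boundary is hit, or the move would not improve.
    Phases repeat in order until a full pass makes no move (at most
    ``max_passes`` passes), or until ``success_predicate`` reports that all
    outputs reached their binary targets.  The recorded cost sequence over
    accepted steps is non-increasing."""
    cost = _as_cost_fn(evaluator)
    if phase_order is None:
        phase_order = list(libraries)
    if isinstance(start, str):
        if start != "lowest":
            raise ValueError("start must be an index mapping or 'lowest'")
        config_idx = {name: 0 for name in libraries}
    else:
        config_idx = dict(start)
    for name in phase_order:
        if name not in libraries:
            raise KeyError(f"phase weight {name!r} has no library")

    def values_of(cfg):
        return {n: libraries[n].values[i] for n, i in cfg.items()}

    traj = Trajectory()
    c = cost(values_of(config_idx))
    traj.steps.append((values_of(config_idx), c, "start"))
    if success_predicate is not None and success_predicate(values_of(config_idx)):
        traj.converged = True
        traj.reason = "all outputs at their binary targets"
        return traj
    for _pass in range(max_passes):
        moved_in_pass = False
        for phase, weight in enumerate(phase_order, start=1):
            while True:
                sign = gradient_sign(evaluator, weight, config_idx, libraries)
                if sign == 0:
                    break
                candidate = config_idx[weight] - sign
                if candidate < 0 or candidate >= len(libraries[weight]):
                    break  # boundary: only the interior remains, already here
                trial = dict(config_idx)
                trial[weight] = candidate
                c_new = cost(values_of(trial))
                if not (c_new < c - 0.0):
                    break  # adjacent move would not improve: local minimum
                config_idx = trial
                c = c_new
                moved_in_pass = True
                traj.steps.append((values_of(config_idx), c, f"phase {phase}"))
                if success_predicate is not None and success_predicate(
                        values_of(config_idx)):
                    traj.converged = True
                    traj.reason = "all outputs at their binary targets"
                    return traj
        if not moved_in_pass:
            traj.converged = True
            traj.reason = "no move in a full pass (local minimum)"
            return traj
    traj.converged = False
    traj.reason = f"pass budget ({max_passes}) exhausted"
    return traj


@dataclass
class CostGrid:
    """Exhaustive cost surface over the full library product."""

    weight_names: tuple[str, ...]
    axes: tuple[tuple[float, ...], ...]
    costs: np.ndarray

    @property
    def argmin(self) -> dict[str, float]:
        idx = np.unravel_index(int(np.argmin(self.costs)), self.costs.shape)
        return {n: self.axes[k][i] for k, (n, i) in enumerate(zip(self.weight_names, idx))}

    @property
    def min_cost(self) -> float:
        return float(self.costs.min())

    @property
    def n_configurations(self) -> int:
        return int(self.costs.size)


def exhaustive_cost_surface(evaluator, libraries: Mapping[str, WeightLibrary]) -> CostGrid:
    """Evaluate the cost at every library combination."""
    cost = _as_cost_fn(evaluator)
    names = tuple(libraries)
    axes = tuple(libraries[n].values for n in names)
    shape = tuple(len(a) for a in axes)
    grid = np.empty(shape)
    for idx in itertools.product(*(range(s) for s in shape)):
        values = {n: axes[k][i] for k, (n, i) in enumerate(zip(names, idx))}
        grid[idx] = cost(values)
    return CostGrid(weight_names=names, axes=axes, costs=grid)


def majority_truth_spec(low_output: float = 0.01) -> TruthSpec:
    """Truth table for the 3-input soft majority on the network fixture.

    Desired outputs are 1 for majority-high states and the basal level for
    majority-low states."""
    from .network import majority_binary_states

    states = majority_binary_states()
    desired = []
    for k, _ in enumerate(states):
        bits = [(k >> (2 - i)) & 1 for i in range(3)]
        desired.append(1.0 if sum(bits) >= 2 else low_output)
    return TruthSpec(states=tuple(states), desired=tuple(desired))


def sample_count(configurations: int, states: int, replicates: int = 1) -> int:
    """Measurements consumed: states x configurations x replicates."""
    if configurations < 0 or states < 0 or replicates < 0:
        raise ValueError("counts must be >= 0")
    return int(configurations) * int(states) * int(replicates)
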