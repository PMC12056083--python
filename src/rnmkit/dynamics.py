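"""Continuous-logic dynamics: clamped sigmoid-decay updates to steady state.

The update rule is the standardized continuous-logic ordinary differential
equation family used for semi-quantitative regulatory networks: each
unclamped node relaxes toward a normalized sigmoid of its aggregated
regulator input,

    dx_i/dt = f(ω_i) − γ x_i,

discretized by explicit Euler with step ``dt``.  The sigmoid is calibrated
so that ω = 0 maps to target 0, ω = 0.5 to 0.5 and ω = 1 to 1, which makes
the clamp semantics 0 / 0.5 / 1 (knock-down / basal / full activation)
carry over to downstream targets.

Aggregated input ω of a node combines its activators and inhibitors as

    ω = (Σ w_a x_a / Σ w_a) · (1 − Σ w_b x_b / Σ w_b),

with the activator factor taken as 1 (full basal drive) when the node has
inhibitors but no activators.  A node with no regulators at all either
self-sustains (ω equals its own activation; generic nodes) or, when it is
a pure external input (an unregulated mechanoreceptor or cytokine), has
ω = 0 and decays unless clamped.

Clamped nodes are held at their clamp value at every iteration; all state
values live in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .network import NetworkError, RegulatoryNetwork

__all__ = [
    "DynamicsParams",
    "DynamicsError",
    "StateVector",
    "ClampSet",
    "CompiledNetwork",
    "input_strength",
    "step_dynamics",
    "solve_steady_state",
    "solve_ensemble",
    "sample_initial_states",
]

StateVector = Mapping[str, float]
ClampSet = Mapping[str, float]


class DynamicsError(RuntimeError):
    """Raised when an update produces a non-finite activation."""


@dataclass(frozen=True)
class DynamicsParams:
    """Parameters of the continuous-logic update.

    gain:
        Sigmoid steepness h; larger values sharpen the switch around
        ω = 0.5 (and enable bistability through positive feedback).
    decay:
        Linear decay rate γ; the steady state of an isolated regulated
        node is f(ω)/γ.
    step:
        Euler step dt.
    tol:
        Convergence tolerance on the flow residual max_i |f(ω_i) − γ x_i|.
    max_iter:
        Iteration cap; hitting it flags non-convergence (e.g. an
        oscillatory attractor) rather than raising.
    """

    gain: float = 10.0
    decay: float = 1.0
    step: float = 0.1
    tol: float = 1e-6
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.decay <= 0 or self.step <= 0:
            raise ValueError("gain, decay and step must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def _validate_state(network: RegulatoryNetwork, state: StateVector) -> None:
    names = set(network.node_names)
    extra = set(state) - names
    missing = names - set(state)
    if extra or missing:
        raise NetworkError(
            f"state does not match network nodes (missing={sorted(missing)}, "
            f"unknown={sorted(extra)})"
        )
    bad = {k: v for k, v in state.items() if not (0.0 <= v <= 1.0)}
    if bad:
        raise NetworkError(f"state values outside [0,1]: {bad}")


def _validate_clamps(network: RegulatoryNetwork, clamps: ClampSet) -> None:
    unknown = [k for k in clamps if k not in network]
    if unknown:
        raise NetworkError(f"clamped nodes not in network: {sorted(unknown)}")
    bad = {k: v for k, v in clamps.items() if not (0.0 <= v <= 1.0)}
    if bad:
        raise NetworkError(f"clamp values outside [0,1]: {bad}")


class CompiledNetwork:
    """Adjacency arrays for vectorized batch iteration of one network."""

    def __init__(self, network: RegulatoryNetwork):
        self.network = network
        names = network.node_names
        n = len(names)
        self.names = names
        self.n = n
        Wa = np.zeros((n, n))  # Wa[target, source]
        Wi = np.zeros((n, n))
        for e in network.edges:
            t, s = network.index(e.target), network.index(e.source)
            if e.sign > 0:
                Wa[t, s] += e.weight
            else:
                Wi[t, s] += e.weight
        self.Wa, self.Wi = Wa, Wi
        self.act_den = Wa.sum(axis=1)
        self.inh_den = Wi.sum(axis=1)
        self.has_act = self.act_den > 0
        self.has_inh = self.inh_den > 0
        no_reg = ~self.has_act & ~self.has_inh
        pure = np.array([network.is_pure_input(nm) for nm in names])
        self.self_sustain = no_reg & ~pure
        self.pure_input = no_reg & pure

    def omega(self, states: np.ndarray) -> np.ndarray:
        """Aggregated input for a batch of states, shape (runs, nodes)."""
        act = np.ones_like(states)
        np.divide(
            states @ self.Wa.T,
            self.act_den,
            out=act,
            where=self.has_act,
        )
        inh = np.zeros_like(states)
        np.divide(
            states @ self.Wi.T,
            self.inh_den,
            out=inh,
            where=self.has_inh,
        )
        w = act * (1.0 - inh)
        w = np.where(self.self_sustain, states, w)
        w = np.where(self.pure_input, 0.0, w)
        return w

    def clamp_arrays(self, clamps: ClampSet) -> tuple[np.ndarray, np.ndarray]:
        mask = np.zeros(self.n, dtype=bool)
        values = np.zeros(self.n)
        for name, value in clamps.items():
            i = self.network.index(name)
            mask[i] = True
            values[i] = value
        return mask, values

    def state_array(self, state: StateVector) -> np.ndarray:
        return np.array([state[nm] for nm in self.names], dtype=float)

    def as_dict(self, arr: np.ndarray) -> dict[str, float]:
        return {nm: float(v) for nm, v in zip(self.names, arr)}


def _sigmoid(omega: np.ndarray, gain: float) -> np.ndarray:
    """Normalized logistic: f(0)=0, f(0.5)=0.5, f(1)=1."""
    lo = 1.0 / (1.0 + np.exp(gain * 0.5))
    hi = 1.0 / (1.0 + np.exp(-gain * 0.5))
    raw = 1.0 / (1.0 + np.exp(-gain * (omega - 0.5)))
    return (raw - lo) / (hi - lo)


def input_strength(
    network: RegulatoryNetwork, node: str, state: StateVector
) -> float:
    """Aggregated regulator influence ω of ``node`` under ``state``.

    Returns a value in [0, 1]; see the module docstring for the rule.
    """
    comp = CompiledNetwork(network)
    arr = comp.state_array(state)
    return float(comp.omega(arr[None, :])[0, comp.network.index(node)])


def _step_batch(
    comp: CompiledNetwork,
    states: np.ndarray,
    clamp_mask: np.ndarray,
    clamp_values: np.ndarray,
    params: DynamicsParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One Euler step for a batch; returns (new states, flow residual)."""
    target = _sigmoid(comp.omega(states), params.gain)
    residual = target - params.decay * states
    new = np.clip(states + params.step * residual, 0.0, 1.0)
    new = np.where(clamp_mask, clamp_values, new)
    residual = np.where(clamp_mask, 0.0, residual)
    if not np.all(np.isfinite(new)):
        bad = np.argwhere(~np.isfinite(new))
        node = comp.names[int(bad[0][1])]
        raise DynamicsError(f"non-finite activation produced at node {node!r}")
    return new, residual


def step_dynamics(
    network: RegulatoryNetwork,
    state: StateVector,
    clamps: ClampSet,
    params: DynamicsParams | None = None,
) -> dict[str, float]:
    """Advance the state by one explicit-Euler step.

    Clamped nodes are returned exactly at their clamp values; unclamped
    nodes move toward the sigmoid target implied by their aggregated
    input.  All outputs are in [0, 1].
    """
    params = params or DynamicsParams()
    _validate_state(network, state)
    _validate_clamps(network, clamps)
    comp = CompiledNetwork(network)
    mask, values = comp.clamp_arrays(clamps)
    arr = comp.state_array(state)
    arr = np.where(mask, values, arr)
    new, _ = _step_batch(comp, arr[None, :], mask, values, params)
    return comp.as_dict(new[0])


def solve_steady_state(
    network: RegulatoryNetwork,
    initial: StateVector,
    clamps: ClampSet,
    params: DynamicsParams | None = None,
) -> tuple[dict[str, float], bool, int]:
    """Iterate the dynamics from ``initial`` until the flow residual
    max_i |f(ω_i) − γ x_i| drops below ``params.tol``.

    Returns ``(state, converged, iterations)``; non-convergence within
    ``max_iter`` steps is a flagged outcome, not an error.  Clamped nodes
    are exactly at their clamp values in the result.
    """
    params = params or DynamicsParams()
    _validate_state(network, initial)
    _validate_clamps(network, clamps)
    comp = CompiledNetwork(network)
    mask, values = comp.clamp_arrays(clamps)
    arr = comp.state_array(initial)
    arr = np.where(mask, values, arr)
    states, converged, iters = _solve_batch(comp, arr[None, :], mask, values, params)
    return comp.as_dict(states[0]), bool(converged[0]), int(iters[0])


def _solve_batch(
    comp: CompiledNetwork,
    states: np.ndarray,
    clamp_mask: np.ndarray,
    clamp_values: np.ndarray,
    params: DynamicsParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Iterate a batch of trajectories to steady state.

    All trajectories are stepped together until every one has converged
    (or the cap is reached); per-run iteration counts record the first
    step at which each run's residual fell below tolerance.
    """
    n_runs = states.shape[0]
    converged = np.zeros(n_runs, dtype=bool)
    iterations = np.full(n_runs, params.max_iter, dtype=int)
    current = states.copy()
    for it in range(1, params.max_iter + 1):
        current, residual = _step_batch(
            comp, current, clamp_mask, clamp_values, params
        )
        ok = np.abs(residual).max(axis=1) < params.tol
        newly = ok & ~converged
        iterations[newly] = it
        converged |= ok
        if converged.all():
            break
    return current, converged, iterations


def sample_initial_states(
    network: RegulatoryNetwork,
    clamps: ClampSet,
    n: int,
    seed: int,
) -> list[dict[str, float]]:
    """Draw ``n`` random initial conditions.

    Unclamped nodes are independent uniform on [0, 1]; clamped nodes are
    set to their clamp values.  The same seed reproduces the same list
    bit for bit.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    _validate_clamps(network, clamps)
    comp = CompiledNetwork(network)
    mask, values = comp.clamp_arrays(clamps)
    rng = np.random.default_rng(seed)
    draws = rng.uniform(0.0, 1.0, size=(n, comp.n))
    draws = np.where(mask, values, draws)
    return [comp.as_dict(row) for row in draws]


def _sample_batch(
    comp: CompiledNetwork,
    clamp_mask: np.ndarray,
    clamp_values: np.ndarray,
    n: int,
    seed: int,
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    draws = rng.uniform(0.0, 1.0, size=(n, comp.n))
    return np.where(clamp_mask, clamp_values, draws)


def solve_ensemble(
    network: RegulatoryNetwork,
    clamps: ClampSet,
    n: int,
    seed: int,
    params: DynamicsParams | None = None,
) -> tuple["CompiledNetwork", np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized attractor search from ``n`` random initial conditions.

    Returns ``(compiled, states, converged, iterations)`` where ``states``
    has shape (n, nodes).  This is the engine behind condition ensembles;
    it is equivalent to ``n`` calls of :func:`solve_steady_state` on
    :func:`sample_initial_states` draws with the same seed.
    """
    params = params or DynamicsParams()
    _validate_clamps(network, clamps)
    comp = CompiledNetwork(network)
    mask, values = comp.clamp_arrays(clamps)
    initial = _sample_batch(comp, mask, values, n, seed)
    states, converged, iterations = _solve_batch(comp, initial, mask, values, params)
    return comp, states, converged, iterations
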