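"""Condition presets, attractor ensembles and phenotype classification.

The experimental conditions (control / TNF-stimulated, unloaded / dynamic
compression, plus a day-0 baseline) are encoded as *clamp sets*: nodes
held at fixed activation for the whole simulation.  Two derivations
exist for the built-in presets: literature-derived mechanoreceptor
activation, and experiment-derived activation inferred from gene
expression and secretome measurements (where the dynamic presets reuse
the unloaded clamps, actin is clamped off, and IL-4 sits at its critical
level 0.2585).

Each condition is simulated as an ensemble of attractor searches from
random initial states; converged steady states are classified
pro-anabolic (readout ACAN >= 0.5) or pro-catabolic (< 0.5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    DynamicsParams,
    solve_ensemble,
)
from .network import NetworkError, RegulatoryNetwork

__all__ = [
    "ConditionPreset",
    "ClassificationRule",
    "SteadyStateEnsemble",
    "builtin_presets",
    "get_preset",
    "classify_state",
    "run_ensemble",
    "predict_condition_deltas",
    "find_critical_clamp",
    "NoCrossingError",
    "PRO_ANABOLIC",
    "PRO_CATABOLIC",
    "ATTRACTOR_TOL",
]

PRO_ANABOLIC = "pro-anabolic"
PRO_CATABOLIC = "pro-catabolic"

#: Two converged states closer than this (max node-wise difference) are
#: counted as the same attractor when reporting attractor counts.
ATTRACTOR_TOL = 1e-3

#: Critical IL-4 activation below which the network tips catabolic.
IL4_CRITICAL = 0.2585


@dataclass(frozen=True)
class ConditionPreset:
    """A named experimental condition encoded as a sustained clamp set."""

    name: str
    derivation: str  # "literature" | "experiment"
    treatment: str  # "control" | "TNF"
    loading: str  # "day0" | "unloaded" | "dynamic"
    clamps: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.derivation not in ("literature", "experiment"):
            raise ValueError(f"bad derivation {self.derivation!r}")
        if self.treatment not in ("control", "TNF"):
            raise ValueError(f"bad treatment {self.treatment!r}")
        if self.loading not in ("day0", "unloaded", "dynamic"):
            raise ValueError(f"bad loading {self.loading!r}")

    @property
    def condition(self) -> str:
        """Condition label without the derivation prefix, e.g. ``TNF_unloaded``."""
        if self.loading == "day0":
            return "day0"
        return f"{self.treatment}_{self.loading}"


def builtin_presets() -> list[ConditionPreset]:
    """The ten built-in condition presets.

    Literature-derived presets clamp the mechanosensors (α5β1, αvβ3,
    TRPV4) at basal 0.5 for free swelling and at 1 for dynamic
    compression; TNF stimulation adds TNF = 1.  Experiment-derived
    presets clamp α5β1 = 0.5, actin = 0 (deficient mechanotransduction in
    agarose), IL4 at its critical level 0.2585, and TRPV4 at 1 / 0.5 /
    0.25 for day 0 / control / TNF; their dynamic presets carry the same
    clamps as the unloaded ones.
    """
    lit_basal = {"α5β1": 0.5, "αvβ3": 0.5, "TRPV4": 0.5}
    lit_dyn = {"α5β1": 1.0, "αvβ3": 1.0, "TRPV4": 1.0}
    exp_base = {"α5β1": 0.5, "Actin": 0.0, "IL4": IL4_CRITICAL}
    return [
        ConditionPreset("lit_day0", "literature", "control", "day0", dict(lit_basal)),
        ConditionPreset("lit_control_unloaded", "literature", "control", "unloaded", dict(lit_basal)),
        ConditionPreset("lit_control_dynamic", "literature", "control", "dynamic", dict(lit_dyn)),
        ConditionPreset("lit_TNF_unloaded", "literature", "TNF", "unloaded", {**lit_basal, "TNF": 1.0}),
        ConditionPreset("lit_TNF_dynamic", "literature", "TNF", "dynamic", {**lit_dyn, "TNF": 1.0}),
        ConditionPreset("exp_day0", "experiment", "control", "day0", {**exp_base, "TRPV4": 1.0}),
        ConditionPreset("exp_control_unloaded", "experiment", "control", "unloaded", {**exp_base, "TRPV4": 0.5}),
        ConditionPreset("exp_control_dynamic", "experiment", "control", "dynamic", {**exp_base, "TRPV4": 0.5}),
        ConditionPreset("exp_TNF_unloaded", "experiment", "TNF", "unloaded", {**exp_base, "TRPV4": 0.25, "TNF": 1.0}),
        ConditionPreset("exp_TNF_dynamic", "experiment", "TNF", "dynamic", {**exp_base, "TRPV4": 0.25, "TNF": 1.0}),
    ]


def get_preset(name: str) -> ConditionPreset:
    for preset in builtin_presets():
        if preset.name == name:
            return preset
    known = [p.name for p in builtin_presets()]
    raise KeyError(f"unknown preset {name!r}; known presets: {known}")


@dataclass(frozen=True)
class ClassificationRule:
    """Phenotype dichotomy on the readout node.

    States with readout activation at or above ``threshold`` are labelled
    pro-anabolic (matrix building), below it pro-catabolic.
    """

    readout: str = "ACAN"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")


def classify_state(state: Mapping[str, float], rule: ClassificationRule) -> str:
    """Label one steady state; the threshold itself counts as anabolic."""
    if rule.readout not in state:
        raise NetworkError(f"readout node {rule.readout!r} absent from state")
    return PRO_ANABOLIC if state[rule.readout] >= rule.threshold else PRO_CATABOLIC


def _dedup_attractors(states: np.ndarray, tol: float = ATTRACTOR_TOL) -> np.ndarray:
    """Greedy clustering of converged states into distinct attractors."""
    reps: list[np.ndarray] = []
    for row in states:
        if not any(np.max(np.abs(row - r)) < tol for r in reps):
            reps.append(row)
    return np.array(reps) if reps else np.empty((0, states.shape[1] if states.ndim == 2 else 0))


@dataclass
class SteadyStateEnsemble:
    """Result of ``n`` attractor searches under one condition."""

    preset_name: str
    n_runs: int
    seed: int
    node_names: list[str]
    states: list[dict[str, float]]
    converged: list[bool]
    labels: list[str]
    iterations: list[int]
    mean_activation: dict[str, float]  # over converged runs; {} if none
    pct_anabolic: float | None  # % of converged runs; None if none converged
    pct_catabolic: float | None
    n_converged: int
    attractors: list[dict[str, float]]
    clamps: dict[str, float] = field(default_factory=dict)

    @property
    def attractor_count(self) -> int:
        return len(self.attractors)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, ensure_ascii=False))

    def mean_series(self) -> pd.Series:
        return pd.Series(self.mean_activation, name=self.preset_name)

    def states_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states)
        df["converged"] = self.converged
        df["label"] = self.labels
        return df


def run_ensemble(
    network: RegulatoryNetwork,
    preset: ConditionPreset,
    rule: ClassificationRule | None = None,
    n: int = 100,
    seed: int = 0,
    params: DynamicsParams | None = None,
) -> SteadyStateEnsemble:
    """Simulate one condition as ``n`` attractor searches.

    Initial states are uniform random on unclamped nodes (clamped nodes
    at their clamp values); each run iterates to steady state.  Summary
    statistics — mean activation per node and the pro-anabolic /
    pro-catabolic split — are computed over converged runs only, and
    distinct attractors are counted after deduplication.

    Raises
    ------
    NetworkError
        If the preset clamps nodes the network does not contain (the
        expected failure mode when a user's network lacks e.g. "Actin"),
        listing the missing names.
    """
    rule = rule or ClassificationRule()
    missing = [k for k in preset.clamps if k not in network]
    if missing:
        raise NetworkError(
            f"preset {preset.name!r} clamps nodes missing from the network: "
            f"{sorted(missing)}"
        )
    if rule.readout not in network:
        raise NetworkError(f"readout node {rule.readout!r} not in network")
    comp, states, converged, iterations = solve_ensemble(
        network, preset.clamps, n=n, seed=seed, params=params
    )
    state_dicts = [comp.as_dict(row) for row in states]
    labels = [classify_state(s, rule) for s in state_dicts]
    conv_mask = np.asarray(converged, dtype=bool)
    n_conv = int(conv_mask.sum())
    if n_conv:
        means = states[conv_mask].mean(axis=0)
        conv_labels = [l for l, c in zip(labels, conv_mask) if c]
        pct_ana = 100.0 * conv_labels.count(PRO_ANABOLIC) / n_conv
        pct_cat = 100.0 * conv_labels.count(PRO_CATABOLIC) / n_conv
        attractors = [comp.as_dict(r) for r in _dedup_attractors(states[conv_mask])]
    else:
        means = None
        pct_ana = pct_cat = None
        attractors = []
    return SteadyStateEnsemble(
        preset_name=preset.name,
        n_runs=n,
        seed=seed,
        node_names=list(comp.names),
        states=state_dicts,
        converged=[bool(c) for c in conv_mask],
        labels=labels,
        iterations=[int(i) for i in iterations],
        mean_activation=comp.as_dict(means) if means is not None else {},
        pct_anabolic=pct_ana,
        pct_catabolic=pct_cat,
        n_converged=n_conv,
        attractors=attractors,
        clamps=dict(preset.clamps),
    )


def predict_condition_deltas(
    ensemble_a: SteadyStateEnsemble,
    ensemble_b: SteadyStateEnsemble,
    nodes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-node change in ensemble-mean activation between two conditions.

    Returns a frame with columns ``node, mean_a, mean_b, delta,
    rel_change_pct`` where ``delta = mean_b − mean_a`` and the relative
    change uses ``mean_a`` as denominator (NaN with ``rel_defined=False``
    when ``mean_a`` is 0).  Nodes absent from the ensembles are skipped
    and listed in ``frame.attrs["skipped"]``.
    """
    if ensemble_a.node_names != ensemble_b.node_names:
        raise NetworkError("ensembles come from different networks")
    nodes = list(nodes) if nodes is not None else list(ensemble_a.node_names)
    rows = []
    skipped = []
    for node in nodes:
        if node not in ensemble_a.mean_activation:
            skipped.append(node)
            continue
        a = ensemble_a.mean_activation[node]
        b = ensemble_b.mean_activation[node]
        delta = b - a
        defined = a != 0.0
        rows.append(
            {
                "node": node,
                "mean_a": a,
                "mean_b": b,
                "delta": delta,
                "rel_change_pct": 100.0 * delta / a if defined else float("nan"),
                "rel_defined": defined,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["node", "mean_a", "mean_b", "delta", "rel_change_pct", "rel_defined"]
    )
    frame.attrs["skipped"] = skipped
    return frame


class NoCrossingError(RuntimeError):
    """The clamped node does not flip the phenotype on the search interval."""


def _probe_seed(seed: int, probe: int) -> int:
    return int(np.random.SeedSequence([seed, probe]).generate_state(1)[0] % (2**31))


def find_critical_clamp(
    network: RegulatoryNetwork,
    node: str,
    base_clamps: Mapping[str, float],
    rule: ClassificationRule | None = None,
    interval: tuple[float, float] = (0.0, 1.0),
    tol: float = 1e-3,
    n_per_probe: int = 25,
    seed: int = 0,
    params: DynamicsParams | None = None,
) -> float:
    """Bisect for the clamp level at which the phenotype flips.

    This is the procedure that locates the critical IL-4 activation:
    ``node`` is clamped at a candidate value on top of ``base_clamps``,
    an ensemble of ``n_per_probe`` attractor searches is run, and the
    majority label decides which side of the switch the candidate sits
    on.  Bisection continues until the bracket is narrower than ``tol``
    and returns its midpoint.

    Raises
    ------
    NoCrossingError
        If the majority label is the same at both interval endpoints —
        the network has no IL-4-type switch along this clamp.
    """
    rule = rule or ClassificationRule()
    lo, hi = interval
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("search interval must satisfy 0 <= lo < hi <= 1")

    probe_counter = [0]

    def majority(value: float) -> str:
        preset = ConditionPreset(
            name=f"probe_{node}",
            derivation="experiment",
            treatment="control",
            loading="unloaded",
            clamps={**base_clamps, node: value},
        )
        ens = run_ensemble(
            network,
            preset,
            rule,
            n=n_per_probe,
            seed=_probe_seed(seed, probe_counter[0]),
            params=params,
        )
        probe_counter[0] += 1
        if ens.n_converged == 0:
            raise NoCrossingError(
                f"no converged runs at clamp {node}={value}; cannot classify"
            )
        return PRO_ANABOLIC if ens.pct_anabolic >= 50.0 else PRO_CATABOLIC

    label_lo = majority(lo)
    label_hi = majority(hi)
    if label_lo == label_hi:
        raise NoCrossingError(
            f"majority label {label_lo!r} identical at {node}={lo} and "
            f"{node}={hi}: no phenotype flip on the interval"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if majority(mid) == label_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
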