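"""Synthetic benchmark inputs: networks with known attractor structure
and Luminex-style secretome tables with planted effects.

The real chondrocyte mechanotransduction network and the measured
secretome are external; this module generates desk-scale stand-ins whose
ground truth is known by construction, so every pipeline stage can be
tested end to end:

* a **benchmark network** containing the canonical condition-preset
  nodes (α5β1, αvβ3, TRPV4, Actin, TNF, IL4, ACAN) plus secreted-protein
  nodes, wired so that TNF stimulation forces the catabolic steady state
  and the IL4 clamp flips the phenotype at an exactly planted critical
  value;
* a **bistable toggle** whose two basins are separated by a known
  boundary (the diagonal), giving an analytic basin-volume oracle;
* a **synthetic secretome**: per-analyte 5PL assay truth, LOQ limits,
  blanks, standards and donor-replicated measurements with planted
  TNF-up / TNF-down / time-decaying / detected-only-under-TNF classes
  and log-normal donor and residual noise;
* a **paired fixture** whose secretome truth equals the network's
  condition-ensemble means on a declared shared-analyte set, so the
  end-to-end concordance is zero by construction and planted deviations
  propagate to exactly computable NMAD values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .concordance import DEFAULT_ALIASES
from .conditions import (
    ClassificationRule,
    ConditionPreset,
    SteadyStateEnsemble,
    builtin_presets,
    run_ensemble,
)
from .dynamics import DynamicsParams
from .luminex import SecretomePanel
from .network import Edge, Node, RegulatoryNetwork

__all__ = [
    "SyntheticNetworkSpec",
    "SyntheticSecretomeSpec",
    "PairedFixture",
    "make_benchmark_network",
    "make_toggle_network",
    "make_synthetic_secretome",
    "make_paired_fixture",
    "CONDITIONS",
    "SHARED_NODES",
]

#: The four experimental conditions, reference first.
CONDITIONS = ("control_unloaded", "control_dynamic", "TNF_unloaded", "TNF_dynamic")

#: Benchmark nodes with measurable secretome counterparts (alias names in
#: parentheses follow the immunoassay panel vocabulary).
SHARED_NODES = ("ACAN", "CCL2", "IL17", "IL6", "IL8", "LIF", "NGF", "RETN", "TGFB", "VEGF")

SHARED_ALIASES: Mapping[str, str] = {
    "IL-6": "IL6",
    "IL-8": "IL8",
    "IL-17": "IL17",
    "TGF-β": "TGFB",
    "CCL2": "CCL2",
    "LIF": "LIF",
    "VEGF": "VEGF",
    "NGF": "NGF",
    "RETN": "RETN",
    "ACAN": "ACAN",
}


def _subseed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Recipe for the benchmark network.

    ``flip_value`` is the planted critical IL4 clamp at which the
    readout crosses the anabolic threshold (under the base clamps stored
    in the truth record); it must lie strictly inside (0, 1).
    """

    seed: int = 0
    flip_value: float = 0.2585
    readout: str = "ACAN"

    def __post_init__(self) -> None:
        if not (0.0 < self.flip_value < 1.0):
            raise ValueError("flip_value must lie strictly inside (0, 1)")


def make_benchmark_network(
    spec: SyntheticNetworkSpec | None = None,
) -> tuple[RegulatoryNetwork, dict]:
    """Benchmark network runnable under every built-in condition preset.

    Wiring (all weights 1): the integrins drive actin assembly; TNF
    induces the inflammatory hub IL6 and the inflammatory secretome
    (IL8, IL17) while suppressing CCL2; IL6 drives LIF and RETN; TRPV4
    drives TGFB and NGF; actin drives VEGF.  The readout ACAN is
    activated by IL4, actin and TRPV4 and inhibited by IL6, so clamping
    TNF to 1 forces the pro-catabolic steady state regardless of initial
    conditions.

    With base clamps ``{α5β1: 0.5, αvβ3: 0.5, TRPV4: 1 − c}`` the
    steady-state readout equals the anabolic threshold exactly when the
    IL4 clamp equals ``c``: actin settles at 0.5, IL6 at 0, and the
    readout's aggregated input is (IL4 + 0.5 + (1 − c))/3, which crosses
    0.5 precisely at IL4 = c.  The truth record carries these base
    clamps alongside the planted flip value.

    Returns ``(network, truth)``; the truth record is sufficient to
    compute every downstream expectation without re-deriving by hand.
    """
    spec = spec or SyntheticNetworkSpec()
    c = spec.flip_value
    edges = [
        Edge("α5β1", "Actin", 1),
        Edge("αvβ3", "Actin", 1),
        Edge("TNF", "IL6", 1),
        Edge("TNF", "IL8", 1),
        Edge("TNF", "IL17", 1),
        Edge("TNF", "CCL2", -1),
        Edge("IL6", "LIF", 1),
        Edge("IL6", "RETN", 1),
        Edge("TRPV4", "TGFB", 1),
        Edge("TRPV4", "NGF", 1),
        Edge("Actin", "VEGF", 1),
        Edge("IL4", spec.readout, 1),
        Edge("Actin", spec.readout, 1),
        Edge("TRPV4", spec.readout, 1),
        Edge("IL6", spec.readout, -1),
    ]
    roles = {spec.readout: "readout"}
    network = RegulatoryNetwork.from_edges(edges, roles=roles)
    truth = {
        "seed": spec.seed,
        "flip_value": c,
        "flip_node": "IL4",
        "flip_base_clamps": {"α5β1": 0.5, "αvβ3": 0.5, "TRPV4": 1.0 - c},
        "readout": spec.readout,
        "tnf_forced_label": "pro-catabolic",
        "inflammatory_node": "IL6",
        "measurable_nodes": list(SHARED_NODES),
    }
    return network, truth


def make_toggle_network(
    anabolic: str = "ACAN", catabolic: str = "MMP13"
) -> tuple[RegulatoryNetwork, dict]:
    """Symmetric two-node mutual-inhibition toggle.

    The two stable attractors are (1, 0) and (0, 1); by symmetry of the
    dynamics the basin boundary is the diagonal, so the pro-anabolic
    basin fraction under uniform initial conditions is exactly 1/2, and
    a sampled initial state converges anabolic iff its readout component
    exceeds the other node's.  The truth record carries both facts for
    oracle tests.
    """
    network = RegulatoryNetwork(
        nodes=[Node(anabolic, "readout"), Node(catabolic, "generic")],
        edges=[Edge(anabolic, catabolic, -1), Edge(catabolic, anabolic, -1)],
    )
    truth = {
        "attractors": [
            {anabolic: 1.0, catabolic: 0.0},
            {anabolic: 0.0, catabolic: 1.0},
        ],
        "unstable_fixed_point": {anabolic: 0.5, catabolic: 0.5},
        "basin_fraction_anabolic": 0.5,
        "basin_rule": f"initial {anabolic} >= initial {catabolic}",
    }
    return network, truth


# ---------------------------------------------------------------------------
# secretome
# ---------------------------------------------------------------------------

_PANEL_NAMES = [
    "IL-1β", "IL-2", "IL-4", "IL-5", "IL-6", "IL-7", "IL-8", "IL-10",
    "IL-12p70", "IL-13", "IL-15", "IL-17", "IL-18", "IL-21", "IL-23",
    "TNF-α", "IFN-γ", "TGF-β", "GM-CSF", "G-CSF", "LIF", "OSM",
    "CCL2", "CCL3", "CCL4", "CCL5", "CCL7", "CCL11", "CCL20", "CCL22",
    "CXCL1", "CXCL5", "CXCL9", "CXCL10", "CXCL12", "CXCL13",
    "VEGF", "NGF", "BDNF", "FGF-2", "EGF", "HGF", "IGF-1", "PDGF-BB",
    "BMP-2", "BMP-7", "MMP-1", "MMP-2", "MMP-3", "MMP-9", "MMP-13",
    "TIMP-1", "TIMP-2", "TIMP-4", "RETN", "Leptin", "Adiponectin",
    "OPG", "RANKL", "OPN", "COMP", "DEFB1", "IP-10", "SCF", "TRAIL",
    "ICAM-1", "VCAM-1", "Fractalkine", "Periostin", "Galectin-3",
    "YKL-40", "Serpin-E1", "Fetuin-A",
]

#: Canonical effect-class assignments mirroring the qualitative secretome
#: structure: inflammation raises the pro-inflammatory factors, lowers
#: CCL2, some trophic factors decay over culture time, and IL-4-like
#: analytes are only detectable under TNF stimulation.
_FIXED_CLASSES = {
    "IL-6": "tnf_up",
    "IL-8": "tnf_up",
    "IL-17": "tnf_up",
    "IL-1β": "tnf_up",
    "CCL2": "tnf_down",
    "VEGF": "time_decay",
    "NGF": "time_decay",
    "RETN": "time_decay",
    "IL-4": "tnf_only",
    "DEFB1": "tnf_only",
}

_CLASS_POOL = ("null", "tnf_up", "tnf_down", "time_decay")
_CLASS_PROBS = (0.4, 0.3, 0.15, 0.15)


@dataclass(frozen=True)
class SyntheticSecretomeSpec:
    """Recipe for a synthetic multiplex secretome dataset.

    Planted effects live on the LOQ-normalized [0, 1] scale: TNF-up
    analytes gain ``tnf_effect`` under TNF stimulation, TNF-down lose
    it, time-decaying analytes fall to ``time_decay_factor`` of their
    day-7 level on day 14, and ``tnf_only`` analytes sit below the lower
    LOQ except under TNF.  Noise is multiplicative log-normal on
    concentration with a per-donor component ``sigma_donor`` and a
    residual ``sigma_resid`` (log scale).
    """

    seed: int = 0
    n_analytes: int = 73
    n_donors: int = 5
    days: tuple[int, ...] = (7, 14)
    conditions: tuple[str, ...] = CONDITIONS
    tnf_effect: float = 0.3
    dynamic_effect: float = 0.0
    time_decay_factor: float = 0.5
    sigma_donor: float = 0.2
    sigma_resid: float = 0.1
    analyte_names: tuple[str, ...] | None = None
    planted_x: Mapping[str, Mapping[str, float]] | None = None
    n_standards: int = 10

    def names(self) -> list[str]:
        if self.analyte_names is not None:
            return list(self.analyte_names)
        base = list(_PANEL_NAMES[: self.n_analytes])
        for k in range(len(base), self.n_analytes):
            base.append(f"ANL-{k + 1}")
        return base


def _assay_truth(names: Sequence[str], rng: np.random.Generator) -> pd.DataFrame:
    """Per-analyte 5PL curve, LOQ and blank truth."""
    rows = []
    for name in names:
        lloq = 10.0 ** rng.uniform(0.0, 1.0)
        uloq = lloq * 10.0 ** rng.uniform(2.0, 3.0)
        rows.append(
            {
                "analyte": name,
                "lloq": lloq,
                "uloq": uloq,
                "blank": rng.uniform(10.0, 40.0),
                "L": rng.uniform(20.0, 80.0),
                "U": rng.uniform(8_000.0, 20_000.0),
                "C": float(np.sqrt(lloq * uloq)),
                "B": rng.uniform(1.0, 2.0),
                "G": rng.uniform(0.8, 1.5),
            }
        )
    return pd.DataFrame(rows).set_index("analyte")


def _curve_mfi(row: pd.Series, conc: np.ndarray | float) -> np.ndarray | float:
    conc = np.asarray(conc, dtype=float)
    return row["L"] + (row["U"] - row["L"]) / (1.0 + (row["C"] / conc) ** row["B"]) ** row["G"]


def make_synthetic_secretome(
    spec: SyntheticSecretomeSpec | None = None,
) -> tuple[SecretomePanel, dict]:
    """Generate a raw secretome panel plus its ground-truth record.

    Returns ``(panel, truth)``.  ``truth["x_true"]`` holds the planted
    normalized value per (analyte, condition, day); ``truth["classes"]``
    the effect class per analyte; ``truth["assay"]`` the per-analyte 5PL
    curve, LOQ and blank parameters.  With both noise parameters at 0
    the calibration pipeline recovers ``x_true`` to float precision.
    """
    spec = spec or SyntheticSecretomeSpec()
    rng = np.random.default_rng(spec.seed)
    names = spec.names()
    assay = _assay_truth(names, rng)

    classes: dict[str, str] = {}
    for name in names:
        if spec.planted_x is not None and name in spec.planted_x:
            classes[name] = "planted"
        elif name in _FIXED_CLASSES:
            classes[name] = _FIXED_CLASSES[name]
        else:
            classes[name] = str(rng.choice(_CLASS_POOL, p=_CLASS_PROBS))

    # planted normalized truth per (analyte, condition, day)
    truth_rows = []
    for name in names:
        baseline = rng.uniform(0.2, 0.6)
        for cond in spec.conditions:
            is_tnf = cond.startswith("TNF")
            is_dyn = cond.endswith("dynamic")
            for day in spec.days:
                cls = classes[name]
                if cls == "planted":
                    # planted values are exact by contract: no loading shift, no clip
                    x = float(spec.planted_x[name][cond])  # type: ignore[index]
                    if not (0.0 <= x <= 1.0):
                        raise ValueError(f"planted x for {name}/{cond} outside [0,1]: {x}")
                    lloq = assay.loc[name, "lloq"]
                    uloq = assay.loc[name, "uloq"]
                    truth_rows.append(
                        {
                            "analyte": name,
                            "condition": cond,
                            "day": day,
                            "x_true": x,
                            "conc_true": lloq + x * (uloq - lloq),
                        }
                    )
                    continue
                if cls == "tnf_up":
                    x = baseline + (spec.tnf_effect if is_tnf else 0.0)
                elif cls == "tnf_down":
                    x = baseline - (spec.tnf_effect if is_tnf else 0.0)
                elif cls == "tnf_only":
                    x = baseline if is_tnf else 0.0
                elif cls == "time_decay":
                    x = baseline * (spec.time_decay_factor if day == max(spec.days) else 1.0)
                else:
                    x = baseline
                if is_dyn:
                    x = x + spec.dynamic_effect
                x = float(np.clip(x, 0.0, 0.95))
                lloq = assay.loc[name, "lloq"]
                uloq = assay.loc[name, "uloq"]
                if cls == "tnf_only" and not is_tnf:
                    conc = 0.5 * lloq  # below quantification: censored at lloq
                else:
                    conc = lloq + x * (uloq - lloq)
                truth_rows.append(
                    {"analyte": name, "condition": cond, "day": day, "x_true": x, "conc_true": conc}
                )
    x_true = pd.DataFrame(truth_rows)

    # donor-level measurements through the true assay
    donor_effect = {
        (name, d): rng.normal(0.0, spec.sigma_donor) if spec.sigma_donor > 0 else 0.0
        for name in names
        for d in range(1, spec.n_donors + 1)
    }
    meas_rows = []
    for rec in x_true.itertuples(index=False):
        row = assay.loc[rec.analyte]
        for d in range(1, spec.n_donors + 1):
            noise = donor_effect[(rec.analyte, d)]
            if spec.sigma_resid > 0:
                noise += rng.normal(0.0, spec.sigma_resid)
            conc = rec.conc_true * float(np.exp(noise))
            meas_rows.append(
                {
                    "analyte": rec.analyte,
                    "donor": f"donor{d}",
                    "condition": rec.condition,
                    "day": rec.day,
                    "mfi": float(_curve_mfi(row, conc)) + row["blank"],
                }
            )
    measurements = pd.DataFrame(meas_rows)

    std_rows = []
    for name in names:
        row = assay.loc[name]
        concs = np.geomspace(row["lloq"] / 3.0, row["uloq"] * 3.0, spec.n_standards)
        for conc in concs:
            std_rows.append(
                {
                    "analyte": name,
                    "concentration": float(conc),
                    "mfi": float(_curve_mfi(row, conc)) + row["blank"],
                }
            )
    standards = pd.DataFrame(std_rows)
    blanks = pd.DataFrame({"analyte": names, "mfi": [assay.loc[n, "blank"] for n in names]})
    loq = pd.DataFrame(
        {
            "analyte": names,
            "lloq": [assay.loc[n, "lloq"] for n in names],
            "uloq": [assay.loc[n, "uloq"] for n in names],
        }
    )
    panel = SecretomePanel(
        measurements=measurements, standards=standards, blanks=blanks, loq=loq
    )
    truth = {"x_true": x_true, "classes": classes, "assay": assay.reset_index(), "spec": spec}
    return panel, truth


# ---------------------------------------------------------------------------
# paired fixture
# ---------------------------------------------------------------------------


@dataclass
class PairedFixture:
    """Jointly generated network + secretome with matched ground truth."""

    network: RegulatoryNetwork
    network_truth: dict
    panel: SecretomePanel
    secretome_truth: dict
    aliases: dict[str, str]
    shared_analytes: list[str]  # panel spellings
    shared_nodes: list[str]
    condition_means: dict[str, dict[str, float]]
    ensembles: dict[str, SteadyStateEnsemble]
    seeds: dict[str, int]
    planted_deviation: tuple[str, float] | None = None
    incongruent_nodes: list[str] = field(default_factory=list)

    @property
    def n_shared(self) -> int:
        return len(self.shared_analytes)


def _condition_presets() -> dict[str, ConditionPreset]:
    presets = {p.condition: p for p in builtin_presets() if p.derivation == "literature"}
    return {c: presets[c] for c in CONDITIONS}


def make_paired_fixture(
    seed: int,
    n_runs: int = 100,
    deviation: tuple[str, float] | None = None,
    incongruent: Sequence[str] = (),
    incongruent_magnitude: float = 0.5,
    params: DynamicsParams | None = None,
    rule: ClassificationRule | None = None,
) -> PairedFixture:
    """Benchmark network and secretome with matched condition truth.

    The network's four condition ensembles (literature-derived presets
    for control/TNF × unloaded/dynamic) are run first; the secretome's
    planted normalized values for the shared analytes are then set equal
    to the ensemble means, noise-free, so the end-to-end concordance is
    exactly zero.

    ``deviation=(node, δ)`` shifts that node's secretome value by δ in
    every non-reference condition (direction chosen to stay inside
    [0, 1]; NMAD uses the magnitude), making the expected NMAD exactly
    100·δ/N there.  ``incongruent`` lists nodes whose secretome values
    are planted maximally discordant with graded magnitudes (largest
    first), so they occupy the top of the error ranking by construction.
    """
    network, net_truth = make_benchmark_network(SyntheticNetworkSpec(seed=seed))
    presets = _condition_presets()
    seeds = {cond: _subseed(seed, 1, i) for i, cond in enumerate(CONDITIONS)}
    ensembles = {
        cond: run_ensemble(network, presets[cond], rule, n=n_runs, seed=seeds[cond], params=params)
        for cond in CONDITIONS
    }
    condition_means = {c: dict(e.mean_activation) for c, e in ensembles.items()}

    node_for = dict(SHARED_ALIASES)  # panel name -> node
    panel_for = {v: k for k, v in node_for.items()}
    shared_nodes = list(SHARED_NODES)
    shared_analytes = [panel_for[n] for n in shared_nodes]

    planted: dict[str, dict[str, float]] = {}
    for node in shared_nodes:
        planted[panel_for[node]] = {
            cond: condition_means[cond][node] for cond in CONDITIONS
        }

    def shift(values: dict[str, float], delta: float) -> dict[str, float]:
        out = dict(values)
        for cond in CONDITIONS:
            if cond == "control_unloaded":
                continue
            x = out[cond]
            out[cond] = x + delta if x + delta <= 1.0 else x - delta
        return out

    if deviation is not None:
        node, delta = deviation
        if node not in shared_nodes:
            raise ValueError(f"deviation node {node!r} not in shared nodes {shared_nodes}")
        if not (0.0 < delta <= 0.5):
            raise ValueError("deviation magnitude must lie in (0, 0.5]")
        planted[panel_for[node]] = shift(planted[panel_for[node]], delta)

    incongruent = list(incongruent)
    for rank, node in enumerate(incongruent):
        if node not in shared_nodes:
            raise ValueError(f"incongruent node {node!r} not in shared nodes")
        mag = incongruent_magnitude * (1.0 - 0.1 * rank)  # graded, largest first
        planted[panel_for[node]] = shift(planted[panel_for[node]], mag)

    # two extra analytes with no model counterpart exercise unmatched reporting
    extra = ["IP-10", "Fetuin-A"]
    sec_spec = SyntheticSecretomeSpec(
        seed=_subseed(seed, 2),
        n_analytes=len(shared_analytes) + len(extra),
        n_donors=5,
        sigma_donor=0.0,
        sigma_resid=0.0,
        analyte_names=tuple(shared_analytes + extra),
        planted_x=planted,
    )
    panel, sec_truth = make_synthetic_secretome(sec_spec)
    return PairedFixture(
        network=network,
        network_truth=net_truth,
        panel=panel,
        secretome_truth=sec_truth,
        aliases={**DEFAULT_ALIASES, **node_for},
        shared_analytes=shared_analytes,
        shared_nodes=shared_nodes,
        condition_means=condition_means,
        ensembles=ensembles,
        seeds=seeds,
        planted_deviation=deviation,
        incongruent_nodes=incongruent,
    )
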