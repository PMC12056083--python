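"""Plot helpers for ensembles and concordance reports (matplotlib)."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .conditions import SteadyStateEnsemble


def plot_steady_state_fractions(
    ensembles: Sequence[SteadyStateEnsemble], ax=None
):
    """Stacked bars of pro-anabolic / pro-catabolic percentages."""
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(ensembles) + 2, 4))
    names = [e.preset_name for e in ensembles]
    ana = [e.pct_anabolic for e in ensembles]
    cat = [e.pct_catabolic for e in ensembles]
    ax.bar(names, ana, label="pro-anabolic", color="#2b8cbe")
    ax.bar(names, cat, bottom=ana, label="pro-catabolic", color="#e34a33")
    ax.set_ylabel("% of converged runs")
    ax.set_ylim(0, 100)
    ax.legend()
    ax.tick_params(axis="x", rotation=45)
    return ax


def plot_nrse(report: Mapping, condition: str, ax=None):
    """Per-protein NRSE bars for one condition of a concordance report."""
    block = report["conditions"][condition]
    proteins = block["error_ranking"]
    values = [block["nrse"][p]["nrse"] for p in proteins]
    if ax is None:
        _, ax = plt.subplots(figsize=(0.5 * len(proteins) + 2, 4))
    ax.bar(proteins, values, color="#756bb1")
    ax.set_ylabel("NRSE")
    ax.set_title(f"{condition} (NMAD {block['nmad_pct']:.2f}%)")
    ax.set_ylim(0, 1.05)
    ax.tick_params(axis="x", rotation=45)
    return ax
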