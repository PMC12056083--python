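"""Model-experiment concordance: NMAD, per-protein NRSE and error ranking.

Predicted protein activations (ensemble means, reference-subtracted) are
aligned by name with calibrated secretome values and compared with two
semi-quantitative statistics:

* **NMAD** — normalized mean absolute deviation over the N aligned
  pairs, Σ|x_n − y_n| / N, reported as a percentage.  x_n is the
  referenced experimental value and y_n the referenced model value,
  both in [−1, 1].
* **NRSE** — per-protein root squared error scaled by the worst
  protein's error (MAX.RSE), so the most discordant protein scores
  exactly 1.  Two conventions for the per-protein error are available:
  ``difference`` (default), RSE_n = |x_n − y_n|, and ``as-printed``,
  RSE_n = √((x_n + y_n)²) = |x_n + y_n|.  The summed form vanishes when
  model and experiment agree in magnitude with opposite sign, so the
  difference form is the default error measure; both are retained.

Analyte naming differs between model nodes and immunoassay panels
("IL-6" vs "IL6"); an explicit alias table maps panel names onto node
names, and only the aligned intersection enters N.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .luminex import CalibratedSecretome, REFERENCE_CONDITION

__all__ = [
    "DEFAULT_ALIASES",
    "ComparisonTable",
    "ConcordanceResult",
    "AlignmentError",
    "load_aliases",
    "save_aliases",
    "model_reference_deltas",
    "align",
    "nmad",
    "nrse",
    "rank_error_proteins",
    "concordance_report",
]

#: Panel-analyte -> model-node spelling map for the common vocabulary.
DEFAULT_ALIASES: Mapping[str, str] = {
    "IL-4": "IL4",
    "IL-6": "IL6",
    "IL-8": "IL8",
    "IL-17": "IL17",
    "IL-17A": "IL17",
    "TNF-α": "TNF",
    "TNF-a": "TNF",
    "TNFα": "TNF",
    "TGF-β": "TGFB",
    "TGF-b": "TGFB",
    "TGF-β1": "TGFB",
    "MCP-1": "CCL2",
    "IP-10": "IP10",
    "a5b1": "α5β1",
    "avb3": "αvβ3",
}


class AlignmentError(ValueError):
    """No overlap between model nodes and panel analytes."""


def load_aliases(path: str | Path) -> dict[str, str]:
    """Read an alias CSV with header ``analyte,node``."""
    df = pd.read_csv(path)
    return dict(zip(df["analyte"].str.strip(), df["node"].str.strip()))


def save_aliases(aliases: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"analyte": list(aliases), "node": list(aliases.values())}
    ).to_csv(path, index=False)


@dataclass
class ComparisonTable:
    """Aligned (x_n, y_n) pairs for one condition."""

    condition: str
    pairs: pd.DataFrame  # columns: protein, x, y
    alias_map: dict[str, str] = field(default_factory=dict)
    unmatched_model: list[str] = field(default_factory=list)
    unmatched_panel: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.pairs) < 1:
            raise AlignmentError(f"condition {self.condition!r}: no aligned pairs")
        if self.pairs[["x", "y"]].isna().any().any():
            raise AlignmentError(f"condition {self.condition!r}: NaN in aligned pair")

    @property
    def n(self) -> int:
        return len(self.pairs)


def model_reference_deltas(
    condition_means: Mapping[str, Mapping[str, float]],
    reference: str = REFERENCE_CONDITION,
) -> dict[str, dict[str, float]]:
    """Subtract the reference condition's ensemble means node-wise.

    ``condition_means`` maps condition name -> {node: ensemble-mean
    activation}; the returned referenced values y' lie in [-1, 1] and the
    reference condition itself maps to all-zero.
    """
    if reference not in condition_means:
        raise AlignmentError(
            f"reference condition {reference!r} missing from model means "
            f"(have {sorted(condition_means)})"
        )
    ref = condition_means[reference]
    out: dict[str, dict[str, float]] = {}
    for cond, means in condition_means.items():
        out[cond] = {node: means[node] - ref[node] for node in means if node in ref}
    return out


def _close_names(name: str, candidates: Sequence[str]) -> list[str]:
    """Cheap near-miss suggestions: same letters ignoring case/dashes."""
    key = name.replace("-", "").replace(" ", "").casefold()
    return [c for c in candidates if c.replace("-", "").replace(" ", "").casefold() == key]


def align(
    model_values: Mapping[str, float],
    experimental: pd.Series | Mapping[str, float],
    aliases: Mapping[str, str] | None = None,
    condition: str = "",
) -> ComparisonTable:
    """Intersect model nodes with panel analytes through the alias map.

    ``model_values`` are referenced model activations y' per node (the
    ensemble means, averaged over the runs, minus the reference
    condition's means).  ``experimental`` maps analyte -> referenced
    experimental value x'.  Panel analytes are translated through
    ``aliases`` (falling back to :data:`DEFAULT_ALIASES` entries) and
    matched to node names; only the intersection is kept.

    Raises
    ------
    AlignmentError
        If the intersection is empty, listing near-miss names.
    """
    aliases = dict(DEFAULT_ALIASES) | dict(aliases or {})
    exp = dict(experimental.items() if isinstance(experimental, pd.Series) else experimental.items())
    rows = []
    matched_nodes = set()
    unmatched_panel = []
    for analyte, x in exp.items():
        node = aliases.get(analyte, analyte)
        if node in model_values:
            rows.append({"protein": node, "x": float(x), "y": float(model_values[node])})
            matched_nodes.add(node)
        else:
            unmatched_panel.append(analyte)
    unmatched_model = sorted(set(model_values) - matched_nodes)
    if not rows:
        hints = {
            a: _close_names(a, list(model_values)) for a in exp
        }
        hints = {a: h for a, h in hints.items() if h}
        raise AlignmentError(
            f"no analyte aligns with any model node; near misses: {hints or 'none'}"
        )
    pairs = pd.DataFrame(rows).sort_values("protein").reset_index(drop=True)
    return ComparisonTable(
        condition=condition,
        pairs=pairs,
        alias_map=dict(aliases),
        unmatched_model=unmatched_model,
        unmatched_panel=sorted(unmatched_panel),
    )


def nmad(table: ComparisonTable) -> float:
    """Normalized mean absolute deviation, as a percentage.

    Σ|x_n − y_n| / N over the aligned pairs, times 100.
    """
    x = table.pairs["x"].to_numpy()
    y = table.pairs["y"].to_numpy()
    return float(100.0 * np.mean(np.abs(x - y)))


def nrse(table: ComparisonTable, mode: str = "difference") -> tuple[pd.DataFrame, float]:
    """Per-protein normalized root squared error and MAX.RSE.

    ``mode='difference'`` uses RSE_n = |x_n − y_n|; ``mode='as-printed'``
    uses RSE_n = √((x_n + y_n)²) = |x_n + y_n|.  NRSE_n = RSE_n /
    MAX.RSE where MAX.RSE is the maximum RSE over the proteins in the
    table; when MAX.RSE is 0 all NRSE are defined as 0.

    Returns ``(frame, max_rse)`` with frame columns ``protein, rse, nrse``.
    """
    if mode not in ("difference", "as-printed"):
        raise ValueError(f"mode must be 'difference' or 'as-printed', got {mode!r}")
    x = table.pairs["x"].to_numpy()
    y = table.pairs["y"].to_numpy()
    rse = np.abs(x - y) if mode == "difference" else np.sqrt((x + y) ** 2)
    max_rse = float(rse.max())
    norm = rse / max_rse if max_rse > 0 else np.zeros_like(rse)
    frame = pd.DataFrame(
        {"protein": table.pairs["protein"], "rse": rse, "nrse": norm}
    )
    return frame, max_rse


@dataclass
class ConcordanceResult:
    """Concordance statistics for one condition."""

    condition: str
    table: ComparisonTable
    nmad_pct: float
    nmad_fraction: float
    nrse_table: pd.DataFrame
    max_rse: float
    mode: str

    @classmethod
    def from_table(cls, table: ComparisonTable, mode: str = "difference") -> "ConcordanceResult":
        value = nmad(table)
        frame, max_rse = nrse(table, mode=mode)
        return cls(
            condition=table.condition,
            table=table,
            nmad_pct=value,
            nmad_fraction=value / 100.0,
            nrse_table=frame,
            max_rse=max_rse,
            mode=mode,
        )


def rank_error_proteins(result: ConcordanceResult, k: int | None = None) -> list[str]:
    """Proteins sorted by NRSE descending (alphabetical tie-break).

    Asking for more proteins than the table holds returns all of them
    with a warning note rather than raising.
    """
    frame = result.nrse_table.sort_values(
        ["nrse", "protein"], ascending=[False, True]
    )
    names = frame["protein"].tolist()
    if k is None:
        return names
    if k > len(names):
        warnings.warn(
            f"requested top {k} of {len(names)} proteins; returning all",
            stacklevel=2,
        )
        return names
    return names[:k]


def concordance_report(
    condition_means: Mapping[str, Mapping[str, float]],
    secretome: CalibratedSecretome,
    aliases: Mapping[str, str] | None = None,
    mode: str = "difference",
    reference: str = REFERENCE_CONDITION,
    seeds: Mapping[str, int] | None = None,
    include_reference: bool = True,
    extra_provenance: Mapping[str, object] | None = None,
) -> dict:
    """Assemble the full per-condition concordance report.

    ``condition_means`` maps condition -> node -> ensemble-mean
    activation (one entry must be the reference condition).  Secretome
    conditions without a model counterpart are skipped with a note.  The
    returned dict is JSON-serializable and carries a provenance block
    (mode, alias map, excluded analytes, seeds) sufficient to regenerate
    it.
    """
    model_refs = model_reference_deltas(condition_means, reference=reference)
    conditions = [
        c
        for c in secretome.conditions
        if c in model_refs and (include_reference or c != reference)
    ]
    skipped = [c for c in secretome.conditions if c not in model_refs]
    per_condition = {}
    for cond in conditions:
        table = align(
            model_refs[cond], secretome.vector(cond), aliases=aliases, condition=cond
        )
        result = ConcordanceResult.from_table(table, mode=mode)
        per_condition[cond] = {
            "n_aligned": table.n,
            "nmad_pct": result.nmad_pct,
            "nmad_fraction": result.nmad_fraction,
            "max_rse": result.max_rse,
            "nrse": {
                row.protein: {"rse": float(row.rse), "nrse": float(row.nrse)}
                for row in result.nrse_table.itertuples(index=False)
            },
            "error_ranking": rank_error_proteins(result),
            "pairs": {
                row.protein: {"x": float(row.x), "y": float(row.y)}
                for row in table.pairs.itertuples(index=False)
            },
        }
    first_table = None
    if conditions:
        first_table = align(
            model_refs[conditions[0]],
            secretome.vector(conditions[0]),
            aliases=aliases,
            condition=conditions[0],
        )
    return {
        "conditions": per_condition,
        "provenance": {
            "mode": mode,
            "reference_condition": reference,
            "alias_map": dict(DEFAULT_ALIASES) | dict(aliases or {}),
            "excluded_analytes": list(secretome.excluded),
            "skipped_conditions": skipped,
            "unmatched_model_nodes": first_table.unmatched_model if first_table else [],
            "unmatched_panel_analytes": first_table.unmatched_panel if first_table else [],
            "seeds": dict(seeds or {}),
            **dict(extra_provenance or {}),
        },
    }


def write_report(report: dict, json_path: str | Path, csv_path: str | Path | None = None) -> None:
    """Write a concordance report to JSON (and optionally a flat CSV)."""
    Path(json_path).write_text(
        json.dumps(report, indent=1, sort_keys=True, ensure_ascii=False)
    )
    if csv_path is not None:
        rows = []
        for cond, block in report["conditions"].items():
            for protein, vals in block["nrse"].items():
                rows.append(
                    {
                        "condition": cond,
                        "protein": protein,
                        "x": block["pairs"][protein]["x"],
                        "y": block["pairs"][protein]["y"],
                        "rse": vals["rse"],
                        "nrse": vals["nrse"],
                        "nmad_pct": block["nmad_pct"],
                    }
                )
        pd.DataFrame(rows).to_csv(csv_path, index=False)
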