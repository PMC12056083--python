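"""Signed, weighted regulatory-network container and file I/O.

A regulatory network model (RNM) is a directed graph whose nodes carry
activation levels in [0, 1] and whose edges are signed (+1 activation,
-1 inhibition) with strictly positive weights.  Node *roles* distinguish
external inputs (mechanoreceptors, cytokines) from internal nodes and
mark the phenotype readout (ACAN by default).

File dialects
-------------
* Edge list CSV with header ``source,target,sign,weight``.
* Optional node-metadata CSV with header ``node,role``.
* SIF (``source<TAB>relation<TAB>target``, relation in
  {activates, inhibits}) imported with unit weights.

Names are stored case-sensitively after whitespace trimming; uniqueness
is enforced case-insensitively, so ``TNF`` and ``tnf`` in one file is a
load error rather than two nodes.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ROLES",
    "DEFAULT_ROLES",
    "DEFAULT_READOUT",
    "NetworkError",
    "Node",
    "Edge",
    "RegulatoryNetwork",
    "load_network",
    "load_sif",
]

ROLES = ("generic", "mechanoreceptor", "cytokine", "readout", "ecm")

#: Role defaults applied when a node appears without metadata.  These cover
#: the canonical chondrocyte mechanotransduction vocabulary: the integrins
#: and the TRPV4 channel are mechanosensors, TNF and IL4 are soluble
#: cytokine inputs, ACAN (aggrecan) is the anabolic readout.
DEFAULT_ROLES: Mapping[str, str] = {
    "α5β1": "mechanoreceptor",
    "αvβ3": "mechanoreceptor",
    "a5b1": "mechanoreceptor",
    "avb3": "mechanoreceptor",
    "TRPV4": "mechanoreceptor",
    "TNF": "cytokine",
    "IL4": "cytokine",
    "ACAN": "readout",
}

DEFAULT_READOUT = "ACAN"


class NetworkError(ValueError):
    """Raised for malformed or inconsistent network definitions."""


@dataclass(frozen=True)
class Node:
    name: str
    role: str = "generic"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise NetworkError(
                f"unknown role {self.role!r} for node {self.name!r}; "
                f"expected one of {ROLES}"
            )


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    sign: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise NetworkError(
                f"edge {self.source}->{self.target}: sign must be +1 or -1, "
                f"got {self.sign}"
            )
        if not self.weight > 0:
            raise NetworkError(
                f"edge {self.source}->{self.target}: weight must be strictly "
                f"positive, got {self.weight} (use sign=-1 for inhibition)"
            )


@dataclass
class RegulatoryNetwork:
    """Validated signed weighted network with role-tagged nodes."""

    nodes: list[Node]
    edges: list[Edge]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        seen_folded: dict[str, str] = {}
        for i, node in enumerate(self.nodes):
            folded = node.name.casefold()
            if folded in seen_folded:
                raise NetworkError(
                    f"duplicate node name {node.name!r} "
                    f"(collides with {seen_folded[folded]!r})"
                )
            seen_folded[folded] = node.name
            self._index[node.name] = i
        for edge in self.edges:
            for endpoint in (edge.source, edge.target):
                if endpoint not in self._index:
                    raise NetworkError(
                        f"edge {edge.source!r} -> {edge.target!r} references "
                        f"undeclared node {endpoint!r}"
                    )
        if not any(n.role == "readout" for n in self.nodes):
            raise NetworkError(
                f"network has no readout node (tag one with role 'readout', "
                f"default name {DEFAULT_READOUT!r})"
            )

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, int, float] | Edge],
        roles: Mapping[str, str] | None = None,
    ) -> "RegulatoryNetwork":
        """Build a network from edge tuples, inferring the node list.

        Roles come from ``roles`` if given, else from :data:`DEFAULT_ROLES`,
        else ``generic``.
        """
        edge_objs = [
            e if isinstance(e, Edge) else Edge(e[0].strip(), e[1].strip(), int(e[2]), float(e[3]))
            for e in edges
        ]
        names: list[str] = []
        for e in edge_objs:
            for n in (e.source, e.target):
                if n not in names:
                    names.append(n)
        roles = dict(roles or {})
        nodes = [
            Node(n, roles.get(n, DEFAULT_ROLES.get(n, "generic"))) for n in names
        ]
        return cls(nodes=nodes, edges=edge_objs)

    # -- lookups ----------------------------------------------------------

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def node(self, name: str) -> Node:
        try:
            return self.nodes[self._index[name]]
        except KeyError:
            raise NetworkError(f"unknown node {name!r}") from None

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise NetworkError(f"unknown node {name!r}") from None

    def readouts(self) -> list[str]:
        return [n.name for n in self.nodes if n.role == "readout"]

    def regulators(self, target: str) -> tuple[list[Edge], list[Edge]]:
        """Incoming (activator, inhibitor) edges of ``target``."""
        self.node(target)
        acts = [e for e in self.edges if e.target == target and e.sign > 0]
        inhs = [e for e in self.edges if e.target == target and e.sign < 0]
        return acts, inhs

    def is_pure_input(self, name: str) -> bool:
        """External-input nodes decay when unclamped instead of
        self-sustaining: mechanoreceptors and cytokines with no regulators."""
        node = self.node(name)
        acts, inhs = self.regulators(name)
        return not acts and not inhs and node.role in ("mechanoreceptor", "cytokine")

    # -- serialization ----------------------------------------------------

    def to_csv(self, edge_path: str | Path, node_path: str | Path | None = None) -> None:
        edge_path = Path(edge_path)
        with edge_path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "sign", "weight"])
            for e in self.edges:
                writer.writerow([e.source, e.target, f"{e.sign:+d}", repr(e.weight)])
        if node_path is not None:
            with Path(node_path).open("w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["node", "role"])
                for n in self.nodes:
                    writer.writerow([n.name, n.role])

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["source", "target", "sign", "weight"])
        for e in self.edges:
            writer.writerow([e.source, e.target, f"{e.sign:+d}", repr(e.weight)])
        return buf.getvalue()


def _parse_sign(raw: str, context: str) -> int:
    token = raw.strip()
    if token in ("+1", "1", "+"):
        return 1
    if token in ("-1", "−1", "-"):
        return -1
    raise NetworkError(f"{context}: cannot parse sign {raw!r}")


def load_network(
    edge_path: str | Path, node_path: str | Path | None = None
) -> RegulatoryNetwork:
    """Load and validate a network from the edge-list CSV dialect.

    Parameters
    ----------
    edge_path:
        CSV with header ``source,target,sign,weight``.
    node_path:
        Optional node-metadata CSV with header ``node,role``; nodes not
        listed get default roles.

    Raises
    ------
    NetworkError
        On missing endpoints, duplicate nodes, non-positive weights or
        unparseable rows, naming the offending element.
    """
    edge_path = Path(edge_path)
    if not edge_path.exists():
        raise NetworkError(f"network file not found: {edge_path}")
    edges: list[Edge] = []
    with edge_path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"source", "target", "sign", "weight"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise NetworkError(
                f"{edge_path}: expected header source,target,sign,weight, "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            context = f"{edge_path}:{lineno}"
            try:
                weight = float(row["weight"])
            except (TypeError, ValueError):
                raise NetworkError(
                    f"{context}: cannot parse weight {row['weight']!r}"
                ) from None
            edges.append(
                Edge(
                    source=row["source"].strip(),
                    target=row["target"].strip(),
                    sign=_parse_sign(row["sign"], context),
                    weight=weight,
                )
            )
    roles: dict[str, str] = {}
    declared: list[str] = []
    if node_path is not None:
        with Path(node_path).open(newline="") as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                name = row["node"].strip()
                declared.append(name)
                roles[name] = row.get("role", "generic").strip() or "generic"
    net = RegulatoryNetwork.from_edges(edges, roles=roles)
    # metadata may declare isolated nodes absent from the edge list
    extra = [n for n in declared if n not in net]
    if extra:
        nodes = net.nodes + [
            Node(n, roles.get(n, DEFAULT_ROLES.get(n, "generic"))) for n in extra
        ]
        net = RegulatoryNetwork(nodes=nodes, edges=net.edges)
    return net


_SIF_RELATIONS = {"activates": 1, "inhibits": -1}


def load_sif(path: str | Path, roles: Mapping[str, str] | None = None) -> RegulatoryNetwork:
    """Import a SIF file (``source<TAB>relation<TAB>target``) with unit weights."""
    path = Path(path)
    if not path.exists():
        raise NetworkError(f"network file not found: {path}")
    edges: list[tuple[str, str, int, float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 3:
            raise NetworkError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
        source, relation, target = (p.strip() for p in parts)
        if relation not in _SIF_RELATIONS:
            raise NetworkError(
                f"{path}:{lineno}: unknown relation {relation!r}; "
                f"expected one of {sorted(_SIF_RELATIONS)}"
            )
        edges.append((source, target, _SIF_RELATIONS[relation], 1.0))
    return RegulatoryNetwork.from_edges(edges, roles=roles)
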