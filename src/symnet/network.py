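"""Weighted undirected network container and serialization.

A :class:`Network` holds the partial-correlation matrix of a Gaussian
graphical model: node labels plus a symmetric, zero-diagonal weight matrix
with entries in [-1, 1].  Three on-disk formats are supported and round-trip
exactly (to 1e-12): edge-list CSV, a JSON document, and GraphML.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import networkx as nx
import numpy as np

from .datasets import ValidationError

_SYM_TOL = 1e-12


@dataclass
class Network:
    """Node labels plus a symmetric weighted adjacency (partial correlations)."""

    labels: tuple[str, ...]
    weights: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = tuple(str(x) for x in self.labels)
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("node labels must be unique")
        w = np.asarray(self.weights, dtype=float)
        p = len(self.labels)
        if w.shape != (p, p):
            raise ValidationError(f"weights must be {p}x{p}; got {w.shape}")
        if not np.all(np.abs(w - w.T) <= _SYM_TOL):
            raise ValidationError("weight matrix must be symmetric (tol 1e-12)")
        w = (w + w.T) / 2.0
        if np.any(np.diag(w) != 0.0):
            raise ValidationError("diagonal must be exactly zero")
        if np.any(np.abs(w) > 1.0 + 1e-9):
            raise ValidationError("partial correlations must lie in [-1, 1]")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown node label {label!r}") from None

    def edge(self, a: str, b: str) -> float:
        return float(self.weights[self.index(a), self.index(b)])

    def upper_weights(self) -> np.ndarray:
        """Vector of the p(p-1)/2 upper-triangle weights, row-major order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.weights[iu]

    def edge_labels(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(self.n_nodes, k=1)
        return [(self.labels[i], self.labels[j]) for i, j in zip(*iu)]

    def to_graph(self) -> nx.Graph:
        """networkx view: nodes in label order, edges for nonzero weights."""
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        iu = np.triu_indices(self.n_nodes, k=1)
        for i, j in zip(*iu):
            w = self.weights[i, j]
            if w != 0.0:
                g.add_edge(self.labels[i], self.labels[j], weight=float(w))
        return g


def write_network(network: Network, path: str | Path) -> Path:
    """Write a network; format inferred from suffix (.csv, .json, .graphml)."""
    path = Path(path)
    fmt = path.suffix.lower().lstrip(".")
    if fmt == "csv":
        _write_csv(network, path)
    elif fmt == "json":
        _write_json(network, path)
    elif fmt == "graphml":
        _write_graphml(network, path)
    else:
        raise ValidationError(f"unsupported network format {fmt!r}")
    return path


def read_network(path: str | Path) -> Network:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    fmt = path.suffix.lower().lstrip(".")
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "json":
        return _read_json(path)
    if fmt == "graphml":
        return _read_graphml(path)
    raise ValidationError(f"unsupported network format {fmt!r}")


# --- edge-list CSV: a '# nodes:' header preserves labels and order even for
# --- empty networks; only nonzero edges are listed.

def _write_csv(net: Network, path: Path) -> None:
    lines = ["# nodes: " + ",".join(net.labels), "node_i,node_j,weight"]
    iu = np.triu_indices(net.n_nodes, k=1)
    for i, j in zip(*iu):
        w = net.weights[i, j]
        if w != 0.0:
            lines.append(f"{net.labels[i]},{net.labels[j]},{float(w)!r}")
    path.write_text("\n".join(lines) + "\n")


def _read_csv(path: Path) -> Network:
    text = path.read_text().strip().splitlines()
    if not text or not text[0].startswith("# nodes:"):
        raise ValidationError(f"{path.name}: missing '# nodes:' header")
    labels = tuple(s.strip() for s in text[0].split(":", 1)[1].split(","))
    idx = {lab: k for k, lab in enumerate(labels)}
    w = np.zeros((len(labels), len(labels)))
    for line in text[2:]:
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise ValidationError(f"{path.name}: malformed edge row {line!r}")
        a, b, val = parts
        try:
            i, j = idx[a.strip()], idx[b.strip()]
        except KeyError as err:
            raise ValidationError(f"{path.name}: unknown node {err}") from None
        w[i, j] = w[j, i] = float(val)
    return Network(labels=labels, weights=w, meta={"source": str(path)})


def _write_json(net: Network, path: Path) -> None:
    doc = {
        "labels": list(net.labels),
        "weights": net.weights.tolist(),
        "meta": _jsonable(net.meta),
    }
    path.write_text(json.dumps(doc, indent=1))


def _read_json(path: Path) -> Network:
    try:
        doc = json.loads(path.read_text())
        return Network(
            labels=tuple(doc["labels"]),
            weights=np.asarray(doc["weights"], dtype=float),
            meta=doc.get("meta", {}),
        )
    except (KeyError, json.JSONDecodeError) as err:
        raise ValidationError(f"{path.name}: malformed network JSON ({err})") from err


def _write_graphml(net: Network, path: Path) -> None:
    g = nx.Graph()
    for k, lab in enumerate(net.labels):
        g.add_node(lab, order=k)
    iu = np.triu_indices(net.n_nodes, k=1)
    for i, j in zip(*iu):
        w = net.weights[i, j]
        if w != 0.0:
            g.add_edge(net.labels[i], net.labels[j], weight=float(w))
    nx.write_graphml(g, path)


def _read_graphml(path: Path) -> Network:
    g = nx.read_graphml(path)
    nodes = sorted(g.nodes(data=True), key=lambda kv: kv[1].get("order", 0))
    labels = tuple(str(n) for n, _ in nodes)
    idx = {lab: k for k, lab in enumerate(labels)}
    w = np.zeros((len(labels), len(labels)))
    for a, b, data in g.edges(data=True):
        i, j = idx[str(a)], idx[str(b)]
        w[i, j] = w[j, i] = float(data["weight"])
    return Network(labels=labels, weights=w, meta={"source": str(path)})


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
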