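"""Trait-level network reconstruction from fitted parameters.

A fitted model predicts, for every ordered member pair, the measurement-
error-free response to each item.  Summing predictions within a subscale
gives the weight of the directed trait-level tie from sender to receiver,
interpretable in the original response-scale units; the collection of all
ordered pairs is a complete weighted digraph per trait dimension.  The
raw-score counterpart (summed observed responses) is emitted alongside
for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .data import DyadicResponseTable, NetworkSpec
from .model import predict_response
from .parameters import LidmParameters

__all__ = ["TraitNetwork", "predicted_tie_weight", "build_network",
           "export_network", "read_edge_list"]


def predicted_tie_weight(params: LidmParameters, model: int,
                         spec: NetworkSpec, sender: int, receiver: int,
                         subscale: int) -> float:
    """Sum of predicted (noise-free) responses over a subscale's items;
    the directed trait-level tie weight sender -> receiver.  Member
    indices 0-based, subscale 1-based."""
    items = [i for i, s in enumerate(spec.item_to_subscale) if s == subscale]
    if not items:
        raise KeyError(f"no such subscale: {subscale}")
    return float(sum(
        predict_response(model, params, spec, i, sender, receiver)
        for i in items))


@dataclass
class TraitNetwork:
    """Complete weighted digraph of predicted trait-level ties for one
    subscale, with provenance."""

    subscale: int
    member_ids: tuple
    weights: np.ndarray          # (n, n), zero diagonal
    model: int
    source: str = "eap"          # which posterior summary produced it

    def __post_init__(self):
        if not np.all(np.diag(self.weights) == 0.0):
            raise ValueError("self-ties must be zero")

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    def weight(self, sender, receiver) -> float:
        ids = list(self.member_ids)
        return float(self.weights[ids.index(sender), ids.index(receiver)])

    def edge_frame(self) -> pd.DataFrame:
        rows = []
        for a, src in enumerate(self.member_ids):
            for b, dst in enumerate(self.member_ids):
                if a == b:
                    continue
                rows.append({"source": src, "target": dst,
                             "subscale": self.subscale,
                             "weight": self.weights[a, b]})
        return pd.DataFrame(rows)

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph(subscale=self.subscale, model=self.model,
                       source=self.source)
        for row in self.edge_frame().itertuples(index=False):
            g.add_edge(row.source, row.target, weight=float(row.weight),
                       subscale=int(row.subscale))
        return g


def build_network(params: LidmParameters, model: int, spec: NetworkSpec,
                  subscale: int, data: DyadicResponseTable | None = None
                  ) -> tuple[TraitNetwork, np.ndarray | None]:
    """Predicted trait-level network for one subscale, plus the raw-score
    sociomatrix for the same subscale when the observed table is given."""
    n = spec.n_members
    W = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a != b:
                W[a, b] = predicted_tie_weight(params, model, spec, a, b,
                                               subscale)
    net = TraitNetwork(subscale, tuple(spec.member_ids), W, model)
    raw = data.sociomatrix(subscale) if data is not None else None
    return net, raw


def export_network(net: TraitNetwork, path: str | Path,
                   fmt: str = "csv") -> Path:
    """Write the network as an edge-list CSV (source, target, subscale,
    weight) or GraphML with a weight attribute.  Output is bit-stable for
    identical inputs."""
    path = Path(path)
    if fmt == "csv":
        net.edge_frame().to_csv(path, index=False)
    elif fmt == "graphml":
        nx.write_graphml(net.to_graph(), path)
    else:
        raise ValueError(f"unsupported format: {fmt!r} (use csv or graphml)")
    return path


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Round-trip companion of the CSV export."""
    return pd.read_csv(path)
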