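"""Graph-theoretic choice of validation nodes.

Validation proteins are picked among the RPPA-measured, non-calibration
nodes by ranking closeness centrality (CC = (n-1) / sum of shortest-path
distances, computed within a node's connected component) and eccentricity
(E = maximum shortest-path distance), both on the undirected skeleton of
the interaction graph.  Well-connected yet peripheral read-outs integrate
signal from much of the network while remaining distinct from the
calibration inputs.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .model import PathwayModel

log = logging.getLogger(__name__)


def skeleton(model: PathwayModel) -> nx.Graph:
    """Undirected skeleton of the interaction list."""
    g = nx.Graph()
    g.add_nodes_from(model.node_names())
    g.add_edges_from((e.source, e.target) for e in model.interactions)
    return g


def graph_metrics(model: PathwayModel) -> pd.DataFrame:
    """Closeness centrality and eccentricity per node (undirected skeleton).

    Disconnected graphs are handled per component (with a warning);
    isolated nodes get CC = 0 and E = 0 by convention.
    """
    g = skeleton(model)
    components = list(nx.connected_components(g))
    if len(components) > 1:
        log.warning("skeleton has %d components; metrics are per-component",
                    len(components))
    rows = {}
    for comp in components:
        sub = g.subgraph(comp)
        if len(comp) == 1:
            node = next(iter(comp))
            rows[node] = (0.0, 0)
            continue
        cc = nx.closeness_centrality(sub, wf_improved=False)
        ecc = nx.eccentricity(sub)
        for node in comp:
            rows[node] = (cc[node], ecc[node])
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=["CC", "E"])
    return frame.loc[model.node_names()]


def select_validation_nodes(
    metrics: pd.DataFrame,
    k: int,
    exclude: Iterable[str] = (),
    measured: Sequence[str] | None = None,
) -> list[str]:
    """Top-k eligible nodes by (CC, E) lexicographic rank.

    Eligible nodes are those not excluded (calibration proteins) and,
    when ``measured`` is given, restricted to RPPA-measured nodes.  Ties
    beyond (CC, E) break alphabetically and are logged.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    excluded = set(exclude)
    eligible = [n for n in metrics.index if n not in excluded]
    if measured is not None:
        eligible = [n for n in eligible if n in set(measured)]
    if k > len(eligible):
        raise ValueError(f"k={k} exceeds {len(eligible)} eligible nodes")
    ranked = sorted(
        eligible,
        key=lambda n: (-metrics.at[n, "CC"], -metrics.at[n, "E"], n),
    )
    chosen = ranked[:k]
    if k and k < len(ranked):
        last = chosen[-1]
        runner = ranked[k]
        if (metrics.at[last, "CC"], metrics.at[last, "E"]) == (
            metrics.at[runner, "CC"], metrics.at[runner, "E"]
        ):
            log.info("tie at rank %d broken alphabetically: %s over %s",
                     k, last, runner)
    return chosen
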