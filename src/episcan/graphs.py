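"""Export interaction results as Cytoscape-loadable graph files.

Two graph modes:

* **pair** — SNVs are nodes and interactions are edges.  An m-SNV
  tuple with m > 2 is projected onto its C(m, 2) pairwise clique; when
  the same SNV pair appears in several tuples the edge keeps the
  maximum statistic.  The projection is recorded in the graph metadata.
* **bipartite** — both SNVs and interactions are nodes; each
  interaction node is connected to exactly its m member SNVs.  Suited
  to in-depth inspection of higher-order tuples.

Node sizes are a linear map of the chosen statistic (alpha by default)
onto a configured range, so stronger interactions draw bigger nodes.
Formats: GraphML, Cytoscape JSON, and SIF with a sidecar attribute
table (SIF itself carries no attributes).
"""

from __future__ import annotations

import json
import logging
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .stats import AssociationResult

logger = logging.getLogger(__name__)

PAIR = "pair"
BIPARTITE = "bipartite"
FORMATS = ("graphml", "sif", "cytoscape-json")

#: node-size range (arbitrary display units) the statistic maps onto
DEFAULT_SIZE_RANGE = (10.0, 50.0)


class GraphExportError(ValueError):
    """Invalid graph-export request."""


def _size_scale(values: list[float], size_range: tuple[float, float]):
    lo = min(values)
    hi = max(values)
    smin, smax = size_range

    def scale(v: float) -> float:
        if hi == lo:
            return (smin + smax) / 2.0
        return smin + (v - lo) / (hi - lo) * (smax - smin)

    return scale


def build_graph(
    results: Iterable[AssociationResult],
    snv_ids: tuple[str, ...] | None = None,
    annotations: pd.DataFrame | None = None,
    mode: str = PAIR,
    statistic: str = "alpha",
    size_range: tuple[float, float] = DEFAULT_SIZE_RANGE,
) -> nx.Graph:
    """Build the interaction network for a list of ranked results.

    ``annotations``, if given, is a table indexed by SNV id (or with an
    ``SNV`` column) whose columns become node attributes; SNVs missing
    from it keep empty attributes with a logged warning.
    """
    results = list(results)
    if not results:
        raise GraphExportError("no results to export")
    if mode not in (PAIR, BIPARTITE):
        raise GraphExportError(f"mode must be '{PAIR}' or '{BIPARTITE}'")
    if statistic not in ("alpha", "beta"):
        raise GraphExportError("statistic must be 'alpha' or 'beta'")

    def name(i: int) -> str:
        return snv_ids[i] if snv_ids is not None else str(i)

    def stat(res: AssociationResult) -> float:
        return res.alpha if statistic == "alpha" else res.beta

    ann: Mapping[str, dict] = {}
    if annotations is not None:
        table = annotations
        if "SNV" in table.columns:
            table = table.set_index("SNV")
        ann = {str(k): v.to_dict() for k, v in table.iterrows()}

    G = nx.Graph(
        mode=mode,
        statistic=statistic,
        clique_expanded=(mode == PAIR),
    )
    scale = _size_scale([stat(r) for r in results], size_range)

    # per-SNV statistic: the best value over tuples containing the SNV
    snv_stat: dict[str, float] = {}
    for res in results:
        for i in res.snv_tuple:
            sid = name(i)
            snv_stat[sid] = max(snv_stat.get(sid, float("-inf")), stat(res))

    for sid, value in snv_stat.items():
        attrs = {"node_type": "snv", "statistic": value, "size": scale(value)}
        if ann:
            if sid in ann:
                attrs.update(ann[sid])
            else:
                logger.warning("no annotation for SNV %s", sid)
        G.add_node(sid, **attrs)

    for res in results:
        ids = tuple(name(i) for i in res.snv_tuple)
        if mode == PAIR:
            for a, b in combinations(ids, 2):
                value = stat(res)
                if G.has_edge(a, b):
                    if value <= G.edges[a, b]["statistic"]:
                        continue
                G.add_edge(
                    a, b, statistic=value, alpha=res.alpha, beta=res.beta,
                    order=res.order,
                )
        elif res.order >= 2:
            inode = "I:" + "+".join(ids)
            G.add_node(
                inode,
                node_type="interaction",
                order=res.order,
                alpha=res.alpha,
                beta=res.beta,
                statistic=stat(res),
                size=scale(stat(res)),
            )
            for sid in ids:
                G.add_edge(inode, sid, statistic=stat(res))
    return G


def write_graph(graph: nx.Graph, fmt: str, path: str | Path) -> None:
    """Write the graph in GraphML, SIF or Cytoscape JSON.

    SIF carries no attributes: node attributes go to a sidecar TSV
    (``<path>.attrs.tsv``) with a logged warning.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(_stringify_missing(graph), path)
    elif fmt == "cytoscape-json":
        path.write_text(json.dumps(nx.cytoscape_data(graph), indent=1))
    elif fmt == "sif":
        _write_sif(graph, path)
    else:
        raise GraphExportError(
            f"unknown format {fmt!r}; choose one of {FORMATS}"
        )


def _stringify_missing(graph: nx.Graph) -> nx.Graph:
    """GraphML cannot serialise None attributes; blank them out."""
    g = graph.copy()
    for _, attrs in g.nodes(data=True):
        for k, v in attrs.items():
            if v is None or (isinstance(v, float) and v != v):
                attrs[k] = ""
    return g


def _write_sif(graph: nx.Graph, path: Path) -> None:
    lines = []
    isolated = set(graph.nodes)
    for a, b in graph.edges:
        lines.append(f"{a}\tinteracts\t{b}")
        isolated.discard(a)
        isolated.discard(b)
    lines.extend(sorted(str(n) for n in isolated))
    path.write_text("\n".join(lines) + "\n")
    if any(attrs for _, attrs in graph.nodes(data=True)):
        sidecar = path.with_name(path.name + ".attrs.tsv")
        rows = [
            {"node": str(n), **attrs} for n, attrs in graph.nodes(data=True)
        ]
        pd.DataFrame(rows).to_csv(sidecar, sep="\t", index=False)
        logger.warning(
            "SIF cannot hold attributes; node attributes written to %s",
            sidecar,
        )
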