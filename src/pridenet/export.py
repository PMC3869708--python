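"""Machine-readable exports: GraphML sociograms, edge lists, clique maps."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence
from xml.etree import ElementTree as ET
from xml.dom import minidom

import numpy as np
import pandas as pd

from .matrices import LabeledMatrix

_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


def to_graphml(matrix: LabeledMatrix, path: str | Path, directed: bool) -> None:
    """Write a weighted sociogram as GraphML (edge attribute ``weight``)."""
    ET.register_namespace("", _GRAPHML_NS)
    root = ET.Element(f"{{{_GRAPHML_NS}}}graphml")
    key = ET.SubElement(root, f"{{{_GRAPHML_NS}}}key")
    key.set("id", "w")
    key.set("for", "edge")
    key.set("attr.name", "weight")
    key.set("attr.type", "double")
    graph = ET.SubElement(root, f"{{{_GRAPHML_NS}}}graph")
    graph.set("id", matrix.name or "network")
    graph.set("edgedefault", "directed" if directed else "undirected")
    for a in matrix.ids:
        node = ET.SubElement(graph, f"{{{_GRAPHML_NS}}}node")
        node.set("id", a)
    edges = matrix.to_edgelist(directed=directed)
    for k, row in edges.iterrows():
        e = ET.SubElement(graph, f"{{{_GRAPHML_NS}}}edge")
        e.set("id", f"e{k}")
        e.set("source", str(row["source"]))
        e.set("target", str(row["target"]))
        d = ET.SubElement(e, f"{{{_GRAPHML_NS}}}data")
        d.set("key", "w")
        d.text = repr(float(row["weight"]))
    pretty = minidom.parseString(ET.tostring(root)).toprettyxml(indent="  ")
    Path(path).write_text(pretty)


def clique_bipartite(cliques: Sequence[Sequence[str]], network_name: str = "") -> pd.DataFrame:
    """(individual, clique_id) membership edge list, one clique per id.

    Mirrors the clique-diagram convention of drawing individuals tied to
    the clique nodes they belong to.
    """
    rows = []
    for k, clique in enumerate(cliques, start=1):
        cid = f"{network_name + '_' if network_name else ''}clique_{k}"
        for member in clique:
            rows.append((member, cid))
    return pd.DataFrame(rows, columns=["individual", "clique_id"])
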