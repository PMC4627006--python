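"""Graph-structure indices of an ecological corridor network.

An ecological network abstracts green-space patches of ecological or
cultural importance as nodes v and planned green corridors as links l with
lengths in kilometres summing to d.  Its structure is summarised by the
classical planar-connectivity indices:

``alpha``   (l - v + 1) / (2v - 5)   loops present over loops possible
``beta``    l / v                    links per node (<1 dendroid, =1 single
                                     loop, >1 complex)
``gamma``   l / (3 (v - 2))          links over the planar maximum
``cost``    1 - l / d                cost ratio, an efficiency proxy trading
                                     connectivity against corridor length

Corridor density d / landscape area (km/km^2) describes how densely the
network threads the district.  Connectivity of the graph is not required:
indices are computed on the graph as given.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import LineString

__all__ = [
    "EcoNetwork",
    "alpha_index",
    "beta_index",
    "beta_classification",
    "gamma_index",
    "cost_ratio",
    "corridor_density",
    "network_report",
    "round_half_up",
    "read_network_geojson",
    "write_network_geojson",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, the convention used in the rendered tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class Link:
    """An undirected corridor between two nodes."""

    source: object
    target: object
    length_km: float | None = None
    geometry: LineString | None = None


@dataclass
class EcoNetwork:
    """Node points plus corridor links with lengths in kilometres.

    Node coordinates are planar metres.  Link lengths: an explicit
    ``length_km`` wins; otherwise the polyline arc length (corridors follow
    roads and rivers, not straight chords); otherwise the node chord.
    Self-loops, duplicate links and non-positive lengths are rejected.
    """

    nodes: dict = field(default_factory=dict)  # id -> (x, y) metres
    links: list[Link] = field(default_factory=list)
    landscape_area_km2: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        seen: set[frozenset] = set()
        for lk in self.links:
            if lk.source not in self.nodes or lk.target not in self.nodes:
                raise ValueError(
                    f"link ({lk.source}, {lk.target}) references a missing node"
                )
            if lk.source == lk.target:
                raise ValueError(f"self-loop at node {lk.source} is not allowed")
            key = frozenset((lk.source, lk.target))
            if key in seen:
                raise ValueError(
                    f"duplicate corridor between {lk.source} and {lk.target}: "
                    "duplicated links between a pair of nodes are not allowed"
                )
            seen.add(key)
            if lk.length_km is None and lk.geometry is not None:
                lk.length_km = lk.geometry.length / 1000.0
            if lk.length_km is None:
                ax, ay = self.nodes[lk.source]
                bx, by = self.nodes[lk.target]
                lk.length_km = float(np.hypot(bx - ax, by - ay)) / 1000.0
            if lk.length_km <= 0:
                raise ValueError(
                    f"link ({lk.source}, {lk.target}) has non-positive length "
                    f"{lk.length_km} km"
                )

    @property
    def v(self) -> int:
        return len(self.nodes)

    @property
    def l(self) -> int:  # noqa: E741 - the field's symbol for link count
        return len(self.links)

    @property
    def total_length_km(self) -> float:
        """d: summed corridor length in km."""
        return float(sum(lk.length_km for lk in self.links))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for nid, xy in self.nodes.items():
            g.add_node(nid, pos=xy)
        for lk in self.links:
            g.add_edge(lk.source, lk.target, length_km=lk.length_km)
        return g


def alpha_index(net: EcoNetwork) -> float:
    """Circuitry: (l - v + 1) / (2v - 5); 0 for trees, 1 at the planar maximum.

    Returned unclamped; values outside [0, 1] flag a non-planar or
    disconnected input.
    """
    if net.v < 3:
        raise ValueError(f"alpha undefined for v={net.v} (< 3 nodes)")
    return (net.l - net.v + 1) / (2 * net.v - 5)


def beta_index(net: EcoNetwork) -> float:
    """Links per node, l / v."""
    if net.v == 0:
        raise ValueError("beta undefined for an empty network")
    return net.l / net.v


def beta_classification(beta: float) -> str:
    if beta < 1:
        return "dendroid"
    if beta == 1:
        return "single-loop"
    return "complex"


def gamma_index(net: EcoNetwork) -> float:
    """Connectivity: l / (3 (v - 2)), links over the planar maximum."""
    if net.v < 3:
        raise ValueError(f"gamma undefined for v={net.v} (< 3 nodes)")
    return net.l / (3 * (net.v - 2))


def cost_ratio(net: EcoNetwork) -> float:
    """1 - l / d with d in km; negative when corridors average under 1 km."""
    d = net.total_length_km
    if d <= 0:
        raise ValueError("cost ratio undefined: total corridor length is 0")
    value = 1.0 - net.l / d
    if value < 0:
        warnings.warn(
            f"cost ratio {value:.3f} is negative (mean corridor < 1 km); "
            "returned unclamped"
        )
    return value


def corridor_density(net: EcoNetwork) -> float:
    """d over the district area, km of corridor per km^2."""
    if net.landscape_area_km2 is None or net.landscape_area_km2 <= 0:
        raise ValueError("corridor density needs a positive landscape_area_km2")
    return net.total_length_km / net.landscape_area_km2


def network_report(net: EcoNetwork) -> dict:
    """All indices plus counts/length, full precision and 2-dp display values."""
    record = {
        "name": net.name,
        "nodes": net.v,
        "corridors": net.l,
        "length_km": net.total_length_km,
        "alpha": alpha_index(net),
        "beta": beta_index(net),
        "beta_class": beta_classification(beta_index(net)),
        "gamma": gamma_index(net),
        "cost_ratio": cost_ratio(net),
    }
    if net.landscape_area_km2 is not None:
        record["corridor_density_km_per_km2"] = corridor_density(net)
    record["display"] = {
        k: round_half_up(record[k], 2)
        for k in ("length_km", "alpha", "beta", "gamma", "cost_ratio")
    }
    return record


def report_frame(records: Sequence[dict]) -> pd.DataFrame:
    """Fixed-column table of rounded index values, one row per network."""
    rows = []
    for r in records:
        rows.append(
            {
                "name": r["name"],
                "nodes": r["nodes"],
                "corridors": r["corridors"],
                "length_km": r["display"]["length_km"],
                "alpha": r["display"]["alpha"],
                "beta": r["display"]["beta"],
                "gamma": r["display"]["gamma"],
                "cost_ratio": r["display"]["cost_ratio"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "name",
            "nodes",
            "corridors",
            "length_km",
            "alpha",
            "beta",
            "gamma",
            "cost_ratio",
        ],
    )


# -- GeoJSON I/O -----------------------------------------------------------


def read_network_geojson(
    nodes_path: str | Path,
    links_path: str | Path,
    landscape_area_km2: float | None = None,
    name: str = "",
) -> EcoNetwork:
    """Read node Points and corridor LineStrings from GeoJSON files.

    Node features: Point geometry + property ``id``.  Link features:
    LineString geometry + properties ``source``, ``target`` and optional
    ``length_km`` (which overrides the arc length).  Schema violations
    name the offending feature index.
    """
    nodes_fc = json.loads(Path(nodes_path).read_text())
    links_fc = json.loads(Path(links_path).read_text())
    nodes: dict = {}
    for i, feat in enumerate(nodes_fc.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValueError(f"node feature {i}: geometry must be a Point")
        props = feat.get("properties") or {}
        if "id" not in props:
            raise ValueError(f"node feature {i}: missing 'id' property")
        nodes[props["id"]] = tuple(geom["coordinates"][:2])
    links: list[Link] = []
    for i, feat in enumerate(links_fc.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "LineString":
            raise ValueError(f"link feature {i}: geometry must be a LineString")
        props = feat.get("properties") or {}
        for key in ("source", "target"):
            if key not in props:
                raise ValueError(f"link feature {i}: missing '{key}' property")
        line = LineString(geom["coordinates"])
        links.append(
            Link(
                source=props["source"],
                target=props["target"],
                length_km=props.get("length_km"),
                geometry=line,
            )
        )
    return EcoNetwork(
        nodes=nodes, links=links, landscape_area_km2=landscape_area_km2, name=name
    )


def write_network_geojson(
    net: EcoNetwork, nodes_path: str | Path, links_path: str | Path
) -> None:
    nodes_fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": list(xy)},
                "properties": {"id": nid},
            }
            for nid, xy in net.nodes.items()
        ],
    }
    links_fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": (
                        [list(c) for c in lk.geometry.coords]
                        if lk.geometry is not None
                        else [list(net.nodes[lk.source]), list(net.nodes[lk.target])]
                    ),
                },
                "properties": {
                    "source": lk.source,
                    "target": lk.target,
                    "length_km": lk.length_km,
                },
            }
            for lk in net.links
        ],
    }
    Path(nodes_path).write_text(json.dumps(nodes_fc, indent=1))
    Path(links_path).write_text(json.dumps(links_fc, indent=1))
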