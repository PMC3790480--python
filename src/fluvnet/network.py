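"""Dendritic stream-network model.

A sampled river network is represented as a rooted tree of sites.  Edges
are directed child -> parent in the direction of flow, so the root is the
catchment outlet.  All topological queries the diversity analysis needs —
Strahler orders, flow connectivity, along-network (hydrologic) distances,
confluence triplets and the headwater/mid-sized classification — live here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .errors import ConfigurationError, SiteLookupError, TopologyError

__all__ = [
    "SiteNode",
    "StreamNetwork",
    "ConfluenceTriplet",
    "euclidean_distance",
    "read_network",
    "write_network",
]


@dataclass
class SiteNode:
    """A sampling site with its physical and chemical descriptors.

    ``env`` holds the environmental covariates (SUVA254 in L mg-C^-1 m^-1,
    DOC in mg L^-1, dimensionless channel slope and Froude number, forest
    cover as a fraction, depth in m, velocity in m s^-1, ...).
    """

    id: str
    x: float
    y: float
    elevation: float
    catchment_area_km2: float
    env: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"site {self.id!r}: non-finite coordinates")
        if not (self.catchment_area_km2 > 0):
            raise ValueError(
                f"site {self.id!r}: catchment area must be positive, "
                f"got {self.catchment_area_km2}"
            )


@dataclass(frozen=True)
class ConfluenceTriplet:
    """Two tributaries immediately upstream of a junction plus the
    recipient site downstream of it."""

    tributary_a: str
    tributary_b: str
    recipient: str


def euclidean_distance(a: SiteNode, b: SiteNode) -> float:
    """Planar distance between two sites, in metres."""
    return math.hypot(a.x - b.x, a.y - b.y)


class StreamNetwork:
    """Rooted tree of sites; edges point downstream (child -> parent).

    Parameters
    ----------
    sites
        The site nodes; ids must be unique.
    edges
        ``(child, parent, length_m)`` triples, one per non-outlet site.

    Raises
    ------
    TopologyError
        If the edges do not form a single rooted tree, a junction has more
        than two upstream branches, an edge length is not positive, or the
        catchment area decreases downstream.
    """

    def __init__(
        self,
        sites: Iterable[SiteNode],
        edges: Iterable[tuple[str, str, float]],
    ) -> None:
        self.sites: dict[str, SiteNode] = {}
        for s in sites:
            if s.id in self.sites:
                raise TopologyError(f"duplicate site id {s.id!r}")
            self.sites[s.id] = s

        self.parent: dict[str, str] = {}
        self.edge_length: dict[str, float] = {}
        self.children: dict[str, list[str]] = {sid: [] for sid in self.sites}
        for child, parent, length in edges:
            for sid in (child, parent):
                if sid not in self.sites:
                    raise TopologyError(f"edge references unknown site {sid!r}")
            if child in self.parent:
                raise TopologyError(f"site {child!r} has two downstream edges")
            if not (length > 0):
                raise TopologyError(
                    f"edge {child!r}->{parent!r}: length must be > 0, got {length}"
                )
            self.parent[child] = parent
            self.edge_length[child] = float(length)
            self.children[parent].append(child)

        roots = [sid for sid in self.sites if sid not in self.parent]
        if len(roots) != 1:
            raise TopologyError(
                f"network must have exactly one outlet, found {len(roots)}"
            )
        self.outlet: str = roots[0]

        for sid, kids in self.children.items():
            if len(kids) > 2:
                raise TopologyError(
                    f"site {sid!r} has {len(kids)} upstream branches; only "
                    "pairwise confluences are supported"
                )

        # cycle check + downstream distance to outlet (also caches ancestry)
        self._dist_to_outlet: dict[str, float] = {self.outlet: 0.0}
        self._downstream_path: dict[str, tuple[str, ...]] = {}
        for sid in self.sites:
            path = []
            cur = sid
            seen = {sid}
            while cur != self.outlet:
                cur = self.parent[cur]
                if cur in seen:
                    raise TopologyError("cycle detected in edge list")
                seen.add(cur)
                path.append(cur)
            self._downstream_path[sid] = tuple(path)
        for sid in self._topological_order():
            if sid != self.outlet:
                self._dist_to_outlet[sid] = (
                    self._dist_to_outlet[self.parent[sid]] + self.edge_length[sid]
                )

        for child, parent in self.parent.items():
            a_child = self.sites[child].catchment_area_km2
            a_parent = self.sites[parent].catchment_area_km2
            if a_parent < a_child:
                raise TopologyError(
                    f"catchment area decreases downstream across "
                    f"{child!r}->{parent!r} ({a_child} -> {a_parent} km2)"
                )

        self._orders: dict[str, int] | None = None

    # -- basic queries -----------------------------------------------------

    def __contains__(self, site_id: str) -> bool:
        return site_id in self.sites

    def __len__(self) -> int:
        return len(self.sites)

    def site(self, site_id: str) -> SiteNode:
        try:
            return self.sites[site_id]
        except KeyError:
            raise SiteLookupError(f"unknown site id {site_id!r}") from None

    def _topological_order(self) -> list[str]:
        """Outlet first, every parent before its children."""
        order = [self.outlet]
        i = 0
        while i < len(order):
            order.extend(self.children[order[i]])
            i += 1
        return order

    def upstream_order(self) -> list[str]:
        """Leaves first, every child before its parent."""
        return self._topological_order()[::-1]

    # -- spec operations ---------------------------------------------------

    def strahler_orders(self) -> dict[str, int]:
        """Strahler stream order for every site.

        Leaves are order 1; a junction of two equal orders *i* is *i* + 1,
        otherwise the larger order carries through.  Pass-through sites
        (single upstream branch) keep the upstream order.
        """
        if self._orders is None:
            orders: dict[str, int] = {}
            for sid in self.upstream_order():
                kids = self.children[sid]
                if not kids:
                    orders[sid] = 1
                elif len(kids) == 1:
                    orders[sid] = orders[kids[0]]
                else:
                    i, j = sorted(orders[k] for k in kids)
                    orders[sid] = i + 1 if i == j else j
            self._orders = orders
        return dict(self._orders)

    def flow_connected(self, a: str, b: str) -> bool:
        """True iff one site drains through the other."""
        if a not in self.sites or b not in self.sites:
            raise SiteLookupError(f"unknown site id in pair ({a!r}, {b!r})")
        if a == b:
            raise ValueError("flow_connected requires two distinct sites")
        return a in self._downstream_path[b] or b in self._downstream_path[a]

    def hydrologic_distance(self, a: str, b: str) -> float:
        """Along-network path length between two sites, in metres."""
        if a not in self.sites or b not in self.sites:
            raise SiteLookupError(f"unknown site id in pair ({a!r}, {b!r})")
        if a == b:
            return 0.0
        anc_a = {a, *self._downstream_path[a]}
        lca = b
        for node in (b, *self._downstream_path[b]):
            if node in anc_a:
                lca = node
                break
        else:  # pragma: no cover - outlet is a common ancestor by construction
            raise TopologyError(f"sites {a!r} and {b!r} share no downstream node")
        da = self._dist_to_outlet[a] - self._dist_to_outlet[lca]
        db = self._dist_to_outlet[b] - self._dist_to_outlet[lca]
        return da + db

    def euclidean_distance(self, a: str, b: str) -> float:
        return euclidean_distance(self.site(a), self.site(b))

    def classify_headwaters(self, sampled_sites: Iterable[str]) -> dict[str, str]:
        """Partition sampled sites into ``headwater`` and ``midsized``.

        The threshold is the largest catchment area among sampled
        first-order (Strahler) sites; a site is a headwater iff its area
        does not exceed that threshold.  The inclusive boundary keeps the
        defining first-order site itself in the headwater group.
        """
        sampled = list(sampled_sites)
        orders = self.strahler_orders()
        first_order_areas = [
            self.site(s).catchment_area_km2 for s in sampled if orders[s] == 1
        ]
        if not first_order_areas:
            raise ConfigurationError(
                "headwater classification requires at least one sampled "
                "first-order site"
            )
        threshold = max(first_order_areas)
        return {
            s: (
                "headwater"
                if self.site(s).catchment_area_km2 <= threshold
                else "midsized"
            )
            for s in sampled
        }

    def find_triplets(self, sampled_sites: Iterable[str]) -> list[ConfluenceTriplet]:
        """All confluences with both immediate tributaries sampled and a
        sampled recipient downstream.

        The recipient is the nearest sampled site at or below the junction.
        When two junctions would claim the same recipient, the junction
        closer to it wins, keeping triplets disjoint in their recipient.
        """
        sampled = set(sampled_sites)
        for s in sampled:
            if s not in self.sites:
                raise SiteLookupError(f"sampled site {s!r} not in network")
        best: dict[str, tuple[float, ConfluenceTriplet]] = {}
        for junction in self.sites:
            kids = self.children[junction]
            if len(kids) != 2 or not all(k in sampled for k in kids):
                continue
            # nearest sampled site at/below the junction
            recipient = None
            dist = 0.0
            cur = junction
            while True:
                if cur in sampled:
                    recipient = cur
                    break
                if cur == self.outlet:
                    break
                dist += self.edge_length[cur]
                cur = self.parent[cur]
            if recipient is None or recipient in kids:
                continue
            trip = ConfluenceTriplet(kids[0], kids[1], recipient)
            if recipient not in best or dist < best[recipient][0]:
                best[recipient] = (dist, trip)
        return sorted((t for _, t in best.values()), key=lambda t: t.recipient)


# -- I/O -------------------------------------------------------------------

_SITE_COLUMNS = ["site_id", "x", "y", "elevation", "catchment_area_km2"]


def read_network(edges_path: str, sites_path: str) -> StreamNetwork:
    """Load a network from an edge-list TSV and a site-metadata TSV.

    The edge list has columns ``child``, ``parent``, ``length_m`` (direction
    child -> parent is downstream).  The site table is keyed by ``site_id``
    and carries coordinates, elevation, catchment area and any further
    columns as environmental covariates.
    """
    edges_df = pd.read_csv(edges_path, sep="\t", dtype={"child": str, "parent": str})
    for col in ("child", "parent", "length_m"):
        if col not in edges_df.columns:
            raise TopologyError(f"edge list is missing column {col!r}")
    sites_df = pd.read_csv(sites_path, sep="\t", dtype={"site_id": str})
    for col in _SITE_COLUMNS:
        if col not in sites_df.columns:
            raise TopologyError(f"site table is missing column {col!r}")
    env_cols = [c for c in sites_df.columns if c not in _SITE_COLUMNS]
    sites = [
        SiteNode(
            id=row["site_id"],
            x=float(row["x"]),
            y=float(row["y"]),
            elevation=float(row["elevation"]),
            catchment_area_km2=float(row["catchment_area_km2"]),
            env={c: float(row[c]) for c in env_cols},
        )
        for _, row in sites_df.iterrows()
    ]
    edges = [
        (str(r["child"]), str(r["parent"]), float(r["length_m"]))
        for _, r in edges_df.iterrows()
    ]
    return StreamNetwork(sites, edges)


def write_network(net: StreamNetwork, edges_path: str, sites_path: str) -> None:
    edges_df = pd.DataFrame(
        [
            {"child": c, "parent": p, "length_m": net.edge_length[c]}
            for c, p in sorted(net.parent.items())
        ]
    )
    env_keys: list[str] = sorted({k for s in net.sites.values() for k in s.env})
    rows = []
    for sid in sorted(net.sites):
        s = net.sites[sid]
        row: dict[str, object] = {
            "site_id": s.id,
            "x": s.x,
            "y": s.y,
            "elevation": s.elevation,
            "catchment_area_km2": s.catchment_area_km2,
        }
        row.update({k: s.env.get(k, float("nan")) for k in env_keys})
        rows.append(row)
    pd.DataFrame(rows).to_csv(sites_path, sep="\t", index=False)
    edges_df.to_csv(edges_path, sep="\t", index=False)


def site_env_frame(net: StreamNetwork, sampled: Iterable[str] | None = None) -> pd.DataFrame:
    """Site metadata (area, coordinates and env covariates) as a DataFrame."""
    ids = list(sampled) if sampled is not None else sorted(net.sites)
    rows = []
    for sid in ids:
        s = net.site(sid)
        row: dict[str, float] = {
            "x": s.x,
            "y": s.y,
            "elevation": s.elevation,
            "catchment_area_km2": s.catchment_area_km2,
        }
        row.update(s.env)
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(ids, name="site_id"))
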