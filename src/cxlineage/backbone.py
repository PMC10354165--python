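"""Tract-backbone extraction from neuron skeletons.

Full EM skeletons carry dense terminal arborisations and skeletonisation
artifacts; the lineage tract is the long, synapse-poor core that follows
the neuroblast fiber bundle.  The extraction runs four rule-based steps:

1. *Twig pruning* — terminal branches shorter than ``twig_node_max``
   nodes (15 nodes at 8 nm spacing, ~120 nm) that carry no connector are
   removed, iterating to a fixpoint so nested twigs cannot survive.
2. *Fragmentation* — the cleaned tree is cut at every branch point into
   maximal unbranched paths (branch-point nodes are shared by every
   incident fragment).
3. *Selection* — fragments longer than ``large_fragment_min_len``
   (2500 nm) are kept outright; shorter fragments are kept only if they
   exceed ``small_fragment_min_len`` (80 nm) and their connector count is
   below ``connector_density_max`` (0.01) times their cable length in nm.
   Secondary fragments much shorter than the largest fragment (by the
   ``relative_length_factor`` of 2.5) are then dropped.
4. *Distal trimming* — any remaining fragment farther than
   ``distal_trim_distance`` (5000 nm) from both endpoints of the largest
   fragment is discarded.

Connectors are mapped to skeleton nodes by nearest node within
``connector_map_radius`` (250 nm); unmapped connectors are ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io import SkeletonGraph

__all__ = [
    "BackboneParams",
    "Fragment",
    "BackboneResult",
    "map_connectors_to_nodes",
    "prune_twigs",
    "fragment_at_branchpoints",
    "select_fragments",
    "trim_distal_fragments",
    "extract_backbone",
    "backbone_polylines",
]


@dataclass
class BackboneParams:
    twig_node_max: int = 15                 # nodes; twigs strictly smaller are candidates
    large_fragment_min_len: float = 2500.0  # nm
    small_fragment_min_len: float = 80.0    # nm
    connector_density_max: float = 0.01     # connectors per nm of cable
    relative_length_factor: float = 2.5
    distal_trim_distance: float = 5000.0    # nm
    connector_map_radius: float = 250.0     # nm
    literal_relative_rule: bool = False     # alternative reading of the 2.5x rule

    def __post_init__(self):
        for name in ("twig_node_max", "large_fragment_min_len",
                     "small_fragment_min_len", "connector_density_max",
                     "relative_length_factor", "distal_trim_distance",
                     "connector_map_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.connector_density_max >= 1:
            raise ValueError("connector_density_max must be < 1")


@dataclass
class Fragment:
    """Maximal unbranched node path with its cable length and connector load."""

    node_ids: np.ndarray            # ordered along the path
    points: np.ndarray              # (n, 3) nm
    cable_length: float
    connector_count: int

    @classmethod
    def from_path(cls, node_ids, points, connector_counts: dict | None = None):
        node_ids = np.asarray(node_ids, dtype=np.int64)
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        length = float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum()) if len(points) > 1 else 0.0
        cc = 0
        if connector_counts:
            cc = int(sum(connector_counts.get(int(n), 0) for n in node_ids))
        return cls(node_ids, points, length, cc)

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points[0], self.points[-1]


@dataclass
class BackboneResult:
    fragments: list
    node_ids: set
    warning: str | None = None
    report: list = field(default_factory=list)  # (frag idx, length, n_conn, kept, rule)


def map_connectors_to_nodes(skel: SkeletonGraph, connector_xyz: np.ndarray,
                            radius: float = 250.0) -> dict[int, int]:
    """Nearest-node assignment of connector positions within ``radius`` nm.

    Returns node_id -> number of connectors mapped there; connectors with
    no node inside the radius are dropped.
    """
    counts: dict[int, int] = {}
    connector_xyz = np.asarray(connector_xyz, dtype=float).reshape(-1, 3)
    if skel.n_nodes == 0 or len(connector_xyz) == 0:
        return counts
    tree = cKDTree(skel.xyz)
    dist, idx = tree.query(connector_xyz, distance_upper_bound=radius)
    for d, i in zip(dist, idx):
        if np.isfinite(d):
            nid = int(skel.node_ids[i])
            counts[nid] = counts.get(nid, 0) + 1
    return counts


def prune_twigs(skel: SkeletonGraph, connector_nodes: dict[int, int] | set,
                p: BackboneParams = None) -> SkeletonGraph:
    """Remove connector-free terminal branches of < ``twig_node_max`` nodes.

    A twig is the chain from a leaf up to (excluding) the first node of
    degree >= 3.  Twigging is root-protected: a chain that reaches the
    root (the soma side) before meeting a branch point is not a twig, so
    an unbranched skeleton is returned unchanged and the soma-side tip
    of the tract can never be eaten.  Applied iteratively until no twig
    qualifies.
    """
    p = p or BackboneParams()
    if skel.n_nodes == 0:
        return skel
    has_conn = set(connector_nodes)
    keep = set(int(n) for n in skel.node_ids)
    parent = {int(n): int(pp) for n, pp in zip(skel.node_ids, skel.parent_ids)}

    changed = True
    while changed:
        changed = False
        deg: dict[int, int] = {n: 0 for n in keep}
        for n in keep:
            pp = parent[n]
            if pp != -1 and pp in keep:
                deg[n] += 1
                deg[pp] += 1
        children: dict[int, int] = {n: 0 for n in keep}
        for n in keep:
            pp = parent[n]
            if pp != -1 and pp in keep:
                children[pp] += 1
        leaves = [n for n in keep if deg[n] == 1 and children[n] == 0]
        removed = set()
        for leaf in leaves:
            if leaf in removed:
                continue
            chain = [leaf]
            u = leaf
            terminus_is_branch = False
            while True:
                pp = parent[u]
                if pp == -1 or pp not in keep:
                    break
                if deg[pp] >= 3:
                    terminus_is_branch = True
                    break
                chain.append(pp)
                u = pp
            if not terminus_is_branch:
                continue
            if len(chain) < p.twig_node_max and not (set(chain) & has_conn):
                removed.update(chain)
        if removed:
            keep -= removed
            changed = True
    if len(keep) == skel.n_nodes:
        return skel
    return skel.subgraph(keep)


def fragment_at_branchpoints(skel: SkeletonGraph,
                             connector_nodes: dict[int, int] | None = None
                             ) -> list[Fragment]:
    """Cut the tree at every branch point into maximal unbranched paths.

    Branch-point nodes are duplicated into each incident fragment, so the
    fragments partition the edge set while sharing junction nodes.
    """
    n = skel.n_nodes
    if n == 0:
        return []
    if n == 1:
        return [Fragment.from_path(skel.node_ids, skel.xyz, connector_nodes)]
    adj: dict[int, list[int]] = {int(i): [] for i in skel.node_ids}
    for nid, pid in zip(skel.node_ids, skel.parent_ids):
        if pid != -1:
            adj[int(nid)].append(int(pid))
            adj[int(pid)].append(int(nid))
    deg = {u: len(vs) for u, vs in adj.items()}
    junctions = [u for u in adj if deg[u] != 2]
    if not junctions:   # defensive: a tree always has leaves
        junctions = [skel.root]
    visited_edges: set[tuple[int, int]] = set()
    frags: list[Fragment] = []
    for j in junctions:
        for nb in adj[j]:
            e = (min(j, nb), max(j, nb))
            if e in visited_edges:
                continue
            path = [j, nb]
            visited_edges.add(e)
            u, prev = nb, j
            while deg[u] == 2:
                nxt = adj[u][0] if adj[u][0] != prev else adj[u][1]
                visited_edges.add((min(u, nxt), max(u, nxt)))
                path.append(nxt)
                prev, u = u, nxt
            pts = np.stack([skel.position_of(x) for x in path])
            frags.append(Fragment.from_path(path, pts, connector_nodes))
    return frags


def select_fragments(frags: list[Fragment], p: BackboneParams = None,
                     report: list | None = None) -> list[Fragment]:
    """Apply the length / connector-density / relative-length rules.

    Rule (a): cable length > ``large_fragment_min_len``.
    Rule (b): length > ``small_fragment_min_len`` and connector count
    < ``connector_density_max`` x length (nm).  Rule-(b) survivors much
    shorter than the largest fragment (< largest / 2.5 under the default
    reading) are then dropped.
    """
    p = p or BackboneParams()
    if not frags:
        return []
    largest_len = max(f.cable_length for f in frags)
    kept: list[Fragment] = []
    for i, f in enumerate(frags):
        if f.cable_length > p.large_fragment_min_len:
            kept.append(f)
            if report is not None:
                report.append((i, f.cable_length, f.connector_count, True, "large"))
            continue
        ok = (f.cable_length > p.small_fragment_min_len
              and f.connector_count < p.connector_density_max * f.cable_length)
        if ok:
            if p.literal_relative_rule:
                ok = f.cable_length >= p.relative_length_factor * largest_len
            else:
                ok = f.cable_length >= largest_len / p.relative_length_factor
            rule = "small" if ok else "relative_length"
        else:
            rule = "small_reject"
        if report is not None:
            report.append((i, f.cable_length, f.connector_count, ok, rule))
        if ok:
            kept.append(f)
    return kept


def trim_distal_fragments(frags: list[Fragment], p: BackboneParams = None) -> list[Fragment]:
    """Drop fragments farther than ``distal_trim_distance`` from both
    endpoints of the largest fragment (minimum over the fragment's nodes)."""
    p = p or BackboneParams()
    if len(frags) <= 1:
        return list(frags)
    largest = max(frags, key=lambda f: f.cable_length)
    e1, e2 = largest.endpoints
    kept = []
    for f in frags:
        if f is largest:
            kept.append(f)
            continue
        d1 = np.linalg.norm(f.points - e1, axis=1).min()
        d2 = np.linalg.norm(f.points - e2, axis=1).min()
        if min(d1, d2) <= p.distal_trim_distance:
            kept.append(f)
    return kept


def extract_backbone(skel: SkeletonGraph, connector_xyz: np.ndarray = None,
                     p: BackboneParams = None) -> BackboneResult:
    """Full pipeline: prune twigs, fragment, select, trim distal fragments."""
    p = p or BackboneParams()
    if connector_xyz is None:
        connector_xyz = np.empty((0, 3))
    conn = map_connectors_to_nodes(skel, connector_xyz, p.connector_map_radius)
    cleaned = prune_twigs(skel, conn, p)
    frags = fragment_at_branchpoints(cleaned, conn)
    report: list = []
    selected = select_fragments(frags, p, report)
    trimmed = trim_distal_fragments(selected, p)
    node_ids = set()
    for f in trimmed:
        node_ids.update(int(n) for n in f.node_ids)
    warning = None
    if not trimmed:
        warning = f"{skel.neuron_id}: no fragment survived selection; empty backbone"
        warnings.warn(warning)
    return BackboneResult(trimmed, node_ids, warning, report)


def backbone_polylines(skel: SkeletonGraph, result: BackboneResult) -> list[np.ndarray]:
    """Order backbone fragments root-outward for soma-side traversal.

    Each fragment is oriented so its end closer (in hop depth) to the
    root comes first; fragments are sorted by that depth.  Used by portal
    crossing, which needs the polyline walked from the soma side.
    """
    depth = skel.depths()
    ordered = []
    for f in result.fragments:
        d0 = depth.get(int(f.node_ids[0]), 0)
        d1 = depth.get(int(f.node_ids[-1]), 0)
        pts = f.points if d0 <= d1 else f.points[::-1]
        ordered.append((min(d0, d1), pts))
    ordered.sort(key=lambda t: t[0])
    return [pts for _, pts in ordered]
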