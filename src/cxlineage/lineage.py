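"""Neuroblast-lineage assignment from tract geometry, and the
central-complex large-field catalog filter.

Each lineage's fiber bundle is described by a :class:`BundleAnnotation`:
an entry portal (the point and plane where the bundle enters the
neuropil from the cortical rind), seed fiber positions on that plane,
and a capture radius.  A neuron is assigned to the bundle whose seeds
are nearest to the point where its backbone first crosses the portal
plane (method PORTAL); neurons whose backbone crosses no portal are
assigned by closest approach of the backbone to the seed fibers
(method TRAJECTORY).  Ties break by soma-cluster distance, then
lexicographic lineage id.  The assignment score is exp(-d / capture_radius).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BundleAnnotation",
    "CxFilterParams",
    "portal_crossing",
    "assign_lineage",
    "assign_catalog",
    "filter_cx_largefield",
    "count_by_lineage_and_compartment",
    "split_by_crossing",
    "read_bundles",
    "write_bundles",
]

CATALOG_COLUMNS = ["neuron_id", "lineage", "hemilineage", "score", "method"]


@dataclass
class BundleAnnotation:
    lineage_id: str
    portal_point: np.ndarray          # nm, on the entry plane
    portal_normal: np.ndarray         # unit vector
    seed_fibers: np.ndarray           # (k, 3) points on the portal plane
    capture_radius: float             # nm
    soma_cluster_center: np.ndarray | None = None
    hemilineage_axis: np.ndarray | None = None  # dorsal direction for d/v labels

    def __post_init__(self):
        self.portal_point = np.asarray(self.portal_point, float)
        n = np.asarray(self.portal_normal, float)
        nn = np.linalg.norm(n)
        if not math.isclose(nn, 1.0, rel_tol=1e-6):
            n = n / nn
        self.portal_normal = n
        self.seed_fibers = np.asarray(self.seed_fibers, float).reshape(-1, 3)
        if self.capture_radius <= 0:
            raise ValueError("capture_radius must be > 0")
        off = np.abs((self.seed_fibers - self.portal_point) @ self.portal_normal)
        if off.size and off.max() > 1.0:
            raise ValueError(
                f"{self.lineage_id}: seed fibers up to {off.max():.2f} nm off the portal plane"
            )
        if self.soma_cluster_center is not None:
            self.soma_cluster_center = np.asarray(self.soma_cluster_center, float)


@dataclass
class CxFilterParams:
    """Inclusion rules for the central-complex large-field catalog.

    A neuron is kept when it (1) has at least one connector in a CX
    region, (2) forms strictly more than ``min_cx_synapses`` T-bars plus
    PSDs there, and (3) makes at least one output connection onto a
    single partner stronger than ``min_single_connection`` synapses.
    """

    min_cx_synapses: int = 15
    min_single_connection: int = 5
    cx_regions: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.min_cx_synapses < 0 or self.min_single_connection < 0:
            raise ValueError("filter bounds must be >= 0")
        self.cx_regions = frozenset(self.cx_regions)


#: region-name prefixes that constitute the central complex
CX_PREFIXES = ("PB", "EB", "FB", "NO", "AB")


def cx_region_names(names) -> frozenset:
    """All region names that belong to a CX compartment, by prefix."""
    return frozenset(n for n in names if str(n).startswith(CX_PREFIXES))


def portal_crossing(polylines, portal_point, portal_normal) -> np.ndarray | None:
    """First intersection of an ordered polyline sequence with a plane.

    ``polylines`` is a list of (n, 3) arrays ordered (and oriented) from
    the soma side outward; the first segment whose endpoints straddle the
    plane yields the linearly interpolated crossing point.  Returns None
    if no segment crosses.
    """
    p0 = np.asarray(portal_point, float)
    n = np.asarray(portal_normal, float)
    n = n / np.linalg.norm(n)
    for pts in polylines:
        pts = np.asarray(pts, float)
        if len(pts) == 0:
            continue
        s = (pts - p0) @ n
        if len(pts) == 1:
            if s[0] == 0:
                return pts[0].copy()
            continue
        for i in range(len(pts) - 1):
            a, b = s[i], s[i + 1]
            if a == 0.0:
                return pts[i].copy()
            if a * b < 0.0:
                t = a / (a - b)
                return pts[i] + t * (pts[i + 1] - pts[i])
        if s[-1] == 0.0:
            return pts[-1].copy()
    return None


def assign_lineage(neuron_id, polylines, soma_position,
                   bundles: list[BundleAnnotation]) -> dict:
    """One catalog row: best bundle by portal-crossing (or trajectory)
    distance, gated by the bundle's capture radius."""
    row, _ = _assign(neuron_id, polylines, soma_position, bundles)
    return row


def _assign(neuron_id, polylines, soma_position, bundles):
    if not bundles:
        raise ValueError("bundles must be non-empty")
    soma = np.asarray(soma_position, float)
    all_pts = ([np.concatenate([np.asarray(p, float).reshape(-1, 3) for p in polylines])]
               if polylines else [np.empty((0, 3))])[0]
    candidates = []  # (d, method, bundle)
    for b in bundles:
        crossing = portal_crossing(polylines, b.portal_point, b.portal_normal)
        if crossing is not None:
            d = float(np.linalg.norm(b.seed_fibers - crossing, axis=1).min())
            method = "PORTAL"
        elif len(all_pts):
            # closest approach of the whole backbone to the seed fibers
            d = float(min(np.linalg.norm(all_pts - s, axis=1).min()
                          for s in b.seed_fibers))
            method = "TRAJECTORY"
        else:
            continue
        if d <= b.capture_radius:
            candidates.append((d, method, b))
    if not candidates:
        return ({"neuron_id": neuron_id, "lineage": None, "hemilineage": None,
                 "score": 0.0, "method": "UNASSIGNED"}, None)

    def sort_key(cand):
        d, method, b = cand
        if b.soma_cluster_center is not None:
            soma_d = float(np.linalg.norm(soma - b.soma_cluster_center))
        else:
            soma_d = float("inf")
        return (round(d, 9), soma_d, b.lineage_id)

    d, method, best = min(candidates, key=sort_key)
    return ({
        "neuron_id": neuron_id,
        "lineage": best.lineage_id,
        "hemilineage": None,
        "score": math.exp(-d / best.capture_radius),
        "method": method,
    }, best)


def assign_catalog(backbones: dict, somas: dict, bundles: list[BundleAnnotation],
                   split_hemilineages: bool = True) -> pd.DataFrame:
    """Assign every neuron; optionally split each lineage into <= 2
    hemilineage groups by portal-crossing position (see
    :func:`split_by_crossing`)."""
    rows, crossings = [], {}
    by_bundle: dict[int, list] = {}
    bundle_info: dict[int, tuple] = {}
    for nid, polylines in backbones.items():
        row, bundle = _assign(nid, polylines, somas[nid], bundles)
        rows.append(row)
        if bundle is not None:
            c = portal_crossing(polylines, bundle.portal_point, bundle.portal_normal)
            if c is not None:
                crossings[nid] = c
                key = id(bundle)
                by_bundle.setdefault(key, []).append(nid)
                bundle_info[key] = (row["lineage"], bundle.hemilineage_axis)
    cat = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    if split_hemilineages:
        # split per annotated bundle (mirrored hemispheres keep their own
        # portal, so crossings are never pooled across the midline)
        hl = {}
        for key, nids in by_bundle.items():
            lin, axis = bundle_info[key]
            if axis is None:
                # no annotated dorsal axis: leave the lineage unsplit
                for n in nids:
                    hl[n] = lin
                continue
            pts = np.stack([crossings[n] for n in nids])
            labels = split_by_crossing(pts, axis=axis)
            for n, lab in zip(nids, labels):
                hl[n] = f"{lin}{lab}" if lab else lin
        cat["hemilineage"] = cat["neuron_id"].map(hl)
    return cat


def split_by_crossing(points: np.ndarray, labels=("d", "v"),
                      axis: np.ndarray | None = None,
                      min_gap: float = 0.0) -> list[str]:
    """Split crossing points into <= 2 groups along their widest direction.

    Points are projected onto ``axis`` (or the first principal component
    when absent) and cut at the largest inter-point gap; the group with
    the higher mean projection onto the dorsal axis gets ``labels[0]``.
    A single point, or a spread not exceeding ``min_gap``, yields one
    group labelled ``labels[0]``.
    """
    pts = np.asarray(points, float).reshape(-1, 3)
    n = len(pts)
    if n == 0:
        return []
    if n == 1:
        return [labels[0]]
    if axis is not None:
        direction = np.asarray(axis, float)
        direction = direction / np.linalg.norm(direction)
    else:
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        direction = vt[0]
    proj = pts @ direction
    order = np.argsort(proj, kind="stable")
    gaps = np.diff(proj[order])
    if len(gaps) == 0 or gaps.max() <= min_gap:
        return [labels[0]] * n
    cut = int(np.argmax(gaps))
    group = np.empty(n, dtype=int)
    group[order[: cut + 1]] = 0
    group[order[cut + 1:]] = 1
    # higher projection -> first label (dorsal by convention)
    mean0 = proj[group == 0].mean()
    mean1 = proj[group == 1].mean()
    hi = 0 if mean0 >= mean1 else 1
    return [labels[0] if g == hi else labels[1] for g in group]


def filter_cx_largefield(connectors: pd.DataFrame, catalog: pd.DataFrame,
                         p: CxFilterParams) -> pd.DataFrame:
    """Keep catalog neurons passing the three CX large-field rules.

    CX involvement of neuron n counts every connector row with n
    presynaptic plus every row with n postsynaptic in a CX region
    (weights summed: aggregated rows count fully).  Output-connection
    strength is the summed weight per ordered (pre, post) pair over the
    whole table.
    """
    cx = connectors[connectors["compartment"].isin(p.cx_regions)]
    pre_w = cx.groupby("pre_neuron")["weight"].sum()
    post_w = cx.groupby("post_neuron")["weight"].sum()
    cx_total = pre_w.add(post_w, fill_value=0)
    pair = connectors.groupby(["pre_neuron", "post_neuron"])["weight"].sum()
    max_out = pair.groupby(level=0).max()

    def keep(nid):
        total = cx_total.get(nid, 0)
        if total <= 0:
            return False
        if total <= p.min_cx_synapses:
            return False
        return max_out.get(nid, 0) > p.min_single_connection

    return catalog[catalog["neuron_id"].map(keep)].reset_index(drop=True)


def count_by_lineage_and_compartment(catalog: pd.DataFrame,
                                     connectors: pd.DataFrame) -> pd.DataFrame:
    """Lineage x compartment table of contributing neuron counts.

    A neuron counts in every compartment where it has at least one
    connector (pre- or postsynaptic); both hemispheres are summed.
    """
    lin = catalog.set_index("neuron_id")["lineage"]
    pre = connectors[["pre_neuron", "compartment"]].rename(columns={"pre_neuron": "neuron_id"})
    post = connectors[["post_neuron", "compartment"]].rename(columns={"post_neuron": "neuron_id"})
    both = pd.concat([pre, post]).drop_duplicates()
    both = both[both["neuron_id"].isin(lin.index)]
    both["lineage"] = both["neuron_id"].map(lin)
    tab = (both.groupby(["lineage", "compartment"])["neuron_id"]
           .nunique().unstack(fill_value=0))
    return tab


def write_bundles(bundles: list[BundleAnnotation], path) -> None:
    doc = []
    for b in bundles:
        d = {
            "lineage_id": b.lineage_id,
            "portal": {"point": list(b.portal_point), "normal": list(b.portal_normal)},
            "seeds": [list(s) for s in b.seed_fibers],
            "capture_radius_nm": b.capture_radius,
        }
        if b.soma_cluster_center is not None:
            d["soma_center"] = list(b.soma_cluster_center)
        if b.hemilineage_axis is not None:
            d["hemilineage_axis"] = list(b.hemilineage_axis)
        doc.append(d)
    Path(path).write_text(json.dumps(doc, indent=1))


def read_bundles(path) -> list[BundleAnnotation]:
    doc = json.loads(Path(path).read_text())
    out = []
    for d in doc:
        out.append(BundleAnnotation(
            d["lineage_id"],
            d["portal"]["point"],
            d["portal"]["normal"],
            d["seeds"],
            d["capture_radius_nm"],
            d.get("soma_center"),
            np.asarray(d["hemilineage_axis"], float) if "hemilineage_axis" in d else None,
        ))
    return out
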