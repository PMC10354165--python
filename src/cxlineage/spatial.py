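"""Geometric summaries: toroidal (ring) projection, density profiles,
domain occupancy, and the input-domain / output-layer topography statistic.

The ellipsoid body is a torus; collapsing synapse positions over the
ring azimuth yields the standard circular-projection view: each point is
mapped to ``(u, v)`` where ``v`` is the signed offset along the ring
axis and ``u`` the radial offset from the ring circle, so a cross
section of the tube becomes a disc and annular domains become ``u``/``v``
bands.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .compartments import CompartmentModel

__all__ = [
    "TorusAxisModel",
    "fit_torus_axis",
    "circular_project",
    "density_profile",
    "domain_occupancy",
    "topography_correlation",
]


class TorusAxisModel:
    """Ring symmetry axis of a toroidal neuropil (axis unit, radius > 0)."""

    def __init__(self, center, axis, ring_radius: float):
        self.center = np.asarray(center, float)
        axis = np.asarray(axis, float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("axis must be non-zero")
        self.axis = axis / n
        if ring_radius <= 0:
            raise ValueError("ring_radius must be > 0")
        self.ring_radius = float(ring_radius)


def fit_torus_axis(points, anterior_axis=(0.0, 1.0, 0.0)) -> TorusAxisModel:
    """Fit center/axis/ring radius to a toroidal point cloud.

    Center is the centroid; the axis is the direction of least variance
    (a filled ring is flat along its symmetry axis); the ring radius is
    the mean distance of the points from the axis line.  The axis sign
    is fixed toward ``anterior_axis`` so the fit is fully deterministic.
    """
    p = np.asarray(points, float).reshape(-1, 3)
    if len(p) < 10:
        raise ValueError("need at least 10 points to fit a torus axis")
    center = p.mean(axis=0)
    d = p - center
    cov = d.T @ d / len(p)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-9 * max(evals[2], 1e-30):
        raise ValueError("degenerate (collinear) point cloud")
    axis = evecs[:, 0]
    ref = np.asarray(anterior_axis, float)
    dot = float(axis @ ref)
    if dot < 0 or (dot == 0 and axis[np.nonzero(axis)[0][0]] < 0):
        axis = -axis
    v = d @ axis
    radial = d - np.outer(v, axis)
    ring_radius = float(np.linalg.norm(radial, axis=1).mean())
    return TorusAxisModel(center, axis, ring_radius)


def circular_project(points, model: TorusAxisModel, weights=None) -> pd.DataFrame:
    """Collapse 3-D points over the ring azimuth onto the (u, v) plane.

    ``v`` = signed offset along the ring axis from the center, ``u`` =
    distance to the axis minus the ring radius.  Point count and total
    weight are conserved exactly; azimuth is discarded.
    """
    p = np.asarray(points, float).reshape(-1, 3)
    w = np.ones(len(p)) if weights is None else np.asarray(weights, float)
    if len(w) != len(p):
        raise ValueError("weights length mismatch")
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    d = p - model.center
    v = d @ model.axis
    radial = d - np.outer(v, model.axis)
    u = np.linalg.norm(radial, axis=1) - model.ring_radius
    return pd.DataFrame({"u": u, "v": v, "weight": w})


def density_profile(projected: pd.DataFrame, axis: str = "u",
                    bins=20, range=None) -> tuple[np.ndarray, np.ndarray]:
    """Weighted histogram along ``u`` or ``v``; bin mass sums to total weight."""
    if axis not in ("u", "v"):
        raise ValueError("axis must be 'u' or 'v'")
    x = projected[axis].to_numpy()
    w = projected["weight"].to_numpy()
    if len(x) == 0:
        edges = np.linspace(0, 1, (bins if np.isscalar(bins) else len(bins)) + 1) \
            if range is None else np.linspace(range[0], range[1], bins + 1)
        return np.zeros(len(edges) - 1), edges
    counts, edges = np.histogram(x, bins=bins, range=range, weights=w)
    return counts, edges


def domain_occupancy(connectors: pd.DataFrame, model: CompartmentModel,
                     grouping, kinds=("TBAR",), side: str = "pre",
                     domains=None) -> pd.DataFrame:
    """Group x domain synapse counts from connector positions.

    Rows of the requested ``kinds`` whose ``side`` neuron is covered by
    ``grouping`` are assigned to domains by point membership in the
    compartment model; column sums are conserved against the total and
    invariant to refining the grouping.
    """
    col = "pre_neuron" if side == "pre" else "post_neuron"
    df = connectors[connectors["kind"].isin(set(kinds))
                    & connectors[col].isin(set(grouping))]
    if df.empty:
        cols = domains if domains is not None else model.region_names()
        return pd.DataFrame(0, index=sorted(set(grouping.values())), columns=cols)
    labels = model.regions_of(df[["x", "y", "z"]].to_numpy())
    g = df[col].map(grouping)
    tab = (pd.DataFrame({"g": g.to_numpy(), "dom": labels, "w": df["weight"].to_numpy()})
           .pivot_table(index="g", columns="dom", values="w", aggfunc="sum", fill_value=0))
    if domains is not None:
        tab = tab.reindex(columns=list(domains), fill_value=0)
    tab = tab.reindex(index=sorted(set(grouping.values())), fill_value=0)
    tab.index.name, tab.columns.name = "group", "domain"
    return tab.astype(np.int64)


def topography_correlation(connectors: pd.DataFrame, lineage_of,
                           layer_regions, axis, exclude_regions,
                           min_neurons: int = 3) -> pd.DataFrame:
    """Spearman correlation between dendrite position and output layer.

    For each neuron covered by ``lineage_of``: the dendritic centroid is
    the weighted mean position of its postsynaptic (PSD-side) connectors
    outside ``exclude_regions``, projected onto the anatomical ``axis``
    unit vector; the output layer is the index (0-based position in
    ``layer_regions``) holding the plurality of its presynaptic
    connectors, ties to the lower index.  Returns one row per lineage
    (rho, n; NA when fewer than ``min_neurons`` neurons qualify) plus a
    pooled row labelled ``"__all__"``.
    """
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    layer_index = {r: i for i, r in enumerate(layer_regions)}

    dend = connectors[connectors["post_neuron"].isin(set(lineage_of))
                      & ~connectors["compartment"].isin(set(exclude_regions))]
    out = connectors[connectors["pre_neuron"].isin(set(lineage_of))
                     & connectors["compartment"].isin(layer_index)]

    coords, layers, lineages = [], [], []
    out_by_neuron = out.groupby("pre_neuron")
    layer_sum = {n: g.groupby("compartment")["weight"].sum()
                 for n, g in out_by_neuron}
    for nid, g in dend.groupby("post_neuron"):
        if nid not in layer_sum:
            continue
        w = g["weight"].to_numpy().astype(float)
        centroid = (g[["x", "y", "z"]].to_numpy() * w[:, None]).sum(axis=0) / w.sum()
        ls = layer_sum[nid]
        best = min((r for r in ls.index if ls[r] == ls.max()),
                   key=lambda r: layer_index[r])
        coords.append(float(centroid @ axis))
        layers.append(layer_index[best])
        lineages.append(lineage_of[nid])

    df = pd.DataFrame({"lineage": lineages, "coord": coords, "layer": layers})
    rows = []
    for lin, g in df.groupby("lineage"):
        if len(g) < min_neurons:
            rows.append({"lineage": lin, "rho": np.nan, "n": len(g)})
        else:
            rho = spearmanr(g["coord"], g["layer"]).statistic
            rows.append({"lineage": lin, "rho": float(rho), "n": len(g)})
    if len(df) >= min_neurons:
        rho = spearmanr(df["coord"], df["layer"]).statistic
        rows.append({"lineage": "__all__", "rho": float(rho), "n": len(df)})
    else:
        rows.append({"lineage": "__all__", "rho": np.nan, "n": len(df)})
    return pd.DataFrame(rows)
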