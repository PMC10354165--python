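"""Readers and writers for the pipeline's standard inputs.

Skeletons come as SWC files (one neuron per file), synapses as CSV
connector tables (one row per synaptic contact), compartments and bundle
annotations as JSON.  All coordinates are nanometres internally; the SWC
reader accepts a units declaration (``nm``/``um``) or an explicit voxel
size so that 8 nm-voxel connectome exports can be ingested directly.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SkeletonGraph",
    "SwcParseError",
    "read_swc",
    "write_swc",
    "read_synapse_table",
    "write_synapse_table",
    "validate_connector_table",
    "read_neuron_records",
    "CONNECTOR_COLUMNS",
]

#: canonical connector-table columns, in emitted order
CONNECTOR_COLUMNS = [
    "synapse_id",
    "pre_neuron",
    "post_neuron",
    "kind",
    "x",
    "y",
    "z",
    "compartment",
    "weight",
]

CONNECTOR_KINDS = frozenset({"TBAR", "PSD"})


class SwcParseError(ValueError):
    """Structural error in an SWC file (dangling parent, cycle, bad root)."""


@dataclass
class SkeletonGraph:
    """Rooted tree of 3-D skeleton nodes for one neuron (coordinates in nm).

    ``parent_ids`` uses ``-1`` for the root.  Exactly one root must exist,
    every parent reference must resolve, and the parent relation must be
    acyclic; :meth:`validate` enforces this.
    """

    neuron_id: object
    node_ids: np.ndarray          # (n,) int64
    parent_ids: np.ndarray        # (n,) int64, -1 at the root
    xyz: np.ndarray               # (n, 3) float64, nm
    radius: np.ndarray            # (n,) float64, nm
    soma_node: int | None = None

    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.parent_ids = np.asarray(self.parent_ids, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=np.float64).reshape(-1, 3)
        self.radius = np.asarray(self.radius, dtype=np.float64)
        self._index = {int(nid): i for i, nid in enumerate(self.node_ids)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, node_id: int) -> int:
        return self._index[int(node_id)]

    def position_of(self, node_id: int) -> np.ndarray:
        return self.xyz[self.index_of(node_id)]

    @property
    def root(self) -> int:
        (ri,) = np.nonzero(self.parent_ids == -1)
        return int(self.node_ids[ri[0]])

    def soma_position(self) -> np.ndarray:
        nid = self.soma_node if self.soma_node is not None else self.root
        return self.position_of(nid)

    def children_map(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {int(n): [] for n in self.node_ids}
        for nid, pid in zip(self.node_ids, self.parent_ids):
            if pid != -1:
                ch[int(pid)].append(int(nid))
        return ch

    def degrees(self) -> dict[int, int]:
        """Undirected degree per node id."""
        deg = {int(n): 0 for n in self.node_ids}
        for nid, pid in zip(self.node_ids, self.parent_ids):
            if pid != -1:
                deg[int(nid)] += 1
                deg[int(pid)] += 1
        return deg

    def depths(self) -> dict[int, int]:
        """Hop distance from the root per node id."""
        ch = self.children_map()
        depth = {self.root: 0}
        stack = [self.root]
        while stack:
            u = stack.pop()
            for v in ch[u]:
                depth[v] = depth[u] + 1
                stack.append(v)
        return depth

    def subgraph(self, keep_ids) -> "SkeletonGraph":
        """Restrict to ``keep_ids``; nodes whose parent is dropped become roots
        only if they are the original root's surviving ancestor chain — callers
        must pass connected node sets containing the root-side attachment."""
        keep = set(int(k) for k in keep_ids)
        mask = np.array([int(n) in keep for n in self.node_ids])
        new_parents = self.parent_ids[mask].copy()
        for i, pid in enumerate(new_parents):
            if pid != -1 and int(pid) not in keep:
                new_parents[i] = -1
        soma = self.soma_node if (self.soma_node in keep) else None
        return SkeletonGraph(
            self.neuron_id,
            self.node_ids[mask],
            new_parents,
            self.xyz[mask],
            self.radius[mask],
            soma_node=soma,
        )

    def validate(self) -> "SkeletonGraph":
        if self.n_nodes == 0:
            return self
        if len(set(self._index)) != self.n_nodes:
            raise SwcParseError(f"{self.neuron_id}: duplicate node ids")
        roots = np.nonzero(self.parent_ids == -1)[0]
        if len(roots) == 0:
            raise SwcParseError(f"{self.neuron_id}: no root node")
        if len(roots) > 1:
            ids = ", ".join(str(int(self.node_ids[i])) for i in roots)
            raise SwcParseError(f"{self.neuron_id}: multiple roots ({ids})")
        for nid, pid in zip(self.node_ids, self.parent_ids):
            if pid != -1 and int(pid) not in self._index:
                raise SwcParseError(
                    f"{self.neuron_id}: dangling parent {int(pid)} of node {int(nid)}"
                )
        # acyclicity: walk to root from every node with memoisation
        ok: dict[int, bool] = {}
        for nid in self.node_ids:
            seen = []
            u = int(nid)
            while u != -1 and u not in ok:
                seen.append(u)
                u = int(self.parent_ids[self._index[u]])
                if u in seen:
                    raise SwcParseError(f"{self.neuron_id}: cycle at node {u}")
            for s in seen:
                ok[s] = True
        if not np.all(np.isfinite(self.xyz)):
            raise SwcParseError(f"{self.neuron_id}: non-finite coordinates")
        if np.any(self.radius < 0):
            raise SwcParseError(f"{self.neuron_id}: negative radius")
        return self

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "parent_id": self.parent_ids,
                "x": self.xyz[:, 0],
                "y": self.xyz[:, 1],
                "z": self.xyz[:, 2],
                "radius": self.radius,
            }
        )


_UNIT_SCALE = {"nm": 1.0, "um": 1000.0, "µm": 1000.0, "micron": 1000.0}


def read_swc(path, *, units: str = "nm", voxel_size: float | None = None,
             neuron_id=None) -> SkeletonGraph:
    """Read one SWC file into a validated :class:`SkeletonGraph` in nm.

    Parameters
    ----------
    units
        ``"nm"`` or ``"um"``; µm coordinates are scaled by 1000.
    voxel_size
        If given, coordinates are voxel indices and are multiplied by this
        many nm per voxel (connectome exports commonly use 8 nm voxels).
        Overrides ``units``.
    """
    path = Path(path)
    if voxel_size is not None:
        scale = float(voxel_size)
    else:
        try:
            scale = _UNIT_SCALE[units.lower()]
        except KeyError:
            raise ValueError(f"unknown SWC units {units!r}") from None
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SwcParseError(f"{path.name}:{lineno}: expected 7 columns, got {len(parts)}")
        rows.append(parts)
    if not rows:
        return SkeletonGraph(neuron_id or path.stem, [], [], np.empty((0, 3)), [])
    arr = np.asarray(rows)
    node_ids = arr[:, 0].astype(np.int64)
    ntype = arr[:, 1].astype(np.int64)
    xyz = arr[:, 2:5].astype(np.float64) * scale
    radius = arr[:, 5].astype(np.float64) * scale
    parent_ids = arr[:, 6].astype(np.int64)
    soma_rows = np.nonzero(ntype == 1)[0]
    soma = int(node_ids[soma_rows[0]]) if len(soma_rows) else None
    skel = SkeletonGraph(neuron_id or path.stem, node_ids, parent_ids, xyz,
                         radius, soma_node=soma)
    return skel.validate()


def write_swc(skel: SkeletonGraph, path) -> None:
    """Write a skeleton as SWC (nm coordinates; soma node gets type 1)."""
    buf = _io.StringIO()
    buf.write("# id type x y z radius parent\n")
    for i in range(skel.n_nodes):
        nid = int(skel.node_ids[i])
        ntype = 1 if nid == skel.soma_node else 0
        x, y, z = skel.xyz[i]
        buf.write(
            f"{nid} {ntype} {x:.6f} {y:.6f} {z:.6f} {skel.radius[i]:.6f} "
            f"{int(skel.parent_ids[i])}\n"
        )
    Path(path).write_text(buf.getvalue())


def validate_connector_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a connector table in place.

    Enforces kind in {TBAR, PSD} and integer weights >= 1; adds an
    ``autapse`` flag column for pre == post rows; preserves unknown
    compartment names verbatim.
    """
    missing = [c for c in CONNECTOR_COLUMNS if c not in df.columns and c != "weight"]
    if missing:
        raise ValueError(f"connector table missing columns: {missing}")
    df = df.copy()
    bad_kind = ~df["kind"].isin(CONNECTOR_KINDS)
    if bad_kind.any():
        bad = sorted(df.loc[bad_kind, "kind"].unique())
        raise ValueError(f"connector kind must be TBAR or PSD, got {bad}")
    if "weight" not in df.columns:
        df["weight"] = 1
    w = df["weight"]
    if not np.allclose(w, np.round(w)):
        raise ValueError("connector weight must be integer")
    df["weight"] = w.astype(np.int64)
    if (df["weight"] < 1).any():
        raise ValueError("connector weight must be >= 1")
    if "compartment" not in df.columns:
        df["compartment"] = None
    df["autapse"] = df["pre_neuron"] == df["post_neuron"]
    for c in ("x", "y", "z"):
        df[c] = df[c].astype(np.float64)
    return df


def read_synapse_table(path, *, column_map: dict | None = None) -> pd.DataFrame:
    """Read a synapse CSV into a validated connector table.

    ``column_map`` maps file column names onto the canonical names in
    :data:`CONNECTOR_COLUMNS` for exports with differing headers.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return validate_connector_table(df)


def write_synapse_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in CONNECTOR_COLUMNS if c in df.columns]
    df.to_csv(path, columns=cols, index=False)


def read_neuron_records(path) -> pd.DataFrame:
    """Read a neuron catalog CSV (neuron_id, type_label, hemisphere, ...)."""
    df = pd.read_csv(path)
    if "neuron_id" not in df.columns:
        raise ValueError("neuron record table requires a neuron_id column")
    if df["neuron_id"].duplicated().any():
        dup = df.loc[df["neuron_id"].duplicated(), "neuron_id"].iloc[0]
        raise ValueError(f"duplicate neuron_id {dup!r}")
    return df
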