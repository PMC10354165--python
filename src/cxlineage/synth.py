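"""Miniature connectome generator with planted ground truth.

Emulates the structure of an EM hemibrain-style dataset at desk scale:
nm-coordinate skeletons sampled every ``node_spacing`` (8 nm, so a
15-node twig is ~120 nm), neuroblast lineages whose 50–150 fibers run as
a tight noisy bundle from a cortical soma cluster through an annotated
entry portal into the neuropil, terminal arbors confined to analytic
compartment volumes (EB torus with five annular domains, nine fan-shaped
body layer slabs, bulb/noduli/bridge primitives), connector-free twig
artifacts along the tract, and block-structured source -> target synapse
tables with exact (deterministic) budgets.

Everything is reproducible from ``(config, seed)`` through a single
random stream, and the emitted ground truth (lineage labels, backbone
node sets, realized block counts, per-synapse domain labels) is what the
planted-truth tests compare against.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .compartments import CompartmentModel, Region, write_compartments
from .io import CONNECTOR_COLUMNS, SkeletonGraph, validate_connector_table, write_swc
from .lineage import BundleAnnotation, write_bundles

__all__ = [
    "TypeSpec",
    "LineageSpec",
    "BlockSpec",
    "SynthConfig",
    "GroundTruth",
    "SynthDataset",
    "default_compartment_model",
    "default_config",
    "generate_brain",
    "generate_avp_scenario",
    "generate_fb_scenario",
    "write_dataset",
    "connector_positions_for",
]


# --------------------------------------------------------------------------
# configuration dataclasses
# --------------------------------------------------------------------------

@dataclass
class TypeSpec:
    """One neuron type within a lineage."""

    type_label: str
    n_neurons: int | None = None          # None: share of the lineage fiber draw
    arbor_region: str | None = None       # compartment holding the terminal arbor
    out_layer_cycle: tuple = ()           # per-neuron output layer, cycled
    locus_region: str | None = None       # compartment holding the dendritic locus
    locus_layer_gradient: bool = False    # place locus along the layer gradient


@dataclass
class LineageSpec:
    lineage_id: str
    soma_center: tuple
    centerline: tuple                     # waypoints soma -> neuropil, nm
    types: tuple
    tract_noise_sd: float = 100.0         # nm, per-fiber lateral offset
    capture_radius: float = 800.0         # nm, bundle annotation
    portal_frac: float = 0.4              # fraction of arc length at neuropil entry
    fiber_range: tuple = (50, 150)        # fibers per tract when n_neurons is None
    n_twigs: int = 3
    twig_node_range: tuple = (3, 12)      # strictly below the 15-node threshold
    hemilineage_axis: tuple | None = None


@dataclass
class BlockSpec:
    """Planted connectivity block: ``n_synapses`` contacts src -> tgt in a region."""

    src_group: str
    tgt_group: str
    region: str                           # region name, or "__pre_layer__"
    n_synapses: int
    kind: str = "TBAR"
    placement: str = "uniform"            # uniform | target_locus | pre_layer
    locus_sd: float = 200.0               # nm, scatter around the dendritic locus
    partners_per_source: int | None = None  # concentrate each source on k targets


@dataclass
class SynthConfig:
    seed: int
    lineages: tuple
    compartments: CompartmentModel
    blocks: tuple = ()
    node_spacing: float = 8.0             # nm between skeleton nodes
    node_jitter_sd: float = 2.0           # nm, per-node roughness
    arbor_branches: int = 3
    arbor_nodes: int = 30
    arbor_step: float = 40.0              # nm, arbor walk step
    locus_axis: tuple = (0.0, -1.0, 0.0)  # posterior direction for layer gradients
    locus_step: float = 250.0             # nm between adjacent layer loci
    locus_jitter: float = 300.0           # nm, in-plane locus scatter
    mirror: bool = False
    poisson_budgets: bool = False         # Poisson(n) draws instead of exact budgets

    def __post_init__(self):
        for b in self.blocks:
            if b.n_synapses < 0:
                raise ValueError("synapse budgets must be >= 0")


@dataclass
class GroundTruth:
    lineage_of: dict
    type_of: dict
    backbone_nodes: dict                  # neuron -> frozenset of main-path node ids
    block_counts: pd.DataFrame            # planted vs realized per block
    composition: pd.DataFrame             # lineage x arbor compartment neuron counts


@dataclass
class SynthDataset:
    skeletons: dict
    connectors: pd.DataFrame
    compartments: CompartmentModel
    bundles: list
    neurons: pd.DataFrame
    truth: GroundTruth

    def group_members(self) -> dict:
        """Group label -> neuron ids, for type labels and lineage ids alike."""
        out: dict[str, list] = {}
        for _, row in self.neurons.iterrows():
            out.setdefault(row["type_label"], []).append(row["neuron_id"])
            out.setdefault(row["lineage"], []).append(row["neuron_id"])
        return out


# --------------------------------------------------------------------------
# default geometry (nm); a ~20 um miniature central brain
# --------------------------------------------------------------------------

EB_DOMAINS = ("EBa", "EBoc", "EBic", "EBip", "EBop")
FB_LAYERS = tuple(f"FB_l{k}" for k in range(1, 10))


def default_compartment_model() -> CompartmentModel:
    """EB torus with five annular domains, nine FB layer slabs, PB box,
    noduli, asymmetrical body, bulb partitions, LAL and SMP spheres."""
    regions: list[Region] = []
    eb_center, eb_axis, R, r = [0, 5000.0, 0], [0, 1.0, 0], 2500.0, 1000.0

    def torus(name, u_range=None, v_range=None):
        prm = {"center": eb_center, "axis": eb_axis, "ring_radius": R, "tube_radius": r}
        if u_range:
            prm["u_range"] = list(u_range)
        if v_range:
            prm["v_range"] = list(v_range)
        return Region(name, "torus_sector", prm)

    regions += [
        torus("EBa", v_range=(250, r)),
        torus("EBoc", u_range=(0, r), v_range=(-250, 250)),
        torus("EBic", u_range=(-r, 0), v_range=(-250, 250)),
        torus("EBip", u_range=(-r, 0), v_range=(-r, -250)),
        torus("EBop", u_range=(0, r), v_range=(-r, -250)),
    ]
    regions.append(Region("PB", "box", {"lo": [-7000, -10000, 2000],
                                        "hi": [7000, -8000, 4000]}))
    for name, y, rad in (("NO1", -2600.0, 600.0), ("NO2", -3200.0, 500.0),
                         ("NO3", -3800.0, 400.0)):
        for sx in (1.0, -1.0):
            regions.append(Region(name, "sphere",
                                  {"center": [sx * 1500.0, y, -5500.0], "radius": rad},
                                  hemisphere="RIGHT" if sx > 0 else "LEFT"))
    regions.append(Region("AB", "sphere", {"center": [400.0, -500.0, -4800.0],
                                           "radius": 500.0}))
    for name, c, rad in (("BUs", [6000.0, 4500.0, 1200.0], 900.0),
                         ("BUa", [6300.0, 5200.0, 1800.0], 700.0),
                         ("BUi", [6000.0, 4500.0, -2500.0], 900.0)):
        for sx in (1.0, -1.0):
            cc = [sx * c[0], c[1], c[2]]
            regions.append(Region(name, "sphere", {"center": cc, "radius": rad},
                                  hemisphere="RIGHT" if sx > 0 else "LEFT"))
    for name, c, rad in (("LAL", [7000.0, 2000.0, -2500.0], 1500.0),
                         ("SMP", [6000.0, -500.0, 4500.0], 2500.0)):
        for sx in (1.0, -1.0):
            cc = [sx * c[0], c[1], c[2]]
            regions.append(Region(name, "sphere", {"center": cc, "radius": rad},
                                  hemisphere="RIGHT" if sx > 0 else "LEFT"))
    # the broad FB layer slabs come last so the lateral territories keep
    # priority where the slabs' lateral extent brushes them
    for k in range(1, 10):
        z = -4000.0 + (k - 1) * 1000.0
        regions.append(Region(f"FB_l{k}", "slab", {
            "center": [0, -1000.0, z], "normal": [0, 0, 1.0],
            "half_thickness": 500.0, "lateral_radius": 6000.0}))
    return CompartmentModel(regions)


def _region_center(model: CompartmentModel, name: str, hemisphere="RIGHT") -> np.ndarray:
    for reg in model.regions:
        if reg.name == name and (reg.hemisphere in (None, hemisphere)):
            lo, hi = reg.bounds()
            return (lo + hi) / 2.0
    raise KeyError(name)


# --------------------------------------------------------------------------
# skeleton construction
# --------------------------------------------------------------------------

def _resample_polyline(waypoints: np.ndarray, spacing: float) -> np.ndarray:
    """Evenly spaced points along a polyline (includes both ends)."""
    wp = np.asarray(waypoints, float).reshape(-1, 3)
    seg = np.linalg.norm(np.diff(wp, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(np.floor(total / spacing)) + 1, 2)
    t = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for dim in range(3):
        out[:, dim] = np.interp(t, s, wp[:, dim])
    return out


def _perp_offset(direction: np.ndarray, rng, sd: float) -> np.ndarray:
    o = rng.normal(0.0, sd, size=3)
    d = direction / np.linalg.norm(direction)
    return o - (o @ d) * d


def _arbor_walk(start: np.ndarray, region_test, rng, n_nodes: int,
                step: float) -> np.ndarray:
    """Persistent random walk confined to a compartment primitive."""
    pts = [start]
    heading = rng.normal(size=3)
    heading /= np.linalg.norm(heading)
    for _ in range(n_nodes):
        for _try in range(12):
            prop = heading + 0.8 * rng.normal(size=3)
            prop /= np.linalg.norm(prop)
            cand = pts[-1] + step * prop
            if region_test(cand):
                pts.append(cand)
                heading = prop
                break
        else:
            pts.append(pts[-1])  # stuck at the wall; zero-length step
    return np.stack(pts)


def _build_neuron(nid, lin: LineageSpec, tspec: TypeSpec, cfg: SynthConfig,
                  model: CompartmentModel, rng, hemisphere: str,
                  arbor_region: str | None, portal_idx_holder: list):
    """One skeleton: soma -> noisy tract -> extension into the arbor
    compartment -> confined arbor, plus connector-free twigs pre-portal."""
    center = _resample_polyline(np.asarray(lin.centerline, float), cfg.node_spacing)
    direction = center[-1] - center[0]
    offset = _perp_offset(direction, rng, lin.tract_noise_sd)
    tract = center + offset
    tract += rng.normal(0.0, cfg.node_jitter_sd, size=tract.shape)
    portal_idx = int(lin.portal_frac * (len(tract) - 1))
    portal_idx_holder.append(portal_idx)

    main = tract
    if arbor_region is not None:
        anchor = model.sample_in_region(arbor_region, 1, rng)[0]
        ext = _resample_polyline(np.stack([tract[-1], anchor]), cfg.node_spacing)
        main = np.concatenate([tract, ext[1:]])

    pts = [main]
    parents = [np.concatenate([[-1], np.arange(len(main) - 1)])]
    n_so_far = len(main)

    regs = [r for r in model.regions if r.name == arbor_region] if arbor_region else []

    def in_region(p):
        return any(r.contains(p[None])[0] for r in regs)

    if arbor_region is not None:
        anchor_i = n_so_far - 1
        for _ in range(cfg.arbor_branches):
            walk = _arbor_walk(main[-1], in_region, rng, cfg.arbor_nodes, cfg.arbor_step)
            bp = np.concatenate([[anchor_i], np.arange(len(walk) - 2) + n_so_far])
            pts.append(walk[1:])
            parents.append(bp)
            n_so_far += len(walk) - 1

    # twig artifacts on the cortical (pre-portal) segment of the tract
    lo_t, hi_t = lin.twig_node_range
    for _ in range(lin.n_twigs):
        attach = int(rng.integers(5, max(portal_idx - 5, 6)))
        t_nodes = int(rng.integers(lo_t, hi_t + 1))
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        steps = np.arange(1, t_nodes + 1)[:, None] * (cfg.node_spacing * d)
        twig = main[attach] + steps + rng.normal(0, cfg.node_jitter_sd, (t_nodes, 3))
        bp = np.concatenate([[attach], np.arange(t_nodes - 1) + n_so_far])
        pts.append(twig)
        parents.append(bp)
        n_so_far += t_nodes

    xyz = np.concatenate(pts)
    parent_idx = np.concatenate(parents)
    node_ids = np.arange(1, len(xyz) + 1)
    parent_ids = np.where(parent_idx < 0, -1, parent_idx + 1)
    skel = SkeletonGraph(nid, node_ids, parent_ids, xyz,
                         np.full(len(xyz), 40.0), soma_node=1)
    main_ids = frozenset(range(1, len(main) + 1))
    return skel, main_ids, tract[portal_idx]


# --------------------------------------------------------------------------
# brain generation
# --------------------------------------------------------------------------

def _mirror_lineage(lin: LineageSpec) -> LineageSpec:
    flip = lambda p: (-p[0], p[1], p[2])
    return replace(
        lin,
        soma_center=flip(lin.soma_center),
        centerline=tuple(flip(p) for p in lin.centerline),
        hemilineage_axis=(flip(lin.hemilineage_axis)
                          if lin.hemilineage_axis is not None else None),
    )


def generate_brain(cfg: SynthConfig) -> SynthDataset:
    """Generate skeletons, connectors, bundle annotations and ground truth.

    Deterministic under ``(cfg, cfg.seed)``: one random stream, fixed
    iteration order.  Raises for a connectivity block whose source or
    target group is empty or whose region cannot be sampled.
    """
    rng = np.random.default_rng(cfg.seed)
    model = cfg.compartments
    lineage_instances: list[tuple[LineageSpec, str]] = []
    for lin in cfg.lineages:
        lineage_instances.append((lin, "RIGHT"))
        if cfg.mirror:
            lineage_instances.append((_mirror_lineage(lin), "LEFT"))

    skeletons: dict = {}
    neuron_rows = []
    backbone_nodes = {}
    bundles = []
    next_id = 1001
    for lin, hemi in lineage_instances:
        # fiber draw for types without an explicit size
        types = list(lin.types)
        n_open = [t for t in types if t.n_neurons is None]
        if n_open:
            total = int(rng.integers(lin.fiber_range[0], lin.fiber_range[1] + 1))
            share = total // len(n_open)
            counts = {id(t): share for t in n_open}
            counts[id(n_open[-1])] += total - share * len(n_open)
        crossings = []
        layer_counter: dict[str, int] = {}
        for tspec in types:
            n = tspec.n_neurons if tspec.n_neurons is not None else counts[id(tspec)]
            for i in range(n):
                nid = next_id
                next_id += 1
                out_layer = None
                if tspec.out_layer_cycle:
                    c = layer_counter.get(tspec.type_label, 0)
                    out_layer = tspec.out_layer_cycle[c % len(tspec.out_layer_cycle)]
                    layer_counter[tspec.type_label] = c + 1
                arbor = tspec.arbor_region or out_layer
                holder: list = []
                skel, main_ids, crossing = _build_neuron(
                    nid, lin, tspec, cfg, model, rng, hemi, arbor, holder)
                skeletons[nid] = skel
                backbone_nodes[nid] = main_ids
                crossings.append(crossing)
                locus = None
                if tspec.locus_region is not None:
                    base = _region_center(model, tspec.locus_region, hemi)
                    jit = rng.normal(0.0, cfg.locus_jitter, size=3)
                    ax = np.asarray(cfg.locus_axis, float)
                    ax = ax / np.linalg.norm(ax)
                    jit -= (jit @ ax) * ax      # keep the gradient axis noise-free
                    locus = base + jit
                    if tspec.locus_layer_gradient and out_layer is not None:
                        k = FB_LAYERS.index(out_layer) + 1
                        locus = locus + ax * ((k - 5) * cfg.locus_step)
                neuron_rows.append({
                    "neuron_id": nid,
                    "type_label": tspec.type_label,
                    "lineage": lin.lineage_id,
                    "hemisphere": hemi,
                    "soma_x": skel.xyz[0, 0], "soma_y": skel.xyz[0, 1],
                    "soma_z": skel.xyz[0, 2],
                    "out_layer": out_layer,
                    "locus_x": locus[0] if locus is not None else np.nan,
                    "locus_y": locus[1] if locus is not None else np.nan,
                    "locus_z": locus[2] if locus is not None else np.nan,
                })
        # bundle annotation from the true portal geometry
        center = _resample_polyline(np.asarray(lin.centerline, float), cfg.node_spacing)
        pi = int(lin.portal_frac * (len(center) - 1))
        tangent = center[min(pi + 1, len(center) - 1)] - center[pi - 1]
        tangent = tangent / np.linalg.norm(tangent)
        seed_pts = np.asarray(crossings)
        # project the realized crossings onto the portal plane as seed fibers
        rel = seed_pts - center[pi]
        seed_pts = seed_pts - np.outer(rel @ tangent, tangent)
        seeds = np.concatenate([center[pi][None], seed_pts[:8]])
        bundles.append(BundleAnnotation(
            lin.lineage_id, center[pi], tangent, seeds, lin.capture_radius,
            soma_cluster_center=np.asarray(lin.soma_center, float),
            hemilineage_axis=(np.asarray(lin.hemilineage_axis, float)
                              if lin.hemilineage_axis is not None else None)))

    neurons = pd.DataFrame(neuron_rows)
    members: dict[str, list] = {}
    for _, row in neurons.iterrows():
        members.setdefault(row["type_label"], []).append(row["neuron_id"])
        members.setdefault(row["lineage"], []).append(row["neuron_id"])
    loci = {row["neuron_id"]: np.array([row["locus_x"], row["locus_y"], row["locus_z"]])
            for _, row in neurons.iterrows()}
    out_layer_of = dict(zip(neurons["neuron_id"], neurons["out_layer"]))

    # ---- synapse realization -------------------------------------------
    syn_rows = []
    block_rows = []
    syn_id = 1
    for b in cfg.blocks:
        if b.src_group not in members or not members[b.src_group]:
            raise ValueError(f"block {b.src_group}->{b.tgt_group}: empty source group")
        if b.tgt_group not in members or not members[b.tgt_group]:
            raise ValueError(f"block {b.src_group}->{b.tgt_group}: empty target group")
        n = int(rng.poisson(b.n_synapses)) if cfg.poisson_budgets else b.n_synapses
        src = np.asarray(members[b.src_group])
        tgt = np.asarray(members[b.tgt_group])
        pre = src[rng.integers(0, len(src), n)]
        if b.partners_per_source is not None:
            # each source keeps a small partner set, giving the strong
            # single-partner connections real connectomes show
            k = min(b.partners_per_source, len(tgt))
            partner = {int(s): rng.choice(tgt, size=k, replace=False)
                       for s in src}
            post = np.array([partner[int(s)][rng.integers(0, k)] for s in pre])
        else:
            post = tgt[rng.integers(0, len(tgt), n)]
        if b.placement == "uniform":
            pos = model.sample_in_region(b.region, n, rng)
            comp = np.full(n, b.region, dtype=object)
        elif b.placement == "target_locus":
            pos = np.empty((n, 3))
            for t in np.unique(post):
                idx = np.nonzero(post == t)[0]
                locus = loci[int(t)]
                if np.any(np.isnan(locus)):
                    raise ValueError(
                        f"block {b.src_group}->{b.tgt_group}: target {t} has no locus")
                if b.locus_sd == 0:
                    if model.region_of(locus) != b.region:
                        raise RuntimeError(
                            f"locus of {t} lies outside region {b.region}")
                    pos[idx] = locus
                    continue
                need, got = len(idx), 0
                buf = np.empty((len(idx), 3))
                for _try in range(200):
                    m = max(2 * (need - got), 8)
                    cand = locus + rng.normal(0.0, b.locus_sd, size=(m, 3))
                    hit = cand[model.regions_of(cand) == b.region]
                    take = min(len(hit), need - got)
                    buf[got:got + take] = hit[:take]
                    got += take
                    if got >= need:
                        break
                else:
                    raise RuntimeError("locus sampling failed to land in region")
                pos[idx] = buf
            comp = np.full(n, b.region, dtype=object)
        elif b.placement == "pre_layer":
            comp = np.asarray([out_layer_of[p] for p in pre], dtype=object)
            pos = np.empty((n, 3))
            for layer in pd.unique(comp):
                idx = np.nonzero(comp == layer)[0]
                pos[idx] = model.sample_in_region(str(layer), len(idx), rng)
        else:
            raise ValueError(f"unknown placement {b.placement!r}")
        syn_rows.append(pd.DataFrame({
            "synapse_id": np.arange(syn_id, syn_id + n),
            "pre_neuron": pre.astype(np.int64),
            "post_neuron": post.astype(np.int64),
            "kind": b.kind,
            "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
            "compartment": comp,
            "weight": 1,
        }))
        syn_id += n
        block_rows.append({"src_group": b.src_group, "tgt_group": b.tgt_group,
                           "region": b.region, "planted": b.n_synapses,
                           "realized": n})

    if syn_rows:
        connectors = pd.concat(syn_rows, ignore_index=True)
    else:
        connectors = pd.DataFrame(columns=CONNECTOR_COLUMNS)
        connectors["kind"] = connectors["kind"].astype(object)
    connectors = validate_connector_table(connectors)

    composition = (neurons.groupby(["lineage", "type_label"])["neuron_id"]
                   .count().rename("n_neurons").reset_index())

    truth = GroundTruth(
        lineage_of=dict(zip(neurons["neuron_id"], neurons["lineage"])),
        type_of=dict(zip(neurons["neuron_id"], neurons["type_label"])),
        backbone_nodes=backbone_nodes,
        block_counts=pd.DataFrame(block_rows),
        composition=composition,
    )
    return SynthDataset(skeletons, connectors, model, bundles, neurons, truth)


# --------------------------------------------------------------------------
# canned configurations
# --------------------------------------------------------------------------

def default_config(seed: int, *, mirror: bool = False, n_per_lineage=None,
                   blocks=None) -> SynthConfig:
    """Three well-separated lineages feeding the EB, BU and FB.

    ``n_per_lineage`` fixes the fiber count (otherwise drawn per tract
    from the 50–150 range); separations between bundle portals are tens
    of times the 100 nm tract noise.
    """
    model = default_compartment_model()

    def lin(lid, soma, mid, end, types, **kw):
        return LineageSpec(lid, soma, (soma, mid, end), tuple(types), **kw)

    n = n_per_lineage
    lineages = (
        lin("DALv2", (9000, 9500, -500), (6000, 6500, -100), (3600, 5000, 0),
            [TypeSpec("ER_m", n, arbor_region="EBoc")]),
        lin("DALcl1d", (10000, 6000, 2600), (7800, 5300, 1800), (6200, 4700, 1300),
            [TypeSpec("TuBu_s", n, arbor_region="BUs")],
            hemilineage_axis=(0, 0, 1)),
        lin("CP2d", (3000, -9000, 4200), (2400, -6000, 3600), (500, -1000, 3000),
            [TypeSpec("FBt_CP2d", n, arbor_region="FB_l7")]),
    )
    if blocks is None:
        blocks = (
            BlockSpec("TuBu_s", "ER_m", "BUs", 6000, partners_per_source=3),
            BlockSpec("ER_m", "FBt_CP2d", "EBoc", 6000, partners_per_source=3),
            BlockSpec("FBt_CP2d", "ER_m", "FB_l7", 5000, partners_per_source=3),
        )
    return SynthConfig(seed=seed, lineages=lineages, compartments=model,
                       blocks=tuple(blocks), mirror=mirror)


def generate_avp_scenario(seed: int) -> SynthDataset:
    """Anterior-visual-pathway scenario with planted exclusivity.

    Two tuberculo-bulbar hemilineages target disjoint bulb partitions
    (DALcl1d -> BUa/BUs, DALcl2d -> BUi) and each ring-neuron subclass
    receives input from exactly one of them; ring-neuron outputs fill
    their planted EB annular domains.
    """
    model = default_compartment_model()
    lineages = (
        LineageSpec("DALcl1d", (10000, 6000, 2600),
                    ((10000, 6000, 2600), (7800, 5300, 1800), (6200, 4700, 1300)),
                    (TypeSpec("TuBu_s", 8, arbor_region="BUs"),
                     TypeSpec("TuBu_a", 4, arbor_region="BUa")),
                    hemilineage_axis=(0, 0, 1)),
        LineageSpec("DALcl2d", (10200, 7800, -2800),
                    ((10200, 7800, -2800), (7800, 5600, -2600), (6200, 4700, -2500)),
                    (TypeSpec("TuBu_i", 10, arbor_region="BUi"),)),
        LineageSpec("DALv2", (9000, 9500, -500),
                    ((9000, 9500, -500), (6000, 6500, -100), (3600, 5000, 0)),
                    (TypeSpec("ER_out1", 6, arbor_region="EBa"),
                     TypeSpec("ER_out2", 6, arbor_region="EBoc"),
                     TypeSpec("ER_in1", 6, arbor_region="EBic"),
                     TypeSpec("ER_in2", 4, arbor_region="EBip"))),
        LineageSpec("DM_epg", (2500, -9500, -3500),
                    ((2500, -9500, -3500), (1800, -5500, -1500), (800, 2500, 0)),
                    (TypeSpec("EPG", 10, arbor_region="EBic"),)),
    )
    blocks = (
        # exclusive TuBu -> ER channels in the bulb partitions
        BlockSpec("TuBu_s", "ER_out1", "BUs", 1500),
        BlockSpec("TuBu_s", "ER_out2", "BUs", 1200),
        BlockSpec("TuBu_a", "ER_out1", "BUa", 800),
        BlockSpec("TuBu_i", "ER_in1", "BUi", 1500),
        BlockSpec("TuBu_i", "ER_in2", "BUi", 900),
        # ring-neuron output in their planted annular domains
        BlockSpec("ER_out1", "EPG", "EBa", 1000),
        BlockSpec("ER_out2", "EPG", "EBoc", 1000),
        BlockSpec("ER_in1", "EPG", "EBic", 1000),
        BlockSpec("ER_in2", "EPG", "EBip", 600),
    )
    return generate_brain(SynthConfig(seed=seed, lineages=lineages,
                                      compartments=model, blocks=blocks))


#: planted lateral-input shares for the FB scenario (printed as 28.6%,
#: 23.2%, 22.3% for the three dominant lineages; remainder split below)
FB_INPUT_SHARES = {
    "DALcl2v": 0.286,
    "CP2d": 0.232,
    "BAmv1": 0.223,
    "DM6c": 0.140,
    "DPMpl2": 0.119,
}


def generate_fb_scenario(seed: int, total_lateral: int = 20000,
                         locus_sd: float = 200.0) -> SynthDataset:
    """Fan-shaped-body scenario: planted lateral-input fractions and a
    perfect dendrite-position / output-layer gradient.

    Five lineages of FB large-field neurons receive ``total_lateral``
    input synapses in the lateral SMP territory, allocated exactly by
    :data:`FB_INPUT_SHARES`; each neuron's dendritic locus sits along the
    posterior axis in proportion to its output layer, so the topography
    correlation is +1 by construction (``locus_sd=0`` gives the
    noiseless variant).
    """
    model = default_compartment_model()
    sizes = {"DALcl2v": 48, "CP2d": 44, "BAmv1": 40, "DM6c": 24, "DPMpl2": 20}
    somas = {
        "DALcl2v": ((9000, 4000, -3500), (7500, 2500, -2500), (4500, -800, -2000)),
        "CP2d": ((3000, -9000, 4200), (2400, -6000, 3600), (500, -1000, 3000)),
        "BAmv1": ((8000, 7000, -4200), (6800, 4500, -3200), (3200, -800, -3400)),
        "DM6c": ((4200, -10000, -3200), (3600, -7600, -2200), (1200, -1200, -800)),
        "DPMpl2": ((6500, -9500, 2500), (5200, -6800, 2100), (2200, -1200, 1400)),
    }
    layer_cycles = {
        "DALcl2v": FB_LAYERS,
        "CP2d": ("FB_l4", "FB_l5", "FB_l6", "FB_l7", "FB_l1", "FB_l2", "FB_l8"),
        "BAmv1": ("FB_l1", "FB_l2", "FB_l3", "FB_l8", "FB_l9"),
        "DM6c": ("FB_l2", "FB_l4", "FB_l6"),
        "DPMpl2": ("FB_l3", "FB_l5", "FB_l7"),
    }
    lineages = []
    for lid, n in sizes.items():
        lineages.append(LineageSpec(
            lid, somas[lid][0], somas[lid], (
                TypeSpec(f"FBt_{lid}", n, out_layer_cycle=layer_cycles[lid],
                         locus_region="SMP", locus_layer_gradient=True),)))
    lineages.append(LineageSpec(
        "LNlat", (9500, -2000, 5200), ((9500, -2000, 5200), (8000, -1200, 4800),
                                       (6500, -600, 4500)),
        (TypeSpec("LN_in", 30, arbor_region="SMP"),)))
    lineages.append(LineageSpec(
        "DM_col", (2500, -9500, -3500), ((2500, -9500, -3500), (1800, -5500, -1000),
                                         (700, -1000, 0)),
        (TypeSpec("FB_col", 12, arbor_region="FB_l5"),)))

    # exact multinomial allocation of the lateral-input budget
    alloc = {lid: int(round(share * total_lateral))
             for lid, share in FB_INPUT_SHARES.items()}
    drift = total_lateral - sum(alloc.values())
    alloc["DALcl2v"] += drift
    blocks = [BlockSpec("LN_in", f"FBt_{lid}", "SMP", alloc[lid], kind="PSD",
                        placement="target_locus", locus_sd=locus_sd)
              for lid in sizes]
    # FB output synapses of every large-field neuron in its planted layer
    blocks += [BlockSpec(f"FBt_{lid}", "FB_col", "__pre_layer__", 30 * sizes[lid],
                         placement="pre_layer") for lid in sizes]
    return generate_brain(SynthConfig(seed=seed, lineages=tuple(lineages),
                                      compartments=model, blocks=tuple(blocks)))


# --------------------------------------------------------------------------
# emission & helpers
# --------------------------------------------------------------------------

def write_dataset(ds: SynthDataset, out_dir) -> dict:
    """Write the dataset as plain-text files; returns SHA-256 per file."""
    out = Path(out_dir)
    (out / "swc").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    for nid in sorted(ds.skeletons):
        write_swc(ds.skeletons[nid], out / "swc" / f"{nid}.swc")
    ds.connectors.to_csv(out / "synapses.csv", index=False,
                         columns=CONNECTOR_COLUMNS)
    write_compartments(ds.compartments, out / "compartments.json")
    write_bundles(ds.bundles, out / "bundles.json")
    ds.neurons.to_csv(out / "neurons.csv", index=False)
    rows = [(nid, node) for nid in sorted(ds.truth.backbone_nodes)
            for node in sorted(ds.truth.backbone_nodes[nid])]
    pd.DataFrame(rows, columns=["neuron_id", "node_id"]).to_csv(
        out / "truth" / "backbone_nodes.csv", index=False)
    ds.truth.block_counts.to_csv(out / "truth" / "block_counts.csv", index=False)
    pd.DataFrame({"neuron_id": list(ds.truth.lineage_of),
                  "lineage": list(ds.truth.lineage_of.values())}).to_csv(
        out / "truth" / "lineages.csv", index=False)
    hashes = {}
    for f in sorted(out.rglob("*")):
        if f.is_file():
            hashes[str(f.relative_to(out))] = hashlib.sha256(f.read_bytes()).hexdigest()
    return hashes


def connector_positions_for(connectors: pd.DataFrame, neuron_id) -> np.ndarray:
    """Positions of all connectors in which a neuron takes part."""
    m = (connectors["pre_neuron"] == neuron_id) | (connectors["post_neuron"] == neuron_id)
    return connectors.loc[m, ["x", "y", "z"]].to_numpy()
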