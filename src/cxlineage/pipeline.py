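"""End-to-end orchestration: dataset directory -> report tables.

Stages: read inputs, extract tract backbones, assign lineages, apply the
CX large-field filter, then emit connectivity and spatial summary tables
plus a manifest with parameter values and input hashes.  A stage failure
halts the run with the stage name and removes partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .backbone import BackboneParams, backbone_polylines, extract_backbone
from .compartments import read_compartments
from .connectivity import build_connection_matrix, input_fraction_by_group, \
    normalize_to_max, pairwise_strength_ecdf
from .io import read_swc, read_synapse_table
from .lineage import CxFilterParams, assign_catalog, count_by_lineage_and_compartment, \
    cx_region_names, filter_cx_largefield, read_bundles
from .synth import connector_positions_for

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline",
           "load_pipeline_config", "hemibrain_export_adapter", "load_dataset"]

_KNOWN_KEYS = {
    "data_dir", "out_dir", "backbone", "cx_filter", "grouping", "seed",
    "anatomical_axes", "swc_units", "swc_voxel_size",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    data_dir: str
    out_dir: str
    backbone: BackboneParams = field(default_factory=BackboneParams)
    cx_filter: CxFilterParams = field(default_factory=CxFilterParams)
    grouping: str = "lineage"             # lineage | type_label
    seed: int = 0
    anatomical_axes: dict = field(default_factory=lambda: {
        "anterior": [0.0, 1.0, 0.0], "dorsal": [0.0, 0.0, 1.0]})
    swc_units: str = "nm"
    swc_voxel_size: float | None = None


def load_pipeline_config(path) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys are rejected."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(doc) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kw = dict(doc)
    if "backbone" in kw:
        kw["backbone"] = BackboneParams(**kw["backbone"])
    if "cx_filter" in kw:
        kw["cx_filter"] = CxFilterParams(**kw["cx_filter"])
    return PipelineConfig(**kw)


def load_dataset(data_dir, *, swc_units="nm", swc_voxel_size=None):
    """Read a dataset directory (swc/, synapses.csv, compartments.json,
    bundles.json, optional neurons.csv)."""
    data_dir = Path(data_dir)
    skeletons = {}
    for f in sorted((data_dir / "swc").glob("*.swc")):
        skel = read_swc(f, units=swc_units, voxel_size=swc_voxel_size)
        try:
            nid = int(skel.neuron_id)
        except (TypeError, ValueError):
            nid = skel.neuron_id
        skel.neuron_id = nid
        skeletons[nid] = skel
    connectors = read_synapse_table(data_dir / "synapses.csv")
    model = read_compartments(data_dir / "compartments.json")
    bundles = read_bundles(data_dir / "bundles.json")
    neurons = None
    if (data_dir / "neurons.csv").exists():
        neurons = pd.read_csv(data_dir / "neurons.csv")
    return skeletons, connectors, model, bundles, neurons


def _hash_inputs(data_dir: Path) -> dict:
    hashes = {}
    for f in sorted(data_dir.rglob("*")):
        if f.is_file() and not f.name.startswith("."):
            hashes[str(f.relative_to(data_dir))] = hashlib.sha256(
                f.read_bytes()).hexdigest()
    return hashes


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages and write the report bundle under ``cfg.out_dir``.

    Returns a report dict with the main tables; all numbers in it are
    also written as CSV so each is reproducible from emitted files.
    """
    out = Path(cfg.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    stage = "read_inputs"
    try:
        skeletons, connectors, model, bundles, neurons = load_dataset(
            cfg.data_dir, swc_units=cfg.swc_units, swc_voxel_size=cfg.swc_voxel_size)

        stage = "extract_backbones"
        backbones, somas = {}, {}
        for nid, skel in skeletons.items():
            pos = connector_positions_for(connectors, nid)
            res = extract_backbone(skel, pos, cfg.backbone)
            backbones[nid] = backbone_polylines(skel, res)
            somas[nid] = skel.soma_position()

        stage = "assign_lineages"
        catalog = assign_catalog(backbones, somas, bundles)

        stage = "filter_catalog"
        cx = cx_region_names(model.region_names())
        fp = cfg.cx_filter
        if not fp.cx_regions:
            fp = CxFilterParams(fp.min_cx_synapses, fp.min_single_connection, cx)
        filtered = filter_cx_largefield(connectors, catalog, fp)

        stage = "connectivity"
        counts = count_by_lineage_and_compartment(filtered, connectors)
        group_col = cfg.grouping if neurons is not None else None
        if group_col is not None and group_col in (neurons.columns if neurons is not None else []):
            grouping = dict(zip(neurons["neuron_id"], neurons[group_col]))
        else:
            grouping = dict(zip(catalog["neuron_id"], catalog["lineage"].fillna("UNASSIGNED")))
        matrix = build_connection_matrix(connectors, grouping, grouping)
        norm = normalize_to_max(matrix)
        fractions = input_fraction_by_group(connectors, grouping, exclude_regions=cx)
        ecdfs = {}
        for region in sorted({r for r in connectors["compartment"].dropna().unique()
                              if r in cx}):
            ecdfs[region] = pairwise_strength_ecdf(
                connectors, set(grouping), region)

        stage = "write_report"
        catalog.to_csv(out / "catalog.csv", index=False)
        filtered.to_csv(out / "catalog_filtered.csv", index=False)
        counts.to_csv(out / "lineage_by_compartment.csv")
        matrix.to_csv(out / "connection_matrix.csv")
        norm.to_csv(out / "connection_matrix_normalized.csv")
        fractions.to_csv(out / "input_fractions.csv")
        for region, e in ecdfs.items():
            e.to_csv(out / f"ecdf_{region}.csv", index=False)
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "params": {
                "backbone": dataclasses.asdict(cfg.backbone),
                "cx_filter": {"min_cx_synapses": fp.min_cx_synapses,
                              "min_single_connection": fp.min_single_connection,
                              "cx_regions": sorted(fp.cx_regions)},
                "grouping": cfg.grouping,
                "anatomical_axes": cfg.anatomical_axes,
            },
            "inputs": _hash_inputs(Path(cfg.data_dir)),
            "counts": {"neurons": len(skeletons),
                       "synapses": int(connectors["weight"].sum()),
                       "catalog": len(catalog),
                       "catalog_filtered": len(filtered)},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    except Exception as exc:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise PipelineError(stage, exc) from exc
    return {"catalog": catalog, "catalog_filtered": filtered,
            "lineage_by_compartment": counts, "matrix": matrix,
            "matrix_normalized": norm, "input_fractions": fractions,
            "ecdfs": ecdfs, "manifest": manifest}


# --------------------------------------------------------------------------
# connectome-server export adapter
# --------------------------------------------------------------------------

_EXPORT_NEURON_COLS = {"bodyId": "neuron_id", "type": "type_label"}
_EXPORT_SYN_COLS = {
    "bodyId_pre": "pre_neuron", "bodyId_post": "post_neuron",
    "type": "kind", "x": "x", "y": "y", "z": "z", "roi": "compartment",
}


def hemibrain_export_adapter(dump_dir, voxel_size: float = 8.0):
    """Map a local connectome-server CSV export into pipeline inputs.

    Expects ``neurons.csv`` (bodyId, type, ...), ``synapses.csv``
    (bodyId_pre, bodyId_post, type in {pre, post}, x, y, z in voxels,
    roi) and optional ``swc/<bodyId>.swc`` files in voxel coordinates;
    coordinates are scaled by ``voxel_size`` nm per voxel.  Schema
    mismatches raise with an explicit column report.
    """
    dump = Path(dump_dir)
    ndf = pd.read_csv(dump / "neurons.csv")
    missing = [c for c in _EXPORT_NEURON_COLS if c not in ndf.columns]
    if missing:
        raise ValueError(
            f"neurons.csv: missing columns {missing}; found {list(ndf.columns)}")
    neurons = ndf.rename(columns=_EXPORT_NEURON_COLS)
    sdf = pd.read_csv(dump / "synapses.csv")
    missing = [c for c in _EXPORT_SYN_COLS if c not in sdf.columns]
    if missing:
        raise ValueError(
            f"synapses.csv: missing columns {missing}; found {list(sdf.columns)}")
    syn = sdf.rename(columns=_EXPORT_SYN_COLS)
    syn["kind"] = syn["kind"].map({"pre": "TBAR", "post": "PSD"}).fillna(syn["kind"])
    for c in ("x", "y", "z"):
        syn[c] = syn[c].astype(float) * voxel_size
    syn["synapse_id"] = np.arange(1, len(syn) + 1)
    syn["weight"] = syn.get("weight", 1)
    skeletons: dict = {}
    swc_dir = dump / "swc"
    if swc_dir.exists():
        for f in sorted(swc_dir.glob("*.swc")):
            skel = read_swc(f, voxel_size=voxel_size)
            skeletons[int(f.stem)] = skel
    from .io import validate_connector_table
    return neurons, skeletons, validate_connector_table(syn)
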