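"""Analytic compartment volumes and point -> region membership.

A :class:`CompartmentModel` is an ordered list of named primitives
(sphere, box, slab, torus sector) plus a midline plane.  Membership is
boundary-inclusive and a point belonging to several regions is resolved
by list order (earlier wins), which makes every query deterministic.
The torus sector supports the ellipsoid-body annular domains: within the
tube cross-section, ``u`` is the radial offset from the ring circle and
``v`` the signed offset along the ring axis, so anterior/posterior and
inner/outer annuli are plain ``u``/``v`` ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Region",
    "CompartmentModel",
    "UNASSIGNED",
    "read_compartments",
    "write_compartments",
]

UNASSIGNED = "unassigned"

_PRIMITIVES = ("sphere", "box", "slab", "torus_sector")


def _unit(v):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length axis vector")
    return v / n


@dataclass
class Region:
    """One named analytic volume.  ``params`` are nm quantities.

    sphere: center, radius
    box: lo, hi (corner points)
    slab: center, normal, half_thickness, optional lateral_radius
        (finite disc slab when lateral_radius is given)
    torus_sector: center, axis, ring_radius, tube_radius,
        optional u_range / v_range restricting the tube cross-section
    """

    name: str
    primitive: str
    params: dict
    hemisphere: str | None = None

    def __post_init__(self):
        if self.primitive not in _PRIMITIVES:
            raise ValueError(f"unknown primitive {self.primitive!r}")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership for an (n, 3) array."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        prm = self.params
        if self.primitive == "sphere":
            c = np.asarray(prm["center"], float)
            return np.linalg.norm(p - c, axis=1) <= float(prm["radius"])
        if self.primitive == "box":
            lo = np.asarray(prm["lo"], float)
            hi = np.asarray(prm["hi"], float)
            return np.all((p >= lo) & (p <= hi), axis=1)
        if self.primitive == "slab":
            c = np.asarray(prm["center"], float)
            n = _unit(prm["normal"])
            d = p - c
            ax = d @ n
            ok = np.abs(ax) <= float(prm["half_thickness"])
            lr = prm.get("lateral_radius")
            if lr is not None:
                lat = d - np.outer(ax, n)
                ok &= np.linalg.norm(lat, axis=1) <= float(lr)
            return ok
        # torus_sector
        c = np.asarray(prm["center"], float)
        a = _unit(prm["axis"])
        R = float(prm["ring_radius"])
        r = float(prm["tube_radius"])
        d = p - c
        v = d @ a
        radial = d - np.outer(v, a)
        dist_axis = np.linalg.norm(radial, axis=1)
        u = dist_axis - R
        ok = np.hypot(u, v) <= r
        for key, coord in (("u_range", u), ("v_range", v)):
            rng = prm.get(key)
            if rng is not None:
                ok &= (coord >= float(rng[0])) & (coord <= float(rng[1]))
        return ok

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box (used by rejection samplers)."""
        prm = self.params
        if self.primitive == "sphere":
            c = np.asarray(prm["center"], float)
            r = float(prm["radius"])
            return c - r, c + r
        if self.primitive == "box":
            return np.asarray(prm["lo"], float), np.asarray(prm["hi"], float)
        if self.primitive == "slab":
            c = np.asarray(prm["center"], float)
            ht = float(prm["half_thickness"])
            lr = prm.get("lateral_radius")
            ext = ht + (float(lr) if lr is not None else 1e7)
            return c - ext, c + ext
        c = np.asarray(prm["center"], float)
        ext = float(prm["ring_radius"]) + float(prm["tube_radius"])
        return c - ext, c + ext


@dataclass
class CompartmentModel:
    regions: list[Region]
    midline_plane: dict = field(
        default_factory=lambda: {"point": [0.0, 0.0, 0.0], "normal": [1.0, 0.0, 0.0]}
    )

    def region_names(self) -> list[str]:
        seen, out = set(), []
        for r in self.regions:
            if r.name not in seen:
                seen.add(r.name)
                out.append(r.name)
        return out

    def region_of(self, point) -> str:
        return self.regions_of(np.atleast_2d(point))[0]

    def regions_of(self, points) -> np.ndarray:
        """Vectorised membership: first matching region in priority order,
        else ``"unassigned"``.  Total: every point gets a label."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.full(len(p), UNASSIGNED, dtype=object)
        pending = np.ones(len(p), dtype=bool)
        for reg in self.regions:
            if not pending.any():
                break
            idx = np.nonzero(pending)[0]
            hit = reg.contains(p[idx])
            out[idx[hit]] = reg.name
            pending[idx[hit]] = False
        return out

    def hemisphere_of(self, points) -> np.ndarray:
        """LEFT/RIGHT by signed distance to the midline plane; on-plane -> UNKNOWN."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.asarray(self.midline_plane["point"], float)
        n = _unit(self.midline_plane["normal"])
        s = (p - c) @ n
        out = np.where(s > 0, "RIGHT", np.where(s < 0, "LEFT", "UNKNOWN"))
        return out.astype(object)

    def sample_in_region(self, name: str, n: int, rng: np.random.Generator,
                         max_tries: int = 10000) -> np.ndarray:
        """Uniform points whose priority-resolved label equals ``name``.

        Rejection sampling in the union bounding box of the primitives
        carrying that name; guarantees ``regions_of`` consistency.
        """
        regs = [r for r in self.regions if r.name == name]
        if not regs:
            raise KeyError(f"no region named {name!r}")
        los = np.stack([r.bounds()[0] for r in regs])
        his = np.stack([r.bounds()[1] for r in regs])
        lo, hi = los.min(axis=0), his.max(axis=0)
        out = np.empty((n, 3))
        got = 0
        for _ in range(max_tries):
            if got >= n:
                break
            m = max(4 * (n - got), 64)
            cand = rng.uniform(lo, hi, size=(m, 3))
            lab = self.regions_of(cand)
            hit = cand[lab == name]
            take = min(len(hit), n - got)
            out[got:got + take] = hit[:take]
            got += take
        if got < n:
            raise RuntimeError(f"could not sample {n} points in region {name!r}")
        return out


def write_compartments(model: CompartmentModel, path) -> None:
    doc = {
        "midline_plane": model.midline_plane,
        "regions": [
            {
                "name": r.name,
                "primitive": r.primitive,
                "params": {
                    k: (list(v) if isinstance(v, (list, tuple, np.ndarray)) else v)
                    for k, v in r.params.items()
                },
                **({"hemisphere": r.hemisphere} if r.hemisphere else {}),
            }
            for r in model.regions
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_compartments(path) -> CompartmentModel:
    doc = json.loads(Path(path).read_text())
    regions = [
        Region(d["name"], d["primitive"], d["params"], d.get("hemisphere"))
        for d in doc["regions"]
    ]
    return CompartmentModel(regions, doc.get("midline_plane",
                                             {"point": [0, 0, 0], "normal": [1, 0, 0]}))
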