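"""Operator-defined gates, per-sample gate sets and the experiment-wide template.

A gate marks a cluster of cells (a subcommunity) in the 2D histogram. The
Dalmatian Plot works from per-sample gate sets; CyBar combines all samples'
gates into one ordered template applied to every sample as a mask. Gating
itself remains operator input — no automatic clustering lives here.

Membership conventions, fixed for deterministic counting: gates are defined
in transformed [0, 1] channel space; boundaries are inclusive everywhere;
polygon membership uses even-odd ray casting with on-edge points counted
inside. Overlapping template gates are permitted — each gate counts
independently and relative abundances always use the sample's total event
count as denominator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .events import EventTable

__all__ = [
    "Gate",
    "GateSet",
    "GateTemplate",
    "count_in_gate",
    "build_template",
    "apply_template",
]

_EDGE_TOL = 1e-12


def _points_on_segment(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Boundary test: is each point on the closed segment a-b?"""
    ab = b - a
    ap = pts - a
    cross = ab[0] * ap[:, 1] - ab[1] * ap[:, 0]
    dot = ap @ ab
    return (np.abs(cross) <= _EDGE_TOL * max(1.0, np.abs(ab).max())) & (
        dot >= -_EDGE_TOL
    ) & (dot <= ab @ ab + _EDGE_TOL)


def _polygon_contains(pts: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Even-odd ray casting, on-edge -> inside. Vectorized over points."""
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    on_edge = np.zeros(len(pts), dtype=bool)
    n = len(verts)
    for i in range(n):
        a, b = verts[i], verts[(i + 1) % n]
        on_edge |= _points_on_segment(pts, a, b)
        (x1, y1), (x2, y2) = a, b
        with np.errstate(divide="ignore", invalid="ignore"):
            # horizontal edges never satisfy the straddle test; the division
            # result is discarded there
            crosses = ((y1 > y) != (y2 > y)) & (
                x < (x2 - x1) * (y - y1) / (y2 - y1) + x1
            )
        inside ^= crosses
    return inside | on_edge


def _polygon_is_simple(verts: np.ndarray) -> bool:
    """Reject self-intersecting polygons (non-adjacent edge crossings)."""

    def cross2(u, v):
        return u[0] * v[1] - u[1] * v[0]

    def seg_intersect(p, q, r, s):
        d1 = cross2(q - p, r - p)
        d2 = cross2(q - p, s - p)
        d3 = cross2(s - r, p - r)
        d4 = cross2(s - r, q - r)
        return (d1 * d2 < 0) and (d3 * d4 < 0)

    n = len(verts)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(i - j) in (0, 1) or (i == 0 and j == n - 1):
                continue
            if seg_intersect(verts[i], verts[(i + 1) % n],
                             verts[j], verts[(j + 1) % n]):
                return False
    return True


@dataclass(frozen=True)
class Gate:
    """A named 2D region: rectangle, rotated ellipse, or simple polygon."""

    name: str
    shape: str  # "rectangle" | "ellipse" | "polygon"
    channels: tuple[str, str] = ("FSC", "DNA")
    # rectangle
    x0: float | None = None
    x1: float | None = None
    y0: float | None = None
    y1: float | None = None
    # ellipse
    center: tuple[float, float] | None = None
    semi_axes: tuple[float, float] | None = None
    rotation: float = 0.0  # radians, counter-clockwise
    # polygon
    vertices: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.shape == "rectangle":
            if None in (self.x0, self.x1, self.y0, self.y1):
                raise ValueError(f"gate {self.name!r}: rectangle needs x0,x1,y0,y1")
            if not (self.x0 < self.x1 and self.y0 < self.y1):
                raise ValueError(f"gate {self.name!r}: requires x0<x1 and y0<y1")
        elif self.shape == "ellipse":
            if self.center is None or self.semi_axes is None:
                raise ValueError(f"gate {self.name!r}: ellipse needs center, semi_axes")
            if min(self.semi_axes) <= 0:
                raise ValueError(f"gate {self.name!r}: semi-axes must be positive")
        elif self.shape == "polygon":
            if self.vertices is None or len(self.vertices) < 3:
                raise ValueError(f"gate {self.name!r}: polygon needs >= 3 vertices")
            object.__setattr__(
                self, "vertices", tuple(tuple(map(float, v)) for v in self.vertices)
            )
            if not _polygon_is_simple(np.asarray(self.vertices, float)):
                raise ValueError(f"gate {self.name!r}: polygon is self-intersecting")
        else:
            raise ValueError(f"gate {self.name!r}: unknown shape {self.shape!r}")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership for an (n, 2) array of (x, y)."""
        pts = np.asarray(pts, dtype=float)
        if self.shape == "rectangle":
            return (
                (pts[:, 0] >= self.x0) & (pts[:, 0] <= self.x1)
                & (pts[:, 1] >= self.y0) & (pts[:, 1] <= self.y1)
            )
        if self.shape == "ellipse":
            c, s = np.cos(self.rotation), np.sin(self.rotation)
            d = pts - np.asarray(self.center)
            u = d[:, 0] * c + d[:, 1] * s
            v = -d[:, 0] * s + d[:, 1] * c
            a, b = self.semi_axes
            return (u / a) ** 2 + (v / b) ** 2 <= 1.0 + _EDGE_TOL
        return _polygon_contains(pts, np.asarray(self.vertices, float))

    def geometry_key(self) -> tuple:
        """Hashable geometry identity, used for template de-duplication."""
        return (self.shape, self.channels, self.x0, self.x1, self.y0, self.y1,
                self.center, self.semi_axes, self.rotation, self.vertices)

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "shape": self.shape}
        if self.shape == "rectangle":
            d.update(x0=self.x0, x1=self.x1, y0=self.y0, y1=self.y1)
        elif self.shape == "ellipse":
            d.update(center=list(self.center), semi_axes=list(self.semi_axes),
                     rotation=self.rotation)
        else:
            d["vertices"] = [list(v) for v in self.vertices]
        return d

    @classmethod
    def from_dict(cls, d: dict, channels=("FSC", "DNA")) -> "Gate":
        kw = dict(d)
        name = kw.pop("name")
        shape = kw.pop("shape")
        if "center" in kw:
            kw["center"] = tuple(kw["center"])
        if "semi_axes" in kw:
            kw["semi_axes"] = tuple(kw["semi_axes"])
        if "vertices" in kw:
            kw["vertices"] = tuple(tuple(v) for v in kw["vertices"])
        return cls(name=name, shape=shape, channels=tuple(channels), **kw)


def _check_unique_names(gates) -> None:
    names = [g.name for g in gates]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate gate names: {dup}")


@dataclass
class GateSet:
    """One sample's gates (the Dalmatian Plot's operator input)."""

    sample_id: str
    gates: list[Gate]

    def __post_init__(self) -> None:
        _check_unique_names(self.gates)


@dataclass
class GateTemplate:
    """Experiment-wide ordered gate list; order defines the barcode rows."""

    gates: list[Gate]

    def __post_init__(self) -> None:
        _check_unique_names(self.gates)

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.gates]

    def to_json(self, path) -> None:
        channels = self.gates[0].channels if self.gates else ("FSC", "DNA")
        with open(path, "w") as fh:
            json.dump(
                {"channels": list(channels),
                 "gates": [g.to_dict() for g in self.gates]},
                fh, indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "GateTemplate":
        with open(path) as fh:
            d = json.load(fh)
        channels = tuple(d.get("channels", ("FSC", "DNA")))
        return cls([Gate.from_dict(g, channels) for g in d["gates"]])


def load_gate_set(path, sample_id: str | None = None) -> GateSet:
    tpl = GateTemplate.from_json(path)
    if sample_id is None:
        import os

        sample_id = os.path.splitext(os.path.basename(str(path)))[0]
    return GateSet(sample_id=sample_id, gates=list(tpl.gates))


def count_in_gate(t: EventTable, g: Gate) -> int:
    """Number of events inside or on the boundary of the gate."""
    pts = t.xy(*g.channels)  # raises KeyError on channel mismatch
    return int(np.count_nonzero(g.contains(pts)))


def build_template(sets: list[GateSet]) -> GateTemplate:
    """Combine per-sample gate sets into one template, first-appearance order.

    Gates sharing a name must share geometry; a name collision with different
    geometry is an error (the analyst must resolve it), identical gates
    collapse to one.
    """
    if not sets:
        raise ValueError("need at least one gate set")
    seen: dict[str, Gate] = {}
    for gs in sets:
        for g in gs.gates:
            if g.name in seen:
                if seen[g.name].geometry_key() != g.geometry_key():
                    raise ValueError(
                        f"gate name {g.name!r} appears with conflicting geometry"
                    )
            else:
                seen[g.name] = g
    return GateTemplate(list(seen.values()))


def apply_template(t: EventTable, tpl: GateTemplate) -> tuple[np.ndarray, int]:
    """Count events per template gate; returns (counts, outside_count).

    Gates may overlap, so the count vector can sum past the event total;
    ``outside_count`` is the number of events covered by no gate at all.
    """
    if not tpl.gates:
        raise ValueError("gate template is empty")
    pts = t.xy(*tpl.gates[0].channels)
    inside_any = np.zeros(t.n_events, dtype=bool)
    counts = np.empty(len(tpl.gates), dtype=np.int64)
    for i, g in enumerate(tpl.gates):
        member = g.contains(pts)
        counts[i] = int(np.count_nonzero(member))
        inside_any |= member
    return counts, int(t.n_events - np.count_nonzero(inside_any))
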