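"""FlowFP-style recursive probability binning.

A binary tree of axis-aligned splits is grown on pooled *training* events:
each node splits its rectangle in two halves holding an equal number of
training events (the lower half takes the extra event when the count is odd),
recursively, r times. The resulting 2^r leaves form a fixed geometrical grid
— small bins where training cells are dense, large bins where they are sparse
— that is applied as a mask to every sample; per-bin counts are the sample's
fingerprint vector.

The split axis is the one with larger event variance inside the node (tie
goes to x) and the threshold is the midpoint between the two events adjacent
to the median — choices from the probability-binning literature, isolated
here so they can be substituted. Events exactly on a threshold go to the
lower/left bin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .dissim import DissimilarityMatrix
from .events import EventTable

__all__ = ["FPModel", "BinCountVector", "fit_model", "apply_model", "fp_matrix"]


@dataclass
class _Node:
    axis: int | None = None  # None -> leaf
    threshold: float | None = None
    lower: "_Node | None" = None
    upper: "_Node | None" = None
    bounds: tuple[float, float, float, float] = (0.0, 1.0, 0.0, 1.0)  # x0,x1,y0,y1
    leaf_index: int | None = None

    def to_dict(self) -> dict:
        if self.axis is None:
            return {"leaf": self.leaf_index, "bounds": list(self.bounds)}
        return {
            "axis": "xy"[self.axis],
            "threshold": self.threshold,
            "bounds": list(self.bounds),
            "lower": self.lower.to_dict(),
            "upper": self.upper.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_Node":
        if "leaf" in d:
            return cls(bounds=tuple(d["bounds"]), leaf_index=d["leaf"])
        return cls(
            axis="xy".index(d["axis"]),
            threshold=d["threshold"],
            bounds=tuple(d["bounds"]),
            lower=cls.from_dict(d["lower"]),
            upper=cls.from_dict(d["upper"]),
        )


@dataclass
class FPModel:
    """Fitted probability-binning grid: 2^r leaves partitioning [0, 1]^2."""

    root: _Node
    n_recursions: int
    training_ids: list[str] = field(default_factory=list)
    channels: tuple[str, str] = ("FSC", "DNA")

    @property
    def n_bins(self) -> int:
        return 2 ** self.n_recursions

    def leaves(self) -> list[_Node]:
        out: list[_Node] = []

        def walk(node: _Node) -> None:
            if node.axis is None:
                out.append(node)
            else:
                walk(node.lower)
                walk(node.upper)

        walk(self.root)
        return sorted(out, key=lambda nd: nd.leaf_index)

    def leaf_areas(self) -> np.ndarray:
        return np.array(
            [(b[1] - b[0]) * (b[3] - b[2]) for b in
             (leaf.bounds for leaf in self.leaves())]
        )

    def assign(self, pts: np.ndarray) -> np.ndarray:
        """Leaf index per point; boundary points go to the lower/left leaf."""
        pts = np.asarray(pts, dtype=float)
        out = np.empty(len(pts), dtype=np.int64)

        def walk(node: _Node, idx: np.ndarray) -> None:
            if node.axis is None:
                out[idx] = node.leaf_index
                return
            low = pts[idx, node.axis] <= node.threshold
            walk(node.lower, idx[low])
            walk(node.upper, idx[~low])

        walk(self.root, np.arange(len(pts)))
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"n_recursions": self.n_recursions,
                 "training_ids": self.training_ids,
                 "channels": list(self.channels),
                 "tree": self.root.to_dict()},
                fh, indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "FPModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(_Node.from_dict(d["tree"]), d["n_recursions"],
                   d.get("training_ids", []), tuple(d.get("channels", ("FSC", "DNA"))))


@dataclass
class BinCountVector:
    """Per-sample fingerprint: cell count in each of the model's bins."""

    sample_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.total


def fit_model(training: list[EventTable], r: int,
              channels: tuple[str, str] = ("FSC", "DNA")) -> FPModel:
    """Fit the equal-count grid on the pooled training events.

    Fitting several training samples is by definition identical to fitting
    their concatenation. Deterministic for fixed input.
    """
    if r < 1:
        raise ValueError("number of recursions must be >= 1")
    if not training:
        raise ValueError("need at least one training sample")
    pts = np.concatenate([t.xy(*channels) for t in training])
    if len(pts) < 2 ** r:
        raise ValueError(
            f"{len(pts)} pooled training events cannot fill 2^{r} = {2 ** r} bins"
        )
    next_leaf = 0

    def split(idx: np.ndarray, depth: int,
              bounds: tuple[float, float, float, float]) -> _Node:
        nonlocal next_leaf
        if depth == r:
            node = _Node(bounds=bounds, leaf_index=next_leaf)
            next_leaf += 1
            return node
        sub = pts[idx]
        var = sub.var(axis=0)
        axis = 0 if var[0] >= var[1] else 1
        v = np.sort(sub[:, axis])
        n = len(v)
        nl = (n + 1) // 2  # lower child takes the extra event when odd
        thr = 0.5 * (v[nl - 1] + v[nl])
        low = sub[:, axis] <= thr
        x0, x1, y0, y1 = bounds
        if axis == 0:
            b_low, b_up = (x0, thr, y0, y1), (thr, x1, y0, y1)
        else:
            b_low, b_up = (x0, x1, y0, thr), (x0, x1, thr, y1)
        return _Node(
            axis=axis, threshold=float(thr), bounds=bounds,
            lower=split(idx[low], depth + 1, b_low),
            upper=split(idx[~low], depth + 1, b_up),
        )

    root = split(np.arange(len(pts)), 0, (0.0, 1.0, 0.0, 1.0))
    return FPModel(root, r, [t.sample_id for t in training], channels)


def apply_model(m: FPModel, t: EventTable) -> BinCountVector:
    """Count the sample's events per bin; counts sum to n_events exactly."""
    pts = t.xy(*m.channels)
    if pts.min() < 0 or pts.max() > 1:
        raise ValueError("events must lie in [0, 1]^2; transform first")
    idx = m.assign(pts)
    return BinCountVector(t.sample_id,
                          np.bincount(idx, minlength=m.n_bins))


def fp_matrix(
    m: FPModel, samples: list[EventTable], metric: str = "l1"
) -> DissimilarityMatrix:
    """Pairwise dissimilarity of bin-fraction fingerprints.

    ``l1``: d(a, b) = 0.5 * sum_i |f_ai - f_bi|, in [0, 1].
    """
    if metric != "l1":
        raise ValueError(f"unsupported metric {metric!r}")
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    vecs = [apply_model(m, t) for t in samples]
    for v in vecs:
        if v.total == 0:
            raise ValueError(f"sample {v.sample_id!r} has no events")
    frac = np.vstack([v.fractions for v in vecs])
    d = squareform(pdist(frac, metric="cityblock")) / 2.0
    return DissimilarityMatrix([t.sample_id for t in samples], d,
                               method="flowfp/l1",
                               meta={"n_recursions": m.n_recursions,
                                     "training_ids": list(m.training_ids)})
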