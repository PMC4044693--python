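"""Dalmatian Plot: gate masks compared by a Jaccard-type pixel dissimilarity.

Each sample is reduced to the "black blots on a white background" left after
the operator encircles its most abundant cell clusters. Relative abundance
information is lost in the binary form; the gray variant restores it by
carrying each blot's cell count as intensity. Pairwise dissimilarity is the
Jaccard distance on black-pixel sets (binary) or the Ruzicka / weighted
Jaccard distance on intensities (gray); the exact formula is isolated in
:func:`jaccard_dissimilarity` so a different variant can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dissim import DissimilarityMatrix
from .events import _round_half_up
from .gating import GateSet
from .pgm import read_pgm, write_pgm

__all__ = [
    "MaskImage",
    "render_mask",
    "jaccard_dissimilarity",
    "dalmatian_matrix",
]


@dataclass
class MaskImage:
    """Rasterized gate-set image: 0 = white background, >0 = inside a gate."""

    resolution: int
    pixels: np.ndarray
    mode: str = "binary"  # "binary" | "gray"
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.int64)
        if self.pixels.shape != (self.resolution, self.resolution):
            raise ValueError("pixel array shape does not match resolution")
        if self.mode == "binary" and not np.all(np.isin(self.pixels, (0, 255))):
            raise ValueError("binary masks hold only 0 and 255")

    @property
    def support(self) -> np.ndarray:
        return self.pixels > 0

    def to_pgm(self, path, binary: bool = False) -> None:
        write_pgm(path, self.pixels, binary=binary)

    @classmethod
    def from_pgm(cls, path, mode: str = "gray", sample_id: str = "") -> "MaskImage":
        px = read_pgm(path)
        return cls(px.shape[0], px, mode=mode, sample_id=sample_id)


def _pixel_centers(resolution: int) -> np.ndarray:
    """(R*R, 2) array of pixel-center coordinates, row-major (row = y)."""
    c = (np.arange(resolution) + 0.5) / resolution
    xx, yy = np.meshgrid(c, c)  # xx varies along columns, yy along rows
    return np.column_stack([xx.ravel(), yy.ravel()])


def render_mask(
    gs: GateSet,
    resolution: int = 128,
    mode: str = "binary",
    counts: dict[str, int] | None = None,
) -> MaskImage:
    """Rasterize a gate set by pixel-center sampling (no anti-aliasing).

    A pixel is black iff its center lies in at least one gate. In gray mode
    the pixel takes the largest intensity among covering gates, with gate
    intensity ``max(1, round(255 * count / max_count))`` from the supplied
    per-gate cell counts.
    """
    if mode not in ("binary", "gray"):
        raise ValueError(f"unknown mask mode {mode!r}")
    if mode == "gray":
        if counts is None:
            raise ValueError("gray mode requires per-gate counts")
        missing = [g.name for g in gs.gates if g.name not in counts]
        if missing:
            raise ValueError(f"gray mode missing counts for gates: {missing}")
    centers = _pixel_centers(resolution)
    pixels = np.zeros(resolution * resolution, dtype=np.int64)
    if mode == "gray" and gs.gates:
        max_count = max(counts[g.name] for g in gs.gates)
    for g in gs.gates:
        member = g.contains(centers)
        if mode == "binary":
            pixels[member] = 255
        else:
            if max_count > 0:
                level = int(max(1, _round_half_up(255.0 * counts[g.name] / max_count)))
            else:
                level = 1
            np.maximum.at(pixels, np.nonzero(member)[0], level)
    return MaskImage(resolution, pixels.reshape(resolution, resolution),
                     mode=mode, sample_id=gs.sample_id)


def jaccard_dissimilarity(a: MaskImage, b: MaskImage) -> float:
    """Jaccard distance between two masks.

    Binary: 1 - |A n B| / |A u B| on black-pixel sets. Gray: the weighted
    (Ruzicka) form 1 - sum(min) / sum(max) over pixel intensities, which
    reduces to the binary form when all intensities are equal.
    """
    if a.resolution != b.resolution:
        raise ValueError("mask resolutions differ")
    pa, pb = a.pixels, b.pixels
    if not (pa.any() or pb.any()):
        raise ValueError("Jaccard dissimilarity undefined for two empty masks")
    if a.mode == "binary" and b.mode == "binary":
        sa, sb = a.support, b.support
        inter = np.count_nonzero(sa & sb)
        union = np.count_nonzero(sa | sb)
        return 1.0 - inter / union
    num = np.minimum(pa, pb).sum()
    den = np.maximum(pa, pb).sum()
    return float(1.0 - num / den)


def dalmatian_matrix(masks: list[MaskImage]) -> DissimilarityMatrix:
    """All-pairs Jaccard dissimilarity matrix of the rendered masks."""
    if len(masks) < 2:
        raise ValueError("need at least 2 masks")
    res = {m.resolution for m in masks}
    if len(res) != 1:
        raise ValueError(f"mixed mask resolutions: {sorted(res)}")
    n = len(masks)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = jaccard_dissimilarity(masks[i], masks[j])
            except ValueError as exc:
                raise ValueError(
                    f"pair ({masks[i].sample_id!r}, {masks[j].sample_id!r}): {exc}"
                ) from exc
    ids = [m.sample_id or f"mask{i}" for i, m in enumerate(masks)]
    mode = masks[0].mode
    return DissimilarityMatrix(ids, d, method=f"dalmatian/{mode}",
                               meta={"resolution": masks[0].resolution})
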