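"""CHIC — Cytometric Histogram Image Comparison.

Gating-free: every sample's 2D histogram is rendered as a gray-scale image
and pairs of images are compared pixel by pixel. The XOR image holds the
absolute intensity difference, the overlap image the pixel-wise maximum; the
dissimilarity P_sim is the average gray value per *informative* pixel — the
XOR image's total intensity divided by the overlap image's count of non-zero
pixels. P_sim is reported in raw gray-level units (0-255); divide by 255 for
a normalized scale when comparing across methods.

"Informative in at least one image" (union semantics) keeps P_sim defined for
fully disjoint fingerprints; intersection semantics are available via
``overlap="intersection"`` for comparison, at the price of being undefined on
disjoint supports.
"""

from __future__ import annotations

import numpy as np

from .dissim import DissimilarityMatrix
from .events import GrayImage

__all__ = ["xor_image", "overlap_image", "chic_dissimilarity", "chic_matrix"]


def _check_pair(a: GrayImage, b: GrayImage) -> None:
    if a.resolution != b.resolution:
        raise ValueError(
            f"image resolutions differ: {a.resolution} vs {b.resolution}"
        )


def xor_image(a: GrayImage, b: GrayImage) -> GrayImage:
    """Pixel-wise absolute intensity difference |a - b|."""
    _check_pair(a, b)
    return GrayImage(a.resolution, np.abs(a.pixels - b.pixels),
                     sample_id=f"xor({a.sample_id},{b.sample_id})")


def overlap_image(a: GrayImage, b: GrayImage) -> GrayImage:
    """Pixel-wise maximum; non-zero wherever either image has virtual cells."""
    _check_pair(a, b)
    return GrayImage(a.resolution, np.maximum(a.pixels, b.pixels),
                     sample_id=f"overlap({a.sample_id},{b.sample_id})")


def chic_dissimilarity(
    a: GrayImage, b: GrayImage, overlap: str = "union"
) -> float:
    """P_sim = (sum of XOR intensities) / (number of informative overlap pixels)."""
    _check_pair(a, b)
    diff = np.abs(a.pixels - b.pixels)
    if overlap == "union":
        informative = int(np.count_nonzero(a.pixels | b.pixels))
    elif overlap == "intersection":
        informative = int(np.count_nonzero(np.minimum(a.pixels, b.pixels)))
    else:
        raise ValueError(f"unknown overlap semantics {overlap!r}")
    if informative == 0:
        raise ValueError("P_sim undefined: no informative pixels in the overlap")
    return float(diff.sum() / informative)


def chic_matrix(
    images: list[GrayImage], overlap: str = "union"
) -> DissimilarityMatrix:
    """All-pairs CHIC dissimilarity matrix."""
    if len(images) < 2:
        raise ValueError("need at least 2 images")
    res = {im.resolution for im in images}
    if len(res) != 1:
        raise ValueError(f"mixed image resolutions: {sorted(res)}")
    n = len(images)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = chic_dissimilarity(images[i], images[j], overlap)
            except ValueError as exc:
                raise ValueError(
                    f"pair ({images[i].sample_id!r}, {images[j].sample_id!r}): {exc}"
                ) from exc
    ids = [im.sample_id or f"image{i}" for i, im in enumerate(images)]
    return DissimilarityMatrix(ids, d, method="chic",
                               meta={"resolution": images[0].resolution,
                                     "overlap": overlap})
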