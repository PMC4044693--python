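"""Cytometric diversity indices derived from fingerprint images and matrices.

* Range-weighted richness ``Rr = N_i / N_all`` — the fraction of histogram
  pixels carrying virtual-cell information; low Rr means few distinct cell
  states (a specialized community).
* Structural organization ``So = sum_i |P_ij - P_average| / N_i`` — the mean
  absolute deviation of informative-pixel intensities from their mean; high
  So means abundance is concentrated in a few dominant clusters.
* Dynamics ``Dy`` (mean dissimilarity of consecutive samples) and ``Da``
  (mean over all sample pairs) — computed on any method's dissimilarity
  matrix, conventionally CHIC's.

Both Rr and So depend on the histogram resolution and the number of recorded
events, so comparisons across samples require matched settings; a mismatch
triggers a warning, never a silent rescale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dissim import DissimilarityMatrix
from .events import GrayImage

__all__ = [
    "range_weighted_richness",
    "structural_organization",
    "dynamics_consecutive",
    "dynamics_all",
    "index_table",
]


def range_weighted_richness(img: GrayImage) -> float:
    """Rr = informative pixels / all pixels, in (0, 1]. Support-only: the
    intensities of informative pixels do not matter."""
    ni = img.n_informative
    if ni == 0:
        raise ValueError("Rr undefined for an empty image (no informative pixels)")
    return ni / img.n_pixels


def structural_organization(img: GrayImage) -> float:
    """So = mean |P_ij - P_average| over informative pixels only.

    Background (white) pixels are excluded from both the mean and the
    deviations; including them would conflate So with Rr.
    """
    vals = img.pixels[img.pixels > 0]
    if vals.size == 0:
        raise ValueError("So undefined for an empty image (no informative pixels)")
    return float(np.abs(vals - vals.mean()).mean())


def dynamics_consecutive(d: DissimilarityMatrix, order: list[str]) -> float:
    """Dy: mean dissimilarity of consecutive samples in time order."""
    if len(order) < 2:
        raise ValueError("Dy needs at least 2 samples in the time order")
    unknown = [s for s in order if s not in d.ids]
    if unknown:
        raise ValueError(f"time order references unknown samples: {unknown}")
    steps = [d.pair(a, b) for a, b in zip(order[:-1], order[1:])]
    return float(np.mean(steps))


def consecutive_terms(d: DissimilarityMatrix, order: list[str]) -> np.ndarray:
    """The individual consecutive-pair dissimilarities averaged by Dy."""
    return np.array([d.pair(a, b) for a, b in zip(order[:-1], order[1:])])


def dynamics_all(d: DissimilarityMatrix) -> float:
    """Da: mean dissimilarity over all sample pairs (strict upper triangle)."""
    if d.n < 2:
        raise ValueError("Da needs at least 2 samples")
    return float(d.condensed().mean())


def index_table(images: list[GrayImage]) -> pd.DataFrame:
    """Per-sample Rr and So with the settings they depend on."""
    res = {im.resolution for im in images}
    if len(res) > 1:
        warnings.warn(
            f"mixed image resolutions {sorted(res)}: Rr/So are not comparable "
            "across samples", stacklevel=2,
        )
    rows = []
    for im in images:
        rows.append({
            "sample_id": im.sample_id,
            "resolution": im.resolution,
            "n_events": im.n_events,
            "Rr": range_weighted_richness(im),
            "So": structural_organization(im),
        })
    return pd.DataFrame(rows)
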