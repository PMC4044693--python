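"""Single-cell event tables, channel transforms, 2D histograms and gray images.

A *cytometric fingerprint* is the 2D histogram of a sample's per-cell optical
measurements — here forward scatter (FSC, cell-size related) against DNA
fluorescence (e.g. DAPI, which doubles through the cell cycle). All four
comparison methods in this package consume either the event table, the binned
histogram, or its 8-bit gray-scale image rendering.

Conventions fixed here (bit-exact tests depend on them):

* channel values after transform live in [0, 1];
* bins are half-open ``[k/R, (k+1)/R)`` with the last bin closed, 0-based;
* histogram row index = y channel (DNA), column index = x channel (FSC),
  row 0 / column 0 = lowest signal (image writers flip rows for display only);
* gray mapping is linear in count with a floor of 1 for any non-zero count,
  so rare populations stay *informative* (non-white) pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EventTable",
    "Histogram2D",
    "GrayImage",
    "ChannelTransform",
    "read_events",
    "transform_channels",
    "bin2d",
    "to_gray_image",
    "ALLOWED_RESOLUTIONS",
]

log = logging.getLogger(__name__)

#: Histogram resolutions supported by typical instrument signal acquisition.
ALLOWED_RESOLUTIONS = (64, 128, 256, 512, 1024)


@dataclass
class EventTable:
    """Per-sample matrix of single-cell measurements (rows = cells)."""

    sample_id: str
    channels: list[str]
    values: np.ndarray
    dropped_rows: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channels):
            raise ValueError("values must be n_events x n_channels")
        if self.n_events < 1:
            raise ValueError("an event table needs at least one event")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("event table contains non-finite values")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.values[:, self.channels.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not in table {self.sample_id!r}") from None

    def xy(self, x_channel: str, y_channel: str) -> np.ndarray:
        return np.column_stack([self.channel(x_channel), self.channel(y_channel)])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, columns=self.channels).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class Histogram2D:
    """Binned 2D fingerprint: ``counts[row, col]`` with row = y, col = x."""

    resolution: int
    x_channel: str
    y_channel: str
    counts: np.ndarray
    total_events: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.resolution not in ALLOWED_RESOLUTIONS:
            raise ValueError(
                f"resolution {self.resolution} not in {ALLOWED_RESOLUTIONS}"
            )
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.resolution, self.resolution):
            raise ValueError("counts shape does not match resolution")
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be non-negative")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.counts).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class GrayImage:
    """8-bit gray rendering of a histogram.

    Pixel 0 is background (white, no virtual cells); values 1-255 are
    *informative* intensities linear in cell count. ``n_informative`` is the
    N_i of the diversity indices, ``n_pixels`` the N_all.
    """

    resolution: int
    pixels: np.ndarray
    sample_id: str = ""
    n_events: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.int64)
        if self.pixels.shape != (self.resolution, self.resolution):
            raise ValueError("pixel array shape does not match resolution")
        if self.pixels.min(initial=0) < 0 or self.pixels.max(initial=0) > 255:
            raise ValueError("pixel values must be in [0, 255]")

    @property
    def n_pixels(self) -> int:
        return self.resolution * self.resolution

    @property
    def n_informative(self) -> int:
        return int(np.count_nonzero(self.pixels))

    @property
    def support(self) -> np.ndarray:
        return self.pixels > 0


@dataclass(frozen=True)
class ChannelTransform:
    """Map raw instrument units onto [0, 1], linearly or on a log10 scale."""

    kind: str  # "linear" | "log10"
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "log10"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if not self.min < self.max:
            raise ValueError("transform requires min < max")
        if self.kind == "log10" and self.min <= 0:
            raise ValueError("log10 transform requires min > 0")

    def __call__(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if self.kind == "linear":
            out = (v - self.min) / (self.max - self.min)
        else:
            lo, hi = np.log10(self.min), np.log10(self.max)
            out = (np.log10(np.clip(v, self.min, None)) - lo) / (hi - lo)
        return np.clip(out, 0.0, 1.0)

    @classmethod
    def parse(cls, text: str) -> "ChannelTransform":
        """Parse CLI syntax ``log10:1,262144`` or ``linear:0,1000``."""
        kind, _, rng = text.partition(":")
        lo, _, hi = rng.partition(",")
        return cls(kind, float(lo), float(hi))


def read_events(path, format: str | None = None, sample_id: str | None = None) -> EventTable:
    """Read a per-sample event file (TSV with channel headers, or FCS list mode).

    Rows containing non-finite values are dropped and counted in
    ``EventTable.dropped_rows`` rather than raising; real exports contain
    saturated/invalid rows.
    """
    path = str(path)
    if format is None:
        format = "fcs" if path.lower().endswith(".fcs") else "tsv"
    if sample_id is None:
        import os

        sample_id = os.path.splitext(os.path.basename(path))[0]
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t")
        except pd.errors.EmptyDataError:
            raise ValueError(f"{path}: empty event file") from None
        if df.shape[1] == 0 or df.shape[0] == 0:
            raise ValueError(f"{path}: no event rows")
        channels = [str(c) for c in df.columns]
        if any(c.strip() == "" or c.startswith("Unnamed") for c in channels):
            raise ValueError(f"{path}: missing channel headers")
        values = df.to_numpy(dtype=float)
    elif format == "fcs":
        from .fcsio import read_fcs

        channels, values = read_fcs(path)
    else:
        raise ValueError(f"unsupported event format {format!r}")
    finite = np.all(np.isfinite(values), axis=1)
    dropped = int(values.shape[0] - finite.sum())
    if dropped:
        log.info("%s: dropped %d non-finite event rows", sample_id, dropped)
        values = values[finite]
    if values.shape[0] == 0:
        raise ValueError(f"{path}: no finite event rows")
    return EventTable(sample_id, channels, values, dropped_rows=dropped)


def transform_channels(
    t: EventTable, spec: Mapping[str, ChannelTransform]
) -> EventTable:
    """Apply per-channel transforms; channels absent from ``spec`` pass through."""
    cols = []
    for i, name in enumerate(t.channels):
        col = t.values[:, i]
        if name in spec:
            col = spec[name](col)
        cols.append(col)
    return EventTable(t.sample_id, list(t.channels), np.column_stack(cols),
                      dropped_rows=t.dropped_rows)


def bin2d(
    t: EventTable, x_channel: str, y_channel: str, resolution: int = 128
) -> Histogram2D:
    """Bin events into a resolution x resolution histogram.

    The event at (x, y) lands in ``counts[floor(y*R), floor(x*R)]``; indices
    are clamped so x = 1 or y = 1 falls in the last bin. Counts sum to the
    table's event count exactly.
    """
    if resolution not in ALLOWED_RESOLUTIONS:
        raise ValueError(f"resolution {resolution} not in {ALLOWED_RESOLUTIONS}")
    xy = t.xy(x_channel, y_channel)
    if xy.min() < 0 or xy.max() > 1:
        raise ValueError("channel values must lie in [0, 1]; transform first")
    ix = np.minimum((xy[:, 0] * resolution).astype(np.int64), resolution - 1)
    iy = np.minimum((xy[:, 1] * resolution).astype(np.int64), resolution - 1)
    counts = np.bincount(
        iy * resolution + ix, minlength=resolution * resolution
    ).reshape(resolution, resolution)
    return Histogram2D(resolution, x_channel, y_channel, counts,
                       total_events=t.n_events, sample_id=t.sample_id)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def to_gray_image(h: Histogram2D) -> GrayImage:
    """Render a histogram as a linear gray-scale image.

    pixel = 0 where count = 0, else ``max(1, round(255 * count / max_count))``
    with round-half-up; the maximum-count pixel always maps to 255.
    """
    if h.total_events < 1 or h.counts.max() == 0:
        raise ValueError("cannot render an empty histogram (no informative pixels)")
    mx = h.counts.max()
    scaled = _round_half_up(255.0 * h.counts / mx)
    pixels = np.where(h.counts > 0, np.maximum(scaled, 1), 0).astype(np.int64)
    return GrayImage(h.resolution, pixels, sample_id=h.sample_id,
                     n_events=h.total_events,
                     meta={"x_channel": h.x_channel, "y_channel": h.y_channel})


def fingerprint_image(
    t: EventTable,
    x_channel: str = "FSC",
    y_channel: str = "DNA",
    resolution: int = 128,
    transforms: Mapping[str, ChannelTransform] | None = None,
) -> GrayImage:
    """Convenience: events -> (optional transform) -> histogram -> gray image."""
    if transforms:
        t = transform_channels(t, transforms)
    return to_gray_image(bin2d(t, x_channel, y_channel, resolution))


def fingerprint_images(
    tables: Iterable[EventTable], **kwargs
) -> list[GrayImage]:
    return [fingerprint_image(t, **kwargs) for t in tables]
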