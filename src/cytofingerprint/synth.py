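"""Synthetic DAPI-stained microbial-community event data with known ground truth.

A community is modelled as a mixture of 2D Gaussian clusters in transformed
(FSC, DNA-fluorescence) space — each cluster a subcommunity with a known
abundance fraction. Because per-cell DNA content doubles through the cell
cycle, a configurable fraction of each cluster's cells is shifted up the DNA
axis by one doubling (+log10(2) in the log-scaled channel units), producing
the proliferation satellite seen in real fingerprints. Channels are generated
directly in transformed [0, 1] space; out-of-range draws are clamped (as a
saturating detector would) so the event count stays exact.

Everything downstream — gating, the four comparison methods, the diversity
indices, the ordination statistics — is testable against the ground-truth
abundances these generators return.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .events import EventTable
from .gating import Gate, GateSet

__all__ = [
    "Component",
    "CommunitySpec",
    "SeriesSpec",
    "SeriesResult",
    "GroupsResult",
    "simulate_community",
    "simulate_series",
    "simulate_groups",
    "operator_gate_sets",
    "component_gate",
    "DNA_DOUBLING_SHIFT",
]

log = logging.getLogger(__name__)

#: One DNA doubling on the log10 scale, applied additively in transformed units.
DNA_DOUBLING_SHIFT = float(np.log10(2.0))

CHANNELS = ["FSC", "DNA"]


@dataclass(frozen=True)
class Component:
    """One subcommunity: a 2D Gaussian cluster plus a proliferation satellite."""

    mean: tuple[float, float]
    covariance: tuple[tuple[float, float], tuple[float, float]]
    abundance_fraction: float
    proliferation_fraction: float = 0.0

    def cov_array(self) -> np.ndarray:
        return np.asarray(self.covariance, dtype=float)

    def validate(self) -> None:
        cov = self.cov_array()
        if cov.shape != (2, 2):
            raise ValueError("covariance must be 2x2")
        if not np.allclose(cov, cov.T, atol=1e-12):
            raise ValueError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("covariance must be positive-definite")
        if not 0.0 <= self.proliferation_fraction <= 1.0:
            raise ValueError("proliferation_fraction must lie in [0, 1]")
        if self.abundance_fraction < 0:
            raise ValueError("abundance fractions must be non-negative")


@dataclass(frozen=True)
class CommunitySpec:
    """A mixture of components whose abundance fractions sum to 1."""

    components: tuple[Component, ...]

    def __init__(self, components) -> None:
        object.__setattr__(self, "components", tuple(components))

    def validate(self) -> None:
        if not self.components:
            raise ValueError("a community needs at least one component")
        for c in self.components:
            c.validate()
        total = sum(c.abundance_fraction for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundance fractions sum to {total!r}, expected 1")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([c.abundance_fraction for c in self.components])

    def with_fractions(self, fractions) -> "CommunitySpec":
        fractions = np.asarray(fractions, dtype=float)
        if len(fractions) != len(self.components):
            raise ValueError("fraction vector length mismatch")
        return CommunitySpec(
            Component(c.mean, c.covariance, float(f), c.proliferation_fraction)
            for c, f in zip(self.components, fractions)
        )

    # --- JSON round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "components": [
                {
                    "mean": list(c.mean),
                    "covariance": [list(r) for r in np.asarray(c.covariance)],
                    "abundance_fraction": c.abundance_fraction,
                    "proliferation_fraction": c.proliferation_fraction,
                }
                for c in self.components
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CommunitySpec":
        return cls(
            Component(
                tuple(c["mean"]),
                tuple(tuple(r) for r in c["covariance"]),
                c["abundance_fraction"],
                c.get("proliferation_fraction", 0.0),
            )
            for c in d["components"]
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CommunitySpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _draw_component(
    rng: np.random.Generator, comp: Component, n: int
) -> tuple[np.ndarray, int]:
    """Sample n events for one component; returns (events, n_clamped)."""
    pts = rng.multivariate_normal(np.asarray(comp.mean, float), comp.cov_array(),
                                  size=n, method="cholesky")
    if comp.proliferation_fraction > 0 and n > 0:
        n_prolif = rng.binomial(n, comp.proliferation_fraction)
        pts[:n_prolif, 1] += DNA_DOUBLING_SHIFT
    out_of_range = int(np.count_nonzero((pts < 0) | (pts > 1)))
    np.clip(pts, 0.0, 1.0, out=pts)
    return pts, out_of_range


def _simulate(
    rng: np.random.Generator, spec: CommunitySpec, n_events: int, sample_id: str
) -> tuple[EventTable, np.ndarray]:
    counts = rng.multinomial(n_events, spec.fractions)
    chunks, labels, clamped = [], [], 0
    for k, (comp, n_k) in enumerate(zip(spec.components, counts)):
        if n_k == 0:
            continue
        pts, n_clamp = _draw_component(rng, comp, int(n_k))
        clamped += n_clamp
        chunks.append(pts)
        labels.append(np.full(int(n_k), k))
    values = np.concatenate(chunks)
    lab = np.concatenate(labels)
    perm = rng.permutation(n_events)
    if clamped:
        log.info("%s: clamped %d of %d coordinates to [0, 1]",
                 sample_id, clamped, 2 * n_events)
    return EventTable(sample_id, list(CHANNELS), values[perm]), lab[perm]


def simulate_community(
    spec: CommunitySpec,
    n_events: int,
    seed: int,
    sample_id: str = "sample",
    return_labels: bool = False,
):
    """Draw one sample; component membership is multinomial in the fractions.

    Identical (spec, n_events, seed) reproduces the identical table. With
    ``return_labels=True`` the ground-truth component index of every event is
    returned alongside.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    spec.validate()
    rng = np.random.default_rng(seed)
    table, labels = _simulate(rng, spec, n_events, sample_id)
    return (table, labels) if return_labels else table


@dataclass(frozen=True)
class SeriesSpec:
    """Abundance schedule over time: linear drift plus an optional changepoint.

    The ground-truth fraction vector at step t (0-based) is
    ``base + t * drift`` before the changepoint and
    ``replacement + (t - changepoint) * drift`` from the changepoint on,
    renormalized to the simplex at every step.
    """

    base: CommunitySpec
    n_steps: int
    drift: tuple[float, ...] = ()
    changepoint: int | None = None
    replacement: tuple[float, ...] | None = None

    def schedule(self) -> np.ndarray:
        """Ground-truth (renormalized) abundance vectors, one row per step."""
        if self.n_steps < 2:
            raise ValueError("a series needs at least 2 steps")
        k = len(self.base.components)
        drift = np.zeros(k) if not self.drift else np.asarray(self.drift, float)
        if drift.shape != (k,):
            raise ValueError("drift vector length must match component count")
        if (self.changepoint is None) != (self.replacement is None):
            raise ValueError("changepoint and replacement go together")
        if self.changepoint is not None and not (
            0 < self.changepoint < self.n_steps
        ):
            raise ValueError("changepoint must be an interior step index")
        rows = []
        for t in range(self.n_steps):
            if self.changepoint is not None and t >= self.changepoint:
                f = np.asarray(self.replacement, float) + (t - self.changepoint) * drift
            else:
                f = self.base.fractions + t * drift
            if np.any(f < 0):
                raise ValueError(f"schedule yields negative abundance at step {t}")
            if f.sum() <= 0:
                raise ValueError(f"schedule yields all-zero abundances at step {t}")
            rows.append(f / f.sum())
        return np.array(rows)


@dataclass
class SeriesResult:
    tables: list[EventTable]
    abundances: np.ndarray  # ground truth, n_steps x n_components
    labels: list[np.ndarray] = field(default_factory=list)


def simulate_series(
    spec: SeriesSpec, n_events_per_step: int, seed: int, id_prefix: str = "t"
) -> SeriesResult:
    """One sample per time step following the drift/changepoint schedule."""
    schedule = spec.schedule()
    spec.base.validate()
    rng = np.random.default_rng(seed)
    tables, labels = [], []
    for t, fractions in enumerate(schedule):
        step_spec = spec.base.with_fractions(fractions)
        table, lab = _simulate(rng, step_spec, n_events_per_step, f"{id_prefix}{t}")
        tables.append(table)
        labels.append(lab)
    return SeriesResult(tables, schedule, labels)


@dataclass
class GroupsResult:
    tables: list[EventTable]
    labels: list[str]  # group label per table, e.g. "A"/"B"

    def by_group(self, label: str) -> list[EventTable]:
        return [t for t, g in zip(self.tables, self.labels) if g == label]


def simulate_groups(
    spec_a: CommunitySpec,
    spec_b: CommunitySpec,
    reps: int,
    n_events: int,
    seed: int,
) -> GroupsResult:
    """Two groups of replicate samples (an inoculum-style design).

    Replicate-to-replicate variation comes from resampling alone; identical
    specs give a valid null fixture in which the labels carry no information.
    """
    if reps < 2:
        raise ValueError("need at least 2 replicates per group")
    spec_a.validate()
    spec_b.validate()
    rng = np.random.default_rng(seed)
    tables, labels = [], []
    for label, spec in (("A", spec_a), ("B", spec_b)):
        for r in range(reps):
            table, _ = _simulate(rng, spec, n_events, f"{label}{r + 1}")
            tables.append(table)
            labels.append(label)
    return GroupsResult(tables, labels)


# --- reference community specs ------------------------------------------
#
# Fixed study conditions used by the examples, tests and the acceptance
# script. Cluster scales mirror DAPI-stained community fingerprints on
# log-scaled channels: tight dominant clusters (sigma ~ 0.02-0.04 in [0,1]
# units), a visible proliferation satellite, and abundances spanning an
# order of magnitude.


def _iso(s: float) -> tuple[tuple[float, float], tuple[float, float]]:
    return ((s * s, 0.0), (0.0, s * s))


#: Broad low-abundance component emulating debris, noise and rare
#: populations — present in every real DAPI fingerprint and responsible for
#: most of its informative-pixel background.
_BACKGROUND = Component((0.5, 0.5), _iso(0.25), 0.05, 0.0)


def specialist_community() -> CommunitySpec:
    """Few distinct clusters of strongly unequal abundance — a specialized
    community. Its fingerprint shows isolated sharp peaks over a sparse
    background: few occupied positions (low Rr) whose intensities are very
    unevenly distributed (high So)."""
    return CommunitySpec([
        Component((0.35, 0.40), _iso(0.050), 0.59, 0.10),
        Component((0.55, 0.55), _iso(0.050), 0.285, 0.05),
        Component((0.70, 0.35), _iso(0.045), 0.075, 0.0),
        _BACKGROUND,
    ])


def diverse_community() -> CommunitySpec:
    """Many broad, overlapping clusters of similar abundance — a diverse
    community. The clusters merge into an even carpet: most histogram
    positions occupied (high Rr) at comparatively uniform intensity
    (low So)."""
    means = [(x, y) for x in (0.25, 0.45, 0.65, 0.85) for y in (0.3, 0.5, 0.7)]
    f = 0.95 / len(means)
    return CommunitySpec(
        [Component(m, _iso(0.15), f, 0.05) for m in means] + [_BACKGROUND]
    )


def two_group_specs(separation: float = 0.18) -> tuple[CommunitySpec, CommunitySpec]:
    """Two communities whose cluster means differ by ``separation`` channel
    units (many sigma for the default scales) — the inoculum-group design."""
    a = CommunitySpec([
        Component((0.30, 0.35), _iso(0.020), 0.55, 0.08),
        Component((0.55, 0.55), _iso(0.025), 0.30, 0.0),
        Component((0.75, 0.30), _iso(0.020), 0.15, 0.0),
    ])
    b = CommunitySpec([
        Component((0.30 + separation, 0.35 + separation), _iso(0.020), 0.55, 0.08),
        Component((0.55 - separation, 0.55 + separation), _iso(0.025), 0.30, 0.0),
        Component((0.75 - separation, 0.30 + separation), _iso(0.020), 0.15, 0.0),
    ])
    return a, b


# --- emulated operator gating -------------------------------------------


def component_gate(comp: Component, name: str, k_sigma: float = 3.0) -> Gate:
    """Ellipse gate at +/- k_sigma along the component's principal axes."""
    cov = comp.cov_array()
    evals, evecs = np.linalg.eigh(cov)
    angle = float(np.arctan2(evecs[1, 1], evecs[0, 1]))  # major axis direction
    semi = k_sigma * np.sqrt(evals)
    return Gate(
        name=name,
        shape="ellipse",
        center=tuple(float(v) for v in comp.mean),
        semi_axes=(float(semi[1]), float(semi[0])),
        rotation=angle,
    )


def operator_gate_sets(
    tables: list[EventTable],
    spec: CommunitySpec,
    labels: list[np.ndarray] | None = None,
    min_fraction: float = 0.05,
    k_sigma: float = 3.0,
) -> list[GateSet]:
    """Emulate the operator who encircles the *most abundant* clusters.

    For each sample a component receives a gate only when its event fraction
    reaches ``min_fraction`` — rare clusters go ungated, exactly as a human
    analyst would skip faint blots. Fractions come from ground-truth labels
    when given, otherwise from gate-membership counts.
    """
    gates = [component_gate(c, f"C{k + 1}", k_sigma) for k, c in enumerate(spec.components)]
    sets = []
    for i, t in enumerate(tables):
        kept = []
        for k, g in enumerate(gates):
            if labels is not None:
                frac = float(np.mean(labels[i] == k))
            else:
                frac = float(np.count_nonzero(g.contains(t.xy("FSC", "DNA")))) / t.n_events
            if frac >= min_fraction:
                kept.append(g)
        sets.append(GateSet(sample_id=t.sample_id, gates=kept))
    return sets
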