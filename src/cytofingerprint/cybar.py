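"""CyBar — cytometric barcoding over an experiment-wide gate template.

The template's per-gate cell abundances, extracted from every sample, form
the abundance matrix. For the barcode heat map each gate column is normalized
to log2 fold change against the gate's geometric mean across samples (with a
small pseudo-abundance so empty gates stay finite), which puts high- and
low-abundance gates on one scale. Sample dissimilarity uses Bray-Curtis on
the raw relative abundances; *index subcommunities* — gates whose abundance
tracks an external parameter such as current density or biomass — are found
by Spearman correlation with a permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .dissim import DissimilarityMatrix
from .events import EventTable
from .gating import GateTemplate, apply_template

__all__ = [
    "AbundanceMatrix",
    "BarcodeMatrix",
    "ExternalParameters",
    "GateCorrelation",
    "abundance_table",
    "normalize_cybar",
    "cybar_matrix",
    "correlate_gates",
    "plot_barcode",
]

log = logging.getLogger(__name__)


@dataclass
class AbundanceMatrix:
    """Samples x gates relative abundances (gate count / sample event count)."""

    samples: list[str]
    gates: list[str]
    values: np.ndarray
    n_events: np.ndarray = field(default=None)  # per-sample totals

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.gates)):
            raise ValueError("abundance matrix shape mismatch")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("relative abundances must lie in [0, 1]")
        if self.n_events is None:
            self.n_events = np.zeros(len(self.samples), dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.gates)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class BarcodeMatrix:
    """Samples x gates log2 fold changes vs the per-gate geometric mean."""

    samples: list[str]
    gates: list[str]
    values: np.ndarray
    epsilon: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.gates)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class ExternalParameters:
    """Per-sample numeric covariates (e.g. j_max, coulombic efficiency, biomass)."""

    samples: list[str]
    table: pd.DataFrame  # index = samples, one column per covariate

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExternalParameters":
        return cls([str(s) for s in df.index], df.astype(float))

    @classmethod
    def from_tsv(cls, path, sample_col: str = "sample_id",
                 drop: tuple[str, ...] = ("order",)) -> "ExternalParameters":
        df = pd.read_csv(path, sep="\t").set_index(sample_col)
        df = df.drop(columns=[c for c in drop if c in df.columns])
        return cls.from_frame(df)

    @property
    def names(self) -> list[str]:
        return [str(c) for c in self.table.columns]

    def values_for(self, name: str, samples: list[str]) -> np.ndarray:
        return self.table.loc[samples, name].to_numpy(dtype=float)


def abundance_table(
    samples: list[EventTable], tpl: GateTemplate
) -> AbundanceMatrix:
    """Relative abundance of every template gate in every sample."""
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    rows, totals = [], []
    for t in samples:
        counts, _ = apply_template(t, tpl)
        rows.append(counts / t.n_events)
        totals.append(t.n_events)
    values = np.vstack(rows)
    for j, name in enumerate(tpl.names):
        if np.all(values[:, j] == 0):
            log.warning("gate %r contains no cells in any sample", name)
    return AbundanceMatrix([t.sample_id for t in samples], tpl.names, values,
                           n_events=np.asarray(totals))


def normalize_cybar(
    a: AbundanceMatrix, epsilon: float | None = None
) -> BarcodeMatrix:
    """Per-gate log2 fold change against the gate's geometric mean.

    value(s, g) = log2((a_sg + eps) / gmean_s(a_sg + eps)). Each column's
    log mean is 0, a gate constant across samples maps to an all-zero column,
    and scaling a gate's abundances by any factor leaves its column unchanged.
    The default pseudo-abundance eps is one cell in the largest sample.
    """
    if epsilon is None:
        mx = int(a.n_events.max()) if a.n_events.max() > 0 else 0
        epsilon = 1.0 / mx if mx else 1e-6
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    shifted = np.log2(a.values + epsilon)
    values = shifted - shifted.mean(axis=0, keepdims=True)
    return BarcodeMatrix(list(a.samples), list(a.gates), values, epsilon=epsilon)


def cybar_matrix(
    a: AbundanceMatrix, metric: str = "bray_curtis"
) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity between samples' relative-abundance rows."""
    if metric != "bray_curtis":
        raise ValueError(f"unsupported metric {metric!r}")
    if np.any(a.values.sum(axis=1) == 0):
        empty = [s for s, row in zip(a.samples, a.values) if row.sum() == 0]
        raise ValueError(f"all-zero abundance rows for samples: {empty}")
    d = squareform(pdist(a.values, metric="braycurtis"))
    return DissimilarityMatrix(list(a.samples), d, method="cybar/bray_curtis")


@dataclass
class GateCorrelation:
    gate: str
    parameter: str
    rho: float | None
    p_value: float | None
    n: int
    reason: str = ""


def _spearman_perm(
    x: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Spearman rho with a two-sided permutation p (add-one estimator)."""
    rx = rankdata(x)
    ry = rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
    rho = float(rxc @ ryc / denom)
    # vectorized null: permute the parameter's ranks
    perms = np.array([rng.permutation(len(y)) for _ in range(n_perm)])
    null = (ryc[perms] @ rxc) / denom
    p = (1 + int(np.count_nonzero(np.abs(null) >= abs(rho) - 1e-12))) / (n_perm + 1)
    return rho, p


def correlate_gates(
    a: AbundanceMatrix,
    p: ExternalParameters,
    n_perm: int = 999,
    seed: int = 0,
) -> list[GateCorrelation]:
    """Spearman correlation of every gate with every external parameter.

    Samples with a missing parameter value are excluded pairwise; constant
    gates or parameters are reported as missing with a reason instead of a
    spurious coefficient. Deterministic for a given seed.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    out: list[GateCorrelation] = []
    for param in p.names:
        y_all = p.values_for(param, a.samples)
        ok = np.isfinite(y_all)
        n_ok = int(ok.sum())
        for j, gate in enumerate(a.gates):
            x = a.values[ok, j]
            y = y_all[ok]
            if n_ok < 4:
                out.append(GateCorrelation(gate, param, None, None, n_ok,
                                           "fewer than 4 samples with data"))
                continue
            if np.all(x == x[0]):
                out.append(GateCorrelation(gate, param, None, None, n_ok,
                                           "gate abundance is constant"))
                continue
            if np.all(y == y[0]):
                out.append(GateCorrelation(gate, param, None, None, n_ok,
                                           "parameter is constant"))
                continue
            rho, pval = _spearman_perm(x, y, n_perm, rng)
            out.append(GateCorrelation(gate, param, rho, pval, n_ok))
    return out


def correlations_to_frame(results: list[GateCorrelation]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gate": r.gate, "parameter": r.parameter, "rho": r.rho,
          "p_value": r.p_value, "n": r.n, "reason": r.reason} for r in results]
    )


def plot_barcode(b: BarcodeMatrix, path=None, ax=None):
    """Barcode-like heat map: gates as rows, samples as columns."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(
            figsize=(max(4, 0.5 * len(b.samples)), max(3, 0.3 * len(b.gates)))
        )
    data = b.values.T  # gates x samples
    vmax = max(1e-9, np.abs(data).max())
    im = ax.imshow(data, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(b.samples)), b.samples, rotation=90)
    ax.set_yticks(range(len(b.gates)), b.gates)
    ax.set_xlabel("sample")
    ax.set_ylabel("gate")
    ax.figure.colorbar(im, ax=ax, label="log2 fold change vs gate mean")
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
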