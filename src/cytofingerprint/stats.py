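"""Ordination and inference downstream of any dissimilarity matrix.

NMDS embeds the samples in k dimensions by minimizing Kruskal stress-1 with
monotone (isotonic) regression of the fitted distances on the dissimilarities
— only the rank order of the dissimilarities matters. Numeric covariates are
fitted as directions in ordination space (envfit) and two ordinations are
compared by Procrustes superposition (protest); both use add-one permutation
p-values, so the minimum attainable p with 999 permutations is 1/1000.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .cybar import ExternalParameters
from .dissim import DissimilarityMatrix

__all__ = [
    "Ordination",
    "EnvfitResult",
    "ProcrustesResult",
    "nmds",
    "envfit",
    "procrustes",
    "within_between",
]

_EPS = 1e-12


@dataclass
class Ordination:
    """An n x k embedding with its Kruskal stress-1."""

    ids: list[str]
    coords: np.ndarray
    stress: float
    k: int = 2
    n_starts: int = 0
    seed: int | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape[0] != len(self.ids):
            raise ValueError("coordinate rows must match sample ids")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, index=self.ids, columns=cols)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# stress={self.stress!r} k={self.k} "
                     f"n_starts={self.n_starts} seed={self.seed}\n")
            self.to_frame().to_csv(fh, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "Ordination":
        stress = 0.0
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    key, _, val = tok.partition("=")
                    if key == "stress":
                        stress = float(val)
                df = pd.read_csv(fh, sep="\t", index_col=0)
            else:
                import io

                df = pd.read_csv(io.StringIO(first + fh.read()), sep="\t",
                                 index_col=0)
        return cls([str(s) for s in df.index], df.to_numpy(float),
                   stress=stress, k=df.shape[1])


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson double-centering initialization."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = eigh(b)
    order = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[order], 0, None)
    return evecs[:, order] * np.sqrt(lam)


def kruskal_stress(d: np.ndarray, coords: np.ndarray) -> float:
    """Stress-1 with primary treatment of ties.

    Disparities are the isotonic (pool-adjacent-violators) regression of the
    configuration distances on the dissimilarities; tied dissimilarities may
    take different disparities (ties broken by distance order).
    """
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    diss = d[iu]
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))[iu]
    order = np.lexsort((dist, diss))  # primary ties: untie by distance
    fitted = IsotonicRegression().fit_transform(
        np.arange(len(diss)), dist[order]
    )
    dhat = np.empty_like(dist)
    dhat[order] = fitted
    denom = (dist ** 2).sum()
    if denom <= _EPS:
        return 0.0
    return float(np.sqrt(((dist - dhat) ** 2).sum() / denom))


def nmds(
    d: DissimilarityMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-9,
    seed: int = 0,
) -> Ordination:
    """Non-metric MDS: best of a classical-scaling start plus random starts.

    Returns the lowest-stress solution, with coordinates centered. An
    all-zero matrix yields a degenerate zero-stress solution with a warning.
    """
    n = d.n
    if n == 2:
        # both points on a line, separated by the lone dissimilarity
        half = d.values[0, 1] / 2
        coords = np.array([[-half] + [0.0] * (k - 1), [half] + [0.0] * (k - 1)])
        return Ordination(list(d.ids), coords, 0.0, k=k, n_starts=0, seed=seed)
    if n < 2:
        raise ValueError("NMDS needs at least 2 samples")
    if k >= n:
        raise ValueError("embedding dimension k must be smaller than n")
    if np.all(d.values == 0):
        warnings.warn("all-zero dissimilarity matrix: degenerate NMDS solution",
                      stacklevel=2)
        return Ordination(list(d.ids), np.zeros((n, k)), 0.0, k=k,
                          n_starts=0, seed=seed, converged=False)
    rng = np.random.default_rng(seed)
    inits = [_classical_scaling(d.values, k)]
    inits += [rng.standard_normal((n, k)) for _ in range(n_starts)]
    best_coords, best_stress = None, np.inf
    for init in inits:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords, _ = smacof(
                d.values, metric=False, n_components=k, init=init, n_init=1,
                max_iter=max_iter, eps=tol, normalized_stress=True,
            )
        s = kruskal_stress(d.values, coords)
        if s < best_stress:
            best_stress, best_coords = s, coords
    best_coords = best_coords - best_coords.mean(axis=0, keepdims=True)
    return Ordination(list(d.ids), best_coords, best_stress, k=k,
                      n_starts=n_starts, seed=seed)


@dataclass
class EnvfitResult:
    """One covariate fitted as a direction in ordination space."""

    name: str
    direction: np.ndarray | None
    r_squared: float | None
    p_value: float | None
    n_used: int
    reason: str = ""


def _fit_r2(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit of centered covariate y on centered coords x."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    yhat = x @ beta
    r2 = min(1.0, float((yhat ** 2).sum() / (y ** 2).sum()))
    return beta, r2


def envfit(
    o: Ordination,
    p: ExternalParameters,
    n_perm: int = 999,
    seed: int = 0,
) -> list[EnvfitResult]:
    """Fit each numeric covariate as the direction of steepest increase.

    r^2 is the squared multiple correlation of the covariate with the
    ordination coordinates; significance permutes the covariate across
    samples, p = (1 + #{r^2* >= r^2}) / (n_perm + 1). Samples missing a
    covariate value are excluded for that covariate.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    out: list[EnvfitResult] = []
    for name in p.names:
        y_all = p.values_for(name, o.ids)
        ok = np.isfinite(y_all)
        n_ok = int(ok.sum())
        if n_ok < 3:
            out.append(EnvfitResult(name, None, None, None, n_ok,
                                    "fewer than 3 samples with data"))
            continue
        y = y_all[ok]
        if np.all(y == y[0]):
            out.append(EnvfitResult(name, None, None, None, n_ok,
                                    "covariate is constant"))
            continue
        x = o.coords[ok]
        x = x - x.mean(axis=0)
        yc = y - y.mean()
        beta, r2 = _fit_r2(x, yc)
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else beta
        # vectorized permutation null: project permuted covariates on coords
        xtx_inv = np.linalg.pinv(x.T @ x)
        proj = x @ xtx_inv @ x.T  # hat matrix, n x n
        perms = np.array([rng.permutation(n_ok) for _ in range(n_perm)])
        yp = yc[perms]  # n_perm x n
        null = np.einsum("pn,nm,pm->p", yp, proj, yp) / (yc ** 2).sum()
        pval = (1 + int(np.count_nonzero(null >= r2 - _EPS))) / (n_perm + 1)
        out.append(EnvfitResult(name, direction, r2, pval, n_ok))
    return out


@dataclass
class ProcrustesResult:
    """Optimal superposition of ordination b onto a."""

    m_squared: float  # standardized residual sum of squares, in [0, 1]
    correlation: float  # sqrt(1 - m_squared)
    p_value: float | None = None
    n_perm: int = 0
    seed: int | None = None


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0, keepdims=True)
    norm = np.sqrt((x ** 2).sum())
    if norm <= _EPS:
        raise ValueError("degenerate configuration (all points coincide)")
    return x / norm


def _protest_stat(xs: np.ndarray, ys: np.ndarray) -> float:
    """Sum of singular values of Ys'Xs = sqrt(1 - m^2) for standardized inputs."""
    return float(np.linalg.svd(ys.T @ xs, compute_uv=False).sum())


def procrustes(
    a: Ordination,
    b: Ordination,
    n_perm: int = 999,
    seed: int = 0,
) -> ProcrustesResult:
    """Procrustes comparison with a permutation test (protest).

    b is superimposed on a by optimal translation, orthogonal rotation
    (reflections allowed) and isotropic scaling; the standardized residual
    m^2 and correlation sqrt(1 - m^2) quantify agreement. Significance
    permutes b's sample labels. ``n_perm=0`` skips the test.
    """
    if set(a.ids) != set(b.ids):
        raise ValueError("ordinations carry different sample ids")
    if len(a.ids) < 3:
        raise ValueError("Procrustes needs at least 3 samples")
    b = b if b.ids == a.ids else _reorder_ordination(b, a.ids)
    xs = _standardize(a.coords)
    ys = _standardize(b.coords)
    t = _protest_stat(xs, ys)
    m2 = max(0.0, 1.0 - t ** 2)
    corr = min(1.0, t)
    if n_perm == 0:
        return ProcrustesResult(m2, corr)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99 (or 0 to skip the test)")
    rng = np.random.default_rng(seed)
    n = len(a.ids)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    yp = ys[perms]  # n_perm x n x k — row permutation keeps standardization
    m = np.einsum("nk,pnj->pjk", xs, yp)  # Yp' Xs per permutation
    null = np.linalg.svd(m, compute_uv=False).sum(axis=1)
    p = (1 + int(np.count_nonzero(null >= t - _EPS))) / (n_perm + 1)
    return ProcrustesResult(m2, corr, p, n_perm=n_perm, seed=seed)


def _reorder_ordination(o: Ordination, ids: list[str]) -> Ordination:
    idx = [o.ids.index(s) for s in ids]
    return Ordination(list(ids), o.coords[idx], o.stress, o.k,
                      o.n_starts, o.seed, o.converged)


def within_between(
    d: DissimilarityMatrix, groups: dict[str, str]
) -> tuple[float, float]:
    """Mean within-group and between-group dissimilarity."""
    within, between = [], []
    for i in range(d.n):
        for j in range(i + 1, d.n):
            same = groups[d.ids[i]] == groups[d.ids[j]]
            (within if same else between).append(d.values[i, j])
    return float(np.mean(within)), float(np.mean(between))


def plot_nmds(o: Ordination, groups: dict[str, str] | None = None, path=None,
              ax=None):
    """Basic NMDS scatter; samples sharing a group get a convex hull."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xy = o.coords[:, :2]
    ax.scatter(xy[:, 0], xy[:, 1], color="k", zorder=3)
    for sid, (x, y) in zip(o.ids, xy):
        ax.annotate(sid, (x, y), fontsize=8, xytext=(3, 3),
                    textcoords="offset points")
    if groups:
        from scipy.spatial import ConvexHull

        for g in sorted(set(groups.values())):
            pts = xy[[i for i, s in enumerate(o.ids) if groups[s] == g]]
            if len(pts) >= 3:
                hull = ConvexHull(pts)
                poly = pts[np.append(hull.vertices, hull.vertices[0])]
                ax.plot(poly[:, 0], poly[:, 1], color="gray", alpha=0.6)
    ax.set_xlabel("NMDS1")
    ax.set_ylabel("NMDS2")
    ax.set_title(f"stress = {o.stress:.3f}")
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
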