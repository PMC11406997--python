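"""Procrustes superimposition and the PROTEST permutation test.

Two multivariate views of the same hosts -- device-performance metrics
and differential-expression profiles -- are each projected onto their
first two principal components, then superimposed by centering, scaling
to unit sum of squares, and the optimal rotation/reflection (symmetric
Procrustes).  The residual sum of squares after superimposition is the
Gower statistic

    m2 = 1 - (sigma_1 + sigma_2 + ...)**2

where sigma_i are the singular values of the cross-product of the two
normalized configurations; smaller m2 means more concordant geometries.
Significance uses the PROTEST statistic t = sqrt(1 - m2): rows of one
configuration are permuted, t recomputed, and the add-one p-value
p = (1 + #{t_perm >= t_obs}) / (n_perm + 1) reported.  For six hosts all
719 non-identity orderings can be enumerated, so 719 permutations make
the test exact.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Configuration2D",
    "ProcrustesResult",
    "pca_project",
    "procrustes_m2",
    "protest",
    "per_category_concordance",
]


@dataclass
class Configuration2D:
    """Items embedded in a low-dimensional ordination (column means 0)."""

    item_ids: list
    coords: np.ndarray
    variance_explained: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape[0] < 3:
            raise ValueError("need >= 3 items for a configuration")


@dataclass
class ProcrustesResult:
    m2: float
    t_stat: float
    p_value: float = np.nan
    n_perm: int = 0
    seed: int | None = None
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    rotation: np.ndarray = field(default_factory=lambda: np.eye(2))
    scaling: float = 1.0
    item_ids: list = field(default_factory=list)
    exhaustive: bool = False


def pca_project(
    matrix: pd.DataFrame, n_components: int = 2, scale: bool = False
) -> Configuration2D:
    """Project items (rows) onto their first principal components.

    Columns are centered; with ``scale=True`` they are also divided by
    their standard deviation (correlation-mode PCA), appropriate when
    features carry heterogeneous units.  All-zero columns are dropped
    first.  The sign of each component is fixed so its largest-magnitude
    loading is positive.  Rank-deficient inputs get zero-filled trailing
    components with a warning.
    """
    if matrix.shape[0] < 3:
        raise ValueError("need >= 3 items for PCA")
    X = np.asarray(matrix, dtype=float)
    X = X[:, (X != 0).any(axis=0)]
    if X.shape[1] < 2:
        raise ValueError("need >= 2 non-zero features")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        X = X[:, keep] / sd[keep]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((s**2).sum())
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    k = min(n_components, s.size)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k]
    # deterministic sign: largest-magnitude loading of each PC is positive
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i] < 0:
            loadings[j] *= -1
            scores[:, j] *= -1
    if k < n_components or rank < n_components:
        warnings.warn(
            f"input rank {rank} < {n_components}: trailing components are zero",
            stacklevel=2,
        )
        pad = np.zeros((X.shape[0], n_components - k))
        scores = np.hstack([scores, pad])
        s = np.concatenate([s, np.zeros(n_components - k)])
    var_exp = (s[:n_components] ** 2) / total if total > 0 else s[:n_components] * 0
    return Configuration2D(list(matrix.index), scores, var_exp)


def _as_coords(conf) -> tuple[list, np.ndarray]:
    if isinstance(conf, Configuration2D):
        return conf.item_ids, conf.coords
    arr = np.asarray(conf, dtype=float)
    return list(range(arr.shape[0])), arr


def _normalize(X: np.ndarray) -> np.ndarray:
    """Center and scale to unit sum of squares (symmetric Procrustes)."""
    X = X - X.mean(axis=0)
    norm = np.sqrt((X**2).sum())
    if norm == 0:
        raise ValueError("degenerate configuration: all points identical")
    return X / norm


def procrustes_m2(X, Y, scale: bool = True, symmetric: bool = True) -> ProcrustesResult:
    """Gower m2 after optimal superimposition of Y onto X.

    Both configurations are centered; under the symmetric form both are
    scaled to unit sum of squares before the optimal rotation (reflection
    allowed) and uniform scaling of Y are applied.  m2 is the residual
    sum of squares, bounded in [0, 1] under symmetric scaling; per-item
    residual vector lengths are returned for diagnostic plots.
    """
    ids_x, Xc = _as_coords(X)
    ids_y, Yc = _as_coords(Y)
    if Xc.shape != Yc.shape:
        raise ValueError("configurations must have identical shape")
    if list(ids_x) != list(ids_y):
        raise ValueError("configurations must carry the same items in the same order")
    if Xc.shape[0] < 3:
        raise ValueError("need >= 3 items")
    if not symmetric:
        warnings.warn("asymmetric form not standard here; using symmetric", stacklevel=2)
    Xs = _normalize(Xc)
    Ys = _normalize(Yc)
    U, sv, Vt = np.linalg.svd(Xs.T @ Ys)
    R = Vt.T @ U.T  # rotation (possibly improper) applied as Ys @ R
    trace = float(sv.sum())
    c = trace if scale else 1.0
    Yrot = c * (Ys @ R)
    resid = Xs - Yrot
    m2 = float((resid**2).sum())
    m2 = max(m2, 0.0)
    return ProcrustesResult(
        m2=m2,
        t_stat=math.sqrt(max(1.0 - m2, 0.0)),
        residuals=np.sqrt((resid**2).sum(axis=1)),
        rotation=R,
        scaling=c,
        item_ids=list(ids_x),
    )


def _nuclear_norms(M: np.ndarray) -> np.ndarray:
    """Sum of singular values for a batch of small matrices (P, d, d)."""
    return np.linalg.svd(M, compute_uv=False).sum(axis=-1)


def protest(
    X,
    Y,
    n_perm: int = 719,
    seed=None,
    scale: bool = True,
) -> ProcrustesResult:
    """Permutation test of Procrustes concordance (PROTEST).

    Rows of ``Y`` are reordered, t = sqrt(1 - m2) recomputed, and the
    add-one p-value reported.  With <= 7 items every non-identity
    permutation is enumerated (for 6 items: 719, making n_perm = 719 an
    exact test); larger configurations fall back to uniform sampling of
    ``n_perm`` permutations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    base = procrustes_m2(X, Y, scale=scale)
    _, Xc = _as_coords(X)
    _, Yc = _as_coords(Y)
    Xs = _normalize(Xc)
    Ys = _normalize(Yc)
    n = Xs.shape[0]

    rng = np.random.default_rng(seed)
    exhaustive = n <= 7
    if exhaustive:
        perms = np.array(
            [p for p in itertools.permutations(range(n)) if p != tuple(range(n))]
        )
        n_perm = len(perms)
    else:
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    # permuting rows of a centered matrix keeps it centered and unit-SS,
    # so t for each permutation is the nuclear norm of Xs' @ Ys[perm]
    M = np.einsum("ij,pik->pjk", Xs, Ys[perms])
    t_perm = _nuclear_norms(M)
    t_obs = base.t_stat
    p = (1.0 + int((t_perm >= t_obs - 1e-12).sum())) / (n_perm + 1.0)

    base.p_value = float(p)
    base.n_perm = int(n_perm)
    base.seed = seed
    base.exhaustive = exhaustive
    return base


def per_category_concordance(
    logfc_matrix: pd.DataFrame,
    cluster_cog: pd.Series,
    performance: Configuration2D,
    n_perm: int = 719,
    seed=None,
    alpha: float = 0.05,
    scale_pca: bool = False,
) -> pd.DataFrame:
    """PROTEST of each COG category's expression submatrix vs performance.

    For every category the hosts x clusters log2FC submatrix is projected
    to two principal components and tested against the performance
    configuration.  Categories whose submatrix has fewer than two
    informative (non-zero) clusters are reported as untestable rather
    than raising.  Raw p-values are reported with a significance flag at
    ``alpha``; no multiplicity correction is applied by default.
    """
    cats = cluster_cog.reindex(logfc_matrix.columns).fillna("NA")
    records = []
    for cat in sorted(cats.unique()):
        cols = logfc_matrix.columns[(cats == cat).to_numpy()]
        sub = logfc_matrix[cols]
        informative = (sub != 0).any(axis=0).sum()
        if informative < 2:
            records.append(
                {
                    "cog_category": cat,
                    "n_clusters": int(len(cols)),
                    "testable": False,
                    "m2": np.nan,
                    "t_stat": np.nan,
                    "p_value": np.nan,
                }
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            conf = pca_project(sub, scale=scale_pca)
        res = protest(performance, conf, n_perm=n_perm, seed=seed)
        records.append(
            {
                "cog_category": cat,
                "n_clusters": int(len(cols)),
                "testable": True,
                "m2": res.m2,
                "t_stat": res.t_stat,
                "p_value": res.p_value,
            }
        )
    out = pd.DataFrame.from_records(records)
    out["significant"] = out["p_value"] < alpha
    return out
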