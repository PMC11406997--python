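"""Ranking gene clusters by cross-host expression differentiation.

A cluster is "differentiated" when hosts disagree about its response to
the device's induction states.  Three components capture this:

* ``n_sig`` -- how many hosts express it significantly differentially;
* ``s_abs`` -- the summed magnitude of those responses,
  sum_h |log2FC_h|;
* ``s_pairwise`` -- the combinatorial sum of between-host differences,
  sum_{i<j} |log2FC_i - log2FC_j|.

Non-significant or absent host entries count as 0 (matching the masked
log2FC matrix).  Each component is ranked descending (average ranks for
ties) and the default combiner ranks clusters by the sum of the three
component ranks -- a scale-free aggregation across heterogeneous
components; a weighted sum of the raw components is available as an
alternative.  Final ties break by ``s_abs`` descending, then cluster id.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["score_clusters", "top_differentiated"]


def score_clusters(
    logfc_matrix: pd.DataFrame,
    significance_mask: pd.DataFrame | None = None,
    pairs_require_both_significant: bool = False,
    weights: tuple[float, float, float] | None = None,
) -> pd.DataFrame:
    """Differentiation scores and ranks for every cluster (column).

    Parameters
    ----------
    logfc_matrix
        Hosts x clusters log2FC with non-significant cells already 0.
    significance_mask
        Optional hosts x clusters boolean matrix; defaults to
        ``logfc_matrix != 0``.
    pairs_require_both_significant
        Restrict ``s_pairwise`` to host pairs where both entries are
        significant (default: pairs with one masked host contribute
        |log2FC| of the other).
    weights
        When given, clusters are ordered by the weighted sum
        ``w1*n_sig + w2*s_abs + w3*s_pairwise`` instead of the sum of
        component ranks.
    """
    if logfc_matrix.shape[1] == 0:
        raise ValueError("empty log2FC matrix")
    M = logfc_matrix.to_numpy(dtype=float)
    if significance_mask is None:
        sig = M != 0
    else:
        sig = (
            significance_mask.reindex(
                index=logfc_matrix.index, columns=logfc_matrix.columns
            )
            .fillna(False)
            .to_numpy(dtype=bool)
        )
    vals = np.where(sig, M, 0.0)

    n_sig = sig.sum(axis=0)
    s_abs = np.abs(vals).sum(axis=0)
    diff = np.abs(vals[:, None, :] - vals[None, :, :])
    if pairs_require_both_significant:
        pair_ok = sig[:, None, :] & sig[None, :, :]
        diff = np.where(pair_ok, diff, 0.0)
    iu = np.triu_indices(M.shape[0], k=1)
    s_pairwise = diff[iu].sum(axis=0)

    rank_n = rankdata(-n_sig, method="average")
    rank_a = rankdata(-s_abs, method="average")
    rank_p = rankdata(-s_pairwise, method="average")
    if weights is None:
        key = rank_n + rank_a + rank_p
        ascending = True
    else:
        w1, w2, w3 = weights
        key = w1 * n_sig + w2 * s_abs + w3 * s_pairwise
        ascending = False

    out = pd.DataFrame(
        {
            "n_sig": n_sig.astype(int),
            "s_abs": s_abs,
            "s_pairwise": s_pairwise,
            "rank_n_sig": rank_n,
            "rank_s_abs": rank_a,
            "rank_s_pairwise": rank_p,
            "rank_sum": rank_n + rank_a + rank_p,
        },
        index=logfc_matrix.columns,
    )
    out.index.name = "cluster_id"
    # unique combined rank: key, then s_abs descending, then cluster id
    sort_key = key if ascending else -key
    order = np.lexsort(
        (out.index.to_numpy(), -out["s_abs"].to_numpy(), sort_key)
    )
    combined = np.empty(len(out), dtype=int)
    combined[order] = np.arange(1, len(out) + 1)
    out["combined_rank"] = combined
    return out.sort_values("combined_rank")


def top_differentiated(scores: pd.DataFrame, n: int = 100) -> pd.DataFrame:
    """First ``n`` clusters by combined rank (all if fewer are available)."""
    if n > len(scores):
        import warnings

        warnings.warn(
            f"requested top {n} of {len(scores)} clusters: returning all",
            stacklevel=2,
        )
    return scores.nsmallest(min(n, len(scores)), "combined_rank")
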