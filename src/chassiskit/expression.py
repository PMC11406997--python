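"""Cluster-level differential expression across hosts.

Cross-species comparison works at the level of orthologous gene clusters:
read counts of all gene calls belonging to one cluster are pooled per
sample, making counts comparable between genomes with different gene
complements.  Differential expression between the two induction states
(Ara vs aTc) is then tested per host with a deliberately simple negative
binomial Wald stage:

1. median-of-ratios size factors;
2. per-cluster method-of-moments dispersion, shrunk in log space toward
   a fitted mean-dispersion trend ``alpha(mu) = a0 + a1/mu``;
3. Wald statistic log2FC / SE with a two-sided normal p-value;
4. Benjamini-Hochberg adjustment over all tested clusters of one host.

This stage is calibrated by simulation (see the test suite); numerical
equivalence with any particular published DE engine is not a goal.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from chassiskit.pangenome import ACCESSORY, CORE, UNIQUE

__all__ = [
    "pool_counts",
    "compute_tpm",
    "size_factors",
    "nb_wald_test",
    "build_logfc_matrix",
    "significance_mask",
    "deg_frequency_enrichment",
    "deg_cog_distribution",
]


def pool_counts(
    counts: pd.DataFrame, cluster_map: pd.Series, on_unmapped: str = "error"
) -> pd.DataFrame:
    """Pool gene-call counts to gene-cluster level.

    Parameters
    ----------
    counts
        Gene calls x samples integer counts.
    cluster_map
        Series mapping gene_call_id -> cluster_id (many-to-one).
    on_unmapped
        ``"error"`` (default) or ``"drop"`` gene calls missing from the map.

    The pooled table conserves per-sample totals over mapped gene calls
    exactly (integer equality).
    """
    mapped = counts.index.isin(cluster_map.index)
    if not mapped.all():
        missing = list(counts.index[~mapped][:5])
        if on_unmapped == "error":
            raise KeyError(f"gene calls missing from cluster map, e.g. {missing}")
        if on_unmapped != "drop":
            raise ValueError(f"unknown on_unmapped={on_unmapped!r}")
        warnings.warn(
            f"dropping {int((~mapped).sum())} unmapped gene calls", stacklevel=2
        )
        counts = counts.loc[mapped]
    clusters = cluster_map.reindex(counts.index)
    pooled = counts.groupby(clusters.to_numpy()).sum()
    pooled.index.name = "cluster_id"
    return pooled


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million; columns sum to 1e6.

    TPM_g = (count_g / length_kb_g) / sum_h(count_h / length_kb_h) * 1e6.
    All-zero samples have no defined TPM and come back as NaN columns
    with a warning.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("every gene call needs a length")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths / 1e3, axis=0)
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        warnings.warn(
            f"samples with zero counts have undefined TPM: {list(denom.index[zero])}",
            stacklevel=2,
        )
        denom = denom.replace(0, np.nan)
    return rate.div(denom, axis=1) * 1e6


def size_factors(cluster_counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, geometric mean 1.

    Each sample's factor is the median, over clusters with nonzero counts
    in every sample, of its count divided by the cluster's geometric
    mean.  When no cluster is nonzero everywhere, falls back to
    library-size ratios with a warning.
    """
    mat = cluster_counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if all_nonzero.any():
        sub = mat[all_nonzero]
        log_geo = np.log(sub).mean(axis=1, keepdims=True)
        sf = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    else:
        warnings.warn(
            "no cluster observed in every sample: using library-size factors",
            stacklevel=2,
        )
        lib = mat.sum(axis=0)
        if (lib == 0).any():
            raise ValueError("cannot normalize samples with zero total counts")
        sf = lib
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=cluster_counts.columns, name="size_factor")


def _dispersion_trend(mu, alpha_mom):
    """Fit alpha(mu) = a0 + a1/mu by least squares on moment estimates."""
    keep = (alpha_mom > 1e-6) & (mu > 0)
    if keep.sum() < 10:
        return np.full_like(mu, max(float(np.median(alpha_mom)), 1e-6))
    X = np.column_stack([np.ones(keep.sum()), 1.0 / mu[keep]])
    coef, *_ = np.linalg.lstsq(X, alpha_mom[keep], rcond=None)
    a0, a1 = np.maximum(coef, 0.0)
    trend = a0 + a1 / np.maximum(mu, 1e-8)
    return np.maximum(trend, 1e-6)


def nb_wald_test(
    cluster_counts: pd.DataFrame,
    condition: pd.Series,
    alpha: float = 0.05,
    shrinkage: float = 0.9,
    pseudo_mean: float = 0.5,
) -> pd.DataFrame:
    """Negative binomial Wald test of condition effect per cluster.

    Parameters
    ----------
    cluster_counts
        Clusters x samples pooled integer counts.
    condition
        Series sample -> condition label with exactly two levels; the
        log2 fold-change reported is level_1 vs level_2 in sorted label
        order (``"Ara"`` vs ``"aTc"`` in the standard design).
    alpha
        BH significance threshold.
    shrinkage
        Weight in [0, 1] of the fitted mean-dispersion trend in the
        log-space shrinkage of the per-cluster moment dispersion.
    pseudo_mean
        Pseudo-count added to normalized group means so clusters
        expressed in only one condition get finite estimates.

    Clusters with all-zero counts are excluded from testing and from the
    BH family; the returned frame contains only tested clusters, with
    columns base_mean, log2fc, lfc_se, stat, p_value, p_adj, significant.
    """
    condition = condition.reindex(cluster_counts.columns)
    if condition.isna().any():
        raise ValueError("every sample needs a condition label")
    levels = sorted(condition.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {levels}")
    g1 = condition == levels[0]
    g2 = condition == levels[1]
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("need >= 2 replicates per condition")

    tested = cluster_counts.loc[cluster_counts.sum(axis=1) > 0]
    sf = size_factors(tested)
    norm = tested.to_numpy(dtype=float) / sf.to_numpy()

    n1, n2 = int(g1.sum()), int(g2.sum())
    y1, y2 = norm[:, g1.to_numpy()], norm[:, g2.to_numpy()]
    mu1, mu2 = y1.mean(axis=1), y2.mean(axis=1)
    mu = norm.mean(axis=1)

    # pooled within-condition variance -> moment dispersion
    ss = ((y1 - mu1[:, None]) ** 2).sum(axis=1) + ((y2 - mu2[:, None]) ** 2).sum(axis=1)
    var_within = ss / (n1 + n2 - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_mom = (var_within - mu) / mu**2
    alpha_mom = np.clip(np.nan_to_num(alpha_mom), 1e-8, 10.0)
    trend = _dispersion_trend(mu, alpha_mom)
    log_alpha = (1.0 - shrinkage) * np.log(alpha_mom) + shrinkage * np.log(trend)
    disp = np.exp(log_alpha)

    m1 = mu1 + pseudo_mean
    m2 = mu2 + pseudo_mean
    log2fc = np.log2(m1 / m2)
    # delta-method SE of log2 group-mean ratio under NB sampling
    se = np.sqrt((1.0 / m1 + disp) / n1 + (1.0 / m2 + disp) / n2) / np.log(2)
    stat = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(stat))
    p_adj = stats.false_discovery_control(p, method="bh")

    out = pd.DataFrame(
        {
            "base_mean": mu,
            "log2fc": log2fc,
            "lfc_se": se,
            "stat": stat,
            "p_value": p,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
            "dispersion": disp,
        },
        index=tested.index,
    )
    out.index.name = "cluster_id"
    return out


def _scope_clusters(groups: pd.DataFrame, scope: str) -> pd.Index:
    if scope == "all":
        return groups.index
    if scope == CORE:
        return groups.index[groups["group"] == CORE]
    if scope == ACCESSORY:
        # accessory without unique clusters, which would artificially
        # inflate between-host distances (each is nonzero in one host only)
        return groups.index[(groups["group"] == ACCESSORY) & ~groups["is_unique"]]
    raise ValueError(f"unknown scope {scope!r}")


def build_logfc_matrix(
    de_results: dict[str, pd.DataFrame],
    groups: pd.DataFrame,
    scope: str = "all",
) -> pd.DataFrame:
    """Hosts x clusters log2FC matrix with non-significant cells zeroed.

    Cells where a host's cluster is absent or not significant carry
    exactly 0; ``scope`` restricts columns to ``"core"`` or
    ``"accessory"`` (the latter excluding unique clusters).  Clusters
    zero in every host are dropped.
    """
    clusters = _scope_clusters(groups, scope)
    hosts = sorted(de_results)
    mat = pd.DataFrame(0.0, index=hosts, columns=clusters)
    for host in hosts:
        de = de_results[host]
        sig = de.loc[de["significant"]]
        common = sig.index.intersection(clusters)
        mat.loc[host, common] = sig.loc[common, "log2fc"].to_numpy()
    mat = mat.loc[:, (mat != 0).any(axis=0)]
    if mat.shape[1] == 0:
        raise ValueError(f"no clusters with significant signal under scope {scope!r}")
    mat.index.name = "host"
    return mat


def significance_mask(
    de_results: dict[str, pd.DataFrame], clusters: pd.Index
) -> pd.DataFrame:
    """Hosts x clusters boolean matrix of significant differential expression."""
    hosts = sorted(de_results)
    mask = pd.DataFrame(False, index=hosts, columns=clusters)
    for host in hosts:
        de = de_results[host]
        sig = de.index[de["significant"]].intersection(clusters)
        mask.loc[host, sig] = True
    return mask


def deg_frequency_enrichment(
    de_results: dict[str, pd.DataFrame],
    groups: pd.DataFrame,
    universe: str = "expressed",
) -> pd.DataFrame:
    """Fisher tests of DEG over/under-representation per frequency group.

    For each host and frequency group (core / accessory / unique) a 2x2
    table of (DEG vs non-DEG) x (in group vs not) is tested one-sided in
    both directions.  The background is the host's expressed (tested)
    clusters by default, or every cluster of the pangenome with
    ``universe="genome"``.
    """
    from chassiskit.pangenome import _fisher_one_sided

    records = []
    for host in sorted(de_results):
        de = de_results[host]
        if universe == "expressed":
            background = de.index
        elif universe == "genome":
            background = groups.index
        else:
            raise ValueError(f"unknown universe {universe!r}")
        degs = de.index[de["significant"]]
        if len(degs) == 0:
            warnings.warn(f"host {host}: empty DEG set, tests skipped", stacklevel=2)
            continue
        is_deg = background.isin(degs)
        sub = groups.reindex(background)
        for group_label in (CORE, ACCESSORY, UNIQUE):
            if group_label == UNIQUE:
                in_group = sub["is_unique"].to_numpy()
            else:
                in_group = (sub["group"] == group_label).to_numpy()
            a = int((is_deg & in_group).sum())
            b = int((is_deg & ~in_group).sum())
            c = int((~is_deg & in_group).sum())
            d = int((~is_deg & ~in_group).sum())
            odds, p_enrich, p_deplete = _fisher_one_sided(a, b, c, d)
            records.append(
                {
                    "host": host,
                    "group": group_label,
                    "n_deg_in_group": a,
                    "n_deg": a + b,
                    "n_group": a + c,
                    "n_background": a + b + c + d,
                    "odds_ratio": odds,
                    "p_enrich": p_enrich,
                    "p_deplete": p_deplete,
                }
            )
    return pd.DataFrame.from_records(records)


def deg_cog_distribution(
    de_results: dict[str, pd.DataFrame],
    cluster_cog: pd.Series,
    groups: pd.DataFrame,
) -> pd.DataFrame:
    """Counts of up/down-regulated DEG clusters per host x COG x group.

    ``cluster_cog`` maps cluster_id -> COG category (``"NA"`` included as
    its own category).  Up = log2FC > 0, down = log2FC < 0 among
    significant clusters.
    """
    records = []
    for host in sorted(de_results):
        de = de_results[host]
        sig = de.loc[de["significant"]]
        cats = cluster_cog.reindex(sig.index).fillna("NA")
        grp = groups.reindex(sig.index)
        frame = pd.DataFrame(
            {
                "cog_category": cats,
                "group": grp["group"],
                "is_unique": grp["is_unique"],
                "up": (sig["log2fc"] > 0).to_numpy(),
                "down": (sig["log2fc"] < 0).to_numpy(),
            }
        )
        agg = (
            frame.groupby(["cog_category", "group"], dropna=False)[["up", "down"]]
            .sum()
            .reset_index()
        )
        agg.insert(0, "host", host)
        records.append(agg)
    if not records:
        return pd.DataFrame(columns=["host", "cog_category", "group", "up", "down"])
    out = pd.concat(records, ignore_index=True)
    out[["up", "down"]] = out[["up", "down"]].astype(int)
    return out
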