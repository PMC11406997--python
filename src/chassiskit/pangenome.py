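"""Pangenome frequency groups, composition summaries, and enrichment.

A pangenome is represented as a clusters x genomes matrix of gene-call
counts (``GeneClusterMatrix`` in the docs): entry ``(c, g)`` is the number
of gene calls genome ``g`` contributes to orthologous gene cluster ``c``.
A cluster is *core* when it has hits in every genome, *accessory*
otherwise, and *unique* (a subset of accessory) when it hits exactly one
genome.  Presence is defined as >= 1 gene call; paralog multiplicity only
affects gene-call tallies, never the binning.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import fisher_exact

logger = logging.getLogger(__name__)

CORE = "core"
ACCESSORY = "accessory"
UNIQUE = "unique"

#: the 23 broad COG functional categories used for annotation
COG_CATEGORIES = tuple("CDEFGHIJKLMNOPQRSTUVWYZ")


def _validate_matrix(matrix: pd.DataFrame) -> None:
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("gene-cluster matrix is empty")
    values = matrix.to_numpy()
    if (values < 0).any():
        raise ValueError("gene-call counts must be non-negative")
    if (values.sum(axis=1) == 0).any():
        raise ValueError("every cluster must have at least one gene call")


def assign_frequency_groups(matrix: pd.DataFrame) -> pd.DataFrame:
    """Bin clusters by genome occupancy and label frequency groups.

    Parameters
    ----------
    matrix
        Clusters x genomes gene-call counts; index = cluster ids,
        columns = genome ids.

    Returns
    -------
    DataFrame indexed like ``matrix`` with columns

    ``bin``
        number of genomes with >= 1 gene call (1..n_genomes),
    ``group``
        ``"core"`` when ``bin == n_genomes`` else ``"accessory"``,
    ``is_unique``
        ``bin == 1`` (always an accessory cluster).
    """
    _validate_matrix(matrix)
    n_genomes = matrix.shape[1]
    occupancy = (matrix.to_numpy() > 0).sum(axis=1)
    groups = pd.DataFrame(
        {
            "bin": occupancy,
            "group": np.where(occupancy == n_genomes, CORE, ACCESSORY),
            "is_unique": occupancy == 1,
        },
        index=matrix.index,
    )
    return groups


def summarize_groups(groups: pd.DataFrame) -> pd.DataFrame:
    """Counts and one-decimal percentages for core / accessory / unique.

    Percentages are taken against the total cluster count, so
    core% + accessory% = 100.0 up to rounding; unique is reported as a
    subset of accessory.
    """
    total = len(groups)
    if total == 0:
        raise ValueError("no clusters to summarize")
    n_core = int((groups["group"] == CORE).sum())
    n_unique = int(groups["is_unique"].sum())
    n_accessory = total - n_core
    rows = [
        (CORE, n_core),
        (ACCESSORY, n_accessory),
        (UNIQUE, n_unique),
    ]
    out = pd.DataFrame(rows, columns=["group", "n_clusters"])
    out["percent"] = (100.0 * out["n_clusters"] / total).round(1)
    out["total_clusters"] = total
    return out


def _fisher_one_sided(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Odds ratio plus one-sided enrichment / depletion p for a 2x2 table."""
    table = [[a, b], [c, d]]
    odds, p_greater = fisher_exact(table, alternative="greater")
    _, p_less = fisher_exact(table, alternative="less")
    return odds, p_greater, p_less


def cog_group_enrichment(
    groups: pd.DataFrame,
    annotations: pd.DataFrame,
    alpha: float = 0.05,
    min_genomes: int = 3,
    unit: str = "gene_call",
) -> pd.DataFrame:
    """Per-genome Fisher tests of COG-category enrichment within frequency groups.

    For every genome x frequency group x COG category a 2x2 table is built
    (units in the group vs the genome's remaining units, in the category
    vs not), and both one-sided Fisher exact tests are run (enrichment =
    over-representation, depletion = under-representation).  P-values are
    Bonferroni-corrected across the categories tested within one
    genome x group family.  A category is flagged *consistently* enriched
    (or depleted) when it is significant in >= ``min_genomes`` genomes.

    Parameters
    ----------
    groups
        Output of :func:`assign_frequency_groups`.
    annotations
        One row per gene call with columns ``gene_call_id``, ``genome``,
        ``cluster_id``, ``cog_category`` (``"NA"`` for unassigned).
    unit
        ``"gene_call"`` (default) counts gene calls; ``"cluster"`` counts
        each cluster once per genome.

    Returns
    -------
    Tidy DataFrame with one row per genome x group x category.
    """
    if unit not in ("gene_call", "cluster"):
        raise ValueError(f"unknown unit {unit!r}")
    ann = annotations.merge(
        groups[["group", "is_unique"]], left_on="cluster_id", right_index=True
    )
    if unit == "cluster":
        ann = ann.drop_duplicates(["genome", "cluster_id"])

    records = []
    group_labels = [CORE, ACCESSORY, UNIQUE]
    for genome, sub in ann.groupby("genome", sort=True):
        categories = sorted(sub["cog_category"].unique())
        n_tests = len(categories)
        for group_label in group_labels:
            if group_label == UNIQUE:
                in_group = sub["is_unique"].to_numpy()
            else:
                in_group = (sub["group"] == group_label).to_numpy()
            for cat in categories:
                in_cat = (sub["cog_category"] == cat).to_numpy()
                if not in_cat.any():
                    logger.warning(
                        "category %s absent from genome %s: skipped", cat, genome
                    )
                    continue
                a = int((in_group & in_cat).sum())
                b = int((in_group & ~in_cat).sum())
                c = int((~in_group & in_cat).sum())
                d = int((~in_group & ~in_cat).sum())
                odds, p_enrich, p_deplete = _fisher_one_sided(a, b, c, d)
                records.append(
                    {
                        "genome": genome,
                        "group": group_label,
                        "cog_category": cat,
                        "n_in_group_in_cat": a,
                        "n_in_group": a + b,
                        "n_in_cat": a + c,
                        "n_total": a + b + c + d,
                        "odds_ratio": odds,
                        "p_enrich": p_enrich,
                        "p_deplete": p_deplete,
                        "p_enrich_bonf": min(1.0, p_enrich * n_tests),
                        "p_deplete_bonf": min(1.0, p_deplete * n_tests),
                    }
                )
    result = pd.DataFrame.from_records(records)
    if result.empty:
        return result
    result["significant_enrich"] = result["p_enrich_bonf"] < alpha
    result["significant_deplete"] = result["p_deplete_bonf"] < alpha
    # consistency across genomes: in how many genomes is this (group, cat)
    # significantly enriched / depleted?
    for direction in ("enrich", "deplete"):
        counts = result.groupby(["group", "cog_category"])[
            f"significant_{direction}"
        ].transform("sum")
        result[f"n_genomes_{direction}"] = counts.astype(int)
        result[f"consistent_{direction}"] = counts >= min_genomes
    return result


def hierarchical_cluster(
    matrix: pd.DataFrame, metric: str = "euclidean", method: str = "complete"
) -> dict:
    """Agglomerative clustering of matrix rows (complete linkage, Euclidean).

    Used both for clustering genomes by cluster presence/absence and for
    clustering hosts by their log2 fold-change profiles.  Returns a dict
    with the SciPy ``linkage`` array, the row ``labels``, the ``order`` of
    leaves, and the ``cophenetic`` distance matrix (condensed).
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    data = np.asarray(matrix, dtype=float)
    dist = pdist(data, metric=metric)
    linkage = hierarchy.linkage(dist, method=method)
    coph = hierarchy.cophenet(linkage)
    return {
        "linkage": linkage,
        "labels": list(matrix.index),
        "order": list(hierarchy.leaves_list(linkage)),
        "cophenetic": coph,
        "pairwise": dist,
    }


def presence_absence(matrix: pd.DataFrame) -> pd.DataFrame:
    """Genomes x clusters 0/1 presence matrix (rows = genomes)."""
    _validate_matrix(matrix)
    return (matrix > 0).astype(int).T


def pairwise_shared_fraction(matrix: pd.DataFrame) -> pd.DataFrame:
    """Fraction of each genome pair's union of clusters that is shared."""
    pa = presence_absence(matrix).to_numpy().astype(bool)
    genomes = list(matrix.columns)
    n = len(genomes)
    out = np.ones((n, n))
    for i, j in itertools.combinations(range(n), 2):
        inter = np.logical_and(pa[i], pa[j]).sum()
        union = np.logical_or(pa[i], pa[j]).sum()
        out[i, j] = out[j, i] = inter / union if union else np.nan
    return pd.DataFrame(out, index=genomes, columns=genomes)
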