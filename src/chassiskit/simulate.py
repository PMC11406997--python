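"""Synthetic chassis-effect study with planted ground truth.

Generates every input the analysis pipeline consumes -- a pangenome of
orthologous gene clusters across several host genomes, RNA-seq gene-call
counts in a two-condition (Ara vs aTc) replicated design, plate-reader
induction/toggle/growth curves -- together with the truth behind them:
per-host per-cluster log2 fold-changes, the planted differential
expression flags, and a latent two-dimensional factor per host that
couples device-performance metrics to the core-genome expression
response.

The coupling is the point of the generator.  Each host h carries a
latent vector L_h in R^2; with concordance strength ``c`` the
performance block uses Z_perf = sqrt(c) L + sqrt(1-c) E_perf and the
core-expression block Z_expr = sqrt(c) L + sqrt(1-c) E_expr, with
independent host-level noise E.  Both blocks map their latents through
matrices with orthonormal rows, i.e. similarity transforms, so that at
c = 1 with no measurement noise the two configurations have identical
geometry (Procrustes m2 = 0 exactly), and at c = 0 they are independent
(the PROTEST null holds).  Recovering the planted concordance through
the full pipeline is therefore a well-posed end-to-end check.

All randomness flows from a single master seed through named substreams
(pangenome, counts, curves, coupling), so each stage is independently
reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chassiskit import kinetics
from chassiskit.pangenome import ACCESSORY, COG_CATEGORIES, CORE, assign_frequency_groups

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "ConcordancePlan",
    "nb_counts",
    "simulate_pangenome",
    "plant_concordance",
    "simulate_counts",
    "simulate_curves",
    "simulate_study",
]


def nb_counts(rng: np.random.Generator, mean, dispersion: float, size=None):
    """Negative binomial draws with mean ``mean`` and var mean + disp*mean^2."""
    n = 1.0 / dispersion
    p = n / (n + np.asarray(mean, dtype=float))
    return rng.negative_binomial(n, p, size=size)

#: COG categories treated as housekeeping-associated; their frequency is
#: skewed upward in the core genome so enrichment tests have signal.
HOUSEKEEPING_COGS = tuple("JKLCEFGHI")

#: device-performance metrics with plausible base values (units in name)
METRIC_BASES = {
    "beta_Ara_rfu": 3000.0,
    "K_Ara_mM": 0.2,
    "n_Ara": 2.0,
    "C_Ara_rfu": 300.0,
    "beta_aTc_rfu": 2000.0,
    "K_aTc_nM": 10.0,
    "n_aTc": 1.5,
    "C_aTc_rfu": 250.0,
    "mu_per_h": 0.6,
    "A_ln": 3.0,
    "lag_h": 2.0,
}

#: log-scale spread of each metric across hosts (geometric CV ~ 25%)
METRIC_LOG_SD = 0.25

ARA_CONCENTRATIONS = (0.0, 0.005, 0.02, 0.05, 0.1, 0.25, 0.75, 2.0)  # mM
ATC_CONCENTRATIONS = (0.0, 0.5, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0)  # nM


@dataclass
class SimConfig:
    """Study design and noise parameters for the synthetic generator.

    Defaults emulate the study design the package targets: six host
    genomes, a pangenome of 6,469 clusters split 42.5% core / 31.1%
    unique, biological triplicates per induction state, negative binomial
    counts, and 5% multiplicative plate-reader noise.
    """

    n_genomes: int = 6
    n_clusters: int = 6469
    core_fraction: float = 0.425
    unique_fraction: float = 0.311
    genes_per_cluster_mean: float = 1.05
    nb_mean_log_range: tuple[float, float] = (1.0, 3.0)
    nb_dispersion: float = 0.1
    n_replicates: int = 3
    de_fraction_core: float = 0.15
    de_fraction_accessory: float = 0.05
    planted_log2fc_magnitude: float = 2.0
    concordance_strength: float = 0.9
    curve_noise_cv: float = 0.05
    cog_skew: float = 3.0
    cog_na_weight: float = 0.23
    seed: int = 0

    def __post_init__(self):
        for name in (
            "core_fraction",
            "unique_fraction",
            "de_fraction_core",
            "de_fraction_accessory",
            "concordance_strength",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.core_fraction + self.unique_fraction > 1.0:
            raise ValueError("core_fraction + unique_fraction must be <= 1")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        if self.n_genomes < 2:
            raise ValueError("need >= 2 genomes")
        if self.genes_per_cluster_mean < 1:
            raise ValueError("genes_per_cluster_mean must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.curve_noise_cv < 0:
            raise ValueError("curve_noise_cv must be >= 0")
        if self.planted_log2fc_magnitude < 0:
            raise ValueError("planted_log2fc_magnitude must be >= 0")

    @property
    def genome_ids(self) -> list[str]:
        return [f"host_{i + 1}" for i in range(self.n_genomes)]

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream off the master seed (order-independent)."""
        key = zlib.crc32(stream.encode())
        return np.random.default_rng(np.random.SeedSequence([self.seed, key]))


@dataclass
class ConcordancePlan:
    latent_factors: pd.DataFrame  # hosts x 2
    true_performance: pd.DataFrame  # hosts x metrics, natural units
    log_performance_z: pd.DataFrame  # hosts x metrics, latent log deviations
    core_lfc: pd.DataFrame  # hosts x planted core clusters (unlabeled cols)


@dataclass
class SimulatedStudy:
    config: SimConfig
    pangenome: pd.DataFrame
    annotations: pd.DataFrame
    groups: pd.DataFrame
    cluster_cog: pd.Series
    counts: dict
    truth: pd.DataFrame
    curves: pd.DataFrame
    true_performance: pd.DataFrame
    latent_factors: pd.DataFrame
    hill_params: pd.DataFrame
    gompertz_params: pd.DataFrame
    growth_burden: pd.DataFrame = field(default=None)


# ---------------------------------------------------------------------------
# pangenome


def _cog_weights(group: str, config: SimConfig) -> np.ndarray:
    """Category sampling weights (23 categories + NA), skewed by group."""
    w = np.full(len(COG_CATEGORIES) + 1, (1.0 - config.cog_na_weight) / len(COG_CATEGORIES))
    w[-1] = config.cog_na_weight
    hk = np.array([c in HOUSEKEEPING_COGS for c in COG_CATEGORIES] + [False])
    if group == CORE:
        w[hk] *= config.cog_skew
        w[-1] /= config.cog_skew
    elif group == "unique":
        w[hk] /= config.cog_skew
        w[-1] *= config.cog_skew
    return w / w.sum()


def simulate_pangenome(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the clusters x genomes gene-call matrix and annotations.

    Cluster counts per frequency group are exact after rounding the
    requested fractions; accessory (non-unique) clusters draw an
    occupancy size uniformly from {2..n_genomes-1} and a uniform random
    genome subset.  Each occupied genome contributes
    1 + Poisson(genes_per_cluster_mean - 1) gene calls.  Every cluster
    gets one of the 23 COG categories or "NA", with housekeeping
    categories enriched in the core and "NA" in unique clusters.

    Returns the matrix and a one-row-per-gene-call annotation table
    (gene_call_id, genome, cluster_id, cog_category).
    """
    rng = config.rng("pangenome")
    g = config.n_genomes
    n = config.n_clusters
    n_core = int(round(config.core_fraction * n))
    n_unique = int(round(config.unique_fraction * n))
    if n_core + n_unique > n:
        raise ValueError("rounded core + unique cluster counts exceed n_clusters")
    n_multi = n - n_core - n_unique
    if g == 2 and n_multi > 0:
        raise ValueError("accessory multi-genome clusters impossible with 2 genomes")

    occupancy = np.zeros((n, g), dtype=bool)
    occupancy[:n_core] = True
    uniq_rows = np.arange(n_core, n_core + n_unique)
    occupancy[uniq_rows, rng.integers(0, g, size=n_unique)] = True
    for row in range(n_core + n_unique, n):
        size = int(rng.integers(2, g))  # uniform over {2..g-1}
        cols = rng.choice(g, size=size, replace=False)
        occupancy[row, cols] = True

    calls = np.zeros((n, g), dtype=int)
    extra = rng.poisson(config.genes_per_cluster_mean - 1.0, size=(n, g))
    calls[occupancy] = 1 + extra[occupancy]

    cluster_ids = [f"GC_{i:05d}" for i in range(1, n + 1)]
    matrix = pd.DataFrame(calls, index=cluster_ids, columns=config.genome_ids)
    matrix.index.name = "cluster_id"

    group_of = np.array(
        [CORE] * n_core + ["unique"] * n_unique + [ACCESSORY] * n_multi
    )
    cats = np.array(list(COG_CATEGORIES) + ["NA"])
    cluster_cog = np.empty(n, dtype=object)
    for grp in (CORE, "unique", ACCESSORY):
        idx = np.flatnonzero(group_of == grp)
        cluster_cog[idx] = rng.choice(cats, size=len(idx), p=_cog_weights(grp, config))

    records = []
    for j, genome in enumerate(config.genome_ids):
        rows = np.flatnonzero(calls[:, j] > 0)
        reps = calls[rows, j]
        cl = np.repeat(np.array(cluster_ids, dtype=object)[rows], reps)
        cg = np.repeat(cluster_cog[rows], reps)
        ids = [f"{genome}|call{k:06d}" for k in range(len(cl))]
        records.append(
            pd.DataFrame(
                {
                    "gene_call_id": ids,
                    "genome": genome,
                    "cluster_id": cl,
                    "cog_category": cg,
                }
            )
        )
    annotations = pd.concat(records, ignore_index=True)
    return matrix, annotations


# ---------------------------------------------------------------------------
# latent coupling


def _orthonormal_rows(rng: np.random.Generator, k: int, m: int) -> np.ndarray:
    """k x m matrix with orthonormal rows (a similarity-preserving map)."""
    Q, _ = np.linalg.qr(rng.standard_normal((m, k)))
    return Q[:, :k].T


def plant_concordance(
    config: SimConfig, n_core_de: int, rng: np.random.Generator | None = None
) -> ConcordancePlan:
    """Draw host latents and couple performance metrics to core log2FCs.

    ``n_core_de`` is the number of planted differentially expressed core
    clusters whose hosts x clusters log2FC block is generated from the
    expression-side latents.  The block is scaled so its root mean
    square entry equals ``planted_log2fc_magnitude``.
    """
    if rng is None:
        rng = config.rng("coupling")
    g = config.n_genomes
    c = config.concordance_strength
    L = rng.standard_normal((g, 2))
    E_perf = rng.standard_normal((g, 2))
    E_expr = rng.standard_normal((g, 2))
    Z_perf = np.sqrt(c) * L + np.sqrt(1.0 - c) * E_perf
    Z_expr = np.sqrt(c) * L + np.sqrt(1.0 - c) * E_expr

    metrics = list(METRIC_BASES)
    W_perf = _orthonormal_rows(rng, 2, len(metrics))
    log_z = METRIC_LOG_SD * (Z_perf @ W_perf)
    base = np.array([METRIC_BASES[m] for m in metrics])
    perf = pd.DataFrame(
        base * np.exp(log_z), index=config.genome_ids, columns=metrics
    )

    if n_core_de > 0:
        V = _orthonormal_rows(rng, 2, max(n_core_de, 2))[:, :n_core_de]
        block = Z_expr @ V
        rms = np.sqrt(np.mean(block**2))
        if rms > 0:
            block = block * (config.planted_log2fc_magnitude / rms)
    else:
        block = np.zeros((g, 0))
    core_lfc = pd.DataFrame(block, index=config.genome_ids)

    return ConcordancePlan(
        latent_factors=pd.DataFrame(
            L, index=config.genome_ids, columns=["latent_1", "latent_2"]
        ),
        true_performance=perf,
        log_performance_z=pd.DataFrame(log_z, index=config.genome_ids, columns=metrics),
        core_lfc=core_lfc,
    )


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    pangenome: pd.DataFrame,
    annotations: pd.DataFrame,
    config: SimConfig,
    plan: ConcordancePlan | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Draw gene-call count tables per genome with planted log2FCs.

    Per cluster a baseline mean is drawn log-uniform over
    ``nb_mean_log_range`` (log10 counts).  Planted core clusters take
    their per-host log2FC from the concordance plan; planted accessory
    clusters get independent +/- ``planted_log2fc_magnitude`` shifts per
    host.  Cluster totals are negative binomial (dispersion
    ``nb_dispersion``) and split multinomially across the genome's gene
    calls in that cluster, so pooling recovers the totals exactly.

    Returns ``(counts, truth)``: ``counts[genome]`` is a dict with keys
    ``counts`` (gene calls x samples), ``design`` (sample, condition,
    replicate) and ``lengths``; ``truth`` has one row per occupied
    genome x cluster with ``true_log2fc`` and ``is_de``.
    """
    rng = config.rng("counts")
    groups = assign_frequency_groups(pangenome)
    clusters = pangenome.index
    n = len(clusters)

    base_mean = 10.0 ** rng.uniform(*config.nb_mean_log_range, size=n)
    base_mean = pd.Series(base_mean, index=clusters)

    core_ids = clusters[groups["group"] == CORE]
    acc_ids = clusters[groups["group"] == ACCESSORY]
    n_core_de = int(round(config.de_fraction_core * len(core_ids)))
    n_acc_de = int(round(config.de_fraction_accessory * len(acc_ids)))
    if config.planted_log2fc_magnitude == 0:
        n_core_de = n_acc_de = 0
    de_core = pd.Index(rng.choice(core_ids, size=n_core_de, replace=False))
    de_acc = pd.Index(rng.choice(acc_ids, size=n_acc_de, replace=False))

    if plan is None:
        plan = plant_concordance(config, n_core_de)
    if plan.core_lfc.shape[1] != n_core_de:
        raise ValueError("concordance plan does not match the planted core DE count")

    lfc = pd.DataFrame(0.0, index=config.genome_ids, columns=clusters)
    if n_core_de:
        lfc.loc[:, de_core] = plan.core_lfc.to_numpy()
    if n_acc_de:
        signs = rng.choice([-1.0, 1.0], size=(config.n_genomes, n_acc_de))
        lfc.loc[:, de_acc] = signs * config.planted_log2fc_magnitude

    n_rep = config.n_replicates
    sample_names = [f"Ara_{r + 1}" for r in range(n_rep)] + [
        f"aTc_{r + 1}" for r in range(n_rep)
    ]
    conditions = ["Ara"] * n_rep + ["aTc"] * n_rep
    disp = config.nb_dispersion

    counts_out = {}
    truth_rows = []
    for genome in config.genome_ids:
        occupied = pangenome[genome] > 0
        occ_ids = clusters[occupied]
        mu0 = base_mean[occ_ids].to_numpy()
        l2 = lfc.loc[genome, occ_ids].to_numpy()
        mu_ara = mu0 * 2.0 ** (l2 / 2.0)
        mu_atc = mu0 * 2.0 ** (-l2 / 2.0)
        mus = np.column_stack([np.repeat(mu_ara[:, None], n_rep, 1),
                               np.repeat(mu_atc[:, None], n_rep, 1)])
        totals = nb_counts(rng, mus, disp)

        ann = annotations[annotations["genome"] == genome]
        # annotation rows are emitted in cluster order per genome, so the
        # gene calls of occ_ids[i] are the i-th contiguous block
        id_blocks = ann.groupby("cluster_id", sort=False)["gene_call_id"].agg(list)
        n_calls_per_cluster = pangenome.loc[occ_ids, genome].to_numpy()
        call_rows = []
        call_ids = []
        for ci, (cid, m_calls) in enumerate(zip(occ_ids, n_calls_per_cluster)):
            if m_calls == 1:
                call_rows.append(totals[ci][None, :])
            else:
                split = np.column_stack(
                    [
                        rng.multinomial(t, np.full(m_calls, 1.0 / m_calls))
                        for t in totals[ci]
                    ]
                )
                call_rows.append(split)
            call_ids.extend(id_blocks[cid])
        call_counts = np.vstack(call_rows)
        counts_df = pd.DataFrame(call_counts, index=call_ids, columns=sample_names)
        counts_df.index.name = "gene_call_id"
        design = pd.DataFrame(
            {
                "sample": sample_names,
                "condition": conditions,
                "replicate": list(range(1, n_rep + 1)) * 2,
            }
        )
        lengths = pd.Series(
            rng.integers(200, 3000, size=len(call_ids)),
            index=call_ids,
            name="length_bp",
        )
        counts_out[genome] = {
            "counts": counts_df,
            "design": design,
            "lengths": lengths,
            # simulated cluster totals (before the multinomial gene-call
            # split); pooling the call counts must reproduce these exactly
            "cluster_totals": pd.DataFrame(
                totals, index=occ_ids, columns=sample_names
            ),
        }
        truth_rows.append(
            pd.DataFrame(
                {
                    "cluster_id": occ_ids,
                    "genome": genome,
                    "true_log2fc": l2,
                    "is_de": occ_ids.isin(de_core) | occ_ids.isin(de_acc),
                }
            )
        )
    truth = pd.concat(truth_rows, ignore_index=True)
    return counts_out, truth


# ---------------------------------------------------------------------------
# curves


TIME_GRID = np.round(np.arange(0.0, 24.0 + 1e-9, 1.0 / 6.0), 6)  # 10-min steps


def _noise(rng, cv, shape):
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(-(sigma**2) / 2.0, sigma, size=shape)


def _rise(t, tau=1.0):
    """Saturating onset of reporter expression (fraction of steady state)."""
    return 1.0 - np.exp(-np.asarray(t) / tau)


def simulate_curves(
    config: SimConfig,
    hill_params: pd.DataFrame,
    gompertz_params: pd.DataFrame,
    growth_burden: pd.DataFrame | None = None,
    n_induction_replicates: int = 8,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Forward-simulate plate-reader time series from fitted-model forms.

    ``hill_params`` has one row per host x inducer with columns
    ``host, inducer, beta, K, n, C``; ``gompertz_params`` one row per
    host with ``A_ln`` (log-scale span), ``mu`` (1/h) and ``lag`` (h).
    OD600 follows OD0 * exp(Gompertz) so the rolling log-slope equals
    mu; OD-normalized fluorescence approaches its steady state with a
    1-hour rise constant.  All observations are multiplied by lognormal
    noise with coefficient of variation ``curve_noise_cv``.

    Returns a long-format table with columns well, host, assay, channel,
    condition, inducer, concentration, time_h, value.
    """
    if rng is None:
        rng = config.rng("curves")
    for col in ("beta", "K", "n", "C"):
        if (hill_params[col] <= 0).any():
            raise ValueError(f"Hill parameter {col} must be positive")
    if (gompertz_params[["A_ln", "mu"]] <= 0).to_numpy().any():
        raise ValueError("Gompertz A and mu must be positive")
    if (gompertz_params["lag"] < 0).any():
        raise ValueError("lag must be >= 0")

    t = TIME_GRID
    cv = config.curve_noise_cv
    frames = []
    well = 0

    def emit(host, assay, channel, condition, inducer, conc, values):
        nonlocal well
        well += 1
        frames.append(
            pd.DataFrame(
                {
                    "well": f"W{well:04d}",
                    "host": host,
                    "assay": assay,
                    "channel": channel,
                    "condition": condition,
                    "inducer": inducer,
                    "concentration": conc,
                    "time_h": t,
                    "value": values,
                }
            )
        )

    # induction assays: Fss vs concentration, read as fluorescence dynamics
    for _, row in hill_params.iterrows():
        concs = ARA_CONCENTRATIONS if row["inducer"] == "Ara" else ATC_CONCENTRATIONS
        channel = "sfGFP/OD" if row["inducer"] == "Ara" else "mKate/OD"
        for conc in concs:
            fss = kinetics.hill(conc, row["beta"], row["K"], row["n"], row["C"])
            for _ in range(n_induction_replicates):
                values = fss * _rise(t) * _noise(rng, cv, t.shape)
                emit(row["host"], "induction", channel, "induction",
                     row["inducer"], conc, values)

    # growth + toggle assays under NI / Ara / aTc
    hp = hill_params.set_index(["host", "inducer"])
    od0 = 0.02
    for host, gp in gompertz_params.iterrows():
        for condition in ("NI", "Ara", "aTc"):
            burden = (
                1.0
                if growth_burden is None or condition == "NI"
                else float(growth_burden.loc[host, condition])
            )
            mu = gp["mu"] * burden
            for _ in range(3):
                g = kinetics.gompertz_lag(t, gp["A_ln"], mu, gp["lag"], 0.0)
                od = od0 * np.exp(g) * _noise(rng, cv, t.shape)
                emit(host, "growth", "OD600", condition, condition, np.nan, od)
            # toggle fluorescence steady states derived from Hill params
            ara = hp.loc[(host, "Ara")]
            atc = hp.loc[(host, "aTc")]
            targets = {
                "sfGFP/OD": {
                    "NI": ara["C"],
                    "Ara": ara["C"] + ara["beta"],
                    "aTc": 0.7 * ara["C"],
                }[condition],
                "mKate/OD": {
                    "NI": atc["C"],
                    "aTc": atc["C"] + atc["beta"],
                    "Ara": 0.7 * atc["C"],
                }[condition],
            }
            for channel, fss in targets.items():
                for _ in range(3):
                    values = fss * _rise(t) * _noise(rng, cv, t.shape)
                    emit(host, "toggle", channel, condition, condition, np.nan, values)

    return pd.concat(frames, ignore_index=True)


def _hill_param_table(perf: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for host, r in perf.iterrows():
        rows.append(
            {"host": host, "inducer": "Ara", "beta": r["beta_Ara_rfu"],
             "K": r["K_Ara_mM"], "n": r["n_Ara"], "C": r["C_Ara_rfu"]}
        )
        rows.append(
            {"host": host, "inducer": "aTc", "beta": r["beta_aTc_rfu"],
             "K": r["K_aTc_nM"], "n": r["n_aTc"], "C": r["C_aTc_rfu"]}
        )
    return pd.DataFrame(rows)


def _gompertz_param_table(perf: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {"A_ln": perf["A_ln"], "mu": perf["mu_per_h"], "lag": perf["lag_h"]},
        index=perf.index,
    )


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Run the full generator: pangenome, coupling, counts, curves."""
    pangenome, annotations = simulate_pangenome(config)
    groups = assign_frequency_groups(pangenome)
    cluster_cog = (
        annotations.drop_duplicates("cluster_id")
        .set_index("cluster_id")["cog_category"]
        .reindex(pangenome.index)
    )
    n_core = int((groups["group"] == CORE).sum())
    n_core_de = (
        int(round(config.de_fraction_core * n_core))
        if config.planted_log2fc_magnitude > 0
        else 0
    )
    plan = plant_concordance(config, n_core_de)
    counts, truth = simulate_counts(pangenome, annotations, config, plan)

    hill_params = _hill_param_table(plan.true_performance)
    gompertz_params = _gompertz_param_table(plan.true_performance)
    rng_curves = config.rng("curves")
    # induced states carry a small host-specific growth burden
    burden = pd.DataFrame(
        np.exp(-np.abs(rng_curves.normal(0.08, 0.04, size=(config.n_genomes, 2)))),
        index=config.genome_ids,
        columns=["Ara", "aTc"],
    )
    curves = simulate_curves(
        config, hill_params, gompertz_params, growth_burden=burden, rng=rng_curves
    )

    return SimulatedStudy(
        config=config,
        pangenome=pangenome,
        annotations=annotations,
        groups=groups,
        cluster_cog=cluster_cog,
        counts=counts,
        truth=truth,
        curves=curves,
        true_performance=plan.true_performance,
        latent_factors=plan.latent_factors,
        hill_params=hill_params,
        gompertz_params=gompertz_params,
        growth_burden=burden,
    )
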