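"""End-to-end orchestration of the chassis-effect analysis.

Two entry points:

* :func:`run_synthetic_study` -- in-memory end-to-end run on a synthetic
  study: simulate, estimate performance metrics from the curves, run the
  cluster-level DE stage per host, and test performance/expression
  concordance by PROTEST.  Used by the test suite and the acceptance
  script.
* :func:`run_all` -- file-based pipeline: each stage reads the previous
  stage's TSV/CSV outputs from the output directory and writes its own
  before the next starts, finishing with a JSON run manifest (config
  snapshot, seeds, row counts, checksums, warnings).
"""

from __future__ import annotations

import dataclasses
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from chassiskit import concordance, expression, io, kinetics, pangenome, ranking
from chassiskit.simulate import SimConfig, SimulatedStudy, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "chassiskit_run"
    seed: int = 0
    synthetic: dict = field(default_factory=dict)
    fss_window: tuple[float, float] = (6.0, 12.0)
    rolling_h: int = 5
    r2_min: float = 0.95
    alpha: float = 0.05
    n_perm: int = 719
    scopes: tuple[str, ...] = ("core", "accessory")
    top_n: int = 100
    deg_universe: str = "expressed"
    enrichment_unit: str = "gene_call"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fss_window" in raw:
            raw["fss_window"] = tuple(raw["fss_window"])
        if "scopes" in raw:
            raw["scopes"] = tuple(raw["scopes"])
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.synthetic)

    @property
    def inputs(self) -> Path:
        return Path(self.out_dir) / "inputs"

    @property
    def outputs(self) -> Path:
        return Path(self.out_dir) / "outputs"


# ---------------------------------------------------------------------------
# kinetics stage (in-memory core)


def estimate_performance(
    curves: pd.DataFrame,
    fss_window=(6.0, 12.0),
    rolling_h: int = 5,
    r2_min: float = 0.95,
    include_toggle_lag: bool = False,
):
    """Estimate the hosts x metrics performance matrix from plate curves.

    Returns ``(performance, hill_fits, growth_metrics, toggle_metrics)``.
    The performance matrix combines Hill parameters and dynamic ranges
    for both inducers, growth parameters (mu, A, lambda under no
    induction) plus the induced-state growth changes delta-mu, and toggle
    steady states, specific dynamic ranges, and ON-state max specific
    fluorescence rates.  Gompertz growth fits run on the log-OD scale so
    mu is the maximum specific growth rate.
    """
    t0, t1 = fss_window
    win = curves[(curves["time_h"] >= t0) & (curves["time_h"] <= t1)]

    # --- induction: Fss per well -> Hill fit per host x inducer
    ind = win[win["assay"] == "induction"]
    fss = (
        ind.groupby(["host", "inducer", "concentration", "well"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    hill_rows = []
    for (host, inducer), sub in fss.groupby(["host", "inducer"]):
        fit = kinetics.fit_hill(sub["concentration"], sub["value"])
        hill_rows.append(
            {
                "host": host,
                "inducer": inducer,
                "beta": fit.beta,
                "K": fit.K,
                "n": fit.n,
                "C": fit.C,
                "DR": fit.dr,
                "ss_res": fit.ss_res,
                "converged": fit.converged,
            }
        )
    hill_fits = pd.DataFrame(hill_rows)

    # --- growth: mean log-OD curve per host x condition
    growth = curves[curves["assay"] == "growth"]
    growth_rows = []
    for (host, condition), sub in growth.groupby(["host", "condition"]):
        mean_log = np.log(sub.groupby("time_h")["value"].apply(
            lambda v: np.exp(np.log(v).mean())
        ))
        tgrid = mean_log.index.to_numpy()
        od = np.exp(mean_log.to_numpy())
        rate = kinetics.rolling_max_rate(tgrid, od, h=rolling_h, r2_min=r2_min)
        gfit = kinetics.fit_gompertz_lag(tgrid, od, log_input=True, h=rolling_h)
        growth_rows.append(
            {
                "host": host,
                "condition": condition,
                "mu": rate.mu if rate.ok else np.nan,
                "mu_gompertz": gfit.mu,
                "A": gfit.A,
                "lag": gfit.lam,
                "converged": gfit.converged and rate.ok,
            }
        )
    growth_metrics = pd.DataFrame(growth_rows)

    # --- toggle: Fss, DR_S, Rate per host x channel x state
    tog = curves[curves["assay"] == "toggle"]
    tog_win = win[win["assay"] == "toggle"]
    fss_tog = (
        tog_win.groupby(["host", "channel", "condition"], sort=True)["value"]
        .mean()
        .reset_index(name="fss")
    )
    toggle_rows = []
    for (host, channel), sub in fss_tog.groupby(["host", "channel"]):
        by_state = sub.set_index("condition")["fss"]
        baseline = by_state.get("NI", np.nan)
        for state, f in by_state.items():
            series = tog[
                (tog["host"] == host)
                & (tog["channel"] == channel)
                & (tog["condition"] == state)
            ]
            mean_curve = series.groupby("time_h")["value"].mean()
            rate = kinetics.rolling_max_rate(
                mean_curve.index.to_numpy(), mean_curve.to_numpy(),
                h=rolling_h, r2_min=r2_min,
            )
            row = {
                "host": host,
                "channel": channel,
                "state": state,
                "fss": f,
                "dr_s": kinetics.specific_dynamic_range(f, baseline)
                if baseline > 0
                else np.nan,
                "rate": rate.mu if rate.ok else np.nan,
            }
            if include_toggle_lag:
                gfit = kinetics.fit_gompertz_lag(
                    mean_curve.index.to_numpy(), mean_curve.to_numpy()
                )
                row["lag"] = gfit.lam
            toggle_rows.append(row)
    toggle_metrics = pd.DataFrame(toggle_rows)

    # --- assemble hosts x metrics
    perf = {}
    for _, r in hill_fits.iterrows():
        for p in ("beta", "K", "n", "C", "DR"):
            perf.setdefault(f"{p}_{r['inducer']}", {})[r["host"]] = r[p]
    gm = growth_metrics.set_index(["host", "condition"])
    hosts = sorted(curves["host"].unique())
    for host in hosts:
        ni = gm.loc[(host, "NI")]
        perf.setdefault("mu", {})[host] = ni["mu"]
        perf.setdefault("A", {})[host] = ni["A"]
        perf.setdefault("lag", {})[host] = ni["lag"]
        for state in ("Ara", "aTc"):
            if (host, state) in gm.index:
                perf.setdefault(f"dmu_{state}", {})[host] = kinetics.delta_mu(
                    ni["mu"], gm.loc[(host, state), "mu"]
                )
    tm = toggle_metrics.set_index(["host", "channel", "state"])
    for host in hosts:
        for channel, tag in (("sfGFP/OD", "gfp"), ("mKate/OD", "kate")):
            for state in ("Ara", "aTc"):
                key = (host, channel, state)
                if key in tm.index:
                    perf.setdefault(f"fss_{tag}_{state}", {})[host] = tm.loc[key, "fss"]
                    perf.setdefault(f"drs_{tag}_{state}", {})[host] = tm.loc[key, "dr_s"]
        on = (host, "sfGFP/OD", "Ara")
        if on in tm.index:
            perf.setdefault("rate_gfp_on", {})[host] = tm.loc[on, "rate"]
        on = (host, "mKate/OD", "aTc")
        if on in tm.index:
            perf.setdefault("rate_kate_on", {})[host] = tm.loc[on, "rate"]
    performance = pd.DataFrame(perf).loc[hosts]
    performance.index.name = "host"
    return performance, hill_fits, growth_metrics, toggle_metrics


# ---------------------------------------------------------------------------
# DE stage (in-memory core)


def run_de(
    counts_bundle: dict, annotations: pd.DataFrame, alpha: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Pool gene-call counts to clusters and run the NB Wald stage per host."""
    cluster_map = annotations.set_index("gene_call_id")["cluster_id"]
    de_results = {}
    for host, bundle in counts_bundle.items():
        pooled = expression.pool_counts(bundle["counts"], cluster_map)
        cond = bundle["design"].set_index("sample")["condition"]
        de_results[host] = expression.nb_wald_test(pooled, cond, alpha=alpha)
    return de_results


# ---------------------------------------------------------------------------
# concordance stage (in-memory core)


def run_concordance(
    performance: pd.DataFrame,
    de_results: dict,
    groups: pd.DataFrame,
    scopes=("core", "accessory"),
    n_perm: int = 719,
    seed=None,
    cluster_cog: pd.Series | None = None,
):
    """PROTEST of device performance vs expression response per scope.

    The performance matrix is projected in correlation mode (its metrics
    carry heterogeneous units); log2FC matrices in covariance mode.
    Returns ``(report, per_category, configs)``.
    """
    perf_conf = concordance.pca_project(performance, scale=True)
    rows = []
    per_cat = None
    configs = {"performance": perf_conf}
    for scope in scopes:
        try:
            mat = expression.build_logfc_matrix(de_results, groups, scope=scope)
        except ValueError as err:
            warnings.warn(f"scope {scope}: {err}", stacklevel=2)
            continue
        mat = mat.loc[performance.index]
        expr_conf = concordance.pca_project(mat)
        res = concordance.protest(perf_conf, expr_conf, n_perm=n_perm, seed=seed)
        configs[scope] = expr_conf
        rows.append(
            {
                "scope": scope,
                "n_clusters": mat.shape[1],
                "m2": res.m2,
                "t_stat": res.t_stat,
                "p_value": res.p_value,
                "n_perm": res.n_perm,
                "seed": seed,
            }
        )
        if scope == "core" and cluster_cog is not None:
            per_cat = concordance.per_category_concordance(
                mat, cluster_cog, perf_conf, n_perm=n_perm, seed=seed
            )
    return pd.DataFrame(rows), per_cat, configs


# ---------------------------------------------------------------------------
# fully in-memory end-to-end run


def run_synthetic_study(
    config: SimConfig,
    n_perm: int = 719,
    alpha: float = 0.05,
    scopes=("core", "accessory"),
    full: bool = True,
    study: SimulatedStudy | None = None,
) -> dict:
    """Simulate a study and run the complete analysis on it.

    With ``full=False`` only the concordance-critical path runs
    (performance estimation, DE, core-scope PROTEST), which is what the
    repeated end-to-end power checks use.
    """
    if study is None:
        study = simulate_study(config)
    performance, hill_fits, growth_metrics, toggle_metrics = estimate_performance(
        study.curves
    )
    de_results = run_de(study.counts, study.annotations, alpha=alpha)
    report, per_cat, configs = run_concordance(
        performance,
        de_results,
        study.groups,
        scopes=scopes if full else ("core",),
        n_perm=n_perm,
        seed=config.seed,
        cluster_cog=study.cluster_cog if full else None,
    )
    out = {
        "study": study,
        "performance": performance,
        "hill_fits": hill_fits,
        "growth_metrics": growth_metrics,
        "toggle_metrics": toggle_metrics,
        "de_results": de_results,
        "concordance": report,
        "per_category": per_cat,
        "configs": configs,
    }
    if full:
        out["summary"] = pangenome.summarize_groups(study.groups)
        out["enrichment"] = pangenome.cog_group_enrichment(
            study.groups, study.annotations
        )
        out["deg_enrichment"] = expression.deg_frequency_enrichment(
            de_results, study.groups
        )
        logfc_all = expression.build_logfc_matrix(de_results, study.groups, scope="all")
        out["logfc_all"] = logfc_all
        out["ranking"] = ranking.score_clusters(logfc_all)
        out["top100"] = ranking.top_differentiated(out["ranking"], 100)
    return out


# ---------------------------------------------------------------------------
# file-based stages


def _manifest_entry(path: Path) -> dict:
    df = None
    n_rows = None
    try:
        if path.suffix == ".tsv":
            df = pd.read_csv(path, sep="\t")
        elif path.suffix == ".csv":
            df = pd.read_csv(path)
        if df is not None:
            n_rows = int(len(df))
    except Exception:  # pragma: no cover - manifest is best-effort
        pass
    return {"sha256": io.sha256_of(path), "n_rows": n_rows}


def stage_simulate(cfg: PipelineConfig) -> list[Path]:
    study = simulate_study(cfg.sim_config())
    paths = []
    inp = cfg.inputs
    paths.append(io.write_tsv(study.pangenome, inp / "gene_cluster_matrix.tsv"))
    paths.append(io.write_tsv(study.annotations, inp / "annotations.tsv", index=False))
    paths.append(io.write_tsv(study.truth, inp / "truth.tsv", index=False))
    for host, bundle in study.counts.items():
        paths.append(io.write_tsv(bundle["counts"], inp / f"counts_{host}.tsv"))
        paths.append(
            io.write_tsv(bundle["design"], inp / f"design_{host}.tsv", index=False)
        )
        paths.append(io.write_tsv(bundle["lengths"].to_frame(), inp / f"lengths_{host}.tsv"))
    curves_path = inp / "plate_curves.csv"
    curves_path.parent.mkdir(parents=True, exist_ok=True)
    study.curves.to_csv(curves_path, index=False)
    paths.append(curves_path)
    paths.append(io.write_tsv(study.true_performance, inp / "true_performance.tsv"))
    return paths


def stage_partition(cfg: PipelineConfig) -> list[Path]:
    matrix = io.read_cluster_matrix(cfg.inputs / "gene_cluster_matrix.tsv")
    ann = io.read_annotations(cfg.inputs / "annotations.tsv")
    groups = pangenome.assign_frequency_groups(matrix)
    summary = pangenome.summarize_groups(groups)
    enrich = pangenome.cog_group_enrichment(
        groups, ann, alpha=cfg.alpha, unit=cfg.enrichment_unit
    )
    dendro = pangenome.hierarchical_cluster(pangenome.presence_absence(matrix))
    out = cfg.outputs
    paths = [
        io.write_tsv(groups, out / "frequency_groups.tsv"),
        io.write_tsv(summary, out / "pangenome_summary.tsv", index=False),
        io.write_tsv(enrich, out / "cog_enrichment.tsv", index=False),
        io.write_json(
            {
                "labels": dendro["labels"],
                "order": dendro["order"],
                "linkage": dendro["linkage"].tolist(),
            },
            out / "genome_dendrogram.json",
        ),
    ]
    return paths


def stage_kinetics(cfg: PipelineConfig) -> list[Path]:
    curves = io.read_plate_csv(cfg.inputs / "plate_curves.csv")
    performance, hill_fits, growth_metrics, toggle_metrics = estimate_performance(
        curves, fss_window=cfg.fss_window, rolling_h=cfg.rolling_h, r2_min=cfg.r2_min
    )
    out = cfg.outputs
    return [
        io.write_tsv(performance, out / "performance.tsv"),
        io.write_tsv(hill_fits, out / "hill_fits.tsv", index=False),
        io.write_tsv(growth_metrics, out / "growth_metrics.tsv", index=False),
        io.write_tsv(toggle_metrics, out / "toggle_metrics.tsv", index=False),
    ]


def _load_counts_bundle(cfg: PipelineConfig) -> dict:
    bundles = {}
    for counts_path in sorted(cfg.inputs.glob("counts_*.tsv")):
        host = counts_path.stem.removeprefix("counts_")
        bundles[host] = {
            "counts": io.read_counts(counts_path),
            "design": io.read_design(cfg.inputs / f"design_{host}.tsv"),
            "lengths": io.read_lengths(cfg.inputs / f"lengths_{host}.tsv"),
        }
    if not bundles:
        raise FileNotFoundError(f"no counts_*.tsv files under {cfg.inputs}")
    return bundles


def stage_de(cfg: PipelineConfig) -> list[Path]:
    ann = io.read_annotations(cfg.inputs / "annotations.tsv")
    groups = pd.read_csv(cfg.outputs / "frequency_groups.tsv", sep="\t", index_col=0)
    bundles = _load_counts_bundle(cfg)
    de_results = run_de(bundles, ann, alpha=cfg.alpha)
    paths = []
    for host, de in de_results.items():
        paths.append(io.write_tsv(de, cfg.outputs / f"de_{host}.tsv"))
    for scope in ("all", *cfg.scopes):
        try:
            mat = expression.build_logfc_matrix(de_results, groups, scope=scope)
        except ValueError as err:
            logger.warning("scope %s skipped: %s", scope, err)
            continue
        paths.append(io.write_tsv(mat, cfg.outputs / f"logfc_{scope}.tsv"))
    deg_enrich = expression.deg_frequency_enrichment(
        de_results, groups, universe=cfg.deg_universe
    )
    paths.append(io.write_tsv(deg_enrich, cfg.outputs / "deg_enrichment.tsv", index=False))
    return paths


def stage_concord(cfg: PipelineConfig) -> list[Path]:
    performance = pd.read_csv(cfg.outputs / "performance.tsv", sep="\t", index_col=0)
    ann = io.read_annotations(cfg.inputs / "annotations.tsv")
    cluster_cog = ann.drop_duplicates("cluster_id").set_index("cluster_id")[
        "cog_category"
    ]
    perf_conf = concordance.pca_project(performance, scale=True)
    rows = []
    paths = []
    coords = [
        pd.DataFrame(
            perf_conf.coords,
            index=perf_conf.item_ids,
            columns=["PC1", "PC2"],
        ).assign(dataset="performance")
    ]
    per_cat = None
    for scope in cfg.scopes:
        path = cfg.outputs / f"logfc_{scope}.tsv"
        if not path.exists():
            logger.warning("missing %s: scope skipped", path)
            continue
        mat = pd.read_csv(path, sep="\t", index_col=0).loc[performance.index]
        expr_conf = concordance.pca_project(mat)
        res = concordance.protest(
            perf_conf, expr_conf, n_perm=cfg.n_perm, seed=cfg.seed
        )
        rows.append(
            {
                "scope": scope,
                "n_clusters": mat.shape[1],
                "m2": res.m2,
                "t_stat": res.t_stat,
                "p_value": res.p_value,
                "n_perm": res.n_perm,
                "seed": cfg.seed,
            }
        )
        coords.append(
            pd.DataFrame(
                expr_conf.coords, index=expr_conf.item_ids, columns=["PC1", "PC2"]
            ).assign(dataset=f"expression_{scope}")
        )
        if scope == "core":
            per_cat = concordance.per_category_concordance(
                mat, cluster_cog, perf_conf, n_perm=cfg.n_perm, seed=cfg.seed
            )
    paths.append(
        io.write_tsv(pd.DataFrame(rows), cfg.outputs / "concordance.tsv", index=False)
    )
    paths.append(io.write_tsv(pd.concat(coords), cfg.outputs / "ordination_coords.tsv"))
    if per_cat is not None:
        paths.append(
            io.write_tsv(per_cat, cfg.outputs / "per_category_concordance.tsv", index=False)
        )
    return paths


def stage_rank(cfg: PipelineConfig) -> list[Path]:
    path = cfg.outputs / "logfc_all.tsv"
    mat = pd.read_csv(path, sep="\t", index_col=0)
    scores = ranking.score_clusters(mat)
    ann = io.read_annotations(cfg.inputs / "annotations.tsv")
    cluster_cog = ann.drop_duplicates("cluster_id").set_index("cluster_id")[
        "cog_category"
    ]
    scores["cog_category"] = cluster_cog.reindex(scores.index).fillna("NA")
    top = ranking.top_differentiated(scores, cfg.top_n)
    return [
        io.write_tsv(scores, cfg.outputs / "differentiation_scores.tsv"),
        io.write_tsv(top, cfg.outputs / "top_differentiated.tsv"),
    ]


STAGES = {
    "simulate": stage_simulate,
    "partition": stage_partition,
    "kinetics": stage_kinetics,
    "de": stage_de,
    "concord": stage_concord,
    "rank": stage_rank,
}


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage in order and write the run manifest last.

    Any stage error aborts the run; the manifest (written even on
    failure) records which stages completed.
    """
    manifest = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "warnings": [],
    }
    manifest_path = Path(cfg.out_dir) / "manifest.json"
    try:
        for name, stage in STAGES.items():
            start = time.perf_counter()
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                paths = stage(cfg)
            manifest["warnings"].extend(
                f"{name}: {w.message}" for w in caught
            )
            manifest["stages"][name] = {
                "elapsed_s": round(time.perf_counter() - start, 3),
                "outputs": {str(p): _manifest_entry(Path(p)) for p in paths},
            }
            logger.info("stage %s done in %.2fs", name,
                        manifest["stages"][name]["elapsed_s"])
    finally:
        io.write_json(manifest, manifest_path)
    return manifest
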