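"""End-to-end orchestration: simulate/ingest -> normalize -> analyses -> report.

``run_all`` executes the full analysis under a single :class:`RunConfig`,
writing each stage's TSV outputs and a machine-readable JSON report.  The
report carries every seed and parameter used, so a config + report pair
reproduces the run; wall-clock timings go to the log, not the report, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clocks, convergence, enrichment, mortality, trajectories
from .normalization import normalize
from .synthetic import SimulationConfig, simulate_metabolome, simulate_mortality, simulate_network
log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Flat parameter set for an end-to-end run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    output_dir: str = "metaboclock_run"
    # samples excluded from clock fitting and trajectory models
    exclusions: tuple = (("A", 9),)
    comparable_ages: tuple = (21, 28, 35)
    n_pcs: int = 12
    alpha: float = 0.05
    folds: int = 5
    fdr: float = 0.01
    enrichment_fdr: float = 0.05
    min_cluster: int = 4
    k_max: int = 60
    n_init: int = 10
    n_perm: int = 2000
    restart_prob: float = 0.5
    clock_l1_ratios: tuple = clocks.DEFAULT_L1_RATIOS
    clock_n_alphas: int = clocks.DEFAULT_N_ALPHAS
    clock_eps: float = clocks.DEFAULT_EPS
    mortality_params: dict = field(
        default_factory=lambda: {"A": (1e-4, 0.25), "C": (1e-4, 0.10)}
    )
    cohort_size: int = 500
    network_pathways: int = 5
    network_pathway_size: int = 8
    seed: int = 0

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = dataclasses.asdict(self.simulation)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str, t0: float, **info) -> None:
    log.info("stage=%s wall_s=%.2f %s", name, time.time() - t0,
             " ".join(f"{k}={v}" for k, v in info.items()))


def run_all(config: RunConfig) -> dict:
    """Run every stage in order and return the JSON-serializable report.

    A stage failure aborts the run with the failing stage named; outputs of
    completed stages are retained on disk.
    """
    state = {"stage": "init"}
    try:
        return _run_all(config, state)
    except Exception as exc:
        raise RuntimeError(f"pipeline aborted in stage {state['stage']!r}: {exc}") from exc


def _run_all(config: RunConfig, state: dict) -> dict:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_jsonable()}
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        df.to_csv(path, sep="\t", **kw)
        written.append(path)

    # -- simulate ----------------------------------------------------------
    state["stage"] = "simulate"
    t0 = time.time()
    raw, truth = simulate_metabolome(config.simulation)
    raw.write(out / "abundance_raw.tsv", out / "sample_metadata.tsv")
    written += [out / "abundance_raw.tsv", out / "sample_metadata.tsv"]
    save(truth.effects, "ground_truth_effects.tsv")
    _stage("simulate", t0, n_samples=raw.n_samples, n_metabolites=raw.n_metabolites)

    # -- normalize ---------------------------------------------------------
    state["stage"] = "normalize"
    t0 = time.time()
    norm = normalize(raw)
    norm.write(out / "abundance_normalized.tsv", out / "sample_metadata_normalized.tsv")
    written += [out / "abundance_normalized.tsv", out / "sample_metadata_normalized.tsv"]
    _stage("normalize", t0, stage=norm.stage)

    # -- convergence (history divergence + regime discrimination) ----------
    state["stage"] = "convergence"
    t0 = time.time()
    pcs = convergence.pca_covariance(norm, ages=set(config.comparable_ages))
    div = convergence.test_pc_divergence(pcs, n_components=config.n_pcs, alpha=config.alpha)
    save(div.table, "pc_divergence_tests.tsv", index_label="component")
    long_tab = norm.subset(norm.metadata["history"] == "long")
    disc = convergence.train_regime_discriminator(
        long_tab, ages=set(config.comparable_ages), folds=config.folds, seed=config.seed
    )
    save(disc.roc, "discriminator_roc.tsv", index=False)
    recent = norm.subset(
        (norm.metadata["history"] == "recent")
        & norm.metadata["age_days"].isin(config.comparable_ages)
    )
    probs, heldout_acc = convergence.predict_regime(disc, recent)
    save(probs, "discriminator_heldout.tsv", index_label="sample_id")
    report["convergence"] = {
        "divergence_declared": div.divergence,
        "components_flagging": div.components_flagging(),
        "variance_explained_first4": float(np.sum(pcs.variance_explained[:4])),
        "training_accuracy": disc.training_accuracy,
        "training_auc": disc.training_auc,
        "heldout_accuracy": heldout_acc,
    }
    _stage("convergence", t0, divergence=div.divergence, heldout_acc=heldout_acc)

    # -- clocks ------------------------------------------------------------
    state["stage"] = "clocks"
    t0 = time.time()
    grid = dict(
        l1_ratios=config.clock_l1_ratios,
        n_alphas=config.clock_n_alphas,
        eps=config.clock_eps,
    )
    clock_input = norm.exclude(list(config.exclusions))
    regime_tables = {
        r: clock_input.subset(clock_input.metadata["regime"] == r) for r in ("A", "C")
    }
    clock_report = {}
    pred_frames = []
    between_clocks = {}
    for regime in ("A", "C"):
        other = "C" if regime == "A" else "A"
        within = clocks.loro_predictions(
            regime_tables[regime], folds=config.folds, seed=config.seed, **grid
        )
        model, between = clocks.between_regime_predictions(
            regime_tables[regime], regime_tables[other],
            folds=config.folds, seed=config.seed, **grid,
        )
        between_clocks[regime] = model
        accel = clocks.fit_age_acceleration(within, between)
        r2 = clocks.r_squared(
            within.predictions["age_days"], within.predictions["predicted_age"]
        )
        clock_report[regime] = {
            "within_r2": r2,
            "n_features": len(model.nonzero_features),
            "l1_ratio": model.l1_ratio,
            "alpha": model.alpha,
            "acceleration": {
                name: {
                    "estimate": float(accel.params[name]),
                    "se": float(accel.bse[name]),
                    "p": float(accel.pvalues[name]),
                }
                for name in accel.params.index
            },
        }
        pred_frames += [within.predictions, between.predictions]
        save(
            model.coef.rename("beta").to_frame(),
            f"clock_{regime}_coefficients.tsv",
            index_label="metabolite",
        )
    save(pd.concat(pred_frames, ignore_index=True), "age_predictions.tsv", index=False)
    comp = clocks.compare_features(
        between_clocks["A"], between_clocks["C"], panel_size=norm.n_metabolites
    )
    clock_report["feature_comparison"] = {
        "n_features_a": comp.n_features_a,
        "n_features_c": comp.n_features_c,
        "n_shared": comp.n_shared,
        "odds_ratio": comp.odds_ratio,
        "fisher_p": comp.fisher_p,
        "shared_correlation": comp.shared_correlation,
    }
    report["clocks"] = clock_report
    _stage("clocks", t0, r2_a=clock_report["A"]["within_r2"], r2_c=clock_report["C"]["within_r2"])

    # -- trajectories ------------------------------------------------------
    state["stage"] = "trajectories"
    t0 = time.time()
    lmm_input = norm.exclude(list(config.exclusions))
    lmm = trajectories.fit_metabolite_lmms(lmm_input, fdr=config.fdr)
    save(lmm.table, "lmm_results.tsv")
    counts = trajectories.term_overlap_counts(lmm)
    gm = trajectories.group_means(norm)  # day-9 retained for display/clustering
    flat = gm.matrix.copy()
    flat.columns = [f"{r}_{a}" for r, a in flat.columns]
    save(flat, "group_means.tsv", index_label="metabolite")
    k_max = min(config.k_max, gm.matrix.shape[0] - 1)
    k, wss = trajectories.choose_k_elbow(
        gm, k_max=k_max, n_init=config.n_init, seed=config.seed
    )
    save(wss.to_frame(), "wss_curve.tsv")
    sol = trajectories.hierarchical_cluster(gm, k)
    flags = trajectories.flag_aged_phenotype(sol, gm)
    sol.aged_flags = flags
    assign = sol.assignments.to_frame()
    assign["aged_phenotype"] = assign["cluster"].map(flags)
    save(assign, "clusters.tsv", index_label="metabolite")
    report["trajectories"] = {
        "significant_counts": counts,
        "chosen_k": int(k),
        "aged_phenotype_clusters": sorted(c for c, f in flags.items() if f),
    }
    _stage("trajectories", t0, k=k, n_sig=counts["any"])

    # -- enrichment --------------------------------------------------------
    state["stage"] = "enrichment"
    t0 = time.time()
    n_bg = max(0, norm.n_metabolites - config.network_pathways * config.network_pathway_size)
    net, planted = simulate_network(
        config.network_pathways, config.network_pathway_size, n_bg, seed=config.seed
    )
    net.write(out / "network_edges.tsv", out / "network_nodes.tsv")
    written += [out / "network_edges.tsv", out / "network_nodes.tsv"]
    enr_report = {}
    enr_frames = []
    for cluster_id in sorted(sol.assignments.unique()):
        members = set(sol.assignments.index[sol.assignments == cluster_id])
        res = enrichment.permutation_enrichment(
            net,
            members,
            n_perm=config.n_perm,
            min_cluster=config.min_cluster,
            restart_prob=config.restart_prob,
            fdr=config.enrichment_fdr,
            seed=config.seed + int(cluster_id),
        )
        if res is None:
            continue
        enr_report[str(cluster_id)] = res.significant_pathways()
        frame = res.table.reset_index()
        frame.insert(0, "cluster", cluster_id)
        enr_frames.append(frame)
    if enr_frames:
        save(pd.concat(enr_frames, ignore_index=True), "enrichment.tsv", index=False)
    report["enrichment"] = {"significant_pathways_by_cluster": enr_report}
    _stage("enrichment", t0, n_clusters_tested=len(enr_report))

    # -- mortality ---------------------------------------------------------
    state["stage"] = "mortality"
    t0 = time.time()
    deaths = simulate_mortality(
        config.mortality_params, cohort_size=config.cohort_size, seed=config.seed
    )
    deaths.write(out / "death_counts.tsv")
    written.append(out / "death_counts.tsv")
    mort_report = {}
    m_frames = []
    for population in sorted(deaths.counts["population"].unique()):
        sub = mortality.DeathCountTable(
            deaths.counts[deaths.counts["population"] == population]
        )
        pooled = mortality.pool_cohorts([sub])
        series = mortality.age_specific_mortality(pooled)[0]
        alive = pooled.alive_series(pooled.cohorts[0])
        total = int(pooled.counts["deaths"].sum())
        median_day = int((alive <= total / 2.0).idxmax())
        mort_report[population] = {"median_death_day": median_day}
        f = series.mortality.rename("M").to_frame()
        f.insert(0, "population", population)
        m_frames.append(f)
    save(pd.concat(m_frames), "mortality_series.tsv", index_label="day")
    report["mortality"] = {
        "median_death_day": {p: v["median_death_day"] for p, v in mort_report.items()}
    }
    _stage("mortality", t0, n_populations=len(mort_report))

    # -- manifest + report -------------------------------------------------
    state["stage"] = "report"
    report["manifest"] = {p.name: _sha256(p) for p in sorted(set(written))}
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
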