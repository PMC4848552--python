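"""Configuration-driven orchestration of the analysis stages.

Stages run in dependency order — context -> ages -> expression ->
stats/conservation — each reading the file dialects written by the synthetic
generator (or equivalent real inputs), writing intermediate TSVs, and
contributing to a machine-readable JSON report. One global seed fans out to
per-stage streams so toggling a stage never shifts another stage's
randomness.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .ages import (
    HUMAN_12_BRANCH_TREE,
    assign_ages,
    call_orthologs,
    origination_stats,
    reconcile_pairs,
)
from .context import GeneIndex, classify_contexts, cluster_mirnas
from .conservation import summarize_conservation
from .expression import quantify
from .intervals import ValidationError
from .stats import (
    coexpression_randomization_group,
    compare_correlations,
    correlate,
    enrichment_fisher,
    host_age_randomization,
    mannwhitney,
    tau,
)
from .synthetic import CROSS_SPECIES_TISSUES

log = logging.getLogger("mircontext")

_STAGE_SEEDS = {"context": 10, "ages": 11, "expression": 12, "stats": 13, "conserve": 14}


@dataclass
class PipelineConfig:
    """Flat, typed pipeline configuration; every analysis default is a named
    key, never a hard-coded literal downstream."""

    # inputs (paths; see synthetic.simulate_bundle for the emitted bundle)
    genes_gff3: str = ""
    precursor_bed: str = ""
    mature_bed: str = ""
    gene_ages_tsv: str = ""
    hits_tsv: str = ""
    annotated_orthologs_tsv: str = ""
    reads_tsv: str = ""
    samples_tsv: str = ""
    gene_expression_tsv: str = ""
    track_bedgraph: str = ""
    species_tree_yaml: str = ""
    outdir: str = "out"
    # thresholds (analysis defaults)
    cluster_gap_bp: int = 10_000
    cpm_threshold: float = 1.0
    ratio_min: float = 0.70
    ratio_max: float = 1.30
    context_score_max: float = -0.25
    n_background: int = 100
    background_window_bp: int = 10_000
    n_resampling_draws: int = 10_000
    n_shuffles: int = 3_000
    binomial_p0: float = 0.5
    seed: int = 0
    # stage toggles
    run_context: bool = True
    run_ages: bool = True
    run_expression: bool = True
    run_stats: bool = True
    run_conserve: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def validate(self) -> None:
        for name in ("cluster_gap_bp", "n_background", "n_resampling_draws", "n_shuffles"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.cpm_threshold <= 0:
            raise ValidationError("cpm_threshold must be positive")
        required = ["genes_gff3", "precursor_bed", "mature_bed"]
        if self.run_ages:
            required += ["gene_ages_tsv", "hits_tsv", "species_tree_yaml"]
        if self.run_expression:
            required += ["reads_tsv", "samples_tsv"]
        if self.run_conserve:
            required += ["track_bedgraph"]
        for name in required:
            p = getattr(self, name)
            if not p:
                raise ValidationError(f"config key {name} is required for the enabled stages")
            if not os.path.exists(p):
                raise ValidationError(f"input path does not exist: {name}={p}")

    def stage_rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STAGE_SEEDS[stage],))
        )


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute the enabled stages; returns (and writes) the run report.

    A stage failure aborts with the failing stage named; outputs of completed
    stages are retained in ``config.outdir``.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    report: Dict = {"stages": {}, "seed": config.seed}
    t0 = time.time()

    state: Dict = {}
    order = [
        ("context", config.run_context, _stage_context),
        ("ages", config.run_ages, _stage_ages),
        ("expression", config.run_expression, _stage_expression),
        ("stats", config.run_stats, _stage_stats),
        ("conserve", config.run_conserve, _stage_conserve),
    ]
    for name, enabled, fn in order:
        if not enabled:
            report["stages"][name] = {"status": "skipped"}
            continue
        log.info("stage %s: start", name)
        try:
            rec = fn(config, state)
        except Exception as exc:  # noqa: BLE001 - abort names the stage
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_report(report, config, t0)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        rec["status"] = "ok"
        report["stages"][name] = _jsonable(rec)
        log.info("stage %s: ok", name)
    _write_report(report, config, t0)
    return report


def _write_report(report: Dict, config: PipelineConfig, t0: float) -> None:
    report["wall_clock_s"] = round(time.time() - t0, 3)
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        # wall clock is the only non-reproducible field; keep it last and
        # stable-sort everything else
        json.dump(report, fh, indent=2, sort_keys=True)


def _stage_context(cfg: PipelineConfig, state: Dict) -> Dict:
    genes = mio.read_gff3_genes(cfg.genes_gff3)
    precursors = mio.read_precursors(cfg.precursor_bed, cfg.mature_bed)
    index = GeneIndex(genes)
    annotations = classify_contexts(precursors, index)
    clusters = cluster_mirnas(precursors, cfg.cluster_gap_bp, cfg.stage_rng("context"))
    cluster_of = {}
    rep = {}
    for c in clusters:
        for m in c.member_ids:
            cluster_of[m] = c.cluster_id
            rep[m] = m == c.representative_id
    rows = []
    for a in annotations:
        rows.append(
            {
                "mirna_id": a.mirna_id,
                "category": a.category,
                "orientation": a.orientation,
                "subregion": a.subregion,
                "host_gene_id": a.host_gene_id or "",
                "neighbor_gene_id": a.neighbor_gene_id or "",
                "neighbor_distance_bp": a.neighbor_distance_bp
                if a.neighbor_distance_bp is not None
                else "",
                "cluster_id": cluster_of[a.mirna_id],
                "is_representative": rep[a.mirna_id],
            }
        )
    table = pd.DataFrame(rows)
    mio.write_tsv(table, os.path.join(cfg.outdir, "context.tsv"))
    state.update(genes=genes, gene_index=index, precursors=precursors,
                 contexts=table, clusters=clusters)
    n_intra = int((table["category"] == "intragenic").sum()) if len(table) else 0
    n_sense = int((table["orientation"] == "sense").sum()) if len(table) else 0
    return {
        "n_mirnas": len(table),
        "n_intragenic": n_intra,
        "n_intergenic": len(table) - n_intra,
        "n_sense": n_sense,
        "n_hosts": int(table.loc[table["host_gene_id"] != "", "host_gene_id"].nunique())
        if len(table)
        else 0,
        "n_clusters": len(clusters),
    }


def _stage_ages(cfg: PipelineConfig, state: Dict) -> Dict:
    tree = (
        mio.read_species_tree(cfg.species_tree_yaml)
        if cfg.species_tree_yaml
        else HUMAN_12_BRANCH_TREE
    )
    hits = mio.read_tsv(cfg.hits_tsv)
    annotated = (
        mio.read_tsv(cfg.annotated_orthologs_tsv)
        if cfg.annotated_orthologs_tsv and os.path.exists(cfg.annotated_orthologs_tsv)
        else None
    )
    calls = call_orthologs(
        hits, annotated, tree, ratio_min=cfg.ratio_min, ratio_max=cfg.ratio_max
    )
    all_ids = [p.mirna_id for p in state["precursors"]]
    ages = assign_ages(calls, tree, all_mirna_ids=all_ids)
    mio.write_tsv(
        ages.rename(columns={"entity_id": "mirna_id"}),
        os.path.join(cfg.outdir, "mirna_ages.tsv"),
    )
    gene_ages = mio.read_gene_ages(cfg.gene_ages_tsv)
    contexts = state["contexts"]
    pairs, n_removed = reconcile_pairs(ages, gene_ages, contexts)
    mio.write_tsv(pairs, os.path.join(cfg.outdir, "host_pairs.tsv"))

    age_ctx = ages.rename(columns={"entity_id": "mirna_id"}).merge(
        contexts[["mirna_id", "category"]], on="mirna_id"
    )
    orig = origination_stats(age_ctx, tree, p0=cfg.binomial_p0)
    mio.write_tsv(orig, os.path.join(cfg.outdir, "origination.tsv"))
    state.update(tree=tree, mirna_ages=ages, gene_ages=gene_ages, pairs=pairs)
    return {
        "n_dated": len(ages),
        "n_pairs": len(pairs),
        "n_inconsistent_pairs_removed": n_removed,
        "peak_branch": int(
            age_ctx.groupby("branch_age").size().idxmax()
        )
        if len(age_ctx)
        else None,
    }


def _stage_expression(cfg: PipelineConfig, state: Dict) -> Dict:
    reads = mio.read_tsv(cfg.reads_tsv)
    meta = mio.read_tsv(cfg.samples_tsv)
    ages_map = None
    if "mirna_ages" in state:
        a = state["mirna_ages"]
        ages_map = dict(zip(a["entity_id"], a["branch_age"]))
    profiles = quantify(
        reads,
        meta,
        state["precursors"],
        ages=ages_map,
        threshold_cpm=cfg.cpm_threshold,
    )
    long = profiles.reset_index().melt(
        id_vars="mirna_id", var_name="tissue", value_name="cpm"
    )
    mio.write_tsv(long, os.path.join(cfg.outdir, "expression.tsv"))
    state["profiles"] = profiles
    return {"n_expressed": len(profiles), "n_tissues": profiles.shape[1]}


def _stage_stats(cfg: PipelineConfig, state: Dict) -> Dict:
    rng = cfg.stage_rng("stats")
    out: Dict = {}
    contexts = state["contexts"]
    ctx = contexts.set_index("mirna_id")

    # host-age constrained resampling
    if "pairs" in state and len(state["pairs"]):
        pairs = state["pairs"]
        res = host_age_randomization(
            pairs["host_age"],
            pairs["mirna_age"],
            state["gene_ages"]["branch_age"],
            n_draws=cfg.n_resampling_draws,
            rng=rng,
        )
        out["host_age_test"] = {
            "observed_old_host_fraction": res.observed_statistic,
            "null_mean": float(res.null_values.mean()),
            "empirical_p": res.empirical_p,
            "chi2_p": res.chi2_p,
            "n_pairs": len(pairs),
            "n_draws": res.n_draws,
        }

    # expression breadth (tau) per expressed miRNA, grouped by context/age
    stats_rows = []
    if "profiles" in state and len(state["profiles"]):
        profiles = state["profiles"]
        taus = {mid: tau(profiles.loc[mid].to_numpy(), mid).tau for mid in profiles.index}
        tau_df = pd.DataFrame(
            {"mirna_id": list(taus), "tau": [taus[k] for k in taus]}
        )
        if "mirna_ages" in state:
            tau_df = tau_df.merge(
                state["mirna_ages"].rename(columns={"entity_id": "mirna_id"}),
                on="mirna_id",
                how="left",
            )
        tau_df = tau_df.merge(
            contexts[["mirna_id", "category", "orientation", "host_gene_id"]],
            on="mirna_id",
            how="left",
        )
        mio.write_tsv(tau_df, os.path.join(cfg.outdir, "tau.tsv"))

        if "gene_ages" in state:
            host_age = dict(
                zip(state["gene_ages"]["gene_id"], state["gene_ages"]["branch_age"])
            )
            tau_df["host_age"] = tau_df["host_gene_id"].map(host_age)
            strict = tau_df[
                (tau_df["category"] == "intergenic")
                | (tau_df["orientation"] == "sense")
            ]
            old_host = strict[strict["host_age"] == 1]["tau"]
            young_host = strict[strict["host_age"] >= 2]["tau"]
            inter = strict[strict["category"] == "intergenic"]["tau"]
            if len(old_host) >= 2 and len(young_host) >= 2:
                _, p = mannwhitney(old_host, young_host)
                out["tau_old_vs_young_host"] = {
                    "median_old_host": float(old_host.median()),
                    "median_young_host": float(young_host.median()),
                    "mwu_p": p,
                }
            if len(old_host) >= 2 and len(inter) >= 2:
                _, p = mannwhitney(old_host, inter)
                out["tau_old_host_vs_intergenic"] = {
                    "median_old_host": float(old_host.median()),
                    "median_intergenic": float(inter.median()),
                    "mwu_p": p,
                }

        # miRNA-host expression breadth correlation and co-expression
        if cfg.gene_expression_tsv and os.path.exists(cfg.gene_expression_tsv):
            gexp = mio.read_tsv(cfg.gene_expression_tsv)
            gmat = gexp.pivot_table(index="gene_id", columns="tissue", values="fpkm")
            host_tau = {
                gid: tau(gmat.loc[gid].to_numpy(), gid).tau
                for gid in gmat.index
                if gmat.loc[gid].max() > 0
            }
            paired = tau_df[
                (tau_df["category"] == "intragenic")
                & (tau_df["orientation"] == "sense")
                & tau_df["host_gene_id"].map(lambda g: g in host_tau)
            ]
            if len(paired) >= 4:
                corr = correlate(
                    paired["tau"].to_numpy(),
                    paired["host_gene_id"].map(host_tau).to_numpy(),
                )
                out["mirna_host_breadth_correlation"] = {
                    "rho": corr.rho,
                    "n": corr.n,
                    "p": corr.p,
                }
            panel = [t for t in CROSS_SPECIES_TISSUES if t in state["profiles"].columns]
            pairs_px = []
            for row in paired.itertuples(index=False):
                m = state["profiles"].loc[row.mirna_id, panel].to_numpy(dtype=float)
                h = gmat.loc[row.host_gene_id, panel].to_numpy(dtype=float)
                if np.all(m == m[0]) or np.all(h == h[0]):
                    continue
                pairs_px.append((m, h))
            if pairs_px:
                co = coexpression_randomization_group(
                    pairs_px, n_shuffles=cfg.n_shuffles, rng=rng
                )
                out["coexpression_test"] = {
                    "observed_mean_rank_match": co.observed_statistic,
                    "null_mean": float(co.null_values.mean()),
                    "empirical_p": co.empirical_p,
                    "n_pairs": len(pairs_px),
                    "n_shuffles": co.n_draws,
                }

    # cluster-propensity enrichment (intergenic vs intragenic in multi-miRNA
    # clusters)
    if "clusters" in state:
        in_multi = {
            m: len(c.member_ids) > 1 for c in state["clusters"] for m in c.member_ids
        }
        cat = ctx["category"]
        a = int(sum(1 for m, v in in_multi.items() if v and cat.get(m) == "intergenic"))
        b = int(sum(1 for m, v in in_multi.items() if not v and cat.get(m) == "intergenic"))
        c_ = int(sum(1 for m, v in in_multi.items() if v and cat.get(m) == "intragenic"))
        d = int(sum(1 for m, v in in_multi.items() if not v and cat.get(m) == "intragenic"))
        enr = enrichment_fisher([[a, b], [c_, d]])
        out["cluster_enrichment"] = {
            "table": [[a, b], [c_, d]],
            "odds_ratio": enr.odds_ratio,
            "p": enr.p,
            "undefined": enr.undefined,
        }

    with open(os.path.join(cfg.outdir, "stats.json"), "w") as fh:
        json.dump(_jsonable(out), fh, indent=2, sort_keys=True)
    rec = {"analyses": sorted(out)}
    rec.update(_jsonable(out))
    return rec


def _stage_conserve(cfg: PipelineConfig, state: Dict) -> Dict:
    rng = cfg.stage_rng("conserve")
    track = mio.read_bedgraph(cfg.track_bedgraph)
    contexts = state["contexts"].set_index("mirna_id")
    index = state["gene_index"]
    rows = []
    from .intervals import ContextAnnotation

    for p in state["precursors"]:
        row = contexts.loc[p.mirna_id]
        ann = ContextAnnotation(
            mirna_id=p.mirna_id,
            category=row["category"],
            orientation=row["orientation"] if row["category"] == "intragenic" else "not-applicable",
            subregion=row["subregion"] if row["category"] == "intragenic" else "not-applicable",
            host_gene_id=row["host_gene_id"] or None if row["category"] == "intragenic" else None,
        )
        mature = p.matures[0].interval if p.matures else None
        try:
            summ = summarize_conservation(
                track,
                p.mirna_id,
                p.interval,
                ann,
                index,
                mature_interval=mature,
                n_samples=cfg.n_background,
                window_bp=cfg.background_window_bp,
                rng=rng,
            )
        except ValidationError as exc:
            log.warning("conservation skipped for %s: %s", p.mirna_id, exc)
            continue
        bg = [m for m in summ.background_means if m is not None]
        rows.append(
            {
                "entity_id": summ.entity_id,
                "mean": summ.mean_score,
                "n_covered": summ.n_bases_covered,
                "background_mean": float(np.mean(bg)) if bg else "",
                "background_sd": float(np.std(bg, ddof=1)) if len(bg) > 1 else "",
                "background_kind": summ.background_kind,
                "n_samples": cfg.n_background,
                "seed_mean": summ.seed_mean if summ.seed_mean is not None else "",
            }
        )
    table = pd.DataFrame(rows)
    mio.write_tsv(table, os.path.join(cfg.outdir, "conservation.tsv"))
    state["conservation"] = table
    rec: Dict = {"n_scored": len(table)}
    if len(table):
        diffs = table["mean"] - pd.to_numeric(table["background_mean"], errors="coerce")
        rec["mean_precursor_minus_background"] = float(diffs.mean())
    return rec
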