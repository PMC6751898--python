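"""Seed-correlation candidate discovery and the end-to-end pipeline.

Known regulators act as "seeds": every other motif's activity profile is
correlated (Pearson, across the T-1 intervals) against each seed's profile,
and positively correlated motifs below the p threshold become candidates.
Candidates are then intersected with the expression-based TF filter, and the
top-affinity genes of each candidate motif are listed as predicted targets.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _pkg_version
from .activity import (
    ActivityFit,
    activity_zscores,
    default_ridge_lambda,
    fit_activities,
    fit_both_region_classes,
    log_fold_changes,
    standardize_design,
)
from .affinity import MotifMatrix, affinity_matrix, read_jaspar
from .clustering import kmeans_fit, select_k, within_cluster_spearman
from .expression import (
    ExpressionTable,
    evidence_filter_stage2,
    max_mean_score,
    qc_ordination,
    rank_and_filter_stage1,
    read_expression_table,
    timepoint_means,
    tpm_normalize,
)
from .synthetic import SimulationConfig, simulate_bundle, write_bundle


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of two activity profiles with its t-based p."""

    r: float
    p: float
    n: int


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Sample Pearson r with the two-sided p from
    ``t = r sqrt(n-2) / sqrt(1-r^2)`` against Student t on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation for a constant vector")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=n)


def _seed_table(seeds) -> pd.DataFrame:
    if isinstance(seeds, pd.DataFrame):
        if not {"symbol", "motif_id"} <= set(seeds.columns):
            raise ValueError("seed table needs 'symbol' and 'motif_id' columns")
        return seeds
    if isinstance(seeds, Mapping):
        return pd.DataFrame(
            {"symbol": list(seeds.keys()), "motif_id": list(seeds.values())}
        )
    raise TypeError("seeds must be a DataFrame or a mapping symbol -> motif id")


def find_seed_neighbors(
    activities: pd.DataFrame,
    seeds,
    r_min: float = 0.80,
    p_max: float = 0.05,
    exclude: Sequence[str] = (),
) -> pd.DataFrame:
    """All (candidate, seed) pairs whose activity profiles are positively
    correlated with r > r_min and p < p_max.

    Seed motifs themselves and any motif in ``exclude`` (other known
    regulators) never appear on the candidate side.  Every tested pair
    receives a Benjamini-Hochberg q-value for transparency (the filter itself
    uses the raw p, as is conventional for this screen).  ``is_best`` marks
    each candidate's highest-r seed; ``highly_correlated`` flags r > 0.80.
    """
    seed_df = _seed_table(seeds)
    if seed_df.empty:
        raise ValueError("empty seed set")
    missing = [m for m in seed_df["motif_id"] if m not in activities.index]
    if missing:
        raise ValueError(f"seed motif(s) absent from activities: {missing}")
    banned = set(seed_df["motif_id"]) | set(exclude)
    candidates = [m for m in activities.index if m not in banned]
    rows = []
    for cand in candidates:
        x = activities.loc[cand].to_numpy()
        if np.std(x) == 0:
            continue
        for _, seed_row in seed_df.iterrows():
            y = activities.loc[seed_row["motif_id"]].to_numpy()
            if np.std(y) == 0:
                continue
            res = pearson_with_p(x, y)
            rows.append(
                {
                    "candidate": cand,
                    "seed_symbol": seed_row["symbol"],
                    "seed_motif": seed_row["motif_id"],
                    "r": res.r,
                    "p": res.p,
                    "n": res.n,
                }
            )
    all_pairs = pd.DataFrame(
        rows, columns=["candidate", "seed_symbol", "seed_motif", "r", "p", "n"]
    )
    if len(all_pairs):
        all_pairs["q"] = stats.false_discovery_control(all_pairs["p"], method="bh")
    else:
        all_pairs["q"] = pd.Series(dtype=float)
    kept = all_pairs[
        (all_pairs["r"] > max(r_min, 0.0)) & (all_pairs["p"] < p_max)
    ].copy()
    kept["highly_correlated"] = kept["r"] > 0.80
    kept = kept.sort_values(["candidate", "r"], ascending=[True, False])
    kept["is_best"] = ~kept.duplicated("candidate")
    return kept.sort_values("r", ascending=False).reset_index(drop=True)


def intersect_with_filter(
    neighbors: pd.DataFrame,
    filter_report: pd.DataFrame,
    motif_to_symbol: Mapping[str, str],
    clusters: pd.Series | None = None,
    aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Final candidate report: seed neighbors whose TF symbol survives the
    stage-2 expression filter, annotated with rank, Max score, evidence flags
    and cluster membership; sorted by best r descending.

    Symbol matching is case-insensitive; ``aliases`` maps motif names to TF
    symbols when they differ.  Motifs with no symbol resolution are skipped
    with a warning, never silently matched.
    """
    if neighbors.empty:
        return pd.DataFrame(
            columns=[
                "symbol", "candidate_motif", "best_seed", "r", "p",
                "highly_correlated", "cluster", "rank", "max",
                "eurexpress", "allen",
            ]
        )
    report_by_symbol = {s.lower(): row for s, row in filter_report.set_index("symbol").iterrows()}
    alias_map = {k.lower(): v for k, v in (aliases or {}).items()}
    rows = []
    for _, nb in neighbors[neighbors["is_best"]].iterrows():
        motif = nb["candidate"]
        symbol = motif_to_symbol.get(motif)
        if symbol is None:
            warnings.warn(f"no TF symbol for motif {motif}; skipped", stacklevel=2)
            continue
        symbol = alias_map.get(symbol.lower(), symbol)
        hit = report_by_symbol.get(symbol.lower())
        if hit is None:
            continue
        rows.append(
            {
                "symbol": symbol,
                "candidate_motif": motif,
                "best_seed": nb["seed_symbol"],
                "r": nb["r"],
                "p": nb["p"],
                "highly_correlated": bool(nb["highly_correlated"]),
                "cluster": (
                    int(clusters.loc[motif]) if clusters is not None else pd.NA
                ),
                "rank": int(hit["rank"]),
                "max": float(hit["max"]),
                "eurexpress": bool(hit["eurexpress"]),
                "allen": bool(hit["allen"]),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("r", ascending=False).reset_index(drop=True)
    return out


def predicted_targets(
    affinities: pd.DataFrame,
    fit: ActivityFit,
    motif: str,
    top_q: float = 0.01,
) -> pd.DataFrame:
    """Genes in the top ``top_q`` affinity quantile for ``motif``, ranked by
    affinity (non-increasing), labelled with the fit's region class."""
    if not 0 < top_q <= 1:
        raise ValueError("top_q must be in (0, 1]")
    if motif not in affinities.columns:
        raise KeyError(f"motif {motif} absent from affinity matrix")
    if motif not in fit.activities.index:
        raise KeyError(f"motif {motif} absent from activity fit")
    col = affinities[motif]
    n_top = max(1, int(np.ceil(top_q * len(col))))
    ranked = col.sort_values(ascending=False, kind="mergesort").head(n_top)
    return pd.DataFrame(
        {
            "gene": ranked.index,
            "affinity": ranked.to_numpy(),
            "region_class": fit.region_class,
            "motif": motif,
        }
    ).reset_index(drop=True)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; message names the stage."""


@dataclass
class PipelineConfig:
    """Run configuration; currently the synthetic study is the only bundled
    input source, real inputs enter through the stage functions directly."""

    outdir: str = "cagemara_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    top_n: int = 20
    pseudocount: float = 1.0
    ridge_lambda: float | None = None  # None -> automatic
    k_min: int = 2
    k_max: int = 10
    cap_fraction: float = 0.5
    restarts: int = 20
    r_min: float = 0.0  # candidate rule: positive correlation ...
    p_max: float = 0.05  # ... below this p; r > 0.80 flagged separately
    z_min: float = 2.0
    top_q: float = 0.01
    write_fixtures: bool = True

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        raw = dict(raw)
        sim_raw = raw.pop("simulation", None) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise PipelineError(f"stage config: unknown key(s) {sorted(bad)}")
        cfg = cls(**raw)
        sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
        bad = set(sim_raw) - sim_known
        if bad:
            raise PipelineError(f"stage config: unknown simulation key(s) {sorted(bad)}")
        sim_raw.setdefault("seed", cfg.seed)
        cfg.simulation = SimulationConfig(**sim_raw)
        return cfg


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - reframe with stage name
                raise PipelineError(f"stage {name}: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig | Mapping) -> dict:
    """Execute filter -> affinities -> activities -> clustering -> candidates
    on a simulated study, writing every artifact plus a run manifest.

    Reruns with the same configuration produce byte-identical outputs.
    Returns a result dictionary with the in-memory objects of every stage.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_dict(config)
    if config.simulation is None:
        config.simulation = SimulationConfig(seed=config.seed)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    bundle = _stage("simulate")(simulate_bundle)(config.simulation)
    if config.write_fixtures:
        _stage("simulate")(write_bundle)(bundle, out / "inputs")

    # --- expression filtering -------------------------------------------------
    @_stage("filter")
    def run_filter():
        table = bundle.expression
        means = timepoint_means(table)
        scores = max_mean_score(means)
        symbol_scores = scores.groupby(table.gene_symbols).max()
        symbol_means = means.mean(axis=1).groupby(table.gene_symbols).mean()
        tf_scores = symbol_scores.reindex(bundle.annotations.index)
        report1 = rank_and_filter_stage1(
            tf_scores,
            bundle.annotations,
            top_n=config.top_n,
            mean_scores=symbol_means.reindex(bundle.annotations.index),
        )
        report2 = evidence_filter_stage2(report1)
        newick, pca = qc_ordination(table, config.pseudocount)
        return means, report1, report2, newick, pca

    means, report1, report2, newick, pca = run_filter()
    report2.to_csv(out / "filter_report.tsv", sep="\t", index=False, float_format="%.6g")
    (out / "qc_tree.nwk").write_text(newick + "\n")
    pca.to_csv(out / "qc_pca.tsv", sep="\t", float_format="%.6g")

    # --- affinities -----------------------------------------------------------
    @_stage("affinities")
    def run_affinities():
        N_prom = affinity_matrix(bundle.sequences, bundle.motifs)
        N_enh = (
            affinity_matrix(bundle.enhancer_sequences, bundle.motifs)
            if bundle.enhancer_sequences
            else None
        )
        return N_prom, N_enh

    N_prom, N_enh = run_affinities()
    N_prom.to_csv(out / "affinity_promoter.tsv", sep="\t", float_format="%.10g")
    if N_enh is not None:
        N_enh.to_csv(out / "affinity_enhancer.tsv", sep="\t", float_format="%.10g")

    # --- activities -----------------------------------------------------------
    @_stage("activities")
    def run_activities():
        delta = log_fold_changes(means, config.pseudocount)
        lam = (
            config.ridge_lambda
            if config.ridge_lambda is not None
            else default_ridge_lambda(*N_prom.shape)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prom_fit, enh_fit = fit_both_region_classes(
                delta, N_prom, N_enh, lam, bundle.enhancer_links or None
            )
        z, activated = activity_zscores(prom_fit, config.z_min)
        return delta, prom_fit, enh_fit, z, activated

    delta, prom_fit, enh_fit, zscores, activated = run_activities()
    prom_fit.activities.to_csv(out / "activity_promoter.tsv", sep="\t",
                               float_format="%.10g")
    prom_fit.standard_errors.to_csv(out / "activity_promoter_se.tsv", sep="\t",
                                    float_format="%.10g")
    zscores.to_csv(out / "activity_promoter_z.tsv", sep="\t", float_format="%.10g")
    if enh_fit is not None:
        enh_fit.activities.to_csv(out / "activity_enhancer.tsv", sep="\t",
                                  float_format="%.10g")

    # --- clustering -----------------------------------------------------------
    @_stage("cluster")
    def run_cluster():
        profiles = prom_fit.activities
        k_max = min(config.k_max, len(profiles) - 1)
        report = select_k(
            profiles,
            range(config.k_min, k_max + 1),
            cap_fraction=config.cap_fraction,
            seed=config.seed,
            restarts=config.restarts,
        )
        model = kmeans_fit(profiles, report.chosen_k, seed=config.seed,
                           restarts=config.restarts)
        spearman = within_cluster_spearman(profiles, model.assignments)
        return report, model, spearman

    k_report, model, spearman = run_cluster()
    k_report.table.to_csv(out / "k_selection.tsv", sep="\t", index=False,
                          float_format="%.6g")
    model.assignments.to_frame().to_csv(out / "clusters.tsv", sep="\t")
    pd.DataFrame(
        model.centroids, columns=prom_fit.activities.columns
    ).to_csv(out / "cluster_profiles.tsv", sep="\t", float_format="%.6g")

    # --- candidates -----------------------------------------------------------
    @_stage("candidates")
    def run_candidates():
        neighbors = find_seed_neighbors(
            prom_fit.activities,
            bundle.seeds,
            r_min=config.r_min,
            p_max=config.p_max,
        )
        motif_to_symbol = {m.motif_id: m.tf_name for m in bundle.motifs}
        cand = intersect_with_filter(
            neighbors, report2, motif_to_symbol, clusters=model.assignments
        )
        targets = pd.concat(
            [
                predicted_targets(N_prom, prom_fit, m, config.top_q)
                for m in cand["candidate_motif"]
            ],
            ignore_index=True,
        ) if len(cand) else pd.DataFrame(columns=["gene", "affinity",
                                                  "region_class", "motif"])
        return neighbors, cand, targets

    neighbors, cand_report, targets = run_candidates()
    neighbors.to_csv(out / "correlations.tsv", sep="\t", index=False,
                     float_format="%.6g")
    cand_report.to_csv(out / "candidates.tsv", sep="\t", index=False,
                       float_format="%.6g")
    targets.to_csv(out / "targets.tsv", sep="\t", index=False, float_format="%.6g")

    manifest = {
        "package_version": _pkg_version,
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items()
               if k != "simulation"},
            "simulation": dataclasses.asdict(config.simulation),
        },
        "stage_counts": {
            "promoters": int(bundle.expression.n_promoters),
            "motifs": len(bundle.motifs),
            "stage1_candidates": int(len(report1)),
            "stage2_candidates": int(len(report2)),
            "activated_motifs": len(activated),
            "chosen_k": int(k_report.chosen_k),
            "correlation_pairs": int(len(neighbors)),
            "final_candidates": int(len(cand_report)),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return {
        "bundle": bundle,
        "filter_stage1": report1,
        "filter_stage2": report2,
        "qc_newick": newick,
        "qc_pca": pca,
        "affinity_promoter": N_prom,
        "affinity_enhancer": N_enh,
        "delta": delta,
        "promoter_fit": prom_fit,
        "enhancer_fit": enh_fit,
        "zscores": zscores,
        "activated": activated,
        "k_report": k_report,
        "cluster_model": model,
        "within_cluster_spearman": spearman,
        "neighbors": neighbors,
        "candidates": cand_report,
        "targets": targets,
        "manifest": manifest,
    }
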