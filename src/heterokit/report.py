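"""Cross-tabulation of heterotic groups against marker clusters and the
end-to-end pipeline driver.

The pipeline runs: cell means -> effects -> ANOVA -> SCA / HSGCA grouping
(per trait) -> method concordance -> marker QC -> diversity summary -> IBS
-> Ward -> PCA -> admixture (+ Evanno over a K range) -> group x cluster
cross-tabs, and writes every artifact as CSV/JSON plus a run log of the
conventions and seeds used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from heterokit import combining, grouping, markers, structure
from heterokit.combining import CrossMeansTable
from heterokit.grouping import UNASSIGNED, GroupingConfig, HeteroticAssignment
from heterokit.io import (
    GenotypeMatrix,
    TrialTable,
    write_genotypes_csv,
    write_newick,
)
from heterokit.markers import FilterThresholds
from heterokit.structure import ClusterResult

logger = logging.getLogger(__name__)


@dataclass
class CrossTab:
    counts: pd.DataFrame  # group rows (incl. "unassigned" when present) x cluster cols
    percentages: pd.DataFrame  # row-normalized, summing to 100 per row

    def to_frame(self) -> pd.DataFrame:
        merged = self.counts.copy().astype(object)
        for r in merged.index:
            for c in merged.columns:
                merged.loc[r, c] = (
                    f"{self.counts.loc[r, c]} ({self.percentages.loc[r, c]:.1f}%)"
                )
        return merged


@dataclass
class PipelineConfig:
    traits: list[str] = field(default_factory=lambda: ["pva"])
    grouping: GroupingConfig = field(default_factory=GroupingConfig)
    filter_thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    n_clusters: int = 3
    k_range: tuple[int, int] = (1, 5)
    n_replicates: int = 5
    admixture_max_iter: int = 2000
    seed: int = 0
    out_dir: str | Path | None = None


def crosstab_groups_clusters(
    assignment: HeteroticAssignment, clusters: ClusterResult
) -> CrossTab:
    """Counts and row percentages of heterotic groups across marker clusters.

    Testers (absent from the assignment) are excluded; lines the method left
    unassigned occupy their own row.
    """
    common = [s for s in clusters.samples if s in assignment.groups]
    if not common:
        raise ValueError("no overlap between assigned lines and clustered samples")
    cluster_ids = clusters.clusters
    group_labels = sorted(
        {g for g in assignment.groups.values() if g != UNASSIGNED}
    )
    if any(assignment.groups[s] == UNASSIGNED for s in common):
        group_labels.append(UNASSIGNED)

    counts = pd.DataFrame(
        0,
        index=group_labels,
        columns=[f"Cluster-{c}" for c in cluster_ids],
        dtype=int,
    )
    for s in common:
        counts.loc[assignment.groups[s], f"Cluster-{clusters.labels[s]}"] += 1
    row_tot = counts.sum(axis=1).replace(0, np.nan)
    pct = counts.div(row_tot, axis=0) * 100.0
    return CrossTab(counts=counts, percentages=pct.fillna(0.0))


def cluster_trait_means(
    clusters: ClusterResult,
    means_by_trait: dict[str, CrossMeansTable],
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """Mean testcross value of cluster-member lines, by tester and trait.

    Empty clusters (after exclusions) yield NaN rows.  ``exclude`` removes
    e.g. the testers themselves from the member lists.
    """
    exclude = exclude or set()
    rows = []
    for c in clusters.clusters:
        members = [s for s in clusters.members(c) if s not in exclude]
        row: dict = {"cluster": f"Cluster-{c}", "n_lines": len(members)}
        for trait, means in means_by_trait.items():
            for t in means.testers:
                vals = [
                    means.cross_means[(l, t)]
                    for l in members
                    if (l, t) in means.cross_means
                ]
                row[f"{trait}_{t}"] = float(np.mean(vals)) if vals else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    trial: TrialTable,
    geno: GenotypeMatrix,
    config: PipelineConfig,
) -> dict:
    """Execute the full analysis and return (and optionally write) a bundle.

    Returns a dict with keys: ``means``, ``effects``, ``anova``,
    ``assignments``, ``concordance``, ``filter_report``, ``marker_stats``,
    ``diversity``, ``distance``, ``clusters``, ``pca_scores``,
    ``eigenvalues``, ``admixture``, ``evanno``, ``crosstabs``,
    ``cluster_means``, ``log``.
    """
    log: list[str] = [f"seed={config.seed}"]
    bundle: dict = {"log": log}

    def stage(name):
        log.append(f"stage:{name}")
        logger.info("pipeline stage %s", name)

    try:
        means_by_trait: dict[str, CrossMeansTable] = {}
        effects_by_trait = {}
        anova_by_trait = {}
        assignments: dict[str, HeteroticAssignment] = {}
        scores: dict[str, dict[str, float]] = {}
        gcfg = config.grouping
        t1 = gcfg.testers[0]
        for trait in config.traits:
            stage(f"cell_means[{trait}]")
            means = combining.cell_means(trial, trait)
            means_by_trait[trait] = means
            stage(f"effects[{trait}]")
            nl, nt, ne, nr = trial.design
            stage(f"anova[{trait}]")
            anova = combining.anova_line_by_tester(trial, trait)
            anova_by_trait[trait] = anova
            effects = combining.estimate_effects(
                means, ms_error=anova.ms_error, n_obs_per_cross=ne * nr
            )
            effects_by_trait[trait] = effects
            lsd_value = combining.lsd(anova, gcfg.alpha, ne * nr)
            check_key = next(iter(means.check_means), None)
            check_mean = (
                means.check_means[check_key]
                if check_key is not None
                else float(np.mean(list(means.tester_means.values())))
            )
            if check_key is None:
                log.append(
                    f"no check cross present for {trait}; "
                    "using mean of tester margins as check mean"
                )
            stage(f"assign_sca[{trait}]")
            sca_assign = grouping.assign_sca(
                effects, means, check_mean, lsd_value, gcfg, trait
            )
            stage(f"assign_hsgca[{trait}]")
            hsgca_assign = grouping.assign_hsgca(effects, gcfg, trait)
            assignments[f"{trait}-SCA"] = sca_assign
            assignments[f"{trait}-HSGCA"] = hsgca_assign
            scores[f"{trait}-SCA"] = {
                l: effects.sca[(l, t1)] for l in effects.lines
            }
            scores[f"{trait}-HSGCA"] = {
                l: effects.hsgca[(l, t1)] for l in effects.lines
            }

        stage("compare_methods")
        concordance = grouping.compare_methods(assignments, scores)

        stage("filter_markers")
        filtered, filter_report = markers.filter_markers(
            geno, config.filter_thresholds
        )
        stage("marker_stats")
        stats = markers.marker_stats(filtered)
        diversity = markers.summarize_diversity(stats)

        stage("ibs_distance")
        dist = structure.ibs_distance(filtered)
        stage("ward_cluster")
        clusters = structure.ward_cluster(dist, config.n_clusters)
        stage("pca")
        pca_scores, eigvals = structure.pca_genotypes(filtered)

        stage("admixture")
        k_lo, k_hi = config.k_range
        logliks = {}
        admix_by_k = {}
        for k in range(k_lo, k_hi + 1):
            res = structure.admixture_em(
                filtered,
                k,
                n_replicates=config.n_replicates,
                seed=config.seed,
                max_iter=config.admixture_max_iter,
            )
            logliks[k] = res.replicate_logliks
            admix_by_k[k] = res
        stage("evanno")
        try:
            evanno = structure.evanno_delta_k(logliks)
            best_k = evanno.best_k
        except ValueError as exc:
            log.append(f"evanno undefined: {exc}; falling back to n_clusters")
            evanno = None
            best_k = config.n_clusters
        admixture = admix_by_k.get(best_k) or admix_by_k[min(admix_by_k)]

        stage("crosstabs")
        crosstabs = {
            name: crosstab_groups_clusters(a, clusters)
            for name, a in assignments.items()
        }
        cmeans = cluster_trait_means(
            clusters, means_by_trait, exclude=set(trial.testers)
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at {log[-1]}: {exc}") from exc

    bundle.update(
        means=means_by_trait,
        effects=effects_by_trait,
        anova=anova_by_trait,
        assignments=assignments,
        concordance=concordance,
        filter_report=filter_report,
        marker_stats=stats,
        diversity=diversity,
        distance=dist,
        clusters=clusters,
        pca_scores=pca_scores,
        eigenvalues=eigvals,
        admixture=admixture,
        evanno=evanno,
        crosstabs=crosstabs,
        cluster_means=cmeans,
    )
    if config.out_dir is not None:
        write_bundle(bundle, Path(config.out_dir), filtered)
    return bundle


def write_bundle(bundle: dict, out_dir: Path, filtered: GenotypeMatrix) -> None:
    """Write every pipeline artifact as UTF-8 CSV/JSON/newick text."""
    out_dir.mkdir(parents=True, exist_ok=True)
    for trait, eff in bundle["effects"].items():
        eff.to_frame().to_csv(out_dir / f"effects_{trait}.csv", index=False)
    for trait, anova in bundle["anova"].items():
        anova.table.to_csv(out_dir / f"anova_{trait}.csv", index=False)
        meta = {
            "trait": trait,
            "repeatability": anova.repeatability,
            "cv_pct": anova.cv_pct,
            "grand_mean": anova.grand_mean,
            "conventions": {
                "design": "RCBD sequential SS (no lattice adjustment)",
                "margins": "computed from cross means",
                "f_denominators": "genetic terms vs matching xEnv MS",
                "repeatability": "entry-mean, moment estimators truncated at 0",
            },
        }
        (out_dir / f"anova_{trait}.json").write_text(json.dumps(meta, indent=2))
    assign_frames = []
    for name, a in bundle["assignments"].items():
        frame = a.support.copy()
        frame.insert(0, "method", name)
        assign_frames.append(frame)
    pd.concat(assign_frames, ignore_index=True).to_csv(
        out_dir / "assignments.csv", index=False
    )
    (out_dir / "concordance.json").write_text(
        json.dumps(bundle["concordance"].to_dict(), indent=2)
    )
    (out_dir / "filter_report.json").write_text(
        json.dumps(bundle["filter_report"].to_dict(), indent=2)
    )
    bundle["marker_stats"].to_csv(out_dir / "marker_stats.csv", index=False)
    bundle["diversity"].to_csv(out_dir / "diversity_summary.csv", index=False)
    write_genotypes_csv(filtered, out_dir / "genotypes_filtered.csv")
    bundle["distance"].to_frame().to_csv(out_dir / "ibs_distance.csv")
    clusters = bundle["clusters"]
    pd.DataFrame(
        {"sample": clusters.samples,
         "cluster": [clusters.labels[s] for s in clusters.samples]}
    ).to_csv(out_dir / "clusters.csv", index=False)
    (out_dir / "dendrogram.nwk").write_text(
        write_newick(clusters.linkage_matrix, clusters.samples) + "\n"
    )
    bundle["pca_scores"].to_csv(out_dir / "pca_scores.csv", index_label="sample")
    np.savetxt(out_dir / "eigenvalues.csv", bundle["eigenvalues"], delimiter=",")
    admix = bundle["admixture"]
    q = admix.q.copy()
    q["assignment"] = [str(admix.assignments[s]) for s in admix.samples]
    q.to_csv(out_dir / "admixture_q.csv", index_label="sample")
    if bundle["evanno"] is not None:
        bundle["evanno"].table.to_csv(out_dir / "evanno.csv", index=False)
    for name, ct in bundle["crosstabs"].items():
        ct.counts.to_csv(out_dir / f"crosstab_{name}_counts.csv")
        ct.percentages.to_csv(out_dir / f"crosstab_{name}_pct.csv")
    bundle["cluster_means"].to_csv(out_dir / "cluster_trait_means.csv", index=False)
    (out_dir / "run_log.txt").write_text("\n".join(bundle["log"]) + "\n")
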