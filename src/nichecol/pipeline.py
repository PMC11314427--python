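"""End-to-end orchestration of the colonization analysis.

Runs, in order: stage assignment, per-stage niche metrics (records,
overlap, pairwise-difference framework), alpha diversity, Bray-Curtis and
environmental Euclidean distances, normalized dissimilarities (Xd / Ed),
beta-diversity partition, PCoA, PERMANOVA / PERMDISP / ANOSIM (community
and environment, by stage), RDA, and group summaries. Every table is
written as tidy CSV next to a machine-readable ``summary.json``; the whole
run is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import kruskal

from . import diversity, niche, ordination
from .config import AnalysisConfig
from .data import Bundle, group_rare_taxa, split_by_stage
from .stages import StagePartition, assign_stages

log = logging.getLogger(__name__)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def _long_form(dm: diversity.DistanceMatrix) -> pd.DataFrame:
    n = len(dm.samples)
    rows = [
        (dm.samples[i], dm.samples[j], dm.matrix[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", dm.metric])


def run_pipeline(
    bundle: Bundle,
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
    partition: StagePartition | None = None,
) -> dict:
    """Execute the full analysis; returns (and optionally writes) the
    summary. Any stage failure aborts with a stage-named message; tables
    already written are retained."""
    config = config or AnalysisConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def save(df: pd.DataFrame, name: str, **kw):
        if out is not None:
            df.to_csv(out / name, **kw)

    summary: dict = {"config": config.to_dict(), "seed": config.seed}
    step = "stage assignment"
    try:
        if partition is None:
            partition = assign_stages(bundle.meta, config.stage_ranges)
        save(partition.to_frame(bundle.meta), "stages.csv")
        stage_bundles = split_by_stage(bundle, partition)
        summary["stages"] = {
            s: {"n_samples": b.n_samples, "richness": b.n_taxa, "total_count": b.grand_total}
            for s, b in stage_bundles.items()
        }
        n_unassigned = sum(
            1 for s in bundle.counts.columns
            if partition.labels.get(s) == "unassigned"
        )
        summary["n_unassigned_samples"] = n_unassigned

        step = "niche metrics"
        niche_summary = {}
        for stage, sb in stage_bundles.items():
            rec = niche.stage_niche_records(sb, config)
            save(rec, f"niche_records_{stage}.csv")
            ov = niche.overlap_tables(sb, config)
            save(ov, f"overlap_{stage}.csv", index=False)
            pd_tab = niche.pairwise_differences(
                rec, niche.pianka_overlap(niche.utilization_profiles(sb.counts))
            )
            save(pd_tab, f"pairdiff_{stage}.csv", index=False)
            save(group_rare_taxa(sb, config), f"reporting_counts_{stage}.csv")
            gs = niche.group_summary(rec)
            dom = rec.index[rec["dominant"]].tolist()
            niche_summary[stage] = {
                "dominant_species": dom,
                "n_dominant": len(dom),
                "mean_Bi_dominant": rec.loc[rec["dominant"], "Bi"].mean(),
                "mean_Bi_nondominant": rec.loc[~rec["dominant"], "Bi"].mean(),
                "mean_absdOi_dominant": rec.loc[rec["dominant"], "dOi"].abs().mean(),
                "mean_absdOi_nondominant": rec.loc[~rec["dominant"], "dOi"].abs().mean(),
                "mean_Ri_dominant": rec.loc[rec["dominant"], "Ri"].mean(),
                "mean_Ri_nondominant": rec.loc[~rec["dominant"], "Ri"].mean(),
                "mean_Oik": ov["Oik"].mean(),
                "gaps": {
                    f"{c}_{m}": g
                    for c, m, g in gs["gaps"].itertuples(index=False)
                },
            }
        summary["niche"] = niche_summary

        step = "alpha diversity"
        alpha = diversity.alpha_diversity(bundle, level="sample")
        alpha["stage"] = [partition.labels.get(s) for s in alpha.index]
        save(alpha, "alpha_diversity.csv", index_label="sample")
        staged = alpha[alpha["stage"].isin(partition.stages)]
        kw_tests = {}
        for metric in ("Chao1", "Shannon", "J"):
            groups = [
                staged.loc[staged["stage"] == s, metric].dropna()
                for s in partition.stages
            ]
            groups = [g for g in groups if len(g) > 0]
            if len(groups) >= 2:
                stat, p = kruskal(*groups)
                kw_tests[metric] = {"H": stat, "pvalue": p}
        summary["alpha_kruskal_wallis"] = kw_tests

        step = "distances and normalized dissimilarity"
        bray = diversity.bray_curtis(bundle, relative=config.bray_relative)
        save(_long_form(bray), "distances_bray.csv", index=False)
        xd = diversity.normalized_dissimilarity(bray, partition, config.epsilon)
        tables = {"Xd": xd}
        ed = None
        if bundle.env is not None:
            euc = diversity.euclidean_env(bundle.env, config.env_standardize)
            save(_long_form(euc), "distances_euclid.csv", index=False)
            ed = diversity.normalized_dissimilarity(euc, partition, config.epsilon)
            tables["Ed"] = ed
        both = pd.concat(tables, names=["index", "stage"]).reset_index()
        save(both, "xd_ed_by_stage.csv", index=False)
        summary["dissimilarity"] = {
            name: tab["mean"].to_dict() for name, tab in tables.items()
        }

        step = "beta partition"
        beta = diversity.beta_partition(bundle, partition, scope="multisite")
        save(beta, "beta_partition.csv")
        overall = diversity.beta_multisite(bundle.counts)
        summary["beta"] = {
            "per_stage": {s: dict(r) for s, r in beta.iterrows()},
            "overall": overall,
            "turnover_exceeds_nestedness": bool(
                overall["beta_SIM"] > overall["beta_SNE"]
            ),
        }

        step = "environment summary"
        if bundle.env is not None:
            envsum = diversity.env_summary(bundle.env, partition)
            save(envsum, "env_summary.csv", index=False)
            summary["env_cv_pct"] = {
                s: envsum.loc[envsum["stage"] == s]
                .set_index("variable")["cv_pct"]
                .to_dict()
                for s in partition.stages
            }

        step = "ordination"
        staged_samples = [
            s for s in bundle.counts.columns
            if partition.labels.get(s) in partition.stages
        ]
        labels = np.array([partition.labels[s] for s in staged_samples])
        idx = [bray.samples.index(s) for s in staged_samples]
        bray_staged = diversity.DistanceMatrix(
            staged_samples, bray.matrix[np.ix_(idx, idx)], "bray"
        )
        pc = ordination.pcoa(bray_staged)
        save(pc.coordinates, "pcoa_coords.csv", index_label="sample")
        save(
            pd.DataFrame({"eigenvalue": pc.eigenvalues}),
            "pcoa_eigen.csv", index_label="axis",
        )
        summary["pcoa"] = {
            "proportion_explained_first2": _first2(pc.proportion_explained),
            "n_negative_eigenvalues": int(len(pc.negative_eigenvalues)),
        }

        step = "permutation tests (community)"
        nperm, seed = config.permutations, config.seed
        tests = {}
        tests["permanova_community"] = ordination.permanova(
            bray_staged, labels, nperm, seed + 11
        )
        tests["permdisp_community"] = ordination.permdisp(
            bray_staged, labels, nperm, seed + 12
        )
        tests["anosim_community"] = ordination.anosim(
            bray_staged, labels, nperm, seed + 13
        )
        if bundle.env is not None:
            step = "permutation tests (environment)"
            env_staged = bundle.env.loc[staged_samples]
            euc_staged = diversity.euclidean_env(env_staged, config.env_standardize)
            tests["permanova_env"] = ordination.permanova(
                euc_staged, labels, nperm, seed + 21
            )
            tests["permdisp_env"] = ordination.permdisp(
                euc_staged, labels, nperm, seed + 22
            )
            tests["anosim_env"] = ordination.anosim(
                euc_staged, labels, nperm, seed + 23
            )
        for name, t in tests.items():
            if out is not None:
                (out / f"{name}.json").write_text(
                    json.dumps(_jsonable(t.to_dict()), sort_keys=True, indent=1)
                )
        summary["tests"] = {k: _jsonable(t.to_dict()) for k, t in tests.items()}

        step = "RDA"
        if bundle.env is not None:
            sub = bundle.subset_samples(staged_samples).drop_empty_taxa()
            res = ordination.rda(
                sub.counts, bundle.env.loc[staged_samples],
                n_perm=nperm, seed=seed + 31,
            )
            save(res.ordination.coordinates, "rda_axes.csv", index_label="sample")
            scores = pd.concat(
                {"env": res.env_scores, "species": res.species_scores},
                names=["score_type", "name"],
            )
            save(scores, "rda_scores.csv")
            summary["rda"] = {
                "constrained_proportion": res.constrained_proportion,
                "axes_pct_first2": _first2(res.ordination.proportion_explained),
                "pseudo_F": res.test.statistic,
                "pvalue": res.test.pvalue,
                "dropped_variables": res.dropped_variables,
            }
            summary["rda_dominant_by_stage"] = {}
            for stage, sb in stage_bundles.items():
                dom = [
                    s for s in niche_summary[stage]["dominant_species"]
                    if s in sb.counts.index
                ]
                r = _stage_dominant_rda(sb, bundle.env, dom, config, seed + 41)
                if r is not None:
                    summary["rda_dominant_by_stage"][stage] = r
    except Exception as err:  # noqa: BLE001 - re-raise with the failing stage named
        raise RuntimeError(f"pipeline failed at step: {step}: {err}") from err

    summary = _jsonable(summary)
    if out is not None:
        (out / "summary.json").write_text(
            json.dumps(summary, sort_keys=True, indent=1) + "\n"
        )
    return summary


def _first2(prop: np.ndarray) -> list[float]:
    return [float(100 * p) for p in prop[:2]]


def _stage_dominant_rda(sb: Bundle, env, dominant, config, seed):
    """RDA of a stage's dominant-species abundances on its environment.

    A stage has few samples, so the environmental table is reduced to the
    variables with highest within-stage CV% until fewer variables than
    samples remain (the selection is logged).
    """
    if len(dominant) < 2 or sb.n_samples < 4:
        log.info("dominant-species RDA skipped (too few species or samples)")
        return None
    stage_env = env.loc[sb.counts.columns]
    max_vars = sb.n_samples - 2
    if stage_env.shape[1] > max_vars:
        cv = (stage_env.std(ddof=1) / stage_env.mean().abs().replace(0, np.nan)).abs()
        keep = cv.sort_values(ascending=False).index[:max_vars].tolist()
        log.info("dominant-species RDA uses top-CV variables: %s", keep)
        stage_env = stage_env[sorted(keep)]
    res = ordination.rda(
        sb.counts.loc[dominant], stage_env, n_perm=config.permutations, seed=seed
    )
    return {
        "axes_pct_first2": _first2(res.ordination.proportion_explained),
        "constrained_proportion": res.constrained_proportion,
        "pvalue": res.test.pvalue,
        "variables": list(stage_env.columns),
    }
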