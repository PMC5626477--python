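"""End-to-end synthetic study driver.

``run_full_study`` replays the whole design on synthetic data: a trained
ASD-like arm whose target-target coupling is programmed to rise while the
target-control couplings fall, and a TD-like control arm with no programmed
change on the trained pairs.  It produces, in order, the cohorts, feedback
logs, connectivity records, day-contrast statistics, the group interaction,
a small voxelwise change-map analysis with cluster correction, the
brain-behavior analysis, and a single JSON + markdown report.  Every
stochastic stage derives its seed from the study seed, and the report embeds
the full provenance, so the same config reproduces the same bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from covertnf.behavior import brain_behavior_correlation, flag_outliers, partial_brain_behavior
from covertnf.cohort import (
    CohortSpec,
    SyntheticBehaviorSpec,
    VoxelGridSpec,
    generate_behavior,
    generate_reference_changes,
    generate_roi_cohort,
    generate_voxel_cohort,
)
from covertnf.connectivity import pairwise_connectivity, validate_proxy
from covertnf.feedback import run_feedback_session
from covertnf.learning import (
    aggregate_by_day,
    day_contrast_permutation,
    group_interaction,
    paired_changes,
    retention_analysis,
)
from covertnf.voxelmaps import cluster_permutation_correct, subject_change_map


@dataclass
class StudyConfig:
    """All knobs of the synthetic study, each stage's seed derived from one."""

    seed: int = 0
    asd_spec: CohortSpec | None = None
    td_spec: CohortSpec | None = None
    n_iterations: int = 5000
    day_a: str = "day1"
    day_b: str = "day4"
    # voxelwise stage (kept small; set n_voxel_subjects=0 to skip)
    n_voxel_subjects: int = 10
    voxel_runs_per_day: int = 2
    voxel_coupling_delta: float = 0.3
    voxel_n_permutations: int = 500
    # behavior stage
    behavior_spec: SyntheticBehaviorSpec | None = None

    def resolve(self) -> "StudyConfig":
        if self.asd_spec is None:
            self.asd_spec = CohortSpec.asd_like(seed=self.seed)
        if self.td_spec is None:
            self.td_spec = CohortSpec.td_like(seed=self.seed + 1)
        if self.behavior_spec is None:
            self.behavior_spec = SyntheticBehaviorSpec(seed=self.seed)
        return self


def _corr_result_dict(res) -> dict:
    return {"r": res.r, "p": res.p_value, "n": res.n, "degenerate": res.degenerate}


def run_full_study(config: StudyConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage of the synthetic study; optionally write the report."""
    config = config.resolve()
    report: dict = {"config": {"seed": config.seed, "n_iterations": config.n_iterations}}

    # --- cohorts -----------------------------------------------------------
    asd = generate_roi_cohort(config.asd_spec)
    td = generate_roi_cohort(config.td_spec)
    report["cohorts"] = {
        "asd": {"n_subjects": config.asd_spec.n_subjects, "repaired_days": asd.repaired_days},
        "td": {"n_subjects": config.td_spec.n_subjects, "repaired_days": td.repaired_days},
    }

    # --- feedback ----------------------------------------------------------
    fb_runs = asd.select(run_type="feedback")
    logs = [run_feedback_session(r) for r in fb_runs]
    report["feedback"] = {
        "n_runs": len(logs),
        "mean_fired_fraction": float(np.mean([l.fired_fraction for l in logs])),
        "mean_pieces_per_run": float(np.mean([l.pieces_revealed for l in logs])),
        "mean_boards_per_run": float(np.mean([l.boards_completed for l in logs])),
    }

    # --- connectivity ------------------------------------------------------
    records = {
        "asd": [pairwise_connectivity(r) for r in asd.runs],
        "td": [pairwise_connectivity(r) for r in td.runs],
    }
    proxy = validate_proxy(
        fb_runs, n_iterations=config.n_iterations, seed=config.seed + 11
    )
    report["proxy_validation"] = {
        "r": proxy["proxy_pearson_correlation"],
        "p": proxy["permutation_p"],
        "within_subject_mean": proxy.get("within_subject_mean"),
        "n_runs": proxy["n_runs"],
    }

    # --- learning ----------------------------------------------------------
    summaries = {g: aggregate_by_day(records[g], scope="feedback_all") for g in records}
    contrasts = {}
    for measure in ("composite", "r_t1t2", "r_t1c", "r_t2c"):
        res = day_contrast_permutation(
            summaries["asd"],
            config.day_a,
            config.day_b,
            measure=measure,
            n_iterations=config.n_iterations,
            seed=config.seed + 21,
        )
        contrasts[measure] = {"mean_change": res.mean_change, "p": res.p_value}
    td_res = day_contrast_permutation(
        summaries["td"],
        config.day_a,
        config.day_b,
        measure="composite",
        n_iterations=config.n_iterations,
        seed=config.seed + 22,
    )
    asd_changes = paired_changes(summaries["asd"], config.day_a, config.day_b, "composite")
    td_changes = paired_changes(summaries["td"], config.day_a, config.day_b, "composite")
    inter = group_interaction(asd_changes, td_changes)
    report["learning"] = {
        "asd_contrasts_day1_day4": contrasts,
        "asd_fraction_positive_composite": float((asd_changes > 0).mean()),
        "td_composite": {"mean_change": td_res.mean_change, "p": td_res.p_value},
        "group_interaction": {
            "t": inter.t_statistic,
            "df": inter.df,
            "p": inter.p_value,
        },
    }

    # --- rest transfer & retention ----------------------------------------
    rest_pre = aggregate_by_day(records["asd"], scope="rest_pre")
    rest_res = day_contrast_permutation(
        rest_pre, config.day_a, config.day_b, "composite",
        n_iterations=config.n_iterations, seed=config.seed + 23,
    )
    report["rest_transfer"] = {"mean_change": rest_res.mean_change, "p": rest_res.p_value}
    if "followup" in config.asd_spec.days:
        rng = np.random.default_rng([config.seed, 31])
        weeks = {
            sid: float(w)
            for sid, w in zip(asd.subject_ids, rng.uniform(5, 56, len(asd.subject_ids)))
        }
        first2 = aggregate_by_day(records["asd"], scope="feedback_first2")
        ret = retention_analysis(
            first2, weeks, n_iterations=config.n_iterations, seed=config.seed + 32
        )
        report["retention"] = {
            # the ratio is heavy-tailed when a subject's training change is
            # small, so the median is the stable summary
            "median_retention": float(ret.retention.median()),
            "mean_retention": float(ret.retention.mean()),
            "r_vs_elapsed_weeks": ret.pearson_r,
            "p": ret.p_value,
            "n_excluded": ret.n_excluded,
        }

    # --- voxelwise maps ----------------------------------------------------
    if config.n_voxel_subjects >= 5:
        vspec = VoxelGridSpec(
            baseline_coupling=np.eye(3),
            day_deltas={config.day_b: (config.voxel_coupling_delta, 0.0, 0.0)},
        )
        cspec = CohortSpec(
            n_subjects=config.n_voxel_subjects,
            days=(config.day_a, config.day_b),
            runs_per_day={
                "rest_pre": 0,
                "feedback": config.voxel_runs_per_day,
                "rest_post": 0,
            },
            day_deltas={},
            seed=config.seed + 41,
        )
        vc = generate_voxel_cohort(vspec, cspec)
        grids = [
            subject_change_map(vc, s, config.day_a, config.day_b).data
            for s in range(config.n_voxel_subjects)
        ]
        excl = vc.roi_masks["target1"] | vc.roi_masks["control"]
        corr = cluster_permutation_correct(
            grids,
            n_permutations=config.voxel_n_permutations,
            seed=config.seed + 42,
            exclude_mask=excl,
        )
        peak_in_target2 = False
        if len(corr.clusters):
            top = corr.clusters.sort_values("size", ascending=False).iloc[0]
            if top.peak_index is not None:
                peak_in_target2 = bool(vc.network_masks["network2"][tuple(top.peak_index)])
        report["voxelwise"] = {
            "min_cluster_sizes": {str(k): v for k, v in corr.min_cluster_sizes.items()},
            "n_surviving_clusters": int(len(corr.clusters)),
            "union_mask_voxels": int(corr.union_mask.sum()),
            "largest_cluster_peak_in_network2": peak_in_target2,
        }

    # --- behavior ----------------------------------------------------------
    rest_post = aggregate_by_day(records["asd"], scope="rest_post")
    pre_c = rest_pre[rest_pre.day == config.day_a].set_index("subject_id")["composite"]
    post_c = rest_post[rest_post.day == config.day_b].set_index("subject_id")["composite"]
    conn_change = (post_c - pre_c).dropna()
    behavior = generate_behavior(conn_change, config.behavior_spec)
    reference = generate_reference_changes(
        mean=config.behavior_spec.reference_mean,
        sd=config.behavior_spec.reference_sd,
        seed=config.seed + 51,
    )
    behavior = flag_outliers(behavior, reference, "srs_change")
    bb = brain_behavior_correlation(
        conn_change.loc[behavior.index],
        behavior["srs_change"],
        behavior["outlier_flag"],
        n_iterations=config.n_iterations,
        seed=config.seed + 52,
    )
    keep = ~behavior["outlier_flag"].to_numpy()
    partial = partial_brain_behavior(
        conn_change.loc[behavior.index].to_numpy()[keep],
        behavior["srs_change"].to_numpy()[keep],
        np.column_stack(
            [behavior["srs_pre"].to_numpy()[keep], pre_c.loc[behavior.index].to_numpy()[keep]]
        ),
        n_iterations=config.n_iterations,
        seed=config.seed + 53,
    )
    brief = brain_behavior_correlation(
        conn_change.loc[behavior.index],
        behavior["brief_change"],
        behavior["outlier_flag"],
        n_iterations=config.n_iterations,
        seed=config.seed + 54,
    )
    report["behavior"] = {
        "srs": {
            "with_outliers": _corr_result_dict(bb.with_outliers),
            "without_outliers": _corr_result_dict(bb.without_outliers),
            "n_excluded": bb.n_excluded,
        },
        "partial_srs_controlling_baselines": _corr_result_dict(partial),
        "brief_without_outliers": _corr_result_dict(brief.without_outliers),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        (out_dir / "report.md").write_text(_markdown_report(report))
    return report


def _markdown_report(report: dict) -> str:
    lines = ["# Synthetic covert-neurofeedback study report", ""]
    fb = report["feedback"]
    lines += [
        "## Feedback",
        f"- mean fired fraction: {fb['mean_fired_fraction']:.3f}",
        f"- mean pieces / run: {fb['mean_pieces_per_run']:.1f}",
        "",
        "## Proxy validation",
        f"- proxy vs Pearson r: {report['proxy_validation']['r']:.3f} "
        f"(p = {report['proxy_validation']['p']:.2g})",
        "",
        "## Learning (trained arm, day1 -> day4)",
    ]
    for m, c in report["learning"]["asd_contrasts_day1_day4"].items():
        lines.append(f"- {m}: mean change {c['mean_change']:+.3f}, p = {c['p']:.2g}")
    gi = report["learning"]["group_interaction"]
    lines += [
        f"- control arm composite p = {report['learning']['td_composite']['p']:.2g}",
        f"- group interaction: t = {gi['t']:.2f}, df = {gi['df']:.1f}, p = {gi['p']:.2g}",
        "",
    ]
    if "voxelwise" in report:
        v = report["voxelwise"]
        lines += [
            "## Voxelwise change map",
            f"- surviving clusters: {v['n_surviving_clusters']}"
            f" (union mask {v['union_mask_voxels']} voxels)",
            f"- largest-cluster peak inside network2: {v['largest_cluster_peak_in_network2']}",
            "",
        ]
    b = report["behavior"]["srs"]["without_outliers"]
    lines += [
        "## Brain-behavior",
        f"- SRS change vs rest change (outliers excluded): r = {b['r']:.3f}, p = {b['p']:.2g}",
        "",
    ]
    return "\n".join(lines)
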