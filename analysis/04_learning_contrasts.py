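"""Learning inference: day contrasts, subsets, interaction, rest, retention.

Reproduces the full learning analysis chain on the synthetic arms:
day1->day4 permutation contrasts for each connectivity measure, robustness
over all C(17,10) subject subsets, the Welch interaction between arms, the
pre-feedback rest-transfer contrast, and retention at follow-up vs elapsed
time.  Results go to results/learning.json.
"""

import json
import sys
from pathlib import Path

import numpy as np

from covertnf.cohort import CohortSpec, generate_roi_cohort
from covertnf.connectivity import pairwise_connectivity
from covertnf.learning import (
    aggregate_by_day,
    day_contrast_permutation,
    group_interaction,
    paired_changes,
    retention_analysis,
    subset_robustness,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results")
N_ITER = 5000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = {}
    for name, spec in (("asd", CohortSpec.asd_like(seed=SEED)),
                       ("td", CohortSpec.td_like(seed=SEED + 1))):
        cohort = generate_roi_cohort(spec)
        records[name] = [pairwise_connectivity(r) for r in cohort.runs]
    out: dict = {}

    summ = {g: aggregate_by_day(records[g], scope="feedback_all") for g in records}
    print("trained arm, day1 -> day4 (feedback runs):")
    out["asd_contrasts"] = {}
    for measure in ("r_t1t2", "r_t1c", "r_t2c", "composite"):
        res = day_contrast_permutation(summ["asd"], "day1", "day4", measure,
                                       n_iterations=N_ITER, seed=SEED)
        out["asd_contrasts"][measure] = {"mean_change": res.mean_change, "p": res.p_value}
        print(f"  {measure:9s} mean change {res.mean_change:+.3f}   p = {res.p_value:.2g}")

    sub = subset_robustness(summ["asd"], "day1", "day4", "composite",
                            subset_size=10, n_iterations=1000, seed=SEED)
    out["subsets"] = {
        "n_subsets": sub.n_subsets,
        "mean_change_range": sub.mean_change_range,
        "fraction_significant": sub.fraction_significant,
    }
    print(f"\nall {sub.n_subsets} subsets of 10: mean change in "
          f"[{sub.mean_change_range[0]:+.3f}, {sub.mean_change_range[1]:+.3f}], "
          f"{100 * sub.fraction_significant:.1f}% significant at 0.05")

    td_res = day_contrast_permutation(summ["td"], "day1", "day4", "composite",
                                      n_iterations=N_ITER, seed=SEED)
    inter = group_interaction(
        paired_changes(summ["asd"], "day1", "day4", "composite"),
        paired_changes(summ["td"], "day1", "day4", "composite"),
    )
    out["td_composite"] = {"mean_change": td_res.mean_change, "p": td_res.p_value}
    out["group_interaction"] = {"t": inter.t_statistic, "df": inter.df, "p": inter.p_value}
    print(f"control arm composite: {td_res.mean_change:+.3f} (p = {td_res.p_value:.2g})")
    print(f"arm interaction (Welch): t = {inter.t_statistic:.2f}, "
          f"df = {inter.df:.1f}, p = {inter.p_value:.2g}")

    rest = aggregate_by_day(records["asd"], scope="rest_pre")
    rest_res = day_contrast_permutation(rest, "day1", "day4", "composite",
                                        n_iterations=N_ITER, seed=SEED)
    out["rest_transfer"] = {"mean_change": rest_res.mean_change, "p": rest_res.p_value}
    print(f"pre-feedback rest transfer: {rest_res.mean_change:+.3f} "
          f"(p = {rest_res.p_value:.2g})")

    rng = np.random.default_rng([SEED, 31])
    sids = sorted({r.subject_id for r in records["asd"]})
    weeks = {sid: float(w) for sid, w in zip(sids, rng.uniform(5, 56, len(sids)))}
    first2 = aggregate_by_day(records["asd"], scope="feedback_first2")
    ret = retention_analysis(first2, weeks, n_iterations=N_ITER, seed=SEED)
    out["retention"] = {
        "median_retention": float(ret.retention.median()),
        "r_vs_weeks": ret.pearson_r,
        "p": ret.p_value,
    }
    print(f"retention at follow-up: median {ret.retention.median():.2f}; "
          f"r vs elapsed weeks = {ret.pearson_r:+.3f} (p = {ret.p_value:.2g})")

    (OUT / "learning.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"\nwritten: {OUT / 'learning.json'}")


if __name__ == "__main__":
    main()
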