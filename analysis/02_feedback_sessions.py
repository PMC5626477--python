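"""Stream every feedback run through the two-point decision engine.

Writes per-run feedback summaries to results/feedback_summary.tsv and
prints the day-by-day mean fired fraction for the trained arm.  Because the
rule fires on trend agreement, its rate tracks the programmed connectivity:
near the 0.25 chance level on day1 and rising with training.
"""

import sys
from pathlib import Path

import pandas as pd

from covertnf.cohort import CohortSpec, generate_roi_cohort
from covertnf.feedback import run_feedback_session

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = generate_roi_cohort(CohortSpec.asd_like(seed=SEED))
    rows = []
    for run in cohort.select(run_type="feedback"):
        log = run_feedback_session(run)
        rows.append(
            {
                "subject_id": run.subject_id,
                "day": run.day,
                "run_index": run.run_index,
                "fired_fraction": log.fired_fraction,
                "pieces_revealed": log.pieces_revealed,
                "boards_completed": log.boards_completed,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "feedback_summary.tsv", sep="\t", index=False)
    print("mean fired fraction by day (chance level = 0.25):")
    print(table.groupby("day").fired_fraction.mean().round(3).to_string())
    print(f"\nmean pieces per 9-min run: {table.pieces_revealed.mean():.1f} "
          f"(boards: {table.boards_completed.mean():.2f})")
    print(f"written: {OUT / 'feedback_summary.tsv'}")


if __name__ == "__main__":
    main()
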