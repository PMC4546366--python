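"""Simulate the three-arm cine cohort and measure every study.

Generates the sham / MI / MI+Val cohort (12 animals per arm, four
timepoints, anterior-infarct contraction fields, exponential mortality in
the infarcted arms), runs the full measurement pipeline on every surviving
study, and writes:

  results/cohort_table.csv   tidy (subject, group, timepoint, index, value)
  results/rfac_maps.csv      resampled 10-slice RFAC per subject map cell
  results/survival.csv       per-subject survival records

Run from the repository root:  python analysis/01_simulate_cohort.py
"""

from pathlib import Path

import pandas as pd

from rfackit import (
    compute_rfac,
    default_cohort_design,
    detect_ed_es,
    generate_cohort,
    resample_slices,
    sector_areas,
)

SEED = 7
OUT = Path("results")


def main():
    OUT.mkdir(exist_ok=True)
    design = default_cohort_design(n_per_group=12, matrix_px=96, jitter_px=0.4, seed=SEED)
    cohort = generate_cohort(design)
    cohort.table.to_csv(OUT / "cohort_table.csv", index=False)
    cohort.survival.to_csv(OUT / "survival.csv", index=False)

    rows = []
    for (subj, tp), study in cohort.studies.items():
        table = sector_areas(study)
        ed, es, _ = detect_ed_es(table)
        rmap = resample_slices(compute_rfac(table, ed, es))
        group = subj.rsplit("-", 1)[0]
        for s in range(rmap.n_slices):
            for k, lab in enumerate(rmap.sector_labels):
                rows.append({"subject": subj, "group": group, "timepoint": tp,
                             "slice": s, "sector": lab,
                             "rfac_pct": rmap.rfac_pct[s, k]})
    pd.DataFrame(rows).to_csv(OUT / "rfac_maps.csv", index=False)

    n_dead = int(cohort.survival["event"].sum())
    print(f"simulated {len(cohort.studies)} studies "
          f"({cohort.survival.shape[0]} animals, {n_dead} deaths before 4w)")
    ip = cohort.table[cohort.table["index"] == "ipRFAC"]
    print("group-mean ipRFAC (%):")
    print(ip.pivot_table(index="group", columns="timepoint", values="value")
          .reindex(columns=["baseline", "24h", "1w", "4w"]).round(1))


if __name__ == "__main__":
    main()
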