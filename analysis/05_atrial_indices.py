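"""Summarise the echo-derived atrial indices per group and timepoint.

Builds the mean +/- SEM table of LA Vmin, LA Vmax, LA EF, LAA length and
LAA duct FS from the simulated cohort and tests the 4w MI vs MI+Val
differences (unpaired t-test per index).  Writes results/table_atrial.csv.

Requires results/cohort_table.csv from 01_simulate_cohort.py.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

INDICES = ["LA Vmin", "LA Vmax", "LA EF", "LAA length", "LAA duct FS"]


def main():
    table = pd.read_csv(Path("results/cohort_table.csv"))
    sel = table[table["index"].isin(INDICES)]
    summary = (
        sel.groupby(["timepoint", "group", "index"])["value"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="count")
        .round(2).reset_index()
    )
    out = Path("results/table_atrial.csv")
    summary.to_csv(out, index=False)
    print(f"wrote {out}")
    wide = summary.pivot_table(index=["timepoint", "group"], columns="index",
                               values="mean").reindex(columns=INDICES)
    print(wide.reindex(["baseline", "24h", "1w", "4w"], level=0).round(1))

    w4 = sel[sel["timepoint"] == "4w"]
    print("\n4w MI vs MI+Val:")
    for idx in INDICES:
        a = w4[(w4["index"] == idx) & (w4.group == "MI")]["value"]
        b = w4[(w4["index"] == idx) & (w4.group == "MI+Val")]["value"]
        t, p = sps.ttest_ind(a, b)
        print(f"  {idx:12s} t={t:6.2f}  p={p:.4f}")


if __name__ == "__main__":
    main()
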