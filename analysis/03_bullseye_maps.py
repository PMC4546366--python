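"""Render group-mean bull's-eye maps with MI vs MI+Val significance marks.

For each post-surgery timepoint, draws one bull's-eye per group from the
resampled 10-slice maps (apex ring at the center, six 60-degree wedges,
red = low, green = high RFAC over a fixed 0-100% scale) and annotates the
MI+Val map with the cell-wise unpaired t-test against MI: a dot for
0.05<p<0.1, * for p<0.05, ** for p<0.01.  Writes results/bullseye_*.png.

Requires results/rfac_maps.csv from 01_simulate_cohort.py.
"""

from pathlib import Path

import matplotlib.pyplot as plt
import pandas as pd

from rfackit import BullseyeGrid, render_bullseye, sectorwise_tests
from rfackit.cine import SECTOR_LABELS

OUT = Path("results")


def stack_maps(df, group, tp):
    sel = df[(df["group"] == group) & (df["timepoint"] == tp)]
    return [
        g.pivot(index="slice", columns="sector", values="rfac_pct")
        .reindex(columns=list(SECTOR_LABELS)).to_numpy()
        for _, g in sel.groupby("subject")
    ]


def main():
    df = pd.read_csv(OUT / "rfac_maps.csv")
    for tp in ("24h", "1w", "4w"):
        stacks = {g: stack_maps(df, g, tp) for g in ("sham", "MI", "MI+Val")}
        pmap = sectorwise_tests(stacks["MI"], stacks["MI+Val"]).p_value
        for group, maps in stacks.items():
            mean_map = pd.concat(
                [pd.DataFrame(m) for m in maps]
            ).groupby(level=0).mean().to_numpy()
            grid = BullseyeGrid(
                mean_map, p_value=pmap if group == "MI+Val" else None
            )
            path = OUT / f"bullseye_{group.replace('+', '')}_{tp}.png"
            fig = render_bullseye(grid, path, title=f"{group} at {tp}")
            plt.close(fig)
            print(f"wrote {path}")
        n_sig = int((pmap < 0.05).sum())
        print(f"  {tp}: {n_sig} of 60 cells differ between MI and MI+Val (p<0.05)")


if __name__ == "__main__":
    main()
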