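# rfac-kit

Regional analysis of left-ventricular (LV) systolic function from cine
short-axis cavity segmentations — for small-animal cardiac MRI groups who
need to localize contractile dysfunction and detect treatment effects that
global ejection fraction misses.

After an anterior myocardial infarction, function is lost regionally: the
infarcted territory turns akinetic while the remote inferior/posterior wall
deteriorates more subtly under adverse remodeling, and a successful therapy
shows up there first. A single global number averages all of this away.
`rfac-kit` instead divides each short-axis cavity slice into six 60° sectors
and computes the **regional fractional area change** per sector and slice,

```
RFAC = (EDA − ESA) / EDA × 100 %
```

where EDA/ESA are the sector cavity areas at end-diastole and end-systole
(chosen globally as the phases of maximal/minimal cavity volume). Profiles
are spline-resampled to a common 10-slice apex→base grid, displayed as
bull's-eye polar maps (apex at the center, red = low, green = high), and
summarized over the remote wall by

```
iRFAC, pRFAC = mid-apical means of the inferior / posterior sectors
               (resampled slices 2–7: apex slice and 3 basal slices excluded)
ipRFAC       = (iRFAC + pRFAC) / 2
```

Global volumetrics come for free — EDV/ESV by stacked disks, and
EF = 100·(EDV−ESV)/EDV, which equals the EDA-weighted mean of the regional
RFACs exactly (an identity the test suite enforces to 1e-9).

The package also ships the surrounding study machinery:

* **phantom** — a synthetic beating-LV generator with closed-form ground
  truth (`RFAC = (1−(1−c)²)·100` for radial contraction amplitude `c`),
  plus a full three-arm cohort simulator (sham / infarct / treated infarct)
  with dilatation, mortality, atrial traces and coupled expression data;
* **cine** — NIfTI / multi-page TIFF / contour-CSV readers, exact even-odd
  polygon rasterization, sector-area tables;
* **bullseye** — polar maps with significance marks (• 0.05<p<0.1,
  \* p<0.05, \*\* p<0.01);
* **stats** — Helmert and treatment contrast ANOVAs, repeated-measures
  ANOVA with Holm, sector-by-sector t-tests, noncentral-t power,
  Kaplan–Meier / log-rank;
* **echo** — Simpson method-of-disks atrial volumes, LA emptying fraction,
  appendage length and duct fractional shortening;
* **expression** — microarray probe filtering, multivariate permutation
  screens controlling the false-discovery proportion with confidence
  (FDR < 10 % with 80 % confidence), fold-change gates, and
  quantitative-trait correlation against ipRFAC.

## Worked example

Measure one synthetic study end to end:

```python
import numpy as np
from rfackit import (PhantomSpec, generate_lv_phantom, sector_areas,
                     detect_ed_es, compute_rfac, resample_slices,
                     regional_summary, global_function, analytic_rfac)

c = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])     # one amplitude per sector
spec = PhantomSpec(contraction_field=np.tile(c, (7, 1)),
                   matrix_px=256, jitter_px=0.0, transition_deg=0.0)
study = generate_lv_phantom(spec)

table = sector_areas(study)                       # areas per (slice, phase, sector)
ed, es, _ = detect_ed_es(table)
rmap = compute_rfac(table, ed, es)                # RFAC per (slice, sector)
summ = regional_summary(resample_slices(rmap))    # 10-slice grid, remote wall
glob = global_function(table, ed, es)

print("measured  ", rmap.rfac_pct[3].round(1))
print("closed form", analytic_rfac(c).round(1))
print(f"iRFAC {summ.irfac_pct:.1f}  pRFAC {summ.prfac_pct:.1f}  "
      f"ipRFAC {summ.iprfac_pct:.1f}  EF {glob.ef_pct:.1f}")
```

prints

```
measured   [19.  35.9 50.9 64.  74.9 83.9]
closed form [19. 36. 51. 64. 75. 84.]
iRFAC 84.0  pRFAC 75.0  ipRFAC 79.5  EF 54.8
```

— each sector recovers its closed-form RFAC to a fraction of a percent, and
the remote-wall indices and EF follow. (The sector order is anterior,
antero-septal, septal, lateral, posterior, inferior; EF is the EDA-weighted
mean of the map.)

## The study workflow

Numbered drivers under `analysis/` run the whole simulated study from the
repository root and write tables/figures to `results/`:

```
python analysis/01_simulate_cohort.py     # cine cohort -> tidy tables
python analysis/02_regional_function.py   # Table-1-style regional/global summary
python analysis/03_bullseye_maps.py       # group bull's-eyes with p-marks
python analysis/04_cohort_statistics.py   # contrast ANOVAs, RM-ANOVA, log-rank, power
python analysis/05_atrial_indices.py      # Table-2-style atrial summary
python analysis/06_expression_screen.py   # filtering + permutation screens
```

With the default design (12/arm), the untreated infarct's group-mean ipRFAC
falls from ~72 % at baseline to ~19 % at 4 weeks while the treated arm holds
~35 %, the sector-by-sector comparison finds ~24 of 60 bull's-eye cells
significantly different between the arms at 4 weeks (9 at 24 h — the
treatment effect grows), EDV dilates 42 → 117 μl untreated vs 42 → 90 μl
treated, and the expression screens recover most planted class-affected and
trait-coupled genes.

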