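"""Regional fractional area change, slice resampling, and global volumetrics.

RFAC is computed per sector and slice as

    RFAC = (EDA - ESA) / EDA * 100,

where EDA and ESA are the sector cavity areas at the end-diastolic and
end-systolic phases (chosen globally as the phases of maximal / minimal total
cavity volume).  To compare hearts covered by different slice counts, the
per-sector RFAC profiles are resampled by cubic spline to a common 10-slice
apex-to-base grid; the remote-wall summary indices iRFAC and pRFAC average
the inferior and posterior sectors over the mid-apical window (resampled
slices 2-7, excluding the apex slice and the three basal slices), and ipRFAC
is their mean.  Global volumes use stacked-disk summation (area x spacing),
and the ejection fraction equals the EDA-weighted mean of the regional RFACs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .cine import SectorAreaTable

__all__ = [
    "EDES",
    "GlobalFunction",
    "RFACMap",
    "RegionalSummary",
    "MID_APICAL_WINDOW",
    "compute_rfac",
    "detect_ed_es",
    "global_function",
    "regional_summary",
    "resample_slices",
]

#: Resampled-slice window (0-based, inclusive-exclusive) for the mid-apical
#: summary: slices 2-7 of 10 in 1-based terms (apex slice and three basal
#: slices excluded).
MID_APICAL_WINDOW = (1, 7)


class EDES(NamedTuple):
    ed_phase: int
    es_phase: int
    degenerate: bool


@dataclass
class RFACMap:
    """RFAC (%) per (slice, sector); NaN marks missing cells."""

    rfac_pct: np.ndarray  # (n_slices, n_sectors)
    slice_pos: np.ndarray  # normalized apex->base in [0, 1]
    sector_labels: tuple
    resampled: bool
    ed_phase: int
    es_phase: int
    subject_id: str = "subject"

    @property
    def n_slices(self) -> int:
        return self.rfac_pct.shape[0]

    def to_frame(self) -> pd.DataFrame:
        n_s, n_k = self.rfac_pct.shape
        idx = pd.MultiIndex.from_product(
            [range(n_s), self.sector_labels], names=["slice", "sector"]
        )
        df = pd.DataFrame({"rfac_pct": self.rfac_pct.ravel()}, index=idx).reset_index()
        df.insert(0, "subject", self.subject_id)
        return df


@dataclass
class GlobalFunction:
    """Stacked-disk LV volumes (ul) and ejection fraction (%)."""

    edv_ul: float
    esv_ul: float
    sv_ul: float
    ef_pct: float


@dataclass
class RegionalSummary:
    """Mid-apical remote-wall indices (%): inferior, posterior, their mean."""

    irfac_pct: float
    prfac_pct: float
    iprfac_pct: float


def detect_ed_es(table: SectorAreaTable) -> EDES:
    """End-diastolic / end-systolic phases from total cavity area.

    ED maximizes and ES minimizes the cavity area summed over slices; ties go
    to the earlier phase.  If every phase has identical total area the result
    is (0, 0) with ``degenerate=True``.
    """
    totals = table.total_area_mm2.sum(axis=0)
    if totals.size < 2:
        raise ValueError("need at least 2 phases")
    if np.allclose(totals, totals[0]):
        warnings.warn("cavity area constant across phases; ED/ES undefined")
        return EDES(0, 0, True)
    return EDES(int(np.argmax(totals)), int(np.argmin(totals)), False)


def compute_rfac(table: SectorAreaTable, ed: int, es: int) -> RFACMap:
    """RFAC per (slice, sector) from the chosen ED/ES phases.

    Cells with zero end-diastolic area are marked missing (NaN) with a
    warning, never reported as zero.
    """
    eda = table.area_mm2[:, ed, :]
    esa = table.area_mm2[:, es, :]
    rfac = np.full(eda.shape, np.nan)
    ok = eda > 0
    rfac[ok] = 100.0 * (eda[ok] - esa[ok]) / eda[ok]
    if not ok.all():
        bad = np.argwhere(~ok)
        warnings.warn(f"zero end-diastolic area in {len(bad)} cell(s); marked missing")
    n_s = eda.shape[0]
    pos = np.linspace(0.0, 1.0, n_s) if n_s > 1 else np.array([0.0])
    return RFACMap(
        rfac_pct=rfac,
        slice_pos=pos,
        sector_labels=table.sector_labels,
        resampled=False,
        ed_phase=ed,
        es_phase=es,
        subject_id=table.subject_id,
    )


def resample_slices(rmap: RFACMap, n_out: int = 10, kind: str = "not-a-knot") -> RFACMap:
    """Resample each sector's apex-to-base RFAC profile to ``n_out`` slices.

    A cubic spline (not-a-knot by default; ``kind="natural"`` for a natural
    spline) is fitted through (slice position, RFAC) per sector and evaluated
    at ``n_out`` equally spaced positions spanning [0, 1].  Sectors with
    missing cells are fitted on the available slices only; fewer than 4
    available points falls back to linear interpolation with a warning, and
    an all-missing sector stays all-missing.
    """
    if kind not in ("not-a-knot", "natural"):
        raise ValueError("kind must be 'not-a-knot' or 'natural'")
    pos_out = np.linspace(0.0, 1.0, n_out)
    n_k = rmap.rfac_pct.shape[1]
    out = np.full((n_out, n_k), np.nan)
    for k in range(n_k):
        y = rmap.rfac_pct[:, k]
        ok = np.isfinite(y)
        if not ok.any():
            continue
        x = rmap.slice_pos[ok]
        if ok.sum() >= 4:
            spl = CubicSpline(x, y[ok], bc_type=kind)
            out[:, k] = spl(pos_out)
        elif ok.sum() >= 2:
            warnings.warn(
                f"sector '{rmap.sector_labels[k]}' has {int(ok.sum())} slices; "
                "falling back to linear interpolation"
            )
            out[:, k] = np.interp(pos_out, x, y[ok])
        else:
            out[:, k] = y[ok][0]
    return RFACMap(
        rfac_pct=out,
        slice_pos=pos_out,
        sector_labels=rmap.sector_labels,
        resampled=True,
        ed_phase=rmap.ed_phase,
        es_phase=rmap.es_phase,
        subject_id=rmap.subject_id,
    )


def regional_summary(rmap: RFACMap) -> RegionalSummary:
    """Mid-apical remote-wall indices from a resampled 10-slice map.

    iRFAC (pRFAC) averages the inferior (posterior) sector over resampled
    slices 2-7 (1-based), i.e. excluding the apex slice and the three basal
    slices; ipRFAC is their mean.  Missing cells inside the window are
    dropped from the average with a warning.
    """
    if not rmap.resampled:
        raise ValueError("regional_summary requires a resampled map")
    lo, hi = MID_APICAL_WINDOW
    vals = {}
    for name in ("inferior", "posterior"):
        k = rmap.sector_labels.index(name)
        window = rmap.rfac_pct[lo:hi, k]
        if np.isnan(window).any():
            warnings.warn(f"missing cells in the {name} mid-apical window")
        vals[name] = float(np.nanmean(window))
    return RegionalSummary(
        irfac_pct=vals["inferior"],
        prfac_pct=vals["posterior"],
        iprfac_pct=(vals["inferior"] + vals["posterior"]) / 2.0,
    )


def global_function(table: SectorAreaTable, ed: int | None = None, es: int | None = None) -> GlobalFunction:
    """Stacked-disk volumes and ejection fraction.

    EDV = sum over slices of total cavity area at ED times slice spacing
    (mm^3 = ul); likewise ESV.  EF = 100 (EDV - ESV)/EDV; with uniform
    spacing this equals the EDA-weighted mean of the per-cell RFACs.
    """
    if ed is None or es is None:
        ed, es, _ = detect_ed_es(table)
    edv = float(table.total_area_mm2[:, ed].sum() * table.slice_spacing_mm)
    esv = float(table.total_area_mm2[:, es].sum() * table.slice_spacing_mm)
    if edv <= 0:
        raise ValueError("end-diastolic volume is zero")
    sv = edv - esv
    return GlobalFunction(edv_ul=edv, esv_ul=esv, sv_ul=sv, ef_pct=100.0 * sv / edv)
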