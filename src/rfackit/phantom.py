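"""Synthetic beating-LV phantom, cohorts, atrial traces, and expression data.

The phantom emulates a mouse left ventricle imaged as 6-8 short-axis slices
spaced 1 mm: each slice's cavity is a star-convex region whose boundary radius
contracts over the cardiac cycle,

    rho(theta, t, s) = R(s) * (1 - c(theta, s) * g(t)),

where R(s) is the end-diastolic endocardial radius of slice s (apex to base),
c(theta, s) is a per-sector radial contraction amplitude smoothly blended
across sector boundaries, and g(t) is a periodic waveform with g(0) = 0
(end-diastole) and maximum 1 at end-systole.  Because contraction acts on the
radius, a sector with uniform amplitude c has a closed-form regional
fractional area change of (1 - (1 - c)^2) * 100 percent, which every
downstream measurement can be checked against.

Cohort generation layers group structure on top (sham / MI / MI+Val with
infarct-territory hypokinesis and exponential mortality), plus synthetic
atrial traces and a log-normal expression model with genes linearly coupled
to the remote-wall contraction index on the log scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cine import SECTOR_LABELS, CineStudy, sector_areas
from .echo import AtrialTrace, la_ef, spindle_polygon
from .rfac import compute_rfac, detect_ed_es, global_function, regional_summary, resample_slices

__all__ = [
    "PhantomSpec",
    "GroupSpec",
    "CohortDesign",
    "CohortResult",
    "ExpressionModel",
    "analytic_rfac",
    "blend_contraction",
    "contraction_for_rfac",
    "default_cohort_design",
    "generate_cohort",
    "generate_expression",
    "generate_lv_phantom",
]


def analytic_rfac(c) -> np.ndarray:
    """Closed-form RFAC (%) of a sector with uniform radial contraction c."""
    c = np.asarray(c, dtype=float)
    return (1.0 - (1.0 - c) ** 2) * 100.0


def contraction_for_rfac(rfac_pct) -> np.ndarray:
    """Radial contraction amplitude producing a target RFAC (%)."""
    r = np.asarray(rfac_pct, dtype=float)
    return 1.0 - np.sqrt(1.0 - r / 100.0)


def _default_waveform(n_phases: int) -> np.ndarray:
    g = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n_phases) / n_phases))
    return g / g.max()


@dataclass
class PhantomSpec:
    """Geometry and motion parameters of one synthetic cine study.

    ``radius_profile`` holds end-diastolic endocardial radii (mm) per slice,
    apex to base; ``contraction_field`` is (n_slices, n_sectors) with values
    in (-0.3, 0.9) (negative = paradoxical bulging).  ``waveform`` may be an
    array of length ``n_phases``; by default a raised cosine with g(0)=0 and
    peak 1 at mid-cycle.  ``jitter_px`` is the SD (pixels) of smooth angular
    boundary noise, independent per frame.
    """

    n_slices: int = 7
    n_phases: int = 8
    matrix_px: int = 128
    pixel_mm: float = 0.1
    slice_spacing_mm: float = 1.0
    radius_profile: np.ndarray | None = None
    contraction_field: np.ndarray | float = 0.4
    waveform: np.ndarray | None = None
    jitter_px: float = 0.0
    transition_deg: float = 10.0
    n_sectors: int = 6
    seed: int | None = None

    def __post_init__(self):
        if self.radius_profile is None:
            # apex smaller than base, nondecreasing
            self.radius_profile = np.linspace(0.55, 1.0, self.n_slices) * (
                0.35 * self.matrix_px * self.pixel_mm
            )
        self.radius_profile = np.asarray(self.radius_profile, dtype=float)
        if self.radius_profile.shape != (self.n_slices,):
            raise ValueError("radius_profile must have one radius per slice")
        if np.any(self.radius_profile <= 0):
            raise ValueError("radius_profile must be positive")
        if np.any(np.diff(self.radius_profile) < 0):
            raise ValueError("radius_profile must be nondecreasing apex to base")
        c = np.broadcast_to(
            np.asarray(self.contraction_field, dtype=float),
            (self.n_slices, self.n_sectors),
        ).copy()
        if np.any(c <= -0.3):
            raise ValueError("contraction amplitudes must exceed -0.3")
        self.contraction_field = c
        if self.waveform is None:
            self.waveform = _default_waveform(self.n_phases)
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.shape != (self.n_phases,):
            raise ValueError("waveform must have one value per phase")
        if abs(self.waveform[0]) > 1e-12 or abs(self.waveform.max() - 1.0) > 1e-12:
            raise ValueError("waveform must satisfy g(0)=0 and max g=1")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be >= 0")

    @property
    def es_phase(self) -> int:
        return int(np.argmax(self.waveform))


def blend_contraction(theta_deg, sector_values, transition_deg: float = 10.0):
    """Contraction amplitude at angles ``theta_deg`` for one slice.

    Piecewise-constant per 60-degree sector with a cosine taper of width
    ``transition_deg`` centred on each boundary, so the field is continuous
    in angle.  ``sector_values`` has one amplitude per sector in wedge order
    starting at 0 degrees.
    """
    theta = np.asarray(theta_deg, dtype=float) % 360.0
    vals = np.asarray(sector_values, dtype=float)
    n_k = vals.size
    span = 360.0 / n_k
    k = np.floor(theta / span).astype(int) % n_k
    c = vals[k]
    if transition_deg > 0:
        half = transition_deg / 2.0
        frac = theta - k * span  # position within the wedge, [0, span)
        near_start = frac < half
        u = (frac[near_start] + half) / transition_deg  # 0.5 .. 1 ramp
        prev = vals[(k[near_start] - 1) % n_k]
        w = 0.5 * (1.0 - np.cos(np.pi * u))
        c = c.astype(float)
        c[near_start] = prev + (vals[k[near_start]] - prev) * w
        near_end = frac >= span - half
        u = (frac[near_end] - (span - half)) / transition_deg  # 0 .. 0.5 ramp
        nxt = vals[(k[near_end] + 1) % n_k]
        w = 0.5 * (1.0 - np.cos(np.pi * u))
        c[near_end] = vals[k[near_end]] + (nxt - vals[k[near_end]]) * w
    return c


def _ground_truth_areas(spec: PhantomSpec, n_quad: int = 7200) -> np.ndarray:
    """Analytic per-sector cavity areas (mm^2), (n_slices, n_phases, n_sectors).

    Integrates A_k(t) = int_{sector k} rho(theta, t)^2 / 2 dtheta over the
    blended contraction field (no jitter).
    """
    theta = (np.arange(n_quad) + 0.5) * (360.0 / n_quad)
    dtheta = 2.0 * np.pi / n_quad
    span = 360.0 / spec.n_sectors
    sector_of = np.floor(theta / span).astype(int) % spec.n_sectors
    areas = np.zeros((spec.n_slices, spec.n_phases, spec.n_sectors))
    for s in range(spec.n_slices):
        c = blend_contraction(theta, spec.contraction_field[s], spec.transition_deg)
        for t, g in enumerate(spec.waveform):
            rho = spec.radius_profile[s] * (1.0 - c * g)
            contrib = 0.5 * rho**2 * dtheta
            areas[s, t] = np.bincount(sector_of, weights=contrib, minlength=spec.n_sectors)
    return areas


def generate_lv_phantom(spec: PhantomSpec, subject_id: str = "phantom") -> CineStudy:
    """Render a cine mask stack from a phantom specification.

    The returned study's ``metadata`` carries the analytic ground truth:
    per-sector areas (``gt_sector_area_mm2``), RFAC per (slice, sector)
    (``gt_rfac_pct``), and the systolic phase (``gt_es_phase``).  The same
    seed yields bit-identical masks.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.matrix_px
    center = (n - 1) / 2.0
    ys, xs = np.mgrid[0:n, 0:n]
    dx = xs - center
    dy = ys - center
    r_mm = np.hypot(dx, dy) * spec.pixel_mm
    theta = np.degrees(np.arctan2(dx, -dy)) % 360.0
    g_max = spec.waveform.max()
    masks = np.zeros((spec.n_slices, spec.n_phases, n, n), dtype=bool)
    for s in range(spec.n_slices):
        cmax = spec.contraction_field[s].max()
        rho_min = spec.radius_profile[s] * (1.0 - cmax * g_max)
        if rho_min <= 0:
            k = int(np.argmax(spec.contraction_field[s]))
            raise ValueError(
                f"cavity radius <= 0 at slice {s}, sector "
                f"'{SECTOR_LABELS[k]}' (c={cmax:.3f}): contraction too strong"
            )
        c_px = blend_contraction(theta.ravel(), spec.contraction_field[s], spec.transition_deg)
        c_px = c_px.reshape(n, n)
        for t, g in enumerate(spec.waveform):
            rho = spec.radius_profile[s] * (1.0 - c_px * g)
            if spec.jitter_px > 0:
                k_ctrl = 32
                ctrl = rng.normal(0.0, spec.jitter_px * spec.pixel_mm, k_ctrl)
                ang = np.arange(k_ctrl + 1) * (360.0 / k_ctrl)
                rho = rho + np.interp(theta, ang, np.append(ctrl, ctrl[0]))
            masks[s, t] = r_mm <= rho
    gt_areas = _ground_truth_areas(spec)
    es = spec.es_phase
    gt_rfac = 100.0 * (gt_areas[:, 0, :] - gt_areas[:, es, :]) / gt_areas[:, 0, :]
    return CineStudy(
        subject_id=subject_id,
        masks=masks,
        pixel_mm=spec.pixel_mm,
        slice_spacing_mm=spec.slice_spacing_mm,
        n_sectors=spec.n_sectors,
        metadata={
            "gt_sector_area_mm2": gt_areas,
            "gt_rfac_pct": gt_rfac,
            "gt_es_phase": es,
            "spec": spec,
        },
    )


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass
class GroupSpec:
    """One experimental arm: contraction fields per timepoint plus mortality.

    ``contraction_mean`` maps timepoint label to an (n_slices, n_sectors)
    amplitude field; ``contraction_sd`` is the between-subject SD of a
    subject-level additive offset applied to the whole field.  ``dilation``
    maps timepoint to a radius scale factor emulating post-infarct chamber
    dilatation (1.0 = baseline size).  ``hazard_per_week`` is the
    exponential death rate after randomization.
    ``atrial`` maps timepoint to mean/SD tuples for (LA Vmax ul, LA EF %,
    LAA length mm, LAA duct FS %); LA Vmin is derived from Vmax and LA EF.
    """

    label: str
    n: int
    contraction_mean: dict
    contraction_sd: float = 0.02
    dilation: dict = field(default_factory=dict)
    hazard_per_week: float = 0.0
    atrial: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"group '{self.label}' must have n >= 1")
        if self.contraction_sd < 0:
            raise ValueError("contraction_sd must be >= 0")
        if self.hazard_per_week < 0:
            raise ValueError("hazard_per_week must be >= 0")


@dataclass
class ExpressionModel:
    """Log-normal microarray model with class effects and trait coupling.

    Intensity = exp(baseline + class_effect + beta * (trait - mean) + noise).
    ``n_class_affected`` genes receive group effects (half up in MI, half
    down); ``n_trait_coupled`` of the affected genes additionally get a
    negative log-slope ``beta_per_pct`` on the remote-wall contraction index,
    mimicking remodeling genes that fall as regional function recovers.
    ``frac_low`` of probes are low-intensity (below detection) and
    ``frac_duplicate`` of genes carry a second, noisier probe, to exercise
    probe filtering.
    """

    n_genes: int = 800
    n_class_affected: int = 80
    n_trait_coupled: int = 40
    class_effect_log: float = 0.6
    beta_per_pct: float = -0.03
    noise_sd_log: float = 0.25
    baseline_log_mean: float = math.log(500.0)
    baseline_log_sd: float = 0.8
    frac_low: float = 0.15
    frac_duplicate: float = 0.10

    def __post_init__(self):
        if self.noise_sd_log < 0:
            raise ValueError("noise SD must be >= 0")
        if not (0 <= self.n_trait_coupled <= self.n_class_affected <= self.n_genes):
            raise ValueError("need n_trait_coupled <= n_class_affected <= n_genes")


@dataclass
class CohortDesign:
    """Study design for a synthetic cohort (groups x timepoints)."""

    groups: list
    timepoints: tuple = ("baseline", "24h", "1w", "4w")
    timepoint_weeks: tuple = (0.0, 1.0 / 7.0, 1.0, 4.0)
    follow_up_weeks: float = 4.0
    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec(matrix_px=96, jitter_px=0.4))
    expression: ExpressionModel = field(default_factory=ExpressionModel)
    seed: int | None = None

    def __post_init__(self):
        if not self.groups:
            raise ValueError("design needs at least one group")
        for g in self.groups:
            if g.n < 1:
                raise ValueError(f"group '{g.label}' has n=0")
        if len(self.timepoints) != len(self.timepoint_weeks):
            raise ValueError("timepoints and timepoint_weeks must align")


@dataclass
class CohortResult:
    """Output of :func:`generate_cohort`.

    ``studies`` maps (subject_id, timepoint) to a CineStudy; ``table`` is the
    tidy cohort table (subject, group, timepoint, index, value); ``survival``
    has one row per subject (time_weeks, event); ``atrial`` maps
    (subject_id, timepoint) to an AtrialTrace.
    """

    studies: dict
    table: pd.DataFrame
    survival: pd.DataFrame
    atrial: dict

    def pivot(self, index_name: str, timepoint: str) -> pd.DataFrame:
        """Wide per-subject values of one index at one timepoint."""
        df = self.table
        sel = df[(df["index"] == index_name) & (df["timepoint"] == timepoint)]
        return sel.pivot_table(index=["subject", "group"], values="value").reset_index()


def _ramp_field(mid_rfac: dict, basal_rfac: dict, n_slices: int) -> np.ndarray:
    """Contraction field from mid-apical and basal RFAC targets per sector.

    Mid-apical values hold from the apex through the mid cavity; the last
    three slices ramp linearly toward the basal values (the infarct territory
    is mid-apical; basal slices are relatively spared).
    """
    field_ = np.zeros((n_slices, len(SECTOR_LABELS)))
    n_base = min(3, n_slices - 1)
    for k, lab in enumerate(SECTOR_LABELS):
        mid_c = contraction_for_rfac(mid_rfac[lab])
        base_c = contraction_for_rfac(basal_rfac.get(lab, mid_rfac[lab]))
        col = np.full(n_slices, mid_c)
        if n_base:
            col[-n_base:] = np.linspace(mid_c, base_c, n_base + 1)[1:]
        field_[:, k] = col
    return field_


_SHAM_RFAC = {lab: 70.0 for lab in SECTOR_LABELS} | {"inferior": 71.0, "posterior": 77.0}

# Mid-apical RFAC targets (%) per sector emulating an anterior infarct:
# anterior / antero-septal / lateral territory severely hypokinetic, remote
# inferior + posterior moderately depressed, septum intermediate; treated
# animals keep more remote-wall function at follow-up.
_MI_MID = {
    "24h": {"anterior": 8, "antero-septal": 10, "septal": 20, "lateral": 12,
            "posterior": 27, "inferior": 29},
    "1w": {"anterior": 5, "antero-septal": 8, "septal": 15, "lateral": 9,
           "posterior": 18, "inferior": 21},
    "4w": {"anterior": 4, "antero-septal": 7, "septal": 14, "lateral": 8,
           "posterior": 17, "inferior": 22},
}
_MIVAL_MID = {
    "24h": {"anterior": 9, "antero-septal": 12, "septal": 24, "lateral": 14,
            "posterior": 35, "inferior": 36},
    "1w": {"anterior": 6, "antero-septal": 12, "septal": 22, "lateral": 11,
           "posterior": 31, "inferior": 34},
    "4w": {"anterior": 5, "antero-septal": 11, "septal": 21, "lateral": 10,
           "posterior": 30, "inferior": 38},
}
_BASAL = {lab: 55.0 for lab in SECTOR_LABELS}

# (mean, SD) per timepoint for LA Vmax (ul), LA EF (%), LAA length (mm),
# LAA duct FS (%); Vmin is derived per subject as Vmax * (1 - EF/100) so the
# two volumes stay physiologically coupled.  SDs on the individual-animal
# scale (emulating a dilating, poorly emptying atrium after infarction).
_ATRIAL = {
    "sham": {
        "baseline": ((4.7, 1.4), (57.2, 5.9), (3.5, 0.35), (47.9, 8.0)),
        "24h": ((4.6, 1.0), (53.6, 5.9), (3.4, 0.35), (51.4, 5.5)),
        "1w": ((4.9, 1.0), (52.7, 5.5), (3.5, 0.35), (48.2, 10.7)),
        "4w": ((5.6, 1.4), (54.3, 4.2), (3.5, 0.35), (43.3, 6.9)),
    },
    "MI": {
        "baseline": ((4.7, 1.4), (57.2, 5.9), (3.5, 0.35), (47.9, 8.0)),
        "24h": ((5.6, 3.4), (49.9, 8.3), (3.5, 0.7), (43.6, 6.2)),
        "1w": ((7.6, 1.4), (45.6, 10.0), (4.2, 0.7), (32.2, 15.0)),
        "4w": ((8.8, 3.4), (43.1, 7.3), (4.8, 0.7), (19.2, 13.0)),
    },
    "MI+Val": {
        "baseline": ((4.7, 1.4), (57.2, 5.9), (3.5, 0.35), (47.9, 8.0)),
        "24h": ((5.5, 1.4), (48.3, 14.9), (3.8, 0.35), (38.9, 5.5)),
        "1w": ((7.5, 2.0), (50.8, 5.5), (4.1, 0.35), (30.8, 12.8)),
        "4w": ((7.3, 1.4), (50.1, 5.9), (4.0, 0.35), (40.6, 6.9)),
    },
}


def default_cohort_design(
    n_per_group: int = 12,
    n_slices: int = 7,
    matrix_px: int = 96,
    jitter_px: float = 0.4,
    seed: int | None = None,
) -> CohortDesign:
    """Sham / MI / MI+Val design emulating an anterior-infarct mouse study.

    Mid-apical contraction targets follow the observed pattern of an anterior
    LAD infarct (severe anterior/antero-septal/lateral hypokinesis, moderate
    remote-wall depression, partial preservation under treatment); mortality
    is confined to the infarcted arms.
    """
    sham_field = _ramp_field(_SHAM_RFAC, _SHAM_RFAC, n_slices)
    # radius scale factors emulating progressive post-infarct dilatation
    # (square roots of EDV ratios typical of untreated / treated infarcts)
    dil_mi = {"baseline": 1.0, "24h": 1.15, "1w": 1.51, "4w": 1.67}
    dil_val = {"baseline": 1.0, "24h": 1.12, "1w": 1.38, "4w": 1.46}
    groups = [
        GroupSpec(
            "sham", n_per_group,
            {tp: sham_field for tp in ("baseline", "24h", "1w", "4w")},
            contraction_sd=0.015, hazard_per_week=0.0, atrial=_ATRIAL["sham"],
        ),
        GroupSpec(
            "MI", n_per_group,
            {"baseline": sham_field}
            | {tp: _ramp_field(_MI_MID[tp], _BASAL, n_slices) for tp in ("24h", "1w", "4w")},
            contraction_sd=0.035, dilation=dil_mi, hazard_per_week=0.07,
            atrial=_ATRIAL["MI"],
        ),
        GroupSpec(
            "MI+Val", n_per_group,
            {"baseline": sham_field}
            | {tp: _ramp_field(_MIVAL_MID[tp], _BASAL, n_slices) for tp in ("24h", "1w", "4w")},
            contraction_sd=0.045, dilation=dil_val, hazard_per_week=0.025,
            atrial=_ATRIAL["MI+Val"],
        ),
    ]
    # end-diastolic radii on the mouse scale: ~1 mm at the apex slice to
    # ~1.75 mm at the base, giving a baseline EDV near 40 ul over 7 slices
    phantom = PhantomSpec(
        n_slices=n_slices, matrix_px=matrix_px, jitter_px=jitter_px,
        pixel_mm=0.1, slice_spacing_mm=1.0,
        radius_profile=np.linspace(0.55, 1.0, n_slices) * 1.75,
    )
    return CohortDesign(groups=groups, phantom=phantom, seed=seed)


def _measure_study(study: CineStudy) -> dict:
    """Run the full measurement pipeline on one study; returns index values."""
    table = sector_areas(study)
    ed, es, _ = detect_ed_es(table)
    rmap = compute_rfac(table, ed, es)
    rmap10 = resample_slices(rmap)
    summ = regional_summary(rmap10)
    glob = global_function(table, ed, es)
    return {
        "iRFAC": summ.irfac_pct,
        "pRFAC": summ.prfac_pct,
        "ipRFAC": summ.iprfac_pct,
        "LV EF": glob.ef_pct,
        "LV EDV": glob.edv_ul,
        "LV ESV": glob.esv_ul,
        "LV SV": glob.sv_ul,
    }


def _sample_atrial(params, rng) -> tuple:
    """Draw one subject's atrial indices and build a matching trace geometry."""
    (vmax_m, vmax_s), (laef_m, laef_s), (len_m, len_s), (fs_m, fs_s) = params
    vmax = max(rng.normal(vmax_m, vmax_s), 0.5)
    laef = float(np.clip(rng.normal(laef_m, laef_s), 5.0, 95.0))
    vmin = vmax * (1.0 - laef / 100.0)
    laa_len = max(rng.normal(len_m, len_s), 0.5)
    fs = float(np.clip(rng.normal(fs_m, fs_s), 0.0, 95.0))
    d_max = max(rng.normal(1.0, 0.1), 0.3)
    d_min = d_max * (1.0 - fs / 100.0)
    poly_min, axis = spindle_polygon(vmin)
    poly_max, axis_max = spindle_polygon(vmax)
    n_mid = 40
    xs = np.linspace(0.0, laa_len * 0.8, n_mid)
    arc = np.column_stack([xs, 0.3 * np.sin(xs / max(laa_len, 1e-6))])
    seg = np.diff(arc, axis=0)
    arc *= laa_len / np.sum(np.hypot(seg[:, 0], seg[:, 1]))
    trace = AtrialTrace(
        la_polygon_min=poly_min,
        la_polygon_max=poly_max,
        long_axis=axis_max,
        laa_midline=arc,
        duct_d_min=d_min,
        duct_d_max=d_max,
    )
    return trace, {"LA Vmin": vmin, "LA Vmax": vmax,
                   "LA EF": la_ef(vmin, vmax), "LAA length": laa_len,
                   "LAA duct FS": fs}


def generate_cohort(design: CohortDesign) -> CohortResult:
    """Simulate a full cohort: cine studies, survival, atrial traces, table.

    Subjects are randomized at the first post-surgery timepoint; death times
    are exponential with the group hazard, measured from randomization, and
    censored at the end of follow-up.  Every surviving subject contributes a
    CineStudy per timepoint, measured with the actual analysis pipeline to
    fill the cohort table.
    """
    rng = np.random.default_rng(design.seed)
    studies, atrial, rows, surv_rows = {}, {}, [], []
    for g in design.groups:
        for i in range(g.n):
            subj = f"{g.label}-{i + 1:02d}"
            if g.hazard_per_week > 0:
                death = float(rng.exponential(1.0 / g.hazard_per_week))
            else:
                death = math.inf
            event = death <= design.follow_up_weeks
            surv_rows.append(
                {"subject": subj, "group": g.label,
                 "time_weeks": min(death, design.follow_up_weeks),
                 "event": int(event)}
            )
            offset = rng.normal(0.0, g.contraction_sd)
            for tp, wk in zip(design.timepoints, design.timepoint_weeks):
                if wk > 0 and death <= wk:
                    continue
                c = np.clip(g.contraction_mean[tp] + offset, -0.25, 0.88)
                scale = g.dilation.get(tp, 1.0)
                spec_t = PhantomSpec(
                    n_slices=design.phantom.n_slices,
                    n_phases=design.phantom.n_phases,
                    matrix_px=design.phantom.matrix_px,
                    pixel_mm=design.phantom.pixel_mm,
                    slice_spacing_mm=design.phantom.slice_spacing_mm,
                    radius_profile=design.phantom.radius_profile * scale,
                    contraction_field=c,
                    jitter_px=design.phantom.jitter_px,
                    transition_deg=design.phantom.transition_deg,
                    seed=int(rng.integers(2**31 - 1)),
                )
                study = generate_lv_phantom(spec_t, subject_id=subj)
                studies[(subj, tp)] = study
                for name, val in _measure_study(study).items():
                    rows.append({"subject": subj, "group": g.label,
                                 "timepoint": tp, "index": name, "value": val})
                if g.atrial:
                    trace, vals = _sample_atrial(g.atrial[tp], rng)
                    atrial[(subj, tp)] = trace
                    for name, val in vals.items():
                        rows.append({"subject": subj, "group": g.label,
                                     "timepoint": tp, "index": name, "value": val})
    return CohortResult(
        studies=studies,
        table=pd.DataFrame(rows),
        survival=pd.DataFrame(surv_rows),
        atrial=atrial,
    )


def generate_expression(
    trait,
    classes,
    model: ExpressionModel | None = None,
    seed: int | None = None,
):
    """Simulate a probes x samples intensity matrix tied to a functional trait.

    ``trait`` is the per-sample remote-wall contraction index (e.g. ipRFAC, %)
    and ``classes`` the per-sample group labels (same order).  Returns an
    :class:`~rfackit.expression.ExpressionMatrix` whose metadata records the
    ground-truth affected and trait-coupled gene sets.
    """
    from .expression import ExpressionMatrix  # local import to avoid a cycle

    model = model or ExpressionModel()
    trait = np.asarray(trait, dtype=float)
    classes = np.asarray(classes)
    if trait.shape != classes.shape:
        raise ValueError("trait and classes must align")
    labels, counts = np.unique(classes, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("need >= 2 samples per class")
    rng = np.random.default_rng(seed)
    n_g, n_s = model.n_genes, trait.size
    genes = np.array([f"G{i + 1:05d}" for i in range(n_g)])
    baseline = rng.normal(model.baseline_log_mean, model.baseline_log_sd, n_g)
    n_low = int(round(model.frac_low * n_g))
    low_idx = rng.choice(n_g, n_low, replace=False)
    baseline[low_idx] = rng.normal(math.log(40.0), 0.3, n_low)
    affected = rng.choice(np.setdiff1d(np.arange(n_g), low_idx),
                          model.n_class_affected, replace=False)
    coupled = affected[: model.n_trait_coupled]
    # class effect on log scale: "MI" fully shifted, "MI+Val" halfway, others 0
    eff = np.zeros((n_g, n_s))
    sign = np.where(np.arange(model.n_class_affected) % 2 == 0, 1.0, -1.0)
    is_mi = classes == "MI"
    is_val = classes == "MI+Val"
    for j, gi in enumerate(affected):
        eff[gi, is_mi] = sign[j] * model.class_effect_log
        eff[gi, is_val] = sign[j] * model.class_effect_log * 0.4
    beta = np.zeros(n_g)
    beta[coupled] = model.beta_per_pct
    log_i = (
        baseline[:, None]
        + eff
        + beta[:, None] * (trait - trait.mean())[None, :]
        + rng.normal(0.0, model.noise_sd_log, (n_g, n_s))
    )
    intensity = np.exp(log_i)
    probe_ids = [f"ILMN_{i + 1:06d}" for i in range(n_g)]
    gene_map = dict(zip(probe_ids, genes))
    # duplicate probes for a fraction of genes (noisier copies)
    n_dup = int(round(model.frac_duplicate * n_g))
    dup_idx = rng.choice(n_g, n_dup, replace=False)
    dup_rows = intensity[dup_idx] * np.exp(rng.normal(0, 0.1, (n_dup, n_s)))
    dup_ids = [f"ILMN_D{i + 1:06d}" for i in range(n_dup)]
    for pid, gi in zip(dup_ids, dup_idx):
        gene_map[pid] = genes[gi]
    intensity = np.vstack([intensity, dup_rows])
    probe_ids = probe_ids + dup_ids
    samples = [f"S{i + 1:02d}" for i in range(n_s)]
    return ExpressionMatrix(
        intensity=pd.DataFrame(intensity, index=probe_ids, columns=samples),
        genes=pd.Series({p: gene_map[p] for p in probe_ids}),
        classes=pd.Series(classes, index=samples),
        trait=pd.Series(trait, index=samples),
        metadata={
            "affected_genes": set(genes[affected]),
            "coupled_genes": set(genes[coupled]),
            "low_probes": set(np.array(probe_ids[:n_g])[low_idx]),
        },
    )


def write_ground_truth(study: CineStudy, path) -> None:
    """JSON sidecar with the phantom's analytic ground truth."""
    meta = study.metadata
    payload = {
        "subject_id": study.subject_id,
        "es_phase": int(meta["gt_es_phase"]),
        "gt_rfac_pct": np.asarray(meta["gt_rfac_pct"]).tolist(),
        "gt_sector_area_mm2": np.asarray(meta["gt_sector_area_mm2"]).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
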