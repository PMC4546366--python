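"""Cine segmentation I/O and per-sector cavity geometry.

A cine study is a stack of binary left-ventricular cavity masks indexed by
(slice, phase), ordered apex-to-base, with pixel size and slice spacing in
millimetres.  The cavity of each slice is divided into six 60-degree angular
sectors (anterior, antero-septal, septal, lateral, posterior, inferior) about
the end-diastolic cavity centroid, and the cavity area falling in each sector
is tabulated per phase.

Angle convention: 0 degrees points "up" in image coordinates (toward
decreasing row index) and angles increase clockwise as the image is displayed.
`reference_angle_deg` rotates the start boundary of the first sector so the
wedges can be anchored to anatomy; the six sectors then span consecutive
half-open 60-degree intervals in label order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SECTOR_LABELS",
    "CineStudy",
    "SectorAreaTable",
    "cavity_centroid",
    "load_cine",
    "pixel_angles_deg",
    "rasterize_polygon",
    "save_nifti",
    "save_tiff",
    "sector_areas",
]

#: Sector labels in wedge order, starting at ``reference_angle_deg``.
SECTOR_LABELS = (
    "anterior",
    "antero-septal",
    "septal",
    "lateral",
    "posterior",
    "inferior",
)


@dataclass
class CineStudy:
    """Binary cavity masks for one subject, shaped (slice, phase, row, col).

    Slices are ordered apex to base.  ``pixel_mm`` is the in-plane pixel size
    and ``slice_spacing_mm`` the inter-slice distance; both in millimetres.
    """

    subject_id: str
    masks: np.ndarray  # bool, (n_slices, n_phases, H, W)
    pixel_mm: float
    slice_spacing_mm: float
    n_sectors: int = 6
    sector_labels: tuple = SECTOR_LABELS
    reference_angle_deg: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 4:
            raise ValueError(
                f"masks must be 4-D (slice, phase, row, col); got {self.masks.shape}"
            )
        if self.pixel_mm <= 0 or self.slice_spacing_mm <= 0:
            raise ValueError("pixel_mm and slice_spacing_mm must be positive")
        if len(self.sector_labels) != self.n_sectors:
            raise ValueError("sector_labels length must equal n_sectors")
        empties = np.argwhere(~self.masks.any(axis=(2, 3)))
        if empties.size:
            s, t = empties[0]
            raise ValueError(f"empty cavity mask at slice={s}, phase={t}")

    @property
    def n_slices(self) -> int:
        return self.masks.shape[0]

    @property
    def n_phases(self) -> int:
        return self.masks.shape[1]


def save_nifti(study: CineStudy, path) -> None:
    """Write masks as a 4-D NIfTI volume ordered (x, y, slice, phase)."""
    data = np.transpose(study.masks.astype(np.uint8), (3, 2, 0, 1))
    affine = np.diag([study.pixel_mm, study.pixel_mm, study.slice_spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def save_tiff(study: CineStudy, path) -> None:
    """Write masks as a multi-page TIFF, pages in slice-major order."""
    n_s, n_t, h, w = study.masks.shape
    pages = study.masks.reshape(n_s * n_t, h, w).astype(np.uint8)
    tifffile.imwrite(str(path), pages)


def _rasterize_contours(df: pd.DataFrame, shape: tuple) -> np.ndarray:
    n_s = int(df["slice"].max()) + 1
    n_t = int(df["phase"].max()) + 1
    masks = np.zeros((n_s, n_t, *shape), dtype=bool)
    for (s, t), grp in df.groupby(["slice", "phase"]):
        grp = grp.sort_values("vertex_index")
        poly = grp[["x_px", "y_px"]].to_numpy(float)
        masks[int(s), int(t)] = rasterize_polygon(poly, shape)
    return masks


def rasterize_polygon(vertices: np.ndarray, shape: tuple) -> np.ndarray:
    """Even-odd rasterization of a closed polygon on pixel centers.

    Pixel (row r, col c) has its center at coordinates (x=c, y=r); a pixel is
    set when its center lies inside the polygon under the even-odd rule.
    Vertices are (x, y) in pixel units; the closing edge is implicit.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("polygon needs >= 3 (x, y) vertices")
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    px = xs.ravel().astype(float)
    py = ys.ravel().astype(float)
    x1, y1 = verts[:, 0], verts[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    inside = np.zeros(px.shape, dtype=bool)
    for ex1, ey1, ex2, ey2 in zip(x1, y1, x2, y2):
        if ey1 == ey2:
            continue  # horizontal edges never cross a pixel-center ray
        crosses = (ey1 > py) != (ey2 > py)
        with np.errstate(invalid="ignore"):
            xint = ex1 + (py - ey1) * (ex2 - ex1) / (ey2 - ey1)
        inside ^= crosses & (px < xint)
    return inside.reshape(h, w)


def load_cine(
    path,
    subject_id: str = "subject",
    pixel_mm: float = 1.0,
    slice_spacing_mm: float = 1.0,
    *,
    tiff_layout: tuple | None = None,
    csv_shape: tuple | None = None,
    **kwargs,
) -> CineStudy:
    """Load a cine study from NIfTI, multi-page TIFF, or contour CSV.

    NIfTI volumes are expected ordered (x, y, slice, phase); pixel size and
    slice spacing are taken from the affine when available.  TIFF requires
    ``tiff_layout=(n_slices, n_phases)`` with pages in slice-major order.
    Contour CSV requires columns (slice, phase, vertex_index, x_px, y_px) and
    ``csv_shape=(rows, cols)`` for the raster grid.
    """
    p = str(path)
    if p.endswith((".nii", ".nii.gz")):
        img = nib.load(p)
        data = np.asarray(img.dataobj)
        if data.ndim != 4:
            raise ValueError(f"expected 4-D NIfTI, got {data.ndim}-D")
        masks = np.transpose(data > 0, (2, 3, 1, 0))
        zooms = img.header.get_zooms()
        pixel_mm = float(zooms[0]) or pixel_mm
        slice_spacing_mm = float(zooms[2]) or slice_spacing_mm
    elif p.endswith((".tif", ".tiff")):
        if tiff_layout is None:
            raise ValueError("tiff_layout=(n_slices, n_phases) is required for TIFF")
        pages = tifffile.imread(p)
        if pages.ndim == 2:
            pages = pages[None]
        n_s, n_t = tiff_layout
        if pages.shape[0] != n_s * n_t:
            raise ValueError(
                f"TIFF has {pages.shape[0]} pages; layout {tiff_layout} "
                f"requires {n_s * n_t}"
            )
        masks = (pages > 0).reshape(n_s, n_t, *pages.shape[1:])
    elif p.endswith(".csv"):
        if csv_shape is None:
            raise ValueError("csv_shape=(rows, cols) is required for contour CSV")
        df = pd.read_csv(p)
        required = {"slice", "phase", "vertex_index", "x_px", "y_px"}
        if not required.issubset(df.columns):
            raise ValueError(f"contour CSV must have columns {sorted(required)}")
        masks = _rasterize_contours(df, csv_shape)
    else:
        raise ValueError(f"unrecognized cine format: {p}")
    return CineStudy(
        subject_id=subject_id,
        masks=masks,
        pixel_mm=pixel_mm,
        slice_spacing_mm=slice_spacing_mm,
        **kwargs,
    )


@dataclass
class SectorAreaTable:
    """Cavity area per (slice, phase, sector) in mm^2.

    ``centroid_px`` is the (x, y) centroid used as the sector origin for each
    slice.  Pixel-exact conservation holds: sector areas of a (slice, phase)
    sum to ``total_area_mm2`` because every cavity pixel is assigned to
    exactly one sector.
    """

    subject_id: str
    area_mm2: np.ndarray  # (n_slices, n_phases, n_sectors)
    total_area_mm2: np.ndarray  # (n_slices, n_phases)
    centroid_px: np.ndarray  # (n_slices, 2) as (x, y)
    sector_labels: tuple
    pixel_mm: float
    slice_spacing_mm: float

    @property
    def n_slices(self) -> int:
        return self.area_mm2.shape[0]

    @property
    def n_phases(self) -> int:
        return self.area_mm2.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: (subject, slice, phase, sector, area_mm2)."""
        n_s, n_t, n_k = self.area_mm2.shape
        idx = pd.MultiIndex.from_product(
            [range(n_s), range(n_t), self.sector_labels],
            names=["slice", "phase", "sector"],
        )
        df = pd.DataFrame({"area_mm2": self.area_mm2.ravel()}, index=idx).reset_index()
        df.insert(0, "subject", self.subject_id)
        return df


def cavity_centroid(study: CineStudy, slice_idx: int, phase: int) -> tuple:
    """Pixel-area-weighted centroid (x, y) of the cavity mask of one frame."""
    mask = study.masks[slice_idx, phase]
    if not mask.any():
        raise ValueError(f"empty mask at slice={slice_idx}, phase={phase}")
    rows, cols = np.nonzero(mask)
    return float(cols.mean()), float(rows.mean())


def pixel_angles_deg(shape: tuple, center_xy: tuple) -> np.ndarray:
    """Polar angle of every pixel center about ``center_xy``, in [0, 360).

    0 deg at image up (decreasing row), increasing clockwise on screen.
    """
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    dx = xs - center_xy[0]
    dy = ys - center_xy[1]
    return np.degrees(np.arctan2(dx, -dy)) % 360.0


def _ed_phase_from_masks(masks: np.ndarray) -> int:
    totals = masks.sum(axis=(0, 2, 3))
    return int(np.argmax(totals))


def sector_areas(study: CineStudy, centroid_mode: str = "ed") -> SectorAreaTable:
    """Tabulate cavity area per (slice, phase, sector).

    Each cavity pixel is assigned to the sector whose half-open angular
    interval [start, start + 60) contains its center's polar angle about the
    slice centroid, with the first interval starting at
    ``reference_angle_deg``.  With ``centroid_mode="ed"`` (default) the
    centroid is taken from the end-diastolic frame of each slice and held
    fixed across phases; ``"per-phase"`` recomputes it every frame.
    """
    if centroid_mode not in ("ed", "per-phase"):
        raise ValueError("centroid_mode must be 'ed' or 'per-phase'")
    n_s, n_t = study.n_slices, study.n_phases
    n_k = study.n_sectors
    span = 360.0 / n_k
    px_area = study.pixel_mm**2
    ed = _ed_phase_from_masks(study.masks)
    areas = np.zeros((n_s, n_t, n_k))
    centroids = np.zeros((n_s, 2))
    for s in range(n_s):
        cx, cy = cavity_centroid(study, s, ed)
        centroids[s] = (cx, cy)
        for t in range(n_t):
            if centroid_mode == "per-phase":
                cx, cy = cavity_centroid(study, s, t)
            mask = study.masks[s, t]
            rows, cols = np.nonzero(mask)
            theta = np.degrees(np.arctan2(cols - cx, -(rows - cy))) % 360.0
            k = np.floor(((theta - study.reference_angle_deg) % 360.0) / span)
            k = k.astype(int) % n_k
            areas[s, t] = np.bincount(k, minlength=n_k) * px_area
    totals = areas.sum(axis=2)
    return SectorAreaTable(
        subject_id=study.subject_id,
        area_mm2=areas,
        total_area_mm2=totals,
        centroid_px=centroids,
        sector_labels=tuple(study.sector_labels),
        pixel_mm=study.pixel_mm,
        slice_spacing_mm=study.slice_spacing_mm,
    )
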