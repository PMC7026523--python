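"""Cell segmentation and the 17-parameter phase signature.

Cells are segmented from height maps by automatic thresholding, hole
filling and a distance-transform watershed that splits touching cells. Each
retained cell yields 17 features: six shape parameters (area, perimeter,
circularity, eccentricity, solidity, aspect ratio), five height statistics
(mean, max, SD, skewness, kurtosis), phase volume, intensity entropy, and
four Haralick texture statistics (contrast, correlation, energy,
homogeneity) from a gray-level co-occurrence matrix of the interior heights.

GLCM details: interior heights are quantized to 32 levels over the cell's
own range; offsets (0,1), (1,0), (1,1), (1,-1) are accumulated into one
symmetric, normalized matrix (background pairs are stripped before
normalization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.feature import graycomatrix
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .holography import HeightMap

#: Canonical order of the 17 phase parameters.
FEATURE_NAMES = [
    "area_um2",
    "perimeter_um",
    "circularity",
    "eccentricity",
    "solidity",
    "aspect_ratio",
    "mean_height_nm",
    "max_height_nm",
    "height_sd_nm",
    "phase_volume_um3",
    "height_skewness",
    "height_kurtosis",
    "intensity_entropy_bits",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_energy",
    "glcm_homogeneity",
]

METADATA_COLUMNS = ["line", "field_id", "cell_id", "blend_m", "touches_border"]

_GLCM_LEVELS = 32


@dataclass
class CellMask:
    """One segmented cell: label id, boolean patch and bounding box."""

    label: int
    patch: np.ndarray          # boolean mask within the bounding box
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    field_id: str = ""
    touches_border: bool = False

    @property
    def area_px(self) -> int:
        return int(self.patch.sum())


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_cells(
    height: HeightMap | np.ndarray,
    min_area: int = 50,
    threshold: float | str | None = None,
    field_id: str = "",
    split_h_frac: float = 0.5,
    min_height: float = 500.0,
) -> list[CellMask]:
    """Segment individual cells from a height map.

    Automatic threshold → fill holes → split touching cells by a watershed
    on the distance transform, seeded at the core regions deeper than
    ``split_h_frac`` × each component's peak distance → drop components
    below ``min_area`` pixels.

    Components whose peak height is below ``min_height`` (nm) are also
    dropped: no adherent cell is thinner than a few hundred nm anywhere,
    while band-limiting ripples around cells in numerically reconstructed
    maps stay well under that.

    ``threshold`` may be a number, ``"triangle"`` (default), or ``"otsu"``.
    Cells in a height map are smooth domes over a flat background, so the
    histogram is a background spike with a long foreground tail; the
    triangle rule thresholds at the foot of the spike and keeps the full
    cell footprint, whereas Otsu bisects the dome and erodes it. Determinis-
    tic for fixed input; an all-background map yields an empty list.
    """
    arr = height.height if isinstance(height, HeightMap) else np.asarray(height, float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("height map must be finite")
    if arr.max() <= 0:
        return []

    if threshold is None or isinstance(threshold, str):
        policy = threshold or "triangle"
        if arr.min() == arr.max():
            return []
        if policy == "triangle":
            threshold = float(threshold_triangle(arr))
        elif policy == "otsu":
            threshold = float(threshold_otsu(arr))
        else:
            raise ValueError(f"unknown threshold policy {policy!r}")
    binary = ndimage.binary_fill_holes(arr > threshold)
    if not binary.any():
        return []

    dist = ndimage.distance_transform_edt(binary)
    comp_labels, n_comp = ndimage.label(binary)
    markers = np.zeros_like(comp_labels)
    next_marker = 1
    for comp, sl in enumerate(ndimage.find_objects(comp_labels), start=1):
        if sl is None:
            continue
        comp_mask = comp_labels[sl] == comp
        d = np.where(comp_mask, dist[sl], 0.0)
        peak = d.max()
        if peak <= 0:
            continue
        # core markers: pixels deeper than split_h_frac × the component's
        # peak distance. A single cell's medial ridge stays above this level
        # (boundary irregularity thins it far less than 2×), so it yields
        # one marker; touching cells meet at a shallow neck well below it,
        # so each contributes its own marker.
        seeds, n_seeds = ndimage.label(
            d >= split_h_frac * peak, structure=np.ones((3, 3))
        )
        if n_seeds <= 1:
            markers[sl][comp_mask] = next_marker
            next_marker += 1
        else:
            for s in range(1, n_seeds + 1):
                markers[sl][(seeds == s) & comp_mask] = next_marker
                next_marker += 1
    labels = watershed(-dist, markers=markers, mask=binary)

    masks: list[CellMask] = []
    out_label = 1
    for prop in regionprops(labels, intensity_image=arr):
        if prop.area < min_area:
            continue
        if prop.intensity_max < min_height:
            continue
        minr, minc, maxr, maxc = prop.bbox
        touches = (
            minr == 0 or minc == 0 or maxr == arr.shape[0] or maxc == arr.shape[1]
        )
        masks.append(
            CellMask(
                label=out_label,
                patch=prop.image.copy(),
                bbox=(minr, minc, maxr, maxc),
                field_id=field_id,
                touches_border=touches,
            )
        )
        out_label += 1
    return masks


def masks_to_label_image(masks: list[CellMask], shape: tuple[int, int]) -> np.ndarray:
    """Rasterize segmented masks into a uint16 label image."""
    out = np.zeros(shape, dtype=np.uint16)
    for m in masks:
        minr, minc, maxr, maxc = m.bbox
        out[minr:maxr, minc:maxc][m.patch] = m.label
    return out


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def _masked_glcm(heights_patch: np.ndarray, mask: np.ndarray) -> dict:
    """Haralick statistics of interior heights, background pairs excluded."""
    vals = heights_patch[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        q = np.floor((heights_patch - lo) / (hi - lo) * _GLCM_LEVELS).astype(int)
        q = np.clip(q, 0, _GLCM_LEVELS - 1) + 1  # interior levels 1..32
    else:
        q = np.ones_like(heights_patch, dtype=int)
    q[~mask] = 0  # background sentinel level

    glcm = graycomatrix(
        q.astype(np.uint8),
        distances=[1],
        angles=[0.0, np.pi / 2, np.pi / 4, -np.pi / 4],
        levels=_GLCM_LEVELS + 1,
        symmetric=True,
        normed=False,
    )
    # accumulate offsets, strip background row/col, renormalize
    mat = glcm[:, :, 0, :].sum(axis=-1).astype(float)[1:, 1:]
    total = mat.sum()
    if total == 0:
        return {
            "glcm_contrast": 0.0,
            "glcm_correlation": 1.0,
            "glcm_energy": 1.0,
            "glcm_homogeneity": 1.0,
        }
    p = mat / total
    i = np.arange(_GLCM_LEVELS, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float(np.sum(p * (ii - jj) ** 2))
    homogeneity = float(np.sum(p / (1.0 + np.abs(ii - jj))))
    energy = float(np.sum(p**2))
    mu_i = float(np.sum(ii * p))
    mu_j = float(np.sum(jj * p))
    sd_i = float(np.sqrt(np.sum((ii - mu_i) ** 2 * p)))
    sd_j = float(np.sqrt(np.sum((jj - mu_j) ** 2 * p)))
    if sd_i > 0 and sd_j > 0:
        correlation = float(np.sum((ii - mu_i) * (jj - mu_j) * p) / (sd_i * sd_j))
    else:
        correlation = 1.0  # constant interior: perfectly correlated by convention
    return {
        "glcm_contrast": contrast,
        "glcm_correlation": correlation,
        "glcm_energy": energy,
        "glcm_homogeneity": homogeneity,
    }


def extract_features(mask: CellMask, height: HeightMap | np.ndarray) -> dict:
    """Compute the 17-parameter phase signature of one segmented cell."""
    arr = height.height if isinstance(height, HeightMap) else np.asarray(height, float)
    pitch = height.pixel_pitch if isinstance(height, HeightMap) else 0.18
    if not mask.patch.any():
        raise ValueError("empty cell mask")
    minr, minc, maxr, maxc = mask.bbox
    patch = arr[minr:maxr, minc:maxc]
    vals = patch[mask.patch]
    if not np.all(np.isfinite(vals)):
        raise ValueError("height map not finite on mask")

    prop = regionprops(mask.patch.astype(np.uint8))[0]
    area_um2 = prop.area * pitch**2
    # Crofton perimeter: unbiased for rasterized smooth shapes, unlike the
    # chain-code estimate, which inflates circularity errors to ~10%
    perimeter_px = prop.perimeter_crofton
    perimeter_um = perimeter_px * pitch
    circularity = (
        4.0 * np.pi * prop.area / perimeter_px**2 if perimeter_px > 0 else 1.0
    )
    aspect = (
        prop.axis_major_length / prop.axis_minor_length
        if prop.axis_minor_length > 0
        else 1.0
    )

    sd = float(vals.std())
    skew = float(stats.skew(vals)) if sd > 0 else 0.0
    kurt = float(stats.kurtosis(vals)) if sd > 0 else 0.0

    # Shannon entropy (bits) of the 32-bin interior height histogram
    hist, _ = np.histogram(vals, bins=_GLCM_LEVELS)
    pk = hist[hist > 0] / hist.sum()
    entropy_bits = float(-np.sum(pk * np.log2(pk)))

    rec = {
        "area_um2": float(area_um2),
        "perimeter_um": float(perimeter_um),
        "circularity": float(min(circularity, 1.0)),
        "eccentricity": float(prop.eccentricity),
        "solidity": float(prop.solidity),
        "aspect_ratio": float(aspect),
        "mean_height_nm": float(vals.mean()),
        "max_height_nm": float(vals.max()),
        "height_sd_nm": sd,
        "phase_volume_um3": float(vals.sum() * pitch**2 * 1e-3),  # nm→μm
        "height_skewness": skew,
        "height_kurtosis": kurt,
        "intensity_entropy_bits": entropy_bits,
    }
    rec.update(_masked_glcm(patch, mask.patch))
    return rec


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

def build_feature_table(
    fields,
    min_area: int = 50,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Build the per-cell feature table from one or more fields.

    Parameters
    ----------
    fields
        Iterable of ``(field_id, line_label, height_map)`` or
        ``(field_id, line_label, height_map, ground_truth)`` tuples. When
        ground truth is provided, each segmented cell inherits the true
        blend fraction of the generated cell its centroid falls on.

    Returns one row per retained cell: 17 features plus metadata columns.
    Raises on duplicate field ids; an empty input yields an empty table with
    the full header.
    """
    rows = []
    seen = set()
    for entry in fields:
        if len(entry) == 4:
            field_id, line, hmap, gt = entry
        else:
            field_id, line, hmap = entry
            gt = None
        if field_id in seen:
            raise ValueError(f"duplicate field id {field_id!r}")
        seen.add(field_id)

        blend_by_gen_label = {}
        if gt is not None:
            blend_by_gen_label = {c["cell_id"]: c["blend_m"] for c in gt.cells}

        masks = segment_cells(hmap, min_area=min_area, threshold=threshold,
                              field_id=str(field_id))
        for m in masks:
            rec = extract_features(m, hmap)
            blend = np.nan
            if gt is not None:
                minr, minc, maxr, maxc = m.bbox
                seg_region = np.zeros(gt.labels.shape, dtype=bool)
                seg_region[minr:maxr, minc:maxc] = m.patch
                gen_labels = gt.labels[seg_region]
                gen_labels = gen_labels[gen_labels > 0]
                if gen_labels.size:
                    gen_id = int(np.bincount(gen_labels).argmax())
                    blend = blend_by_gen_label.get(gen_id, np.nan)
            rec.update(
                {
                    "line": line,
                    "field_id": str(field_id),
                    "cell_id": m.label,
                    "blend_m": blend,
                    "touches_border": m.touches_border,
                }
            )
            rows.append(rec)

    columns = FEATURE_NAMES + METADATA_COLUMNS
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)[columns]
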