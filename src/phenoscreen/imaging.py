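"""Two-channel image analysis: nuclei/cell segmentation and features.

The pipeline mirrors a standard high-content workflow: crop the image
border (to remove illumination falloff), segment nuclei from the DNA
channel by local-mean adaptive thresholding (10x10-pixel window), expand
the nuclei into a thresholded actin mask with a seeded watershed (a
Voronoi-style propagation: one cell region per nucleus, regions disjoint
and confined to the actin mask), and extract per-cell morphology,
intensity and texture features, aggregated per well with the nucleus count
serving as the cell-count proxy.

Coordinate convention: row-major, 0-based pixel indices, shared by images
and masks.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, morphology, segmentation
from skimage.feature import graycomatrix

__all__ = [
    "crop_border",
    "adaptive_threshold",
    "segment_nuclei",
    "segment_cells",
    "extract_cell_features",
    "aggregate_well",
    "process_well",
    "INTENSITY_FEATURES",
]

#: per-cell features that additionally get a cell-to-cell sd aggregate
INTENSITY_FEATURES = ("n_dna_mean", "c_actin_mean")


def crop_border(image: np.ndarray, margin: int) -> np.ndarray:
    """Remove ``margin`` pixels from every side of a 2-D image."""
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    if margin == 0:
        return image.copy()
    h, w = image.shape[-2:]
    if h <= 2 * margin or w <= 2 * margin:
        raise ValueError(
            f"margin {margin} too large for a {h}x{w} image (needs > 2*margin per axis)"
        )
    return image[..., margin:-margin, margin:-margin].copy()


def adaptive_threshold(
    image: np.ndarray, window: int = 10, offset: float | None = None
) -> np.ndarray:
    """Foreground mask: pixels brighter than their local mean plus an offset.

    The local mean is a ``window`` x ``window`` uniform filter. The default
    offset is 10% of the image's dynamic range, so a constant (blank) image
    yields an empty mask.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D intensity image")
    if offset is None:
        offset = 0.10 * float(img.max() - img.min())
    local = ndi.uniform_filter(img, size=window)
    return img > local + offset


def segment_nuclei(
    dna_image: np.ndarray,
    window: int = 10,
    offset: float | None = None,
    min_size: int = 20,
    smooth: float = 1.0,
) -> np.ndarray:
    """Label nuclei in the DNA channel by adaptive thresholding.

    Bright blobs against local background become foreground; interior holes
    (where a nucleus is larger than the averaging window) are filled and
    specks below ``min_size`` pixels removed. Returns a label image with
    consecutive positive integers; a blank image yields zero labels. The
    label count is the cell-count proxy.
    """
    img = np.asarray(dna_image, dtype=float)
    if smooth > 0:
        img = ndi.gaussian_filter(img, smooth)
    fg = adaptive_threshold(img, window=window, offset=offset)
    fg = ndi.binary_fill_holes(fg)
    fg = morphology.remove_small_objects(fg, max_size=max(min_size - 1, 0))
    return measure.label(fg)


def segment_cells(
    nuclei: np.ndarray,
    actin_image: np.ndarray,
    window: int = 50,
    offset: float | None = None,
) -> np.ndarray:
    """Propagate nuclei labels into the actin mask (one cell per nucleus).

    The actin channel is adaptively thresholded with a larger window and
    united with the nuclei so that every seed lies inside the mask; a
    seeded watershed on the actin gradient then partitions the mask into
    disjoint cell regions, each containing exactly its seed nucleus. With
    an empty actin mask the cell regions equal the nuclei regions.
    """
    nuclei = np.asarray(nuclei)
    actin = np.asarray(actin_image, dtype=float)
    if nuclei.shape != actin.shape:
        raise ValueError("nuclei mask and actin image must share dimensions")
    if nuclei.max() == 0:
        return np.zeros_like(nuclei)
    mask = adaptive_threshold(actin, window=window, offset=offset)
    mask = ndi.binary_fill_holes(mask) | (nuclei > 0)
    from skimage.filters import sobel

    return segmentation.watershed(sobel(actin), markers=nuclei, mask=mask)


def _glcm_props(values: np.ndarray, levels: int = 32) -> dict[str, float]:
    """Haralick-style texture statistics of a masked pixel population.

    Intensities are quantized to ``levels`` gray levels within the region's
    range; the co-occurrence matrix is computed at 1-pixel offset in four
    directions (averaged, symmetric) with background pairs removed. A
    constant region has zero contrast by construction.
    """
    img, mask = values
    lo, hi = img[mask].min(), img[mask].max()
    if hi > lo:
        q = np.zeros(img.shape, dtype=np.uint8)
        q[mask] = 1 + np.minimum(
            ((img[mask] - lo) / (hi - lo) * (levels - 1)).astype(int), levels - 1
        )
    else:
        q = np.where(mask, 1, 0).astype(np.uint8)
    glcm = graycomatrix(
        q,
        distances=[1],
        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=levels + 1,
        symmetric=True,
    ).astype(float)
    glcm = glcm[1:, 1:, 0, :].sum(axis=-1)  # strip background row/col, pool angles
    total = glcm.sum()
    if total == 0:
        return {"contrast": 0.0, "energy": 1.0, "homogeneity": 1.0, "correlation": 0.0}
    P = glcm / total
    i, j = np.indices(P.shape)
    contrast = float((P * (i - j) ** 2).sum())
    energy = float(np.sqrt((P**2).sum()))
    homogeneity = float((P / (1.0 + (i - j) ** 2)).sum())
    mu_i = (P * i).sum()
    mu_j = (P * j).sum()
    sd_i = np.sqrt((P * (i - mu_i) ** 2).sum())
    sd_j = np.sqrt((P * (j - mu_j) ** 2).sum())
    if sd_i > 0 and sd_j > 0:
        correlation = float(((P * (i - mu_i) * (j - mu_j)).sum()) / (sd_i * sd_j))
    else:
        correlation = 0.0
    return {
        "contrast": contrast,
        "energy": energy,
        "homogeneity": homogeneity,
        "correlation": correlation,
    }


def extract_cell_features(
    nuclei: np.ndarray,
    cells: np.ndarray,
    dna_image: np.ndarray,
    actin_image: np.ndarray,
) -> pd.DataFrame:
    """Per-cell morphology, intensity and texture features.

    One record per labeled cell: nuclear area/perimeter/eccentricity/
    equivalent radius, DNA intensity statistics and DNA textures over the
    nucleus; cell area/perimeter/eccentricity/elongation, actin intensity
    statistics and actin textures over the cell body. Nuclear area never
    exceeds cell area and eccentricities lie in [0, 1].
    """
    nuclei = np.asarray(nuclei)
    cells = np.asarray(cells)
    n_labels = set(np.unique(nuclei)) - {0}
    c_labels = set(np.unique(cells)) - {0}
    if n_labels != c_labels:
        raise ValueError("nuclei and cell masks carry inconsistent label sets")
    if not n_labels:
        return pd.DataFrame()
    dna = np.asarray(dna_image, dtype=float)
    actin = np.asarray(actin_image, dtype=float)

    records = []
    n_props = {p.label: p for p in measure.regionprops(nuclei, intensity_image=dna)}
    c_props = {p.label: p for p in measure.regionprops(cells, intensity_image=actin)}
    for label in sorted(n_labels):
        np_, cp = n_props[label], c_props[label]
        rec = {"cell_id": label, "centroid_y": np_.centroid[0], "centroid_x": np_.centroid[1]}
        dna_px = dna[nuclei == label]
        actin_px = actin[cells == label]
        rec.update(
            n_area=float(np_.area),
            n_perimeter=float(np_.perimeter),
            n_eccentricity=float(np_.eccentricity),
            n_radius=float(np_.equivalent_diameter_area) / 2.0,
            n_dna_mean=float(dna_px.mean()),
            n_dna_sd=float(dna_px.std()),
            c_area=float(cp.area),
            c_perimeter=float(cp.perimeter),
            c_eccentricity=float(cp.eccentricity),
            c_elongation=float(
                cp.axis_major_length / cp.axis_minor_length
                if cp.axis_minor_length > 0
                else 1.0
            ),
            c_actin_mean=float(actin_px.mean()),
            c_actin_sd=float(actin_px.std()),
        )
        for prefix, img, mask in (
            ("n_dna", dna, nuclei == label),
            ("c_actin", actin, cells == label),
        ):
            for name, val in _glcm_props((img, mask)).items():
                rec[f"{prefix}_{name}"] = val
        records.append(rec)
    return pd.DataFrame.from_records(records)


def aggregate_well(records: pd.DataFrame, count_name: str = "cell_number") -> pd.Series:
    """Collapse per-cell records to a well-level feature vector.

    The number of cells is the first entry; every per-cell feature is
    averaged across cells, with an additional cell-to-cell standard
    deviation for the intensity features. An empty record list yields a
    count of 0 and missing (NaN) aggregates.
    """
    base = {count_name: 0.0}
    if records is None or len(records) == 0:
        return pd.Series(base)
    feats = [c for c in records.columns if c not in ("cell_id", "centroid_y", "centroid_x")]
    out = {count_name: float(len(records))}
    for f in feats:
        out[f] = float(records[f].mean())
    for f in INTENSITY_FEATURES:
        if f in records.columns:
            out[f"{f}_cellsd"] = float(records[f].std(ddof=0))
    return pd.Series(out)


def process_well(
    dna_image: np.ndarray,
    actin_image: np.ndarray,
    margin: int = 0,
    window: int = 10,
    saturation_level: int = 65535,
) -> tuple[pd.Series, pd.DataFrame]:
    """Full well pipeline: crop, segment, extract, aggregate.

    Returns the well feature vector (including the fraction of saturated
    pixels for QC) and the per-cell records.
    """
    if margin > 0:
        dna_image = crop_border(dna_image, margin)
        actin_image = crop_border(actin_image, margin)
    nuclei = segment_nuclei(dna_image, window=window)
    cells = segment_cells(nuclei, actin_image)
    records = extract_cell_features(nuclei, cells, dna_image, actin_image)
    well = aggregate_well(records)
    sat = max(
        float(np.mean(np.asarray(dna_image) >= saturation_level)),
        float(np.mean(np.asarray(actin_image) >= saturation_level)),
    )
    well["saturated_frac"] = sat
    return well, records
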