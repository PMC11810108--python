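"""Cell and inclusion segmentation, and the mask combination that yields
per-cell inclusion counts.

Cells and inclusions are separated from background purely by intensity: cells
by Otsu thresholding on log intensity followed by a distance-transform
watershed that splits touching cells; inclusions by a robust per-cell
threshold (median + k * MAD inside each cell) followed by a local-maxima
watershed that splits merged puncta.  All thresholds are data-derived, so both
masks are invariant to a positive rescaling of the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, morphology, segmentation as sk_seg
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

__all__ = [
    "LabeledMask",
    "segment_cells",
    "segment_inclusions",
    "assign_inclusions",
]


@dataclass
class LabeledMask:
    """Integer-labeled segmentation: 0 = background, labels consecutive 1..n."""

    labels: np.ndarray
    kind: str  # "cell" or "inclusion"

    def __post_init__(self) -> None:
        if self.kind not in ("cell", "inclusion"):
            raise ValueError(f"kind must be 'cell' or 'inclusion', got {self.kind!r}")
        present = np.unique(self.labels)
        present = present[present > 0]
        if len(present) and (present[0] != 1 or present[-1] != len(present)):
            raise ValueError("labels must be consecutive 1..n")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def border_labels(self) -> np.ndarray:
        """Labels of objects touching the image border."""
        edges = np.concatenate([self.labels[0], self.labels[-1],
                                self.labels[:, 0], self.labels[:, -1]])
        out = np.unique(edges)
        return out[out > 0]


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Relabel to 1..n preserving raster-scan order of first appearance."""
    out = np.zeros_like(labels, dtype=np.int32)
    present = labels[labels > 0]
    if present.size == 0:
        return out
    order = pd.unique(present)  # first-appearance order, deterministic
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[order] = np.arange(1, len(order) + 1, dtype=np.int32)
    out = lut[labels]
    return out


def segment_cells(image: np.ndarray, min_area_px: int = 200,
                  max_area_px: int = 5000, marker_h: float = 2.0,
                  ) -> LabeledMask:
    """Separate cells from background on a shading-corrected image.

    Otsu on log intensity -> fill holes -> distance-transform watershed with
    h-maxima markers (h in pixels of distance) -> area filter [min, max].
    An empty or constant image yields an empty mask; non-finite pixels raise.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    empty = LabeledMask(np.zeros(image.shape, dtype=np.int32), "cell")
    if image.max() <= 0 or image.max() == image.min():
        return empty

    # light denoising first: at camera noise levels the raw background log-
    # histogram is broad enough to defeat Otsu, and cells are much larger than
    # the smoothing scale.  The scale-adaptive offset keeps the log transform
    # (and hence Otsu) exactly equivariant under multiplication by a positive
    # constant.
    smoothed = ndi.gaussian_filter(image, 2.0)
    logim = np.log(smoothed + 1e-3 * image.mean() + np.finfo(float).tiny)
    thr = threshold_otsu(logim)
    fg = logim > thr
    # contrast guard: on a field with no cells, Otsu merely splits the noise
    # of the (unimodal) background, leaving the two classes ~1.6 sigma apart;
    # genuine cells sit many background-sigmas above.  Require real contrast.
    bg_vals, fg_vals = logim[~fg], logim[fg]
    if fg_vals.size == 0:
        return empty
    bg_med = np.median(bg_vals)
    bg_sigma = 1.4826 * np.median(np.abs(bg_vals - bg_med))
    if fg_vals.mean() - bg_vals.mean() < 4.0 * bg_sigma:
        return empty
    fg = ndi.binary_fill_holes(fg)
    lab0, _ = ndi.label(fg)
    sizes = np.bincount(lab0.ravel())
    fg = sizes[lab0] >= max(1, min_area_px // 4)
    fg &= lab0 > 0
    if not fg.any():
        return empty

    dist = ndi.distance_transform_edt(fg)
    dist_s = ndi.gaussian_filter(dist, 2.0)
    peaks = morphology.h_maxima(dist_s, marker_h)
    markers, n_markers = ndi.label(peaks)
    if n_markers == 0:
        markers, _ = ndi.label(fg)
    labels = sk_seg.watershed(-dist_s, markers, mask=fg, connectivity=1)

    areas = np.bincount(labels.ravel())
    bad = np.flatnonzero((areas < min_area_px) | (areas > max_area_px))
    labels[np.isin(labels, bad[bad > 0])] = 0
    return LabeledMask(_relabel_consecutive(labels), "cell")


def _per_label_threshold(image: np.ndarray, labels: np.ndarray, k: float,
                         ) -> np.ndarray:
    """Per-cell robust threshold (median + k * MAD) as a full-size map."""
    n = int(labels.max())
    thr_map = np.full(image.shape, np.inf)
    for lab in range(1, n + 1):
        mask = labels == lab
        vals = image[mask]
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        thr_map[mask] = med + k * mad
    return thr_map


def segment_inclusions(image: np.ndarray, cell_mask: LabeledMask,
                       min_area_px: int = 4, intensity_k: float = 6.0,
                       min_peak_distance: int = 1) -> LabeledMask:
    """Detect inclusion puncta inside cells on the spot-enhanced residual.

    Candidate pixels exceed the per-cell robust threshold (median +
    ``intensity_k`` x MAD over that cell's pixels) and lie on cell foreground;
    connected components below ``min_area_px`` are dropped; merged puncta are
    split by a watershed seeded at local intensity maxima.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != cell_mask.labels.shape:
        raise ValueError("image and cell mask shapes differ")
    empty = LabeledMask(np.zeros(image.shape, dtype=np.int32), "inclusion")
    if cell_mask.n_objects == 0:
        return empty

    thr_map = _per_label_threshold(image, cell_mask.labels, intensity_k)
    cand = (image > thr_map) & (cell_mask.labels > 0)
    comp, _ = ndi.label(cand, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    sizes = np.bincount(comp.ravel())
    comp[sizes[comp] < min_area_px] = 0
    if not comp.any():
        return empty

    smoothed = ndi.gaussian_filter(image, 1.0)
    coords = peak_local_max(smoothed, min_distance=min_peak_distance,
                            labels=comp, exclude_border=False)
    markers = np.zeros(image.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    # guarantee at least one seed per component (plateaus can defeat the
    # peak finder); use the component's brightest pixel
    seeded = np.unique(comp[markers > 0])
    next_id = len(coords) + 1
    for lab in np.unique(comp[comp > 0]):
        if lab not in seeded:
            inside = np.where(comp == lab)
            best = np.argmax(smoothed[inside])
            markers[inside[0][best], inside[1][best]] = next_id
            next_id += 1
    labels = sk_seg.watershed(-smoothed, markers, mask=comp > 0, connectivity=1)
    return LabeledMask(_relabel_consecutive(labels), "inclusion")


def assign_inclusions(cell_mask: LabeledMask, ib_mask: LabeledMask,
                      intensity: np.ndarray | None = None,
                      field_id: str = "field_0",
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine the two masks: per-inclusion owners and per-cell counts.

    Each inclusion is assigned to the cell label covering the majority of its
    pixels (ties broken toward the smaller cell label; majority on background
    gives owner 0 and the inclusion is reported but excluded from counts).

    Returns ``(inclusion_records, cell_counts)`` where the records carry
    label, centroid, area, perimeter, mean intensity (if an intensity image is
    given) and owner, and the counts table has one row per cell label.
    """
    if cell_mask.kind != "cell" or ib_mask.kind != "inclusion":
        raise ValueError("expected a cell mask and an inclusion mask, in that order")
    if cell_mask.labels.shape != ib_mask.labels.shape:
        raise ValueError("mask shapes differ")

    props = measure.regionprops(ib_mask.labels,
                                intensity_image=intensity)
    owners = np.zeros(ib_mask.n_objects, dtype=int)
    for p in props:
        under = cell_mask.labels[tuple(p.coords.T)]
        counts = np.bincount(under)
        # argmax returns the first (= smallest) index on ties
        owners[p.label - 1] = int(np.argmax(counts))

    records = pd.DataFrame({
        "field_id": field_id,
        "ib_label": [p.label for p in props],
        "owner_cell_label": owners,
        "area_px": [int(p.area) for p in props],
        "centroid_row": [p.centroid[0] for p in props],
        "centroid_col": [p.centroid[1] for p in props],
        "perimeter_px": [float(p.perimeter) for p in props],
        "mean_intensity": [float(p.intensity_mean) if intensity is not None
                           else np.nan for p in props],
    })

    n_cells = cell_mask.n_objects
    counts = np.zeros(n_cells, dtype=int)
    owned = owners[owners > 0]
    if owned.size:
        counts[: owned.max()] += np.bincount(owned)[1:]
    cell_counts = pd.DataFrame({
        "field_id": field_id,
        "cell_label": np.arange(1, n_cells + 1, dtype=int),
        "ib_count": counts,
    })
    return records, cell_counts
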