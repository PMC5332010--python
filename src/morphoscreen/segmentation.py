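"""Segmentation: nuclei from the nuclear stain, cells from tubulin.

Nuclei are found by Gaussian smoothing, a global threshold (Otsu by
default) and a distance-transform watershed to split touching nuclei.
Cells are then grown from the nucleus seeds by a seeded watershed on the
(inverted) tubulin intensity restricted to the tubulin foreground, giving
exactly one cell per nucleus.  A separate cytoplasm-first pass (connected
components of the tubulin foreground, no seeding) supports multinucleate
detection, which the nucleus-seeded path cannot observe by construction.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import relabel_sequential, watershed

from .config import SegmentationConfig

log = logging.getLogger(__name__)

_CROSS = ndi.generate_binary_structure(2, 1)


def _threshold(img: np.ndarray, spec: str | float) -> float:
    if isinstance(spec, (int, float)):
        return float(spec)
    if spec == "otsu":
        if img.max() == img.min():
            return np.inf  # no foreground on a flat image
        return float(threshold_otsu(img))
    raise ValueError(f"unknown threshold {spec!r}")


def _check_raster(img: np.ndarray) -> None:
    if img.ndim != 2:
        raise ValueError(f"expected 2-D raster, got {img.ndim}-D")
    if not np.isfinite(img).all():
        raise ValueError("raster contains non-finite values")


def segment_nuclei(
    nuclear_channel: np.ndarray, params: SegmentationConfig | None = None
) -> np.ndarray:
    """Label mask of nuclei, one label per nucleus."""
    _check_raster(nuclear_channel)
    p = params or SegmentationConfig()
    smooth = gaussian(nuclear_channel.astype(float), sigma=p.nucleus_smooth_sigma,
                      preserve_range=True)
    thr = _threshold(smooth, p.nucleus_threshold)
    fg = smooth > thr
    if not fg.any():
        return np.zeros_like(nuclear_channel, dtype=np.int32)
    fg = ndi.binary_fill_holes(fg)
    dist = ndi.distance_transform_edt(fg)
    # smoothing the distance map suppresses spurious maxima in elongated nuclei
    dist_s = ndi.gaussian_filter(dist, p.peak_smooth_sigma)
    coords = peak_local_max(
        dist_s, min_distance=p.peak_min_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros_like(fg, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    markers, _ = ndi.label(markers > 0)
    labels = watershed(-dist, markers, mask=fg)
    # minimum-area filter
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < p.min_nucleus_area)
    labels[np.isin(labels, small[small > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def segment_cells(
    tubulin_channel: np.ndarray,
    nuclei: np.ndarray,
    params: SegmentationConfig | None = None,
) -> np.ndarray:
    """Seeded watershed of the tubulin foreground: one cell per nucleus."""
    _check_raster(tubulin_channel)
    p = params or SegmentationConfig()
    if nuclei.max() == 0:
        return np.zeros_like(nuclei, dtype=np.int32)
    smooth = gaussian(tubulin_channel.astype(float), sigma=p.cell_smooth_sigma,
                      preserve_range=True)
    thr = _threshold(smooth, p.cell_threshold)
    fg = (smooth > thr) | (nuclei > 0)
    fg = ndi.binary_fill_holes(fg)
    labels = watershed(-smooth, nuclei.astype(np.int32), mask=fg)
    # a nucleus whose seed fell outside the tubulin foreground may come back
    # as a bare seed; give it its nucleus dilated by 1 px
    for lab in range(1, int(nuclei.max()) + 1):
        nuc = nuclei == lab
        cell = labels == lab
        if not (cell & nuc).sum() == nuc.sum():
            log.warning("nucleus %d outside tubulin foreground; using dilated nucleus", lab)
            patch = ndi.binary_dilation(nuc, structure=_CROSS) & (labels == 0)
            labels[patch | nuc] = lab
    return labels.astype(np.int32)


def filter_border(
    cells: np.ndarray, nuclei: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Remove cells touching any image edge, with their nuclei; relabel."""
    if cells.shape != nuclei.shape:
        raise ValueError("cell and nucleus masks must be aligned")
    border_labels = np.unique(
        np.concatenate([cells[0], cells[-1], cells[:, 0], cells[:, -1]])
    )
    border_labels = border_labels[border_labels > 0]
    cells_f = np.where(np.isin(cells, border_labels), 0, cells)
    # drop nuclei whose cell was removed
    keep_nuc = np.zeros(int(nuclei.max()) + 1, dtype=bool)
    for lab in range(1, int(nuclei.max()) + 1):
        m = nuclei == lab
        owners = np.unique(cells_f[m])
        keep_nuc[lab] = bool((owners > 0).any())
    nuclei_f = np.where(keep_nuc[nuclei], nuclei, 0)
    cells_f, fwd, _ = relabel_sequential(cells_f)
    nuclei_f, _, _ = relabel_sequential(nuclei_f)
    return cells_f.astype(np.int32), nuclei_f.astype(np.int32)


def match_nuclei_to_cells(cells: np.ndarray, nuclei: np.ndarray) -> dict[int, int]:
    """Map each nucleus label to the cell label containing its majority."""
    out: dict[int, int] = {}
    for lab in np.unique(nuclei):
        if lab == 0:
            continue
        owners, counts = np.unique(cells[nuclei == lab], return_counts=True)
        nz = owners > 0
        if nz.any():
            out[int(lab)] = int(owners[nz][np.argmax(counts[nz])])
    return out


def detect_multinucleate(
    tubulin_channel: np.ndarray,
    nuclei: np.ndarray,
    params: SegmentationConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Cytoplasm-first multinucleate detection.

    Connected components of the tubulin foreground (no nuclear seeding) are
    counted against the nucleus centroids they contain; a component with
    >= 2 nuclei is multinucleate.  Returns (per-component nucleus counts,
    multinucleate percentage over components containing >= 1 nucleus); the
    percentage is NaN when there are no such components.
    """
    _check_raster(tubulin_channel)
    p = params or SegmentationConfig()
    smooth = gaussian(tubulin_channel.astype(float), sigma=p.cell_smooth_sigma,
                      preserve_range=True)
    thr = _threshold(smooth, p.cell_threshold)
    fg = ndi.binary_fill_holes((smooth > thr) | (nuclei > 0))
    comps, n_comps = ndi.label(fg)
    counts = np.bincount(comps.ravel())
    small = np.flatnonzero(counts < p.min_cell_area)
    comps[np.isin(comps, small[small > 0])] = 0
    comps, _, _ = relabel_sequential(comps)
    n_comps = int(comps.max())
    if n_comps == 0:
        return np.zeros(0, dtype=int), float("nan")
    nuc_counts = np.zeros(n_comps + 1, dtype=int)
    for lab in np.unique(nuclei):
        if lab == 0:
            continue
        cr, cc = ndi.center_of_mass(nuclei == lab)
        comp = comps[int(round(cr)), int(round(cc))]
        if comp > 0:
            nuc_counts[comp] += 1
    with_nuclei = nuc_counts[1:][nuc_counts[1:] >= 1]
    if with_nuclei.size == 0:
        return nuc_counts[1:], float("nan")
    pct = 100.0 * float((with_nuclei >= 2).sum()) / float(with_nuclei.size)
    return nuc_counts[1:], pct
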