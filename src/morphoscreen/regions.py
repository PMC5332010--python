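"""Sub-cellular region geometry.

Border percentages are realised through a per-pixel normalised radial
coordinate rho: 0 at the cell centroid, 1 on the cell boundary along the ray
through the pixel, >1 outside the cell.  A band between an inner border of
``inner_pct`` percent and an outer border of ``outer_pct`` percent (both
measured inward from the cell edge as a fraction of the edge-to-centroid
distance; negative values reach outside the cell) is the set of pixels with

    1 - inner_pct/100 <= rho <= 1 - outer_pct/100

so an inner border of 100 percent encompasses the whole cell and an outer
border of -5 percent extends 5 percent beyond the edge.  The regions built
here are the published ones: the protrusion membrane region (10 / -5), the
perinuclear ring (inner 40, outer 20 percent of the edge-to-inner-border
distance), the eroded nucleus (2 percent of the equivalent radius) and the
two 1-px membrane bands used for the neighbour fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

_CROSS = ndi.generate_binary_structure(2, 1)
_EPS = 1e-6
#: outside-of-cell pixels are clamped strictly above 1 by this margin
_OUT_EPS = 1e-3


@dataclass
class RadialCoordinateField:
    """Normalised radial coordinate on (a bounding window of) the raster."""

    rho: np.ndarray  # float, full image size; np.inf where undefined
    centroid: tuple[float, float]


def _pole_of_inaccessibility(mask: np.ndarray) -> tuple[float, float]:
    dist = ndi.distance_transform_edt(mask)
    r, c = np.unravel_index(int(np.argmax(dist)), mask.shape)
    return float(r), float(c)


def radial_field(
    mask: np.ndarray, n_theta: int = 720, margin: int | None = None
) -> RadialCoordinateField:
    """Per-pixel normalised radial coordinate of a single cell mask.

    The boundary radius r_b(theta) is the outermost mask pixel in each
    angular bin around the centroid (for rays with several boundary
    crossings the outermost crossing is used, which keeps rho <= 1 inside
    the mask); empty bins are filled by circular interpolation.  Pixels
    inside the mask are clamped to rho <= 1, pixels outside to rho > 1.
    """
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    area = int(mask.sum())
    if area == 0:
        raise ValueError("mask has zero area")
    cr, cc = ndi.center_of_mass(mask)
    if not mask[min(int(round(cr)), mask.shape[0] - 1), min(int(round(cc)), mask.shape[1] - 1)]:
        cr, cc = _pole_of_inaccessibility(mask)

    if margin is None:
        margin = max(4, int(0.1 * np.sqrt(area / np.pi)) + 2)
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    r0 = max(0, rows[0] - margin)
    r1 = min(mask.shape[0], rows[-1] + margin + 1)
    c0 = max(0, cols[0] - margin)
    c1 = min(mask.shape[1], cols[-1] + margin + 1)

    # boundary radius per angular bin, from all mask pixels (outermost wins)
    mr, mc = np.nonzero(mask)
    dr = mr - cr
    dc = mc - cc
    theta = np.arctan2(dr, dc)
    rad = np.hypot(dr, dc)
    bins = ((theta + np.pi) / (2 * np.pi) * n_theta).astype(int) % n_theta
    r_b = np.zeros(n_theta)
    np.maximum.at(r_b, bins, rad)
    empty = r_b == 0
    if empty.any():
        idx = np.arange(n_theta)
        good = ~empty
        # circular linear interpolation over missing bins
        r_b = np.interp(
            idx,
            np.concatenate([idx[good] - n_theta, idx[good], idx[good] + n_theta]),
            np.concatenate([r_b[good]] * 3),
        )
    r_b = np.maximum(r_b, 0.5)

    rho = np.full(mask.shape, np.inf, dtype=np.float64)
    rr, cc2 = np.mgrid[r0:r1, c0:c1]
    dr = rr - cr
    dc = cc2 - cc
    th = np.arctan2(dr, dc)
    rad = np.hypot(dr, dc)
    # linear interpolation of r_b over angle
    pos = (th + np.pi) / (2 * np.pi) * n_theta
    i0 = np.floor(pos).astype(int) % n_theta
    i1 = (i0 + 1) % n_theta
    frac = pos - np.floor(pos)
    rb_pix = r_b[i0] * (1 - frac) + r_b[i1] * frac
    win_rho = rad / np.maximum(rb_pix, 0.5)
    inside = mask[r0:r1, c0:c1]
    win_rho = np.where(inside, np.minimum(win_rho, 1.0), np.maximum(win_rho, 1.0 + _OUT_EPS))
    rho[r0:r1, c0:c1] = win_rho
    return RadialCoordinateField(rho=rho, centroid=(cr, cc))


def band_from_borders(
    mask: np.ndarray,
    inner_pct: float,
    outer_pct: float,
    field: RadialCoordinateField | None = None,
) -> np.ndarray:
    """Shell between two borders given as depths from the cell edge.

    ``inner_pct`` and ``outer_pct`` are percentages of the edge-to-centroid
    distance measured inward from the edge; negative values lie outside the
    cell.  ``band_from_borders(mask, 100, 0)`` is exactly the cell mask.
    """
    if inner_pct < outer_pct:
        raise ValueError(
            f"inner border ({inner_pct}) must be at least outer border ({outer_pct})"
        )
    if field is None:
        field = radial_field(mask)
    lo = 1.0 - inner_pct / 100.0
    hi = 1.0 - outer_pct / 100.0
    return (field.rho >= lo - _EPS) & (field.rho <= hi + _EPS)


def build_ring(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    field: RadialCoordinateField | None = None,
    inner_pct: float = 40.0,
    outer_frac: float = 0.20,
    outer_from_edge: bool = True,
) -> np.ndarray:
    """Perinuclear ring region.

    Inner border at ``inner_pct`` (100 = whole cell); the outer border is
    ``outer_frac`` of the edge-to-inner-border distance.  With the default
    reading the outer border sits at depth inner_pct*outer_frac measured
    from the cell edge (ring 0.60 <= rho <= 0.92); the alternative reading
    measures it from the inner border instead.  The (uneroded) nucleus is
    excluded so nuclear and ring signals never share pixels.
    """
    if outer_from_edge:
        outer_pct = inner_pct * outer_frac
    else:
        outer_pct = inner_pct * (1.0 - outer_frac)
    ring = band_from_borders(cell_mask, inner_pct, outer_pct, field=field)
    ring &= ~nucleus_mask
    if not ring.any():
        warnings.warn("ring region empty after nucleus exclusion")
    return ring


def erode_nucleus(nucleus_mask: np.ndarray, pct: float = 2.0) -> np.ndarray:
    """Nucleus eroded by ``pct`` percent of its equivalent radius.

    The erosion radius is max(1, round(pct/100 * sqrt(A/pi))) px.  If the
    erosion would empty the mask, a 1-px erosion is tried; if that is also
    empty the original mask is returned with a warning.
    """
    area = int(nucleus_mask.sum())
    if area == 0:
        raise ValueError("empty nucleus mask")
    r_eq = np.sqrt(area / np.pi)
    r = max(1, int(round(pct / 100.0 * r_eq)))
    eroded = ndi.binary_erosion(nucleus_mask, structure=disk(r))
    if not eroded.any() and r > 1:
        eroded = ndi.binary_erosion(nucleus_mask, structure=disk(1))
    if not eroded.any():
        warnings.warn("nuclear erosion emptied the mask; returning it uneroded")
        return nucleus_mask.copy()
    return eroded


def neighbour_bands(
    cell_mask: np.ndarray, labels: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """The two 1-px membrane bands used for the neighbour fraction.

    membrane1 is the 1-px band just inside the cell boundary (purely
    geometric); membrane2 is the 1-px band just outside it, excluding pixels
    occupied by other cells, so cell-cell contact clips the outside band.
    """
    m1 = cell_mask & ~ndi.binary_erosion(cell_mask, structure=_CROSS)
    m2 = ndi.binary_dilation(cell_mask, structure=_CROSS) & ~cell_mask
    if labels is not None:
        m2 &= labels == 0
    return m1, m2


@dataclass
class RegionSet:
    """All region masks of one cell."""

    label: int
    nucleus: np.ndarray
    eroded_nucleus: np.ndarray
    cell: np.ndarray
    cytoplasm: np.ndarray
    ring: np.ndarray
    membrane_protrusion: np.ndarray
    membrane1: np.ndarray
    membrane2: np.ndarray
    radial: RadialCoordinateField


def build_region_set(
    label: int,
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    labels: np.ndarray | None = None,
    protrusion_inner_pct: float = 10.0,
    protrusion_outer_pct: float = -5.0,
    ring_inner_pct: float = 40.0,
    ring_outer_frac: float = 0.20,
    ring_outer_from_edge: bool = True,
    erode_pct: float = 2.0,
    n_theta: int = 720,
) -> RegionSet:
    """Build every region mask for one segmented cell."""
    if not (nucleus_mask & cell_mask).sum() == nucleus_mask.sum():
        # tolerate stray pixels from upstream segmentation; clip to the cell
        nucleus_mask = nucleus_mask & cell_mask
    field = radial_field(cell_mask, n_theta=n_theta)
    ring = build_ring(
        cell_mask,
        nucleus_mask,
        field=field,
        inner_pct=ring_inner_pct,
        outer_frac=ring_outer_frac,
        outer_from_edge=ring_outer_from_edge,
    )
    protrusion = band_from_borders(
        cell_mask, protrusion_inner_pct, protrusion_outer_pct, field=field
    )
    m1, m2 = neighbour_bands(cell_mask, labels)
    eroded = (
        erode_nucleus(nucleus_mask, pct=erode_pct)
        if nucleus_mask.any()
        else nucleus_mask.copy()
    )
    return RegionSet(
        label=label,
        nucleus=nucleus_mask,
        eroded_nucleus=eroded,
        cell=cell_mask,
        cytoplasm=cell_mask & ~nucleus_mask,
        ring=ring,
        membrane_protrusion=protrusion,
        membrane1=m1,
        membrane2=m2,
        radial=field,
    )
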