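"""Per-cell feature extraction and well-level aggregation.

Field-wide response maps (SER, Gabor) are computed once per channel and
scale; per-cell region means are then labelled reductions over region
label rasters, which keeps extraction linear in image size rather than in
cell count.  Haralick features and geometry are computed per cell on a
bounding-box window.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from ..config import Config
from ..imageio import FieldImage
from ..regions import RegionSet, build_region_set
from .morphology import morphology_of_mask
from .registry import (
    AUX_COLUMNS,
    GABOR_STATS,
    HARALICK_FEATURES,
    HARALICK_PAIRS,
    REGISTRY_NAMES,
    SER_PAIRS,
    SER_RESPONSES,
    NEIGHBOUR_FRACTION,
    WELL_FEATURE_NAMES,
)
from .texture import (
    gabor_bank,
    gabor_response_maps,
    haralick_features,
    ser_derivative_stack,
    ser_responses,
)

log = logging.getLogger(__name__)


def intensity_features(
    channels: dict[str, np.ndarray], rs: RegionSet
) -> dict[str, float]:
    """Region-mean intensities for one cell."""

    def mean(ch: str, mask: np.ndarray) -> float:
        return float(channels[ch][mask].mean()) if mask.any() else np.nan

    return {
        "yap_nucleus_mean": mean("yaptaz", rs.nucleus),
        "yap_eroded_nucleus_mean": mean("yaptaz", rs.eroded_nucleus),
        "yap_ring_mean": mean("yaptaz", rs.ring),
        "yap_cell_mean": mean("yaptaz", rs.cell),
        "yap_cytoplasm_mean": mean("yaptaz", rs.cytoplasm),
        "dna_nucleus_mean": mean("dna", rs.nucleus),
        "tubulin_cytoplasm_mean": mean("tubulin", rs.cytoplasm),
        "tubulin_cell_mean": mean("tubulin", rs.cell),
    }


def _safe_div(a: float, b: float) -> float:
    if not np.isfinite(a) or not np.isfinite(b) or b <= 0:
        return np.nan
    return a / b


def ratio_features(intens: dict[str, float], morph: dict[str, float]) -> dict[str, float]:
    """Derived translocation and normalisation ratios for one cell.

    Zero or missing denominators give missing values, never infinities.
    """
    nuc_ring = _safe_div(intens["yap_nucleus_mean"], intens["yap_ring_mean"])
    ero_ring = _safe_div(intens["yap_eroded_nucleus_mean"], intens["yap_ring_mean"])
    nuc_area = morph["nucleus_area"]
    cell_area = morph["cell_area"]
    out = {
        "yap_ratio_nuc_ring": nuc_ring,
        "yap_ratio_nuc_ring_log10": np.log10(nuc_ring) if nuc_ring and np.isfinite(nuc_ring) and nuc_ring > 0 else np.nan,
        "yap_ratio_eroded_ring": ero_ring,
        "yap_ratio_eroded_ring_log10": np.log10(ero_ring) if ero_ring and np.isfinite(ero_ring) and ero_ring > 0 else np.nan,
        "dna_nucleus_per_area": _safe_div(intens["dna_nucleus_mean"], nuc_area),
        "yap_nucleus_per_area": _safe_div(intens["yap_nucleus_mean"], nuc_area),
        "cell_area_per_yap_cell": _safe_div(cell_area, intens["yap_cell_mean"]),
        "nucleus_area_per_yap_cell": _safe_div(nuc_area, intens["yap_cell_mean"]),
    }
    # total YAP/TAZ: summed nuclear + ring intensity normalised to nuclear
    # area (auxiliary; the hit-selection readout for overall YAP/TAZ level)
    s = intens["yap_nucleus_mean"] + intens["yap_ring_mean"]
    out["total_yaptaz"] = _safe_div(s, nuc_area)
    return out


def neighbour_fraction(area_m1: float, area_m2: float) -> tuple[float, float]:
    """(raw, calibrated) neighbour fraction from the membrane-band areas.

    raw = 1 - A1/(2*A2), clamped to [0, 1]; a fully enclosed cell (A2 = 0)
    is 1 by contract.  With the outside band clipped by neighbours, an
    isolated cell sits near 0.5 raw; the calibrated value rescales so
    isolated -> 0 and fully enclosed -> 1 (calibrated = 2*raw - 1, clamped),
    approximating the fraction of perimeter in cell-cell contact.
    """
    if area_m2 <= 0:
        return 1.0, 1.0
    raw = float(np.clip(1.0 - area_m1 / (2.0 * area_m2), 0.0, 1.0))
    cal = float(np.clip(2.0 * raw - 1.0, 0.0, 1.0))
    return raw, cal


def morphology_features(rs: RegionSet) -> dict[str, float]:
    """The 16 registry morphology values for one cell's region set."""
    out: dict[str, float] = {}
    for region, mask in (
        ("nucleus", rs.nucleus),
        ("cell", rs.cell),
        ("cytoplasm", rs.cytoplasm),
    ):
        m = morphology_of_mask(mask)
        for prop, v in m.items():
            out[f"{region}_{prop}"] = v
    out["membrane_protrusion_area"] = float(rs.membrane_protrusion.sum())
    return out


def _expand(sl, margin, shape):
    return (
        slice(max(0, sl[0].start - margin), min(shape[0], sl[0].stop + margin)),
        slice(max(0, sl[1].start - margin), min(shape[1], sl[1].stop + margin)),
    )


def extract_all(
    field: FieldImage,
    cells: np.ndarray,
    nuclei: np.ndarray,
    config: Config | None = None,
) -> pd.DataFrame:
    """Extract the full 126-feature vector (plus auxiliaries) per cell.

    ``cells`` and ``nuclei`` are label rasters; a cell's nucleus mask is the
    union of nucleus labels whose majority pixel lies inside it.  Per-feature
    failures become missing values; the field is never aborted.
    """
    cfg = config or Config()
    rc, fc = cfg.regions, cfg.features
    labels = sorted(int(v) for v in np.unique(cells) if v > 0)
    empty = pd.DataFrame(
        columns=["cell", *REGISTRY_NAMES, *AUX_COLUMNS]
    )
    if not labels:
        return empty

    H, W = cells.shape
    slices = ndi.find_objects(cells)
    rows: list[dict[str, float]] = []
    # region label rasters for vectorised texture means
    region_rasters = {
        "nucleus": np.zeros_like(cells),
        "cytoplasm": np.zeros_like(cells),
    }
    region_sets: dict[int, tuple] = {}

    for lab in labels:
        sl = slices[lab - 1]
        if sl is None:
            continue
        area_guess = (sl[0].stop - sl[0].start) * (sl[1].stop - sl[1].start)
        margin = max(6, int(0.12 * np.sqrt(area_guess)) + 2)
        win = _expand(sl, margin, cells.shape)
        cwin = cells[win]
        nwin = nuclei[win]
        cmask = cwin == lab
        # nuclei owned by this cell: majority of the nucleus inside the cell
        nmask = np.zeros_like(cmask)
        for nl in np.unique(nwin):
            if nl == 0:
                continue
            nm = nwin == nl
            if (cwin[nm] == lab).sum() > 0.5 * nm.sum():
                nmask |= nm
        try:
            rs = build_region_set(
                lab,
                cmask,
                nmask & cmask,
                labels=np.where(cmask, 0, cwin),
                protrusion_inner_pct=rc.protrusion_inner_pct,
                protrusion_outer_pct=rc.protrusion_outer_pct,
                ring_inner_pct=rc.ring_inner_pct,
                ring_outer_frac=rc.ring_outer_frac,
                ring_outer_from_edge=rc.ring_outer_from_edge,
                erode_pct=rc.erode_pct,
                n_theta=rc.n_theta,
            )
        except ValueError as e:
            log.warning("cell %d: region construction failed (%s)", lab, e)
            continue
        region_sets[lab] = (win, rs)
        region_rasters["nucleus"][win][rs.nucleus] = lab
        region_rasters["cytoplasm"][win][rs.cytoplasm] = lab

        chans_win = {k: v[win] for k, v in field.channels.items()}
        row: dict[str, float] = {"cell": lab}
        row.update(morphology_features(rs))
        intens = intensity_features(chans_win, rs)
        row.update({k: v for k, v in intens.items() if k != "yap_eroded_nucleus_mean"})
        row.update(
            ratio_features(
                intens,
                {"nucleus_area": row["nucleus_area"], "cell_area": row["cell_area"]},
            )
        )
        for channel, region in HARALICK_PAIRS:
            mask = rs.cytoplasm if region == "cytoplasm" else rs.nucleus
            hf = haralick_features(
                chans_win[channel], mask, levels=fc.glcm_levels, distance=fc.glcm_distance
            )
            for feat in HARALICK_FEATURES:
                row[f"haralick_{feat}_{channel}_{region}"] = hf[feat]
        a1 = float(rs.membrane1.sum())
        a2 = float(rs.membrane2.sum())
        nf_raw, nf_cal = neighbour_fraction(a1, a2)
        row["membrane1_area"] = a1
        row["membrane2_area"] = a2
        row["neighbour_fraction_raw"] = nf_raw
        row["neighbour_fraction"] = nf_cal
        rows.append(row)

    if not rows:
        return empty
    df = pd.DataFrame(rows).set_index("cell")
    kept = df.index.to_numpy()

    # flattened foreground reductions: one gather per region raster, then
    # bincount means per response, instead of full-raster scans per feature
    label_pos = {lab: i for i, lab in enumerate(kept)}
    reducers = {}
    for region, raster in region_rasters.items():
        flat = raster.ravel()
        pos = np.flatnonzero(flat)
        lab = flat[pos]
        compact = np.array([label_pos[v] for v in np.unique(lab)])
        remap = np.zeros(int(lab.max()) + 1, dtype=np.int64)
        for v in np.unique(lab):
            remap[v] = label_pos[v]
        cidx = remap[lab]
        counts = np.bincount(cidx, minlength=len(kept)).astype(float)
        counts[counts == 0] = np.nan
        reducers[region] = (pos, cidx, counts)
        del compact

    def region_means(map1d_or_2d: np.ndarray, region: str) -> np.ndarray:
        pos, cidx, counts = reducers[region]
        vals = map1d_or_2d.ravel()[pos] if map1d_or_2d.ndim == 2 else map1d_or_2d
        return np.bincount(cidx, weights=vals, minlength=len(kept)) / counts

    # field-wide SER derivative stacks; nonlinear response math only on
    # region-foreground pixels
    for scale in fc.ser_scales:
        needed = {ch for ch, _ in SER_PAIRS}
        stacks = {
            ch: ser_derivative_stack(field.channels[ch], scale, sigma0=fc.ser_sigma0)
            for ch in needed
        }
        for channel, region in SER_PAIRS:
            sigma, stack = stacks[channel]
            pos, cidx, counts = reducers[region]
            gathered = tuple(a.ravel()[pos] for a in stack)
            resp = ser_responses(gathered, sigma)
            for name in SER_RESPONSES:
                df[f"ser_{name}_{channel}_{region}_s{scale}"] = (
                    np.bincount(cidx, weights=resp[name], minlength=len(kept)) / counts
                )

    # Gabor maps for actin over the cytoplasm
    kernels = gabor_bank(fc.gabor_wavelength, fc.gabor_orientations)
    gmaps = gabor_response_maps(field.channels["actin"], kernels)
    for stat in GABOR_STATS:
        df[f"gabor_{stat}_actin_cytoplasm"] = region_means(gmaps[stat], "cytoplasm")

    # enforce registry order, auxiliaries last
    df = df[[*REGISTRY_NAMES, *AUX_COLUMNS]]
    df.index.name = "cell"
    return df.reset_index()


def aggregate_well(
    cell_table: pd.DataFrame, shape_labels: pd.Series | None = None
) -> pd.Series:
    """Well profile: per-feature mean over cells, ignoring missing values,
    plus the neighbour fraction (the 127th feature), cell count and
    optional shape-class counts."""
    out: dict[str, float] = {}
    n = len(cell_table)
    for name in REGISTRY_NAMES:
        out[name] = float(cell_table[name].mean()) if n else np.nan
    out[NEIGHBOUR_FRACTION] = (
        float(cell_table[NEIGHBOUR_FRACTION].mean()) if n else np.nan
    )
    out["total_yaptaz"] = float(cell_table["total_yaptaz"].mean()) if n else np.nan
    out["n_cells"] = float(n)
    if shape_labels is not None and n:
        from .registry import SHAPE_CLASSES

        counts = shape_labels.value_counts()
        for cls in SHAPE_CLASSES:
            out[f"shape_n_{cls}"] = float(counts.get(cls, 0))
            out[f"shape_frac_{cls}"] = float(counts.get(cls, 0)) / n
    s = pd.Series(out)
    assert sum(1 for k in s.index if k in WELL_FEATURE_NAMES) == len(WELL_FEATURE_NAMES)
    return s
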