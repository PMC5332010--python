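"""Field assembly: place rendered cells on a canvas and add imaging noise.

Cells are placed without overlap; designed cell-cell contacts share a
zero-width boundary (adjacent labels), matching watershed-style space-filling
segmentation output.  The noiseless render and the full label masks are kept
in the ground truth so every designed quantity can be re-measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.signal import fftconvolve

from ..imageio import FieldImage
from .shapes import CHANNELS, CellRender, GeometryError, ShapeSpec, render_cell

_CROSS = ndi.generate_binary_structure(2, 1)


class PlacementError(RuntimeError):
    """Could not place the requested number of cells."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(f"placed {achieved} of {requested} requested cells")
        self.requested = requested
        self.achieved = achieved


@dataclass
class NoiseModel:
    """Poisson shot noise plus additive Gaussian read noise, per channel."""

    poisson_gain: float = 1.0  # photons per intensity unit; <=0 disables
    gaussian_sigma: float = 2.0
    background: float = 10.0

    def apply(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = img.astype(np.float64) + self.background
        if self.poisson_gain > 0:
            lam = np.clip(out, 0, None) * self.poisson_gain
            # constant-rate background is sampled in one vectorised call;
            # per-pixel rates only where there is signal
            fg = img != 0
            shot = np.empty_like(out)
            shot[~fg] = rng.poisson(self.background * self.poisson_gain,
                                    int((~fg).sum()))
            shot[fg] = rng.poisson(lam[fg])
            out = shot / self.poisson_gain
        if self.gaussian_sigma > 0:
            out = out + rng.normal(0.0, self.gaussian_sigma, img.shape)
        return out.astype(np.float32)


@dataclass
class FieldSpec:
    image_shape: tuple[int, int] = (512, 512)
    n_cells: int = 50
    contact_probability: float = 0.0
    multinucleate_fraction: float = 0.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    rng_seed: int | None = None
    #: minimum clearance (px) between non-contacting cells, so that chance
    #: neighbours do not merge under cytoplasm-first thresholding
    min_gap: int = 3
    #: number of cells deliberately placed overlapping the image border
    border_cells: int = 0
    #: raise PlacementError when n_cells cannot be placed; if False, stop at
    #: the achieved count (emulating confluence at high plating density)
    strict: bool = True
    max_tries: int = 40

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for p in (self.contact_probability, self.multinucleate_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class GroundTruth:
    """Per-field ground truth: label masks, per-cell table, noiseless render."""

    cells: np.ndarray  # int32 label raster
    nuclei: np.ndarray  # int32 label raster (one label per nucleus)
    nucleus_to_cell: dict[int, int]
    records: pd.DataFrame  # label, shape_class, yap_ratio, n_nuclei, ...
    noiseless: FieldImage

    @property
    def n_cells(self) -> int:
        return len(self.records)


def _window(pos: tuple[int, int], shape: tuple[int, int], canvas: tuple[int, int]):
    """Clip a patch window to the canvas; returns canvas and patch slices."""
    r0, c0 = pos
    pr0, pc0 = max(0, -r0), max(0, -c0)
    cr0, cc0 = max(0, r0), max(0, c0)
    cr1 = min(canvas[0], r0 + shape[0])
    cc1 = min(canvas[1], c0 + shape[1])
    pr1 = pr0 + (cr1 - cr0)
    pc1 = pc0 + (cc1 - cc0)
    return (slice(cr0, cr1), slice(cc0, cc1)), (slice(pr0, pr1), slice(pc0, pc1))


def _try_place(
    render: CellRender,
    pos: tuple[int, int],
    occupied: np.ndarray,
    allow_clip: bool = False,
) -> bool:
    mask = render.cell_mask
    H, W = occupied.shape
    if not allow_clip:
        if pos[0] < 0 or pos[1] < 0 or pos[0] + mask.shape[0] > H or pos[1] + mask.shape[1] > W:
            return False
    win, pwin = _window(pos, mask.shape, occupied.shape)
    sub = mask[pwin]
    if sub.size == 0 or not sub.any():
        return False
    return not (occupied[win] & sub).any()


def _free_positions(
    occupied: np.ndarray, patch: np.ndarray, adjacent: bool = False
) -> np.ndarray:
    """All top-left positions where the patch fits without overlap.

    Exhaustive search by cross-correlating the occupancy map with the patch;
    with ``adjacent`` only positions touching an existing cell are returned.
    Used as a fallback when rejection sampling stalls at high packing.
    """
    ph, pw = patch.shape
    H, W = occupied.shape
    if ph > H or pw > W:
        return np.empty((0, 2), dtype=int)
    flipped = patch[::-1, ::-1].astype(np.float32)
    overlap = fftconvolve(occupied.astype(np.float32), flipped, mode="valid")
    ok = overlap < 0.5
    if adjacent:
        grown = ndi.binary_dilation(occupied, structure=_CROSS)
        touch = fftconvolve(grown.astype(np.float32), flipped, mode="valid")
        ok &= touch > 0.5
    return np.argwhere(ok)


def _paste(
    render: CellRender,
    pos: tuple[int, int],
    label: int,
    next_nucleus: int,
    cells: np.ndarray,
    nuclei: np.ndarray,
    channels: dict[str, np.ndarray],
    nucleus_to_cell: dict[int, int],
) -> int:
    win, pwin = _window(pos, render.cell_mask.shape, cells.shape)
    sub = render.cell_mask[pwin]
    cells[win][sub] = label
    for nmask in render.nucleus_masks:
        nsub = nmask[pwin]
        if nsub.any():
            nuclei[win][nsub] = next_nucleus
            nucleus_to_cell[next_nucleus] = label
            next_nucleus += 1
    for name in CHANNELS:
        patch = render.channels[name][pwin]
        channels[name][win][sub] = patch[sub]
    return next_nucleus


def render_field(
    fspec: FieldSpec,
    mixture: list[tuple[ShapeSpec, float]],
    rng: np.random.Generator | None = None,
) -> tuple[FieldImage, GroundTruth]:
    """Render a whole field from a weighted mixture of shape specs."""
    fspec.validate()
    weights = np.array([w for _, w in mixture], dtype=float)
    if mixture and abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError(f"mixture weights must sum to 1, got {weights.sum():.4f}")
    if rng is None:
        rng = np.random.default_rng(fspec.rng_seed)
    H, W = fspec.image_shape
    cells = np.zeros((H, W), dtype=np.int32)
    nuclei = np.zeros((H, W), dtype=np.int32)
    channels = {name: np.zeros((H, W), dtype=np.float32) for name in CHANNELS}
    nucleus_to_cell: dict[int, int] = {}
    records: list[dict] = []
    next_nucleus = 1
    occupied = np.zeros((H, W), dtype=bool)
    # occupancy grown by min_gap: keeps chance (non-designed) neighbours apart
    blocked = np.zeros((H, W), dtype=bool)
    gap_struct = (
        ndi.iterate_structure(_CROSS, fspec.min_gap) if fspec.min_gap > 0 else None
    )

    for i in range(fspec.n_cells):
        k = int(rng.choice(len(mixture), p=weights)) if mixture else 0
        if not mixture:
            break
        spec = mixture[k][0]
        n_nuc = 2 if rng.random() < fspec.multinucleate_fraction else 1
        try:
            render = render_cell(spec, rng, n_nuclei=n_nuc)
        except GeometryError:
            if n_nuc == 1:
                raise
            # cell too small for two nuclei; render it mononucleate
            render = render_cell(spec, rng, n_nuclei=1)
        ph, pw = render.cell_mask.shape
        on_border = i < fspec.border_cells
        want_contact = (not on_border) and records and rng.random() < fspec.contact_probability
        placed_pos = None
        for _ in range(fspec.max_tries):
            if on_border:
                # deliberately straddle a randomly chosen image edge
                edge = rng.integers(4)
                if edge == 0:
                    pos = (-ph // 2, int(rng.integers(0, max(1, W - pw))))
                elif edge == 1:
                    pos = (H - ph // 2, int(rng.integers(0, max(1, W - pw))))
                elif edge == 2:
                    pos = (int(rng.integers(0, max(1, H - ph))), -pw // 2)
                else:
                    pos = (int(rng.integers(0, max(1, H - ph))), W - pw // 2)
                if _try_place(render, pos, occupied, allow_clip=True):
                    placed_pos = pos
                    break
            elif want_contact:
                anchor = records[int(rng.integers(len(records)))]
                ar, ac = anchor["centroid_r"], anchor["centroid_c"]
                phi = rng.uniform(0, 2 * np.pi)
                d = np.array([np.sin(phi), np.cos(phi)])
                r_sum = np.sqrt(anchor["area"] / np.pi) + np.sqrt(render.cell_mask.sum() / np.pi)
                base = np.array([ar - ph / 2, ac - pw / 2])
                area_new = float(render.cell_mask.sum())
                found = None
                # slide outward: accept a small overlap (carved below into a
                # shared space-filling boundary) for an extended interface
                for t in np.arange(0.3 * r_sum, 3.5 * r_sum, 1.0):
                    pos = tuple(np.round(base + d * t).astype(int))
                    if (pos[0] < 0 or pos[1] < 0 or pos[0] + ph > H or pos[1] + pw > W):
                        continue
                    win, pwin = _window(pos, render.cell_mask.shape, cells.shape)
                    sub = render.cell_mask[pwin]
                    ovl = occupied[win] & sub
                    n_ovl = int(ovl.sum())
                    if n_ovl == 0 or n_ovl > 0.10 * area_new:
                        continue
                    carved = render.cell_mask.copy()
                    carved[pwin] = sub & ~occupied[win]
                    # carving must not clip a nucleus or disconnect the cell
                    nuc_ok = all(
                        (nm & ~carved).sum() == 0 for nm in render.nucleus_masks
                    )
                    if not nuc_ok or ndi.label(carved, structure=_CROSS)[1] != 1:
                        continue
                    render.cell_mask = carved
                    found = pos
                    break
                if found is not None:
                    placed_pos = found
                    break
            else:
                pos = (
                    int(rng.integers(0, max(1, H - ph))),
                    int(rng.integers(0, max(1, W - pw))),
                )
                if _try_place(render, pos, blocked):
                    placed_pos = pos
                    break
        if placed_pos is None and not on_border:
            # exhaustive fallback: enumerate every admissible position
            cand = _free_positions(
                occupied if want_contact else blocked,
                render.cell_mask,
                adjacent=want_contact,
            )
            if cand.shape[0] == 0 and want_contact:
                cand = _free_positions(blocked, render.cell_mask, adjacent=False)
            if cand.shape[0]:
                placed_pos = tuple(cand[int(rng.integers(cand.shape[0]))])
        if placed_pos is None:
            if fspec.strict:
                raise PlacementError(fspec.n_cells, len(records))
            break
        label = len(records) + 1
        next_nucleus = _paste(
            render, placed_pos, label, next_nucleus, cells, nuclei, channels, nucleus_to_cell
        )
        win, pwin = _window(placed_pos, render.cell_mask.shape, cells.shape)
        sub = cells[win] == label
        occupied[win] |= sub
        if gap_struct is not None:
            gwin, _ = _window(
                (placed_pos[0] - fspec.min_gap, placed_pos[1] - fspec.min_gap),
                (sub.shape[0] + 2 * fspec.min_gap, sub.shape[1] + 2 * fspec.min_gap),
                cells.shape,
            )
            blocked[gwin] |= ndi.binary_dilation(
                occupied[gwin], structure=gap_struct
            )
        else:
            blocked[win] |= sub
        cr, cc = ndi.center_of_mass(sub)
        cr += win[0].start
        cc += win[1].start
        records.append(
            {
                "label": label,
                "shape_class": render.shape_class,
                "yap_ratio": render.yap_ratio,
                "n_nuclei": int(
                    len({n for n, c in nucleus_to_cell.items() if c == label})
                ),
                "touches_border": bool(on_border),
                "area": float(sub.sum()),
                "centroid_r": float(cr),
                "centroid_c": float(cc),
            }
        )

    # designed-contact bookkeeping: fraction of boundary adjacent to another label
    contact_fracs = []
    slices = ndi.find_objects(cells, max_label=len(records))
    for rec in records:
        sl = slices[rec["label"] - 1]
        sl = (
            slice(max(0, sl[0].start - 3), min(H, sl[0].stop + 3)),
            slice(max(0, sl[1].start - 3), min(W, sl[1].stop + 3)),
        )
        win = cells[sl]
        mask = win == rec["label"]
        boundary = mask & ~ndi.binary_erosion(mask, structure=_CROSS)
        others = (win > 0) & ~mask
        adj = ndi.binary_dilation(mask, structure=_CROSS) & others
        near = ndi.binary_dilation(adj, structure=_CROSS, iterations=2) & boundary
        contact_fracs.append(float(near.sum()) / max(float(boundary.sum()), 1.0))
    df = pd.DataFrame(
        records,
        columns=[
            "label",
            "shape_class",
            "yap_ratio",
            "n_nuclei",
            "touches_border",
            "area",
            "centroid_r",
            "centroid_c",
        ],
    )
    df["contact_fraction"] = contact_fracs if records else []

    noiseless = FieldImage({name: channels[name].copy() for name in CHANNELS})
    noisy = FieldImage(
        {name: fspec.noise.apply(channels[name], rng) for name in CHANNELS}
    )
    gt = GroundTruth(
        cells=cells,
        nuclei=nuclei,
        nucleus_to_cell=nucleus_to_cell,
        records=df,
        noiseless=noiseless,
    )
    return noisy, gt
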