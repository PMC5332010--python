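"""Parametric single-cell renderer.

Cells are drawn as smoothed star polygons: a periodic radial profile
r(theta) carrying the class protrusions, anisotropically scaled for
elongation, rotated, and rasterised.  The five reference morphologies are

* ``spindly``      -- elongated, typically two protrusions
* ``large_spread`` -- large area, close to circular
* ``triangular``   -- three distinct protrusions
* ``fan``          -- asymmetric, spread to one side, nucleus at the other
* ``small_round``  -- low area, high roundness

The YAP/TAZ channel is rendered piecewise-constant so that the mean nuclear
intensity over the mean perinuclear-band intensity equals the requested
nucleus:ring ratio exactly before noise; this is what makes the generator
its own oracle for translocation measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon
from skimage.morphology import disk

CHANNELS = ("dna", "tubulin", "actin", "yaptaz")

SHAPE_CLASSES = ("spindly", "large_spread", "triangular", "fan", "small_round")


class GeometryError(ValueError):
    """Degenerate cell geometry (e.g. nucleus does not fit in the cell)."""


@dataclass
class ShapeSpec:
    """Parameters of one reference morphology."""

    shape_class: str
    cell_area_range: tuple[float, float]
    protrusion_count: int = 0
    protrusion_amp: float = 0.0
    elongation: float = 1.0
    nucleus_area_fraction: float = 0.2
    nucleus_offset: float = 0.0
    yaptaz_nuc_ring_ratio: float = 1.0
    #: cell-to-cell biological spread of the ratio (sd of log10 ratio);
    #: the sampled per-cell ratio is recorded in the ground truth
    ratio_log10_sd: float = 0.10
    irregularity: float = 0.05
    channel_levels: dict[str, float] = field(
        default_factory=lambda: {
            "dna": 200.0,
            "tubulin": 120.0,
            "actin": 110.0,
            "yaptaz": 100.0,
        }
    )
    texture_amplitude: dict[str, float] = field(
        default_factory=lambda: {
            "dna": 0.10,
            "tubulin": 0.15,
            "actin": 0.15,
            "yaptaz": 0.0,
        }
    )

    def validate(self) -> None:
        lo, hi = self.cell_area_range
        if not (0 < lo <= hi):
            raise GeometryError(f"cell_area_range must be positive, got {self.cell_area_range}")
        if self.elongation < 1:
            raise GeometryError(f"elongation must be >= 1, got {self.elongation}")
        if not 0 < self.nucleus_area_fraction < 1:
            raise GeometryError(
                f"nucleus_area_fraction must be in (0, 1), got {self.nucleus_area_fraction}"
            )
        if self.yaptaz_nuc_ring_ratio <= 0:
            raise GeometryError(
                f"yaptaz_nuc_ring_ratio must be > 0, got {self.yaptaz_nuc_ring_ratio}"
            )
        if self.shape_class not in SHAPE_CLASSES:
            raise GeometryError(f"unknown shape class {self.shape_class!r}")


def reference_shapes() -> dict[str, ShapeSpec]:
    """The five reference morphologies with class-typical geometry.

    Parameter bands are chosen so the classes are visually distinctive and
    linearly separable in the extracted feature space (asserted by test).
    """
    return {
        "spindly": ShapeSpec(
            "spindly",
            cell_area_range=(900.0, 1500.0),
            protrusion_count=2,
            protrusion_amp=0.45,
            elongation=4.0,
            nucleus_area_fraction=0.24,
        ),
        "large_spread": ShapeSpec(
            "large_spread",
            cell_area_range=(4200.0, 6500.0),
            protrusion_count=0,
            elongation=1.15,
            nucleus_area_fraction=0.12,
            irregularity=0.06,
        ),
        "triangular": ShapeSpec(
            "triangular",
            cell_area_range=(1600.0, 2600.0),
            protrusion_count=3,
            protrusion_amp=0.65,
            elongation=1.1,
            nucleus_area_fraction=0.18,
        ),
        "fan": ShapeSpec(
            "fan",
            cell_area_range=(1800.0, 3000.0),
            protrusion_count=0,
            elongation=1.2,
            nucleus_area_fraction=0.16,
            nucleus_offset=0.45,
        ),
        "small_round": ShapeSpec(
            "small_round",
            cell_area_range=(320.0, 620.0),
            protrusion_count=0,
            elongation=1.05,
            nucleus_area_fraction=0.32,
            irregularity=0.03,
        ),
    }


@dataclass
class CellRender:
    """One rendered cell on its own patch, plus its ground truth."""

    cell_mask: np.ndarray  # bool
    nucleus_masks: list[np.ndarray]  # bool, disjoint, inside cell
    channels: dict[str, np.ndarray]  # float32 patches, background 0
    shape_class: str
    yap_ratio: float

    @property
    def nucleus_mask(self) -> np.ndarray:
        m = np.zeros_like(self.cell_mask)
        for n in self.nucleus_masks:
            m |= n
        return m


def _radial_profile(spec: ShapeSpec, rng: np.random.Generator, m: int = 128) -> np.ndarray:
    theta = np.linspace(0, 2 * np.pi, m, endpoint=False)
    if spec.shape_class == "fan":
        # spread half-disc: wide on one side, flat on the other
        r = 0.5 + 0.75 * np.clip(np.cos(theta), 0, None) ** 0.8
    elif spec.protrusion_count > 0:
        # spindle-like cells carry their two protrusions on the long axis;
        # other protrusion patterns are free to rotate
        phase = 0.0 if spec.elongation > 1.5 else rng.uniform(0, 2 * np.pi)
        r = 1.0 + spec.protrusion_amp * np.cos(spec.protrusion_count * theta + phase)
    else:
        r = np.ones(m)
    if spec.irregularity > 0:
        noise = rng.standard_normal(m)
        noise = ndi.gaussian_filter1d(noise, m / 32, mode="wrap")
        noise /= max(noise.std(), 1e-9)
        r = r * (1.0 + spec.irregularity * noise)
    return np.clip(r, 0.2, None)


def _ellipse_mask(shape, center, a, b, angle) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    # axis a along the (cos, sin) direction in (col, row) order
    u = dc * ca + dr * sa
    v = -dc * sa + dr * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _place_nuclei(
    spec: ShapeSpec,
    cell: np.ndarray,
    angle: float,
    n_nuclei: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    area = float(cell.sum())
    interior = ndi.binary_erosion(cell, structure=disk(2))
    if not interior.any():
        raise GeometryError("cell too small to contain a nucleus")
    cr, cc = ndi.center_of_mass(cell)
    r_eff = np.sqrt(area / np.pi)
    nuc_area_total = spec.nucleus_area_fraction * area
    per_nucleus = nuc_area_total / n_nuclei
    aspect = min(spec.elongation, 2.0)
    direction = np.array([np.sin(angle), np.cos(angle)])  # row, col unit vector
    if spec.shape_class == "fan":
        # nucleus to the flat side (opposite the spread lobe)
        offset_dir = -direction
    else:
        offset_dir = direction
    masks: list[np.ndarray] = []
    spine_points = None
    if n_nuclei > 1:
        # multiple nuclei sit spread along the cell's interior spine, as far
        # apart as the geometry allows
        b0 = np.sqrt(per_nucleus / (np.pi * aspect))
        safe = ndi.binary_erosion(cell, structure=disk(max(2, int(b0) + 1)))
        if not safe.any():
            safe = interior
        coords = np.argwhere(safe)
        proj = coords @ direction
        order = np.argsort(proj)
        coords, proj = coords[order], proj[order]
        spine_points = []
        for i in range(n_nuclei):
            q = 0.05 + 0.90 * i / max(n_nuclei - 1, 1)
            target = np.quantile(proj, q)
            j = int(np.searchsorted(proj, target))
            j = min(j, len(proj) - 1)
            # among points near this axial position, take the most interior
            near = np.abs(proj - proj[j]) <= 1.5
            cand = coords[near]
            dists = ndi.distance_transform_edt(cell)[cand[:, 0], cand[:, 1]]
            spine_points.append(cand[int(np.argmax(dists))].astype(float))
    for i in range(n_nuclei):
        b = np.sqrt(per_nucleus / (np.pi * aspect))
        a = aspect * b
        if n_nuclei == 1:
            off = spec.nucleus_offset * r_eff
            center0 = np.array([cr, cc]) + off * offset_dir
        else:
            center0 = spine_points[i]
        placed = None
        # pulling toward the centroid would collapse multi-nucleus spacing
        pulls = (1.0, 0.6, 0.3, 0.0) if n_nuclei == 1 else (1.0,)
        for shrink in (1.0, 0.85, 0.7, 0.55, 0.4):
            for pull in pulls:
                center = np.array([cr, cc]) + (center0 - np.array([cr, cc])) * pull
                m = _ellipse_mask(cell.shape, center, a * shrink, b * shrink, angle)
                m &= interior
                for prev in masks:
                    m &= ~ndi.binary_dilation(prev, structure=disk(1))
                if m.sum() >= 0.5 * per_nucleus * shrink**2 and m.sum() >= 9:
                    if ndi.label(m)[1] == 1:
                        placed = m
                        break
            if placed is not None:
                break
        if placed is None:
            raise GeometryError(
                f"could not place nucleus {i + 1}/{n_nuclei} inside "
                f"{spec.shape_class} cell of area {area:.0f}"
            )
        masks.append(placed)
    return masks


def _texture(shape, amp: float, rng: np.random.Generator) -> np.ndarray:
    if amp <= 0:
        return np.ones(shape, dtype=np.float32)
    t = rng.standard_normal(shape)
    t = ndi.gaussian_filter(t, 1.5)
    t /= max(t.std(), 1e-9)
    return np.clip(1.0 + amp * t, 0.1, None).astype(np.float32)


def render_cell(
    spec: ShapeSpec,
    rng: np.random.Generator,
    n_nuclei: int = 1,
    margin: int = 6,
) -> CellRender:
    """Render one cell on its own patch.

    Returns masks and noiseless per-channel intensity patches.  The YAP/TAZ
    channel is constant over the cytoplasm and constant over the nucleus, so
    mean(nucleus)/mean(any cytoplasmic band) equals the spec ratio exactly.
    """
    spec.validate()
    if n_nuclei < 1:
        raise GeometryError("n_nuclei must be >= 1")
    ratio = spec.yaptaz_nuc_ring_ratio
    if spec.ratio_log10_sd > 0:
        ratio = float(ratio * 10 ** rng.normal(0.0, spec.ratio_log10_sd))
    # multinucleate cells (failed cytokinesis) carry roughly the combined
    # cytoplasm of their nuclei
    area = float(rng.uniform(*spec.cell_area_range)) * (1 + 0.6 * (n_nuclei - 1))
    prof = _radial_profile(spec, rng)
    m = prof.size
    theta = np.linspace(0, 2 * np.pi, m, endpoint=False)
    x = prof * np.cos(theta) * np.sqrt(spec.elongation)
    y = prof * np.sin(theta) / np.sqrt(spec.elongation)
    angle = rng.uniform(0, np.pi)
    ca, sa = np.cos(angle), np.sin(angle)
    xr = x * ca - y * sa
    yr = x * sa + y * ca
    # scale to the target area (shoelace area of the polygon)
    poly_area = 0.5 * abs(np.dot(xr, np.roll(yr, -1)) - np.dot(yr, np.roll(xr, -1)))
    s = np.sqrt(area / poly_area)
    xr *= s
    yr *= s
    half_w = int(np.ceil(max(abs(xr).max(), 1))) + margin
    half_h = int(np.ceil(max(abs(yr).max(), 1))) + margin
    shape = (2 * half_h + 1, 2 * half_w + 1)
    rr, cc = draw_polygon(yr + half_h, xr + half_w, shape)
    cell = np.zeros(shape, dtype=bool)
    cell[rr, cc] = True
    cell = ndi.binary_fill_holes(cell)
    if cell.sum() < 25:
        raise GeometryError("degenerate cell mask")
    nuclei = _place_nuclei(spec, cell, angle, n_nuclei, rng)
    nucleus = np.zeros(shape, dtype=bool)
    for nmask in nuclei:
        nucleus |= nmask
    cyto = cell & ~nucleus

    lv = spec.channel_levels
    amp = spec.texture_amplitude
    chans: dict[str, np.ndarray] = {}
    chans["dna"] = (nucleus * lv["dna"] * _texture(shape, amp.get("dna", 0), rng)).astype(
        np.float32
    )
    # microtubule density falls off toward the cell periphery (MTOC-centred),
    # giving seeded watershed a genuine intensity valley at cell contacts
    dist = ndi.distance_transform_edt(cell)
    radial = 0.75 + 0.5 * dist / max(dist.max(), 1.0)
    chans["tubulin"] = (
        cell * lv["tubulin"] * radial * _texture(shape, amp.get("tubulin", 0), rng)
    ).astype(np.float32)
    edge_band = cell & ~ndi.binary_erosion(cell, structure=disk(2))
    actin = cell * lv["actin"] * (1.0 + 0.5 * edge_band)
    chans["actin"] = (actin * _texture(shape, amp.get("actin", 0), rng)).astype(np.float32)
    yap = np.zeros(shape, dtype=np.float32)
    yap[cyto] = lv["yaptaz"]
    yap[nucleus] = lv["yaptaz"] * ratio
    yap_tex = _texture(shape, amp.get("yaptaz", 0), rng)
    chans["yaptaz"] = yap * yap_tex
    return CellRender(
        cell_mask=cell,
        nucleus_masks=nuclei,
        channels=chans,
        shape_class=spec.shape_class,
        yap_ratio=ratio,
    )


def with_ratio(spec: ShapeSpec, ratio: float) -> ShapeSpec:
    """Copy of ``spec`` with a different designed nucleus:ring ratio."""
    return replace(spec, yaptaz_nuc_ring_ratio=ratio)
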