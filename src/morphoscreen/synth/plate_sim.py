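"""Whole-plate simulation.

Maps well roles to rendered phenotypes:

* mock / sample wells draw from the baseline shape mixture;
* siLATS1-like wells raise the YAP/TAZ nuclear:ring ratio;
* siYAP-like wells reduce total YAP/TAZ intensity;
* siECT2-like wells raise the multinucleate and large-spread fractions;
* density-dilution wells (columns 1, 2, 23, 24) scale the number of cells
  per field with the plated cell count.

Per-well seeds are derived deterministically from the plate seed and the
well position, so two plates simulated with the same seed are bit-identical
and replicate plates (different seeds, same effects) share only biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from ..plate import (
    ROLE_DILUTION,
    ROLE_ECT2,
    ROLE_LATS1,
    ROLE_YAP,
    PlateLayout,
    parse_well_id,
)
from .field import FieldSpec, GroundTruth, NoiseModel, render_field
from .shapes import ShapeSpec, reference_shapes

#: Baseline (mock-like) shape mixture.
BASELINE_MIXTURE = {
    "spindly": 0.20,
    "large_spread": 0.10,
    "triangular": 0.20,
    "fan": 0.20,
    "small_round": 0.30,
}


@dataclass
class WellEffect:
    """Designed phenotype shift for one well."""

    log_ratio_shift: float = 0.0  # added to log10 nucleus:ring ratio
    total_yap_scale: float = 1.0  # multiplies the YAP/TAZ stain level
    multinucleate_fraction: float | None = None
    mixture: dict[str, float] | None = None  # overrides the baseline mixture


#: Documented default phenotypes for the positive-control roles.
ROLE_EFFECTS = {
    ROLE_LATS1: WellEffect(log_ratio_shift=0.3),
    ROLE_YAP: WellEffect(total_yap_scale=0.4),
    ROLE_ECT2: WellEffect(
        multinucleate_fraction=0.5,
        mixture={
            "spindly": 0.10,
            "large_spread": 0.45,
            "triangular": 0.10,
            "fan": 0.10,
            "small_round": 0.25,
        },
    ),
}


@dataclass
class PlateSimSpec:
    layout: PlateLayout
    image_shape: tuple[int, int] = (512, 512)
    n_cells: int = 40
    contact_probability: float = 0.1
    multinucleate_fraction: float = 0.04
    noise: NoiseModel = field(default_factory=NoiseModel)
    effects: dict[str, WellEffect] = field(default_factory=dict)
    apply_role_effects: bool = True
    #: cells rendered per field = cells_plated * this factor (dilution wells)
    cells_per_plated: float = 0.02
    #: densest permitted packing; requested cell counts are capped so the
    #: expected foreground fill stays placeable
    max_fill: float = 0.40
    rng_seed: int = 0
    shapes: dict[str, ShapeSpec] = field(default_factory=reference_shapes)
    baseline_mixture: dict[str, float] = field(
        default_factory=lambda: dict(BASELINE_MIXTURE)
    )

    def validate(self) -> None:
        for w in self.effects:
            if w not in self.layout.wells:
                raise ValueError(f"effect assigned to unknown well {w!r}")

    def effect_for(self, well: str) -> WellEffect:
        if well in self.effects:
            return self.effects[well]
        role = self.layout[well].role
        if self.apply_role_effects and role in ROLE_EFFECTS:
            return ROLE_EFFECTS[role]
        return WellEffect()


def well_seed(base_seed: int, well: str) -> int:
    row, col = parse_well_id(well)
    idx = (ord(row) - ord("A")) * 24 + (col - 1)
    return int(np.random.SeedSequence([base_seed, idx]).generate_state(1)[0] % (2**31))


def _apply_effect(
    spec: PlateSimSpec, eff: WellEffect
) -> tuple[list[tuple[ShapeSpec, float]], float]:
    mixture_w = eff.mixture if eff.mixture is not None else spec.baseline_mixture
    total = sum(mixture_w.values())
    mix: list[tuple[ShapeSpec, float]] = []
    for name, w in mixture_w.items():
        s = spec.shapes[name]
        ratio = s.yaptaz_nuc_ring_ratio * 10**eff.log_ratio_shift
        levels = dict(s.channel_levels)
        levels["yaptaz"] = levels["yaptaz"] * eff.total_yap_scale
        mix.append((replace(s, yaptaz_nuc_ring_ratio=ratio, channel_levels=levels), w / total))
    multinuc = (
        eff.multinucleate_fraction
        if eff.multinucleate_fraction is not None
        else spec.multinucleate_fraction
    )
    return mix, multinuc


def simulate_well(
    spec: PlateSimSpec, well: str
) -> tuple["FieldSpec", GroundTruth, pd.Series]:
    """Simulate a single well; returns (image, ground truth, bookkeeping)."""
    rec = spec.layout[well]
    eff = spec.effect_for(well)
    mix, multinuc = _apply_effect(spec, eff)
    n_cells = spec.n_cells
    if rec.role == ROLE_DILUTION and rec.cells_plated:
        n_cells = max(2, int(round(rec.cells_plated * spec.cells_per_plated)))
    mean_area = sum(
        w * (s.cell_area_range[0] + s.cell_area_range[1]) / 2 for s, w in mix
    )
    cap = int(spec.max_fill * spec.image_shape[0] * spec.image_shape[1] / mean_area)
    n_cells = min(n_cells, max(2, cap))
    fspec = FieldSpec(
        image_shape=spec.image_shape,
        n_cells=n_cells,
        contact_probability=spec.contact_probability,
        multinucleate_fraction=multinuc,
        noise=spec.noise,
        rng_seed=well_seed(spec.rng_seed, well),
        strict=False,
    )
    img, gt = render_field(fspec, mix)
    truth = pd.Series(
        {
            "well": well,
            "role": rec.role,
            "gene": rec.gene,
            "cells_plated": rec.cells_plated,
            "n_cells": gt.n_cells,
            "true_mean_log_ratio": float(np.log10(gt.records["yap_ratio"]).mean())
            if gt.n_cells
            else np.nan,
            "true_multinucleate_frac": float((gt.records["n_nuclei"] >= 2).mean())
            if gt.n_cells
            else np.nan,
            "total_yap_scale": eff.total_yap_scale,
        }
    )
    return img, gt, truth


def simulate_plate(
    spec: PlateSimSpec, wells: list[str] | None = None
) -> Iterator[tuple[str, "FieldSpec", GroundTruth, pd.Series]]:
    """Yield (well, image, ground truth, bookkeeping) for each well."""
    spec.validate()
    for well in wells if wells is not None else list(spec.layout.wells):
        img, gt, truth = simulate_well(spec, well)
        yield well, img, gt, truth
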