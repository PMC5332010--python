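"""Generator correctness: cell geometry, field assembly, plate phenotypes."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi
from scipy.stats import binom, chisquare, kruskal
from skimage.measure import regionprops

from morphoscreen.plate import default_layout
from morphoscreen.regions import build_ring
from morphoscreen.synth import (
    FieldSpec,
    GeometryError,
    PlateSimSpec,
    ShapeSpec,
    WellEffect,
    reference_shapes,
    render_cell,
    render_field,
    simulate_well,
)
from morphoscreen.synth.field import PlacementError

CROSS = ndi.generate_binary_structure(2, 1)


def exact_spec(spec: ShapeSpec, ratio: float = 1.0) -> ShapeSpec:
    """Spec with the biological ratio spread disabled (exact designed ratio)."""
    return dataclasses.replace(spec, yaptaz_nuc_ring_ratio=ratio, ratio_log10_sd=0.0)


class TestRenderCell:
    def test_ratio_exact_on_noiseless_render(self, shapes):
        """Measured nucleus:ring ratio equals the designed ratio on the
        noiseless render, using ground-truth masks and the ring builder."""
        rng = np.random.default_rng(1)
        spec = exact_spec(shapes["small_round"], ratio=1.0)
        r = render_cell(spec, rng)
        ring = build_ring(r.cell_mask, r.nucleus_mask)
        yap = r.channels["yaptaz"]
        measured = yap[r.nucleus_mask].mean() / yap[ring].mean()
        assert measured == pytest.approx(1.0, rel=0.01)

    def test_spindly_elongation(self, shapes):
        rng = np.random.default_rng(2)
        for _ in range(5):
            r = render_cell(shapes["spindly"], rng)
            p = regionprops(r.cell_mask.astype(int))[0]
            assert p.axis_major_length / p.axis_minor_length >= 3.0

    def test_degenerate_nucleus_fraction_rejected(self, shapes):
        spec = dataclasses.replace(shapes["small_round"], nucleus_area_fraction=0.0)
        with pytest.raises(GeometryError):
            render_cell(spec, np.random.default_rng(0))

    @pytest.mark.parametrize("cls", list(reference_shapes()))
    def test_nucleus_strictly_inside_cell(self, shapes, cls):
        rng = np.random.default_rng(3)
        r = render_cell(shapes[cls], rng)
        interior = ndi.binary_erosion(r.cell_mask, structure=CROSS)
        assert (r.nucleus_mask & ~interior).sum() == 0

    def test_two_nuclei_disjoint(self, shapes):
        rng = np.random.default_rng(4)
        r = render_cell(shapes["large_spread"], rng, n_nuclei=2)
        assert len(r.nucleus_masks) == 2
        assert not (r.nucleus_masks[0] & r.nucleus_masks[1]).any()

    def test_invalid_specs_rejected(self, shapes):
        base = shapes["fan"]
        for bad in (
            dict(elongation=0.5),
            dict(yaptaz_nuc_ring_ratio=-1.0),
            dict(cell_area_range=(-10.0, 100.0)),
        ):
            with pytest.raises(GeometryError):
                dataclasses.replace(base, **bad).validate()


class TestRenderField:
    def test_empty_field(self, shapes):
        img, gt = render_field(
            FieldSpec(image_shape=(128, 128), n_cells=0, rng_seed=0),
            [(shapes["small_round"], 1.0)],
        )
        assert gt.n_cells == 0
        assert gt.cells.max() == 0
        # pure-noise image: positive background, no structure
        assert img["dna"].std() > 0

    def test_determinism(self, shapes):
        mix = [(shapes["spindly"], 0.5), (shapes["small_round"], 0.5)]
        fspec = FieldSpec(image_shape=(384, 384), n_cells=12, rng_seed=7)
        img1, gt1 = render_field(fspec, mix)
        img2, gt2 = render_field(fspec, mix)
        for ch in img1.channels:
            np.testing.assert_array_equal(img1[ch], img2[ch])
        np.testing.assert_array_equal(gt1.cells, gt2.cells)
        pd.testing.assert_frame_equal(gt1.records, gt2.records)

    def test_mixture_proportions_within_binomial_ci(self, shapes):
        mix = [(shapes["spindly"], 0.5), (shapes["small_round"], 0.5)]
        n = 200
        img, gt = render_field(
            FieldSpec(image_shape=(1400, 1400), n_cells=n, rng_seed=8), mix
        )
        k = int((gt.records["shape_class"] == "spindly").sum())
        lo, hi = binom.ppf([0.005, 0.995], n, 0.5)
        assert lo <= k <= hi

    def test_forced_contact_shares_boundary(self, shapes):
        mix = [(shapes["small_round"], 1.0)]
        img, gt = render_field(
            FieldSpec(image_shape=(256, 256), n_cells=2, rng_seed=9,
                      contact_probability=1.0),
            mix,
        )
        m1, m2 = gt.cells == 1, gt.cells == 2
        assert (ndi.binary_dilation(m1, structure=CROSS) & m2).any()
        assert not (m1 & m2).any()

    def test_weights_must_sum_to_one(self, shapes):
        with pytest.raises(ValueError, match="sum to 1"):
            render_field(
                FieldSpec(image_shape=(128, 128), n_cells=1),
                [(shapes["small_round"], 0.7)],
            )

    def test_placement_error_names_achieved_count(self, shapes):
        fspec = FieldSpec(image_shape=(96, 96), n_cells=50, rng_seed=1)
        with pytest.raises(PlacementError, match=r"placed \d+ of 50"):
            render_field(fspec, [(shapes["large_spread"], 1.0)])

    def test_border_cells_touch_border(self, shapes):
        img, gt = render_field(
            FieldSpec(image_shape=(512, 512), n_cells=10, rng_seed=10,
                      border_cells=3),
            [(shapes["small_round"], 1.0)],
        )
        assert gt.records["touches_border"].sum() == 3
        edge = np.zeros_like(gt.cells, dtype=bool)
        edge[0] = edge[-1] = True
        edge[:, 0] = edge[:, -1] = True
        border_labels = set(np.unique(gt.cells[edge])) - {0}
        flagged = set(gt.records.loc[gt.records["touches_border"], "label"])
        assert border_labels == flagged

    def test_mixture_chi_square_convergence(self, shapes):
        """Class proportions converge to the mixture weights (n=2,000)."""
        weights = {"spindly": 0.3, "triangular": 0.2, "small_round": 0.5}
        mix = [(shapes[c], w) for c, w in weights.items()]
        counts = {c: 0 for c in weights}
        n_total = 0
        seed = 0
        while n_total < 2000:
            img, gt = render_field(
                FieldSpec(image_shape=(1200, 1200), n_cells=250, rng_seed=seed),
                mix,
            )
            for c, k in gt.records["shape_class"].value_counts().items():
                counts[c] += int(k)
            n_total += gt.n_cells
            seed += 1
        obs = np.array([counts[c] for c in weights])
        exp = np.array([weights[c] * n_total for c in weights])
        assert chisquare(obs, exp).pvalue > 0.001

    def test_ground_truth_ratio_recomputable(self, shapes):
        """Generator/oracle closure: recorded ratios re-measure exactly on
        the noiseless render."""
        mix = [(shapes["fan"], 0.5), (shapes["triangular"], 0.5)]
        img, gt = render_field(
            FieldSpec(image_shape=(640, 640), n_cells=10, rng_seed=12), mix
        )
        yap = gt.noiseless["yaptaz"]
        for _, rec in gt.records.iterrows():
            cell = gt.cells == rec["label"]
            nucs = [
                n for n, c in gt.nucleus_to_cell.items() if c == rec["label"]
            ]
            nuc = np.isin(gt.nuclei, nucs)
            ring = build_ring(cell, nuc)
            measured = yap[nuc].mean() / yap[ring].mean()
            assert measured == pytest.approx(rec["yap_ratio"], rel=0.01)


@pytest.fixture(scope="module")
def small_layout():
    full = default_layout()
    return full.subset(["C12", "D12", "E12", "F12", "B23", "J23", "A1"])


class TestSimulatePlate:
    def test_lats1_like_shift(self, small_layout):
        spec = PlateSimSpec(
            layout=small_layout, image_shape=(768, 768), n_cells=100, rng_seed=5
        )
        _, gt_mock, truth_mock = simulate_well(spec, "C12")
        _, gt_lats, truth_lats = simulate_well(spec, "B23")
        shift = truth_lats["true_mean_log_ratio"] - truth_mock["true_mean_log_ratio"]
        # designed +0.3 on log10 ratio; sd 0.1/sqrt(100) per well
        assert shift == pytest.approx(0.3, abs=0.06)

    def test_ect2_like_multinucleation(self, small_layout):
        spec = PlateSimSpec(
            layout=small_layout, image_shape=(900, 900), n_cells=100, rng_seed=6
        )
        _, gt, truth = simulate_well(spec, "J23")
        frac = (gt.records["n_nuclei"] >= 2).mean()
        assert frac >= 0.40  # designed 0.5, binomial n~100

    def test_yap_like_dims_channel(self, small_layout):
        spec = PlateSimSpec(layout=small_layout, image_shape=(512, 512),
                            n_cells=30, rng_seed=7)
        layout2 = small_layout.subset(["C12"])
        _, gt_mock, _ = simulate_well(spec, "C12")
        spec_yap = PlateSimSpec(
            layout=default_layout().subset(["F23"]), image_shape=(512, 512),
            n_cells=30, rng_seed=7,
        )
        _, gt_yap, truth = simulate_well(spec_yap, "F23")
        mock_yap = gt_mock.noiseless["yaptaz"][gt_mock.cells > 0].mean()
        dim_yap = gt_yap.noiseless["yaptaz"][gt_yap.cells > 0].mean()
        assert dim_yap < 0.6 * mock_yap

    def test_null_plate_exchangeable(self):
        """Without effects, per-cell areas are exchangeable across mock
        wells (Kruskal-Wallis sanity check at alpha=0.01)."""
        layout = default_layout().subset(["C12", "D12", "E12", "F12", "G12"])
        spec = PlateSimSpec(
            layout=layout, image_shape=(640, 640), n_cells=40,
            apply_role_effects=False, rng_seed=8,
        )
        groups = []
        for well in layout.wells:
            _, gt, _ = simulate_well(spec, well)
            groups.append(gt.records["area"].to_numpy())
        assert kruskal(*groups).pvalue > 0.01

    def test_effect_on_unknown_well_rejected(self, small_layout):
        spec = PlateSimSpec(
            layout=small_layout, effects={"Z99": WellEffect()}, rng_seed=0
        )
        with pytest.raises(ValueError, match="unknown well"):
            spec.validate()

    def test_dilution_well_scales_cells(self, small_layout):
        spec = PlateSimSpec(
            layout=small_layout, image_shape=(1024, 1024), n_cells=10,
            cells_per_plated=0.02, rng_seed=9,
        )
        _, gt, truth = simulate_well(spec, "A1")  # 250 plated -> 5 cells
        assert gt.n_cells == 5
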