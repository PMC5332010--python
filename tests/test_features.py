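"""Feature extraction: registry accounting, morphology, intensities,
ratios, SER / Haralick / Gabor textures, neighbour fraction, aggregation."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from morphoscreen.features import (
    AUX_COLUMNS,
    N_CELL_FEATURES,
    N_WELL_FEATURES,
    REGISTRY,
    REGISTRY_NAMES,
    SHAPE_CLASSES,
    WELL_FEATURE_NAMES,
    aggregate_well,
    extract_all,
    gabor_features,
    haralick_features,
    neighbour_fraction,
    ratio_features,
    ser_features,
)
from morphoscreen.features.morphology import morphology_of_mask
from morphoscreen.features.texture import ser_response_maps
from morphoscreen.imageio import FieldImage
from morphoscreen.regions import build_region_set
from morphoscreen.synth import FieldSpec, render_cell, render_field
from tests.conftest import disc_mask

# ------------------------------------------------------------------ oracle


def brute_force_glcm_features(
    img: np.ndarray, mask: np.ndarray, levels: int = 64, distance: int = 1
) -> dict[str, float]:
    """Independent pure-Python GLCM: explicit pixel-pair enumeration."""
    vals = img[mask]
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax <= vmin:
        return {"correlation": np.nan, "contrast": 0.0, "variance": 0.0,
                "homogeneity": 1.0}
    q = {}
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            if mask[r, c]:
                q[(r, c)] = min(
                    int((img[r, c] - vmin) / (vmax - vmin) * levels), levels - 1
                )
    P = np.zeros((levels, levels))
    for (r, c), i in q.items():
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
            rr, cc = r + dr * distance, c + dc * distance
            if (rr, cc) in q:
                j = q[(rr, cc)]
                P[i, j] += 1
                P[j, i] += 1
    if P.sum() == 0:
        return {"correlation": np.nan, "contrast": 0.0, "variance": 0.0,
                "homogeneity": 1.0}
    P /= P.sum()
    idx = np.arange(levels)
    mu = sum(i * P[i, j] for i in idx for j in idx if P[i, j])
    var = sum((i - mu) ** 2 * P[i, j] for i in idx for j in idx if P[i, j])
    contrast = sum((i - j) ** 2 * P[i, j] for i in idx for j in idx if P[i, j])
    homog = sum(P[i, j] / (1 + (i - j) ** 2) for i in idx for j in idx if P[i, j])
    corr = (
        sum((i - mu) * (j - mu) * P[i, j] for i in idx for j in idx if P[i, j]) / var
        if var > 0
        else np.nan
    )
    return {"correlation": corr, "contrast": contrast, "variance": var,
            "homogeneity": homog}


class TestRegistry:
    def test_cardinality(self):
        assert N_CELL_FEATURES == 126
        assert len(REGISTRY_NAMES) == 126
        assert N_WELL_FEATURES == 127
        assert len(WELL_FEATURE_NAMES) == 127
        assert len(SHAPE_CLASSES) == 5

    def test_names_unique(self):
        assert len(set(REGISTRY_NAMES)) == 126

    def test_group_accounting(self):
        groups = pd.Series([d.group for d in REGISTRY]).value_counts().to_dict()
        assert groups == {
            "morphology": 16,
            "intensity": 7,
            "ratio": 8,
            "ser": 80,
            "haralick": 12,
            "gabor": 3,
        }


class TestMorphology:
    def test_disc_roundness_and_aspect(self, disc50):
        m = morphology_of_mask(disc50)
        assert m["roundness"] == pytest.approx(1.0, abs=0.05)
        assert m["width_to_length"] == pytest.approx(1.0, abs=0.02)
        assert m["area"] == disc50.sum()

    def test_rectangle_aspect(self):
        mask = np.zeros((40, 120), dtype=bool)
        mask[10:30, 10:110] = True  # 100 x 20
        m = morphology_of_mask(mask)
        assert m["width_to_length"] == pytest.approx(0.20, abs=0.02)
        # moment-ellipse convention: a uniform rectangle of side L has
        # major axis 2L/sqrt(3) ~ 1.155 L
        assert m["length"] == pytest.approx(100 * 2 / np.sqrt(3), rel=0.01)

    def test_cytoplasm_is_cell_minus_nucleus(self):
        cell = disc_mask(40)
        nucleus = disc_mask(15, pad=31)
        rs = build_region_set(1, cell, nucleus & cell)
        assert rs.cytoplasm.sum() == cell.sum() - (nucleus & cell).sum()

    def test_empty_mask_missing(self):
        m = morphology_of_mask(np.zeros((5, 5), dtype=bool))
        assert all(np.isnan(v) for v in m.values())


def two_level_cell():
    """Disc cell with nucleus at 200, cytoplasm at 100 on every channel."""
    cell = disc_mask(40)
    nucleus = disc_mask(15, pad=31)
    img = np.where(nucleus, 200.0, np.where(cell, 100.0, 0.0))
    return cell, nucleus & cell, img


class TestIntensityAndRatios:
    def test_constant_image_means(self):
        cell = disc_mask(30)
        nucleus = disc_mask(10, pad=26)
        rs = build_region_set(1, cell, nucleus & cell)
        from morphoscreen.features import intensity_features

        chans = {c: np.full(cell.shape, 7.0) for c in ("dna", "tubulin", "actin", "yaptaz")}
        intens = intensity_features(chans, rs)
        for k, v in intens.items():
            assert v == pytest.approx(7.0)

    def test_two_level_fixture(self):
        cell, nucleus, img = two_level_cell()
        rs = build_region_set(1, cell, nucleus)
        from morphoscreen.features import intensity_features

        chans = {c: img for c in ("dna", "tubulin", "actin", "yaptaz")}
        intens = intensity_features(chans, rs)
        assert intens["yap_nucleus_mean"] == pytest.approx(200.0)
        assert intens["yap_ring_mean"] == pytest.approx(100.0)

    def test_ratio_arithmetic(self):
        intens = {
            "yap_nucleus_mean": 300.0,
            "yap_eroded_nucleus_mean": 300.0,
            "yap_ring_mean": 100.0,
            "yap_cell_mean": 150.0,
            "yap_cytoplasm_mean": 100.0,
            "dna_nucleus_mean": 50.0,
            "tubulin_cytoplasm_mean": 10.0,
            "tubulin_cell_mean": 10.0,
        }
        morph = {"nucleus_area": 200.0, "cell_area": 1000.0}
        r = ratio_features(intens, morph)
        assert r["yap_ratio_nuc_ring"] == pytest.approx(3.0)
        assert r["yap_ratio_nuc_ring_log10"] == pytest.approx(0.4771, abs=1e-4)
        assert r["dna_nucleus_per_area"] == pytest.approx(0.25)
        assert r["cell_area_per_yap_cell"] == pytest.approx(1000 / 150)
        assert r["total_yaptaz"] == pytest.approx(400 / 200)

    def test_uniform_ratio_log_zero_exact(self):
        intens = {
            "yap_nucleus_mean": 100.0,
            "yap_eroded_nucleus_mean": 100.0,
            "yap_ring_mean": 100.0,
            "yap_cell_mean": 100.0,
            "yap_cytoplasm_mean": 100.0,
            "dna_nucleus_mean": 1.0,
            "tubulin_cytoplasm_mean": 1.0,
            "tubulin_cell_mean": 1.0,
        }
        r = ratio_features(intens, {"nucleus_area": 10.0, "cell_area": 20.0})
        assert r["yap_ratio_nuc_ring"] == 1.0
        assert r["yap_ratio_nuc_ring_log10"] == 0.0

    def test_zero_ring_missing_not_inf(self):
        intens = {
            "yap_nucleus_mean": 100.0,
            "yap_eroded_nucleus_mean": 100.0,
            "yap_ring_mean": 0.0,
            "yap_cell_mean": 100.0,
            "yap_cytoplasm_mean": 100.0,
            "dna_nucleus_mean": 1.0,
            "tubulin_cytoplasm_mean": 1.0,
            "tubulin_cell_mean": 1.0,
        }
        r = ratio_features(intens, {"nucleus_area": 10.0, "cell_area": 20.0})
        assert np.isnan(r["yap_ratio_nuc_ring"])
        assert np.isnan(r["yap_ratio_nuc_ring_log10"])

    def test_generator_ratio_recovered_within_1pct(self, shapes):
        rng = np.random.default_rng(31)
        spec = dataclasses.replace(
            shapes["triangular"], yaptaz_nuc_ring_ratio=2.0, ratio_log10_sd=0.0
        )
        r = render_cell(spec, rng)
        rs = build_region_set(1, r.cell_mask, r.nucleus_mask)
        from morphoscreen.features import intensity_features

        intens = intensity_features(r.channels, rs)
        measured = intens["yap_nucleus_mean"] / intens["yap_ring_mean"]
        assert measured == pytest.approx(2.0, rel=0.01)

    def test_intensity_shift_outside_mask_invariant_and_scaling(self):
        cell, nucleus, img = two_level_cell()
        rs = build_region_set(1, cell, nucleus)
        from morphoscreen.features import intensity_features

        chans = {c: img for c in ("dna", "tubulin", "actin", "yaptaz")}
        base = intensity_features(chans, rs)
        shifted = {c: img + 55.0 * (~cell) for c in chans}
        scaled = {c: img * 3.0 for c in chans}
        for k in base:
            assert intensity_features(shifted, rs)[k] == pytest.approx(base[k])
            assert intensity_features(scaled, rs)[k] == pytest.approx(3 * base[k])


class TestSER:
    def test_constant_image_all_zero(self):
        mask = disc_mask(10, pad=10)
        img = np.full(mask.shape, 9.0)
        f = ser_features(img, mask, scale=0)
        for k, v in f.items():
            assert v == pytest.approx(0.0, abs=1e-6)

    def test_gaussian_blob_spot_dominates(self):
        # blob matched to the detector scale (sigma0 + 1 = 1.5 px)
        mask = disc_mask(5, pad=15)
        c = mask.shape[0] // 2
        rr, cc = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
        img = 100 * np.exp(-((rr - c) ** 2 + (cc - c) ** 2) / (2 * 1.5**2))
        f = ser_features(img, mask, scale=1)
        assert f["spot"] == max(f.values())

    def test_dark_blob_is_hole(self):
        mask = disc_mask(5, pad=15)
        c = mask.shape[0] // 2
        rr, cc = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
        img = 100 - 100 * np.exp(-((rr - c) ** 2 + (cc - c) ** 2) / (2 * 1.5**2))
        f = ser_features(img, mask, scale=1)
        assert f["hole"] == max(f.values())

    def test_bright_line_ridge_ordering(self):
        mask = disc_mask(8, pad=12)
        c = mask.shape[0] // 2
        img = np.zeros(mask.shape)
        img[c, :] = 100.0
        f = ser_features(img, mask, scale=1)
        assert f["ridge"] > f["spot"]
        # on the line interior (the crest) ridge beats edge; the flanks are
        # legitimately edge-like
        crest = np.zeros(mask.shape, bool)
        crest[c, :] = True
        f_crest = ser_features(img, crest & mask, scale=1)
        assert f_crest["ridge"] > f_crest["edge"]

    def test_step_is_edge(self):
        mask = disc_mask(8, pad=12)
        c = mask.shape[0] // 2
        cc = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]][1]
        img = np.where(cc > c, 100.0, 0.0)
        f = ser_features(img, mask, scale=1)
        assert f["edge"] == max(f.values())

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        patch = rng.random((30, 30)) * 50
        img1 = np.zeros((80, 80))
        img1[10:40, 10:40] = patch
        img2 = np.zeros((80, 80))
        img2[35:65, 30:60] = patch
        m1 = np.zeros((80, 80), bool)
        m1[15:35, 15:35] = True
        m2 = np.zeros((80, 80), bool)
        m2[40:60, 35:55] = True
        f1 = ser_features(img1, m1, scale=1)
        f2 = ser_features(img2, m2, scale=1)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-6, abs=1e-9)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            ser_response_maps(np.zeros((8, 8)), scale=2)


class TestHaralick:
    def test_constant_region(self):
        img = np.full((10, 10), 5.0)
        mask = np.ones((10, 10), bool)
        f = haralick_features(img, mask)
        assert f["contrast"] == 0.0
        assert f["homogeneity"] == 1.0
        assert np.isnan(f["correlation"])

    def test_checkerboard_contrast(self):
        img = np.indices((8, 8)).sum(axis=0) % 2 * 63.0
        mask = np.ones((8, 8), bool)
        f = haralick_features(img, mask)
        oracle = brute_force_glcm_features(img, mask)
        # every horizontal/vertical pair flips level; diagonals agree
        assert f["contrast"] == pytest.approx(oracle["contrast"])
        assert f["homogeneity"] == pytest.approx(oracle["homogeneity"])

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_random_patches(self, seed):
        """Masked GLCM features equal the brute-force oracle exactly."""
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (8, 8)).astype(float)
        mask = rng.random((8, 8)) > 0.2
        if mask.sum() < 4:
            mask[:] = True
        ours = haralick_features(img, mask)
        oracle = brute_force_glcm_features(img, mask)
        for k in ours:
            if np.isnan(oracle[k]):
                assert np.isnan(ours[k])
            else:
                assert ours[k] == pytest.approx(oracle[k], rel=1e-10)

    def test_too_small_region_missing(self):
        img = np.zeros((4, 4))
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        f = haralick_features(img, mask)
        assert all(np.isnan(v) for v in f.values())


class TestGabor:
    def test_constant_image_near_zero(self):
        mask = disc_mask(20, pad=11)
        img = np.full(mask.shape, 50.0)
        f = gabor_features(img, mask)
        for v in f.values():
            assert abs(v) < 1e-6 * 50

    def test_oriented_stripes_anisotropy(self):
        mask = disc_mask(20, pad=11)
        cc = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]][1]
        stripes = 50 + 50 * np.sin(2 * np.pi * cc / 4.0)
        f = gabor_features(stripes, mask)
        assert f["max"] / max(f["min"], 1e-9) > 2.0

    def test_stripes_more_anisotropic_than_noise(self):
        rng = np.random.default_rng(8)
        mask = disc_mask(20, pad=11)
        cc = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]][1]
        stripes = 50 + 50 * np.sin(2 * np.pi * cc / 4.0)
        noise = 50 + 50 * rng.standard_normal(mask.shape)
        fs = gabor_features(stripes, mask)
        fn = gabor_features(noise, mask)
        ratio_s = fs["max"] / max(fs["min"], 1e-9)
        ratio_n = fn["max"] / max(fn["min"], 1e-9)
        assert ratio_s > ratio_n


class TestNeighbourFraction:
    @pytest.mark.parametrize(
        "a1,a2,raw", [(200.0, 100.0, 0.0), (100.0, 100.0, 0.5), (50.0, 100.0, 0.75)]
    )
    def test_formula(self, a1, a2, raw):
        got_raw, _ = neighbour_fraction(a1, a2)
        assert got_raw == pytest.approx(raw)

    def test_fully_enclosed(self):
        raw, cal = neighbour_fraction(100.0, 0.0)
        assert raw == 1.0 and cal == 1.0

    def test_calibrated_matches_shared_boundary_oracle(self, shapes):
        """Two contacting cells: calibrated NF within 0.1 of the direct
        label-adjacency measurement of shared perimeter."""
        img, gt = render_field(
            FieldSpec(image_shape=(320, 320), n_cells=2, rng_seed=33,
                      contact_probability=1.0),
            [(shapes["triangular"], 1.0)],
        )
        from morphoscreen.regions import neighbour_bands

        cross = ndi.generate_binary_structure(2, 1)
        for lab in (1, 2):
            cell = gt.cells == lab
            m1, m2 = neighbour_bands(cell, gt.cells)
            _, cal = neighbour_fraction(float(m1.sum()), float(m2.sum()))
            boundary = cell & ~ndi.binary_erosion(cell, structure=cross)
            other = (gt.cells > 0) & ~cell
            touching = boundary & ndi.binary_dilation(other, structure=cross)
            oracle = touching.sum() / boundary.sum()
            assert cal == pytest.approx(oracle, abs=0.1)


class TestExtractAll:
    def test_table_shape_and_determinism(self, balanced_field, config):
        img, gt = balanced_field
        t1 = extract_all(img, gt.cells, gt.nuclei, config)
        assert len(t1) == gt.n_cells
        assert list(t1.columns) == ["cell", *REGISTRY_NAMES, *AUX_COLUMNS]
        t2 = extract_all(img, gt.cells, gt.nuclei, config)
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_field_full_header(self, config):
        img = FieldImage({c: np.zeros((64, 64), np.float32)
                          for c in ("dna", "tubulin", "actin", "yaptaz")})
        out = extract_all(img, np.zeros((64, 64), np.int32),
                          np.zeros((64, 64), np.int32), config)
        assert len(out) == 0
        assert list(out.columns) == ["cell", *REGISTRY_NAMES, *AUX_COLUMNS]


class TestAggregateWell:
    def test_single_cell_profile_equals_vector(self, balanced_field, config):
        img, gt = balanced_field
        table = extract_all(img, gt.cells, gt.nuclei, config)
        one = table.iloc[[0]]
        prof = aggregate_well(one)
        for name in REGISTRY_NAMES:
            if np.isfinite(one[name].iloc[0]):
                assert prof[name] == one[name].iloc[0]
        assert prof["n_cells"] == 1

    def test_mean_of_two(self):
        cols = ["cell", *REGISTRY_NAMES, *AUX_COLUMNS]
        a = {c: 1.0 for c in cols}
        b = {c: 3.0 for c in cols}
        table = pd.DataFrame([a, b])
        prof = aggregate_well(table)
        assert prof[REGISTRY_NAMES[0]] == 2.0
        assert prof["neighbour_fraction"] == 2.0

    def test_well_profile_has_127_features(self, balanced_field, config):
        img, gt = balanced_field
        table = extract_all(img, gt.cells, gt.nuclei, config)
        prof = aggregate_well(table)
        n_registry = sum(1 for k in prof.index if k in WELL_FEATURE_NAMES)
        assert n_registry == 127

    def test_empty_well(self, config):
        empty = pd.DataFrame(columns=["cell", *REGISTRY_NAMES, *AUX_COLUMNS])
        prof = aggregate_well(empty)
        assert prof["n_cells"] == 0
        assert np.isnan(prof[REGISTRY_NAMES[0]])

    def test_missing_values_ignored_in_mean(self):
        cols = ["cell", *REGISTRY_NAMES, *AUX_COLUMNS]
        a = {c: 1.0 for c in cols}
        b = {c: np.nan for c in cols}
        b["cell"] = 2.0
        table = pd.DataFrame([a, b])
        prof = aggregate_well(table)
        assert prof[REGISTRY_NAMES[0]] == 1.0
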