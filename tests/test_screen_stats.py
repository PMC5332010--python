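"""Screen statistics: normalisation, control Z-scores, hit calling,
density regression."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphoscreen.config import ScreenConfig
from morphoscreen.screen import (
    call_hits,
    density_regression,
    plate_normalise,
    zscore_to_controls,
)
from morphoscreen.synth.screen_sim import (
    simulate_dilution_curve,
    simulate_null_screen,
)


def small_table(values, plate="P1"):
    return pd.DataFrame(
        {
            "plate": plate,
            "well": [f"W{i}" for i in range(len(values))],
            "role": "sample",
            "f001": values,
        }
    )


class TestPlateNormalise:
    def test_three_values(self):
        out = plate_normalise(small_table([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(
            out["f001"].to_numpy(), [-1.224745, 0.0, 1.224745], atol=1e-6
        )

    def test_constant_feature_skipped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            out = plate_normalise(small_table([5.0, 5.0, 5.0]))
        assert out["f001"].isna().all()
        assert "constant" in caplog.text

    def test_offset_plates_align(self):
        a = small_table([1.0, 2.0, 3.0], plate="P1")
        b = small_table([11.0, 12.0, 13.0], plate="P2")
        out = plate_normalise(pd.concat([a, b], ignore_index=True))
        np.testing.assert_allclose(
            out.loc[out.plate == "P1", "f001"].to_numpy(),
            out.loc[out.plate == "P2", "f001"].to_numpy(),
        )

    def test_idempotent(self):
        t = small_table([1.0, 5.0, 2.0, 8.0])
        once = plate_normalise(t)
        twice = plate_normalise(once)
        np.testing.assert_allclose(
            once["f001"].to_numpy(), twice["f001"].to_numpy(), atol=1e-12
        )

    def test_robust_variant(self):
        t = small_table([1.0, 2.0, 3.0, 100.0])
        out = plate_normalise(t, ScreenConfig(robust=True))
        # median 2.5, MAD*1.4826; the outlier does not distort the centre
        assert out["f001"].iloc[1] < 0 < out["f001"].iloc[2]

    def test_single_well_plate_rejected(self):
        with pytest.raises(ValueError):
            plate_normalise(small_table([1.0]))


class TestZScore:
    def make(self, ctrl_vals, sample_vals):
        rows = []
        for i, v in enumerate(ctrl_vals):
            rows.append({"plate": "P1", "well": f"C{i}", "role": "mock", "f001": v})
        for i, v in enumerate(sample_vals):
            rows.append({"plate": "P1", "well": f"S{i}", "role": "sample", "f001": v})
        return pd.DataFrame(rows)

    def test_well_at_control_mean_is_zero(self):
        t = self.make([1.0, 2.0, 3.0], [2.0])
        z = zscore_to_controls(t)
        assert z.loc[z.role == "sample", "f001"].iloc[0] == pytest.approx(0.0)

    def test_controls_standardised(self):
        rng = np.random.default_rng(3)
        t = self.make(rng.normal(5, 2, 50), [])
        z = zscore_to_controls(t)
        ctrl = z.loc[z.role == "mock", "f001"]
        assert ctrl.mean() == pytest.approx(0.0, abs=1e-10)
        assert ctrl.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_simulated_shift_recovered(self):
        rng = np.random.default_rng(4)
        t = self.make(rng.normal(0, 1, 200), [1.5])
        z = zscore_to_controls(t)
        got = z.loc[z.role == "sample", "f001"].iloc[0]
        assert got == pytest.approx(1.5, abs=0.25)

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError):
            zscore_to_controls(self.make([1.0, 2.0], [3.0]))


class TestCallHits:
    def make_z(self, z_values):
        zt = pd.DataFrame(
            {
                "plate": "P1",
                "well": [f"S{i}" for i in range(len(z_values))],
                "role": "sample",
                "gene": [f"G{i}" for i in range(len(z_values))],
                "f001": z_values,
            }
        )
        raw = zt.copy()
        raw["f001"] = 10.0
        ctrl = pd.DataFrame(
            [{"plate": "P1", "well": "C0", "role": "mock", "gene": "", "f001": 5.0}]
        )
        raw = pd.concat([raw, ctrl], ignore_index=True)
        zt = pd.concat([zt, ctrl.assign(f001=0.0)], ignore_index=True)
        return zt, raw

    def test_threshold_boundary(self):
        zt, raw = self.make_z([1.49, 1.50, -1.50, -1.49])
        hits = call_hits(zt, raw, ["f001"])
        by_well = hits.set_index("well")
        assert not by_well.loc["S0", "hit"]
        assert by_well.loc["S1", "hit"]
        assert by_well.loc["S2", "hit"]
        assert not by_well.loc["S3", "hit"]
        assert by_well.loc["S2", "direction"] == "down"

    def test_monotone_in_abs_z(self):
        zt, raw = self.make_z([0.5, 1.0, 1.6, 2.5, -3.0])
        hits = call_hits(zt, raw, ["f001"]).set_index("well")
        flags = hits["hit"]
        zs = hits["z"].abs()
        for w1 in flags.index:
            for w2 in flags.index:
                if zs[w1] >= zs[w2] and flags[w2]:
                    assert flags[w1]

    def test_fold_change_vs_control_mean(self):
        zt, raw = self.make_z([2.0])
        hits = call_hits(zt, raw, ["f001"])
        assert hits["fold_change"].iloc[0] == pytest.approx(2.0)  # 10 / 5

    def test_null_hit_rate_matches_gaussian_tail(self):
        """Null screen: empirical |Z|>=1.5 rate within 3 MC SEs of 13.36%."""
        table = simulate_null_screen(
            n_plates=4, wells_per_plate=96, n_features=20,
            n_controls_per_plate=24, seed=90,
        )
        feats = [c for c in table.columns if c.startswith("f")]
        normalised = plate_normalise(table)
        z = zscore_to_controls(normalised)
        hits = call_hits(z, table, feats)
        rate = hits["hit"].mean()
        p = 2 * stats.norm.sf(1.5)
        n = len(hits)
        se = np.sqrt(p * (1 - p) / n)
        # finite control count inflates the tail slightly; 3 SE + 1 point
        assert abs(rate - p) < 3 * se + 0.01

    def test_spike_recovery_sensitivity(self):
        """+3 control-sd spikes are recovered with sensitivity >= 0.9.

        Screen-realistic geometry: four replicate plates of 96 wells with
        24 pooled mock controls each and one spiked well per plate,
        over 200 replicates."""
        spikes = {(p, 95): {0: 3.0} for p in range(4)}
        found = total = 0
        for rep in range(200):
            table = simulate_null_screen(
                n_plates=4, wells_per_plate=96, n_features=1,
                n_controls_per_plate=24, seed=1000 + rep, spikes=spikes,
            )
            normalised = plate_normalise(table)
            z = zscore_to_controls(normalised)
            hits = call_hits(z, table, ["f001"])
            sel = hits[hits["well"] == "W096"]
            found += int(sel["hit"].sum())
            total += len(sel)
        assert found / total >= 0.9


class TestDensityRegression:
    def test_exact_line_recovered(self):
        x = np.array([250, 500, 1000, 2000])
        y = 0.001 * x + 0.3
        fit = density_regression(x, y)
        assert fit.slope == pytest.approx(0.001)
        assert fit.intercept == pytest.approx(0.3)

    def test_too_few_densities_rejected(self):
        with pytest.raises(ValueError):
            density_regression([100, 100, 200], [1, 2, 3])

    def test_null_slope_ci_coverage(self):
        """Zero-slope generator: 95% CI covers 0 in >= 90% of 100 runs."""
        covered = 0
        for seed in range(100):
            df = simulate_dilution_curve(
                [250, 500, 1000, 1500, 2000, 3000], slope=0.0, intercept=0.2,
                noise_sd=0.05, seed=seed,
            )
            fit = density_regression(df["cells_plated"], df["yap_ratio"])
            lo, hi = fit.slope_ci(0.95)
            if lo <= 0 <= hi:
                covered += 1
        assert covered >= 90

    def test_dilution_cells_plated_parsed_from_gene_column(self):
        """Dilution wells carry the plated cell number in the gene column."""
        from morphoscreen.tables import dilution_cells_plated

        df = pd.DataFrame(
            {
                "well": ["A1", "B1", "C5"],
                "gene": ["250", "3000", "ECT2"],
                "role": ["dilution", "dilution", "sample"],
            }
        )
        parsed = dilution_cells_plated(df)
        assert parsed.iloc[0] == 250
        assert parsed.iloc[1] == 3000
        assert np.isnan(parsed.iloc[2])
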