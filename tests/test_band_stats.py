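"""Band summaries, repeated-measures ANOVA and post-hoc comparisons."""

import numpy as np
import pandas as pd
import pytest

from swdmaps.band_stats import (MapRecord, band_summary, central_electrodes,
                                interictal_band_stats, posthoc_vs_baseline,
                                rm_anova_2way)
from swdmaps.spectral import TFGrid, TFMap
from swdmaps.synth_lfp import default_layout


def _rescaled_map(value, n_t=25, n_f=161, noise=0.0, rng=None):
    grid = TFGrid(times=np.linspace(-0.1, 1.1, n_t), freqs=4.0 + 0.1 * np.arange(n_f))
    vals = np.full((n_t, n_f), float(value))
    if noise and rng is not None:
        vals += noise * rng.standard_normal((n_t, n_f))
    return TFMap(grid=grid, values=vals, kind="z-power", rescaled=True)


def _records(values_by_key, layout):
    """values_by_key: {(animal, timepoint, side): value}; one map per central electrode."""
    recs = []
    for (a, tp, side), v in values_by_key.items():
        for el in central_electrodes(layout, side):
            recs.append(MapRecord(a, tp, side, "power", el, _rescaled_map(v)))
    return recs


class TestCentralElectrodes:
    def test_middle_three_of_five_by_ap(self):
        layout = default_layout()
        assert central_electrodes(layout, "left") == ["L2", "L3", "L4"]
        assert central_electrodes(layout, "right") == ["R2", "R3", "R4"]

    def test_too_few_electrodes_rejected(self):
        with pytest.raises(ValueError):
            central_electrodes(default_layout()[:2], "left")


class TestBandSummary:
    def test_constant_maps_give_the_constant(self):
        layout = default_layout()
        vals = {("a0", "baseline", "left"): 4.0, ("a0", "baseline", "right"): 4.0,
                ("a0", "1w", "left"): 2.0, ("a0", "1w", "right"): 4.0}
        df = band_summary(_records(vals, layout), layout)
        row = df[(df.timepoint == "1w") & (df.side == "left")]
        assert row.value.iloc[0] == pytest.approx(2.0)

    def test_baseline_percent_is_exactly_100(self):
        layout = default_layout()
        vals = {("a0", "baseline", "left"): 3.3, ("a0", "baseline", "right"): 5.1,
                ("a0", "1w", "left"): 3.0, ("a0", "1w", "right"): 5.1}
        df = band_summary(_records(vals, layout), layout)
        assert (df[df.timepoint == "baseline"].percent_baseline == 100.0).all()
        left_1w = df[(df.timepoint == "1w") & (df.side == "left")]
        assert left_1w.percent_baseline.iloc[0] == pytest.approx(100 * 3.0 / 3.3)

    def test_invariant_to_electrode_ordering(self, rng):
        layout = default_layout()
        vals = {("a0", "baseline", "left"): 1.0, ("a0", "baseline", "right"): 1.0}
        recs = _records(vals, layout)
        df1 = band_summary(recs, layout)
        df2 = band_summary(recs[::-1], layout)
        pd.testing.assert_frame_equal(df1, df2)

    def test_band_outside_grid_rejected(self):
        layout = default_layout()
        vals = {("a0", "baseline", "left"): 1.0}
        with pytest.raises(ValueError, match="outside"):
            band_summary(_records(vals, layout), layout, band=(30.0, 40.0))

    def test_non_central_electrodes_excluded(self):
        layout = default_layout()
        recs = [MapRecord("a0", "baseline", "left", "power", "L1", _rescaled_map(99.0)),
                MapRecord("a0", "baseline", "left", "power", "L3", _rescaled_map(1.0))]
        df = band_summary(recs, layout)
        assert df.value.iloc[0] == pytest.approx(1.0)  # L1 (edge electrode) ignored


def _balanced_toy(rng, effect_side=0.0, n_animals=4,
                  timepoints=("baseline", "1w", "3w")):
    rows = []
    for tp in timepoints:
        for a in range(n_animals):
            base = rng.normal(100, 3)
            for side in ("left", "right"):
                y = base + (effect_side if side == "left" else 0.0) + rng.normal(0, 1)
                rows.append((f"{tp}_a{a}", tp, side, y))
    return pd.DataFrame(rows, columns=["animal", "timepoint", "side", "percent_baseline"])


class TestRmAnova:
    def test_all_identical_values_give_f_zero_p_one(self):
        df = _balanced_toy(np.random.default_rng(0))
        df["percent_baseline"] = 7.0
        table = rm_anova_2way(df)
        effects = table[table.F.notna()]
        assert (effects.F == 0).all()
        assert (effects.p == 1).all()

    def test_matches_independent_mixed_anova_oracle(self, rng):
        pg = pytest.importorskip("pingouin")
        df = _balanced_toy(rng, effect_side=4.0)
        mine = rm_anova_2way(df).set_index("effect")
        theirs = pg.mixed_anova(data=df.rename(columns={"percent_baseline": "y"}),
                                dv="y", within="side", between="timepoint",
                                subject="animal").set_index("Source")
        for ours, th in [("timepoint", "timepoint"), ("side", "side"),
                         ("timepoint x side", "Interaction")]:
            assert mine.loc[ours, "SS"] == pytest.approx(theirs.loc[th, "SS"], rel=1e-8)
            assert mine.loc[ours, "F"] == pytest.approx(theirs.loc[th, "F"], rel=1e-8)
            assert mine.loc[ours, "p"] == pytest.approx(theirs.loc[th, "p_unc"], rel=1e-8)

    def test_sums_of_squares_partition_the_total(self, rng):
        df = _balanced_toy(rng, effect_side=2.0)
        table = rm_anova_2way(df)
        y = df.percent_baseline.to_numpy()
        ss_total = ((y - y.mean()) ** 2).sum()
        assert table.SS.sum() == pytest.approx(ss_total, rel=1e-10)

    def test_missing_cell_rejected(self, rng):
        df = _balanced_toy(rng).iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            rm_anova_2way(df)

    def test_within_mode_runs_on_shared_subjects(self, rng):
        rows = []
        for tp in ("baseline", "1w"):
            for a in range(4):
                for side in ("left", "right"):
                    rows.append((f"a{a}", tp, side, rng.normal(100, 5)))
        df = pd.DataFrame(rows, columns=["animal", "timepoint", "side", "percent_baseline"])
        table = rm_anova_2way(df, mode="within")
        assert set(table.effect) == {"A", "B", "A x B"}
        assert table.p.between(0, 1).all()


def _longitudinal_toy(rng, drop_left_1w=0.0,
                      timepoints=("baseline", "1w", "3w"), n_animals=4):
    """Same animals at every timepoint (the study's longitudinal design)."""
    rows = []
    for tp in timepoints:
        for a in range(n_animals):
            for side in ("left", "right"):
                y = 100 + rng.normal(0, 2)
                if side == "left" and tp != "baseline":
                    y -= drop_left_1w
                rows.append((f"a{a}", tp, side, y))
    return pd.DataFrame(rows, columns=["animal", "timepoint", "side", "percent_baseline"])


class TestPostHoc:
    def test_bonferroni_scales_p_by_family_size(self, rng):
        df = _longitudinal_toy(rng)
        ph = posthoc_vs_baseline(df)
        # family = 2 sides x 2 post timepoints
        assert len(ph) == 4
        np.testing.assert_allclose(ph.p_adj, np.minimum(ph.p_unc * 4, 1.0))

    def test_sidak_less_conservative_than_bonferroni(self, rng):
        df = _longitudinal_toy(rng, drop_left_1w=5.0)
        bon = posthoc_vs_baseline(df, correction="bonferroni")
        sid = posthoc_vs_baseline(df, correction="sidak")
        assert np.isfinite(bon.p_adj).all()
        assert (sid.p_adj <= bon.p_adj + 1e-12).all()

    def test_strong_unilateral_effect_flagged_on_that_side_only(self, rng):
        rows = []
        for tp in ("baseline", "1w"):
            for a in range(5):
                for side in ("left", "right"):
                    y = 100 + rng.normal(0, 1)
                    if side == "left" and tp == "1w":
                        y -= 40
                    rows.append((f"a{a}", tp, side, y))
        df = pd.DataFrame(rows, columns=["animal", "timepoint", "side", "percent_baseline"])
        ph = posthoc_vs_baseline(df).set_index(["side", "timepoint"])
        assert ph.loc[("left", "1w"), "p_adj"] < 0.01
        assert ph.loc[("right", "1w"), "p_adj"] > 0.05


class TestInterictalBandStats:
    def _frame(self, rng, boost_band=None, n_animals=4):
        rows = []
        base = {"delta": 10.0, "theta": 6.0, "alpha": 3.0, "beta": 1.5}
        for a in range(n_animals):
            for cond in ("pre", "post"):
                for band, amp in base.items():
                    y = amp * (2.0 if (cond == "post" and band == boost_band) else 1.0)
                    rows.append((f"a{a}", cond, band, y + rng.normal(0, 0.02)))
        return pd.DataFrame(rows, columns=["animal", "condition", "band", "amplitude"])

    def test_identical_conditions_yield_no_significant_band(self, rng):
        df = self._frame(rng)
        _, ph = interictal_band_stats(df)
        assert (ph.p_adj > 0.05).all()

    def test_doubled_band_flagged_others_not(self, rng):
        df = self._frame(rng, boost_band="theta")
        _, ph = interictal_band_stats(df)
        ph = ph.set_index("band")
        assert ph.loc["theta", "p_adj"] < 0.05
        assert (ph.drop("theta").p_adj > 0.05).all()

    def test_single_animal_rejected(self, rng):
        df = self._frame(rng, n_animals=1)
        with pytest.raises(ValueError, match="animals"):
            interictal_band_stats(df)

    def test_differing_band_sets_rejected(self, rng):
        df = self._frame(rng)
        df = df[~((df.condition == "post") & (df.band == "beta"))]
        with pytest.raises(ValueError, match="band sets"):
            interictal_band_stats(df)
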