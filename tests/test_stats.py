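import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from plvnet.connectivity import PLVMatrix
from plvnet.montage import default_montage
from plvnet.stats import (
    compare_edges,
    compare_global_across_thresholds,
    fdr_adjust,
    node_difference_map,
    paired_compare,
    significance_stars,
)


class TestPairedCompare:
    def test_identical_data_degenerate(self):
        x = np.arange(10.0)
        r = paired_compare(x, x)
        assert r.test_used == "degenerate"
        assert r.p_value == 1.0
        assert r.statistic == 0.0

    def test_degenerate_raise_mode(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="degenerate"):
            paired_compare(x, x, on_degenerate="raise")

    def test_nan_rejected(self):
        x = np.array([1.0, 2.0, np.nan, 4.0])
        with pytest.raises(ValueError, match="NaN"):
            paired_compare(x, x + 1)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            paired_compare(np.array([1.0, 2.0]), np.array([2.0, 3.0]))

    def test_normal_differences_select_t(self, rng):
        """Shapiro gate at alpha=0.05 keeps the t-test ~95% of the time."""
        chosen = 0
        reps = 1000
        for _ in range(reps):
            c = rng.normal(0, 1, 18)
            f = c + rng.normal(0.5, 1, 18)
            if paired_compare(c, f).test_used == "paired_t":
                chosen += 1
        assert chosen / reps >= 0.90

    def test_heavy_tailed_differences_select_wilcoxon(self, rng):
        chosen = 0
        reps = 300
        for _ in range(reps):
            c = rng.normal(0, 1, 18)
            f = c + 0.5 + rng.standard_cauchy(18)
            if paired_compare(c, f).test_used == "wilcoxon":
                chosen += 1
        assert chosen / reps > 0.5

    def test_one_tailed_direction(self, rng):
        c = rng.normal(0, 1, 18)
        f = c + 1.0  # fatigue systematically higher
        r = paired_compare(c, f, tail="one", force_test="paired_t")
        assert r.p_value < 0.001
        assert r.statistic < 0
        # opposite direction: one-tailed p near 1
        r2 = paired_compare(f, c, tail="one", force_test="paired_t")
        assert r2.p_value > 0.9

    def test_t_statistic_matches_scipy(self, rng):
        c = rng.normal(0, 1, 15)
        f = rng.normal(0.3, 1, 15)
        r = paired_compare(c, f, force_test="paired_t")
        ref = sps.ttest_rel(c, f)
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue)

    def test_wilcoxon_z_matches_scipy_approx(self, rng):
        c = rng.normal(0, 1, 25)
        f = rng.normal(0.4, 1, 25)
        r = paired_compare(c, f, force_test="wilcoxon")
        ref = sps.wilcoxon(c, f, zero_method="pratt", method="approx", correction=False)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_wilcoxon_exact_small_n(self, rng):
        c = rng.normal(0, 1, 8)
        f = c + rng.normal(0.5, 1, 8)
        r = paired_compare(c, f, force_test="wilcoxon")
        ref = sps.wilcoxon(c, f, method="exact")
        assert r.p_value == pytest.approx(ref.pvalue)

    def test_descriptive_formats(self, rng):
        c = rng.normal(0, 1, 18)
        f = rng.normal(1, 1, 18)
        r_t = paired_compare(c, f, force_test="paired_t")
        assert "(" in r_t.describe("comfort") and "~" not in r_t.describe("comfort")
        r_w = paired_compare(c, f, force_test="wilcoxon")
        assert "~" in r_w.describe("fatigue")


class TestFDR:
    def test_hand_worked_step_up(self):
        adj, rej = fdr_adjust([0.01, 0.02, 0.03, 0.04], q=0.05)
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
        assert rej.all()

    def test_all_ones(self):
        adj, rej = fdr_adjust([1.0, 1.0, 1.0])
        np.testing.assert_allclose(adj, 1.0)
        assert not rej.any()

    def test_single_p(self):
        adj, _ = fdr_adjust([0.031])
        assert adj[0] == pytest.approx(0.031)

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(0, 1, 100)
        adj, rej = fdr_adjust(p, q=0.05)
        rej_sm, adj_sm, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(adj, adj_sm)
        np.testing.assert_array_equal(rej, rej_sm)

    def test_order_invariance(self, rng):
        p = rng.uniform(0, 1, 30)
        perm = rng.permutation(30)
        adj, _ = fdr_adjust(p)
        adj_perm, _ = fdr_adjust(p[perm])
        np.testing.assert_allclose(adj_perm, adj[perm])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_raw_p(self, pvals):
        p = np.asarray(pvals)
        adj, _ = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fdr_adjust([])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fdr_adjust([0.5, 1.2])


def _plv_list(rng, n_participants, mean, sd, labels, condition):
    out = []
    n = len(labels)
    for p in range(n_participants):
        v = np.clip(rng.normal(mean, sd, (n, n)), 0, 1)
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        out.append(
            PLVMatrix(
                values=v, channel_labels=labels, band="alpha",
                condition=condition, participant=f"P{p:02d}",
            )
        )
    return out


class TestCompareEdges:
    labels = tuple(f"c{i}" for i in range(8))

    def test_identical_conditions_nothing_significant(self, rng):
        comfort = _plv_list(rng, 10, 0.5, 0.05, self.labels, "comfort")
        fatigue = [
            PLVMatrix(values=m.values.copy(), channel_labels=m.channel_labels,
                      band=m.band, condition="fatigue", participant=m.participant)
            for m in comfort
        ]
        emap = compare_edges(comfort, fatigue)
        assert emap.summary["n_significant"] == 0
        assert (emap.table["test_used"] == "degenerate").all()

    def test_clear_effect_detected(self, rng):
        comfort = _plv_list(rng, 12, 0.45, 0.04, self.labels, "comfort")
        fatigue = _plv_list(rng, 12, 0.70, 0.04, self.labels, "fatigue")
        emap = compare_edges(comfort, fatigue)
        assert emap.summary["n_significant"] > 0.8 * emap.summary["n_pairs"]
        assert emap.summary["plv_fatigue_mean"] > emap.summary["plv_comfort_mean"]

    def test_misaligned_participants_rejected(self, rng):
        comfort = _plv_list(rng, 4, 0.5, 0.05, self.labels, "comfort")
        fatigue = _plv_list(rng, 4, 0.5, 0.05, self.labels, "fatigue")
        fatigue = fatigue[1:] + fatigue[:1]
        with pytest.raises(ValueError, match="participant mismatch"):
            compare_edges(comfort, fatigue)

    def test_gated_method_runs(self, rng):
        comfort = _plv_list(rng, 8, 0.5, 0.05, self.labels, "comfort")
        fatigue = _plv_list(rng, 8, 0.6, 0.05, self.labels, "fatigue")
        emap = compare_edges(comfort, fatigue, method="gated")
        assert set(emap.table["test_used"]) <= {"paired_t", "wilcoxon", "degenerate"}

    def test_table_shape(self, rng):
        comfort = _plv_list(rng, 5, 0.5, 0.05, self.labels, "comfort")
        fatigue = _plv_list(rng, 5, 0.5, 0.05, self.labels, "fatigue")
        emap = compare_edges(comfort, fatigue)
        assert len(emap.table) == 28  # C(8, 2)


def _metrics_frame(rng, bands, thresholds, participants, effect=0.0):
    """Synthetic long-format metrics table (no NaNs)."""
    import pandas as pd

    labels = [f"c{i}" for i in range(4)]
    rows = []
    for band in bands:
        for thr in thresholds:
            for p in range(participants):
                for condition, shift in (("comfort", 0.0), ("fatigue", effect)):
                    base = rng.normal(0.5 + shift, 0.1)
                    for metric in ("bc", "ne", "cc"):
                        for lab in labels:
                            rows.append(
                                dict(participant=f"P{p:02d}", condition=condition,
                                     band=band, threshold=thr, node=lab,
                                     metric=metric,
                                     value=base + rng.normal(0, 0.02))
                            )
                    rows.append(
                        dict(participant=f"P{p:02d}", condition=condition,
                             band=band, threshold=thr, node="GLOBAL",
                             metric="cpl", value=base + rng.normal(0, 0.02))
                    )
                    rows.append(
                        dict(participant=f"P{p:02d}", condition=condition,
                             band=band, threshold=thr, node="GLOBAL",
                             metric="cc_global", value=base)
                    )
    return pd.DataFrame(rows)


class TestThresholdComparison:
    def test_shape_contract(self, rng):
        grid = [0.72, 0.73, 0.74, 0.75, 0.76]
        df = _metrics_frame(rng, ["alpha", "theta", "delta"], grid, 8)
        out = compare_global_across_thresholds(df, grid=grid)
        assert len(out) == 5 * 4 * 3  # thresholds x metrics x bands

    def test_effect_direction(self, rng):
        grid = [0.72]
        df = _metrics_frame(rng, ["alpha"], grid, 10, effect=0.3)
        out = compare_global_across_thresholds(df, grid=grid)
        assert (out["fatigue_mean"] > out["comfort_mean"]).all()
        assert out["significant"].all()

    def test_missing_threshold_rejected(self, rng):
        df = _metrics_frame(rng, ["alpha"], [0.72], 5)
        with pytest.raises(ValueError, match="no metric rows"):
            compare_global_across_thresholds(df, grid=[0.72, 0.99])


class TestNodeDifferenceMap:
    def _frame(self, rng, effect_channels=(), effect=0.0):
        import pandas as pd

        montage = default_montage()
        rows = []
        for p in range(8):
            for condition in ("comfort", "fatigue"):
                for ch in montage.channels:
                    shift = effect if (condition == "fatigue" and ch in effect_channels) else 0.0
                    rows.append(
                        dict(participant=f"P{p:02d}", condition=condition,
                             band="alpha", threshold=0.72, node=ch, metric="ne",
                             value=0.5 + shift + rng.normal(0, 0.03))
                    )
        return pd.DataFrame(rows)

    def test_identical_conditions_zero_differences(self, rng):
        df = self._frame(rng)
        ndm = node_difference_map(df, "ne", "alpha", 0.72, default_montage())
        assert len(ndm.table) == 24
        assert set(ndm.table["region"]) == {
            "frontal", "temporal", "central", "parietal", "occipital"
        }
        assert ndm.table["mean_diff"].abs().max() < 0.05

    def test_targeted_effect_recovered_in_region(self, rng):
        montage = default_montage()
        frontal = montage.channels_in("frontal")
        df = self._frame(rng, effect_channels=frontal, effect=0.4)
        ndm = node_difference_map(df, "ne", "alpha", 0.72, montage)
        sig = ndm.table[ndm.table["significant"]]
        assert len(sig) > 0
        in_region = (sig["region"] == "frontal").mean()
        assert in_region >= 0.8

    def test_unknown_channel_rejected(self, rng):
        df = self._frame(rng)
        df.loc[df["node"] == "Fp1", "node"] = "XX9"
        with pytest.raises(KeyError, match="XX9"):
            node_difference_map(df, "ne", "alpha", 0.72, default_montage())

    def test_bad_metric_rejected(self, rng):
        with pytest.raises(ValueError, match="bc, ne, cc"):
            node_difference_map(self._frame(rng), "cpl", "alpha", 0.72, default_montage())


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.2, ""), (0.04, "*"), (0.009, "**"), (0.0005, "***"), (0.05, "")],
    )
    def test_levels(self, p, expected):
        assert significance_stars(p) == expected
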