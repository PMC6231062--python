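import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bfndecode import reference_tables as ref
from bfndecode import selection as sel
from bfndecode._utils import round_half_up


def kw_h_oracle(*groups):
    """Brute-force Kruskal-Wallis H: rank by sorting, apply the rank-sum formula."""
    allv = np.concatenate(groups)
    order = np.argsort(allv, kind="stable")
    ranks = np.empty(len(allv))
    ranks[order] = np.arange(1, len(allv) + 1)
    # average ranks over ties
    for v in np.unique(allv):
        mask = allv == v
        ranks[mask] = ranks[mask].mean()
    n = len(allv)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    return 12 / (n * (n + 1)) * h - 3 * (n + 1)


def make_samples(degree_lists, band="theta", electrodes=("E1",)):
    """degree_lists: mode -> list of per-epoch degree values (single electrode)."""
    out = []
    i = 0
    for mode, values in degree_lists.items():
        for v in values:
            vec = np.atleast_1d(v)
            out.append(sel.DegreeSample(epoch=i, mode=mode, band=band,
                                        degrees=vec, electrodes=list(electrodes)))
            i += 1
    return out


class TestPerModeMetricMeans:
    def _records(self, rows):
        return [
            {"mode": m, "band": b, "VDegree": d, "VPLength": p, "Cluster": c}
            for m, b, d, p, c in rows
        ]

    def test_single_epoch_identity(self):
        rows = [("BF", "delta", 4.0, 2.0, 0.5), ("LR", "delta", 5.0, 2.1, 0.4),
                ("UD", "delta", 6.0, 2.2, 0.3)]
        out = sel.per_mode_metric_means(self._records(rows))
        assert out["VDegree"].loc["delta", "BF"] == 4.0
        assert out["Cluster"].loc["delta", "UD"] == 0.3

    def test_two_epoch_mean(self):
        rows = [("BF", "delta", 4.0, 2.0, 0.5), ("BF", "delta", 5.0, 2.0, 0.5),
                ("LR", "delta", 4.0, 2.0, 0.5), ("UD", "delta", 4.0, 2.0, 0.5)]
        out = sel.per_mode_metric_means(self._records(rows))
        assert out["VDegree"].loc["delta", "BF"] == pytest.approx(4.5)

    def test_missing_mode_raises(self):
        rows = [("BF", "delta", 4.0, 2.0, 0.5), ("LR", "delta", 5.0, 2.1, 0.4)]
        with pytest.raises(ValueError, match="UD"):
            sel.per_mode_metric_means(self._records(rows))


class TestModeSpread:
    @pytest.mark.parametrize(
        "triple, expected, digits",
        [
            ((4.24, 4.27, 4.31), 0.035, 3),  # published degree row
            ((2.08, 2.04, 2.13), 0.045, 3),  # published path-length row
            ((4.41, 4.27, 4.46), 0.098, 3),  # published degree row (theta)
            ((0.51, 0.51, 0.52), 0.006, 3),  # published clustering row
        ],
    )
    def test_published_worked_examples(self, triple, expected, digits):
        assert round_half_up(sel.mode_spread(triple), digits) == expected

    def test_constant_zero(self):
        assert sel.mode_spread((3.3, 3.3, 3.3)) == pytest.approx(0.0, abs=1e-12)

    def test_wrong_arity(self):
        with pytest.raises(ValueError):
            sel.mode_spread((1.0, 2.0))


class TestDegreeSpreadTable:
    def test_identical_distributions_zero(self):
        samples = make_samples(
            {"BF": [1, 2, 3], "LR": [1, 2, 3], "UD": [1, 2, 3]}
        )
        table = sel.degree_spread_table(samples)
        assert table.per_electrode.loc["E1", "theta"] == pytest.approx(0.0)

    def test_known_mode_means(self):
        samples = make_samples({"BF": [0, 2], "LR": [2, 4], "UD": [4, 6]})
        table = sel.degree_spread_table(samples)
        # mode means 1, 3, 5 -> sample SD 2.0
        assert table.per_electrode.loc["E1", "theta"] == pytest.approx(2.0)

    def test_published_column_means(self):
        spread = ref.spread_table()
        assert round_half_up(spread.band_means["delta"], 2) == 0.66
        assert round_half_up(spread.band_means["gamma1"], 2) == 0.37

    def test_requires_all_modes(self):
        samples = make_samples({"BF": [1, 2], "LR": [1, 2]})
        with pytest.raises(ValueError, match="modes"):
            sel.degree_spread_table(samples)


class TestKruskalWallis:
    def test_h_statistic_matches_oracle(self):
        groups = ([1, 2, 3], [4, 5, 6], [7, 8, 9])
        h = sel.kruskal_wallis_statistic(*[np.asarray(g, float) for g in groups])
        assert h == pytest.approx(kw_h_oracle(*map(np.asarray, groups)), abs=1e-9)
        assert h == pytest.approx(7.2, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_h_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.integers(0, 4, size=6).astype(float) for _ in range(3)]
        if len(np.unique(np.concatenate(groups))) < 2:
            pytest.skip("degenerate draw")
        h = sel.kruskal_wallis_statistic(*groups)
        # scipy applies the tie correction; the plain oracle must match after it
        allv = np.concatenate(groups)
        _, counts = np.unique(allv, return_counts=True)
        tie = 1 - (counts**3 - counts).sum() / (len(allv) ** 3 - len(allv))
        assert h == pytest.approx(kw_h_oracle(*groups) / tie, abs=1e-9)

    def test_all_zero_degenerate_marker(self):
        samples = make_samples({"BF": [0, 0, 0], "LR": [0, 0, 0], "UD": [0, 0, 0]})
        table = sel.kruskal_wallis_table(samples)
        assert np.isnan(table.pvalues.loc["E1", "theta"])

    def test_type_one_error_calibrated(self):
        # identical continuous distributions -> p uniform; alpha=0.05
        rng = np.random.default_rng(42)
        hits = 0
        n = 500
        for _ in range(n):
            g = [rng.standard_normal(8) for _ in range(3)]
            hits += stats.kruskal(*g).pvalue < 0.05
        assert 0.03 <= hits / n <= 0.07

    def test_pipeline_table_type_one(self):
        # same check routed through kruskal_wallis_table on integer degrees
        rng = np.random.default_rng(7)
        hits = tot = 0
        for _ in range(300):
            samples = make_samples(
                {m: rng.integers(0, 6, size=10).tolist() for m in ("BF", "LR", "UD")}
            )
            p = sel.kruskal_wallis_table(samples).pvalues.loc["E1", "theta"]
            if not np.isnan(p):
                tot += 1
                hits += p < 0.05
        assert 0.02 <= hits / tot <= 0.08


class TestSelectFeatures:
    def test_published_delta_count(self):
        assert ref.kw_table().significant_count("delta") == 14

    def test_published_theta_count(self):
        assert ref.kw_table().significant_count("theta") == 15

    def test_published_full_rule(self):
        s = sel.select_features(ref.kw_table(), spread=ref.spread_table())
        assert s.selected_bands == ["delta", "theta", "gamma1"]
        assert s.selected_electrodes == ["F4", "F8", "C3", "CZ", "C4", "CP4", "T3", "T4"]
        reasons = {e["electrode"]: e["reason"] for e in s.exclusion_log}
        assert "FP1" in reasons and "ocular" in reasons["FP1"]

    def test_monotone_in_alpha_with_fixed_bands(self):
        # with a free band set, raising alpha can retain extra bands and so
        # add constraints; monotonicity is guaranteed for a fixed band set
        kw, spread = ref.kw_table(), ref.spread_table()
        fixed = ("delta", "theta", "gamma1")
        prev: set = set()
        for alpha in (0.01, 0.05, 0.2, 0.5):
            got = set(
                sel.select_features(
                    kw, alpha=alpha, spread=spread, bands=fixed
                ).selected_electrodes
            )
            assert prev <= got
            prev = got

    def test_empty_selection_warns(self):
        pv = pd.DataFrame({"delta": [0.9, 0.8], "theta": [0.7, 0.6]}, index=["C3", "C4"])
        with pytest.warns(UserWarning, match="no band"):
            s = sel.select_features(sel.KWTable(pvalues=pv))
        assert s.selected_bands == [] and s.selected_electrodes == []

    def test_degenerate_fails_without_spread(self):
        pv = pd.DataFrame(
            {"delta": [0.01, 0.01, np.nan], "theta": [0.01, 0.2, 0.01]},
            index=["C3", "C4", "CZ"],
        )
        s = sel.select_features(
            sel.KWTable(pvalues=pv), min_electrode_fraction=0.5, manual_exclusions=()
        )
        assert s.selected_electrodes == ["C3"]

    def test_bonferroni_option(self):
        kw = ref.kw_table()
        plain = set(sel.select_features(kw, spread=ref.spread_table()).selected_electrodes)
        bonf = set(
            sel.select_features(kw, spread=ref.spread_table(), bonferroni=True).selected_electrodes
        )
        assert bonf <= plain
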