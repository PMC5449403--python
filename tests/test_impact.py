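"""Response-group assignment, K-point detection and indicator validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import vegextent as vx
from vegextent.impact import (
    GroupParams,
    StabilizationParams,
    crossing_interval,
    detect_stabilization,
)
from vegextent.importance import IIVTable


def brute_force_stabilization_scan(series, distances, far_window=3, tol=0.15):
    """Independent oracle: try every candidate start, keep the smallest."""
    ref = np.mean(series[-far_window:])
    lo, hi = ref - tol * abs(ref), ref + tol * abs(ref)
    for i, d in enumerate(distances):
        if all(lo <= v <= hi for v in series[i:]):
            return d
    return None


class TestAssignGroups:
    def test_reference_table_maps_clusters_to_groups_in_order(
            self, table1_iiv, s1_layout):
        ga = vx.assign_groups(table1_iiv, s1_layout)
        assert ga.mapping == {"Cluster 1": "G1", "Cluster 2": "G2",
                              "Cluster 3": "G3"}

    def test_constant_trajectory_is_accompanying(self, s1_layout):
        ids = [t.transect_id for t in s1_layout]
        iiv = IIVTable({"c": ["x"]},
                       pd.DataFrame([[0.4] * len(ids)], index=["c"], columns=ids))
        ga = vx.assign_groups(iiv, s1_layout)
        assert ga.mapping == {"c": "G3"}

    @pytest.mark.parametrize("seed", range(6))
    def test_rule_matches_independent_predicate_evaluation(self, seed, s1_layout):
        rng = np.random.default_rng(seed)
        ids = [t.transect_id for t in s1_layout]
        n_cl = 4
        table = pd.DataFrame(rng.random((n_cl, len(ids))) * 0.5,
                             index=[f"c{i}" for i in range(n_cl)], columns=ids)
        iiv = IIVTable({f"c{i}": [f"s{i}"] for i in range(n_cl)}, table)
        p = GroupParams()
        ga = vx.assign_groups(iiv, s1_layout, p)

        dist = sorted((t for t in s1_layout if t.zone is vx.Zone.DISTANCE),
                      key=lambda t: t.distance_m)
        near = [t.transect_id for t in s1_layout
                if t.zone in (vx.Zone.PIPELINE_AREA, vx.Zone.INTER_PIPELINE)
                or (t.zone is vx.Zone.DISTANCE
                    and t.distance_m <= p.near_max_distance_m)]
        far = [t.transect_id for t in dist][-p.far_window:]
        for label in table.index:
            nm = table.loc[label, near].mean()
            fm = table.loc[label, far].mean()
            rho = stats.spearmanr([t.distance_m for t in dist],
                                  table.loc[label, [t.transect_id for t in dist]])[0]
            if nm >= p.ratio * fm and nm >= p.dominance_floor and rho <= -p.trend_rho:
                expected = "G1"
            elif fm >= p.ratio * nm and fm >= p.dominance_floor and rho >= p.trend_rho:
                expected = "G2"
            else:
                expected = "G3"
            assert ga.mapping[label] == expected

    def test_scale_equivariance(self, table1_iiv, s1_layout):
        scaled = IIVTable(table1_iiv.clusters, table1_iiv.IIV * 0.37)
        a = vx.assign_groups(table1_iiv, s1_layout).mapping
        b = vx.assign_groups(scaled, s1_layout).mapping
        assert a == b

    def test_needs_distance_transects(self, table1_iiv):
        corridor_only = [t for t in vx.table1_layout()
                         if t.zone is not vx.Zone.DISTANCE]
        with pytest.raises(ValueError):
            vx.assign_groups(table1_iiv, corridor_only)


class TestDetectStabilization:
    DISTANCES = [10.0, 30.0, 50.0, 100.0, 300.0, 500.0, 800.0, 1000.0]

    def test_constant_series_settles_immediately(self):
        res = detect_stabilization([0.3] * 8, self.DISTANCES)
        assert res.K == 10.0 and res.resolved

    def test_reference_indicator_cluster_settles_at_100m(self, table1_iiv):
        series = table1_iiv.IIV.loc[
            "Cluster 2", ["10m", "30m", "50m", "100m", "300m",
                          "500m", "800m", "1000m"]].to_numpy()
        res = detect_stabilization(series, self.DISTANCES)
        assert res.K == 100.0
        assert res.K == brute_force_stabilization_scan(list(series), self.DISTANCES)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_scan_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        series = rng.random(8)
        res = detect_stabilization(series, self.DISTANCES)
        expected = brute_force_stabilization_scan(list(series), self.DISTANCES)
        assert res.K == expected
        assert res.resolved == (expected is not None)

    def test_rising_series_entering_band_only_at_last_point(self):
        # against an external far-field reference (e.g. CK plots), a
        # strictly rising trajectory that reaches the band only at the
        # outermost transect settles exactly there
        series = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.95]
        res = detect_stabilization(series, self.DISTANCES, reference=1.0)
        assert res.K == 1000.0

    def test_tightening_the_band_never_moves_K_inward(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            series = rng.random(8)
            ks = []
            for tol in (0.5, 0.3, 0.15, 0.05):
                r = detect_stabilization(series, self.DISTANCES,
                                         StabilizationParams(tolerance=tol))
                ks.append(np.inf if r.K is None else r.K)
            assert all(a <= b for a, b in zip(ks, ks[1:]))

    def test_zero_reference_with_signal_is_an_error(self):
        with pytest.raises(ValueError, match="reference"):
            detect_stabilization([0.5, 0.2, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
                                 self.DISTANCES)

    def test_external_reference_is_respected(self):
        series = [0.5, 0.45, 0.42, 0.41, 0.4, 0.4, 0.4, 0.4]
        res = detect_stabilization(series, self.DISTANCES, reference=0.4)
        assert res.K == brute_force_stabilization_scan(series, self.DISTANCES)


class TestCrossingInterval:
    def test_reference_table_crossover_is_50_to_100(self, table1_iiv):
        order = table1_iiv.transects
        res = crossing_interval(table1_iiv.IIV.loc["Cluster 1", order],
                                table1_iiv.IIV.loc["Cluster 2", order],
                                [0, 0, 0, 0, 0, 10, 30, 50, 100, 300, 500,
                                 800, 1000])
        assert res.as_tuple() == (50.0, 100.0)
        assert not res.empty and not res.warnings

    def test_g2_dominant_everywhere_is_empty_with_flag(self):
        res = crossing_interval([0.1, 0.1, 0.1], [0.5, 0.5, 0.5], [10, 30, 50])
        assert res.empty and res.dominant == "G2"

    def test_g1_dominant_everywhere_is_empty_with_flag(self):
        res = crossing_interval([0.5, 0.5, 0.5], [0.1, 0.1, 0.1], [10, 30, 50])
        assert res.empty and res.dominant == "G1"

    def test_alternating_series_returns_first_crossing_with_warning(self):
        g1 = [0.5, 0.1, 0.5, 0.1]
        g2 = [0.1, 0.5, 0.1, 0.5]
        res = crossing_interval(g1, g2, [10, 30, 50, 100])
        assert res.as_tuple() == (10.0, 30.0)
        assert res.warnings

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            crossing_interval([1, 2], [1, 2, 3], [10, 30, 50])


class TestEffectExtent:
    def test_reference_table_headline_numbers(self, table1_iiv, s1_layout):
        ga = vx.assign_groups(table1_iiv, s1_layout)
        est = vx.effect_extent(table1_iiv, ga, s1_layout)
        assert est.K2.K == 100.0 and est.K2.resolved
        assert est.K3.as_tuple() == (50.0, 100.0)
        assert est.K1 is not None

    def test_no_indicator_group_is_an_error(self, table1_iiv, s1_layout):
        ga = vx.assign_groups(table1_iiv, s1_layout)
        ga.mapping = {c: "G3" for c in ga.mapping}
        with pytest.raises(ValueError, match="no indicator group"):
            vx.effect_extent(table1_iiv, ga, s1_layout)

    def test_null_scenario_has_no_indicator_group(self):
        cfg = vx.load_preset("null", seed=0)
        ds = vx.generate(cfg)
        iv = vx.importance_values(ds)
        iiv = vx.integrated_iv(iv, {"all": list(iv.species)})
        ga = vx.assign_groups(iiv, cfg.layout)
        assert set(ga.mapping.values()) == {"G3"}
        with pytest.raises(ValueError, match="no indicator group"):
            vx.effect_extent(iiv, ga, cfg.layout)


class TestIndicatorCorrelation:
    def test_collinear_series_attain_smallest_p(self):
        x = np.arange(10.0)
        r, p = vx.indicator_correlation(x, 2 * x + 1, n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_pearson_matches_hand_formula_on_five_points(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 3.0, 3.0, 6.0, 7.0])
        sx, sy = x - x.mean(), y - y.mean()
        expected = (sx * sy).sum() / np.sqrt((sx**2).sum() * (sy**2).sum())
        r, _ = vx.indicator_correlation(x, y, n_perm=99, seed=1)
        assert r == pytest.approx(expected, abs=1e-12)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(5)
        x, y = rng.random(20), rng.random(20)
        assert (vx.indicator_correlation(x, y, 499, seed=7)
                == vx.indicator_correlation(x, y, 499, seed=7))

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            vx.indicator_correlation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_indicator_group_tracks_cover_on_synthetic_survey(self):
        # the suppressed-dominant group's IIV should correlate positively
        # with community percent cover across transects
        cfg = vx.load_preset("s1_like", seed=11)
        ds = vx.generate(cfg)
        iv = vx.importance_values(ds)
        truth = {}
        for a in cfg.archetypes:
            truth.setdefault(a.role, []).append(a.name)
        iiv = vx.integrated_iv(iv, {"dom": truth["original_dominant"]})
        cover = [vx.percent_cover(ds, t) for t in iiv.transects]
        r, p = vx.indicator_correlation(iiv.IIV.loc["dom"], cover,
                                        n_perm=999, seed=2)
        assert r > 0
        assert p < 0.05
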