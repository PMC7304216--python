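import numpy as np
import pytest

from comorbmap.hotspot import (classify, cluster_values, distance_band_weights,
                               gi_star, hotspots, knn_weights,
                               tabulate_by_region, HotspotResult)
from comorbmap.synthetic import SimulationConfig, simulate_dataset

import pandas as pd


def gi_star_bruteforce(x, W):
    """Independent double-loop implementation of the Gi* statistic."""
    n = len(x)
    xbar = sum(x) / n
    s = (sum(v * v for v in x) / n - xbar ** 2) ** 0.5
    out = []
    for i in range(n):
        wi = sum(W[i][j] for j in range(n))
        num = sum(W[i][j] * x[j] for j in range(n)) - xbar * wi
        w2 = sum(W[i][j] ** 2 for j in range(n))
        den = s * ((n * w2 - wi ** 2) / (n - 1)) ** 0.5
        out.append(num / den)
    return np.array(out)


class TestGiStar:
    def test_line_of_five_matches_loop_oracle(self):
        x = np.array([0.0, 0, 10, 0, 0])
        W = np.eye(5)
        for i in range(4):
            W[i, i + 1] = W[i + 1, i] = 1.0
        z = gi_star(x, W)
        assert np.max(np.abs(z - gi_star_bruteforce(x, W))) < 1e-12
        assert z[2] > 0 and z[2] == max(z)

    def test_random_inputs_match_loop_oracle(self):
        rng = np.random.default_rng(5)
        for n in (3, 10, 50):
            x = rng.normal(size=n)
            W = (rng.random((n, n)) < 0.3).astype(float)
            np.fill_diagonal(W, 1.0)
            assert np.max(np.abs(gi_star(x, W) - gi_star_bruteforce(x, W))) < 1e-10

    def test_all_equal_values_give_zero(self):
        with pytest.warns(UserWarning, match="all values equal"):
            z = gi_star(np.full(6, 2.5), np.eye(6))
        assert np.all(z == 0)

    def test_two_clusters_identity_weights_antisymmetric(self):
        z = gi_star(np.array([0.0, 1.0]), np.eye(2))
        assert z[0] == pytest.approx(-z[1])
        assert z[1] > 0

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=20)
        W = (rng.random((20, 20)) < 0.4).astype(float)
        np.fill_diagonal(W, 1.0)
        assert np.allclose(gi_star(x, W), gi_star(3.2 * x + 7.0, W), atol=1e-10)

    def test_zero_weight_row_rejected(self):
        W = np.eye(3)
        W[1] = 0.0
        with pytest.raises(ValueError, match="all-zero weights"):
            gi_star(np.arange(3.0), W)


class TestClassify:
    @pytest.mark.parametrize("z,expected", [(2.5, "high"), (0.0, "insignificant"),
                                            (-3.1, "low"), (1.0, "insignificant")])
    def test_classes(self, z, expected):
        p, cls = classify(np.array([z]))
        assert cls[0] == expected
        if expected != "insignificant":
            assert p[0] < 0.05

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            classify(np.array([1.0]), alpha=1.5)


class TestWeights:
    def test_knn_self_weight_and_count(self):
        rng = np.random.default_rng(0)
        lon, lat = rng.uniform(30, 40, 30), rng.uniform(5, 12, 30)
        W = knn_weights(lon, lat, k=4)
        assert np.all(np.diag(W) == 1.0)
        assert np.all(W.sum(axis=1) == 5.0)  # self + 4 neighbours

    def test_knn_k_too_large(self):
        with pytest.raises(ValueError):
            knn_weights(np.zeros(3), np.zeros(3), k=3)

    def test_distance_band_includes_self(self):
        W = distance_band_weights(np.array([0.0, 1.0]), np.array([0.0, 0.0]),
                                  band_km=50)
        assert np.array_equal(W, np.eye(2))


class TestRegionTabulation:
    def _result(self, classes, regions):
        t = pd.DataFrame({"value": np.zeros(len(classes)), "region_id": regions,
                          "lon": 0.0, "lat": 0.0, "z": 0.0, "p": 1.0,
                          "cls": classes},
                         index=pd.Index([f"c{i}" for i in range(len(classes))],
                                        name="cluster_id"))
        return HotspotResult(table=t, alpha=0.05)

    def test_single_region_counts(self):
        res = self._result(["high", "low", "insignificant", "insignificant"],
                           ["R"] * 4)
        tab = tabulate_by_region(res)
        assert tab.iloc[0][["overall", "high", "low", "insignificant"]].tolist() \
            == [4, 1, 1, 2]

    def test_counts_partition_on_random_syntheses(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = rng.integers(2, 40)
            classes = rng.choice(["high", "low", "insignificant"], n)
            regions = rng.choice(["A", "B", "C"], n)
            tab = tabulate_by_region(self._result(classes, regions))
            assert (tab["high"] + tab["low"] + tab["insignificant"]
                    == tab["overall"]).all()

    def test_planted_hotspot_region_detected(self, lattice):
        hits = 0
        for rep in range(3):
            cfg = SimulationConfig(seed=100 + rep, planted_region="Tigray",
                                   planted_effect=1.0)
            ds, _ = simulate_dataset(cfg, lattice)
            res = hotspots(ds)
            high = res.table.loc[res.table["cls"] == "high", "region_id"]
            if len(high) and high.value_counts().idxmax() == "Tigray":
                hits += 1
        assert hits == 3

    def test_cluster_values_kinds(self, default_sim):
        ds, _ = default_sim
        for kind in ("mean_count", "any_illness", "multi_illness"):
            cv = cluster_values(ds, kind)
            assert np.all(np.isfinite(cv["value"]))
        assert (cluster_values(ds, "any_illness")["value"]
                >= cluster_values(ds, "multi_illness")["value"]).all()
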