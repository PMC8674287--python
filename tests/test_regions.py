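import numpy as np
import pandas as pd
import pytest

from florahom.checklists import PresenceData
from florahom.exceptions import CollinearityError, DomainError
from florahom.regions import (
    donor_score,
    endemic_proportion,
    faith_pd,
    hotspot_ranking,
    mean_homogenization,
    morans_i,
    region_regression,
    spatial_autocovariate,
)

from .oracles import brute_faith_pd, random_tree


def _pair_table(rows):
    frame = pd.DataFrame(rows, columns=["region_a", "region_b", "h_tax", "h_phyl"])
    frame["flag"] = ""
    return frame


class TestMeanHomogenization:
    def test_three_region_arithmetic(self):
        table = _pair_table(
            [("A", "B", 0.2, 0.0), ("A", "C", 0.4, 0.0), ("B", "C", 0.6, 0.0)]
        )
        means = mean_homogenization(table).set_index("region_id")
        assert means.loc["A", "mean_h_tax"] == pytest.approx(0.3)
        assert means.loc["B", "mean_h_tax"] == pytest.approx(0.4)
        assert means.loc["C", "mean_h_tax"] == pytest.approx(0.5)

    def test_all_zero(self):
        table = _pair_table([("A", "B", 0.0, 0.0)])
        means = mean_homogenization(table)
        assert (means["mean_h_tax"] == 0).all()

    def test_flagged_pairs_excluded(self):
        table = _pair_table(
            [("A", "B", 0.2, 0.0), ("A", "C", np.nan, np.nan)]
        )
        table.loc[1, "flag"] = "undefined_similarity"
        means = mean_homogenization(table).set_index("region_id")
        assert means.loc["A", "mean_h_tax"] == pytest.approx(0.2)
        assert means.loc["A", "n_flagged"] == 1


class TestFloraScores:
    @pytest.fixture
    def presence(self):
        # 4 regions, 5 species
        native = np.array(
            [
                [1, 1, 1, 0, 0],
                [1, 0, 0, 1, 0],
                [0, 0, 0, 1, 1],
                [1, 0, 0, 0, 0],
            ],
            dtype=bool,
        )
        naturalized = np.array(
            [
                [0, 0, 0, 1, 0],
                [0, 1, 0, 0, 0],
                [1, 1, 0, 0, 0],
                [0, 0, 0, 1, 1],
            ],
            dtype=bool,
        )
        return PresenceData(
            regions=["A", "B", "C", "D"],
            species=["s1", "s2", "s3", "s4", "s5"],
            native=native,
            naturalized=naturalized,
        )

    def test_donor_score(self, presence):
        # A's natives: s1 (naturalized in C), s2 (in B and C), s3 (nowhere)
        assert donor_score(presence, "A") == pytest.approx((1 + 2 + 0) / 3)

    def test_donor_score_zero(self, presence):
        # C's natives: s4 (naturalized in A and D), s5 (in D)
        assert donor_score(presence, "C") == pytest.approx((2 + 1) / 2)
        bounded = donor_score(presence, "C")
        assert 0 <= bounded <= len(presence.regions) - 1

    def test_endemic_proportion(self, presence):
        # A: s1 shared with B,D; s2 unique; s3 unique -> 2/3
        assert endemic_proportion(presence, "A") == pytest.approx(2 / 3)
        # D: s1 shared -> 0
        assert endemic_proportion(presence, "D") == 0.0


class TestFaithPD:
    def test_examples(self, toy_tree):
        assert faith_pd(toy_tree, {"s1", "s2", "s3", "s4"}) == pytest.approx(6.0)
        assert faith_pd(toy_tree, {"s1"}) == pytest.approx(2.0)
        assert faith_pd(toy_tree, {"s1", "s3"}) == pytest.approx(4.0)

    def test_monotone(self, toy_tree):
        assert faith_pd(toy_tree, {"s1"}) <= faith_pd(toy_tree, {"s1", "s2"})

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(21)
        for k in range(30):
            n_tips = int(rng.integers(4, 13))
            tree = random_tree(100 + k, n_tips)
            labels = [f"t{i + 1}" for i in range(n_tips)]
            for _ in range(4):
                size = int(rng.integers(1, min(6, n_tips) + 1))
                flora = set(rng.choice(labels, size=size, replace=False))
                assert faith_pd(tree, flora) == pytest.approx(
                    brute_faith_pd(tree, flora)
                )


class TestSpatialAutocovariate:
    def test_constant_response(self):
        coords = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], float)
        out = spatial_autocovariate(coords, np.full(4, 3.3))
        assert np.allclose(out, 3.3)

    def test_two_regions_swap(self):
        coords = np.array([[0, 0], [10, 0]], float)
        out = spatial_autocovariate(coords, np.array([1.0, 5.0]))
        assert np.allclose(out, [5.0, 1.0])

    def test_hand_computed_weights(self):
        from florahom.geoclim import pairwise_geographic

        coords = np.array([[0, 0], [1, 0], [0, 2], [50, 50]], float)
        y = np.array([1.0, 2.0, 3.0, 4.0])
        D = pairwise_geographic(coords[:, 0], coords[:, 1])
        radius = D[D > 0].max() + 1
        out = spatial_autocovariate(coords, y, radius_km=radius)
        w = 1.0 / D[0, 1:]
        assert out[0] == pytest.approx((w * y[1:]).sum() / w.sum())

    def test_isolated_region_error(self):
        coords = np.array([[0, 0], [0.1, 0], [120, 0]], float)
        with pytest.raises(DomainError, match="radius"):
            spatial_autocovariate(coords, np.zeros(3), radius_km=100.0)


def _synthetic_summary(rng, n=60, beta=None, noise=0.05, coords=None):
    beta = beta or {}
    summary = pd.DataFrame(
        {
            "region_id": [f"r{i}" for i in range(n)],
            "native_richness": rng.integers(20, 2000, n),
            "naturalized_richness": rng.integers(5, 300, n),
            "native_pd": rng.uniform(10, 500, n),
            "naturalized_pd": rng.uniform(1, 100, n),
            "endemic_proportion": rng.uniform(0, 0.6, n),
            "donor_score": rng.uniform(0.1, 8.0, n),
            "area_km2": np.exp(rng.normal(9, 1.5, n)),
            "is_island": rng.random(n) < 0.3,
        }
    )
    X = np.column_stack(
        [
            np.log(summary["native_richness"]),
            np.log(summary["naturalized_richness"]),
            summary["endemic_proportion"],
            np.log(summary["donor_score"]),
            np.log(summary["area_km2"]),
            summary["is_island"].astype(float),
        ]
    )
    Xs = (X - X.mean(0)) / X.std(0)
    b = np.array(
        [
            beta.get("native_richness", -0.2),
            beta.get("naturalized_richness", 0.3),
            beta.get("endemic_proportion", 0.15),
            beta.get("donor_score", -0.1),
            beta.get("area_km2", -0.25),
            beta.get("is_island", -0.05),
        ]
    )
    summary["mean_h_tax"] = Xs @ b + noise * rng.standard_normal(n)
    summary["mean_h_phyl"] = summary["mean_h_tax"]
    return summary, b


class TestRegionRegression:
    def test_coverage_of_true_coefficients(self):
        rng = np.random.default_rng(31)
        coords = np.column_stack(
            [rng.uniform(-180, 180, 60), rng.uniform(-60, 60, 60)]
        )
        names = [
            "native_richness",
            "naturalized_richness",
            "endemic_proportion",
            "donor_score",
            "area_km2",
            "is_island",
        ]
        covered = np.zeros(6)
        reps = 40
        for _ in range(reps):
            summary, b = _synthetic_summary(rng)
            res = region_regression(summary, coords, include_autocov=False)
            tab = res.table.set_index("term")
            for k, name in enumerate(names):
                lo, hi = tab.loc[name, ["ci_low", "ci_high"]]
                covered[k] += lo <= b[k] <= hi
        assert np.all(covered / reps >= 0.85)

    def test_zero_response(self):
        rng = np.random.default_rng(32)
        coords = np.column_stack(
            [rng.uniform(-180, 180, 30), rng.uniform(-60, 60, 30)]
        )
        summary, _ = _synthetic_summary(rng, n=30)
        summary["mean_h_tax"] = 0.0
        res = region_regression(summary, coords, include_autocov=False)
        assert np.allclose(res.table["estimate"], 0.0, atol=1e-10)

    def test_duplicate_predictor_collinearity(self):
        rng = np.random.default_rng(33)
        coords = np.column_stack(
            [rng.uniform(-180, 180, 30), rng.uniform(-60, 60, 30)]
        )
        summary, _ = _synthetic_summary(rng, n=30)
        summary["native_pd"] = summary["native_richness"]  # duplicate column
        with pytest.raises(CollinearityError):
            region_regression(
                summary,
                coords,
                predictors=[("native_richness", "log"), ("native_pd", "log")],
            )

    def test_log_positivity_guard(self):
        rng = np.random.default_rng(34)
        coords = np.column_stack(
            [rng.uniform(-180, 180, 30), rng.uniform(-60, 60, 30)]
        )
        summary, _ = _synthetic_summary(rng, n=30)
        summary.loc[0, "donor_score"] = 0.0
        with pytest.raises(DomainError, match="donor_score"):
            region_regression(summary, coords, include_autocov=False)

    def test_autocovariate_reduces_residual_autocorrelation(self):
        rng = np.random.default_rng(35)
        n = 80
        coords = np.column_stack(
            [rng.uniform(-180, 180, n), rng.uniform(-60, 60, n)]
        )
        summary, _ = _synthetic_summary(rng, n=n, noise=0.0)
        # inject a smooth spatial signal into the response
        from florahom.geoclim import pairwise_geographic

        D = pairwise_geographic(coords[:, 0], coords[:, 1])
        field = np.exp(-D / 3000.0) @ rng.standard_normal(n)
        summary["mean_h_tax"] = summary["mean_h_tax"] + 0.5 * (
            field - field.mean()
        ) / field.std()
        res_without = region_regression(summary, coords, include_autocov=False)
        res_with = region_regression(summary, coords, include_autocov=True)
        assert abs(res_with.moran_i_residuals) < abs(res_without.moran_i_residuals)


class TestHotspots:
    def test_ranking_order(self):
        summary = pd.DataFrame(
            {"region_id": ["a", "b", "c"], "mean_h_tax": [0.1, 0.5, 0.3]}
        )
        ranked = hotspot_ranking(summary)
        assert list(ranked["region_id"]) == ["b", "c", "a"]
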