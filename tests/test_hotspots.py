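import numpy as np
import pandas as pd
import pytest

from conftest import naive_gi_star
from ipcz.grid import GridSpec
from ipcz.hotspots import (
    GiStarResult,
    classify_tiers,
    composite,
    gi_star,
    normalize_layer,
    priority_areas,
    summarize_priority,
)


class TestNormalize:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([0, 5, 10], [0.0, 0.5, 1.0]),
            ([2, 4, 8], [0.0, 1 / 3, 1.0]),
            ([7, 7, 7], [0.0, 0.0, 0.0]),  # constant layer -> zeros
        ],
    )
    def test_min_max_scaling(self, values, expected):
        assert normalize_layer(np.array(values)) == pytest.approx(expected)

    def test_empty_layer_rejected(self):
        with pytest.raises(ValueError):
            normalize_layer(np.array([]))


class TestComposite:
    def test_expert_weighted_sum(self):
        out = composite("SE", {"ALL": np.array([0.5]), "TSP": np.array([1.0]), "CSM": np.array([0.0])})
        assert out[0] == pytest.approx(0.625)

    @pytest.mark.parametrize("value, expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_constant_inputs_map_to_constant(self, value, expected):
        layers = {k: np.full(4, value) for k in ("ALL", "TSP", "CSM")}
        assert composite("SE", layers) == pytest.approx(np.full(4, expected))

    def test_weights_not_summing_to_one_fatal(self):
        layers = {"ALL": np.ones(2), "TSP": np.ones(2), "CSM": np.ones(2)}
        with pytest.raises(ValueError, match="sum to 1"):
            composite("SE", layers, {"ALL": 0.5, "TSP": 0.5, "CSM": 0.1})

    def test_composite_is_linear_in_each_layer(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(size=30)
        zeros = np.zeros(30)
        out = composite("SE", {"ALL": a, "TSP": zeros, "CSM": zeros})
        assert out == pytest.approx(0.35 * a)


class TestGiStar:
    def test_constant_field_gives_zero_z_everywhere(self, small_spec):
        res = gi_star(np.full(small_spec.n_cells, 3.0), small_spec)
        assert np.all(res.z == 0)
        assert set(res.tier) == {"not_significant"}

    def test_single_spike_center_matches_hand_formula(self, small_spec):
        """5x5 grid, one 1 at the center: n=25, W=9, X=1/25, S=sqrt(24)/25."""
        x = np.zeros(25)
        x[12] = 1.0
        res = gi_star(x, small_spec)
        n, w = 25, 9
        xbar = 1 / 25
        s = np.sqrt(1 / 25 - xbar**2)
        expected = (1 - xbar * w) / (s * np.sqrt((n * w - w**2) / (n - 1)))
        assert res.z[12] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("scheme", ["queen", "rook"])
    def test_vectorized_matches_naive_double_loop_oracle(self, scheme):
        spec = GridSpec(lat_min=0, lat_max=20, lon_min=100, lon_max=120)
        rng = np.random.default_rng(12)
        for _ in range(10):
            x = rng.gamma(1.0, 2.0, spec.n_cells) * (rng.random(spec.n_cells) < 0.4)
            res = gi_star(x, spec, scheme=scheme)
            assert np.abs(res.z - naive_gi_star(x, spec, scheme)).max() < 1e-10

    def test_mean_z_near_zero_under_spatial_randomness(self, small_spec):
        """Over seeded permutations of a fixed value set, the grand mean of z
        is ~0 (within 3 standard errors)."""
        spec = GridSpec(lat_min=0, lat_max=10, lon_min=100, lon_max=110)
        base = np.random.default_rng(0).gamma(2.0, 1.0, spec.n_cells)
        rng = np.random.default_rng(1)
        means = [gi_star(rng.permutation(base), spec).z.mean() for _ in range(200)]
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * max(se, 1e-12)

    def test_false_positive_rate_bounded_without_autocorrelation(self):
        """On permuted (spatially random) fields the hot99+cold99 fraction
        stays small — an upper bound, not a nominal rate, because the
        overlapping neighborhood weights correlate nearby scores."""
        spec = GridSpec(lat_min=0, lat_max=15, lon_min=100, lon_max=115)
        base = np.random.default_rng(3).gamma(2.0, 1.0, spec.n_cells)
        rng = np.random.default_rng(4)
        fracs = []
        for _ in range(200):
            res = gi_star(rng.permutation(base), spec)
            fracs.append((np.abs(res.z) >= 2.576).mean())
        assert np.mean(fracs) <= 0.05

    def test_occupied_background_restricts_support(self, small_spec):
        x = np.zeros(25)
        x[[6, 7, 8, 11, 12]] = [1, 2, 1, 3, 4.0]
        res = gi_star(x, small_spec, background="occupied")
        assert np.all(res.z[x == 0] == 0)
        assert np.any(res.z[x > 0] != 0)

    def test_degenerate_variance_flags_all_not_significant(self, small_spec):
        res = gi_star(np.zeros(25), small_spec, background="occupied")
        assert set(res.tier) == {"not_significant"}


class TestTiers:
    @pytest.mark.parametrize(
        "z, tier",
        [
            (1.95, "hot90"),  # the printed 90%-tier maximum sits below 1.96
            (2.53, "hot95"),  # the printed 95%-tier maximum sits below 2.576
            (2.576, "hot99"),
            (1.645, "hot90"),
            (1.644, "not_significant"),
            (-2.576, "cold99"),
            (-1.7, "cold90"),
            (0.0, "not_significant"),
        ],
    )
    def test_bin_edges(self, z, tier):
        assert classify_tiers(np.array([z]))[0] == tier

    def test_tier_areas_are_monotone(self, spec, occurrences):
        from ipcz.diversity import attach_cells, layer_metrics

        t = layer_metrics(attach_cells(occurrences, spec), spec)
        res = gi_star(normalize_layer(t["SE"]), spec, background="occupied")
        counts = res.tier_counts()
        h99 = counts["hot99"]
        h95 = h99 + counts["hot95"]
        h90 = h95 + counts["hot90"]
        assert h99 <= h95 <= h90

    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError):
            classify_tiers(np.zeros(3), thresholds=(2.0, 1.9, 2.5))


def _result(spec, hot_cells, metric):
    z = np.zeros(spec.n_cells)
    z[list(hot_cells)] = 3.0
    return GiStarResult(metric=metric, z=z, tier=classify_tiers(z), scheme="queen")


class TestPriorityAreas:
    def test_disjoint_singletons_union_to_three_sites(self, small_spec):
        results = [
            _result(small_spec, {0}, "SE"),
            _result(small_spec, {12}, "SR"),
            _result(small_spec, {24}, "SN"),
        ]
        mask = priority_areas(results, small_spec)
        assert set(mask.cells) == {0, 12, 24}
        assert mask.n_sites == 3

    def test_identical_hot_sets_are_idempotent(self, small_spec):
        results = [_result(small_spec, {5, 6}, m) for m in ("SE", "SR", "SN")]
        mask = priority_areas(results, small_spec)
        assert set(mask.cells) == {5, 6}
        assert mask.provenance[5] == ("SE", "SR", "SN")

    def test_sites_are_labeled_largest_first(self, small_spec):
        results = [
            _result(small_spec, {0, 1, 2}, "SE"),  # one 3-cell site
            _result(small_spec, {24}, "SR"),  # one singleton
            _result(small_spec, set(), "SN"),
        ]
        mask = priority_areas(results, small_spec)
        sites = mask.sites
        assert sites[0] == sites[1] == sites[2] == 1
        assert sites[24] == 2


class TestSummarize:
    def _tables(self, small_spec):
        occ = pd.DataFrame(
            {
                "species": [f"s{i}" for i in range(10)],
                "cell_id": [0, 0, 1, 1, 2, 5, 6, 7, 8, 9],
            }
        )
        thr = occ.head(4).copy()
        hab = pd.DataFrame({"habitat": ["coral", "seagrass", "mangrove"], "cell_id": [0, 0, 0]})
        return occ, thr, hab

    def test_empty_mask_is_all_zeros(self, small_spec):
        occ, thr, hab = self._tables(small_spec)
        mask = priority_areas([_result(small_spec, set(), m) for m in ("SE", "SR", "SN")], small_spec)
        s = summarize_priority(mask, occ, thr, hab, small_spec)
        assert s["records_in_mask"] == 0 and s["species_fraction"] == 0.0

    def test_whole_grid_mask_gives_unit_fractions(self, small_spec):
        occ, thr, hab = self._tables(small_spec)
        mask = priority_areas(
            [_result(small_spec, set(range(small_spec.n_cells)), m) for m in ("SE", "SR", "SN")],
            small_spec,
        )
        s = summarize_priority(mask, occ, thr, hab, small_spec)
        assert s["species_fraction"] == 1.0
        assert s["threatened_species_fraction"] == 1.0

    def test_species_fraction_counts_distinct_species_inside_mask(self, small_spec):
        occ, thr, hab = self._tables(small_spec)
        mask = priority_areas(
            [_result(small_spec, {0, 1}, "SE")] + [_result(small_spec, set(), m) for m in ("SR", "SN")],
            small_spec,
        )
        s = summarize_priority(mask, occ, thr, hab, small_spec)
        assert s["species_in_mask"] == 4
        assert s["species_fraction"] == pytest.approx(0.4)
        assert s["all_three_habitats_fraction"] == pytest.approx(0.5)
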