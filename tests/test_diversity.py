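import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipcz.diversity import (
    attach_cells,
    correlation_matrix,
    layer_metrics,
    occupancy_fraction,
    shannon_index,
)


def _records(spec, cells_species):
    """Build a record table from [(row, col, species), ...]."""
    rows = []
    for r, c, sp in cells_species:
        la0, la1, lo0, lo1 = spec.cell_bounds(r, c)
        rows.append({"species": sp, "lat": (la0 + la1) / 2, "lon": (lo0 + lo1) / 2})
    return pd.DataFrame(rows, columns=["species", "lat", "lon"])


class TestShannon:
    def test_single_species_has_zero_entropy(self):
        assert shannon_index(np.array([17])) == 0.0

    def test_hand_computed_three_species_cell(self):
        # counts {5, 3, 2}: -(0.5 ln 0.5 + 0.3 ln 0.3 + 0.2 ln 0.2)
        assert shannon_index(np.array([5, 3, 2])) == pytest.approx(1.02965, abs=1e-4)

    @given(k=st.integers(2, 30), m=st.integers(1, 50))
    @settings(max_examples=50, deadline=None)
    def test_equal_counts_reach_log_k_and_scaling_invariance(self, k, m):
        counts = np.full(k, 7)
        assert shannon_index(counts) == pytest.approx(np.log(k))
        assert shannon_index(counts * m) == pytest.approx(shannon_index(counts))


class TestLayerMetrics:
    def test_counts_and_entropy_per_cell(self, small_spec):
        recs = attach_cells(
            _records(small_spec, [(0, 0, "a")] * 5 + [(0, 0, "b")] * 3 + [(0, 0, "c")] * 2
                     + [(2, 2, "a")]),
            small_spec,
        )
        t = layer_metrics(recs, small_spec)
        cell = small_spec.cell_id(0, 0)
        assert t.loc[cell, "SE"] == 10
        assert t.loc[cell, "SR"] == 3
        assert t.loc[cell, "SN"] == pytest.approx(1.02965, abs=1e-4)
        lone = small_spec.cell_id(2, 2)
        assert t.loc[lone, ["SE", "SR", "SN"]].tolist() == [1, 1, 0.0]

    def test_empty_cells_are_flagged_and_zero(self, small_spec):
        t = layer_metrics(attach_cells(_records(small_spec, [(0, 0, "a")]), small_spec), small_spec)
        assert len(t) == small_spec.n_cells
        assert t["empty"].sum() == small_spec.n_cells - 1
        assert (t.loc[t["empty"], ["SE", "SR", "SN"]] == 0).all().all()

    def test_sn_bounded_by_log_richness_on_synthetic_layer(self, occurrences, spec):
        t = layer_metrics(attach_cells(occurrences, spec), spec)
        occupied = t[t["SE"] > 0]
        assert (occupied["SE"] >= occupied["SR"]).all()
        assert (occupied["SN"] <= np.log(occupied["SR"].clip(lower=1)) + 1e-9).all()
        assert (t.loc[t["SR"] <= 1, "SN"] == 0).all()

    def test_merging_disjoint_record_sets_adds_se_and_grows_sr(self, small_spec):
        a = attach_cells(_records(small_spec, [(1, 1, "a"), (1, 1, "b")]), small_spec)
        b = attach_cells(_records(small_spec, [(1, 1, "b"), (1, 1, "c")]), small_spec)
        merged = pd.concat([a, b], ignore_index=True)
        cell = small_spec.cell_id(1, 1)
        ta, tb, tm = (layer_metrics(x, small_spec) for x in (a, b, merged))
        assert tm.loc[cell, "SE"] == ta.loc[cell, "SE"] + tb.loc[cell, "SE"]
        assert tm.loc[cell, "SR"] >= max(ta.loc[cell, "SR"], tb.loc[cell, "SR"])

    def test_new_singleton_species_strictly_increases_richness(self, small_spec):
        base = _records(small_spec, [(0, 0, "a")] * 4)
        plus = pd.concat([base, _records(small_spec, [(0, 0, "z")])], ignore_index=True)
        cell = small_spec.cell_id(0, 0)
        t0 = layer_metrics(attach_cells(base, small_spec), small_spec)
        t1 = layer_metrics(attach_cells(plus, small_spec), small_spec)
        assert t1.loc[cell, "SR"] == t0.loc[cell, "SR"] + 1
        assert t1.loc[cell, "SN"] > t0.loc[cell, "SN"]


class TestOccupancy:
    def test_empty_and_full_layers(self, small_spec):
        empty = layer_metrics(attach_cells(_records(small_spec, []), small_spec), small_spec)
        assert occupancy_fraction(empty, small_spec) == 0.0
        everywhere = _records(
            small_spec, [(r, c, "a") for r in range(5) for c in range(5)]
        )
        full = layer_metrics(attach_cells(everywhere, small_spec), small_spec)
        assert occupancy_fraction(full, small_spec) == 1.0

    def test_fraction_is_occupied_over_total(self, small_spec):
        recs = _records(small_spec, [(0, 0, "a"), (1, 1, "b"), (2, 2, "c"), (3, 3, "d")])
        t = layer_metrics(attach_cells(recs, small_spec), small_spec)
        assert occupancy_fraction(t, small_spec) == pytest.approx(4 / 25)


class TestCorrelations:
    def _layers(self, small_spec, seed=0):
        rng = np.random.default_rng(seed)
        out = {}
        for name in ("ALL", "TSP", "CSM"):
            se = rng.poisson(3, small_spec.n_cells)
            out[name] = pd.DataFrame(
                {
                    "SE": se,
                    "SR": np.minimum(se, rng.poisson(2, small_spec.n_cells) + 1),
                    "SN": rng.uniform(0, 2, small_spec.n_cells) * (se > 0),
                    "empty": se == 0,
                }
            )
        return out

    def test_self_correlation_is_one_and_matrix_symmetric(self, small_spec):
        corr = correlation_matrix(self._layers(small_spec))
        assert np.allclose(np.diag(corr.r), 1.0)
        assert np.allclose(corr.r, corr.r.T, equal_nan=True)

    def test_anticorrelated_vectors_give_minus_one(self, small_spec):
        layers = self._layers(small_spec)
        layers["TSP"]["SE"] = 10 - layers["ALL"]["SE"]
        corr = correlation_matrix(layers, support="all_cells")
        assert corr.r.loc["ALL_SE", "TSP_SE"] == pytest.approx(-1.0)

    def test_r_matches_direct_covariance_formula_on_ten_cells(self, small_spec):
        layers = self._layers(small_spec, seed=5)
        corr = correlation_matrix(layers, support="all_cells")
        x = layers["ALL"]["SE"].to_numpy(float)
        y = layers["CSM"]["SN"].to_numpy(float)
        direct = ((x - x.mean()) * (y - y.mean())).mean() / (x.std() * y.std())
        assert corr.r.loc["ALL_SE", "CSM_SN"] == pytest.approx(direct)

    def test_zero_variance_vector_reported_missing(self, small_spec):
        layers = self._layers(small_spec)
        layers["CSM"]["SN"] = 0.0
        corr = correlation_matrix(layers, support="all_cells")
        assert np.isnan(corr.r.loc["CSM_SN", "ALL_SE"])

    def test_union_nonzero_support_smaller_than_all_cells(self, small_spec):
        layers = self._layers(small_spec)
        layers["TSP"].loc[:15, "SE"] = 0
        layers["ALL"].loc[10:, "SE"] = 0
        corr = correlation_matrix(layers, support="union_nonzero")
        assert corr.n.loc["ALL_SE", "TSP_SE"] < small_spec.n_cells
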