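"""Distance primitives and assembly of the modelling table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from naturadist.distance_engine import (
    bidirectional_distance,
    build_distance_table,
    great_circle_km,
    unidirectional_weighted_mean,
)
from naturadist.phylo import TreeIndex


class TestBidirectional:
    @pytest.mark.parametrize(
        "recipient, donors, areas, expected",
        [
            (5.0, [1.0], [7.0], 4.0),
            (2.0, [1.0, 3.0], [1.0, 1.0], 0.0),
            (0.0, [2.0, 4.0], [1.0, 3.0], -3.5),
        ],
    )
    def test_hand_cases(self, recipient, donors, areas, expected):
        assert bidirectional_distance(recipient, donors, areas) == pytest.approx(expected)

    def test_matches_pairwise_sum_oracle(self):
        """recipient - weighted donor mean == weighted mean of pairwise diffs."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            k = int(rng.integers(1, 8))
            donors = rng.normal(size=k)
            areas = rng.uniform(0.1, 10, size=k)
            recipient = rng.normal()
            oracle = float(np.sum(areas * (recipient - donors)) / np.sum(areas))
            got = bidirectional_distance(recipient, donors, areas)
            assert got == pytest.approx(oracle, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        donors=st.lists(st.floats(-50, 50), min_size=1, max_size=8),
        recipient=st.floats(-50, 50),
        data=st.data(),
    )
    def test_weight_cancellation_property(self, donors, recipient, data):
        """Equal areas reduce to the plain mean; the single-donor case is a
        plain difference regardless of the weight."""
        areas = data.draw(
            st.lists(
                st.floats(0.1, 1e6), min_size=len(donors), max_size=len(donors)
            )
        )
        if len(donors) == 1:
            got = bidirectional_distance(recipient, donors, areas)
            assert got == pytest.approx(recipient - donors[0], abs=1e-9)
        equal = bidirectional_distance(recipient, donors, [1.0] * len(donors))
        assert equal == pytest.approx(recipient - np.mean(donors), abs=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            bidirectional_distance(1.0, [], [])
        with pytest.raises(ValueError):
            bidirectional_distance(1.0, [1.0], [-1.0])
        with pytest.raises(ValueError):
            bidirectional_distance(np.nan, [1.0], [1.0])


class TestUnidirectional:
    def test_hand_cases(self):
        assert unidirectional_weighted_mean([0.2], [99.0]) == pytest.approx(0.2)
        assert unidirectional_weighted_mean([0.0, 1.0], [1.0, 1.0]) == pytest.approx(0.5)

    def test_convexity(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            k = int(rng.integers(1, 8))
            vals = rng.uniform(0, 1, size=k)
            areas = rng.uniform(0.1, 10, size=k)
            got = unidirectional_weighted_mean(vals, areas)
            assert vals.min() - 1e-12 <= got <= vals.max() + 1e-12

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            unidirectional_weighted_mean([-0.1], [1.0])


class TestGreatCircle:
    def test_closed_forms(self):
        assert great_circle_km(10.0, 20.0, 10.0, 20.0) == 0.0
        assert great_circle_km(0, 0, 90, 0) == pytest.approx(10_007.5, abs=0.1)
        assert great_circle_km(0, 0, 0, 180) == pytest.approx(20_015.1, abs=0.1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            great_circle_km(91.0, 0, 0, 0)


def _toy_world():
    """Three regions, two species; everything hand-computable."""
    import dendropy

    tree = dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")
    index = TreeIndex(tree)
    regions = pd.DataFrame(
        {
            "region_id": ["r1", "r2", "r3"],
            "area_km2": [100.0, 300.0, 50.0],
            "centroid_lat": [0.0, 10.0, -10.0],
            "centroid_lon": [0.0, 10.0, 20.0],
            "is_island": [False, False, True],
            "continent_id": ["c0", "c0", "c1"],
        }
    )
    flora = pd.DataFrame(
        {
            "region_id": ["r1", "r1", "r2", "r3", "r3"],
            "species_id": ["A", "B", "B", "C", "A"],
            "status": "native",
        }
    )
    region_climate = pd.DataFrame(
        {"region_id": ["r1", "r2", "r3"], "pc_temp": [1.0, 2.0, 4.0], "pc_prec": [0.5, 0.0, 1.0]}
    )
    region_hmi = {"r1": 0.2, "r2": 0.6, "r3": 0.4}
    region_resid = {"r1": 0.1, "r2": -0.2, "r3": 0.3}
    union_resid = {"A": 0.05, "B": -0.1, "C": 0.3}
    return index, regions, flora, region_climate, region_hmi, region_resid, union_resid


def test_row_count_and_candidate_exclusion():
    index, regions, flora, clim, hmi, rr, ur = _toy_world()
    table = build_distance_table(regions, flora, clim, hmi, rr, ur, index)
    # A native to r1,r3 -> 1 candidate; B native r1,r2 -> 1; C native r3 -> 2
    assert len(table) == 4
    for _, row in table.iterrows():
        natives = set(flora[flora["species_id"] == row["species_id"]]["region_id"])
        assert row["recipient_region_id"] not in natives


def test_flora_pd_distance_uses_union_residual():
    index, regions, flora, clim, hmi, rr, ur = _toy_world()
    table = build_distance_table(regions, flora, clim, hmi, rr, ur, index)
    t = table.set_index(["species_id", "recipient_region_id"])
    # species A: recipient r2; union residual 0.05 -> single subtraction
    assert t.loc[("A", "r2"), "d_flora_pd"] == pytest.approx(-0.2 - 0.05)
    # per-donor mode instead averages the per-region residual differences
    table2 = build_distance_table(
        regions, flora, clim, hmi, rr, ur, index, flora_distance_mode="per_donor"
    )
    t2 = table2.set_index(["species_id", "recipient_region_id"])
    expected = (100.0 * (-0.2 - 0.1) + 50.0 * (-0.2 - 0.3)) / 150.0
    assert t2.loc[("A", "r2"), "d_flora_pd"] == pytest.approx(expected)


def test_hand_computed_bidirectional_row():
    index, regions, flora, clim, hmi, rr, ur = _toy_world()
    table = build_distance_table(regions, flora, clim, hmi, rr, ur, index)
    t = table.set_index(["species_id", "recipient_region_id"])
    # species B donors r1 (area 100), r2 (area 300); recipient r3
    w_mean_temp = (100 * 1.0 + 300 * 2.0) / 400
    assert t.loc[("B", "r3"), "d_pc_temp"] == pytest.approx(4.0 - w_mean_temp)
    w_mean_hmi = (100 * 0.2 + 300 * 0.6) / 400
    assert t.loc[("B", "r3"), "d_hmi"] == pytest.approx(0.4 - w_mean_hmi)


def test_single_donor_swap_negates_bidirectional_keeps_unidirectional():
    """Swapping the donor and recipient roles of two regions for a
    single-donor species negates every signed distance and preserves the
    unidirectional ones."""
    index, regions, flora, clim, hmi, rr, ur = _toy_world()
    # world 1: C native only to r3 (recipient r1); world 2: C native only to r1
    flora_a = flora[~((flora["species_id"] == "C"))]
    flora_a = pd.concat(
        [flora_a, pd.DataFrame({"region_id": ["r3"], "species_id": ["C"], "status": "native"})],
        ignore_index=True,
    )
    flora_b = pd.concat(
        [
            flora[flora["species_id"] != "C"],
            pd.DataFrame({"region_id": ["r1"], "species_id": ["C"], "status": "native"}),
        ],
        ignore_index=True,
    )
    ur_a = dict(ur, C=rr["r3"])  # union of one region = that region's residual
    ur_b = dict(ur, C=rr["r1"])
    ta = build_distance_table(regions, flora_a, clim, hmi, rr, ur_a, index).set_index(
        ["species_id", "recipient_region_id"]
    )
    tb = build_distance_table(regions, flora_b, clim, hmi, rr, ur_b, index).set_index(
        ["species_id", "recipient_region_id"]
    )
    for col in ("d_pc_temp", "d_pc_prec", "d_hmi", "d_flora_pd"):
        assert ta.loc[("C", "r1"), col] == pytest.approx(-tb.loc[("C", "r3"), col])
    assert ta.loc[("C", "r1"), "d_geo"] == pytest.approx(tb.loc[("C", "r3"), "d_geo"])


def test_outcome_marking():
    index, regions, flora, clim, hmi, rr, ur = _toy_world()
    outcomes = pd.DataFrame(
        {"species_id": ["A"], "recipient_region_id": ["r2"], "outcome": [1]}
    )
    table = build_distance_table(regions, flora, clim, hmi, rr, ur, index, outcomes=outcomes)
    t = table.set_index(["species_id", "recipient_region_id"])
    assert t.loc[("A", "r2"), "outcome"] == 1
    assert t["outcome"].sum() == 1


def test_row_count_formula(small_world):
    from naturadist.climate_pca import fit_pca, transform_scores, region_pc_means
    from naturadist.flora_diversity import area_correction, donor_union_metrics, region_diversity

    w = small_world
    index = TreeIndex(w.phylogeny.tree)
    model = fit_pca(w.cells)
    clim = region_pc_means(transform_scores(model, w.cells), w.regions["region_id"])
    reg = region_diversity(w.flora, w.regions, index)
    uni = donor_union_metrics(w.flora, w.regions, index)
    records = pd.concat([reg, uni], ignore_index=True)
    _, resid = area_correction(records, metric="faith_pd")
    records["resid"] = resid
    rr = records[records["unit_type"] == "region"].set_index("unit_id")["resid"].to_dict()
    ur = records[records["unit_type"] == "donor_union"].set_index("unit_id")["resid"].to_dict()
    hmi = w.cells.groupby("region_id")["hmi"].mean().to_dict()
    table = build_distance_table(w.regions, w.flora, clim, hmi, rr, ur, index)
    n_regions = len(w.regions)
    native_counts = w.flora.groupby("species_id")["region_id"].nunique()
    expected = int((n_regions - native_counts).sum())
    # rows with undefined distances (regions lacking native flora) are dropped
    assert len(table) <= expected
    assert table["d_phylo_dissim"].between(0, 1).all()
    assert (table["d_geo"] >= 0).all()
    if len(table) < expected:
        empty_regions = set(w.regions["region_id"]) - set(w.flora["region_id"])
        assert empty_regions
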