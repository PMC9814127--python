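"""Protected-area overlay, designation precedence and protection summaries."""

import pytest
from shapely.geometry import box

from cwrgap.errors import ValidationError
from cwrgap.occurrence_io import LayerFeature, OccurrenceRecord, PolygonLayer
from cwrgap.spatial_overlay import (aggregate_counts, assign_sites, percent,
                                    summarize_counts, summarize_protection)
from cwrgap.synthetic_data import published_tables


def _rec(rid, lon, lat, species="montana"):
    return OccurrenceRecord(rid, "Brassica", species, lat=lat, lon=lon)


def _sites_layer(feats):
    return PolygonLayer("protected_sites", feats, "planar-km synthetic")


OVERLAPPING = _sites_layer([
    LayerFeature({"site_code": "S2", "site_name": "a", "site_type": "A"},
                 box(0, 0, 10, 10)),
    LayerFeature({"site_code": "S1", "site_name": "c", "site_type": "C"},
                 box(5, 5, 15, 15)),
    LayerFeature({"site_code": "S3", "site_name": "b", "site_type": "B"},
                 box(20, 20, 30, 30)),
])


def test_single_site_assignment():
    [a] = assign_sites([_rec("x", 25, 25)], OVERLAPPING)
    assert a.inside_network and a.site_type == "B" and a.site_code == "S3"


def test_outside_assignment_has_no_site_fields():
    [a] = assign_sites([_rec("x", 50, 50)], OVERLAPPING)
    assert not a.inside_network
    assert a.site_code is None and a.site_type is None


def test_overlap_precedence_c_over_a():
    [a] = assign_sites([_rec("x", 7, 7)], OVERLAPPING)  # inside both A and C
    assert a.site_type == "C" and a.site_code == "S1"


def test_tie_within_type_smallest_code():
    layer = _sites_layer([
        LayerFeature({"site_code": "S9", "site_name": "n", "site_type": "B"},
                     box(0, 0, 10, 10)),
        LayerFeature({"site_code": "S2", "site_name": "n", "site_type": "B"},
                     box(0, 0, 10, 10)),
    ])
    [a] = assign_sites([_rec("x", 5, 5)], layer)
    assert a.site_code == "S2"


def test_assignment_matches_generator_bookkeeping(qc_chain, synthetic_world):
    _, world, _, truth = synthetic_world
    kept = qc_chain["kept"]
    assignments = assign_sites(kept, world.protected_sites,
                               world.admin_regions, world.biogeo_regions)
    assert len(assignments) == len(kept)
    for a in assignments:
        rt = truth.per_record[a.record_id]
        if rt.expected_snap:
            continue  # repositioned onto the coast; original membership moot
        assert a.inside_network == rt.inside_sites
        if a.inside_network:
            assert a.site_code == rt.site_code
        assert a.biogeo_region is not None


# --- integer percentages -----------------------------------------------------

def test_percent_reproduces_all_printed_priority_percentages():
    fx = published_tables()
    for row in fx.table3.values():
        assert percent(row.within_n, row.populations) == row.within_pct_printed


@pytest.mark.parametrize("n,total,expected", [
    (33, 44, 75), (38, 61, 62), (0, 3, 0), (10, 15, 67), (1, 2, 50),
])
def test_percent_half_away_from_zero(n, total, expected):
    assert percent(n, total) == expected


def test_percent_undefined_for_zero_total():
    with pytest.raises(ValidationError):
        percent(0, 0)


# --- summaries ---------------------------------------------------------------

def test_genus_summary_from_priority_table():
    fx = published_tables()
    counts = {s: (r.populations, r.within_n) for s, r in fx.table3.items()}
    genus = summarize_counts(
        aggregate_counts(counts, lambda s: fx.table3[s].genus), "genus")
    assert genus.rows["Allium"] == (61, 38, 62)
    assert genus.rows["Brassica"] == (141, 83, 59)
    assert genus.rows["Triticum"] == (7, 4, 57)


def test_species_percentages_span_printed_range():
    fx = published_tables()
    brassica = [r.within_pct_printed for r in fx.table3.values()
                if r.genus == "Brassica"]
    assert min(brassica) == 26 and max(brassica) == 100


def test_group_totals_conserved_for_any_partition(qc_chain, synthetic_world):
    _, world, _, _ = synthetic_world
    kept = qc_chain["kept"]
    assignments = assign_sites(kept, world.protected_sites,
                               world.admin_regions, world.biogeo_regions)
    for key in ("species", "genus", "biogeo_region"):
        table = summarize_protection(assignments, kept, key)
        assert sum(t for t, _, _ in table.rows.values()) == len(kept)


def test_site_type_breakdown_among_inside_only(qc_chain, synthetic_world):
    _, world, _, _ = synthetic_world
    kept = qc_chain["kept"]
    assignments = assign_sites(kept, world.protected_sites)
    n_inside = sum(a.inside_network for a in assignments)
    table = summarize_protection(assignments, kept, "site_type")
    assert sum(i for _, i, _ in table.rows.values()) == n_inside
    assert all(t == n_inside for t, _, _ in table.rows.values())


def test_single_record_inside_is_100_percent():
    layer = _sites_layer([LayerFeature(
        {"site_code": "S1", "site_name": "n", "site_type": "B"}, box(0, 0, 10, 10))])
    recs = [_rec("x", 5, 5)]
    table = summarize_protection(assign_sites(recs, layer), recs, "species")
    assert list(table.rows.values()) == [(1, 1, 100)]


def test_all_inside_when_fraction_is_one():
    from cwrgap.synthetic_data import (SyntheticConfig, make_world,
                                       simulate_occurrences)
    cfg = SyntheticConfig(seed=9, n_species=2, records_per_species=8,
                          fraction_inside_sites=1.0,
                          defect_rates=tuple((d, 0.0) for d, _ in
                                             SyntheticConfig().defect_rates))
    world = make_world(cfg)
    records, _ = simulate_occurrences(cfg, world)
    in_situ = [r for r in records if r.conservation_side == "in_situ"]
    assignments = assign_sites(in_situ, world.protected_sites)
    table = summarize_protection(assignments, in_situ, "species")
    assert all(p == 100 for _, _, p in table.rows.values())
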