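"""QC cascade: precision rule, thresholds, dedup and spatial consistency."""

import random

import numpy as np
import pytest
from shapely.geometry import LineString, Polygon

from cwrgap.errors import ValidationError
from cwrgap.occurrence_io import LayerFeature, OccurrenceRecord, PolygonLayer
from cwrgap.qc_filter import (FilterConfig, apply_attribute_filters,
                              count_decimal_digits, deduplicate,
                              spatial_consistency)

CRS = "planar-km synthetic"


def _rec(rid, lat=45.12345, lon=9.12345, **kw):
    defaults = dict(genus="Brassica", species_epithet="montana",
                    lat=lat, lon=lon,
                    lat_text=None if lat is None else f"{lat}",
                    lon_text=None if lon is None else f"{lon}")
    defaults.update(kw)
    return OccurrenceRecord(rid, **defaults)


@pytest.mark.parametrize("text,digits", [
    ("38.12", 2), ("38.120", 3), ("-12", 0), ("0.1", 1), ("+41.00000", 5),
])
def test_decimal_digits_counted_as_written(text, digits):
    assert count_decimal_digits(text) == digits


def test_decimal_digits_rejects_non_numeric():
    with pytest.raises(ValidationError):
        count_decimal_digits("12,34")


@pytest.mark.parametrize("unc,removed", [(501.0, True), (500.0, False)])
def test_uncertainty_threshold_is_strict(unc, removed):
    res = apply_attribute_filters([_rec("a", uncertainty_m=unc)])
    assert (len(res.kept) == 0) == removed
    if removed:
        assert res.removed[0].reason == "uncertainty_too_large"


@pytest.mark.parametrize("year,removed", [(1969, True), (1970, False)])
def test_date_cutoff(year, removed):
    res = apply_attribute_filters([_rec("a", event_year=year)])
    assert (len(res.kept) == 0) == removed


@pytest.mark.parametrize("lat_text,lon_text,removed", [
    ("45.12", "9.12345", True),      # 2 digits on one coordinate suffices
    ("45.123", "9.123", False),
    ("45.120", "9.1200", False),     # trailing zeros count as written
])
def test_precision_rule_on_written_digits(lat_text, lon_text, removed):
    r = _rec("a", lat=float(lat_text), lon=float(lon_text),
             lat_text=lat_text, lon_text=lon_text)
    res = apply_attribute_filters([r])
    assert (len(res.kept) == 0) == removed


def test_precision_inferred_when_text_missing():
    low = _rec("a", lat=45.12, lon=9.3, lat_text=None, lon_text=None)
    fine = _rec("b", lat=45.12345, lon=9.54321, lat_text=None, lon_text=None)
    res = apply_attribute_filters([low, fine])
    assert [r.record_id for r in res.kept] == ["b"]
    assert res.removed[0].reason == "coords_low_precision"


def test_cascade_conservation_and_first_reason(synthetic_world):
    _, _, records, truth = synthetic_world
    in_situ = [r for r in records if r.conservation_side == "in_situ"]
    res = apply_attribute_filters(in_situ)
    assert len(res.kept) + len(res.removed) == len(in_situ)
    ids = [r.record_id for r in res.removed]
    assert len(ids) == len(set(ids))


def test_attribute_filters_order_insensitive_kept_set(synthetic_world):
    _, _, records, _ = synthetic_world
    in_situ = [r for r in records if r.conservation_side == "in_situ"]
    shuffled = in_situ[:]
    random.Random(0).shuffle(shuffled)
    a = {r.record_id for r in apply_attribute_filters(in_situ).kept}
    b = {r.record_id for r in apply_attribute_filters(shuffled).kept}
    assert a == b


# --- deduplication -----------------------------------------------------------

def test_dedup_keeps_most_recent():
    old = _rec("old", event_year=1990)
    new = _rec("new", event_year=2005)
    res = deduplicate([old, new])
    assert [r.record_id for r in res.kept] == ["new"]
    assert res.removed[0].reason == "duplicate"


def test_dedup_ties_broken_by_completeness():
    sparse = _rec("sparse", event_year=2000)
    rich = _rec("rich", event_year=2000, uncertainty_m=30.0, author="Biv.")
    res = deduplicate([sparse, rich])
    assert [r.record_id for r in res.kept] == ["rich"]


def test_dedup_different_species_or_place_not_merged():
    a = _rec("a")
    b = _rec("b", species_epithet="villosa")
    c = _rec("c", lat=45.2000)
    res = deduplicate([a, b, c])
    assert len(res.kept) == 3


def test_dedup_idempotent(qc_chain):
    once = deduplicate(qc_chain["attr"].kept)
    twice = deduplicate(once.kept)
    assert [r.record_id for r in twice.kept] == [r.record_id for r in once.kept]
    assert twice.removed == []


# --- spatial consistency -----------------------------------------------------

def _square_world(side=100.0):
    """Planar-km square country with the full boundary as coastline."""
    poly = Polygon([(0, 0), (side, 0), (side, side), (0, side), (0, 0)])
    country = PolygonLayer("country", [LayerFeature({}, poly)], CRS)
    coast = PolygonLayer("coastline",
                         [LayerFeature({}, LineString(poly.exterior.coords))], CRS)
    return country, coast, (side / 2, side / 2)


def test_point_just_offshore_is_snapped():
    country, coast, centroid = _square_world()
    r = _rec("a", lat=40.0, lon=-0.5)   # 500 m west of the x=0 edge
    res = spatial_consistency([r], country, coast, centroid)
    assert len(res.kept) == 1 and len(res.snapped) == 1
    s = res.snapped[0]
    assert abs(s.distance_m - 500.0) < 1.0
    assert abs(s.lon_after - 0.0) < 1e-9 and abs(s.lat_after - 40.0) < 1e-9


def test_point_far_offshore_is_removed():
    country, coast, centroid = _square_world()
    res = spatial_consistency([_rec("a", lat=40.0, lon=-2.0)],
                              country, coast, centroid)
    assert res.kept == [] and res.removed[0].reason == "in_sea_far"


def test_centroid_placeholder_removed_inland_point_kept():
    country, coast, centroid = _square_world()
    at = _rec("at", lat=50.0004, lon=50.0)        # ~40 m from the centroid
    ok = _rec("ok", lat=70.0, lon=20.0)
    res = spatial_consistency([at, ok], country, coast, centroid)
    assert [r.record_id for r in res.kept] == ["ok"]
    assert res.removed[0].reason == "at_centroid"


def test_island_partition_matches_brute_force_oracle():
    """Random points around an island agree with per-segment distance math."""
    island = Polygon([(10, 10), (30, 8), (38, 20), (28, 32), (12, 28), (10, 10)])
    country = PolygonLayer("country", [LayerFeature({}, island)], CRS)
    coast = PolygonLayer(
        "coastline", [LayerFeature({}, LineString(island.exterior.coords))], CRS)
    centroid = (island.centroid.x, island.centroid.y)
    rng = np.random.default_rng(11)
    pts = np.column_stack([rng.uniform(0, 48, 300), rng.uniform(0, 42, 300)])
    records = [_rec(f"p{i}", lat=float(y), lon=float(x))
               for i, (x, y) in enumerate(pts)]
    res = spatial_consistency(records, country, coast, centroid)
    kept_ids = {r.record_id for r in res.kept}
    snapped_ids = {s.record_id for s in res.snapped}
    ring = list(island.exterior.coords)
    from shapely.geometry import Point
    for r in records:
        p = Point(r.lon, r.lat)
        d_m = min(_seg_dist(r.lon, r.lat, a, b)
                  for a, b in zip(ring[:-1], ring[1:])) * 1000.0
        d_cen = p.distance(Point(centroid)) * 1000.0
        if d_cen < 1000.0:
            assert r.record_id not in kept_ids
        elif island.covers(p):
            assert r.record_id in kept_ids and r.record_id not in snapped_ids
        elif d_m < 1000.0:
            assert r.record_id in snapped_ids
        else:
            assert r.record_id not in kept_ids


def _seg_dist(px, py, a, b):
    ax, ay = a
    bx, by = b
    dx, dy = bx - ax, by - ay
    t = max(0.0, min(1.0, ((px - ax) * dx + (py - ay) * dy) / (dx * dx + dy * dy)))
    return ((ax + t * dx - px) ** 2 + (ay + t * dy - py) ** 2) ** 0.5


def test_snapped_points_lie_on_coastline(qc_chain, synthetic_world):
    _, world, _, _ = synthetic_world
    from cwrgap.qc_filter import _coastline_segments
    from cwrgap.geometry import nearest_point_on_segments
    segs = _coastline_segments(world.coastline)
    for s in qc_chain["spatial"].snapped:
        _, _, d = nearest_point_on_segments(s.lon_after, s.lat_after, segs)
        assert d < 1e-9
        assert s.distance_m < FilterConfig().coast_snap_max_m


def test_geodesic_snap_distance_accurate():
    """A point ~500 m offshore of a lon/lat world snaps back within 0.1 %."""
    import math
    from cwrgap.synthetic_data import make_geo_world
    world = make_geo_world()
    lat = 41.25
    # 500 m west of the lon=12 meridian edge at this latitude
    n = 6378137.0 / math.sqrt(1 - 0.00669438 * math.sin(math.radians(lat)) ** 2)
    dlon = math.degrees(500.0 / (n * math.cos(math.radians(lat))))
    r = _rec("g", lat=lat, lon=12.0 - dlon)
    res = spatial_consistency([r], world.country, world.coastline, world.centroid)
    assert len(res.snapped) == 1
    assert abs(res.snapped[0].distance_m - 500.0) < 0.5
    assert abs(res.snapped[0].lon_after - 12.0) < 1e-8
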