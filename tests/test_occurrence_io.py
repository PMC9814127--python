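"""Record and layer I/O: dialects, round trips, validation, harmonisation."""

import json

import pytest

from cwrgap.errors import ConfigurationError, ValidationError
from cwrgap.occurrence_io import (OccurrenceRecord, SynonymTable, harmonize_taxa,
                                  read_layer, read_occurrences, write_layer,
                                  write_records)

GENERIC_HEADER = ("record_id,source,genus,species_epithet,author,subspecies,"
                  "latitude,longitude,uncertainty_m,year,provider,"
                  "basis_of_record,issue_flags,is_cultivated,"
                  "conservation_side,admin_region,country")


def test_blank_latitude_stays_absent(tmp_path):
    f = tmp_path / "r.csv"
    f.write_text(GENERIC_HEADER + "\n"
                 "a,gbif,Brassica,villosa,Biv.,,38.123,12.5,,2001,NBN,,,,in_situ,,IT\n"
                 "b,gbif,Brassica,villosa,Biv.,,,12.5,,2001,NBN,,,,in_situ,,IT\n"
                 "c,gbif,Brassica,villosa,Biv.,,37.9,12.1,,2001,NBN,,,,in_situ,,IT\n")
    records = read_occurrences(f, "generic")
    assert len(records) == 3
    assert sum(r.lat is None for r in records) == 1
    assert records[1].lat is None and records[1].lat_text is None


def test_genesys_dialect_forces_ex_situ(tmp_path):
    f = tmp_path / "g.csv"
    rows = ["ACCENUMB,GENUS,SPECIES,DECLATITUDE,DECLONGITUDE,COLLYEAR,INSTCODE"]
    rows += [f"ACC{i},Brassica,insularis,39.{i}1234,9.01234,1999,ITA{i}"
             for i in range(5)]
    f.write_text("\n".join(rows) + "\n")
    records = read_occurrences(f, "genesys")
    assert len(records) == 5
    assert all(r.conservation_side == "ex_situ" for r in records)
    assert all(r.source == "genesys" for r in records)


def test_unknown_dialect_is_a_configuration_error(tmp_path):
    f = tmp_path / "r.csv"
    f.write_text("record_id\nx\n")
    with pytest.raises(ConfigurationError):
        read_occurrences(f, "obis")


def test_unparseable_coordinate_kept_with_field_absent(tmp_path):
    f = tmp_path / "r.csv"
    f.write_text(GENERIC_HEADER + "\n"
                 "a,gbif,Allium,roseum,,,not-a-number,12.5,,2001,,,,,in_situ,,\n")
    records = read_occurrences(f, "generic")
    assert len(records) == 1
    assert records[0].lat is None


def test_record_round_trip_is_identity(tmp_path, synthetic_world):
    _, _, records, _ = synthetic_world
    f = tmp_path / "out.csv"
    write_records(records, f)
    back = read_occurrences(f, "generic")
    assert len(back) == len(records)
    for a, b in zip(records, back):
        for field in ("record_id", "source", "genus", "species_epithet", "author",
                      "subspecies", "lat", "lon", "lat_text", "lon_text",
                      "uncertainty_m", "event_year", "provider",
                      "basis_of_record", "issue_flags", "is_cultivated",
                      "conservation_side", "country_claimed"):
            assert getattr(a, field) == getattr(b, field), field


def test_coordinate_range_invariant():
    with pytest.raises(ValidationError):
        OccurrenceRecord("x", "Beta", "vulgaris", lat=91.0, lon=0.0)
    with pytest.raises(ValidationError):
        OccurrenceRecord("x", "Beta", "vulgaris", lat=0.0, lon=-181.0)


# --- taxon harmonisation -----------------------------------------------------

SYNONYMS = SynonymTable({
    "Beta maritima L.": ("Beta", "vulgaris", "L.", "maritima"),
    "Allium arvense Guss.": ("Allium", "sphaerocephalon", "L.", "arvense"),
})


@pytest.mark.parametrize("genus,epithet,author,expected", [
    ("Beta", "maritima", "L.", "Beta vulgaris subsp. maritima"),
    ("Allium", "arvense", "Guss.", "Allium sphaerocephalon subsp. arvense"),
])
def test_harmonize_replaces_synonyms(genus, epithet, author, expected):
    rec = OccurrenceRecord("x", genus, epithet, author=author)
    out = harmonize_taxa([rec], SYNONYMS)
    assert out[0].taxon == expected


def test_harmonize_is_idempotent_and_length_preserving():
    records = [OccurrenceRecord("a", "Beta", "maritima", author="L."),
               OccurrenceRecord("b", "Brassica", "villosa", author="Biv."),
               OccurrenceRecord("c", "Allium", "arvense", author="Guss.")]
    once = harmonize_taxa(records, SYNONYMS)
    twice = harmonize_taxa(once, SYNONYMS)
    assert len(once) == len(records)
    assert [r.taxon for r in once] == [r.taxon for r in twice]
    assert once[1].taxon == "Brassica villosa"  # unknown name passes through


# --- polygon layers ----------------------------------------------------------

def _unit_square_geojson(site_type="B"):
    return {"type": "FeatureCollection", "features": [{
        "type": "Feature",
        "properties": {"site_code": "S1", "site_name": "one",
                       "site_type": site_type},
        # deliberately open ring: the reader must close it
        "geometry": {"type": "Polygon",
                     "coordinates": [[[0, 0], [1, 0], [1, 1], [0, 1]]]}}]}


def test_layer_rings_are_normalised_closed(tmp_path):
    f = tmp_path / "l.geojson"
    f.write_text(json.dumps(_unit_square_geojson()))
    layer = read_layer(f, "protected_sites")
    assert len(layer.features) == 1
    ring = layer.features[0].rings()[0][0]
    assert len(ring) == 5 and ring[0] == ring[-1]


def test_invalid_site_type_rejected(tmp_path):
    f = tmp_path / "l.geojson"
    f.write_text(json.dumps(_unit_square_geojson(site_type="D")))
    with pytest.raises(ValidationError, match="site_type"):
        read_layer(f, "protected_sites")


def test_missing_site_attribute_names_feature_index(tmp_path):
    doc = _unit_square_geojson()
    del doc["features"][0]["properties"]["site_name"]
    f = tmp_path / "l.geojson"
    f.write_text(json.dumps(doc))
    with pytest.raises(ValidationError, match="feature 0"):
        read_layer(f, "protected_sites")


def test_layer_round_trip_preserves_coordinates(tmp_path, synthetic_world):
    _, world, _, _ = synthetic_world
    f = tmp_path / "sites.geojson"
    write_layer(world.protected_sites, f)
    back = read_layer(f, "protected_sites")
    for orig, rt in zip(world.protected_sites.features, back.features):
        a = orig.rings()
        b = rt.rings()
        assert len(a) == len(b)
        for ra, rb in zip(a, b):
            for ring_a, ring_b in zip(ra, rb):
                for (xa, ya), (xb, yb) in zip(ring_a, ring_b):
                    assert abs(xa - xb) < 1e-9 and abs(ya - yb) < 1e-9
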