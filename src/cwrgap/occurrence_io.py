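"""Reading, normalising and writing occurrence records and polygon layers.

Occurrence records travel as delimited text (comma by default, tab
accepted) with a header row.  Column names differ between providers, so a
*dialect* — an editable mapping shipped in ``data/dialects.json`` — declares
how provider columns map onto the canonical record schema.  Genesys holds
genebank accessions, so its dialect marks every record as *ex situ*; the
other sources describe wild populations (*in situ*).

Original coordinate strings are preserved verbatim alongside the parsed
floats: the coordinate-precision QC rule is defined on decimal digits *as
written*, which parsing destroys.

Polygon layers travel as GeoJSON (RFC 7946, WGS84 lon-lat axis order, or a
declared planar pseudo-CRS for synthetic worlds).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from shapely.geometry import LineString, MultiLineString, MultiPolygon, Polygon, mapping, shape

from .errors import ConfigurationError, ValidationError

log = logging.getLogger(__name__)

SOURCE_KINDS = ("geoportal", "gbif", "genesys", "other")
CONSERVATION_SIDES = ("in_situ", "ex_situ")
LAYER_KINDS = ("country", "coastline", "protected_sites", "admin_regions",
               "biogeo_regions", "lclu")
SITE_TYPES = ("A", "B", "C")

#: optional fields counted when ranking duplicate completeness
OPTIONAL_INFO_FIELDS = ("author", "subspecies", "uncertainty_m", "event_year",
                        "basis_of_record", "admin_region_claimed")


@dataclass
class OccurrenceRecord:
    """One population (in situ) or accession (ex situ) observation."""

    record_id: str
    genus: str
    species_epithet: str
    author: Optional[str] = None
    subspecies: Optional[str] = None
    lat_text: Optional[str] = None
    lon_text: Optional[str] = None
    lat: Optional[float] = None
    lon: Optional[float] = None
    uncertainty_m: Optional[float] = None
    event_year: Optional[int] = None
    source: str = "other"
    provider: Optional[str] = None
    basis_of_record: Optional[str] = None
    issue_flags: set[str] = field(default_factory=set)
    is_cultivated: bool = False
    conservation_side: str = "in_situ"
    admin_region_claimed: Optional[str] = None
    country_claimed: Optional[str] = None
    natura2000_claimed: Optional[bool] = None
    site_code_claimed: Optional[str] = None
    site_type_claimed: Optional[str] = None

    def __post_init__(self) -> None:
        if self.source not in SOURCE_KINDS:
            raise ValidationError(f"unknown source kind {self.source!r}")
        if self.conservation_side not in CONSERVATION_SIDES:
            raise ValidationError(
                f"unknown conservation side {self.conservation_side!r}")
        if self.lat is not None and not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"latitude {self.lat} out of range")
        if self.lon is not None and not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"longitude {self.lon} out of range")

    @property
    def has_coords(self) -> bool:
        return self.lat is not None and self.lon is not None

    @property
    def taxon(self) -> str:
        """Accepted binomial (plus subspecies when present), without author."""
        name = f"{self.genus} {self.species_epithet}"
        if self.subspecies:
            name += f" subsp. {self.subspecies}"
        return name

    @property
    def full_name(self) -> str:
        """Taxon plus author string, the form synonym tables usually key on."""
        if self.author:
            return f"{self.genus} {self.species_epithet} {self.author}"
        return self.taxon

    def n_populated_optional(self) -> int:
        return sum(getattr(self, f) is not None for f in OPTIONAL_INFO_FIELDS)


@dataclass
class SynonymTable:
    """Raw-name → accepted-name mapping used for nomenclature harmonisation.

    The mapping is idempotent by construction: every accepted name is also
    inserted as a key pointing to itself.
    """

    entries: dict[str, tuple[str, str, Optional[str], Optional[str]]]

    def __post_init__(self) -> None:
        for accepted in list(self.entries.values()):
            genus, epithet, author, subsp = accepted
            name = f"{genus} {epithet}"
            if subsp:
                name += f" subsp. {subsp}"
            self.entries.setdefault(name, accepted)
            if author:
                self.entries.setdefault(f"{genus} {epithet} {author}", accepted)

    def lookup(self, record: OccurrenceRecord):
        candidates = [record.full_name, record.taxon,
                      f"{record.genus} {record.species_epithet}"]
        for name in candidates:
            if name in self.entries:
                return self.entries[name]
        return None


@dataclass
class LayerFeature:
    attributes: dict
    geometry: object  # shapely Polygon / MultiPolygon (LineString for coastline)

    def polygons(self) -> list[Polygon]:
        geom = self.geometry
        if isinstance(geom, Polygon):
            return [geom]
        if isinstance(geom, MultiPolygon):
            return list(geom.geoms)
        return []

    def rings(self) -> list[list[list[tuple[float, float]]]]:
        """Per polygon: [exterior ring, hole rings...] as coordinate lists."""
        out = []
        for poly in self.polygons():
            rings = [list(poly.exterior.coords)]
            rings += [list(r.coords) for r in poly.interiors]
            out.append(rings)
        return out


@dataclass
class PolygonLayer:
    layer_kind: str
    features: list[LayerFeature]
    crs_note: str = "WGS84 lon-lat"

    def __post_init__(self) -> None:
        if self.layer_kind not in LAYER_KINDS:
            raise ValidationError(f"unknown layer kind {self.layer_kind!r}")


# ---------------------------------------------------------------------------
# record reading / writing

def _load_dialects() -> dict:
    with resources.files("cwrgap.data").joinpath("dialects.json").open() as fh:
        return json.load(fh)


_DIALECTS = _load_dialects()


def _parse_float(text: str, record_id: str, what: str) -> Optional[float]:
    try:
        return float(text)
    except ValueError:
        log.warning("record %s: unparseable %s %r, left absent", record_id, what, text)
        return None


def _parse_cultivated(text: str) -> bool:
    t = text.strip().lower()
    if t in {"1", "true", "yes", "y", "cultivated", "managed"}:
        return True
    try:
        # MCPD SAMPSTAT: 300-599 are cultivated/breeding materials
        return 300 <= int(float(t)) < 600
    except ValueError:
        return False


def _split_delimited(path: Path, delimiter: Optional[str]) -> tuple[list[str], list[list[str]]]:
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValidationError(f"{path}: empty file")
    if delimiter is None:
        header = lines[0]
        delimiter = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    header = lines[0].split(delimiter)
    rows = [ln.split(delimiter) for ln in lines[1:]]
    return [h.strip() for h in header], rows


def read_occurrences(path, dialect: str = "generic") -> list[OccurrenceRecord]:
    """Read delimited occurrence text under a named column dialect.

    Missing fields stay absent (``None``), never zero-filled.  Rows whose
    numeric fields fail to parse keep the record, drop the field and log a
    warning.  The genesys dialect forces ``conservation_side='ex_situ'``.
    """
    if dialect not in _DIALECTS:
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    spec = _DIALECTS[dialect]
    cols = spec["columns"]
    header, rows = _split_delimited(Path(path), spec.get("delimiter"))
    index = {name: i for i, name in enumerate(header)}

    def get(row: list[str], key: str) -> Optional[str]:
        col = cols.get(key)
        if col is None or col not in index:
            return None
        i = index[col]
        if i >= len(row):
            return None
        val = row[i].strip()
        return val if val != "" else None

    records = []
    for n, row in enumerate(rows):
        rid = get(row, "record_id") or f"row{n + 1}"
        lat_text, lon_text = get(row, "lat"), get(row, "lon")
        lat = _parse_float(lat_text, rid, "latitude") if lat_text else None
        lon = _parse_float(lon_text, rid, "longitude") if lon_text else None
        unc_text = get(row, "uncertainty_m")
        year_text = get(row, "event_year")
        year = None
        if year_text is not None:
            try:
                year = int(float(year_text))
            except ValueError:
                log.warning("record %s: unparseable year %r", rid, year_text)
        flags_text = get(row, "issue_flags")
        flags = set()
        if flags_text:
            flags = {f.strip() for f in flags_text.replace("|", ";").split(";") if f.strip()}
        cult_text = get(row, "is_cultivated")
        source = get(row, "source")
        if source not in SOURCE_KINDS:
            source = spec["source_kind"]
        side = get(row, "conservation_side") or spec["conservation_side_default"]
        n2k = get(row, "natura2000_claimed")
        records.append(OccurrenceRecord(
            record_id=rid,
            genus=get(row, "genus") or "",
            species_epithet=get(row, "species_epithet") or "",
            author=get(row, "author"),
            subspecies=get(row, "subspecies"),
            lat_text=lat_text if lat is not None else None,
            lon_text=lon_text if lon is not None else None,
            lat=lat, lon=lon,
            uncertainty_m=_parse_float(unc_text, rid, "uncertainty") if unc_text else None,
            event_year=year,
            source=source,
            provider=get(row, "provider"),
            basis_of_record=get(row, "basis_of_record"),
            issue_flags=flags,
            is_cultivated=_parse_cultivated(cult_text) if cult_text else False,
            conservation_side=side,
            admin_region_claimed=get(row, "admin_region_claimed"),
            country_claimed=get(row, "country_claimed"),
            natura2000_claimed=(n2k.lower() in {"1", "true", "yes"}) if n2k else None,
            site_code_claimed=get(row, "site_code_claimed"),
            site_type_claimed=get(row, "site_type_claimed"),
        ))
    return records


_WRITE_COLUMNS = ("record_id", "source", "genus", "species_epithet", "author",
                  "subspecies", "latitude", "longitude", "uncertainty_m", "year",
                  "provider", "basis_of_record", "issue_flags", "is_cultivated",
                  "conservation_side", "admin_region", "country")


def write_records(records: Iterable[OccurrenceRecord], path) -> None:
    """Write records as generic-dialect CSV (lossless for canonical fields)."""
    lines = [",".join(_WRITE_COLUMNS)]
    for r in records:
        vals = [
            r.record_id, r.source, r.genus, r.species_epithet, r.author or "",
            r.subspecies or "",
            r.lat_text if r.lat_text is not None else (repr(r.lat) if r.lat is not None else ""),
            r.lon_text if r.lon_text is not None else (repr(r.lon) if r.lon is not None else ""),
            repr(r.uncertainty_m) if r.uncertainty_m is not None else "",
            str(r.event_year) if r.event_year is not None else "",
            r.provider or "", r.basis_of_record or "",
            ";".join(sorted(r.issue_flags)),
            "1" if r.is_cultivated else "",
            r.conservation_side, r.admin_region_claimed or "", r.country_claimed or "",
        ]
        lines.append(",".join(vals))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def harmonize_taxa(records: list[OccurrenceRecord],
                   table: SynonymTable) -> list[OccurrenceRecord]:
    """Replace each record's name by its accepted form.

    Names absent from the table pass through unchanged with a warning.
    Idempotent (accepted names map to themselves) and length-preserving.
    """
    out = []
    for r in records:
        accepted = table.lookup(r)
        if accepted is None:
            log.warning("record %s: name %r not in synonym table", r.record_id, r.full_name)
            out.append(r)
        else:
            genus, epithet, author, subsp = accepted
            out.append(replace(r, genus=genus, species_epithet=epithet,
                               author=author, subspecies=subsp))
    return out


# ---------------------------------------------------------------------------
# polygon layers

def _close_ring(coords: list) -> list[tuple[float, float]]:
    pts = [tuple(c[:2]) for c in coords]
    if pts[0] != pts[-1]:
        pts.append(pts[0])
    if len(pts) < 4:
        raise ValidationError("exterior/hole ring has fewer than 4 vertices")
    return pts


def _normalize_geometry(geom_json: dict):
    gtype = geom_json.get("type")
    if gtype == "Polygon":
        rings = [_close_ring(r) for r in geom_json["coordinates"]]
        return Polygon(rings[0], rings[1:])
    if gtype == "MultiPolygon":
        polys = []
        for poly in geom_json["coordinates"]:
            rings = [_close_ring(r) for r in poly]
            polys.append(Polygon(rings[0], rings[1:]))
        return MultiPolygon(polys)
    if gtype in ("LineString", "MultiLineString"):
        return shape(geom_json)
    raise ValidationError(f"unsupported geometry type {gtype!r}")


def read_layer(path, layer_kind: str) -> PolygonLayer:
    """Read a GeoJSON FeatureCollection into a validated :class:`PolygonLayer`.

    Rings are normalised to closed form.  ``protected_sites`` features must
    carry ``site_code``, ``site_name`` and ``site_type`` in {A, B, C};
    violations raise :class:`ValidationError` naming the feature index.
    """
    if layer_kind not in LAYER_KINDS:
        raise ConfigurationError(f"unknown layer kind {layer_kind!r}")
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if data.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: not a GeoJSON FeatureCollection")
    features = []
    for i, feat in enumerate(data.get("features", [])):
        attrs = dict(feat.get("properties") or {})
        if layer_kind == "protected_sites":
            for key in ("site_code", "site_name", "site_type"):
                if key not in attrs or attrs[key] in (None, ""):
                    raise ValidationError(f"feature {i}: missing mandatory attribute {key!r}")
            if attrs["site_type"] not in SITE_TYPES:
                raise ValidationError(
                    f"feature {i}: invalid site_type {attrs['site_type']!r}")
        geom = _normalize_geometry(feat["geometry"])
        if layer_kind != "coastline" and isinstance(geom, (LineString, MultiLineString)):
            raise ValidationError(f"feature {i}: line geometry in a polygon layer")
        features.append(LayerFeature(attrs, geom))
    crs = data.get("crs_note", "WGS84 lon-lat")
    return PolygonLayer(layer_kind, features, crs_note=crs)


def write_layer(layer: PolygonLayer, path) -> None:
    """Write a layer back to GeoJSON; coordinates are emitted at full precision."""
    features = []
    for f in layer.features:
        features.append({"type": "Feature", "properties": f.attributes,
                         "geometry": mapping(f.geometry)})
    doc = {"type": "FeatureCollection", "crs_note": layer.crs_note,
           "features": features}
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def write_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True),
                          encoding="utf-8")
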