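"""Synthetic test world and transcribed reference tables.

The generator builds a download-free stand-in for the real study inputs: a
planar "country" (mainland plus an island, exercising multipolygon
handling) with coastline, protected sites of types A/B/C (including one
deliberately overlapping A–C pair, exercising designation precedence),
administrative and biogeographic region layers, a land-cover mosaic that
tiles the country, and occurrence records with independently injected QC
defects.  Every stochastic choice is driven by one seed, and a
:class:`GroundTruth` object records what was injected so the QC cascade,
overlay and density grid can be checked against exact bookkeeping.

Coordinates are planar kilometres declared as the pseudo-CRS
``planar-km`` (an identity projection), so every geometric oracle is
exact.  A second, tiny lon/lat world (:func:`make_geo_world`) exercises
the geodesic code paths.

Defaults mirror the study conditions: seven target species of one genus,
roughly two thirds of populations inside protected sites, a protected
network covering ~20 % of the land (the Natura 2000 share of Italy), an
ex situ side drawn as a sparse (~9 %) subsample of the in situ records,
and defect rates of 5–8 % per class.

The module also ships verbatim transcriptions of the printed reference
tables (priority-species population counts, per-region in situ / ex situ
counts, land-cover code groups, per-genus totals) as packaged CSV
resources, exposed through :func:`published_tables`.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
from shapely.geometry import LineString, MultiPolygon, Polygon, box
from shapely.geometry import Point as ShPoint
from shapely.prepared import prep

from .errors import ConfigurationError
from .lclu_reclass import ReclassTable, load_reclass_table
from .occurrence_io import LayerFeature, OccurrenceRecord, PolygonLayer

DEFECTS = ("cultivated", "missing_coords", "low_precision", "high_uncertainty",
           "pre_1970", "duplicate", "excluded_source", "bad_issue_flag",
           "sea_near_coast", "sea_far", "at_centroid")

DEFAULT_DEFECT_RATES = {
    "cultivated": 0.06,
    "missing_coords": 0.05,
    "low_precision": 0.08,
    "high_uncertainty": 0.06,
    "pre_1970": 0.05,
    "duplicate": 0.08,
    "excluded_source": 0.05,
    "bad_issue_flag": 0.05,
    "sea_near_coast": 0.05,
    "sea_far": 0.05,
    "at_centroid": 0.05,
}

#: QC reason produced by each attribute-level defect, in cascade order
_ATTRIBUTE_REASON = (
    ("cultivated", "cultivated"),
    ("excluded_source", "excluded_source"),
    ("bad_issue_flag", "bad_issue_flag"),
    ("missing_coords", "coords_missing"),
    ("low_precision", "coords_low_precision"),
    ("high_uncertainty", "uncertainty_too_large"),
    ("pre_1970", "too_old"),
)


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_species: int = 7
    records_per_species: int = 30
    fraction_inside_sites: float = 0.68
    site_type_mix: tuple = (("A", 0.16), ("B", 0.76), ("C", 0.08))
    site_coverage: float = 0.20
    defect_rates: tuple = tuple(sorted(DEFAULT_DEFECT_RATES.items()))
    ex_situ_subsample_rate: float = 0.09
    lclu_patch_count: int = 48
    lclu_scheme: str = "corine"

    def rates(self) -> dict[str, float]:
        d = dict(self.defect_rates)
        unknown = set(d) - set(DEFECTS)
        if unknown:
            raise ConfigurationError(f"unknown defect names {sorted(unknown)}")
        if any(not 0.0 <= p <= 1.0 for p in d.values()):
            raise ConfigurationError("defect probabilities must lie in [0, 1]")
        return {name: d.get(name, 0.0) for name in DEFECTS}


@dataclass
class RecordTruth:
    defects: list[str]
    inside_sites: bool
    site_code: Optional[str]
    site_type: Optional[str]
    lclu_code: Optional[int]
    lclu_group: Optional[str]
    expected_reason: Optional[str]    # None when the record should be kept
    expected_snap: bool = False
    snap_target: Optional[tuple[float, float]] = None
    final_position: Optional[tuple[float, float]] = None


@dataclass
class GroundTruth:
    per_record: dict[str, RecordTruth] = field(default_factory=dict)
    expected_kept_ids: set[str] = field(default_factory=set)
    expected_reason_counts: Counter = field(default_factory=Counter)
    expected_snapped_ids: set[str] = field(default_factory=set)
    injected_counts: Counter = field(default_factory=Counter)
    ex_situ_ids: set[str] = field(default_factory=set)
    centroid: tuple[float, float] = (0.0, 0.0)
    expected_in_situ_cells: Counter = field(default_factory=Counter)
    expected_ex_situ_cells: Counter = field(default_factory=Counter)


@dataclass
class World:
    country: PolygonLayer
    coastline: PolygonLayer
    protected_sites: PolygonLayer
    admin_regions: PolygonLayer
    biogeo_regions: PolygonLayer
    lclu: PolygonLayer
    centroid: tuple[float, float]

    def layers(self) -> dict[str, PolygonLayer]:
        return {"country": self.country, "coastline": self.coastline,
                "protected_sites": self.protected_sites,
                "admin_regions": self.admin_regions,
                "biogeo_regions": self.biogeo_regions, "lclu": self.lclu}


_CRS = "planar-km (synthetic identity projection, units km)"

# fixed, irregular mainland (km); an island sits offshore to the east
_MAINLAND = Polygon([
    (6, 10), (30, 5), (52, 8), (68, 14), (72, 28), (70, 44), (60, 54),
    (40, 56), (22, 52), (10, 44), (5, 30), (6, 10)])
_ISLAND = Polygon([(76, 16), (84, 14), (88, 20), (83, 26), (77, 23), (76, 16)])


def _site_rectangles(rng: np.random.Generator, country: MultiPolygon,
                     config: SyntheticConfig) -> list[dict]:
    """Random non-overlapping rectangular sites reaching the coverage target."""
    target_area = config.site_coverage * country.area
    prepared = prep(country)
    types, weights = zip(*config.site_type_mix)
    sites: list[dict] = []
    placed = []
    total = 0.0
    minx, miny, maxx, maxy = country.bounds
    tries = 0
    while total < target_area and tries < 20_000:
        tries += 1
        w = rng.uniform(4.0, 10.0)
        h = rng.uniform(4.0, 10.0)
        cx = rng.uniform(minx, maxx)
        cy = rng.uniform(miny, maxy)
        rect = box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
        if not prepared.contains(rect):
            continue
        if any(rect.distance(p) < 0.5 for p in placed):
            continue
        stype = types[int(rng.choice(len(types), p=np.asarray(weights) / sum(weights)))]
        sites.append({"geometry": rect, "site_type": stype})
        placed.append(rect)
        total += rect.area
    if total < target_area:
        raise ConfigurationError("could not reach the site coverage target")
    # one deliberately overlapping A-C pair on top of the first site
    base = sites[0]["geometry"]
    bx, by = base.centroid.x, base.centroid.y
    shifted = box(bx, by, bx + (base.bounds[2] - base.bounds[0]),
                  by + (base.bounds[3] - base.bounds[1]))
    if prepared.contains(shifted):
        sites[0]["site_type"] = "A"
        sites.append({"geometry": shifted, "site_type": "C", "overlap_pair": True})
    for i, s in enumerate(sites):
        s["site_code"] = f"S{i:03d}"
        s["site_name"] = f"Synthetic site {i}"
    return sites


def _clip_bands(country: MultiPolygon, cuts: list[float], axis: int,
                names: list[str]) -> list[LayerFeature]:
    minx, miny, maxx, maxy = country.bounds
    edges = [(-1e9, *cuts, 1e9)[i:i + 2] for i in range(len(cuts) + 1)]
    feats = []
    for (lo, hi), name in zip(edges, names):
        band = box(lo, miny - 1, hi, maxy + 1) if axis == 0 else \
            box(minx - 1, lo, maxx + 1, hi)
        clipped = country.intersection(band)
        if clipped.is_empty:
            continue
        if clipped.geom_type == "GeometryCollection":
            polys = [g for g in clipped.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
            clipped = MultiPolygon(
                [p for g in polys for p in (g.geoms if hasattr(g, "geoms") else [g])])
        feats.append(LayerFeature({"name": name}, clipped))
    return feats


def _lclu_mosaic(rng: np.random.Generator, country: MultiPolygon,
                 config: SyntheticConfig) -> list[LayerFeature]:
    """Square tiling clipped to the country: patches partition the land."""
    table = load_reclass_table(config.lclu_scheme)
    codes = sorted(table.mapping)
    if config.lclu_scheme == "corine":
        # favour agricultural and seminatural codes, as real mosaics do
        weights = np.array([3.0 if c // 100 in (2, 3) else 1.0 for c in codes])
    else:
        weights = np.array([3.0 if table.mapping[c] != "Other" else 0.5 for c in codes])
    weights = weights / weights.sum()
    tile = max(2.0, (country.area / max(config.lclu_patch_count, 1)) ** 0.5)
    minx, miny, maxx, maxy = country.bounds
    feats = []
    y = miny
    i = 0
    while y < maxy:
        x = minx
        while x < maxx:
            patch = box(x, y, x + tile, y + tile).intersection(country)
            if not patch.is_empty and patch.area > 0:
                code = int(codes[int(rng.choice(len(codes), p=weights))])
                feats.append(LayerFeature({"code": code, "patch_id": i}, patch))
                i += 1
            x += tile
        y += tile
    return feats


def make_world(config: SyntheticConfig = SyntheticConfig()) -> World:
    """Build the synthetic country and all overlay layers, deterministically."""
    rng = np.random.default_rng(config.seed)
    country_geom = MultiPolygon([_MAINLAND, _ISLAND])
    country = PolygonLayer("country", [LayerFeature({"name": "Synthetia"},
                                                    country_geom)], _CRS)
    coast_feats = [LayerFeature({"part": i}, LineString(p.exterior.coords))
                   for i, p in enumerate(country_geom.geoms)]
    coastline = PolygonLayer("coastline", coast_feats, _CRS)
    sites = _site_rectangles(rng, country_geom, config)
    site_feats = [LayerFeature({k: s[k] for k in ("site_code", "site_name", "site_type")},
                               s["geometry"]) for s in sites]
    protected = PolygonLayer("protected_sites", site_feats, _CRS)
    admin = PolygonLayer("admin_regions",
                         _clip_bands(country_geom, [30.0, 55.0, 74.0], 0,
                                     ["West", "Center", "East", "Island"]), _CRS)
    biogeo = PolygonLayer("biogeo_regions",
                          _clip_bands(country_geom, [22.0, 40.0], 1,
                                      ["Mediterranean", "Continental", "Alpine"]), _CRS)
    lclu = PolygonLayer("lclu", _lclu_mosaic(rng, country_geom, config), _CRS)
    c = country_geom.centroid
    return World(country, coastline, protected, admin, biogeo, lclu,
                 (round(c.x, 5), round(c.y, 5)))


def make_geo_world() -> World:
    """A tiny lon/lat (degree) world for exercising the geodesic code paths."""
    square = Polygon([(12.0, 41.0), (12.6, 41.0), (12.6, 41.5),
                      (12.0, 41.5), (12.0, 41.0)])
    crs = "WGS84 lon-lat"
    country = PolygonLayer("country", [LayerFeature({"name": "Geo"}, square)], crs)
    coast = PolygonLayer("coastline",
                         [LayerFeature({}, LineString(square.exterior.coords))], crs)
    site = box(12.2, 41.1, 12.4, 41.3)
    sites = PolygonLayer("protected_sites",
                         [LayerFeature({"site_code": "G001", "site_name": "Geo site",
                                        "site_type": "B"}, site)], crs)
    empty = PolygonLayer("admin_regions", [LayerFeature({"name": "Geo"}, square)], crs)
    bio = PolygonLayer("biogeo_regions",
                       [LayerFeature({"name": "Mediterranean"}, square)], crs)
    lclu = PolygonLayer("lclu", [LayerFeature({"code": 243, "patch_id": 0}, square)], crs)
    c = square.centroid
    return World(country, coast, sites, empty, bio, lclu, (c.x, c.y))


# ---------------------------------------------------------------------------
# occurrence simulation

def _sample_point(rng, polygon, boundary, centroid,
                  forbid_sites=None) -> tuple[float, float]:
    """Uniform point in `polygon`, rounded to 5 decimals, honouring margins."""
    minx, miny, maxx, maxy = polygon.bounds
    pre = prep(polygon)
    for _ in range(10_000):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        p = ShPoint(x, y)
        if not pre.contains(p):
            continue
        x, y = round(x, 5), round(y, 5)
        p = ShPoint(x, y)
        if boundary.distance(p) < 0.05:       # stay clear of the coast
            continue
        if p.distance(ShPoint(*centroid)) < 1.2:   # clear of the centroid rule
            continue
        if forbid_sites is not None and forbid_sites.intersects(p):
            continue
        return x, y
    raise ConfigurationError("rejection sampling failed; polygon too thin?")


def _offshore_point(rng, coast_rings, prepared_country, dist_range,
                    min_clear: float) -> tuple[tuple[float, float], tuple[float, float]]:
    """A point `d` km seaward of a coastline segment plus its snap anchor."""
    ring_lines = [np.asarray(r) for r in coast_rings]
    all_segs = np.vstack([np.hstack([r[:-1], r[1:]]) for r in ring_lines])
    for _ in range(2_000):
        i = int(rng.integers(len(all_segs)))
        ax, ay, bx, by = all_segs[i]
        t = rng.uniform(0.25, 0.75)
        fx, fy = ax + t * (bx - ax), ay + t * (by - ay)
        dx, dy = bx - ax, by - ay
        norm = float(np.hypot(dx, dy))
        if norm == 0:
            continue
        nx, ny = dy / norm, -dx / norm     # one of the two normals
        d = rng.uniform(*dist_range)
        for sign in (1.0, -1.0):
            px, py = fx + sign * nx * d, fy + sign * ny * d
            p = ShPoint(px, py)
            if prepared_country.contains(p) or prepared_country.intersects(p):
                continue
            # verify the offset really is the coast distance (convex stretch)
            qd = _min_dist_to_segments(px, py, all_segs)
            if abs(qd - d) > 1e-6 or qd < min_clear:
                continue
            return (round(px, 5), round(py, 5)), (fx, fy)
    raise ConfigurationError("could not place an offshore defect point")


def _min_dist_to_segments(px, py, segs) -> float:
    ax, ay, bx, by = segs[:, 0], segs[:, 1], segs[:, 2], segs[:, 3]
    dx, dy = bx - ax, by - ay
    l2 = dx * dx + dy * dy
    with np.errstate(invalid="ignore", divide="ignore"):
        t = ((px - ax) * dx + (py - ay) * dy) / l2
    t = np.where(l2 == 0, 0.0, np.clip(t, 0.0, 1.0))
    qx, qy = ax + t * dx, ay + t * dy
    return float(np.sqrt(((qx - px) ** 2 + (qy - py) ** 2).min()))


def _fmt(value: float, decimals: int) -> str:
    return f"{value:.{decimals}f}"


def simulate_occurrences(config: SyntheticConfig,
                         world: World) -> tuple[list[OccurrenceRecord], GroundTruth]:
    """Generate occurrence records with injected defects and full bookkeeping.

    Clean records survive the entire QC cascade by construction (placed
    inside the country, away from coast and centroid, with 5-decimal
    coordinates, small stated uncertainty and post-1970 dates, and unique
    rounded coordinates per species).  Defects are drawn independently per
    record; the expected removal reason is the first matching rule in the
    cascade order.  Duplicate clones are only attached to otherwise clean
    records so the dedup survivor is predictable.  The ex situ side is a
    seeded Bernoulli subsample of the expected-kept in situ records.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1017]))
    rates = config.rates()
    country_geom = MultiPolygon(
        [p for f in world.country.features for p in f.polygons()])
    prepared_country = prep(country_geom)
    boundary = country_geom.boundary
    site_geoms = [(f.attributes, g) for f in world.protected_sites.features
                  for g in f.polygons()]
    sites_union = prep(MultiPolygon([g for _, g in site_geoms]).buffer(0))
    coast_rings = [list(p.exterior.coords) for p in country_geom.geoms]
    lclu_feats = world.lclu.features
    lclu_table = load_reclass_table(config.lclu_scheme)
    centroid = world.centroid

    precedence = {"C": 0, "A": 1, "B": 2}

    def truth_site(x: float, y: float):
        hits = [a for a, g in site_geoms if g.covers(ShPoint(x, y))]
        if not hits:
            return None
        best = min(hits, key=lambda a: (precedence[a["site_type"]], a["site_code"]))
        return best

    def truth_lclu(x: float, y: float):
        p = ShPoint(x, y)
        for f in lclu_feats:
            if f.geometry.covers(p):
                return int(f.attributes["code"])
        return None

    truth = GroundTruth(centroid=centroid)
    records: list[OccurrenceRecord] = []
    used_keys: set = set()
    providers = ("NBN", "HerbariumX", "BotGard")

    for s in range(config.n_species):
        species = f"synthetica{s + 1:02d}"
        for k in range(config.records_per_species):
            rid = f"R{s:02d}{k:03d}"
            # --- placement
            place_inside = rng.random() < config.fraction_inside_sites
            while True:
                if place_inside:
                    _, geom = site_geoms[int(rng.integers(len(site_geoms)))]
                    x, y = _sample_point(rng, geom, boundary, centroid)
                else:
                    x, y = _sample_point(rng, country_geom, boundary, centroid,
                                         forbid_sites=sites_union)
                key = (species, round(x, 4), round(y, 4))
                if key not in used_keys:
                    used_keys.add(key)
                    break
            # --- defects
            defects = [d for d in DEFECTS if rng.random() < rates[d]]
            site_attrs = truth_site(x, y)
            lclu_code = truth_lclu(x, y)
            year = int(rng.integers(1980, 2021))
            unc = float(np.round(rng.uniform(10, 400), 1))
            provider = providers[int(rng.integers(len(providers)))]
            issue_flags: set[str] = set()
            is_cultivated = False
            snap_target = None

            if "at_centroid" in defects:
                # jittered inside the tolerance radius so placeholders of the
                # same species stay distinct through deduplication
                while True:
                    ang = rng.uniform(0, 2 * np.pi)
                    rad = rng.uniform(0.0, 0.3)
                    x = round(centroid[0] + rad * np.cos(ang), 5)
                    y = round(centroid[1] + rad * np.sin(ang), 5)
                    if (species, round(x, 4), round(y, 4)) not in used_keys:
                        break
            elif "sea_far" in defects:
                (x, y), _anchor = _offshore_point(rng, coast_rings,
                                                  prepared_country,
                                                  (2.0, 20.0), 1.8)
            elif "sea_near_coast" in defects:
                (x, y), snap_target = _offshore_point(rng, coast_rings,
                                                      prepared_country,
                                                      (0.1, 0.9), 0.05)
            if {"at_centroid", "sea_far", "sea_near_coast"} & set(defects):
                used_keys.add((species, round(x, 4), round(y, 4)))
            decimals = 5
            if "low_precision" in defects:
                decimals = 2
                x, y = round(x, 2), round(y, 2)
            lat_text, lon_text = _fmt(y, decimals), _fmt(x, decimals)
            lat: Optional[float] = float(lat_text)
            lon: Optional[float] = float(lon_text)
            if "missing_coords" in defects:
                lat = lon = lat_text = lon_text = None
            if "high_uncertainty" in defects:
                unc = float(np.round(rng.uniform(501, 5000), 1))
            if "pre_1970" in defects:
                year = int(rng.integers(1900, 1970))
            if "excluded_source" in defects:
                provider = "iNaturalist"
            if "bad_issue_flag" in defects:
                issue_flags.add("country coordinate mismatch")
            if "cultivated" in defects:
                is_cultivated = True

            record = OccurrenceRecord(
                record_id=rid, genus="Brassica", species_epithet=species,
                author="Auct.", lat_text=lat_text, lon_text=lon_text,
                lat=lat, lon=lon, uncertainty_m=unc, event_year=year,
                source="gbif" if rng.random() < 0.5 else "geoportal",
                provider=provider, basis_of_record="HUMAN_OBSERVATION",
                issue_flags=issue_flags, is_cultivated=is_cultivated,
                conservation_side="in_situ", country_claimed="IT")
            records.append(record)

            # --- expected fate under the cascade
            reason = None
            for defect, rsn in _ATTRIBUTE_REASON:
                if defect in defects:
                    reason = rsn
                    break
            expected_snap = False
            final = (lon, lat) if lat is not None else None
            if reason is None:
                if "at_centroid" in defects:
                    reason = "at_centroid"
                elif "sea_far" in defects:
                    reason = "in_sea_far"
                elif "sea_near_coast" in defects:
                    expected_snap = True
                    final = snap_target
            rt = RecordTruth(
                defects=defects, inside_sites=site_attrs is not None,
                site_code=site_attrs["site_code"] if site_attrs else None,
                site_type=site_attrs["site_type"] if site_attrs else None,
                lclu_code=lclu_code,
                lclu_group=(lclu_table.reclassify(lclu_code)
                            if lclu_code is not None else None),
                expected_reason=reason, expected_snap=expected_snap,
                snap_target=snap_target, final_position=final)
            truth.per_record[rid] = rt
            for d in defects:
                if d == "duplicate":
                    continue   # only counts when a clone is actually emitted
                truth.injected_counts[d] += 1
            if reason is not None:
                truth.expected_reason_counts[reason] += 1
            else:
                truth.expected_kept_ids.add(rid)
                if expected_snap:
                    truth.expected_snapped_ids.add(rid)

            # --- duplicate clone: only for otherwise clean records
            if "duplicate" in defects and len(defects) == 1:
                clone_id = rid + "D"
                clone = OccurrenceRecord(
                    record_id=clone_id, genus="Brassica", species_epithet=species,
                    author=None, lat_text=lat_text, lon_text=lon_text,
                    lat=lat, lon=lon, uncertainty_m=None,
                    event_year=year - int(rng.integers(1, 10)),
                    source=record.source, provider=provider,
                    basis_of_record=None, conservation_side="in_situ",
                    country_claimed="IT")
                records.append(clone)
                truth.per_record[clone_id] = RecordTruth(
                    defects=["duplicate"], inside_sites=rt.inside_sites,
                    site_code=rt.site_code, site_type=rt.site_type,
                    lclu_code=rt.lclu_code, lclu_group=rt.lclu_group,
                    expected_reason="duplicate")
                truth.injected_counts["duplicate"] += 1
                truth.expected_reason_counts["duplicate"] += 1

    # --- ex situ side: Bernoulli subsample of expected-kept records
    ex_records = []
    for r in records:
        rt = truth.per_record[r.record_id]
        if rt.expected_reason is None and rng.random() < config.ex_situ_subsample_rate:
            lon, lat = rt.final_position
            lat_text, lon_text = _fmt(float(lat), 5), _fmt(float(lon), 5)
            lat, lon = float(lat_text), float(lon_text)
            ex_id = "EX" + r.record_id
            ex_records.append(OccurrenceRecord(
                record_id=ex_id, genus=r.genus, species_epithet=r.species_epithet,
                author=r.author, lat=lat, lon=lon,
                lat_text=lat_text, lon_text=lon_text,
                uncertainty_m=50.0, event_year=2015, source="genesys",
                provider="GENESYS", conservation_side="ex_situ",
                country_claimed="IT"))
            truth.ex_situ_ids.add(ex_id)
    records.extend(ex_records)

    # --- expected 10-km grid cells from final kept positions
    for rid in truth.expected_kept_ids:
        lon, lat = truth.per_record[rid].final_position
        truth.expected_in_situ_cells[(int(np.floor(lon / 10.0)),
                                      int(np.floor(lat / 10.0)))] += 1
    for r in ex_records:
        truth.expected_ex_situ_cells[(int(np.floor(r.lon / 10.0)),
                                      int(np.floor(r.lat / 10.0)))] += 1
    return records, truth


# ---------------------------------------------------------------------------
# transcribed reference tables

@dataclass
class PriorityRow:
    species: str
    genus: str
    endemism: Optional[str]
    red_list: Optional[str]
    populations: int
    within_n: int
    within_pct_printed: int


@dataclass
class GenusTotals:
    genus: str
    n_species: int
    populations: int
    within_n: Optional[int]
    within_pct_printed: int


@dataclass
class Fixtures:
    table1: dict[str, ReclassTable]               # scheme -> reclass table
    table3: dict[str, PriorityRow]                # species -> counts
    table4: dict[str, dict[str, tuple[int, int]]]  # species -> region -> (in, ex)
    genus_totals: dict[str, GenusTotals]


def _read_resource_csv(name: str):
    with resources.files("cwrgap.data").joinpath(name).open() as fh:
        return list(csv.DictReader(fh))


def published_tables() -> Fixtures:
    """Verbatim transcriptions of the printed reference tables."""
    table3 = {}
    for row in _read_resource_csv("table3_priority_species.csv"):
        table3[row["species"]] = PriorityRow(
            species=row["species"], genus=row["genus"],
            endemism=row["endemism"] or None, red_list=row["red_list"] or None,
            populations=int(row["populations"]), within_n=int(row["within_n"]),
            within_pct_printed=int(row["within_pct_printed"]))
    table4: dict = {}
    for row in _read_resource_csv("table4_brassica_regions.csv"):
        table4.setdefault(row["species"], {})[row["region"]] = (
            int(row["in_situ"]), int(row["ex_situ"]))
    totals = {}
    for row in _read_resource_csv("genus_totals.csv"):
        totals[row["genus"]] = GenusTotals(
            genus=row["genus"], n_species=int(row["n_species"]),
            populations=int(row["populations"]),
            within_n=int(row["within_n"]) if row["within_n"] else None,
            within_pct_printed=int(row["within_pct_printed"]))
    table1 = {s: load_reclass_table(s) for s in ("corine", "esacci")}
    return Fixtures(table1, table3, table4, totals)
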