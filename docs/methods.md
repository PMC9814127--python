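# Methods

This note documents the analysis model implemented by `cwrgap`, the
parameters that matter, the synthetic-data design, and the numerical
choices made where the design was genuinely open.

## The analysis

The pipeline evaluates the in situ conservation status of crop wild
relative (CWR) populations from point occurrence records.  Records come
from heterogeneous providers — a national biodiversity geoportal, GBIF
(wild observations) and Genesys (genebank accessions, by definition
*ex situ*) — in delimited text with provider-specific column names; a
*dialect* mapping (editable JSON resource) normalises them into one
schema.  Original coordinate strings are kept verbatim because one QC rule
is defined on decimal digits as written.

### Quality-control cascade

Removals happen in a fixed order, and each removed record is ledgered
under the **first** matching reason, so `|kept| + |removed| = |input|`
and ledgers are reproducible.  The order (attribute rules, then
deduplication, then spatial rules) reflects the two-pass structure of
standard occurrence cleaning: cheap attribute checks first, geometry last.

| rule | default | notes |
|---|---|---|
| cultivated material | — | flag from provider fields (e.g. MCPD SAMPSTAT ≥ 300) |
| declared country | IT + SM | attribute check only; geometry handled later |
| excluded providers | iNaturalist | unqualified-source rule |
| issue flags | invalid basis of record; fuzzy institution match; country coordinate mismatch | any overlap removes |
| missing coordinates | — | absent, never zero-filled |
| coordinate precision | ≥ 3 decimal digits required | on text when available; numerically, x is "≤ 2-decimal" when \|100x − round(100x)\| < 1e-9 |
| stated uncertainty | > 500 m removed | strict inequality |
| date | year < 1970 removed | year-only resolution suffices |
| duplicates | same side + taxon + coords at 4 decimals (~11 m) | survivor: latest year, then most populated optional fields, then smallest id |
| centroid placeholder | < 1 km from country centroid | tolerance chosen to match the coastal scale; not stated by the source rule |
| outside border / at sea | snap if < 1 km from coast, else remove | snapping automates the "manually repositioned along the coast" practice |

Ambiguities resolved here: (i) a record violating several rules is counted
once, under the first rule — per-reason tallies are therefore
order-dependent and must not be compared across pipelines with different
orders; (ii) the duplicate rule needs a coordinate-equality definition,
set to 4 decimals and configurable; (iii) deduplication never merges an
in situ record with an ex situ accession at the same place — the two
databases are distinct by construction.

### Distances and projection

Planar synthetic layers (pseudo-CRS `planar-km`) use Euclidean distances.
Geographic layers use a local ellipsoidal tangent-plane chart (prime
vertical and meridional curvature radii at the point); its relative error
is far below 0.1 % at the ≤ 10 km ranges where metric decisions are made
(coast snapping, centroid tolerance).  The density grid for geographic
data lives in ETRS89-LAEA (EPSG:3035), implemented in closed form on
GRS80; the forward transform reproduces the standard published worked
example (50°N 5°E → 3962799.45 E, 2999718.85 N) to the centimetre, and a
test verifies the equal-area property by independent line-integral area
computation on the authalic sphere.  The grid origin is fixed at projected
(0, 0) with 10 km alignment, which reproduces the geometry of the standard
European reference grid without shipping it.

### Overlay

Point-in-polygon membership is the even–odd (ray-casting) predicate on
ring coordinates, with holes excluded and boundary points counted
**inside** (deterministic, and conservative toward protection status).
It is applied in geographic coordinates; at national scale polygon edges
are dense relative to geodesic curvature, so the planar predicate matches
GIS practice (antimeridian neighbourhoods are out of scope).  When a point
lies in several protected sites the retained site follows precedence
C > A > B — C (dual SPA + SCI/SAC designation) is the most informative
class — with ties broken by smallest site code.  This covers both
pre-resolved and overlapping source encodings, but on multiply-covered
points a tally may differ from one produced under another convention.

Percentages are integers rounded **half away from zero**, computed in
exact integer arithmetic; this convention reproduces all 19 printed
percentages of the packaged priority-species table.  A zero-total group is
reported absent, never as 0 %.  Site-type breakdowns are shares *within*
the protected subset; every other grouping partitions the full record set.

### Land cover

Corine level-3 codes (44 codes, 111–523) collapse to the five principal
classes by leading digit; the packaged ESA CCI table maps 190 → Urban
areas, {10, 11, 12, 30} → "Cropland, rainfed + Mosaic cropland",
{40, 60, 70, 90, 100, 120, 130, 150, 180} → "Natural vegetation".  ESA CCI
codes outside that published list are *retained but display-suppressed*
(Bare areas, Water, Other) rather than rejected: full national layers
contain them even when a comparison displays only the groups above.
Per-stratum proportions always sum to 1 over all groups including
suppressed ones and `Unclassified`; suppression affects display output
only.  The anthropized / natural-seminatural dichotomy is a derived
aggregate, not a third scheme.  Land cover is modelled as a polygon layer
(vectorised raster): the overlay contract is identical and the package
stays download-free; raster ingestion is out of scope.

### Density grid

Cells are half-open squares [x, x+s) × [y, y+s), so edge points belong to
exactly one (the higher-index) cell.  Density classes are, among occupied
cells of one conservation side, the fraction holding exactly k records.
Gap cells (≥ 1 in situ, 0 ex situ) are returned ranked by in situ count
with the dominant species attached; naming the regions they fall in is
left to the caller.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *structure* of the real inputs, not their
geography: a two-part country (mainland + island) in planar km
coordinates declared as an identity pseudo-CRS, so geometric oracles are
exact; rectangular protected sites placed to a coverage target of 0.20 of
the land area (the approximate Natura 2000 share of the study country)
with type mix A/B/C = 0.16/0.76/0.08 (the study's reported breakdown for
the case-study genus) and one deliberately overlapping A–C pair; vertical
administrative bands and three horizontal biogeographic bands
(Mediterranean / Continental / Alpine); and a square land-cover mosaic
that exactly tiles the country.

Defaults mirror the study conditions: 7 target species of one genus,
30 records per species (≥ 200 records total), 0.68 of records placed
inside sites, and an ex situ side drawn as a 0.09 Bernoulli subsample of
the clean in situ records (31/354 ≈ 0.088 in the study).  Defect rates are
0.05–0.08 per class, applied independently per record.  Bookkeeping
choices that keep ground truth exact: duplicate clones are only attached
to otherwise-clean records (so the dedup survivor is predictable);
centroid placeholders are jittered within the 1 km tolerance radius so
same-species placeholders stay distinct through deduplication; offshore
defect points are placed along segment normals after verifying the
offset equals the true coast distance; clean records keep ≥ 50 m from the
coast, ≥ 1.2 km from the centroid, and unique 4-decimal coordinates per
species.

Passing tests on this world therefore demonstrate that the machinery is
correct (counts conserved, injections recovered, oracles matched).  They
do **not** demonstrate robustness to properties the generator omits:
clustered or autocorrelated sampling, taxonomic ambiguity beyond a
synonym table, datum errors, non-perpendicular coastal displacement, or
raster-resolution land-cover effects.  A second, tiny lon/lat world
exercises the geodesic code paths (tangent-plane distances, degree
coordinates) at realistic Mediterranean latitudes.

## Transcribed reference tables

The packaged CSVs transcribe the printed tables the analysis is anchored
to: 19 priority species with population and within-network counts (sum =
209), per-region in situ / ex situ counts for 7 case-study species (sums =
354 and 31, including 2 populations recorded in San Marino as a table
footnote), the land-cover code groups, and per-genus totals (sum = 1996).
One internal inconsistency in the source is preserved as printed: the
regional table's Sicily column sums to 144 in situ records, while the
accompanying prose total for Sicily (133) omits one species' 11 records;
the fixtures transcribe the table, and consumers aggregating by region
will obtain 144.

## Problem sizes and determinism

Default test and acceptance runs use the 210-record synthetic world,
10 000 point-in-polygon oracle instances and 500-point grid checks —
sizes at which every oracle is exhaustive and runs complete in seconds
while the combinatorics (multi-site overlap, multi-defect records,
boundary cases) are all exercised.  Every stochastic component takes a
single integer seed; same seed ⇒ byte-identical layers, records, and
pipeline reports.

## Known limitations

* Even–odd membership is planar; polygons spanning the antimeridian or
  pole are unsupported.
* The tangent-plane distance degrades beyond a few tens of km; it is only
  used for sub-10 km decisions.
* No fuzzy duplicate detection beyond the 4-decimal rule; records of the
  same population digitised with different coordinate precision can
  survive as distinct.
* File-based pipeline runs require GeoJSON layers; shapefile and raster
  ingestion are out of scope.
* The removal ledger's per-reason totals depend on the documented cascade
  order and are not comparable to tallies produced under other orders.
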