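# cwrgap

In situ conservation gap analysis for crop wild relatives (CWR): a tested,
reusable pipeline for cleaning occurrence records, overlaying them on a
protected-area network, reclassifying land cover, and comparing in situ vs
ex situ record densities on an equal-area grid.

## Who this is for

Conservation scientists and biodiversity informaticians who aggregate
population occurrence records from heterogeneous sources (national
geoportals, GBIF, Genesys genebank exports) and need to answer questions
like: *what share of the wild populations of a priority species lies inside
the Natura 2000 network? What is the land use at unprotected sites? Where
do wild populations occur that have never been collected into genebanks?*

## What it computes

1. **Quality control** (`cwrgap.qc_filter`). Records are removed, each with
   exactly one ledgered reason, in a fixed cascade: cultivated material,
   declared outside the target country, excluded providers (e.g.
   iNaturalist), disqualifying issue flags, missing coordinates,
   low-precision coordinates (≤ 2 decimal digits *as written*, or stated
   uncertainty > 500 m), records dated before 1970, duplicates (same taxon
   and coordinates to 4 decimals; the most recent and most complete record
   survives). A spatial pass then drops points outside the national border
   or parked on the country centroid, and repositions points < 1 km
   offshore onto the nearest coastline point.
2. **Protection status** (`cwrgap.spatial_overlay`). Boundary-inclusive
   even–odd point-in-polygon overlay against protected sites (designation
   types A = SPA, B = pSCI/SCI/SAC, C = dual; precedence C > A > B when
   sites overlap), administrative regions and biogeographical regions.
   Summaries report n_total, n_inside and an integer percentage
   `percent(n, N) = round_half_away(100·n/N)`.
3. **Land cover / land use** (`cwrgap.lclu_reclass`). Corine level-3 codes
   collapse to the five principal classes (leading digit); ESA CCI codes
   collapse to Urban areas / Cropland + Mosaic cropland / Natural
   vegetation, with remaining codes retained but display-suppressed.
   Per-species, inside-vs-outside-network group proportions plus the
   derived *anthropized* and *natural/seminatural* aggregates.
4. **Density grids and gap cells** (`cwrgap.density_grid`). 10 km × 10 km
   cells in ETRS89-LAEA (EPSG:3035, implemented in-package) for real
   lon/lat data, identity projection for planar synthetic worlds; per-cell
   in situ and ex situ counts; a *gap cell* has ≥ 1 in situ and 0 ex situ
   records.
5. **Synthetic worlds** (`cwrgap.synthetic_data`). A seeded generator
   builds a planar country (mainland + island), protected sites, region
   layers, a land-cover mosaic and occurrence records with independently
   injected defects — and the exact bookkeeping needed to verify every
   stage. It also ships transcriptions of the published reference tables
   (19 priority species, per-region Brassica counts, land-cover groups).

## Worked example

Run the full pipeline on a seeded synthetic world:

```python
from cwrgap.pipeline import PipelineConfig, run_pipeline
rep = run_pipeline(PipelineConfig(outdir="out", seed=7))
print(rep["stages"])
print(rep["protection"]["overall"])
```

prints

```
{'input': 219, 'after_attribute_filters': 141, 'after_dedup': 132, 'after_spatial': 121}
{'n_total': 121, 'n_inside': 81, 'pct_inside': 67}
```

219 in situ records were simulated; the attribute filters removed 78 (11
cultivated, 18 from an excluded provider, 8 flagged, 15 without
coordinates, 8 too coarse, 8 too uncertain, 10 too old), deduplication 9,
and the spatial pass 11 (5 at the country centroid, 6 far out at sea) —
leaving 121 clean populations, of which 81 (67 %) lie inside the protected
network. The density section of the same report counts 33 occupied in situ
cells, 9 ex situ cells and 24 gap cells — unprotected-by-collection areas
a gene-bank mission could target.

Aggregating the packaged priority-species table instead:

```python
from cwrgap.pipeline import fixture_report
print(fixture_report("table3")["genus"])
```

```
{'Allium':   {'n_total': 61,  'n_inside': 38, 'pct_inside': 62},
 'Brassica': {'n_total': 141, 'n_inside': 83, 'pct_inside': 59},
 'Triticum': {'n_total': 7,   'n_inside': 4,  'pct_inside': 57}}
```

i.e. of the 209 populations of the 19 highest-priority species, 62 % of
*Allium*, 59 % of *Brassica* and 57 % of *Triticum* populations fall in
Natura 2000 sites.

A command-line interface mirrors the stages
(`cwrgap simulate | qc | overlay | lclu | grid | report`); see
`cwrgap --help`.

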