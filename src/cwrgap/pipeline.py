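"""End-to-end orchestration: QC → overlay → land cover → density grid.

``run_pipeline`` executes the stages in the order the analysis defines
them, writes every intermediate artifact under an output directory, and
returns (and writes) a consolidated JSON report: record counts per stage,
per-reason removal tallies, protection summaries, land-cover proportions,
density-class proportions and gap cells.  Reports are pure functions of
(inputs, configuration, seed); rerunning with the same configuration
yields a byte-identical report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import density_grid, lclu_reclass, spatial_overlay
from .occurrence_io import (SynonymTable, harmonize_taxa, read_layer,
                            read_occurrences, write_layer, write_records)
from .qc_filter import (FilterConfig, FilterResult, apply_attribute_filters,
                        deduplicate, spatial_consistency)
from .synthetic_data import SyntheticConfig, World, make_world, simulate_occurrences

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration; defaults reproduce the study rules."""

    outdir: Path = Path("cwrgap_out")
    seed: int = 0
    records_path: Optional[Path] = None     # None -> simulate a synthetic world
    layer_paths: Optional[dict] = None      # layer_kind -> GeoJSON path
    centroid: Optional[tuple[float, float]] = None
    dialect: str = "generic"
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    synthetic: SyntheticConfig = None  # type: ignore[assignment]
    group_by: tuple[str, ...] = ("species", "genus", "site_type", "biogeo_region")
    lclu_scheme: str = "corine"
    cell_size: Optional[float] = None       # default: 10 km in layer units
    synonyms: Optional[SynonymTable] = None

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed)


def _write_ledger(result: FilterResult, path: Path) -> None:
    lines = ["record_id,reason,detail"]
    for rem in result.removed:
        detail = rem.detail.replace(",", ";")
        lines.append(f"{rem.record_id},{rem.reason},{detail}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_snapped(result: FilterResult, path: Path) -> None:
    lines = ["record_id,lon_before,lat_before,lon_after,lat_after,distance_m"]
    for s in result.snapped:
        lines.append(f"{s.record_id},{s.lon_before!r},{s.lat_before!r},"
                     f"{s.lon_after!r},{s.lat_after!r},{s.distance_m:.3f}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_assignments(assignments, path: Path) -> None:
    lines = ["record_id,inside_network,site_code,site_name,site_type,"
             "admin_region,biogeo_region"]
    for a in assignments:
        lines.append(",".join([
            a.record_id, "1" if a.inside_network else "0",
            a.site_code or "", (a.site_name or "").replace(",", ";"),
            a.site_type or "", a.admin_region or "", a.biogeo_region or ""]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the consolidated report dict."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    # --- input: read or simulate
    if config.records_path is not None:
        records = read_occurrences(config.records_path, config.dialect)
        layers = {kind: read_layer(config.layer_paths[kind], kind)
                  for kind in ("country", "coastline", "protected_sites",
                               "admin_regions", "biogeo_regions", "lclu")}
        if config.centroid is not None:
            centroid = config.centroid
        else:
            from shapely.ops import unary_union
            c = unary_union([f.geometry for f in layers["country"].features]).centroid
            centroid = (c.x, c.y)
        world = World(layers["country"], layers["coastline"],
                      layers["protected_sites"], layers["admin_regions"],
                      layers["biogeo_regions"], layers["lclu"], centroid)
    else:
        world = make_world(config.synthetic)
        records, _truth = simulate_occurrences(config.synthetic, world)
        for name, layer in world.layers().items():
            write_layer(layer, out / f"{name}.geojson")
    write_records(records, out / "records_input.csv")

    in_situ = [r for r in records if r.conservation_side == "in_situ"]
    ex_situ = [r for r in records if r.conservation_side == "ex_situ"]
    report["stages"]["input"] = len(in_situ)

    # --- harmonise
    if config.synonyms is not None:
        in_situ = harmonize_taxa(in_situ, config.synonyms)

    # --- QC cascade
    attr = apply_attribute_filters(in_situ, config.filter_config)
    report["stages"]["after_attribute_filters"] = len(attr.kept)
    dedup = deduplicate(attr.kept, config.filter_config)
    report["stages"]["after_dedup"] = len(dedup.kept)
    spatial = spatial_consistency(dedup.kept, world.country, world.coastline,
                                  world.centroid, config.filter_config)
    report["stages"]["after_spatial"] = len(spatial.kept)
    combined = FilterResult(spatial.kept,
                            attr.removed + dedup.removed + spatial.removed,
                            spatial.snapped)
    report["removal_reasons"] = dict(sorted(combined.reason_counts().items()))
    report["n_snapped"] = len(combined.snapped)
    _write_ledger(combined, out / "removal_ledger.csv")
    _write_snapped(combined, out / "snapped.csv")
    write_records(combined.kept, out / "records_kept.csv")
    kept = combined.kept

    # --- overlay + protection summaries
    assignments = spatial_overlay.assign_sites(
        kept, world.protected_sites, world.admin_regions, world.biogeo_regions)
    write_assignments(assignments, out / "assignments.csv")
    report["protection"] = {}
    for key in config.group_by:
        table = spatial_overlay.summarize_protection(assignments, kept, key)
        report["protection"][key] = table.to_dict()
    n_inside = sum(a.inside_network for a in assignments)
    report["protection"]["overall"] = {
        "n_total": len(kept), "n_inside": n_inside,
        "pct_inside": (spatial_overlay.percent(n_inside, len(kept))
                       if kept else None)}

    # --- land cover
    labels = lclu_reclass.classify_record_lclu(kept, world.lclu,
                                               config.lclu_scheme)
    props = lclu_reclass.lclu_proportions(labels, assignments, kept,
                                          config.lclu_scheme)
    report["lclu"] = {
        "scheme": config.lclu_scheme,
        "display": {f"{sp}|{stratum}": vals
                    for (sp, stratum), vals in sorted(props.display().items())},
        "aggregates": {f"{sp}|{stratum}": {
            "anthropized": s["anthropized"],
            "natural_seminatural": s["natural_seminatural"],
            "n_sites": s["n_sites"]}
            for (sp, stratum), s in sorted(props.strata.items())},
    }

    # --- density grid
    planar = "planar" in world.country.crs_note.lower()
    cell = config.cell_size if config.cell_size is not None else \
        (10.0 if planar else 10_000.0)
    pts = [density_grid.project_point(r.lon, r.lat, planar)
           for r in kept + ex_situ if r.has_coords]
    xs, ys = [p[0] for p in pts], [p[1] for p in pts]
    grid = density_grid.build_grid((min(xs), min(ys), max(xs), max(ys)), cell)
    in_counts = density_grid.count_points(grid, kept, "in_situ", planar)
    ex_counts = density_grid.count_points(grid, ex_situ, "ex_situ", planar)
    gaps, diffs = density_grid.gap_cells(in_counts, ex_counts)
    density_grid.write_grid_counts(in_counts, ex_counts, out / "grid_counts.csv")
    report["density"] = {
        "n_cells_in_situ": len(in_counts.occupied()),
        "n_cells_ex_situ": len(ex_counts.occupied()),
        "class_proportions_in_situ": {
            str(k): v for k, v in
            density_grid.density_class_proportions(in_counts).items()},
        "class_proportions_ex_situ": (
            {str(k): v for k, v in
             density_grid.density_class_proportions(ex_counts).items()}
            if ex_counts.occupied() else None),
        "n_gap_cells": len(gaps),
        "top_gap_cells": [{"col": g.col, "row": g.row, "n_in_situ": g.n_in_situ,
                           "dominant_species": g.dominant_species}
                          for g in gaps[:10]],
        "max_density_difference": max(diffs.values()) if diffs else None,
    }

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True), encoding="utf-8")
    return report


def fixture_report(which: str = "table3") -> dict:
    """Aggregate a transcribed reference table (no synthetic world involved)."""
    from .synthetic_data import published_tables
    fx = published_tables()
    if which == "table3":
        counts = {s: (row.populations, row.within_n)
                  for s, row in fx.table3.items()}
        species = spatial_overlay.summarize_counts(counts, "species")
        genus = spatial_overlay.summarize_counts(
            spatial_overlay.aggregate_counts(
                counts, lambda s: fx.table3[s].genus), "genus")
        return {"species": species.to_dict(), "genus": genus.to_dict()}
    if which == "table4":
        per_species = {s: sum(v[0] for v in regions.values())
                       for s, regions in fx.table4.items()}
        per_region: dict[str, int] = {}
        ex_total = 0
        for regions in fx.table4.values():
            for region, (n_in, n_ex) in regions.items():
                per_region[region] = per_region.get(region, 0) + n_in
                ex_total += n_ex
        return {"in_situ_per_species": per_species,
                "in_situ_per_region": dict(sorted(per_region.items())),
                "in_situ_total": sum(per_species.values()),
                "ex_situ_total": ex_total}
    raise ValueError(f"unknown fixture {which!r}")
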