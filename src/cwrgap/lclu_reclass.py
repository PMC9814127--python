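"""Land-cover / land-use reclassification and per-stratum proportions.

Two classification schemes are supported, harmonised into comparable
groups so that sites inside and outside the protected network can be
contrasted on the same axis:

* **Corine Land Cover** level-3 codes (111–523) collapse to the five
  principal classes given by the leading digit: Artificial surfaces,
  Agricultural areas, Forest and seminatural areas, Wetlands, Water
  bodies.
* **ESA CCI Land Cover** numeric codes collapse to Urban areas (190),
  "Cropland, rainfed + Mosaic cropland" (10, 11, 12, 30) and "Natural
  vegetation" (40, 60, 70, 90, 100, 120, 130, 150, 180); remaining codes
  of the product are retained but display-suppressed (Bare areas, Water,
  Other), since full national layers contain them even when a comparison
  only displays the groups above.

The *anthropized* aggregate (Artificial + Agricultural, or Urban +
Cropland groups) and the *natural/seminatural* aggregate are derived
quantities, not a third scheme.

The code→group mapping ships as an editable delimited-text resource
(``data/lclu_reclass.tsv``: scheme, code, group, suppressed flag).
"""

from __future__ import annotations

import csv
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

from .errors import ValidationError
from .geometry import point_in_rings
from .occurrence_io import OccurrenceRecord, PolygonLayer
from .spatial_overlay import Assignment

SCHEMES = ("corine", "esacci")
UNCLASSIFIED = "Unclassified"

ANTHROPIZED_GROUPS = {
    "corine": frozenset({"Artificial surfaces", "Agricultural areas"}),
    "esacci": frozenset({"Urban areas", "Cropland, rainfed + Mosaic cropland"}),
}
NATURAL_GROUPS = {
    "corine": frozenset({"Forest and seminatural areas"}),
    "esacci": frozenset({"Natural vegetation"}),
}


@dataclass
class ReclassTable:
    scheme: str
    mapping: dict[int, str]
    display_suppressed: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValidationError(f"unknown scheme {self.scheme!r}")

    def reclassify(self, code: int) -> str:
        if code not in self.mapping:
            raise ValidationError(f"{self.scheme} code {code} outside the code universe")
        return self.mapping[code]


def _load_tables() -> dict[str, ReclassTable]:
    tables = {s: ReclassTable(s, {}, set()) for s in SCHEMES}
    with resources.files("cwrgap.data").joinpath("lclu_reclass.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            t = tables[row["scheme"]]
            t.mapping[int(row["code"])] = row["group"]
            if row["suppressed"] == "1":
                t.display_suppressed.add(row["group"])
    return tables


_TABLES = _load_tables()


def load_reclass_table(scheme: str) -> ReclassTable:
    if scheme not in _TABLES:
        raise ValidationError(f"unknown scheme {scheme!r}")
    return _TABLES[scheme]


def reclassify_corine(level3_code: int) -> str:
    """Principal Corine class for a level-3 code (the leading digit)."""
    if not 111 <= level3_code <= 523:
        raise ValidationError(f"Corine level-3 code {level3_code} out of range 111-523")
    return _TABLES["corine"].reclassify(level3_code)


def reclassify_esacci(code: int) -> str:
    """Harmonised group for an ESA CCI land-cover code."""
    return _TABLES["esacci"].reclassify(code)


def classify_record_lclu(records: Iterable[OccurrenceRecord],
                         lclu_layer: PolygonLayer,
                         scheme: str) -> dict[str, str]:
    """Label each record by the group of the land-cover patch containing it.

    Patches carry a ``code`` attribute in the declared scheme.  Records
    outside every patch (or without coordinates) are labelled
    ``Unclassified``.
    """
    table = load_reclass_table(scheme)
    labels: dict[str, str] = {}
    for r in records:
        label = UNCLASSIFIED
        if r.has_coords:
            for f in lclu_layer.features:
                if any(point_in_rings(r.lon, r.lat, rings) for rings in f.rings()):
                    label = table.reclassify(int(f.attributes["code"]))
                    break
        labels[r.record_id] = label
    return labels


@dataclass
class LcluProportions:
    """Per (species, inside/outside network) stratum group proportions."""

    scheme: str
    strata: dict  # (species, "inside"|"outside") -> {"groups", "n_sites", aggregates}

    def display(self) -> dict:
        """Proportions with display-suppressed groups (and Unclassified) hidden."""
        hidden = _TABLES[self.scheme].display_suppressed | {UNCLASSIFIED}
        out = {}
        for key, s in self.strata.items():
            out[key] = {g: p for g, p in s["groups"].items() if g not in hidden}
        return out


def lclu_proportions(labels: dict[str, str],
                     assignments: Sequence[Assignment],
                     records: Sequence[OccurrenceRecord],
                     scheme: str,
                     species_of: Optional[dict[str, str]] = None) -> LcluProportions:
    """Group proportions per species × inside/outside-network stratum.

    Proportions per stratum sum to 1 over *all* groups, including
    suppressed ones and Unclassified; display suppression only affects
    :meth:`LcluProportions.display`.  Also attaches the derived
    ``anthropized`` and ``natural_seminatural`` aggregates.  Strata with
    zero records are omitted.
    """
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}")
    inside_by_id = {a.record_id: a.inside_network for a in assignments}
    if species_of is None:
        species_of = {r.record_id: r.taxon for r in records}
    tallies: dict = defaultdict(Counter)
    for r in records:
        if r.record_id not in labels:
            continue
        stratum = (species_of[r.record_id],
                   "inside" if inside_by_id.get(r.record_id, False) else "outside")
        tallies[stratum][labels[r.record_id]] += 1
    strata = {}
    for key, counter in tallies.items():
        n = sum(counter.values())
        groups = {g: c / n for g, c in sorted(counter.items())}
        strata[key] = {
            "groups": groups,
            "n_sites": n,
            "anthropized": sum(p for g, p in groups.items()
                               if g in ANTHROPIZED_GROUPS[scheme]),
            "natural_seminatural": sum(p for g, p in groups.items()
                                       if g in NATURAL_GROUPS[scheme]),
        }
    return LcluProportions(scheme, strata)
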