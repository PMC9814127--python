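{
  "generic": {
    "delimiter": null,
    "conservation_side_default": "in_situ",
    "source_kind": "other",
    "columns": {
      "record_id": "record_id",
      "source": "source",
      "genus": "genus",
      "species_epithet": "species_epithet",
      "author": "author",
      "subspecies": "subspecies",
      "lat": "latitude",
      "lon": "longitude",
      "uncertainty_m": "uncertainty_m",
      "event_year": "year",
      "provider": "provider",
      "basis_of_record": "basis_of_record",
      "issue_flags": "issue_flags",
      "is_cultivated": "is_cultivated",
      "conservation_side": "conservation_side",
      "admin_region_claimed": "admin_region",
      "country_claimed": "country"
    }
  },
  "geoportal": {
    "delimiter": null,
    "conservation_side_default": "in_situ",
    "source_kind": "geoportal",
    "columns": {
      "record_id": "codice",
      "genus": "genere",
      "species_epithet": "specie",
      "author": "autore",
      "subspecies": "sottospecie",
      "lat": "latitudine",
      "lon": "longitudine",
      "uncertainty_m": "incertezza_m",
      "event_year": "anno",
      "provider": "fonte",
      "admin_region_claimed": "regione",
      "country_claimed": "paese",
      "natura2000_claimed": "natura2000",
      "site_code_claimed": "sito_codice",
      "site_type_claimed": "sito_tipo"
    }
  },
  "gbif": {
    "delimiter": "\t",
    "conservation_side_default": "in_situ",
    "source_kind": "gbif",
    "columns": {
      "record_id": "gbifID",
      "genus": "genus",
      "species_epithet": "specificEpithet",
      "author": "scientificNameAuthorship",
      "subspecies": "infraspecificEpithet",
      "lat": "decimalLatitude",
      "lon": "decimalLongitude",
      "uncertainty_m": "coordinateUncertaintyInMeters",
      "event_year": "year",
      "provider": "institutionCode",
      "basis_of_record": "basisOfRecord",
      "issue_flags": "issue",
      "is_cultivated": "establishmentMeans",
      "admin_region_claimed": "stateProvince",
      "country_claimed": "countryCode"
    }
  },
  "genesys": {
    "delimiter": null,
    "conservation_side_default": "ex_situ",
    "source_kind": "genesys",
    "columns": {
      "record_id": "ACCENUMB",
      "genus": "GENUS",
      "species_epithet": "SPECIES",
      "author": "SPAUTHOR",
      "subspecies": "SUBTAXA",
      "lat": "DECLATITUDE",
      "lon": "DECLONGITUDE",
      "uncertainty_m": "COORDUNCERT",
      "event_year": "COLLYEAR",
      "provider": "INSTCODE",
      "is_cultivated": "SAMPSTAT",
      "country_claimed": "ORIGCTY"
    }
  }
}
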