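import pytest

from cwrgap.qc_filter import (FilterResult, apply_attribute_filters, deduplicate,
                              spatial_consistency)
from cwrgap.synthetic_data import SyntheticConfig, make_world, simulate_occurrences

WORLD_SEED = 3


@pytest.fixture(scope="session")
def synthetic_world():
    """One seeded synthetic world + records + ground truth, shared read-only."""
    cfg = SyntheticConfig(seed=WORLD_SEED)
    world = make_world(cfg)
    records, truth = simulate_occurrences(cfg, world)
    return cfg, world, records, truth


@pytest.fixture(scope="session")
def qc_chain(synthetic_world):
    """The full QC cascade applied to the shared world's in situ records."""
    cfg, world, records, truth = synthetic_world
    in_situ = [r for r in records if r.conservation_side == "in_situ"]
    attr = apply_attribute_filters(in_situ)
    dedup = deduplicate(attr.kept)
    spatial = spatial_consistency(dedup.kept, world.country, world.coastline,
                                  world.centroid)
    combined = FilterResult(spatial.kept,
                            attr.removed + dedup.removed + spatial.removed,
                            spatial.snapped)
    return {"in_situ": in_situ,
            "ex_situ": [r for r in records if r.conservation_side == "ex_situ"],
            "attr": attr, "dedup": dedup, "spatial": spatial,
            "combined": combined, "kept": combined.kept}
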