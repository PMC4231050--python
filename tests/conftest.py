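"""Shared fixtures: one synthetic genome and one full pipeline run per session."""

from types import SimpleNamespace

import pytest

from ssratlas import (assign_linkage_group, build_atlas, classify_location,
                      design_primers_for_hits, find_repeats, ssr_id_of)
from ssratlas.synthetic_fixtures import default_fixture, simulate_genome


@pytest.fixture(scope="session")
def sim():
    """The standard 20-plant ~100 kb validation genome."""
    return simulate_genome(default_fixture(seed=1))


@pytest.fixture(scope="session")
def pipeline(sim):
    """Scan + classify + LG + primers + atlas over the validation genome."""
    hits = []
    for rec in sim.records:
        hits.extend(find_repeats(rec))
    contexts = {ssr_id_of(h): classify_location(h, sim.annotation) for h in hits}
    lgs = {ssr_id_of(h): assign_linkage_group(h.scaffold, sim.lg_map).lg_label
           for h in hits}
    primers = design_primers_for_hits(sim.records, hits)
    records = build_atlas(hits, contexts, lgs, primer_results=primers)
    return SimpleNamespace(sim=sim, hits=hits, contexts=contexts, lgs=lgs,
                           primers=primers, records=records)
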