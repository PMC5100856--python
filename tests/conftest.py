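"""Shared fixtures: seeded synthetic panels and reference strains."""

from __future__ import annotations

import pytest

from consomix import simulate as sim
from consomix import variants as var


@pytest.fixture(scope="session")
def painting_config() -> sim.SimConfig:
    """Study conditions for ancestry-recovery runs: 6 lines, 2-Mb donor
    chromosome, three lineages at 0.008/bp divergence, lineage segments of
    at least 50 kb, no background islands."""
    return sim.SimConfig(
        seed=11,
        n_lines=6,
        subspecies_rates={lin: 0.008 for lin in sim.LINEAGES},
        ancestry_segment_min_bp=50_000,
        island_rate_per_line=0.0,
    )


@pytest.fixture(scope="session")
def painting_panel(painting_config):
    """(founders, strains, lines) for the painting study conditions."""
    founders = sim.simulate_founders(painting_config)
    strains = {
        lin: sim.founder_records(founders[lin][0], painting_config.donor_chrom)
        for lin in painting_config.lineages
    }
    lines = sim.simulate_panel(painting_config)
    return founders, strains, lines


@pytest.fixture(scope="session")
def panel6(painting_panel) -> var.VariantPanel:
    _, _, lines = painting_panel
    return var.VariantPanel({line_id: recs for line_id, recs, _ in lines})
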