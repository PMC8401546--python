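from pathlib import Path

import pytest

from uspprof.cdsearch_io import parse_coordinate_string
from uspprof.synthetic_data import SimulationConfig, simulate

#: The canonical 12-contact ATP example: MJ0577-style ligand-binding sites.
ATP_COORD_STRING = "P9, V10, D11, C39, M108, G109, R111, G112, G122, S123, V124, T125"


@pytest.fixture
def atp_sites():
    return parse_coordinate_string(ATP_COORD_STRING)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A fixed 6-genome synthetic cohort, simulated once per session."""
    out = tmp_path_factory.mktemp("cohort")
    return simulate(SimulationConfig(n_genomes=6, seed=42), out)
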