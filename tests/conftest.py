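from pathlib import Path

import pytest

from aoxkit.catalogs import load_catalogs
from aoxkit.simulate import make_family

REPO_ROOT = Path(__file__).resolve().parents[1]

# Drop-in location for transcriptions of the published supplementary
# sequence figures.  The acceptance tests that assert printed values need
# these files; they fail with a pointer here when the transcriptions are
# absent (they are not redistributable as text in this repository's inputs).
PUBLISHED_DATA_DIR = REPO_ROOT / "data" / "published"


@pytest.fixture(scope="session")
def catalogs():
    return load_catalogs()


SIM_CONFIG = {
    "clade_counts": {"AOX1a": 2, "AOX1c": 1, "AOX1e": 1, "AOX1d": 2},
    "intron_choices": {"AOX1a": [3], "AOX1c": [4], "AOX1e": [2], "AOX1d": [0, 1]},
    "knockouts": [[1, ["LETVAA"]], [3, ["LETVAA", "ERMHLMT", "LEEEA", "RADEAHH"]]],
    "low_confidence": [2],
    "splice_variants": 1,
    "cpg_genes": 1,
    "promoter_motifs": {"MDM_stringent": 2, "W_box": 1},
}


@pytest.fixture(scope="session")
def family(catalogs):
    """A small synthetic family with knockouts, variants and planted motifs."""
    return make_family(SIM_CONFIG, seed=11, catalogs=catalogs)
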