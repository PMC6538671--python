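import pytest

from edmark.markerdesign import extract_amplicons
from edmark.seqio import ReferencePanel, SeqRecord
from edmark.simdata import (
    MarkerFixtureSpec,
    plant_marker_alignment,
    planted_primer_pair,
)

DEFAULT_SEED = 3


@pytest.fixture(scope="session")
def planted():
    """A default planted alignment with its ground truth and primer pair."""
    panel, truth = plant_marker_alignment(MarkerFixtureSpec(seed=DEFAULT_SEED))
    return panel, truth, planted_primer_pair(truth)


@pytest.fixture(scope="session")
def refdb(planted):
    """Reference amplicon panel (core sequences, taxon-labelled)."""
    panel, truth, pair = planted
    amps, failures = extract_amplicons(pair, panel, max_mm=1)
    assert not failures
    taxon_of = {r.id: r.taxon for r in panel.records}
    return ReferencePanel(
        [SeqRecord(id=tid, seq=core, taxon=taxon_of[tid]) for tid, core in amps]
    )
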