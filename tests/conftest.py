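import numpy as np
import pytest

from scatbarcode.primer_eval import ATP6_DF3, ATP6_DR1, DEFAULT_PRIMERS
from scatbarcode.seqcore import BarcodeSeq, reverse_complement
from scatbarcode.surveystats import IncidenceTable

REV_SITE = reverse_complement(BarcodeSeq("DR1", ATP6_DR1)).residues


def make_amplicon(insert=None, substitutions=None, rng=None, name="tmpl"):
    """Construct a 172 nt sense amplicon: DF3 + insert + revcomp(DR1).

    ``substitutions`` maps 1-based amplicon positions to replacement sense
    bases (applied last, so primer-site variants can be planted).
    """
    if insert is None:
        rng = rng or np.random.default_rng(0)
        insert = "".join(rng.choice(list("ACGT"), size=126))
    assert len(insert) == 126
    amp = list(ATP6_DF3 + insert + REV_SITE)
    for pos, base in (substitutions or {}).items():
        amp[pos - 1] = base
    return BarcodeSeq(name, "".join(amp))


@pytest.fixture
def case_table():
    """The case-study incidence table: six carnivore species, 149 samples."""
    return IncidenceTable(
        T=149,
        counts={
            "black-backed jackal": 130,
            "leopard": 12,
            "caracal": 3,
            "banded mongoose": 2,
            "Afro-asiatic wildcat": 1,
            "common genet": 1,
        },
    )


@pytest.fixture(scope="session")
def primers():
    return DEFAULT_PRIMERS
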