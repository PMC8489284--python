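import pytest
from hypothesis import HealthCheck, settings

from triadpipe.proteome import ProteinRecord, SubgenomeProteinDB

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def small_db() -> SubgenomeProteinDB:
    """Hand-built proteome: one triplet family, one competing family and
    one singleton, with planted shared / unique / cross-family peptides.

    - ``SHAREDPEPK`` occurs in all three F1 homoeologs (family-shared)
    - ``WWWWDDDDK`` only in F1.4B (locus-unique)
    - ``EEEEEEEK`` only in F1.4D (locus-unique)
    - ``CCCCCCCCC`` in F1.4A and F2.1A (cross-family)
    - ``HHHHHHHH`` only in the singleton F3.2D
    """
    records = [
        ProteinRecord("F1.4A", "A", "4A", "F1", "MSHAREDPEPKCCCCCCCCCR"),
        ProteinRecord("F1.4B", "B", "4B", "F1", "MSHAREDPEPKWWWWDDDDKR"),
        ProteinRecord("F1.4D", "D", "4D", "F1", "MSHAREDPEPKEEEEEEEKR"),
        ProteinRecord("F2.1A", "A", "1A", "F2", "MFFFFFFKCCCCCCCCCR"),
        ProteinRecord("F3.2D", "D", "2D", "F3", "MHHHHHHHHK"),
    ]
    return SubgenomeProteinDB(records)
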