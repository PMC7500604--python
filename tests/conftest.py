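import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from codonramp import OrfRecord, NineMerRecord


@pytest.fixture
def quad_orfs():
    """Four identical minimal complete ORFs (start + Ala + stop)."""
    return [OrfRecord.from_raw(f"g{i}", "", "ATGGCTTAA", "") for i in range(4)]


@pytest.fixture
def mixed_orfs():
    """Five ORFs of varying lengths with UTRs, expression and flags."""
    rows = [
        ("yal001", "TTAAC", "ATGGCTGCTGGTTAA", "ACGT", 12.0, True),
        ("yal002", "AAATGAA", "ATGGCTATGGCTTAA", "", 5.0, False),
        ("yal003", "", "ATGAAACCCGGGTTTTAA", "GG", 30.0, True),
        ("yal004", "CCC", "ATGTCTTAA", "A", 1.0, False),
        ("yal005", "G", "ATGGGTATTCATCGATAA", "TT", 7.5, False),
    ]
    return [
        OrfRecord.from_raw(g, u5, cds, u3, expr, msms)
        for g, u5, cds, u3, expr, msms in rows
    ]


@pytest.fixture
def ninemers():
    return [
        NineMerRecord.from_raw("GCAGCCGCG", 4.2),
        NineMerRecord.from_raw("AAAAAAAAA", 1.0),
        NineMerRecord.from_raw("GGAACCGTA", 3.0, structured=True),
        NineMerRecord.from_raw("GCTGCAGCC", 2.5),
    ]
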