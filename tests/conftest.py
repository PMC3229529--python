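import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Synthetic reconstruction of the classic two-header, six-record example SAM
# file: one reference ("ref"), template read names r001..r004, sorted
# positions 7,7,9,9,9,16, a mix of '=' and '*' mate references and two
# NM:i tags. Typed in, not extracted from any dataset.
FIG1_SAM = (
    b"@HD\tVN:1.0\tSO:coordinate\n"
    b"@SQ\tSN:ref\tLN:45\n"
    b"r001\t163\tref\t7\t30\t8M2I4M1D3M\t=\t37\t39\tTTAGATAAAGGATACTG\t*\n"
    b"r002\t0\tref\t7\t30\t3S6M1P1I4M\t*\t0\t0\tAAAAGATAAGGATA\t*\n"
    b"r002\t0\tref\t9\t30\t5H6M\t*\t0\t0\tAGCTAA\t*\tNM:i:1\n"
    b"r003\t0\tref\t9\t30\t6M14N5M\t*\t0\t0\tATAGCTTCAGC\t*\n"
    b"r003\t16\tref\t9\t30\t6H5M\t*\t0\t0\tTAGGC\t*\tNM:i:0\n"
    b"r004\t0\tref\t16\t30\t9M\t=\t7\t39\tCAGCGCCAT\t*\n"
)


@pytest.fixture
def fig1_sam() -> bytes:
    return FIG1_SAM
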