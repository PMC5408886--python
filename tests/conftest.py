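import pytest

from allosite.numbering import GenericPosition, ReceptorAnnotation, SegmentSpan
from allosite.study import study_spec
from allosite.synthetic_data import make_bundle, random_spec


@pytest.fixture
def simple_annotation() -> ReceptorAnnotation:
    """A receptor with TM6 (anchor at 712) and ECL2 (Cys anchor at 520)."""
    seq = "A" * 760
    seq = seq[:519] + "C" + seq[520:]
    return ReceptorAnnotation(
        receptor_id="RX",
        segments=[
            SegmentSpan(45, 516, 524, 520),     # ECL2, 45x46..45x54
            SegmentSpan(6, 700, 730, 712),      # TM6, 6x38..6x68
        ],
        sequence=seq,
    )


@pytest.fixture(scope="session")
def small_bundle():
    """One deterministic closed-loop bundle shared by read-only tests."""
    return make_bundle(random_spec(11, site_size=12))


@pytest.fixture(scope="session")
def study_bundle():
    """The study-scale planted dataset (22 receptors, 28-position site)."""
    return make_bundle(study_spec(0))


def pos(label: str) -> GenericPosition:
    return GenericPosition.parse(label)
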