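import pytest

from bgcmine.core import CdsFeature, GenomeRecord
from bgcmine.profiles import NaiveSignatureScanner, load_catalogue
from bgcmine.rules import bundled_ruleset


@pytest.fixture(scope="session")
def catalogue():
    return load_catalogue()


@pytest.fixture(scope="session")
def ruleset():
    return bundled_ruleset()


@pytest.fixture(scope="session")
def scanner():
    return NaiveSignatureScanner()


def make_record(cds_specs, length=None, record_id="R1"):
    """Build a GenomeRecord from (cds_id, start, end, strand, translation)."""
    features = [CdsFeature(*spec) for spec in cds_specs]
    if length is None:
        length = max((f.end for f in features), default=0) + 1000
    return GenomeRecord(record_id, length, features)
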