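import pytest
from hypothesis import settings

from twolist.registry import CaseRecord, ContingencyTable

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def table1() -> ContingencyTable:
    """The published overall contingency table: 856 shared, 2,968 A-only,
    1,738 B-only (lists of 3,824 and 2,594; union 5,562)."""
    return ContingencyTable(m=856, a_only=2968, b_only=1738)


def make_records(keys, source, age=80, gender="F"):
    return [CaseRecord(k, source, age, gender) for k in keys]
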