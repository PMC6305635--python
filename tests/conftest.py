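import pytest

from hapnet import Haplotype, world_frequency_table


def hap(pattern: str, label: str | None = None) -> Haplotype:
    """Shorthand: build a Haplotype from a compact +/- or 0/1 string."""
    return Haplotype(tuple(1 if c in "+1" else 0 for c in pattern), label=label)


@pytest.fixture(scope="session")
def world_table():
    return world_frequency_table()
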