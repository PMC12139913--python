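import pytest

from splicecraft.synthetic import generate_genome, spec_grid


@pytest.fixture(scope="session")
def grid_genome():
    """Synthetic genome over the full spec grid (all classes, both strands)."""
    return generate_genome(spec_grid(), seed=7)
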