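import numpy as np
import pytest
from hypothesis import settings

from parbseq.genome import GenomeSpec, PlantedSite, build_genome, make_palindromic_site

# reproducible property tests: no flakiness across re-runs
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def single_site_genome():
    """1-kb circular genome with one 16-bp palindromic site at [500, 516)."""
    site = PlantedSite(
        start=500, sequence=make_palindromic_site("GTGAAA", "ACGT"), kd=30.0, label="parS"
    )
    return build_genome(GenomeSpec(length=1000, circular=True), [site], seed=0)


def exhaustive_containing_fragments(site_start, site_width, min_len, max_len, genome_length):
    """Every (start, length) fully containing the site, linear coordinates."""
    from parbseq.simulate import FragmentRecord

    out = []
    for length in range(min_len, max_len + 1):
        for start in range(site_start + site_width - length, site_start + 1):
            if 0 <= start and start + length <= genome_length:
                out.append(FragmentRecord(start, length, "idap"))
    return out
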