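import pytest

from ricebarrier import VariantSite


def make_site(pos, calls, chrom="chr1", ref="A", alt="T"):
    """Shorthand for building a biallelic site from a list of (h1, h2) pairs."""
    return VariantSite(chrom, pos, ref, alt, tuple(tuple(c) for c in calls))


@pytest.fixture
def published_f2_counts():
    """The published F2 marginal counts at the locus-2 marker."""
    from ricebarrier import CountsTable

    return CountsTable(("W2W2", "W2G2", "G2G2"), (99, 113, 14))
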