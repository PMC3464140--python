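import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bactquant import BACTQUANT, TaxSeqRecord
from bactquant import iupac  # noqa: F401  (re-exported for tests)

settings.register_profile(
    "ci",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def assay():
    return BACTQUANT


@pytest.fixture(scope="session")
def target_record(assay):
    """A synthetic sense-strand 16S-like fragment that is a perfect match.

    Carries the canonical (E. coli-style) variant of each assay site at its
    reference coordinates, embedded in a fixed pseudo-random background: the
    forward site with D->A and W->A, the probe verbatim, and the reverse
    primer site as the reverse complement of the H->C, V->A, M->A expansion.
    """
    from bactquant.iupac import reverse_complement
    from bactquant.synthdata import _scrub_chance_matches

    rng = np.random.default_rng(20120417)
    seq = list(rng.choice(list("ACGT"), size=900))
    forward_site = "CCTACGGGAGGCAGCA"
    reverse_site = "GGACTACCAGGGTATCTAATC"
    probe_site = "CAGCAGCCGCGGTA"
    seq[assay.forward.ref_start - 1 : assay.forward.ref_end] = list(forward_site)
    seq[assay.probe.ref_start - 1 : assay.probe.ref_end] = list(probe_site)
    seq[assay.reverse.ref_start - 1 : assay.reverse.ref_end] = list(
        reverse_complement(reverse_site)
    )
    protected = [
        (o.ref_start - 1, o.ref_end - 1)
        for o in (assay.forward, assay.reverse, assay.probe)
    ]
    _scrub_chance_matches(seq, assay, protected, rng)
    return TaxSeqRecord(
        seq_id="TARGET00001",
        phylum="Proteobacteria",
        genus="Escherichia",
        species="coli-like",
        sequence="".join(seq),
        ref_start=1,
        ref_end=900,
    )
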