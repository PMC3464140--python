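"""Packaged assay definitions.

``BACTQUANT`` is the broad-coverage 16S rRNA gene TaqMan assay targeting the
466-bp V3-V4 amplicon (E. coli positions 341-806): a forward primer with two
degenerate bases, a reverse primer with three, and a non-degenerate MGB probe.

``PUBLISHED_COMPARISON`` is the earlier universal bacterial TaqMan assay of
Nadkarni et al. (2002) commonly used as the benchmark for broad-coverage
quantification; coordinates are approximate E. coli 16S numbering.
"""
from .design import AssayDefinition, Oligo

BACTQUANT = AssayDefinition(
    assay_name="BactQuant",
    forward=Oligo(
        name="BactQuant-F",
        sequence="CCTACGGGDGGCWGCA",
        role="forward_primer",
        ref_start=341,
        ref_end=356,
    ),
    reverse=Oligo(
        name="BactQuant-R",
        sequence="GGACTACHVGGGTMTCTAATC",
        role="reverse_primer",
        ref_start=786,
        ref_end=806,
    ),
    probe=Oligo(
        name="BactQuant-P",
        sequence="CAGCAGCCGCGGTA",
        role="probe",
        ref_start=519,
        ref_end=532,
    ),
)

PUBLISHED_COMPARISON = AssayDefinition(
    assay_name="Universal-2002",
    forward=Oligo(
        name="331F",
        sequence="TCCTACGGGAGGCAGCAGT",
        role="forward_primer",
        ref_start=331,
        ref_end=349,
    ),
    reverse=Oligo(
        name="797R",
        sequence="GGACTACCAGGGTATCTAATCCTGTT",
        role="reverse_primer",
        ref_start=772,
        ref_end=797,
    ),
    probe=Oligo(
        name="BacProbe",
        sequence="CGTATTACCGCGGCTGCTGGCAC",
        role="probe",
        ref_start=506,
        ref_end=528,
    ),
)
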