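"""Shared fixtures: a transcript carrying the published variant codons.

The `screening_transcript` fixture is a synthetic 1100-codon CDS into
which the codons underlying the well-known C-terminal-domain variants are
patched (codon 935 GAT followed by a G, 952 CGC, 987 CCG, 1048 CGG,
1049 CGC), with the regulatory-domain span aa 894-1086 and the ISO
subdomain aa 1022-1037 registered, and a +69 nt / +23 aa alternate
isoform offset.  This lets the annotation tests assert the published
c./p. pairings on a sequence the repository can ship.
"""
from __future__ import annotations


import pytest

from cpgburden.gene_model import IsoformOffset, TranscriptModel
from cpgburden.synthetic_data import generate_reference

#: codon index -> codon, reproducing the published variant sites
PATCHED_CODONS = {
    935: "GAT",  # c.2805 T>C -> p.D935D, CpG gained (next codon starts with G)
    936: "GAA",
    952: "CGC",  # c.2855 G>A -> p.R952H, CpG disrupted
    987: "CCG",  # c.2961 G>A -> p.P987P, CpG disrupted
    1048: "CGG",  # c.3142 C>T -> p.R1048W, CpG disrupted
    1049: "CGC",  # c.3145 C>T -> p.R1049C, CpG disrupted
}


def build_screening_transcript(seed: int = 11, n_codons: int = 1100) -> TranscriptModel:
    base = generate_reference(seed, n_codons=n_codons, arg_cgn_fraction=0.15)
    codons = [base.cds[i : i + 3] for i in range(0, len(base.cds), 3)]
    for aa_index, codon in PATCHED_CODONS.items():
        codons[aa_index - 1] = codon
    return TranscriptModel(
        transcript_id="SYNTX900.1",
        protein_id="SYNP900",
        cds="".join(codons),
        exon_cds_spans=base.exon_cds_spans,
        flank_5p=base.flank_5p,
        flank_3p=base.flank_3p,
        regions={"CTRD": (894, 1086), "ISO": (1022, 1037)},
        offsets=(IsoformOffset("SYNTX900.1", "SYNTX900.2", 69, 23),),
    )


@pytest.fixture(scope="session")
def screening_transcript() -> TranscriptModel:
    return build_screening_transcript()


@pytest.fixture(scope="session")
def random_transcript() -> TranscriptModel:
    return generate_reference(seed=7, n_codons=600, arg_cgn_fraction=0.2)
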