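"""Coding-transcript model: CDS coordinates, codons, isoforms and regions.

All positions are 1-based and inclusive, HGVS-c.-style on the coding
sequence only.  Exon boundaries are carried so that a ±1-base sequence
context can be flagged as crossing an exon edge (where the true neighbour
is intronic); intronic context is supplied as explicit flank bases, never
modelled sequence.  Named regions (e.g. a C-terminal regulatory domain)
are protein-coordinate spans registered on the transcript.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError, CoordinateError, DataIntegrityError

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class IsoformOffset:
    """Constant shift between the coding coordinates of two isoforms.

    ``c_offset`` is in nucleotides, ``p_offset`` in residues; a pure
    N-terminal extension keeps them locked at ``c_offset = 3 * p_offset``.
    """

    from_id: str
    to_id: str
    c_offset: int
    p_offset: int

    def __post_init__(self) -> None:
        if self.c_offset != 3 * self.p_offset:
            raise ConfigurationError(
                f"isoform offset {self.from_id}->{self.to_id}: "
                f"c_offset {self.c_offset} != 3 * p_offset {self.p_offset}"
            )

    def inverse(self) -> "IsoformOffset":
        return IsoformOffset(self.to_id, self.from_id, -self.c_offset, -self.p_offset)


@dataclass
class TranscriptModel:
    """One coding transcript: CDS, exon structure, flanks and regions.

    Parameters
    ----------
    transcript_id, protein_id
        Accession strings for the nucleotide and protein products.
    cds
        Coding sequence (A/C/G/T), length divisible by three.
    exon_cds_spans
        Ordered ``(c_start, c_end)`` pairs, 1-based inclusive, that
        partition ``1..len(cds)``.
    flank_5p, flank_3p
        Optional single intronic bases immediately beyond the 5'/3' edge
        of each exon, keyed by 0-based exon index.
    regions
        Named protein-coordinate spans ``name -> (start_aa, end_aa)``.
    offsets
        Registered coordinate shifts to alternate isoforms.
    """

    transcript_id: str
    protein_id: str
    cds: str
    exon_cds_spans: Sequence[tuple[int, int]]
    flank_5p: Mapping[int, str] = field(default_factory=dict)
    flank_3p: Mapping[int, str] = field(default_factory=dict)
    regions: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    offsets: Sequence[IsoformOffset] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        if set(self.cds) - _BASES:
            raise DataIntegrityError("CDS contains non-ACGT characters")
        if len(self.cds) == 0 or len(self.cds) % 3:
            raise DataIntegrityError(f"CDS length {len(self.cds)} is not a positive multiple of 3")
        spans = [(int(s), int(e)) for s, e in self.exon_cds_spans]
        expected_start = 1
        for s, e in spans:
            if s != expected_start or e < s:
                raise DataIntegrityError(f"exon spans do not partition the CDS at ({s}, {e})")
            expected_start = e + 1
        if expected_start != len(self.cds) + 1:
            raise DataIntegrityError("exon spans do not cover the full CDS")
        self.exon_cds_spans = tuple(spans)
        for name, (sa, ea) in self.regions.items():
            if not (1 <= sa <= ea <= self.n_codons):
                raise ConfigurationError(f"region {name!r} span ({sa}, {ea}) outside 1..{self.n_codons}")

    # -- basic geometry -------------------------------------------------

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    def base(self, pos_c: int) -> str:
        if not 1 <= pos_c <= len(self.cds):
            raise CoordinateError(f"c.{pos_c} outside 1..{len(self.cds)}")
        return self.cds[pos_c - 1]

    def aa_index_of(self, pos_c: int) -> int:
        """Protein residue index whose codon contains CDS position ``pos_c``."""
        self.base(pos_c)
        return (pos_c - 1) // 3 + 1

    def exon_index_of(self, pos_c: int) -> int:
        self.base(pos_c)
        for i, (s, e) in enumerate(self.exon_cds_spans):
            if s <= pos_c <= e:
                return i
        raise CoordinateError(f"c.{pos_c} not covered by any exon")  # pragma: no cover

    def context(self, pos_c: int) -> tuple[Optional[str], Optional[str]]:
        """±1-base sequence context of ``pos_c``.

        Within an exon the neighbours come from the CDS itself; at an exon
        edge the genomic neighbour is intronic and is taken from the
        registered flank base, or reported as ``None`` (unknown) if no
        flank was supplied.
        """
        i = self.exon_index_of(pos_c)
        s, e = self.exon_cds_spans[i]
        ctx5 = self.flank_5p.get(i) if pos_c == s else self.cds[pos_c - 2]
        ctx3 = self.flank_3p.get(i) if pos_c == e else self.cds[pos_c]
        return (ctx5.upper() if ctx5 else None, ctx3.upper() if ctx3 else None)

    def translate(self) -> str:
        return str(Seq(self.cds).translate())


# -- operations ---------------------------------------------------------


def codon_span(transcript: TranscriptModel, aa_index: int) -> tuple[int, int, str]:
    """CDS span and codon string of protein residue ``aa_index``."""
    if not 1 <= aa_index <= transcript.n_codons:
        raise CoordinateError(f"aa index {aa_index} outside 1..{transcript.n_codons}")
    c_start = 3 * (aa_index - 1) + 1
    return c_start, c_start + 2, transcript.cds[c_start - 1 : c_start + 2]


def map_isoform(pos_c: int, offset: IsoformOffset) -> int:
    """Shift a coding coordinate onto the target isoform."""
    mapped = pos_c + offset.c_offset
    if mapped < 1:
        raise CoordinateError(f"c.{pos_c} maps to non-positive c.{mapped} on {offset.to_id}")
    return mapped


def in_region(aa_index: int, region_name: str, transcript: TranscriptModel) -> bool:
    """True iff the residue lies within the named registered region."""
    try:
        start_aa, end_aa = transcript.regions[region_name]
    except KeyError:
        raise ConfigurationError(
            f"region {region_name!r} not registered on {transcript.transcript_id}"
        ) from None
    return start_aa <= aa_index <= end_aa


# -- serialization ------------------------------------------------------


def load_transcript(fasta_path, exon_tsv_path, meta_yaml_path) -> TranscriptModel:
    """Assemble a transcript model from FASTA + exon TSV + YAML metadata."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise DataIntegrityError(f"expected exactly one CDS record in {fasta_path}")
    cds = str(records[0].seq).upper()

    spans: list[tuple[int, int]] = []
    with open(exon_tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            spans.append((int(parts[cols["c_start"]]), int(parts[cols["c_end"]])))

    with open(meta_yaml_path) as fh:
        meta = yaml.safe_load(fh)
    offsets = tuple(
        IsoformOffset(o["from"], o["to"], int(o["c_offset"]), int(o["p_offset"]))
        for o in meta.get("offsets", [])
    )
    regions = {
        name: (int(span["start_aa"]), int(span["end_aa"]))
        for name, span in (meta.get("regions") or {}).items()
    }
    flanks = meta.get("flanks") or {}
    flank_5p = {int(k): str(v) for k, v in (flanks.get("five_prime") or {}).items()}
    flank_3p = {int(k): str(v) for k, v in (flanks.get("three_prime") or {}).items()}
    return TranscriptModel(
        transcript_id=meta["transcript_id"],
        protein_id=meta["protein_id"],
        cds=cds,
        exon_cds_spans=spans,
        flank_5p=flank_5p,
        flank_3p=flank_3p,
        regions=regions,
        offsets=offsets,
    )


def write_transcript(model: TranscriptModel, fasta_path, exon_tsv_path, meta_yaml_path) -> None:
    record = SeqRecord(Seq(model.cds), id=model.transcript_id, description="coding sequence")
    SeqIO.write([record], str(fasta_path), "fasta")

    with open(exon_tsv_path, "w") as fh:
        fh.write("exon_index\tc_start\tc_end\n")
        for i, (s, e) in enumerate(model.exon_cds_spans):
            fh.write(f"{i}\t{s}\t{e}\n")

    meta = {
        "transcript_id": model.transcript_id,
        "protein_id": model.protein_id,
        "offsets": [
            {"from": o.from_id, "to": o.to_id, "c_offset": o.c_offset, "p_offset": o.p_offset}
            for o in model.offsets
        ],
        "regions": {
            name: {"start_aa": s, "end_aa": e} for name, (s, e) in sorted(model.regions.items())
        },
        "flanks": {
            "five_prime": dict(sorted(model.flank_5p.items())),
            "three_prime": dict(sorted(model.flank_3p.items())),
        },
    }
    with open(meta_yaml_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
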