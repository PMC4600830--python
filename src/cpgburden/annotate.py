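"""Variant consequence and CpG-site impact annotation.

Every burden table downstream is stratified on the two labels produced
here: the coding consequence (synonymous / nonsynonymous / other) obtained
by translating the reference and alternate codons, and the CpG impact of
the substitution within its ±1-base context.  A single-base substitution
can only create or destroy a 5'-CG-3' dinucleotide that overlaps the
substituted base itself, so the ±1-base window is sufficient; because CG
is its own reverse complement the classification is strand-symmetric.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from Bio.Seq import Seq

from .errors import DataIntegrityError
from .gene_model import TranscriptModel, codon_span, in_region

_BASES = ("A", "C", "G", "T")

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
OTHER = "other"

CPG_DISRUPTED = "disrupted"
CPG_GAINED = "gained"
CPG_NONE = "none"
CPG_INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class SequenceVariant:
    """One SNV in transcript coding coordinates with flanking context.

    ``context_5p`` / ``context_3p`` are the single bases adjacent to the
    variant on the genomic strand of the transcript; ``None`` means
    unknown (e.g. an exon-edge variant whose intronic neighbour was not
    supplied).
    """

    transcript_id: str
    pos_c: int
    ref: str
    alt: str
    context_5p: Optional[str] = None
    context_3p: Optional[str] = None
    rs_id: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("ref", "alt"):
            base = getattr(self, name)
            if base not in _BASES:
                raise DataIntegrityError(f"{name} base {base!r} not one of A/C/G/T")
        if self.ref == self.alt:
            raise DataIntegrityError(f"ref == alt == {self.ref!r} at c.{self.pos_c}")
        for name in ("context_5p", "context_3p"):
            base = getattr(self, name)
            if base is not None and base not in _BASES:
                raise DataIntegrityError(f"{name} base {base!r} not one of A/C/G/T or unknown")
        if self.pos_c < 1:
            raise DataIntegrityError(f"c.{self.pos_c} is not a valid CDS position")

    def with_context_from(self, transcript: TranscriptModel) -> "SequenceVariant":
        """Fill missing context bases from the transcript (exon-aware)."""
        ctx5, ctx3 = transcript.context(self.pos_c)
        return replace(
            self,
            context_5p=self.context_5p or ctx5,
            context_3p=self.context_3p or ctx3,
        )


@dataclass(frozen=True)
class VariantAnnotation:
    """Class labels for one variant: consequence, protein change, CpG impact."""

    consequence: str
    protein_change: Optional[tuple[str, int, str]]
    cpg_impact: str
    in_ctrd: bool
    regions: frozenset[str] = frozenset()

    @property
    def hgvs_p(self) -> str:
        if self.protein_change is None:
            return "p.?"
        ref_aa, idx, alt_aa = self.protein_change
        return f"p.{ref_aa}{idx}{alt_aa}"


def classify_consequence(
    variant: SequenceVariant, transcript: TranscriptModel
) -> tuple[str, tuple[str, int, str]]:
    """Translate reference and alternate codons and compare residues.

    Returns the consequence class and the ``(ref_aa, aa_index, alt_aa)``
    protein change.  Stop gain/loss is classed ``other`` so it never
    inflates the synonymous or nonsynonymous tallies.
    """
    if transcript.base(variant.pos_c) != variant.ref:
        raise DataIntegrityError(
            f"ref {variant.ref} at c.{variant.pos_c} does not match transcript "
            f"{transcript.transcript_id} base {transcript.base(variant.pos_c)}"
        )
    aa_index = transcript.aa_index_of(variant.pos_c)
    c_start, _, ref_codon = codon_span(transcript, aa_index)
    within = variant.pos_c - c_start
    alt_codon = ref_codon[:within] + variant.alt + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        consequence = SYNONYMOUS
    elif "*" in (ref_aa, alt_aa):
        consequence = OTHER
    else:
        consequence = NONSYNONYMOUS
    return consequence, (ref_aa, aa_index, alt_aa)


def _window_has_cg(ctx5: str, center: str, ctx3: str) -> bool:
    # only CG pairs overlapping the variant base matter for an SNV
    return (ctx5 == "C" and center == "G") or (center == "C" and ctx3 == "G")


def classify_cpg_impact(variant: SequenceVariant) -> str:
    """CpG impact of the substitution within its ±1-base window.

    An unknown context base is marginalised over all four bases: if every
    completion yields the same label the site is determinate, otherwise it
    is ``indeterminate``.  A substitution that both destroys one CG and
    creates another in the same window nets to ``none``.
    """
    choices_5p = (variant.context_5p,) if variant.context_5p else _BASES
    choices_3p = (variant.context_3p,) if variant.context_3p else _BASES
    labels = set()
    for c5 in choices_5p:
        for c3 in choices_3p:
            ref_cg = _window_has_cg(c5, variant.ref, c3)
            alt_cg = _window_has_cg(c5, variant.alt, c3)
            if ref_cg and not alt_cg:
                labels.add(CPG_DISRUPTED)
            elif alt_cg and not ref_cg:
                labels.add(CPG_GAINED)
            else:
                labels.add(CPG_NONE)
            if len(labels) > 1:
                return CPG_INDETERMINATE
    return labels.pop()


def annotate_variant(
    variant: SequenceVariant,
    transcript: TranscriptModel,
    ctrd_region: str = "CTRD",
) -> VariantAnnotation:
    """Full annotation: consequence, protein change, CpG impact, regions."""
    consequence, protein_change = classify_consequence(variant, transcript)
    cpg_impact = classify_cpg_impact(variant)
    aa_index = protein_change[1]
    regions = frozenset(
        name for name in transcript.regions if in_region(aa_index, name, transcript)
    )
    return VariantAnnotation(
        consequence=consequence,
        protein_change=protein_change,
        cpg_impact=cpg_impact,
        in_ctrd=ctrd_region in regions,
        regions=regions,
    )
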