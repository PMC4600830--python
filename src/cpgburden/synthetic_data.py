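"""Synthetic reference and cohort generator for end-to-end testing.

Real targeted-screening and exome datasets of this kind cannot be
redistributed, so the generator builds (i) a coding sequence enriched in
CGN arginine codons — the CpG-rich sites where C>T / G>A deamination
substitutions concentrate — with a regulatory-domain-like region on its
3' third, and (ii) multi-stratum case/control variant observations with
binomially drawn carrier-allele counts at rare-variant frequencies
(defaults emulate three ancestry strata of 427/1214, 1892/4300 and
82/2203 individuals with allele frequencies of 0.04-0.7%).

The generator chooses each site's ref/alt/context so that the annotated
consequence and CpG class match the requested class exactly, making it an
adversarial fixture for the annotator.  A single global seed drives
everything through a documented split (reference: seed, cohort: seed + 1),
so fixtures are reproducible piecewise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotate import SequenceVariant, annotate_variant
from .cohorts import (
    CASE,
    CONTROL,
    Stratum,
    VariantObservation,
    write_manifest,
    write_observations,
)
from .errors import ConfigurationError, GenerationError
from .gene_model import IsoformOffset, TranscriptModel, write_transcript

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = tuple(
    sorted(
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in _STOPS
    )
)
_CGN_CODONS = ("CGA", "CGC", "CGG", "CGT")
_NON_CGN_CODONS = tuple(c for c in _SENSE_CODONS if c not in _CGN_CODONS)


@dataclass(frozen=True)
class VariantSpec:
    """One synthetic site: where it goes, what classes it must realize.

    ``rel_pos`` places the site at a fraction of the CDS length;
    ``freqs`` maps ``(stratum_label, role)`` to the allele frequency used
    for the binomial carrier draw (missing strata draw nothing).
    """

    rel_pos: float
    consequence: str
    cpg: str
    freqs: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.rel_pos <= 1.0:
            raise ConfigurationError(f"rel_pos {self.rel_pos} outside [0, 1]")
        for key, freq in self.freqs.items():
            if not 0.0 <= freq <= 1.0:
                raise ConfigurationError(f"frequency {freq} for stratum {key} outside [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Blueprint for one synthetic multi-stratum case/control dataset."""

    strata: Sequence[Stratum]
    variant_specs: Sequence[VariantSpec]
    maf_common_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.strata:
            raise ConfigurationError("cohort spec needs at least one stratum")
        if not 0.0 <= self.maf_common_fraction <= 1.0:
            raise ConfigurationError("maf_common_fraction outside [0, 1]")


def generate_reference(
    seed: int,
    n_codons: int = 1200,
    arg_cgn_fraction: float = 0.15,
    n_exons: int = 5,
    region_name: str = "CTRD",
) -> TranscriptModel:
    """Deterministic synthetic coding transcript.

    The CDS starts with ATG, contains no internal stop codon, and a
    binomial ``arg_cgn_fraction`` of codons are CGN (arginine), seeding
    CpG dinucleotides throughout.  A region named ``region_name`` is
    registered on the 3' third of the protein, with a short ISO-like
    subdomain inside it, and an alternate isoform offset of +69 nt / +23
    aa is attached.  The same seed always returns the same transcript.
    """
    if not 0.0 <= arg_cgn_fraction <= 1.0:
        raise ConfigurationError(f"arg_cgn_fraction {arg_cgn_fraction} outside [0, 1]")
    if n_codons < 30:
        raise ConfigurationError("n_codons too small to carry the required regions")
    rng = np.random.default_rng(seed)
    is_cgn = rng.random(n_codons) < arg_cgn_fraction
    codons = [
        str(rng.choice(_CGN_CODONS)) if cgn else str(rng.choice(_NON_CGN_CODONS))
        for cgn in is_cgn
    ]
    codons[0] = "ATG"
    cds = "".join(codons)

    bounds = np.linspace(0, len(cds), n_exons + 1).astype(int)
    spans = [(int(bounds[i]) + 1, int(bounds[i + 1])) for i in range(n_exons)]
    flank_5p = {i: str(rng.choice(list("ACGT"))) for i in range(1, n_exons)}
    flank_3p = {i: str(rng.choice(list("ACGT"))) for i in range(n_exons - 1)}

    region_start = 2 * n_codons // 3 + 1
    iso_start = region_start + (n_codons - region_start) // 3
    regions = {
        region_name: (region_start, n_codons),
        "ISO": (iso_start, min(iso_start + 15, n_codons)),
    }
    return TranscriptModel(
        transcript_id=f"SYNTX{seed % 1000:03d}.1",
        protein_id=f"SYNP{seed % 1000:03d}",
        cds=cds,
        exon_cds_spans=spans,
        flank_5p=flank_5p,
        flank_3p=flank_3p,
        regions=regions,
        offsets=(
            IsoformOffset(f"SYNTX{seed % 1000:03d}.1", f"SYNTX{seed % 1000:03d}.2", 69, 23),
        ),
    )


def _find_site(
    transcript: TranscriptModel,
    spec: VariantSpec,
    used: set[int],
) -> SequenceVariant:
    """Pick (position, alt) realizing the requested classes, nearest to rel_pos."""
    target = max(1, min(len(transcript.cds), round(spec.rel_pos * len(transcript.cds))))
    order = sorted(range(1, len(transcript.cds) + 1), key=lambda p: (abs(p - target), p))
    for pos in order:
        if pos in used:
            continue
        ctx5, ctx3 = transcript.context(pos)
        if ctx5 is None or ctx3 is None:
            continue  # exon-edge sites without flanks would be indeterminate
        ref = transcript.base(pos)
        for alt in "ACGT":
            if alt == ref:
                continue
            variant = SequenceVariant(
                transcript_id=transcript.transcript_id,
                pos_c=pos,
                ref=ref,
                alt=alt,
                context_5p=ctx5,
                context_3p=ctx3,
            )
            ann = annotate_variant(variant, transcript)
            if ann.consequence == spec.consequence and ann.cpg_impact == spec.cpg:
                used.add(pos)
                return variant
    raise GenerationError(
        f"no site near relative position {spec.rel_pos} (c.{target}) can realize "
        f"consequence={spec.consequence!r} with cpg={spec.cpg!r}"
    )


def realize_sites(spec: CohortSpec, transcript: TranscriptModel) -> list[SequenceVariant]:
    """Deterministically realize each requested site class on the transcript.

    Positions are chosen nearest to each spec's relative position, without
    reuse; the returned variants annotate back to exactly the requested
    consequence and CpG classes.
    """
    used: set[int] = set()
    return [_find_site(transcript, vs, used) for vs in spec.variant_specs]


def generate_cohort(
    spec: CohortSpec, transcript: TranscriptModel
) -> tuple[list[VariantObservation], list[VariantObservation], list[Stratum]]:
    """Draw per-stratum carrier-allele counts for each requested site.

    Carrier counts are binomial(2N, freq) — cohort sizes dwarf carrier
    counts in the rare-variant regime, so sampling with replacement is an
    adequate model.  Zero draws are omitted from the output.  A random
    ``maf_common_fraction`` of the sites are marked common (reference MAF
    2-10%) so the rarity filter has something to remove; the rest carry
    their own control-arm generating frequency as reference MAF.
    """
    rng = np.random.default_rng(spec.seed + 1)
    strata = list(spec.strata)
    used: set[int] = set()
    variants = [_find_site(transcript, vs, used) for vs in spec.variant_specs]

    n_sites = len(variants)
    common_mask = rng.random(n_sites) < spec.maf_common_fraction
    common_maf = rng.uniform(0.02, 0.10, size=n_sites)

    case_obs: list[VariantObservation] = []
    control_obs: list[VariantObservation] = []
    for i, (variant, vspec) in enumerate(zip(variants, spec.variant_specs)):
        control_freqs = {
            label: freq for (label, role), freq in vspec.freqs.items() if role == CONTROL
        }
        for stratum in strata:
            freq = vspec.freqs.get((stratum.label, stratum.role), 0.0)
            carriers = int(rng.binomial(stratum.n_alleles, freq))
            if carriers == 0:
                continue
            maf = (
                float(common_maf[i])
                if common_mask[i]
                else control_freqs.get(stratum.label, freq)
            )
            obs = VariantObservation(
                variant=variant,
                stratum_label=stratum.label,
                carrier_alleles=carriers,
                maf_reference=maf,
            )
            (case_obs if stratum.role == CASE else control_obs).append(obs)
    return case_obs, control_obs, strata


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """Study-shaped default: three ancestry strata, mixed variant classes.

    Sizes are 427/1214 (targeted screening stratum), 1892/4300 and
    82/2203 (exome strata); site frequencies span 0.04-0.7%, a mix of
    synonymous/nonsynonymous and CpG-affecting/non-affecting sites sits
    inside the 3'-region, a couple of sites fall outside it, and 20% of
    sites are made common to exercise the rarity filter.
    """
    strata = [
        Stratum("FC", CASE, 427),
        Stratum("FC", CONTROL, 1214),
        Stratum("EA", CASE, 1892),
        Stratum("EA", CONTROL, 4300),
        Stratum("AA", CASE, 82),
        Stratum("AA", CONTROL, 2203),
    ]

    def freqs(case_pct: float, control_pct: float) -> dict[tuple[str, str], float]:
        return {
            (label, role): (case_pct if role == CASE else control_pct) / 100.0
            for label in ("FC", "EA", "AA")
            for role in (CASE, CONTROL)
        }

    variant_specs = [
        # inside the 3' region: the class mix the burden tables stratify on
        VariantSpec(0.80, "nonsynonymous", "disrupted", freqs(0.30, 0.12)),
        VariantSpec(0.84, "nonsynonymous", "gained", freqs(0.20, 0.08)),
        VariantSpec(0.88, "synonymous", "disrupted", freqs(0.15, 0.05)),
        VariantSpec(0.92, "synonymous", "gained", freqs(0.10, 0.04)),
        VariantSpec(0.96, "nonsynonymous", "none", freqs(0.12, 0.06)),
        VariantSpec(0.90, "synonymous", "none", freqs(0.08, 0.04)),
        # outside the region: exercises the region filter
        VariantSpec(0.10, "nonsynonymous", "disrupted", freqs(0.30, 0.15)),
        VariantSpec(0.30, "synonymous", "none", freqs(0.20, 0.10)),
        # common sites: exercise the MAF filter
        VariantSpec(0.50, "nonsynonymous", "none", freqs(0.70, 0.70)),
        VariantSpec(0.60, "synonymous", "gained", freqs(0.50, 0.50)),
    ]
    return CohortSpec(
        strata=strata,
        variant_specs=variant_specs,
        maf_common_fraction=0.2,
        seed=seed,
    )


def write_cohort(
    spec: CohortSpec,
    transcript: TranscriptModel,
    outdir,
) -> dict[str, Path]:
    """Generate and serialize the full fixture set; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "transcript.fasta",
        "exons": outdir / "exons.tsv",
        "meta": outdir / "transcript.yaml",
        "observations": outdir / "observations.tsv",
        "manifest": outdir / "manifest.tsv",
    }
    write_transcript(transcript, paths["fasta"], paths["exons"], paths["meta"])
    case_obs, control_obs, strata = generate_cohort(spec, transcript)
    write_observations(case_obs, control_obs, paths["observations"])
    write_manifest(strata, paths["manifest"])
    return paths
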