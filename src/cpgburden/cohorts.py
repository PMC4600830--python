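"""Cohort manifests, rarity filtering and stratified allele-count tables.

The counting unit throughout is ALLELES: a stratum of N diploid
individuals contributes 2N alleles, and distinct rare variants within a
stratum are pooled by summing carrier alleles (a collapsing burden).
Each ancestry stratum yields one 2x2 table of variant vs reference
alleles in cases vs controls, optionally restricted to a variant class
(consequence or CpG impact) and/or a named transcript region.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .annotate import (
    CPG_DISRUPTED,
    CPG_GAINED,
    CPG_NONE,
    NONSYNONYMOUS,
    OTHER,
    SYNONYMOUS,
    SequenceVariant,
    VariantAnnotation,
)
from .errors import ConfigurationError, DataIntegrityError

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"

#: Predicates defining the variant classes the burden tables stratify on.
#: Indeterminate CpG sites are deliberately excluded from both CpG classes,
#: and stop-involving ("other") consequences from both coding classes.
CLASS_PREDICATES: Mapping[str, Callable[[VariantAnnotation], bool]] = {
    "all": lambda ann: True,
    "nonsynonymous": lambda ann: ann.consequence == NONSYNONYMOUS,
    "synonymous": lambda ann: ann.consequence == SYNONYMOUS,
    "other": lambda ann: ann.consequence == OTHER,
    "cpg_affected": lambda ann: ann.cpg_impact in (CPG_DISRUPTED, CPG_GAINED),
    "cpg_not_affected": lambda ann: ann.cpg_impact == CPG_NONE,
}


@dataclass(frozen=True)
class Stratum:
    """One arm of one ancestry stratum (e.g. the EA cases)."""

    label: str
    role: str
    n_individuals: int

    def __post_init__(self) -> None:
        if self.role not in (CASE, CONTROL):
            raise ConfigurationError(f"stratum role {self.role!r} must be case or control")
        if self.n_individuals < 1:
            raise ConfigurationError(f"stratum {self.label}/{self.role}: n_individuals must be >= 1")

    @property
    def n_alleles(self) -> int:
        return 2 * self.n_individuals


@dataclass(frozen=True)
class VariantObservation:
    """One variant's carrier-allele count in one stratum arm."""

    variant: SequenceVariant
    stratum_label: str
    carrier_alleles: int
    maf_reference: Optional[float] = None  # population MAF (fraction), None = unknown

    def __post_init__(self) -> None:
        if self.carrier_alleles < 0:
            raise DataIntegrityError("carrier_alleles must be non-negative")
        if self.maf_reference is not None and not 0.0 <= self.maf_reference <= 1.0:
            raise DataIntegrityError(f"maf_reference {self.maf_reference} outside [0, 1]")


@dataclass(frozen=True)
class StratumTable:
    """2x2 allele-count table (variant/reference x case/control) for one stratum."""

    a: int  # variant alleles in cases
    b: int  # reference alleles in cases
    c: int  # variant alleles in controls
    d: int  # reference alleles in controls
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataIntegrityError(f"negative cell in stratum table {self.label!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def filter_rare(
    observations: Iterable[VariantObservation], maf_threshold: float = 0.01
) -> list[VariantObservation]:
    """Keep observations rare within their own ancestry stratum.

    An observation is retained iff its stratum-matched reference MAF is
    strictly below the threshold; an unknown MAF is treated as rare and
    retained.
    """
    if not 0.0 < maf_threshold <= 1.0:
        raise ConfigurationError(f"MAF threshold {maf_threshold} outside (0, 1]")
    observations = list(observations)
    kept = [
        obs
        for obs in observations
        if obs.maf_reference is None or obs.maf_reference < maf_threshold
    ]
    logger.info(
        "rarity filter (MAF < %g): %d of %d observations retained",
        maf_threshold,
        len(kept),
        len(observations),
    )
    return kept


def allele_frequency(carrier_alleles: int, n_alleles: int, *, percent: bool = True) -> float:
    """Allele frequency of a carrier count, as a percentage by default."""
    if n_alleles <= 0:
        raise DataIntegrityError("allele frequency undefined for zero total alleles")
    if not 0 <= carrier_alleles <= n_alleles:
        raise DataIntegrityError(
            f"carrier alleles {carrier_alleles} outside 0..{n_alleles}"
        )
    frac = carrier_alleles / n_alleles
    return 100.0 * frac if percent else frac


def _index_strata(strata: Iterable[Stratum]) -> dict[tuple[str, str], Stratum]:
    index: dict[tuple[str, str], Stratum] = {}
    for s in strata:
        key = (s.label, s.role)
        if key in index:
            raise ConfigurationError(f"duplicate stratum {key} in manifest")
        index[key] = s
    return index


def _sum_alleles(
    observations: Iterable[VariantObservation],
    label: str,
    annotations: Mapping[SequenceVariant, VariantAnnotation],
    class_filter: Optional[Callable[[VariantAnnotation], bool]],
    region_filter: Optional[str],
) -> int:
    total = 0
    for obs in observations:
        if obs.stratum_label != label:
            continue
        try:
            ann = annotations[obs.variant]
        except KeyError:
            raise DataIntegrityError(
                f"no annotation for variant c.{obs.variant.pos_c} "
                f"{obs.variant.ref}>{obs.variant.alt}"
            ) from None
        if class_filter is not None and not class_filter(ann):
            continue
        if region_filter is not None and region_filter not in ann.regions:
            continue
        total += obs.carrier_alleles
    return total


def build_tables(
    case_obs: Sequence[VariantObservation],
    control_obs: Sequence[VariantObservation],
    strata: Sequence[Stratum],
    annotations: Mapping[SequenceVariant, VariantAnnotation],
    class_filter: Optional[Callable[[VariantAnnotation], bool]] = None,
    region_filter: Optional[str] = None,
) -> list[StratumTable]:
    """One pooled 2x2 allele table per ancestry label, in manifest order.

    ``a`` sums carrier alleles over case observations passing both filters
    (``b`` is the remaining case alleles), and likewise ``c``/``d`` for
    controls.  Every ancestry label must appear with both a case and a
    control arm in the manifest; observations referencing an unknown
    stratum are a data-integrity error.
    """
    index = _index_strata(strata)
    labels = list(dict.fromkeys(s.label for s in strata))
    known = set(index)
    for obs, role in [(o, CASE) for o in case_obs] + [(o, CONTROL) for o in control_obs]:
        if (obs.stratum_label, role) not in known:
            raise DataIntegrityError(
                f"observation references unknown stratum ({obs.stratum_label}, {role})"
            )
    tables = []
    for label in labels:
        try:
            case_stratum = index[(label, CASE)]
            control_stratum = index[(label, CONTROL)]
        except KeyError as exc:
            raise ConfigurationError(
                f"stratum {label!r} lacks a case or control arm in the manifest"
            ) from exc
        a = _sum_alleles(case_obs, label, annotations, class_filter, region_filter)
        c = _sum_alleles(control_obs, label, annotations, class_filter, region_filter)
        if a > case_stratum.n_alleles or c > control_stratum.n_alleles:
            raise DataIntegrityError(
                f"stratum {label!r}: pooled carrier alleles exceed 2N manifest alleles"
            )
        tables.append(
            StratumTable(
                a=a,
                b=case_stratum.n_alleles - a,
                c=c,
                d=control_stratum.n_alleles - c,
                label=label,
            )
        )
    return tables


# -- TSV serialization --------------------------------------------------

_OBS_COLUMNS = [
    "transcript_id",
    "pos_c",
    "ref",
    "alt",
    "ctx5",
    "ctx3",
    "rs_id",
    "stratum_label",
    "role",
    "carrier_alleles",
    "maf_reference",
]


def read_manifest(path) -> list[Stratum]:
    df = pd.read_csv(path, sep="\t", dtype={"label": str, "role": str})
    return [
        Stratum(label=row.label, role=row.role, n_individuals=int(row.n_individuals))
        for row in df.itertuples()
    ]


def write_manifest(strata: Sequence[Stratum], path) -> None:
    pd.DataFrame(
        [(s.label, s.role, s.n_individuals) for s in strata],
        columns=["label", "role", "n_individuals"],
    ).to_csv(path, sep="\t", index=False)


def read_observations(path) -> tuple[list[VariantObservation], list[VariantObservation]]:
    """Read the observations TSV, split into (case, control) lists."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)

    def _opt(value: str) -> Optional[str]:
        return None if value in (".", "") else value

    cases: list[VariantObservation] = []
    controls: list[VariantObservation] = []
    for row in df.itertuples():
        variant = SequenceVariant(
            transcript_id=row.transcript_id,
            pos_c=int(row.pos_c),
            ref=row.ref,
            alt=row.alt,
            context_5p=_opt(row.ctx5),
            context_3p=_opt(row.ctx3),
            rs_id=_opt(row.rs_id),
        )
        maf = _opt(row.maf_reference)
        obs = VariantObservation(
            variant=variant,
            stratum_label=row.stratum_label,
            carrier_alleles=int(row.carrier_alleles),
            maf_reference=float(maf) if maf is not None else None,
        )
        if row.role == CASE:
            cases.append(obs)
        elif row.role == CONTROL:
            controls.append(obs)
        else:
            raise DataIntegrityError(f"observation role {row.role!r} must be case or control")
    return cases, controls


def write_observations(
    case_obs: Sequence[VariantObservation],
    control_obs: Sequence[VariantObservation],
    path,
) -> None:
    rows = []
    for role, obs_list in ((CASE, case_obs), (CONTROL, control_obs)):
        for obs in obs_list:
            v = obs.variant
            rows.append(
                (
                    v.transcript_id,
                    v.pos_c,
                    v.ref,
                    v.alt,
                    v.context_5p or ".",
                    v.context_3p or ".",
                    v.rs_id or ".",
                    obs.stratum_label,
                    role,
                    obs.carrier_alleles,
                    f"{obs.maf_reference:.6f}" if obs.maf_reference is not None else ".",
                )
            )
    pd.DataFrame(rows, columns=_OBS_COLUMNS).to_csv(path, sep="\t", index=False)
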