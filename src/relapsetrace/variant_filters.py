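"""Variant domain types, tier classification, unpaired-sample filters and
copy-number VAF correction.

Tiers follow the four-level scheme used for pediatric leukemia genomes:
tier 1 coding (synonymous, nonsynonymous, splice-site and noncoding-RNA
variants), tier 2 conserved or regulatory (conservation score >= 500 or an
annotated regulatory element), tier 3 non-repeat-masked regions, tier 4 the
remainder.  The unpaired-sample cascade drops variants with population
allele frequency > 0.01, germline VAF > 0.2, or mutant reads on a single
strand only.  Cancer cell fractions are recovered from VAFs with the
standard purity/copy-number/multiplicity relation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

TIER1_CONSEQUENCES = frozenset(
    {
        "synonymous",
        "nonsynonymous",
        "missense",
        "nonsense",
        "stop_gained",
        "stop_lost",
        "splice_site",
        "splice_region",
        "noncoding_rna",
        "ncrna",
        "frameshift",
        "inframe_indel",
    }
)

REGION_CLASSES = ("coding", "conserved_or_regulatory", "nonrepeat", "repeat")


class VariantClass(str, Enum):
    SNV = "SNV"
    INDEL = "indel"
    SV = "SV"
    CNA = "CNA"


class MissingAnnotationError(ValueError):
    """A variant cannot be tiered because required annotation is absent."""


@dataclass
class Variant:
    """A somatic alteration with genomic coordinates and annotations."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vclass: str = VariantClass.SNV.value
    gene: str | None = None
    consequence: str | None = None
    conservation_score: int | None = None
    region_class: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.vclass == VariantClass.SNV.value and self.ref == self.alt:
            raise ValueError(f"SNV with ref == alt at {self.chrom}:{self.pos}")
        if self.conservation_score is not None and self.conservation_score < 0:
            raise ValueError("conservation_score must be non-negative")
        if self.region_class is not None and self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region_class {self.region_class!r}")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_snv(self) -> bool:
        return self.vclass == VariantClass.SNV.value


@dataclass
class Observation:
    """Read counts for one variant in one sample."""

    sample: str
    ref_reads: int
    alt_reads: int
    fwd_alt: int
    rev_alt: int
    other_reads: int = 0

    def __post_init__(self) -> None:
        for name in ("ref_reads", "alt_reads", "fwd_alt", "rev_alt", "other_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.fwd_alt + self.rev_alt != self.alt_reads:
            raise ValueError(
                f"strand counts {self.fwd_alt}+{self.rev_alt} != alt {self.alt_reads}"
            )

    @property
    def depth(self) -> int:
        return self.ref_reads + self.alt_reads

    @property
    def vaf(self) -> float | None:
        """Alt fraction of ref+alt reads; None when depth is 0."""
        return self.alt_reads / self.depth if self.depth > 0 else None

    @property
    def other_vaf(self) -> float:
        total = self.depth + self.other_reads
        return self.other_reads / total if total > 0 else 0.0

    @property
    def informative(self) -> bool:
        return self.depth > 0


@dataclass(frozen=True)
class CopyNumberSegment:
    """0-based half-open copy-number segment."""

    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.minor_cn > self.total_cn / 2:
            raise ValueError(
                f"minor_cn {self.minor_cn} exceeds total_cn/2 ({self.total_cn}/2)"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        """1-based position membership."""
        return chrom == self.chrom and self.start < pos <= self.end


def classify_tier(v: Variant) -> int:
    """Assign a variant to tier 1-4; first matching rule wins.

    Raises :class:`MissingAnnotationError` when consequence or region class
    are absent so that a variant is reported unclassifiable rather than
    silently tiered.
    """
    if v.consequence is None or v.region_class is None:
        raise MissingAnnotationError(
            f"{v.id}: cannot tier without consequence and region_class"
        )
    if v.region_class == "coding" or v.consequence.lower() in TIER1_CONSEQUENCES:
        return 1
    if (
        v.region_class == "conserved_or_regulatory"
        or (v.conservation_score is not None and v.conservation_score >= 500)
    ):
        return 2
    if v.region_class == "nonrepeat":
        return 3
    return 4


def classify_tiers(variants) -> tuple[dict[str, int], list[str]]:
    """Batch tiering; returns (variant id -> tier, unclassifiable ids)."""
    tiers: dict[str, int] = {}
    unclassifiable: list[str] = []
    for v in variants:
        try:
            tiers[v.id] = classify_tier(v)
        except MissingAnnotationError:
            unclassifiable.append(v.id)
    return tiers, unclassifiable


@dataclass(frozen=True)
class FilterDecision:
    keep: bool
    reason: str | None = None
    flags: tuple[str, ...] = ()


def filter_unpaired(
    v: Variant,
    tumor_obs: Observation,
    germline_vaf: float | None = None,
    population_af: float | None = None,
    pop_af_max: float = 0.01,
    germline_vaf_max: float = 0.2,
    min_alt_for_strand: int = 3,
) -> FilterDecision:
    """Unpaired-sample filter cascade.

    Drops a putative somatic variant when its population allele frequency
    exceeds ``pop_af_max``, when the germline VAF exceeds ``germline_vaf_max``,
    or when mutant reads sit on one strand only.  The single-strand rule is
    applied only with ``min_alt_for_strand`` or more alt reads: with 1-2 alt
    reads single-strandedness carries no evidence and the variant is kept
    with a ``low_evidence_strand`` flag.
    """
    if tumor_obs.depth <= 0:
        raise ValueError("filter_unpaired requires tumor depth > 0")
    if population_af is not None and population_af > pop_af_max:
        return FilterDecision(False, "population")
    if germline_vaf is not None and germline_vaf > germline_vaf_max:
        return FilterDecision(False, "germline")
    if tumor_obs.alt_reads > 0 and (tumor_obs.fwd_alt == 0 or tumor_obs.rev_alt == 0):
        if tumor_obs.alt_reads >= min_alt_for_strand:
            return FilterDecision(False, "single-strand")
        return FilterDecision(True, None, ("low_evidence_strand",))
    return FilterDecision(True)


def depth_gate(obs: Observation, min_depth: int = 10) -> bool:
    """Keep a variant observation iff ref+alt reads reach ``min_depth``."""
    return obs.depth >= min_depth


@dataclass(frozen=True)
class CcfEstimate:
    value: float
    capped: bool = False

    def __float__(self) -> float:
        return self.value


def correct_vaf(
    obs: Observation | float,
    seg: CopyNumberSegment | None = None,
    purity: float = 1.0,
    multiplicity: int = 1,
) -> CcfEstimate:
    """Convert an observed VAF to a cancer cell fraction.

    CCF = VAF * (purity * total_cn + 2 * (1 - purity)) / (purity * multiplicity),
    the mean-consistent inversion of binomial read sampling from a tumor of
    the given purity with ``multiplicity`` mutant copies per carrying cell.
    A diploid segment (total_cn 2) is assumed when ``seg`` is None.  Values
    above 1 are capped at 1 and flagged.
    """
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if multiplicity < 1:
        raise ValueError(f"multiplicity must be >= 1, got {multiplicity}")
    total_cn = 2 if seg is None else seg.total_cn
    if total_cn == 0:
        raise ValueError(
            "segment with total_cn 0 cannot carry an SNV (homozygous deletion)"
        )
    vaf = obs if isinstance(obs, (int, float)) else obs.vaf
    if vaf is None:
        raise ValueError("cannot correct a VAF at zero depth")
    ccf = vaf * (purity * total_cn + 2.0 * (1.0 - purity)) / (purity * multiplicity)
    if ccf > 1.0:
        return CcfEstimate(1.0, capped=True)
    return CcfEstimate(ccf)


@dataclass
class FilteredVariant:
    variant: Variant
    observation: Observation
    tier: int | None
    decision: FilterDecision


def apply_filters(
    records,
    min_depth: int = 10,
    pop_af_max: float = 0.01,
    germline_vaf_max: float = 0.2,
    gene_scope: set[str] | None = None,
) -> tuple[list[FilteredVariant], list[FilteredVariant]]:
    """Run depth gate + unpaired cascade + tiering over (variant, obs,
    germline_vaf, population_af) records.

    ``gene_scope`` optionally restricts the unpaired cascade to a gene list
    (variants outside the list are kept untouched by that cascade).  Returns
    (kept, dropped); the cascade is idempotent - re-filtering the kept set
    removes nothing.
    """
    kept: list[FilteredVariant] = []
    dropped: list[FilteredVariant] = []
    for rec in records:
        v, obs, germline_vaf, population_af = rec
        try:
            tier: int | None = classify_tier(v)
        except MissingAnnotationError:
            tier = None
        if not depth_gate(obs, min_depth=min_depth):
            dropped.append(FilteredVariant(v, obs, tier, FilterDecision(False, "depth")))
            continue
        if gene_scope is not None and v.gene not in gene_scope:
            kept.append(FilteredVariant(v, obs, tier, FilterDecision(True)))
            continue
        decision = filter_unpaired(
            v,
            obs,
            germline_vaf=germline_vaf,
            population_af=population_af,
            pop_af_max=pop_af_max,
            germline_vaf_max=germline_vaf_max,
        )
        (kept if decision.keep else dropped).append(
            FilteredVariant(v, obs, tier, decision)
        )
    return kept, dropped
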