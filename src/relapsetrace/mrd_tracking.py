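"""Molecular MRD calling from patient-specific deep-sequencing panels.

The leukemic burden at a timepoint is the mean of the two highest VAFs
among the tracked variants, gated on identification of the KMT2A fusion
marker.  Samples without the fusion are rescued when more than two variants
from the major diagnostic clone and/or the relapse clone exceed the
detection limit (VAF > 0.002); tracked sites where a *non-tracked*
alternate allele exceeds that limit are treated as artifacts and excluded.
The panel's limit of detection is estimated by an in-silico serial dilution
under binomial read sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .variant_filters import Observation

DETECTION_LIMIT_VAF = 0.002


@dataclass(frozen=True)
class PanelSpec:
    """Patient-specific tracked mutations, incl. one fusion-marker SV."""

    variants: tuple[str, ...]
    fusion_id: str
    major_diag_clone: frozenset[str]
    relapse_clone: frozenset[str]
    detection_limit: float = DETECTION_LIMIT_VAF
    min_fusion_reads: int = 1

    def __post_init__(self) -> None:
        if self.fusion_id not in self.variants:
            raise ValueError("fusion marker must be among the tracked variants")
        extra = (set(self.major_diag_clone) | set(self.relapse_clone)) - set(self.variants)
        if extra:
            raise ValueError(f"clone subsets outside the panel: {sorted(extra)}")
        if not 0 < self.detection_limit < 1:
            raise ValueError("detection_limit must be in (0, 1)")


@dataclass
class MRDCall:
    day: int
    burden_vaf: float | None
    status: str  # detected | undetected | rescued_detected | invalid
    gate: str  # fusion_present | fusion_absent_rescued | fusion_absent_failed
    variants_used: list[str] = field(default_factory=list)
    excluded_artifacts: list[str] = field(default_factory=list)
    single_variant: bool = False

    def __post_init__(self) -> None:
        if self.status in ("detected", "rescued_detected"):
            if self.burden_vaf is None:
                raise ValueError("detected call without a burden")
        if self.status == "detected" and self.gate != "fusion_present":
            raise ValueError("detected requires the fusion gate")


def call_mrd(
    panel: PanelSpec,
    obs: dict[str, Observation],
    day: int = 0,
    rescue_sets_union: bool = True,
) -> MRDCall:
    """One timepoint's MRD call.

    Order of operations: (i) artifact check - any tracked site where a
    non-tracked alternate allele exceeds the detection limit is excluded;
    (ii) burden = mean of the two highest remaining VAFs (a single usable
    variant is used alone, flagged); (iii) with the fusion marker observed
    the call is detected when the burden reaches the detection limit;
    (iv) without the fusion the sample is rescued only when strictly more
    than two variants from the major diagnostic and/or relapse clone exceed
    the detection limit.
    """
    limit = panel.detection_limit
    excluded = []
    usable: dict[str, Observation] = {}
    for vid in panel.variants:
        if vid == panel.fusion_id:
            continue
        o = obs.get(vid)
        if o is None or o.depth <= 0:
            continue
        if o.other_vaf > limit:
            excluded.append(vid)
            continue
        usable[vid] = o
    fusion_obs = obs.get(panel.fusion_id)
    fusion_present = (
        fusion_obs is not None
        and fusion_obs.alt_reads >= panel.min_fusion_reads
    )

    if not usable:
        return MRDCall(
            day=day, burden_vaf=None, status="invalid",
            gate="fusion_present" if fusion_present else "fusion_absent_failed",
            excluded_artifacts=excluded,
        )

    vafs = sorted(
        ((vid, o.vaf) for vid, o in usable.items()),
        key=lambda t: (-t[1], t[0]),
    )
    top = vafs[:2]
    burden = float(np.mean([v for _, v in top]))
    used = [vid for vid, _ in top]
    single = len(usable) == 1

    if fusion_present:
        if burden >= limit:
            return MRDCall(
                day=day, burden_vaf=burden, status="detected",
                gate="fusion_present", variants_used=used,
                excluded_artifacts=excluded, single_variant=single,
            )
        return MRDCall(
            day=day, burden_vaf=None, status="undetected",
            gate="fusion_present", variants_used=used,
            excluded_artifacts=excluded, single_variant=single,
        )

    if rescue_sets_union:
        rescue_pool = set(panel.major_diag_clone) | set(panel.relapse_clone)
        n_above = sum(
            1 for vid, o in usable.items()
            if vid in rescue_pool and o.vaf is not None and o.vaf > limit
        )
        rescued = n_above > 2
    else:
        counts = [
            sum(
                1 for vid, o in usable.items()
                if vid in pool and o.vaf is not None and o.vaf > limit
            )
            for pool in (panel.major_diag_clone, panel.relapse_clone)
        ]
        rescued = any(c > 2 for c in counts)
    if rescued:
        return MRDCall(
            day=day, burden_vaf=burden, status="rescued_detected",
            gate="fusion_absent_rescued", variants_used=used,
            excluded_artifacts=excluded, single_variant=single,
        )
    return MRDCall(
        day=day, burden_vaf=None, status="undetected",
        gate="fusion_absent_failed", variants_used=used,
        excluded_artifacts=excluded, single_variant=single,
    )


@dataclass
class MRDTimeline:
    calls: list[MRDCall]
    lead_time_days: int | None
    first_detection_day: int | None


def mrd_timeline(
    panel: PanelSpec,
    serial_obs: dict[int, dict[str, Observation]],
    relapse_day: int | None = None,
    min_day: int | None = 0,
) -> MRDTimeline:
    """MRD calls across serial timepoints with a relapse lead-time summary.

    Lead time is the number of days between the first detected (or rescued)
    call in which at least one relapse-clone variant exceeds the detection
    limit and the annotated relapse day.  Timepoints at or before
    ``min_day`` (the diagnostic sample by default) are excluded from the
    lead-time search but still called.  Without a relapse annotation the
    timeline is emitted with an undefined lead time.
    """
    calls = [
        call_mrd(panel, obs, day=day) for day, obs in sorted(serial_obs.items())
    ]
    first_day = None
    for call in calls:
        if call.status not in ("detected", "rescued_detected"):
            continue
        if min_day is not None and call.day <= min_day:
            continue
        if relapse_day is not None and call.day > relapse_day:
            continue
        obs = serial_obs[call.day]
        relapse_signal = any(
            (o := obs.get(vid)) is not None
            and o.vaf is not None
            and o.vaf > panel.detection_limit
            for vid in panel.relapse_clone
        )
        if relapse_signal:
            first_day = call.day
            break
    lead = None
    if relapse_day is not None and first_day is not None:
        lead = int(relapse_day - first_day)
    return MRDTimeline(calls=calls, lead_time_days=lead, first_detection_day=first_day)


@dataclass(frozen=True)
class DetectionRule:
    """Alt-read evidence required to score a replicate as detected."""

    min_alt_reads: int = 3
    require_both_strands: bool = True


@dataclass
class DilutionResult:
    lod_vaf: float | None
    step_vafs: list[float]
    detection_probability: list[float]
    replicates: int


def lod_dilution(
    depth: float = 3250.0,
    error_rate: float = 1e-4,
    n_steps: int = 9,
    factor: float = 0.5,
    start_vaf: float = 1.0,
    replicates: int = 1000,
    detection_rule: DetectionRule = DetectionRule(),
    reliability: float = 0.9,
    seed: int = 0,
) -> DilutionResult:
    """In-silico serial dilution: the panel's limit of detection.

    Step k has expected VAF ``start_vaf * factor**k`` (nine two-fold steps
    from a homozygous variant end at 0.5**9 ~ 0.0019).  Each replicate draws
    a Poisson depth around the mean and binomial alt reads at the expected
    VAF adjusted for symmetric per-base error; the default rule calls a
    replicate detected at >= 3 alt reads with both strands represented.
    Returns the smallest step VAF detected in at least ``reliability`` of
    replicates, plus the full detection-probability curve.
    """
    if not 0.0 < factor < 1.0:
        raise ValueError(f"dilution factor must be in (0, 1), got {factor}")
    if replicates < 100:
        raise ValueError("need >= 100 replicates for a stable LOD")
    rng = np.random.default_rng(seed)
    step_vafs = [start_vaf * factor**k for k in range(1, n_steps + 1)]
    probs = []
    for vaf in step_vafs:
        q = vaf * (1.0 - 3.0 * error_rate) + (1.0 - vaf) * error_rate
        d = rng.poisson(depth, size=replicates)
        alt = rng.binomial(d, q)
        detected = alt >= detection_rule.min_alt_reads
        if detection_rule.require_both_strands:
            fwd = rng.binomial(alt, 0.5)
            detected &= (fwd >= 1) & (alt - fwd >= 1)
        probs.append(float(detected.mean()))
    lod = None
    for vaf, p in sorted(zip(step_vafs, probs)):
        if p >= reliability:
            lod = vaf
            break
    return DilutionResult(
        lod_vaf=lod, step_vafs=step_vafs, detection_probability=probs,
        replicates=replicates,
    )


def round_to_one_significant_figure(x: float) -> float:
    if x == 0:
        return 0.0
    exp = int(np.floor(np.log10(abs(x))))
    return float(round(x, -exp))
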