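"""Synthetic clonal-evolution cohorts for relapsed KMT2A-rearranged leukemia.

Generates fully specified patients: a clonal tree with treatment-modulated
cell-fraction trajectories, signature-attributed point mutations placed on a
reference sequence, binomially sampled read counts at serial timepoints, and
a truth record for every downstream stage.

Three scenarios emulate the relapse mechanisms seen in this disease:

``very_early_multiclonal``
    Several diagnostic clones survive induction and jointly seed a very
    early relapse; relapse-private mutations carry a thiopurine-like
    chemotherapy signature.
``early_sweep_chemo``
    A minor diagnostic clone (detectable or not, configurable) sweeps at an
    early relapse; its relapse-private mutations are chemotherapy-dominated.
    The dominant diagnostic clone is lost (branching evolution).
``aml_dormant``
    The relapse arises from a dormant, evolutionarily early clone whose
    mutational processes are identical to the diagnostic clone's - no
    chemotherapy imprint, as seen in relapsed AML.

Clone fractions are cancer-cell fractions of all nucleated cells and are
*inclusive* of descendant clones (a clone's fraction counts every cell
carrying its private mutations), so a child's fraction can never exceed its
parent's and sibling fractions sum to at most the parent fraction.  The
truncal (root) clone carries the fusion marker and, in the sweep scenarios,
no private SNVs: the relapse lineage branches off before the bulk of the
diagnostic clone's mutations, which is what makes the swept diagnostic
cluster disappear at relapse.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import SignatureCatalog, bundled_catalog
from .contexts import CONTEXTS_96, context_alt, context_ref
from .reference import (
    ContextLocusIndex,
    ReferenceGenome,
    synthesize_reference,
    write_fasta,
)
from .variant_filters import Observation, Variant, VariantClass

SCENARIOS = ("very_early_multiclonal", "early_sweep_chemo", "aml_dormant")

#: Seed of the shared synthetic reference contig (not a per-patient choice).
REFERENCE_SEED = 20_240

#: Panel detection limit used for truth-side seeding labels.
DETECTION_LIMIT_VAF = 0.002
#: VAF above which a cluster counts as clonally present in a sample.
PRESENCE_VAF = 0.05

FUSION_ALT = "<KMT2A-FUSION>"

_EXP_CLOCK = {"SBS_SYN_CLOCK": 0.8, "SBS_SYN_UNKNOWN": 0.2}
_EXP_CLOCK_B = {"SBS_SYN_CLOCK": 0.7, "SBS_SYN_UNKNOWN": 0.3}
_EXP_CHEMO = {"SBS_SYN_THIO": 0.7, "SBS_SYN_CLOCK": 0.3}
_EXP_CHEMO_MILD = {"SBS_SYN_THIO": 0.6, "SBS_SYN_CLOCK": 0.4}


class ScenarioError(ValueError):
    pass


@dataclass
class CloneNode:
    """One clone: tree position, private mutation load, exposures, trajectory."""

    id: str
    parent: str | None
    private_mutation_count: int
    signature_exposures: dict[str, float]
    fraction_by_timepoint: dict[int, float]

    def __post_init__(self) -> None:
        if self.private_mutation_count < 0:
            raise ValueError("private_mutation_count must be non-negative")
        total = sum(self.signature_exposures.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"clone {self.id}: exposures sum to {total}, expected 1"
            )
        for day, frac in self.fraction_by_timepoint.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"clone {self.id} day {day}: fraction {frac}")

    def fraction(self, day: int) -> float:
        return self.fraction_by_timepoint[day]


class CloneTree:
    """A rooted clone tree over shared timepoints."""

    def __init__(self, nodes: list[CloneNode]) -> None:
        self.nodes: dict[str, CloneNode] = {n.id: n for n in nodes}
        if len(self.nodes) != len(nodes):
            raise ValueError("duplicate clone ids")
        roots = [n for n in nodes if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, got {len(roots)}")
        self.root = roots[0]
        self.validate()

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(sorted(self.root.fraction_by_timepoint))

    def children(self, clone_id: str) -> list[CloneNode]:
        return [n for n in self.nodes.values() if n.parent == clone_id]

    def non_root(self) -> list[CloneNode]:
        return [n for n in self.nodes.values() if n.parent is not None]

    def validate(self) -> None:
        """Nesting invariants: child <= parent and sibling sums <= parent."""
        days = self.days
        for node in self.nodes.values():
            if tuple(sorted(node.fraction_by_timepoint)) != days:
                raise ValueError(f"clone {node.id}: timepoint mismatch")
            if node.parent is not None and node.parent not in self.nodes:
                raise ValueError(f"clone {node.id}: unknown parent {node.parent}")
        for node in self.nodes.values():
            kids = self.children(node.id)
            for day in days:
                pf = node.fraction(day)
                for k in kids:
                    if k.fraction(day) > pf + 1e-12:
                        raise ValueError(
                            f"clone {k.id} exceeds parent {node.id} on day {day}"
                        )
                sib_sum = sum(k.fraction(day) for k in kids)
                if sib_sum > pf + 1e-9:
                    raise ValueError(
                        f"children of {node.id} sum to {sib_sum} > {pf} on day {day}"
                    )

    def interpolated(self, days: tuple[int, ...]) -> "CloneTree":
        """Resample every trajectory onto ``days`` by linear interpolation.

        Linear interpolation between shared knots preserves the nesting
        invariants; requested days outside the simulated range clamp to the
        endpoint fractions.
        """
        base = np.asarray(self.days, dtype=float)
        nodes = []
        for n in self.nodes.values():
            y = np.asarray([n.fraction(d) for d in self.days])
            f = np.interp(np.asarray(days, dtype=float), base, y)
            nodes.append(
                replace(n, fraction_by_timepoint={d: float(v) for d, v in zip(days, f)})
            )
        return CloneTree(nodes)


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic patient.

    ``panel_depth`` is the deep targeted panel's mean coverage per site;
    ``wgs_depth`` the discovery-sequencing coverage.  ``error_rate`` is the
    probability that a read reports one *specific* incorrect base (the three
    miscall directions are symmetric, so total miscalls occur at three times
    this rate).  ``sweep_diag_fraction`` sets the sweeping clone's diagnostic
    cell fraction in ``early_sweep_chemo`` - above or below the panel
    detection limit.  ``depth_dispersion`` switches per-site depth from
    Poisson (None) to negative binomial with that shape parameter.
    """

    scenario: str
    n_clones: int | None = None
    panel_depth: float = 3250.0
    wgs_depth: float = 43.0
    error_rate: float = 1e-4
    seed: int = 0
    days: tuple[int, ...] | None = None
    sweep_diag_fraction: float = 0.008
    remission: bool = False
    purity: float = 1.0
    depth_dispersion: float | None = None
    mutation_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ScenarioError(
                f"unknown scenario {self.scenario!r}; valid scenarios: "
                f"{', '.join(SCENARIOS)}"
            )
        if self.n_clones is not None and self.n_clones < 2:
            raise ScenarioError("n_clones must be >= 2")
        if self.panel_depth <= 0 or self.wgs_depth <= 0:
            raise ScenarioError("depths must be > 0")
        if not 0.0 <= self.error_rate < 0.01:
            raise ScenarioError("error_rate must be in [0, 0.01)")
        if not 0.0 < self.purity <= 1.0:
            raise ScenarioError("purity must be in (0, 1]")
        if not 0.0 <= self.sweep_diag_fraction <= 0.5:
            raise ScenarioError("sweep_diag_fraction must be in [0, 0.5]")


# (parent, exposures, mutation count, fractions on the canonical day grid)
_CANONICAL_DAYS = {
    "very_early_multiclonal": (0, 15, 29, 80, 120),
    "early_sweep_chemo": (0, 15, 29, 80, 250),
    "aml_dormant": (0, 15, 29, 80, 400),
}

_DEFAULT_N_CLONES = {
    "very_early_multiclonal": 4,
    "early_sweep_chemo": 3,
    "aml_dormant": 3,
}


def _scenario_clones(spec: ScenarioSpec) -> list[tuple]:
    s = spec.scenario
    if s == "very_early_multiclonal":
        base = [
            ("trunk", None, _EXP_CLOCK, 400, (0.95, 0.30, 0.05, 0.40, 0.95)),
            ("c1", "trunk", _EXP_CLOCK_B, 250, (0.55, 0.18, 0.03, 0.25, 0.50)),
            ("c2", "trunk", _EXP_CLOCK, 250, (0.35, 0.10, 0.02, 0.12, 0.40)),
            ("c3", "c1", _EXP_CHEMO_MILD, 200, (0.0, 0.0, 0.0, 0.05, 0.25)),
            ("c4", "c1", _EXP_CLOCK, 150, (0.15, 0.05, 0.0, 0.0, 0.0)),
        ]
    elif s == "early_sweep_chemo":
        d = spec.sweep_diag_fraction
        sweep_exp = _EXP_CHEMO if (spec.n_clones or 3) == 2 else _EXP_CLOCK
        base = [
            ("trunk", None, _EXP_CLOCK, 0, (0.95, 0.31, 0.05, 0.16, 0.95)),
            ("c1", "trunk", _EXP_CLOCK, 500, (0.90, 0.30, 0.045, 0.004, 0.0)),
            ("c2", "trunk", sweep_exp, 250, (d, d / 2, d / 4, 0.10, 0.90)),
            ("c3", "c2", _EXP_CHEMO, 250, (0.0, 0.0, 0.0, 0.05, 0.45)),
            ("c4", "c3", _EXP_CHEMO_MILD, 150, (0.0, 0.0, 0.0, 0.0, 0.15)),
        ]
    else:  # aml_dormant
        base = [
            ("trunk", None, _EXP_CLOCK, 0, (0.93, 0.27, 0.04, 0.09, 0.92)),
            ("c1", "trunk", _EXP_CLOCK, 500, (0.90, 0.25, 0.03, 0.002, 0.0)),
            ("c2", "trunk", _EXP_CLOCK, 250, (0.02, 0.01, 0.005, 0.08, 0.88)),
            ("c3", "c2", _EXP_CLOCK, 250, (0.0, 0.0, 0.0, 0.03, 0.45)),
            ("c4", "c3", _EXP_CLOCK, 150, (0.0, 0.0, 0.0, 0.0, 0.15)),
        ]
    n = spec.n_clones if spec.n_clones is not None else _DEFAULT_N_CLONES[s]
    clones = base[: 1 + n]
    # beyond the named set, chain small late subclones under the deepest clone
    while len(clones) - 1 < n:
        parent = clones[-1] if len(clones) > len(base) else base[-1]
        pid, _, pexp, _, pfrac = parent
        cid = f"c{len(clones)}"
        frac = tuple(0.0 if i < 3 else 0.4 * f for i, f in enumerate(pfrac))
        clones.append((cid, pid, pexp, 100, frac))
    return clones


def simulate_clone_tree(spec: ScenarioSpec) -> CloneTree:
    """Build the clone tree of one scenario, treatment modulation included.

    The postconditions hold on non-truncal clones (the root by definition
    spans all cancer cells): ``very_early_multiclonal`` keeps >= 2 diagnostic
    clones alive at relapse; ``early_sweep_chemo`` has exactly one clone
    above cell fraction 0.5 at relapse; ``aml_dormant``'s relapse-dominant
    clone is present at diagnosis with exposures identical to the dominant
    diagnostic clone's.
    """
    days = _CANONICAL_DAYS[spec.scenario]
    nodes = []
    for cid, parent, exposures, count, fracs in _scenario_clones(spec):
        n_mut = int(round(count * spec.mutation_scale))
        traj = dict(zip(days, fracs))
        if spec.remission:
            traj = {d: (f if d <= 29 else 0.0) for d, f in traj.items()}
        nodes.append(
            CloneNode(
                id=cid,
                parent=parent,
                private_mutation_count=n_mut,
                signature_exposures=dict(exposures),
                fraction_by_timepoint=traj,
            )
        )
    tree = CloneTree(nodes)
    if spec.days is not None:
        tree = tree.interpolated(tuple(spec.days))
    return tree


def relapse_day(spec: ScenarioSpec) -> int | None:
    if spec.remission:
        return None
    days = spec.days if spec.days is not None else _CANONICAL_DAYS[spec.scenario]
    return int(max(days))


@dataclass
class SimulatedVariant:
    """A generated variant with its truth labels."""

    variant: Variant
    clone: str
    signature: str | None
    context: str | None

    @property
    def id(self) -> str:
        return self.variant.id


class _PositionSampler:
    """Draws unused loci matching a trinucleotide, deterministically."""

    def __init__(self, index: ContextLocusIndex, rng: np.random.Generator) -> None:
        self.index = index
        self.rng = rng
        self._pools: dict[str, np.ndarray] = {}
        self._ptr: dict[str, int] = {}

    def draw(self, trinuc: str, n: int) -> np.ndarray:
        if trinuc not in self._pools:
            self._pools[trinuc] = self.rng.permutation(self.index.positions(trinuc))
            self._ptr[trinuc] = 0
        ptr = self._ptr[trinuc]
        pool = self._pools[trinuc]
        if ptr + n > pool.size:
            raise ValueError(
                f"reference exhausted for context trinucleotide {trinuc} "
                f"({pool.size} loci available)"
            )
        self._ptr[trinuc] = ptr + n
        return pool[ptr : ptr + n]


def simulate_mutations(
    tree: CloneTree,
    catalog: SignatureCatalog,
    reference: ReferenceGenome,
    seed: int,
    index: ContextLocusIndex | None = None,
) -> list[SimulatedVariant]:
    """Draw each clone's private mutations from its signature mixture.

    Every mutation first draws a generating signature from the clone's
    exposures, then a trinucleotide substitution class from that signature's
    catalog column, and is finally placed at an unused reference locus whose
    trinucleotide matches the class.  The empirical per-clone spectrum
    therefore converges to the exposure-weighted mixture of catalog columns.
    """
    for node in tree.nodes.values():
        for sig in node.signature_exposures:
            if sig not in catalog.names:
                raise ValueError(
                    f"clone {node.id} exposure {sig!r} not in catalog"
                )
    rng = np.random.default_rng(seed)
    if index is None:
        index = ContextLocusIndex(reference)
    sampler = _PositionSampler(index, rng)
    out: list[SimulatedVariant] = []
    for node in sorted(tree.nodes.values(), key=lambda n: n.id):
        n = node.private_mutation_count
        if n == 0:
            continue
        names = sorted(node.signature_exposures)
        weights = np.array([node.signature_exposures[s] for s in names])
        sig_idx = rng.choice(len(names), size=n, p=weights)
        ctx_idx = np.empty(n, dtype=np.int64)
        for j, sig in enumerate(names):
            mask = sig_idx == j
            m = int(mask.sum())
            if m:
                col = catalog.column(sig)
                ctx_idx[mask] = rng.choice(96, size=m, p=col)
        for k in range(n):
            context = CONTEXTS_96[ctx_idx[k]]
            trinuc = context[0] + context_ref(context) + context[6]
            pos = int(sampler.draw(trinuc, 1)[0])
            ref_base = reference.base(pos)
            if ref_base == context_ref(context):
                alt = context_alt(context)
            else:  # locus matched on the opposite strand
                alt = _complement(context_alt(context))
            out.append(
                SimulatedVariant(
                    variant=Variant(
                        chrom=reference.name, pos=pos, ref=ref_base, alt=alt
                    ),
                    clone=node.id,
                    signature=names[sig_idx[k]],
                    context=context,
                )
            )
    out.sort(key=lambda sv: sv.variant.pos)
    return out


def _complement(base: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A"}[base]


def make_fusion_marker(reference: ReferenceGenome, pos: int = 500_000) -> SimulatedVariant:
    """The truncal fusion-marker SV, trackable by breakpoint-supporting reads."""
    return SimulatedVariant(
        variant=Variant(
            chrom=reference.name,
            pos=pos,
            ref=reference.base(pos),
            alt=FUSION_ALT,
            vclass=VariantClass.SV.value,
            gene="KMT2A",
            consequence="fusion",
            region_class="coding",
        ),
        clone="trunk",
        signature=None,
        context=None,
    )


_GENE_POOL = (
    "KRAS", "NRAS", "FLT3", "PAX5", "IKZF1", "CDKN2A", "WT1", "SETD2",
    "CCND3", "ETV6", "NT5C2", "CREBBP", "TP53", "PTPN11", "NF1", "ARID1A",
    "UBR7", "PRPS2", "CDKN1B", "CTNNB1", "APC", "NFE2", "POU2F2",
)

_REGION_P = {"coding": 0.05, "conserved_or_regulatory": 0.08,
             "nonrepeat": 0.72, "repeat": 0.15}
_CODING_CSQ = ("nonsynonymous", "synonymous", "splice_site", "noncoding_rna")


def annotate_variants(
    variants: list[SimulatedVariant], seed: int
) -> list[SimulatedVariant]:
    """Attach annotation columns (region class, consequence, gene, scores).

    Region classes are drawn independently of clone and context, so spectra
    restricted to non-repeat regions stay unbiased estimates of the
    generating mixture.  A small fraction of variants gets population or
    germline evidence to exercise the unpaired-sample cascade; those values
    travel in the ``PAF``/``GVAF`` annotations, not on the Variant itself.
    """
    rng = np.random.default_rng(seed)
    regions = list(_REGION_P)
    probs = np.array([_REGION_P[r] for r in regions])
    annotated = []
    for sv in variants:
        if sv.variant.vclass != VariantClass.SNV.value:
            annotated.append(sv)
            continue
        region = regions[rng.choice(len(regions), p=probs)]
        if region == "coding":
            csq = _CODING_CSQ[rng.integers(len(_CODING_CSQ))]
            gene = _GENE_POOL[rng.integers(len(_GENE_POOL))]
            cons = int(rng.integers(0, 500))
        elif region == "conserved_or_regulatory":
            csq = "intergenic"
            gene = None
            cons = int(rng.integers(500, 900))
        else:
            csq = "intergenic"
            gene = None
            cons = int(rng.integers(0, 500))
        annotated.append(
            replace(
                sv,
                variant=replace(
                    sv.variant,
                    gene=gene,
                    consequence=csq,
                    conservation_score=cons,
                    region_class=region,
                ),
            )
        )
    return annotated


def sample_annotation_evidence(
    variants: list[SimulatedVariant], seed: int
) -> pd.DataFrame:
    """Population AF / germline VAF evidence table for the filter cascade."""
    rng = np.random.default_rng(seed)
    rows = []
    for sv in variants:
        u = rng.random()
        pop_af = 0.0
        germ = 0.0
        if u < 0.01:
            pop_af = float(rng.uniform(0.011, 0.2))
        elif u < 0.02:
            germ = float(rng.uniform(0.21, 0.5))
        rows.append({"variant_id": sv.id, "population_af": pop_af,
                     "germline_vaf": germ})
    return pd.DataFrame(rows)


@dataclass
class VariantReadout:
    """One variant's read counts at one timepoint."""

    variant_id: str
    day: int
    observation: Observation
    expected_vaf: float
    uninformative: bool = False


def sample_reads(
    variants: list[SimulatedVariant],
    tree: CloneTree,
    timepoint: int,
    depth: float,
    error_rate: float,
    purity: float = 1.0,
    seed: int | tuple = 0,
    dispersion: float | None = None,
    sample: str = "S",
) -> list[VariantReadout]:
    """Binomial read sampling for every variant at one timepoint.

    Per-site depth is Poisson around the mean (negative binomial when
    ``dispersion`` is given).  For a heterozygous diploid variant in clone
    ``c`` the expected VAF is ``purity * fraction(c, t) / 2``; alt reads are
    Binomial(depth, q) with ``q`` the expected VAF adjusted for symmetric
    per-base error, strand counts split binomially, and reads carrying a
    third allele are reported separately (``other_reads``).  Structural
    variants use the same sampling for breakpoint-supporting reads but are
    immune to substitution error.  A site drawn at depth 0 is returned
    flagged uninformative.
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError("purity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for sv in variants:
        frac = tree.nodes[sv.clone].fraction(timepoint)
        expected = purity * frac / 2.0
        if dispersion is None:
            d = int(rng.poisson(depth))
        else:
            p = dispersion / (dispersion + depth)
            d = int(rng.negative_binomial(dispersion, p))
        e = 0.0 if sv.variant.vclass == VariantClass.SV.value else error_rate
        q = expected * (1.0 - 3.0 * e) + (1.0 - expected) * e
        if d == 0:
            obs = Observation(sample=sample, ref_reads=0, alt_reads=0,
                              fwd_alt=0, rev_alt=0)
            out.append(VariantReadout(sv.id, timepoint, obs, expected, True))
            continue
        alt = int(rng.binomial(d, q))
        rest = d - alt
        p_other = (2.0 * e) / (1.0 - q) if e > 0 and rest > 0 else 0.0
        other = int(rng.binomial(rest, min(p_other, 1.0))) if p_other > 0 else 0
        fwd = int(rng.binomial(alt, 0.5))
        obs = Observation(
            sample=sample,
            ref_reads=d - alt - other,
            alt_reads=alt,
            fwd_alt=fwd,
            rev_alt=alt - fwd,
            other_reads=other,
        )
        out.append(VariantReadout(sv.id, timepoint, obs, expected, False))
    return out


def true_seeding_pattern(tree: CloneTree) -> tuple[str, bool]:
    """Seeding label implied by the truth trajectories.

    Mirrors the classifier's definition on true clone fractions: relapse
    clones are non-truncal clones clonally present at relapse (VAF scale
    > PRESENCE_VAF); the pattern depends on how many of them were above the
    panel detection limit at diagnosis.  Branching is the loss at relapse of
    a clone present at diagnosis.
    """
    days = tree.days
    diag, rel = days[0], days[-1]
    non_root = tree.non_root()
    relapse_clones = [n for n in non_root if n.fraction(rel) / 2 > PRESENCE_VAF]
    if not relapse_clones:
        return "none", False
    detected = [
        n for n in relapse_clones if n.fraction(diag) / 2 >= DETECTION_LIMIT_VAF
    ]
    if len(detected) >= 2:
        value = "multiple_clones"
    elif len(detected) == 1:
        value = "sweep_detected"
    else:
        value = "sweep_not_detected"
    branching = any(
        n.fraction(diag) / 2 >= PRESENCE_VAF and n.fraction(rel) / 2 < DETECTION_LIMIT_VAF
        for n in non_root
    )
    return value, branching


@dataclass
class TruthSet:
    """Ground truth emitted alongside a synthetic patient."""

    patient: str
    scenario: str
    seed: int
    days: tuple[int, ...]
    relapse_day: int | None
    clones: list[dict]
    variant_clone: dict[str, str]
    variant_signature: dict[str, str | None]
    seeding_pattern: str
    branching: bool
    panel: dict
    detection: dict

    def to_json(self) -> str:
        payload = {
            "patient": self.patient,
            "scenario": self.scenario,
            "seed": self.seed,
            "days": list(self.days),
            "relapse_day": self.relapse_day,
            "clones": self.clones,
            "variant_clone": self.variant_clone,
            "variant_signature": self.variant_signature,
            "seeding_pattern": self.seeding_pattern,
            "branching": self.branching,
            "panel": self.panel,
            "detection": self.detection,
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    @staticmethod
    def from_json(text: str) -> "TruthSet":
        d = json.loads(text)
        return TruthSet(
            patient=d["patient"],
            scenario=d["scenario"],
            seed=d["seed"],
            days=tuple(d["days"]),
            relapse_day=d["relapse_day"],
            clones=d["clones"],
            variant_clone=d["variant_clone"],
            variant_signature=d["variant_signature"],
            seeding_pattern=d["seeding_pattern"],
            branching=d["branching"],
            panel=d["panel"],
            detection=d["detection"],
        )


@dataclass
class CohortBundle:
    patient: str
    paths: dict[str, Path]
    truth: TruthSet
    tree: CloneTree
    variants: list[SimulatedVariant]


def _select_panel(
    variants: list[SimulatedVariant],
    tree: CloneTree,
    fusion: SimulatedVariant,
    per_clone: int = 8,
) -> dict:
    """Patient-specific tracked panel: top variants of the major diagnostic
    clone and of the relapse clone, plus the fusion marker."""
    days = tree.days
    diag, rel = days[0], days[-1]
    non_root = tree.non_root()
    major = max(non_root, key=lambda n: (n.fraction(diag), n.id))
    relapse = max(non_root, key=lambda n: (n.fraction(rel), n.id))
    by_clone: dict[str, list[str]] = {}
    for sv in variants:
        by_clone.setdefault(sv.clone, []).append(sv.id)
    major_ids = by_clone.get(major.id, [])[:per_clone]
    relapse_ids = by_clone.get(relapse.id, [])[:per_clone]
    tracked = sorted(set(major_ids) | set(relapse_ids)) + [fusion.id]
    return {
        "variants": tracked,
        "fusion_id": fusion.id,
        "major_diag_clone": major_ids,
        "relapse_clone": relapse_ids,
        "major_diag_clone_id": major.id,
        "relapse_clone_id": relapse.id,
    }


def emit_cohort(
    spec: ScenarioSpec,
    outdir: str | Path,
    patient: str = "SIM01",
    reference: ReferenceGenome | None = None,
    index: ContextLocusIndex | None = None,
    catalog: SignatureCatalog | None = None,
    write_reference: bool = True,
) -> CohortBundle:
    """Write one synthetic patient's file bundle and return its truth.

    Emits a VCF (v4.2, minimal INFO), an observation TSV with per-timepoint
    read counts, a BED-like copy-number file, a metadata TSV, and a truth
    JSON.  Re-running with the same spec and seed is byte-identical.
    """
    from . import io as rio  # local import to keep module load light

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if reference is None:
        reference = synthesize_reference(seed=REFERENCE_SEED)
    if catalog is None:
        catalog = bundled_catalog()
    tree = simulate_clone_tree(spec)
    variants = simulate_mutations(tree, catalog, reference, spec.seed, index=index)
    variants = annotate_variants(variants, seed=(spec.seed, 1))
    fusion = make_fusion_marker(reference)
    evidence = sample_annotation_evidence(variants, seed=(spec.seed, 2))
    panel = _select_panel(variants, tree, fusion)
    all_variants = variants + [fusion]
    days = tree.days
    diag, rel = days[0], days[-1]
    tracked = set(panel["variants"])

    rows = []
    for di, day in enumerate(days):
        panel_vars = [sv for sv in all_variants if sv.id in tracked]
        readouts = sample_reads(
            panel_vars, tree, day, spec.panel_depth, spec.error_rate,
            purity=spec.purity, seed=(spec.seed, 3, di, 0),
            dispersion=spec.depth_dispersion,
            sample=f"{patient}_d{day}_panel",
        )
        rows.extend(_readout_rows(patient, day, "panel", panel_vars, readouts))
        if day in (diag, rel):
            readouts = sample_reads(
                all_variants, tree, day, spec.wgs_depth, spec.error_rate,
                purity=spec.purity, seed=(spec.seed, 3, di, 1),
                dispersion=spec.depth_dispersion,
                sample=f"{patient}_d{day}_wgs",
            )
            rows.extend(_readout_rows(patient, day, "wgs", all_variants, readouts))
    obs = pd.DataFrame(rows)

    seeding, branching = true_seeding_pattern(tree)
    truth = TruthSet(
        patient=patient,
        scenario=spec.scenario,
        seed=spec.seed,
        days=days,
        relapse_day=relapse_day(spec),
        clones=[
            {
                "id": n.id,
                "parent": n.parent,
                "private_mutation_count": n.private_mutation_count,
                "signature_exposures": n.signature_exposures,
                "fraction_by_timepoint": {str(d): n.fraction(d) for d in days},
            }
            for n in sorted(tree.nodes.values(), key=lambda n: n.id)
        ],
        variant_clone={sv.id: sv.clone for sv in all_variants},
        variant_signature={sv.id: sv.signature for sv in all_variants},
        seeding_pattern=seeding,
        branching=branching,
        panel=panel,
        detection={
            "panel_depth": spec.panel_depth,
            "wgs_depth": spec.wgs_depth,
            "error_rate": spec.error_rate,
            "detection_limit": DETECTION_LIMIT_VAF,
        },
    )

    paths = {
        "vcf": outdir / f"{patient}.vcf",
        "observations": outdir / f"{patient}.observations.tsv",
        "cn": outdir / f"{patient}.cn.bed",
        "meta": outdir / f"{patient}.meta.tsv",
        "truth": outdir / f"{patient}.truth.json",
        "reference": outdir / "reference.fa",
    }
    rio.write_vcf(all_variants, evidence, paths["vcf"], reference)
    obs.to_csv(paths["observations"], sep="\t", index=False)
    rio.write_cn_bed(
        [
            {"chrom": reference.name, "start": 0, "end": len(reference),
             "total_cn": 2, "minor_cn": 1}
        ],
        paths["cn"],
    )
    meta = pd.DataFrame(
        [
            {
                "patient": patient,
                "scenario": spec.scenario,
                "day": day,
                "sample": f"{patient}_d{day}_panel",
                "tissue": "BM",
                "relapse_day": relapse_day(spec) if relapse_day(spec) is not None else "",
                "remission": spec.remission,
            }
            for day in days
        ]
    )
    meta.to_csv(paths["meta"], sep="\t", index=False)
    paths["truth"].write_text(truth.to_json())
    if write_reference:
        write_fasta(reference, paths["reference"])
    return CohortBundle(
        patient=patient, paths=paths, truth=truth, tree=tree, variants=all_variants
    )


def _readout_rows(patient, day, platform, variants, readouts):
    rows = []
    for sv, ro in zip(variants, readouts):
        o = ro.observation
        rows.append(
            {
                "patient": patient,
                "sample": o.sample,
                "day": day,
                "tissue": "BM",
                "chrom": sv.variant.chrom,
                "pos": sv.variant.pos,
                "ref": sv.variant.ref,
                "alt": sv.variant.alt,
                "ref_reads": o.ref_reads,
                "alt_reads": o.alt_reads,
                "fwd_alt": o.fwd_alt,
                "rev_alt": o.rev_alt,
                "other_reads": o.other_reads,
                "platform": platform,
                "variant_id": sv.id,
            }
        )
    return rows


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
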