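"""End-to-end orchestration: simulate -> filter -> signatures -> clones -> mrd.

The pipeline runs each stage per patient, writes per-patient JSON/TSV
outputs plus a cohort summary (seeding-pattern counts, primary-signature
table, MRD timelines), and logs one entry per stage per patient.  All
thresholds live in :class:`RunConfig`, which round-trips losslessly through
YAML.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .catalog import SignatureCatalog, bundled_catalog
from .clonal_evolution import (
    classify_seeding,
    cluster_vafs,
    track_trajectories,
    trajectory_table,
)
from .mrd_tracking import PanelSpec, mrd_timeline
from .reference import ContextLocusIndex, ReferenceGenome, synthesize_reference
from .signature_analysis import (
    build_spectrum,
    classify_etiology,
    compare_profiles,
    motif_signature_map,
    primary_signature,
    refit_exposures,
    average_vaf_per_signature,
)
from .synthetic_cohort import (
    REFERENCE_SEED,
    SCENARIOS,
    ScenarioSpec,
    emit_cohort,
)
from .variant_filters import Observation, apply_filters

logger = logging.getLogger("relapse_trace")


@dataclass
class RunConfig:
    """All pipeline thresholds and scenario parameters in one place."""

    outdir: str = "relapse_trace_run"
    seed: int = 0
    n_patients_per_scenario: int = 2
    scenarios: list[str] = field(default_factory=lambda: list(SCENARIOS))
    min_depth: int = 10
    pop_af_max: float = 0.01
    germline_vaf_max: float = 0.2
    detection_limit: float = 0.002
    subclonal_vaf: float = 0.3
    presence_threshold: float = 0.05
    panel_depth: float = 3250.0
    wgs_depth: float = 43.0
    error_rate: float = 1e-4
    max_k: int = 6
    em_restarts: int = 10
    mutation_scale: float = 1.0

    def validate(self) -> None:
        checks = [
            (0 < self.detection_limit < 1, "detection_limit must be in (0, 1)"),
            (0 < self.subclonal_vaf <= 1, "subclonal_vaf must be in (0, 1]"),
            (0 <= self.pop_af_max <= 1, "pop_af_max must be in [0, 1]"),
            (0 <= self.germline_vaf_max <= 1, "germline_vaf_max must be in [0, 1]"),
            (self.min_depth >= 0, "min_depth must be non-negative"),
            (self.panel_depth > 0 and self.wgs_depth > 0, "depths must be > 0"),
            (0 <= self.error_rate < 0.01, "error_rate must be in [0, 0.01)"),
            (self.n_patients_per_scenario >= 1, "need >= 1 patient per scenario"),
            (self.max_k >= 1, "max_k must be >= 1"),
            (all(s in SCENARIOS for s in self.scenarios),
             f"scenarios must be among {SCENARIOS}"),
        ]
        for ok, message in checks:
            if not ok:
                raise ValueError(f"invalid configuration: {message}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in fields(RunConfig)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return RunConfig(**data)


def flag_subclonal(obs: Observation, cutoff: float = 0.3) -> bool:
    """True iff the observation's VAF is strictly below the subclonal cutoff."""
    if obs.depth <= 0:
        raise ValueError("cannot flag subclonality at zero depth")
    return obs.vaf < cutoff


def mutation_status(
    diag_vaf: float | None,
    relapse_vaf: float | None,
    deep_diag_vaf: float | None = None,
    detection_limit: float = 0.002,
) -> str:
    """Shared/gained/lost status of a mutation between diagnosis and relapse.

    Computed after the depth gate: shared when present in both samples,
    gained when relapse-only, lost when diagnosis-only.  A variant gained by
    discovery sequencing but re-detected at diagnosis by the deep panel is
    reclassified shared (status ``shared_by_deep``).
    """
    present_d = diag_vaf is not None and diag_vaf > 0
    present_r = relapse_vaf is not None and relapse_vaf > 0
    if present_d and present_r:
        return "shared"
    if present_r:
        if deep_diag_vaf is not None and deep_diag_vaf >= detection_limit:
            return "shared_by_deep"
        return "gained"
    if present_d:
        return "lost"
    return "absent"


def _schema(name: str) -> dict:
    with resources.as_file(resources.files("relapsetrace.schemas") / name) as p:
        return json.loads(Path(p).read_text())


def validate_schema(obj, schema, path="$") -> list[str]:
    """Minimal structural validation (type, required, properties, enum)."""
    errors: list[str] = []
    t = schema.get("type")
    typemap = {
        "object": dict, "array": list, "string": str, "boolean": bool,
        "number": (int, float), "integer": int, "null": type(None),
    }
    if t is not None:
        expected = typemap[t] if isinstance(t, str) else tuple(typemap[x] for x in t)
        if t == "number" and isinstance(obj, bool):
            errors.append(f"{path}: bool is not a number")
        elif not isinstance(obj, expected):
            errors.append(f"{path}: expected {t}, got {type(obj).__name__}")
            return errors
    if "enum" in schema and obj not in schema["enum"]:
        errors.append(f"{path}: {obj!r} not in {schema['enum']}")
    if isinstance(obj, dict):
        for key in schema.get("required", []):
            if key not in obj:
                errors.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                errors.extend(validate_schema(obj[key], sub, f"{path}.{key}"))
    if isinstance(obj, list) and "items" in schema:
        for i, item in enumerate(obj):
            errors.extend(validate_schema(item, schema["items"], f"{path}[{i}]"))
    return errors


@dataclass
class PatientReport:
    patient: str
    scenario: str
    stages_completed: list[str]
    report: dict
    error: str | None = None


@dataclass
class ReportBundle:
    outdir: Path
    summary: dict
    patients: list[PatientReport]
    failed: int = 0


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute every stage for a synthetic cohort and write the report bundle.

    Any stage failure is logged with the stage name and the patient's partial
    outputs are preserved; the bundle records the number of failed patients.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = synthesize_reference(seed=REFERENCE_SEED)
    index = ContextLocusIndex(reference)
    catalog = bundled_catalog()

    patients: list[PatientReport] = []
    pid_counter = 0
    for scenario in config.scenarios:
        for rep in range(config.n_patients_per_scenario):
            pid_counter += 1
            patient = f"SIM{pid_counter:02d}"
            seed = (config.seed * 1009 + pid_counter * 7919) % (2**31)
            spec = ScenarioSpec(
                scenario=scenario,
                seed=seed,
                panel_depth=config.panel_depth,
                wgs_depth=config.wgs_depth,
                error_rate=config.error_rate,
                mutation_scale=config.mutation_scale,
            )
            patients.append(
                _run_patient(patient, spec, config, outdir, reference, index, catalog)
            )

    seeding_counts: dict[str, int] = {}
    primary_rows = []
    mrd_rows = []
    for p in patients:
        if p.error is None:
            seeding = p.report["clones"]["seeding_pattern"]
            seeding_counts[seeding] = seeding_counts.get(seeding, 0) + 1
            primary_rows.append(
                {
                    "patient": p.patient,
                    "scenario": p.scenario,
                    "primary_signature": p.report["signatures"]["primary"],
                    "primary_known_signature": p.report["signatures"]["primary_known"],
                    **{
                        f"frac_{k}": v
                        for k, v in p.report["signatures"]["class_sums"].items()
                    },
                }
            )
            for call in p.report["mrd"]["calls"]:
                mrd_rows.append({"patient": p.patient, **call})
    summary = {
        "n_patients": len(patients),
        "n_failed": sum(1 for p in patients if p.error is not None),
        "seeding_pattern_counts": seeding_counts,
        "patients": [
            {
                "patient": p.patient,
                "scenario": p.scenario,
                "error": p.error,
                "stages_completed": p.stages_completed,
            }
            for p in patients
        ],
    }
    errors = validate_schema(summary, _schema("cohort_summary.schema.json"))
    if errors:
        raise AssertionError(f"cohort summary fails its schema: {errors[:3]}")
    (outdir / "cohort_summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=1)
    )
    pd.DataFrame(primary_rows).to_csv(
        outdir / "primary_signatures.tsv", sep="\t", index=False
    )
    pd.DataFrame(mrd_rows).to_csv(outdir / "mrd_timelines.tsv", sep="\t", index=False)
    return ReportBundle(
        outdir=outdir, summary=summary, patients=patients,
        failed=summary["n_failed"],
    )


def _run_patient(
    patient: str,
    spec: ScenarioSpec,
    config: RunConfig,
    outdir: Path,
    reference: ReferenceGenome,
    index: ContextLocusIndex,
    catalog: SignatureCatalog,
) -> PatientReport:
    pdir = outdir / patient
    report: dict = {}
    stages: list[str] = []
    try:
        stage = "simulate"
        logger.info("%s: stage %s", patient, stage)
        bundle = emit_cohort(
            spec, pdir, patient=patient, reference=reference, index=index,
            catalog=catalog, write_reference=False,
        )
        stages.append(stage)

        stage = "filter"
        logger.info("%s: stage %s", patient, stage)
        variants_ev = rio.read_vcf(bundle.paths["vcf"])
        obs_df = rio.read_observations(bundle.paths["observations"])
        kept, dropped = _filter_stage(variants_ev, obs_df, config)
        report["filter"] = {
            "n_input": len(variants_ev),
            "n_kept": len(kept),
            "n_dropped": len(dropped),
        }
        stages.append(stage)

        stage = "signatures"
        logger.info("%s: stage %s", patient, stage)
        report["signatures"] = _signature_stage(
            kept, obs_df, bundle, reference, catalog, config
        )
        stages.append(stage)

        stage = "clones"
        logger.info("%s: stage %s", patient, stage)
        clones_report, clusters = _clone_stage(kept, obs_df, bundle, config, pdir)
        report["clones"] = clones_report
        stages.append(stage)

        stage = "mrd"
        logger.info("%s: stage %s", patient, stage)
        report["mrd"] = _mrd_stage(kept, obs_df, bundle, clusters, config)
        stages.append(stage)

        stage = "report"
        logger.info("%s: stage %s", patient, stage)
        payload = {"patient": patient, "scenario": spec.scenario, **report}
        errors = validate_schema(payload, _schema("patient_report.schema.json"))
        if errors:
            raise AssertionError(f"patient report fails its schema: {errors[:3]}")
        (pdir / f"{patient}.report.json").write_text(
            json.dumps(payload, sort_keys=True, indent=1)
        )
        stages.append(stage)
        return PatientReport(
            patient=patient, scenario=spec.scenario,
            stages_completed=stages, report=report,
        )
    except Exception as exc:  # noqa: BLE001 - stage failures are reported
        logger.error("%s: stage %s failed: %s", patient, stage, exc)
        return PatientReport(
            patient=patient, scenario=spec.scenario, stages_completed=stages,
            report=report, error=f"{stage}: {exc}",
        )


def _obs_lookup(obs_df: pd.DataFrame) -> dict[tuple[str, int], Observation]:
    """(variant_id, day) -> highest-coverage Observation."""
    best: dict[tuple[str, int], Observation] = {}
    for row in obs_df.itertuples(index=False):
        o = Observation(
            sample=row.sample, ref_reads=int(row.ref_reads),
            alt_reads=int(row.alt_reads), fwd_alt=int(row.fwd_alt),
            rev_alt=int(row.rev_alt), other_reads=int(row.other_reads),
        )
        key = (row.variant_id, int(row.day))
        if key not in best or o.depth > best[key].depth:
            best[key] = o
    return best


def _filter_stage(variants_ev, obs_df, config):
    days = sorted(obs_df["day"].unique())
    relapse_day = days[-1]
    lookup = _obs_lookup(obs_df)
    records = []
    for v, paf, gvaf in variants_ev:
        o = lookup.get((v.id, relapse_day))
        if o is None or o.depth == 0:
            continue
        records.append((v, o, gvaf, paf))
    return apply_filters(
        records,
        min_depth=config.min_depth,
        pop_af_max=config.pop_af_max,
        germline_vaf_max=config.germline_vaf_max,
    )


def _gated_vafs(lookup, variant_ids, day, min_depth):
    out = {}
    for vid in variant_ids:
        o = lookup.get((vid, day))
        if o is None or o.depth < min_depth:
            out[vid] = None
        else:
            out[vid] = o.vaf
    return out


def _signature_stage(kept, obs_df, bundle, reference, catalog, config):
    days = sorted(obs_df["day"].unique())
    diag_day, relapse_day = days[0], days[-1]
    lookup = _obs_lookup(obs_df)
    snvs = {fv.variant.id: fv.variant for fv in kept if fv.variant.is_snv}
    diag_vafs = _gated_vafs(lookup, snvs, diag_day, config.min_depth)
    relapse_vafs = _gated_vafs(lookup, snvs, relapse_day, config.min_depth)

    diag_present = [
        snvs[vid] for vid, v in diag_vafs.items() if v is not None and v > 0
    ]
    relapse_specific = [
        snvs[vid]
        for vid, v in relapse_vafs.items()
        if v is not None and v > 0 and diag_vafs.get(vid) == 0
    ]
    spec_diag = build_spectrum(diag_present, reference)
    spec_rel = build_spectrum(relapse_specific, reference)

    relapse_present = [
        snvs[vid] for vid, v in relapse_vafs.items() if v is not None and v > 0
    ]
    spec_sample = build_spectrum(relapse_present, reference)
    profile = refit_exposures(spec_sample, catalog)
    class_sums = classify_etiology(profile, catalog)
    call = primary_signature(class_sums) if class_sums else None
    motif_map = motif_signature_map(catalog)
    from .contexts import classify_substitution

    mutations = []
    for v in relapse_present:
        ctx = classify_substitution(reference.trinucleotide(v.pos), v.alt)
        mutations.append((ctx, relapse_vafs[v.id]))
    avg_vaf = average_vaf_per_signature(mutations, motif_map)
    r2 = compare_profiles(spec_diag, spec_rel)
    return {
        "n_diagnostic_snvs": spec_diag.n,
        "n_relapse_specific_snvs": spec_rel.n,
        "exposures": profile.contributions,
        "residual": profile.residual,
        "class_sums": class_sums,
        "primary": call.primary if call else None,
        "primary_known": call.primary_known if call else None,
        "primary_tie": call.tie if call else False,
        "average_vaf_per_signature": avg_vaf,
        "diag_vs_relapse_specific_r2": None if np.isnan(r2) else r2,
    }


def _clone_stage(kept, obs_df, bundle, config, pdir: Path):
    days = sorted(int(d) for d in obs_df["day"].unique())
    diag_day, relapse_day = days[0], days[-1]
    lookup = _obs_lookup(obs_df)
    pairs = []
    for fv in kept:
        if not fv.variant.is_snv:
            continue
        od = lookup.get((fv.variant.id, diag_day))
        orl = lookup.get((fv.variant.id, relapse_day))
        if od is None or orl is None:
            continue
        if od.depth < config.min_depth or orl.depth < config.min_depth:
            continue
        pairs.append((fv.variant.id, od, orl))
    clusters = cluster_vafs(
        pairs,
        min_depth=config.min_depth,
        max_k=config.max_k,
        seed=bundle.truth.seed,
        restarts=config.em_restarts,
        detection_limit=config.detection_limit,
    )
    seeding = classify_seeding(
        clusters,
        detection_limit=config.detection_limit,
        presence_threshold=config.presence_threshold,
    )
    serial_vafs = {
        vid: _per_day_vafs(lookup, vid, days, config.min_depth)
        for vid in {m for c in clusters for m in c.members}
    }
    trajectories = track_trajectories(serial_vafs, clusters)
    trajectory_table(trajectories).to_csv(
        pdir / "clone_trajectories.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "cluster": c.id,
                "n_members": len(c.members),
                "centroid_diag": c.centroid_diag,
                "centroid_relapse": c.centroid_relapse,
                "detected_at_diagnosis": c.detected_at_diagnosis,
            }
            for c in clusters
        ]
    ).to_csv(pdir / "clusters.tsv", sep="\t", index=False)
    return (
        {
            "n_clusters": len(clusters),
            "seeding_pattern": seeding.value,
            "branching": seeding.branching,
            "centroids": [
                [c.centroid_diag, c.centroid_relapse] for c in clusters
            ],
        },
        clusters,
    )


def _per_day_vafs(lookup, vid, days, min_depth):
    out = {}
    for d in days:
        o = lookup.get((vid, d))
        out[d] = o.vaf if o is not None and o.depth >= min_depth else None
    return out


def _mrd_stage(kept, obs_df, bundle, clusters, config):
    days = sorted(int(d) for d in obs_df["day"].unique())
    lookup = _obs_lookup(obs_df)
    fusion_id = bundle.truth.panel["fusion_id"]
    # the tracked panel: variants with coverage at every timepoint
    tracked = [
        vid
        for vid in obs_df["variant_id"].unique()
        if all((vid, d) in lookup for d in days)
    ]
    snv_tracked = [v for v in tracked if v != fusion_id]
    member_cluster = {m: c for c in clusters for m in c.members}
    major = max(clusters, key=lambda c: c.centroid_diag, default=None)
    relapse = max(clusters, key=lambda c: c.centroid_relapse, default=None)
    major_set = frozenset(
        v for v in snv_tracked
        if major is not None and member_cluster.get(v) is major
    )
    relapse_set = frozenset(
        v for v in snv_tracked
        if relapse is not None and member_cluster.get(v) is relapse
    )
    panel = PanelSpec(
        variants=tuple(sorted(snv_tracked) + [fusion_id]),
        fusion_id=fusion_id,
        major_diag_clone=major_set,
        relapse_clone=relapse_set,
        detection_limit=config.detection_limit,
    )
    serial = {
        d: {
            vid: lookup[(vid, d)]
            for vid in panel.variants
            if (vid, d) in lookup
        }
        for d in days
    }
    timeline = mrd_timeline(
        panel, serial, relapse_day=bundle.truth.relapse_day, min_day=days[0]
    )
    return {
        "calls": [
            {
                "day": c.day,
                "status": c.status,
                "gate": c.gate,
                "burden_vaf": c.burden_vaf,
            }
            for c in timeline.calls
        ],
        "lead_time_days": timeline.lead_time_days,
        "first_detection_day": timeline.first_detection_day,
    }
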