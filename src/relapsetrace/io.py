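"""Readers and writers for the pipeline's file formats.

Coordinate conventions are centralized here: VCF positions are 1-based,
copy-number BED-like segments 0-based half-open.  The observation table is
a TSV with columns (patient, sample, day, tissue, chrom, pos, ref, alt,
ref_reads, alt_reads, fwd_alt, rev_alt) plus the extra columns other_reads,
platform and variant_id.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .variant_filters import CopyNumberSegment, Observation, Variant, VariantClass

OBS_COLUMNS = [
    "patient", "sample", "day", "tissue", "chrom", "pos", "ref", "alt",
    "ref_reads", "alt_reads", "fwd_alt", "rev_alt",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=relapse-trace
##INFO=<ID=VC,Number=1,Type=String,Description="Variant class">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">
##INFO=<ID=REGION,Number=1,Type=String,Description="Region class">
##INFO=<ID=CONS,Number=1,Type=Integer,Description="Conservation score">
##INFO=<ID=PAF,Number=1,Type=Float,Description="Population allele frequency">
##INFO=<ID=GVAF,Number=1,Type=Float,Description="Germline VAF">
"""


def write_vcf(simulated_variants, evidence: pd.DataFrame | None, path, reference) -> None:
    """Write variants as minimal VCF v4.2 (annotations in INFO)."""
    ev = {}
    if evidence is not None:
        ev = {
            r["variant_id"]: (r["population_af"], r["germline_vaf"])
            for _, r in evidence.iterrows()
        }
    lines = [_VCF_HEADER]
    lines.append(f"##contig=<ID={reference.name},length={len(reference)}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for sv in sorted(simulated_variants, key=lambda s: (s.variant.chrom, s.variant.pos)):
        v = sv.variant
        info = [f"VC={v.vclass}"]
        if v.gene:
            info.append(f"GENE={v.gene}")
        if v.consequence:
            info.append(f"CSQ={v.consequence}")
        if v.region_class:
            info.append(f"REGION={v.region_class}")
        if v.conservation_score is not None:
            info.append(f"CONS={v.conservation_score}")
        if sv.id in ev:
            paf, gvaf = ev[sv.id]
            info.append(f"PAF={paf:.6g}")
            info.append(f"GVAF={gvaf:.6g}")
        alt = v.alt if v.vclass != VariantClass.SV.value else "<FUS>"
        lines.append(
            f"{v.chrom}\t{v.pos}\t{sv.id}\t{v.ref}\t{alt}\t.\tPASS\t"
            + ";".join(info) + "\n"
        )
    Path(path).write_text("".join(lines))


def read_vcf(path) -> list[tuple[Variant, float | None, float | None]]:
    """Read a VCF into (Variant, population_af, germline_vaf) tuples."""
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        alt = rec.ALT[0] if rec.ALT else "."
        vclass = rec.INFO.get("VC") or (
            VariantClass.SV.value if alt.startswith("<") else VariantClass.SNV.value
        )
        cons = rec.INFO.get("CONS")
        v = Variant(
            chrom=rec.CHROM,
            pos=rec.POS,
            ref=rec.REF,
            alt=alt,
            vclass=vclass,
            gene=rec.INFO.get("GENE"),
            consequence=rec.INFO.get("CSQ"),
            conservation_score=int(cons) if cons is not None else None,
            region_class=rec.INFO.get("REGION"),
        )
        paf = rec.INFO.get("PAF")
        gvaf = rec.INFO.get("GVAF")
        out.append((v, float(paf) if paf is not None else None,
                    float(gvaf) if gvaf is not None else None))
    return out


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: observation table lacks columns {missing}")
    if "other_reads" not in df.columns:
        df["other_reads"] = 0
    if "variant_id" not in df.columns:
        df["variant_id"] = (
            df["chrom"].astype(str) + ":" + df["pos"].astype(str)
            + ":" + df["ref"] + ":" + df["alt"]
        )
    return df


def observation_from_row(row) -> Observation:
    return Observation(
        sample=str(row["sample"]),
        ref_reads=int(row["ref_reads"]),
        alt_reads=int(row["alt_reads"]),
        fwd_alt=int(row["fwd_alt"]),
        rev_alt=int(row["rev_alt"]),
        other_reads=int(row.get("other_reads", 0)),
    )


def write_cn_bed(segments, path) -> None:
    """BED-like copy-number file: chrom, start, end, total_cn, minor_cn."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\ttotal_cn\tminor_cn\n")
        for s in segments:
            if isinstance(s, CopyNumberSegment):
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.total_cn}\t{s.minor_cn}\n")
            else:
                fh.write(
                    f"{s['chrom']}\t{s['start']}\t{s['end']}\t"
                    f"{s['total_cn']}\t{s['minor_cn']}\n"
                )


def read_cn_bed(path) -> list[CopyNumberSegment]:
    segs = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, start, end, total_cn, minor_cn = line.split("\t")[:5]
        segs.append(
            CopyNumberSegment(
                chrom=chrom, start=int(start), end=int(end),
                total_cn=int(total_cn), minor_cn=int(minor_cn),
            )
        )
    return segs


def segment_for(segments: list[CopyNumberSegment], chrom: str, pos: int):
    """First segment containing a 1-based position, else None."""
    for s in segments:
        if s.contains(chrom, pos):
            return s
    return None
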