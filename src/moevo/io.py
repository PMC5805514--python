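"""Readers, writers and the multi-caller consensus merge.

Conventions: VCF positions are 1-based inclusive; segment tables are BED-like
0-based half-open (a ``one_based`` flag at the reader converts); the merged
SNV table is a TSV with one ``af_<sample>`` column per sample, empty meaning
undetected. All coordinate conversions happen at the reader boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .af import SomaticSNV

log = logging.getLogger(__name__)

__all__ = [
    "Sample",
    "CaseBundle",
    "consensus_merge",
    "read_snv_table",
    "write_snv_table",
    "read_vcf",
    "write_vcf",
    "read_cna_segments",
    "write_cna_segments",
]

POLYP_TISSUES = ("villous", "tubular")


@dataclass(frozen=True)
class Sample:
    id: str
    tissue: str  # normal | tubular | villous | cancer


@dataclass
class CaseBundle:
    """One patient case: ordered tissue samples, the SNV set, CNA profiles."""

    case_id: str
    samples: list
    snvs: list
    cna_profiles: dict = field(default_factory=dict)
    cna_segments: dict = field(default_factory=dict)
    provenance: list = field(default_factory=list)
    true_moe: Optional[str] = None

    def __post_init__(self) -> None:
        ids = {s.id for s in self.samples}
        if len(ids) != len(self.samples):
            raise ValueError("duplicate sample ids")
        cancers = [s for s in self.samples if s.tissue == "cancer"]
        if len(cancers) != 1:
            raise ValueError("a case needs exactly one cancer sample")
        referenced = {sid for snv in self.snvs for sid in snv.af_by_sample}
        unknown = referenced - ids
        if unknown:
            raise ValueError(f"SNVs reference unknown samples: {sorted(unknown)}")

    @property
    def cancer_sample_id(self) -> str:
        return next(s.id for s in self.samples if s.tissue == "cancer")

    @property
    def polyp_sample_id(self) -> str:
        """The designated polyp compartment: the most advanced polyp stage
        present (villous before tubular)."""
        for tissue in POLYP_TISSUES:
            for s in self.samples:
                if s.tissue == tissue:
                    return s.id
        raise ValueError(f"case {self.case_id} has no polyp-stage sample")

    @property
    def sample_ids(self) -> list:
        return [s.id for s in self.samples]


def consensus_merge(
    per_caller_variant_sets: Sequence[Iterable[SomaticSNV]],
    min_callers: int = 3,
) -> list:
    """k-of-n consensus over per-caller SNV sets keyed by
    (chrom, pos, ref, alt).

    Keeps keys present in at least ``min_callers`` sets. Allele fractions
    (and annotations) come from the first set listing the key; AF
    discordance above 0.01 between callers is logged.
    """
    sets = [list(s) for s in per_caller_variant_sets]
    if min_callers > len(sets):
        raise ValueError(
            f"min_callers={min_callers} exceeds the {len(sets)} caller sets provided"
        )
    support: dict = {}
    primary: dict = {}
    for caller_idx, snvs in enumerate(sets):
        seen = set()
        for snv in snvs:
            if snv.key in seen:
                continue
            seen.add(snv.key)
            support[snv.key] = support.get(snv.key, 0) + 1
            if snv.key not in primary:
                primary[snv.key] = snv
            else:
                ref = primary[snv.key]
                for sample, af in snv.af_by_sample.items():
                    ref_af = ref.af_by_sample.get(sample)
                    if ref_af is not None and abs(ref_af - af) > 0.01:
                        log.info(
                            "AF discordance at %s (sample %s): primary %.3f vs caller %d %.3f",
                            snv.key, sample, ref_af, caller_idx, af,
                        )
    return [primary[k] for k in primary if support[k] >= min_callers]


def _sample_columns(columns: Iterable[str]) -> list:
    return [c[3:] for c in columns if c.startswith("af_")]


def write_snv_table(snvs: Iterable[SomaticSNV], path, samples: Optional[Sequence[str]] = None) -> None:
    """Write the merged TSV dialect (round-trips with read_snv_table)."""
    snvs = list(snvs)
    if samples is None:
        samples = sorted({sid for s in snvs for sid in s.af_by_sample})
    rows = []
    for s in snvs:
        row = {
            "chrom": s.chrom,
            "pos": s.pos,
            "ref": s.ref,
            "alt": s.alt,
            "context": s.context or "",
            "gene": s.gene or "",
            "is_driver": int(s.is_driver),
        }
        for sid in samples:
            af = s.af_by_sample.get(sid)
            row[f"af_{sid}"] = "" if af is None else repr(af)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_snv_table(path, require_samples: Optional[Sequence[str]] = None) -> list:
    """Read the merged TSV dialect back into SNV objects."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "context": str, "gene": str})
    samples = _sample_columns(df.columns)
    if require_samples:
        missing = [s for s in require_samples if s not in samples]
        if missing:
            raise ValueError(f"missing sample column(s) in {path}: {missing}")
    snvs = []
    for idx, row in df.iterrows():
        try:
            afs = {}
            for sid in samples:
                val = row[f"af_{sid}"]
                if pd.notna(val) and val != "":
                    afs[sid] = float(val)
            context = row.get("context")
            gene = row.get("gene")
            snvs.append(
                SomaticSNV(
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    ref=str(row["ref"]),
                    alt=str(row["alt"]),
                    af_by_sample=afs,
                    context=None if pd.isna(context) or context == "" else str(context),
                    gene=None if pd.isna(gene) or gene == "" else str(gene),
                    is_driver=bool(int(row.get("is_driver", 0) or 0)),
                )
            )
        except (ValueError, KeyError) as exc:
            log.warning("skipping malformed SNV row %d in %s: %s", idx, path, exc)
    return snvs


_VCF_HEADER = """##fileformat=VCFv4.2
##source=moevo
{contigs}##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CTX,Number=1,Type=String,Description="Reference 3-mer context">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AF,Number=1,Type=Float,Description="Allele fraction">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf(snvs: Iterable[SomaticSNV], sample: str, path, depth: int = 100) -> None:
    """Write one sample's detected SNVs as a minimal VCF (AF in FORMAT,
    with consistent AD/DP derived from the nominal depth)."""
    ordered = sorted(
        (s for s in snvs if s.af_by_sample.get(sample) is not None),
        key=lambda s: (s.chrom, s.pos),
    )
    contigs = "".join(
        f"##contig=<ID={c}>\n" for c in sorted({s.chrom for s in ordered})
    )
    lines = [_VCF_HEADER.format(sample=sample, contigs=contigs)]
    for s in ordered:
        af = s.af_by_sample[sample]
        alt_reads = int(round(af * depth))
        info_parts = []
        if s.gene:
            info_parts.append(f"GENE={s.gene}")
        if s.context:
            info_parts.append(f"CTX={s.context}")
        info = ";".join(info_parts) or "."
        lines.append(
            f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t{info}\t"
            f"GT:AF:AD:DP\t0/1:{af:.6f}:{depth - alt_reads},{alt_reads}:{depth}\n"
        )
    Path(path).write_text("".join(lines))


def read_vcf(path, sample: Optional[str] = None) -> list:
    """Read SNVs from a (single-sample) VCF via cyvcf2.

    AF comes from the AF FORMAT field when present, else AD/DP. Positions
    stay 1-based. Multi-allelic records are split by cyvcf2's first ALT.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample is None:
        if len(vcf.samples) != 1:
            raise ValueError(f"{path} has {len(vcf.samples)} samples; specify one")
        sample = vcf.samples[0]
    try:
        sidx = vcf.samples.index(sample)
    except ValueError:
        raise ValueError(f"sample {sample!r} not in {path} (has {vcf.samples})")

    snvs = []
    for var in vcf:
        if not var.ALT or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue
        af = None
        try:
            fmt_af = var.format("AF")
            if fmt_af is not None:
                af = float(fmt_af[sidx][0])
        except KeyError:
            pass
        if af is None or np.isnan(af):
            ad = var.format("AD")
            if ad is not None:
                ref_reads, alt_reads = int(ad[sidx][0]), int(ad[sidx][1])
                total = ref_reads + alt_reads
                af = alt_reads / total if total > 0 else None
        if af is None:
            log.warning("no AF derivable at %s:%s in %s; skipped", var.CHROM, var.POS, path)
            continue
        info = dict(var.INFO)
        snvs.append(
            SomaticSNV(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=var.ALT[0],
                af_by_sample={sample: float(af)},
                context=info.get("CTX"),
                gene=info.get("GENE"),
            )
        )
    return snvs


def merge_sample_snv_sets(per_sample: dict) -> list:
    """Union per-sample SNV lists into multi-sample SNV objects keyed by
    (chrom, pos, ref, alt)."""
    merged: dict = {}
    for sample_id, snvs in per_sample.items():
        for s in snvs:
            af = s.af_by_sample.get(sample_id)
            if af is None:
                continue
            if s.key not in merged:
                merged[s.key] = SomaticSNV(
                    chrom=s.chrom, pos=s.pos, ref=s.ref, alt=s.alt,
                    af_by_sample={sample_id: af},
                    context=s.context, gene=s.gene, is_driver=s.is_driver,
                )
            else:
                merged[s.key].af_by_sample[sample_id] = af
    return list(merged.values())


def write_cna_segments(segments: pd.DataFrame, path) -> None:
    """BED-like TSV: chrom, start, end, tumor_cn, normal_cn (0-based half-open)."""
    segments.to_csv(path, sep="\t", index=False)


def read_cna_segments(path, one_based: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "tumor_cn", "normal_cn"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path} missing columns {sorted(missing)}")
    if one_based:
        df = df.assign(start=df["start"] - 1)
    return df
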