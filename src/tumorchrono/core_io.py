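"""Domain types and readers/writers shared by every pipeline stage.

Internal coordinates are 0-based half-open.  VCF input/output stays 1-based
per the standard; the segment TSV on disk is declared 1-based inclusive and
converted on read/write.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

GROUPS = ("AS_N", "EU_N", "EU_S", "OTHER")
SMOKING = ("never", "smoker", "unknown")
SEXES = ("F", "M")

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SampleProfile:
    """Per-tumor scalars used by NRPCC gating and multiplicity estimation."""

    sample_id: str
    purity: float          # rho in (0, 1]
    ploidy: float          # psi, mean tumor copy number
    mean_depth: float      # d, mean sequencing depth
    age_dx: float          # age at diagnosis, years
    sex: str = "F"
    group: str = "OTHER"
    smoking: str = "unknown"

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must be in (0,1], got {self.purity}")
        if self.ploidy <= 0:
            raise ValueError(f"ploidy must be > 0, got {self.ploidy}")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if self.age_dx < 0:
            raise ValueError("age_dx must be >= 0")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.smoking not in SMOKING:
            raise ValueError(f"smoking must be one of {SMOKING}")


@dataclass(frozen=True)
class Mutation:
    """A somatic variant with tumor read counts and sequence context.

    ``pos`` is 0-based.  ``context`` holds the pyrimidine-strand trinucleotide
    (``A[C>T]G``) for SNVs and a verbatim flanking window for indels written
    as ``<left>[<ref]>/<alt>]<right>`` with up to 10 bp per flank.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_reads: int
    total_reads: int
    context: str = ""
    gene: Optional[str] = None
    is_driver: bool = False
    is_clock: bool = False
    neoantigenic: Optional[bool] = None

    def __post_init__(self) -> None:
        if not (0 <= self.alt_reads <= self.total_reads):
            raise ValueError(
                f"need 0 <= alt_reads <= total_reads, got "
                f"{self.alt_reads}/{self.total_reads}"
            )

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.total_reads

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos + 1}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class CNSegment:
    """Allele-specific copy-number interval (0-based half-open internally)."""

    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int
    clonal_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if self.major_cn < self.minor_cn:
            raise ValueError("major_cn must be >= minor_cn")
        if self.minor_cn < 0:
            raise ValueError("copy numbers must be >= 0")
        if not (0.0 < self.clonal_fraction <= 1.0):
            raise ValueError("clonal_fraction must be in (0,1]")

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    @property
    def length(self) -> int:
        return self.end - self.start


class AttributionTable:
    """Per-mutation signature attribution probabilities.

    Wraps a DataFrame indexed by (sample_id, mutation key) with one column
    per signature; rows must sum to 1 within 1e-6.
    """

    def __init__(self, probs: pd.DataFrame):
        if probs.shape[1] == 0:
            raise ValueError("attribution table needs >= 1 signature column")
        if (probs.values < 0).any():
            raise ValueError("attribution probabilities must be >= 0")
        sums = probs.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = int((~np.isclose(sums, 1.0, atol=1e-6)).sum())
            raise ValueError(f"{bad} rows do not sum to 1 within 1e-6")
        self.probs = probs

    @property
    def signatures(self) -> list[str]:
        return list(self.probs.columns)

    @classmethod
    def read_tsv(cls, path: str) -> "AttributionTable":
        df = pd.read_csv(path, sep="\t", index_col=[0, 1])
        return cls(df)

    def write_tsv(self, path: str) -> None:
        self.probs.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class SampleData:
    """One tumor: profile, mutations, segments and the mutation->segment map."""

    profile: SampleProfile
    mutations: list[Mutation]
    segments: list[CNSegment]
    seg_index: list[Optional[int]] = field(default_factory=list)
    n_rejected: int = 0

    @property
    def unassigned(self) -> list[Mutation]:
        return [m for m, i in zip(self.mutations, self.seg_index) if i is None]


@dataclass
class Cohort:
    samples: dict[str, SampleData]

    def __iter__(self):
        return iter(self.samples.items())

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, sample_id: str) -> SampleData:
        return self.samples[sample_id]


# ---------------------------------------------------------------------------
# Context normalization and clock-mutation flagging


def normalize_snv_context(context: str) -> str:
    """Return the pyrimidine-strand representation of ``X[R>A]Y``.

    Purine-reference contexts (G>A etc.) are reverse-complemented so that the
    substituted base is C or T.
    """
    left, rest = context.split("[")
    change, right = rest.split("]")
    ref, alt = change.split(">")
    if ref in ("C", "T"):
        return context
    return f"{revcomp(right)}[{revcomp(ref)}>{revcomp(alt)}]{revcomp(left)}"


def is_clock_context(context: str) -> bool:
    """True for CpG>TpG substitutions in an NpCpG context (SBS1-like)."""
    try:
        norm = normalize_snv_context(context)
    except ValueError:
        return False
    left, rest = norm.split("[")
    change, right = rest.split("]")
    return change == "C>T" and right.startswith("G") and len(left) >= 1


def flag_clock_mutations(mutations: Sequence[Mutation]) -> list[Mutation]:
    """Set ``is_clock`` on SNVs whose context is C>T at a CpG dinucleotide.

    Indels are never flagged.  Contexts given on the purine strand are
    reverse-complemented before testing.
    """
    out = []
    for m in mutations:
        flag = bool(m.is_snv and m.context and is_clock_context(m.context))
        out.append(replace(m, is_clock=flag) if flag != m.is_clock else m)
    return out


# ---------------------------------------------------------------------------
# Segment assignment


def assign_segments(
    mutations: Sequence[Mutation], segments: Sequence[CNSegment]
) -> list[Optional[int]]:
    """Map each mutation to the index of its overlapping segment (or None).

    Overlapping segments on the same chromosome are resolved toward the
    segment starting first, so the result does not depend on input order.
    """
    trees: dict[str, IntervalTree] = {}
    for i, seg in enumerate(segments):
        trees.setdefault(seg.chrom, IntervalTree()).addi(seg.start, seg.end, i)
    out: list[Optional[int]] = []
    for m in mutations:
        tree = trees.get(m.chrom)
        hits = sorted(tree[m.pos]) if tree is not None else []
        out.append(hits[0].data if hits else None)
    return out


# ---------------------------------------------------------------------------
# Cohort I/O

_SAMPLE_COLS = [
    "sample_id", "purity", "ploidy", "mean_depth",
    "age_dx", "sex", "group", "smoking",
]
_SEGMENT_COLS = [
    "sample_id", "chrom", "start", "end",
    "major_cn", "minor_cn", "clonal_fraction",
]

_CONTIG_LENGTH = 400_000_000  # generous upper bound for header declarations


def _vcf_header(sample_id: str, contigs: Iterable[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for c in contigs:
        header.add_line(f"##contig=<ID={c},length={_CONTIG_LENGTH}>")
    header.add_line('##INFO=<ID=CTX,Number=1,Type=String,Description="Mutation context">')
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    header.add_line('##INFO=<ID=DRV,Number=0,Type=Flag,Description="Driver mutation">')
    header.add_line('##INFO=<ID=NEO,Number=1,Type=Integer,Description="Neoantigenic (0/1)">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">')
    header.add_sample(sample_id)
    return header


def write_sample_vcf(path: str, sample_id: str, mutations: Sequence[Mutation]) -> None:
    contigs = sorted({m.chrom for m in mutations})
    header = _vcf_header(sample_id, contigs)
    muts = sorted(mutations, key=lambda m: (m.chrom, m.pos, m.ref, m.alt))
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for m in muts:
            rec = vcf.new_record(
                contig=m.chrom, start=m.pos, alleles=(m.ref, m.alt)
            )
            if m.context:
                rec.info["CTX"] = m.context
            if m.gene:
                rec.info["GENE"] = m.gene
            if m.is_driver:
                rec.info["DRV"] = True
            if m.neoantigenic is not None:
                rec.info["NEO"] = int(m.neoantigenic)
            rec.samples[sample_id]["AD"] = (m.total_reads - m.alt_reads, m.alt_reads)
            rec.samples[sample_id]["DP"] = m.total_reads
            vcf.write(rec)


def _read_counts(rec: pysam.VariantRecord, sample_id: str) -> tuple[int, int]:
    """Extract (alt_reads, total_reads) from FORMAT/AD or the t_*_count dialect."""
    if sample_id in rec.samples:
        fmt = rec.samples[sample_id]
        ad = fmt.get("AD")
        if ad is not None and ad[0] is not None:
            ref_reads, alt_reads = int(ad[0]), int(ad[1])
            return alt_reads, ref_reads + alt_reads
    info = rec.info
    if "t_alt_count" in info and "t_ref_count" in info:
        alt_reads = int(info["t_alt_count"])
        return alt_reads, alt_reads + int(info["t_ref_count"])
    raise ValueError(f"no read counts for record at {rec.contig}:{rec.pos}")


def read_sample_vcf(path: str, sample_id: Optional[str] = None) -> tuple[str, list[Mutation], int]:
    """Read one tumor VCF; returns (sample_id, kept mutations, n_rejected).

    Records with zero total reads are rejected (counted, not raised).
    """
    n_rejected = 0
    mutations: list[Mutation] = []
    with pysam.VariantFile(path) as vcf:
        vcf_samples = list(vcf.header.samples)
        if sample_id is None:
            sample_id = vcf_samples[0] if vcf_samples else os.path.basename(path).split(".")[0]
        for rec in vcf:
            alt_reads, total = _read_counts(rec, sample_id)
            if total == 0:
                n_rejected += 1
                continue
            info = rec.info
            neo = info.get("NEO")
            mutations.append(
                Mutation(
                    chrom=rec.contig,
                    pos=rec.start,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    alt_reads=alt_reads,
                    total_reads=total,
                    context=info.get("CTX", "") or "",
                    gene=info.get("GENE"),
                    is_driver=bool(info.get("DRV", False)),
                    neoantigenic=None if neo is None else bool(neo),
                )
            )
    if n_rejected:
        warnings.warn(f"{path}: rejected {n_rejected} records with zero depth")
    mutations = flag_clock_mutations(mutations)
    return sample_id, mutations, n_rejected


def read_samples_tsv(path: str) -> dict[str, SampleProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    profiles = {}
    for _, row in df.iterrows():
        if pd.isna(row.get("purity")) or pd.isna(row.get("ploidy")):
            raise ValueError(f"sample {row['sample_id']}: missing purity or ploidy")
        profiles[row["sample_id"]] = SampleProfile(
            sample_id=row["sample_id"],
            purity=float(row["purity"]),
            ploidy=float(row["ploidy"]),
            mean_depth=float(row["mean_depth"]),
            age_dx=float(row["age_dx"]),
            sex=str(row.get("sex", "F")),
            group=str(row.get("group", "OTHER")),
            smoking=str(row.get("smoking", "unknown")),
        )
    return profiles


def read_segments_tsv(path: str) -> dict[str, list[CNSegment]]:
    """Segment TSV is 1-based inclusive on disk; converted to half-open here."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    out: dict[str, list[CNSegment]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["sample_id"], []).append(
            CNSegment(
                chrom=row["chrom"],
                start=int(row["start"]) - 1,
                end=int(row["end"]),
                major_cn=int(row["major_cn"]),
                minor_cn=int(row["minor_cn"]),
                clonal_fraction=float(row.get("clonal_fraction", 1.0)),
            )
        )
    return out


def load_cohort(
    mutation_vcf_paths: Sequence[str],
    segment_tsv_path: str,
    sample_tsv_path: str,
) -> Cohort:
    """Assemble a cohort from per-sample VCFs plus segment and sample TSVs.

    Every mutation is mapped to at most one overlapping segment; unmapped
    mutations stay in the cohort but are excluded from timing downstream.
    Samples lacking purity or ploidy raise; zero-depth records are rejected
    with a warning count.
    """
    profiles = read_samples_tsv(sample_tsv_path)
    segments = read_segments_tsv(segment_tsv_path)
    samples: dict[str, SampleData] = {}
    for path in mutation_vcf_paths:
        sid, muts, n_rej = read_sample_vcf(path)
        if sid not in profiles:
            raise ValueError(f"VCF sample {sid} absent from sample table")
        segs = segments.get(sid, [])
        samples[sid] = SampleData(
            profile=profiles[sid],
            mutations=muts,
            segments=segs,
            seg_index=assign_segments(muts, segs),
            n_rejected=n_rej,
        )
    return Cohort(samples)


def write_cohort(cohort: Cohort, out_dir: str) -> dict[str, str]:
    """Write a cohort back to the VCF/TSV dialects ``load_cohort`` reads."""
    os.makedirs(out_dir, exist_ok=True)
    sample_rows, segment_rows = [], []
    paths: dict[str, str] = {}
    for sid in sorted(cohort.samples):
        data = cohort[sid]
        p = data.profile
        sample_rows.append([sid, p.purity, p.ploidy, p.mean_depth,
                            p.age_dx, p.sex, p.group, p.smoking])
        for seg in data.segments:
            segment_rows.append([sid, seg.chrom, seg.start + 1, seg.end,
                                 seg.major_cn, seg.minor_cn, seg.clonal_fraction])
        vcf_path = os.path.join(out_dir, f"{sid}.vcf")
        write_sample_vcf(vcf_path, sid, data.mutations)
        paths[sid] = vcf_path
    pd.DataFrame(sample_rows, columns=_SAMPLE_COLS).to_csv(
        os.path.join(out_dir, "samples.tsv"), sep="\t", index=False)
    pd.DataFrame(segment_rows, columns=_SEGMENT_COLS).to_csv(
        os.path.join(out_dir, "segments.tsv"), sep="\t", index=False)
    paths["samples"] = os.path.join(out_dir, "samples.tsv")
    paths["segments"] = os.path.join(out_dir, "segments.tsv")
    return paths


def write_results(
    tables: Mapping[str, pd.DataFrame], out_dir: str, float_fmt: str = "%.6g"
) -> dict[str, str]:
    """Write result tables as TSV: header always present, NaN serialized "NA",
    column order as given, floats at fixed precision — reruns are
    byte-identical."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=float_fmt)
        paths[name] = path
    return paths
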