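"""Reading, validation, filtering and matrix construction for somatic variant tables.

The canonical on-disk format is a long-form TSV with one row per
(variant, sample) observation, with header columns::

    sample_id chrom pos ref alt gene aa_change consequence vaf
    alt_reads depth copy_number context

``vaf`` is the raw variant allele frequency in [0, 1] as reported by the
caller; copy number is carried as annotation only and VAFs are never
copy-number-corrected.  Blank cells in the source grids mean "not
detected" and are simply absent from the long form -- they are distinct
from a VAF of 0.

A one-sample-per-file VCF with AF/AD/DP FORMAT fields maps onto the same
in-memory type via :func:`read_vcf`.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import RowParseError, SchemaError

CONSEQUENCES = {"missense", "nonsense", "frameshift", "inframe", "synonymous", "noncoding"}

REQUIRED_COLUMNS = ("sample_id", "chrom", "pos", "ref", "alt", "vaf")
ALL_COLUMNS = (
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "aa_change",
    "consequence", "vaf", "alt_reads", "depth", "copy_number", "context",
)


@dataclass
class VariantCall:
    """One somatic variant observation in one sample."""

    chrom: str
    pos: int                      # 1-based genomic coordinate
    ref_allele: str
    alt_allele: str
    vaf: float
    sample_id: str
    gene: str = ""
    aa_change: str = ""
    consequence: str = "missense"
    alt_reads: Optional[int] = None
    depth: Optional[int] = None
    copy_number: Optional[float] = None
    context: Optional[str] = None  # 3-mer + strand sign, e.g. "CCG+"

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.pos < 1:
            raise ValueError(f"pos {self.pos} must be >= 1")
        if self.consequence and self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.context is not None and self.context != "":
            if len(self.context) != 4 or self.context[3] not in "+-":
                raise ValueError(f"context {self.context!r} must be a 3-mer plus strand sign")
        if self.alt_reads is not None and self.depth:
            if abs(self.vaf - vaf_from_reads(self.alt_reads, self.depth)) > 0.0005:
                raise ValueError(
                    f"vaf {self.vaf} inconsistent with {self.alt_reads}/{self.depth}"
                )

    @property
    def key(self) -> str:
        """Variant identity: chrom:pos:ref:alt.  Gene/aa_change are annotation only."""
        return f"{self.chrom}:{self.pos}:{self.ref_allele}:{self.alt_allele}"

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)


@dataclass
class Sample:
    sample_id: str
    patient_id: str
    specimen: str  # bulk | gliomasphere | attached_2D | germline | colony
    sector: Optional[str] = None
    passage: Optional[int] = None
    collection_day: Optional[int] = None


class SampleSheet:
    """Sample metadata with unique sample ids and at most one germline per patient."""

    def __init__(self, samples: Iterable[Sample]):
        self.samples = list(samples)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise SchemaError("sample_id values must be unique")
        germ: dict[str, int] = {}
        for s in self.samples:
            if s.specimen == "germline":
                germ[s.patient_id] = germ.get(s.patient_id, 0) + 1
        for pid, n in germ.items():
            if n > 1:
                raise SchemaError(f"patient {pid} has {n} germline samples (at most 1 allowed)")
        self._by_id = {s.sample_id: s for s in self.samples}

    def __len__(self) -> int:
        return len(self.samples)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def __getitem__(self, sample_id: str) -> Sample:
        return self._by_id[sample_id]

    @property
    def tumor_sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.specimen != "germline"]

    def sector_of(self, sample_id: str) -> Optional[str]:
        return self._by_id[sample_id].sector

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        missing = {"sample_id", "patient_id", "specimen"} - set(df.columns)
        if missing:
            raise SchemaError(f"sample sheet missing columns: {sorted(missing)}")
        samples = []
        for _, r in df.iterrows():
            samples.append(Sample(
                sample_id=r["sample_id"],
                patient_id=r["patient_id"],
                specimen=r["specimen"],
                sector=r.get("sector") or None,
                passage=int(r["passage"]) if r.get("passage") else None,
                collection_day=int(r["collection_day"]) if r.get("collection_day") else None,
            ))
        return cls(samples)


@dataclass
class VariantMatrix:
    """Variants x samples VAF grid with explicit presence flags.

    ``vaf`` holds NaN where a variant was not observed in a sample;
    ``present`` is True where the VAF is observed and >= the presence
    threshold (inclusive).
    """

    vaf: pd.DataFrame          # index: variant keys, columns: sample ids
    present: pd.DataFrame      # same shape, bool
    presence_threshold: float
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)  # per-variant gene/aa

    @property
    def variants(self) -> list[str]:
        return list(self.vaf.index)

    @property
    def samples(self) -> list[str]:
        return list(self.vaf.columns)

    def carriers(self, variant_key: str) -> frozenset[str]:
        row = self.present.loc[variant_key]
        return frozenset(row.index[row])

    def write_wide_tsv(self, path: str | Path) -> None:
        self.vaf.to_csv(path, sep="\t", index_label="variant")


def vaf_from_reads(alt_reads: int, depth: int) -> float:
    """Variant allele frequency = alt_reads/depth, rounded to 3 decimals.

    Rounds ties away from zero (so 1/2000 -> 0.001), matching how
    sequencing reports print VAFs.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= alt_reads <= depth:
        raise ValueError("alt_reads must lie in [0, depth]")
    return math.floor(alt_reads / depth * 1000 + 0.5) / 1000


def read_variant_table(path: str | Path, dialect: str = "tsv") -> list[VariantCall]:
    """Parse a long-form variant TSV into a list of :class:`VariantCall`.

    Malformed rows are collected and reported with their 1-based line
    numbers in a single :class:`RowParseError`; a missing required column
    raises :class:`SchemaError` immediately.
    """
    delim = {"tsv": "\t", "csv": ","}[dialect]
    calls: list[VariantCall] = []
    row_errors: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        missing = set(REQUIRED_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            if not any((v or "").strip() for v in row.values()):
                continue
            try:
                calls.append(_call_from_row(row))
            except (ValueError, KeyError) as exc:
                row_errors.append((lineno, str(exc)))
    if row_errors:
        raise RowParseError(row_errors)
    return calls


def _call_from_row(row: Mapping[str, str]) -> VariantCall:
    def opt(name, conv):
        v = (row.get(name) or "").strip()
        return conv(v) if v else None

    vaf_text = (row.get("vaf") or "").strip()
    try:
        vaf = float(vaf_text)
    except ValueError:
        raise ValueError(f"non-numeric VAF {vaf_text!r}")
    return VariantCall(
        chrom=str(row["chrom"]).strip(),
        pos=int(row["pos"]),
        ref_allele=row["ref"].strip(),
        alt_allele=row["alt"].strip(),
        vaf=vaf,
        sample_id=row["sample_id"].strip(),
        gene=(row.get("gene") or "").strip(),
        aa_change=(row.get("aa_change") or "").strip(),
        consequence=(row.get("consequence") or "missense").strip(),
        alt_reads=opt("alt_reads", lambda v: int(float(v))),
        depth=opt("depth", lambda v: int(float(v))),
        copy_number=opt("copy_number", float),
        context=opt("context", str),
    )


def write_variant_table(calls: Iterable[VariantCall], path: str | Path) -> None:
    """Write calls back to the long-form TSV (round-trips with :func:`read_variant_table`)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(ALL_COLUMNS)
        for c in calls:
            w.writerow([
                c.sample_id, c.chrom, c.pos, c.ref_allele, c.alt_allele, c.gene,
                c.aa_change, c.consequence, c.vaf,
                "" if c.alt_reads is None else c.alt_reads,
                "" if c.depth is None else c.depth,
                "" if c.copy_number is None else c.copy_number,
                c.context or "",
            ])


def read_vcf(path: str | Path, sample_id: Optional[str] = None) -> list[VariantCall]:
    """Read a one-sample VCF (uncompressed or bgzipped) into VariantCalls.

    VAF is taken from FORMAT/AF when present, otherwise derived from
    AD/DP via :func:`vaf_from_reads`.
    """
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        if len(vcf_samples) != 1:
            raise SchemaError(f"{path}: expected exactly one sample, found {len(vcf_samples)}")
        sid = sample_id or vcf_samples[0]
        for rec in vcf:
            sdata = rec.samples[vcf_samples[0]]
            for i, alt in enumerate(rec.alts or ()):
                depth = sdata.get("DP")
                ad = sdata.get("AD")
                alt_reads = ad[i + 1] if ad is not None and len(ad) > i + 1 else None
                af = sdata.get("AF")
                if af is not None:
                    vaf = af[i] if isinstance(af, (tuple, list)) else af
                elif alt_reads is not None and depth:
                    vaf = vaf_from_reads(alt_reads, depth)
                else:
                    raise SchemaError(f"{path}: record {rec.chrom}:{rec.pos} lacks AF and AD/DP")
                calls.append(VariantCall(
                    chrom=rec.chrom, pos=rec.pos, ref_allele=rec.ref, alt_allele=alt,
                    vaf=round(float(vaf), 3), sample_id=sid,
                    alt_reads=None if alt_reads is None else int(alt_reads),
                    depth=None if depth is None else int(depth),
                ))
    return calls


def filter_somatic(
    calls: Sequence[VariantCall],
    germline_calls: Sequence[VariantCall] = (),
    vaf_min: float = 0.05,
    coding_only: bool = False,
) -> list[VariantCall]:
    """Apply the study's variant filters, preserving input order.

    Removes calls with VAF strictly below ``vaf_min`` (a call at exactly
    the threshold is retained), calls whose chrom:pos:ref:alt matches any
    germline call, and -- when ``coding_only`` -- synonymous and
    noncoding consequences.  Idempotent.
    """
    if not 0.0 <= vaf_min <= 1.0:
        raise ValueError("vaf_min must lie in [0, 1]")
    germline_keys = {g.key for g in germline_calls}
    out = []
    for c in calls:
        if c.vaf < vaf_min:
            continue
        if c.key in germline_keys:
            continue
        if coding_only and c.consequence in ("synonymous", "noncoding"):
            continue
        out.append(c)
    return out


def build_variant_matrix(
    calls: Sequence[VariantCall],
    sample_sheet: SampleSheet,
    presence_threshold: float = 0.05,
) -> VariantMatrix:
    """Pivot calls into a variants x samples VAF grid.

    Columns are the sheet's non-germline samples in sheet order; rows are
    distinct variant keys in first-seen order.  A germline sample in the
    sheet is excluded; a call referencing a sample absent from the sheet
    raises ``KeyError``.
    """
    samples = sample_sheet.tumor_sample_ids
    sample_set = set(samples)
    variant_order: list[str] = []
    ann: dict[str, tuple[str, str]] = {}
    cells: dict[tuple[str, str], float] = {}
    for c in calls:
        if c.sample_id not in sample_sheet:
            raise KeyError(f"sample {c.sample_id!r} not in sample sheet")
        if c.sample_id not in sample_set:  # germline observation, excluded
            continue
        if c.key not in ann:
            variant_order.append(c.key)
            ann[c.key] = (c.gene, c.aa_change)
        cells[(c.key, c.sample_id)] = c.vaf
    vaf = pd.DataFrame(float("nan"), index=variant_order, columns=samples)
    for (vk, sid), v in cells.items():
        vaf.at[vk, sid] = v
    present = vaf.ge(presence_threshold) & vaf.notna()
    annotations = pd.DataFrame(
        [(k, *ann[k]) for k in variant_order],
        columns=["variant", "gene", "aa_change"],
    ).set_index("variant")
    return VariantMatrix(vaf=vaf, present=present,
                         presence_threshold=presence_threshold, annotations=annotations)


def matrix_to_calls(matrix: VariantMatrix) -> list[tuple[str, str, float]]:
    """Flatten a matrix back to (variant_key, sample_id, vaf) triples (observed cells only)."""
    out = []
    for vk in matrix.variants:
        for sid in matrix.samples:
            v = matrix.vaf.at[vk, sid]
            if pd.notna(v):
                out.append((vk, sid, float(v)))
    return out
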