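"""Domain types and file I/O shared by every pipeline stage.

The pipeline compares somatic variation between bulk tumor lesions
(primary tumor, metastasis), matched controls (white blood cells,
adjacent normal tissue) and whole-genome-amplified single circulating
tumor cells (CTCs).  This module holds the in-memory containers for
that multi-sample design and the readers/writers for their on-disk
forms:

==================  =============================================
object              on-disk form
==================  =============================================
SampleManifest      YAML (or 3-column TSV)
AlleleCountTable    TSV (sample_id chrom pos ref alt ref_depth alt_depth)
VariantCallSet      VCF v4.x (biallelic PASS SNVs retained)
CoverageTrack       bedGraph + BED-like GC sidecar TSV
BreakpointRecord    BEDPE (10 columns) + clipped-read evidence TSV
==================  =============================================

Coordinate conventions: point loci are 1-based (VCF convention);
bins and BEDPE intervals are 0-based half-open on disk and converted
losslessly on read/write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

logger = logging.getLogger("ctcwgs")

IUPAC_BASES = set("ACGTRYSWKMBDHVN")

COUNT_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "ref_depth", "alt_depth"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Sample manifest
# ---------------------------------------------------------------------------


class Role(str, Enum):
    """Role a sample plays in the concordance design."""

    WBC_CONTROL = "wbc_control"
    NORMAL_TISSUE = "normal_tissue"
    PRIMARY_TUMOR = "primary_tumor"
    METASTASIS = "metastasis"
    SINGLE_CTC = "single_ctc"


CONTROL_ROLES = (Role.WBC_CONTROL, Role.NORMAL_TISSUE)
TUMOR_ROLES = (Role.PRIMARY_TUMOR, Role.METASTASIS, Role.SINGLE_CTC)


@dataclass(frozen=True)
class Sample:
    sample_id: str
    role: Role
    collection_label: Optional[str] = None


@dataclass
class SampleManifest:
    """Declares each sample's identity and role.

    For the concordance analysis the design requires exactly one primary
    tumor, exactly one metastasis and at least one control sample;
    ``validate_for_concordance`` enforces this.
    """

    samples: list[Sample] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sample_ids in manifest: {dupes}")

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def by_role(self, role: Role) -> list[Sample]:
        return [s for s in self.samples if s.role is role]

    @property
    def primary_tumor(self) -> Sample:
        return self._single(Role.PRIMARY_TUMOR)

    @property
    def metastasis(self) -> Sample:
        return self._single(Role.METASTASIS)

    @property
    def controls(self) -> list[Sample]:
        return [s for s in self.samples if s.role in CONTROL_ROLES]

    @property
    def ctcs(self) -> list[Sample]:
        return self.by_role(Role.SINGLE_CTC)

    def _single(self, role: Role) -> Sample:
        found = self.by_role(role)
        if len(found) != 1:
            raise FormatError(
                f"manifest must declare exactly one {role.value} sample, found {len(found)}"
            )
        return found[0]

    def validate_for_concordance(self) -> None:
        self._single(Role.PRIMARY_TUMOR)
        self._single(Role.METASTASIS)
        if not self.controls:
            raise FormatError("manifest declares no control sample (wbc_control / normal_tissue)")


def read_manifest(path: str | Path) -> SampleManifest:
    """Read a sample manifest from YAML (``samples:`` list) or TSV."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        entries = doc["samples"] if isinstance(doc, dict) else doc
        samples = [
            Sample(
                sample_id=str(e["sample_id"]),
                role=Role(e["role"]),
                collection_label=e.get("collection_label"),
            )
            for e in entries
        ]
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"sample_id", "role"} <= set(df.columns):
            raise FormatError(f"{path}: manifest TSV needs sample_id and role columns")
        samples = [
            Sample(
                sample_id=row.sample_id,
                role=Role(row.role),
                collection_label=getattr(row, "collection_label", None),
            )
            for row in df.itertuples(index=False)
        ]
    return SampleManifest(samples)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    doc = {
        "samples": [
            {
                "sample_id": s.sample_id,
                "role": s.role.value,
                **({"collection_label": s.collection_label} if s.collection_label else {}),
            }
            for s in manifest
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Loci and allele counts
# ---------------------------------------------------------------------------


class Locus(NamedTuple):
    """A biallelic point locus, 1-based as in VCF."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def validate(self) -> "Locus":
        if self.pos < 1:
            raise FormatError(f"locus position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise FormatError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        for base in (self.ref, self.alt):
            if base not in IUPAC_BASES:
                raise FormatError(f"non-IUPAC allele {base!r} at {self.chrom}:{self.pos}")
        return self

    def __str__(self) -> str:  # e.g. chr1:100A>T
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


class AlleleCountTable:
    """Per (sample, locus) ref/alt read depths.

    Backed by a pandas DataFrame with columns
    ``sample_id chrom pos ref alt ref_depth alt_depth``; the
    (sample_id, locus) pair is unique and depths are non-negative.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"allele-count table missing columns {missing}")
        df = df[COUNT_COLUMNS].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["ref_depth"] = df["ref_depth"].astype(np.int64)
        df["alt_depth"] = df["alt_depth"].astype(np.int64)
        neg = df[(df.ref_depth < 0) | (df.alt_depth < 0)]
        if len(neg):
            first = neg.iloc[0]
            raise FormatError(
                f"negative depth for {first.sample_id} at {first.chrom}:{first.pos}"
            )
        if (df.pos < 1).any():
            raise FormatError("positions must be 1-based (>= 1)")
        if (df.ref == df.alt).any():
            bad = df[df.ref == df.alt].iloc[0]
            raise FormatError(f"ref == alt at {bad.chrom}:{bad.pos}")
        key = df[["sample_id", "chrom", "pos", "ref", "alt"]]
        dup_mask = key.duplicated(keep=False)
        if dup_mask.any():
            first = df[dup_mask].iloc[0]
            raise FormatError(
                "duplicate (sample, locus) pair: "
                f"{first.sample_id} {first.chrom}:{first.pos}{first.ref}>{first.alt}"
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AlleleCountTable):
            return NotImplemented
        a = self.df.sort_values(COUNT_COLUMNS[:5]).reset_index(drop=True)
        b = other.df.sort_values(COUNT_COLUMNS[:5]).reset_index(drop=True)
        return a.equals(b)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.df.sample_id.unique())

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.df[self.df.sample_id == sample_id]

    def depth_lookup(self, sample_id: str) -> dict[Locus, tuple[int, int]]:
        """Map Locus -> (ref_depth, alt_depth) for one sample."""
        sub = self.for_sample(sample_id)
        return {
            Locus(r.chrom, int(r.pos), r.ref, r.alt): (int(r.ref_depth), int(r.alt_depth))
            for r in sub.itertuples(index=False)
        }

    def loci(self) -> set[Locus]:
        return {
            Locus(r.chrom, int(r.pos), r.ref, r.alt)
            for r in self.df.itertuples(index=False)
        }

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, Locus, int, int]]
    ) -> "AlleleCountTable":
        rows = [
            (sid, loc.chrom, loc.pos, loc.ref, loc.alt, rd, ad)
            for sid, loc, rd, ad in records
        ]
        return cls(pd.DataFrame(rows, columns=COUNT_COLUMNS))

    @classmethod
    def concat(cls, tables: Sequence["AlleleCountTable"]) -> "AlleleCountTable":
        return cls(pd.concat([t.df for t in tables], ignore_index=True))


def read_allele_counts(path: str | Path) -> AlleleCountTable:
    """Read a per-sample per-locus allele-count TSV.

    Malformed rows are rejected with their (1-based, header-inclusive)
    row number; duplicate (sample, locus) pairs and negative depths are
    hard errors.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse allele-count TSV: {exc}") from exc
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("pos", "ref_depth", "alt_depth"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.flatnonzero(bad | df[col].isna())[0]) + 2  # +1 header, +1 1-based
            raise FormatError(f"{path}: malformed {col} value at row {row}")
        df[col] = numeric.astype(np.int64)
    return AlleleCountTable(df)


def write_allele_counts(table: AlleleCountTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variant call sets (VCF)
# ---------------------------------------------------------------------------


@dataclass
class VariantCallSet:
    """Called SSNV loci for one sample, with optional caller scores."""

    sample_id: str
    scores: dict[Locus, Optional[float]] = field(default_factory=dict)

    @property
    def loci(self) -> set[Locus]:
        return set(self.scores)

    def __contains__(self, locus: Locus) -> bool:
        return locus in self.scores

    def __len__(self) -> int:
        return len(self.scores)

    @classmethod
    def from_loci(
        cls, sample_id: str, loci: Iterable[Locus], score: Optional[float] = None
    ) -> "VariantCallSet":
        return cls(sample_id, {l: score for l in loci})


def read_vcf_calls(path: str | Path, sample_id: str) -> VariantCallSet:
    """Load biallelic SNV calls from a VCF.

    Only records with FILTER ``PASS`` or ``.`` are retained (external
    somatic callers mark non-calls REJECT); multi-allelic records and
    indels are skipped with a logged count.
    """
    calls: dict[Locus, Optional[float]] = {}
    n_skipped = 0
    n_filtered = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n_skipped += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or alt == "*":
                n_skipped += 1
                continue
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                n_filtered += 1
                continue
            score = rec.qual if rec.qual is not None else None
            calls[Locus(rec.chrom, rec.pos, ref, alt).validate()] = score
    if n_skipped or n_filtered:
        logger.info(
            "%s: skipped %d multi-allelic/indel and %d non-PASS records",
            path, n_skipped, n_filtered,
        )
    return VariantCallSet(sample_id, calls)


def write_vcf_calls(
    callset: VariantCallSet, path: str | Path, contigs: Optional[dict[str, int]] = None
) -> None:
    """Write a call set as a minimal VCF v4.2 (all records PASS)."""
    header = pysam.VariantHeader()
    chroms = sorted({l.chrom for l in callset.loci})
    if contigs is None:
        maxpos = {c: 0 for c in chroms}
        for l in callset.loci:
            maxpos[l.chrom] = max(maxpos[l.chrom], l.pos)
        contigs = {c: maxpos[c] + 1000 for c in chroms}
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for locus in sorted(callset.loci):
            score = callset.scores[locus]
            rec = out.new_record(
                contig=locus.chrom,
                start=locus.pos - 1,
                stop=locus.pos,
                alleles=(locus.ref, locus.alt),
                qual=score,
            )
            rec.filter.add("PASS")
            out.write(rec)


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------


class CoverageTrack:
    """Fixed-width binned coverage with per-bin GC fraction.

    Bins are 0-based half-open, non-overlapping and sorted; the bin
    width is constant within a track (100 kb by default throughout the
    pipeline).
    """

    def __init__(self, df: pd.DataFrame):
        req = ["chrom", "start", "end", "depth", "gc"]
        missing = [c for c in req if c not in df.columns]
        if missing:
            raise FormatError(f"coverage track missing columns {missing}")
        df = df[req].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["depth"] = df["depth"].astype(float)
        df["gc"] = df["gc"].astype(float)
        if ((df.gc < 0) | (df.gc > 1)).any():
            raise FormatError("gc fractions must lie in [0, 1]")
        if (df.depth < 0).any():
            raise FormatError("depths must be non-negative")
        widths = (df.end - df.start).unique()
        if len(widths) != 1 or widths[0] <= 0:
            raise FormatError(f"bin width must be constant and positive, got {sorted(widths)}")
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub.start.to_numpy()
            ends = sub.end.to_numpy()
            if not (np.diff(starts) > 0).all() or (starts[1:] < ends[:-1]).any():
                raise FormatError(f"{chrom}: bins must be sorted and non-overlapping")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def bin_width(self) -> int:
        return int((self.df.end - self.df.start).iloc[0])

    @property
    def depths(self) -> np.ndarray:
        return self.df.depth.to_numpy()

    @property
    def gc(self) -> np.ndarray:
        return self.df.gc.to_numpy()

    def same_grid(self, other: "CoverageTrack") -> bool:
        a, b = self.df, other.df
        return (
            len(a) == len(b)
            and (a.chrom.to_numpy() == b.chrom.to_numpy()).all()
            and (a.start.to_numpy() == b.start.to_numpy()).all()
            and np.allclose(a.gc.to_numpy(), b.gc.to_numpy())
        )


def read_coverage_track(bedgraph: str | Path, gc_sidecar: str | Path) -> CoverageTrack:
    """Read a bedGraph (chrom start end depth) plus a GC sidecar TSV
    (chrom start end gc) sharing the same bin grid."""
    cov = pd.read_csv(
        bedgraph, sep="\t", header=None, names=["chrom", "start", "end", "depth"],
        dtype={0: str}, comment="#",
    )
    gc = pd.read_csv(
        gc_sidecar, sep="\t", header=None, names=["chrom", "start", "end", "gc"],
        dtype={0: str}, comment="#",
    )
    if len(cov) != len(gc):
        raise FormatError("bedGraph and GC sidecar disagree on bin count")
    merged = cov.merge(gc, on=["chrom", "start", "end"], how="inner")
    if len(merged) != len(cov):
        raise FormatError("bedGraph and GC sidecar bin grids differ")
    return CoverageTrack(merged)


def write_coverage_track(
    track: CoverageTrack, bedgraph: str | Path, gc_sidecar: str | Path
) -> None:
    track.df[["chrom", "start", "end", "depth"]].to_csv(
        bedgraph, sep="\t", header=False, index=False
    )
    track.df[["chrom", "start", "end", "gc"]].to_csv(
        gc_sidecar, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Structural-variant breakpoints (BEDPE)
# ---------------------------------------------------------------------------


class BreakpointEnd(NamedTuple):
    chrom: str
    pos: int  # 1-based
    orientation: str  # '+' or '-'


@dataclass(frozen=True)
class ClippedRead:
    """Split-read evidence for a junction: where the read is clipped and
    where its clipped mate segment maps."""

    read_pos: int
    clip_side: str  # 'L' or 'R'
    mate_chrom: str
    mate_pos: int


@dataclass(frozen=True)
class BreakpointRecord:
    """A rearrangement junction between two oriented genomic positions."""

    pos_a: BreakpointEnd
    pos_b: BreakpointEnd
    name: str = "."
    score: float = 0.0
    evidence: tuple[ClippedRead, ...] = ()

    def __post_init__(self):
        if (self.pos_a.chrom, self.pos_a.pos) > (self.pos_b.chrom, self.pos_b.pos):
            raise FormatError(
                f"breakpoint ends out of order: {self.pos_a} > {self.pos_b}"
            )
        for end in (self.pos_a, self.pos_b):
            if end.orientation not in {"+", "-"}:
                raise FormatError(f"orientation must be + or -, got {end.orientation!r}")
            if end.pos < 1:
                raise FormatError("breakpoint positions are 1-based (>= 1)")

    @property
    def sv_class(self) -> str:
        return "intra" if self.pos_a.chrom == self.pos_b.chrom else "inter"

    @property
    def size(self) -> Optional[int]:
        if self.sv_class == "inter":
            return None
        return self.pos_b.pos - self.pos_a.pos

    @staticmethod
    def make(
        chrom_a: str, pos_a: int, orient_a: str,
        chrom_b: str, pos_b: int, orient_b: str,
        name: str = ".", score: float = 0.0,
        evidence: Sequence[ClippedRead] = (),
    ) -> "BreakpointRecord":
        a = BreakpointEnd(chrom_a, pos_a, orient_a)
        b = BreakpointEnd(chrom_b, pos_b, orient_b)
        if (a.chrom, a.pos) > (b.chrom, b.pos):
            a, b = b, a
        return BreakpointRecord(a, b, name=name, score=score, evidence=tuple(evidence))


def read_bedpe(path: str | Path) -> list[BreakpointRecord]:
    """Read 10-column BEDPE; start columns are 0-based half-open and
    converted to 1-based internal junction positions."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise FormatError(f"{path}:{lineno}: BEDPE needs >= 10 columns")
            c1, s1, _e1, c2, s2, _e2, name, score, o1, o2 = fields[:10]
            for strand in (o1, o2):
                if strand not in {"+", "-", "."}:
                    raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            records.append(
                BreakpointRecord.make(
                    c1, int(s1) + 1, "+" if o1 == "." else o1,
                    c2, int(s2) + 1, "+" if o2 == "." else o2,
                    name=name,
                    score=float(score) if score not in {".", ""} else 0.0,
                )
            )
    return records


def write_bedpe(records: Sequence[BreakpointRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                "\t".join(
                    [
                        rec.pos_a.chrom, str(rec.pos_a.pos - 1), str(rec.pos_a.pos),
                        rec.pos_b.chrom, str(rec.pos_b.pos - 1), str(rec.pos_b.pos),
                        rec.name, f"{rec.score:g}",
                        rec.pos_a.orientation, rec.pos_b.orientation,
                    ]
                )
                + "\n"
            )


EVIDENCE_COLUMNS = [
    "sample_id", "sv_name", "chrom", "read_pos", "clip_side", "mate_chrom", "mate_pos",
]


def read_evidence(path: str | Path) -> pd.DataFrame:
    """Read a clipped-read evidence TSV (one row per supporting read)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str, "mate_chrom": str})
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: evidence TSV missing columns {missing}")
    if not df.clip_side.isin(["L", "R"]).all():
        raise FormatError(f"{path}: clip_side must be L or R")
    return df[EVIDENCE_COLUMNS]


def write_evidence(df: pd.DataFrame, path: str | Path) -> None:
    df[EVIDENCE_COLUMNS].to_csv(path, sep="\t", index=False)
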