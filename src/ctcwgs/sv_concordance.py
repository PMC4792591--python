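"""Cross-sample structural-variant breakpoint concordance.

Rearrangement junctions called per sample (externally, e.g. by a
split-read caller) are matched across samples by breakpoint identity:
two records match when both oriented ends agree within a coordinate
tolerance (0 bp by default — the shared events of interest have
literally identical breakpoints across tissues and CTCs).  Matching
records are grouped by single-linkage clustering, each cluster is
classified by which manifest roles carry it, supporting clipped reads
are re-counted per carrier from the evidence table (automating the
manual review step), short SVs are partitioned by the characteristic
0.6-2 kb size class, and junctions are screened against tumor
suppressor gene intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .io_model import (
    BreakpointRecord,
    CONTROL_ROLES,
    FormatError,
    SampleManifest,
)


# ---------------------------------------------------------------------------
# Breakpoint matching
# ---------------------------------------------------------------------------


def breakpoints_match(a: BreakpointRecord, b: BreakpointRecord, tol_bp: int = 0) -> bool:
    """True when both oriented junction ends agree within tol_bp."""
    return (
        a.pos_a.chrom == b.pos_a.chrom
        and a.pos_b.chrom == b.pos_b.chrom
        and a.pos_a.orientation == b.pos_a.orientation
        and a.pos_b.orientation == b.pos_b.orientation
        and abs(a.pos_a.pos - b.pos_a.pos) <= tol_bp
        and abs(a.pos_b.pos - b.pos_b.pos) <= tol_bp
    )


@dataclass
class SvCluster:
    """One matched junction across samples."""

    records: list[tuple[str, BreakpointRecord]]  # (sample_id, record)
    sharing_class: str = "private"               # shared_all_tumor | shared_some | private
    somatic: bool = True
    max_deviation: int = 0
    support: dict[str, int] = field(default_factory=dict)

    @property
    def carriers(self) -> list[str]:
        return sorted({sid for sid, _ in self.records})

    @property
    def representative(self) -> BreakpointRecord:
        return self.records[0][1]


@dataclass
class SvMatchReport:
    clusters: list[SvCluster]

    def somatic_clusters(self) -> list[SvCluster]:
        return [c for c in self.clusters if c.somatic]

    def by_class(self, sharing_class: str) -> list[SvCluster]:
        return [c for c in self.clusters if c.sharing_class == sharing_class]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.clusters):
            rep = c.representative
            rows.append(
                {
                    "cluster": i,
                    "chrom_a": rep.pos_a.chrom, "pos_a": rep.pos_a.pos,
                    "chrom_b": rep.pos_b.chrom, "pos_b": rep.pos_b.pos,
                    "sv_class": rep.sv_class,
                    "size": rep.size,
                    "sharing_class": c.sharing_class,
                    "somatic": c.somatic,
                    "n_carriers": len(c.carriers),
                    "carriers": ",".join(c.carriers),
                    "max_deviation": c.max_deviation,
                    "support": ";".join(f"{s}:{n}" for s, n in sorted(c.support.items())),
                }
            )
        return pd.DataFrame(rows)


def match_breakpoints(
    callsets: dict[str, Sequence[BreakpointRecord]],
    manifest: SampleManifest,
    tol_bp: int = 0,
) -> SvMatchReport:
    """Single-linkage clustering of breakpoint records across samples.

    Sharing classes, from the manifest roles: ``shared_all_tumor`` when
    every tumor/CTC sample carries the cluster, ``shared_some`` for >1
    carrier, ``private`` for exactly one.  A cluster with any
    control-role carrier is flagged non-somatic.
    """
    flat: list[tuple[str, BreakpointRecord]] = [
        (sid, rec) for sid, recs in callsets.items() for rec in recs
    ]
    n = len(flat)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            if breakpoints_match(flat[i][1], flat[j][1], tol_bp):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    role_of = {s.sample_id: s.role for s in manifest}
    tumor_ids = {s.sample_id for s in manifest if s.role not in CONTROL_ROLES}
    clusters = []
    for members in groups.values():
        records = [flat[i] for i in members]
        carriers = {sid for sid, _ in records}
        somatic = all(role_of.get(sid) not in CONTROL_ROLES for sid in carriers)
        tumor_carriers = carriers & tumor_ids
        if somatic and tumor_carriers == tumor_ids:
            sharing = "shared_all_tumor"
        elif len(carriers) > 1:
            sharing = "shared_some"
        else:
            sharing = "private"
        dev = 0
        for _, rec in records[1:]:
            ref = records[0][1]
            dev = max(
                dev,
                abs(rec.pos_a.pos - ref.pos_a.pos),
                abs(rec.pos_b.pos - ref.pos_b.pos),
            )
        clusters.append(
            SvCluster(records=records, sharing_class=sharing, somatic=somatic, max_deviation=dev)
        )
    clusters.sort(key=lambda c: (c.representative.pos_a.chrom, c.representative.pos_a.pos))
    return SvMatchReport(clusters)


# ---------------------------------------------------------------------------
# Supporting-read verification
# ---------------------------------------------------------------------------


def verify_support(
    record: BreakpointRecord,
    evidence: pd.DataFrame,
    sample_id: Optional[str] = None,
    tol_bp: int = 5,
    tol_window: int = 500,
) -> int:
    """Count clipped reads supporting a junction in one sample.

    A read supports the junction when its clip position lies within
    ``tol_bp`` of either junction end (matching chromosome) and its
    clipped mate segment maps within ``tol_window`` of the partner end.
    """
    df = evidence
    if sample_id is not None:
        df = df[df.sample_id == sample_id]
    count = 0
    ends = (
        (record.pos_a, record.pos_b),
        (record.pos_b, record.pos_a),
    )
    for row in df.itertuples(index=False):
        for end, partner in ends:
            if (
                row.chrom == end.chrom
                and abs(int(row.read_pos) - end.pos) <= tol_bp
                and row.mate_chrom == partner.chrom
                and abs(int(row.mate_pos) - partner.pos) <= tol_window
            ):
                count += 1
                break
    return count


def annotate_support(
    report: SvMatchReport,
    evidence: pd.DataFrame,
    tol_bp: int = 5,
    tol_window: int = 500,
    min_support: int = 2,
) -> SvMatchReport:
    """Fill per-carrier supporting-read counts into each cluster.

    ``min_support`` is the threshold for declaring the event present in
    a sample when reporting (exposed, default 2 reads).
    """
    for cluster in report.clusters:
        rep = cluster.representative
        cluster.support = {
            sid: verify_support(rep, evidence, sample_id=sid, tol_bp=tol_bp, tol_window=tol_window)
            for sid in cluster.carriers
        }
        cluster.support = {
            sid: n for sid, n in cluster.support.items()
        }
    return report


# ---------------------------------------------------------------------------
# Size classes and gene screening
# ---------------------------------------------------------------------------


def classify_short_svs(
    records: Sequence[BreakpointRecord],
    size_range: tuple[int, int] = (600, 2000),
) -> dict[str, list[BreakpointRecord]]:
    """Partition records into ``short`` (intra-chromosomal, size within
    the range), ``other_intra`` and ``inter``."""
    lo, hi = size_range
    out: dict[str, list[BreakpointRecord]] = {"short": [], "other_intra": [], "inter": []}
    for rec in records:
        if rec.sv_class == "inter":
            out["inter"].append(rec)
        elif lo <= rec.size <= hi:
            out["short"].append(rec)
        else:
            out["other_intra"].append(rec)
    return out


def read_gene_bed(path: str | Path) -> dict[str, tuple[str, int, int]]:
    """Read named gene intervals from 4-column BED (half-open)."""
    genes: dict[str, tuple[str, int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: gene BED needs 4 columns")
            chrom, start, end, name = fields[:4]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed coordinates") from exc
            if end_i <= start_i:
                raise FormatError(f"{path}:{lineno}: empty/negative interval")
            genes[name] = (chrom, start_i, end_i)
    return genes


def screen_genes(
    callsets: dict[str, Sequence[BreakpointRecord]],
    gene_intervals: dict[str, tuple[str, int, int]],
) -> pd.DataFrame:
    """Per-gene per-sample SV hits.

    A record hits a gene when either junction end falls inside the
    gene's half-open interval [start, end).  Returns one row per
    (gene, sample, record) hit with the junction coordinates and size.
    """
    rows = []
    for gene, (chrom, start, end) in gene_intervals.items():
        for sid, records in callsets.items():
            for rec in records:
                hit = any(
                    e.chrom == chrom and start <= e.pos - 1 < end
                    for e in (rec.pos_a, rec.pos_b)
                )
                if hit:
                    rows.append(
                        {
                            "gene": gene,
                            "sample_id": sid,
                            "name": rec.name,
                            "chrom_a": rec.pos_a.chrom, "pos_a": rec.pos_a.pos,
                            "chrom_b": rec.pos_b.chrom, "pos_b": rec.pos_b.pos,
                            "sv_class": rec.sv_class,
                            "size": rec.size,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "sample_id", "name", "chrom_a", "pos_a",
            "chrom_b", "pos_b", "sv_class", "size",
        ],
    )
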