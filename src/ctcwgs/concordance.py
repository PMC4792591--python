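"""Founder/clonal SSNV classification and bidirectional tracing.

The central concordance question: how much of the somatic mutational
landscape of the solid tumors is visible in single circulating tumor
cells, and vice versa?  Two classifications drive it:

* **founder SSNVs** — somatic SNVs shared between the primary tumor
  and the metastasis (minus anything seen in any control), inferred to
  predate the lesions' divergence; traced *forward* into each CTC.
* **clonal SSNVs (CTC sense)** — SNVs detected in at least k (default
  3) single CTCs; traced *back* into the tissues.

Tracing distinguishes two evidence levels at each target locus: formal
caller detection (membership in the sample's call set) and the weaker
"supporting reads" criterion (>= support_min_alt alt reads in the
sample's allele counts), which rescues true mutations that ADO and
amplification imbalance reduced to a handful of minor-allele reads.
The module also provides the CTC-pool accumulation curve (how the
discovered founder count grows with the number of cells analysed, by
exact subset enumeration), the allele-fraction vs CTC-recurrence
association, the germline-contamination check and the count/percentage
summaries (percentages rounded half-up to one decimal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotyping import LodModelParams
from .io_model import AlleleCountTable, Locus, VariantCallSet

logger = logging.getLogger("ctcwgs")


def percentage(numerator: int, denominator: int) -> Optional[float]:
    """100 * numerator / denominator rounded half-up to one decimal;
    None when the denominator is zero (undefined, never reported as 0)."""
    if denominator == 0:
        return None
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def identify_founders(
    primary_calls: VariantCallSet,
    met_calls: VariantCallSet,
    control_calls: Sequence[VariantCallSet] = (),
) -> set[Locus]:
    """Founder SSNVs: loci called in BOTH lesions and in NO control.

    Controls are subtracted as a union — a locus seen in either the
    WBC or the adjacent-normal call set is treated as germline.
    """
    if primary_calls is None or met_calls is None:
        raise ValueError("both primary and metastasis call sets are required")
    control_union: set[Locus] = set()
    for cs in control_calls:
        control_union |= cs.loci
    return (primary_calls.loci & met_calls.loci) - control_union


def identify_clonal(ctc_calls: Sequence[VariantCallSet], k: int = 3) -> set[Locus]:
    """Clonal SSNVs: loci detected in at least k single-CTC call sets."""
    if len(ctc_calls) < k:
        raise ValueError(f"need at least k={k} CTC call sets, got {len(ctc_calls)}")
    tally: dict[Locus, int] = {}
    for cs in ctc_calls:
        for locus in cs.loci:
            tally[locus] = tally.get(locus, 0) + 1
    return {locus for locus, n in tally.items() if n >= k}


# ---------------------------------------------------------------------------
# Tracing
# ---------------------------------------------------------------------------


@dataclass
class TracingTable:
    """Per-locus evidence flags across traced samples.

    ``df`` has one row per target locus with boolean columns
    ``supported_in_<sample>`` / ``called_in_<sample>`` for every traced
    sample plus tissue allele fractions ``af_primary`` / ``af_met``
    (NaN when the tissue has no reads at the locus).
    """

    df: pd.DataFrame
    sample_ids: list[str]

    def loci(self) -> list[Locus]:
        return [
            Locus(r.chrom, int(r.pos), r.ref, r.alt)
            for r in self.df.itertuples(index=False)
        ]

    def supported_union(self, sample_ids: Optional[Iterable[str]] = None) -> pd.Series:
        ids = list(sample_ids) if sample_ids is not None else self.sample_ids
        cols = [f"supported_in_{s}" for s in ids]
        return self.df[cols].any(axis=1)

    def called_union(self, sample_ids: Optional[Iterable[str]] = None) -> pd.Series:
        ids = list(sample_ids) if sample_ids is not None else self.sample_ids
        cols = [f"called_in_{s}" for s in ids]
        return self.df[cols].any(axis=1)

    def per_sample_counts(self, mode: str = "supported") -> dict[str, int]:
        return {
            s: int(self.df[f"{mode}_in_{s}"].sum()) for s in self.sample_ids
        }


def trace(
    targets: Iterable[Locus],
    counts: AlleleCountTable,
    calls: dict[str, VariantCallSet],
    params: LodModelParams,
    sample_ids: Sequence[str],
    af_primary_id: str = "PRIMARY",
    af_met_id: str = "MET",
) -> TracingTable:
    """Trace a target locus set through the given samples.

    ``supported_in`` applies the alt-read threshold to the sample's
    allele counts (a locus absent from the counts is treated as
    zero-depth, with a logged warning); ``called_in`` is membership in
    the sample's call set.  Tissue allele fractions are computed from
    the primary/metastasis count rows when present.
    """
    targets = sorted(set(targets))
    lookups = {sid: counts.depth_lookup(sid) for sid in set(sample_ids) | {af_primary_id, af_met_id}}
    n_missing = 0
    rows = []
    for locus in targets:
        row: dict = {
            "chrom": locus.chrom, "pos": locus.pos, "ref": locus.ref, "alt": locus.alt,
        }
        for sid in sample_ids:
            depths = lookups[sid].get(locus)
            if depths is None:
                n_missing += 1
                depths = (0, 0)
            row[f"supported_in_{sid}"] = depths[1] >= params.support_min_alt
            row[f"called_in_{sid}"] = sid in calls and locus in calls[sid]
        for label, sid in (("af_primary", af_primary_id), ("af_met", af_met_id)):
            depths = lookups.get(sid, {}).get(locus)
            if depths is None or sum(depths) == 0:
                row[label] = np.nan
            else:
                row[label] = depths[1] / (depths[0] + depths[1])
        rows.append(row)
    if n_missing:
        logger.warning(
            "trace: %d (sample, locus) pairs had no count row; treated as zero depth",
            n_missing,
        )
    return TracingTable(pd.DataFrame(rows), sample_ids=list(sample_ids))


# ---------------------------------------------------------------------------
# Accumulation curve
# ---------------------------------------------------------------------------


def accumulation_curve(
    tracing: TracingTable,
    ctc_ids: Sequence[str],
    mode: str = "supported",
) -> pd.DataFrame:
    """Discovered-locus count as a function of CTC pool size.

    For every pool size m = 1..N, enumerates all C(N, m) subsets of
    ``ctc_ids`` exactly and reports the mean/min/max number of target
    loci with evidence (``mode`` = supported or called) in at least one
    cell of the subset.  The mean is non-decreasing in m and the m = N
    value equals the plain union count.  N is capped at 12 (4096
    subsets); beyond that, subsample cells instead.
    """
    if mode not in {"supported", "called"}:
        raise ValueError("mode must be 'supported' or 'called'")
    n = len(ctc_ids)
    if n > 12:
        raise ValueError(
            f"{n} CTCs: exact enumeration capped at 12; subsample the cell list"
        )
    flags = np.column_stack(
        [tracing.df[f"{mode}_in_{sid}"].to_numpy(dtype=bool) for sid in ctc_ids]
    )
    rows = []
    for m in range(1, n + 1):
        sizes = [
            int(flags[:, list(subset)].any(axis=1).sum())
            for subset in combinations(range(n), m)
        ]
        rows.append((m, float(np.mean(sizes)), int(min(sizes)), int(max(sizes))))
    return pd.DataFrame(rows, columns=["m", "mean_count", "min_count", "max_count"])


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceSummary:
    """Count summary of the bidirectional tracing."""

    n_founder: int
    n_founder_supported_union: int
    n_founder_called_union: int
    founder_supported_per_ctc: dict[str, int]
    founder_called_per_ctc: dict[str, int]
    n_clonal: int
    n_clonal_supported_in_tissue: int
    n_clonal_called_in_tissue: int
    pct_founder_supported: Optional[float] = None
    pct_clonal_supported: Optional[float] = None
    pct_clonal_called: Optional[float] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pct_founder_supported = percentage(
            self.n_founder_supported_union, self.n_founder
        )
        self.pct_clonal_supported = percentage(
            self.n_clonal_supported_in_tissue, self.n_clonal
        )
        self.pct_clonal_called = percentage(self.n_clonal_called_in_tissue, self.n_clonal)

    @staticmethod
    def _median_range(values: Iterable[int]) -> dict:
        v = sorted(values)
        if not v:
            return {"median": None, "min": None, "max": None}
        return {"median": float(np.median(v)), "min": v[0], "max": v[-1]}

    def to_dict(self) -> dict:
        return {
            "n_founder": self.n_founder,
            "n_founder_supported_union": self.n_founder_supported_union,
            "n_founder_called_union": self.n_founder_called_union,
            "pct_founder_supported": self.pct_founder_supported,
            "founder_supported_per_ctc": self.founder_supported_per_ctc,
            "founder_supported_stats": self._median_range(
                self.founder_supported_per_ctc.values()
            ),
            "founder_called_per_ctc": self.founder_called_per_ctc,
            "founder_called_stats": self._median_range(
                self.founder_called_per_ctc.values()
            ),
            "n_clonal": self.n_clonal,
            "n_clonal_supported_in_tissue": self.n_clonal_supported_in_tissue,
            "n_clonal_called_in_tissue": self.n_clonal_called_in_tissue,
            "pct_clonal_supported": self.pct_clonal_supported,
            "pct_clonal_called": self.pct_clonal_called,
            **self.extras,
        }


def summarize(
    founder_tracing: TracingTable,
    clonal_tracing: TracingTable,
    ctc_ids: Sequence[str],
    tissue_ids: Sequence[str] = ("PRIMARY", "MET"),
) -> ConcordanceSummary:
    """Aggregate both tracing directions into the count summary."""
    return ConcordanceSummary(
        n_founder=len(founder_tracing.df),
        n_founder_supported_union=int(founder_tracing.supported_union(ctc_ids).sum()),
        n_founder_called_union=int(
            (founder_tracing.supported_union(ctc_ids)
             & founder_tracing.called_union(ctc_ids)).sum()
        ),
        founder_supported_per_ctc={
            s: int(founder_tracing.df[f"supported_in_{s}"].sum()) for s in ctc_ids
        },
        founder_called_per_ctc={
            s: int(founder_tracing.df[f"called_in_{s}"].sum()) for s in ctc_ids
        },
        n_clonal=len(clonal_tracing.df),
        n_clonal_supported_in_tissue=int(clonal_tracing.supported_union(tissue_ids).sum()),
        n_clonal_called_in_tissue=int(clonal_tracing.called_union(tissue_ids).sum()),
    )


# ---------------------------------------------------------------------------
# Allele fraction vs CTC recurrence; germline check
# ---------------------------------------------------------------------------


def af_recurrence_association(
    tracing: TracingTable, ctc_ids: Sequence[str]
) -> tuple[Optional[float], int]:
    """Spearman rank correlation between a locus' maximum tissue allele
    fraction and the number of CTCs with supporting reads at it.

    Returns (rho, n).  rho is None when undefined (all-tied ranks).
    More clonal mutations (higher tissue AF) recur in more CTCs under
    the lineage model, so rho > 0 is the expected signature.
    """
    df = tracing.df
    af = df[["af_primary", "af_met"]].max(axis=1)
    support_cols = [f"supported_in_{s}" for s in ctc_ids]
    n_cells = df[support_cols].sum(axis=1)
    keep = af.notna()
    af, n_cells = af[keep], n_cells[keep]
    if len(af) < 5:
        raise ValueError(f"need >= 5 loci with defined allele fractions, got {len(af)}")
    if af.nunique() <= 1 or n_cells.nunique() <= 1:
        return None, int(len(af))
    rho, _ = stats.spearmanr(af, n_cells)
    if np.isnan(rho):
        return None, int(len(af))
    return float(rho), int(len(af))


def germline_check(
    ssnvs: set[Locus], extra_control_calls: VariantCallSet
) -> tuple[int, int, Optional[float]]:
    """Fraction of an SSNV set absent from an additional germline
    control call set: (n_clean, n_total, pct at one decimal)."""
    n_total = len(ssnvs)
    n_clean = len(ssnvs - extra_control_calls.loci)
    return n_clean, n_total, percentage(n_clean, n_total)


def validation_summary(validation: pd.DataFrame) -> tuple[int, int, Optional[float]]:
    """Orthogonal-validation (e.g. Sanger) confirmation summary."""
    n_total = len(validation)
    n_confirmed = int(validation["confirmed"].sum())
    return n_confirmed, n_total, percentage(n_confirmed, n_total)
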