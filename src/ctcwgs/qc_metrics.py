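"""Sequencing-quality metrics for binned coverage tracks.

Covers the quality battery used to show that single-cell (MDA-amplified
CTC) whole-genome sequencing is comparable to bulk tissue sequencing:
depth and breadth summaries, the fraction of the genome covered deeply
enough for confident variant calling (>10X, strict), coverage-uniformity
Lorenz curves with the Gini index, GC-profile correlation against a
control sample as a WGA-bias check, and per-100-kb SNP density.

All metrics operate on fixed-width binned coverage (CoverageTrack),
not per-base pileups; 100-kb bins are the working resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import CoverageTrack, VariantCallSet


@dataclass
class QcReport:
    """Per-sample coverage QC summary."""

    sample_id: str
    mean_depth: float
    breadth_ge1: float
    frac_ge10: float
    gini: float
    lorenz_points: list[tuple[float, float]] = field(default_factory=list)
    gc_correlation_vs_control: float | None = None

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "mean_depth": self.mean_depth,
            "breadth_ge1": self.breadth_ge1,
            "frac_ge10": self.frac_ge10,
            "gini": self.gini,
            "gc_correlation_vs_control": self.gc_correlation_vs_control,
            "lorenz_points": [[float(x), float(y)] for x, y in self.lorenz_points],
        }


def depth_summary(track: CoverageTrack) -> tuple[float, float, float]:
    """Mean depth, breadth (fraction of bins with depth >= 1) and the
    fraction of bins covered above 10X (strictly > 10)."""
    if len(track) == 0:
        raise ValueError("empty coverage track")
    d = track.depths
    return float(d.mean()), float((d >= 1).mean()), float((d > 10).mean())


def lorenz_gini(track: CoverageTrack) -> tuple[list[tuple[float, float]], float]:
    """Lorenz curve and Gini index of coverage uniformity.

    Bins are sorted by depth ascending; the curve plots cumulative
    genome fraction against cumulative coverage fraction and the Gini
    index is the normalised mean absolute difference
    ``G = sum_ij |x_i - x_j| / (2 n^2 mu)``, computed via the
    equivalent sorted form.  A perfectly uniform track has G = 0 and a
    diagonal Lorenz curve.
    """
    d = np.sort(track.depths.astype(float))
    n = len(d)
    total = d.sum()
    if total <= 0:
        raise ValueError("total depth is zero; Lorenz curve undefined")
    cum_genome = np.arange(0, n + 1) / n
    cum_cov = np.concatenate([[0.0], np.cumsum(d)]) / total
    points = list(zip(cum_genome.tolist(), cum_cov.tolist()))
    i = np.arange(1, n + 1)
    # clamp: rounding can give -1e-17 on perfectly uniform tracks
    gini = max(float(np.sum((2 * i - n - 1) * d) / (n * total)), 0.0)
    return points, gini


def gc_correlation(
    track_a: CoverageTrack, track_b: CoverageTrack, gc_bin_width: float = 0.01
) -> float:
    """Pearson correlation of the coverage-weighted GC profiles of two
    samples sharing a bin grid.

    Genome bins are grouped into GC-percentage bins of ``gc_bin_width``;
    within each GC bin the coverage mass (total depth) of each sample is
    accumulated, and the two profiles are correlated over GC bins
    populated in both.  Because the profile is dominated by the shared
    genome GC composition, unbiased WGA yields correlations near 1; a
    GC-dependent amplification bias in one sample pulls it down.
    Pearson is invariant to per-sample scaling, so raw coverage mass and
    normalised base fractions give identical results.
    """
    if not track_a.same_grid(track_b):
        raise ValueError("tracks must share the same bin grid and GC values")
    gc_bin = np.floor(track_a.gc / gc_bin_width).astype(int)
    prof_a = pd.Series(track_a.depths).groupby(gc_bin).sum()
    prof_b = pd.Series(track_b.depths).groupby(gc_bin).sum()
    both = prof_a.index.intersection(prof_b.index)
    a = prof_a.loc[both].to_numpy()
    b = prof_b.loc[both].to_numpy()
    populated = (a > 0) | (b > 0)
    a, b = a[populated], b[populated]
    if len(a) < 3:
        raise ValueError(f"only {len(a)} populated GC bins; correlation degenerate")
    return float(np.corrcoef(a, b)[0, 1])


def snp_density(
    calls: VariantCallSet,
    genome_bins: dict[str, int] | int,
    bin_width: int = 100_000,
    cap: int = 1000,
) -> pd.DataFrame:
    """Per-bin SNP counts at a fixed bin width (default 100 kb).

    ``genome_bins`` gives the number of bins per chromosome (a bare int
    means a single-chromosome genome named ``chr1``).  Returns columns
    ``chrom start end count display`` where ``display`` is the count
    capped at ``cap`` (the plotting range 0-1000 per 100 kb).
    """
    if isinstance(genome_bins, int):
        genome_bins = {"chr1": genome_bins}
    frames = []
    for chrom, nbins in genome_bins.items():
        counts = np.zeros(nbins, dtype=np.int64)
        for locus in calls.loci:
            if locus.chrom != chrom:
                continue
            idx = (locus.pos - 1) // bin_width
            if not 0 <= idx < nbins:
                raise ValueError(f"call {locus} outside genome bounds for {chrom}")
            counts[idx] += 1
        starts = np.arange(nbins, dtype=np.int64) * bin_width
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + bin_width,
                    "count": counts,
                    "display": np.minimum(counts, cap),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def qc_report(
    sample_id: str,
    track: CoverageTrack,
    control_track: CoverageTrack | None = None,
) -> QcReport:
    """Assemble the full QC summary for one sample."""
    mean_depth, breadth, ge10 = depth_summary(track)
    points, gini = lorenz_gini(track)
    corr = None
    if control_track is not None:
        corr = gc_correlation(track, control_track)
    return QcReport(
        sample_id=sample_id,
        mean_depth=mean_depth,
        breadth_ge1=breadth,
        frac_ge10=ge10,
        gini=gini,
        lorenz_points=points,
        gc_correlation_vs_control=corr,
    )
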