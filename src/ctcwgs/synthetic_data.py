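"""Ground-truthed synthetic datasets for the multi-sample CTC design.

The generator emulates the study design the analysis assumes: one
patient with a primary tumor and one metastasis (bulk WGS), matched
white-blood-cell and adjacent-normal controls, and N single circulating
tumor cells whole-genome-amplified by MDA before sequencing.  Somatic
point mutations come in tiers:

* **founder** SSNVs present in both lesions (and every tumor cell),
* **lesion-private** SSNVs confined to one lesion at sub-clonal
  allele fractions,
* **cell-private** SSNVs unique to a single CTC (late events plus
  any amplification artifacts worth modelling explicitly),

on top of germline heterozygous SNPs shared by every sample.  Bulk
read counts follow a negative-binomial depth law and binomial allele
sampling; single-cell counts additionally pass through the WGA
artifact channel — allele dropout (ADO), Beta-distributed allelic
amplification imbalance, and the low (~1e-5) MDA polymerase error
rate.  Binned coverage tracks follow a lognormal uniformity law with a
genome-wide GC landscape shared by all samples, and the structural
variant truth contains breakpoint-identical shared rearrangements plus
per-sample private short SVs inside configurable tumor-suppressor gene
intervals, each with synthetic clipped-read evidence.

Every ``simulate_*`` output is reproducible byte-for-byte from
(config, seed); per-stage child generators are derived from the master
seed with fixed offsets so stages are independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io_model import (
    AlleleCountTable,
    BreakpointRecord,
    CoverageTrack,
    EVIDENCE_COLUMNS,
    Locus,
    Role,
    Sample,
    SampleManifest,
    VariantCallSet,
    write_allele_counts,
    write_bedpe,
    write_coverage_track,
    write_evidence,
    write_manifest,
    write_vcf_calls,
)

BIN_WIDTH = 100_000

# fixed child-seed offsets per stage
_STAGE_TRUTH = 0
_STAGE_BULK = 1
_STAGE_CELL = 2
_STAGE_COVERAGE = 3
_STAGE_SV = 4

SOMATIC_TIERS = ("founder", "primary_private", "met_private", "cell_private")
TIERS = ("germline_het", "germline_hom_alt") + SOMATIC_TIERS


def _default_gene_intervals() -> dict[str, tuple[str, int, int]]:
    # synthetic stand-ins for the screened tumor-suppressor loci; widths
    # comfortably exceed the largest short-SV size (2 kb)
    return {
        "PTEN": ("chr1", 40_000_000, 40_150_000),
        "RB1": ("chr1", 90_000_000, 90_150_000),
        "BRCA2": ("chr2", 20_000_000, 20_150_000),
        "TMEM207": ("chr1", 140_000_000, 140_150_000),
    }


@dataclass
class SimConfig:
    """Study-condition parameters of the generator.

    Defaults mirror the study scale: 802 founder SSNVs shared by the
    two lesions, four single CTCs, ~32X depths, short private SVs of
    0.6-2 kb, and the ~1e-5 MDA substitution error rate.
    """

    genome_bins: int = 3000              # 100-kb bins across the genome
    n_germline_het: int = 20_000
    n_germline_hom_alt: int = 0
    n_founder: int = 802
    n_primary_private: int = 300
    n_met_private: int = 300
    n_ctc: int = 4
    n_cell_private_per_ctc: int = 50
    bulk_depth_mean: float = 32.0
    cell_depth_mean: float = 32.0
    depth_dispersion: float = 0.1        # NB variance = mu + disp * mu^2
    ado_rate: float = 0.2
    amp_imbalance_alpha: float = 2.0     # math.inf -> balanced binomial
    seq_error: float = 1e-3
    mda_error: float = 1e-5
    bulk_purity: float = 0.8
    founder_af_beta: tuple[float, float] = (20.0, 2.0)   # clonal fraction law
    private_af_beta: tuple[float, float] = (2.0, 6.0)    # subclone fraction law
    ctc_lineage: str = "metastasis"      # which lesion's private set CTCs sample
    bulk_uniformity_sigma: float = 0.12  # lognormal sigma of bulk bin coverage
    cell_uniformity_sigma: float = 0.30  # lognormal sigma of MDA bin coverage
    gc_beta: tuple[float, float] = (32.0, 46.0)  # per-bin GC fraction law
    gc_bias_strength: float = 0.0        # monotone GC response; 0 = no coupling
    sv_shared: int = 2
    sv_private_short: int = 4
    sv_short_size_range: tuple[int, int] = (600, 2000)
    sv_evidence_reads: int = 6
    gene_intervals: dict[str, tuple[str, int, int]] = field(
        default_factory=_default_gene_intervals
    )
    seed: int = 0

    def __post_init__(self):
        for name in ("ado_rate", "seq_error", "mda_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.bulk_purity <= 1.0:
            raise ValueError("bulk_purity must lie in (0, 1]")
        if self.n_founder < 0:
            raise ValueError("n_founder must be >= 0")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be >= 0")
        lo, hi = self.sv_short_size_range
        if not 0 < lo <= hi:
            raise ValueError("sv_short_size_range must be a positive ordered pair")
        for gene, (chrom, start, end) in self.gene_intervals.items():
            if end - start < hi:
                raise ValueError(
                    f"gene interval {gene} ({end - start} bp) smaller than max SV size {hi}"
                )

    @property
    def chromosomes(self) -> dict[str, int]:
        """Bins per chromosome; the genome is split 2:1 over two
        synthetic chromosomes so inter-chromosomal SVs exist."""
        n1 = (2 * self.genome_bins + 2) // 3
        return {"chr1": n1, "chr2": self.genome_bins - n1}

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: n * BIN_WIDTH for c, n in self.chromosomes.items()}

    def rng(self, stage: int, extra: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage, extra])


def default_manifest(config: SimConfig) -> SampleManifest:
    samples = [
        Sample("WBC", Role.WBC_CONTROL),
        Sample("NORMAL", Role.NORMAL_TISSUE),
        Sample("PRIMARY", Role.PRIMARY_TUMOR),
        Sample("MET", Role.METASTASIS),
    ]
    samples += [Sample(f"CTC-{i + 1}", Role.SINGLE_CTC) for i in range(config.n_ctc)]
    return SampleManifest(samples)


# ---------------------------------------------------------------------------
# Point-mutation truth
# ---------------------------------------------------------------------------


@dataclass
class TruthSet:
    """Ground truth: per-locus tier labels, bulk allele fractions and
    CTC carrier sets, plus the SV truth (filled in by simulate_sv_truth)."""

    variants: pd.DataFrame  # chrom pos ref alt tier cell_id af_primary af_met carried_by
    config: SimConfig
    breakpoints: list[tuple[BreakpointRecord, list[str]]] = field(default_factory=list)
    sv_evidence: Optional[pd.DataFrame] = None

    def loci(self, tier: Optional[str] = None) -> set[Locus]:
        df = self.variants if tier is None else self.variants[self.variants.tier == tier]
        return {Locus(r.chrom, int(r.pos), r.ref, r.alt) for r in df.itertuples(index=False)}

    def tier_counts(self) -> dict[str, int]:
        return self.variants.tier.value_counts().to_dict()

    def cell_somatic_loci(self, cell_id: str) -> set[Locus]:
        """All somatic loci carried (heterozygously) by one CTC."""
        df = self.variants
        carried = df.apply(
            lambda r: (
                r.tier == "founder"
                or (r.tier in ("primary_private", "met_private") and cell_id in r.carried_by)
                or (r.tier == "cell_private" and r.cell_id == cell_id)
            ),
            axis=1,
        )
        return {
            Locus(r.chrom, int(r.pos), r.ref, r.alt)
            for r in df[carried].itertuples(index=False)
        }


_BASES = np.array(list("ACGT"))


def _draw_loci(config: SimConfig, rng: np.random.Generator, n: int) -> pd.DataFrame:
    """n distinct biallelic loci placed uniformly over the genome."""
    lengths = config.chrom_lengths
    genome_size = sum(lengths.values())
    if n > genome_size // 10:
        raise ValueError(
            f"infeasible: {n} loci requested for a {genome_size}-bp genome"
        )
    chroms = list(lengths)
    probs = np.array([lengths[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    seen: set[tuple[str, int]] = set()
    rows: list[tuple[str, int]] = []
    while len(rows) < n:
        k = n - len(rows)
        idx = rng.choice(len(chroms), size=k, p=probs)
        pos = rng.integers(1, high=np.array([lengths[chroms[i]] for i in idx]) + 1)
        for i, p in zip(idx, pos):
            key = (chroms[i], int(p))
            if key not in seen:
                seen.add(key)
                rows.append(key)
                if len(rows) == n:
                    break
    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    alt_idx = (ref_idx + alt_shift) % 4
    return pd.DataFrame(
        {
            "chrom": [r[0] for r in rows],
            "pos": [r[1] for r in rows],
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
        }
    )


def simulate_truth(config: SimConfig) -> TruthSet:
    """Draw the ground-truth genotype structure.

    Tier counts equal the configured counts exactly.  Each CTC carries
    all founders, a random subset of its lineage lesion's private set
    (each private locus with probability equal to its subclonal
    fraction), and its own cell-private set.  Bulk allele fractions
    are drawn from the configured clonality mixture and scaled by
    purity (a fully clonal het mutation in a pure tumor has AF 0.5).
    """
    rng = config.rng(_STAGE_TRUTH)
    counts = {
        "germline_het": config.n_germline_het,
        "germline_hom_alt": config.n_germline_hom_alt,
        "founder": config.n_founder,
        "primary_private": config.n_primary_private,
        "met_private": config.n_met_private,
        "cell_private": config.n_ctc * config.n_cell_private_per_ctc,
    }
    total = sum(counts.values())
    loci = _draw_loci(config, rng, total)
    tiers = np.repeat(list(counts), list(counts.values()))
    loci["tier"] = tiers

    cell_ids = [f"CTC-{i + 1}" for i in range(config.n_ctc)]
    cell_col = np.full(total, "", dtype=object)
    cp_mask = tiers == "cell_private"
    cell_col[cp_mask] = np.repeat(cell_ids, config.n_cell_private_per_ctc)
    loci["cell_id"] = cell_col

    half = 0.5 * config.bulk_purity
    af_p = np.zeros(total)
    af_m = np.zeros(total)
    g_mask = tiers == "germline_het"
    af_p[g_mask] = af_m[g_mask] = 0.5
    h_mask = tiers == "germline_hom_alt"
    af_p[h_mask] = af_m[h_mask] = 1.0
    f_mask = tiers == "founder"
    fa, fb = config.founder_af_beta
    clonal_frac = rng.beta(fa, fb, size=int(f_mask.sum()))
    af_p[f_mask] = half * clonal_frac
    clonal_frac_m = rng.beta(fa, fb, size=int(f_mask.sum()))
    af_m[f_mask] = half * clonal_frac_m
    pa, pb = config.private_af_beta
    pp_mask = tiers == "primary_private"
    sub_p = rng.beta(pa, pb, size=int(pp_mask.sum()))
    af_p[pp_mask] = half * sub_p
    mp_mask = tiers == "met_private"
    sub_m = rng.beta(pa, pb, size=int(mp_mask.sum()))
    af_m[mp_mask] = half * sub_m
    loci["af_primary"] = af_p
    loci["af_met"] = af_m

    # CTC lineage: which lesion-private mutations each cell carries
    lineage_mask = mp_mask if config.ctc_lineage == "metastasis" else pp_mask
    lineage_frac = sub_m if config.ctc_lineage == "metastasis" else sub_p
    carried = [frozenset() for _ in range(total)]
    lineage_idx = np.flatnonzero(lineage_mask)
    for j, (i, frac) in enumerate(zip(lineage_idx, lineage_frac)):
        carriers = [cid for cid in cell_ids if rng.random() < frac]
        carried[i] = frozenset(carriers)
    for i in np.flatnonzero(f_mask | g_mask | h_mask):
        carried[i] = frozenset(cell_ids)
    for i in np.flatnonzero(cp_mask):
        carried[i] = frozenset([cell_col[i]])
    loci["carried_by"] = carried

    truth = TruthSet(variants=loci.reset_index(drop=True), config=config)
    records, evidence = simulate_sv_truth(config)
    truth.breakpoints = records
    truth.sv_evidence = evidence
    return truth


# ---------------------------------------------------------------------------
# Read-count emission
# ---------------------------------------------------------------------------


def _draw_depths(rng: np.random.Generator, mean: float, dispersion: float, n: int) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean, size=n)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean), size=n)


def _seq_channel(f: np.ndarray, e: float) -> np.ndarray:
    """Per-read alt probability after the sequencing error channel:
    a true-alt read survives with 1-e, a true-ref read miscalls to the
    specific alt with e/3."""
    return f * (1.0 - e) + (1.0 - f) * (e / 3.0)


def simulate_bulk_counts(
    truth: TruthSet, config: Optional[SimConfig] = None
) -> AlleleCountTable:
    """Binomial read sampling for the four bulk samples (WBC, NORMAL,
    PRIMARY, MET) at every truth locus."""
    config = config or truth.config
    df = truth.variants
    n_loci = len(df)
    sample_af = {
        "WBC": np.where(df.tier.str.startswith("germline"), df.af_primary, 0.0),
        "NORMAL": np.where(df.tier.str.startswith("germline"), df.af_primary, 0.0),
        "PRIMARY": df.af_primary.to_numpy(),
        "MET": df.af_met.to_numpy(),
    }
    frames = []
    for k, (sid, f) in enumerate(sample_af.items()):
        rng = config.rng(_STAGE_BULK, k)
        depth = _draw_depths(rng, config.bulk_depth_mean, config.depth_dispersion, n_loci)
        alt = rng.binomial(depth, _seq_channel(np.asarray(f, dtype=float), config.seq_error))
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "chrom": df.chrom,
                    "pos": df.pos,
                    "ref": df.ref,
                    "alt": df.alt,
                    "ref_depth": depth - alt,
                    "alt_depth": alt,
                }
            )
        )
    return AlleleCountTable(pd.concat(frames, ignore_index=True))


#: amplification branch codes emitted alongside cell counts
BRANCH_REF_ONLY, BRANCH_ALT_ONLY, BRANCH_BOTH = 0, 1, 2


def simulate_cell_counts(
    truth: TruthSet,
    cell_id: str,
    config: Optional[SimConfig] = None,
    return_branches: bool = False,
):
    """WGA + sequencing emission for one single cell at every truth locus.

    Heterozygous loci pass through the three-branch amplification
    channel: with probability p/2 only the ref allele amplifies, p/2
    only the alt allele, and 1-p both amplify with a per-locus alt
    fraction drawn Beta(alpha, alpha) (exactly 0.5 in the alpha -> inf
    limit).  The MDA polymerase channel then flips each sampled base to
    the other allele with probability e_mda, and the sequencing channel
    miscalls with rate e (specific-allele miscall e/3).  Homozygous
    loci emit from the corresponding single allele through the same
    error channels.
    """
    config = config or truth.config
    cell_ids = [f"CTC-{i + 1}" for i in range(config.n_ctc)]
    if cell_id not in cell_ids:
        raise ValueError(f"unknown cell_id {cell_id!r}")
    rng = config.rng(_STAGE_CELL, cell_ids.index(cell_id))
    df = truth.variants
    n_loci = len(df)

    is_hom_alt = (df.tier == "germline_hom_alt").to_numpy()
    carried = df.carried_by.apply(lambda s: cell_id in s).to_numpy()
    is_het = carried & ~is_hom_alt

    # amplification branch and pre-error alt fraction
    u = rng.random(n_loci)
    branch = np.full(n_loci, BRANCH_BOTH, dtype=np.int8)
    p = config.ado_rate
    branch[is_het & (u < p / 2)] = BRANCH_REF_ONLY
    branch[is_het & (u >= p / 2) & (u < p)] = BRANCH_ALT_ONLY
    if np.isinf(config.amp_imbalance_alpha):
        q = np.full(n_loci, 0.5)
    else:
        q = rng.beta(config.amp_imbalance_alpha, config.amp_imbalance_alpha, size=n_loci)
    f_amp = np.zeros(n_loci)
    f_amp[is_het & (branch == BRANCH_BOTH)] = q[is_het & (branch == BRANCH_BOTH)]
    f_amp[is_het & (branch == BRANCH_ALT_ONLY)] = 1.0
    f_amp[is_hom_alt] = 1.0
    branch[~is_het] = BRANCH_BOTH  # branch codes only meaningful for het loci

    # MDA error channel (ref/alt flip), then sequencing channel
    f_mda = f_amp * (1.0 - config.mda_error) + (1.0 - f_amp) * config.mda_error
    f_read = _seq_channel(f_mda, config.seq_error)

    depth = _draw_depths(rng, config.cell_depth_mean, config.depth_dispersion, n_loci)
    alt = rng.binomial(depth, f_read)
    table = AlleleCountTable(
        pd.DataFrame(
            {
                "sample_id": cell_id,
                "chrom": df.chrom,
                "pos": df.pos,
                "ref": df.ref,
                "alt": df.alt,
                "ref_depth": depth - alt,
                "alt_depth": alt,
            }
        )
    )
    if return_branches:
        return table, branch, is_het
    return table


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------


def simulate_coverage_tracks(
    config: SimConfig,
    manifest: Optional[SampleManifest] = None,
    sigma_overrides: Optional[dict[str, float]] = None,
) -> dict[str, CoverageTrack]:
    """Lognormal per-bin coverage for every manifest sample on a shared
    100-kb bin grid with a genome-wide GC landscape drawn once.

    Single-cell samples use ``cell_uniformity_sigma``, bulk samples
    ``bulk_uniformity_sigma`` (per-sample overrides allowed).  With
    ``gc_bias_strength`` zero (the default) coverage is uncoupled from
    GC; a nonzero strength applies the monotone response
    ``depth *= exp(strength * (gc - mean_gc))`` shared by all samples.
    """
    manifest = manifest or default_manifest(config)
    rng = config.rng(_STAGE_COVERAGE)
    bins = []
    for chrom, nbins in config.chromosomes.items():
        starts = np.arange(nbins, dtype=np.int64) * BIN_WIDTH
        bins.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + BIN_WIDTH}))
    grid = pd.concat(bins, ignore_index=True)
    ga, gb = config.gc_beta
    gc = rng.beta(ga, gb, size=len(grid))
    grid["gc"] = gc

    tracks = {}
    for k, sample in enumerate(manifest):
        srng = config.rng(_STAGE_COVERAGE, k + 1)
        if sample.role is Role.SINGLE_CTC:
            mean, sigma = config.cell_depth_mean, config.cell_uniformity_sigma
        else:
            mean, sigma = config.bulk_depth_mean, config.bulk_uniformity_sigma
        if sigma_overrides and sample.sample_id in sigma_overrides:
            sigma = sigma_overrides[sample.sample_id]
        if sigma == 0:
            depth = np.full(len(grid), mean)
        else:
            depth = np.exp(srng.normal(np.log(mean) - sigma**2 / 2.0, sigma, size=len(grid)))
        if config.gc_bias_strength != 0.0:
            depth = depth * np.exp(config.gc_bias_strength * (gc - gc.mean()))
        df = grid.copy()
        df["depth"] = depth
        tracks[sample.sample_id] = CoverageTrack(df[["chrom", "start", "end", "depth", "gc"]])
    return tracks


# ---------------------------------------------------------------------------
# Structural-variant truth
# ---------------------------------------------------------------------------


def simulate_sv_truth(
    config: SimConfig,
) -> tuple[list[tuple[BreakpointRecord, list[str]]], pd.DataFrame]:
    """Breakpoint truth with sharing labels and clipped-read evidence.

    The shared rearrangements (one large intra-chromosomal, the rest
    inter-chromosomal) carry IDENTICAL breakpoints in the primary,
    the metastasis and every CTC, and are absent from controls.  Each
    tumor/CTC sample additionally receives private short SVs (sizes
    uniform in ``sv_short_size_range``) placed inside the configured
    gene intervals, with distinct positions across samples.  Every
    true junction gets ``sv_evidence_reads`` synthetic clipped reads
    per carrying sample.
    """
    rng = config.rng(_STAGE_SV)
    manifest = default_manifest(config)
    tumor_samples = [s.sample_id for s in manifest if s.role is not Role.WBC_CONTROL
                     and s.role is not Role.NORMAL_TISSUE]
    chroms = list(config.chrom_lengths)
    records: list[tuple[BreakpointRecord, list[str]]] = []

    for i in range(config.sv_shared):
        if i == 0 or len(chroms) < 2:
            chrom = chroms[0]
            length = config.chrom_lengths[chrom]
            a = int(rng.integers(length // 10, length // 2))
            b = a + int(rng.integers(2_000_000, min(50_000_000, length - a - 1)))
            rec = BreakpointRecord.make(chrom, a, "+", chrom, b, "-", name=f"SV_SHARED_{i + 1}")
        else:
            c1, c2 = chroms[0], chroms[1]
            a = int(rng.integers(1, config.chrom_lengths[c1]))
            b = int(rng.integers(1, config.chrom_lengths[c2]))
            rec = BreakpointRecord.make(c1, a, "+", c2, b, "+", name=f"SV_SHARED_{i + 1}")
        records.append((rec, list(tumor_samples)))

    lo, hi = config.sv_short_size_range
    genes = list(config.gene_intervals.items())
    used_positions: set[tuple[str, int]] = set()
    for sid in tumor_samples:
        for j in range(config.sv_private_short):
            gene, (chrom, gstart, gend) = genes[j % len(genes)]
            size = int(rng.integers(lo, hi + 1))
            while True:
                a = int(rng.integers(gstart + 1, gend - size))
                if (chrom, a) not in used_positions:
                    used_positions.add((chrom, a))
                    break
            rec = BreakpointRecord.make(
                chrom, a, "+", chrom, a + size, "-", name=f"SV_{sid}_{gene}_{j + 1}"
            )
            records.append((rec, [sid]))

    evidence_rows = []
    for rec, carriers in records:
        for sid in carriers:
            for r in range(config.sv_evidence_reads):
                # alternate clipped ends; mates map near the partner junction
                if r % 2 == 0:
                    end, partner = rec.pos_a, rec.pos_b
                    side = "R" if end.orientation == "+" else "L"
                else:
                    end, partner = rec.pos_b, rec.pos_a
                    side = "L" if end.orientation == "-" else "R"
                evidence_rows.append(
                    (
                        sid, rec.name, end.chrom,
                        end.pos + int(rng.integers(-2, 3)),
                        side,
                        partner.chrom,
                        partner.pos + int(rng.integers(-100, 101)),
                    )
                )
    evidence = pd.DataFrame(evidence_rows, columns=EVIDENCE_COLUMNS)
    return records, evidence


# ---------------------------------------------------------------------------
# Naive bulk caller + full-dataset orchestration
# ---------------------------------------------------------------------------


def naive_bulk_calls(
    counts: AlleleCountTable, sample_id: str, min_alt: int = 3
) -> VariantCallSet:
    """Detection rule standing in for an external bulk somatic caller on
    synthetic data: a locus is called when alt reads reach ``min_alt``
    (at 32X and e = 1e-3 chance alt>=3 is ~2e-7 per locus)."""
    sub = counts.for_sample(sample_id)
    hits = sub[sub.alt_depth >= min_alt]
    return VariantCallSet(
        sample_id,
        {
            Locus(r.chrom, int(r.pos), r.ref, r.alt): float(r.alt_depth)
            for r in hits.itertuples(index=False)
        },
    )


@dataclass
class SimulatedDataset:
    """A complete simulated study: manifest, truth, counts, coverage,
    per-sample call sets and the SV truth with evidence."""

    config: SimConfig
    manifest: SampleManifest
    truth: TruthSet
    counts: AlleleCountTable
    tracks: dict[str, CoverageTrack]
    calls: dict[str, VariantCallSet]

    @property
    def sv_records(self) -> list[tuple[BreakpointRecord, list[str]]]:
        return self.truth.breakpoints

    @property
    def sv_evidence(self) -> pd.DataFrame:
        return self.truth.sv_evidence


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate the whole multi-sample dataset deterministically from
    (config, seed).  Bulk call sets use the naive alt-read rule; CTC
    call sets are produced downstream by the LOD genotyper."""
    manifest = default_manifest(config)
    truth = simulate_truth(config)
    tables = [simulate_bulk_counts(truth, config)]
    for s in manifest.ctcs:
        tables.append(simulate_cell_counts(truth, s.sample_id, config))
    counts = AlleleCountTable.concat(tables)
    tracks = simulate_coverage_tracks(config, manifest)
    calls = {
        sid: naive_bulk_calls(counts, sid)
        for sid in ("WBC", "NORMAL", "PRIMARY", "MET")
    }
    return SimulatedDataset(config, manifest, truth, counts, tracks, calls)


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write every artifact of a simulated dataset: manifest YAML,
    allele-count TSV, truth JSON, per-sample VCFs, BEDPE + evidence TSV
    and per-sample bedGraph/GC tracks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_manifest(dataset.manifest, outdir / "manifest.yaml")
    write_allele_counts(dataset.counts, outdir / "allele_counts.tsv")

    truth_doc = {
        "config": _config_to_jsonable(dataset.config),
        "variants": dataset.truth.variants.assign(
            carried_by=dataset.truth.variants.carried_by.apply(sorted)
        ).to_dict(orient="records"),
        "breakpoints": [
            {
                "name": rec.name,
                "pos_a": list(rec.pos_a),
                "pos_b": list(rec.pos_b),
                "carriers": carriers,
            }
            for rec, carriers in dataset.sv_records
        ],
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_doc, fh, indent=1)

    contigs = dataset.config.chrom_lengths
    for sid, callset in dataset.calls.items():
        write_vcf_calls(callset, outdir / f"{sid}.vcf", contigs=contigs)
    write_bedpe([rec for rec, _ in dataset.sv_records], outdir / "svs.bedpe")
    write_evidence(dataset.sv_evidence, outdir / "sv_evidence.tsv")
    for sid, track in dataset.tracks.items():
        write_coverage_track(track, outdir / f"{sid}.bedgraph", outdir / f"{sid}.gc.tsv")


def _config_to_jsonable(config: SimConfig) -> dict:
    doc = asdict(config)
    if np.isinf(doc["amp_imbalance_alpha"]):
        doc["amp_imbalance_alpha"] = "inf"
    return doc


# ---------------------------------------------------------------------------
# Deterministic worked-example fixture
# ---------------------------------------------------------------------------


@dataclass
class PaperFixture:
    """A deterministic multi-sample fixture whose classification
    summaries land on the worked example's printed counts: 802 founder
    SSNVs of which 230 have CTC supporting reads (117 caller-flagged),
    229 clonal CTC SSNVs of which 197 trace to tissue (116
    caller-flagged), a 777-locus exonic set with 770 germline-clean,
    and a 25-locus validation panel with 23 confirmations."""

    manifest: SampleManifest
    counts: AlleleCountTable
    calls: dict[str, VariantCallSet]
    exonic_ssnvs: set[Locus]
    wbc_wes_calls: VariantCallSet
    validation: pd.DataFrame  # chrom pos ref alt confirmed

    @property
    def ctc_ids(self) -> list[str]:
        return [s.sample_id for s in self.manifest.ctcs]


def _ranges(*pairs: tuple[int, int]) -> set[int]:
    out: set[int] = set()
    for lo, hi in pairs:
        out |= set(range(lo, hi + 1))
    return out


def make_paper_fixture() -> PaperFixture:
    """Build the deterministic worked-example dataset.

    Founder index sets (into the 802 founder loci) are chosen so that
    per-CTC supported counts are {125, 150, 164, 177} (median 157,
    range 125-177), per-CTC caller-flagged counts are {43, 74, 67, 55}
    (median 61, range 43-74), the supported union is exactly 230 and
    the caller-flagged union exactly 117.  A further 217 CTC-clonal
    loci (called in three CTCs) split into 104 called-in-tissue, 81
    supported-only-in-tissue and 32 with no tissue evidence, so the
    clonal set of 229 traces 197/229 supported and 116/229 called.
    """
    manifest = SampleManifest(
        [
            Sample("WBC", Role.WBC_CONTROL),
            Sample("NORMAL", Role.NORMAL_TISSUE),
            Sample("PRIMARY", Role.PRIMARY_TUMOR),
            Sample("MET", Role.METASTASIS),
            Sample("CTC-1", Role.SINGLE_CTC),
            Sample("CTC-2", Role.SINGLE_CTC),
            Sample("CTC-3", Role.SINGLE_CTC),
            Sample("CTC-4", Role.SINGLE_CTC),
        ]
    )
    ctc_ids = ["CTC-1", "CTC-2", "CTC-3", "CTC-4"]

    n_founder = 802
    founder_loci = [Locus("chr1", 10_000 + 1000 * i, "A", "T") for i in range(n_founder)]
    supported_idx = {
        "CTC-1": _ranges((0, 124)),                  # 125
        "CTC-2": _ranges((0, 133), (214, 229)),      # 150
        "CTC-3": _ranges((50, 213)),                 # 164
        "CTC-4": _ranges((0, 176)),                  # 177
    }
    called_idx = {
        "CTC-1": _ranges((0, 42)),                   # 43
        "CTC-2": _ranges((0, 73)),                   # 74
        "CTC-3": _ranges((50, 116)),                 # 67
        "CTC-4": _ranges((62, 116)),                 # 55
    }

    n_extra = 217
    extra_loci = [Locus("chr2", 10_000 + 1000 * j, "C", "G") for j in range(n_extra)]
    extra_called_tissue = set(range(0, 104))         # called + supported in MET
    extra_supported_tissue = set(range(0, 185))      # supported in MET (>= called)

    records: list[tuple[str, Locus, int, int]] = []
    # founder loci: tissue counts (always supported, AF decreasing with index)
    for i, loc in enumerate(founder_loci):
        af = max(0.40 - 0.0004 * i, 0.05)
        depth = 60
        alt = max(2, round(af * depth))
        records.append(("PRIMARY", loc, depth - alt, alt))
        records.append(("MET", loc, depth - alt, alt))
        records.append(("WBC", loc, 40, 0))
        records.append(("NORMAL", loc, 40, 0))
        for cid in ctc_ids:
            alt_c = 3 if i in supported_idx[cid] else 0
            records.append((cid, loc, 30 - alt_c, alt_c))
    # extra clonal loci
    for j, loc in enumerate(extra_loci):
        met_alt = 5 if j in extra_supported_tissue else 0
        records.append(("PRIMARY", loc, 30, 0))
        records.append(("MET", loc, 30 - met_alt, met_alt))
        records.append(("WBC", loc, 40, 0))
        records.append(("NORMAL", loc, 40, 0))
        for cid in ctc_ids:
            alt_c = 5 if cid in ("CTC-1", "CTC-2", "CTC-3") else 0
            records.append((cid, loc, 30 - alt_c, alt_c))
    counts = AlleleCountTable.from_records(records)

    calls: dict[str, VariantCallSet] = {
        "WBC": VariantCallSet("WBC", {}),
        "NORMAL": VariantCallSet("NORMAL", {}),
        "PRIMARY": VariantCallSet.from_loci("PRIMARY", founder_loci),
        "MET": VariantCallSet.from_loci(
            "MET",
            founder_loci + [extra_loci[j] for j in sorted(extra_called_tissue)],
        ),
    }
    for cid in ctc_ids:
        loci = [founder_loci[i] for i in sorted(called_idx[cid])]
        if cid in ("CTC-1", "CTC-2", "CTC-3"):
            loci += extra_loci
        calls[cid] = VariantCallSet.from_loci(cid, loci)

    exonic = [Locus("chr3", 10_000 + 1000 * i, "G", "A") for i in range(777)]
    wbc_wes = VariantCallSet.from_loci("WBC-WES", exonic[:7])

    validation = pd.DataFrame(
        {
            "chrom": [l.chrom for l in exonic[:25]],
            "pos": [l.pos for l in exonic[:25]],
            "ref": [l.ref for l in exonic[:25]],
            "alt": [l.alt for l in exonic[:25]],
            "confirmed": [True] * 23 + [False] * 2,
        }
    )
    return PaperFixture(
        manifest=manifest,
        counts=counts,
        calls=calls,
        exonic_ssnvs=set(exonic),
        wbc_wes_calls=wbc_wes,
        validation=validation,
    )
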