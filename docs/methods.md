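# Methods

## The genotype likelihood

A single cell amplified by multiple displacement amplification (MDA)
does not present clean diploid read counts. The model scores the read
pair (r ref, a alt; n = r + a) at a candidate somatic site under two
hypotheses.

**Normal** (no mutation): every alt read is an error,
`L_norm = Binom(a; n, ε)`, with ε = (e + e_mda)/3 — a miscall lands on
one specific alternative base a third of the time. Defaults
e = 10⁻³ (per-base sequencing error) and e_mda = 10⁻⁵ (the established
MDA polymerase error scale).

**Mutant** (heterozygous somatic variant), a three-branch mixture over
the amplification outcome:

* with probability p/2 the alt allele dropped out → reads look normal,
  `Binom(a; n, ε)`;
* with p/2 the ref allele dropped out → reads look homozygous alt,
  `Binom(a; n, 1 − ε)`;
* with 1 − p both alleles amplified, with a per-locus alt read
  fraction q ~ Beta(α, α) capturing amplification imbalance →
  `BetaBinom(a; n, α, α)`. α → ∞ (a flag, not a number to overflow)
  selects the balanced `Binom(n, ½)` limit.

The reported statistic is the posterior log-odds in base 10,
`LOD = log10 L_mut − log10 L_norm + log10(prior odds)`, prior odds
10⁻⁵ per base. Two consequences are forced by this construction and
are asserted by tests: LOD(0, 0) = −5 exactly (no data leaves the
prior), and LOD ≥ −5 iff the likelihood ratio is ≥ 1. Stored scores
are truncated above at 1 (posterior odds 10:1), matching the display
convention of the source heatmaps; the untruncated value is kept for
threshold decisions (`call_threshold`, default 0, i.e. posterior odds
even). All likelihoods are computed in log space and are finite for
depths up to 10⁵.

A homozygous-alt somatic hypothesis is not scored separately: the
ref-dropout branch of the mixture already explains all-alt read
profiles, and at the depths involved the two are not distinguishable.

### Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `seq_error` e | per-base sequencing miscall | 1e-3 | Illumina-scale substitution rate |
| `mda_error` e_mda | MDA polymerase substitution | 1e-5 | established MDA error-rate scale |
| `ado_rate` p | allele-dropout probability | 0.2 | typical MDA single-cell value; re-estimated per cell in the pipeline |
| `amp_imbalance_alpha` α | Beta(α, α) imbalance concentration | 2 | heavy-tailed imbalance that produces few-read minor alleles |
| `log10_prior_odds` | prior log-odds of a somatic mutation | −5 | ~10 somatic point mutations per Mb prior; also what makes the −5 threshold the likelihood-ratio boundary |
| `lod_cap` | display truncation | 1 | reporting convention |
| `support_min_alt` | supporting-reads threshold | 2 | one alt read at 30X is within the error regime |

## ADO estimation

The ADO rate is estimated per cell from germline heterozygous sites
confirmed in the controls (sites with depth < 10 excluded). Two
estimators are provided. The **threshold** rule — the fraction of
sites whose minor-allele read fraction is ≤ 0.05 — is simple but
conflates dropout with extreme amplification imbalance: under
Beta(2, 2) imbalance at 30X, a both-alleles-amplified site lands below
the threshold with probability ≈ 0.03, so the rule overshoots p = 0.3
by ≈ +0.023 in expectation. The default **mle** estimator fits the
same three-component mixture the LOD uses (dropout-ref / dropout-alt /
beta-binomial) by maximum likelihood jointly over (p, α)
(Nelder–Mead on logit-p and log-α, two starts), and is consistent for
the dropout branch probability; on simulated cells it recovers
p = 0.3 to within ±0.02 from 10⁴ sites. The pipeline pools the
per-CTC estimates into the scoring parameters.

## Concordance analysis

Founder SSNVs are the call-set intersection of primary and metastasis
minus the union of all control call sets (both controls are used, not
one). Clonal CTC SSNVs are loci called in ≥ k cells (k = 3). Tracing
records two evidence levels per (locus, sample): formal caller
detection, and "supporting reads" (alt depth ≥ `support_min_alt`) —
the automated version of a manual read review, which rescues true
mutations reduced to minor-allele traces by the WGA channel. Loci with
no count row for a traced sample are treated as zero depth with a
logged warning (real pileups have gaps), not as errors.

The accumulation curve enumerates all C(N, m) CTC subsets exactly for
m = 1..N (N ≤ 12; 4096 subsets at the cap) and reports mean/min/max of
the per-subset union count, so its endpoint equals the plain union and
its mean is non-decreasing by construction. Percentages are rounded
half-up to one decimal — the convention that reproduces every printed
summary (28.7, 86.0, 50.7, 99.1, 92.0) from its integer counts.
The allele-fraction/recurrence association is a Spearman rank
correlation between max(primary AF, metastasis AF) and the number of
CTCs with supporting reads, computed over the full tissue-somatic call
union (founders alone have too little AF spread to carry a rank
signal); all-tied inputs are reported as undefined rather than 0.

In `run_all`, internal LOD calls on CTCs are control-subtracted before
clonal identification, mirroring the fact that an external somatic
caller's output is somatic by construction; without this, germline
heterozygous sites (called mutant in every cell, correctly) would
dominate the clonal set.

## Coverage QC

All metrics run on fixed-width (100 kb) binned coverage, the working
resolution of the data model — Lorenz/Gini on bins, not per-base.
Gini is the normalised mean absolute difference
`G = Σᵢⱼ|xᵢ − xⱼ| / (2n²μ)`, computed via the equivalent sorted form
(clamped at 0 against −10⁻¹⁷ rounding on uniform tracks) and verified
against the brute-force double sum in tests. The deep-coverage
fraction is strict (> 10X). GC comparison correlates the
coverage-weighted GC profile of two samples — total coverage mass per
1 % GC bin, Pearson over GC bins populated in both (≥ 3 required).
This profile is dominated by the shared genome GC composition, so
unbiased WGA gives correlations near 1 while a GC-dependent
amplification bias in one sample pulls it down; Pearson's scale
invariance makes raw mass and normalised base fractions equivalent.
Per-GC-bin *mean* depth is deliberately not used: without GC-coupled
signal its profile is flat plus independent sampling noise, and its
correlation between samples estimates 0 regardless of WGA quality.

## The synthetic generator

The generator emulates the study design: one patient, two bulk lesions,
two controls, N = 4 single CTCs, a 300 Mb two-chromosome genome in
3000 × 100 kb bins. What it models, and what it does not:

* **Mutation tiers.** 20 000 germline het SNPs; 802 founder SSNVs
  present in both lesions; 300 lesion-private SSNVs per lesion;
  50 cell-private SSNVs per CTC. Founder bulk allele fractions are
  `purity · ½ · Beta(20, 2)` (near-clonal), lesion-private fractions
  `purity · ½ · Beta(2, 6)` (sub-clonal), purity 0.8. Each CTC carries
  all founders, its own private set, and each lesion-private mutation
  of its lineage lesion (metastatic by default — the sampled CTCs
  co-occurred with metastatic disease) with probability equal to that
  mutation's sub-clonal fraction. This is what produces the positive
  AF-recurrence association: more clonal ⇒ carried by more cells.
* **Read counts.** Per-locus depth ~ negative binomial
  (mean 32, variance μ + 0.1 μ²; dispersion 0 selects Poisson). Bulk
  alt reads ~ Binom(n, f(1−e) + (1−f)e/3). Cell counts pass through
  the three-branch amplification channel above, then an MDA flip
  (ref↔alt with probability e_mda — so the hom-ref alt rate equals
  e_mda, measurable directly), then the sequencing channel.
* **Coverage.** Per-bin depth ~ lognormal, σ = 0.12 for bulk and 0.30
  for cells (the study reports single-CTC uniformity comparable to
  tissue — unusually good for MDA; these values give bin-scale Gini
  ≈ 0.07 and ≈ 0.17 respectively). GC per bin ~ Beta(32, 46) (mean
  0.41, sd 0.055, matching human 100-kb GC), drawn once per genome and
  shared by all samples. By default coverage is uncoupled from GC; a
  monotone response `depth ∝ exp(strength · (gc − mean))`, shared
  across samples, is available.
* **Structural variants.** Two shared rearrangements — one large
  intra-chromosomal, one inter-chromosomal — with breakpoints
  *identical* in both lesions and every CTC and absent from controls,
  plus four private short SVs per tumor/CTC sample with sizes uniform
  in 600–2000 bp placed inside synthetic stand-ins for the screened
  tumor-suppressor intervals (PTEN, RB1, BRCA2, TMEM207), positions
  distinct across samples. Every junction gets 6 synthetic clipped
  reads per carrier (clip within ±2 bp of the junction, mate within
  ±100 bp of the partner end).
* **Not modelled:** read-level FASTQ/BAM output, MDA chimeric
  junctions, GC-coupled dropout, copy-number change, contaminating
  cell-free DNA. Passing tests therefore demonstrate the bookkeeping
  and the statistics under the stated generative assumptions, not
  robustness to artifact classes the generator does not produce.

Determinism: one master seed; per-stage child generators derive from
`(seed, stage, substream)` so each stage is independently reproducible,
and every artifact writer is byte-stable under a fixed config.

The deterministic worked-example fixture is separate from the
stochastic generator: its per-CTC supported/called index sets are
constructed so the classification summaries land exactly on the
published counts (230/802 supported with per-cell counts
{125, 150, 164, 177}; 117 caller-flagged with per-cell counts
{43, 74, 67, 55}; 229 clonal splitting 197 supported / 116 called in
tissue; 770/777 germline-clean; 23/25 validated), which makes it a
regression oracle for the whole tracing pathway.

## Numerical and design choices

* Point loci are 1-based (VCF convention); bins and BEDPE are 0-based
  half-open on disk with lossless conversion.
* Only biallelic SNVs enter the SSNV analysis; indels and
  multi-allelic records are dropped with a logged count. VCF FILTER
  `PASS` or `.` is accepted (external somatic callers mark non-calls
  REJECT).
* Breakpoint matching defaults to tolerance 0 — the shared-event claim
  is literal breakpoint identity — with single-linkage clustering, so
  raising the tolerance can only merge clusters, never split them.
  Orientations must agree. A cluster with any control carrier is
  flagged non-somatic. Declaring an event present in a sample requires
  ≥ 2 supporting clipped reads by default (exposed as a flag; no
  published rule exists for this).
* The α → ∞ flag in the likelihood is an exact closed form, not a
  large-α evaluation; tests check monotone convergence of finite-α
  scores toward it (to ~10⁻⁵ in log10 by α = 10⁸, where the
  beta-binomial pmf reaches its floating-point accuracy floor).
* Problem sizes in the test suite are scaled-down versions of the
  default study (e.g. 150–300 founders, 300-bin genomes) chosen so the
  full suite exercises every stage end to end in well under a minute,
  with the calibration checks (10⁷-base error rate, 10⁴-site ADO
  recovery) run at full size.

## Known limitations

* The LOD model treats reads as exchangeable and ignores base
  qualities and strand; joint multi-cell site models are out of scope.
* The naive alt-read bulk caller used on synthetic data is a stand-in
  detection rule for an external somatic caller's role in the design,
  adequate for call-set algebra on clean simulations but not a somatic
  caller (no strand/quality modelling, no tumor-in-normal handling).
  Low-allele-fraction founders below its alt-read threshold are missed,
  which is why simulated founder recovery is ~98 %, not 100 %.
* Accumulation curves use exact enumeration and refuse N > 12 rather
  than silently switching to sampling.
* Coverage QC is bin-scale; per-base breadth metrics from real BAMs
  will differ from bin-level breadth on the same sample.
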