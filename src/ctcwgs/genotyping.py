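"""ADO-adjusted Bayesian LOD genotyping of single amplified cells.

Whole-genome amplification of a single cell (here, MDA of a single
circulating tumor cell) distorts the read evidence at a heterozygous
locus in two ways: *allele dropout* (ADO) — one allele fails to
amplify at all — and *allelic amplification imbalance* — both alleles
amplify but to very unequal copy numbers.  A naive diploid genotype
likelihood therefore under-calls true mutations that surface as a
handful of minor-allele reads, and over-calls amplification errors.

The model scored here treats the read pair (r ref reads, a alt reads)
under two hypotheses:

* **normal** (no somatic mutation): every alt read is an error, so
  ``a ~ Binomial(n, eps)`` with n = r + a and the specific-allele error
  rate ``eps = (e + e_mda) / 3`` combining sequencing error e and the
  MDA polymerase error e_mda (a miscall lands on a specific alternative
  base a third of the time).

* **mutant** (heterozygous somatic variant): a three-branch ADO
  mixture,

  ``L_mut = (p/2)·Binom(a; n, eps) + (p/2)·Binom(a; n, 1-eps)
            + (1-p)·BetaBinom(a; n, alpha, alpha)``

  — with probability p/2 the alt allele dropped out (reads look
  normal), with p/2 the ref allele dropped out (reads look homozygous
  alt), and with 1-p both amplified with a per-locus alt read fraction
  drawn Beta(alpha, alpha) to capture amplification imbalance
  (alpha → ∞ recovers the balanced Binomial(n, 1/2) model).

The reported score is the posterior log-odds in base 10,

  ``LOD = log10 L_mut - log10 L_norm + log10_prior_odds``,

with prior odds 10^-5 for a somatic mutation at a given base, so
LOD >= -5 exactly when the likelihood ratio favours the mutant
hypothesis; for reporting, the score is truncated above at 1
(posterior odds 10:1) matching the convention of the source heatmaps.

The module also provides the ADO-rate estimator (from control-confirmed
germline heterozygous sites in the same cell) and the supporting-reads
operator used for cross-sample mutation tracing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import betaln, gammaln, logsumexp
from scipy.stats import betabinom, binom

from .io_model import AlleleCountTable, Locus

LOG10 = np.log(10.0)

#: alpha at or above this is treated as the balanced-binomial limit
ALPHA_INF = np.inf


@dataclass(frozen=True)
class LodModelParams:
    """Parameters of the ADO-adjusted genotype likelihood.

    seq_error
        per-base sequencing miscall rate e (default 1e-3).
    mda_error
        MDA polymerase substitution rate e_mda (default 1e-5, the
        established MDA error-rate scale).
    ado_rate
        allele-dropout probability p in [0, 1].
    amp_imbalance_alpha
        symmetric Beta(alpha, alpha) concentration of the per-locus alt
        read fraction in the both-alleles-amplified branch; ``math.inf``
        selects the balanced Binomial(n, 1/2) limit.
    log10_prior_odds
        prior log10-odds of a somatic mutation at a base (default -5).
    lod_cap
        reporting truncation of the LOD score (default 1).
    support_min_alt
        minimum alt reads for the supporting-reads operator (default 2).
    call_threshold
        LOD threshold of the internal caller (default 0).
    """

    seq_error: float = 1e-3
    mda_error: float = 1e-5
    ado_rate: float = 0.2
    amp_imbalance_alpha: float = 2.0
    log10_prior_odds: float = -5.0
    lod_cap: float = 1.0
    support_min_alt: int = 2
    call_threshold: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.ado_rate <= 1.0:
            raise ValueError("ado_rate must lie in [0, 1]")
        if self.seq_error + self.mda_error >= 0.5:
            raise ValueError("total error rate must be < 0.5")
        if not self.amp_imbalance_alpha > 0:
            raise ValueError("amp_imbalance_alpha must be > 0 (or inf)")
        if self.lod_cap < self.log10_prior_odds:
            raise ValueError("lod_cap must be >= log10_prior_odds")

    @property
    def eps(self) -> float:
        """Specific-allele error rate (e + e_mda) / 3."""
        return (self.seq_error + self.mda_error) / 3.0


# ---------------------------------------------------------------------------
# Likelihoods (log space, underflow-safe to depths of 1e5)
# ---------------------------------------------------------------------------


def log_likelihood_normal(ref_depth: int, alt_depth: int, params: LodModelParams) -> float:
    """log P(a alt reads | no mutation) = log Binom(a; r+a, eps)."""
    _check_depths(ref_depth, alt_depth)
    n = ref_depth + alt_depth
    if n == 0:
        return 0.0
    return float(binom.logpmf(alt_depth, n, params.eps))


def log_likelihood_mutant(ref_depth: int, alt_depth: int, params: LodModelParams) -> float:
    """log P(a alt reads | het somatic mutation) under the ADO mixture."""
    _check_depths(ref_depth, alt_depth)
    n = ref_depth + alt_depth
    if n == 0:
        return 0.0
    p, a = params.ado_rate, alt_depth
    eps = params.eps
    parts = []
    weights = []
    if p > 0:
        parts.append(binom.logpmf(a, n, eps))  # alt allele dropped out
        weights.append(np.log(p / 2.0))
        parts.append(binom.logpmf(a, n, 1.0 - eps))  # ref allele dropped out
        weights.append(np.log(p / 2.0))
    if p < 1:
        parts.append(_log_both_amplified(a, n, params.amp_imbalance_alpha))
        weights.append(np.log1p(-p))
    return float(logsumexp(np.asarray(parts) + np.asarray(weights)))


def _log_both_amplified(a: int, n: int, alpha: float) -> float:
    if np.isinf(alpha):
        # balanced binomial limit: C(n, a) 0.5^n
        return gammaln(n + 1) - gammaln(a + 1) - gammaln(n - a + 1) - n * np.log(2.0)
    return float(betabinom.logpmf(a, n, alpha, alpha))


def likelihood_normal(ref_depth: int, alt_depth: int, params: LodModelParams) -> float:
    """P(reads | normal); see :func:`log_likelihood_normal`."""
    return float(np.exp(log_likelihood_normal(ref_depth, alt_depth, params)))


def likelihood_mutant(ref_depth: int, alt_depth: int, params: LodModelParams) -> float:
    """P(reads | mutant); see :func:`log_likelihood_mutant`."""
    return float(np.exp(log_likelihood_mutant(ref_depth, alt_depth, params)))


def lod_score(
    ref_depth: int, alt_depth: int, params: LodModelParams, truncate: bool = True
) -> float:
    """Posterior log10-odds of mutant vs normal.

    ``LOD = log10 L_mut - log10 L_norm + log10_prior_odds``, truncated
    above at ``params.lod_cap`` unless ``truncate=False``.  With no
    reads both likelihoods are 1 and the score equals the prior odds
    exactly.
    """
    raw = (
        (log_likelihood_mutant(ref_depth, alt_depth, params)
         - log_likelihood_normal(ref_depth, alt_depth, params)) / LOG10
        + params.log10_prior_odds
    )
    return float(min(raw, params.lod_cap)) if truncate else float(raw)


def _check_depths(ref_depth: int, alt_depth: int) -> None:
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError("read depths must be non-negative")


def has_supporting_reads(ref_depth: int, alt_depth: int, params: LodModelParams) -> bool:
    """True when alt reads meet the tracing evidence threshold."""
    return alt_depth >= params.support_min_alt


def call_mutation(lod: float, params: LodModelParams) -> bool:
    """Internal caller: declare a mutation when LOD >= call_threshold."""
    return lod >= params.call_threshold


# ---------------------------------------------------------------------------
# ADO estimation from germline heterozygous sites
# ---------------------------------------------------------------------------


def estimate_ado(
    het_counts: AlleleCountTable | pd.DataFrame,
    min_depth: int = 10,
    dropout_max_minor_frac: float = 0.05,
    method: str = "mle",
    params: Optional[LodModelParams] = None,
) -> tuple[float, int]:
    """Estimate the allele-dropout rate from control-confirmed germline
    heterozygous sites of one amplified cell.

    Sites with total depth below ``min_depth`` are excluded.  Two
    estimators are offered:

    ``"mle"`` (default)
        maximum likelihood under the same three-branch emission model
        the LOD score uses (ADO-ref / ADO-alt at error rate eps, plus a
        symmetric beta-binomial both-amplified branch), fit jointly over
        (p, alpha).  This is consistent for the dropout branch
        probability even when amplification imbalance alone produces
        single-allele-looking sites.

    ``"threshold"``
        the empirical fraction of usable sites whose minor-allele read
        fraction is <= ``dropout_max_minor_frac``.  Simple and fast, but
        biased upward when imbalance is heavy-tailed (small alpha).

    Returns ``(p_hat, n_sites_used)``.
    """
    df = het_counts.df if isinstance(het_counts, AlleleCountTable) else het_counts
    ref = df["ref_depth"].to_numpy(dtype=np.int64)
    alt = df["alt_depth"].to_numpy(dtype=np.int64)
    n = ref + alt
    usable = n >= min_depth
    ref, alt, n = ref[usable], alt[usable], n[usable]
    if len(n) == 0:
        raise ValueError("no usable heterozygous sites at the requested depth")
    if method == "threshold":
        minor = np.minimum(ref, alt)
        p_hat = float(np.mean(minor / n <= dropout_max_minor_frac))
        return p_hat, int(len(n))
    if method != "mle":
        raise ValueError(f"unknown ADO estimation method {method!r}")

    eps = (params or LodModelParams()).eps

    log_drop_ref = binom.logpmf(alt, n, eps)        # alt allele dropped
    log_drop_alt = binom.logpmf(alt, n, 1.0 - eps)  # ref allele dropped
    log_choose = gammaln(n + 1) - gammaln(alt + 1) - gammaln(ref + 1)

    def neg_loglik(theta: np.ndarray) -> float:
        p = 1.0 / (1.0 + np.exp(-theta[0]))       # logit
        alpha = np.exp(theta[1])                   # log
        log_both = log_choose + betaln(alt + alpha, ref + alpha) - betaln(alpha, alpha)
        stack = np.stack([
            np.log(p / 2.0) + log_drop_ref,
            np.log(p / 2.0) + log_drop_alt,
            np.log1p(-p) + log_both,
        ])
        return -float(np.sum(logsumexp(stack, axis=0)))

    best = None
    for p0 in (0.1, 0.3):
        res = optimize.minimize(
            neg_loglik, x0=np.array([np.log(p0 / (1 - p0)), np.log(2.0)]),
            method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    p_hat = float(1.0 / (1.0 + np.exp(-best.x[0])))
    return p_hat, int(len(n))


# ---------------------------------------------------------------------------
# Table-level scoring
# ---------------------------------------------------------------------------


def lod_scores(
    ref_depth: np.ndarray, alt_depth: np.ndarray, params: LodModelParams
) -> np.ndarray:
    """Vectorised untruncated LOD over parallel depth arrays."""
    ref = np.asarray(ref_depth, dtype=np.int64)
    alt = np.asarray(alt_depth, dtype=np.int64)
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("read depths must be non-negative")
    n = ref + alt
    eps = params.eps
    log_norm = binom.logpmf(alt, n, eps)
    p = params.ado_rate
    alpha = params.amp_imbalance_alpha
    if np.isinf(alpha):
        log_both = (
            gammaln(n + 1) - gammaln(alt + 1) - gammaln(ref + 1) - n * np.log(2.0)
        )
    else:
        log_both = betabinom.logpmf(alt, n, alpha, alpha)
    parts = [np.log1p(-p) + log_both] if p < 1 else []
    if p > 0:
        parts.append(np.log(p / 2.0) + log_norm)
        parts.append(np.log(p / 2.0) + binom.logpmf(alt, n, 1.0 - eps))
    log_mut = logsumexp(np.stack(parts), axis=0)
    out = (log_mut - log_norm) / LOG10 + params.log10_prior_odds
    return np.where(n == 0, params.log10_prior_odds, out)


def score_table(
    counts: AlleleCountTable,
    params: LodModelParams,
    sample_ids: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Score every (sample, locus) row of an allele-count table.

    Returns a DataFrame with columns ``sample_id chrom pos ref alt
    ref_depth alt_depth lod lod_raw supported called``; ``lod`` is the
    truncated display score, ``lod_raw`` the untruncated one used for
    thresholding.
    """
    df = counts.df
    if sample_ids is not None:
        df = df[df.sample_id.isin(sample_ids)]
    out = df.copy()
    out["lod_raw"] = lod_scores(
        out.ref_depth.to_numpy(), out.alt_depth.to_numpy(), params
    )
    out["lod"] = np.minimum(out["lod_raw"], params.lod_cap)
    out["supported"] = out.alt_depth >= params.support_min_alt
    out["called"] = out.lod_raw >= params.call_threshold
    return out.reset_index(drop=True)


def calls_from_lod(scored: pd.DataFrame, sample_id: str):
    """Build a VariantCallSet from the internal caller's scored table."""
    from .io_model import VariantCallSet

    sub = scored[(scored.sample_id == sample_id) & scored.called]
    return VariantCallSet(
        sample_id,
        {
            Locus(r.chrom, int(r.pos), r.ref, r.alt): float(r.lod_raw)
            for r in sub.itertuples(index=False)
        },
    )
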