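"""End-to-end orchestration: simulate -> qc -> genotype -> concord -> sv -> report.

``run_all`` executes the whole analysis on a simulated dataset (the
worked-example fixture path runs the same stages on the deterministic
fixture) and writes every stage artifact under one output directory:
per-sample QC JSON, the per-(sample, locus) LOD table, the founder and
clonal tracing tables, the accumulation curve, the SV match report and
an aggregate JSON + markdown report.  Runs are deterministic given
(config, seed); logs carry the stage name and a config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import concordance, qc_metrics, sv_concordance
from .genotyping import LodModelParams, calls_from_lod, estimate_ado, score_table
from .io_model import AlleleCountTable, VariantCallSet
from .synthetic_data import (
    PaperFixture,
    SimConfig,
    SimulatedDataset,
    make_paper_fixture,
    simulate_dataset,
    write_dataset,
)

logger = logging.getLogger("ctcwgs")


def configure_logging(logfile: Optional[Path] = None, level: int = logging.INFO) -> None:
    fmt = logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s %(message)s", datefmt="%Y-%m-%dT%H:%M:%S"
    )
    logger.setLevel(level)
    logger.handlers.clear()
    stream = logging.StreamHandler(sys.stderr)
    stream.setFormatter(fmt)
    logger.addHandler(stream)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


@dataclass
class RunConfig:
    """Single-document configuration of an end-to-end run."""

    sim: SimConfig = field(default_factory=SimConfig)
    lod: LodModelParams = field(default_factory=LodModelParams)
    k_clonal: int = 3
    sv_tol_bp: int = 0
    sv_min_support: int = 2
    sv_size_range: tuple[int, int] = (600, 2000)
    estimate_ado_from_data: bool = True

    def config_hash(self) -> str:
        doc = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        sim_doc = doc.get("sim", {})
        for tup_key in ("founder_af_beta", "private_af_beta", "gc_beta",
                        "sv_short_size_range"):
            if tup_key in sim_doc:
                sim_doc[tup_key] = tuple(sim_doc[tup_key])
        if "gene_intervals" in sim_doc:
            sim_doc["gene_intervals"] = {
                g: tuple(v) for g, v in sim_doc["gene_intervals"].items()
            }
        if sim_doc.get("amp_imbalance_alpha") == "inf":
            sim_doc["amp_imbalance_alpha"] = float("inf")
        lod_doc = doc.get("lod", {})
        if lod_doc.get("amp_imbalance_alpha") == "inf":
            lod_doc["amp_imbalance_alpha"] = float("inf")
        kwargs = {
            k: v for k, v in doc.items()
            if k in {"k_clonal", "sv_tol_bp", "sv_min_support", "estimate_ado_from_data"}
        }
        if "sv_size_range" in doc:
            kwargs["sv_size_range"] = tuple(doc["sv_size_range"])
        return cls(sim=SimConfig(**sim_doc), lod=LodModelParams(**lod_doc), **kwargs)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and np.isinf(obj):
        return "inf"
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------


def run_qc_stage(dataset: SimulatedDataset) -> dict[str, qc_metrics.QcReport]:
    """Coverage QC for every sample, GC correlation against the WBC control."""
    control = dataset.tracks.get("WBC")
    reports = {}
    for sid, track in dataset.tracks.items():
        ctrl = control if (control is not None and sid != "WBC") else None
        reports[sid] = qc_metrics.qc_report(sid, track, control_track=ctrl)
    return reports


def run_genotype_stage(
    dataset: SimulatedDataset, params: LodModelParams, estimate_from_data: bool = True
) -> tuple[pd.DataFrame, dict, LodModelParams]:
    """LOD-score every CTC locus; optionally re-estimate the ADO rate
    from germline het sites confirmed in both controls first."""
    ctc_ids = [s.sample_id for s in dataset.manifest.ctcs]
    ado_estimates = {}
    if estimate_from_data and ctc_ids:
        germ = dataset.truth.variants[dataset.truth.variants.tier == "germline_het"]
        key = pd.MultiIndex.from_frame(germ[["chrom", "pos"]])
        for sid in ctc_ids:
            sub = dataset.counts.for_sample(sid)
            mask = pd.MultiIndex.from_frame(sub[["chrom", "pos"]]).isin(key)
            het_sub = sub[mask]
            # cap the fit size; the estimator is stable beyond a few
            # thousand sites and the fit cost is linear in sites
            p_hat, n_used = estimate_ado(het_sub.head(5000), params=params)
            ado_estimates[sid] = {"p_hat": p_hat, "n_sites": n_used}
        p_mean = float(np.mean([v["p_hat"] for v in ado_estimates.values()]))
        params = dataclasses.replace(params, ado_rate=p_mean)
        logger.info("genotype: ADO re-estimated, pooled p=%.3f", p_mean)
    ctc_counts = AlleleCountTable(
        dataset.counts.df[dataset.counts.df.sample_id.isin(ctc_ids)]
    )
    scored = score_table(ctc_counts, params)
    return scored, ado_estimates, params


def run_concordance_stage(
    dataset: SimulatedDataset,
    scored: pd.DataFrame,
    params: LodModelParams,
    k_clonal: int = 3,
) -> dict:
    """Founder/clonal classification, bidirectional tracing, accumulation
    curve, AF-recurrence association and founder recovery vs truth."""
    manifest = dataset.manifest
    manifest.validate_for_concordance()
    ctc_ids = [s.sample_id for s in manifest.ctcs]
    control_loci = dataset.calls["WBC"].loci | dataset.calls["NORMAL"].loci
    calls = dict(dataset.calls)
    for sid in ctc_ids:
        # somatic CTC calls: LOD calls minus germline evidence in controls
        raw = calls_from_lod(scored, sid)
        calls[sid] = VariantCallSet(
            sid, {l: s for l, s in raw.scores.items() if l not in control_loci}
        )

    founders = concordance.identify_founders(
        calls["PRIMARY"], calls["MET"], [calls["WBC"], calls["NORMAL"]]
    )
    clonal = concordance.identify_clonal([calls[s] for s in ctc_ids], k=k_clonal)

    founder_tracing = concordance.trace(
        founders, dataset.counts, calls, params, sample_ids=ctc_ids
    )
    clonal_tracing = concordance.trace(
        clonal, dataset.counts, calls, params, sample_ids=["PRIMARY", "MET"]
    )
    summary = concordance.summarize(founder_tracing, clonal_tracing, ctc_ids)

    curve = concordance.accumulation_curve(founder_tracing, ctc_ids, mode="supported")

    true_founders = dataset.truth.loci("founder")
    recovered = founders & true_founders
    summary.extras["founder_recovery"] = {
        "n_true": len(true_founders),
        "n_identified": len(founders),
        "n_recovered": len(recovered),
        "pct_recovered": concordance.percentage(len(recovered), len(true_founders)),
    }
    # AF vs CTC recurrence over the full tissue-somatic spectrum: founders
    # (high AF, carried by every cell) plus lesion-private calls (sub-clonal
    # AF, carried by a lineage-dependent subset of cells)
    tissue_somatic = (
        (calls["PRIMARY"].loci | calls["MET"].loci)
        - calls["WBC"].loci - calls["NORMAL"].loci
    )
    somatic_tracing = concordance.trace(
        tissue_somatic, dataset.counts, calls, params, sample_ids=ctc_ids
    )
    try:
        rho, n_assoc = concordance.af_recurrence_association(somatic_tracing, ctc_ids)
    except ValueError:
        rho, n_assoc = None, 0
    summary.extras["af_recurrence"] = {"spearman_rho": rho, "n": n_assoc}
    return {
        "founders": founders,
        "clonal": clonal,
        "founder_tracing": founder_tracing,
        "clonal_tracing": clonal_tracing,
        "summary": summary,
        "accumulation": curve,
    }


def run_sv_stage(dataset: SimulatedDataset, config: RunConfig) -> dict:
    """Cluster SV callsets across samples, verify support, classify
    sizes and screen tumor-suppressor genes."""
    callsets = {}
    for rec, carriers in dataset.sv_records:
        for sid in carriers:
            callsets.setdefault(sid, []).append(rec)
    report = sv_concordance.match_breakpoints(
        callsets, dataset.manifest, tol_bp=config.sv_tol_bp
    )
    sv_concordance.annotate_support(report, dataset.sv_evidence)
    all_records = [rec for recs in callsets.values() for rec in recs]
    sizes = sv_concordance.classify_short_svs(all_records, config.sv_size_range)
    genes = sv_concordance.screen_genes(callsets, dataset.config.gene_intervals)
    return {
        "report": report,
        "size_classes": {k: len(v) for k, v in sizes.items()},
        "gene_screen": genes,
    }


# ---------------------------------------------------------------------------
# run_all + report
# ---------------------------------------------------------------------------


def run_all(config: RunConfig, outdir: str | Path, write_inputs: bool = False) -> dict:
    """Execute every stage on a simulated dataset and write the bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    logger.info("run_all: seed=%d config=%s", config.sim.seed, chash)

    stage = "simulate"
    try:
        dataset = simulate_dataset(config.sim)
        if write_inputs:
            write_dataset(dataset, outdir / "inputs")

        stage = "qc"
        qc_reports = run_qc_stage(dataset)
        qc_doc = {sid: r.to_dict() for sid, r in qc_reports.items()}
        _write_json(qc_doc, outdir / "qc_report.json")

        stage = "genotype"
        scored, ado_estimates, params = run_genotype_stage(
            dataset, config.lod, config.estimate_ado_from_data
        )
        scored.to_csv(outdir / "lod_scores.tsv", sep="\t", index=False)

        stage = "concord"
        conc = run_concordance_stage(dataset, scored, params, config.k_clonal)
        conc["founder_tracing"].df.to_csv(outdir / "founder_tracing.tsv", sep="\t", index=False)
        conc["clonal_tracing"].df.to_csv(outdir / "clonal_tracing.tsv", sep="\t", index=False)
        conc["accumulation"].to_csv(outdir / "accumulation.tsv", sep="\t", index=False)
        summary_doc = conc["summary"].to_dict()
        summary_doc["ado_estimates"] = ado_estimates
        _write_json(summary_doc, outdir / "concordance_summary.json")

        stage = "sv"
        sv = run_sv_stage(dataset, config)
        sv["report"].to_frame().to_csv(outdir / "sv_clusters.tsv", sep="\t", index=False)
        sv["gene_screen"].to_csv(outdir / "sv_gene_screen.tsv", sep="\t", index=False)
        sv_doc = {
            "n_clusters": len(sv["report"].clusters),
            "n_shared_all_tumor": len(sv["report"].by_class("shared_all_tumor")),
            "size_classes": sv["size_classes"],
            "clusters": json.loads(sv["report"].to_frame().to_json(orient="records")),
        }
        _write_json(sv_doc, outdir / "sv_report.json")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed (outdir={outdir}): {exc}") from exc

    bundle = {
        "seed": config.sim.seed,
        "config_hash": chash,
        "qc": qc_doc,
        "concordance": summary_doc,
        "sv": sv_doc,
        "accumulation": json.loads(conc["accumulation"].to_json(orient="records")),
    }
    report_doc = report(bundle)
    _write_json(report_doc, outdir / "report.json")
    (outdir / "report.md").write_text(render_markdown(report_doc))
    return bundle


def report(bundle: dict) -> dict:
    """Aggregate stage outputs into one report document.

    Never recomputes statistics; stages missing from the bundle are
    listed as absent rather than fabricated.
    """
    sections = ("qc", "concordance", "sv", "accumulation")
    doc = {
        "seed": bundle.get("seed"),
        "config_hash": bundle.get("config_hash"),
        "absent_sections": [s for s in sections if s not in bundle],
    }
    for s in sections:
        if s in bundle:
            doc[s] = bundle[s]
    return doc


def render_markdown(doc: dict) -> str:
    lines = ["# Single-CTC concordance report", ""]
    lines.append(f"seed: {doc.get('seed')}  config: {doc.get('config_hash')}")
    if doc.get("absent_sections"):
        lines.append(f"absent sections: {', '.join(doc['absent_sections'])}")
    if "qc" in doc:
        lines += ["", "## Coverage QC", "",
                  "| sample | mean depth | breadth >=1 | frac >10X | Gini | GC corr |",
                  "|---|---|---|---|---|---|"]
        for sid, r in doc["qc"].items():
            corr = r.get("gc_correlation_vs_control")
            lines.append(
                f"| {sid} | {r['mean_depth']:.1f} | {r['breadth_ge1']:.3f} "
                f"| {r['frac_ge10']:.3f} | {r['gini']:.3f} "
                f"| {'' if corr is None else format(corr, '.4f')} |"
            )
    if "concordance" in doc:
        c = doc["concordance"]
        lines += ["", "## SSNV concordance", ""]
        lines.append(
            f"- founders: {c['n_founder']}; supported in >=1 CTC: "
            f"{c['n_founder_supported_union']} ({c['pct_founder_supported']}%), "
            f"of which caller-flagged: {c['n_founder_called_union']}"
        )
        lines.append(
            f"- clonal CTC SSNVs: {c['n_clonal']}; supported in tissue: "
            f"{c['n_clonal_supported_in_tissue']} ({c['pct_clonal_supported']}%); "
            f"called in tissue: {c['n_clonal_called_in_tissue']} ({c['pct_clonal_called']}%)"
        )
        if "founder_recovery" in c:
            r = c["founder_recovery"]
            lines.append(
                f"- founder recovery vs truth: {r['n_recovered']}/{r['n_true']} "
                f"({r['pct_recovered']}%)"
            )
        if "af_recurrence" in c:
            a = c["af_recurrence"]
            lines.append(
                f"- allele fraction vs CTC recurrence: Spearman rho = {a['spearman_rho']}"
                f" (n = {a['n']})"
            )
    if "sv" in doc:
        s = doc["sv"]
        lines += ["", "## Structural variants", ""]
        lines.append(
            f"- clusters: {s['n_clusters']}; shared across all tumor samples: "
            f"{s['n_shared_all_tumor']}; size classes: {s['size_classes']}"
        )
    return "\n".join(lines) + "\n"


def run_fixture(outdir: str | Path, params: Optional[LodModelParams] = None) -> dict:
    """Run the tracing analysis on the deterministic worked-example
    fixture and write its summary (the regression path)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params or LodModelParams()
    fixture = make_paper_fixture()
    summary = fixture_summary(fixture, params)
    _write_json(summary, outdir / "fixture_summary.json")
    return summary


def fixture_summary(fixture: PaperFixture, params: Optional[LodModelParams] = None) -> dict:
    """Compute every worked-example count/percentage from the fixture."""
    params = params or LodModelParams()
    ctc_ids = fixture.ctc_ids
    founders = concordance.identify_founders(
        fixture.calls["PRIMARY"], fixture.calls["MET"],
        [fixture.calls["WBC"], fixture.calls["NORMAL"]],
    )
    clonal = concordance.identify_clonal([fixture.calls[s] for s in ctc_ids], k=3)
    founder_tracing = concordance.trace(
        founders, fixture.counts, fixture.calls, params, sample_ids=ctc_ids
    )
    clonal_tracing = concordance.trace(
        clonal, fixture.counts, fixture.calls, params, sample_ids=["PRIMARY", "MET"]
    )
    summary = concordance.summarize(founder_tracing, clonal_tracing, ctc_ids)
    curve = concordance.accumulation_curve(founder_tracing, ctc_ids, mode="supported")
    n_clean, n_total, pct_clean = concordance.germline_check(
        fixture.exonic_ssnvs, fixture.wbc_wes_calls
    )
    n_conf, n_val, pct_conf = concordance.validation_summary(fixture.validation)
    doc = summary.to_dict()
    doc["germline_check"] = {"n_clean": n_clean, "n_total": n_total, "pct": pct_clean}
    doc["validation"] = {"n_confirmed": n_conf, "n_total": n_val, "pct": pct_conf}
    doc["accumulation_supported"] = json.loads(curve.to_json(orient="records"))
    return doc


def _write_json(doc: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(doc), fh, indent=1, sort_keys=False)
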