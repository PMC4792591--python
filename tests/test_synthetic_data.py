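"""The generator: determinism, tier structure, emission-channel
calibration and SV truth properties."""

import dataclasses

import numpy as np
import pytest

from ctcwgs.synthetic_data import (
    BRANCH_BOTH,
    SimConfig,
    make_paper_fixture,
    simulate_bulk_counts,
    simulate_cell_counts,
    simulate_dataset,
    simulate_sv_truth,
    simulate_truth,
)


class TestTruth:
    def test_default_founder_count(self):
        truth = simulate_truth(SimConfig(seed=0, n_germline_het=1000, genome_bins=600))
        assert truth.tier_counts()["founder"] == 802

    def test_tier_counts_match_config(self, small_config, small_truth):
        counts = small_truth.tier_counts()
        assert counts["germline_het"] == small_config.n_germline_het
        assert counts["founder"] == small_config.n_founder
        assert counts["primary_private"] == small_config.n_primary_private
        assert counts["met_private"] == small_config.n_met_private
        assert counts["cell_private"] == (
            small_config.n_ctc * small_config.n_cell_private_per_ctc
        )

    def test_no_ctc_means_no_cell_private(self):
        cfg = SimConfig(seed=0, n_ctc=0, n_germline_het=100, genome_bins=300)
        truth = simulate_truth(cfg)
        assert "cell_private" not in truth.tier_counts()

    def test_same_seed_identical(self, small_config):
        a = simulate_truth(small_config)
        b = simulate_truth(small_config)
        assert a.variants.equals(b.variants)
        assert [(r.pos_a, r.pos_b) for r, _ in a.breakpoints] == [
            (r.pos_a, r.pos_b) for r, _ in b.breakpoints
        ]

    def test_tier_exclusivity(self, small_truth):
        key = small_truth.variants[["chrom", "pos"]]
        assert not key.duplicated().any()

    def test_af_structure(self, small_truth):
        v = small_truth.variants
        f = v[v.tier == "founder"]
        assert (f.af_primary > 0).all() and (f.af_met > 0).all()
        pp = v[v.tier == "primary_private"]
        assert (pp.af_met == 0).all() and (pp.af_primary > 0).all()
        mp = v[v.tier == "met_private"]
        assert (mp.af_primary == 0).all() and (mp.af_met > 0).all()
        g = v[v.tier == "germline_het"]
        assert (g.af_primary == 0.5).all()
        # germline and founders carried by every cell
        cells = {f"CTC-{i+1}" for i in range(4)}
        assert all(s == cells for s in v[v.tier.isin(["germline_het", "founder"])].carried_by)

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_truth(SimConfig(genome_bins=1, n_germline_het=10**6))


class TestBulkEmission:
    def test_degenerate_fractions(self):
        cfg = SimConfig(
            seed=2, genome_bins=300, n_germline_het=200, n_founder=100,
            n_primary_private=0, n_met_private=0, n_ctc=0,
            n_cell_private_per_ctc=0, seq_error=0.0, bulk_purity=1.0,
            founder_af_beta=(1e6, 1e-9),  # degenerate: clonal fraction -> 1
        )
        truth = simulate_truth(cfg)
        counts = simulate_bulk_counts(truth, cfg)
        wbc = counts.for_sample("WBC").merge(
            truth.variants[["chrom", "pos", "tier"]], on=["chrom", "pos"]
        )
        # f=0, e=0 at somatic loci in controls: alt always 0
        assert (wbc[wbc.tier == "founder"].alt_depth == 0).all()

    def test_binomial_mean_conservation(self):
        """Empirical alt fraction at f=0.5 with n ~ 1e6 total reads sits
        within 3 sigma of the f(1-e) + (1-f)e/3 expectation."""
        cfg = SimConfig(
            seed=3, genome_bins=3000, n_germline_het=30_000, n_founder=0,
            n_primary_private=0, n_met_private=0, n_ctc=0,
            n_cell_private_per_ctc=0, bulk_depth_mean=34, depth_dispersion=0.0,
        )
        truth = simulate_truth(cfg)
        counts = simulate_bulk_counts(truth, cfg).for_sample("WBC")
        tot = (counts.ref_depth + counts.alt_depth).sum()
        assert tot > 10**6
        e = cfg.seq_error
        expect = 0.5 * (1 - e) + 0.5 * e / 3
        frac = counts.alt_depth.sum() / tot
        sigma = np.sqrt(expect * (1 - expect) / tot)
        assert abs(frac - expect) < 3 * sigma


class TestCellEmission:
    def _het_only_config(self, **kw):
        base = dict(
            seed=4, genome_bins=600, n_germline_het=4000, n_founder=0,
            n_primary_private=0, n_met_private=0, n_ctc=1,
            n_cell_private_per_ctc=0, cell_depth_mean=30, depth_dispersion=0.0,
        )
        base.update(kw)
        return SimConfig(**base)

    def test_full_ado_single_allele_only(self):
        cfg = self._het_only_config(ado_rate=1.0, seq_error=0.0, mda_error=0.0)
        truth = simulate_truth(cfg)
        t = simulate_cell_counts(truth, "CTC-1", cfg)
        minor = np.minimum(t.df.ref_depth, t.df.alt_depth)
        assert (minor == 0).all()

    def test_no_ado_binomial_limit_is_balanced(self):
        cfg = self._het_only_config(
            ado_rate=0.0, amp_imbalance_alpha=np.inf, seq_error=0.0, mda_error=0.0,
            n_germline_het=20_000,
        )
        truth = simulate_truth(cfg)
        t = simulate_cell_counts(truth, "CTC-1", cfg)
        tot = (t.df.ref_depth + t.df.alt_depth).sum()
        frac = t.df.alt_depth.sum() / tot
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / tot)

    def test_mda_error_rate_recovered(self):
        """1e7 hom-ref bases with e=0, e_mda=1e-5: empirical alt rate
        within the Poisson 99% band around 1e-5."""
        cfg = SimConfig(
            seed=3, genome_bins=30_000, n_germline_het=0, n_founder=0,
            n_primary_private=100_000, n_met_private=0, n_ctc=1,
            n_cell_private_per_ctc=0, seq_error=0.0, mda_error=1e-5,
            cell_depth_mean=100, depth_dispersion=0.0,
        )
        # primary-private loci are not carried by the (met-lineage) cell,
        # so every base is hom-ref
        truth = simulate_truth(cfg)
        t = simulate_cell_counts(truth, "CTC-1", cfg)
        tot = int((t.df.ref_depth + t.df.alt_depth).sum())
        alt = int(t.df.alt_depth.sum())
        assert tot >= 9_000_000
        lam = tot * 1e-5
        assert abs(alt - lam) < 3 * np.sqrt(lam)

    def test_ado_branch_fraction_converges(self):
        """The fraction of het loci with true single-allele emission
        matches the configured p within 3 sigma at 1e5 loci."""
        cfg = self._het_only_config(n_germline_het=100_000, genome_bins=3000, ado_rate=0.2)
        truth = simulate_truth(cfg)
        _, branch, is_het = simulate_cell_counts(truth, "CTC-1", cfg, return_branches=True)
        frac = (branch[is_het] != BRANCH_BOTH).mean()
        n = is_het.sum()
        assert abs(frac - 0.2) < 3 * np.sqrt(0.2 * 0.8 / n)

    def test_unknown_cell_rejected(self, small_truth, small_config):
        with pytest.raises(ValueError, match="cell_id"):
            simulate_cell_counts(small_truth, "CTC-99", small_config)


class TestSvTruth:
    def test_shared_records_identical_across_carriers(self, small_config):
        records, evidence = simulate_sv_truth(small_config)
        shared = [(r, c) for r, c in records if r.name.startswith("SV_SHARED")]
        assert len(shared) == small_config.sv_shared == 2
        tumor = {"PRIMARY", "MET", "CTC-1", "CTC-2", "CTC-3", "CTC-4"}
        for rec, carriers in shared:
            assert set(carriers) == tumor
        # evidence present for every carrier of every record
        for rec, carriers in records:
            for sid in carriers:
                sub = evidence[(evidence.sv_name == rec.name) & (evidence.sample_id == sid)]
                assert len(sub) == small_config.sv_evidence_reads

    def test_private_sizes_within_range(self, small_config):
        records, _ = simulate_sv_truth(small_config)
        lo, hi = small_config.sv_short_size_range
        privates = [r for r, c in records if len(c) == 1]
        assert privates
        assert all(lo <= r.size <= hi for r in privates)

    def test_no_private_svs_when_disabled(self):
        cfg = SimConfig(seed=0, sv_private_short=0, genome_bins=300, n_germline_het=10)
        records, _ = simulate_sv_truth(cfg)
        assert all(r.name.startswith("SV_SHARED") for r, _ in records)

    def test_controls_never_carry(self, small_config):
        records, evidence = simulate_sv_truth(small_config)
        for _, carriers in records:
            assert not ({"WBC", "NORMAL"} & set(carriers))
        assert not evidence.sample_id.isin(["WBC", "NORMAL"]).any()

    def test_gene_interval_too_small_rejected(self):
        with pytest.raises(ValueError, match="smaller than max SV size"):
            SimConfig(gene_intervals={"PTEN": ("chr1", 100, 1000)})


def test_dataset_determinism(tmp_path, small_config):
    from ctcwgs.synthetic_data import write_dataset

    a = simulate_dataset(small_config)
    b = simulate_dataset(small_config)
    assert a.counts == b.counts
    write_dataset(a, tmp_path / "a")
    write_dataset(b, tmp_path / "b")
    for name in ("allele_counts.tsv", "truth.json", "svs.bedpe", "WBC.bedgraph"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_paper_fixture_structure(paper_fixture):
    assert len(paper_fixture.manifest) == 8
    assert len(paper_fixture.exonic_ssnvs) == 777
    assert len(paper_fixture.validation) == 25
    # a second build is byte-identical
    again = make_paper_fixture()
    assert again.counts == paper_fixture.counts
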