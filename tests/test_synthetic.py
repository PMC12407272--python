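"""Generator structure: determinism, truth-table coverage, parameter targets."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import curve_fit

from subdom.synthetic import (
    SimConfig,
    distance_to_nearest,
    generate_dataset,
    simulate_acrs_and_variants,
    simulate_expression,
    simulate_genome_and_genes,
    simulate_m6a,
    simulate_methylome,
    simulate_tes,
)


def _sha_dir(d):
    return {f.name: hashlib.sha256(f.read_bytes()).hexdigest()
            for f in sorted(Path(d).iterdir())}


def test_identical_seeds_give_byte_identical_bundles(tmp_path):
    cfg = SimConfig(n_chrom_per_subgenome=1, genes_per_chrom=80, seed=3)
    generate_dataset(cfg, outdir=tmp_path / "a")
    generate_dataset(cfg, outdir=tmp_path / "b")
    assert _sha_dir(tmp_path / "a") == _sha_dir(tmp_path / "b")


def test_different_seeds_differ(tmp_path):
    generate_dataset(SimConfig(n_chrom_per_subgenome=1, genes_per_chrom=80,
                               seed=3), outdir=tmp_path / "a")
    generate_dataset(SimConfig(n_chrom_per_subgenome=1, genes_per_chrom=80,
                               seed=4), outdir=tmp_path / "b")
    assert _sha_dir(tmp_path / "a") != _sha_dir(tmp_path / "b")


def test_infeasible_geometry_raises():
    with pytest.raises(ValueError, match="geometry"):
        SimConfig(gene_len_bp=3900, gene_spacing_bp=4000)
    with pytest.raises(ValueError, match="UTR"):
        SimConfig(gene_len_bp=1000, utr5_len_bp=600, utr3_len_bp=500)


def test_truth_tables_cover_every_unit(small_bundle):
    b = small_bundle
    # pair classes partition the ancestral slots
    assert set(b.truth_pairs["class"]) <= {"both", "A_only", "B_only"}
    n_slots = b.config.n_chrom_per_subgenome * b.config.genes_per_chrom
    assert len(b.truth_pairs) == n_slots
    # every pair has a bias-truth row, every gene a DEG-truth row
    pairs = b.truth_pairs[b.truth_pairs["class"] == "both"]
    assert len(b.truth_bias) == len(pairs)
    assert set(b.truth_deg["gene_id"]) == set(b.genes["gene_id"])
    # every ACR name resolves to a truth row, every peak to a gene
    acr_ids = set(b.truth_acrs["acr_id"])
    assert all(n.rsplit("_", 1)[0] in acr_ids for n in b.acrs.df["name"])
    assert set(b.truth_peaks["gene_id"]) <= set(b.genes["gene_id"])


def test_all_pairs_no_bias_limits():
    cfg = SimConfig(n_chrom_per_subgenome=1, genes_per_chrom=200,
                    pair_fraction=1.0, bias_fraction=0.0, seed=5)
    _, genes, anc, _ = simulate_genome_and_genes(cfg)
    assert (anc["class"] == "both").all()
    _, _, truth_bias, _ = simulate_expression(genes, anc, cfg)
    assert (truth_bias["bias_class"] == "unbiased").all()


def test_realized_bias_fraction_concentrates():
    cfg = SimConfig(n_chrom_per_subgenome=2, genes_per_chrom=2500,
                    pair_fraction=1.0, seed=17)
    _, genes, anc, _ = simulate_genome_and_genes(cfg)
    _, _, truth_bias, _ = simulate_expression(genes, anc, cfg)
    frac = (truth_bias["bias_class"] != "unbiased").mean()
    n = len(truth_bias)
    assert abs(frac - 0.70) <= 3 * np.sqrt(0.7 * 0.3 / n)


def test_nb_counts_match_dispersion_moment():
    # flat means isolate the gamma-Poisson variance: var/mean = 1 + mean*phi
    cfg = SimConfig(n_chrom_per_subgenome=2, genes_per_chrom=2500,
                    expr_log_sd=1e-9, tissue_log_sd=1e-9, bias_fraction=0.0,
                    deg_fraction_A=0.0, deg_fraction_B=0.0, seed=2)
    _, genes, anc, _ = simulate_genome_and_genes(cfg)
    counts, samples, _, _ = simulate_expression(genes, anc, cfg)
    x = counts.to_numpy(float)
    mean, var = x.mean(), x.var()
    phi_hat = (var / mean - 1) / mean
    assert phi_hat == pytest.approx(cfg.nb_dispersion, rel=0.10)


def test_bias_effect_is_planted_symmetrically():
    cfg = SimConfig(n_chrom_per_subgenome=1, genes_per_chrom=500,
                    pair_fraction=1.0, bias_fraction=1.0, bias_toward_A=1.0,
                    nb_dispersion=1e-6, expr_mean=2000.0, seed=8)
    _, genes, anc, _ = simulate_genome_and_genes(cfg)
    counts, samples, truth_bias, _ = simulate_expression(genes, anc, cfg)
    tissue_cols = samples.loc[samples["condition"] == "none", "sample"]
    mean_a = counts.loc[truth_bias["gene_A"], tissue_cols].mean(axis=1).to_numpy()
    mean_b = counts.loc[truth_bias["gene_B"], tissue_cols].mean(axis=1).to_numpy()
    lfc = np.log2(mean_a / mean_b)
    assert np.corrcoef(lfc, truth_bias["log2fc_AB"])[0, 1] > 0.95
    assert np.median(lfc - truth_bias["log2fc_AB"]) == pytest.approx(0.0, abs=0.1)


class TestMethylome:
    def test_plateau_inside_te_and_background_far_away(self, small_bundle):
        b = small_bundle
        cg = b.methylation[b.methylation["context"] == "CG"]
        from subdom.repeats import _merge
        inside_mc = inside_tot = far_mc = far_tot = 0
        for chrom, sub in cg.groupby("chrom"):
            te = b.tes.df[b.tes.df["chrom"] == chrom]
            ivs = _merge(te[["start", "end"]].to_numpy())
            d = distance_to_nearest(sub["pos"].to_numpy(float), ivs)
            inside = d == 0
            far = d > 6 * b.config.meth_decay_bp
            inside_mc += sub["mc_count"].to_numpy()[inside].sum()
            inside_tot += sub["total_count"].to_numpy()[inside].sum()
            far_mc += sub["mc_count"].to_numpy()[far].sum()
            far_tot += sub["total_count"].to_numpy()[far].sum()
        assert inside_mc / inside_tot == pytest.approx(
            b.config.meth_te_level["CG"], abs=0.01)
        assert far_mc / far_tot == pytest.approx(
            b.config.meth_background["CG"], abs=0.01)

    def test_decay_length_recovered_by_fit(self, medium_bundle):
        b = medium_bundle
        cg = b.methylation[b.methylation["context"] == "CG"]
        from subdom.repeats import _merge
        dist, level = [], []
        for chrom, sub in cg.groupby("chrom"):
            te = b.tes.df[b.tes.df["chrom"] == chrom]
            ivs = _merge(te[["start", "end"]].to_numpy())
            d = distance_to_nearest(sub["pos"].to_numpy(float), ivs)
            ok = (sub["total_count"].to_numpy() > 0) & np.isfinite(d) & (d < 4000)
            dist.append(d[ok])
            level.append(sub["mc_count"].to_numpy()[ok]
                         / sub["total_count"].to_numpy()[ok])
        d = np.concatenate(dist)
        lv = np.concatenate(level)

        def model(x, bg, plateau, lam):
            return bg + (plateau - bg) * np.exp(-x / lam)

        popt, _ = curve_fit(model, d, lv, p0=[0.2, 0.8, 300.0],
                            bounds=([0, 0, 10], [1, 1, 5000]))
        assert popt[2] == pytest.approx(b.config.meth_decay_bp, rel=0.15)


class TestAcrsVariants:
    def test_no_loss_means_all_conserved(self):
        cfg = SimConfig(n_chrom_per_subgenome=1, genes_per_chrom=200,
                        pair_fraction=1.0, acr_prob_A=1.0, acr_prob_B=1.0,
                        acr_indel_loss_prob=0.0, seed=4)
        _, genes, anc, _ = simulate_genome_and_genes(cfg)
        _, _, truth = simulate_acrs_and_variants(genes, anc, cfg)
        assert (truth["class"] == "conserved").all()

    def test_perfect_ancestry_match(self):
        cfg = SimConfig(n_chrom_per_subgenome=1, genes_per_chrom=200,
                        ancestry_match_p=1.0, var_missing_p=0.0, seed=4)
        _, genes, anc, _ = simulate_genome_and_genes(cfg)
        _, variants, _ = simulate_acrs_and_variants(genes, anc, cfg)
        spec = variants[variants["acr_class"].str.endswith("specific")]
        carrier_prog = np.where(spec["carrier"] == "A", spec["progA"],
                                spec["progB"])
        carrier_sub = np.where(spec["carrier"] == "A", spec["subA"],
                               spec["subB"])
        assert (carrier_prog == carrier_sub).all()

    def test_indel_loss_recorded_as_insertion_variant(self, small_bundle):
        b = small_bundle
        indels = b.variants[b.variants["type"] == "InDel"]
        lost = b.truth_acrs[b.truth_acrs["cause"] == "indel"]
        assert len(indels) == len(lost)
        assert (indels["alt"].str.len()
                == 1 + b.config.indel_len_bp).all()
        assert (indels["subB"] == "alt").all()


class TestM6A:
    def test_planted_sharing_structure(self):
        # pair-level shared / A-only / B-only split concentrates at the
        # configured 0.82 / 0.15 / 0.03 (binomial 3 sigma at ~2,900
        # methylated pairs is under 0.022)
        cfg = SimConfig(n_chrom_per_subgenome=2, genes_per_chrom=4000, seed=13)
        _, genes, anc, models = simulate_genome_and_genes(cfg)
        _, _, truth_bias, td = simulate_expression(genes, anc, cfg)
        _, truth_peaks = simulate_m6a(models, anc, td, cfg)
        has = set(truth_peaks["gene_id"])
        cats = []
        for r in truth_bias.itertuples():
            a, b = r.gene_A in has, r.gene_B in has
            if a or b:
                cats.append("S" if (a and b) else ("A" if a else "B"))
        cats = pd.Series(cats)
        frac = cats.value_counts(normalize=True)
        assert frac["S"] == pytest.approx(cfg.m6a_pair_shared, abs=0.03)
        assert frac["A"] == pytest.approx(cfg.m6a_pair_A_only, abs=0.03)
        assert frac["B"] == pytest.approx(cfg.m6a_pair_B_only, abs=0.03)

    def test_pure_3utr_placement(self):
        cfg = SimConfig(n_chrom_per_subgenome=1, genes_per_chrom=150,
                        m6a_utr3_weight=1.0, m6a_peak_prob=1.0, seed=6)
        _, genes, anc, models = simulate_genome_and_genes(cfg)
        _, _, _, td = simulate_expression(genes, anc, cfg)
        _, truth = simulate_m6a(models, anc, td, cfg)
        assert (truth["feature"] == "3'UTR").all()

    def test_flat_enrichment_yields_no_planted_peaks(self):
        cfg = SimConfig(n_chrom_per_subgenome=1, genes_per_chrom=100,
                        m6a_enrichment=1.0, m6a_ip_background=10.0, seed=6)
        _, genes, anc, models = simulate_genome_and_genes(cfg)
        _, _, _, td = simulate_expression(genes, anc, cfg)
        windows, truth = simulate_m6a(models, anc, td, cfg)
        from subdom.m6a import call_peaks
        called = call_peaks(windows, "CTL")
        # enrichment factor 1: only type-I noise remains, bounded by the
        # nominal window-level rate (every called window has p < 0.05)
        n_windows = int((windows["condition"] == "CTL").sum())
        assert len(called) <= 0.05 * n_windows
        # and the "peaks" show no affinity for the planted-but-flat spans
        hits = 0
        spans = {r.gene_id: (r.win_lo, r.win_hi) for r in truth.itertuples()}
        for r in called.itertuples():
            t = spans.get(r.gene_id)
            if t and r.win_lo < t[1] and r.win_hi > t[0]:
                hits += 1
        assert hits <= 0.35 * len(called)

    def test_loss_fraction_concentrates(self, medium_bundle):
        truth = medium_bundle.truth_peaks
        lost = (truth["fate"] == "lost").mean()
        n = len(truth)
        target = medium_bundle.config.m6a_loss_fraction
        assert abs(lost - target) <= 3 * np.sqrt(target * (1 - target) / n)


def test_te_density_ordering_and_intergenic_placement(small_bundle):
    b = small_bundle
    df = b.tes.df.copy()
    df["sub"] = df["chrom"].str[-1]
    per_mb = df.groupby("sub").size() / (
        b.genes.groupby("subgenome")["chrom"].nunique()
        * b.genome.chromosomes[0].length / 1e6)
    assert per_mb["B"] > per_mb["A"]
    # no TE overlaps a gene body
    for chrom, te in df.groupby("chrom"):
        g = b.genes[b.genes["chrom"] == chrom]
        spans = g[["start", "end"]].to_numpy()
        for s, e in te[["start", "end"]].to_numpy():
            assert not ((spans[:, 0] < e) & (spans[:, 1] > s)).any()
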