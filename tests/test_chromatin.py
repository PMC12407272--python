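"""ACR positional classes, conservation calling, divergence and ancestry."""

import numpy as np
import pandas as pd
import pytest

from subdom.chromatin import (
    acr_per_gene,
    acr_variant_density,
    ancestry_attribution,
    classify_conservation,
    classify_position,
    tissue_specific_acrs,
)
from subdom.homoeology import HomoeologMap, pair_homoeologs
from subdom.model import Interval, IntervalSet


def _acrs(*rows):
    return IntervalSet([Interval(*r) for r in rows])


class TestClassifyPosition:
    def test_genic_beats_proximal(self, toy_genes):
        # overlaps a2's body and sits near a1's neighborhood
        acrs = _acrs(("chr01A", 49_900, 50_100, "x", 1.0, ".", "leaf", "."))
        out = classify_position(acrs, toy_genes)
        assert out.loc[0, "position_class"] == "genic"

    def test_boundary_exactly_5kb_upstream_is_proximal(self, toy_genes):
        # + strand gene a1 at TSS 10000: ACR ending 5 kb upstream
        acrs = _acrs(("chr01A", 4800, 5000, "x", 1.0, ".", "leaf", "."))
        out = classify_position(acrs, toy_genes, proximal_bp=5000)
        assert out.loc[0, "position_class"] == "proximal"
        assert out.loc[0, "nearest_gene"] == "a1"

    def test_beyond_5kb_is_distal(self, toy_genes):
        acrs = _acrs(("chr01A", 3000, 3500, "x", 1.0, ".", "leaf", "."))
        out = classify_position(acrs, toy_genes, proximal_bp=5000)
        assert out.loc[0, "position_class"] == "distal"

    def test_minus_strand_upstream_is_right_side(self, toy_genes):
        # a2 on - strand: TSS at 51_999, upstream means larger coordinates
        acrs = _acrs(("chr01A", 52_500, 52_700, "x", 1.0, ".", "leaf", "."))
        out = classify_position(acrs, toy_genes)
        assert out.loc[0, "position_class"] == "proximal"
        # same interval relative to a + strand gene would be downstream
        out2 = classify_position(acrs, toy_genes, flank_mode="upstream")
        assert out2.loc[0, "nearest_gene"] == "a2"

    def test_downstream_of_plus_gene_needs_both_mode(self, toy_genes):
        acrs = _acrs(("chr01A", 12_500, 12_700, "x", 1.0, ".", "leaf", "."))
        up = classify_position(acrs, toy_genes, flank_mode="upstream")
        both = classify_position(acrs, toy_genes, flank_mode="both")
        assert up.loc[0, "position_class"] == "distal"
        assert both.loc[0, "position_class"] == "proximal"

    def test_classes_partition(self, small_bundle):
        out = classify_position(small_bundle.acrs, small_bundle.genes)
        assert out["position_class"].isin(["genic", "proximal", "distal"]).all()


class TestAcrPerGene:
    def test_order_invariance_and_counts(self, toy_genes):
        rows = [("chr01A", 9500, 9700, "p1", 1.0, ".", "leaf", "."),
                ("chr01A", 9000, 9200, "p2", 1.0, ".", "leaf", ".")]
        fwd, _ = acr_per_gene(classify_position(_acrs(*rows), toy_genes),
                              toy_genes)
        rev, _ = acr_per_gene(classify_position(_acrs(*rows[::-1]), toy_genes),
                              toy_genes)
        assert fwd.equals(rev)
        assert fwd.set_index("gene_id").loc["a1", "n_proximal_acrs"] == 2

    def test_equal_rates_p_one(self, toy_genes):
        rows = [("chr01A", 9500, 9700, "p1", 1.0, ".", "leaf", "."),
                ("chr01B", 9500, 9700, "p2", 1.0, ".", "leaf", "."),
                ("chr01A", 52_500, 52_700, "p3", 1.0, ".", "leaf", "."),
                ("chr01B", 52_500, 52_700, "p4", 1.0, ".", "leaf", ".")]
        per_gene, test = acr_per_gene(
            classify_position(_acrs(*rows), toy_genes), toy_genes)
        assert (per_gene["n_proximal_acrs"] == 1).all()
        assert test.p_value == 1.0

    def test_subgenome_asymmetry_recovered(self, medium_bundle):
        b = medium_bundle
        classified = classify_position(b.acrs, b.genes)
        per_gene, test = acr_per_gene(classified, b.genes)
        rates = per_gene.groupby("subgenome")["n_proximal_acrs"].mean()
        # truth rates from the generator's own ACR truth table
        truth_rate = {}
        for s in ("A", "B"):
            has = b.truth_acrs[f"gene_{s}"].ne("") & b.truth_acrs["class"] \
                .isin(["conserved", f"{s}_specific"])
            truth_rate[s] = has.sum() / (b.genes["subgenome"] == s).sum()
        assert rates["A"] == pytest.approx(truth_rate["A"], abs=0.03)
        assert rates["B"] == pytest.approx(truth_rate["B"], abs=0.03)
        assert test.p_value < 0.01


def _mirrored_setup():
    genes = pd.DataFrame({
        "gene_id": ["a1", "b1"], "chrom": ["c1A", "c1B"],
        "subgenome": ["A", "B"], "strand": ["+", "+"],
        "start": [10_000, 10_000], "end": [11_000, 11_000]})
    hmap = HomoeologMap(pairs=pd.DataFrame({
        "gene_A": ["a1"], "gene_B": ["b1"], "block_id": "b1",
        "similarity": 1.0}))
    return genes, hmap


class TestConservation:
    def test_mirrored_acrs_conserved_and_mutual(self):
        genes, hmap = _mirrored_setup()
        acrs = _acrs(("c1A", 9700, 9900, "acrA", 1.0, ".", "leaf", "."),
                     ("c1B", 9700, 9900, "acrB", 1.0, ".", "leaf", "."))
        out = classify_conservation(classify_position(acrs, genes), genes, hmap)
        assert (out["conservation_class"] == "conserved").all()
        assert list(out["partner_acr"]) == ["acrB", "acrA"]

    def test_deleted_partner_is_specific(self):
        genes, hmap = _mirrored_setup()
        acrs = _acrs(("c1A", 9700, 9900, "acrA", 1.0, ".", "leaf", "."))
        out = classify_conservation(classify_position(acrs, genes), genes, hmap)
        assert out.loc[0, "conservation_class"] == "A-specific"

    def test_different_tissue_not_conserved(self):
        genes, hmap = _mirrored_setup()
        acrs = _acrs(("c1A", 9700, 9900, "acrA", 1.0, ".", "leaf", "."),
                     ("c1B", 9700, 9900, "acrB", 1.0, ".", "root", "."))
        out = classify_conservation(classify_position(acrs, genes), genes, hmap)
        assert (out["conservation_class"] != "conserved").all()

    def test_no_anchor_flagged(self):
        genes, _ = _mirrored_setup()
        hmap = HomoeologMap(pairs=pd.DataFrame(
            columns=["gene_A", "gene_B", "block_id", "similarity"]),
            singletons_A=["a1"], singletons_B=["b1"])
        acrs = _acrs(("c1A", 9700, 9900, "acrA", 1.0, ".", "leaf", "."))
        out = classify_conservation(classify_position(acrs, genes), genes, hmap)
        assert out.loc[0, "conservation_flag"] == "no-anchor"
        assert out.loc[0, "conservation_class"] == "A-specific"

    def test_f1_against_simulator_truth(self, medium_bundle):
        b = medium_bundle
        hmap = pair_homoeologs(b.genes, b.anchors)
        classified = classify_position(b.acrs, b.genes)
        cons = classify_conservation(classified, b.genes, hmap)
        cons["acr_id"] = cons["name"].str.rsplit("_", n=1).str[0]
        called = cons.drop_duplicates("name").set_index("name")
        truth = b.truth_acrs.set_index("acr_id")["class"]
        tp = fp = fn = 0
        for name, row in called.iterrows():
            t = truth.get(row["acr_id"])
            want = "conserved" if t == "conserved" else \
                f"{row['subgenome']}-specific"
            got = row["conservation_class"]
            if got == "conserved" and want == "conserved":
                tp += 1
            elif got == "conserved":
                fp += 1
            elif want == "conserved":
                fn += 1
            else:
                tp += 1  # specific called specific
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        assert 2 * precision * recall / (precision + recall) >= 0.95


class TestVariantDensity:
    def test_arithmetic(self):
        genes, hmap = _mirrored_setup()
        acrs = _acrs(("c1A", 9400, 10_000, "acrA", 1.0, ".", "leaf", "."))
        cons = classify_conservation(classify_position(acrs, genes), genes, hmap)
        variants = pd.DataFrame({
            "chrom": ["c1A"] * 3, "pos": [9450, 9500, 9990],
            "subA": "alt", "subB": "ref", "progA": "alt", "progB": "ref"})
        dens, _ = acr_variant_density(cons, variants)
        assert dens.loc[0, "variants_per_kb"] == pytest.approx(5.0)

    def test_no_variants_zero(self):
        genes, hmap = _mirrored_setup()
        acrs = _acrs(("c1A", 9700, 9900, "acrA", 1.0, ".", "leaf", "."))
        cons = classify_conservation(classify_position(acrs, genes), genes, hmap)
        dens, _ = acr_variant_density(cons, pd.DataFrame(
            columns=["chrom", "pos"]))
        assert (dens["variants_per_kb"] == 0).all()

    def test_specific_more_divergent_on_simulation(self, medium_bundle):
        b = medium_bundle
        hmap = pair_homoeologs(b.genes, b.anchors)
        cons = classify_conservation(
            classify_position(b.acrs, b.genes), b.genes, hmap)
        dens, test = acr_variant_density(cons, b.variants)
        spec = dens.loc[dens["conservation_class"].str.endswith("specific"),
                        "variants_per_kb"]
        consv = dens.loc[dens["conservation_class"] == "conserved",
                         "variants_per_kb"]
        assert spec.mean() > consv.mean()
        assert test.p_value < 0.01


class TestAncestry:
    def test_all_matching_is_hundred_percent(self):
        genes, hmap = _mirrored_setup()
        acrs = _acrs(("c1A", 9700, 9900, "acrA", 1.0, ".", "leaf", "."))
        cons = classify_conservation(classify_position(acrs, genes), genes, hmap)
        variants = pd.DataFrame({
            "chrom": ["c1A"] * 4, "pos": [9710, 9750, 9800, 9850],
            "alt": ["T"] * 4,
            "subA": ["alt"] * 4, "subB": ["ref"] * 4,
            "progA": ["alt"] * 4, "progB": ["ref"] * 4})
        res = ancestry_attribution(cons, variants)
        assert res["fraction"] == 1.0 and res["informative"] == 4

    def test_missing_genotypes_excluded(self):
        genes, hmap = _mirrored_setup()
        acrs = _acrs(("c1A", 9700, 9900, "acrA", 1.0, ".", "leaf", "."))
        cons = classify_conservation(classify_position(acrs, genes), genes, hmap)
        variants = pd.DataFrame({
            "chrom": ["c1A"] * 2, "pos": [9710, 9720], "alt": ["T", "T"],
            "subA": ["alt", "alt"], "subB": ["ref", "ref"],
            "progA": ["alt", "missing"], "progB": ["ref", "ref"]})
        res = ancestry_attribution(cons, variants)
        assert res["informative"] == 1

    def test_no_informative_raises(self):
        genes, hmap = _mirrored_setup()
        acrs = _acrs(("c1A", 9700, 9900, "acrA", 1.0, ".", "leaf", "."))
        cons = classify_conservation(classify_position(acrs, genes), genes, hmap)
        with pytest.raises(ValueError):
            ancestry_attribution(cons, pd.DataFrame(
                columns=["chrom", "pos", "alt", "subA", "subB",
                         "progA", "progB"]))


class TestTissueSpecific:
    def _classified(self, rows):
        genes = pd.DataFrame({
            "gene_id": ["g1"], "chrom": ["c1A"], "subgenome": ["A"],
            "strand": ["+"], "start": [50_000], "end": [51_000]})
        return classify_position(_acrs(*rows), genes)

    def test_identical_sets_all_constitutive(self):
        rows = [("c1A", 100, 300, f"a_{t}", 1.0, ".", t, ".")
                for t in ("leaf", "root")]
        out = tissue_specific_acrs(self._classified(rows), top_n=10)
        assert len(out["constitutive"]) == 1
        assert all(len(v) == 0 for v in out["specific"].values())

    def test_private_acrs_are_specific(self):
        rows = [("c1A", 100, 300, "shared_leaf", 1.0, ".", "leaf", "."),
                ("c1A", 100, 300, "shared_root", 1.0, ".", "root", ".")]
        rows += [("c1A", 1000 + 500 * i, 1200 + 500 * i, f"leaf{i}", float(i),
                  ".", "leaf", ".") for i in range(10)]
        out = tissue_specific_acrs(self._classified(rows), top_n=5)
        assert len(out["specific"]["leaf"]) == 5  # top_n kept, ranked by score
        assert out["specific"]["leaf"]["score"].is_monotonic_decreasing
        assert len(out["specific"]["root"]) == 0

    def test_planted_term_enrichment(self):
        rng = np.random.default_rng(0)
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(200)], "chrom": "c1A",
            "subgenome": "A", "strand": "+",
            "start": np.arange(200) * 10_000 + 50_000,
            "end": np.arange(200) * 10_000 + 51_000})
        rows = []
        # leaf-private ACRs near genes 0..19, root-private near 100..119
        for i in range(20):
            rows.append(("c1A", 50_000 + i * 10_000 - 600,
                         50_000 + i * 10_000 - 400, f"leaf{i}", 5.0, ".",
                         "leaf", "."))
            rows.append(("c1A", 50_000 + (100 + i) * 10_000 - 600,
                         50_000 + (100 + i) * 10_000 - 400, f"root{i}", 5.0,
                         ".", "root", "."))
        classified = classify_position(_acrs(*rows), genes)
        term_map = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(20)]
            + [f"g{i}" for i in rng.choice(range(20, 200), 30, replace=False)],
            "term": ["photosynthesis"] * 20 + ["other"] * 30})
        out = tissue_specific_acrs(classified, top_n=20, term_map=term_map,
                                   universe=list(genes["gene_id"]))
        enr = out["enrichment"]["leaf"].set_index("term")
        assert enr.loc["photosynthesis", "adj_p"] < 0.05
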