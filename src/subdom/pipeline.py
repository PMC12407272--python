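"""End-to-end pipeline: chain the analysis stages over a dataset bundle.

Each stage reads the standard-format files written by ``subdom simulate``
(or assembled by the user in the same layout), writes its result tables
under the output directory, and contributes to a run summary.  Outputs
are a pure function of (inputs, config); numeric formatting is fixed so
repeated runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from subdom import chromatin, expression, homoeology, m6a, repeats
from subdom import io as sio
from subdom.model import AnalysisConfig, IntervalSet
from subdom.synthetic import BUNDLE_FILES

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineInputs:
    genome: Path
    genes: Path
    anchors: Path
    ancestral: Path | None
    tes: Path
    acrs: Path
    methylation: Path
    counts: Path
    samples: Path
    m6a_windows: Path
    variants: Path

    @classmethod
    def from_bundle_dir(cls, d) -> "PipelineInputs":
        d = Path(d)
        return cls(
            genome=d / BUNDLE_FILES["genome"],
            genes=d / BUNDLE_FILES["genes"],
            anchors=d / BUNDLE_FILES["anchors"],
            ancestral=d / BUNDLE_FILES["ancestral"],
            tes=d / BUNDLE_FILES["tes"],
            acrs=d / BUNDLE_FILES["acrs"],
            methylation=d / BUNDLE_FILES["methylation"],
            counts=d / BUNDLE_FILES["counts"],
            samples=d / BUNDLE_FILES["samples"],
            m6a_windows=d / BUNDLE_FILES["m6a_windows"],
            variants=d / BUNDLE_FILES["variants"],
        )


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _genes_frame(models) -> pd.DataFrame:
    return pd.DataFrame(
        [(g.gene_id, g.chrom, g.subgenome, g.strand, g.start, g.end)
         for g in models],
        columns=["gene_id", "chrom", "subgenome", "strand", "start", "end"])


def run_pipeline(config: AnalysisConfig, inputs: PipelineInputs, outdir,
                 stages: tuple[str, ...] = ("homoeology", "expression",
                                            "methylome", "chromatin", "m6a"),
                 ) -> dict:
    out = sio.ensure_dir(outdir)
    summary: dict = {}
    stage = "load"
    try:
        genome = sio.read_genome_tsv(inputs.genome)
        models = sio.read_gff3(inputs.genes, genome)
        genes = _genes_frame(models)
        gene_sub = genes.set_index("gene_id")["subgenome"]

        hmap = None
        deg = None
        if "homoeology" in stages:
            stage = "homoeology"
            anchors = sio.read_anchors(inputs.anchors)
            hmap = homoeology.pair_homoeologs(genes, anchors,
                                              max_gap=config.max_gap,
                                              min_block=config.min_block)
            _write(hmap.pairs, out / "homoeolog_pairs.tsv")
            _write(pd.DataFrame({
                "gene_id": hmap.singletons_A + hmap.singletons_B,
                "subgenome": (["A"] * len(hmap.singletons_A)
                              + ["B"] * len(hmap.singletons_B))}),
                out / "singletons.tsv")
            if inputs.ancestral and Path(inputs.ancestral).exists():
                ancestral = pd.read_csv(inputs.ancestral, sep="\t",
                                        keep_default_na=False)
                profile = homoeology.fractionation_profile(
                    ancestral, genes, window_genes=config.window_genes)
                _write(profile, out / "fractionation_profile.tsv")
                if len(profile) >= 2:
                    bal = homoeology.retention_balance_test(profile)
                    summary["retention_balance_p"] = bal.p_value
                    summary["retention_mean_diff"] = bal.effect
                else:
                    logger.warning("single retention window; balance test "
                                   "skipped")
            summary["n_pairs"] = int(len(hmap.pairs))
            summary["n_singletons_A"] = len(hmap.singletons_A)
            summary["n_singletons_B"] = len(hmap.singletons_B)

        if "expression" in stages:
            stage = "expression"
            counts = sio.read_counts(inputs.counts)
            samples = pd.read_csv(inputs.samples, sep="\t")
            lengths = pd.Series(
                {g.gene_id: g.transcript_length for g in models}, name="length")
            table = expression.ExpressionTable(counts, lengths, samples)
            tpm = expression.compute_tpm(table)
            _write(tpm.round(3), out / "tpm.tsv", index=True)
            expressed = expression.filter_expressed(tpm, config.tpm_min)
            summary["n_expressed"] = int(len(expressed))
            for s in ("A", "B"):
                summary[f"n_expressed_{s}"] = int(
                    (gene_sub.reindex(expressed) == s).sum())
            if hmap is not None and len(hmap.pairs):
                calls, pooled = expression.homoeolog_bias(
                    table, hmap, adj_p_max=config.bias_adj_p,
                    pooling=config.bias_pooling)
                _write(calls, out / "bias_calls.tsv")
                _write(pooled, out / "bias_pooled.tsv")
                biased = int((pooled["class"] != "unbiased").sum())
                summary["n_pairs_tested"] = int(len(pooled))
                summary["n_pairs_biased"] = biased
                summary["biased_pair_percent"] = expression.bias_percentage(
                    biased, len(pooled))
                summary["biased_toward_A_percent"] = (
                    100.0 * (pooled["class"] == "A-dominant").sum() / biased
                    if biased else float("nan"))
                st = expression.singleton_comparison(tpm, hmap)
                summary["singleton_p"] = st.p_value
                summary["singleton_shift"] = st.effect
            if set(samples["condition"]) >= {"CTL", "WL"}:
                deg = expression.nb_differential(
                    table, ("CTL", "WL"), fc_min=config.de_fc,
                    fdr_max=config.de_fdr)
                _write(deg, out / "deg.tsv", index=True)
                degsum = expression.subgenome_deg_summary(deg, gene_sub)
                _write(degsum, out / "subgenome_deg_summary.tsv")
                for r in degsum.itertuples(index=False):
                    summary[f"deg_rate_{r.subgenome}"] = r.rate
                    summary[f"deg_total_{r.subgenome}"] = r.total

        if "methylome" in stages:
            stage = "methylome"
            tes = sio.read_bed(inputs.tes)
            meth = sio.read_methylation(inputs.methylation)
            content = repeats.te_content(tes, genome)
            summary["te_fraction_A"] = float(content["A"])
            summary["te_fraction_B"] = float(content["B"])
            dist, dtest = repeats.nearest_te_distance(genes, tes, genome)
            _write(dist, out / "te_distance.tsv")
            med = dist.groupby("subgenome")["te_distance"].median()
            summary["te_distance_median_A"] = float(med.get("A", np.nan))
            summary["te_distance_median_B"] = float(med.get("B", np.nan))
            summary["te_distance_p"] = dtest.p_value
            glob = repeats.global_methylation(meth, genome)
            _write(glob, out / "global_methylation.tsv")
            for r in glob.itertuples(index=False):
                summary[f"meth_{r.context}_{r.subgenome}"] = float(r.level)
            gene_regions = IntervalSet(genes.assign(
                name=genes["gene_id"], score=0.0, category=".", sample="."))
            prof_gene = repeats.metaprofile(
                meth, gene_regions, genome, flank_bp=config.flank_bp,
                body_bins=config.body_bins, flank_bins=config.flank_bins)
            _write(prof_gene, out / "metaprofile_genes.tsv")
            prof_te = repeats.metaprofile(
                meth, tes, genome, flank_bp=config.flank_bp,
                body_bins=config.body_bins, flank_bins=config.flank_bins)
            _write(prof_te, out / "metaprofile_tes.tsv")

        if "chromatin" in stages:
            stage = "chromatin"
            acrs = sio.read_interval_tsv(inputs.acrs)
            classified = chromatin.classify_position(
                acrs, genes, proximal_bp=config.proximal_bp,
                flank_mode=config.flank_mode)
            per_gene, pg_test = chromatin.acr_per_gene(classified, genes)
            _write(per_gene, out / "acr_per_gene.tsv")
            rates = per_gene.groupby("subgenome")["n_proximal_acrs"].mean()
            summary["acr_per_gene_A"] = float(rates.get("A", np.nan))
            summary["acr_per_gene_B"] = float(rates.get("B", np.nan))
            summary["acr_per_gene_p"] = pg_test.p_value
            if hmap is not None:
                cons = chromatin.classify_conservation(classified, genes, hmap)
                _write(cons, out / "acr_classified.tsv")
                loci = cons.drop_duplicates(subset=["chrom", "start", "end"])
                vc = loci["conservation_class"].value_counts()
                for k in ("conserved", "A-specific", "B-specific"):
                    summary[f"acr_{k.replace('-', '_')}"] = int(vc.get(k, 0))
                variants = sio.read_variants(inputs.variants)
                dens, dens_test = chromatin.acr_variant_density(cons, variants)
                _write(dens, out / "acr_divergence.tsv")
                summary["acr_divergence_p"] = dens_test.p_value
                anc = chromatin.ancestry_attribution(cons, variants)
                summary["ancestry_match_percent"] = 100.0 * anc["fraction"]
                summary["ancestry_informative"] = anc["informative"]
                pd.DataFrame([anc]).to_csv(out / "ancestry.tsv", sep="\t",
                                           index=False,
                                           float_format=_FLOAT_FMT)
            ts = chromatin.tissue_specific_acrs(classified, top_n=1000)
            spec_counts = {t: len(v) for t, v in ts["specific"].items()}
            summary["acr_constitutive"] = int(len(ts["constitutive"]))
            summary["acr_tissue_specific"] = spec_counts

        if "m6a" in stages:
            stage = "m6a"
            if not Path(inputs.m6a_windows).exists():
                raise FileNotFoundError(
                    f"m6a stage requested but {inputs.m6a_windows} is missing")
            windows = sio.read_m6a_windows(inputs.m6a_windows)
            model_by_id = {g.gene_id: g for g in models}
            peaks = {}
            for cond in ("CTL", "WL"):
                p = m6a.call_peaks(windows, cond, ratio_min=config.m6a_ratio,
                                   p_max=config.m6a_p)
                p = m6a.annotate_features(p, model_by_id)
                peaks[cond] = p
                _write(p, out / f"m6a_peaks_{cond}.tsv")
                summary[f"m6a_peaks_{cond}"] = int(len(p))
            enr = m6a.feature_enrichment(peaks["CTL"], model_by_id)
            _write(enr, out / "m6a_feature_enrichment.tsv")
            utr3 = enr.loc[enr["feature"] == "3'UTR", "fraction"]
            summary["m6a_utr3_fraction_CTL"] = float(utr3.iloc[0])
            if hmap is not None and len(hmap.pairs):
                share = m6a.homoeolog_sharing(peaks["CTL"], hmap.pairs)
                for k, v in share.items():
                    summary[f"m6a_sharing_{k}"] = float(v)
            comp = m6a.condition_compare(peaks["CTL"], peaks["WL"], gene_sub)
            summary["m6a_peak_change_percent"] = 100.0 * comp["delta_fraction"]
            diff = m6a.differential_m6a(windows, peaks["CTL"], peaks["WL"],
                                        fdr_max=config.m6a_diff_fdr,
                                        delta_min=config.m6a_diff_log2)
            _write(diff, out / "m6a_differential.tsv")
            dsub = diff[diff["differential"]]["gene_id"].map(gene_sub)
            summary["m6a_differential_A"] = int((dsub == "A").sum())
            summary["m6a_differential_B"] = int((dsub == "B").sum())
            if deg is not None:
                integ = m6a.integrate_de_m6a(diff, deg)
                _write(integ["table"], out / "de_m6a_quadrants.tsv", index=True)
                if integ["concordance_test"] is not None:
                    summary["de_m6a_odds_ratio"] = integ["concordance_test"].effect
                    summary["de_m6a_p"] = integ["concordance_test"].p_value
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else round(f, 6)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj
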