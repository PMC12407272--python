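"""Accessible-chromatin-region (ACR) analysis.

Positional classes follow a strict priority: an ACR overlapping any gene
body is genic; otherwise an ACR within ``proximal_bp`` upstream of a TSS
(strand-aware; boundary inclusive) is proximal; everything else is
distal.  Conserved/specific calling projects each ACR into the partner
subgenome through its nearest homoeologous gene anchor, preserving the
TSS offset, and requires a same-tissue partner ACR overlapping the
projection by at least 1 bp.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from subdom.homoeology import HomoeologMap
from subdom.model import IntervalSet
from subdom.stats import TestResult, bh_adjust, hypergeom_enrich, rank_sum_test

logger = logging.getLogger(__name__)

POSITION_CLASSES = ("genic", "proximal", "distal")


def _gene_arrays(genes: pd.DataFrame):
    """Per-chromosome sorted gene span and TSS arrays."""
    out = {}
    for chrom, sub in genes.groupby("chrom"):
        s = sub.sort_values("start")
        tss = np.where(s["strand"].to_numpy() == "+",
                       s["start"].to_numpy(), s["end"].to_numpy() - 1)
        out[chrom] = {
            "start": s["start"].to_numpy(),
            "end": s["end"].to_numpy(),
            "tss_sorted": np.sort(tss),
            "tss_order": np.argsort(tss, kind="mergesort"),
            "tss": tss,
            "strand": s["strand"].to_numpy(),
            "gene_id": s["gene_id"].to_numpy(),
        }
    return out


def _nearest_tss(ga, pos: np.ndarray):
    """Index (into the chromosome's sorted-by-start gene table) of the gene
    whose TSS is nearest to each position."""
    ts = ga["tss_sorted"]
    j = np.searchsorted(ts, pos)
    j0 = np.clip(j - 1, 0, len(ts) - 1)
    j1 = np.clip(j, 0, len(ts) - 1)
    pick = np.where(np.abs(pos - ts[j0]) <= np.abs(ts[j1] - pos), j0, j1)
    return ga["tss_order"][pick]


def classify_position(acrs: IntervalSet, genes: pd.DataFrame,
                      proximal_bp: int = 5000,
                      flank_mode: str = "upstream") -> pd.DataFrame:
    """Assign each ACR a positional class and its nearest-TSS gene.

    ``flank_mode="both"`` counts the window on both sides of the TSS
    instead of upstream only.
    """
    garr = _gene_arrays(genes)
    df = acrs.df.copy()
    classes = np.full(len(df), "distal", dtype=object)
    nearest = np.full(len(df), "", dtype=object)
    tss_dist = np.full(len(df), np.nan)
    for chrom, idx in df.groupby("chrom").groups.items():
        ga = garr.get(chrom)
        rows = df.loc[idx]
        if ga is None:
            continue
        a_start = rows["start"].to_numpy()
        a_end = rows["end"].to_numpy()
        # genic: overlap any gene body
        k = np.searchsorted(ga["start"], a_end, side="left") - 1
        genic = np.zeros(len(rows), dtype=bool)
        # scan backwards is unnecessary: gene spans don't overlap each other in
        # typical annotations, but be safe with a short backward window
        for back in range(0, 4):
            kk = np.clip(k - back, 0, len(ga["start"]) - 1)
            genic |= (k - back >= 0) & (ga["end"][kk] > a_start) \
                & (ga["start"][kk] < a_end)
        mid = (a_start + a_end) // 2
        gi = _nearest_tss(ga, mid)
        tss = ga["tss"][gi]
        strand = ga["strand"][gi]
        # signed gap from ACR to the TSS on the upstream side
        up_gap = np.where(strand == "+", tss - a_end, a_start - tss)
        down_gap = np.where(strand == "+", a_start - tss, tss - a_end + 1)
        proximal = (up_gap >= 0) & (up_gap <= proximal_bp)
        if flank_mode == "both":
            proximal |= (down_gap >= 0) & (down_gap <= proximal_bp)
        pos = np.where(genic, "genic", np.where(proximal, "proximal", "distal"))
        loc = df.index.get_indexer(idx)
        classes[loc] = pos
        nearest[loc] = ga["gene_id"][gi]
        tss_dist[loc] = np.abs(mid - tss)
    df["position_class"] = classes
    df["nearest_gene"] = nearest
    df["tss_distance"] = tss_dist
    return df


def acr_per_gene(classified: pd.DataFrame, genes: pd.DataFrame
                 ) -> tuple[pd.DataFrame, TestResult]:
    """Proximal-ACR count per gene and the A-vs-B rank-sum comparison.

    Distinct ACR loci are counted once per gene even when the ACR is
    reported in several tissues.
    """
    prox = classified[classified["position_class"] == "proximal"]
    loci = prox.drop_duplicates(subset=["chrom", "start", "end", "nearest_gene"])
    counts = loci.groupby("nearest_gene").size()
    out = genes[["gene_id", "subgenome"]].copy()
    out["n_proximal_acrs"] = counts.reindex(genes["gene_id"]).fillna(0).to_numpy(int)
    a = out.loc[out["subgenome"] == "A", "n_proximal_acrs"].to_numpy()
    b = out.loc[out["subgenome"] == "B", "n_proximal_acrs"].to_numpy()
    return out, rank_sum_test(a, b)


def _project(row, gene_by_id: pd.DataFrame, partner_id: str):
    """Project an ACR into the partner subgenome via TSS-offset transfer."""
    g = gene_by_id.loc[row["nearest_gene"]]
    p = gene_by_id.loc[partner_id]
    g_tss = g["start"] if g["strand"] == "+" else g["end"] - 1
    p_tss = p["start"] if p["strand"] == "+" else p["end"] - 1
    # offsets along the gene orientation (positive = downstream of the TSS)
    if g["strand"] == "+":
        off_lo, off_hi = row["start"] - g_tss, row["end"] - g_tss
    else:
        off_lo, off_hi = g_tss - row["end"] + 1, g_tss - row["start"] + 1
    if p["strand"] == "+":
        return p["chrom"], p_tss + off_lo, p_tss + off_hi
    return p["chrom"], p_tss - off_hi + 1, p_tss - off_lo + 1


def classify_conservation(classified: pd.DataFrame, genes: pd.DataFrame,
                          hmap: HomoeologMap,
                          min_overlap: int = 1) -> pd.DataFrame:
    """Call each ACR conserved or subgenome-specific via homoeolog projection.

    An ACR is conserved when a partner-subgenome ACR of the same tissue
    overlaps its projected interval by >= ``min_overlap`` bp.  ACRs whose
    anchor gene has no homoeolog are specific with flag "no-anchor".
    """
    partner = hmap.partner()
    gene_by_id = genes.set_index("gene_id")
    sub_of = gene_by_id["subgenome"]
    df = classified.copy().reset_index(drop=True)
    df["subgenome"] = sub_of.reindex(df["nearest_gene"]).to_numpy()
    # index partner ACRs by (chrom, tissue) for overlap lookup
    by_key: dict[tuple[str, str], np.ndarray] = {}
    names_by_key: dict[tuple[str, str], np.ndarray] = {}
    for key, sub in df.groupby(["chrom", "category"], sort=True):
        arr = sub[["start", "end"]].to_numpy()
        order = np.argsort(arr[:, 0])
        by_key[key] = arr[order]
        names_by_key[key] = sub["name"].to_numpy()[order]
    cls = np.full(len(df), "", dtype=object)
    part = np.full(len(df), "", dtype=object)
    flags = np.full(len(df), "", dtype=object)
    proj_rows = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        pid = partner.get(row["nearest_gene"])
        if pid is None:
            cls[i] = f"{row['subgenome']}-specific"
            flags[i] = "no-anchor"
            proj_rows.append(("", -1, -1))
            continue
        chrom, lo, hi = _project(row, gene_by_id, pid)
        proj_rows.append((chrom, lo, hi))
        key = (chrom, row["category"])
        ivs = by_key.get(key)
        hit = ""
        if ivs is not None and len(ivs):
            j0 = np.searchsorted(ivs[:, 0], hi - min_overlap, side="left")
            cand = slice(max(0, j0 - 32), j0)
            ov = np.minimum(ivs[cand, 1], hi) - np.maximum(ivs[cand, 0], lo)
            good = np.nonzero(ov >= min_overlap)[0]
            if good.size:
                hit = names_by_key[key][cand][good[0]]
        if hit:
            cls[i] = "conserved"
            part[i] = hit
        else:
            cls[i] = f"{row['subgenome']}-specific"
    df["conservation_class"] = cls
    df["partner_acr"] = part
    df["conservation_flag"] = flags
    df[["proj_chrom", "proj_start", "proj_end"]] = pd.DataFrame(
        proj_rows, index=df.index, columns=["proj_chrom", "proj_start", "proj_end"])
    return df


def acr_variant_density(conserved: pd.DataFrame, variants: pd.DataFrame
                        ) -> tuple[pd.DataFrame, TestResult]:
    """Variants per kb over each ACR plus its projection, by class.

    Distinct ACR loci are evaluated once (tissue replicates collapsed);
    the specific-vs-conserved density distributions are compared with a
    rank-sum test.
    """
    loci = conserved.drop_duplicates(subset=["chrom", "start", "end"]).copy()
    var_by_chrom = {c: np.sort(s["pos"].to_numpy())
                    for c, s in variants.groupby("chrom")}

    def count_in(chrom, lo, hi):
        pos = var_by_chrom.get(chrom)
        if pos is None or lo < 0:
            return 0
        return int(np.searchsorted(pos, hi) - np.searchsorted(pos, lo))

    n = [count_in(r.chrom, r.start, r.end)
         + count_in(r.proj_chrom, r.proj_start, r.proj_end)
         for r in loci.itertuples(index=False)]
    loci["n_variants"] = n
    loci["variants_per_kb"] = loci["n_variants"] / ((loci["end"] - loci["start"]) / 1000)
    spec = loci.loc[loci["conservation_class"].str.endswith("specific"),
                    "variants_per_kb"]
    cons = loci.loc[loci["conservation_class"] == "conserved", "variants_per_kb"]
    test = (rank_sum_test(spec.to_numpy(), cons.to_numpy())
            if len(spec) and len(cons) else TestResult(np.nan, np.nan, np.nan))
    return loci, test


def ancestry_attribution(conserved: pd.DataFrame,
                         variants: pd.DataFrame) -> dict:
    """Fraction of specific-ACR variants matching the carrier progenitor.

    For each variant inside a subgenome-specific ACR (or its projection),
    the carrying subgenome's allele is compared with the allele of the
    corresponding progenitor (progA for subgenome A, progB for B).
    Variants with a missing genotype on either side are excluded from
    numerator and denominator.
    """
    spec = conserved[conserved["conservation_class"].str.endswith("specific")]
    spec = spec.drop_duplicates(subset=["chrom", "start", "end"])
    matches = informative = 0
    var_by_chrom = dict(tuple(variants.groupby("chrom")))
    seen: set[tuple[str, int, str]] = set()
    for r in spec.itertuples(index=False):
        carrier = r.conservation_class[0]  # "A" or "B"
        for chrom, lo, hi in ((r.chrom, r.start, r.end),
                              (r.proj_chrom, r.proj_start, r.proj_end)):
            sub = var_by_chrom.get(chrom)
            if sub is None or lo < 0:
                continue
            hitv = sub[(sub["pos"] >= lo) & (sub["pos"] < hi)]
            for v in hitv.itertuples(index=False):
                key = (v.chrom, v.pos, v.alt)
                if key in seen:
                    continue
                seen.add(key)
                a_sub = getattr(v, f"sub{carrier}")
                a_prog = getattr(v, f"prog{carrier}")
                if a_sub == "missing" or a_prog == "missing":
                    continue
                informative += 1
                matches += int(a_sub == a_prog)
    if informative == 0:
        raise ValueError("no informative variants in specific-ACR regions")
    return {"matches": matches, "informative": informative,
            "fraction": matches / informative}


def tissue_specific_acrs(classified: pd.DataFrame, top_n: int = 1000,
                         term_map: pd.DataFrame | None = None,
                         universe: list[str] | None = None) -> dict:
    """Constitutive vs tissue-specific ACR partition with optional enrichment.

    An ACR locus present (>= 1 bp overlap) in every tissue is
    constitutive; loci unique to one tissue are ranked by score
    (descending; ties by length then coordinate) and the top ``top_n``
    kept per tissue.  When a gene->term map is supplied, the nearest genes
    of each tissue-specific set are tested for term enrichment
    (hypergeometric upper tail, BH-adjusted).
    """
    tissues = sorted(classified["category"].unique())
    if len(tissues) < 2:
        raise ValueError("need ACRs from at least 2 tissues")
    df = classified.copy()
    df["locus"] = df["chrom"] + ":" + df["start"].astype(str) + "-" + df["end"].astype(str)

    # overlap-based presence: cluster loci by overlap per chromosome
    loci = df.drop_duplicates("locus").sort_values(["chrom", "start"])
    cluster = np.zeros(len(loci), dtype=np.int64)
    cid = -1
    prev_chrom, prev_end = None, -1
    for i, r in enumerate(loci.itertuples(index=False)):
        if r.chrom != prev_chrom or r.start >= prev_end:
            cid += 1
            prev_end = r.end
        else:
            prev_end = max(prev_end, r.end)
        prev_chrom = r.chrom
        cluster[i] = cid
    loci = loci.assign(cluster=cluster)
    df = df.merge(loci[["locus", "cluster"]], on="locus", how="left")
    support = df.groupby("cluster")["category"].nunique()
    constitutive = set(support[support == len(tissues)].index)
    single = set(support[support == 1].index)

    out = {"constitutive": df[df["cluster"].isin(constitutive)]
           .drop_duplicates("cluster"),
           "specific": {}, "enrichment": {}}
    for t in tissues:
        cand = df[(df["category"] == t) & df["cluster"].isin(single)] \
            .drop_duplicates("locus").copy()
        cand["length"] = cand["end"] - cand["start"]
        cand = cand.sort_values(["score", "length", "chrom", "start"],
                                ascending=[False, False, True, True],
                                kind="mergesort")
        if len(cand) < top_n:
            logger.info("tissue %s: only %d specific ACRs (top_n=%d)",
                        t, len(cand), top_n)
        out["specific"][t] = cand.head(top_n)
        if term_map is not None:
            genes_t = set(out["specific"][t]["nearest_gene"])
            uni = set(universe) if universe else set(classified["nearest_gene"])
            rows = []
            for term, tgenes in term_map.groupby("term")["gene_id"]:
                tset = set(tgenes) & uni
                hits = len(genes_t & tset)
                if not tset:
                    continue
                r = hypergeom_enrich(hits, len(genes_t & uni), len(tset), len(uni))
                rows.append((term, hits, len(tset), r.p_value, r.effect))
            enr = pd.DataFrame(rows, columns=["term", "hits", "term_size",
                                              "p", "fold"])
            if len(enr):
                enr["adj_p"] = bh_adjust(enr["p"].to_numpy())
            out["enrichment"][t] = enr
    return out
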