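"""Windowed MeRIP (m6A) peak calling and downstream integration.

Peak calling tests each transcript window's IP count against the input
count with a Fisher exact test on the 2x2 of (window counts vs remaining
library), calls windows with library-normalized IP/input >= ratio_min
(inclusive) and p < p_max (strict), and merges adjacent significant
windows into peaks.  Reported peak levels are log2 of the normalized
ratio with 0.5 pseudocounts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from subdom.model import GeneModel
from subdom.stats import bh_adjust, fisher_exact, fisher_exact_many, rank_sum_test

logger = logging.getLogger(__name__)

FEATURES = ("5'UTR", "CDS", "3'UTR")


def _normalized_ratio(ip, inp, ip_lib, input_lib, pseudocount=0.0):
    with np.errstate(divide="ignore", invalid="ignore"):
        return ((ip + pseudocount) / ip_lib) / ((inp + pseudocount) / input_lib)


def call_peaks(windows: pd.DataFrame, condition: str,
               ratio_min: float = 2.0, p_max: float = 0.05,
               ip_lib: int | None = None,
               input_lib: int | None = None) -> pd.DataFrame:
    """Call m6A peaks for one condition from the window count table.

    ``windows`` columns: gene_id, win_index, start, end, ip, input,
    condition.  Library sizes default to the column totals of the
    condition.  Returns one row per peak with transcript-coordinate span,
    weighted log2 IP/input ratio (0.5 pseudocounts), and the minimum
    window p value.
    """
    w = windows[windows["condition"] == condition].reset_index(drop=True)
    if not len(w):
        raise ValueError(f"no windows for condition {condition!r}")
    ip_lib = int(ip_lib if ip_lib is not None else w["ip"].sum())
    input_lib = int(input_lib if input_lib is not None else w["input"].sum())
    if ip_lib <= 0 or input_lib <= 0:
        raise ValueError("library sizes must be positive")
    ip = w["ip"].to_numpy(np.int64)
    inp = w["input"].to_numpy(np.int64)
    ratio = _normalized_ratio(ip, inp, ip_lib, input_lib)
    p = fisher_exact_many(ip, inp, ip_lib - ip, input_lib - inp)
    enriched = ip * input_lib > inp * ip_lib  # normalized IP above input
    sig = (ratio >= ratio_min) & (p < p_max) & enriched

    w = w.assign(p=p, sig=sig)
    sigw = w[sig].sort_values(["gene_id", "win_index"], kind="mergesort")
    peaks = []
    for gene, grp in sigw.groupby("gene_id", sort=True):
        wi = grp["win_index"].to_numpy()
        breaks = np.nonzero(np.diff(wi) > 1)[0]
        seg_starts = np.concatenate([[0], breaks + 1])
        seg_ends = np.concatenate([breaks + 1, [len(wi)]])
        for s, e in zip(seg_starts, seg_ends):
            seg = grp.iloc[s:e]
            tot_ip, tot_in = int(seg["ip"].sum()), int(seg["input"].sum())
            lr = np.log2(_normalized_ratio(
                seg["ip"].to_numpy(float), seg["input"].to_numpy(float),
                ip_lib, input_lib, pseudocount=0.5))
            weights = (seg["ip"] + seg["input"]).to_numpy(float)
            wsum = weights.sum()
            log2_ratio = float((lr * weights).sum() / wsum) if wsum else float("nan")
            peaks.append((gene, int(seg["win_index"].min()),
                          int(seg["win_index"].max()) + 1,
                          int(seg["start"].min()), int(seg["end"].max()),
                          tot_ip, tot_in, log2_ratio,
                          float(seg["p"].min()), condition))
    out = pd.DataFrame(peaks, columns=[
        "gene_id", "win_lo", "win_hi", "start", "end", "ip", "input",
        "log2_ratio", "p", "condition"])
    out["adj_p"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def annotate_features(peaks: pd.DataFrame,
                      gene_models: dict[str, GeneModel]) -> pd.DataFrame:
    """Assign each peak the transcript feature with maximal bp overlap.

    Ties break by priority 3'UTR > 5'UTR > CDS; transcripts without UTRs
    map everything to CDS; peaks on unknown genes get "unassigned".
    """
    prio = {"3'UTR": 0, "5'UTR": 1, "CDS": 2}
    feats = []
    for r in peaks.itertuples(index=False):
        g = gene_models.get(r.gene_id)
        if g is None:
            logger.warning("peak on unknown gene %s", r.gene_id)
            feats.append("unassigned")
            continue
        fl = g.feature_lengths()
        u5, cd, u3 = fl["5'UTR"], fl["CDS"], fl["3'UTR"]
        bounds = {"5'UTR": (0, u5), "CDS": (u5, u5 + cd),
                  "3'UTR": (u5 + cd, u5 + cd + u3)}
        if u5 + u3 == 0:
            feats.append("CDS")
            continue
        ov = {f: max(0, min(r.end, hi) - max(r.start, lo))
              for f, (lo, hi) in bounds.items()}
        best = sorted(ov.items(), key=lambda kv: (-kv[1], prio[kv[0]]))[0]
        feats.append(best[0] if best[1] > 0 else "CDS")
    out = peaks.copy()
    out["feature"] = feats
    return out


def feature_enrichment(annotated: pd.DataFrame,
                       gene_models: dict[str, GeneModel]) -> pd.DataFrame:
    """Observed/expected peak density per feature (expected ~ summed length)."""
    lens = {f: 0 for f in FEATURES}
    for g in gene_models.values():
        for f, v in g.feature_lengths().items():
            lens[f] += v
    total_len = sum(lens.values())
    obs = annotated["feature"].value_counts()
    n = len(annotated)
    rows = []
    for f in FEATURES:
        o = int(obs.get(f, 0))
        exp = n * lens[f] / total_len if total_len else np.nan
        rows.append((f, o, o / n if n else np.nan, exp,
                     o / exp if exp else np.nan))
    return pd.DataFrame(rows, columns=["feature", "n_peaks", "fraction",
                                       "expected", "obs_over_exp"])


def peak_gene_summary(annotated: pd.DataFrame) -> dict:
    """Genes with >= 1 peak and the peaks-per-gene histogram, per condition."""
    out = {}
    for cond, grp in annotated.groupby("condition"):
        per_gene = grp.groupby("gene_id").size()
        hist = per_gene.value_counts().sort_index()
        out[cond] = {"n_genes": int(per_gene.size),
                     "n_peaks": int(len(grp)),
                     "peaks_per_gene": hist}
    return out


def homoeolog_sharing(annotated: pd.DataFrame, pairs: pd.DataFrame) -> pd.Series:
    """Shared / A-specific / B-specific fractions among methylated pairs.

    A homoeolog pair with both members methylated is shared; a pair with
    exactly one methylated member is specific to that subgenome.
    Fractions are over pairs with at least one methylated member.
    """
    methylated = set(annotated["gene_id"])
    shared = a_only = b_only = 0
    for r in pairs.itertuples(index=False):
        ma, mb = r.gene_A in methylated, r.gene_B in methylated
        if ma and mb:
            shared += 1
        elif ma:
            a_only += 1
        elif mb:
            b_only += 1
    n = shared + a_only + b_only
    if n == 0:
        return pd.Series({"shared": np.nan, "A_specific": np.nan,
                          "B_specific": np.nan})
    return pd.Series({"shared": shared / n, "A_specific": a_only / n,
                      "B_specific": b_only / n})


def condition_compare(peaks_ctl: pd.DataFrame, peaks_wl: pd.DataFrame,
                      gene_subgenome: pd.Series | None = None) -> dict:
    """Peak-number change and level-distribution shifts between conditions."""
    if not len(peaks_ctl):
        raise ValueError("no control peaks; nothing to compare")
    n_ctl, n_wl = len(peaks_ctl), len(peaks_wl)
    out = {"n_CTL": n_ctl, "n_WL": n_wl,
           "delta_fraction": (n_wl - n_ctl) / n_ctl}
    lv_c = peaks_ctl["log2_ratio"].to_numpy()
    lv_w = peaks_wl["log2_ratio"].to_numpy()
    out["level_test_conditions"] = (rank_sum_test(lv_c, lv_w)
                                    if len(lv_w) else None)
    if gene_subgenome is not None:
        per_sub = {}
        for s in ("A", "B"):
            in_a_c = peaks_ctl["gene_id"].map(gene_subgenome) == s
            in_a_w = peaks_wl["gene_id"].map(gene_subgenome) == s
            nc, nw = int(in_a_c.sum()), int(in_a_w.sum())
            per_sub[s] = {"n_CTL": nc, "n_WL": nw,
                          "delta_fraction": (nw - nc) / nc if nc else np.nan}
        out["per_subgenome"] = per_sub
        sub_c = peaks_ctl["gene_id"].map(gene_subgenome)
        a, b = lv_c[(sub_c == "A").to_numpy()], lv_c[(sub_c == "B").to_numpy()]
        if len(a) and len(b):
            out["level_test_subgenomes_CTL"] = rank_sum_test(a, b)
    return out


def differential_m6a(windows: pd.DataFrame, peaks_ctl: pd.DataFrame,
                     peaks_wl: pd.DataFrame, fdr_max: float = 0.05,
                     delta_min: float = 1.0) -> pd.DataFrame:
    """Per-region differential methylation between conditions.

    Regions are the union of called peak spans per gene (overlapping CTL
    and WL peaks merged).  For each region, the summed IP and input
    counts per condition form a 2x2 Fisher test of enrichment change;
    the level difference is the change in pseudocounted log2 normalized
    ratio.  Differential flag: BH-adjusted p < ``fdr_max`` and
    |delta log2| >= ``delta_min``.
    """
    libs = {}
    for cond in ("CTL", "WL"):
        sub = windows[windows["condition"] == cond]
        libs[cond] = (int(sub["ip"].sum()), int(sub["input"].sum()))
    spans = pd.concat([peaks_ctl[["gene_id", "win_lo", "win_hi"]],
                       peaks_wl[["gene_id", "win_lo", "win_hi"]]])
    regions = []
    for gene, grp in spans.groupby("gene_id", sort=True):
        ivs = sorted(zip(grp["win_lo"], grp["win_hi"]))
        cur = list(ivs[0])
        for lo, hi in ivs[1:]:
            if lo <= cur[1]:
                cur[1] = max(cur[1], hi)
            else:
                regions.append((gene, cur[0], cur[1]))
                cur = [lo, hi]
        regions.append((gene, cur[0], cur[1]))
    wix = windows.set_index(["condition", "gene_id"]).sort_index()
    rows = []
    for gene, lo, hi in regions:
        counts = {}
        for cond in ("CTL", "WL"):
            try:
                g = wix.loc[(cond, gene)]
            except KeyError:
                counts[cond] = (0, 0)
                continue
            m = (g["win_index"] >= lo) & (g["win_index"] < hi)
            counts[cond] = (int(g.loc[m, "ip"].sum()), int(g.loc[m, "input"].sum()))
        (ipc, inc), (ipw, inw) = counts["CTL"], counts["WL"]
        flagged = 0 in (ipc + inc, ipw + inw)
        res = fisher_exact(ipc, inc, ipw, inw) if not flagged else None
        lr_c = np.log2(((ipc + 0.5) / libs["CTL"][0]) / ((inc + 0.5) / libs["CTL"][1]))
        lr_w = np.log2(((ipw + 0.5) / libs["WL"][0]) / ((inw + 0.5) / libs["WL"][1]))
        rows.append((gene, lo, hi, ipc, inc, ipw, inw,
                     lr_c, lr_w, lr_w - lr_c,
                     res.p_value if res else 1.0, flagged))
    out = pd.DataFrame(rows, columns=[
        "gene_id", "win_lo", "win_hi", "ip_CTL", "input_CTL", "ip_WL",
        "input_WL", "log2_ratio_CTL", "log2_ratio_WL", "delta_log2", "p",
        "zero_track"])
    out["adj_p"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["differential"] = (out["adj_p"] < fdr_max) & \
        (out["delta_log2"].abs() >= delta_min)
    out["direction"] = np.where(~out["differential"], "none",
                                np.where(out["delta_log2"] > 0, "up", "down"))
    return out


def integrate_de_m6a(diff_m6a: pd.DataFrame, deg: pd.DataFrame) -> dict:
    """Cross-tabulate m6A change direction against expression change.

    Returns the 2x2 quadrant table over genes differential in both data
    sets, a Fisher test of direction concordance (odds ratio < 1 means
    m6A and expression move in opposite directions), and the per-quadrant
    gene lists.
    """
    m = diff_m6a[diff_m6a["differential"]].set_index("gene_id")["direction"]
    m = m[~m.index.duplicated(keep="first")]
    e = deg[deg["deg"]].copy()
    e["direction"] = np.where(e["log2fc"] > 0, "up", "down")
    e = e["direction"]
    common = m.index.intersection(e.index)
    if not len(common):
        logger.warning("no genes shared between differential m6A and DEGs")
    table = np.zeros((2, 2), dtype=int)
    quadrants: dict[str, list[str]] = {}
    for md in ("up", "down"):
        for ed in ("up", "down"):
            genes = [g for g in common if m[g] == md and e[g] == ed]
            quadrants[f"m6a_{md}__expr_{ed}"] = genes
            table[0 if md == "up" else 1, 0 if ed == "up" else 1] = len(genes)
    if table.sum() > 0:
        test = fisher_exact(int(table[0, 0]), int(table[0, 1]),
                            int(table[1, 0]), int(table[1, 1]))
    else:
        test = None
    return {"table": pd.DataFrame(table, index=["m6a_up", "m6a_down"],
                                  columns=["expr_up", "expr_down"]),
            "concordance_test": test, "quadrants": quadrants,
            "n_common": int(table.sum())}
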