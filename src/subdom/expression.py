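"""Expression analysis: TPM, expressed-gene filter, negative-binomial
differential testing, homoeolog bias classification, singleton comparison
and per-subgenome DEG accounting.

The differential engine is a vectorized negative-binomial Wald test with
median-of-ratios size factors and moderated method-of-moments dispersion
(gene-wise estimates shrunk toward the global trend; the few degrees of
freedom at typical replicate numbers make raw gene-wise estimates far too
unstable for calibrated testing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from subdom.homoeology import HomoeologMap
from subdom.stats import TestResult, bh_adjust, rank_sum_test

logger = logging.getLogger(__name__)

_LN2 = np.log(2.0)
_DISP_FLOOR = 1e-8
_DISP_PRIOR_DF = 10.0


@dataclass
class ExpressionTable:
    """Gene x sample counts with effective lengths and sample metadata."""

    counts: pd.DataFrame
    effective_length: pd.Series  # bp per gene
    samples: pd.DataFrame  # sample, tissue, condition, replicate

    def __post_init__(self) -> None:
        missing = self.counts.index.difference(self.effective_length.index)
        if len(missing):
            raise ValueError(f"no effective length for gene {missing[0]!r}")
        if (self.effective_length.loc[self.counts.index] <= 0).any():
            raise ValueError("effective lengths must be positive")


def compute_tpm(table: ExpressionTable) -> pd.DataFrame:
    """Transcripts per million; every column sums to 1e6."""
    lengths_kb = table.effective_length.loc[table.counts.index] / 1000.0
    rate = table.counts.div(lengths_kb, axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum[colsum == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total counts")
    return rate.div(colsum, axis=1) * 1e6


def filter_expressed(tpm: pd.DataFrame, threshold: float = 0.1) -> pd.Index:
    """Genes with TPM strictly above threshold in at least one sample."""
    return tpm.index[(tpm > threshold).any(axis=1)]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios normalization factors."""
    logs = np.log(counts.where(counts > 0))
    log_geo = logs.mean(axis=1)
    usable = log_geo.notna() & np.isfinite(log_geo)
    if not usable.any():
        raise ValueError("no gene has positive counts in every sample")
    ratios = logs.loc[usable].sub(log_geo[usable], axis=0)
    return np.exp(ratios.median(axis=0))


def _moderated_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Method-of-moments dispersion per gene, shrunk toward the global trend."""
    n_obs = sum(g.size for g in groups)
    resid_df = n_obs - len(groups)
    mean_all = np.zeros(norm.shape[0])
    ss = np.zeros(norm.shape[0])
    for idx in groups:
        sub = norm[:, idx]
        mu = sub.mean(axis=1)
        ss += ((sub - mu[:, None]) ** 2).sum(axis=1)
        mean_all += mu * (idx.size / n_obs)
    pooled_var = ss / max(resid_df, 1)
    grand = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (pooled_var - grand) / np.maximum(grand, 1e-12) ** 2
    raw = np.clip(raw, _DISP_FLOOR, None)
    pos = raw[(grand > 0) & np.isfinite(raw)]
    prior = float(np.mean(np.clip(pos, 0, np.quantile(pos, 0.95)))) if pos.size else _DISP_FLOOR
    shrunk = (resid_df * raw + _DISP_PRIOR_DF * prior) / (resid_df + _DISP_PRIOR_DF)
    return np.clip(shrunk, _DISP_FLOOR, None)


def nb_wald(counts1: np.ndarray, counts2: np.ndarray,
            pseudocount: float = 0.5) -> pd.DataFrame:
    """Vectorized NB Wald test between two replicate groups (rows = genes).

    Counts are assumed already normalized (divide by size factors first).
    Returns columns log2fc (group2 over group1), se, stat, p.
    """
    n1, n2 = counts1.shape[1], counts2.shape[1]
    norm = np.hstack([counts1, counts2])
    groups = [np.arange(n1), np.arange(n1, n1 + n2)]
    disp = _moderated_dispersion(norm, groups)
    mu1 = counts1.mean(axis=1)
    mu2 = counts2.mean(axis=1)
    lfc = np.log2((mu2 + pseudocount) / (mu1 + pseudocount))
    v1 = (mu1 + pseudocount + disp * (mu1 + pseudocount) ** 2) / n1
    v2 = (mu2 + pseudocount + disp * (mu2 + pseudocount) ** 2) / n2
    var_log = (v1 / (mu1 + pseudocount) ** 2 + v2 / (mu2 + pseudocount) ** 2)
    se = np.sqrt(var_log) / _LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = lfc / se
    from scipy.stats import norm as _norm

    p = 2.0 * _norm.sf(np.abs(stat))
    return pd.DataFrame({"log2fc": lfc, "se": se, "stat": stat,
                         "p": np.minimum(p, 1.0), "dispersion": disp})


def nb_differential(table: ExpressionTable, contrast: tuple[str, str],
                    fc_min: float = 2.0, fdr_max: float = 0.05,
                    normalize: bool = True) -> pd.DataFrame:
    """Differential expression between two conditions of the sample sheet.

    DEG flag requires |log2FC| > log2(fc_min) (strict) and BH-adjusted
    p < fdr_max (strict).  Genes with zero counts in every sample of the
    contrast are excluded from testing and reported with NaN statistics.
    """
    c1, c2 = contrast
    s1 = table.samples.loc[table.samples["condition"] == c1, "sample"]
    s2 = table.samples.loc[table.samples["condition"] == c2, "sample"]
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("each condition needs >= 2 replicates")
    sub = table.counts[list(s1) + list(s2)]
    if normalize:
        sf = size_factors(sub)
        norm = sub / sf
    else:
        norm = sub.astype(float)
    nonzero = norm.sum(axis=1) > 0
    excluded = norm.index[~nonzero]
    if len(excluded):
        logger.info("%d all-zero genes excluded from testing", len(excluded))
    res = nb_wald(norm.loc[nonzero, list(s1)].to_numpy(),
                  norm.loc[nonzero, list(s2)].to_numpy())
    res.index = norm.index[nonzero]
    res["adj_p"] = bh_adjust(res["p"].to_numpy())
    res["deg"] = (np.abs(res["log2fc"]) > np.log2(fc_min)) & (res["adj_p"] < fdr_max)
    res = res.reindex(norm.index)
    res["deg"] = res["deg"].eq(True)
    return res


def homoeolog_bias(table: ExpressionTable, hmap: HomoeologMap,
                   adj_p_max: float = 0.01,
                   pooling: str = "any") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify each homoeolog pair as A-dominant, B-dominant or unbiased.

    Within each tissue the A and B counts of a pair (same libraries, so no
    between-condition normalization applies) are contrasted with the NB
    Wald engine, replicates as units; the pair is biased in that tissue
    when BH-adjusted p < ``adj_p_max``, directed by the sign of log2FC
    (A over B).  Pooled class: biased in >= 1 tissue (``pooling="any"``,
    default) or in a majority of tissues (``"majority"``), direction from
    the most significant tissue.

    Returns (per-tissue calls, pooled per-pair calls).
    """
    pairs = hmap.pairs
    have = pairs["gene_A"].isin(table.counts.index) & \
        pairs["gene_B"].isin(table.counts.index)
    skipped = int((~have).sum())
    if skipped:
        logger.info("%d pairs missing from counts; skipped", skipped)
    pairs = pairs[have]
    tissues = [t for t in table.samples["tissue"].unique()
               if (table.samples["tissue"] == t).sum() >= 2]
    percall = []
    for t in tissues:
        in_tissue = table.samples["tissue"] == t
        plain = in_tissue & (table.samples["condition"] == "none")
        cols = table.samples.loc[plain if plain.sum() >= 2 else in_tissue, "sample"]
        if len(cols) < 2:
            continue
        a = table.counts.loc[pairs["gene_A"], cols].to_numpy(dtype=float)
        b = table.counts.loc[pairs["gene_B"], cols].to_numpy(dtype=float)
        both_zero = (a.sum(axis=1) + b.sum(axis=1)) == 0
        res = nb_wald(b, a)  # log2fc = A over B
        res["adj_p"] = bh_adjust(res["p"].to_numpy())
        res.loc[both_zero, ["log2fc", "stat"]] = np.nan
        res.loc[both_zero, ["p", "adj_p"]] = 1.0
        res.insert(0, "tissue", t)
        res.insert(0, "pair_gene_B", pairs["gene_B"].to_numpy())
        res.insert(0, "pair_gene_A", pairs["gene_A"].to_numpy())
        sig = (res["adj_p"] < adj_p_max) & ~both_zero
        res["class"] = np.where(sig & (res["log2fc"] > 0), "A-dominant",
                                np.where(sig & (res["log2fc"] < 0), "B-dominant",
                                         "unbiased"))
        percall.append(res)
    calls = pd.concat(percall, ignore_index=True)

    # pooled per-pair summary (vectorized: tissue of minimal adj_p gives sign)
    key = ["pair_gene_A", "pair_gene_B"]
    agg = (calls.assign(is_biased=calls["class"] != "unbiased")
                .groupby(key, sort=True)
                .agg(n_tissues=("is_biased", "size"),
                     n_biased=("is_biased", "sum")))
    top = (calls.sort_values("adj_p", kind="mergesort")
                .drop_duplicates(subset=key, keep="first")
                .set_index(key)[["log2fc", "adj_p"]])
    pooled = agg.join(top).reset_index()
    need = 1 if pooling == "any" else pooled["n_tissues"] // 2 + 1
    sig = pooled["n_biased"] >= need
    pooled["class"] = np.where(~sig, "unbiased",
                               np.where(pooled["log2fc"] > 0, "A-dominant",
                                        "B-dominant"))
    return calls, pooled


def bias_percentage(n_biased: int, n_pairs: int) -> float:
    """Percent of expressed homoeolog pairs called biased."""
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    return 100.0 * n_biased / n_pairs


def singleton_comparison(tpm: pd.DataFrame, hmap: HomoeologMap) -> TestResult:
    """Rank-sum test of per-gene mean TPM between A and B singletons."""
    a = [g for g in hmap.singletons_A if g in tpm.index]
    b = [g for g in hmap.singletons_B if g in tpm.index]
    if not a or not b:
        raise ValueError("both singleton sets must be nonempty")
    return rank_sum_test(tpm.loc[a].mean(axis=1).to_numpy(),
                         tpm.loc[b].mean(axis=1).to_numpy())


def subgenome_deg_summary(deg: pd.DataFrame, gene_subgenome: pd.Series) -> pd.DataFrame:
    """Up/down/total DEG counts and rates per subgenome.

    ``deg`` is the nb_differential output; rate = DEGs / annotated genes
    of that subgenome.
    """
    sub = gene_subgenome.reindex(deg.index)
    rows = []
    for s in ("A", "B"):
        mask = sub == s
        d = deg.loc[mask]
        up = int((d["deg"] & (d["log2fc"] > 0)).sum())
        down = int((d["deg"] & (d["log2fc"] < 0)).sum())
        n = int(mask.sum())
        rows.append((s, up, down, up + down, n, (up + down) / n if n else np.nan))
    return pd.DataFrame(rows, columns=["subgenome", "up", "down", "total",
                                       "n_genes", "rate"])
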