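"""Homoeolog pairing by collinear anchor chaining, and fractionation profiles.

Pairing works in gene-rank space: anchors between the two subgenomes are
chained where consecutive anchors advance by at most ``max_gap``
intervening genes on both chromosomes in a consistent orientation
(forward or inverted).  Blocks of at least ``min_block`` anchors are kept;
within a block each gene is used at most once (assignment by descending
similarity), and block-spanned genes left unpaired become singletons of
their subgenome.  Genes outside every block remain unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from subdom.stats import TestResult

logger = logging.getLogger(__name__)


@dataclass
class HomoeologMap:
    pairs: pd.DataFrame  # gene_A, gene_B, block_id, similarity
    singletons_A: list[str] = field(default_factory=list)
    singletons_B: list[str] = field(default_factory=list)
    unassigned: list[str] = field(default_factory=list)

    def partner(self) -> dict[str, str]:
        """Symmetric gene -> partner lookup over all pairs."""
        out = {}
        for r in self.pairs.itertuples(index=False):
            out[r.gene_A] = r.gene_B
            out[r.gene_B] = r.gene_A
        return out


def _gene_ranks(genes: pd.DataFrame) -> pd.DataFrame:
    """Rank of each gene along its chromosome by start coordinate."""
    g = genes.sort_values(["chrom", "start"], kind="mergesort").copy()
    g["rank"] = g.groupby("chrom").cumcount()
    return g


def pair_homoeologs(genes: pd.DataFrame, hits: pd.DataFrame,
                    max_gap: int = 10, min_block: int = 5) -> HomoeologMap:
    """Chain anchor hits into collinear blocks and assign homoeolog pairs.

    ``genes`` needs columns gene_id, chrom, subgenome, start;
    ``hits`` needs gene_A, gene_B, similarity.
    """
    ranked = _gene_ranks(genes).set_index("gene_id")
    known = set(ranked.index)
    bad = [g for g in pd.concat([hits["gene_A"], hits["gene_B"]]) if g not in known]
    if bad:
        raise ValueError(f"anchor hit references unknown gene {bad[0]!r}")
    hits = hits.copy()
    dup = hits.duplicated(subset=["gene_A", "gene_B"], keep=False)
    if dup.any():
        logger.info("collapsing %d duplicate anchor hits (max similarity kept)",
                    int(dup.sum()))
        hits = (hits.sort_values("similarity", ascending=False)
                    .drop_duplicates(subset=["gene_A", "gene_B"], keep="first"))
    hits["chrom_A"] = ranked.loc[hits["gene_A"], "chrom"].to_numpy()
    hits["chrom_B"] = ranked.loc[hits["gene_B"], "chrom"].to_numpy()
    hits["rank_A"] = ranked.loc[hits["gene_A"], "rank"].to_numpy()
    hits["rank_B"] = ranked.loc[hits["gene_B"], "rank"].to_numpy()
    sub_a = ranked.loc[hits["gene_A"], "subgenome"].to_numpy()
    sub_b = ranked.loc[hits["gene_B"], "subgenome"].to_numpy()
    if len(hits) and (np.any(sub_a == sub_b)):
        raise ValueError("anchor hit joins genes of the same subgenome")

    blocks = []  # list of DataFrames
    step = max_gap + 1
    for (_ca, _cb), sub in hits.groupby(["chrom_A", "chrom_B"], sort=True):
        sub = sub.sort_values(["rank_A", "rank_B"], kind="mergesort")
        chain: list[pd.Series] = []
        direction = 0
        for _, h in sub.iterrows():
            if chain:
                da = h["rank_A"] - chain[-1]["rank_A"]
                db = h["rank_B"] - chain[-1]["rank_B"]
                want = direction if direction else (1 if db > 0 else -1)
                ok = 0 < da <= step and 0 < db * want <= step
                if ok:
                    direction = want
                    chain.append(h)
                    continue
                blocks.append(pd.DataFrame(chain))
                chain, direction = [h], 0
            else:
                chain.append(h)
        if chain:
            blocks.append(pd.DataFrame(chain))

    pairs_rows = []
    singles_a: set[str] = set()
    singles_b: set[str] = set()
    used: set[str] = set()
    block_id = 0
    by_chrom_rank = _gene_ranks(genes)
    for blk in blocks:
        if len(blk) < min_block:
            continue
        block_id += 1
        blk = blk.sort_values("similarity", ascending=False, kind="mergesort")
        kept = []
        for _, h in blk.iterrows():
            if h["gene_A"] in used or h["gene_B"] in used:
                continue
            used.update((h["gene_A"], h["gene_B"]))
            kept.append((h["gene_A"], h["gene_B"], f"block_{block_id:04d}",
                         float(h["similarity"])))
            pairs_rows.append(kept[-1])
        # genes inside the block span but unpaired -> singletons
        for side, chrom_col, rank_col, bag in (
            ("A", "chrom_A", "rank_A", singles_a),
            ("B", "chrom_B", "rank_B", singles_b),
        ):
            chrom = blk[chrom_col].iloc[0]
            lo, hi = blk[rank_col].min(), blk[rank_col].max()
            span = by_chrom_rank[(by_chrom_rank["chrom"] == chrom)
                                 & (by_chrom_rank["rank"] >= lo)
                                 & (by_chrom_rank["rank"] <= hi)]
            bag.update(span["gene_id"])

    pairs = pd.DataFrame(pairs_rows,
                         columns=["gene_A", "gene_B", "block_id", "similarity"])
    singles_a -= used
    singles_b -= used
    all_genes = set(genes["gene_id"])
    unassigned = sorted(all_genes - used - singles_a - singles_b)
    if not len(hits):
        # no anchors at all: every gene is a singleton of its own subgenome
        singles_a = set(genes.loc[genes["subgenome"] == "A", "gene_id"])
        singles_b = set(genes.loc[genes["subgenome"] == "B", "gene_id"])
        unassigned = []
    return HomoeologMap(pairs=pairs, singletons_A=sorted(singles_a),
                        singletons_B=sorted(singles_b), unassigned=unassigned)


def fractionation_profile(ancestral_order: pd.DataFrame, genes: pd.DataFrame,
                          window_genes: int = 100,
                          step: int | None = None) -> pd.DataFrame:
    """Sliding-window gene retention rates along the ancestral order.

    ``ancestral_order`` has one row per ancestral gene slot (columns
    slot_chrom, slot, gene_A, gene_B; empty/NaN when lost).  Retention is
    checked against the gene set actually present in ``genes``.  Windows
    of ``window_genes`` slots advance by ``step`` (default: non-overlapping).
    """
    step = step or window_genes
    present = set(genes["gene_id"])
    rows = []
    for chrom, sub in ancestral_order.groupby("slot_chrom", sort=True):
        sub = sub.sort_values("slot")
        in_a = sub["gene_A"].fillna("").astype(str).isin(present).to_numpy()
        in_b = sub["gene_B"].fillna("").astype(str).isin(present).to_numpy()
        n = len(sub)
        if window_genes > n:
            logger.warning("window (%d) larger than chromosome %s slots (%d); "
                           "single truncated window", window_genes, chrom, n)
        starts = range(0, n, step) if window_genes <= n else [0]
        for s in starts:
            e = min(s + window_genes, n)
            if e - s < max(1, window_genes // 2) and s > 0:
                continue  # drop tiny trailing remainder windows
            wa, wb = in_a[s:e], in_b[s:e]
            rows.append((chrom, s, e - s,
                         wa.mean(), wb.mean(), (wa & wb).mean()))
    return pd.DataFrame(rows, columns=["slot_chrom", "start_slot", "n_slots",
                                       "rate_A", "rate_B", "rate_both"])


def retention_balance_test(profile: pd.DataFrame) -> TestResult:
    """Paired Wilcoxon signed-rank test of rate_A vs rate_B across windows."""
    from scipy.stats import wilcoxon

    if len(profile) < 2:
        raise ValueError("retention balance test needs at least 2 windows")
    diff = (profile["rate_A"] - profile["rate_B"]).to_numpy()
    effect = float(diff.mean())
    if np.allclose(diff, 0.0):
        return TestResult(statistic=0.0, p_value=1.0, effect=0.0)
    res = wilcoxon(diff, zero_method="wilcox", mode="auto")
    return TestResult(statistic=float(res.statistic),
                      p_value=float(res.pvalue), effect=effect)
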