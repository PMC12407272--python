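"""TE load, LTR turnover statistics, and DNA-methylation levels/metaprofiles.

Methylation averaging is read-weighted throughout (sum of methylated reads
over sum of total reads), which is the robust choice under uneven
coverage; sites with zero coverage contribute nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from subdom.model import Genome, IntervalSet
from subdom.stats import TestResult, rank_sum_test

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass(frozen=True)
class LTRRecord:
    id: str
    subgenome: str
    kind: str  # "solo" or "intact"
    ltr_divergence: float | None = None  # per-site substitutions, intact only
    family: str = "other"

    def __post_init__(self) -> None:
        if self.kind not in ("solo", "intact"):
            raise ValueError(f"{self.id}: kind must be solo or intact")
        if (self.ltr_divergence is not None) != (self.kind == "intact"):
            raise ValueError(f"{self.id}: divergence present iff intact")
        if self.ltr_divergence is not None and self.ltr_divergence < 0:
            raise ValueError(f"{self.id}: negative divergence")


def _merge(ivs: np.ndarray) -> np.ndarray:
    """Merge sorted-or-not (n, 2) half-open intervals."""
    if len(ivs) == 0:
        return ivs.reshape(0, 2)
    ivs = ivs[np.argsort(ivs[:, 0])]
    out = [ivs[0].tolist()]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out)


def span_gap(starts: np.ndarray, ends: np.ndarray, ivs: np.ndarray) -> np.ndarray:
    """Gap in bp between each half-open span and its nearest interval.

    0 when overlapping or abutting; expects ``ivs`` merged and sorted.
    """
    if len(ivs) == 0:
        return np.full(starts.shape, np.inf)
    s_iv, e_iv = ivs[:, 0], ivs[:, 1]
    left = np.searchsorted(s_iv, starts, side="right") - 1
    left_c = np.clip(left, 0, len(s_iv) - 1)
    gap_left = np.where(left >= 0, starts - e_iv[left_c], np.inf)
    nxt = np.clip(left + 1, 0, len(s_iv) - 1)
    gap_right = np.where(left + 1 < len(s_iv), s_iv[nxt] - ends, np.inf)
    return np.minimum(np.maximum(gap_left, 0), np.maximum(gap_right, 0))


def te_content(tes: IntervalSet, genome: Genome) -> pd.Series:
    """Fraction of each subgenome covered by (merged) TEs."""
    covered = {"A": 0, "B": 0}
    for chrom, sub in tes.df.groupby("chrom"):
        merged = _merge(sub[["start", "end"]].to_numpy())
        covered[genome.subgenome_of(chrom)] += int((merged[:, 1] - merged[:, 0]).sum())
    return pd.Series({s: covered[s] / genome.subgenome_bp(s) for s in ("A", "B")})


def nearest_te_distance(genes: pd.DataFrame, tes: IntervalSet,
                        genome: Genome) -> tuple[pd.DataFrame, TestResult]:
    """Span-to-span distance from each gene to its nearest TE.

    Genes on chromosomes without any TE get NaN and are excluded from the
    between-subgenome rank-sum comparison.
    """
    by_chrom = {c: _merge(s[["start", "end"]].to_numpy())
                for c, s in tes.df.groupby("chrom")}
    dist = np.full(len(genes), np.nan)
    for chrom, idx in genes.groupby("chrom").groups.items():
        ivs = by_chrom.get(chrom)
        if ivs is None or not len(ivs):
            logger.warning("chromosome %s has no TE; %d genes excluded",
                           chrom, len(idx))
            continue
        g = genes.loc[idx]
        starts, ends = g["start"].to_numpy(), g["end"].to_numpy()
        dist[genes.index.get_indexer(idx)] = span_gap(starts, ends, ivs)
    out = genes[["gene_id", "chrom", "subgenome"]].copy()
    out["te_distance"] = dist
    a = out.loc[(out["subgenome"] == "A") & out["te_distance"].notna(), "te_distance"]
    b = out.loc[(out["subgenome"] == "B") & out["te_distance"].notna(), "te_distance"]
    if len(a) and len(b):
        test = rank_sum_test(a.to_numpy(), b.to_numpy())
    else:
        test = TestResult(np.nan, np.nan, np.nan)
    return out, test


def solo_intact_ratio(ltrs: list[LTRRecord]) -> pd.Series:
    """solo:intact LTR count ratio per subgenome."""
    out = {}
    for sub in ("A", "B"):
        solo = sum(1 for r in ltrs if r.subgenome == sub and r.kind == "solo")
        intact = sum(1 for r in ltrs if r.subgenome == sub and r.kind == "intact")
        if any(r.subgenome == sub for r in ltrs):
            if intact == 0:
                raise ValueError(f"subgenome {sub}: no intact LTR, ratio undefined")
            out[sub] = solo / intact
    return pd.Series(out)


def ltr_insertion_age(record: LTRRecord, mu: float) -> float:
    """Insertion age in years: divergence / (2 * mu), mu in subs/site/year."""
    if mu <= 0:
        raise ValueError("substitution rate mu must be positive")
    if record.kind != "intact" or record.ltr_divergence is None:
        raise ValueError(f"{record.id}: age defined only for intact LTRs")
    return record.ltr_divergence / (2.0 * mu)


def global_methylation(meth: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """Read-weighted methylation level per (subgenome, context)."""
    df = meth.copy()
    df["subgenome"] = df["chrom"].map({c.id: c.subgenome for c in genome.chromosomes})
    g = df.groupby(["subgenome", "context"])[["mc_count", "total_count"]].sum()
    g["level"] = np.where(g["total_count"] > 0,
                          g["mc_count"] / g["total_count"], np.nan)
    empty = g[g["total_count"] == 0]
    if len(empty):
        logger.warning("no covered cytosine in %d strata", len(empty))
    return g.reset_index()


def metaprofile(meth: pd.DataFrame, regions: IntervalSet, genome: Genome,
                flank_bp: int = 2000, body_bins: int = 20,
                flank_bins: int = 20) -> pd.DataFrame:
    """Read-weighted methylation metaprofile over regions with flanks.

    Bin layout (5'->3', strand-aware when the region carries a strand):
    ``flank_bins`` fixed-bp upstream bins, ``body_bins`` length-normalized
    body bins, ``flank_bins`` downstream bins.  Bins without any covered
    cytosine are emitted with NaN level, never zero.
    """
    if len(regions) == 0:
        raise ValueError("regions must be nonempty")
    n_bins = body_bins + 2 * flank_bins
    mc = np.zeros((len(CONTEXTS), n_bins))
    tot = np.zeros_like(mc)
    meth_sorted = meth.sort_values(["chrom", "pos"], kind="mergesort")
    ctx_code = pd.Categorical(meth_sorted["context"], categories=CONTEXTS).codes
    by_chrom = {c: (s["pos"].to_numpy(),
                    s["mc_count"].to_numpy(),
                    s["total_count"].to_numpy(),
                    ctx_code[meth_sorted["chrom"].to_numpy() == c])
                for c, s in meth_sorted.groupby("chrom")}
    short = 0
    for r in regions.df.itertuples(index=False):
        if r.chrom not in by_chrom:
            continue
        pos, mcc, tcc, ctx = by_chrom[r.chrom]
        lo = np.searchsorted(pos, r.start - flank_bp, side="left")
        hi = np.searchsorted(pos, r.end + flank_bp, side="left")
        if hi <= lo:
            continue
        p = pos[lo:hi]
        body_len = r.end - r.start
        if body_len < body_bins:
            short += 1
        binidx = np.empty(p.size, dtype=np.int64)
        left = p < r.start
        right = p >= r.end
        body = ~(left | right)
        binidx[left] = np.clip((p[left] - (r.start - flank_bp))
                               * flank_bins // flank_bp, 0, flank_bins - 1)
        binidx[body] = flank_bins + np.clip(
            (p[body] - r.start) * body_bins // body_len, 0, body_bins - 1)
        binidx[right] = flank_bins + body_bins + np.clip(
            (p[right] - r.end) * flank_bins // flank_bp, 0, flank_bins - 1)
        if r.strand == "-":
            binidx = n_bins - 1 - binidx
        np.add.at(mc, (ctx[lo:hi], binidx), mcc[lo:hi])
        np.add.at(tot, (ctx[lo:hi], binidx), tcc[lo:hi])
    if short:
        logger.info("%d regions shorter than body_bins; coarse body binning", short)
    kinds = (["upstream"] * flank_bins + ["body"] * body_bins
             + ["downstream"] * flank_bins)
    rows = []
    for ci, ctx in enumerate(CONTEXTS):
        for b in range(n_bins):
            level = mc[ci, b] / tot[ci, b] if tot[ci, b] > 0 else np.nan
            rows.append((ctx, b, kinds[b], level, int(tot[ci, b])))
    return pd.DataFrame(rows, columns=["context", "bin_index", "bin_kind",
                                       "level", "n_reads"])
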