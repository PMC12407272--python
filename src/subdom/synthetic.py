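"""Seeded generator of a complete synthetic allotetraploid dataset bundle.

The generator emulates the statistical structure the analysis stages
assume, with truth tables sufficient to score every downstream call:

* two phased subgenomes (A, B) with a shared ancestral gene order and
  unbiased fractionation to homoeolog pairs and singletons;
* homoeolog expression bias toward subgenome A in a configurable fraction
  of pairs, negative-binomial replicate counts over five tissues plus a
  control/waterlogging contrast with per-subgenome DEG rates;
* asymmetric TE load (denser in B) with DNA methylation spreading
  exponentially from TE edges in the CG/CHG/CHH contexts;
* proximal accessible-chromatin regions lost independently per subgenome
  and additionally destroyed in B by recorded insertion variants, with
  progenitor genotypes matching the carrying subgenome at a set rate;
* 3'UTR-weighted m6A peaks whose IP enrichment disappears for a set
  fraction of peaks under waterlogging, plus differential-level peaks
  coupled (repressively) to expression changes.

Every generator is a pure function of (config, seed): the bundle is
byte-identical across runs at a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from subdom import io as sio
from subdom.model import Chromosome, GeneModel, Genome, IntervalSet

TISSUES = ("leaf", "root", "stem", "peel", "pulp")
CONDITIONS = ("CTL", "WL")

# fixed substream codes so adding a generator never perturbs the others
_STREAMS = {
    "genome": 0,
    "tes": 1,
    "methylome": 2,
    "acrs": 3,
    "variants": 4,
    "expression": 5,
    "m6a": 6,
    "anchors": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class SimConfig:
    """All knobs of the synthetic bundle; defaults are the study conditions.

    Fractions are probabilities in [0, 1]; densities are per Mb; lengths in
    bp.  ``bias_fraction``/``bias_toward_A`` target the observed ~70% of
    homoeolog pairs biased, predominantly toward subgenome A;
    ``ancestry_match_p`` targets the 77.3% progenitor genotype match;
    ``m6a_loss_fraction`` the ~16% peak loss under waterlogging; the DEG
    fractions the 20%/19% per-subgenome waterlogging response.
    """

    n_chrom_per_subgenome: int = 5
    genes_per_chrom: int = 1000
    # homoeology / fractionation
    pair_fraction: float = 0.6
    # expression bias
    bias_fraction: float = 0.70
    bias_log2fc: float = 2.0
    bias_toward_A: float = 0.8
    # TEs
    te_density_A: float = 150.0
    te_density_B: float = 225.0
    te_len_bp: int = 800
    # methylation
    meth_te_level: dict = field(
        default_factory=lambda: {"CG": 0.85, "CHG": 0.65, "CHH": 0.12}
    )
    meth_background: dict = field(
        default_factory=lambda: {"CG": 0.10, "CHG": 0.05, "CHH": 0.02}
    )
    meth_decay_bp: float = 500.0
    meth_site_spacing_bp: int = 100
    meth_coverage: float = 20.0
    # ACRs and variants
    acr_prob_A: float = 0.6
    acr_prob_B: float = 0.5
    acr_indel_loss_prob: float = 0.1
    acr_constitutive_p: float = 0.6
    acr_width_bp: int = 200
    acr_upstream_gap_bp: int = 100
    ancestry_match_p: float = 0.773
    specific_var_rate: float = 3.0
    conserved_var_rate: float = 1.0
    var_missing_p: float = 0.02
    indel_len_bp: int = 126
    # m6A
    m6a_peak_prob: float = 0.6
    m6a_pair_shared: float = 0.82
    m6a_pair_A_only: float = 0.15
    m6a_pair_B_only: float = 0.03
    m6a_utr3_weight: float = 0.8
    m6a_loss_fraction: float = 0.16
    m6a_diff_fraction: float = 0.08
    m6a_diff_log2fc: float = 2.0
    m6a_repression_coupling: float = 0.7
    m6a_input_depth: float = 10.0
    m6a_ip_background: float = 3.0
    m6a_enrichment: float = 10.0
    m6a_peak_windows: int = 3
    m6a_bin_bp: int = 50
    # expression / DEGs
    deg_fraction_A: float = 0.20
    deg_fraction_B: float = 0.19
    deg_up_fraction: float = 0.44
    deg_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    replicates: int = 3
    expr_mean: float = 200.0
    expr_log_sd: float = 1.0
    tissue_log_sd: float = 0.5
    # geometry
    gene_len_bp: int = 1000
    gene_spacing_bp: int = 4000
    utr5_len_bp: int = 200
    utr3_len_bp: int = 400
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "pair_fraction", "bias_fraction", "bias_toward_A", "acr_prob_A",
            "acr_prob_B", "acr_indel_loss_prob", "acr_constitutive_p",
            "ancestry_match_p", "m6a_peak_prob", "m6a_utr3_weight",
            "m6a_loss_fraction", "m6a_diff_fraction", "m6a_repression_coupling",
            "deg_fraction_A", "deg_fraction_B", "deg_up_fraction", "var_missing_p",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2 for downstream variance")
        if self.gene_len_bp + 2 * self.acr_width_bp + 2 * self.acr_upstream_gap_bp \
                > self.gene_spacing_bp:
            raise ValueError(
                "infeasible geometry: genes plus ACR windows exceed gene spacing"
            )
        if self.utr5_len_bp + self.utr3_len_bp >= self.gene_len_bp:
            raise ValueError("UTRs must not exhaust the gene body")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class DatasetBundle:
    """In-memory handles plus the directory the files were written to."""

    outdir: Path | None
    config: SimConfig
    genome: Genome
    genes: pd.DataFrame  # gene_id, chrom, subgenome, strand, start, end, slot_chrom, slot
    gene_models: list[GeneModel]
    ancestral_order: pd.DataFrame
    anchors: pd.DataFrame
    tes: IntervalSet
    acrs: IntervalSet
    methylation: pd.DataFrame
    counts: pd.DataFrame
    samples: pd.DataFrame
    m6a_windows: pd.DataFrame
    variants: pd.DataFrame
    truth_pairs: pd.DataFrame
    truth_bias: pd.DataFrame
    truth_deg: pd.DataFrame
    truth_acrs: pd.DataFrame
    truth_peaks: pd.DataFrame


# ---------------------------------------------------------------------------
# genome, genes, fractionation truth
# ---------------------------------------------------------------------------

def _chrom_id(idx: int, sub: str) -> str:
    return f"chr{idx:02d}{sub}"


def _gene_id(idx: int, sub: str, slot: int) -> str:
    return f"g{idx:02d}{sub}_{slot:05d}"


def simulate_genome_and_genes(config: SimConfig):
    """Lay out both subgenomes from a shared ancestral slot order.

    Each ancestral slot is retained in both subgenomes with probability
    ``pair_fraction`` and otherwise in exactly one (chosen evenly:
    fractionation is unbiased by construction).  Genes sit on a uniform
    grid with per-subgenome jitter; strands alternate deterministically
    with the slot parity of the ancestral gene.
    """
    rng = _rng(config.seed, "genome")
    n_slots = config.genes_per_chrom
    spacing = config.gene_spacing_bp
    chrom_len = n_slots * spacing + spacing
    chroms, gene_rows, slot_rows, models = [], [], [], []
    margin = (spacing - config.gene_len_bp) // 2
    for ci in range(1, config.n_chrom_per_subgenome + 1):
        for sub in ("A", "B"):
            chroms.append(Chromosome(_chrom_id(ci, sub), sub, chrom_len))
        u = rng.random(n_slots)
        cls = np.where(
            u < config.pair_fraction, "both",
            np.where(u < config.pair_fraction + (1 - config.pair_fraction) / 2,
                     "A_only", "B_only"),
        )
        strands = np.where(rng.random(n_slots) < 0.5, "+", "-")
        jitter = rng.integers(-margin // 2, margin // 2 + 1, size=(n_slots, 2))
        for slot in range(n_slots):
            gids = {}
            for k, sub in enumerate(("A", "B")):
                if (cls[slot] == "both" or cls[slot] == f"{sub}_only"):
                    start = slot * spacing + margin + int(jitter[slot, k])
                    end = start + config.gene_len_bp
                    gid = _gene_id(ci, sub, slot)
                    gids[sub] = gid
                    gene_rows.append(
                        (gid, _chrom_id(ci, sub), sub, strands[slot], start, end, ci, slot)
                    )
                    models.append(
                        _gene_model(gid, _chrom_id(ci, sub), strands[slot], start, end,
                                    sub, config)
                    )
            slot_rows.append(
                (ci, slot, cls[slot], gids.get("A", ""), gids.get("B", ""))
            )
    genome = Genome(chroms)
    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "chrom", "subgenome", "strand", "start", "end",
                 "slot_chrom", "slot"],
    )
    ancestral = pd.DataFrame(
        slot_rows, columns=["slot_chrom", "slot", "class", "gene_A", "gene_B"]
    )
    return genome, genes, ancestral, models


def _gene_model(gid, chrom, strand, start, end, sub, config: SimConfig) -> GeneModel:
    u5, u3 = config.utr5_len_bp, config.utr3_len_bp
    if strand == "+":
        utr5 = [(start, start + u5)]
        cds = [(start + u5, end - u3)]
        utr3 = [(end - u3, end)]
    else:
        utr5 = [(end - u5, end)]
        cds = [(start + u3, end - u5)]
        utr3 = [(start, start + u3)]
    return GeneModel(gene_id=gid, chrom=chrom, strand=strand, start=start, end=end,
                     exons=[(start, end)], cds_span=cds, utr5=utr5, utr3=utr3,
                     subgenome=sub)


def simulate_anchors(ancestral: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Anchor hits for every true homoeolog pair, similarity ~ U(0.8, 1)."""
    rng = _rng(config.seed, "anchors")
    pairs = ancestral[ancestral["class"] == "both"]
    sim = 0.8 + 0.2 * rng.random(len(pairs))
    return pd.DataFrame(
        {"gene_A": pairs["gene_A"].to_numpy(),
         "gene_B": pairs["gene_B"].to_numpy(),
         "similarity": np.round(sim, 4)}
    )


# ---------------------------------------------------------------------------
# TEs and methylome
# ---------------------------------------------------------------------------

def simulate_tes(genome: Genome, genes: pd.DataFrame,
                 config: SimConfig) -> IntervalSet:
    """Poisson TE placement with subgenome-specific rate, fixed length.

    TEs land in intergenic space only: start positions are drawn uniformly
    over the set of placements that do not overlap a gene body, with the
    per-chromosome count Poisson(density x chromosome Mb).
    """
    rng = _rng(config.seed, "tes")
    rows = []
    gene_spans = {c: s[["start", "end"]].sort_values("start").to_numpy()
                  for c, s in genes.groupby("chrom")}
    te_len = config.te_len_bp
    for c in genome.chromosomes:
        dens = config.te_density_A if c.subgenome == "A" else config.te_density_B
        spans = gene_spans.get(c.id, np.empty((0, 2), dtype=int))
        # allowed start intervals: gaps between genes shrunk by the TE length
        bounds = [0, *spans.flatten(), c.length]
        allowed = []
        for lo, hi in zip(bounds[::2], bounds[1::2]):
            if hi - te_len > lo:
                allowed.append((lo, hi - te_len))
        allowed = np.asarray(allowed, dtype=np.int64)
        if not len(allowed):
            continue
        lens = allowed[:, 1] - allowed[:, 0]
        cum = np.concatenate([[0], np.cumsum(lens)])
        n = rng.poisson(dens * c.length / 1e6)
        u = np.sort(rng.integers(0, cum[-1], size=n))
        seg = np.searchsorted(cum, u, side="right") - 1
        starts = allowed[seg, 0] + (u - cum[seg])
        for i, s in enumerate(starts):
            rows.append((c.id, int(s), int(s) + te_len,
                         f"te_{c.id}_{i:05d}", 0.0, ".", "LTR", "."))
    return IntervalSet(pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "name", "score", "strand", "category", "sample"]))


def _merged_te_edges(tes: IntervalSet) -> dict[str, np.ndarray]:
    """Merged TE intervals per chromosome as an (n, 2) array."""
    out = {}
    for chrom, sub in tes.df.groupby("chrom", sort=True):
        ivs = sub[["start", "end"]].sort_values("start").to_numpy()
        merged = [ivs[0].tolist()]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.asarray(merged)
    return out


def distance_to_nearest(points: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest interval (0 when inside)."""
    if len(intervals) == 0:
        return np.full(points.shape, np.inf)
    starts, ends = intervals[:, 0], intervals[:, 1]
    idx = np.searchsorted(starts, points, side="right") - 1
    idx_c = np.clip(idx, 0, len(starts) - 1)
    inside = (idx >= 0) & (points < ends[idx_c])
    d_prev = np.where(idx >= 0, points - ends[idx_c] + 1, np.inf)
    nxt = np.clip(idx + 1, 0, len(starts) - 1)
    d_next = np.where(idx + 1 < len(starts), starts[nxt] - points, np.inf)
    d = np.minimum(np.maximum(d_prev, 0), np.maximum(d_next, 0))
    return np.where(inside, 0.0, d)


def simulate_methylome(tes: IntervalSet, genome: Genome, config: SimConfig) -> pd.DataFrame:
    """Per-cytosine binomial methylation with exponential spread from TEs.

    The mean level at distance d from the nearest TE edge is
    ``background + (plateau - background) * exp(-d / meth_decay_bp)`` per
    context (d = 0 inside TEs).  Cytosines are sampled on a regular grid
    (one site per context per ``meth_site_spacing_bp``) with read depth
    Poisson(``meth_coverage``).
    """
    rng = _rng(config.seed, "methylome")
    edges = _merged_te_edges(tes)
    frames = []
    spacing = config.meth_site_spacing_bp
    for c in genome.chromosomes:
        ivs = edges.get(c.id, np.empty((0, 2)))
        for k, ctx in enumerate(sio.METH_CONTEXTS):
            pos = np.arange(7 + 31 * k, c.length, spacing, dtype=np.int64)
            d = distance_to_nearest(pos.astype(float), ivs)
            bg = config.meth_background[ctx]
            plateau = config.meth_te_level[ctx]
            mean = bg + (plateau - bg) * np.exp(-d / config.meth_decay_bp)
            total = rng.poisson(config.meth_coverage, size=pos.size)
            mc = rng.binomial(total, mean)
            frames.append(pd.DataFrame({
                "chrom": c.id, "pos": pos, "context": ctx,
                "mc_count": mc, "total_count": total}))
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["chrom", "pos", "context"], kind="mergesort",
                          ignore_index=True)


# ---------------------------------------------------------------------------
# ACRs and variants
# ---------------------------------------------------------------------------

def _acr_interval(gene, config: SimConfig) -> tuple[int, int]:
    """Proximal ACR span at a fixed upstream offset from the gene TSS."""
    gap, width = config.acr_upstream_gap_bp, config.acr_width_bp
    if gene.strand == "+":
        return gene.start - gap - width, gene.start - gap
    return gene.end + gap, gene.end + gap + width


def simulate_acrs_and_variants(genes: pd.DataFrame, ancestral: pd.DataFrame,
                               config: SimConfig):
    """Place proximal ACRs, destroy some B copies by insertions, seed SNPs.

    Returns (acrs: IntervalSet, variants: DataFrame, truth_acrs: DataFrame).
    Subgenome-specific ACR regions carry SNPs whose carrier-progenitor
    genotype matches the carrying subgenome with ``ancestry_match_p``;
    conserved regions carry a lower variant rate (divergence contrast).
    """
    rng = _rng(config.seed, "acrs")
    vrng = _rng(config.seed, "variants")
    gidx = genes.set_index("gene_id")
    acr_rows, truth_rows, var_rows = [], [], []

    def gene_tuple(gid):
        r = gidx.loc[gid]
        return r

    for row in ancestral.itertuples(index=False):
        has = {}
        spans = {}
        for sub, prob in (("A", config.acr_prob_A), ("B", config.acr_prob_B)):
            gid = getattr(row, f"gene_{sub}")
            present = bool(gid) and rng.random() < prob
            has[sub] = present
            if bool(gid):
                g = gene_tuple(gid)
                spans[sub] = _acr_interval(g, config)
        cause = "sampling"
        indel_pos = None
        if has["A"] and has["B"] and rng.random() < config.acr_indel_loss_prob:
            has["B"] = False
            cause = "indel"
            indel_pos = spans["B"][0] + config.acr_width_bp // 2
        if not (has["A"] or has["B"]):
            continue
        acr_id = f"acr_{row.slot_chrom:02d}_{row.slot:05d}"
        if rng.random() < config.acr_constitutive_p:
            tissues = list(TISSUES)
        else:
            tissues = [TISSUES[rng.integers(0, len(TISSUES))]]
        score = float(np.round(np.exp(rng.normal(3.0, 1.0)), 3))
        if has["A"] and has["B"]:
            acr_class = "conserved"
        elif has["A"]:
            acr_class = "A_specific"
        else:
            acr_class = "B_specific"
        for sub in ("A", "B"):
            if not has[sub]:
                continue
            g = gene_tuple(getattr(row, f"gene_{sub}"))
            s, e = spans[sub]
            for t in tissues:
                acr_rows.append((g["chrom"], s, e, f"{acr_id}_{sub}", score, ".",
                                 t, sub))
        truth_rows.append((
            acr_id, acr_class, cause,
            row.gene_A if bool(row.gene_A) else "",
            row.gene_B if bool(row.gene_B) else "",
            ",".join(tissues),
        ))
        # variants: carrier-divergent SNPs inside the ACR region(s)
        if acr_class == "conserved":
            rate, carrier = config.conserved_var_rate, "A"
        else:
            rate, carrier = config.specific_var_rate, acr_class[0]
        span_sub = carrier if has[carrier] else ("A" if has["A"] else "B")
        s, e = spans[span_sub]
        chrom = gene_tuple(getattr(row, f"gene_{span_sub}"))["chrom"]
        n_var = vrng.poisson(rate)
        positions = np.sort(vrng.integers(s, e, size=n_var))
        for p in positions:
            match = vrng.random() < config.ancestry_match_p
            missing = vrng.random() < config.var_missing_p
            gt = {"subA": "ref", "subB": "ref", "progA": "ref", "progB": "ref"}
            gt[f"sub{carrier}"] = "alt"
            gt[f"prog{carrier}"] = "alt" if match else "ref"
            if missing:
                gt[f"prog{carrier}"] = "missing"
            var_rows.append((chrom, int(p), "C", "T", "SNP",
                             gt["subA"], gt["subB"], gt["progA"], gt["progB"],
                             acr_id, acr_class, carrier, match, missing))
        if indel_pos is not None:
            chromB = gene_tuple(row.gene_B)["chrom"]
            match = vrng.random() < config.ancestry_match_p
            alt = "A" + "T" * config.indel_len_bp
            var_rows.append((chromB, int(indel_pos), "A", alt, "InDel",
                             "ref", "alt", "ref",
                             "alt" if match else "ref",
                             acr_id, "A_specific", "A", match, False))

    acrs = IntervalSet(pd.DataFrame(acr_rows, columns=[
        "chrom", "start", "end", "name", "score", "strand", "category", "sample"]))
    variants = pd.DataFrame(var_rows, columns=[
        "chrom", "pos", "ref", "alt", "type",
        "subA", "subB", "progA", "progB",
        "acr_id", "acr_class", "carrier", "truth_match", "truth_missing"])
    truth = pd.DataFrame(truth_rows, columns=[
        "acr_id", "class", "cause", "gene_A", "gene_B", "tissues"])
    return acrs, variants, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Negative binomial via gamma-Poisson mixture; var = m + phi m^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_expression(genes: pd.DataFrame, ancestral: pd.DataFrame,
                        config: SimConfig):
    """Counts for five tissues x replicates plus a CTL/WL root contrast.

    Biased pairs receive an additive log2 offset split symmetrically
    between the two homoeologs; waterlogging DEGs are drawn per subgenome
    at the configured rates with strong (|log2FC| >= deg_log2fc) effects.

    Returns (counts, samples, truth_bias, truth_deg).
    """
    rng = _rng(config.seed, "expression")
    n_genes = len(genes)
    gene_ids = genes["gene_id"].to_numpy()
    slot_key = genes["slot_chrom"].astype(str) + "_" + genes["slot"].astype(str)

    # per-ancestral-slot baseline and tissue effects, shared by pair members
    slots = ancestral.copy()
    slots["key"] = slots["slot_chrom"].astype(str) + "_" + slots["slot"].astype(str)
    base = np.exp(rng.normal(np.log(config.expr_mean), config.expr_log_sd,
                             size=len(slots)))
    tissue_fac = np.exp(rng.normal(0.0, config.tissue_log_sd,
                                   size=(len(slots), len(TISSUES))))
    slot_pos = {k: i for i, k in enumerate(slots["key"])}
    gene_slot_idx = np.array([slot_pos[k] for k in slot_key])

    # homoeolog bias truth over pairs
    is_pair = (slots["class"] == "both").to_numpy()
    biased = is_pair & (rng.random(len(slots)) < config.bias_fraction)
    toward_a = rng.random(len(slots)) < config.bias_toward_A
    mag = np.clip(rng.normal(config.bias_log2fc, 0.3, size=len(slots)), 1.0, None)
    lfc_ab = np.where(biased, np.where(toward_a, mag, -mag), 0.0)

    # DEG truth per gene
    sub = genes["subgenome"].to_numpy()
    deg_p = np.where(sub == "A", config.deg_fraction_A, config.deg_fraction_B)
    is_deg = rng.random(n_genes) < deg_p
    deg_up = rng.random(n_genes) < config.deg_up_fraction
    deg_mag = config.deg_log2fc + rng.exponential(0.5, size=n_genes)
    deg_lfc = np.where(is_deg, np.where(deg_up, deg_mag, -deg_mag), 0.0)

    # mean matrix over tissue samples
    half = np.where(sub == "A", 1.0, -1.0) * lfc_ab[gene_slot_idx] / 2.0
    gene_base = base[gene_slot_idx] * np.power(2.0, half)
    samples, mean_cols = [], []
    for ti, t in enumerate(TISSUES):
        m = gene_base * tissue_fac[gene_slot_idx, ti]
        for r in range(1, config.replicates + 1):
            samples.append((f"{t}_{r}", t, "none", r))
            mean_cols.append(m)
    root_i = TISSUES.index("root")
    m_root = gene_base * tissue_fac[gene_slot_idx, root_i]
    for cond in CONDITIONS:
        m = m_root if cond == "CTL" else m_root * np.power(2.0, deg_lfc)
        for r in range(1, config.replicates + 1):
            samples.append((f"{cond}_{r}", "root", cond, r))
            mean_cols.append(m)
    mean_mat = np.column_stack(mean_cols)
    counts = _nb_draw(rng, mean_mat, config.nb_dispersion)
    samples_df = pd.DataFrame(samples,
                              columns=["sample", "tissue", "condition", "replicate"])
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=samples_df["sample"]).sort_index()

    pairs = slots[is_pair]
    truth_bias = pd.DataFrame({
        "pair_id": pairs["key"].to_numpy(),
        "gene_A": pairs["gene_A"].to_numpy(),
        "gene_B": pairs["gene_B"].to_numpy(),
        "bias_class": np.where(biased[is_pair],
                               np.where(toward_a[is_pair], "A", "B"), "unbiased"),
        "log2fc_AB": np.round(lfc_ab[is_pair], 4),
    })
    truth_deg = pd.DataFrame({
        "gene_id": gene_ids,
        "subgenome": sub,
        "is_deg": is_deg,
        "direction": np.where(is_deg, np.where(deg_up, "up", "down"), "none"),
        "log2fc": np.round(deg_lfc, 4),
    }).sort_values("gene_id", ignore_index=True)
    return counts_df, samples_df, truth_bias, truth_deg


# ---------------------------------------------------------------------------
# m6A
# ---------------------------------------------------------------------------

def simulate_m6a(gene_models: list[GeneModel], ancestral: pd.DataFrame,
                 truth_deg: pd.DataFrame, config: SimConfig):
    """Windowed IP/input counts with planted, 3'UTR-weighted peaks.

    Peak presence is pair-structured: a homoeolog pair is methylated with
    probability ``m6a_peak_prob`` and then shared / A-only / B-only with
    the configured split (defaults 0.82/0.15/0.03); singletons are
    methylated independently.  A fraction of control peaks lose their
    enrichment entirely under waterlogging (``m6a_loss_fraction``); among
    retained peaks a further fraction shifts level by ``m6a_diff_log2fc``
    (down with probability 0.7), preferentially on waterlogging DEGs with
    the opposite expression direction (``m6a_repression_coupling``).

    Returns (windows, truth_peaks).
    """
    rng = _rng(config.seed, "m6a")
    bin_bp = config.m6a_bin_bp
    deg = truth_deg.set_index("gene_id")

    # pair-structured peak presence
    has_peak: set[str] = set()
    split = np.array([config.m6a_pair_shared, config.m6a_pair_A_only,
                      config.m6a_pair_B_only], dtype=float)
    split = split / split.sum()
    paired_genes: set[str] = set()
    for cls, ga, gb in zip(ancestral["class"], ancestral["gene_A"],
                           ancestral["gene_B"]):
        if cls != "both":
            continue
        paired_genes.update((ga, gb))
        if rng.random() >= config.m6a_peak_prob:
            continue
        cat = rng.choice(3, p=split)
        if cat == 0:
            has_peak.update((ga, gb))
        elif cat == 1:
            has_peak.add(ga)
        else:
            has_peak.add(gb)
    for g in gene_models:
        if g.gene_id not in paired_genes and rng.random() < config.m6a_peak_prob:
            has_peak.add(g.gene_id)

    # peak placement
    peak_meta = []  # (gene, feature, win_lo, win_hi)
    gene_nwin = {}
    for g in gene_models:
        tlen = g.transcript_length
        nwin = max(1, tlen // bin_bp)
        gene_nwin[g.gene_id] = nwin
        if g.gene_id not in has_peak:
            continue
        u = rng.random()
        rest = 1.0 - config.m6a_utr3_weight
        if u < config.m6a_utr3_weight:
            feature = "3'UTR"
        elif u < config.m6a_utr3_weight + 0.75 * rest:
            feature = "CDS"
        else:
            feature = "5'UTR"
        fl = g.feature_lengths()
        if fl["3'UTR"] == 0 and feature == "3'UTR":
            feature = "CDS"
        # feature window span in transcript coordinates (5'->3')
        u5, cd, u3 = fl["5'UTR"], fl["CDS"], fl["3'UTR"]
        bounds = {"5'UTR": (0, u5), "CDS": (u5, u5 + cd),
                  "3'UTR": (u5 + cd, u5 + cd + u3)}
        lo_bp, hi_bp = bounds[feature]
        wlo, whi = lo_bp // bin_bp, max(lo_bp // bin_bp + 1, hi_bp // bin_bp)
        width = min(config.m6a_peak_windows, whi - wlo)
        start = int(rng.integers(wlo, max(wlo + 1, whi - width + 1)))
        peak_meta.append([g.gene_id, feature, start, start + width])

    n_peaks = len(peak_meta)
    lost = rng.random(n_peaks) < config.m6a_loss_fraction
    # differential-level peaks: drawn among retained peaks, preferentially
    # (with prob m6a_repression_coupling) on waterlogging DEGs with the
    # opposite expression direction (repressive coupling)
    diff = np.zeros(n_peaks, dtype=bool)
    diff_down = np.zeros(n_peaks, dtype=bool)
    coupled = np.zeros(n_peaks, dtype=bool)
    retained = np.nonzero(~lost)[0]
    peak_gene = np.array([m[0] for m in peak_meta]) if n_peaks else np.array([])
    n_diff = int(round(config.m6a_diff_fraction * retained.size))
    if n_diff:
        is_deg = deg["is_deg"].reindex(peak_gene[retained]).to_numpy()
        deg_dir = deg["direction"].reindex(peak_gene[retained]).to_numpy()
        deg_pool = list(retained[is_deg == True])  # noqa: E712
        rng.shuffle(deg_pool)
        other_pool = list(retained[is_deg != True])  # noqa: E712
        rng.shuffle(other_pool)
        dir_of = dict(zip(retained, deg_dir))
        taken: set[int] = set()
        for _ in range(n_diff):
            if (rng.random() < config.m6a_repression_coupling and deg_pool):
                i = deg_pool.pop()
                coupled[i] = True
                diff_down[i] = dir_of[i] == "up"
            else:
                pool = other_pool if other_pool else deg_pool
                if not pool:
                    break
                i = pool.pop()
                diff_down[i] = rng.random() < 0.7
            diff[i] = True
            taken.add(i)

    fate = np.where(lost, "lost",
                    np.where(diff, np.where(diff_down, "diff_down", "diff_up"),
                             "kept"))
    truth_peaks = pd.DataFrame(
        [(f"peak_{i:05d}", *m) for i, m in enumerate(peak_meta)],
        columns=["peak_id", "gene_id", "feature", "win_lo", "win_hi"])
    truth_peaks["fate"] = fate
    truth_peaks["coupled"] = coupled

    # window count matrix
    gene_ids = [g.gene_id for g in gene_models]
    nwins = np.array([gene_nwin[g] for g in gene_ids])
    total_w = int(nwins.sum())
    offsets = np.concatenate([[0], np.cumsum(nwins)])
    ip_mean = {c: np.full(total_w, config.m6a_ip_background) for c in CONDITIONS}
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    peak_level = config.m6a_ip_background * config.m6a_enrichment
    for i, (gid, _f, wlo, whi) in enumerate(peak_meta):
        o = offsets[gene_pos[gid]]
        ip_mean["CTL"][o + wlo:o + whi] = peak_level
        if fate[i] == "lost":
            wl_level = config.m6a_ip_background
        elif fate[i] == "diff_down":
            wl_level = peak_level * 2 ** (-config.m6a_diff_log2fc)
        elif fate[i] == "diff_up":
            wl_level = peak_level * 2 ** (config.m6a_diff_log2fc)
        else:
            wl_level = peak_level
        ip_mean["WL"][o + wlo:o + whi] = wl_level

    frames = []
    gene_col = np.repeat(gene_ids, nwins)
    win_col = np.concatenate([np.arange(n) for n in nwins])
    start_col = win_col * bin_bp
    for cond in CONDITIONS:
        ip = rng.poisson(ip_mean[cond])
        inp = rng.poisson(config.m6a_input_depth, size=total_w)
        frames.append(pd.DataFrame({
            "gene_id": gene_col, "win_index": win_col,
            "start": start_col, "end": start_col + bin_bp,
            "ip": ip, "input": inp, "condition": cond}))
    windows = pd.concat(frames, ignore_index=True)
    return windows, truth_peaks


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

def generate_dataset(config: SimConfig, outdir=None) -> DatasetBundle:
    """Generate the full bundle; write it to ``outdir`` when given.

    Identical configs (including seed) produce byte-identical files.
    """
    genome, genes, ancestral, models = simulate_genome_and_genes(config)
    anchors = simulate_anchors(ancestral, config)
    tes = simulate_tes(genome, genes, config)
    methylation = simulate_methylome(tes, genome, config)
    acrs, variants, truth_acrs = simulate_acrs_and_variants(genes, ancestral, config)
    counts, samples, truth_bias, truth_deg = simulate_expression(genes, ancestral,
                                                                 config)
    m6a_windows, truth_peaks = simulate_m6a(models, ancestral, truth_deg, config)

    bundle = DatasetBundle(
        outdir=Path(outdir) if outdir else None,
        config=config, genome=genome, genes=genes, gene_models=models,
        ancestral_order=ancestral, anchors=anchors, tes=tes, acrs=acrs,
        methylation=methylation, counts=counts, samples=samples,
        m6a_windows=m6a_windows, variants=variants,
        truth_pairs=ancestral, truth_bias=truth_bias, truth_deg=truth_deg,
        truth_acrs=truth_acrs, truth_peaks=truth_peaks,
    )
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


BUNDLE_FILES = {
    "genome": "genome.tsv",
    "genes": "genes.gff3",
    "ancestral": "ancestral_order.tsv",
    "anchors": "anchors.tsv",
    "tes": "tes.bed",
    "acrs": "acrs.tsv",
    "methylation": "methylation.tsv",
    "counts": "counts.tsv",
    "samples": "samples.tsv",
    "m6a_windows": "m6a_windows.tsv",
    "variants": "variants.vcf",
    "truth_bias": "truth_bias.tsv",
    "truth_deg": "truth_deg.tsv",
    "truth_acrs": "truth_acrs.tsv",
    "truth_peaks": "truth_peaks.tsv",
    "config": "sim_config.yaml",
}


def write_bundle(bundle: DatasetBundle, outdir) -> Path:
    out = sio.ensure_dir(outdir)
    f = {k: out / v for k, v in BUNDLE_FILES.items()}
    sio.write_genome_tsv(bundle.genome, f["genome"])
    sio.write_gff3(bundle.gene_models, f["genes"])
    bundle.ancestral_order.to_csv(f["ancestral"], sep="\t", index=False)
    bundle.anchors.to_csv(f["anchors"], sep="\t", index=False)
    sio.write_bed(bundle.tes, f["tes"])
    sio.write_interval_tsv(bundle.acrs, f["acrs"])
    sio.write_methylation(bundle.methylation, f["methylation"])
    bundle.counts.to_csv(f["counts"], sep="\t")
    bundle.samples.to_csv(f["samples"], sep="\t", index=False)
    bundle.m6a_windows.to_csv(f["m6a_windows"], sep="\t", index=False)
    sio.write_variants_vcf(bundle.variants, bundle.genome, f["variants"])
    bundle.truth_bias.to_csv(f["truth_bias"], sep="\t", index=False)
    bundle.truth_deg.to_csv(f["truth_deg"], sep="\t", index=False)
    bundle.truth_acrs.to_csv(f["truth_acrs"], sep="\t", index=False)
    bundle.truth_peaks.to_csv(f["truth_peaks"], sep="\t", index=False)
    bundle.config.to_yaml(f["config"])
    bundle.outdir = out
    return out
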