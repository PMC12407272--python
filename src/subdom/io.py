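"""Readers and writers for the standard formats the pipeline consumes.

GFF3 is 1-based closed on disk and converted to the package's 0-based
half-open convention at this boundary; BED is already 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import pysam

from subdom.model import INTERVAL_COLUMNS, GeneModel, Genome, Interval, IntervalSet

logger = logging.getLogger(__name__)

METH_CONTEXTS = ("CG", "CHG", "CHH")
VARIANT_SAMPLES = ("subA", "subB", "progA", "progB")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _subtract(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Interval-list difference a \\ b (both merged, half-open)."""
    out = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def read_gff3(path, genome: Genome | None = None) -> list[GeneModel]:
    """Parse a GFF3 into gene models with one representative mRNA per gene.

    The representative transcript is the mRNA with the longest summed CDS.
    UTRs are taken from five_prime_UTR/three_prime_UTR features when
    present, otherwise derived as exon minus CDS split at the CDS span.
    """
    genes: dict[str, dict] = {}
    mrnas: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            chrom, _src, ftype, start1, end1, _score, strand, _frame, attrs = parts[:9]
            start, end = int(start1) - 1, int(end1)  # GFF3 1-based closed -> half-open
            a = _parse_attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise ValueError(f"gene feature without ID at {chrom}:{start1}")
                genes[gid] = {
                    "chrom": chrom,
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "mrnas": [],
                }
                order.append(gid)
            elif ftype == "mRNA":
                mid, parent = a.get("ID"), a.get("Parent")
                if parent not in genes:
                    raise ValueError(f"mRNA {mid}: unknown parent gene {parent!r}")
                mrnas[mid] = {"gene": parent, "exons": [], "cds": [], "utr5": [], "utr3": []}
                genes[parent]["mrnas"].append(mid)
            elif ftype in ("exon", "CDS", "five_prime_UTR", "three_prime_UTR"):
                for parent in (a.get("Parent") or "").split(","):
                    if parent not in mrnas:
                        raise ValueError(
                            f"{ftype} feature: unknown parent mRNA {parent!r}"
                        )
                    key = {
                        "exon": "exons",
                        "CDS": "cds",
                        "five_prime_UTR": "utr5",
                        "three_prime_UTR": "utr3",
                    }[ftype]
                    mrnas[parent][key].append((start, end))

    out = []
    for gid in order:
        g = genes[gid]
        best = None
        for mid in g["mrnas"]:
            m = mrnas[mid]
            cds_len = sum(e - s for s, e in m["cds"])
            if best is None or cds_len > best[0]:
                best = (cds_len, mid)
        exons: list[tuple[int, int]] = []
        cds: list[tuple[int, int]] = []
        utr5: list[tuple[int, int]] = []
        utr3: list[tuple[int, int]] = []
        if best is not None:
            m = mrnas[best[1]]
            exons = _merge_intervals(m["exons"]) or [(g["start"], g["end"])]
            cds = _merge_intervals(m["cds"])
            for cs, ce in cds:
                if not any(es <= cs and ce <= ee for es, ee in exons):
                    raise ValueError(f"gene {gid}: CDS {cs}-{ce} outside exons")
            utr5, utr3 = _merge_intervals(m["utr5"]), _merge_intervals(m["utr3"])
            if not cds:
                logger.warning("gene %s: representative mRNA lacks CDS", gid)
            elif not (utr5 or utr3):
                cds_lo, cds_hi = cds[0][0], cds[-1][1]
                non_cds = _subtract(exons, cds)
                left = [(s, e) for s, e in non_cds if e <= cds_lo]
                right = [(s, e) for s, e in non_cds if s >= cds_hi]
                utr5, utr3 = (left, right) if g["strand"] == "+" else (right, left)
        sub = genome.subgenome_of(g["chrom"]) if genome else "A"
        out.append(
            GeneModel(
                gene_id=gid,
                chrom=g["chrom"],
                strand=g["strand"],
                start=g["start"],
                end=g["end"],
                exons=exons or [(g["start"], g["end"])],
                cds_span=cds,
                utr5=utr5,
                utr3=utr3,
                subgenome=sub,
            )
        )
    return out


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            f = f"{g.chrom}\tsubdom\t"
            tail = f"\t.\t{g.strand}\t.\t"
            fh.write(f"{f}gene\t{g.start + 1}\t{g.end}{tail}ID={g.gene_id}\n")
            mid = f"{g.gene_id}.t1"
            fh.write(f"{f}mRNA\t{g.start + 1}\t{g.end}{tail}ID={mid};Parent={g.gene_id}\n")
            for kind, ivs in (
                ("exon", g.exons),
                ("five_prime_UTR", g.utr5),
                ("CDS", g.cds_span),
                ("three_prime_UTR", g.utr3),
            ):
                for s, e in ivs:
                    fh.write(f"{f}{kind}\t{s + 1}\t{e}{tail}Parent={mid}\n")


# ---------------------------------------------------------------------------
# BED / interval tables
# ---------------------------------------------------------------------------

def write_bed(intervals: IntervalSet, path) -> None:
    """6-column BED; scores clipped to [0, 1000] per the format."""
    df = intervals.df
    with open(path, "w") as fh:
        for r in df.itertuples(index=False):
            score = min(max(r.score, 0.0), 1000.0)
            score_s = str(int(score)) if float(score).is_integer() else repr(score)
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{score_s}\t{r.strand}\n")


def read_bed(path) -> IntervalSet:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            p = line.split("\t")
            rows.append(
                Interval(
                    chrom=p[0],
                    start=int(p[1]),
                    end=int(p[2]),
                    name=p[3] if len(p) > 3 else ".",
                    score=float(p[4]) if len(p) > 4 else 0.0,
                    strand=p[5] if len(p) > 5 else ".",
                )
            )
    return IntervalSet(rows)


def write_interval_tsv(intervals: IntervalSet, path) -> None:
    """Full 8-column interval table (keeps category and sample)."""
    intervals.df.to_csv(path, sep="\t", index=False)


def read_interval_tsv(path) -> IntervalSet:
    return IntervalSet(pd.read_csv(path, sep="\t", dtype={c: str for c in
                                                          ("chrom", "name", "strand", "category", "sample")}))


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def read_methylation(path) -> pd.DataFrame:
    """Per-cytosine table: chrom, pos, context, mc_count, total_count.

    Rows with total_count == 0 are retained; their level is undefined and
    all downstream averaging is read-weighted, so they contribute nothing.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "pos", "context", "mc_count", "total_count"],
        header=0,
        dtype={"chrom": str, "pos": int, "context": str, "mc_count": int, "total_count": int},
    )
    bad = set(df["context"]) - set(METH_CONTEXTS)
    if bad:
        raise ValueError(f"unknown methylation context token(s): {sorted(bad)}")
    if (df["mc_count"] > df["total_count"]).any() or (df["mc_count"] < 0).any():
        raise ValueError("methylation counts must satisfy 0 <= mc <= total")
    return df


def write_methylation(df: pd.DataFrame, path) -> None:
    df[["chrom", "pos", "context", "mc_count", "total_count"]].to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Variants (VCF)
# ---------------------------------------------------------------------------

def read_variants(path) -> pd.DataFrame:
    """Decode a VCF with the four named samples into a genotype table.

    Returns columns chrom, pos (0-based), ref, alt, type (SNP/InDel) and
    one column per sample with values in {"ref", "alt", "missing"}.
    Multi-allelic sites are split into one row per alternate allele.
    """
    vf = pysam.VariantFile(str(path))
    missing = [s for s in VARIANT_SAMPLES if s not in list(vf.header.samples)]
    if missing:
        raise ValueError(f"VCF missing required sample column(s): {missing}")
    rows = []
    for rec in vf:
        for ai, alt in enumerate(rec.alts or (), start=1):
            vtype = "SNP" if len(rec.ref) == 1 and len(alt) == 1 else "InDel"
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos - 1,
                "ref": rec.ref,
                "alt": alt,
                "type": vtype,
            }
            for s in VARIANT_SAMPLES:
                gt = rec.samples[s].get("GT")
                if gt is None or all(a is None for a in gt):
                    row[s] = "missing"
                elif any(a == ai for a in gt if a is not None):
                    row[s] = "alt"
                else:
                    row[s] = "ref"
            rows.append(row)
    vf.close()
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "type", *VARIANT_SAMPLES]
    )


def write_variants_vcf(df: pd.DataFrame, genome: Genome, path) -> None:
    """Write the genotype table back to a minimal VCF 4.2 text file."""
    code = {"ref": "0/0", "alt": "1/1", "missing": "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in genome.chromosomes:
            fh.write(f"##contig=<ID={c.id},length={c.length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(VARIANT_SAMPLES)
            + "\n"
        )
        for r in df.itertuples(index=False):
            gts = "\t".join(code[getattr(r, s)] for s in VARIANT_SAMPLES)
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Counts / m6A windows / anchors
# ---------------------------------------------------------------------------

def read_counts(path) -> pd.DataFrame:
    """Gene x sample count matrix; first column gene_id, used as index."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_m6a_windows(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        dtype={"gene_id": str, "condition": str},
    )


def read_anchors(path) -> pd.DataFrame:
    """3-column anchor-hit TSV: gene_A, gene_B, similarity."""
    return pd.read_csv(path, sep="\t", names=["gene_A", "gene_B", "similarity"],
                       header=0, dtype={"gene_A": str, "gene_B": str})


def read_genome_tsv(path) -> Genome:
    return Genome.from_frame(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def write_genome_tsv(genome: Genome, path) -> None:
    genome.to_frame().to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
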