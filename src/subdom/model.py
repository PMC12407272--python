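"""Shared data model: genome, gene models, interval sets and configuration.

All internal coordinates are 0-based half-open.  GFF3 I/O converts at the
boundary (1-based closed on disk).  Subgenome membership lives on the
chromosome record and is inherited by every feature on it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import pandas as pd
import yaml

SUBGENOMES = ("A", "B")

#: column order for the extended interval table (BED6 plus category/sample)
INTERVAL_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "category",
    "sample",
]


@dataclass(frozen=True)
class Chromosome:
    id: str
    subgenome: str
    length: int

    def __post_init__(self) -> None:
        if self.subgenome not in SUBGENOMES:
            raise ValueError(f"unknown subgenome label {self.subgenome!r}")
        if self.length <= 0:
            raise ValueError(f"chromosome {self.id}: nonpositive length")


@dataclass
class Genome:
    """Phased allotetraploid genome: chromosomes tagged A or B."""

    chromosomes: list[Chromosome]

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chromosomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate chromosome ids")
        self._by_id = {c.id: c for c in self.chromosomes}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._by_id

    def length(self, chrom: str) -> int:
        return self._by_id[chrom].length

    def subgenome_of(self, chrom: str) -> str:
        return self._by_id[chrom].subgenome

    def subgenome_bp(self, subgenome: str) -> int:
        return sum(c.length for c in self.chromosomes if c.subgenome == subgenome)

    def chrom_ids(self, subgenome: str | None = None) -> list[str]:
        return [
            c.id
            for c in self.chromosomes
            if subgenome is None or c.subgenome == subgenome
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.id, c.subgenome, c.length) for c in self.chromosomes],
            columns=["chrom", "subgenome", "length"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Genome":
        return cls(
            [
                Chromosome(str(r.chrom), str(r.subgenome), int(r.length))
                for r in df.itertuples()
            ]
        )


@dataclass
class GeneModel:
    """One gene with its representative transcript structure.

    ``exons``, ``cds_span``, ``utr5`` and ``utr3`` are lists of 0-based
    half-open ``(start, end)`` genomic tuples.  ``utr5``/``utr3`` are named
    by transcript orientation (5' is upstream of the CDS on the coding
    strand).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_span: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    subgenome: str = "A"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")

    @property
    def tss(self) -> int:
        """Transcription start: leftmost base on +, rightmost (end-1) on -."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons) or (self.end - self.start)

    def feature_lengths(self) -> dict[str, int]:
        return {
            "5'UTR": sum(e - s for s, e in self.utr5),
            "CDS": sum(e - s for s, e in self.cds_span),
            "3'UTR": sum(e - s for s, e in self.utr3),
        }


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    category: str = "."
    sample: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"interval {self.name}: start must be < end")

    def length(self) -> int:
        return self.end - self.start


class IntervalSet:
    """Ordered collection of genomic intervals backed by a DataFrame.

    Used for TEs, ACRs and peaks alike; ``category`` carries the use-specific
    vocabulary (TE class, tissue, condition) and ``sample`` the originating
    library where relevant.
    """

    def __init__(self, records: Sequence[Interval] | pd.DataFrame = ()):  # noqa: D107
        if isinstance(records, pd.DataFrame):
            df = records.copy()
            for col, default in (
                ("name", "."),
                ("score", 0.0),
                ("strand", "."),
                ("category", "."),
                ("sample", "."),
            ):
                if col not in df.columns:
                    df[col] = default
            df = df[INTERVAL_COLUMNS]
        else:
            df = pd.DataFrame(
                [dataclasses.astuple(r) for r in records], columns=INTERVAL_COLUMNS
            )
        df = df.astype(
            {
                "chrom": str,
                "start": int,
                "end": int,
                "name": str,
                "score": float,
                "strand": str,
                "category": str,
                "sample": str,
            }
        )
        if (df["start"] >= df["end"]).any():
            bad = df.loc[df["start"] >= df["end"], "name"].iloc[0]
            raise ValueError(f"interval {bad}: start must be < end")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[Interval]:
        for r in self.df.itertuples(index=False):
            yield Interval(*r)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.df.equals(other.df)

    def sorted(self) -> "IntervalSet":
        return IntervalSet(
            self.df.sort_values(["chrom", "start", "end"], kind="mergesort")
        )

    def subset(self, mask) -> "IntervalSet":
        return IntervalSet(self.df.loc[mask])


@dataclass
class AnalysisConfig:
    """Every threshold used by the analysis stages, with field defaults.

    Thresholds follow the study design: expression filter TPM > 0.1,
    homoeolog-bias call at adjusted p < 0.01, differential expression at
    fold change > 2 and FDR < 0.05, m6A peak call at normalized IP/input
    >= 2 and p < 0.05, proximal ACR window 5 kb upstream of the TSS, 2 kb
    metaprofile flanks, 100-gene retention windows, 50-bp m6A bins.
    """

    tpm_min: float = 0.1
    bias_adj_p: float = 0.01
    de_fc: float = 2.0
    de_fdr: float = 0.05
    m6a_ratio: float = 2.0
    m6a_p: float = 0.05
    m6a_diff_fdr: float = 0.05
    m6a_diff_log2: float = 1.0
    proximal_bp: int = 5000
    flank_bp: int = 2000
    window_genes: int = 100
    m6a_bin_bp: int = 50
    body_bins: int = 20
    flank_bins: int = 20
    max_gap: int = 10
    min_block: int = 5
    flank_mode: str = "upstream"  # or "both": proximal window on both sides of TSS
    bias_pooling: str = "any"  # or "majority": rule pooling per-tissue bias calls
    seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name in ("flank_mode", "bias_pooling"):
                continue
            v = getattr(self, f.name)
            if f.name != "seed" and v <= 0:
                raise ValueError(f"config field {f.name} must be positive, got {v}")
        if self.flank_mode not in ("upstream", "both"):
            raise ValueError("flank_mode must be 'upstream' or 'both'")
        if self.bias_pooling not in ("any", "majority"):
            raise ValueError("bias_pooling must be 'any' or 'majority'")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))
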