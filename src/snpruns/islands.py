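"""ROH/HRR island calling, cross-breed overlap, and gene annotation.

An island is a stretch of map-consecutive SNPs whose within-breed
run-occurrence frequency (fraction of the breed's individuals whose runs
cover the SNP) is both inside the breed's top 0.1% of occurrence values
(nearest-rank, ties admitted) and strictly above a mode-specific frequency
floor (20% for ROH islands, 30% for HRR islands).  Islands are annotated
against a user-supplied gene-interval table; a gene belongs to an island
when their closed intervals share at least one base pair.

Island length is ``end_bp - start_bp`` and Fix% the mean member-SNP
occurrence x 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset, _chrom_sort_key
from .runs_detection import RunSet

__all__ = [
    "OccurrenceTrack",
    "Island",
    "GeneInterval",
    "IslandGeneReport",
    "SharedIsland",
    "snp_occurrence",
    "occurrence_threshold",
    "call_islands",
    "shared_islands",
    "annotate_islands",
    "count_genes",
    "read_gene_table",
    "islands_to_tsv",
    "load_reference_islands",
]


@dataclass
class OccurrenceTrack:
    """Per-SNP run-occurrence fraction for one breed, over the whole map."""

    breed: str
    snp_ids: list[str]
    chroms: list[str]
    positions: np.ndarray
    occurrence: np.ndarray  # fractions in [0, 1], aligned with the map

    def __post_init__(self) -> None:
        self.occurrence = np.asarray(self.occurrence, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)


@dataclass(frozen=True)
class Island:
    """A contiguous high-occurrence SNP interval of one breed."""

    breed: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    fix_pct: float  # mean member occurrence x 100

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass(frozen=True)
class GeneInterval:
    """A gene span (1-based inclusive coordinates)."""

    chrom: str
    start_bp: int
    end_bp: int
    gene_name: str

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise ValueError(f"gene {self.gene_name}: end < start")


@dataclass
class IslandGeneReport:
    """Genes per island plus total / unique tallies."""

    islands: list[Island]
    genes_per_island: list[list[str]]

    def totals(self) -> tuple[int, int]:
        total = sum(len(g) for g in self.genes_per_island)
        unique = len({name for g in self.genes_per_island for name in g})
        return total, unique


@dataclass(frozen=True)
class SharedIsland:
    """An interval where islands of >= 2 breeds intersect."""

    chrom: str
    start_bp: int
    end_bp: int
    breeds: tuple[str, ...]


def snp_occurrence(rs: RunSet, ds: GenotypeDataset, breed: str) -> OccurrenceTrack:
    """Fraction of the breed's individuals whose runs cover each SNP.

    A run covers a SNP iff ``start_bp <= bp <= end_bp`` on the same
    chromosome for that individual; since one individual's runs never
    overlap, summing run indicators counts individuals.  The denominator is
    every genotyped individual of the breed.
    """
    idx = ds.breed_sample_indices(breed)  # raises on unknown breed
    n_breed = idx.size
    member_row = {
        ds.samples[i].sample_id: k for k, i in enumerate(idx)
    }
    covered = np.zeros((n_breed, ds.n_snps), dtype=bool)
    positions = ds.positions
    chrom_slices = {chrom: ds.chrom_slice(chrom) for chrom in ds.chroms}
    for r in rs.runs:
        row = member_row.get(r.sample_id)
        if row is None or r.chrom not in chrom_slices:
            continue
        sl = chrom_slices[r.chrom]
        pos = positions[sl]
        lo = int(np.searchsorted(pos, r.start_bp, side="left"))
        hi = int(np.searchsorted(pos, r.end_bp, side="right"))
        covered[row, sl.start + lo : sl.start + hi] = True
    counts = covered.sum(axis=0)
    return OccurrenceTrack(
        breed=breed,
        snp_ids=[s.snp_id for s in ds.snps],
        chroms=[s.chrom for s in ds.snps],
        positions=positions,
        occurrence=counts / n_breed,
    )


def occurrence_threshold(
    track: OccurrenceTrack, top_fraction: float = 0.001
) -> float:
    """Nearest-rank upper-quantile cut for the top ``top_fraction`` of SNPs.

    ``k = ceil(top_fraction * n_snps)``; the threshold is the k-th largest
    occurrence value, and ties at the threshold are admitted downstream.
    """
    occ = track.occurrence
    if occ.size == 0:
        raise ValueError("empty occurrence track")
    k = max(1, math.ceil(top_fraction * occ.size))
    return float(np.sort(occ)[::-1][k - 1])


def call_islands(
    track: OccurrenceTrack,
    threshold: float,
    min_freq: float,
    min_island_snps: int = 2,
) -> list[Island]:
    """Maximal stretches of map-consecutive qualifying SNPs.

    A SNP qualifies when its occurrence is >= ``threshold`` (the top-0.1%
    cut, inclusive so threshold ties are admitted) and strictly above
    ``min_freq`` (0.20 for ROH, 0.30 for HRR).  Stretches shorter than
    ``min_island_snps`` are discarded.
    """
    qual = (track.occurrence >= threshold) & (track.occurrence > min_freq)
    islands: list[Island] = []
    m = qual.size
    j = 0
    while j < m:
        if not qual[j]:
            j += 1
            continue
        k = j
        while (
            k + 1 < m
            and qual[k + 1]
            and track.chroms[k + 1] == track.chroms[k]
        ):
            k += 1
        n = k - j + 1
        if n >= min_island_snps:
            islands.append(
                Island(
                    breed=track.breed,
                    chrom=track.chroms[j],
                    start_bp=int(track.positions[j]),
                    end_bp=int(track.positions[k]),
                    n_snps=n,
                    fix_pct=float(track.occurrence[j : k + 1].mean() * 100.0),
                )
            )
        j = k + 1
    return islands


def shared_islands(
    islands_by_breed: dict[str, list[Island]],
) -> list[SharedIsland]:
    """Maximal sets of >= 2 breeds whose islands share >= 1 bp.

    For every breed subset and every choice of one island per breed on a
    common chromosome, a non-empty intersection is reported when no further
    breed has an island overlapping it (maximality).
    """
    from itertools import combinations, product

    breeds = [b for b, isl in islands_by_breed.items() if isl]
    chroms = sorted(
        {i.chrom for isl in islands_by_breed.values() for i in isl},
        key=_chrom_sort_key,
    )
    out: list[SharedIsland] = []
    for chrom in chroms:
        per_breed = {
            b: [i for i in islands_by_breed[b] if i.chrom == chrom] for b in breeds
        }
        present = [b for b in breeds if per_breed[b]]
        for r in range(2, len(present) + 1):
            for subset in combinations(present, r):
                for choice in product(*(per_breed[b] for b in subset)):
                    lo = max(i.start_bp for i in choice)
                    hi = min(i.end_bp for i in choice)
                    if lo > hi:
                        continue
                    # maximal iff no outside breed overlaps [lo, hi]
                    extendable = any(
                        isl.start_bp <= hi and isl.end_bp >= lo
                        for b in present
                        if b not in subset
                        for isl in per_breed[b]
                    )
                    if not extendable:
                        cand = SharedIsland(
                            chrom=chrom, start_bp=lo, end_bp=hi, breeds=subset
                        )
                        if cand not in out:
                            out.append(cand)
    return out


def annotate_islands(
    islands: list[Island], genes: list[GeneInterval]
) -> IslandGeneReport:
    """Assign genes to islands by >= 1 shared bp (closed intervals).

    Per-island gene lists are ordered by gene start position.
    """
    genes_sorted = sorted(genes, key=lambda g: (_chrom_sort_key(g.chrom), g.start_bp))
    per_island: list[list[str]] = []
    for isl in islands:
        hits = [
            g.gene_name
            for g in genes_sorted
            if g.chrom == isl.chrom
            and g.start_bp <= isl.end_bp
            and g.end_bp >= isl.start_bp
        ]
        per_island.append(hits)
    return IslandGeneReport(islands=list(islands), genes_per_island=per_island)


def count_genes(report: IslandGeneReport) -> tuple[int, int]:
    """(total gene assignments, distinct gene names) across all islands."""
    return report.totals()


# ---------------------------------------------------------------------------
# I/O helpers


def read_gene_table(path: str | Path, zero_based: bool = False) -> list[GeneInterval]:
    """Read a BED-like TSV (chrom, start, end, name).

    Coordinates are declared 1-based inclusive; ``zero_based`` converts a
    true 0-based half-open BED (start+1).
    """
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start_bp", "end_bp", "gene_name"],
        dtype={"chrom": str, "gene_name": str}, comment="#",
    )
    offset = 1 if zero_based else 0
    return [
        GeneInterval(
            chrom=str(r.chrom),
            start_bp=int(r.start_bp) + offset,
            end_bp=int(r.end_bp),
            gene_name=str(r.gene_name),
        )
        for r in df.itertuples()
    ]


def islands_to_tsv(
    report: IslandGeneReport, path: str | Path
) -> None:
    """Islands with semicolon-joined gene lists (the island-table layout)."""
    rows = []
    for isl, genes in zip(report.islands, report.genes_per_island):
        rows.append(
            {
                "breed": isl.breed,
                "chrom": isl.chrom,
                "start_bp": isl.start_bp,
                "end_bp": isl.end_bp,
                "n_snps": isl.n_snps,
                "fix_pct": round(isl.fix_pct, 2),
                "length_bp": isl.length_bp,
                "genes": ";".join(genes) if genes else "-",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "breed", "chrom", "start_bp", "end_bp",
            "n_snps", "fix_pct", "length_bp", "genes",
        ],
    ).to_csv(path, sep="\t", index=False)


def load_reference_islands(mode: str) -> IslandGeneReport:
    """Bundled reference island tables for the four Mediterranean sheep
    breeds (Barbaresca, Noticiana, Sarda, Valle del Belice).

    ``mode`` is "HOM" (ROH islands) or "HET" (HRR islands).  Coordinates
    are ARS-UI_Ramb_v2.0 base pairs; gene lists are semicolon-joined, "-"
    meaning none.  Used as a desk-scale validation input for interval
    arithmetic, overlap detection and gene counting.
    """
    name = {"HOM": "roh_islands.tsv", "HET": "hrr_islands.tsv"}[mode]
    with resources.files("snpruns.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    islands = []
    genes_per_island = []
    for r in df.itertuples():
        islands.append(
            Island(
                breed=str(r.breed),
                chrom=str(r.chrom),
                start_bp=int(r.start_bp),
                end_bp=int(r.end_bp),
                n_snps=int(r.n_snps),
                fix_pct=float(r.fix_pct),
            )
        )
        genes = [] if r.genes == "-" else str(r.genes).split(";")
        genes_per_island.append(genes)
    return IslandGeneReport(islands=islands, genes_per_island=genes_per_island)
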