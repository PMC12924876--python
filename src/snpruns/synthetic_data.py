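"""Synthetic genotype datasets with known structure.

Emulates a high-density-array design: a handful of autosomes of SNPs at
~4 kb mean spacing (exponential inter-marker gaps), breed groups of
dozens of individuals, Hardy-Weinberg background genotypes with per-SNP
allele frequencies drawn uniformly from a configurable range, optional
missingness, and planted homozygous (ROH-like) or heterozygous (HRR-like)
tracts carried by a chosen fraction of a breed's individuals.  Background
SNPs are independent (no linkage disequilibrium): LD is not needed to
exercise run/island logic and keeps the no-tract null analytically
tractable.

Ground truth is returned as :class:`TruthTract` records;
:func:`evaluate_recovery` scores detected runs and called islands against
them (per-carrier base-pair Jaccard, precision, recall, island flag).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genotype_io import MISSING, GenotypeDataset, SampleRecord, SnpRecord
from .islands import Island
from .runs_detection import RunSet

__all__ = [
    "TractSpec",
    "SimConfig",
    "TruthTract",
    "RecoveryReport",
    "TractRecovery",
    "simulate_dataset",
    "evaluate_recovery",
    "write_truth_tsv",
]


@dataclass(frozen=True)
class TractSpec:
    """Request to plant one tract: where, in whom, and of which kind.

    ``start_snp``/``end_snp`` are 0-based inclusive SNP indices within the
    chromosome; ``carrier_fraction`` of the breed's individuals (rounded to
    the nearest count) receive the tract.
    """

    breed: str
    chrom: str
    start_snp: int
    end_snp: int
    carrier_fraction: float
    mode: str  # HOM | HET

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must be in [0, 1]")
        if self.end_snp < self.start_snp:
            raise ValueError("end_snp < start_snp")
        if self.mode not in ("HOM", "HET"):
            raise ValueError("mode must be HOM or HET")


@dataclass
class SimConfig:
    """Study-design knobs for one simulated dataset.

    Defaults emulate the array design the package targets: ~4 kb mean
    marker spacing and near-uniform allele frequencies.  ``missing_rate``
    applies Bernoulli missingness outside planted tracts (or everywhere
    with ``missing_in_tracts``).
    """

    seed: int
    n_breeds: int = 1
    n_individuals_per_breed: int = 50
    n_chromosomes: int = 1
    snps_per_chromosome: int = 3000
    mean_spacing_bp: float = 4000.0
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.0
    tracts: list[TractSpec] = field(default_factory=list)
    missing_in_tracts: bool = False
    breed_names: list[str] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.allele_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("allele_freq_range must satisfy 0 < lo <= hi < 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class TruthTract:
    """One planted tract, resolved to bp coordinates and carrier ids."""

    breed: str
    chrom: str
    start_bp: int
    end_bp: int
    mode: str
    carriers: tuple[str, ...]


@dataclass(frozen=True)
class TractRecovery:
    """Recovery metrics for one tract (all in [0, 1])."""

    tract: TruthTract
    jaccard_mean: float
    precision: float
    recall: float
    island_called: bool


@dataclass
class RecoveryReport:
    tracts: list[TractRecovery]
    fingerprint: str


def simulate_dataset(cfg: SimConfig) -> tuple[GenotypeDataset, list[TruthTract]]:
    """Generate a dataset and its planted-tract ground truth.

    SNP positions are cumulative exponential spacings (mean
    ``mean_spacing_bp``, rounded up to >= 1 bp); background genotypes are
    HWE draws (p^2, 2pq, q^2) at per-SNP allele-1 frequencies uniform in
    ``allele_freq_range``.  HOM tracts re-draw one allele per carrier and
    SNP from its frequency and double it; HET tracts set carrier genotypes
    heterozygous.  Missingness never hits planted tracts unless
    ``missing_in_tracts``.  Fully reproducible from ``cfg.seed``; output is
    polarity-canonical so it round-trips through PED/MAP exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    breed_names = cfg.breed_names or [f"BREED{i + 1}" for i in range(cfg.n_breeds)]
    if len(breed_names) != cfg.n_breeds:
        raise ValueError("breed_names length must equal n_breeds")

    samples = [
        SampleRecord(sample_id=f"{b}_{i + 1:03d}", breed=b)
        for b in breed_names
        for i in range(cfg.n_individuals_per_breed)
    ]
    n = len(samples)

    snps: list[SnpRecord] = []
    chrom_offsets: dict[str, int] = {}
    for c in range(cfg.n_chromosomes):
        chrom = str(c + 1)
        chrom_offsets[chrom] = len(snps)
        spacings = np.maximum(
            1, np.round(rng.exponential(cfg.mean_spacing_bp, cfg.snps_per_chromosome))
        ).astype(np.int64)
        pos = np.cumsum(spacings)
        for j, bp in enumerate(pos):
            snps.append(
                SnpRecord(chrom=chrom, snp_id=f"snp{chrom}_{j + 1}", bp=int(bp))
            )
    m = len(snps)

    lo, hi = cfg.allele_freq_range
    p = rng.uniform(lo, hi, m)
    u = rng.random((n, m))
    hom1 = p**2
    het = 2.0 * p * (1.0 - p)
    calls = np.where(u < hom1, 0, np.where(u < hom1 + het, 1, 2)).astype(np.int8)

    # resolve tracts, choose carriers, check per-individual collisions
    breed_members: dict[str, list[int]] = {b: [] for b in breed_names}
    for i, s in enumerate(samples):
        breed_members[s.breed].append(i)
    tract_cols: list[np.ndarray] = []
    truths: list[TruthTract] = []
    claimed: dict[int, set[int]] = {}
    for ts in cfg.tracts:
        if ts.breed not in breed_members:
            raise ValueError(f"tract breed {ts.breed!r} not simulated")
        off = chrom_offsets[ts.chrom]
        if ts.end_snp >= cfg.snps_per_chromosome:
            raise ValueError("tract SNP range outside chromosome")
        cols = np.arange(off + ts.start_snp, off + ts.end_snp + 1)
        members = breed_members[ts.breed]
        k = int(round(ts.carrier_fraction * len(members)))
        carrier_idx = rng.choice(members, size=k, replace=False)
        for i in carrier_idx:
            col_set = claimed.setdefault(int(i), set())
            overlap = col_set.intersection(cols.tolist())
            if overlap:
                raise ValueError(
                    f"tract collision in individual {samples[i].sample_id!r}"
                )
            col_set.update(cols.tolist())
        for i in carrier_idx:
            if ts.mode == "HOM":
                a = (rng.random(cols.size) >= p[cols]).astype(np.int8) * 2
                calls[i, cols] = a
            else:
                calls[i, cols] = 1
        tract_cols.append(cols)
        truths.append(
            TruthTract(
                breed=ts.breed,
                chrom=ts.chrom,
                start_bp=snps[cols[0]].bp,
                end_bp=snps[cols[-1]].bp,
                mode=ts.mode,
                carriers=tuple(sorted(samples[i].sample_id for i in carrier_idx)),
            )
        )

    if cfg.missing_rate > 0:
        miss = rng.random((n, m)) < cfg.missing_rate
        if not cfg.missing_in_tracts:
            carrier_rows = {
                s.sample_id: i for i, s in enumerate(samples)
            }
            for truth, cols in zip(truths, tract_cols):
                for sid in truth.carriers:
                    miss[carrier_rows[sid], cols] = False
        calls[miss] = MISSING

    ds = GenotypeDataset(samples=samples, snps=snps, calls=calls).canonical_polarity()
    return ds, truths


def _interval_overlap(a_lo: int, a_hi: int, b_lo: int, b_hi: int) -> int:
    """Shared bp of two closed intervals (0 if disjoint)."""
    lo, hi = max(a_lo, b_lo), min(a_hi, b_hi)
    return max(0, hi - lo)


def evaluate_recovery(
    truth: list[TruthTract],
    rs: RunSet,
    islands: list[Island] | None = None,
    ds: GenotypeDataset | None = None,
) -> RecoveryReport:
    """Score detected runs (and optionally islands) against planted tracts.

    Per carrier, Jaccard = |detected & planted| / |detected | planted| in
    bp over that carrier's runs on the tract chromosome; precision and
    recall aggregate intersect / detected and intersect / planted bp over
    carriers.  ``island_called`` is true when a same-breed island overlaps
    the tract.  When ``ds`` is given, its fingerprint must match the
    RunSet's.
    """
    if ds is not None and rs.fingerprint and ds.fingerprint() != rs.fingerprint:
        raise ValueError("dataset fingerprint does not match RunSet")
    out = []
    for t in truth:
        planted_len = t.end_bp - t.start_bp
        jaccards = []
        tot_inter = 0
        tot_det = 0
        for sid in t.carriers:
            runs = [
                r for r in rs.runs if r.sample_id == sid and r.chrom == t.chrom
            ]
            det = sum(r.length_bp for r in runs)
            inter = sum(
                _interval_overlap(r.start_bp, r.end_bp, t.start_bp, t.end_bp)
                for r in runs
            )
            union = det + planted_len - inter
            jaccards.append(inter / union if union > 0 else 0.0)
            tot_inter += inter
            tot_det += det
        island_called = False
        if islands is not None:
            island_called = any(
                i.breed == t.breed
                and i.chrom == t.chrom
                and _interval_overlap(i.start_bp, i.end_bp, t.start_bp, t.end_bp) > 0
                for i in islands
            )
        out.append(
            TractRecovery(
                tract=t,
                jaccard_mean=float(np.mean(jaccards)) if jaccards else 0.0,
                precision=tot_inter / tot_det if tot_det else 0.0,
                recall=tot_inter / (planted_len * max(1, len(t.carriers)))
                if planted_len
                else 0.0,
                island_called=island_called,
            )
        )
    return RecoveryReport(tracts=out, fingerprint=rs.fingerprint)


def write_truth_tsv(
    truths: list[TruthTract], path: str | Path, seed: int | None = None
) -> None:
    """Truth tracts as TSV; seed recorded in a sidecar JSON when given."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("breed\tchrom\tstart_bp\tend_bp\tmode\tcarriers\n")
        for t in truths:
            fh.write(
                f"{t.breed}\t{t.chrom}\t{t.start_bp}\t{t.end_bp}\t{t.mode}\t"
                + ";".join(t.carriers)
                + "\n"
            )
    if seed is not None:
        path.with_suffix(".json").write_text(json.dumps({"seed": seed}) + "\n")
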