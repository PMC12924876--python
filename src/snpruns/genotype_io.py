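"""PLINK-text genotype I/O, quality control, and LD pruning.

Genotypes are held as a samples x SNPs matrix of small integer codes:
``0`` homozygous for allele-1 (the first allele seen in the file for that
SNP), ``1`` heterozygous, ``2`` homozygous for allele-2, and ``MISSING``
(-1) for no-calls.  Downstream analyses only distinguish heterozygous /
homozygous / missing states, so allele orientation carries no meaning
beyond the round-trip contract of :func:`write_plink_text`.

Coordinates are 1-based inclusive base-pair positions, the MAP convention.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MISSING: int = -1

__all__ = [
    "MISSING",
    "SnpRecord",
    "SampleRecord",
    "GenotypeDataset",
    "QCParams",
    "QCReport",
    "LDPruneParams",
    "PlinkParseError",
    "read_plink_text",
    "write_plink_text",
    "apply_qc",
    "ld_prune",
]


class PlinkParseError(ValueError):
    """Malformed PED/MAP content (ragged row, >2 alleles, duplicate id)."""


@dataclass(frozen=True)
class SnpRecord:
    """One array marker: chromosome label, identifier, bp position (1-based)."""

    chrom: str
    snp_id: str
    bp: int


@dataclass(frozen=True)
class SampleRecord:
    """One genotyped individual with its breed (PED family-ID column)."""

    sample_id: str
    breed: str


def _chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    """Numeric chromosomes sort numerically and before non-numeric labels."""
    try:
        return (0, int(chrom))
    except ValueError:
        return (1, chrom)


@dataclass
class GenotypeDataset:
    """Samples x SNPs genotype call matrix with map and breed labels.

    ``calls[i, j]`` is the code of sample ``i`` at SNP ``j``; ``alleles[j]``
    holds the (allele-1, allele-2) symbols used when writing PED.  SNPs are
    kept sorted by (chromosome, bp).
    """

    samples: list[SampleRecord]
    snps: list[SnpRecord]
    calls: np.ndarray
    alleles: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"({len(self.samples)} samples, {len(self.snps)} SNPs)"
            )
        valid = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid genotype codes {bad.tolist()}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def breeds(self) -> list[str]:
        """Distinct breed labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.breed, None)
        return list(seen)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.bp for s in self.snps], dtype=np.int64)

    @property
    def chroms(self) -> list[str]:
        """Distinct chromosome labels in map order."""
        seen: dict[str, None] = {}
        for s in self.snps:
            seen.setdefault(s.chrom, None)
        return list(seen)

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous column slice of one chromosome (SNPs are map-sorted)."""
        idx = [j for j, s in enumerate(self.snps) if s.chrom == chrom]
        if not idx:
            raise KeyError(f"chromosome {chrom!r} not in dataset")
        lo, hi = idx[0], idx[-1] + 1
        if hi - lo != len(idx):
            raise ValueError(f"chromosome {chrom!r} is not contiguous in the map")
        return slice(lo, hi)

    def breed_sample_indices(self, breed: str) -> np.ndarray:
        idx = np.array(
            [i for i, s in enumerate(self.samples) if s.breed == breed], dtype=np.intp
        )
        if idx.size == 0:
            raise KeyError(f"breed {breed!r} not in dataset")
        return idx

    def subset(
        self, sample_idx: np.ndarray | None = None, snp_idx: np.ndarray | None = None
    ) -> "GenotypeDataset":
        if sample_idx is None:
            sample_idx = np.arange(self.n_samples)
        if snp_idx is None:
            snp_idx = np.arange(self.n_snps)
        sample_idx = np.asarray(sample_idx)
        snp_idx = np.asarray(snp_idx)
        return GenotypeDataset(
            samples=[self.samples[i] for i in sample_idx],
            snps=[self.snps[j] for j in snp_idx],
            calls=self.calls[np.ix_(sample_idx, snp_idx)].copy(),
            alleles=None if self.alleles is None else [self.alleles[j] for j in snp_idx],
        )

    def canonical_polarity(self) -> "GenotypeDataset":
        """Flip SNP columns whose first non-missing call is hom-allele-2.

        After flipping, every SNP's first non-missing genotype carries
        allele-1, which is exactly the orientation :func:`read_plink_text`
        reconstructs — so canonical datasets round-trip losslessly through
        PED/MAP.  Polarity carries no information for any downstream
        statistic (only het/hom/missing states are used).
        """
        calls = self.calls.copy()
        alleles = list(self.alleles) if self.alleles is not None else None
        for j in range(self.n_snps):
            col = calls[:, j]
            nm = np.flatnonzero(col != MISSING)
            if nm.size and col[nm[0]] == 2:
                col[nm] = 2 - col[nm]
                if alleles is not None:
                    a1, a2 = alleles[j]
                    alleles[j] = (a2, a1)
        return GenotypeDataset(
            samples=list(self.samples), snps=list(self.snps),
            calls=calls, alleles=alleles,
        )

    def genome_length_bp(self) -> int:
        """Sum over chromosomes of (last SNP bp - first SNP bp)."""
        total = 0
        for chrom in self.chroms:
            sl = self.chrom_slice(chrom)
            total += self.snps[sl.stop - 1].bp - self.snps[sl.start].bp
        return total

    def fingerprint(self) -> str:
        """Short content hash binding runs/truth back to their dataset."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.calls).tobytes())
        h.update("\n".join(self.sample_ids).encode())
        h.update("\n".join(s.snp_id for s in self.snps).encode())
        return f"{self.n_samples}x{self.n_snps}:{h.hexdigest()[:12]}"


# ---------------------------------------------------------------------------
# PLINK text parsing


def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Read PED/MAP text files into a :class:`GenotypeDataset`.

    MAP rows are ``chrom snp_id cM bp``; PED rows are the six mandatory
    columns followed by two allele columns per SNP in MAP order.  ``0`` is
    the missing-allele symbol.  Allele-1 of each SNP is the first non-missing
    allele symbol encountered in file order; more than two distinct symbols
    at one SNP is an error.  SNPs are returned sorted by (chromosome, bp);
    sample order follows the PED.
    """
    map_path = Path(map_path)
    ped_path = Path(ped_path)

    snps_file_order: list[SnpRecord] = []
    with map_path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise PlinkParseError(
                    f"{map_path.name}:{lineno}: expected 4 columns, got {len(parts)}"
                )
            chrom, snp_id, _cm, bp = parts
            snps_file_order.append(SnpRecord(chrom=chrom, snp_id=snp_id, bp=int(bp)))

    ids = [s.snp_id for s in snps_file_order]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise PlinkParseError(f"duplicate snp_id {dup!r} in {map_path.name}")

    m = len(snps_file_order)
    samples: list[SampleRecord] = []
    rows: list[np.ndarray] = []
    # first-seen allele per SNP (file column order)
    allele1: list[str | None] = [None] * m
    allele2: list[str | None] = [None] * m

    with ped_path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise PlinkParseError(
                    f"{ped_path.name}:{lineno}: expected {6 + 2 * m} fields "
                    f"({m} SNPs), got {len(parts)}"
                )
            fid, iid = parts[0], parts[1]
            samples.append(SampleRecord(sample_id=iid, breed=fid))
            row = np.empty(m, dtype=np.int8)
            for j in range(m):
                a, b = parts[6 + 2 * j], parts[7 + 2 * j]
                if a == "0" or b == "0":
                    row[j] = MISSING
                    continue
                for al in (a, b):
                    if allele1[j] is None:
                        allele1[j] = al
                    elif al != allele1[j] and allele2[j] is None:
                        allele2[j] = al
                    elif al not in (allele1[j], allele2[j]):
                        raise PlinkParseError(
                            f"{ped_path.name}:{lineno}: SNP "
                            f"{snps_file_order[j].snp_id!r} has >2 alleles "
                            f"({allele1[j]}, {allele2[j]}, {al})"
                        )
                # code = number of allele-2 copies
                row[j] = (a == allele2[j]) + (b == allele2[j])
            rows.append(row)

    sids = [s.sample_id for s in samples]
    if len(set(sids)) != len(sids):
        raise PlinkParseError(f"duplicate sample_id in {ped_path.name}")

    calls = (
        np.vstack(rows) if rows else np.empty((0, m), dtype=np.int8)
    )
    order = sorted(
        range(m), key=lambda j: (_chrom_sort_key(snps_file_order[j].chrom),
                                 snps_file_order[j].bp)
    )
    snps = [snps_file_order[j] for j in order]
    calls = calls[:, order] if m else calls
    alleles = [
        (allele1[j] or "A", allele2[j] or _second_symbol(allele1[j]))
        for j in order
    ]
    return GenotypeDataset(samples=samples, snps=snps, calls=calls, alleles=alleles)


def _second_symbol(a1: str | None) -> str:
    return "B" if a1 != "B" else "A"


def write_plink_text(
    ds: GenotypeDataset, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write PED/MAP text re-readable by :func:`read_plink_text`.

    Missing calls become ``0 0``.  Allele symbols come from ``ds.alleles``
    when present, else the default pair ("A", "B").
    """
    map_path = Path(map_path)
    ped_path = Path(ped_path)
    alleles = ds.alleles or [("A", "B")] * ds.n_snps

    with map_path.open("w") as fh:
        for s in ds.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.bp}\n")

    with ped_path.open("w") as fh:
        for i, sample in enumerate(ds.samples):
            fields = [sample.breed, sample.sample_id, "0", "0", "0", "-9"]
            row = ds.calls[i]
            for j in range(ds.n_snps):
                a1, a2 = alleles[j]
                code = row[j]
                if code == MISSING:
                    fields += ["0", "0"]
                elif code == 0:
                    fields += [a1, a1]
                elif code == 1:
                    fields += [a1, a2]
                else:
                    fields += [a2, a2]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Quality control


@dataclass
class QCParams:
    """Marker/sample quality thresholds.

    Markers must have minor allele frequency >= ``maf_min`` and per-SNP call
    rate strictly greater than ``snp_call_rate_min``; individuals must have
    call rate strictly greater than ``ind_call_rate_min``.  With
    ``autosomes_only`` set, only numeric chromosome labels in
    [1, ``autosome_max``] survive (26 = the ovine autosome count).
    """

    maf_min: float = 0.01
    snp_call_rate_min: float = 0.95
    ind_call_rate_min: float = 0.90
    autosomes_only: bool = True
    autosome_max: int = 26

    def __post_init__(self) -> None:
        for name in ("maf_min", "snp_call_rate_min", "ind_call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    """Attrition bookkeeping for one :func:`apply_qc` pass."""

    n_snps_in: int
    n_snps_out: int
    n_samples_in: int
    n_samples_out: int
    removed_snp_ids: list[str] = field(default_factory=list)
    removed_sample_ids: list[str] = field(default_factory=list)
    removed_by_filter: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def _is_autosome(chrom: str, autosome_max: int) -> bool:
    try:
        c = int(chrom)
    except ValueError:
        return False
    return 1 <= c <= autosome_max


def allele1_frequencies(calls: np.ndarray) -> np.ndarray:
    """Per-SNP allele-1 frequency over non-missing calls (NaN if none)."""
    calls = np.asarray(calls)
    nonmiss = calls != MISSING
    n = nonmiss.sum(axis=0)
    # allele-2 dose sums over non-missing
    dose = np.where(nonmiss, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 1.0 - dose / (2.0 * n)
    return np.where(n > 0, p, np.nan)


def minor_allele_frequencies(calls: np.ndarray) -> np.ndarray:
    p = allele1_frequencies(calls)
    return np.minimum(p, 1.0 - p)


def apply_qc(ds: GenotypeDataset, p: QCParams) -> tuple[GenotypeDataset, QCReport]:
    """Filter the dataset, in the fixed order:

    1. drop non-autosomal / unplaced SNPs (if ``autosomes_only``);
    2. drop SNPs with call rate <= ``snp_call_rate_min``;
    3. drop samples with call rate <= ``ind_call_rate_min``;
    4. drop SNPs with MAF < ``maf_min`` computed on surviving samples.

    MAF comes after sample removal, mirroring the usual PLINK practice.
    """
    report = QCReport(
        n_snps_in=ds.n_snps,
        n_snps_out=ds.n_snps,
        n_samples_in=ds.n_samples,
        n_samples_out=ds.n_samples,
    )
    snp_keep = np.ones(ds.n_snps, dtype=bool)

    if p.autosomes_only:
        auto = np.array(
            [_is_autosome(s.chrom, p.autosome_max) for s in ds.snps], dtype=bool
        )
        report.removed_by_filter["non_autosomal"] = int((~auto).sum())
        snp_keep &= auto
    else:
        report.removed_by_filter["non_autosomal"] = 0

    nonmiss = ds.calls != MISSING
    if ds.n_samples > 0:
        snp_cr = nonmiss.mean(axis=0)
    else:
        snp_cr = np.ones(ds.n_snps)
    low_cr = snp_keep & ~(snp_cr > p.snp_call_rate_min)
    report.removed_by_filter["snp_call_rate"] = int(low_cr.sum())
    snp_keep &= ~low_cr

    if snp_keep.any():
        ind_cr = nonmiss[:, snp_keep].mean(axis=1)
    else:
        ind_cr = np.ones(ds.n_samples)
    sample_keep = ind_cr > p.ind_call_rate_min
    report.removed_by_filter["ind_call_rate"] = int((~sample_keep).sum())
    if ds.n_samples > 0 and not sample_keep.any():
        raise ValueError("QC removed every sample (empty dataset)")

    maf = minor_allele_frequencies(ds.calls[sample_keep][:, snp_keep])
    sub_ids = np.flatnonzero(snp_keep)
    low_maf_local = ~(maf >= p.maf_min)  # NaN (all-missing) also drops
    report.removed_by_filter["maf"] = int(low_maf_local.sum())
    snp_keep[sub_ids[low_maf_local]] = False

    report.removed_snp_ids = [
        ds.snps[j].snp_id for j in np.flatnonzero(~snp_keep)
    ]
    report.removed_sample_ids = [
        ds.samples[i].sample_id for i in np.flatnonzero(~sample_keep)
    ]
    report.n_snps_out = int(snp_keep.sum())
    report.n_samples_out = int(sample_keep.sum())
    out = ds.subset(np.flatnonzero(sample_keep), np.flatnonzero(snp_keep))
    return out, report


# ---------------------------------------------------------------------------
# LD pruning


@dataclass
class LDPruneParams:
    """Greedy windowed r^2 pruning.

    ``window_kb`` bounds the physical span of each window; ``step_variants``
    is the advance (in surviving SNPs) between windows; pairs with squared
    Pearson genotype correlation > ``r2_max`` lose their lower-MAF member.
    ``window_snps`` switches the window to a fixed SNP count instead of kb.
    """

    window_kb: float = 50.0
    step_variants: int = 10
    r2_max: float = 0.5
    window_snps: int | None = None

    def __post_init__(self) -> None:
        if self.window_kb <= 0:
            raise ValueError("window_kb must be > 0")
        if self.step_variants < 1:
            raise ValueError("step_variants must be >= 1")
        if not 0.0 <= self.r2_max <= 1.0:
            raise ValueError("r2_max must be in [0, 1]")


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two call vectors over complete pairs."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    xv -= xv.mean()
    yv -= yv.mean()
    denom = (xv @ xv) * (yv @ yv)
    if denom == 0.0:
        return 0.0
    r = (xv @ yv) ** 2 / denom
    return float(r)


def ld_prune(ds: GenotypeDataset, p: LDPruneParams) -> list[str]:
    """Greedy per-chromosome LD pruning; returns retained snp_ids in map order.

    Within each window (SNPs within ``window_kb`` of the window's first
    surviving SNP, or a fixed count when ``window_snps`` is set), every pair
    with r^2 > ``r2_max`` marks for removal the member with the lower MAF
    (ties keep the earlier-bp SNP); the window start then advances by
    ``step_variants`` surviving SNPs.
    """
    maf = minor_allele_frequencies(ds.calls)
    keep = np.ones(ds.n_snps, dtype=bool)
    window_bp = p.window_kb * 1000.0

    for chrom in ds.chroms:
        sl = ds.chrom_slice(chrom)
        idx = np.arange(sl.start, sl.stop)
        pos = ds.positions[sl]
        start = 0
        while start < idx.size:
            if not keep[idx[start]]:
                start += 1
                continue
            surv = [k for k in range(start, idx.size) if keep[idx[k]]]
            if p.window_snps is not None:
                window = surv[: p.window_snps]
            else:
                limit = pos[surv[0]] + window_bp
                window = [k for k in surv if pos[k] <= limit]
            for a_i in range(len(window)):
                ka = window[a_i]
                if not keep[idx[ka]]:
                    continue
                for b_i in range(a_i + 1, len(window)):
                    kb = window[b_i]
                    if not keep[idx[kb]]:
                        continue
                    r2 = _pairwise_r2(ds.calls[:, idx[ka]], ds.calls[:, idx[kb]])
                    if r2 > p.r2_max:
                        ja, jb = idx[ka], idx[kb]
                        if maf[ja] < maf[jb]:
                            keep[ja] = False
                        elif maf[jb] < maf[ja]:
                            keep[jb] = False
                        else:
                            # tie: drop the later-bp member
                            keep[jb] = False
                    if not keep[idx[ka]]:
                        break
            # advance by step_variants among surviving SNPs
            advanced = 0
            k = start
            while k < idx.size and advanced < p.step_variants:
                k += 1
                while k < idx.size and not keep[idx[k]]:
                    k += 1
                advanced += 1
            start = k
    return [ds.snps[j].snp_id for j in np.flatnonzero(keep)]
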