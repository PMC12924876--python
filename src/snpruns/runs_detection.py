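"""Sliding-window detection of runs of homozygosity (ROH) and
heterozygosity-rich regions (HRR).

The detector classifies each SNP of one individual/chromosome by the
fraction of fixed-size genotype windows covering it that are run-compatible
(no more than ``max_opposite_in_window`` opposite genotypes and
``max_missing_in_window`` missing calls; "opposite" is a heterozygote in
HOM mode and a homozygote in HET mode).  SNPs whose passing-window
proportion exceeds ``prop_threshold`` are flagged; maximal flagged
stretches are split at inter-SNP gaps above ``max_gap_bp`` and kept as
runs when they satisfy the minimum SNP count, minimum length and minimum
SNP density.

Only windows fully contained in the chromosome count toward a SNP's
proportion — no phantom windows beyond the ends; a chromosome with fewer
SNPs than the window yields no runs.

:func:`oracle_detect_runs` re-derives the same answer by explicit
enumeration of every window and of every SNP's containing windows, with no
vectorized shortcuts, and serves as the independent reference in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset, _chrom_sort_key

Mode = Literal["HOM", "HET"]

__all__ = [
    "RunParams",
    "Run",
    "RunSet",
    "window_flags",
    "snp_in_run_proportions",
    "assemble_runs",
    "detect_runs",
    "oracle_detect_runs",
]


@dataclass(frozen=True)
class RunParams:
    """The seven sliding-window detection parameters.

    Defaults via :meth:`for_mode`: window of 50 SNPs / minimum 50 SNPs /
    minimum length 1 Mb for ROH ("HOM"); 15 / 15 / 100 kb for HRR ("HET").
    Common to both modes: zero opposite and zero missing genotypes allowed
    per window, maximum inter-SNP gap 1 Mb, minimum density one SNP per
    100 kb, and SNP-in-run proportion threshold 0.05 (strict ``>``).
    """

    mode: Mode
    window_snps: int
    max_opposite_in_window: int = 0
    max_missing_in_window: int = 0
    prop_threshold: float = 0.05
    min_snps: int = 50
    min_length_bp: int = 1_000_000
    max_gap_bp: int = 1_000_000
    min_density_snp_per_bp: float = 1.0 / 100_000

    def __post_init__(self) -> None:
        if self.mode not in ("HOM", "HET"):
            raise ValueError(f"mode must be HOM or HET, got {self.mode!r}")
        if self.window_snps < 2:
            raise ValueError("window_snps must be >= 2")
        if self.min_length_bp <= 0:
            raise ValueError("min_length_bp must be > 0")
        for name in ("max_opposite_in_window", "max_missing_in_window", "min_snps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def for_mode(cls, mode: Mode, **overrides) -> "RunParams":
        if mode == "HOM":
            base = cls(mode="HOM", window_snps=50, min_snps=50,
                       min_length_bp=1_000_000)
        else:
            base = cls(mode="HET", window_snps=15, min_snps=15,
                       min_length_bp=100_000)
        return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class Run:
    """One detected ROH/HRR segment, anchored on its first/last SNP."""

    sample_id: str
    breed: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class RunSet:
    """All runs detected under one parameter set, with dataset fingerprint."""

    runs: list[Run]
    params: RunParams
    fingerprint: str = ""

    def __len__(self) -> int:
        return len(self.runs)

    def sort(self) -> None:
        self.runs.sort(
            key=lambda r: (r.breed, r.sample_id, _chrom_sort_key(r.chrom), r.start_bp)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "breed": r.breed,
                    "sample_id": r.sample_id,
                    "chrom": r.chrom,
                    "start_bp": r.start_bp,
                    "end_bp": r.end_bp,
                    "n_snps": r.n_snps,
                    "length_bp": r.length_bp,
                }
                for r in self.runs
            ],
            columns=[
                "breed", "sample_id", "chrom", "start_bp",
                "end_bp", "n_snps", "length_bp",
            ],
        )

    def to_tsv(self, path: str | Path) -> None:
        """1-based inclusive SNP-anchored intervals."""
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_bed(self, path: str | Path) -> None:
        """0-based half-open export: start-1, end (UCSC BED convention)."""
        df = self.to_frame()
        bed = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start_bp"] - 1,
                "end": df["end_bp"],
                "name": df["breed"] + ":" + df["sample_id"],
            }
        )
        bed.to_csv(path, sep="\t", index=False, header=False)


def _opposite_mask(calls: np.ndarray, mode: Mode) -> np.ndarray:
    if mode == "HOM":
        return calls == 1
    return (calls == 0) | (calls == 2)


def window_flags(calls: np.ndarray, p: RunParams) -> np.ndarray:
    """Pass/fail per sliding window of ``p.window_snps`` consecutive SNPs.

    Window ``i`` covers SNP indices ``[i, i + w - 1]``; a window passes iff
    its opposite-genotype count and missing count are both within bounds.
    Returns an empty array when the vector is shorter than the window.
    """
    calls = np.asarray(calls)
    m = calls.size
    w = p.window_snps
    if m < w:
        return np.zeros(0, dtype=bool)
    opp = _opposite_mask(calls, p.mode).astype(np.int32)
    mis = (calls == MISSING).astype(np.int32)
    c_opp = np.concatenate([[0], np.cumsum(opp)])
    c_mis = np.concatenate([[0], np.cumsum(mis)])
    win_opp = c_opp[w:] - c_opp[:-w]
    win_mis = c_mis[w:] - c_mis[:-w]
    return (win_opp <= p.max_opposite_in_window) & (
        win_mis <= p.max_missing_in_window
    )


def snp_in_run_proportions(
    flags: np.ndarray, m: int, w: int
) -> np.ndarray:
    """Per-SNP fraction of containing windows that pass.

    SNP ``j`` (0-based) is contained in windows ``max(0, j-w+1) ..
    min(j, m-w)``; the proportion is passing/containing.  All zero when
    ``m < w``.
    """
    if m < w:
        return np.zeros(m)
    flags = np.asarray(flags, dtype=bool)
    cum = np.concatenate([[0], np.cumsum(flags)])
    j = np.arange(m)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, m - w)
    c = hi - lo + 1
    passing = cum[hi + 1] - cum[lo]
    return passing / c


def assemble_runs(
    flags: np.ndarray,
    calls: np.ndarray,
    positions: np.ndarray,
    p: RunParams,
    sample_id: str,
    breed: str,
    chrom: str,
) -> list[Run]:
    """Turn per-SNP in-run flags into runs.

    Maximal flagged stretches are first split at adjacent-SNP gaps above
    ``max_gap_bp`` (a gap breaks contiguity before any size filter), then
    kept iff ``n_snps >= min_snps``, span ``>= min_length_bp`` and
    ``n_snps >= span * min_density_snp_per_bp`` (span = end - start).
    """
    flags = np.asarray(flags, dtype=bool)
    positions = np.asarray(positions, dtype=np.int64)
    runs: list[Run] = []
    m = flags.size
    j = 0
    while j < m:
        if not flags[j]:
            j += 1
            continue
        k = j
        while k + 1 < m and flags[k + 1]:
            k += 1
        # split [j, k] at gaps > max_gap_bp
        seg_start = j
        for t in range(j, k + 1):
            gap_break = t < k and positions[t + 1] - positions[t] > p.max_gap_bp
            if t == k or gap_break:
                seg_end = t
                n = seg_end - seg_start + 1
                span = int(positions[seg_end] - positions[seg_start])
                if (
                    n >= p.min_snps
                    and span >= p.min_length_bp
                    and n >= span * p.min_density_snp_per_bp
                ):
                    runs.append(
                        Run(
                            sample_id=sample_id,
                            breed=breed,
                            chrom=chrom,
                            start_bp=int(positions[seg_start]),
                            end_bp=int(positions[seg_end]),
                            n_snps=n,
                        )
                    )
                seg_start = t + 1
        j = k + 1
    return runs


def detect_runs(ds: GenotypeDataset, p: RunParams) -> RunSet:
    """Detect runs for every individual on every chromosome."""
    positions = ds.positions
    runs: list[Run] = []
    for chrom in ds.chroms:
        sl = ds.chrom_slice(chrom)
        pos = positions[sl]
        for i, sample in enumerate(ds.samples):
            calls = ds.calls[i, sl]
            fl = window_flags(calls, p)
            prop = snp_in_run_proportions(fl, calls.size, p.window_snps)
            snp_flags = prop > p.prop_threshold
            runs.extend(
                assemble_runs(
                    snp_flags, calls, pos, p, sample.sample_id, sample.breed, chrom
                )
            )
    rs = RunSet(runs=runs, params=p, fingerprint=ds.fingerprint())
    rs.sort()
    return rs


# ---------------------------------------------------------------------------
# Independent brute-force reference


def oracle_detect_runs(ds: GenotypeDataset, p: RunParams) -> RunSet:
    """Brute-force re-derivation of :func:`detect_runs` for small inputs.

    Every window and every SNP's containing windows are enumerated with
    plain Python loops; no cumulative sums or vectorized shortcuts.  Output
    equals :func:`detect_runs` exactly.
    """
    w = p.window_snps
    runs: list[Run] = []
    for chrom in ds.chroms:
        sl = ds.chrom_slice(chrom)
        pos = [s.bp for s in ds.snps[sl]]
        m = len(pos)
        for i, sample in enumerate(ds.samples):
            calls = [int(c) for c in ds.calls[i, sl]]
            # 1. every window, counted by explicit scan
            passing: list[bool] = []
            for start in range(0, m - w + 1):
                n_opp = 0
                n_mis = 0
                for g in calls[start : start + w]:
                    if g == MISSING:
                        n_mis += 1
                    elif p.mode == "HOM" and g == 1:
                        n_opp += 1
                    elif p.mode == "HET" and g in (0, 2):
                        n_opp += 1
                passing.append(
                    n_opp <= p.max_opposite_in_window
                    and n_mis <= p.max_missing_in_window
                )
            # 2. per-SNP proportion over its containing windows
            flagged: list[bool] = []
            for j in range(m):
                n_contain = 0
                n_pass = 0
                for start in range(max(0, j - w + 1), min(j, m - w) + 1):
                    n_contain += 1
                    if passing[start]:
                        n_pass += 1
                if n_contain == 0:
                    flagged.append(False)
                else:
                    flagged.append(n_pass / n_contain > p.prop_threshold)
            # 3. stretches, gap split, size filters
            j = 0
            while j < m:
                if not flagged[j]:
                    j += 1
                    continue
                k = j
                while k + 1 < m and flagged[k + 1]:
                    k += 1
                seg = [j]
                for t in range(j + 1, k + 1):
                    if pos[t] - pos[t - 1] > p.max_gap_bp:
                        seg.append(t)  # new segment boundary
                # rebuild segments between boundaries
                bounds = seg + [k + 1]
                for b in range(len(bounds) - 1):
                    a, z = bounds[b], bounds[b + 1] - 1
                    n = z - a + 1
                    span = pos[z] - pos[a]
                    if (
                        n >= p.min_snps
                        and span >= p.min_length_bp
                        and n >= span * p.min_density_snp_per_bp
                    ):
                        runs.append(
                            Run(
                                sample_id=sample.sample_id,
                                breed=sample.breed,
                                chrom=chrom,
                                start_bp=pos[a],
                                end_bp=pos[z],
                                n_snps=n,
                            )
                        )
                j = k + 1
    rs = RunSet(runs=runs, params=p, fingerprint=ds.fingerprint())
    rs.sort()
    return rs
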