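"""Diversity indices and IBS/MDS population-structure summaries.

Per-breed observed/expected heterozygosity, per-individual inbreeding F and
its breed mean F_IS, mean MAF; pairwise identity-by-state distances and
classical (Torgerson) multidimensional scaling of the resulting matrix.

Expected heterozygosity uses the small-sample-corrected estimator
``2 p (1-p) * 2n / (2n - 1)`` with ``n`` the non-missing sample count at the
SNP, and the per-individual inbreeding coefficient is the observed-versus-
expected homozygosity contrast ``F = (O_hom - E_hom) / (L - E_hom)`` over
that individual's ``L`` non-missing SNPs — the estimator pair used by
PLINK's ``--het``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset

__all__ = [
    "SnpFrequencyTable",
    "DiversitySummary",
    "DistanceMatrix",
    "MdsResult",
    "snp_frequencies",
    "diversity_summary",
    "ibs_matrix",
    "classical_mds",
]


@dataclass
class SnpFrequencyTable:
    """Per-SNP allele-1 frequency, MAF, call rate and het fraction.

    ``table`` has columns (snp_id, [breed], p, maf, call_rate, het_frac,
    n_nonmissing); SNPs with zero non-missing calls in a group carry NaN
    frequencies and are excluded from downstream means.
    """

    table: pd.DataFrame
    by_breed: bool = False


@dataclass
class DiversitySummary:
    """Per-breed H_O, H_E, F_IS (mean +/- s.d. of individual F), mean MAF."""

    table: pd.DataFrame  # breed, n, h_obs, h_exp, f_is_mean, f_is_sd, maf_mean
    individual_f: pd.DataFrame  # sample_id, breed, f


@dataclass
class DistanceMatrix:
    """Symmetric 1 - IBS distance matrix over ordered samples."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal not zero")
        self.values = v

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)
        df.to_csv(path, sep="\t", float_format="%.8f")


@dataclass
class MdsResult:
    """Classical-scaling coordinates (columns centered) and eigenvalues."""

    sample_ids: list[str]
    coords: np.ndarray  # n x k
    eigenvalues: np.ndarray  # all n, non-increasing

    def to_frame(self, breeds: list[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords,
            columns=[f"C{i + 1}" for i in range(self.coords.shape[1])],
        )
        df.insert(0, "sample_id", self.sample_ids)
        if breeds is not None:
            df.insert(1, "breed", breeds)
        return df


def _group_frequencies(calls: np.ndarray) -> pd.DataFrame:
    calls = np.asarray(calls)
    nonmiss = calls != MISSING
    n = nonmiss.sum(axis=0)
    n_samples = calls.shape[0]
    dose2 = np.where(nonmiss, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 1.0 - dose2 / (2.0 * n)
        het = np.where(nonmiss, calls == 1, False).sum(axis=0) / n
    p = np.where(n > 0, p, np.nan)
    het = np.where(n > 0, het, np.nan)
    return pd.DataFrame(
        {
            "p": p,
            "maf": np.minimum(p, 1.0 - p),
            "call_rate": n / n_samples if n_samples else np.ones_like(n, dtype=float),
            "het_frac": het,
            "n_nonmissing": n,
        }
    )


def snp_frequencies(ds: GenotypeDataset, by_breed: bool = False) -> SnpFrequencyTable:
    """Allele-1 frequency / MAF / call rate / het fraction per SNP.

    With ``by_breed`` the table is stacked per breed, frequencies computed
    over that breed's non-missing calls only.
    """
    snp_ids = [s.snp_id for s in ds.snps]
    if not by_breed:
        tab = _group_frequencies(ds.calls)
        tab.insert(0, "snp_id", snp_ids)
        return SnpFrequencyTable(table=tab, by_breed=False)
    parts = []
    for breed in ds.breeds:
        idx = ds.breed_sample_indices(breed)
        tab = _group_frequencies(ds.calls[idx])
        tab.insert(0, "snp_id", snp_ids)
        tab.insert(1, "breed", breed)
        parts.append(tab)
    return SnpFrequencyTable(table=pd.concat(parts, ignore_index=True), by_breed=True)


def diversity_summary(
    ds: GenotypeDataset, pooled_frequencies: bool = False
) -> DiversitySummary:
    """Per-breed H_O, H_E, F_IS (+/- s.d.) and mean MAF.

    Allele frequencies are within-breed by default (indices are reported per
    breed); ``pooled_frequencies`` switches H_E / F to frequencies computed
    over all samples.  Breeds need at least two individuals.
    """
    rows = []
    f_rows = []
    pooled = _group_frequencies(ds.calls) if pooled_frequencies else None
    for breed in ds.breeds:
        idx = ds.breed_sample_indices(breed)
        if idx.size < 2:
            raise ValueError(f"breed {breed!r} has fewer than 2 samples")
        calls = ds.calls[idx]
        freqs = pooled if pooled_frequencies else _group_frequencies(calls)
        p = freqs["p"].to_numpy()
        n = freqs["n_nonmissing"].to_numpy().astype(float)
        if pooled_frequencies:
            # counts still come from the breed's own calls
            n = (calls != MISSING).sum(axis=0).astype(float)
        ok = (n > 0) & np.isfinite(p)
        with np.errstate(invalid="ignore", divide="ignore"):
            h_exp_snp = 2.0 * p * (1.0 - p) * (2.0 * n) / (2.0 * n - 1.0)
        breed_het = _group_frequencies(calls)["het_frac"].to_numpy()
        h_obs = float(np.nanmean(breed_het[ok]))
        h_exp = float(np.mean(h_exp_snp[ok]))
        maf_mean = float(np.nanmean(freqs["maf"].to_numpy()[ok]))

        # per-individual F over that individual's non-missing SNPs
        nonmiss = calls != MISSING
        exp_hom_snp = np.where(ok, 1.0 - h_exp_snp, 0.0)
        f_vals = []
        for r in range(calls.shape[0]):
            use = nonmiss[r] & ok
            L = int(use.sum())
            o_hom = float(np.sum((calls[r][use] != 1)))
            e_hom = float(exp_hom_snp[use].sum())
            denom = L - e_hom
            f = (o_hom - e_hom) / denom if abs(denom) > 1e-12 else 0.0
            f_vals.append(f)
            f_rows.append(
                {"sample_id": ds.samples[idx[r]].sample_id, "breed": breed, "f": f}
            )
        f_arr = np.array(f_vals)
        rows.append(
            {
                "breed": breed,
                "n": int(idx.size),
                "h_obs": h_obs,
                "h_exp": h_exp,
                "f_is_mean": float(f_arr.mean()),
                "f_is_sd": float(f_arr.std(ddof=1)),
                "maf_mean": maf_mean,
            }
        )
    return DiversitySummary(
        table=pd.DataFrame(rows), individual_f=pd.DataFrame(f_rows)
    )


def ibs_matrix(ds: GenotypeDataset) -> DistanceMatrix:
    """Pairwise 1 - IBS distances.

    Per pair, IBS is the mean over jointly non-missing SNPs of
    ``(2 - |g_i - g_j|) / 2``; a pair sharing zero non-missing SNPs is an
    error.  Typically applied to the LD-pruned marker set.
    """
    n = ds.n_samples
    if n < 2:
        raise ValueError("ibs_matrix needs at least 2 samples")
    calls = ds.calls.astype(np.int16)
    nonmiss = calls != MISSING
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = nonmiss[i] & nonmiss[j]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"samples {ds.samples[i].sample_id!r} and "
                    f"{ds.samples[j].sample_id!r} share no non-missing SNPs"
                )
            d = np.abs(calls[i, ok] - calls[j, ok]).mean() / 2.0
            dist[i, j] = dist[j, i] = d
    return DistanceMatrix(sample_ids=ds.sample_ids, values=dist)


def classical_mds(d: DistanceMatrix, k: int) -> MdsResult:
    """Classical (Torgerson) scaling of a distance matrix.

    Double-centers ``-0.5 * D**2``, eigendecomposes, and returns the top-k
    eigenvector coordinates scaled by sqrt(eigenvalue).  Negative
    eigenvalues (non-Euclidean input) are truncated to zero with a warning.
    Coordinate signs are fixed by making each column's largest-magnitude
    entry positive.
    """
    n = len(d.sample_ids)
    if not 1 <= k < n:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    D2 = d.values**2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if (evals[:k] < -1e-10 * max(1.0, abs(evals[0]))).any():
        warnings.warn(
            "negative eigenvalues truncated to zero (non-Euclidean distances)",
            stacklevel=2,
        )
    lam = np.clip(evals[:k], 0.0, None)
    coords = evecs[:, :k] * np.sqrt(lam)
    for c in range(k):
        col = coords[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    coords -= coords.mean(axis=0)  # numerical re-centering
    return MdsResult(sample_ids=list(d.sample_ids), coords=coords, eigenvalues=evals)
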