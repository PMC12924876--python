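"""Per-individual and per-breed run statistics and length-class tallies.

For each individual: the run count N, mean run length L (Mb), total run
length S (Mb), and the genome fraction F = S / genome length — the genomic
inbreeding coefficient F_ROH in HOM mode, the degree of diversity D_HRR in
HET mode.  Breed summaries are means +/- sample s.d. over individuals
(individuals with zero runs included, N = 0).

Length classes: 1-2, 2-4, 4-8, 8-16, >16 Mb for ROH; <150, 150-200,
200-300, 300-400, >400 kb for HRR.  Edges are right-open so the five
classes partition the runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset
from .runs_detection import RunSet

__all__ = [
    "IndividualRunSummary",
    "BreedRunSummary",
    "LengthClassTable",
    "ROH_CLASS_EDGES_MB",
    "HRR_CLASS_EDGES_KB",
    "summarize_individuals",
    "breed_summary",
    "length_class_histogram",
]

ROH_CLASS_EDGES_MB = (1.0, 2.0, 4.0, 8.0, 16.0)
ROH_CLASS_LABELS = ("1-2 Mb", "2-4 Mb", "4-8 Mb", "8-16 Mb", ">16 Mb")
HRR_CLASS_EDGES_KB = (150.0, 200.0, 300.0, 400.0)
HRR_CLASS_LABELS = ("<150 kb", "150-200 kb", "200-300 kb", "300-400 kb", ">400 kb")


@dataclass(frozen=True)
class IndividualRunSummary:
    """N / L / S / F for one individual (lengths in Mb)."""

    sample_id: str
    breed: str
    n_runs: int
    l_mean_mb: float
    s_sum_mb: float
    f: float


@dataclass
class BreedRunSummary:
    """Breed-level means +/- s.d. over individuals (the Table-1 layout)."""

    breed: str
    n_individuals: int
    total_runs: int
    n_mean: float
    n_sd: float
    l_mean: float
    l_sd: float
    s_mean: float
    s_sd: float
    f_mean: float
    f_sd: float


@dataclass
class LengthClassTable:
    """Run counts per breed x chromosome x length class."""

    mode: str
    table: pd.DataFrame  # breed, chrom, length_class, count
    labels: tuple[str, ...]


def summarize_individuals(
    rs: RunSet,
    genome_length_bp: float,
    ds: GenotypeDataset | None = None,
) -> list[IndividualRunSummary]:
    """Per-individual N, L (Mb), S (Mb) and F = S / genome length.

    When ``ds`` is given, every genotyped individual appears in the output
    (N = 0 without runs); otherwise only individuals with runs do.
    ``genome_length_bp`` is typically the dataset's SNP-covered autosomal
    span, or the study constant ~2.4 Gb.
    """
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be > 0")
    per: dict[str, list] = {}
    breeds: dict[str, str] = {}
    if ds is not None:
        for s in ds.samples:
            per[s.sample_id] = []
            breeds[s.sample_id] = s.breed
    for r in rs.runs:
        per.setdefault(r.sample_id, []).append(r)
        breeds[r.sample_id] = r.breed
    out = []
    for sample_id, runs in per.items():
        n = len(runs)
        s_bp = float(sum(r.length_bp for r in runs))
        s_mb = s_bp / 1e6
        out.append(
            IndividualRunSummary(
                sample_id=sample_id,
                breed=breeds[sample_id],
                n_runs=n,
                l_mean_mb=s_mb / n if n else 0.0,
                s_sum_mb=s_mb,
                f=s_bp / genome_length_bp,
            )
        )
    return out


def breed_summary(
    summaries: list[IndividualRunSummary],
    include_zero_run_individuals: bool = True,
) -> list[BreedRunSummary]:
    """Means and sample s.d. (n-1) over the individuals of each breed.

    ``include_zero_run_individuals=False`` restricts the averages to
    individuals carrying at least one run (an alternative reading of
    per-individual means some studies use).
    """
    if not summaries:
        return []
    df = pd.DataFrame([s.__dict__ for s in summaries])
    out = []
    for breed, grp in df.groupby("breed", sort=False):
        total = int(grp["n_runs"].sum())
        sub = grp if include_zero_run_individuals else grp[grp["n_runs"] > 0]
        if sub.empty:
            sub = grp
        def ms(col: str) -> tuple[float, float]:
            v = sub[col].to_numpy(dtype=float)
            sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
            return float(v.mean()), sd
        n_mean, n_sd = ms("n_runs")
        l_mean, l_sd = ms("l_mean_mb")
        s_mean, s_sd = ms("s_sum_mb")
        f_mean, f_sd = ms("f")
        out.append(
            BreedRunSummary(
                breed=str(breed),
                n_individuals=int(len(sub)),
                total_runs=total,
                n_mean=n_mean, n_sd=n_sd,
                l_mean=l_mean, l_sd=l_sd,
                s_mean=s_mean, s_sd=s_sd,
                f_mean=f_mean, f_sd=f_sd,
            )
        )
    return out


def _classify(length_bp: int, mode: str) -> str:
    if mode == "HOM":
        mb = length_bp / 1e6
        if mb < 1.0:
            raise ValueError(
                f"ROH of {length_bp} bp is below the 1 Mb detection minimum"
            )
        for edge, label in zip(ROH_CLASS_EDGES_MB[1:], ROH_CLASS_LABELS[:-1]):
            if mb < edge:
                return label
        return ROH_CLASS_LABELS[-1]
    kb = length_bp / 1e3
    for edge, label in zip(HRR_CLASS_EDGES_KB, HRR_CLASS_LABELS[:-1]):
        if kb < edge:
            return label
    return HRR_CLASS_LABELS[-1]


def length_class_histogram(rs: RunSet) -> LengthClassTable:
    """Tally runs into the five mode-specific length classes.

    Right-open class edges: a 2.0 Mb ROH falls in "2-4 Mb", a 150.0 kb HRR
    in "150-200 kb".  A HOM run below 1 Mb violates the detection contract
    and raises.
    """
    mode = rs.params.mode
    labels = ROH_CLASS_LABELS if mode == "HOM" else HRR_CLASS_LABELS
    rows = []
    for r in rs.runs:
        rows.append(
            {
                "breed": r.breed,
                "chrom": r.chrom,
                "length_class": _classify(r.length_bp, mode),
            }
        )
    if rows:
        table = (
            pd.DataFrame(rows)
            .groupby(["breed", "chrom", "length_class"], sort=False)
            .size()
            .reset_index(name="count")
        )
    else:
        table = pd.DataFrame(columns=["breed", "chrom", "length_class", "count"])
    return LengthClassTable(mode=mode, table=table, labels=labels)
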