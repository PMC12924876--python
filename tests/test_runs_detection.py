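"""Sliding-window ROH/HRR detection against hand counts and the
brute-force oracle."""

import numpy as np
import pytest

from snpruns import (
    MISSING,
    RunParams,
    assemble_runs,
    detect_runs,
    oracle_detect_runs,
    snp_in_run_proportions,
    window_flags,
)
from snpruns.synthetic_data import SimConfig, TractSpec, simulate_dataset

from conftest import make_dataset

HOM = RunParams.for_mode("HOM")
HET = RunParams.for_mode("HET")


class TestWindowFlags:
    def test_all_homozygous_all_windows_pass(self):
        flags = window_flags(np.zeros(60, dtype=np.int8), HOM)
        assert flags.shape == (11,)
        assert flags.all()

    def test_central_heterozygote_fails_every_window(self):
        calls = np.zeros(60, dtype=np.int8)
        calls[29] = 1  # covered by all 11 windows of size 50
        assert not window_flags(calls, HOM).any()

    def test_vector_shorter_than_window(self):
        assert window_flags(np.zeros(40, dtype=np.int8), HOM).size == 0

    def test_het_mode_opposite_is_homozygote(self):
        calls = np.ones(20, dtype=np.int8)
        assert window_flags(calls, HET).all()
        calls[10] = 2
        assert not window_flags(calls, HET).any()

    def test_missing_budget(self):
        calls = np.zeros(60, dtype=np.int8)
        calls[10] = MISSING
        assert not window_flags(calls, HOM).any()
        p = RunParams.for_mode("HOM", max_missing_in_window=1)
        assert window_flags(calls, p).all()


def brute_force_proportions(flags, m, w):
    out = np.zeros(m)
    for j in range(m):
        contain = [i for i in range(max(0, m - w + 1)) if i <= j <= i + w - 1]
        if contain:
            out[j] = sum(flags[i] for i in contain) / len(contain)
    return out if m >= w else np.zeros(m)


class TestSnpInRunProportions:
    def test_all_pass_gives_ones(self):
        p = snp_in_run_proportions(np.ones(11, dtype=bool), 60, 50)
        np.testing.assert_array_equal(p, np.ones(60))

    def test_all_fail_gives_zeros(self):
        p = snp_in_run_proportions(np.zeros(11, dtype=bool), 60, 50)
        assert not (p > 0).any()

    def test_first_three_windows_pass_matches_enumeration(self):
        m, w = 100, 50
        flags = np.zeros(m - w + 1, dtype=bool)
        flags[:3] = True
        got = snp_in_run_proportions(flags, m, w)
        np.testing.assert_allclose(got, brute_force_proportions(flags, m, w))
        assert got[0] == 1.0  # single containing window, passing
        assert got[59] == 0.0

    def test_shorter_than_window_all_zero(self):
        np.testing.assert_array_equal(
            snp_in_run_proportions(np.zeros(0, dtype=bool), 40, 50), np.zeros(40)
        )


class TestAssembleRuns:
    def test_sixty_snps_twenty_kb_spacing(self):
        pos = np.arange(60) * 20_000 + 1
        flags = np.ones(60, dtype=bool)
        runs = assemble_runs(flags, np.zeros(60), pos, HOM, "s", "b", "1")
        assert len(runs) == 1
        assert runs[0].n_snps == 60
        assert runs[0].length_bp == 1_180_000

    def test_gap_splits_then_min_snps_rejects(self):
        pos = np.concatenate(
            [np.arange(30) * 20_000, 2_100_000 + np.arange(30) * 20_000]
        )
        flags = np.ones(60, dtype=bool)
        runs = assemble_runs(flags, np.zeros(60), pos, HOM, "s", "b", "1")
        assert runs == []  # pieces of 30 < 50 SNPs each

    def test_het_run_thresholds(self):
        pos = np.arange(15) * 8_000 + 1
        flags = np.ones(15, dtype=bool)
        runs = assemble_runs(flags, np.ones(15), pos, HET, "s", "b", "1")
        assert len(runs) == 1
        assert runs[0].length_bp == 112_000

    def test_density_filter(self):
        # 50 SNPs over 6 Mb: density 50/6e6 < 1/100kb
        pos = np.arange(50) * 120_000 + 1
        flags = np.ones(50, dtype=bool)
        runs = assemble_runs(flags, np.zeros(50), pos, HOM, "s", "b", "1")
        assert runs == []


class TestDetectRuns:
    def test_all_heterozygous_individual_no_roh(self):
        ds = make_dataset(np.ones((1, 200), dtype=np.int8),
                          positions=np.arange(200) * 4_000 + 1)
        assert len(detect_runs(ds, HOM)) == 0

    def test_all_homozygous_chromosome_single_run(self):
        pos = np.arange(500) * 4_000 + 1  # ~2 Mb span
        ds = make_dataset(np.zeros((1, 500), dtype=np.int8), positions=pos)
        rs = detect_runs(ds, HOM)
        assert len(rs) == 1
        r = rs.runs[0]
        assert (r.start_bp, r.end_bp, r.n_snps) == (int(pos[0]), int(pos[-1]), 500)

    def test_planted_tract_recovered(self):
        cfg = SimConfig(
            seed=1, n_individuals_per_breed=1, snps_per_chromosome=2000,
            tracts=[TractSpec("BREED1", "1", 800, 1199, 1.0, "HOM")],
        )
        ds, truths = simulate_dataset(cfg)
        rs = detect_runs(ds, HOM)
        t = truths[0]
        hits = [r for r in rs.runs
                if r.chrom == t.chrom
                and r.start_bp <= t.end_bp and r.end_bp >= t.start_bp]
        assert len(hits) == 1
        inter = min(hits[0].end_bp, t.end_bp) - max(hits[0].start_bp, t.start_bp)
        union = max(hits[0].end_bp, t.end_bp) - min(hits[0].start_bp, t.start_bp)
        assert inter / union > 0.95

    def test_runs_contain_only_compatible_genotypes(self):
        """With zero opposite/missing allowed, every SNP inside a HOM run is
        a non-missing homozygote (HET: a heterozygote)."""
        cfg = SimConfig(seed=23, n_individuals_per_breed=8,
                        snps_per_chromosome=800, allele_freq_range=(0.5, 0.95))
        ds, _ = simulate_dataset(cfg)
        for params in (
            RunParams.for_mode("HOM", window_snps=10, min_snps=10,
                               min_length_bp=20_000),
            RunParams.for_mode("HET", window_snps=5, min_snps=5,
                               min_length_bp=5_000),
        ):
            rs = detect_runs(ds, params)
            assert len(rs) > 0
            pos = ds.positions
            sample_row = {s.sample_id: i for i, s in enumerate(ds.samples)}
            for r in rs.runs:
                sl = ds.chrom_slice(r.chrom)
                inside = (pos[sl] >= r.start_bp) & (pos[sl] <= r.end_bp)
                calls = ds.calls[sample_row[r.sample_id], sl][inside]
                if params.mode == "HOM":
                    assert np.isin(calls, (0, 2)).all()
                else:
                    assert (calls == 1).all()

    def test_runs_never_overlap_within_sample(self):
        cfg = SimConfig(seed=31, n_individuals_per_breed=6,
                        snps_per_chromosome=1000, allele_freq_range=(0.6, 0.95))
        ds, _ = simulate_dataset(cfg)
        p = RunParams.for_mode("HOM", window_snps=8, min_snps=8,
                               min_length_bp=10_000)
        rs = detect_runs(ds, p)
        assert len(rs) > 1
        by_key = {}
        for r in rs.runs:
            by_key.setdefault((r.sample_id, r.chrom), []).append(r)
        for runs in by_key.values():
            runs.sort(key=lambda r: r.start_bp)
            for a, b in zip(runs, runs[1:]):
                assert a.end_bp < b.start_bp

    def test_monotonicity_in_min_length_and_min_snps(self):
        cfg = SimConfig(seed=37, n_individuals_per_breed=6,
                        snps_per_chromosome=1000, allele_freq_range=(0.6, 0.95))
        ds, _ = simulate_dataset(cfg)
        base = RunParams.for_mode("HOM", window_snps=8, min_snps=8,
                                  min_length_bp=10_000)
        n0 = len(detect_runs(ds, base))
        assert n0 > 0
        import dataclasses

        for stricter in (
            dataclasses.replace(base, min_length_bp=50_000),
            dataclasses.replace(base, min_snps=20),
        ):
            assert len(detect_runs(ds, stricter)) <= n0

    def test_het_single_window_flags_its_snps(self):
        """w = 15: one passing window gives proportion 1/15 > 0.05."""
        calls = np.ones((1, 15), dtype=np.int8)
        pos = np.arange(15) * 8_000 + 1
        ds = make_dataset(calls, positions=pos)
        rs = detect_runs(ds, HET)
        assert len(rs) == 1 and rs.runs[0].n_snps == 15


class TestOracleEquivalence:
    def test_empty_dataset(self):
        ds = make_dataset(np.empty((0, 0), dtype=np.int8), positions=[])
        assert oracle_detect_runs(ds, HOM).runs == []

    def test_all_homozygous_identical_single_run(self):
        pos = np.arange(500) * 4_000 + 1
        ds = make_dataset(np.zeros((2, 500), dtype=np.int8), positions=pos)
        assert oracle_detect_runs(ds, HOM).runs == detect_runs(ds, HOM).runs

    @pytest.mark.parametrize("seed", range(12))
    def test_randomized_equivalence(self, seed):
        rng = np.random.default_rng(1000 + seed)
        m = int(rng.integers(100, 400))
        cfg = SimConfig(
            seed=int(rng.integers(1, 2**31)), n_individuals_per_breed=5,
            snps_per_chromosome=m, allele_freq_range=(0.2, 0.95),
            missing_rate=float(rng.uniform(0, 0.05)),
        )
        ds, _ = simulate_dataset(cfg)
        for mode in ("HOM", "HET"):
            p = RunParams.for_mode(
                mode,
                window_snps=int(rng.integers(3, 25)),
                min_snps=int(rng.integers(3, 25)),
                min_length_bp=int(rng.integers(5_000, 150_000)),
                max_opposite_in_window=int(rng.integers(0, 3)),
                max_missing_in_window=int(rng.integers(0, 3)),
                max_gap_bp=int(rng.integers(20_000, 2_000_000)),
            )
            assert detect_runs(ds, p).runs == oracle_detect_runs(ds, p).runs
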