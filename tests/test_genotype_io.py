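"""PED/MAP parsing, writing, QC filters, and LD pruning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpruns import (
    MISSING,
    GenotypeDataset,
    LDPruneParams,
    PlinkParseError,
    QCParams,
    apply_qc,
    ld_prune,
    read_plink_text,
    write_plink_text,
)

from conftest import make_dataset


def write_files(tmp_path, ped_text, map_text):
    ped = tmp_path / "t.ped"
    mp = tmp_path / "t.map"
    ped.write_text(ped_text)
    mp.write_text(map_text)
    return ped, mp


MAP3 = "1 s1 0 100\n1 s2 0 200\n1 s3 0 300\n"


class TestReadPlink:
    def test_hand_constructed_allele_dictionary(self, tmp_path):
        """First-seen allele becomes allele-1; codes follow the hand mapping."""
        ped, mp = write_files(
            tmp_path,
            "B1 i1 0 0 0 -9 A A A G G G\nB2 i2 0 0 0 -9 A A G G 0 0\n",
            MAP3,
        )
        ds = read_plink_text(ped, mp)
        assert [s.sample_id for s in ds.samples] == ["i1", "i2"]
        assert [s.breed for s in ds.samples] == ["B1", "B2"]
        assert [s.snp_id for s in ds.snps] == ["s1", "s2", "s3"]
        # SNP1: A only -> both hom allele-1; SNP2: A first -> het / hom-G;
        # SNP3: G first -> hom allele-1 / missing
        expected = np.array([[0, 1, 0], [0, 2, MISSING]], dtype=np.int8)
        np.testing.assert_array_equal(ds.calls, expected)

    def test_snps_sorted_by_chrom_and_bp(self, tmp_path):
        ped, mp = write_files(
            tmp_path,
            "F i1 0 0 0 -9 A A C C G G\n",
            "2 s1 0 100\n1 s2 0 500\n1 s3 0 100\n",
        )
        ds = read_plink_text(ped, mp)
        assert [(s.chrom, s.bp) for s in ds.snps] == [("1", 100), ("1", 500), ("2", 100)]
        # calls follow the SNPs: s3 (G), s2 (C), s1 (A), all hom allele-1
        np.testing.assert_array_equal(ds.calls, [[0, 0, 0]])

    def test_missing_pair_gives_sentinel(self, tmp_path):
        ped, mp = write_files(
            tmp_path, "F i1 0 0 0 -9 0 0 A A A A\n", MAP3
        )
        ds = read_plink_text(ped, mp)
        assert ds.calls[0, 0] == MISSING

    def test_ragged_row_names_line(self, tmp_path):
        ped, mp = write_files(
            tmp_path, "F i1 0 0 0 -9 A A\nF i2 0 0 0 -9 A A A A A A\n", MAP3
        )
        with pytest.raises(PlinkParseError, match=r"t\.ped:1"):
            read_plink_text(ped, mp)

    def test_triallelic_snp_rejected(self, tmp_path):
        ped, mp = write_files(
            tmp_path,
            "F i1 0 0 0 -9 A G A A A A\nF i2 0 0 0 -9 C C A A A A\n",
            MAP3,
        )
        with pytest.raises(PlinkParseError, match="2 alleles"):
            read_plink_text(ped, mp)

    def test_duplicate_snp_id_rejected(self, tmp_path):
        ped, mp = write_files(
            tmp_path,
            "F i1 0 0 0 -9 A A A A\n",
            "1 s1 0 100\n1 s1 0 200\n",
        )
        with pytest.raises(PlinkParseError, match="duplicate snp_id"):
            read_plink_text(ped, mp)


class TestWritePlink:
    def test_code_to_allele_table(self, tmp_path):
        """Codes 0/1/2/MISSING appear as 'A A', 'A B', 'B B', '0 0'."""
        ds = make_dataset([[0, 1, 2, MISSING]])
        write_plink_text(ds, tmp_path / "o.ped", tmp_path / "o.map")
        fields = (tmp_path / "o.ped").read_text().split()
        assert fields[6:] == ["A", "A", "A", "B", "B", "B", "0", "0"]

    def test_empty_dataset(self, tmp_path):
        ds = make_dataset(np.empty((0, 2), dtype=np.int8))
        write_plink_text(ds, tmp_path / "o.ped", tmp_path / "o.map")
        assert (tmp_path / "o.ped").read_text() == ""
        assert len((tmp_path / "o.map").read_text().splitlines()) == 2

    def test_round_trip_identity(self, tmp_path, toy_dataset):
        ds = toy_dataset.canonical_polarity()
        write_plink_text(ds, tmp_path / "o.ped", tmp_path / "o.map")
        back = read_plink_text(tmp_path / "o.ped", tmp_path / "o.map")
        assert back.samples == ds.samples
        assert back.snps == ds.snps
        np.testing.assert_array_equal(back.calls, ds.calls)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    data=st.data(),
    n=st.integers(0, 5),
    m=st.integers(0, 8),
)
def test_round_trip_random_datasets(tmp_path_factory, data, n, m):
    """write then read recovers samples, snps and calls exactly
    (canonical polarity: allele-1 carried by each SNP's first caller)."""
    codes = data.draw(
        st.lists(
            st.lists(st.sampled_from([MISSING, 0, 1, 2]), min_size=m, max_size=m),
            min_size=n,
            max_size=n,
        )
    )
    calls = np.array(codes, dtype=np.int8).reshape(n, m)
    ds = make_dataset(calls).canonical_polarity()
    tmp = tmp_path_factory.mktemp("rt")
    write_plink_text(ds, tmp / "o.ped", tmp / "o.map")
    back = read_plink_text(tmp / "o.ped", tmp / "o.map")
    assert back.samples == ds.samples
    assert back.snps == ds.snps
    np.testing.assert_array_equal(back.calls, ds.calls)


class TestQC:
    def test_monomorphic_snp_removed_by_maf(self):
        ds = make_dataset(
            [[0, 1, 0], [0, 2, 0], [0, 1, 1], [0, 0, 2]]
        )
        out, rep = apply_qc(ds, QCParams())
        assert rep.removed_snp_ids == ["m1"]
        assert rep.removed_by_filter["maf"] == 1
        assert out.n_snps == 2

    def test_low_call_rate_snp_removed_at_step_two(self):
        # SNP 1 missing in 2/4 samples: call rate 0.5 <= 0.95
        ds = make_dataset(
            [[MISSING, 1], [MISSING, 2], [0, 1], [1, 0]]
        )
        out, rep = apply_qc(ds, QCParams())
        assert rep.removed_by_filter["snp_call_rate"] == 1
        assert [s.snp_id for s in out.snps] == ["m2"]

    def test_zero_thresholds_identity(self, toy_dataset):
        p = QCParams(maf_min=0.0, snp_call_rate_min=0.0,
                     ind_call_rate_min=0.0, autosomes_only=False)
        out, rep = apply_qc(toy_dataset, p)
        assert out.n_snps == toy_dataset.n_snps
        assert out.n_samples == toy_dataset.n_samples
        assert sum(rep.removed_by_filter.values()) == 0

    def test_non_autosomal_snps_dropped_first(self):
        ds = make_dataset(
            [[0, 1, 0], [1, 0, 2], [0, 1, 1], [2, 0, 0]],
            chroms=["X", "1", "0"],
            positions=[100, 100, 200],
        )
        out, rep = apply_qc(ds, QCParams(maf_min=0.0, snp_call_rate_min=0.0,
                                         ind_call_rate_min=0.0))
        assert rep.removed_by_filter["non_autosomal"] == 2
        assert [s.chrom for s in out.snps] == ["1"]

    def test_sample_call_rate_filter(self):
        calls = np.zeros((3, 10), dtype=np.int8)
        calls[1, 1] = 1  # keep SNPs polymorphic enough? use maf_min=0
        calls[2, :5] = MISSING  # sample 3 call rate 0.5
        ds = make_dataset(calls)
        out, rep = apply_qc(
            ds, QCParams(maf_min=0.0, snp_call_rate_min=0.0)
        )
        assert rep.removed_sample_ids == ["s3"]
        assert out.n_samples == 2

    def test_idempotent(self, toy_dataset):
        p = QCParams()
        once, _ = apply_qc(toy_dataset, p)
        twice, rep2 = apply_qc(once, p)
        assert twice.n_snps == once.n_snps
        assert twice.n_samples == once.n_samples
        assert sum(rep2.removed_by_filter.values()) == 0

    def test_default_postconditions_hold(self):
        rng = np.random.default_rng(11)
        calls = rng.integers(-1, 3, size=(30, 60)).astype(np.int8)
        ds = make_dataset(calls)
        out, _ = apply_qc(ds, QCParams())
        from snpruns.genotype_io import minor_allele_frequencies

        nonmiss = out.calls != MISSING
        assert (nonmiss.mean(axis=0) > 0.95).all()
        assert (minor_allele_frequencies(out.calls) >= 0.01).all()

    def test_all_samples_removed_is_error(self):
        calls = np.zeros((2, 4), dtype=np.int8)
        calls[0, :2] = MISSING
        calls[1, 2:] = MISSING  # every sample has call rate 0.5
        ds = make_dataset(calls)
        with pytest.raises(ValueError, match="empty dataset"):
            apply_qc(ds, QCParams(snp_call_rate_min=0.0))


class TestLDPrune:
    def test_correlated_pair_drops_lower_maf(self):
        # x and y = x + 1 are perfectly correlated; MAF(x)=1/6 < MAF(y)=1/3
        x = [0, 0, 0, 0, 1, 1]
        y = [1, 1, 1, 1, 2, 2]
        ds = make_dataset(np.array([x, y]).T, positions=[1_000, 11_000])
        kept = ld_prune(ds, LDPruneParams())
        assert kept == ["m2"]

    def test_uncorrelated_pair_kept(self):
        x = [0, 2, 0, 2]
        y = [0, 0, 2, 2]  # orthogonal after centering
        ds = make_dataset(np.array([x, y]).T, positions=[1_000, 11_000])
        assert ld_prune(ds, LDPruneParams()) == ["m1", "m2"]

    def test_window_semantics_far_pair_kept(self):
        x = [0, 0, 1, 1, 2, 2]
        ds = make_dataset(np.array([x, x]).T, positions=[1_000, 201_000])
        assert ld_prune(ds, LDPruneParams()) == ["m1", "m2"]

    def test_r2_max_one_keeps_everything(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 3, size=(20, 30)).astype(np.int8)
        ds = make_dataset(calls, positions=[1_000 * (j + 1) for j in range(30)])
        kept = ld_prune(ds, LDPruneParams(r2_max=1.0))
        assert kept == [s.snp_id for s in ds.snps]

    def test_output_is_subset_in_map_order(self):
        rng = np.random.default_rng(9)
        calls = rng.integers(0, 3, size=(15, 40)).astype(np.int8)
        calls[:, 1] = calls[:, 0]  # force one redundant pair
        ds = make_dataset(calls, positions=[2_000 * (j + 1) for j in range(40)])
        kept = ld_prune(ds, LDPruneParams())
        ids = [s.snp_id for s in ds.snps]
        assert kept == [i for i in ids if i in set(kept)]
        assert set(kept) <= set(ids)
        assert len(kept) < len(ids)
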