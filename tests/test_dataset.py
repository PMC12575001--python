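"""Dataset construction: splitting, labeling, segmentation, HDF5, paralogs."""

import numpy as np
import pytest

from spliceworks.dataset import (
    EncodedDataset,
    LabeledGene,
    SplitSpec,
    filter_pseudogenes,
    label_splice_sites,
    read_dataset,
    remove_paralogs,
    segment,
    split_chromosomes,
    write_dataset,
)
from spliceworks.genomics_io import GeneModel, Transcript


def _labeled(gene_id: str, seq: str) -> LabeledGene:
    return LabeledGene(
        gene_id, seq, np.zeros(len(seq), dtype=np.int8),
        np.array([], dtype=np.int64), np.array([], dtype=np.int64),
    )


class TestSplitChromosomes:
    def test_human_split(self):
        chroms = [(f"chr{c}", 1000) for c in list(range(1, 23)) + ["X", "Y"]]
        train, test = split_chromosomes(chroms, SplitSpec(method="human"))
        assert set(test) == {"chr1", "chr3", "chr5", "chr7", "chr9"}
        assert len(train) == 19

    def test_human_split_accepts_bare_names(self):
        train, test = split_chromosomes(
            [("1", 10), ("2", 10)], SplitSpec(method="human")
        )
        assert test == ["1"] and train == ["2"]

    def test_human_split_rejects_unknown(self):
        with pytest.raises(ValueError, match="scaffold_7"):
            split_chromosomes(
                [("scaffold_7", 10)], SplitSpec(method="human")
            )

    def test_equal_lengths_half_fraction(self):
        train, test = split_chromosomes(
            [("a", 100), ("b", 100)],
            SplitSpec(method="random", train_fraction=0.5, seed=0),
        )
        assert len(train) == 1 and len(test) == 1

    def test_single_chromosome_warns_empty_test(self):
        with pytest.warns(UserWarning, match="empty test set"):
            train, test = split_chromosomes(
                [("a", 100)], SplitSpec(method="random", train_fraction=0.8)
            )
        assert train == ["a"] and test == []

    def test_seed_reproducible_disjoint_exhaustive(self):
        chroms = [(f"c{i}", 50 + 10 * i) for i in range(12)]
        spec = SplitSpec(method="random", seed=42)
        a = split_chromosomes(chroms, spec)
        b = split_chromosomes(chroms, spec)
        assert a == b
        train, test = a
        assert set(train) & set(test) == set()
        assert set(train) | set(test) == {n for n, _ in chroms}


class TestFilterPseudogenes:
    def test_biotypes_removed(self):
        def gene(bt):
            return GeneModel("g_" + bt, "c", 1, 10, "+", bt, [])

        genes = [gene("processed_pseudogene"), gene("protein_coding"),
                 gene("pseudogene"), gene("transcribed_pseudogene")]
        kept = filter_pseudogenes(genes)
        assert [g.biotype for g in kept] == ["protein_coding"]

    def test_empty(self):
        assert filter_pseudogenes([]) == []


class TestLabelSpliceSites:
    def _three_exon_seq(self):
        # exons [0,10), [20,30), [40,50); introns GT..AG
        e1, e2, e3 = "CCCCCCCCAG", "GCCCCCCCAG", "GCCCCCCCCC"
        i1 = "GTAAGTTTAG"
        i2 = "GTAAGTTTAG"
        return e1 + i1 + e2 + i2 + e3

    def test_three_exon_counts(self):
        tx = Transcript("t", [(1, 10), (21, 30), (41, 50)], "+")
        lg = label_splice_sites(tx, self._three_exon_seq(), gene_start=1)
        assert list(lg.donor_positions) == [9, 29]
        assert list(lg.acceptor_positions) == [20, 40]
        assert (lg.labels == 2).sum() == 2 and (lg.labels == 1).sum() == 2

    def test_canonical_only_drops_noncanonical(self):
        seq = self._three_exon_seq()
        # break the first intron's donor dinucleotide: GT -> CT
        seq = seq[:10] + "CT" + seq[12:]
        tx = Transcript("t", [(1, 10), (21, 30), (41, 50)], "+")
        lg = label_splice_sites(tx, seq, canonical_only=True, gene_start=1)
        assert list(lg.donor_positions) == [29]
        assert list(lg.acceptor_positions) == [40]
        # without the filter both introns contribute
        lg_all = label_splice_sites(tx, seq, canonical_only=False, gene_start=1)
        assert len(lg_all.donor_positions) == 2

    def test_gc_ag_and_at_ac_are_canonical(self):
        seq = self._three_exon_seq()
        seq = seq[:10] + "GC" + seq[12:30] + "AT" + seq[32:38] + "AC" + seq[40:]
        tx = Transcript("t", [(1, 10), (21, 30), (41, 50)], "+")
        lg = label_splice_sites(tx, seq, canonical_only=True, gene_start=1)
        assert len(lg.donor_positions) == 2

    def test_single_exon_all_none(self):
        tx = Transcript("t", [(1, 30)], "+")
        lg = label_splice_sites(tx, "A" * 30, gene_start=1)
        assert not lg.labels.any()

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            Transcript("t", [(1, 10), (5, 20)], "+")


class TestSegment:
    def test_worked_example_22kb(self):
        lg = _labeled("g", "A" * 22_000)
        X, Y = segment(lg)
        assert X.shape == (5, 15_000, 4)
        assert Y.shape == (5, 5_000, 3)
        # final core holds 2000 real bases, the rest padding
        assert (Y[4, :2000].sum(axis=1) == 1).all()
        assert (Y[4, 2000:].sum(axis=1) == 0).all()

    @pytest.mark.parametrize("L,n_expected,last_real", [
        (5000, 1, 5000), (5001, 2, 1), (22000, 5, 2000), (1, 1, 1),
    ])
    def test_segment_counts(self, L, n_expected, last_real):
        X, Y = segment(_labeled("g", "C" * L))
        assert X.shape[0] == n_expected
        assert int(Y[-1].sum()) == last_real  # one-hot rows sum to 1

    def test_real_rows_total_equals_length(self):
        for L in (1, 4999, 5000, 12345):
            _, Y = segment(_labeled("g", "G" * L))
            assert int(Y.sum()) == L

    def test_empty_gene_rejected(self):
        with pytest.raises(ValueError):
            segment(_labeled("g", ""))

    def test_label_channels(self):
        seq = "A" * 100
        labels = np.zeros(100, dtype=np.int8)
        labels[10] = 1  # acceptor
        labels[20] = 2  # donor
        lg = LabeledGene("g", seq, labels, np.array([20]), np.array([10]))
        _, Y = segment(lg)
        assert Y[0, 10].tolist() == [0, 1, 0]
        assert Y[0, 20].tolist() == [0, 0, 1]
        assert Y[0, 5].tolist() == [1, 0, 0]


class TestHDF5RoundTrip:
    def _dataset(self, n_genes, rng):
        genes = []
        for i in range(n_genes):
            L = int(rng.integers(100, 7000))
            seq = "".join(rng.choice(list("ACGT"), size=L))
            genes.append(_labeled(f"g{i}", seq))
        return EncodedDataset.from_genes(genes)

    def test_bit_identical_roundtrip(self, tmp_path, rng):
        ds = self._dataset(7, rng)
        path = tmp_path / "ds.h5"
        write_dataset(ds, path, batch_size=3)
        back = read_dataset(path)
        assert back.gene_ids == ds.gene_ids
        for a, b in zip(ds.X, back.X):
            assert np.array_equal(a, b)
        for a, b in zip(ds.Y, back.Y):
            assert np.array_equal(a, b)

    def test_batching_group_count(self, tmp_path, rng):
        import h5py

        ds = self._dataset(11, rng)
        path = tmp_path / "ds.h5"
        write_dataset(ds, path, batch_size=4)
        with h5py.File(path) as f:
            assert f.attrs["n_batches"] == 3  # ceil(11/4)

    def test_empty_dataset(self, tmp_path):
        path = tmp_path / "empty.h5"
        write_dataset(EncodedDataset(), path)
        assert len(read_dataset(path)) == 0


@pytest.fixture(scope="module")
def gene_pool():
    rng = np.random.default_rng(5)
    train = [
        _labeled(f"train{i}", "".join(rng.choice(list("ACGT"), size=3000)))
        for i in range(3)
    ]
    # exact copy, a diverged copy (~10% mutated), and an unrelated gene
    copy = _labeled("copy", train[0].sequence)
    seq = list(train[1].sequence)
    idx = rng.choice(len(seq), size=len(seq) // 10, replace=False)
    for i in idx:
        seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
    diverged = _labeled("diverged", "".join(seq))
    unrelated = _labeled(
        "unrelated", "".join(rng.choice(list("ACGT"), size=3000))
    )
    return train, [copy, diverged, unrelated]


class TestRemoveParalogs:

    @pytest.mark.parametrize("backend", ["minimap2", "kmer"])
    def test_identical_gene_removed_unrelated_kept(self, gene_pool, backend):
        train, test = gene_pool
        kept, report = remove_paralogs(test, train, backend=backend)
        kept_ids = {g.gene_id for g in kept}
        assert "copy" not in kept_ids
        assert "unrelated" in kept_ids
        assert "copy" in set(report["test_id"])

    def test_diverged_copy_removed_by_aligner(self, gene_pool):
        train, test = gene_pool
        kept, report = remove_paralogs(test, train, backend="minimap2")
        assert "diverged" not in {g.gene_id for g in kept}
        row = report[report.test_id == "diverged"].iloc[0]
        assert row.identity > 0.8 and row.coverage > 0.8

    def test_both_thresholds_required(self, gene_pool):
        train, test = gene_pool
        # impossible coverage bar: even the exact copy survives
        kept, _ = remove_paralogs(
            test, train, min_coverage=1.0, backend="minimap2"
        )
        assert {g.gene_id for g in kept} == {"copy", "diverged", "unrelated"}

    def test_monotone_in_thresholds(self, gene_pool):
        train, test = gene_pool
        removed = {}
        for thr in (0.5, 0.8, 0.95):
            kept, _ = remove_paralogs(
                test, train, min_identity=thr, min_coverage=thr,
                backend="minimap2",
            )
            removed[thr] = len(test) - len(kept)
        assert removed[0.5] >= removed[0.8] >= removed[0.95]

    def test_no_alignments_keeps_all(self):
        train = [_labeled("t", "AT" * 600)]
        test = [_labeled("q", "GC" * 600)]
        kept, report = remove_paralogs(test, train, backend="kmer")
        assert len(kept) == 1 and report.empty

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            remove_paralogs([_labeled("q", "")], [_labeled("t", "ACGT")])
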