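"""Coverage engine: CIGAR-aware depth at percentile positions, barcode routing."""

import numpy as np
import pysam
import pytest

from covskew.coverage import (
    AlignmentFilters,
    BarcodeManifest,
    compute_cell_coverage,
    coverage_matrix,
    normalize_coverage,
    split_by_barcode,
)
from covskew.gene_model import TranscriptModel, GeneModelSet


def make_header(chroms=("chr1",), length=5000):
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": c, "LN": length} for c in chroms]}
    )


def make_read(header, chrom, start, cigar, name="r", mapq=60, barcode=None, **flags):
    read = pysam.AlignedSegment(header)
    read.query_name = name
    read.reference_id = header.get_tid(chrom)
    read.reference_start = start
    read.mapping_quality = mapq
    read.cigartuples = cigar
    qlen = sum(n for op, n in cigar if op in (0, 1, 4, 7, 8))
    read.query_sequence = "A" * qlen
    for flag, value in flags.items():
        setattr(read, flag, value)
    if barcode is not None:
        read.set_tag("CB", barcode)
    return read


@pytest.fixture()
def single_gene():
    m = TranscriptModel("tx", "chr1", "+", 1000, 1100, ((1000, 100),))
    return GeneModelSet([m])


class TestComputeCellCoverage:
    def test_uniform_depth_normalizes_to_one(self, single_gene):
        header = make_header()
        # 5 full-length reads covering the whole transcript
        reads = [make_read(header, "chr1", 1000, [(0, 100)], name=f"r{i}") for i in range(5)]
        vec = compute_cell_coverage(reads, single_gene, cell_id="c")
        assert np.array_equal(vec.raw_counts, np.full(100, 5))
        assert np.array_equal(vec.values, np.ones(100))
        assert vec.total_assigned == 5

    def test_empty_input_gives_zero_vector(self, single_gene):
        vec = compute_cell_coverage([], single_gene, cell_id="empty")
        assert vec.total_assigned == 0
        assert not np.isnan(vec.values).any()
        assert np.array_equal(vec.values, np.zeros(100))
        assert vec.is_zero

    def test_three_prime_only_coverage(self):
        # every read covers only the last 20 nt of a 200 nt transcript
        model = TranscriptModel("tx", "chr1", "+", 0, 200, ((0, 200),))
        gms = GeneModelSet([model])
        header = make_header()
        reads = [make_read(header, "chr1", 180, [(0, 20)], name=f"r{i}") for i in range(3)]
        vec = compute_cell_coverage(reads, gms, cell_id="c")
        # brute-force pileup oracle
        depth = np.zeros(5000, dtype=int)
        depth[180:200] += 3
        expected_raw = depth[model.percentile_positions]
        assert np.array_equal(vec.raw_counts, expected_raw)
        assert (vec.values[:90] == 0).all() and vec.values.max() == 1.0

    def test_n_gap_does_not_cover(self, single_gene):
        header = make_header()
        # 10M 80N 10M: covers [1000,1010) and [1090,1100) only
        reads = [make_read(header, "chr1", 1000, [(0, 10), (3, 80), (0, 10)])]
        vec = compute_cell_coverage(reads, single_gene, cell_id="c")
        assert vec.raw_counts[:10].sum() == 10 and vec.raw_counts[90:].sum() == 10
        assert vec.raw_counts[10:90].sum() == 0

    def test_deletion_does_not_cover(self, single_gene):
        header = make_header()
        reads = [make_read(header, "chr1", 1000, [(0, 40), (2, 20), (0, 40)])]
        vec = compute_cell_coverage(reads, single_gene, cell_id="c")
        assert vec.raw_counts[40:60].sum() == 0
        assert vec.raw_counts[:40].sum() == 40 and vec.raw_counts[60:].sum() == 40

    def test_alignment_filters(self, single_gene):
        header = make_header()
        reads = [
            make_read(header, "chr1", 1000, [(0, 100)], name="ok"),
            make_read(header, "chr1", 1000, [(0, 100)], name="dup", is_duplicate=True),
            make_read(header, "chr1", 1000, [(0, 100)], name="sec", is_secondary=True),
            make_read(header, "chr1", 1000, [(0, 100)], name="qf", is_qcfail=True),
            make_read(header, "chr1", 1000, [(0, 100)], name="lowq", mapq=5),
        ]
        vec = compute_cell_coverage(reads, single_gene,
                                    AlignmentFilters(min_mapq=10), cell_id="c")
        assert vec.total_assigned == 1

    def test_missing_chromosome_contributes_zeros(self, single_gene):
        header = make_header(chroms=("chr1", "chrUn"))
        reads = [make_read(header, "chrUn", 1000, [(0, 100)])]
        vec = compute_cell_coverage(reads, single_gene, cell_id="c")
        assert vec.is_zero

    def test_matches_pileup_oracle_on_toy_bams(self, toy_dataset, gene_models):
        for cell_id, path in toy_dataset.bam_paths.items():
            vec = compute_cell_coverage(path, gene_models, cell_id=cell_id)
            truth = toy_dataset.truth_raw_counts[cell_id]
            assert np.array_equal(vec.raw_counts, truth), cell_id
            assert vec.values.max() == 1.0
            assert ((0 <= vec.values) & (vec.values <= 1)).all()


def test_normalization_idempotent(rng):
    v = rng.random(100)
    once = normalize_coverage(v)
    assert np.array_equal(normalize_coverage(once), once)
    assert np.array_equal(normalize_coverage(np.zeros(100)), np.zeros(100))


class TestSplitByBarcode:
    def test_suffix_strip(self):
        header = make_header()
        reads = [make_read(header, "chr1", 10, [(0, 50)], name=f"r{i}", barcode="AAAC-1")
                 for i in range(10)]
        streams, discarded = split_by_barcode(reads, BarcodeManifest(["AAAC"]))
        assert len(streams["AAAC"]) == 10 and discarded == 0

    def test_untagged_and_unlisted_are_counted(self):
        header = make_header()
        reads = [
            make_read(header, "chr1", 10, [(0, 50)], name="tagged", barcode="AAAC"),
            make_read(header, "chr1", 10, [(0, 50)], name="untagged"),
            make_read(header, "chr1", 10, [(0, 50)], name="other", barcode="GGGT"),
        ]
        streams, discarded = split_by_barcode(reads, BarcodeManifest(["AAAC"]))
        assert len(streams["AAAC"]) == 1 and discarded == 2

    def test_zero_routed_is_hard_error(self):
        header = make_header()
        reads = [make_read(header, "chr1", 10, [(0, 50)])]
        with pytest.raises(ValueError, match="no records routed"):
            split_by_barcode(reads, BarcodeManifest(["AAAC"]))

    def test_interleaved_matches_per_barcode_scan(self):
        header = make_header()
        barcodes = ["AAA", "CCC", "GGG"]
        reads = []
        for i in range(4):
            for bc in barcodes:
                reads.append(make_read(header, "chr1", 10 * i, [(0, 50)],
                                       name=f"{bc}_{i}", barcode=bc))
        streams, _ = split_by_barcode(reads, BarcodeManifest(barcodes, suffix_policy="keep"))
        for bc in barcodes:
            # naive one-pass-per-barcode scan
            naive = [r.query_name for r in reads if r.get_tag("CB") == bc]
            assert [r.query_name for r in streams[bc]] == naive
            assert len(streams[bc]) == 4

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            BarcodeManifest(["AAAC-1", "AAAC"])


class TestCoverageMatrix:
    def test_row_order_and_shape(self, toy_dataset, gene_models):
        inputs = [(c, str(p)) for c, p in sorted(toy_dataset.bam_paths.items())]
        mat = coverage_matrix(inputs, gene_models)
        assert mat.values.shape == (3, 100)
        assert mat.cell_ids == [c for c, _ in inputs]

    def test_worker_count_does_not_change_result(self, toy_dataset, gene_models):
        inputs = [(c, str(p)) for c, p in sorted(toy_dataset.bam_paths.items())]
        m1 = coverage_matrix(inputs, gene_models, workers=1)
        m2 = coverage_matrix(inputs, gene_models, workers=3)
        assert m1.cell_ids == m2.cell_ids
        assert np.array_equal(m1.values, m2.values)

    def test_duplicate_cell_ids_rejected(self, toy_dataset, gene_models):
        path = next(iter(toy_dataset.bam_paths.values()))
        with pytest.raises(ValueError, match="duplicate cell ids"):
            coverage_matrix([("c", str(path)), ("c", str(path))], gene_models)

    def test_zero_coverage_cell_flagged(self, gene_models):
        mat = coverage_matrix([("empty", [])], gene_models)
        assert mat.zero_flags.tolist() == [True]
        assert not np.isnan(mat.values).any()
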