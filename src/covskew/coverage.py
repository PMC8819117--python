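"""Per-cell gene-body coverage from aligned reads.

For every transcript in the gene model, depth is counted at its 100
percentile coordinates: an alignment contributes to a coordinate when one of
its reference-consuming segments (CIGAR M/=/X; N and D gaps do not cover)
spans it.  Counts are summed over all transcripts and the 100-vector is
normalized by its maximum, so 1 means full coverage at that relative gene-body
position and 0 means none — the profile characteristic of the library
chemistry (5'-tag, 3'-tag or full-length).

The engine supports per-cell BAM files and 10x-style barcoded BAMs (one
position-sorted file whose records carry the cell barcode in a tag, CB by
default), which are demultiplexed by streaming accumulation without writing
intermediate per-cell files.
"""

from __future__ import annotations

import gzip
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam

from .gene_model import GeneModelSet, N_PERCENTILES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentFilters:
    """Which alignments count toward coverage.

    Defaults follow common gene-body-coverage practice: primary alignments
    only, no QC-fail or duplicate-flagged records, any MAPQ.  UMI
    deduplication is off by default and, when enabled, keeps the first record
    seen per (UMI tag, position) pair.
    """

    primary_only: bool = True
    exclude_qcfail: bool = True
    exclude_duplicates: bool = True
    min_mapq: int = 0
    dedup_umi: bool = False
    umi_tag: str = "UB"

    def passes(self, read: pysam.AlignedSegment) -> bool:
        if read.is_unmapped:
            return False
        if self.primary_only and (read.is_secondary or read.is_supplementary):
            return False
        if self.exclude_qcfail and read.is_qcfail:
            return False
        if self.exclude_duplicates and read.is_duplicate:
            return False
        if read.mapping_quality < self.min_mapq:
            return False
        return True


@dataclass
class BarcodeManifest:
    """Cell barcodes expected in a barcoded BAM.

    ``suffix_policy`` controls the trailing ``-1`` 10x suffix: "strip"
    removes it from both the manifest and BAM tag values before matching,
    "keep" matches verbatim.
    """

    barcodes: list[str]
    tag_name: str = "CB"
    suffix_policy: str = "strip"

    def __post_init__(self) -> None:
        if self.suffix_policy not in ("keep", "strip"):
            raise ValueError(f"suffix_policy must be keep|strip, got {self.suffix_policy!r}")
        self.barcodes = [self.normalize(b) for b in self.barcodes]
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes are not unique after applying suffix policy")

    def normalize(self, barcode: str) -> str:
        if self.suffix_policy == "strip" and barcode.endswith("-1"):
            return barcode[:-2]
        return barcode

    @classmethod
    def from_file(cls, path: str | Path, tag_name: str = "CB", suffix_policy: str = "strip") -> "BarcodeManifest":
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            barcodes = [line.strip() for line in fh if line.strip()]
        if not barcodes:
            raise ValueError(f"empty barcode list: {path}")
        return cls(barcodes=barcodes, tag_name=tag_name, suffix_policy=suffix_policy)


@dataclass
class CoverageVector:
    """One cell's gene-body coverage: raw depth counts and max-normalized values."""

    cell_id: str
    values: np.ndarray
    raw_counts: np.ndarray
    total_assigned: int

    @property
    def is_zero(self) -> bool:
        return self.total_assigned == 0 or int(self.raw_counts.max()) == 0

    @classmethod
    def from_raw(cls, cell_id: str, raw_counts: np.ndarray, total_assigned: int) -> "CoverageVector":
        raw = np.asarray(raw_counts, dtype=np.int64)
        if raw.shape != (N_PERCENTILES,):
            raise ValueError(f"raw_counts must have shape (100,), got {raw.shape}")
        peak = raw.max()
        values = raw / peak if peak > 0 else np.zeros(N_PERCENTILES)
        return cls(cell_id=cell_id, values=values, raw_counts=raw, total_assigned=total_assigned)


def normalize_coverage(values: np.ndarray) -> np.ndarray:
    """Scale a coverage vector so its maximum is 1 (idempotent; zeros stay zeros)."""
    values = np.asarray(values, dtype=float)
    peak = values.max()
    return values / peak if peak > 0 else np.zeros_like(values)


class PercentileIndex:
    """Sorted per-chromosome lookup of every transcript percentile coordinate.

    Duplicate coordinates are kept (several transcripts, or several
    percentiles of one transcript, may land on the same base); each carries
    the percentile bin it feeds, so one pass over a read's reference blocks
    increments every affected bin.
    """

    def __init__(self, gene_models: GeneModelSet):
        if len(gene_models) == 0:
            raise ValueError("gene model set is empty")
        per_chrom: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
        for model in gene_models:
            pos = model.percentile_positions
            bins = np.arange(N_PERCENTILES, dtype=np.int64)
            per_chrom.setdefault(model.chrom, []).append((pos, bins))
        self.positions: dict[str, np.ndarray] = {}
        self.bins: dict[str, np.ndarray] = {}
        for chrom, pairs in per_chrom.items():
            pos = np.concatenate([p for p, _ in pairs])
            bins = np.concatenate([b for _, b in pairs])
            order = np.argsort(pos, kind="stable")
            self.positions[chrom] = pos[order]
            self.bins[chrom] = bins[order]

    def add_read(self, read: pysam.AlignedSegment, chrom: str, raw_counts: np.ndarray) -> bool:
        """Add one alignment's reference-covered bases; True if any bin was hit."""
        pos = self.positions.get(chrom)
        if pos is None:
            return False
        bins = self.bins[chrom]
        hit = False
        for start, end in read.get_blocks():  # M/=/X segments; N and D split
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            if hi > lo:
                np.add.at(raw_counts, bins[lo:hi], 1)
                hit = True
        return hit


def _iter_bam(path: str | Path) -> Iterator[pysam.AlignedSegment]:
    with pysam.AlignmentFile(str(path), "rb", check_sq=False) as bam:
        yield from bam


def compute_cell_coverage(
    alignment_stream: Iterable[pysam.AlignedSegment] | str | Path,
    gene_models: GeneModelSet | PercentileIndex,
    filters: AlignmentFilters | None = None,
    cell_id: str = "",
) -> CoverageVector:
    """Compute one cell's 100-position coverage vector.

    ``alignment_stream`` is a BAM path or any iterable of aligned segments.
    A cell with no passing aligned reads yields the documented all-zero
    vector (never NaN) and ``total_assigned == 0``.
    """
    filters = filters or AlignmentFilters()
    index = gene_models if isinstance(gene_models, PercentileIndex) else PercentileIndex(gene_models)
    if isinstance(alignment_stream, (str, Path)):
        if not cell_id:
            cell_id = Path(alignment_stream).name.removesuffix(".bam")
        stream: Iterable[pysam.AlignedSegment] = _iter_bam(alignment_stream)
    else:
        stream = alignment_stream

    raw = np.zeros(N_PERCENTILES, dtype=np.int64)
    total_assigned = 0
    n_mapped = 0
    seen_umis: set[tuple[str, int]] = set()
    missing_chroms: set[str] = set()
    for read in stream:
        if not filters.passes(read):
            continue
        chrom = read.reference_name
        if chrom not in index.positions:
            if chrom not in missing_chroms:
                missing_chroms.add(chrom)
            continue
        if filters.dedup_umi:
            try:
                umi = read.get_tag(filters.umi_tag)
            except KeyError:
                umi = None
            if umi is not None:
                key = (str(umi), read.reference_start)
                if key in seen_umis:
                    continue
                seen_umis.add(key)
        n_mapped += 1
        if index.add_read(read, chrom, raw):
            total_assigned += 1
    if n_mapped == 0:
        logger.warning("cell %s: no passing mapped alignments; coverage is all-zero", cell_id)
    if missing_chroms:
        logger.info(
            "cell %s: %d reference name(s) absent from gene model, e.g. %s",
            cell_id, len(missing_chroms), sorted(missing_chroms)[:3],
        )
    return CoverageVector.from_raw(cell_id, raw, total_assigned)


def split_by_barcode(
    barcoded_bam: str | Path | Iterable[pysam.AlignedSegment],
    manifest: BarcodeManifest,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, list], int]:
    """Route records of a barcoded BAM to per-barcode streams.

    Returns ``(streams, discarded)`` where ``streams`` maps each manifest
    barcode to its records in input order and ``discarded`` counts records
    whose tag is absent or not listed.  When ``out_dir`` is given, per-barcode
    BAM files ``<barcode>.bam`` are also materialized (workflow parity with
    pipelines that split to disk).  Raises if zero records are routed, which
    usually means a wrong ``tag_name`` or suffix policy.
    """
    wanted = set(manifest.barcodes)
    streams: dict[str, list] = {bc: [] for bc in manifest.barcodes}
    discarded = 0
    header = None
    if isinstance(barcoded_bam, (str, Path)):
        bam = pysam.AlignmentFile(str(barcoded_bam), "rb", check_sq=False)
        header = bam.header
        records: Iterable[pysam.AlignedSegment] = bam
    else:
        records = barcoded_bam
    routed = 0
    for read in records:
        try:
            tag = read.get_tag(manifest.tag_name)
        except KeyError:
            discarded += 1
            continue
        bc = manifest.normalize(str(tag))
        if bc in wanted:
            streams[bc].append(read)
            routed += 1
        else:
            discarded += 1
    if routed == 0:
        raise ValueError(
            f"no records routed to any of {len(wanted)} barcodes; "
            f"check tag_name={manifest.tag_name!r} and suffix_policy={manifest.suffix_policy!r}"
        )
    if out_dir is not None and header is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for bc, reads in streams.items():
            with pysam.AlignmentFile(str(out_dir / f"{bc}.bam"), "wb", header=header) as out:
                for r in reads:
                    out.write(r)
    if isinstance(barcoded_bam, (str, Path)):
        bam.close()
    return streams, discarded


def _coverage_worker(args) -> tuple[str, np.ndarray, int]:
    cell_id, bam_path, bed_models, filters = args
    index = PercentileIndex(bed_models)
    vec = compute_cell_coverage(bam_path, index, filters, cell_id=cell_id)
    return cell_id, vec.raw_counts, vec.total_assigned


def coverage_matrix(
    per_cell_inputs: Sequence[tuple[str, object]],
    gene_models: GeneModelSet,
    filters: AlignmentFilters | None = None,
    workers: int = 1,
):
    """Coverage vectors for many cells, assembled into a CoverageMatrix.

    ``per_cell_inputs`` is an ordered list of ``(cell_id, source)`` where
    source is a BAM path or an iterable of alignments.  Row order follows
    input order and results are merged by cell id, so the matrix is identical
    for any worker count.  Duplicate cell ids are a hard error.
    """
    from .matrix import CoverageMatrix  # local import to avoid cycle

    if len(per_cell_inputs) == 0:
        raise ValueError("need at least one cell input")
    ids = [cid for cid, _ in per_cell_inputs]
    if len(set(ids)) != len(ids):
        dupes = sorted({c for c in ids if ids.count(c) > 1})
        raise ValueError(f"duplicate cell ids: {dupes}")
    filters = filters or AlignmentFilters()

    results: dict[str, CoverageVector] = {}
    path_jobs = [(cid, src) for cid, src in per_cell_inputs if isinstance(src, (str, Path))]
    if workers > 1 and len(path_jobs) == len(per_cell_inputs):
        with ProcessPoolExecutor(max_workers=workers) as pool:
            for cell_id, raw, total in pool.map(
                _coverage_worker,
                [(cid, str(src), gene_models, filters) for cid, src in per_cell_inputs],
            ):
                results[cell_id] = CoverageVector.from_raw(cell_id, raw, total)
    else:
        index = PercentileIndex(gene_models)
        for cell_id, src in per_cell_inputs:
            results[cell_id] = compute_cell_coverage(src, index, filters, cell_id=cell_id)

    vectors = [results[cid] for cid in ids]
    values = np.vstack([v.values for v in vectors])
    zero_flags = np.array([v.is_zero for v in vectors])
    return CoverageMatrix(cell_ids=list(ids), values=values, zero_flags=zero_flags)
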