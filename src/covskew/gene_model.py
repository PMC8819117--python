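"""BED12 gene models and gene-body percentile coordinates.

A transcript's "gene body" is its spliced sequence walked 5' to 3'.  For
coverage profiling we sample exactly 100 positions along that walk — the
percentile positions — and later count aligned-read depth at each.  All
coordinates are 0-based half-open (the BED convention) throughout; conversion
happens only at I/O boundaries (there is none to do for BED itself).
"""

from __future__ import annotations

import fnmatch
import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

N_PERCENTILES = 100

#: transcript name patterns excluded by default (ribosomal and transfer RNA,
#: including mitochondrial variants, matching Gencode naming).
DEFAULT_EXCLUDE_PATTERNS = ("rRNA", "tRNA", "Mt_rRNA", "Mt_tRNA")


class BedParseError(ValueError):
    """Raised for a malformed BED12 record; the message names the line."""


@dataclass(frozen=True)
class TranscriptModel:
    """One BED12 record with its gene-body percentile mapping.

    ``blocks`` are (genomic start, length) exon blocks, ascending and
    non-overlapping.  ``percentile_positions`` holds 100 genomic coordinates:
    index 0 is the 5'-most percentile of the spliced transcript, index 99 the
    3'-most; for minus-strand transcripts index 0 therefore lies at the
    highest-coordinate end.
    """

    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    blocks: tuple[tuple[int, int], ...]
    # BED fields preserved for bit-identical round-trip of retained records
    score: str = "0"
    thick_start: int | None = None
    thick_end: int | None = None
    item_rgb: str = "0"
    extra_fields: tuple[str, ...] = ()

    @property
    def spliced_length(self) -> int:
        return sum(length for _, length in self.blocks)

    @property
    def percentile_positions(self) -> np.ndarray:
        return percentile_positions(self)

    def spliced_coordinates(self) -> np.ndarray:
        """All genomic coordinates of the spliced transcript, 5' -> 3'."""
        coords = np.concatenate(
            [np.arange(start, start + length) for start, length in self.blocks]
        )
        if self.strand == "-":
            coords = coords[::-1]
        return coords

    def to_bed12(self) -> str:
        starts = ",".join(str(s - self.tx_start) for s, _ in self.blocks) + ","
        sizes = ",".join(str(l) for _, l in self.blocks) + ","
        fields = [
            self.chrom,
            str(self.tx_start),
            str(self.tx_end),
            self.transcript_id,
            self.score,
            self.strand,
            str(self.thick_start if self.thick_start is not None else self.tx_start),
            str(self.thick_end if self.thick_end is not None else self.tx_end),
            self.item_rgb,
            str(len(self.blocks)),
            sizes,
            starts,
        ]
        fields.extend(self.extra_fields)
        return "\t".join(fields)


@dataclass
class GeneModelSet:
    """Transcripts retained after filtering, plus bookkeeping."""

    transcripts: list[TranscriptModel]
    excluded_count: int = 0
    source_path: str = ""

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)


def _int_field(value: str, name: str, line_number: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise BedParseError(
            f"line {line_number}: non-numeric {name} field {value!r}"
        ) from None


def _split_csv_ints(value: str, name: str, line_number: int) -> list[int]:
    items = [v for v in value.strip().split(",") if v != ""]
    return [_int_field(v, name, line_number) for v in items]


def parse_bed12(line: str, line_number: int = 0) -> TranscriptModel:
    """Parse one BED12 line into a :class:`TranscriptModel`.

    Coordinates are 0-based half-open.  Exon blocks are reconstructed from
    chromStart + blockStarts with lengths from blockSizes.  Raises
    :class:`BedParseError` naming ``line_number`` on malformed input.
    """
    fields = line.rstrip("\r\n").split("\t")
    if len(fields) < 12:
        raise BedParseError(
            f"line {line_number}: expected >=12 tab-separated fields, got {len(fields)}"
        )
    chrom = fields[0]
    tx_start = _int_field(fields[1], "chromStart", line_number)
    tx_end = _int_field(fields[2], "chromEnd", line_number)
    name = fields[3]
    strand = fields[5]
    if strand not in ("+", "-"):
        raise BedParseError(f"line {line_number}: strand must be '+' or '-', got {strand!r}")
    block_count = _int_field(fields[9], "blockCount", line_number)
    sizes = _split_csv_ints(fields[10], "blockSizes", line_number)
    starts = _split_csv_ints(fields[11], "blockStarts", line_number)
    if len(sizes) != block_count or len(starts) != block_count:
        raise BedParseError(
            f"line {line_number}: blockCount {block_count} does not match "
            f"blockSizes ({len(sizes)}) / blockStarts ({len(starts)})"
        )
    if block_count == 0:
        raise BedParseError(f"line {line_number}: blockCount is zero")
    blocks = []
    prev_end = None
    for rel_start, size in zip(starts, sizes):
        if size <= 0:
            raise BedParseError(f"line {line_number}: non-positive blockSize {size}")
        start = tx_start + rel_start
        end = start + size
        if start < tx_start or end > tx_end:
            raise BedParseError(
                f"line {line_number}: block [{start},{end}) outside "
                f"[{tx_start},{tx_end})"
            )
        if prev_end is not None and start < prev_end:
            raise BedParseError(f"line {line_number}: blocks overlap or are unsorted")
        prev_end = end
        blocks.append((start, size))
    return TranscriptModel(
        transcript_id=name,
        chrom=chrom,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        blocks=tuple(blocks),
        score=fields[4],
        thick_start=_int_field(fields[6], "thickStart", line_number),
        thick_end=_int_field(fields[7], "thickEnd", line_number),
        item_rgb=fields[8],
        extra_fields=tuple(fields[12:]),
    )


def read_bed12(path: str | Path) -> list[TranscriptModel]:
    """Read a BED12 file (plain or gzip); skips comment/track/empty lines."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    models: list[TranscriptModel] = []
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#") or stripped.startswith("track"):
                continue
            models.append(parse_bed12(line, line_number=i))
    return models


def write_bed12(models: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(m.to_bed12() + "\n")


def filter_gene_model(
    models: Sequence[TranscriptModel],
    min_spliced_length: int = 100,
    exclude_patterns: Sequence[str] = DEFAULT_EXCLUDE_PATTERNS,
    source_path: str = "",
) -> GeneModelSet:
    """Drop short transcripts and rRNA/tRNA-like names.

    A transcript is excluded when its spliced length is below
    ``min_spliced_length`` (default 100 nt — below that the percentile
    sampling double-counts bases) or its name matches any exclude pattern
    (substring or fnmatch-style glob).
    """
    if min_spliced_length < N_PERCENTILES:
        raise ValueError(
            f"min_spliced_length must be >= {N_PERCENTILES}, got {min_spliced_length}"
        )
    compiled = [re.compile(fnmatch.translate(f"*{p}*")) for p in exclude_patterns]
    retained: list[TranscriptModel] = []
    excluded = 0
    seen_ids: set[str] = set()
    for m in models:
        if m.spliced_length < min_spliced_length or any(
            rx.match(m.transcript_id) for rx in compiled
        ):
            excluded += 1
            continue
        if m.transcript_id in seen_ids:
            logger.warning("duplicate transcript_id %s retained", m.transcript_id)
        seen_ids.add(m.transcript_id)
        retained.append(m)
    if not retained:
        raise ValueError("no usable transcripts after filtering")
    return GeneModelSet(
        transcripts=retained, excluded_count=excluded, source_path=source_path
    )


def percentile_positions(model: TranscriptModel) -> np.ndarray:
    """Genomic coordinates of the 100 gene-body percentiles, 5' -> 3'.

    Percentile k (k = 0..99) is the genomic coordinate of spliced-transcript
    nucleotide floor(k * L / 100), walked in transcript orientation (reverse
    genomic order on the minus strand).
    """
    L = model.spliced_length
    if L < N_PERCENTILES:
        raise ValueError(
            f"transcript {model.transcript_id}: spliced length {L} < {N_PERCENTILES}"
        )
    k = np.arange(N_PERCENTILES, dtype=np.int64)
    spliced_idx = (k * L) // N_PERCENTILES
    if model.strand == "-":
        spliced_idx = (L - 1) - spliced_idx  # walk from the high-coordinate end
    # map spliced index -> genomic coordinate via cumulative block lengths
    starts = np.array([s for s, _ in model.blocks], dtype=np.int64)
    lengths = np.array([l for _, l in model.blocks], dtype=np.int64)
    cum = np.concatenate(([0], np.cumsum(lengths)))
    block_of = np.searchsorted(cum, spliced_idx, side="right") - 1
    return starts[block_of] + (spliced_idx - cum[block_of])
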