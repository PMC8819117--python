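"""Synthetic inputs with known ground truth, at two levels.

Profile level: cells x 100 coverage matrices built from protocol archetypes
(5'-tag peak, 3'-tag peak, full-length plateau — smooth scaled beta-density
shapes) with a planted fraction of skewed cells.  Skew modes are declared
multiplicative distortions of the archetype, modelling the aberrations seen
in real data: opposite-end bias (a mirrored profile, e.g. 3' bias under a
5'-tag chemistry), mid-body dropout (a notch factor), and 3' degradation (an
exponential ramp pushing signal toward the 3' end).

Read level: miniature BED12 gene models (including a spliced and a
minus-strand transcript) and sorted BAM files whose read placement follows a
stated positional density, together with the exact expected per-cell depth
counts computed by a brute-force per-base pileup — the oracle against which
the streaming coverage engine is checked.

All randomness flows through one seeded generator per call; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam
from scipy import stats

from .gene_model import TranscriptModel, N_PERCENTILES, write_bed12
from .matrix import CoverageMatrix
from .coverage import normalize_coverage

SKEW_MODES = ("opposite_end_bias", "mid_body_dropout", "degradation_3prime")

_BIN_CENTERS = (np.arange(N_PERCENTILES) + 0.5) / N_PERCENTILES


@dataclass(frozen=True)
class ProfileArchetype:
    """A protocol-prototypical coverage shape on the unit gene body.

    The mean curve is a beta density with mode ``peak`` and concentration
    ``concentration`` (a + b), evaluated at the 100 bin centers and scaled to
    maximum 1.  ``noise_sd`` is the per-bin Gaussian noise applied to each
    generated cell before clipping at 0 and re-normalizing.
    """

    name: str
    peak: float
    concentration: float
    noise_sd: float = 0.05

    def beta_params(self) -> tuple[float, float]:
        c = self.concentration
        if c <= 2:
            raise ValueError("concentration must exceed 2 for a modal shape")
        a = 1.0 + self.peak * (c - 2.0)
        b = 1.0 + (1.0 - self.peak) * (c - 2.0)
        return a, b

    def mean_curve(self) -> np.ndarray:
        a, b = self.beta_params()
        curve = stats.beta.pdf(_BIN_CENTERS, a, b)
        return curve / curve.max()


ARCHETYPES = {
    "five_prime_tag": ProfileArchetype("five_prime_tag", peak=0.08, concentration=8.0),
    "three_prime_tag": ProfileArchetype("three_prime_tag", peak=0.92, concentration=8.0),
    "full_length": ProfileArchetype("full_length", peak=0.5, concentration=2.6),
}


@dataclass
class SyntheticSpec:
    """Study conditions for one generated profile matrix."""

    n_cells: int = 200
    skew_fraction: float = 0.1
    archetype: ProfileArchetype = field(default_factory=lambda: ARCHETYPES["five_prime_tag"])
    skew_modes: Sequence[str] = ("opposite_end_bias",)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.archetype, str):
            self.archetype = ARCHETYPES[self.archetype]
        if not 0.0 <= self.skew_fraction < 0.5:
            raise ValueError(f"skew_fraction must be in [0, 0.5), got {self.skew_fraction}")
        if self.n_cells < 20:
            raise ValueError(f"need at least 20 cells, got {self.n_cells}")
        unknown = set(self.skew_modes) - set(SKEW_MODES)
        if unknown:
            raise ValueError(f"unknown skew modes: {sorted(unknown)}")


def _skewed_curve(base: np.ndarray, mode: str) -> np.ndarray:
    x = _BIN_CENTERS
    if mode == "opposite_end_bias":
        curve = base[::-1].copy()
    elif mode == "mid_body_dropout":
        notch = 1.0 - 0.9 * np.exp(-((x - 0.5) ** 2) / (2 * 0.15**2))
        curve = base * notch
    elif mode == "degradation_3prime":
        curve = base * np.exp(-4.0 * (1.0 - x))
    else:
        raise ValueError(f"unknown skew mode {mode!r}")
    return curve / curve.max()


def generate_profiles(spec: SyntheticSpec) -> tuple[CoverageMatrix, np.ndarray]:
    """Draw a labeled coverage matrix: True marks planted skewed cells.

    Typical cells are the archetype mean curve plus per-bin Gaussian noise;
    skewed cells cycle through ``spec.skew_modes``.  Every row is clipped at
    zero and max-normalized, mirroring the real coverage pipeline.
    """
    rng = np.random.default_rng(spec.seed)
    base = spec.archetype.mean_curve()
    n_skew = int(round(spec.n_cells * spec.skew_fraction))
    labels = np.zeros(spec.n_cells, dtype=bool)
    if n_skew:
        labels[rng.choice(spec.n_cells, size=n_skew, replace=False)] = True
    skew_curves = [_skewed_curve(base, m) for m in spec.skew_modes] or [base]
    rows = np.empty((spec.n_cells, N_PERCENTILES))
    skew_counter = 0
    for i in range(spec.n_cells):
        if labels[i]:
            curve = skew_curves[skew_counter % len(skew_curves)]
            skew_counter += 1
        else:
            curve = base
        noisy = curve + rng.normal(0.0, spec.archetype.noise_sd, size=N_PERCENTILES)
        rows[i] = normalize_coverage(np.clip(noisy, 0.0, None))
    cell_ids = [f"cell_{i:04d}" for i in range(spec.n_cells)]
    matrix = CoverageMatrix(
        cell_ids=cell_ids, values=rows, zero_flags=~rows.any(axis=1)
    )
    return matrix, labels


# ---------------------------------------------------------------------------
# toy BAM + BED generation


def toy_transcripts() -> list[TranscriptModel]:
    """Three 300-nt transcripts: plain plus, spliced plus, spliced minus."""
    return [
        TranscriptModel("txPlain", "chr1", "+", 100, 400, ((100, 300),)),
        TranscriptModel("txSpliced", "chr1", "+", 1000, 1800,
                        ((1000, 150), (1650, 150))),
        TranscriptModel("txMinus", "chr2", "-", 500, 1300,
                        ((500, 150), (1150, 150))),
    ]


@dataclass
class ToyReadSpec:
    """Read placement plan: per cell, (transcript_id, n_reads, density).

    density is one of "uniform", "five_prime", "three_prime" over the
    spliced transcript (transcript orientation).  ``barcoded`` writes a
    single BAM with CB tags plus barcodes.tsv; otherwise one BAM per cell.
    """

    cells: dict[str, list[tuple[str, int, str]]]
    read_length: int = 50
    barcoded: bool = False
    seed: int = 0


@dataclass
class ToyDataset:
    bed_path: Path
    bam_paths: dict[str, Path]  # cell_id -> path (single entry "_barcoded" if barcoded)
    barcodes_path: Path | None
    truth_raw_counts: dict[str, np.ndarray]
    transcripts: list[TranscriptModel]


def _draw_starts(rng: np.random.Generator, density: str, n: int, max_start: int) -> np.ndarray:
    if density == "uniform":
        u = rng.random(n)
    elif density == "five_prime":
        u = rng.beta(1.5, 8.0, size=n)
    elif density == "three_prime":
        u = rng.beta(8.0, 1.5, size=n)
    else:
        raise ValueError(f"unknown read density {density!r}")
    return np.minimum((u * (max_start + 1)).astype(int), max_start)


def _genomic_intervals(model: TranscriptModel, spliced_start: int, length: int) -> list[tuple[int, int]]:
    """Covered genomic intervals of a read at a spliced-coordinate start."""
    coords = model.spliced_coordinates()[spliced_start : spliced_start + length]
    coords = np.sort(coords)
    breaks = np.nonzero(np.diff(coords) > 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [len(coords)]))
    return [(int(coords[s]), int(coords[e - 1]) + 1) for s, e in zip(starts, ends)]


def _make_read(name: str, model: TranscriptModel, intervals, read_length: int,
               header: pysam.AlignmentHeader, barcode: str | None) -> pysam.AlignedSegment:
    read = pysam.AlignedSegment(header)
    read.query_name = name
    read.reference_id = header.get_tid(model.chrom)
    read.reference_start = intervals[0][0]
    read.mapping_quality = 60
    read.is_reverse = model.strand == "-"
    cigar = []
    prev_end = None
    for start, end in intervals:
        if prev_end is not None and start > prev_end:
            cigar.append((3, start - prev_end))  # N gap
        cigar.append((0, end - start))  # M
        prev_end = end
    read.cigartuples = cigar
    read.query_sequence = "A" * read_length
    read.query_qualities = pysam.qualitystring_to_array("I" * read_length)
    if barcode is not None:
        read.set_tag("CB", barcode + "-1")
    return read


def generate_toy_bam(spec: ToyReadSpec, out_dir: str | Path) -> ToyDataset:
    """Write the toy BED12 + sorted, indexed BAM(s) and the truth table.

    The truth table holds each cell's expected raw depth counts at the 100
    percentile positions, computed by brute-force pileup over per-base depth
    arrays — independently of the streaming coverage engine.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    transcripts = toy_transcripts()
    by_id = {t.transcript_id: t for t in transcripts}
    bed_path = out_dir / "toy_genes.bed"
    write_bed12(transcripts, bed_path)

    contig_len = 5000
    chroms = sorted({t.chrom for t in transcripts})
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": contig_len} for c in chroms],
        }
    )

    # per-cell reads and brute-force depth arrays
    reads_by_cell: dict[str, list[pysam.AlignedSegment]] = {}
    truth: dict[str, np.ndarray] = {}
    for cell_id, placements in spec.cells.items():
        depth = {c: np.zeros(contig_len, dtype=np.int64) for c in chroms}
        reads: list[pysam.AlignedSegment] = []
        for tx_id, n_reads, density in placements:
            model = by_id[tx_id]
            L = model.spliced_length
            if spec.read_length > L:
                raise ValueError(
                    f"read length {spec.read_length} exceeds transcript {tx_id} ({L} nt)"
                )
            starts = _draw_starts(rng, density, n_reads, L - spec.read_length)
            for j, s in enumerate(starts):
                intervals = _genomic_intervals(model, int(s), spec.read_length)
                for a, b in intervals:
                    depth[model.chrom][a:b] += 1
                reads.append(
                    _make_read(
                        f"{cell_id}_{tx_id}_{j}", model, intervals,
                        spec.read_length, header,
                        barcode=cell_id if spec.barcoded else None,
                    )
                )
        reads_by_cell[cell_id] = reads
        raw = np.zeros(N_PERCENTILES, dtype=np.int64)
        for model in transcripts:
            raw += depth[model.chrom][model.percentile_positions]
        truth[cell_id] = raw

    def _write_sorted(path: Path, reads: list[pysam.AlignedSegment]) -> None:
        unsorted = path.with_suffix(".unsorted.bam")
        with pysam.AlignmentFile(str(unsorted), "wb", header=header) as out:
            for r in reads:
                out.write(r)
        pysam.sort("-o", str(path), str(unsorted))
        unsorted.unlink()
        pysam.index(str(path))

    bam_paths: dict[str, Path] = {}
    barcodes_path: Path | None = None
    if spec.barcoded:
        all_reads = [r for reads in reads_by_cell.values() for r in reads]
        path = out_dir / "possorted.bam"
        _write_sorted(path, all_reads)
        bam_paths["_barcoded"] = path
        barcodes_path = out_dir / "barcodes.tsv"
        barcodes_path.write_text("".join(f"{c}-1\n" for c in spec.cells))
    else:
        for cell_id, reads in reads_by_cell.items():
            path = out_dir / f"{cell_id}.bam"
            _write_sorted(path, reads)
            bam_paths[cell_id] = path

    truth_path = out_dir / "truth_raw_counts.tsv"
    with open(truth_path, "w") as fh:
        fh.write("cell_id\t" + "\t".join(f"pos_{k}" for k in range(N_PERCENTILES)) + "\n")
        for cid, raw in truth.items():
            fh.write(cid + "\t" + "\t".join(str(int(v)) for v in raw) + "\n")

    return ToyDataset(
        bed_path=bed_path,
        bam_paths=bam_paths,
        barcodes_path=barcodes_path,
        truth_raw_counts=truth,
        transcripts=transcripts,
    )
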