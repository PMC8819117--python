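"""Per-cell TYPICAL/SKEWED annotation and output files.

Retained cells are TYPICAL, trimmed cells are SKEWED (reason "clustering"),
and cells flagged for all-zero coverage — which never enter the fit — are
SKEWED with reason "zero_coverage".  Outputs are the two id lists
(TypicalCellsID.tsv, SkewedCellsID.tsv) and the two-column annotation table
(SkewCAnnotation.tsv: cell_id, SkewC) that downstream single-cell toolkits
can load directly as cell metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .matrix import ReducedMatrix
from .tclust import TrimmedFitResult

TYPICAL = "TYPICAL"
SKEWED = "SKEWED"

TYPICAL_FILE = "TypicalCellsID.tsv"
SKEWED_FILE = "SkewedCellsID.tsv"
ANNOTATION_FILE = "SkewCAnnotation.tsv"


@dataclass(frozen=True)
class CellAnnotation:
    cell_id: str
    label: str  # TYPICAL | SKEWED
    reason: str  # clustering | zero_coverage
    alpha_used: float
    mode: str  # auto | manual


def classify(
    fit: TrimmedFitResult,
    matrix: ReducedMatrix,
    zero_flagged: Iterable[str] = (),
    mode: str = "auto",
) -> list[CellAnnotation]:
    """Label every cell of the reduced matrix from a trimmed fit.

    ``fit`` indices refer to the rows of ``matrix.clustering_input()`` — the
    matrix with zero-flagged cells removed.  The returned list covers every
    cell of the matrix exactly once, in matrix order.
    """
    zero_set = set(zero_flagged) | {
        c for c, z in zip(matrix.cell_ids, matrix.zero_flags) if z
    }
    clustered_ids = [c for c in matrix.cell_ids if c not in zero_set]
    n_clustered = len(clustered_ids)
    if len(fit.retained) + len(fit.trimmed) != n_clustered:
        raise ValueError(
            f"fit covers {len(fit.retained) + len(fit.trimmed)} rows but the "
            f"matrix has {n_clustered} clusterable cells"
        )
    retained = set(int(i) for i in fit.retained)
    label_by_id: dict[str, CellAnnotation] = {}
    for row, cid in enumerate(clustered_ids):
        lab = TYPICAL if row in retained else SKEWED
        label_by_id[cid] = CellAnnotation(cid, lab, "clustering", fit.alpha, mode)
    for cid in zero_set:
        label_by_id[cid] = CellAnnotation(cid, SKEWED, "zero_coverage", fit.alpha, mode)
    annotations = [label_by_id[cid] for cid in matrix.cell_ids]
    assert len(annotations) == matrix.n_cells
    return annotations


def write_outputs(annotations: Sequence[CellAnnotation], out_dir: str | Path) -> dict[str, Path]:
    """Write the id lists and annotation table; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for a in annotations:
        if any(ch.isspace() for ch in a.cell_id):
            raise ValueError(f"cell id contains whitespace (unsafe for TSV): {a.cell_id!r}")
    typical = [a.cell_id for a in annotations if a.label == TYPICAL]
    skewed = [a.cell_id for a in annotations if a.label == SKEWED]
    paths = {
        "typical": out_dir / TYPICAL_FILE,
        "skewed": out_dir / SKEWED_FILE,
        "annotation": out_dir / ANNOTATION_FILE,
    }
    paths["typical"].write_text("".join(c + "\n" for c in typical))
    paths["skewed"].write_text("".join(c + "\n" for c in skewed))
    with open(paths["annotation"], "w") as fh:
        fh.write("cell_id\tSkewC\treason\talpha\tmode\n")
        for a in annotations:
            label = "Typical" if a.label == TYPICAL else "Skewed"
            fh.write(f"{a.cell_id}\t{label}\t{a.reason}\t{a.alpha_used:g}\t{a.mode}\n")
    return paths


def read_annotation(path: str | Path) -> list[CellAnnotation]:
    """Load SkewCAnnotation.tsv back into annotations (round-trip of write_outputs)."""
    annotations = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["cell_id", "SkewC"]:
            raise ValueError(f"{path}: unexpected header {header}")
        for line in fh:
            cell_id, label, reason, alpha, mode = line.rstrip("\n").split("\t")
            annotations.append(
                CellAnnotation(
                    cell_id=cell_id,
                    label=TYPICAL if label == "Typical" else SKEWED,
                    reason=reason,
                    alpha_used=float(alpha),
                    mode=mode,
                )
            )
    return annotations


def plot_class_profiles(
    annotations: Sequence[CellAnnotation],
    coverage_values: np.ndarray,
    cell_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Overlay gene-body coverage curves, typical vs skewed panels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    label_by_id = {a.cell_id: a.label for a in annotations}
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    x = np.arange(coverage_values.shape[1])
    for title, ax, want in (("typical", axes[0], TYPICAL), ("skewed", axes[1], SKEWED)):
        for row, cid in enumerate(cell_ids):
            if label_by_id.get(cid) == want:
                ax.plot(x, coverage_values[row], lw=0.5, alpha=0.4, color="C0" if want == TYPICAL else "C3")
        ax.set_title(f"{title} cells")
        ax.set_xlabel("gene body 5' -> 3' (percentile)")
    axes[0].set_ylabel("normalized coverage")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
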