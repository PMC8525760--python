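"""Confusion-matrix bookkeeping and the metrics used to grade pain classifiers.

The whole evaluation surface of the pipeline reduces to K×K count matrices
with human grimace-scale labels on the rows and model predictions on the
columns.  From such a matrix we derive

* per-class recall     — diagonal over row sum,
* per-class precision  — diagonal over column sum,
* overall accuracy     — trace over grand total,

all reported as percentages rounded half-up to one decimal for display while
full precision is retained internally.  The trace/total reading of accuracy
is the multiclass generalisation of (TP+TN)/total and reproduces every corner
value of the reference matrices shipped with the package.

A three-level matrix (not present / moderately present / obviously present)
can be collapsed to a binary pain-present matrix by merging the two pain
levels; merging can only turn cross-level errors into correct calls, so the
binary accuracy never drops below the three-level one.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

THREE_LEVEL_CLASSES = ("Not Present", "Moderately Present", "Obviously Present")
BINARY_CLASSES = ("Not Present", "Present")


class EvaluationError(ValueError):
    """Raised for malformed matrices or label sequences."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, the convention of the reported tables.

    ``round_half_up(90.25) == 90.3`` whereas banker's rounding gives 90.2.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """K×K count matrix; rows = reference (grimace-scale) labels, columns = predicted."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise EvaluationError(f"counts must be square, got shape {counts.shape}")
        if counts.shape[0] != len(self.class_names):
            raise EvaluationError("class_names length must match matrix order")
        if (counts < 0).any():
            raise EvaluationError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "class_names", tuple(self.class_names))

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        """Per-class reference supports (row sums)."""
        return self.counts.sum(axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConfusionMatrix):
            return NotImplemented
        return self.class_names == other.class_names and np.array_equal(
            self.counts, other.counts
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.class_names), columns=list(self.class_names)
        )

    def write_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.insert(0, "class", df.index)
        df.to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def read_csv(cls, path: str | Path | io.TextIOBase) -> "ConfusionMatrix":
        df = pd.read_csv(path)
        names = tuple(str(c) for c in df.columns[1:])
        return cls(df.iloc[:, 1:].to_numpy(dtype=np.int64), names)


@dataclass(frozen=True)
class MetricsReport:
    """Percent-scale metrics derived from one confusion matrix.

    ``recall_pct``/``precision_pct`` hold NaN where the defining ratio has a
    zero denominator (an absent reference class or a never-predicted column);
    an undefined ratio is never reported as 0.
    """

    class_names: tuple[str, ...]
    overall_accuracy_pct: float
    recall_pct: np.ndarray
    precision_pct: np.ndarray
    supports: np.ndarray
    rounded: "MetricsReport | None" = field(default=None, repr=False, compare=False)

    def display(self) -> "MetricsReport":
        """The same report with every percentage rounded half-up to one decimal."""
        if self.rounded is None:
            object.__setattr__(
                self,
                "rounded",
                MetricsReport(
                    self.class_names,
                    round_half_up(self.overall_accuracy_pct),
                    np.array([_round_or_nan(v) for v in self.recall_pct]),
                    np.array([_round_or_nan(v) for v in self.precision_pct]),
                    self.supports,
                ),
            )
        return self.rounded


def _round_or_nan(v: float) -> float:
    return float("nan") if np.isnan(v) else round_half_up(v)


def confusion_matrix(
    true_labels: Sequence,
    predicted_labels: Sequence,
    class_names: Sequence[str],
) -> ConfusionMatrix:
    """Tally ``counts[i][j] = #{true == class i and predicted == class j}``.

    Labels may be given as class names or as integer indices into
    ``class_names``.  Unknown labels are rejected by name.
    """
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise EvaluationError(
            f"label sequences differ in length: {len(true_labels)} vs {len(predicted_labels)}"
        )
    names = tuple(class_names)
    index = {name: i for i, name in enumerate(names)}
    index.update({i: i for i in range(len(names))})

    counts = np.zeros((len(names), len(names)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        for lab in (t, p):
            if lab not in index:
                raise EvaluationError(f"unknown label {lab!r}; classes are {names}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, names)


def metrics_from_matrix(matrix: ConfusionMatrix) -> MetricsReport:
    """Recall, precision and overall accuracy (percent) from a count matrix."""
    counts = matrix.counts
    if counts.sum() == 0:
        raise EvaluationError("cannot compute metrics of an all-zero matrix")
    diag = np.diag(counts).astype(float)
    row = counts.sum(axis=1).astype(float)
    col = counts.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(row > 0, diag / row, np.nan) * 100.0
        precision = np.where(col > 0, diag / col, np.nan) * 100.0
    accuracy = float(diag.sum() / counts.sum()) * 100.0
    return MetricsReport(
        class_names=matrix.class_names,
        overall_accuracy_pct=accuracy,
        recall_pct=recall,
        precision_pct=precision,
        supports=matrix.supports,
    )


def collapse_to_binary(matrix: ConfusionMatrix) -> ConfusionMatrix:
    """Merge the two pain levels of a 3×3 matrix into one "Present" class.

    Class 0 stays "Not Present"; rows and columns 1 and 2 are summed.
    """
    if matrix.n_classes != 3:
        raise EvaluationError(f"binary collapse needs a 3×3 matrix, got {matrix.n_classes}×{matrix.n_classes}")
    c = matrix.counts
    merged = np.array(
        [
            [c[0, 0], c[0, 1] + c[0, 2]],
            [c[1, 0] + c[2, 0], c[1:, 1:].sum()],
        ],
        dtype=np.int64,
    )
    return ConfusionMatrix(merged, BINARY_CLASSES)


# ---------------------------------------------------------------------------
# Reference matrices
# ---------------------------------------------------------------------------

_REFERENCE_FILES = {
    "ears": "ears_cnn.csv",
    "eyes": "eyes_cnn.csv",
    "mouth_nostrils": "mouth_nostrils_cnn.csv",
    "fused": "fused_three_level.csv",
    "fused_binary": "fused_binary.csv",
}


def reference_matrices() -> dict[str, ConfusionMatrix]:
    """The published evaluation matrices of the original study, as fixtures.

    Three region classifiers graded on held-out test images (ears, eyes,
    mouth-and-nostrils), the fused whole-face classifier on three pain
    levels, and its binary pain-present version.
    """
    out = {}
    for key, fname in _REFERENCE_FILES.items():
        with resources.files("equipain.data").joinpath(fname).open("r") as fh:
            out[key] = ConfusionMatrix.read_csv(fh)
    return out


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------


def _fmt_pct(v: float) -> str:
    return "n/a" if np.isnan(v) else f"{_round_fmt(v)}%"


def _round_fmt(v: float) -> str:
    return f"{round_half_up(v):.1f}"


def render_matrix_text(matrix: ConfusionMatrix, title: str = "") -> str:
    """Text table in the layout of the reported matrices.

    Recall margin on the right, precision margin on the bottom with the
    overall accuracy in the corner; diagonal cells are marked with ``*`` in
    place of the original gray shading.
    """
    rep = metrics_from_matrix(matrix)
    names = matrix.class_names
    header = ["Reference \\ Predicted"] + list(names) + ["Recall"]
    rows = [header]
    for i, name in enumerate(names):
        cells = [
            f"{matrix.counts[i, j]}*" if i == j else f"{matrix.counts[i, j]}"
            for j in range(len(names))
        ]
        rows.append([name] + cells + [_fmt_pct(rep.recall_pct[i])])
    rows.append(
        ["Precision"]
        + [_fmt_pct(v) for v in rep.precision_pct]
        + [_fmt_pct(rep.overall_accuracy_pct)]
    )
    widths = [max(len(r[c]) for r in rows) for c in range(len(header))]
    lines = [title] if title else ["(untitled matrix)"]
    for r in rows:
        lines.append("  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip())
    return "\n".join(lines) + "\n"


def render_report(
    reports: Sequence[tuple[str, ConfusionMatrix]],
    out_csv: str | Path,
    out_txt: str | Path,
    metadata: dict | None = None,
) -> None:
    """Write machine-readable metrics CSV and a human-readable text report.

    Output bytes are a pure function of the inputs, so identical runs produce
    identical files.
    """
    if not reports:
        raise EvaluationError("render_report needs at least one (name, matrix) pair")
    records = []
    blocks = []
    meta = metadata or {}
    header = ", ".join(f"{k}={v}" for k, v in sorted(meta.items())) or "no metadata"
    for name, matrix in reports:
        rep = metrics_from_matrix(matrix)
        records.append(
            {
                "name": name,
                "overall_accuracy_pct": _round_fmt(rep.overall_accuracy_pct),
                **{
                    f"recall_{cls}_pct": _fmt_pct(rep.recall_pct[i]).rstrip("%")
                    for i, cls in enumerate(matrix.class_names)
                },
                **{
                    f"precision_{cls}_pct": _fmt_pct(rep.precision_pct[i]).rstrip("%")
                    for i, cls in enumerate(matrix.class_names)
                },
                "total": matrix.total,
            }
        )
        blocks.append(render_matrix_text(matrix, title=name))
    pd.DataFrame(records).to_csv(out_csv, index=False, lineterminator="\n")
    text = f"# Pain-classifier evaluation report ({header})\n\n" + "\n".join(blocks)
    Path(out_txt).write_text(text)
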