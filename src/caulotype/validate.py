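"""Prediction-vs-annotation validation: matching, confusion, agreement.

Predicted objects are matched to reference annotations (expert tables or
generator truth) by greedy nearest-neighbour pairing of reference points
under a distance cap; unmatched objects on either side are reported, never
silently dropped. Confusion matrices cross-tabulate matched label pairs;
headline accuracy is computed restricted to the Swarmer/Stalked classes,
mirroring the convention that debris disagreements (a subjective boundary)
are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LABEL_VOCABULARY = ("Swarmer", "Stalked", "Debris")


@dataclass
class ExpertAnnotation:
    """Point annotations by one annotator on one frame."""

    annotator: str
    points_um: np.ndarray            # (n, 2) reference points, µm
    labels: list[str]

    def __post_init__(self) -> None:
        for lab in self.labels:
            if lab not in LABEL_VOCABULARY:
                raise ValueError(f"label {lab!r} outside vocabulary {LABEL_VOCABULARY}")
        if len(self.points_um) != len(self.labels):
            raise ValueError("points and labels differ in length")


@dataclass
class MatchResult:
    pairs: list[tuple[int, int]]            # (predicted idx, reference idx)
    unmatched_predicted: list[int]
    unmatched_reference: list[int]

    @property
    def excluded_count(self) -> int:
        return len(self.unmatched_predicted) + len(self.unmatched_reference)


@dataclass
class ConfusionMatrix:
    row_labels: tuple[str, ...]             # reference
    col_labels: tuple[str, ...]             # comparison
    counts: np.ndarray                      # integer matrix
    excluded_count: int = 0

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))


def match_objects(
    predicted_points_um: np.ndarray,
    reference: ExpertAnnotation,
    max_dist_um: float = 1.0,
) -> MatchResult:
    """Greedy nearest-neighbour matching under a distance cap.

    Candidate pairs are sorted by (distance, predicted index, reference
    index) and accepted greedily, so each side is used at most once and
    exact ties resolve to the lower predicted index.
    """
    pred = np.asarray(predicted_points_um, dtype=float).reshape(-1, 2)
    ref = np.asarray(reference.points_um, dtype=float).reshape(-1, 2)
    if len(pred) == 0 or len(ref) == 0:
        return MatchResult([], list(range(len(pred))), list(range(len(ref))))

    d = np.linalg.norm(pred[:, None, :] - ref[None, :, :], axis=2)
    cand = np.argwhere(d <= max_dist_um)
    order = sorted(
        (float(d[i, j]), int(i), int(j)) for i, j in cand
    )
    used_p: set[int] = set()
    used_r: set[int] = set()
    pairs = []
    for _, i, j in order:
        if i in used_p or j in used_r:
            continue
        pairs.append((i, j))
        used_p.add(i)
        used_r.add(j)
    return MatchResult(
        pairs=pairs,
        unmatched_predicted=[i for i in range(len(pred)) if i not in used_p],
        unmatched_reference=[j for j in range(len(ref)) if j not in used_r],
    )


def confusion(
    label_pairs: list[tuple[str, str]],
    labels: tuple[str, ...] = LABEL_VOCABULARY,
    excluded_count: int = 0,
) -> ConfusionMatrix:
    """Cross-tabulate (reference, comparison) label pairs.

    Works equally for model-vs-expert and expert-vs-expert input.
    """
    index = {lab: k for k, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for ref_lab, cmp_lab in label_pairs:
        for lab in (ref_lab, cmp_lab):
            if lab not in index:
                raise ValueError(f"label {lab!r} outside vocabulary {labels}")
        counts[index[ref_lab], index[cmp_lab]] += 1
    return ConfusionMatrix(
        row_labels=tuple(labels), col_labels=tuple(labels),
        counts=counts, excluded_count=excluded_count,
    )


def accuracy(
    matrix: ConfusionMatrix, restrict_to: tuple[str, ...] | None = None
) -> float:
    """Trace/total of the (optionally class-restricted) confusion matrix.

    Restriction drops rows *and* columns outside ``restrict_to`` before
    taking trace/total; an empty restricted matrix is undefined (NaN).
    """
    counts = matrix.counts
    rows = list(matrix.row_labels)
    cols = list(matrix.col_labels)
    if restrict_to is not None:
        ri = [rows.index(lab) for lab in restrict_to if lab in rows]
        ci = [cols.index(lab) for lab in restrict_to if lab in cols]
        counts = counts[np.ix_(ri, ci)]
        rows = [rows[i] for i in ri]
        cols = [cols[i] for i in ci]
    total = counts.sum()
    if total == 0:
        return float("nan")
    diag = sum(
        counts[i, cols.index(lab)] for i, lab in enumerate(rows) if lab in cols
    )
    return float(diag / total)


def agreement(
    expert_a: ExpertAnnotation,
    expert_b: ExpertAnnotation,
    max_dist_um: float = 1.0,
    restrict_to: tuple[str, ...] | None = ("Swarmer", "Stalked"),
) -> tuple[float, ConfusionMatrix]:
    """Inter-annotator agreement = accuracy of the A-vs-B confusion matrix."""
    match = match_objects(expert_b.points_um, expert_a, max_dist_um)
    pairs = [
        (expert_a.labels[j], expert_b.labels[i]) for i, j in match.pairs
    ]
    matrix = confusion(pairs, excluded_count=match.excluded_count)
    return accuracy(matrix, restrict_to), matrix


def load_annotation_csv(path, annotator: str | None = None) -> list[ExpertAnnotation]:
    """Read expert point annotations from CSV.

    Expected columns: image, row_um, col_um, label, annotator. Returns one
    annotation per (image, annotator) group, or only the requested
    annotator's groups.
    """
    df = pd.read_csv(path)
    required = {"image", "row_um", "col_um", "label", "annotator"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
    if annotator is not None:
        df = df[df["annotator"] == annotator]
    out = []
    for (_, who), grp in df.groupby(["image", "annotator"], sort=True):
        out.append(ExpertAnnotation(
            annotator=str(who),
            points_um=grp[["row_um", "col_um"]].to_numpy(float),
            labels=list(grp["label"]),
        ))
    return out


def annotation_from_truth(records: pd.DataFrame, annotator: str = "truth") -> ExpertAnnotation:
    """Ground-truth records recast as an annotation table.

    The generator's per-cell truth stands in for the expert: reference
    points are pole midpoints, labels collapse predivisional into Stalked.
    """
    label_map = {"stalked": "Stalked", "predivisional": "Stalked",
                 "swarmer": "Swarmer", "debris": "Debris"}
    pts = np.column_stack([
        (records["pole1_row"] + records["pole2_row"]) / 2.0,
        (records["pole1_col"] + records["pole2_col"]) / 2.0,
    ])
    labels = [label_map[c] for c in records["class"]]
    return ExpertAnnotation(annotator=annotator, points_um=pts, labels=labels)
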