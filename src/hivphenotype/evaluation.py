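"""Annotation-style validation: sampling, confusion matrices, agreement.

Mirrors a blinded clinician annotation exercise: draw a stratified sample of
persons from the assigned cohorts, compare annotator labels against the
algorithm, and report one-vs-rest diagnostics per class plus pairwise
Cohen's kappa between annotators.

Metrics with a zero denominator are reported as ``None`` ("undefined"),
never silently 0 — small per-stratum samples make empty cells routine.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

#: default annotation design: 90 PLWH / 10 PrEP / 10 PEP / 10 not-HIV
DEFAULT_SAMPLE_SIZES: dict[str, int] = {"plwh": 90, "prep": 10, "pep": 10, "not_hiv": 10}


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    """Square count grid indexed (truth row, predicted column)."""

    classes: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        k = len(self.classes)
        if len(self.counts) != k or any(len(r) != k for r in self.counts):
            raise ValueError("counts must be a square grid over classes")
        if any(c < 0 for row in self.counts for c in row):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return sum(sum(row) for row in self.counts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


def sample_annotation_set(
    assignments: Mapping[str, str],
    sizes: Mapping[str, int] | None = None,
    seed: int = 0,
) -> list[str]:
    """Stratified, without-replacement sample of person_ids for annotation.

    ``assignments`` maps person_id -> label.  Strata are sampled in sorted
    label order from sorted id lists, so the draw depends only on the seed
    and the assignment contents.
    """
    if sizes is None:
        sizes = DEFAULT_SAMPLE_SIZES
    rng = np.random.default_rng(seed)
    by_label: dict[str, list[str]] = {}
    for pid, label in assignments.items():
        by_label.setdefault(label, []).append(pid)
    out: list[str] = []
    for label in sorted(sizes):
        want = sizes[label]
        pool = sorted(by_label.get(label, []))
        if len(pool) < want:
            raise ValueError(
                f"stratum {label!r} has {len(pool)} member(s), {want} requested"
            )
        picked = rng.choice(len(pool), size=want, replace=False)
        out.extend(pool[i] for i in sorted(picked))
    return out


def confusion_matrix(
    truth: Sequence[str],
    predicted: Sequence[str],
    classes: Sequence[str],
) -> ConfusionMatrix:
    """counts[i][j] = #(truth == classes[i] and predicted == classes[j])."""
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    grid = [[0] * len(classes) for _ in classes]
    for t, p in zip(truth, predicted):
        if t not in index or p not in index:
            raise ValueError(f"label outside classes: {t!r} / {p!r}")
        grid[index[t]][index[p]] += 1
    return ConfusionMatrix(tuple(classes), tuple(tuple(r) for r in grid))


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def class_metrics(cm: ConfusionMatrix, positive_class: str) -> dict[str, float | None]:
    """One-vs-rest diagnostics for ``positive_class``.

    Returns sensitivity, specificity, PPV, NPV, precision, recall and F1.
    By definition sensitivity == recall and PPV == precision; both names are
    reported because both are conventional.  Undefined ratios are ``None``.
    """
    if positive_class not in cm.classes:
        raise ValueError(f"{positive_class!r} not among classes {cm.classes}")
    a = cm.as_array()
    i = cm.classes.index(positive_class)
    tp = int(a[i, i])
    fn = int(a[i, :].sum() - tp)
    fp = int(a[:, i].sum() - tp)
    tn = int(a.sum() - tp - fn - fp)

    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    if ppv is None or sensitivity is None or (ppv + sensitivity) == 0:
        f1 = None
    else:
        f1 = 2 * ppv * sensitivity / (ppv + sensitivity)
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "ppv": ppv,
        "npv": npv,
        "precision": ppv,
        "recall": sensitivity,
        "f1": f1,
    }


def cohens_kappa(labels_a: Sequence[str], labels_b: Sequence[str]) -> float:
    """Chance-corrected agreement between two raters.

    kappa = (p_o - p_e) / (1 - p_e) with expected agreement p_e from the
    product of the raters' marginal label frequencies.  When both raters use
    a single shared class (p_e == 1, which forces p_o == 1) kappa is defined
    as 1.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences must have equal length")
    n = len(labels_a)
    if n == 0:
        raise ValueError("empty label sequences")
    classes = sorted(set(labels_a) | set(labels_b))
    idx = {c: i for i, c in enumerate(classes)}
    table = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for a, b in zip(labels_a, labels_b):
        table[idx[a], idx[b]] += 1
    p_o = np.trace(table) / n
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if p_e == 1.0:
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))


def annotation_report(
    truth: Sequence[str],
    predictions: Mapping[str, Sequence[str]],
    classes: Sequence[str],
) -> dict:
    """Full annotation summary: per-rater per-class metrics and pairwise kappa.

    ``predictions`` maps rater name -> label sequence aligned with ``truth``.
    """
    report: dict = {"per_rater": {}, "kappa_pairs": {}}
    for rater, pred in predictions.items():
        cm = confusion_matrix(truth, pred, classes)
        report["per_rater"][rater] = {
            "confusion_matrix": [list(r) for r in cm.counts],
            "classes": list(classes),
            "metrics": {c: class_metrics(cm, c) for c in classes},
        }
    raters = sorted(predictions)
    for i, ra in enumerate(raters):
        for rb in raters[i + 1 :]:
            report["kappa_pairs"][f"{ra}|{rb}"] = cohens_kappa(
                predictions[ra], predictions[rb]
            )
    return report
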