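"""Validation protocol: expert agreement, consensus gold standard, ROC analysis.

The protocol mirrors how a diagnostic decision-support system is judged
against an expert panel:

1. each rater labels every (case, diagnosis) pair on the three-state scale
   ``present`` / ``at_risk`` / ``absent``;
2. the panel's labels are merged into a consensus gold standard (unanimity,
   else strict majority, else explicit adjudication);
3. the system (or any rater) is scored against the gold standard by exact
   three-state agreement, and — after collapsing ``present``+``at_risk``
   into ``positive`` — by sensitivity, specificity and an ROC curve on the
   posterior score P(present)+P(at_risk), with trapezoidal AUC, the
   Hanley–McNeil standard error and a normal-approximation 95% CI.

Agreement is exact label match on the three-state scale: confusing "risk"
with "presence" is a genuine disagreement, not a near-miss.

Degenerate denominators (no positives, or no negatives, in the gold
standard) make sensitivity/specificity undefined; they are reported as
``None`` with an explanatory note, never imputed as 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn import metrics as _skm

from .engine import classify_binary
from .errors import AlignmentError, ClassBalanceError, IncompleteConsensusError, NutriDSSError

__all__ = [
    "LabelSet",
    "GoldStandard",
    "AgreementResult",
    "agreement_rate",
    "build_consensus",
    "SensSpecResult",
    "sensitivity_specificity",
    "roc_curve",
    "auc",
    "auc_se",
    "auc_ci",
    "ValidationResult",
    "validate_system",
]

Key = tuple[str, str]  # (case_id, diagnosis_id)

VALID_LABELS = ("present", "at_risk", "absent")


@dataclass
class LabelSet:
    """One rater's three-state labels over a (case, diagnosis) grid."""

    rater_id: str
    labels: dict[Key, str] = field(default_factory=dict)

    def __post_init__(self):
        bad = {k: v for k, v in self.labels.items() if v not in VALID_LABELS}
        if bad:
            raise NutriDSSError(f"rater {self.rater_id!r}: invalid label(s) {bad!r}")

    def keys(self) -> set[Key]:
        return set(self.labels)

    def restrict(self, diagnosis: str) -> dict[Key, str]:
        return {k: v for k, v in self.labels.items() if k[1] == diagnosis}


@dataclass
class GoldStandard:
    """Consensus reference labels with per-entry provenance.

    ``provenance`` values: ``unanimous``, ``majority``, ``adjudicated``.
    Entries whose panel vote tied and that no adjudication resolved sit in
    ``pending`` with no label; :meth:`require_complete` guards every
    downstream use.
    """

    labels: dict[Key, str] = field(default_factory=dict)
    provenance: dict[Key, str] = field(default_factory=dict)
    pending: set[Key] = field(default_factory=set)

    def require_complete(self) -> "GoldStandard":
        if self.pending:
            raise IncompleteConsensusError(self.pending)
        return self

    def as_labelset(self, rater_id: str = "gold") -> LabelSet:
        self.require_complete()
        return LabelSet(rater_id, dict(self.labels))

    def keys(self) -> set[Key]:
        return set(self.labels) | self.pending


def _aligned_keys(a_keys: set[Key], b_keys: set[Key]) -> list[Key]:
    if a_keys != b_keys:
        raise AlignmentError(missing_in_a=b_keys - a_keys, missing_in_b=a_keys - b_keys)
    return sorted(a_keys)


@dataclass(frozen=True)
class AgreementResult:
    """Exact-match agreement between two label sets."""

    count: int
    total: int
    percent: float

    @property
    def percent_rounded(self) -> int:
        return int(round(self.percent))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.count}/{self.total} ({self.percent_rounded}%)"


def agreement_rate(a: LabelSet | GoldStandard, b: LabelSet | GoldStandard) -> AgreementResult:
    """Exact three-state label matches over the shared key grid.

    Both inputs must cover identical (case, diagnosis) keys; a mismatch
    raises :class:`AlignmentError` listing the missing keys.  Symmetric by
    construction.
    """
    la = a.as_labelset() if isinstance(a, GoldStandard) else a
    lb = b.as_labelset() if isinstance(b, GoldStandard) else b
    keys = _aligned_keys(la.keys(), lb.keys())
    if not keys:
        raise AlignmentError(set(), set())
    count = sum(la.labels[k] == lb.labels[k] for k in keys)
    return AgreementResult(count, len(keys), 100.0 * count / len(keys))


def build_consensus(
    panel: Sequence[LabelSet],
    adjudication: Mapping[Key, str] | None = None,
) -> GoldStandard:
    """Merge a rater panel into a consensus gold standard.

    Unanimous entries keep their label (provenance ``unanimous``); a strict
    majority wins otherwise (``majority``); a tie must be resolved by the
    ``adjudication`` mapping (``adjudicated``) or the entry stays pending.
    A single-rater panel is passed through unchanged (and unanimous), which
    makes consensus idempotent.
    """
    if not panel:
        raise NutriDSSError("consensus requires at least one rater")
    keys = panel[0].keys()
    for rater in panel[1:]:
        keys = _aligned_keys(keys, rater.keys()) and keys  # raises on mismatch
    adjudication = dict(adjudication or {})
    bad = {k: v for k, v in adjudication.items() if v not in VALID_LABELS}
    if bad:
        raise NutriDSSError(f"invalid adjudication label(s): {bad!r}")

    gold = GoldStandard()
    for key in sorted(keys):
        votes = [r.labels[key] for r in panel]
        counts = {label: votes.count(label) for label in set(votes)}
        top = max(counts.values())
        winners = sorted(label for label, c in counts.items() if c == top)
        if len(winners) == 1 and top == len(votes):
            gold.labels[key] = winners[0]
            gold.provenance[key] = "unanimous"
        elif len(winners) == 1:
            gold.labels[key] = winners[0]
            gold.provenance[key] = "majority"
        elif key in adjudication:
            gold.labels[key] = adjudication[key]
            gold.provenance[key] = "adjudicated"
        else:
            gold.pending.add(key)
    return gold


@dataclass(frozen=True)
class SensSpecResult:
    """Binary operating point of the system against the gold standard.

    ``sensitivity``/``specificity`` are percentages, or ``None`` when the
    corresponding gold class is empty (see ``notes``).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    notes: tuple[str, ...] = ()

    @property
    def confusion(self) -> dict[str, int]:
        return {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn}


def sensitivity_specificity(
    system: LabelSet, gold: GoldStandard | LabelSet, diagnosis: str
) -> SensSpecResult:
    """Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), after binarization.

    Labels are collapsed with :func:`~nutridss.engine.classify_binary`
    (presence of risk or diagnosis vs absence).
    """
    gold_ls = gold.as_labelset() if isinstance(gold, GoldStandard) else gold
    sys_labels = system.restrict(diagnosis)
    gold_labels = gold_ls.restrict(diagnosis)
    keys = _aligned_keys(set(sys_labels), set(gold_labels))
    if not keys:
        raise AlignmentError(set(), set())

    tp = fp = tn = fn = 0
    for key in keys:
        s = classify_binary(sys_labels[key])
        g = classify_binary(gold_labels[key])
        if g == "positive":
            tp += s == "positive"
            fn += s == "negative"
        else:
            tn += s == "negative"
            fp += s == "positive"

    notes: list[str] = []
    sens = spec = None
    if tp + fn == 0:
        notes.append("sensitivity undefined: gold standard has no positive cases")
    else:
        sens = 100.0 * tp / (tp + fn)
    if tn + fp == 0:
        notes.append("specificity undefined: gold standard has no negative cases")
    else:
        spec = 100.0 * tn / (tn + fp)
    return SensSpecResult(tp, fp, tn, fn, sens, spec, tuple(notes))


def _check_two_classes(y: np.ndarray):
    if len(np.unique(y)) < 2:
        raise ClassBalanceError(
            "ROC analysis needs at least one positive and one negative gold label"
        )


def roc_curve(scores: Sequence[tuple[float, int]]) -> np.ndarray:
    """(FPR, TPR) points at every distinct score threshold, descending.

    ``scores`` holds ``(score, gold)`` pairs with gold 1 = positive.  Tied
    scores are grouped at a single threshold and the curve is anchored at
    (0, 0) and (1, 1).  Thin wrapper over :func:`sklearn.metrics.roc_curve`
    with ``drop_intermediate=False`` so every threshold appears.
    """
    s = np.asarray([x[0] for x in scores], dtype=float)
    y = np.asarray([x[1] for x in scores], dtype=int)
    _check_two_classes(y)
    fpr, tpr, _ = _skm.roc_curve(y, s, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def auc(points: np.ndarray) -> float:
    """Trapezoidal area under an ROC curve given as (FPR, TPR) points."""
    pts = np.asarray(points, dtype=float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def auc_se(area: float, n_pos: int, n_neg: int) -> float:
    """Hanley–McNeil standard error of a trapezoidal AUC.

    SE^2 = [A(1-A) + (n+ - 1)(Q1 - A^2) + (n- - 1)(Q2 - A^2)] / (n+ n-),
    with Q1 = A/(2-A) and Q2 = 2A^2/(1+A).
    """
    if n_pos < 1 or n_neg < 1:
        raise ClassBalanceError("AUC standard error needs n_pos >= 1 and n_neg >= 1")
    a = float(area)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1.0 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def auc_ci(area: float, se: float, z: float = 1.96) -> tuple[float, float]:
    """Normal-approximation confidence interval, clipped to [0, 1]."""
    lo = max(0.0, float(area) - z * float(se))
    hi = min(1.0, float(area) + z * float(se))
    return lo, hi


@dataclass(frozen=True)
class DiagnosisValidation:
    """All validation statistics for one diagnosis."""

    diagnosis: str
    agreement: AgreementResult
    operating_point: SensSpecResult
    roc_points: np.ndarray | None
    auc: float | None
    auc_se: float | None
    auc_ci95: tuple[float, float] | None
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "diagnosis": self.diagnosis,
            "agreement": {
                "count": self.agreement.count,
                "total": self.agreement.total,
                "percent": self.agreement.percent,
                "percent_rounded": self.agreement.percent_rounded,
            },
            "confusion": self.operating_point.confusion,
            "sensitivity_percent": self.operating_point.sensitivity,
            "specificity_percent": self.operating_point.specificity,
            "notes": list(self.operating_point.notes),
            "roc_points": None if self.roc_points is None else self.roc_points.tolist(),
            "auc": self.auc,
            "auc_se": self.auc_se,
            "auc_ci95": None if self.auc_ci95 is None else list(self.auc_ci95),
            "error": self.error,
        }


@dataclass(frozen=True)
class ValidationResult:
    """System-vs-gold validation, overall and per diagnosis."""

    overall_agreement: AgreementResult
    per_diagnosis: dict[str, DiagnosisValidation]

    def to_dict(self) -> dict:
        return {
            "overall_agreement": {
                "count": self.overall_agreement.count,
                "total": self.overall_agreement.total,
                "percent": self.overall_agreement.percent,
                "percent_rounded": self.overall_agreement.percent_rounded,
            },
            "per_diagnosis": {d: v.to_dict() for d, v in self.per_diagnosis.items()},
        }


def validate_system(
    system: LabelSet,
    gold: GoldStandard,
    scores: Mapping[Key, float] | None = None,
    diagnoses: Iterable[str] | None = None,
) -> ValidationResult:
    """Run the full validation battery for the system against the gold standard.

    ``scores`` maps (case, diagnosis) to the continuous risk-or-presence
    score; when provided, the ROC/AUC block is computed per diagnosis.
    Failures inside one diagnosis (e.g. a single-class ROC) are recorded in
    that diagnosis's ``error`` slot and do not abort the others.
    """
    gold_ls = gold.as_labelset()
    overall = agreement_rate(system, gold_ls)
    if diagnoses is None:
        diagnoses = sorted({k[1] for k in gold_ls.keys()})

    per: dict[str, DiagnosisValidation] = {}
    for diag in diagnoses:
        sub_sys = LabelSet(system.rater_id, system.restrict(diag))
        sub_gold = LabelSet("gold", gold_ls.restrict(diag))
        agree = agreement_rate(sub_sys, sub_gold)
        op = sensitivity_specificity(system, gold, diag)
        pts = area = se = ci = None
        error = None
        if scores is not None:
            pairs = [
                (scores[k], 1 if classify_binary(sub_gold.labels[k]) == "positive" else 0)
                for k in sorted(sub_gold.labels)
            ]
            try:
                pts = roc_curve(pairs)
                area = auc(pts)
                n_pos = sum(g for _, g in pairs)
                se = auc_se(area, n_pos, len(pairs) - n_pos)
                ci = auc_ci(area, se)
            except ClassBalanceError as exc:
                error = str(exc)
        per[diag] = DiagnosisValidation(diag, agree, op, pts, area, se, ci, error)
    return ValidationResult(overall, per)
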