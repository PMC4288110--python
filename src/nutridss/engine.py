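"""Turn one patient case into per-diagnosis posteriors and suggested labels.

The report is deliberately probabilistic: the suggested label is the argmax
of the posterior triple (ties resolved toward the clinically cautious label,
present > at_risk > absent) but the full triple is always carried along, so
the professional — not the system — makes the final call.

Each of the five subnets is queried independently with the subset of the
discretized evidence that its nodes cover.  A contradiction in one subnet
(zero-probability evidence, possible with hand-edited deterministic CPTs) is
recorded in that subnet's slot of the report and never voids the other four.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ImpossibleEvidenceError, NutriDSSError
from .inference import Posterior, map_state, posterior
from .knowledge import (
    DIAGNOSIS_STATES,
    KnowledgeBase,
    PatientCase,
    ReferenceRanges,
    default_ranges,
    discretize_case,
)

__all__ = [
    "LABEL_PRIORITY",
    "DiagnosisResult",
    "DiagnosisReport",
    "diagnose",
    "classify_binary",
    "risk_or_presence_score",
    "DiagnosisEngine",
]

#: Tie-break priority for the suggested label (clinically cautious first).
LABEL_PRIORITY = DIAGNOSIS_STATES  # ("present", "at_risk", "absent")


def classify_binary(label: str) -> str:
    """Collapse a three-state label to the binary scale used for validation.

    ``present`` and ``at_risk`` are both ``positive`` — the validation
    contrast is presence of risk or diagnosis versus absence.
    """
    if label in ("present", "at_risk"):
        return "positive"
    if label == "absent":
        return "negative"
    raise NutriDSSError(f"unknown three-state label {label!r}")


def risk_or_presence_score(post: Posterior | Mapping[str, float]) -> float:
    """Posterior mass of the positive super-state, P(present) + P(at_risk).

    This is the continuous score thresholded by the ROC analysis.
    """
    dist = post.distribution if isinstance(post, Posterior) else post
    return float(dist["present"] + dist["at_risk"])


@dataclass(frozen=True)
class DiagnosisResult:
    """One diagnosis slot of a report (posterior triple or a recorded error)."""

    diagnosis: str
    posterior: Posterior | None
    label: str | None
    evidence_used: dict[str, str]
    missing_evidence: tuple[str, ...]
    error: str | None = None

    @property
    def score(self) -> float | None:
        return None if self.posterior is None else risk_or_presence_score(self.posterior)

    def to_dict(self) -> dict:
        return {
            "diagnosis": self.diagnosis,
            "posterior": None if self.posterior is None else dict(self.posterior.distribution),
            "label": self.label,
            "score": self.score,
            "evidence_used": dict(self.evidence_used),
            "missing_evidence": list(self.missing_evidence),
            "error": self.error,
        }


@dataclass(frozen=True)
class DiagnosisReport:
    """Per-diagnosis posterior triples and suggested labels for one patient."""

    patient_id: str
    results: dict[str, DiagnosisResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "results": {d: r.to_dict() for d, r in self.results.items()},
        }

    def labels(self) -> dict[str, str | None]:
        return {d: r.label for d, r in self.results.items()}

    def scores(self) -> dict[str, float | None]:
        return {d: r.score for d, r in self.results.items()}


def diagnose(
    kb: KnowledgeBase,
    case: PatientCase,
    ranges: ReferenceRanges | None = None,
) -> DiagnosisReport:
    """Discretize ``case`` and query every subnet for its diagnosis posterior.

    Deterministic: no randomness is involved and all tie-breaks are fixed,
    so identical inputs give identical reports.
    """
    ranges = ranges if ranges is not None else default_ranges()
    evidence = discretize_case(case, ranges)
    results: dict[str, DiagnosisResult] = {}
    for diag in kb.list_diagnoses():
        subnet_nodes = set(kb.evidence_nodes(diag))
        used = {n: s for n, s in evidence.items() if n in subnet_nodes}
        missing = tuple(sorted(subnet_nodes - set(used)))
        try:
            post = posterior(kb.network(diag), diag, used)
        except ImpossibleEvidenceError as exc:
            results[diag] = DiagnosisResult(diag, None, None, used, missing, error=str(exc))
            continue
        results[diag] = DiagnosisResult(
            diag, post, map_state(post, LABEL_PRIORITY), used, missing
        )
    return DiagnosisReport(case.patient_id, results)


class DiagnosisEngine:
    """Convenience wrapper binding a knowledge base and a range table.

    >>> engine = DiagnosisEngine()          # shipped knowledge base
    >>> report = engine.diagnose(case)      # doctest: +SKIP
    """

    def __init__(self, kb: KnowledgeBase | None = None, ranges: ReferenceRanges | None = None):
        self.kb = kb if kb is not None else KnowledgeBase.load()
        self.ranges = ranges if ranges is not None else default_ranges()

    def diagnose(self, case: PatientCase) -> DiagnosisReport:
        return diagnose(self.kb, case, self.ranges)

    def diagnose_many(self, cases: Iterable[PatientCase]) -> list[DiagnosisReport]:
        return [self.diagnose(c) for c in cases]
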