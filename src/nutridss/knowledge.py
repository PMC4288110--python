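"""Clinical knowledge base: subnet spec files, reference ranges, discretization.

The quantitative knowledge lives entirely in JSON documents (five diagnostic
subnets plus one reference-range table) so that dietitians can revise states,
arcs and probabilities without touching code.  This module loads and
validates those documents, and converts a raw :class:`PatientCase` — lab
values with units, food-pyramid portions or energy, sign/symptom flags —
into the discrete evidence states the networks understand.

Discretization conventions (explicit because boundaries matter clinically):

* a lab value below the lower reference bound is ``low``, above the upper
  bound is ``high``, and the closed interval ``[lower, upper]`` is
  ``normal`` — boundary values are normal;
* daily energy below the intake reference (default 1600 kcal) is
  ``inadequate``, otherwise ``adequate``;
* months since surgery fall into half-open bands ``[min, max)``;
* missing measurements contribute no evidence (logged at DEBUG), they are
  never imputed.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import KnowledgeBaseError, NetworkSpecError, UnitMismatchError
from .network import BayesNetwork, DiscreteNode, validate_network

log = logging.getLogger(__name__)

__all__ = [
    "DIAGNOSES",
    "DIAGNOSIS_STATES",
    "PatientCase",
    "LabValue",
    "Intake",
    "ReferenceRanges",
    "load_network_spec",
    "serialize_network",
    "default_ranges",
    "discretize_case",
    "KnowledgeBase",
    "list_diagnoses",
]

#: The five standard nutritional diagnoses after Roux-en-Y gastric bypass.
DIAGNOSES = (
    "malnutrition",
    "iron_deficiency_anemia",
    "vitamin_b12_deficiency",
    "folic_acid_deficiency",
    "thiamine_deficiency",
)

#: Required states of every diagnosis node, in reporting order.
DIAGNOSIS_STATES = ("present", "at_risk", "absent")

#: PatientCase sign flags -> evidence node (nail and skin changes are pooled
#: into one node; either raw flag set means the pooled node is present).
_SIGN_NODES = {"hair_loss": "hair_loss", "paleness": "paleness"}
_POOLED_SIGNS = ("nail_changes", "skin_changes")
_SYMPTOM_NODES = ("weakness", "paresthesia", "vomiting", "diarrhea", "blood_loss")


# --------------------------------------------------------------------------
# network spec documents (pydantic models mirror data/network.schema.json)
# --------------------------------------------------------------------------


class _CptRow(BaseModel):
    model_config = ConfigDict(extra="forbid")
    given: dict[str, str] = Field(default_factory=dict)
    dist: dict[str, float]


class _NodeSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str = Field(min_length=1)
    states: list[str] = Field(min_length=2)
    parents: list[str] = Field(default_factory=list)
    cpt: list[_CptRow] = Field(min_length=1)


class _NetworkSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str = Field(min_length=1)
    version: str = "1.0"
    nodes: list[_NodeSpec] = Field(min_length=1)
    metadata: dict = Field(default_factory=dict)


def load_network_spec(document: str | bytes | Mapping | Path) -> BayesNetwork:
    """Parse a network-spec JSON document into a validated :class:`BayesNetwork`.

    ``document`` may be a JSON string/bytes, an already-decoded mapping, or a
    path to a ``.json`` file.  Schema violations raise
    :class:`NetworkSpecError` with the JSON path; semantic violations raise
    it with the full :func:`validate_network` diagnostics attached.
    """
    if isinstance(document, Path):
        document = document.read_text()
    if isinstance(document, (str, bytes)):
        try:
            raw = json.loads(document)
        except json.JSONDecodeError as exc:
            raise NetworkSpecError(f"not valid JSON: {exc}") from exc
    else:
        raw = document
    try:
        spec = _NetworkSpec.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError carries JSON paths
        raise NetworkSpecError(f"network spec does not match the schema: {exc}") from exc

    nodes = []
    for ns in spec.nodes:
        cpt: dict[tuple[str, ...], tuple[float, ...]] = {}
        for row in ns.cpt:
            extra = set(row.given) - set(ns.parents)
            if extra:
                raise NetworkSpecError(
                    f"node {ns.name!r}: CPT row conditions on non-parent(s) {sorted(extra)!r}"
                )
            missing = set(ns.parents) - set(row.given)
            if missing:
                raise NetworkSpecError(
                    f"node {ns.name!r}: CPT row omits parent(s) {sorted(missing)!r}"
                )
            missing_states = set(ns.states) - set(row.dist)
            if missing_states:
                raise NetworkSpecError(
                    f"node {ns.name!r}: CPT row omits state(s) {sorted(missing_states)!r}"
                )
            key = tuple(row.given[p] for p in ns.parents)
            if key in cpt:
                raise NetworkSpecError(f"node {ns.name!r}: duplicate CPT row for {key!r}")
            cpt[key] = tuple(row.dist[s] for s in ns.states)
        nodes.append(DiscreteNode(ns.name, tuple(ns.states), tuple(ns.parents), cpt))

    net = BayesNetwork(nodes, name=spec.name, metadata={"version": spec.version, **spec.metadata})
    diagnostics = validate_network(net)
    if diagnostics:
        raise NetworkSpecError(
            f"network {spec.name!r} is semantically invalid ({len(diagnostics)} finding(s))",
            diagnostics,
        )
    return net


def serialize_network(net: BayesNetwork) -> dict:
    """Inverse of :func:`load_network_spec` (structural round-trip)."""
    meta = dict(net.metadata)
    version = meta.pop("version", "1.0")
    return {
        "name": net.name,
        "version": version,
        "nodes": [
            {
                "name": node.name,
                "states": list(node.states),
                "parents": list(node.parents),
                "cpt": [
                    {
                        "given": dict(zip(node.parents, key)),
                        "dist": dict(zip(node.states, dist)),
                    }
                    for key, dist in node.cpt.items()
                ],
            }
            for node in net.nodes.values()
        ],
        "metadata": meta,
    }


# --------------------------------------------------------------------------
# patient cases
# --------------------------------------------------------------------------


class LabValue(BaseModel):
    """One biochemical measurement with its unit (no silent conversion)."""

    model_config = ConfigDict(extra="forbid")
    value: float = Field(gt=0)
    unit: str


class Intake(BaseModel):
    """Daily food intake: direct energy and/or food-pyramid portion counts."""

    model_config = ConfigDict(extra="forbid")
    energy_kcal: Optional[float] = Field(default=None, gt=0)
    portions: Optional[dict[str, float]] = None

    @model_validator(mode="after")
    def _nonneg_portions(self):
        if self.portions is not None and any(v < 0 for v in self.portions.values()):
            raise ValueError("portion counts must be >= 0")
        return self


class PatientCase(BaseModel):
    """Raw assessment data for one post-bariatric patient; any field may be missing."""

    model_config = ConfigDict(extra="forbid")
    patient_id: str
    gender: Literal["female", "male"]
    age: float = Field(gt=0, description="years")
    months_since_surgery: Optional[float] = Field(default=None, ge=0)
    labs: dict[str, LabValue] = Field(default_factory=dict)
    intake: Optional[Intake] = None
    signs: dict[str, bool] = Field(default_factory=dict)
    symptoms: dict[str, bool] = Field(default_factory=dict)


# --------------------------------------------------------------------------
# reference ranges
# --------------------------------------------------------------------------


class MarkerRange(BaseModel):
    model_config = ConfigDict(extra="forbid")
    unit: str
    bounds: dict[str, tuple[float, float]]

    @model_validator(mode="after")
    def _ordered(self):
        for stratum, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"stratum {stratum!r}: lower bound must be < upper bound")
        return self


class SurgeryTimeBand(BaseModel):
    model_config = ConfigDict(extra="forbid")
    state: str
    min_months: float = Field(ge=0)
    max_months: Optional[float] = None  # None = open-ended


class ReferenceRanges(BaseModel):
    """Reference intervals per marker and stratum, plus intake references.

    Strata are keyed by gender (``female``/``male``) with ``any`` as the
    fallback; the shipped table stratifies only the markers whose adult
    intervals genuinely differ by sex.
    """

    model_config = ConfigDict(extra="forbid")
    version: str = "1.0"
    provenance: str = ""
    intake_threshold_kcal: float = Field(default=1600.0, gt=0)
    portion_kcal: dict[str, float] = Field(default_factory=dict)
    surgery_time_bands: list[SurgeryTimeBand] = Field(default_factory=list)
    markers: dict[str, MarkerRange]

    def bounds_for(self, marker: str, gender: str) -> tuple[float, float]:
        spec = self.markers[marker]
        if gender in spec.bounds:
            return spec.bounds[gender]
        return spec.bounds["any"]

    def surgery_band(self, months: float) -> str:
        for band in self.surgery_time_bands:
            if months >= band.min_months and (band.max_months is None or months < band.max_months):
                return band.state
        raise KnowledgeBaseError(f"no surgery-time band covers {months} months")

    def energy_from_portions(self, portions: Mapping[str, float]) -> float:
        unknown = set(portions) - set(self.portion_kcal)
        if unknown:
            raise KnowledgeBaseError(
                f"no kcal-per-portion entry for food group(s) {sorted(unknown)!r}"
            )
        return float(sum(self.portion_kcal[g] * n for g, n in portions.items()))


def _data_file(name: str) -> str:
    return resources.files("nutridss.data").joinpath(name).read_text()


def default_ranges() -> ReferenceRanges:
    """The shipped reference-range table (``data/ranges.json``)."""
    return ReferenceRanges.model_validate(json.loads(_data_file("ranges.json")))


def load_ranges(path: str | Path) -> ReferenceRanges:
    return ReferenceRanges.model_validate(json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# discretization
# --------------------------------------------------------------------------


def discretize_case(case: PatientCase, ranges: ReferenceRanges) -> dict[str, str]:
    """Map raw measurements to evidence states (partial assignment).

    Every provided measurement yields exactly one state; missing inputs are
    logged and simply absent from the result.  Raises
    :class:`UnitMismatchError` when a lab arrives in a unit other than the
    declared one, and ``KeyError`` for a marker the range table does not know.
    """
    evidence: dict[str, str] = {}

    for marker, lab in case.labs.items():
        if marker not in ranges.markers:
            raise KeyError(f"no reference range for marker {marker!r}")
        spec = ranges.markers[marker]
        if lab.unit != spec.unit:
            raise UnitMismatchError(marker, spec.unit, lab.unit)
        lo, hi = ranges.bounds_for(marker, case.gender)
        if lab.value < lo:
            evidence[marker] = "low"
        elif lab.value > hi:
            evidence[marker] = "high"
        else:
            evidence[marker] = "normal"

    if case.intake is not None:
        if case.intake.energy_kcal is not None:
            energy = case.intake.energy_kcal  # direct kcal takes precedence
        elif case.intake.portions is not None:
            energy = ranges.energy_from_portions(case.intake.portions)
        else:
            energy = None
        if energy is not None:
            evidence["intake"] = "inadequate" if energy < ranges.intake_threshold_kcal else "adequate"
    if "intake" not in evidence:
        log.debug("case %s: no intake data; intake node unobserved", case.patient_id)

    if case.months_since_surgery is not None and ranges.surgery_time_bands:
        evidence["surgery_time"] = ranges.surgery_band(case.months_since_surgery)

    for flag, node in _SIGN_NODES.items():
        if flag in case.signs:
            evidence[node] = "present" if case.signs[flag] else "absent"
    pooled = [case.signs[f] for f in _POOLED_SIGNS if f in case.signs]
    if pooled:
        evidence["nail_skin_changes"] = "present" if any(pooled) else "absent"

    for symptom in _SYMPTOM_NODES:
        if symptom in case.symptoms:
            evidence[symptom] = "present" if case.symptoms[symptom] else "absent"

    missing = [m for m in ranges.markers if m not in case.labs]
    if missing:
        log.debug("case %s: no measurement for %s", case.patient_id, ", ".join(missing))
    return evidence


# --------------------------------------------------------------------------
# knowledge base
# --------------------------------------------------------------------------


class KnowledgeBase:
    """The five diagnostic subnets, loaded and cross-checked.

    Construction enforces: every diagnosis of :data:`DIAGNOSES` is present;
    each subnet contains a three-state diagnosis node named after itself with
    states exactly ``present``/``at_risk``/``absent``; and any root node
    shared between subnets (e.g. ``intake``) carries identical states and
    prior everywhere, so a single patient-level value is coherent across
    subnets.
    """

    def __init__(self, networks: Mapping[str, BayesNetwork]):
        missing = [d for d in DIAGNOSES if d not in networks]
        if missing:
            raise KnowledgeBaseError(f"knowledge base is missing subnet(s) for: {', '.join(missing)}")
        self.networks: dict[str, BayesNetwork] = {d: networks[d] for d in DIAGNOSES}
        for diag, net in self.networks.items():
            if diag not in net:
                raise KnowledgeBaseError(f"subnet {diag!r} has no diagnosis node named {diag!r}")
            states = net.node(diag).states
            if tuple(states) != DIAGNOSIS_STATES:
                raise KnowledgeBaseError(
                    f"diagnosis node {diag!r} has states {states!r}; expected {DIAGNOSIS_STATES!r}"
                )
        self._check_shared_roots()

    def _check_shared_roots(self):
        seen: dict[str, tuple[str, DiscreteNode]] = {}
        for diag, net in self.networks.items():
            for node in net.nodes.values():
                if node.parents or node.name == diag:
                    continue
                if node.name in seen:
                    other_diag, other = seen[node.name]
                    if node.states != other.states or node.cpt != other.cpt:
                        raise KnowledgeBaseError(
                            f"shared root node {node.name!r} differs between subnets "
                            f"{other_diag!r} and {diag!r}; shared roots must be identical"
                        )
                else:
                    seen[node.name] = (diag, node)

    @classmethod
    def load(cls, directory: str | Path | None = None) -> "KnowledgeBase":
        """Load subnet files ``<diagnosis>.json``; ``None`` loads the shipped set."""
        networks = {}
        for diag in DIAGNOSES:
            if directory is None:
                try:
                    text = _data_file(f"{diag}.json")
                except FileNotFoundError:
                    raise KnowledgeBaseError(f"shipped knowledge base is missing {diag!r}") from None
            else:
                path = Path(directory) / f"{diag}.json"
                if not path.exists():
                    raise KnowledgeBaseError(f"knowledge base at {directory} is missing {diag!r} ({path.name})")
                text = path.read_text()
            networks[diag] = load_network_spec(text)
        return cls(networks)

    def network(self, diagnosis: str) -> BayesNetwork:
        try:
            return self.networks[diagnosis]
        except KeyError:
            raise KnowledgeBaseError(f"unknown diagnosis {diagnosis!r}") from None

    def evidence_nodes(self, diagnosis: str) -> tuple[str, ...]:
        """All nodes of a subnet except its diagnosis node."""
        net = self.network(diagnosis)
        return tuple(n for n in net.nodes if n != diagnosis)

    def list_diagnoses(self) -> list[str]:
        return list(DIAGNOSES)

    def save(self, directory: str | Path):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for diag, net in self.networks.items():
            (directory / f"{diag}.json").write_text(json.dumps(serialize_network(net), indent=1))


def list_diagnoses(kb: KnowledgeBase) -> list[str]:
    """Ordered identifiers of the five standard diagnoses in ``kb``."""
    return kb.list_diagnoses()
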