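"""Exception hierarchy.

Every error raised by the package derives from :class:`NutriDSSError`, so
callers embedding the engine can catch one base class.  Errors that carry
structured payloads (offending evidence, missing keys, diagnostics) expose
them as attributes rather than only in the message.
"""

from __future__ import annotations


class NutriDSSError(Exception):
    """Base class for all package errors."""


class StructureError(NutriDSSError):
    """The directed graph of a network is not a DAG (or is otherwise unusable)."""


class MissingNodeError(NutriDSSError):
    """An operation requiring a full assignment received a partial one."""


class NetworkSpecError(NutriDSSError):
    """A network specification document failed parsing or semantic validation.

    Attributes
    ----------
    diagnostics : list
        The :class:`~nutridss.network.Diagnostic` items (semantic failures),
        empty for pure parse errors.
    """

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = list(diagnostics or [])


class ImpossibleEvidenceError(NutriDSSError):
    """Observed evidence has probability zero under the network.

    Carries the offending evidence set so downstream reports can record it.
    """

    def __init__(self, evidence: dict):
        super().__init__(f"evidence has zero probability under the network: {dict(evidence)!r}")
        self.evidence = dict(evidence)


class CapacityError(NutriDSSError):
    """The brute-force enumeration guard was exceeded."""


class UnitMismatchError(NutriDSSError):
    """A lab value was supplied in a unit other than the declared one."""

    def __init__(self, marker: str, expected_unit: str, got_unit: str):
        super().__init__(
            f"marker {marker!r}: expected unit {expected_unit!r}, got {got_unit!r} "
            "(no silent conversion is performed)"
        )
        self.marker = marker
        self.expected_unit = expected_unit
        self.got_unit = got_unit


class KnowledgeBaseError(NutriDSSError):
    """A knowledge-base directory is incomplete or inconsistent."""


class AlignmentError(NutriDSSError):
    """Two label sets do not cover the same (case, diagnosis) keys."""

    def __init__(self, missing_in_a: set, missing_in_b: set):
        super().__init__(
            f"label sets are not aligned: {len(missing_in_a)} key(s) absent from the first, "
            f"{len(missing_in_b)} absent from the second"
        )
        self.missing_in_a = set(missing_in_a)
        self.missing_in_b = set(missing_in_b)


class ClassBalanceError(NutriDSSError):
    """An ROC/AUC quantity was requested without both classes represented."""


class IncompleteConsensusError(NutriDSSError):
    """A consensus gold standard still contains unadjudicated ties."""

    def __init__(self, pending: set):
        super().__init__(
            f"{len(pending)} consensus entr(y/ies) need adjudication before the "
            f"gold standard is complete: {sorted(pending)!r}"
        )
        self.pending = set(pending)


class ConfigError(NutriDSSError):
    """A cohort configuration is internally inconsistent."""
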