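"""scikit-learn–style estimators over the inference engine.

The diagnostic pipeline is naturally transform/predict shaped, so two thin
estimators expose it to sklearn composition (``Pipeline``, ``clone``,
``get_params``/``set_params``):

* :class:`CaseDiscretizer` — a transformer turning raw patient records into
  a DataFrame of discrete evidence states (NaN = unobserved);
* :class:`BayesianNetworkClassifier` — a classifier computing exact
  posteriors over one query node of a *fixed*, expert-specified network.
  ``fit`` validates and freezes the network; there is no parameter learning
  (the knowledge base is authored, not estimated).

>>> pipe = Pipeline([("discretize", CaseDiscretizer()),
...                  ("clf", BayesianNetworkClassifier(net, query="iron_deficiency_anemia"))])
... # doctest: +SKIP
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .engine import LABEL_PRIORITY
from .errors import NutriDSSError
from .inference import map_state, posterior
from .knowledge import (
    PatientCase,
    ReferenceRanges,
    default_ranges,
    discretize_case,
)
from .network import BayesNetwork, validate_network

__all__ = ["CaseDiscretizer", "BayesianNetworkClassifier"]


def _as_cases(X) -> list[PatientCase]:
    cases = []
    for item in X:
        if isinstance(item, PatientCase):
            cases.append(item)
        elif isinstance(item, Mapping):
            cases.append(PatientCase.model_validate(item))
        else:
            raise NutriDSSError(f"cannot interpret {type(item).__name__} as a patient case")
    return cases


class CaseDiscretizer(TransformerMixin, BaseEstimator):
    """Transform raw patient cases into discrete evidence states.

    Parameters
    ----------
    ranges : ReferenceRanges, optional
        Reference intervals; the shipped defaults when ``None``.

    ``transform`` accepts an iterable of :class:`PatientCase` (or mappings
    validating as one) and returns a DataFrame indexed by patient id with
    one column per evidence node; missing measurements are NaN.
    """

    def __init__(self, ranges: ReferenceRanges | None = None):
        self.ranges = ranges

    def fit(self, X=None, y=None):
        self.ranges_ = self.ranges if self.ranges is not None else default_ranges()
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "ranges_"):
            self.fit()
        rows = []
        index = []
        for case in _as_cases(X):
            rows.append(discretize_case(case, self.ranges_))
            index.append(case.patient_id)
        return pd.DataFrame(rows, index=index, dtype=object)


class BayesianNetworkClassifier(ClassifierMixin, BaseEstimator):
    """Exact-posterior classifier over one node of a fixed Bayesian network.

    Parameters
    ----------
    network : BayesNetwork
        The (expert-specified) network; validated at ``fit``.
    query : str
        The node whose posterior is predicted.
    tie_priority : sequence of str, optional
        State order resolving exact posterior ties in :meth:`predict`;
        defaults to the clinical priority for diagnosis nodes, else the
        node's declared state order.

    Attributes
    ----------
    classes_ : ndarray of shape (n_states,)
        The query node's states, in declared order.
    network_ : BayesNetwork
        The validated network used for inference.
    """

    def __init__(
        self,
        network: BayesNetwork | None = None,
        query: str | None = None,
        tie_priority: Sequence[str] | None = None,
    ):
        self.network = network
        self.query = query
        self.tie_priority = tie_priority

    def fit(self, X=None, y=None):
        """Validate and freeze the network (no parameters are learned)."""
        if self.network is None or self.query is None:
            raise NutriDSSError("BayesianNetworkClassifier needs both `network` and `query`")
        diagnostics = validate_network(self.network)
        if diagnostics:
            raise NutriDSSError(
                f"network failed validation with {len(diagnostics)} finding(s): "
                + "; ".join(str(d) for d in diagnostics)
            )
        node = self.network.node(self.query)
        self.network_ = self.network
        self.classes_ = np.asarray(node.states, dtype=object)
        if self.tie_priority is not None:
            self.tie_priority_ = tuple(self.tie_priority)
        elif set(node.states) == set(LABEL_PRIORITY):
            self.tie_priority_ = LABEL_PRIORITY
        else:
            self.tie_priority_ = tuple(node.states)
        return self

    def _evidence_rows(self, X) -> list[dict[str, str]]:
        known = set(self.network_.nodes) - {self.query}
        rows: list[dict[str, str]] = []
        if isinstance(X, pd.DataFrame):
            for _, row in X.iterrows():
                rows.append(
                    {c: row[c] for c in X.columns if c in known and isinstance(row[c], str)}
                )
        else:
            for item in X:
                if not isinstance(item, Mapping):
                    raise NutriDSSError("X must be a DataFrame or an iterable of evidence mappings")
                rows.append({k: v for k, v in item.items() if k in known and isinstance(v, str)})
        return rows

    def predict_proba(self, X) -> np.ndarray:
        """Posterior P(query | evidence) per row, columns aligned with ``classes_``."""
        if not hasattr(self, "network_"):
            raise NutriDSSError("classifier is not fitted; call fit() first")
        out = np.empty((0, len(self.classes_)))
        posts = []
        for evidence in self._evidence_rows(X):
            post = posterior(self.network_, self.query, evidence)
            posts.append([post.distribution[s] for s in self.classes_])
        if posts:
            out = np.asarray(posts)
        return out

    def predict(self, X) -> np.ndarray:
        """Maximum-posterior state per row (ties broken by ``tie_priority_``)."""
        if not hasattr(self, "network_"):
            raise NutriDSSError("classifier is not fitted; call fit() first")
        labels = []
        for evidence in self._evidence_rows(X):
            post = posterior(self.network_, self.query, evidence)
            labels.append(map_state(post, self.tie_priority_))
        return np.asarray(labels, dtype=object)

    def score_positive(self, X) -> np.ndarray:
        """P(present) + P(at_risk) per row (diagnosis nodes only)."""
        proba = self.predict_proba(X)
        idx = [list(self.classes_).index(s) for s in ("present", "at_risk")]
        return proba[:, idx].sum(axis=1)
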