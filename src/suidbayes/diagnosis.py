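"""Diagnostic support models for SUID classification.

Three Bayesian-network models estimate the probability that a sudden
unexpected infant death is SIDS rather than another internal or external
cause, from the 16 pre-autopsy risk factors:

* Model 1 — causal orientation (risk factors lead to the outcome);
  outcome states SIDS / non-SIDS.
* Model 2 — retrospective orientation (outcome explains the observed
  factor pattern); outcome states SIDS / non-SIDS.
* Model 3 — retrospective, with the outcome split into SIDS / internal /
  external causes.

Default network structures are shipped as editable JSON assets; the whole
pipeline is structure-agnostic.  The estimator follows the scikit-learn
protocol (``fit`` on a factor table plus labels, ``predict_proba`` /
``predict`` on new cases).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import datasets
from .bayesnet import (
    NEUTRAL,
    BayesNet,
    NetworkError,
    NetworkSpec,
    estimate_cpts,
    posterior_ve,
)
from .coding import (
    DIAGNOSIS_COLLAPSE,
    FACTOR_NAMES,
    NOT_APPLICABLE,
    UNKNOWN,
)
from .cohort import CaseRecord, Cohort


def build_model(model_id: int, structure: Optional[dict] = None) -> NetworkSpec:
    """Return the network structure for a diagnostic model.

    ``structure`` overrides the shipped JSON asset (same schema: ``nodes``
    with ``name``/``states``, ``edges`` as [parent, child] pairs).
    """
    doc = structure if structure is not None else datasets.model_structure(model_id)
    spec = NetworkSpec.from_dicts(doc["nodes"], doc["edges"])
    problems = spec.validate()
    if problems:
        raise NetworkError("; ".join(problems))
    if "diagnosis" not in spec.node_names:
        raise NetworkError("structure lacks an outcome ('diagnosis') node")
    return spec


class DiagnosticModel(BaseEstimator, ClassifierMixin):
    """Bayesian-network classifier over the 16-factor case coding.

    Parameters
    ----------
    model_id : {1, 2, 3}
        Which shipped structure/orientation to use.
    alpha : float
        Additive (Laplace) smoothing for CPT rows.  The default 0 mirrors
        pure count-based tables, which contain deterministic rows (every
        SIDS training death was sleep-related); set ``alpha > 0`` to keep
        all posteriors strictly inside (0, 1).
    unknown_policy : {"as_state", "exclude"}
        Whether ``unknown`` is modelled as an explicit state (the training
        tables report it as a category) or excluded from counting and
        marginalized at prediction time.
    structure : dict, optional
        Overriding network structure document.
    """

    def __init__(self, model_id: int = 3, alpha: float = 0.0,
                 unknown_policy: str = "as_state",
                 structure: Optional[dict] = None):
        self.model_id = model_id
        self.alpha = alpha
        self.unknown_policy = unknown_policy
        self.structure = structure

    # --- fitting -------------------------------------------------------

    def fit(self, X: pd.DataFrame, y: Sequence[str]) -> "DiagnosticModel":
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        records = []
        ids = X["case_id"] if "case_id" in X.columns else [f"c{i}" for i in range(len(X))]
        for (_, row), cid, label in zip(X.iterrows(), ids, y):
            factors = {f: row[f] for f in FACTOR_NAMES}
            records.append(CaseRecord(str(cid), factors, label))
        return self.fit_cohort(Cohort(records))

    def fit_cohort(self, cohort: Cohort) -> "DiagnosticModel":
        if any(r.diagnosis is None for r in cohort):
            raise ValueError("training cohort must be fully labelled")
        self.spec_ = build_model(self.model_id, self.structure)
        outcome_states = self.spec_.states("diagnosis")
        label_map = DIAGNOSIS_COLLAPSE if "non_SIDS" in outcome_states else None
        spec = self.spec_
        if self.unknown_policy == "exclude":
            spec = _drop_missing_states(spec)
            self.spec_ = spec
        self.net_ = estimate_cpts(spec, cohort, alpha=self.alpha,
                                  unknown_policy=self.unknown_policy,
                                  label_map=label_map)
        self.classes_ = np.asarray(outcome_states)
        return self

    # --- prediction ----------------------------------------------------

    def _evidence(self, case: Union[CaseRecord, Mapping[str, str]]) -> dict:
        factors = case.factors if isinstance(case, CaseRecord) else dict(case)
        ev = {}
        for node in self.spec_.node_names:
            if node == "diagnosis" or node not in factors:
                continue
            v = factors[node]
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            if v in (UNKNOWN, NOT_APPLICABLE) and v not in self.spec_.states(node):
                continue  # exclude policy: marginalize missing values
            ev[node] = v
        return ev

    def predict_case(self, case: Union[CaseRecord, Mapping[str, str]]) -> dict[str, float]:
        """Posterior over outcome states for one case."""
        posterior = posterior_ve(self.net_, "diagnosis", self._evidence(case))
        return posterior

    def predict_proba(self, X: Union[pd.DataFrame, Iterable[CaseRecord]]) -> np.ndarray:
        cases = _as_cases(X)
        out = np.empty((len(cases), len(self.classes_)))
        for i, case in enumerate(cases):
            post = self.predict_case(case)
            out[i] = [post[s] for s in self.classes_]
        return out

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        # ties broken by declared state order (first argmax)
        return self.classes_[np.argmax(proba, axis=1)]


def _drop_missing_states(spec: NetworkSpec) -> NetworkSpec:
    """Remove literal unknown/NA states for the exclude policy."""
    nodes = []
    for name, states in spec.nodes:
        kept = tuple(s for s in states if s not in (UNKNOWN, NOT_APPLICABLE))
        nodes.append((name, kept))
    return NetworkSpec(tuple(nodes), spec.edges)


def _as_cases(X) -> list:
    if isinstance(X, pd.DataFrame):
        return [row for _, row in X.iterrows()]
    return list(X)


# --- thin functional wrappers ------------------------------------------

def train(model_id: int, cohort: Cohort, *, alpha: float = 0.0,
          unknown_policy: str = "as_state",
          structure: Optional[dict] = None) -> DiagnosticModel:
    return DiagnosticModel(model_id, alpha, unknown_policy, structure).fit_cohort(cohort)


def diagnose(model: DiagnosticModel, case: CaseRecord) -> dict:
    """One report row: posteriors, most probable state, match vs expert label."""
    post = model.predict_case(case)
    states = list(model.classes_)
    best = states[int(np.argmax([post[s] for s in states]))]
    row = {"case_id": case.case_id, "model": model.model_id}
    row.update({f"p_{s}": post[s] for s in states})
    row["predicted"] = best
    expert = case.diagnosis
    if expert is not None:
        collapsed = DIAGNOSIS_COLLAPSE.get(expert, expert) if "non_SIDS" in states else expert
        row["expert"] = expert
        row["match"] = best == collapsed
    return row


def validate(models: Sequence[DiagnosticModel], cases: Sequence[CaseRecord]) -> pd.DataFrame:
    """Per-model, per-case validation report with concordance flags."""
    if not models:
        raise ValueError("no models supplied")
    if not cases:
        raise ValueError("no validation cases supplied")
    rows = [diagnose(m, c) for m in models for c in cases]
    return pd.DataFrame(rows)


def concordance(report: pd.DataFrame) -> pd.DataFrame:
    """Matches per model (overall and among expert-SIDS cases)."""
    out = []
    for model, grp in report.groupby("model"):
        sids = grp[grp["expert"] == "SIDS"]
        out.append({"model": model,
                    "n_cases": len(grp),
                    "n_match": int(grp["match"].sum()),
                    "n_sids_cases": len(sids),
                    "n_sids_match": int(sids["match"].sum())})
    return pd.DataFrame(out)
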