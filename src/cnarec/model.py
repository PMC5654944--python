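"""Three-phase voting classifier with a derived "unidentifiable" class.

The predictor distinguishes three classes of patients — recurrence/metastasis
(``REC``), no recurrence (``NOREC``), and ``UNID`` ("unidentifiable") — with
three pairwise maximum-margin classifiers combined by one-vs-one voting:

* phase 1: REC vs NOREC,
* phase 2: NOREC vs UNID,
* phase 3: REC vs UNID.

``UNID`` is not observed in the clinical data; it is *derived* during
training: repeated balanced phase-1 rounds are run on the original binary
labels, per-patient held-out misclassification rates are accumulated, and
patients who are frequently and systematically misclassified (rate >= theta
over enough held-out rounds) are relabelled ``UNID``. The working hypothesis
is that these are under-followed patients whose genomic profile matches the
recurrence class although no recurrence was (yet) recorded.

Each pairwise classifier is a linear soft-margin SVM (C = 1.0 by default) on
its own task-specific subset of bins selected by bootstrap Gini importance.
With only ~6 ternary features and ~100 patients a nonlinear kernel is not
justifiable; the linear machines also keep the model exactly serialisable
(coefficients + intercept) without pickling.

The module exposes both the individual operations (:func:`phase1_trace`,
:func:`derive_unidentifiable`, :func:`train_three_phase`, :func:`vote`,
:func:`predict`) and a statsmodels-style pair
:class:`CNARecurrenceModel` / :class:`CNARecurrenceResults` that runs the
whole training chain.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .segments import NOREC, REC, UNID
from .selection import SelectionConfig, select_features

logger = logging.getLogger(__name__)

__all__ = [
    "TASKS",
    "PairwiseLinearSVM",
    "MisclassificationTrace",
    "ThreePhaseModel",
    "phase1_trace",
    "derive_unidentifiable",
    "train_three_phase",
    "vote",
    "predict",
    "CNARecurrenceModel",
    "CNARecurrenceResults",
]

FORMAT_VERSION = 1
_MAX_SEED = 2**31 - 1

# Task order mirrors the three phases.
TASKS: tuple[tuple[str, str], ...] = ((REC, NOREC), (NOREC, UNID), (REC, UNID))
TASK_NAMES: tuple[str, ...] = ("rec_vs_norec", "norec_vs_unid", "rec_vs_unid")


class PairwiseLinearSVM:
    """A linear soft-margin SVM for one class pair, stored as (w, b).

    Fitting delegates to :class:`sklearn.svm.SVC` with a linear kernel and
    class-balanced error weights (each class contributes equally to the hinge
    loss regardless of its size — the classifier is trained on a balanced set
    in effect, without discarding patients). The learned hyperplane is kept
    explicitly so models serialise to plain JSON and prediction is a dot
    product.
    """

    def __init__(self, C: float = 1.0):
        self.C = float(C)
        self.classes_: tuple[str, str] | None = None
        self.coef_: np.ndarray | None = None
        self.intercept_: float | None = None

    def fit(self, X: np.ndarray, y: Sequence[str]) -> "PairwiseLinearSVM":
        y = np.asarray(y, dtype=object)
        classes = sorted(set(y))
        if len(classes) != 2:
            raise ValueError(f"pairwise classifier needs exactly two classes, got {classes}")
        svc = SVC(kernel="linear", C=self.C, class_weight="balanced")
        svc.fit(np.asarray(X, dtype=float), y)
        self.classes_ = (str(svc.classes_[0]), str(svc.classes_[1]))
        self.coef_ = svc.coef_.ravel().astype(float)
        self.intercept_ = float(svc.intercept_[0])
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("classifier is not fitted")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_function(X)
        neg, pos = self.classes_
        return np.where(d > 0, pos, neg).astype(object)

    def to_dict(self) -> dict:
        return {
            "C": self.C,
            "classes": list(self.classes_),
            "coef": [float(c) for c in self.coef_],
            "intercept": self.intercept_,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PairwiseLinearSVM":
        obj = cls(C=d["C"])
        obj.classes_ = tuple(d["classes"])
        obj.coef_ = np.asarray(d["coef"], dtype=float)
        obj.intercept_ = float(d["intercept"])
        return obj


@dataclass
class MisclassificationTrace:
    """Per-patient held-out misclassification bookkeeping from phase-1 rounds."""

    table: pd.DataFrame  # columns: times_held_out, times_misclassified, misclassification_rate
    n_rounds: int
    seed: int

    @property
    def rates(self) -> pd.Series:
        return self.table["misclassification_rate"]


def phase1_trace(
    X: pd.DataFrame,
    y: pd.Series,
    n_rounds: int = 500,
    split_fraction: float = 0.7,
    seed: int = 0,
    features: Sequence[str] | None = None,
    C: float = 1.0,
) -> MisclassificationTrace:
    """Accumulate per-patient phase-1 (REC vs NOREC) misclassification rates.

    Each round draws a balanced training subsample — ``floor(split_fraction x
    minority size)`` patients per class, without replacement — trains the
    phase-1 linear SVM on *features* (all columns of *X* by default) and
    classifies every held-out patient, counting per-patient misclassifications.
    Deterministic given *seed*.
    """
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must be in (0, 1)")
    y = pd.Series(np.asarray(y, dtype=object), index=X.index)
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError(f"phase-1 trace needs exactly two classes, got {classes}")
    cols = list(X.columns) if features is None else list(features)
    missing = [c for c in cols if c not in X.columns]
    if missing:
        raise KeyError(f"feature column(s) missing from matrix: {missing}")
    Xf = X[cols].values.astype(float)
    rng = np.random.default_rng(seed)
    n = len(X)
    held_out = np.zeros(n, dtype=int)
    missed = np.zeros(n, dtype=int)
    class_idx = {c: np.flatnonzero(y.values == c) for c in classes}
    m = int(np.floor(split_fraction * min(len(v) for v in class_idx.values())))
    for _ in range(n_rounds):
        if m < 1:
            logger.warning("degenerate split (empty training class); round skipped")
            continue
        train = np.concatenate(
            [rng.choice(class_idx[c], size=m, replace=False) for c in classes]
        )
        test = np.setdiff1d(np.arange(n), train)
        if test.size == 0:
            logger.warning("degenerate split (no held-out patients); round skipped")
            continue
        clf = PairwiseLinearSVM(C=C).fit(Xf[train], y.values[train])
        pred = clf.predict(Xf[test])
        held_out[test] += 1
        missed[test] += (pred != y.values[test]).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(held_out > 0, missed / np.maximum(held_out, 1), 0.0)
    table = pd.DataFrame(
        {
            "times_held_out": held_out,
            "times_misclassified": missed,
            "misclassification_rate": rate,
        },
        index=X.index,
    )
    return MisclassificationTrace(table=table, n_rounds=n_rounds, seed=seed)


def derive_unidentifiable(
    trace: MisclassificationTrace,
    labels: pd.Series,
    theta: float = 0.5,
    min_held_out: int = 20,
) -> tuple[pd.Series, list[str]]:
    """Relabel systematically misclassified patients as ``UNID``.

    A patient becomes ``UNID`` when held out at least *min_held_out* times
    with misclassification rate >= *theta*; all others keep their original
    REC/NOREC label. Raising *theta* never adds UNID patients.

    Returns the three-class label series and the list of UNID patient ids.
    Raises if every patient would be relabelled (degenerate model).
    """
    if not 0 < theta <= 1:
        raise ValueError("theta must be in (0, 1]")
    labels = pd.Series(np.asarray(labels, dtype=object), index=trace.table.index)
    flag = (trace.table["times_held_out"] >= min_held_out) & (
        trace.table["misclassification_rate"] >= theta
    )
    if flag.all():
        raise ValueError("every patient relabelled UNID; model is degenerate")
    labels3 = labels.copy()
    labels3[flag] = UNID
    return labels3, list(trace.table.index[flag])


@dataclass
class ThreePhaseModel:
    """The trained three-class predictor: three pairwise linear SVMs plus
    their task-specific feature lists; ties in voting resolve to UNID."""

    classifiers: dict[str, PairwiseLinearSVM]
    features: dict[str, list[str]]
    classes: tuple[str, str, str] = (REC, NOREC, UNID)
    tie_class: str = UNID

    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "classes": list(self.classes),
            "tie_class": self.tie_class,
            "tasks": {
                name: {
                    "features": self.features[name],
                    "classifier": self.classifiers[name].to_dict(),
                }
                for name in TASK_NAMES
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ThreePhaseModel":
        if d.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {d.get('format_version')!r}")
        return cls(
            classifiers={n: PairwiseLinearSVM.from_dict(d["tasks"][n]["classifier"])
                         for n in TASK_NAMES},
            features={n: list(d["tasks"][n]["features"]) for n in TASK_NAMES},
            classes=tuple(d["classes"]),
            tie_class=d["tie_class"],
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "ThreePhaseModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train_three_phase(
    X: pd.DataFrame,
    labels3: pd.Series,
    features_per_task: Mapping[str, Sequence[str]],
    C: float = 1.0,
) -> ThreePhaseModel:
    """Train the three pairwise classifiers on their task-specific features.

    *features_per_task* maps task names (``rec_vs_norec``, ``norec_vs_unid``,
    ``rec_vs_unid``) to nonempty bin-name lists; each classifier sees only the
    patients of its two classes, restricted to its columns.
    """
    labels3 = pd.Series(np.asarray(labels3, dtype=object), index=X.index)
    counts = labels3.value_counts()
    for cls_name in (REC, NOREC, UNID):
        if counts.get(cls_name, 0) < 3:
            raise ValueError(
                f"class {cls_name} has {counts.get(cls_name, 0)} patient(s); need >= 3"
            )
    classifiers: dict[str, PairwiseLinearSVM] = {}
    features: dict[str, list[str]] = {}
    for (a, b), name in zip(TASKS, TASK_NAMES):
        cols = list(features_per_task[name])
        if not cols:
            raise ValueError(f"task {name} has an empty feature list")
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise KeyError(f"task {name}: feature column(s) missing from matrix: {missing}")
        mask = labels3.isin([a, b]).values
        clf = PairwiseLinearSVM(C=C).fit(X.loc[mask, cols].values, labels3.values[mask])
        classifiers[name] = clf
        features[name] = cols
    return ThreePhaseModel(classifiers=classifiers, features=features)


def vote(responses: Sequence[str]) -> str:
    """Combine the three pairwise responses by one-vs-one max-wins voting.

    The class receiving two votes wins; the cyclic outcome (one vote for each
    class) resolves to ``UNID``. Total over all 8 response triples.
    """
    r1, r2, r3 = responses
    if r1 not in (REC, NOREC) or r2 not in (NOREC, UNID) or r3 not in (REC, UNID):
        raise ValueError(f"invalid response triple {tuple(responses)!r}")
    tally: dict[str, int] = {}
    for r in (r1, r2, r3):
        tally[r] = tally.get(r, 0) + 1
    best = max(tally.values())
    if best >= 2:
        winners = [c for c, k in tally.items() if k == best]
        return winners[0]
    return UNID


def predict(model: ThreePhaseModel, X_new: pd.DataFrame) -> pd.DataFrame:
    """Apply the three pairwise classifiers and combine their votes.

    Returns a DataFrame indexed like *X_new* with one column per task
    (the pairwise votes) and a ``final`` column. Deterministic; batch
    prediction equals per-row prediction.
    """
    all_needed = sorted({c for cols in model.features.values() for c in cols})
    missing = [c for c in all_needed if c not in X_new.columns]
    if missing:
        raise KeyError(f"feature column(s) missing from matrix: {missing}")
    out = pd.DataFrame(index=X_new.index)
    for name in TASK_NAMES:
        clf = model.classifiers[name]
        out[name] = clf.predict(X_new[model.features[name]].values)
    out["final"] = [
        vote((out[TASK_NAMES[0]].iloc[i], out[TASK_NAMES[1]].iloc[i], out[TASK_NAMES[2]].iloc[i]))
        for i in range(len(out))
    ]
    return out


# ---------------------------------------------------------------------------
# statsmodels-style Model / Results
# ---------------------------------------------------------------------------


class CNARecurrenceModel:
    """Three-phase copy-number recurrence model, built from a bin matrix and
    binary outcome labels.

    Parameters
    ----------
    bin_matrix
        Patients x bins ternary feature matrix (see
        :func:`cnarec.binning.assign_to_bins`).
    outcome
        Per-patient REC/NOREC labels, aligned with ``bin_matrix.index``.
    selection
        Bootstrap Gini selection configuration (applied independently per
        pairwise task, since each phase has its own informative regions).
    n_rounds, split_fraction
        Phase-1 misclassification-trace protocol.
    theta, min_held_out
        UNID derivation thresholds: relabel when the held-out
        misclassification rate reaches ``theta`` over at least
        ``min_held_out`` held-out rounds.
    C
        Soft-margin constant of the linear SVMs.
    scheme
        Optional :class:`cnarec.binning.BinScheme`, kept for reporting
        (cytoband labels) and for harmonising external cohorts.
    """

    def __init__(
        self,
        bin_matrix: pd.DataFrame,
        outcome: pd.Series | Mapping[str, str],
        *,
        selection: SelectionConfig = SelectionConfig(),
        n_rounds: int = 500,
        split_fraction: float = 0.7,
        theta: float = 0.5,
        min_held_out: int = 20,
        C: float = 1.0,
        scheme=None,
    ):
        self.bin_matrix = bin_matrix
        outcome = pd.Series(dict(outcome)) if isinstance(outcome, Mapping) else pd.Series(outcome)
        self.outcome = outcome.reindex(bin_matrix.index).astype(object)
        if self.outcome.isna().any():
            missing = list(self.outcome.index[self.outcome.isna()])
            raise ValueError(f"outcome missing for patient(s): {missing[:5]}")
        self.selection = selection
        self.n_rounds = n_rounds
        self.split_fraction = split_fraction
        self.theta = theta
        self.min_held_out = min_held_out
        self.C = C
        self.scheme = scheme

    @classmethod
    def from_cohort(cls, cohort, cytobands=None, min_overlap_fraction: float = 0.0, **kwargs):
        """Build the model straight from a :class:`~cnarec.segments.Cohort`:
        derives the bin scheme from the cohort's mean alteration sizes,
        assigns segments to bins, and pulls outcomes from the clinical records."""
        from .binning import assign_to_bins, bin_scheme_from_cohort

        scheme = bin_scheme_from_cohort(cohort, cytobands)
        matrix = assign_to_bins(cohort, scheme, min_overlap_fraction)
        outcome = pd.Series(cohort.outcomes())
        return cls(matrix, outcome, scheme=scheme, **kwargs)

    def fit(self, seed: int = 0) -> "CNARecurrenceResults":
        """Run the full training chain.

        1. select phase-1 features on the original REC/NOREC labels;
        2. trace phase-1 held-out misclassification over balanced rounds;
        3. derive the UNID class from the trace;
        4. re-select features for each of the three pairwise tasks on the
           three-class labels;
        5. train the three pairwise linear SVMs.
        """
        rng = np.random.default_rng(seed)
        s_sel1, s_trace, *s_tasks = (int(rng.integers(_MAX_SEED)) for _ in range(5))
        X, y = self.bin_matrix, self.outcome

        phase1_features, phase1_importance = select_features(
            X, y, SelectionConfig(**{**self.selection.__dict__, "seed": s_sel1})
        )
        trace = phase1_trace(
            X, y,
            n_rounds=self.n_rounds,
            split_fraction=self.split_fraction,
            seed=s_trace,
            features=phase1_features,
            C=self.C,
        )
        labels3, unid = derive_unidentifiable(trace, y, self.theta, self.min_held_out)

        features_per_task: dict[str, list[str]] = {}
        importances: dict[str, pd.DataFrame] = {"phase1_screen": phase1_importance}
        for (a, b), name, s in zip(TASKS, TASK_NAMES, s_tasks):
            mask = labels3.isin([a, b]).values
            y_task = (labels3[mask] == a).astype(int)
            feats, table = select_features(
                X.loc[mask], y_task,
                SelectionConfig(**{**self.selection.__dict__, "seed": s}),
            )
            features_per_task[name] = feats
            importances[name] = table
        tpm = train_three_phase(X, labels3, features_per_task, C=self.C)
        return CNARecurrenceResults(
            model_spec=self,
            model=tpm,
            labels3=labels3,
            unid_patients=unid,
            trace=trace,
            features_per_task=features_per_task,
            importances=importances,
            seed=seed,
        )


@dataclass
class CNARecurrenceResults:
    """Fitted three-phase model plus the artefacts of its derivation."""

    model_spec: CNARecurrenceModel
    model: ThreePhaseModel
    labels3: pd.Series
    unid_patients: list[str]
    trace: MisclassificationTrace
    features_per_task: dict[str, list[str]]
    importances: dict[str, pd.DataFrame]
    seed: int
    _evaluation: object = field(default=None, repr=False)

    def predict(self, X_new: pd.DataFrame | None = None) -> pd.DataFrame:
        """Votes and final class for new patients (training matrix by default)."""
        X = self.model_spec.bin_matrix if X_new is None else X_new
        return predict(self.model, X)

    def evaluate(self, config=None):
        """Repeated balanced-split performance estimate (see
        :func:`cnarec.evaluation.evaluate`); the report is cached."""
        from .evaluation import EvalConfig, evaluate

        config = config or EvalConfig()
        report = evaluate(
            self.model_spec.bin_matrix, self.labels3, self.features_per_task,
            config, C=self.model_spec.C,
        )
        self._evaluation = report
        return report

    def external_validate(self, external_matrix: pd.DataFrame, external_labels: pd.Series):
        """Single-pass validation on an external, harmonised cohort."""
        from .evaluation import external_validate

        return external_validate(self.model, external_matrix, external_labels)

    def _bin_display(self, name: str) -> str:
        if self.model_spec.scheme is not None:
            try:
                b = self.model_spec.scheme.by_name(name)
                if b.label != name:
                    return f"{b.label} ({name})"
            except KeyError:
                pass
        return name

    def summary(self) -> str:
        """Human-readable fit summary in the spirit of a statsmodels results
        table: class composition, UNID derivation, per-phase feature lists."""
        counts = self.labels3.value_counts()
        lines = [
            "Three-Phase CNA Recurrence Model",
            "=" * 64,
            f"patients: {len(self.labels3)}   seed: {self.seed}",
            f"classes:  REC={counts.get(REC, 0)}  NOREC={counts.get(NOREC, 0)}  "
            f"UNID={counts.get(UNID, 0)} (derived)",
            f"UNID rule: rate >= {self.model_spec.theta} over >= "
            f"{self.model_spec.min_held_out} held-out rounds "
            f"({self.trace.n_rounds} rounds, {self.model_spec.split_fraction:.0%} balanced train)",
            f"pairwise classifiers: linear SVM, C={self.model_spec.C}",
            "-" * 64,
        ]
        phase_title = {
            "rec_vs_norec": "phase 1 (REC | NOREC)",
            "norec_vs_unid": "phase 2 (NOREC | UNID)",
            "rec_vs_unid": "phase 3 (REC | UNID)",
        }
        for name in TASK_NAMES:
            lines.append(f"{phase_title[name]}:")
            for feat in self.features_per_task[name]:
                imp = self.importances[name].loc[feat, "mean_importance"]
                lines.append(f"    {self._bin_display(feat):<40s} importance {imp:.4f}")
        if self._evaluation is not None:
            lines.append("-" * 64)
            lines.append(self._evaluation.to_text())
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Self-describing archive: classifiers, feature lists, the UNID
        thresholds, and the bin-scheme reference (per-chromosome widths) when
        available. Loadable with :meth:`ThreePhaseModel.load` (extra keys are
        ignored)."""
        d = self.model.to_dict()
        d["unid_thresholds"] = {
            "theta": self.model_spec.theta,
            "min_held_out": self.model_spec.min_held_out,
            "n_rounds": self.trace.n_rounds,
        }
        if self.model_spec.scheme is not None:
            scheme = self.model_spec.scheme
            d["scheme"] = {
                "build": scheme.build.name,
                "mean_alt_size": {c: int(w) for c, w in scheme.mean_alt_size.items()},
            }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)
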