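"""Classifier harness and the OCRI2 risk index.

The oral cancer risk index 2 (OCRI2) is the predicted probability that a
sample is squamous-cell carcinoma, computed from the 10-interval peak
features by a classifier trained on normal (``n``) and cancer (``c``) rows
only — leukoplakia (``k``) rows are *never* fitted, only scored.  For the
forest models the probability is the fraction of trees voting cancer; a
cut-off of 0.5 (inclusive on the high side) separates high- from low-risk
cases.

Five model kinds are supported:

``rf``
    Random forest (the production model): 500 trees, features-per-split
    tuned over {2, 6, 10}.
``cf``
    Extremely randomized forest baseline (split thresholds drawn at random
    rather than exhaustively optimized), standing in for a
    conditional-inference-style forest.
``svm`` / ``svmfull``
    Radial-basis SVM with cost tuned over {0.25, 0.5, 1}; ``svmfull``
    differs only in fitting on 100% of the training cohort instead of a
    70% optimization split.
``knn``
    k-nearest neighbours with k tuned over {5, 7, 9}, counts untransformed.

Hyperparameters are chosen by mean accuracy over 10-fold cross-validation
repeated 5 times (stratified), ties broken toward the earliest candidate in
grid order; everything is reproducible from the spec's seed.

Two entry points coexist: the spec-level functions
(:func:`split_optimization_holdout`, :func:`tune_and_train`,
:func:`compute_ocri2`, :func:`stratify_risk`, :func:`cross_examine`) and a
model/results pair (:class:`OCRI2Model` → :class:`OCRI2Results`) for
interactive use, mirroring the fit/results idiom of statistical modelling
libraries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.metrics import accuracy_score
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigurationError, Ocri2Error, StratificationError, TrainingError
from .evaluation import EvaluationReport, auc_rank, confusion_and_metrics
from .io import FeatureRow, FeatureTable

__all__ = [
    "MODEL_KINDS",
    "DEFAULT_CUTOFF",
    "ModelSpec",
    "TrainedModel",
    "RiskAssessment",
    "split_optimization_holdout",
    "tune_and_train",
    "compute_ocri2",
    "compute_ocri2_table",
    "stratify_risk",
    "assess_table",
    "cross_examine",
    "OCRI2Model",
    "OCRI2Results",
]

MODEL_KINDS = ("rf", "svm", "svmfull", "knn", "cf")

#: Arbitrary probability cut-off between high- and low-risk (inclusive high).
DEFAULT_CUTOFF = 0.5

_DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "rf": {"max_features": [2, 6, 10]},
    "cf": {"max_features": [2, 6, 10]},
    "svm": {"C": [0.25, 0.5, 1.0]},
    "svmfull": {"C": [0.25, 0.5, 1.0]},
    "knn": {"n_neighbors": [5, 7, 9]},
}

_N_TREES = 500


@dataclass(frozen=True)
class ModelSpec:
    """Everything needed to reproduce a model fit.

    Parameters
    ----------
    model_kind : str
        One of ``rf``, ``svm``, ``svmfull``, ``knn``, ``cf``.
    hyperparameter_grid : dict, optional
        Candidate values per hyperparameter name; defaults to the kind's
        standard three-point grid.  May include fixed estimator arguments
        as single-candidate entries (e.g. ``{"n_estimators": [100]}``).
    cv_folds, cv_repeats : int
        Cross-validation geometry for tuning (default 10 folds × 5 repeats).
    optimization_fraction : float
        Share of the training cohort used for tuning/fitting, the rest held
        out (default 0.7); forced to 1.0 for ``svmfull``.
    standardize : bool
        Standardize counts before KNN/SVM distance computations (off by
        default; counts are used untransformed).
    cv_n_estimators : int, optional
        Forest size used while *scoring* hyperparameter candidates in CV
        (default 100).  The winning candidate is always refit at the full
        forest size; candidate ranking for features-per-split is stable
        well below the final tree count, and the smaller scoring forests
        keep the 10-fold × 5-repeat grid search tractable on one core.
        Ignored for non-forest kinds; ``None`` scores at full size.
    seed : int
        Seed for the split, the CV resampling and the estimators.
    """

    model_kind: str = "rf"
    hyperparameter_grid: dict[str, list] | None = None
    cv_folds: int = 10
    cv_repeats: int = 5
    optimization_fraction: float = 0.7
    standardize: bool = False
    cv_n_estimators: int | None = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ConfigurationError(
                f"unknown model kind {self.model_kind!r}; choose from {MODEL_KINDS}"
            )
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")
        if self.cv_repeats < 1:
            raise ConfigurationError("cv_repeats must be >= 1")
        if not 0 < self.optimization_fraction <= 1:
            raise ConfigurationError("optimization_fraction must be in (0, 1]")
        if self.model_kind == "svmfull" and self.optimization_fraction != 1.0:
            object.__setattr__(self, "optimization_fraction", 1.0)
        if self.hyperparameter_grid is not None and not self.hyperparameter_grid:
            raise ConfigurationError("hyperparameter_grid must be non-empty when given")

    @property
    def grid(self) -> dict[str, list]:
        return dict(self.hyperparameter_grid or _DEFAULT_GRIDS[self.model_kind])

    def candidates(self) -> list[dict]:
        """Expand the grid into candidate parameter dicts, grid order preserved."""
        grid = self.grid
        names = list(grid)
        return [dict(zip(names, combo)) for combo in itertools.product(*(grid[n] for n in names))]


def _make_estimator(spec: ModelSpec, params: dict, *, scoring: bool = False):
    kind = spec.model_kind
    params = dict(params)
    if kind in ("rf", "cf"):
        default_trees = _N_TREES
        if scoring and spec.cv_n_estimators is not None:
            default_trees = spec.cv_n_estimators
        params.setdefault("n_estimators", default_trees)
    if kind == "rf":
        return RandomForestClassifier(random_state=spec.seed, bootstrap=True, **params)
    if kind == "cf":
        return ExtraTreesClassifier(random_state=spec.seed, **params)
    if kind in ("svm", "svmfull"):
        return SVC(kernel="rbf", gamma="scale", probability=True,
                   random_state=spec.seed, **params)
    if kind == "knn":
        return KNeighborsClassifier(**params)
    raise ConfigurationError(f"unknown model kind {kind!r}")  # pragma: no cover


@dataclass
class TrainedModel:
    """A fitted classifier plus the audit trail of its tuning.

    ``tuning_table`` has one row per hyperparameter candidate with the mean
    accuracy over all ``cv_repeats × cv_folds`` resample fits.
    """

    model_kind: str
    estimator: object
    selected_params: dict
    class_counts: dict[str, int]
    tuning_table: pd.DataFrame
    seed: int
    scaler: StandardScaler | None = None

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.scaler.transform(X) if self.scaler is not None else X

    def score_c(self, X: np.ndarray) -> np.ndarray:
        """Class-``c`` probability per row: tree-vote fraction for forests,
        the model's probability estimate otherwise."""
        if self.estimator is None:
            raise Ocri2Error("model is not trained")
        X = self._prepare(np.atleast_2d(X))
        est = self.estimator
        if self.model_kind in ("rf", "cf"):
            votes = np.zeros(X.shape[0])
            for tree in est.estimators_:
                pred = est.classes_[tree.predict(X).astype(int)]
                votes += pred == "c"
            return votes / len(est.estimators_)
        proba = est.predict_proba(X)
        c_col = list(est.classes_).index("c")
        return proba[:, c_col]


@dataclass(frozen=True)
class RiskAssessment:
    """One case's OCRI2 value and the risk class it implies."""

    case_id: str
    ocri2: float
    cutoff: float = DEFAULT_CUTOFF
    risk_class: str = field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.ocri2 <= 1:
            raise ValueError(f"OCRI2 must be in [0, 1], got {self.ocri2}")
        object.__setattr__(self, "risk_class", stratify_risk(self.ocri2, self.cutoff))


def split_optimization_holdout(
    table: FeatureTable, fraction: float, seed: int
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified random split of a feature table into optimization/holdout parts.

    Per class, ``round(fraction · class size)`` rows go to the first part;
    row order within each part follows the input table.  Deterministic given
    the seed.  ``fraction = 1.0`` puts everything in the first part.
    """
    if not 0 < fraction <= 1:
        raise ConfigurationError("fraction must be in (0, 1]")
    labels = table.labels
    by_class: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    for lab in ("c", "n"):
        if len(by_class.get(lab, [])) < 2:
            raise StratificationError(
                f"need >= 2 rows of class {lab!r} to stratify, got {len(by_class.get(lab, []))}"
            )
    rng = np.random.default_rng(seed)
    first_idx: set[int] = set()
    for lab in sorted(by_class):
        idx = np.array(by_class[lab])
        n_take = int(round(fraction * idx.size))
        take = rng.permutation(idx.size)[:n_take]
        first_idx.update(idx[take].tolist())
    first = FeatureTable([r for i, r in enumerate(table.rows) if i in first_idx])
    second = FeatureTable([r for i, r in enumerate(table.rows) if i not in first_idx])
    return first, second


def tune_and_train(train_table: FeatureTable, spec: ModelSpec) -> TrainedModel:
    """Grid-tune by repeated stratified CV, then refit the winner on all rows.

    ``train_table`` must contain only ``c``/``n`` rows with both classes
    present.  Mean accuracy over ``cv_repeats × cv_folds`` resamples ranks
    the candidates; exact ties go to the earliest candidate in grid order.
    """
    labels = train_table.labels
    bad = sorted(set(labels) - {"c", "n"})
    if bad:
        raise TrainingError(f"training rows must be labeled c or n; found {bad}")
    counts = {lab: labels.count(lab) for lab in ("c", "n")}
    if min(counts.values()) == 0:
        raise TrainingError(f"both classes required for training; class counts {counts}")
    smallest = min(counts.values())
    if spec.cv_folds > smallest:
        raise ConfigurationError(
            f"cv_folds={spec.cv_folds} exceeds the smallest class size {smallest}; "
            f"use cv_folds <= {smallest}"
        )

    X = train_table.counts_matrix().astype(float)
    y = np.array(labels)
    scaler = None
    if spec.standardize:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)

    cv = RepeatedStratifiedKFold(
        n_splits=spec.cv_folds, n_repeats=spec.cv_repeats, random_state=spec.seed
    )
    splits = list(cv.split(X, y))

    records = []
    best: tuple[float, int] | None = None  # (mean accuracy, -candidate index)
    candidates = spec.candidates()
    for ci, params in enumerate(candidates):
        accs = []
        for tr, te in splits:
            est = _make_estimator(spec, params, scoring=True)
            est.fit(X[tr], y[tr])
            accs.append(accuracy_score(y[te], est.predict(X[te])))
        mean_acc = float(np.mean(accs))
        records.append({**params, "mean_cv_accuracy": mean_acc, "n_resamples": len(splits)})
        if best is None or mean_acc > best[0]:  # strict: first candidate wins ties
            best = (mean_acc, ci)

    selected = candidates[best[1]]
    final = _make_estimator(spec, selected)
    final.fit(X, y)
    return TrainedModel(
        model_kind=spec.model_kind,
        estimator=final,
        selected_params=selected,
        class_counts=counts,
        tuning_table=pd.DataFrame(records),
        seed=spec.seed,
        scaler=scaler,
    )


def compute_ocri2(model: TrainedModel, row: FeatureRow) -> float:
    """OCRI2 of a single feature row — the model's cancer probability."""
    return float(model.score_c(np.array(row.counts, dtype=float)[None, :])[0])


def compute_ocri2_table(model: TrainedModel, table: FeatureTable) -> np.ndarray:
    """OCRI2 for every row of a feature table (vectorized)."""
    if len(table) == 0:
        return np.empty(0)
    return model.score_c(table.counts_matrix().astype(float))


def stratify_risk(ocri2: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """``high`` iff OCRI2 ≥ cutoff, else ``low``."""
    if not 0 <= ocri2 <= 1:
        raise ValueError(f"OCRI2 must be in [0, 1], got {ocri2}")
    return "high" if ocri2 >= cutoff else "low"


def assess_table(
    model: TrainedModel, table: FeatureTable, cutoff: float = DEFAULT_CUTOFF
) -> list[RiskAssessment]:
    """Score every row of a table into :class:`RiskAssessment` objects."""
    scores = compute_ocri2_table(model, table)
    return [
        RiskAssessment(row.case_id, float(s), cutoff)
        for row, s in zip(table.rows, scores)
    ]


def _evaluate_on(model: TrainedModel, test: FeatureTable, cutoff: float) -> EvaluationReport:
    test_cn = test.subset_labels(("c", "n"))
    if len(test_cn) == 0:
        raise Ocri2Error("no c/n rows to evaluate on")
    scores = compute_ocri2_table(model, test_cn)
    predicted = ["c" if s >= cutoff else "n" for s in scores]
    report = confusion_and_metrics(test_cn.labels, predicted)
    if len(set(test_cn.labels)) == 2:
        report.auc = auc_rank(scores, test_cn.labels)
    return report


def cross_examine(
    set_a: FeatureTable,
    set_b: FeatureTable,
    spec: ModelSpec,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[EvaluationReport, EvaluationReport]:
    """Two-cohort cross-examination with identical spec and seed both ways.

    Direction 1 trains on cohort A's ``c``/``n`` rows (after the spec's
    optimization split) and evaluates on all ``c``/``n`` rows of cohort B;
    direction 2 reverses the roles.  Leukoplakia rows are never fitted.
    """

    def one_direction(train: FeatureTable, test: FeatureTable) -> EvaluationReport:
        train_cn = train.subset_labels(("c", "n"))
        opt, _ = split_optimization_holdout(train_cn, spec.optimization_fraction, spec.seed)
        model = tune_and_train(opt, spec)
        return _evaluate_on(model, test, cutoff)

    return one_direction(set_a, set_b), one_direction(set_b, set_a)


# ---------------------------------------------------------------------------
# model/results presentation


class OCRI2Model:
    """Risk-index model over a feature table, in the fit/results idiom.

    Parameters
    ----------
    features : FeatureTable
        The training cohort's reconstructed features.  Only ``c``/``n``
        rows take part in fitting; any ``k`` rows are retained for scoring.
    spec : ModelSpec, optional
        Classifier kind, grids, CV geometry and seed (default: random
        forest with the standard grids).
    """

    def __init__(self, features: FeatureTable, spec: ModelSpec | None = None):
        self.features = features
        self.spec = spec or ModelSpec()

    @classmethod
    def from_cases(cls, cases, density_config=None, spec: ModelSpec | None = None) -> "OCRI2Model":
        """Build the model straight from case records (density → peaks → counts)."""
        from .peaks import reconstruct_dataset

        return cls(reconstruct_dataset(cases, density_config), spec)

    def fit(self, cutoff: float = DEFAULT_CUTOFF) -> "OCRI2Results":
        """Split, tune, refit, and evaluate on the internal holdout (if any)."""
        train_cn = self.features.subset_labels(("c", "n"))
        opt, holdout = split_optimization_holdout(
            train_cn, self.spec.optimization_fraction, self.spec.seed
        )
        trained = tune_and_train(opt, self.spec)
        holdout_report = _evaluate_on(trained, holdout, cutoff) if len(holdout) else None
        return OCRI2Results(self, trained, holdout_report, cutoff)


class OCRI2Results:
    """Results of an :class:`OCRI2Model` fit.

    Carries the fitted classifier, the tuning table, the internal holdout
    evaluation (``None`` when the whole cohort was used for fitting), and
    prediction/summary conveniences.
    """

    def __init__(
        self,
        model: OCRI2Model,
        trained: TrainedModel,
        holdout_report: EvaluationReport | None,
        cutoff: float,
    ):
        self.model = model
        self.trained = trained
        self.holdout_report = holdout_report
        self.cutoff = cutoff

    @property
    def tuning_table(self) -> pd.DataFrame:
        return self.trained.tuning_table

    @property
    def selected_params(self) -> dict:
        return self.trained.selected_params

    def predict(self, table: FeatureTable | None = None) -> pd.DataFrame:
        """OCRI2 and risk class per case (default: the model's own table)."""
        table = table if table is not None else self.model.features
        assessments = assess_table(self.trained, table, self.cutoff)
        return pd.DataFrame(
            {
                "case_id": [a.case_id for a in assessments],
                "ocri2": [a.ocri2 for a in assessments],
                "risk_class": [a.risk_class for a in assessments],
            }
        )

    def summary(self) -> str:
        """Human-readable account of the fit."""
        lines = [
            "OCRI2 model fit",
            "===============",
            f"model kind:        {self.trained.model_kind}",
            f"seed:              {self.trained.seed}",
            f"training classes:  {self.trained.class_counts}",
            f"selected params:   {self.trained.selected_params}",
            f"risk cut-off:      {self.cutoff} (OCRI2 >= cutoff -> high risk)",
            "",
            "tuning (mean accuracy over CV resamples):",
            self.tuning_table.to_string(index=False),
        ]
        if self.holdout_report is not None:
            r = self.holdout_report
            fmt = lambda v: "undefined" if v is None else f"{v:.4f}"
            lines += [
                "",
                "holdout evaluation:",
                f"  sensitivity {fmt(r.sensitivity)}  specificity {fmt(r.specificity)}",
                f"  PPV {fmt(r.ppv)}  NPV {fmt(r.npv)}  AUC {fmt(r.auc)}",
            ]
        return "\n".join(lines)
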