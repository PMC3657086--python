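"""Learner registry, project container and the combinatorial model matrix.

Models are built over the full cartesian product of data splits × descriptor
subsets × learner methods (filtered to learners that support the endpoint
type).  There is deliberately **no competitive selection**: every cell of the
matrix is attempted, failures are captured as data (status ``failed`` with a
reason) without aborting the run, and ranking lives only in the
validation-stage triage views.

The default learner registry mirrors a typical workbench battery: naive
Bayes, a recursive-partitioning tree and forest (categorical only), a neural
network and an SVM (both endpoint kinds) and two partial-least-squares
variants (continuous only; one with a fixed component count, one choosing
components by internal cross-validation).  All learners run with documented
library defaults — declared, not tuned.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier

from .descriptors import (
    DEFAULT_FOLD_WIDTH,
    DEFAULT_SUBSET_CONFIG,
    DescriptorMatrix,
    DescriptorSubset,
    compute_matrices,
    make_subsets,
)
from .prep import Dataset, PrepStep, dataset_digest, replay_prep
from .splitting import SplitAssignment, SplitSpec
from .validation import ValidationStats, stats_for_predictions


# ---------------------------------------------------------------------------
# Learner registry
# ---------------------------------------------------------------------------

@dataclass
class LearnerSpec:
    """A named learner with its endpoint support flags and parameters."""

    name: str
    supports: tuple[str, ...]
    params: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {"name": self.name, "supports": list(self.supports),
                "params": self.params, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "LearnerSpec":
        return cls(d["name"], tuple(d["supports"]), dict(d.get("params", {})),
                   int(d.get("seed", 0)))


def default_learners(seed: int = 0) -> dict[str, LearnerSpec]:
    """The standard seven-learner registry (5 categorical, 4 continuous)."""
    cat = ("categorical",)
    cont = ("continuous",)
    both = ("categorical", "continuous")
    specs = [
        LearnerSpec("pp_bayes", cat, {}, seed),
        LearnerSpec("rp_tree", cat, {}, seed),
        LearnerSpec("rp_forest", cat, {"n_estimators": 100}, seed),
        LearnerSpec("nn", both, {"max_iter": 300}, seed),
        LearnerSpec("svm", both, {}, seed),
        LearnerSpec("pls", cont, {"max_components": 10}, seed),
        LearnerSpec("pls_fixed", cont, {"n_components": 3}, seed),
    ]
    return {s.name: s for s in specs}


class _PLSBase(BaseEstimator, RegressorMixin):
    def _check_X(self, X):
        X = np.asarray(X, dtype=float)
        if X.std(axis=0).max() == 0:
            raise ValueError("descriptor matrix has zero variance; PLS undefined")
        return X


class PLSFixed(_PLSBase):
    """PLS regression with a fixed component count (clipped to the data rank)."""

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    def fit(self, X, y):
        X = self._check_X(X)
        y = np.asarray(y, dtype=float)
        k = max(1, min(self.n_components, X.shape[1], X.shape[0] - 1))
        self.model_ = PLSRegression(n_components=k)
        self.model_.fit(X, y)
        return self

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=float)).ravel()


class PLSWithCV(_PLSBase):
    """PLS regression choosing the component count by internal k-fold CV
    (RMSE criterion), capped at min(max_components, rank)."""

    def __init__(self, max_components: int = 10, cv: int = 3, random_state: int = 0):
        self.max_components = max_components
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X = self._check_X(X)
        y = np.asarray(y, dtype=float)
        upper = max(1, min(self.max_components, X.shape[1], X.shape[0] - 2))
        best_k, best_err = 1, np.inf
        kf = KFold(n_splits=min(self.cv, len(y)), shuffle=True,
                   random_state=self.random_state)
        for k in range(1, upper + 1):
            errs = []
            for tr, va in kf.split(X):
                if len(tr) <= k:
                    continue
                m = PLSRegression(n_components=k)
                try:
                    m.fit(X[tr], y[tr])
                except Exception:
                    continue
                errs.append(float(np.mean((m.predict(X[va]).ravel() - y[va]) ** 2)))
            if errs and np.mean(errs) < best_err:
                best_err, best_k = float(np.mean(errs)), k
        self.n_components_ = best_k
        self.model_ = PLSRegression(n_components=best_k)
        self.model_.fit(X, y)
        return self

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=float)).ravel()


def make_estimator(spec: LearnerSpec, endpoint_type: str):
    """Instantiate the scikit-learn estimator for a learner spec.

    SVM, NN and PLS get a standardisation front-end (descriptor scales span
    orders of magnitude); trees and Bayes consume raw values.
    """
    if endpoint_type not in spec.supports:
        raise ValueError(f"learner {spec.name!r} does not support {endpoint_type}")
    p = spec.params
    seed = spec.seed
    if spec.name == "pp_bayes":
        return GaussianNB()
    if spec.name == "rp_tree":
        return DecisionTreeClassifier(random_state=seed, **p)
    if spec.name == "rp_forest":
        return RandomForestClassifier(random_state=seed, **p)
    if spec.name == "nn":
        est = (MLPClassifier(random_state=seed, **p) if endpoint_type == "categorical"
               else MLPRegressor(random_state=seed, **p))
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if spec.name == "svm":
        est = SVC(random_state=seed, **p) if endpoint_type == "categorical" else SVR(**p)
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if spec.name == "pls":
        return Pipeline([("scale", StandardScaler()),
                         ("model", PLSWithCV(random_state=seed,
                                             max_components=p.get("max_components", 10)))])
    if spec.name == "pls_fixed":
        return Pipeline([("scale", StandardScaler()),
                         ("model", PLSFixed(n_components=p.get("n_components", 3)))])
    raise ValueError(f"unknown learner {spec.name!r}")


def predict_with_scores(estimator, X: pd.DataFrame, positive_class=None):
    """Predictions plus a positive-class score vector where available.

    Classifiers report decision-function values (sign-aligned to the positive
    class) or positive-class probabilities; regressors report the prediction
    itself as the score.
    """
    y_pred = estimator.predict(X)
    final = estimator[-1] if isinstance(estimator, Pipeline) else estimator
    classes = getattr(final, "classes_", None)
    if classes is None:
        return y_pred, np.asarray(y_pred, dtype=float)
    pos = str(positive_class) if positive_class is not None else str(classes[-1])
    class_list = [str(c) for c in classes]
    if pos not in class_list:
        return y_pred, None
    if hasattr(estimator, "decision_function") and len(classes) == 2:
        df = estimator.decision_function(X)
        scores = df if pos == class_list[1] else -df
        return y_pred, np.asarray(scores, dtype=float)
    if hasattr(estimator, "predict_proba"):
        proba = estimator.predict_proba(X)
        return y_pred, np.asarray(proba[:, class_list.index(pos)], dtype=float)
    return y_pred, None


# ---------------------------------------------------------------------------
# Model specs and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    split_label: str
    subset_label: str
    learner_name: str


@dataclass
class ModelResult:
    """One cell of the model matrix."""

    model_id: str
    split_label: str
    subset_label: str
    learner_name: str
    status: str  # built | failed
    failure_reason: str | None = None
    fitted_model: object | None = None
    train_stats: ValidationStats | None = None
    test_stats: ValidationStats | None = None
    train_predictions: pd.Series | None = None
    test_predictions: pd.Series | None = None
    feature_columns: list[str] | None = None

    def __post_init__(self):
        built = self.status == "built"
        present = self.fitted_model is not None and self.train_stats is not None \
            and self.test_stats is not None
        if built != present:
            raise ValueError("status 'built' requires fitted model and both stats")


def enumerate_models(
    splits: Mapping[str, SplitAssignment] | Sequence[str],
    subsets: Mapping[str, DescriptorSubset] | Sequence[str],
    learners: Mapping[str, LearnerSpec],
    endpoint_type: str,
) -> list[ModelSpec]:
    """The cartesian model space, filtered to learners supporting the
    endpoint, ordered (split, subset, learner)."""
    split_labels = list(splits)
    subset_labels = list(subsets)
    supporting = [n for n, s in learners.items() if endpoint_type in s.supports]
    if not split_labels or not subset_labels:
        raise ValueError("splits and subsets must be non-empty")
    if not supporting:
        raise ValueError(f"no learner supports endpoint type {endpoint_type!r}")
    return [
        ModelSpec(sp, su, le)
        for sp in split_labels
        for su in subset_labels
        for le in supporting
    ]


def model_id_for(spec: ModelSpec, learner: LearnerSpec, data_digest: str) -> str:
    payload = json.dumps(
        {
            "split": spec.split_label,
            "subset": spec.subset_label,
            "learner": spec.learner_name,
            "params": learner.params,
            "seed": learner.seed,
            "data": data_digest,
        },
        sort_keys=True,
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def train_model(
    spec: ModelSpec,
    dataset: Dataset,
    matrix: DescriptorMatrix,
    assignment: SplitAssignment,
    learner: LearnerSpec,
    data_digest: str | None = None,
) -> ModelResult:
    """Fit one cell of the matrix; exceptions become status='failed'."""
    digest = data_digest or dataset_digest(dataset)
    mid = model_id_for(spec, learner, digest)
    y = dataset.responses()
    idx = matrix.frame.index
    train_ids = [r for r in assignment.train_ids if r in idx]
    test_ids = [r for r in assignment.test_ids if r in idx]
    try:
        if not train_ids or not test_ids:
            raise ValueError("split side empty after descriptor failures")
        X_train = matrix.frame.loc[train_ids]
        X_test = matrix.frame.loc[test_ids]
        y_train = y.loc[train_ids]
        y_test = y.loc[test_ids]
        est = make_estimator(learner, dataset.endpoint_type)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X_train.to_numpy(), _as_target(y_train, dataset.endpoint_type))
            yp_train, sc_train = predict_with_scores(est, X_train.to_numpy(),
                                                     dataset.positive_class)
            yp_test, sc_test = predict_with_scores(est, X_test.to_numpy(),
                                                   dataset.positive_class)
        train_stats = stats_for_predictions(
            dataset.endpoint_type, list(y_train), list(yp_train), sc_train,
            dataset.positive_class)
        test_stats = stats_for_predictions(
            dataset.endpoint_type, list(y_test), list(yp_test), sc_test,
            dataset.positive_class)
        return ModelResult(
            mid, spec.split_label, spec.subset_label, spec.learner_name,
            status="built", fitted_model=est,
            train_stats=train_stats, test_stats=test_stats,
            train_predictions=pd.Series(yp_train, index=train_ids),
            test_predictions=pd.Series(yp_test, index=test_ids),
            feature_columns=list(matrix.frame.columns),
        )
    except Exception as exc:  # noqa: BLE001 — failures are data
        return ModelResult(
            mid, spec.split_label, spec.subset_label, spec.learner_name,
            status="failed", failure_reason=f"{type(exc).__name__}: {exc}",
        )


def _as_target(y: pd.Series, endpoint_type: str):
    if endpoint_type == "continuous":
        return y.astype(float).to_numpy()
    return y.astype(str).to_numpy()


def y_scramble_model(
    spec: ModelSpec,
    dataset: Dataset,
    matrix: DescriptorMatrix,
    assignment: SplitAssignment,
    learner: LearnerSpec,
    n_permutations: int,
    seed: int,
) -> dict:
    """Y-scrambling for one matrix cell.

    Permutes the responses within the training split, refits, and records the
    test statistic (ROC AUC for categorical endpoints, R² for continuous) per
    permutation; the observed statistic comes from the unscrambled fit.
    """
    from .validation import y_scramble

    y = dataset.responses()
    idx = matrix.frame.index
    train_ids = [r for r in assignment.train_ids if r in idx]
    test_ids = [r for r in assignment.test_ids if r in idx]
    X_train = matrix.frame.loc[train_ids].to_numpy()
    X_test = matrix.frame.loc[test_ids].to_numpy()
    y_train = _as_target(y.loc[train_ids], dataset.endpoint_type)
    y_test = _as_target(y.loc[test_ids], dataset.endpoint_type)

    def fit_fn(X, yy):
        est = make_estimator(learner, dataset.endpoint_type)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X, yy)
        return est

    def score_fn(est):
        yp, sc = predict_with_scores(est, X_test, dataset.positive_class)
        st = stats_for_predictions(dataset.endpoint_type, list(y_test), list(yp),
                                   sc, dataset.positive_class)
        return st.roc_auc if dataset.endpoint_type == "categorical" else st.r_squared

    observed = score_fn(fit_fn(X_train, y_train))
    return y_scramble(fit_fn, score_fn, X_train, y_train, n_permutations, seed,
                      observed=observed)


# ---------------------------------------------------------------------------
# Project
# ---------------------------------------------------------------------------

class Project:
    """A modeling project: prepared dataset, splits, descriptor matrices,
    learner registry and the persisted model matrix, rooted at a directory."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        for sub in ("splits", "matrices", "models", "published"):
            (self.root / sub).mkdir(parents=True, exist_ok=True)
        self.dataset: Dataset | None = None
        self.splits: dict[str, SplitAssignment] = {}
        self.subsets: dict[str, DescriptorSubset] = {}
        self.subset_config: dict[str, list[str]] = {}
        self.matrices: dict[str, DescriptorMatrix] = {}
        self.learners: dict[str, LearnerSpec] = {}
        self.fold_width: int = DEFAULT_FOLD_WIDTH

    # -- stages -------------------------------------------------------------
    def set_dataset(self, dataset: Dataset) -> None:
        self.dataset = dataset
        self._digest = dataset_digest(dataset)

    def add_split(self, assignment: SplitAssignment) -> None:
        self.splits[assignment.label] = assignment
        assignment.save(self.root / "splits" / f"{assignment.label}.tsv")

    def set_subsets(self, config: Mapping[str, Sequence[str]] | None = None,
                    fold_width: int = DEFAULT_FOLD_WIDTH) -> None:
        config = dict(config or DEFAULT_SUBSET_CONFIG)
        self.subset_config = {k: list(v) for k, v in config.items()}
        self.subsets = make_subsets(config)
        self.fold_width = fold_width

    def compute_descriptors(self) -> None:
        if self.dataset is None or not self.subsets:
            raise ValueError("dataset and subsets must be set first")
        self.matrices = compute_matrices(self.dataset, self.subsets, self.fold_width)

    def set_learners(self, learners: Mapping[str, LearnerSpec] | None = None,
                     seed: int = 0) -> None:
        self.learners = dict(learners) if learners else default_learners(seed)

    @property
    def data_digest(self) -> str:
        return dataset_digest(self.dataset)

    # -- model persistence ----------------------------------------------------
    def _model_paths(self, model_id: str) -> tuple[Path, Path]:
        base = self.root / "models" / model_id
        return base.with_suffix(".json"), base.with_suffix(".joblib")

    def save_result(self, result: ModelResult) -> None:
        meta_path, blob_path = self._model_paths(result.model_id)
        meta = {
            "model_id": result.model_id,
            "split_label": result.split_label,
            "subset_label": result.subset_label,
            "learner_name": result.learner_name,
            "status": result.status,
            "failure_reason": result.failure_reason,
            "train_stats": result.train_stats.to_dict() if result.train_stats else None,
            "test_stats": result.test_stats.to_dict() if result.test_stats else None,
        }
        meta_path.write_text(json.dumps(meta, indent=1))
        if result.status == "built":
            joblib.dump(
                {
                    "fitted_model": result.fitted_model,
                    "train_predictions": result.train_predictions,
                    "test_predictions": result.test_predictions,
                    "feature_columns": result.feature_columns,
                    "train_stats": result.train_stats,
                    "test_stats": result.test_stats,
                },
                blob_path,
            )

    def load_result(self, model_id: str) -> ModelResult | None:
        meta_path, blob_path = self._model_paths(model_id)
        if not meta_path.exists():
            return None
        meta = json.loads(meta_path.read_text())
        if meta["status"] == "built":
            blob = joblib.load(blob_path)
            return ModelResult(
                meta["model_id"], meta["split_label"], meta["subset_label"],
                meta["learner_name"], "built",
                fitted_model=blob["fitted_model"],
                train_stats=blob["train_stats"], test_stats=blob["test_stats"],
                train_predictions=blob["train_predictions"],
                test_predictions=blob["test_predictions"],
                feature_columns=blob["feature_columns"],
            )
        return ModelResult(
            meta["model_id"], meta["split_label"], meta["subset_label"],
            meta["learner_name"], "failed", failure_reason=meta["failure_reason"],
        )


def run_matrix(
    project: Project,
    specs: Sequence[ModelSpec] | None = None,
    progress: bool = False,
) -> list[ModelResult]:
    """Attempt every cell of the model matrix.

    Results are persisted incrementally under ``project.root/models``; cells
    whose model_id is already persisted are loaded, not retrained, so an
    interrupted run resumes where it stopped and a completed run is a no-op.
    """
    ds = project.dataset
    if ds is None or not project.splits or not project.matrices or not project.learners:
        raise ValueError("project must have dataset, splits, matrices and learners")
    if specs is None:
        specs = enumerate_models(project.splits, project.subsets, project.learners,
                                 ds.endpoint_type)
    digest = project.data_digest
    results: list[ModelResult] = []
    for i, spec in enumerate(specs):
        learner = project.learners[spec.learner_name]
        mid = model_id_for(spec, learner, digest)
        cached = project.load_result(mid)
        if cached is not None:
            results.append(cached)
            continue
        result = train_model(
            spec, ds, project.matrices[spec.subset_label],
            project.splits[spec.split_label], learner, digest,
        )
        project.save_result(result)
        results.append(result)
        if progress:
            print(f"[{i + 1}/{len(specs)}] {spec.split_label}/{spec.subset_label}/"
                  f"{spec.learner_name}: {result.status}")
    return results


# ---------------------------------------------------------------------------
# Protocols: capture and replay
# ---------------------------------------------------------------------------

WORKFLOW_STAGES = ("prepare", "split", "descriptors", "build")


def save_protocol(project: Project, stages: Sequence[str], path: str | Path) -> dict:
    """Capture the project's configuration for the given contiguous stage range."""
    stages = list(stages)
    idx = [WORKFLOW_STAGES.index(s) for s in stages]
    if idx != list(range(idx[0], idx[0] + len(idx))):
        raise ValueError(f"stages must be a contiguous range of {WORKFLOW_STAGES}")
    ds = project.dataset
    protocol: dict = {
        "stages": stages,
        "endpoint_type": ds.endpoint_type if ds else None,
        "positive_class": ds.positive_class if ds else None,
    }
    if "prepare" in stages:
        protocol["prep_spec"] = [s.to_dict() for s in ds.prep_spec]
    if "split" in stages:
        protocol["split_specs"] = [a.spec.to_dict() for a in project.splits.values()]
        predefined = {
            a.label: {"train": a.train_ids, "test": a.test_ids}
            for a in project.splits.values() if a.spec.algorithm == "predefined"
        }
        if predefined:
            protocol["predefined_splits"] = predefined
    if "descriptors" in stages:
        protocol["subset_config"] = project.subset_config
        protocol["fold_width"] = project.fold_width
    if "build" in stages:
        protocol["learners"] = [s.to_dict() for s in project.learners.values()]
    Path(path).write_text(yaml.safe_dump(protocol, sort_keys=False))
    return protocol


def replay_protocol(
    protocol: dict | str | Path, raw_dataset: Dataset, workdir: str | Path
) -> Project:
    """Execute a saved protocol on a (possibly new) raw dataset.

    Endpoint compatibility is checked before any computation: a categorical
    protocol cannot be replayed on a continuous endpoint or vice versa.
    """
    if not isinstance(protocol, dict):
        protocol = yaml.safe_load(Path(protocol).read_text())
    stages = protocol["stages"]

    # determine the endpoint type the protocol's prep produces
    prep_spec = [PrepStep.from_dict(d) for d in protocol.get("prep_spec", [])]
    replayed_endpoint = raw_dataset.endpoint_type
    if any(s.name == "categorize" for s in prep_spec):
        replayed_endpoint = "categorical"
    if protocol.get("endpoint_type") and replayed_endpoint != protocol["endpoint_type"]:
        raise ValueError(
            f"protocol expects endpoint {protocol['endpoint_type']!r} but replay "
            f"would produce {replayed_endpoint!r}"
        )
    if raw_dataset.endpoint_type == "continuous" and any(
        s.name == "categorize" and "mapping" in s.params for s in prep_spec
    ):
        raise ValueError("label-map categorization cannot replay on a continuous endpoint")

    project = Project(workdir)
    ds = raw_dataset
    if "prepare" in stages:
        ds = replay_prep(prep_spec, raw_dataset)
        if protocol.get("positive_class"):
            ds.positive_class = protocol["positive_class"]
    project.set_dataset(ds)
    if "split" in stages:
        from . import splitting as sp

        cluster_cache: dict[tuple, dict] = {}
        for d in protocol["split_specs"]:
            spec = SplitSpec.from_dict(d)
            if spec.algorithm == "random":
                a = sp.random_split(ds, spec.train_fraction, spec.seed, spec.label)
            elif spec.algorithm == "stratified":
                a = sp.stratified_split(ds, spec.train_fraction, spec.seed,
                                        label=spec.label)
            elif spec.algorithm in ("independent_clusters_optimized", "random_per_cluster"):
                kind = spec.cluster_params.get("fingerprint_kind", "ECFP6")
                thr = spec.cluster_params.get("similarity_threshold", 0.7)
                key = (kind, thr)
                if key not in cluster_cache:
                    cluster_cache[key] = sp.cluster_molecules(ds, kind, thr)
                fn = (sp.independent_cluster_split
                      if spec.algorithm == "independent_clusters_optimized"
                      else sp.random_per_cluster_split)
                a = fn(ds, cluster_cache[key], spec.train_fraction, spec.seed, spec.label)
            elif spec.algorithm == "predefined":
                stored = protocol["predefined_splits"][spec.label]
                a = SplitAssignment(spec, list(stored["train"]), list(stored["test"]))
                ids = set(ds.record_ids)
                if set(a.train_ids) | set(a.test_ids) != ids:
                    raise ValueError(
                        f"predefined split {spec.label!r} does not cover the new dataset"
                    )
            else:
                raise ValueError(f"unknown split algorithm {spec.algorithm!r}")
            project.add_split(a)
    if "descriptors" in stages:
        project.set_subsets(protocol["subset_config"],
                            protocol.get("fold_width", DEFAULT_FOLD_WIDTH))
        project.compute_descriptors()
    if "build" in stages:
        project.set_learners(
            {d["name"]: LearnerSpec.from_dict(d) for d in protocol["learners"]}
        )
        run_matrix(project)
    return project
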