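"""The HybSVM two-stage stacked classifier and the two baselines.

Stage 1 consists of seven generative sequence classifiers (the multinomial
bag-of-letters model, NB 2/3/4-gram, and the order-1/2/3 Markov models
NB(2), NB(3), NB(4)) plus a homology classifier that transfers the label of
the single top-scoring hit.  Each emits a binary vote for the target class;
the fixed 8-tuple of votes is the input of a stage-2 support vector machine
whose margin is mapped to a probability with a Platt-style logistic fit.

To avoid stacking leakage, the stage-2 training vectors are produced
out-of-fold by an internal stratified split: each training sequence is voted
on by stage-1 models that never saw it.  The final stage-1 models are refit
on all training data for use at prediction time.

Baselines: a multinomial Naive Bayes over domain-identifier counts, and
majority-class prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import homology as hom
from .kgram_models import (
    MarkovClassModel,
    NBKgramModel,
    score_sequence,
    train_markov,
    train_nb_kgram,
    train_nb_multinomial,
)
from .sequence_io import LabeledDataset, LabelTable, ProteinRecord

#: Fixed order of the eight stage-1 components.
STAGE1_COMPONENTS = (
    "nb_multinomial",
    "nb_2gram",
    "nb_3gram",
    "nb_4gram",
    "markov_2",
    "markov_3",
    "markov_4",
    "homology_top_hit",
)


@dataclass
class HybSVMConfig:
    kernel_degree: int = 1
    C: float = 1.0
    stacking_folds: int = 5
    e_cutoff: float = hom.DEFAULT_E_CUTOFF
    weight_scheme: str = "bit_score"
    uniform_prior: bool = False
    seed: int = 0

    def search_config(self) -> hom.SearchConfig:
        return hom.SearchConfig(e_cutoff=self.e_cutoff, weight_scheme=self.weight_scheme)


@dataclass
class Stage1Models:
    """The seven sequence models plus the homology reference database."""

    nb: dict[int, NBKgramModel]  # k = 1..4 (k=1 is the multinomial model)
    markov: dict[int, MarkovClassModel]  # k = 2..4
    reference: LabeledDataset


def train_stage1(data: LabeledDataset, config: HybSVMConfig) -> Stage1Models:
    nb = {1: train_nb_multinomial(data, uniform_prior=config.uniform_prior)}
    for k in (2, 3, 4):
        nb[k] = train_nb_kgram(data, k, uniform_prior=config.uniform_prior)
    markov = {k: train_markov(data, k, uniform_prior=config.uniform_prior) for k in (2, 3, 4)}
    return Stage1Models(nb=nb, markov=markov, reference=data)


def build_feature_vectors(
    records: Sequence[ProteinRecord],
    stage1: Stage1Models,
    target_class: str,
    config: HybSVMConfig,
    backend=None,
) -> np.ndarray:
    """(n, 8) binary matrix; bit i = 1 iff component i votes target_class."""
    hits = hom.search_many(
        records, stage1.reference, config.search_config(), backend
    )
    rows = []
    for rec in records:
        bits = []
        for k in (1, 2, 3, 4):
            bits.append(int(score_sequence(stage1.nb[k], rec).label == target_class))
        for k in (2, 3, 4):
            bits.append(int(score_sequence(stage1.markov[k], rec).label == target_class))
        bits.append(hom.classify_by_top_hit(hits[rec.id], target_class))
        rows.append(bits)
    return np.asarray(rows, dtype=float)


def build_feature_vector(
    record: ProteinRecord,
    stage1: Stage1Models,
    target_class: str,
    config: HybSVMConfig | None = None,
    backend=None,
) -> tuple[int, ...]:
    """The 8-tuple of stage-1 votes for one record (fixed component order)."""
    config = config or HybSVMConfig()
    row = build_feature_vectors([record], stage1, target_class, config, backend)[0]
    return tuple(int(b) for b in row)


@dataclass
class HybSVMModel:
    """Trained stacked model: stage-1 components, stage-2 SVM, calibrator."""

    config: HybSVMConfig
    target_class: str
    negative_class: str
    stage1: Stage1Models
    svm: SVC
    calibrator: LogisticRegression

    @property
    def classes(self) -> list[str]:
        return sorted([self.target_class, self.negative_class])

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "HybSVMModel":
        model = joblib.load(path)
        if not isinstance(model, HybSVMModel):
            raise ValueError(f"{path} does not contain a HybSVM model bundle")
        return model


class DegenerateTrainingError(ValueError):
    """All stacking vectors identical; use a baseline instead."""


def train_hybsvm(
    data: LabeledDataset,
    config: HybSVMConfig | None = None,
    target_class: str | None = None,
    backend=None,
) -> HybSVMModel:
    """Train HybSVM on a binary task.

    Stage-2 training features come from an internal stratified J-fold split
    (default J=5): stage-1 models trained on J-1 folds vote on the held
    fold, with the homology reference likewise restricted to those folds.
    The SVM margin on those out-of-fold vectors feeds the logistic
    calibrator; stage-1 models are then refit on all data.
    """
    config = config or HybSVMConfig()
    classes = data.classes
    if len(classes) != 2:
        raise ValueError("HybSVM requires a binary task")
    target = target_class if target_class is not None else classes[0]
    if target not in classes:
        raise ValueError(f"target class {target!r} not in {classes}")
    negative = [c for c in classes if c != target][0]

    y_all = np.array([int(data.class_of(r.id) == target) for r in data.records])
    X = np.zeros((len(data), len(STAGE1_COMPONENTS)))
    skf = StratifiedKFold(
        n_splits=config.stacking_folds, shuffle=True, random_state=config.seed
    )
    for train_idx, held_idx in skf.split(X, y_all):
        inner = data.subset(list(train_idx))
        stage1 = train_stage1(inner, config)
        held_records = [data.records[i] for i in held_idx]
        X[held_idx] = build_feature_vectors(held_records, stage1, target, config, backend)

    if np.all(X == X[0]):
        raise DegenerateTrainingError(
            "all stage-1 vote vectors are identical; stage-2 separation is "
            "impossible — use the majority or domain baseline"
        )
    svm = SVC(kernel="poly", degree=config.kernel_degree, coef0=0.0, C=config.C)
    svm.fit(X, y_all)
    margins = svm.decision_function(X).reshape(-1, 1)
    calibrator = LogisticRegression(C=1e3)
    calibrator.fit(margins, y_all)
    stage1_full = train_stage1(data, config)
    return HybSVMModel(
        config=config,
        target_class=target,
        negative_class=negative,
        stage1=stage1_full,
        svm=svm,
        calibrator=calibrator,
    )


def predict_hybsvm_many(
    model: HybSVMModel,
    records: Sequence[ProteinRecord],
    reference: LabeledDataset | None = None,
    threshold: float = 0.5,
    backend=None,
) -> list[tuple[str, float, float]]:
    """Per record: (label, probability of the predicted class, p_target).

    ``p_target`` is the calibrated probability of the target class; the
    label is target iff p_target >= threshold (adjustable for ROC sweeps),
    and the reported probability of the predicted class is max(p, 1-p), so
    it always lies in [0.5, 1] at the default threshold.
    """
    stage1 = model.stage1
    if reference is not None:
        stage1 = Stage1Models(nb=stage1.nb, markov=stage1.markov, reference=reference)
    X = build_feature_vectors(records, stage1, model.target_class, model.config, backend)
    margins = model.svm.decision_function(X).reshape(-1, 1)
    p_target = model.calibrator.predict_proba(margins)[:, 1]
    out = []
    for p in p_target:
        label = model.target_class if p >= threshold else model.negative_class
        out.append((label, float(max(p, 1.0 - p)), float(p)))
    return out


def predict_hybsvm(
    model: HybSVMModel,
    record: ProteinRecord,
    reference: LabeledDataset | None = None,
    threshold: float = 0.5,
    backend=None,
) -> tuple[str, float]:
    """(label, probability of the predicted class) for a single record."""
    label, prob, _ = predict_hybsvm_many(model, [record], reference, threshold, backend)[0]
    return label, prob


class HybSVMClassifierSpec:
    """Cross-validation adapter; scores are calibrated target probabilities."""

    def __init__(self, positive_class: str, config: HybSVMConfig | None = None, backend=None):
        self.positive_class = positive_class
        self.config = config or HybSVMConfig()
        self.backend = backend

    def fit(self, train: LabeledDataset) -> HybSVMModel:
        return train_hybsvm(train, self.config, self.positive_class, self.backend)

    def predict(self, fitted: HybSVMModel, records, reference: LabeledDataset):
        rows = predict_hybsvm_many(fitted, records, reference, backend=self.backend)
        return [r[0] for r in rows], [r[2] for r in rows]


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------


@dataclass
class DomainBaselineModel:
    """Multinomial NB over domain-identifier counts with add-one smoothing."""

    classes: list[str]
    log_prior: dict[str, float]
    log_theta: dict[str, dict[str, float]]
    vocabulary: list[str]


def train_domain_baseline(
    labels: LabelTable, class_field: str, ids: Sequence[str] | None = None
) -> DomainBaselineModel:
    ids = list(ids) if ids is not None else labels.ids()
    per_class: dict[str, dict[str, int]] = {}
    n_per_class: dict[str, int] = {}
    vocab: set[str] = set()
    any_domain = False
    for ident in ids:
        cls = labels.get(ident, class_field)
        if cls is None:
            raise ValueError(f"id {ident!r} has no {class_field!r} label")
        cls = str(cls)
        counts = labels.get(ident, "domain_counts") or {}
        if counts:
            any_domain = True
        n_per_class[cls] = n_per_class.get(cls, 0) + 1
        bag = per_class.setdefault(cls, {})
        for dom, n in counts.items():
            bag[dom] = bag.get(dom, 0) + n
            vocab.add(dom)
    if not any_domain:
        raise ValueError("no training record has any domain annotation")
    vocabulary = sorted(vocab)
    v = len(vocabulary)
    total = sum(n_per_class.values())
    log_theta = {}
    for cls, bag in per_class.items():
        denom = sum(bag.values()) + v
        log_theta[cls] = {d: math.log((bag.get(d, 0) + 1) / denom) for d in vocabulary}
    return DomainBaselineModel(
        classes=sorted(per_class),
        log_prior={c: math.log(n / total) for c, n in n_per_class.items()},
        log_theta=log_theta,
        vocabulary=vocabulary,
    )


def predict_domain_baseline(
    model: DomainBaselineModel, domain_counts: Mapping[str, int] | None
) -> str:
    """Class with the highest smoothed score; zero domains fall back to the
    prior (ties go to the first class in sorted order)."""
    domain_counts = domain_counts or {}
    scores = {}
    for cls in model.classes:
        s = model.log_prior[cls]
        for dom, n in domain_counts.items():
            if dom in model.log_theta[cls]:
                s += n * model.log_theta[cls][dom]
        scores[cls] = s
    return max(sorted(model.classes), key=lambda c: scores[c])


def majority_baseline(data: LabeledDataset) -> tuple[str, float]:
    """Most frequent class and its frequency (the baseline accuracy);
    ties break toward sorted label order."""
    if not data.records:
        raise ValueError("empty dataset")
    y = data.y()
    best = max(sorted(set(y)), key=y.count)
    return best, y.count(best) / len(y)
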