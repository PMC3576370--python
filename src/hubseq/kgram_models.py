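"""k-gram extraction and generative sequence classifiers.

Three closely related classifiers over the 20-letter amino-acid alphabet:

* **Naive Bayes multinomial** — a bag-of-letters model (k = 1).
* **NB k-gram** — a bag of overlapping k-grams, each gram treated as
  independent given the class; Laplace add-one smoothing over the full
  20^k gram space.
* **NB(k)** — a per-class Markov chain of order k-1 over residues, which
  models the overlap between successive k-grams explicitly.  For k = 1 it
  reduces exactly to the multinomial model.

All probabilities are estimated with Laplace (add-one) smoothing, so every
smoothed table normalises to 1 over its full event space.  k is capped at 4:
beyond that there is too little data per gram to estimate 20^k parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .sequence_io import (
    AMINO_ACIDS,
    DROPPED_SYMBOLS,
    LabeledDataset,
    ProteinRecord,
)

ALPHABET_SIZE = 20
MAX_K = 4


class TrainingError(ValueError):
    """Raised when a class has no usable training sequences."""


def _check_k(k: int, minimum: int = 1) -> None:
    if not (minimum <= k <= MAX_K):
        raise ValueError(f"k must be in [{minimum}, {MAX_K}], got {k}")


# ---------------------------------------------------------------------------
# k-gram profiles
# ---------------------------------------------------------------------------


@dataclass
class KGramProfile:
    """Counts of overlapping k-grams of one sequence.

    Windows containing a dropped symbol (X, ``*``) are skipped.  ``too_short``
    flags sequences with no valid window.
    """

    k: int
    counts: dict[str, int]
    total: int
    too_short: bool = False


def _clean_windows(residues: str, k: int):
    """Yield (start, gram) for every window of length k free of dropped symbols."""
    for i in range(len(residues) - k + 1):
        gram = residues[i : i + k]
        if any(c in DROPPED_SYMBOLS for c in gram):
            continue
        yield i, gram


def extract_kgrams(record: ProteinRecord | str, k: int) -> KGramProfile:
    """Count overlapping k-grams left to right with a sliding window."""
    _check_k(k)
    residues = record if isinstance(record, str) else record.residues
    counts: dict[str, int] = {}
    total = 0
    for _, gram in _clean_windows(residues, k):
        counts[gram] = counts.get(gram, 0) + 1
        total += 1
    return KGramProfile(k=k, counts=counts, total=total, too_short=(total == 0))


# ---------------------------------------------------------------------------
# NB k-gram model (houses the multinomial as k = 1)
# ---------------------------------------------------------------------------


@dataclass
class NBKgramModel:
    """Bag-of-k-grams Naive Bayes with add-one smoothing over 20^k grams.

    ``log_theta[c]`` stores log-probabilities sparsely for observed grams;
    any gram absent from the table has log-probability ``log_default[c]``
    (the smoothed probability of a zero-count gram).
    """

    k: int
    classes: list[str]
    log_prior: dict[str, float]
    log_theta: dict[str, dict[str, float]]
    log_default: dict[str, float]
    alphabet_size: int = ALPHABET_SIZE

    def gram_log_prob(self, cls: str, gram: str) -> float:
        return self.log_theta[cls].get(gram, self.log_default[cls])

    def log_likelihood(self, cls: str, record: ProteinRecord | str) -> float:
        profile = extract_kgrams(record, self.k)
        table = self.log_theta[cls]
        default = self.log_default[cls]
        return sum(n * table.get(g, default) for g, n in profile.counts.items())

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "type": "nb_kgram",
            "k": self.k,
            "classes": self.classes,
            "log_prior": self.log_prior,
            "log_theta": self.log_theta,
            "log_default": self.log_default,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NBKgramModel":
        if d.get("type") != "nb_kgram":
            raise ValueError("not a serialized NB k-gram model")
        return cls(
            k=int(d["k"]),
            classes=list(d["classes"]),
            log_prior=dict(d["log_prior"]),
            log_theta={c: dict(t) for c, t in d["log_theta"].items()},
            log_default=dict(d["log_default"]),
        )


def _class_partition(
    data: LabeledDataset, classes: Sequence[str] | None = None
) -> dict[str, list[ProteinRecord]]:
    part: dict[str, list[ProteinRecord]] = {c: [] for c in (classes or data.classes)}
    for rec in data.records:
        cls = data.class_of(rec.id)
        if cls not in part:
            raise TrainingError(f"record {rec.id!r} has unexpected class {cls!r}")
        part[cls].append(rec)
    return part


def _log_priors(part: Mapping[str, Sequence], uniform: bool) -> dict[str, float]:
    if uniform:
        return {c: -math.log(len(part)) for c in part}
    n = sum(len(v) for v in part.values())
    return {c: math.log(len(v) / n) for c, v in part.items()}


def train_nb_kgram(
    data: LabeledDataset, k: int, *, uniform_prior: bool = False,
    classes: Sequence[str] | None = None,
) -> NBKgramModel:
    """Fit the NB k-gram model: theta[g|c] = (n_gc + 1) / (N_c + 20^k)."""
    _check_k(k)
    part = _class_partition(data, classes)
    for c, recs in part.items():
        if not recs:
            raise TrainingError(f"class {c!r} has no training sequences")
    space = ALPHABET_SIZE**k
    log_theta: dict[str, dict[str, float]] = {}
    log_default: dict[str, float] = {}
    for c, recs in part.items():
        counts: dict[str, int] = {}
        total = 0
        for rec in recs:
            prof = extract_kgrams(rec, k)
            total += prof.total
            for g, n in prof.counts.items():
                counts[g] = counts.get(g, 0) + n
        denom = total + space
        log_theta[c] = {g: math.log((n + 1) / denom) for g, n in counts.items()}
        log_default[c] = math.log(1.0 / denom)
    return NBKgramModel(
        k=k,
        classes=sorted(part),
        log_prior=_log_priors(part, uniform_prior),
        log_theta=log_theta,
        log_default=log_default,
    )


def train_nb_multinomial(data: LabeledDataset, *, uniform_prior: bool = False) -> NBKgramModel:
    """Bag-of-letters Naive Bayes; identical to :func:`train_nb_kgram` at k=1."""
    return train_nb_kgram(data, 1, uniform_prior=uniform_prior)


# ---------------------------------------------------------------------------
# NB(k): per-class Markov chain of order k-1
# ---------------------------------------------------------------------------


@dataclass
class MarkovClassModel:
    """Per-class order-(k-1) Markov chain with Laplace-smoothed tables.

    ``transitions[c][ctx][a]`` is log P(a | ctx, c) for observed (ctx, a)
    pairs; for a seen context, unseen symbols get ``ctx_default[c][ctx]``;
    a wholly unseen context is uniform (log 1/20).  ``initial[c]`` is the
    Laplace-smoothed distribution of the first (k-1)-gram of a sequence over
    the 20^(k-1) context space (for k = 1 there is a single empty context
    with probability 1, so NB(1) coincides with the multinomial model).
    """

    k: int
    classes: list[str]
    log_prior: dict[str, float]
    transitions: dict[str, dict[str, dict[str, float]]]
    ctx_default: dict[str, dict[str, float]]
    initial: dict[str, dict[str, float]]
    initial_default: dict[str, float]

    @property
    def order(self) -> int:
        return self.k - 1

    def transition_log_prob(self, cls: str, ctx: str, sym: str) -> float:
        row = self.transitions[cls].get(ctx)
        if row is None:
            return -math.log(ALPHABET_SIZE)
        return row.get(sym, self.ctx_default[cls][ctx])

    def initial_log_prob(self, cls: str, ctx: str) -> float:
        if self.order == 0:
            return 0.0  # single empty context
        return self.initial[cls].get(ctx, self.initial_default[cls])

    def log_likelihood(self, cls: str, record: ProteinRecord | str) -> float:
        residues = record if isinstance(record, str) else record.residues
        total = 0.0
        if self.order > 0:
            first = next(_clean_windows(residues, self.order), None)
            if first is not None:
                total += self.initial_log_prob(cls, first[1])
        for _, gram in _clean_windows(residues, self.k):
            total += self.transition_log_prob(cls, gram[:-1], gram[-1])
        return total

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "type": "markov",
            "k": self.k,
            "classes": self.classes,
            "log_prior": self.log_prior,
            "transitions": self.transitions,
            "ctx_default": self.ctx_default,
            "initial": self.initial,
            "initial_default": self.initial_default,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MarkovClassModel":
        if d.get("type") != "markov":
            raise ValueError("not a serialized Markov class model")
        return cls(
            k=int(d["k"]),
            classes=list(d["classes"]),
            log_prior=dict(d["log_prior"]),
            transitions={c: {x: dict(r) for x, r in t.items()} for c, t in d["transitions"].items()},
            ctx_default={c: dict(t) for c, t in d["ctx_default"].items()},
            initial={c: dict(t) for c, t in d["initial"].items()},
            initial_default=dict(d["initial_default"]),
        )


def train_markov(
    data: LabeledDataset, k: int, *, uniform_prior: bool = False,
    classes: Sequence[str] | None = None,
) -> MarkovClassModel:
    """Fit NB(k): P(a|ctx,c) = (n_{ctx a,c} + 1) / (n_{ctx *,c} + 20).

    The initial-context distribution is the Laplace-smoothed frequency of the
    first dropped-symbol-free (k-1)-gram over sequence starts, smoothed over
    the 20^(k-1) context space.
    """
    _check_k(k)
    part = _class_partition(data, classes)
    for c, recs in part.items():
        if not recs:
            raise TrainingError(f"class {c!r} has no training sequences")
    order = k - 1
    transitions: dict[str, dict[str, dict[str, float]]] = {}
    ctx_default: dict[str, dict[str, float]] = {}
    initial: dict[str, dict[str, float]] = {}
    initial_default: dict[str, float] = {}
    for c, recs in part.items():
        trans_counts: dict[str, dict[str, int]] = {}
        init_counts: dict[str, int] = {}
        n_starts = 0
        for rec in recs:
            if order > 0:
                first = next(_clean_windows(rec.residues, order), None)
                if first is not None:
                    init_counts[first[1]] = init_counts.get(first[1], 0) + 1
                    n_starts += 1
            for _, gram in _clean_windows(rec.residues, k):
                row = trans_counts.setdefault(gram[:-1], {})
                row[gram[-1]] = row.get(gram[-1], 0) + 1
        transitions[c] = {}
        ctx_default[c] = {}
        for ctx, row in trans_counts.items():
            denom = sum(row.values()) + ALPHABET_SIZE
            transitions[c][ctx] = {a: math.log((n + 1) / denom) for a, n in row.items()}
            ctx_default[c][ctx] = math.log(1.0 / denom)
        init_denom = n_starts + ALPHABET_SIZE**order
        initial[c] = {g: math.log((n + 1) / init_denom) for g, n in init_counts.items()}
        initial_default[c] = math.log(1.0 / init_denom)
    return MarkovClassModel(
        k=k,
        classes=sorted(part),
        log_prior=_log_priors(part, uniform_prior),
        transitions=transitions,
        ctx_default=ctx_default,
        initial=initial,
        initial_default=initial_default,
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


@dataclass
class ScoredPrediction:
    """Per-class posterior log-scores with the winning label and its margin."""

    log_scores: dict[str, float]
    log_likelihoods: dict[str, float]
    label: str
    margin: float
    prior_only: bool = False


def score_sequence(
    model: NBKgramModel | MarkovClassModel, record: ProteinRecord | str
) -> ScoredPrediction:
    """Score a sequence under every class: log prior + log-likelihood.

    Ties are broken toward the first class in sorted label order.  Sequences
    with no scoreable window fall back to the prior alone (flagged).
    """
    logliks = {c: model.log_likelihood(c, record) for c in model.classes}
    scores = {c: model.log_prior[c] + logliks[c] for c in model.classes}
    ordered = sorted(model.classes)
    best = max(ordered, key=lambda c: scores[c])  # max is stable: first of ties
    others = [scores[c] for c in ordered if c != best]
    margin = scores[best] - max(others) if others else 0.0
    return ScoredPrediction(
        log_scores=scores,
        log_likelihoods=logliks,
        label=best,
        margin=margin,
        prior_only=all(v == 0.0 for v in logliks.values()),
    )


def save_model(model: NBKgramModel | MarkovClassModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model.to_dict(), fh)


def load_model(path) -> NBKgramModel | MarkovClassModel:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    if d.get("type") == "nb_kgram":
        return NBKgramModel.from_dict(d)
    if d.get("type") == "markov":
        return MarkovClassModel.from_dict(d)
    raise ValueError(f"unknown model type {d.get('type')!r}")


class KgramClassifierSpec:
    """Cross-validation adapter for the generative sequence classifiers.

    ``kind`` is ``"nb"`` (bag of k-grams) or ``"markov"`` (NB(k)).  Scores
    returned for ROC analysis are the log-odds margin for ``positive_class``.
    """

    def __init__(self, kind: str, k: int, positive_class: str, *, uniform_prior: bool = False):
        if kind not in ("nb", "markov"):
            raise ValueError(f"unknown classifier kind {kind!r}")
        self.kind = kind
        self.k = k
        self.positive_class = positive_class
        self.uniform_prior = uniform_prior

    def fit(self, train: LabeledDataset):
        if self.kind == "nb":
            return train_nb_kgram(train, self.k, uniform_prior=self.uniform_prior)
        if self.k == 1:
            return train_nb_multinomial(train, uniform_prior=self.uniform_prior)
        return train_markov(train, self.k, uniform_prior=self.uniform_prior)

    def predict(self, fitted, records: Sequence[ProteinRecord], reference: LabeledDataset):
        labels, scores = [], []
        pos = self.positive_class
        for rec in records:
            sp = score_sequence(fitted, rec)
            labels.append(sp.label)
            neg = max(v for c, v in sp.log_scores.items() if c != pos)
            scores.append(sp.log_scores[pos] - neg)
        return labels, scores
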