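"""Relevance classifier with an active-learning training protocol.

The predictor stands in for the learning component of online screening tools:
a tf-idf bag-of-words (unigram + bigram) representation fitted on the whole
corpus -- the retrospective setting is transductive, every candidate record
is on hand -- and an L2-regularized logistic model trained on the labeled
records. Reviewer term priors ("dual supervision") enter as the mean of the
Gaussian penalty on the coefficients: tagging a term as indicative of
relevance pulls its coefficient toward +weight rather than toward zero.

The training protocol mirrors practice: label an initial block of records in
seeded random order (default 200), and if the block does not yet contain both
classes, keep labeling in batches (default 100) up to a cap (default 300)
before declaring predictions unavailable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.optimize
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer

from screensim.corpus_io import CitationRecord, ReviewDataset

HARD_THRESHOLD = 0.5


class PredictionsUnavailableError(RuntimeError):
    """The training set never contained both classes; no predictions exist."""


@dataclass(frozen=True)
class RelevancePrediction:
    """Per-record probability of relevance plus the binary hard call."""

    record_id: str
    probability: float
    hard_label: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(
                f"probability must be in [0, 1], got {self.probability}"
            )
        expected = hard_label_from_probability(self.probability)
        if self.hard_label != expected:
            raise ValueError(
                f"hard_label {self.hard_label!r} inconsistent with probability "
                f"{self.probability} (threshold {HARD_THRESHOLD})"
            )


def hard_label_from_probability(
    probability: float, threshold: float = HARD_THRESHOLD
) -> str:
    """Binary call from a probability; a tie at the threshold is relevant.

    Ties err toward inclusion: wrongly advancing a record costs one extra
    full-text look, wrongly excluding it can lose a study.
    """
    return "relevant" if probability >= threshold else "irrelevant"


@dataclass(frozen=True)
class TermPrior:
    """A reviewer-tagged term indicative of relevance or irrelevance."""

    term: str
    polarity: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.polarity not in ("relevant", "irrelevant"):
            raise ValueError(f"polarity must be relevant/irrelevant, got {self.polarity!r}")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass(frozen=True)
class TrainingProtocol:
    """Sizes governing the active-learning training loop.

    The 10-include / 40-exclude figures are tool-vendor guidance; falling
    short of them only triggers a warning. The hard gate for predictions is
    ``min_includes`` relevant plus at least one irrelevant label.
    """

    initial_size: int = 200
    extension_batch: int = 100
    max_size: int = 300
    min_includes: int = 1
    recommended_min_includes: int = 10
    recommended_min_excludes: int = 40

    def __post_init__(self) -> None:
        if self.initial_size > self.max_size:
            raise ValueError("initial_size cannot exceed max_size")
        if self.extension_batch < 1:
            raise ValueError("extension_batch must be >= 1")
        if self.min_includes < 1:
            raise ValueError("min_includes must be >= 1")


@dataclass
class Featurized:
    """tf-idf features for a corpus: row i of ``matrix`` is ``ids[i]``."""

    ids: list[str]
    matrix: sp.csr_matrix
    vocabulary: dict[str, int]

    def rows_for(self, record_ids: Sequence[str]) -> sp.csr_matrix:
        index = {rid: i for i, rid in enumerate(self.ids)}
        return self.matrix[[index[r] for r in record_ids]]


def featurize(records: Sequence[CitationRecord]) -> Featurized:
    """Lower-cased unigram+bigram tf-idf over title + abstract.

    The vocabulary and document frequencies are fitted on the full corpus.
    idf(t) = ln((1 + n) / (1 + df(t))) + 1 with n documents, and each
    document vector is L2-normalized.
    """
    if not records:
        raise ValueError("empty corpus")
    texts = [r.text for r in records]
    if not any(t.strip() for t in texts):
        raise ValueError("all documents are empty; nothing to featurize")
    vectorizer = TfidfVectorizer(
        lowercase=True,
        ngram_range=(1, 2),
        norm="l2",
        smooth_idf=True,
        sublinear_tf=False,
    )
    matrix = vectorizer.fit_transform(texts)
    return Featurized(
        ids=[r.record_id for r in records],
        matrix=matrix.tocsr(),
        vocabulary=vectorizer.vocabulary_,
    )


# ---------------------------------------------------------------------------
# penalized logistic fit
# ---------------------------------------------------------------------------


def _prior_vector(
    priors: Iterable[TermPrior], vocabulary: Mapping[str, int], n_features: int
) -> np.ndarray:
    w0 = np.zeros(n_features)
    for prior in priors:
        idx = vocabulary.get(prior.term.lower())
        if idx is None:
            warnings.warn(
                f"term prior {prior.term!r} not in corpus vocabulary; ignored",
                stacklevel=3,
            )
            continue
        w0[idx] += prior.weight * (1.0 if prior.polarity == "relevant" else -1.0)
    return w0


def _fit_logistic(
    X: sp.csr_matrix, y: np.ndarray, w0: np.ndarray, C: float
) -> tuple[np.ndarray, float]:
    """Minimize weighted sum log-loss + ||w - w0||^2 / (2C).

    Classes are weighted inversely to their frequency (balanced), so the
    scarce relevant class is not swamped: screening prioritizes recall.
    The intercept is unpenalized.
    """
    n, d = X.shape
    n_pos = int((y > 0).sum())
    n_neg = n - n_pos
    sw = np.where(y > 0, n / (2.0 * n_pos), n / (2.0 * n_neg))

    def objective(params: np.ndarray) -> tuple[float, np.ndarray]:
        w, b = params[:d], params[d]
        z = X @ w + b
        # stable log(1 + exp(-y z)) with y in {-1, +1}
        yz = y * z
        loss = np.sum(sw * np.logaddexp(0.0, -yz))
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        resid = sw * (p - (y > 0))
        grad_w = X.T @ resid + (w - w0) / C
        grad_b = resid.sum()
        penalty = 0.5 / C * np.dot(w - w0, w - w0)
        return loss + penalty, np.concatenate([grad_w, [grad_b]])

    x_init = np.concatenate([w0, [0.0]])
    result = scipy.optimize.minimize(
        objective,
        x_init,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 1000, "gtol": 1e-8, "ftol": 1e-12},
    )
    return result.x[:d], float(result.x[d])


def fit_predict(
    train_ids: Sequence[str],
    labels: Mapping[str, str],
    priors: Sequence[TermPrior],
    featurized: Featurized,
    *,
    C: float = 1.0,
) -> list[RelevancePrediction]:
    """Fit on the labeled training records, predict every other record.

    ``labels`` maps training record ids to relevant/irrelevant; both classes
    must be present. Term priors shift the coefficient penalty's center for
    their terms. Output is deterministic given inputs.
    """
    train_set = set(train_ids)
    missing = train_set - set(labels)
    if missing:
        raise ValueError(f"no label for training records: {sorted(missing)[:10]}")
    y = np.array(
        [1.0 if labels[rid] == "relevant" else -1.0 for rid in train_ids]
    )
    if len(set(y)) < 2:
        raise ValueError(
            "training labels contain a single class; extend the training set "
            "until both relevant and irrelevant labels are present"
        )
    X_train = featurized.rows_for(list(train_ids))
    w0 = _prior_vector(priors, featurized.vocabulary, featurized.matrix.shape[1])
    w, b = _fit_logistic(X_train, y, w0, C)

    out_ids = [rid for rid in featurized.ids if rid not in train_set]
    X_out = featurized.rows_for(out_ids)
    z = np.asarray(X_out @ w).ravel() + b
    probs = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    return [
        RelevancePrediction(
            record_id=rid,
            probability=float(p),
            hard_label=hard_label_from_probability(float(p)),
        )
        for rid, p in zip(out_ids, probs)
    ]


# ---------------------------------------------------------------------------
# training protocol
# ---------------------------------------------------------------------------


@dataclass
class TrainingRun:
    """Outcome of the training protocol: who was labeled, and the predictions."""

    train_ids: list[str]
    predictions: list[RelevancePrediction]
    training_labels: dict[str, str] = field(default_factory=dict)

    @property
    def training_size(self) -> int:
        return len(self.train_ids)

    def predictions_by_id(self) -> dict[str, RelevancePrediction]:
        return {p.record_id: p for p in self.predictions}


def run_training_protocol(
    ds: ReviewDataset,
    protocol: TrainingProtocol = TrainingProtocol(),
    order_seed: int = 0,
    priors: Sequence[TermPrior] = (),
) -> TrainingRun:
    """Label records in seeded random order until predictions are available.

    The training labels replicate the senior reviewer's recorded decisions.
    After the initial block, the training set is extended in batches while it
    lacks ``min_includes`` relevant or one irrelevant label, up to
    ``max_size``; if both classes never appear, predictions are unavailable.
    """
    if ds.n_records < protocol.initial_size:
        raise ValueError(
            f"corpus has {ds.n_records} records, fewer than the "
            f"{protocol.initial_size}-record training set"
        )
    senior = ds.decisions_for("senior")
    rng = np.random.default_rng(order_seed)
    order = [ds.records[i].record_id for i in rng.permutation(ds.n_records)]

    size = protocol.initial_size
    while True:
        train_ids = order[:size]
        unlabeled = [rid for rid in train_ids if rid not in senior]
        if unlabeled:
            raise ValueError(
                f"senior decision missing for sampled records: {unlabeled[:10]}"
            )
        n_rel = sum(senior[rid] == "relevant" for rid in train_ids)
        n_irr = size - n_rel
        if n_rel >= protocol.min_includes and n_irr >= 1:
            break
        if size >= min(protocol.max_size, ds.n_records):
            raise PredictionsUnavailableError(
                f"training set reached {size} records with {n_rel} relevant and "
                f"{n_irr} irrelevant labels; predictions unavailable"
            )
        size = min(size + protocol.extension_batch, protocol.max_size, ds.n_records)

    if (
        n_rel < protocol.recommended_min_includes
        or n_irr < protocol.recommended_min_excludes
    ):
        warnings.warn(
            f"training set has {n_rel} includes / {n_irr} excludes, below the "
            f"recommended {protocol.recommended_min_includes}/"
            f"{protocol.recommended_min_excludes}",
            stacklevel=2,
        )

    featurized = featurize(ds.records)
    labels = {rid: senior[rid] for rid in train_ids}
    predictions = fit_predict(train_ids, labels, priors, featurized)
    return TrainingRun(
        train_ids=list(train_ids), predictions=predictions, training_labels=labels
    )
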