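"""Synthetic review corpora, reviewer decisions and meta-analysis study sets.

The generator emulates the statistical shape of real title-abstract screening
data: corpora of a few hundred to ~12,000 records with roughly 9% of records
relevant at the title-abstract stage and roughly 2% included in the final
report, screened in full by an experienced senior reviewer and a second
reviewer whose calls are imperfect Bernoulli corruptions of the latent truth.

Texts follow a two-component multinomial bag-of-words model: an "irrelevant"
background word distribution and a topic distribution, with relevant documents
mixing the two. The divergence between the class distributions is controlled
by a single separation parameter (0 means the classes are textually
indistinguishable), and per-record "hardness" -- the mixing weight pulling a
relevant document's text back toward the background distribution -- can be
multiplied up for chosen study-characteristic categories so that
category/misprediction associations can be induced on demand.

Every generator op draws from its own RNG stream derived from
``(seed, op-name)``, so adding a downstream stage never perturbs upstream
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from screensim.corpus_io import (
    DESIGNS,
    CitationRecord,
    ReviewDataset,
    ReviewMeta,
    ScreeningDecision,
    StudyCharacteristics,
)
from screensim.meta import MetaStudy

# stream ids, one per generator op: stage order never matters
_STREAMS = {"corpus": 11, "decisions": 23, "characteristics": 37, "meta": 53}


def _rng(seed: int, op: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[op]])


def _default_design_probs() -> dict[str, float]:
    # study-design mix typical of a pooled multi-review final-report set:
    # trials dominate, observational next, a sprinkle of qualitative/mixed/reviews
    return {
        "trial": 0.60,
        "observational": 0.27,
        "mixed_methods": 0.005,
        "qualitative": 0.02,
        "review": 0.105,
    }


def _default_hardness_multipliers() -> dict[str, float]:
    # categories observed to be mispredicted more often get text that leans
    # further toward the background distribution
    return {
        "trial": 1.0,
        "observational": 2.0,
        "mixed_methods": 1.0,
        "qualitative": 1.0,
        "review": 1.6,
        "low": 1.6,
        "high_or_unclear": 1.0,
        "unknown": 1.0,
    }


@dataclass(frozen=True)
class SyntheticReviewSpec:
    """Parameters of one synthetic review corpus.

    Defaults follow the across-review medians of retrospective screening
    data: ~9% of candidate records relevant at title-abstract, ~2% in the
    final report, full dual screening by a strong senior reviewer and a
    slightly weaker second reviewer.
    """

    n_records: int = 3000
    ta_inclusion_rate: float = 0.09
    final_inclusion_rate: float = 0.02
    vocab_size: int = 2000
    topic_separation: float = 4.0
    title_length: int = 12
    abstract_length: int = 120
    senior_sensitivity: float = 0.95
    senior_specificity: float = 0.98
    second_sensitivity: float = 0.90
    second_specificity: float = 0.96
    base_hardness: float = 0.25
    characteristic_model: Mapping[str, float] = field(
        default_factory=_default_hardness_multipliers
    )
    design_probs: Mapping[str, float] = field(default_factory=_default_design_probs)
    review_meta: ReviewMeta = field(default_factory=ReviewMeta)
    review_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        probs = {
            "ta_inclusion_rate": self.ta_inclusion_rate,
            "final_inclusion_rate": self.final_inclusion_rate,
            "senior_sensitivity": self.senior_sensitivity,
            "senior_specificity": self.senior_specificity,
            "second_sensitivity": self.second_sensitivity,
            "second_specificity": self.second_specificity,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.final_inclusion_rate > self.ta_inclusion_rate:
            raise ValueError(
                "final_inclusion_rate cannot exceed ta_inclusion_rate"
            )
        if self.topic_separation < 0:
            raise ValueError("topic_separation must be >= 0")
        if self.vocab_size < 10:
            raise ValueError("vocab_size must be >= 10")
        if not 0.0 <= self.base_hardness <= 1.0:
            raise ValueError("base_hardness must be in [0, 1]")


# ---------------------------------------------------------------------------
# text model
# ---------------------------------------------------------------------------


def _word_distributions(spec: SyntheticReviewSpec, rng: np.random.Generator):
    """Background and relevant-class multinomials over the vocabulary."""
    v = spec.vocab_size
    zipf = 1.0 / np.arange(1, v + 1) ** 1.1
    zipf /= zipf.sum()
    p_background = zipf
    # topic distribution: the same Zipf mass over a random permutation, so
    # topic words are spread across the vocabulary independently of rank
    perm = rng.permutation(v)
    p_topic = zipf[np.argsort(perm)]
    a = 1.0 - np.exp(-spec.topic_separation)
    p_relevant = a * p_topic + (1.0 - a) * p_background
    return p_background, p_relevant


def _draw_text(
    rng: np.random.Generator,
    p_background: np.ndarray,
    p_relevant: np.ndarray,
    relevant: bool,
    hardness: float,
    mean_len: int,
) -> str:
    if relevant:
        h = min(1.0, hardness)
        p = (1.0 - h) * p_relevant + h * p_background
    else:
        p = p_background
    n = max(3, rng.poisson(mean_len))
    tokens = rng.choice(len(p), size=n, p=p)
    return " ".join(f"w{t}" for t in tokens)


def _record_texts(
    spec: SyntheticReviewSpec,
    rng: np.random.Generator,
    relevant: bool,
    hardness: float,
    dists,
) -> tuple[str, str]:
    p_bg, p_rel = dists
    title = _draw_text(rng, p_bg, p_rel, relevant, hardness, spec.title_length)
    abstract = _draw_text(rng, p_bg, p_rel, relevant, hardness, spec.abstract_length)
    return title, abstract


# ---------------------------------------------------------------------------
# generator ops
# ---------------------------------------------------------------------------


def generate_corpus(spec: SyntheticReviewSpec) -> ReviewDataset:
    """Generate records, latent truth labels and the final-report set.

    Each record's latent relevance is Bernoulli(ta_inclusion_rate); the final
    report is drawn from the true-relevant records at rate
    final_inclusion_rate / ta_inclusion_rate, mirroring how full-text
    screening whittles the title-abstract includes down to the report.
    """
    rng = _rng(spec.seed, "corpus")
    dists = _word_distributions(spec, rng)
    width = len(str(spec.n_records))

    truth_arr = rng.random(spec.n_records) < spec.ta_inclusion_rate
    records: list[CitationRecord] = []
    truth: dict[str, bool] = {}
    for i in range(spec.n_records):
        rid = f"r{i:0{width}d}"
        title, abstract = _record_texts(
            spec, rng, bool(truth_arr[i]), spec.base_hardness, dists
        )
        records.append(
            CitationRecord(
                record_id=rid, title=title, abstract=abstract, review_id=spec.review_id
            )
        )
        truth[rid] = bool(truth_arr[i])

    if spec.ta_inclusion_rate > 0:
        p_final = spec.final_inclusion_rate / spec.ta_inclusion_rate
    else:
        p_final = 0.0
    final_ids = frozenset(
        rid for rid in sorted(truth) if truth[rid] and rng.random() < p_final
    )

    return ReviewDataset(
        records=records,
        decisions=[],
        final_report_ids=final_ids,
        characteristics=[],
        review_meta=spec.review_meta,
        truth=truth,
    )


def generate_reviewer_decisions(
    ds: ReviewDataset, spec: SyntheticReviewSpec
) -> ReviewDataset:
    """Draw senior and second decisions for every record from truth.

    A reviewer marks a true-relevant record relevant with probability equal to
    their sensitivity, and a true-irrelevant record irrelevant with their
    specificity. Both reviewers screen the whole corpus (retrospective dual
    screening).
    """
    if ds.truth is None:
        raise ValueError("dataset has no latent truth labels; generate_corpus first")
    rng = _rng(spec.seed, "decisions")
    params = {
        "senior": (spec.senior_sensitivity, spec.senior_specificity),
        "second": (spec.second_sensitivity, spec.second_specificity),
    }
    decisions: list[ScreeningDecision] = []
    for role, (sens, spc) in params.items():
        for rec in ds.records:
            truth = ds.truth[rec.record_id]
            p_relevant = sens if truth else 1.0 - spc
            call = "relevant" if rng.random() < p_relevant else "irrelevant"
            decisions.append(ScreeningDecision(rec.record_id, role, call))
    return ReviewDataset(
        records=ds.records,
        decisions=decisions,
        final_report_ids=ds.final_report_ids,
        characteristics=ds.characteristics,
        review_meta=ds.review_meta,
        truth=ds.truth,
    )


def attach_study_characteristics(
    ds: ReviewDataset, spec: SyntheticReviewSpec
) -> ReviewDataset:
    """Assign design/risk-of-bias/year/impact-factor to final-report records.

    The record's text is re-drawn with its hardness multiplied by the
    category's multipliers (design x risk of bias), coupling characteristic
    categories to text difficulty. With all multipliers at 1 the categories
    are independent of the text.
    """
    if ds.truth is None:
        raise ValueError("dataset has no latent truth labels")
    rng = _rng(spec.seed, "characteristics")
    dists = _word_distributions(spec, _rng(spec.seed, "corpus"))

    designs = list(spec.design_probs)
    for d in designs:
        if d not in DESIGNS:
            raise ValueError(f"unknown design category {d!r}")
    design_p = np.array([spec.design_probs[d] for d in designs], dtype=float)
    design_p = design_p / design_p.sum()
    risk_cats = ["low", "high_or_unclear", "unknown"]
    risk_p = np.array([0.15, 0.62, 0.23])

    mult = dict(_default_hardness_multipliers())
    mult.update(spec.characteristic_model)

    characteristics: list[StudyCharacteristics] = []
    new_records = {r.record_id: r for r in ds.records}
    for rid in sorted(ds.final_report_ids):
        design = designs[rng.choice(len(designs), p=design_p)]
        risk = risk_cats[rng.choice(len(risk_cats), p=risk_p)]
        pub_year = int(np.clip(round(rng.normal(2008, 7)), 1950, 2020))
        impact = float(rng.lognormal(mean=0.85, sigma=1.1))
        characteristics.append(
            StudyCharacteristics(
                record_id=rid,
                design=design,
                risk_of_bias=risk,
                pub_year=pub_year,
                impact_factor=round(impact, 3),
            )
        )
        hardness = spec.base_hardness * mult.get(design, 1.0) * mult.get(risk, 1.0)
        title, abstract = _record_texts(spec, rng, True, hardness, dists)
        old = new_records[rid]
        new_records[rid] = replace(old, title=title, abstract=abstract)

    return ReviewDataset(
        records=[new_records[r.record_id] for r in ds.records],
        decisions=ds.decisions,
        final_report_ids=ds.final_report_ids,
        characteristics=characteristics,
        review_meta=ds.review_meta,
        truth=ds.truth,
    )


def generate_review_dataset(spec: SyntheticReviewSpec) -> ReviewDataset:
    """Full pipeline: corpus, characteristics (with text coupling), decisions."""
    ds = generate_corpus(spec)
    ds = attach_study_characteristics(ds, spec)
    ds = generate_reviewer_decisions(ds, spec)
    return ds


# ---------------------------------------------------------------------------
# meta-analysis study sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticMetaSpec:
    """Parameters of a synthetic random-effects meta-analysis study set."""

    k_studies: int = 8
    true_md: float = -1.5
    tau2: float = 0.2
    se_range: tuple[float, float] = (0.3, 0.9)
    analysis_id: str = "primary"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_studies < 1:
            raise ValueError("k_studies must be >= 1")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        lo, hi = self.se_range
        if not (0 < lo <= hi):
            raise ValueError("se_range must satisfy 0 < low <= high")


def generate_meta_study_set(spec: SyntheticMetaSpec) -> list[MetaStudy]:
    """Draw k studies: theta_i ~ N(true_md, tau2), md_i ~ N(theta_i, se_i^2)."""
    rng = _rng(spec.seed, "meta")
    lo, hi = spec.se_range
    studies: list[MetaStudy] = []
    for i in range(spec.k_studies):
        se = float(rng.uniform(lo, hi))
        theta = float(rng.normal(spec.true_md, np.sqrt(spec.tau2)))
        md = float(rng.normal(theta, se))
        studies.append(
            MetaStudy(
                study_id=f"s{i + 1:03d}",
                md=md,
                se=se,
                analysis_id=spec.analysis_id,
            )
        )
    return studies
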