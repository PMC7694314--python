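"""Screening-workflow simulators with exact effort accounting.

Four workflows route each record between the senior reviewer, the second
reviewer and the classifier's predictions:

* dual independent -- both reviewers screen everything; either reviewer's
  relevant call advances a record (merged include/unsure semantics).
* single reviewer -- one reviewer screens everything alone.
* liberal-accelerated ML -- training block dual-screened; the senior reviewer
  screens only predicted-relevant records; the second reviewer double-checks
  exclusions (senior-excluded predicted-relevant records, and everything
  predicted irrelevant). No consensus step.
* ML second screener -- the second reviewer screens everything as usual; the
  senior reviewer screens only the training block and predicted-relevant
  records; a record advances on the second reviewer's relevant call or on the
  senior's relevant call for a record the senior saw.

Each simulator returns the set of advanced records, the missed final-report
records, and a ledger counting every screening decision, so workload savings
against the dual baseline (two screenings per record) is exact arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from screensim.classifier import RelevancePrediction
from screensim.corpus_io import ReviewDataset

WORKFLOWS = (
    "dual_independent",
    "single_reviewer",
    "liberal_accelerated_ml",
    "second_screener_ml",
)


@dataclass(frozen=True)
class EffortLedger:
    """Exact screening-effort bookkeeping for one simulated workflow."""

    n_records: int
    training_size: int
    predicted_relevant: int
    predicted_irrelevant: int
    senior_excluded_among_predicted_relevant: int
    screenings_senior: int
    screenings_second: int

    def __post_init__(self) -> None:
        counts = (
            self.n_records,
            self.training_size,
            self.predicted_relevant,
            self.predicted_irrelevant,
            self.senior_excluded_among_predicted_relevant,
            self.screenings_senior,
            self.screenings_second,
        )
        if any(c < 0 for c in counts):
            raise ValueError("ledger counts must be non-negative")
        if self.n_records != (
            self.training_size + self.predicted_relevant + self.predicted_irrelevant
        ):
            raise ValueError(
                "ledger inconsistent: N != T + predicted_relevant + predicted_irrelevant"
            )
        if self.senior_excluded_among_predicted_relevant > self.predicted_relevant:
            raise ValueError("E_sp cannot exceed the predicted-relevant count")

    @property
    def total_screenings(self) -> int:
        return self.screenings_senior + self.screenings_second

    @property
    def dual_baseline(self) -> int:
        return 2 * self.n_records

    @property
    def workload_savings(self) -> int:
        return self.dual_baseline - self.total_screenings


@dataclass(frozen=True)
class WorkflowResult:
    """Routing outcome of one workflow on one review."""

    workflow: str
    ta_included_ids: frozenset[str]
    missed_ids: frozenset[str]
    ledger: EffortLedger

    def __post_init__(self) -> None:
        if self.workflow not in WORKFLOWS:
            raise ValueError(f"unknown workflow {self.workflow!r}")


def _result(
    workflow: str,
    ds: ReviewDataset,
    advanced: set[str],
    ledger: EffortLedger,
) -> WorkflowResult:
    missed = frozenset(ds.final_report_ids - advanced)
    return WorkflowResult(
        workflow=workflow,
        ta_included_ids=frozenset(advanced),
        missed_ids=missed,
        ledger=ledger,
    )


def _require_decisions(ds: ReviewDataset, roles: Sequence[str]) -> dict[str, dict[str, str]]:
    out: dict[str, dict[str, str]] = {}
    for role in roles:
        calls = ds.decisions_for(role)
        missing = [rid for rid in ds.record_ids if rid not in calls]
        if missing:
            raise ValueError(
                f"{role} decisions missing for {len(missing)} records, "
                f"e.g. {missing[:5]}"
            )
        out[role] = calls
    return out


def simulate_dual_independent(ds: ReviewDataset) -> WorkflowResult:
    """Both reviewers screen every record; either relevant call advances it."""
    calls = _require_decisions(ds, ["senior", "second"])
    advanced = {
        rid
        for rid in ds.record_ids
        if calls["senior"][rid] == "relevant" or calls["second"][rid] == "relevant"
    }
    n = ds.n_records
    ledger = EffortLedger(
        n_records=n,
        training_size=0,
        predicted_relevant=0,
        predicted_irrelevant=n,
        senior_excluded_among_predicted_relevant=0,
        screenings_senior=n,
        screenings_second=n,
    )
    return _result("dual_independent", ds, advanced, ledger)


def simulate_single_reviewer(ds: ReviewDataset, role: str = "senior") -> WorkflowResult:
    """One reviewer screens everything alone (rapid-review style)."""
    calls = _require_decisions(ds, [role])[role]
    advanced = {rid for rid in ds.record_ids if calls[rid] == "relevant"}
    n = ds.n_records
    ledger = EffortLedger(
        n_records=n,
        training_size=0,
        predicted_relevant=0,
        predicted_irrelevant=n,
        senior_excluded_among_predicted_relevant=0,
        screenings_senior=n if role == "senior" else 0,
        screenings_second=n if role == "second" else 0,
    )
    return _result("single_reviewer", ds, advanced, ledger)


def _split_predictions(
    ds: ReviewDataset,
    predictions: Sequence[RelevancePrediction] | Mapping[str, str],
    train_ids: Sequence[str],
) -> tuple[set[str], set[str], set[str]]:
    train = set(train_ids)
    if isinstance(predictions, Mapping):
        pred_labels = dict(predictions)
    else:
        pred_labels = {p.record_id: p.hard_label for p in predictions}
    overlap = train & set(pred_labels)
    if overlap:
        raise ValueError(
            f"predictions overlap the training set: {sorted(overlap)[:5]}"
        )
    expected = set(ds.record_ids) - train
    if set(pred_labels) != expected:
        diff = expected.symmetric_difference(pred_labels)
        raise ValueError(
            f"predictions must cover exactly the non-training records; "
            f"mismatch on {len(diff)} ids, e.g. {sorted(diff)[:5]}"
        )
    pred_rel = {rid for rid, lab in pred_labels.items() if lab == "relevant"}
    pred_irr = expected - pred_rel
    return train, pred_rel, pred_irr


def simulate_liberal_accelerated_ml(
    ds: ReviewDataset,
    predictions: Sequence[RelevancePrediction] | Mapping[str, str],
    train_ids: Sequence[str],
) -> WorkflowResult:
    """ML-assisted liberal-accelerated screening.

    Training records are dual-screened (either relevant call advances).
    Predicted-relevant records go to the senior reviewer; a senior exclusion
    is double-checked by the second reviewer. Predicted-irrelevant records go
    straight to the second reviewer to confirm or refute the exclusion.
    """
    calls = _require_decisions(ds, ["senior", "second"])
    train, pred_rel, pred_irr = _split_predictions(ds, predictions, train_ids)

    advanced: set[str] = set()
    e_sp = 0
    for rid in train:
        if calls["senior"][rid] == "relevant" or calls["second"][rid] == "relevant":
            advanced.add(rid)
    for rid in pred_rel:
        if calls["senior"][rid] == "relevant":
            advanced.add(rid)
        else:
            e_sp += 1
            if calls["second"][rid] == "relevant":
                advanced.add(rid)
    for rid in pred_irr:
        if calls["second"][rid] == "relevant":
            advanced.add(rid)

    ledger = EffortLedger(
        n_records=ds.n_records,
        training_size=len(train),
        predicted_relevant=len(pred_rel),
        predicted_irrelevant=len(pred_irr),
        senior_excluded_among_predicted_relevant=e_sp,
        screenings_senior=len(train) + len(pred_rel),
        screenings_second=len(train) + e_sp + len(pred_irr),
    )
    return _result("liberal_accelerated_ml", ds, advanced, ledger)


def simulate_second_screener_ml(
    ds: ReviewDataset,
    predictions: Sequence[RelevancePrediction] | Mapping[str, str],
    train_ids: Sequence[str],
) -> WorkflowResult:
    """Semi-automated second-screener workflow.

    The second reviewer screens all records as usual; the senior reviewer
    screens the training block plus the predicted-relevant records. A record
    advances on the second reviewer's relevant call, or on the senior's
    relevant call when the senior screened it.
    """
    calls = _require_decisions(ds, ["senior", "second"])
    train, pred_rel, pred_irr = _split_predictions(ds, predictions, train_ids)

    advanced: set[str] = set()
    e_sp = 0
    for rid in ds.record_ids:
        if calls["second"][rid] == "relevant":
            advanced.add(rid)
        if rid in train or rid in pred_rel:
            if calls["senior"][rid] == "relevant":
                advanced.add(rid)
    for rid in pred_rel:
        if calls["senior"][rid] != "relevant":
            e_sp += 1

    ledger = EffortLedger(
        n_records=ds.n_records,
        training_size=len(train),
        predicted_relevant=len(pred_rel),
        predicted_irrelevant=len(pred_irr),
        senior_excluded_among_predicted_relevant=e_sp,
        screenings_senior=len(train) + len(pred_rel),
        screenings_second=ds.n_records,
    )
    return _result("second_screener_ml", ds, advanced, ledger)
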