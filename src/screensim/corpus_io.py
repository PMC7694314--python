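"""Data model for review datasets and readers/writers for citation formats.

A review dataset bundles the candidate records retrieved by the searches
(title + abstract), the two reviewers' title-abstract decisions, the set of
records included in the final report (the gold standard for evaluating a
screening workflow), and study-level characteristics for the final-report
records. Citations travel as RIS; everything tabular is UTF-8 comma-separated
CSV with a header row.
"""

from __future__ import annotations

import csv
import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

REVIEWER_ROLES = ("senior", "second")
DECISIONS = ("relevant", "irrelevant")
DESIGNS = ("trial", "observational", "mixed_methods", "qualitative", "review")
RISK_OF_BIAS = ("low", "high_or_unclear", "unknown")
REVIEW_TYPES = ("systematic", "rapid")
QUESTION_TYPES = ("single", "multiple")
INTERVENTION_TYPES = ("simple", "complex")
DESIGN_SCOPES = ("single_trials", "single_reviews", "multiple")


class DatasetValidationError(ValueError):
    """A dataset violates a structural invariant."""


class RisParseError(ValueError):
    """An RIS file could not be parsed."""


@dataclass(frozen=True)
class CitationRecord:
    """One candidate record: the unit of title-abstract screening."""

    record_id: str
    title: str
    abstract: str = ""
    review_id: str = ""

    def __post_init__(self) -> None:
        if not self.title:
            raise DatasetValidationError(
                f"record {self.record_id!r}: title must be non-empty"
            )

    @property
    def text(self) -> str:
        return f"{self.title} {self.abstract}".strip()


@dataclass(frozen=True)
class ScreeningDecision:
    """A reviewer's title-abstract call on one record.

    ``relevant`` merges the include and unsure labels: either advances a
    record to full text, and retrospectively the two cannot be told apart.
    """

    record_id: str
    reviewer_role: str
    decision: str

    def __post_init__(self) -> None:
        if self.reviewer_role not in REVIEWER_ROLES:
            raise DatasetValidationError(
                f"unknown reviewer role {self.reviewer_role!r}; "
                f"expected one of {REVIEWER_ROLES}"
            )
        if self.decision not in DECISIONS:
            raise DatasetValidationError(
                f"unknown decision {self.decision!r}; expected one of {DECISIONS}"
            )


@dataclass(frozen=True)
class StudyCharacteristics:
    """Design / risk-of-bias / publication metadata for a final-report study."""

    record_id: str
    design: str
    risk_of_bias: str
    pub_year: int
    impact_factor: float | None = None

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise DatasetValidationError(
                f"record {self.record_id!r}: unknown design {self.design!r}"
            )
        if self.risk_of_bias not in RISK_OF_BIAS:
            raise DatasetValidationError(
                f"record {self.record_id!r}: unknown risk_of_bias "
                f"{self.risk_of_bias!r}"
            )
        if not (1900 <= self.pub_year <= 2100):
            raise DatasetValidationError(
                f"record {self.record_id!r}: implausible pub_year {self.pub_year}"
            )
        if self.impact_factor is not None and self.impact_factor < 0:
            raise DatasetValidationError(
                f"record {self.record_id!r}: negative impact_factor"
            )


@dataclass(frozen=True)
class ReviewMeta:
    """Review-level categorical characteristics."""

    review_type: str = "systematic"
    question_type: str = "single"
    intervention_type: str = "simple"
    design_scope: str = "multiple"

    def __post_init__(self) -> None:
        for value, allowed, name in (
            (self.review_type, REVIEW_TYPES, "review_type"),
            (self.question_type, QUESTION_TYPES, "question_type"),
            (self.intervention_type, INTERVENTION_TYPES, "intervention_type"),
            (self.design_scope, DESIGN_SCOPES, "design_scope"),
        ):
            if value not in allowed:
                raise DatasetValidationError(
                    f"{name} must be one of {allowed}, got {value!r}"
                )


@dataclass
class ReviewDataset:
    """A complete review corpus with decisions, labels and characteristics.

    ``truth`` holds latent record-level relevance for synthetic corpora; it is
    absent for real data (the final report is then the only gold standard).
    """

    records: list[CitationRecord]
    decisions: list[ScreeningDecision] = field(default_factory=list)
    final_report_ids: frozenset[str] = frozenset()
    characteristics: list[StudyCharacteristics] = field(default_factory=list)
    review_meta: ReviewMeta = field(default_factory=ReviewMeta)
    truth: dict[str, bool] | None = None

    def __post_init__(self) -> None:
        self.final_report_ids = frozenset(self.final_report_ids)
        self.validate()

    # -- queries ----------------------------------------------------------

    @property
    def record_ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    @property
    def n_records(self) -> int:
        return len(self.records)

    def decisions_for(self, role: str) -> dict[str, str]:
        """Map record_id -> decision for one reviewer role."""
        if role not in REVIEWER_ROLES:
            raise DatasetValidationError(f"unknown reviewer role {role!r}")
        return {
            d.record_id: d.decision
            for d in self.decisions
            if d.reviewer_role == role
        }

    def characteristics_by_id(self) -> dict[str, StudyCharacteristics]:
        return {c.record_id: c for c in self.characteristics}

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        ids = [r.record_id for r in self.records]
        id_set = set(ids)
        if len(id_set) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetValidationError(f"duplicate record ids: {dupes[:10]}")

        seen: set[tuple[str, str]] = set()
        orphans: list[str] = []
        for d in self.decisions:
            key = (d.record_id, d.reviewer_role)
            if key in seen:
                raise DatasetValidationError(
                    f"multiple {d.reviewer_role} decisions for record "
                    f"{d.record_id!r}"
                )
            seen.add(key)
            if d.record_id not in id_set:
                orphans.append(d.record_id)
        if orphans:
            raise DatasetValidationError(
                f"decisions reference unknown record ids: {sorted(set(orphans))[:10]}"
            )

        missing_final = self.final_report_ids - id_set
        if missing_final:
            raise DatasetValidationError(
                f"final-report ids absent from corpus: {sorted(missing_final)[:10]}"
            )

        char_ids = [c.record_id for c in self.characteristics]
        if len(set(char_ids)) != len(char_ids):
            raise DatasetValidationError("duplicate characteristics entries")
        outside = set(char_ids) - self.final_report_ids
        if outside:
            raise DatasetValidationError(
                "characteristics for records outside the final report: "
                f"{sorted(outside)[:10]}"
            )

        if self.truth is not None:
            unknown = set(self.truth) - id_set
            if unknown:
                raise DatasetValidationError(
                    f"truth labels for unknown records: {sorted(unknown)[:10]}"
                )

    # -- equality (structural, order-insensitive) --------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReviewDataset):
            return NotImplemented
        return (
            sorted(self.records, key=lambda r: r.record_id)
            == sorted(other.records, key=lambda r: r.record_id)
            and sorted(self.decisions, key=lambda d: (d.record_id, d.reviewer_role))
            == sorted(other.decisions, key=lambda d: (d.record_id, d.reviewer_role))
            and self.final_report_ids == other.final_report_ids
            and sorted(self.characteristics, key=lambda c: c.record_id)
            == sorted(other.characteristics, key=lambda c: c.record_id)
            and self.review_meta == other.review_meta
            and self.truth == other.truth
        )


# ---------------------------------------------------------------------------
# RIS
# ---------------------------------------------------------------------------

_TITLE_TAGS = ("TI", "T1")


def _generated_id(title: str, abstract: str) -> str:
    digest = hashlib.sha1(f"{title}\x1f{abstract}".encode()).hexdigest()
    return f"gen-{digest[:12]}"


def read_ris(path: str | Path) -> list[CitationRecord]:
    """Read citation records from an RIS file.

    TI/T1 maps to the title, AB to the abstract and ID to the record id.
    Entries without an ID get a content-hash id; colliding ids are
    de-duplicated by numeric suffix (one warning reports the count).
    Entries without a title are skipped with a warning, never silently.
    """
    path = Path(path)
    entries: list[dict[str, str]] = []
    current: dict[str, str] = {}
    last_tag: str | None = None
    in_entry = False
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        tag, sep, value = line[:2], line[2:6], line[6:]
        if sep == "  - " and tag.strip() and tag == tag.upper():
            if tag == "ER":
                entries.append(current)
                current, last_tag, in_entry = {}, None, False
                continue
            in_entry = True
            last_tag = tag
            if tag in current:
                current[tag] += " " + value.strip()
            else:
                current[tag] = value.strip()
        elif in_entry and last_tag is not None:
            # continuation of the previous tag's value
            current[last_tag] += " " + line.strip()
        else:
            raise RisParseError(
                f"{path.name}: malformed line {lineno} in entry "
                f"{len(entries) + 1}: {line[:60]!r}"
            )
    if current:
        entries.append(current)  # tolerate a missing trailing ER

    records: list[CitationRecord] = []
    seen: dict[str, int] = {}
    n_untitled = 0
    n_dupes = 0
    for entry in entries:
        title = next(
            (entry[t] for t in _TITLE_TAGS if entry.get(t, "").strip()), ""
        ).strip()
        abstract = entry.get("AB", "").strip()
        if not title:
            n_untitled += 1
            continue
        rid = entry.get("ID", "").strip() or _generated_id(title, abstract)
        if rid in seen:
            n_dupes += 1
            seen[rid] += 1
            rid = f"{rid}-{seen[rid]}"
        seen.setdefault(rid, 1)
        records.append(
            CitationRecord(
                record_id=rid,
                title=title,
                abstract=abstract,
                review_id=entry.get("C1", "").strip(),
            )
        )
    if n_untitled:
        warnings.warn(
            f"{path.name}: skipped {n_untitled} RIS entr"
            f"{'y' if n_untitled == 1 else 'ies'} without a title",
            stacklevel=2,
        )
    if n_dupes:
        warnings.warn(
            f"{path.name}: de-duplicated {n_dupes} record id(s) by suffixing",
            stacklevel=2,
        )
    return records


def write_ris(records: Iterable[CitationRecord], path: str | Path) -> None:
    """Write records as RIS (TY/ID/TI/AB/ER per entry)."""
    lines: list[str] = []
    for r in records:
        lines.append("TY  - JOUR")
        lines.append(f"ID  - {r.record_id}")
        lines.append(f"TI  - {r.title}")
        if r.abstract:
            lines.append(f"AB  - {r.abstract}")
        if r.review_id:
            lines.append(f"C1  - {r.review_id}")  # custom tag: owning review
        lines.append("ER  - ")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# ---------------------------------------------------------------------------
# Dataset directory layout
# ---------------------------------------------------------------------------

_CITATIONS = "citations.ris"
_DECISIONS = "decisions.csv"
_FINAL = "final_report.csv"
_CHARACTERISTICS = "characteristics.csv"
_TRUTH = "truth.csv"
_META = "review_meta.yaml"


def write_dataset(ds: ReviewDataset, directory: str | Path) -> None:
    """Write a dataset to a directory (RIS + CSVs + YAML meta).

    Output is deterministic: rows are sorted, so the same dataset always
    produces byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_ris(sorted(ds.records, key=lambda r: r.record_id), directory / _CITATIONS)

    with open(directory / _DECISIONS, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "reviewer_role", "decision"])
        for d in sorted(ds.decisions, key=lambda d: (d.record_id, d.reviewer_role)):
            w.writerow([d.record_id, d.reviewer_role, d.decision])

    with open(directory / _FINAL, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id"])
        for rid in sorted(ds.final_report_ids):
            w.writerow([rid])

    with open(directory / _CHARACTERISTICS, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "design", "risk_of_bias", "pub_year", "impact_factor"])
        for c in sorted(ds.characteristics, key=lambda c: c.record_id):
            w.writerow(
                [
                    c.record_id,
                    c.design,
                    c.risk_of_bias,
                    c.pub_year,
                    "" if c.impact_factor is None else repr(c.impact_factor),
                ]
            )

    if ds.truth is not None:
        with open(directory / _TRUTH, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["record_id", "relevant"])
            for rid in sorted(ds.truth):
                w.writerow([rid, int(ds.truth[rid])])

    meta = {
        "review_type": ds.review_meta.review_type,
        "question_type": ds.review_meta.question_type,
        "intervention_type": ds.review_meta.intervention_type,
        "design_scope": ds.review_meta.design_scope,
    }
    (directory / _META).write_text(
        yaml.safe_dump(meta, sort_keys=True), encoding="utf-8"
    )


def _read_csv_rows(path: Path, expected: Sequence[str]) -> list[dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != list(expected):
            raise DatasetValidationError(
                f"{path.name}: expected header {list(expected)}, "
                f"got {reader.fieldnames}"
            )
        return list(reader)


def read_dataset(
    directory: str | Path, config: Mapping[str, str] | None = None
) -> ReviewDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    ``config`` overrides the review-level meta; otherwise ``review_meta.yaml``
    is used when present. All structural invariants are enforced on load.
    """
    directory = Path(directory)
    records = read_ris(directory / _CITATIONS)

    decisions: list[ScreeningDecision] = []
    if (directory / _DECISIONS).exists():
        for row in _read_csv_rows(
            directory / _DECISIONS, ["record_id", "reviewer_role", "decision"]
        ):
            decisions.append(
                ScreeningDecision(row["record_id"], row["reviewer_role"], row["decision"])
            )

    final_ids: frozenset[str] = frozenset()
    if (directory / _FINAL).exists():
        final_ids = frozenset(
            row["record_id"] for row in _read_csv_rows(directory / _FINAL, ["record_id"])
        )

    characteristics: list[StudyCharacteristics] = []
    if (directory / _CHARACTERISTICS).exists():
        for row in _read_csv_rows(
            directory / _CHARACTERISTICS,
            ["record_id", "design", "risk_of_bias", "pub_year", "impact_factor"],
        ):
            characteristics.append(
                StudyCharacteristics(
                    record_id=row["record_id"],
                    design=row["design"],
                    risk_of_bias=row["risk_of_bias"],
                    pub_year=int(row["pub_year"]),
                    impact_factor=(
                        None if row["impact_factor"] == "" else float(row["impact_factor"])
                    ),
                )
            )

    truth: dict[str, bool] | None = None
    if (directory / _TRUTH).exists():
        truth = {
            row["record_id"]: bool(int(row["relevant"]))
            for row in _read_csv_rows(directory / _TRUTH, ["record_id", "relevant"])
        }

    meta_kwargs: dict[str, str] = {}
    if config is not None:
        meta_kwargs = dict(config)
    elif (directory / _META).exists():
        meta_kwargs = yaml.safe_load((directory / _META).read_text(encoding="utf-8"))
    review_meta = ReviewMeta(**meta_kwargs) if meta_kwargs else ReviewMeta()

    return ReviewDataset(
        records=records,
        decisions=decisions,
        final_report_ids=final_ids,
        characteristics=characteristics,
        review_meta=review_meta,
        truth=truth,
    )
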