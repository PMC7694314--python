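"""Contingency tables and exact tests for characteristic-misprediction links.

For the pooled set of final-report studies, each record (outside the training
sets) is either correctly predicted relevant or incorrectly predicted
irrelevant by the classifier. Stratifying those outcomes by a review- or
study-level characteristic gives an r x 2 contingency table, tested with
Fisher's exact test (2 x 2) or its Freeman-Halton generalization (r x c).
Continuous publication characteristics (year, journal impact factor) are
compared between the correctly and incorrectly predicted groups with a
pooled-variance unpaired t-test.

The Freeman-Halton p-value is computed by full enumeration of all tables with
the observed margins, summing the multivariate hypergeometric probabilities
of tables no more probable than the observed one (the point-probability
two-sided criterion, as in standard Fisher implementations). Above a
configurable enumeration budget a seeded Monte-Carlo estimate with its
standard error is returned instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import scipy.stats
from scipy.special import gammaln

from screensim.classifier import RelevancePrediction
from screensim.corpus_io import StudyCharacteristics

# same relative slack scipy uses when comparing point probabilities
_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """r x c table of counts with labeled rows and columns."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        arr = self.to_array()
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2 x 2")
        if arr.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match the count matrix shape")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_array(
        cls,
        counts: Sequence[Sequence[int]],
        row_labels: Sequence[str] | None = None,
        col_labels: Sequence[str] | None = None,
    ) -> "ContingencyTable":
        arr = np.asarray(counts, dtype=int)
        rows = tuple(row_labels) if row_labels else tuple(
            f"row{i}" for i in range(arr.shape[0])
        )
        cols = tuple(col_labels) if col_labels else tuple(
            f"col{j}" for j in range(arr.shape[1])
        )
        return cls(rows, cols, tuple(tuple(int(x) for x in r) for r in arr))

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)

    @property
    def row_margins(self) -> np.ndarray:
        return self.to_array().sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.to_array().sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.to_array().sum())


def build_table(
    predictions: Iterable[RelevancePrediction] | Mapping[str, str],
    characteristics: Iterable[StudyCharacteristics],
    stratifier: str | Callable[[StudyCharacteristics], str | None],
    *,
    train_ids: Iterable[str] = (),
) -> ContingencyTable:
    """Cross-tabulate prediction correctness by a characteristic.

    Rows are the stratifier's categories, columns are correct (predicted
    relevant) vs incorrect (predicted irrelevant). Only final-report records
    with a characteristics entry enter; training-set records are excluded,
    records whose stratifying attribute is missing (None or "unknown") are
    excluded with a warning, and empty categories are dropped with a warning.
    """
    if isinstance(predictions, Mapping):
        pred_labels = dict(predictions)
    else:
        pred_labels = {p.record_id: p.hard_label for p in predictions}
    train = set(train_ids)
    if callable(stratifier):
        get_category = stratifier
    else:
        attr = stratifier
        get_category = lambda c: getattr(c, attr)  # noqa: E731

    counts: dict[str, list[int]] = {}
    n_missing_attr = 0
    n_missing_pred = []
    for char in characteristics:
        rid = char.record_id
        if rid in train:
            continue
        if rid not in pred_labels:
            n_missing_pred.append(rid)
            continue
        category = get_category(char)
        if category is None or category == "unknown":
            n_missing_attr += 1
            continue
        row = counts.setdefault(str(category), [0, 0])
        if pred_labels[rid] == "relevant":
            row[0] += 1
        else:
            row[1] += 1
    if n_missing_pred:
        raise ValueError(
            f"final-report records without a prediction: {n_missing_pred[:10]}"
        )
    if n_missing_attr:
        warnings.warn(
            f"excluded {n_missing_attr} record(s) with missing stratifier value",
            stacklevel=2,
        )
    empty = [k for k, v in counts.items() if sum(v) == 0]
    for k in empty:
        warnings.warn(f"dropped empty category {k!r}", stacklevel=2)
        del counts[k]
    if len(counts) < 2:
        raise ValueError("need at least two non-empty categories to tabulate")
    labels = sorted(counts)
    return ContingencyTable(
        row_labels=tuple(labels),
        col_labels=("correct", "incorrect"),
        counts=tuple(tuple(counts[k]) for k in labels),
    )


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------


def _as_array(table: ContingencyTable | Sequence[Sequence[int]]) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.to_array()
    arr = np.asarray(table, dtype=int)
    if arr.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    return arr


def fisher_exact_2x2(table: ContingencyTable | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2 x 2 table (point-probability rule)."""
    arr = _as_array(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2 x 2 table, got {arr.shape}")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("every margin must be positive")
    return float(scipy.stats.fisher_exact(arr, alternative="two-sided")[1])


@dataclass(frozen=True)
class ExactTestResult:
    """p-value from an exact r x c test, with Monte-Carlo error if sampled."""

    p: float
    method: str  # "enumeration" | "monte_carlo"
    mc_se: float | None = None
    n_tables: int | None = None


@lru_cache(maxsize=None)
def _logfact_table(n: int) -> np.ndarray:
    return gammaln(np.arange(n + 1) + 1.0)


def _count_tables(rows: tuple[int, ...], cols: tuple[int, ...]) -> int:
    """Number of non-negative integer matrices with the given margins."""

    @lru_cache(maxsize=None)
    def count(i: int, rem: tuple[int, ...]) -> int:
        if i == len(rows) - 1:
            return 1 if sum(rem) == rows[i] else 0

        def comps(row_total: int, rem_: tuple[int, ...]):
            if len(rem_) == 1:
                if row_total <= rem_[0]:
                    yield (row_total,)
                return
            for x in range(min(row_total, rem_[0]) + 1):
                for rest in comps(row_total - x, rem_[1:]):
                    yield (x,) + rest

        total = 0
        for comp in comps(rows[i], rem):
            total += count(i + 1, tuple(r - c for r, c in zip(rem, comp)))
        return total

    return count(0, cols)


def _enumerate_p_two_col(
    rows: np.ndarray, col1: int, s_obs: float, log_norm: float
) -> tuple[float, int]:
    """Exact p for an r x 2 table by enumeration, vectorized over one row.

    Table probability is exp(log_norm - S) with S = sum of log x_ij!; a table
    is at least as extreme as the observed one iff S >= s_obs - tol.
    """
    order = np.argsort(rows)  # recurse over small rows, vectorize a large one
    r = rows[order]
    lf = _logfact_table(int(rows.sum()))
    suffix = np.concatenate([np.cumsum(r[::-1])[::-1], [0]])
    tol = _REL_TOL * max(1.0, abs(s_obs))
    p_acc = 0.0
    n_tables = 0

    def rec(i: int, rem1: int, s_partial: float) -> None:
        nonlocal p_acc, n_tables
        if i == len(r) - 2:
            row, last = int(r[i]), int(r[i + 1])
            lo = max(0, rem1 - last)
            hi = min(row, rem1)
            if lo > hi:
                return
            x = np.arange(lo, hi + 1)
            s = (
                s_partial
                + lf[x]
                + lf[row - x]
                + lf[rem1 - x]
                + lf[last - rem1 + x]
            )
            n_tables += len(x)
            qualifying = s >= s_obs - tol
            if qualifying.any():
                p_acc += float(np.exp(log_norm - s[qualifying]).sum())
            return
        row = int(r[i])
        lo = max(0, rem1 - int(suffix[i + 1]))
        hi = min(row, rem1)
        for x in range(lo, hi + 1):
            rec(i + 1, rem1 - x, s_partial + lf[x] + lf[row - x])

    rec(0, col1, 0.0)
    return min(p_acc, 1.0), n_tables


def _enumerate_p_generic(
    rows: np.ndarray, cols: np.ndarray, s_obs: float, log_norm: float
) -> tuple[float, int]:
    lf = _logfact_table(int(rows.sum()))
    tol = _REL_TOL * max(1.0, abs(s_obs))
    p_acc = 0.0
    n_tables = 0

    def comps(row_total: int, rem: tuple[int, ...]):
        if len(rem) == 1:
            if row_total <= rem[0]:
                yield (row_total,)
            return
        for x in range(min(row_total, rem[0]) + 1):
            for rest in comps(row_total - x, rem[1:]):
                yield (x,) + rest

    def rec(i: int, rem: tuple[int, ...], s_partial: float) -> None:
        nonlocal p_acc, n_tables
        if i == len(rows) - 1:
            s = s_partial + sum(lf[c] for c in rem)
            n_tables += 1
            if s >= s_obs - tol:
                p_acc += float(np.exp(log_norm - s))
            return
        for comp in comps(int(rows[i]), rem):
            rec(
                i + 1,
                tuple(r - c for r, c in zip(rem, comp)),
                s_partial + sum(lf[c] for c in comp),
            )

    rec(0, tuple(int(c) for c in cols), 0.0)
    return min(p_acc, 1.0), n_tables


def _mc_p(
    rows: np.ndarray,
    cols: np.ndarray,
    s_obs: float,
    n_mc: int,
    seed: int,
) -> tuple[float, float]:
    """Monte-Carlo p by permuting column labels against row blocks."""
    rng = np.random.default_rng(seed)
    n = int(rows.sum())
    lf = _logfact_table(n)
    labels = np.repeat(np.arange(len(cols), dtype=np.int64), cols)
    row_edges = np.cumsum(rows)[:-1]
    tol = _REL_TOL * max(1.0, abs(s_obs))
    chunk = max(1, min(n_mc, 2_000_000 // max(n, 1)))
    n_extreme = 0
    done = 0
    while done < n_mc:
        b = min(chunk, n_mc - done)
        perm = rng.permuted(np.tile(labels, (b, 1)), axis=1)
        s = np.zeros(b)
        for seg in np.split(perm, row_edges, axis=1):
            for j in range(len(cols)):
                s += lf[(seg == j).sum(axis=1)]
        n_extreme += int((s >= s_obs - tol).sum())
        done += b
    p = n_extreme / n_mc
    se = float(np.sqrt(max(p * (1 - p), 1e-12) / n_mc))
    return p, se


def freeman_halton(
    table: ContingencyTable | Sequence[Sequence[int]],
    *,
    max_tables: int = 10_000_000,
    n_mc: int = 100_000,
    seed: int = 0,
) -> ExactTestResult:
    """Exact two-sided p for an r x c table (Freeman-Halton test).

    Enumerates every table with the observed margins when their number is
    within ``max_tables``; otherwise estimates the p-value by seeded
    Monte-Carlo sampling of tables under the null (reported with its
    standard error). On 2 x 2 input this reduces to Fisher's exact test.
    """
    arr = _as_array(table)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    keep_r, keep_c = rows > 0, cols > 0
    arr = arr[keep_r][:, keep_c]
    rows, cols = rows[keep_r], cols[keep_c]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        # after dropping empty margins no association is testable
        return ExactTestResult(p=1.0, method="enumeration", n_tables=1)
    n = int(arr.sum())
    if n < 1:
        raise ValueError("table total must be >= 1")

    lf = _logfact_table(n)
    # log P(table) = log_norm - sum log x_ij!
    log_norm = float(lf[rows].sum() + lf[cols].sum() - lf[n])
    s_obs = float(lf[arr].sum())

    # orient so columns are the short dimension, rows the long one
    if arr.shape[0] < arr.shape[1]:
        arr = arr.T
        rows, cols = cols, rows

    n_tables = _count_tables(tuple(int(r) for r in rows), tuple(int(c) for c in cols))
    if n_tables <= max_tables:
        if arr.shape[1] == 2:
            p, visited = _enumerate_p_two_col(rows, int(cols[0]), s_obs, log_norm)
        else:
            p, visited = _enumerate_p_generic(rows, cols, s_obs, log_norm)
        return ExactTestResult(p=max(p, np.exp(log_norm - s_obs)), method="enumeration", n_tables=visited)
    p, se = _mc_p(rows, cols, s_obs, n_mc, seed)
    return ExactTestResult(p=max(p, 1.0 / n_mc), method="monte_carlo", mc_se=se)


# ---------------------------------------------------------------------------
# t-test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one group for the pooled t-test."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group needs n >= 2 for testing")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        return cls(n=len(arr), mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


@dataclass(frozen=True)
class TTestResult:
    """Unpaired pooled-variance t-test outcome."""

    mean_difference: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    df: int
    degenerate: bool = False  # zero pooled variance with unequal means


def _coerce_summary(g: GroupSummary | Sequence[float]) -> GroupSummary:
    if isinstance(g, GroupSummary):
        return g
    return GroupSummary.from_values(g)


def pooled_t_test(
    a: GroupSummary | Sequence[float],
    b: GroupSummary | Sequence[float],
    *,
    alpha: float = 0.05,
) -> TTestResult:
    """Student's pooled-variance two-sided t-test from raw values or summaries.

    CI = diff +/- t(df, 1 - alpha/2) * SE with df = n1 + n2 - 2 and the
    pooled standard error. A zero pooled variance with unequal means is
    flagged degenerate, with p reported as 0.
    """
    ga, gb = _coerce_summary(a), _coerce_summary(b)
    diff = ga.mean - gb.mean
    df = ga.n + gb.n - 2
    sp2 = ((ga.n - 1) * ga.sd**2 + (gb.n - 1) * gb.sd**2) / df
    if sp2 == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, 0.0, 0.0, 0.0, 1.0, df)
        return TTestResult(
            diff, diff, diff, float("inf") if diff > 0 else float("-inf"),
            0.0, df, degenerate=True,
        )
    se = float(np.sqrt(sp2 * (1 / ga.n + 1 / gb.n)))
    t_stat, p = scipy.stats.ttest_ind_from_stats(
        ga.mean, ga.sd, ga.n, gb.mean, gb.sd, gb.n, equal_var=True
    )
    crit = float(scipy.stats.t.ppf(1 - alpha / 2, df))
    return TTestResult(
        mean_difference=diff,
        ci_low=diff - crit * se,
        ci_high=diff + crit * se,
        t=float(t_stat),
        p=float(p),
        df=df,
    )
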