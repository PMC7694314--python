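"""Workflow routing, missed sets and exact effort ledgers."""

import numpy as np
import pytest

from screensim import (
    CitationRecord,
    EffortLedger,
    ReviewDataset,
    ScreeningDecision,
    simulate_dual_independent,
    simulate_liberal_accelerated_ml,
    simulate_second_screener_ml,
    simulate_single_reviewer,
)

ALL_ML = (simulate_liberal_accelerated_ml, simulate_second_screener_ml)


def _dataset(n, senior_rel, second_rel, final):
    """Build a dataset with explicit per-reviewer relevant-id sets."""
    records = [CitationRecord(f"r{i:05d}", f"title {i}") for i in range(n)]
    ids = [r.record_id for r in records]
    decisions = []
    for rid in ids:
        decisions.append(
            ScreeningDecision(
                rid, "senior", "relevant" if rid in senior_rel else "irrelevant"
            )
        )
        decisions.append(
            ScreeningDecision(
                rid, "second", "relevant" if rid in second_rel else "irrelevant"
            )
        )
    return ReviewDataset(
        records=records, decisions=decisions, final_report_ids=frozenset(final)
    )


def _random_setup(rng, n=300, n_train=40):
    ids = [f"r{i:05d}" for i in range(n)]
    senior_rel = {i for i in ids if rng.random() < 0.3}
    second_rel = {i for i in ids if rng.random() < 0.3}
    final = set(rng.choice(ids, size=20, replace=False))
    ds = _dataset(n, senior_rel, second_rel, final)
    train = list(rng.choice(ids, size=n_train, replace=False))
    rest = [i for i in ids if i not in set(train)]
    preds = {i: ("relevant" if rng.random() < 0.4 else "irrelevant") for i in rest}
    return ds, preds, train, senior_rel, second_rel, final


class TestDualIndependent:
    def test_perfect_reviewers_miss_nothing(self):
        final = {"r00001", "r00005"}
        ds = _dataset(10, final, final, final)
        assert simulate_dual_independent(ds).missed_ids == frozenset()

    def test_either_reviewer_advances(self):
        ds = _dataset(4, set(), {"r00002"}, {"r00002"})
        result = simulate_dual_independent(ds)
        assert "r00002" in result.ta_included_ids
        assert result.missed_ids == frozenset()

    def test_screenings_are_two_per_record(self):
        ds = _dataset(7, set(), set(), set())
        ledger = simulate_dual_independent(ds).ledger
        assert ledger.total_screenings == 14
        assert ledger.workload_savings == 0

    def test_missed_equals_set_logic_oracle(self, rng):
        ds, _, _, senior_rel, second_rel, final = _random_setup(rng)
        result = simulate_dual_independent(ds)
        # independent recomputation: missed = final records excluded by both
        oracle = {
            rid for rid in final if rid not in senior_rel and rid not in second_rel
        }
        assert result.missed_ids == frozenset(oracle)

    def test_missing_decisions_listed(self):
        ds = _dataset(3, set(), set(), set())
        ds = ReviewDataset(records=ds.records, decisions=ds.decisions[:-1])
        with pytest.raises(ValueError, match="second decisions missing"):
            simulate_dual_independent(ds)


class TestSingleReviewer:
    def test_perfect_reviewer_misses_nothing(self):
        final = {"r00000"}
        ds = _dataset(5, final, set(), final)
        assert simulate_single_reviewer(ds, "senior").missed_ids == frozenset()

    def test_exclude_everything_misses_all_final(self):
        final = {"r00001", "r00003"}
        ds = _dataset(5, set(), final, final)
        result = simulate_single_reviewer(ds, "senior")
        assert result.missed_ids == frozenset(final)

    def test_missed_count_matches_direct_recount(self, rng):
        ds, _, _, senior_rel, _, final = _random_setup(rng)
        result = simulate_single_reviewer(ds, "senior")
        assert len(result.missed_ids) == sum(
            1 for rid in final if rid not in senior_rel
        )

    def test_unknown_role(self):
        ds = _dataset(3, set(), set(), set())
        with pytest.raises(ValueError, match="unknown reviewer role"):
            simulate_single_reviewer(ds, "third")


class TestLiberalAcceleratedML:
    def test_ledger_identity_on_published_row_shape(self):
        """N=2928, T=200, P=319 with 192 senior exclusions among the
        predicted-relevant gives workload savings 2536 (43% of 2N)."""
        n, t, p, e_sp = 2928, 200, 319, 192
        ids = [f"r{i:05d}" for i in range(n)]
        train = ids[:t]
        pred_rel = ids[t : t + p]
        pred_irr = ids[t + p :]
        senior_rel = set(pred_rel[e_sp:])  # senior includes P - E_sp of them
        ds = _dataset(n, senior_rel, set(), set())
        preds = {i: "relevant" for i in pred_rel} | {
            i: "irrelevant" for i in pred_irr
        }
        ledger = simulate_liberal_accelerated_ml(ds, preds, train).ledger
        assert ledger.senior_excluded_among_predicted_relevant == e_sp
        assert ledger.total_screenings == 2 * t + p + e_sp + len(pred_irr)
        assert ledger.workload_savings == 2536
        assert round(100 * ledger.workload_savings / (2 * n)) == 43

    def test_all_predicted_relevant_perfect_senior_misses_nothing(self):
        n = 30
        final = {f"r{i:05d}" for i in (5, 9, 23)}
        ds = _dataset(n, final, set(), final)
        ids = [r.record_id for r in ds.records]
        train = [i for i in ids[:4] if i not in final]
        preds = {i: "relevant" for i in ids if i not in set(train)}
        result = simulate_liberal_accelerated_ml(ds, preds, train)
        assert result.missed_ids == frozenset()

    def test_all_predicted_irrelevant_perfect_second_reviewer(self):
        n, t = 30, 4
        final = {f"r{i:05d}" for i in (7, 11)}
        ds = _dataset(n, set(), final, final)
        ids = [r.record_id for r in ds.records]
        train = ids[:t]
        preds = {i: "irrelevant" for i in ids[t:]}
        result = simulate_liberal_accelerated_ml(ds, preds, train)
        assert result.missed_ids == frozenset()
        assert result.ledger.total_screenings == 2 * t + (n - t)

    def test_prediction_training_overlap_rejected(self):
        ds = _dataset(10, set(), set(), set())
        ids = [r.record_id for r in ds.records]
        preds = {i: "irrelevant" for i in ids}  # includes the training ids
        with pytest.raises(ValueError, match="overlap"):
            simulate_liberal_accelerated_ml(ds, preds, ids[:2])

    def test_routing_matches_brute_force_oracle(self, rng):
        ds, preds, train, senior_rel, second_rel, final = _random_setup(rng)
        result = simulate_liberal_accelerated_ml(ds, preds, train)
        advanced = set()
        for rid in ds.record_ids:  # plain restatement of the routing rules
            if rid in set(train):
                if rid in senior_rel or rid in second_rel:
                    advanced.add(rid)
            elif preds[rid] == "relevant":
                if rid in senior_rel or rid in second_rel:
                    advanced.add(rid)
            elif rid in second_rel:
                advanced.add(rid)
        assert result.ta_included_ids == frozenset(advanced)
        assert result.missed_ids == frozenset(final - advanced)


class TestSecondScreenerML:
    def test_savings_formula_published_row(self):
        """N=2928, T=200, P=319: savings = N - T - P = 2409."""
        n, t, p = 2928, 200, 319
        ids = [f"r{i:05d}" for i in range(n)]
        ds = _dataset(n, set(), set(), set())
        preds = {i: "relevant" for i in ids[t : t + p]} | {
            i: "irrelevant" for i in ids[t + p :]
        }
        ledger = simulate_second_screener_ml(ds, preds, ids[:t]).ledger
        assert ledger.workload_savings == n - t - p == 2409

    def test_degenerates_to_dual_when_all_predicted_relevant(self):
        n, t = 20, 5
        ids = [f"r{i:05d}" for i in range(n)]
        ds = _dataset(n, set(), set(), set())
        preds = {i: "relevant" for i in ids[t:]}
        ledger = simulate_second_screener_ml(ds, preds, ids[:t]).ledger
        assert ledger.workload_savings == 0

    def test_perfect_second_reviewer_safety(self, rng):
        ids = [f"r{i:05d}" for i in range(50)]
        final = {ids[3], ids[17], ids[44]}
        ds = _dataset(50, set(), final, final)
        train = ids[:5]
        preds = {
            i: ("relevant" if rng.random() < 0.5 else "irrelevant")
            for i in ids[5:]
        }
        result = simulate_second_screener_ml(ds, preds, train)
        assert result.missed_ids == frozenset()

    def test_missed_sets_match_liberal_when_senior_never_excludes_predicted(
        self, rng
    ):
        """When the senior includes every predicted-relevant record the two
        ML-assisted workflows miss exactly the same records."""
        ds, preds, train, senior_rel, second_rel, final = _random_setup(rng)
        pred_rel = {i for i, v in preds.items() if v == "relevant"}
        ds = _dataset(
            300,
            senior_rel | pred_rel,
            second_rel,
            final,
        )
        a = simulate_liberal_accelerated_ml(ds, preds, train)
        b = simulate_second_screener_ml(ds, preds, train)
        assert a.missed_ids == b.missed_ids


class TestLedgerInvariants:
    def test_conservation_over_randomized_fixtures(self, rng):
        for _ in range(10):
            ds, preds, train, *_ = _random_setup(rng)
            for result in (
                simulate_dual_independent(ds),
                simulate_single_reviewer(ds, "senior"),
                simulate_liberal_accelerated_ml(ds, preds, train),
                simulate_second_screener_ml(ds, preds, train),
            ):
                ledger = result.ledger
                assert (
                    ledger.workload_savings + ledger.total_screenings
                    == 2 * ledger.n_records
                )
                assert result.missed_ids <= ds.final_report_ids

    def test_perfect_reviewers_zero_missed_everywhere(self, rng):
        ids = [f"r{i:05d}" for i in range(100)]
        final = set(rng.choice(ids, size=12, replace=False))
        ds = _dataset(100, final, final, final)
        train = ids[:10]
        preds = {
            i: ("relevant" if rng.random() < 0.3 else "irrelevant")
            for i in ids[10:]
        }
        assert simulate_dual_independent(ds).missed_ids == frozenset()
        assert simulate_single_reviewer(ds, "senior").missed_ids == frozenset()
        assert simulate_liberal_accelerated_ml(ds, preds, train).missed_ids == frozenset()
        assert simulate_second_screener_ml(ds, preds, train).missed_ids == frozenset()

    def test_inconsistent_ledger_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            EffortLedger(
                n_records=10,
                training_size=5,
                predicted_relevant=3,
                predicted_irrelevant=3,
                senior_excluded_among_predicted_relevant=0,
                screenings_senior=8,
                screenings_second=8,
            )
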