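import itertools
from functools import lru_cache

import numpy as np
import pytest

from processgan import evaluation as ev
from processgan.event_log_io import Event, ProcessCase, build_event_log
from processgan.fixture_simulator import degenerate_log


@lru_cache(maxsize=None)
def recursive_edit_distance(a: tuple, b: tuple) -> int:
    """Exhaustive recursive oracle (memoized), independent of the DP path."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(recursive_edit_distance(a[1:], b) + 1,
               recursive_edit_distance(a, b[1:]) + 1,
               recursive_edit_distance(a[1:], b[1:]) + (a[0] != b[0]))


def log_from_traces(traces, delay=1.0):
    cases = [ProcessCase(f"c{i}", [Event(a, j * delay)
                                   for j, a in enumerate(tr)])
             for i, tr in enumerate(traces)]
    return build_event_log(cases)


class TestLevenshtein:
    def test_against_recursive_oracle_sampled(self, rng):
        alphabet = "xyz"
        for _ in range(300):
            a = tuple(rng.choice(list(alphabet), size=rng.integers(0, 6)))
            b = tuple(rng.choice(list(alphabet), size=rng.integers(0, 6)))
            assert ev.levenshtein(a, b) == recursive_edit_distance(a, b)

    def test_alignment_cost_matches_distance(self, rng):
        for _ in range(100):
            a = tuple(rng.choice(list("abc"), size=rng.integers(1, 7)))
            b = tuple(rng.choice(list("abc"), size=rng.integers(1, 7)))
            pairs = ev.align(a, b)
            cost = sum(1 for i, j in pairs
                       if i is None or j is None or a[i] != b[j])
            assert cost == ev.levenshtein(a, b)


class TestSPE:
    def test_identical_sequences_zero(self):
        assert ev.spe(log_from_traces([["A", "B"], ["A", "B"]])) == 0.0

    def test_hand_example(self):
        # N=2, ED((A,B),(A,C)) = 1 -> (1/4) * (1/4)
        got = ev.spe(log_from_traces([["A", "B"], ["A", "C"]]))
        assert got == pytest.approx(0.0625, abs=1e-12)

    def test_reordering_invariant(self, rng):
        traces = [["A", "B", "C"], ["A", "C"], ["B", "C", "C"], ["A"]]
        a = ev.spe(log_from_traces(traces))
        b = ev.spe(log_from_traces(traces[::-1]))
        assert a == pytest.approx(b, abs=1e-12)

    def test_needs_two(self):
        with pytest.raises(ValueError):
            ev.spe(log_from_traces([["A"]]))


class TestLengthStats:
    def test_hand_example(self):
        mean, sd = ev.length_stats(log_from_traces([["A", "B"],
                                                    ["A", "B", "C", "D"]]))
        assert mean == 3.0
        assert sd == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_equal_lengths_zero_sd(self):
        _, sd = ev.length_stats(log_from_traces([["A"], ["B"]]))
        assert sd == 0.0

    def test_single_case_warns(self, caplog):
        with caplog.at_level("WARNING"):
            mean, sd = ev.length_stats(log_from_traces([["A", "B"]]))
        assert (mean, sd) == (2.0, 0.0)
        assert "single-case" in caplog.text


class TestActivityOccurrenceError:
    def test_identical_zero(self):
        log = log_from_traces([["A", "B"], ["B", "A"]])
        assert ev.activity_occurrence_error(log, log) == 0.0

    def test_hand_example(self):
        auth = log_from_traces([["A", "B"]])          # (0.5, 0.5)
        syn = log_from_traces([["A", "A"]])           # (1, 0)
        assert ev.activity_occurrence_error(auth, syn) == pytest.approx(1.0)

    def test_disjoint_supports_max_two(self):
        auth = log_from_traces([["A", "B"]])
        syn = log_from_traces([["C", "D"]])
        assert ev.activity_occurrence_error(auth, syn) == pytest.approx(2.0)


class TestTimestampError:
    def test_identical_zero(self):
        log = log_from_traces([["A", "B", "C"]], delay=3.0)
        assert ev.timestamp_error(log, log, "mean") == 0.0
        assert ev.timestamp_error(log, log, "p90") == 0.0

    def test_hand_example_scale_100(self):
        # one activity B: authentic scaled mean 0.30, synthetic 0.25 -> 5.0
        auth = build_event_log([ProcessCase("a", [Event("A", 0.0),
                                                  Event("B", 30.0),
                                                  Event("C", 100.0)])])
        syn = build_event_log([ProcessCase("s", [Event("A", 0.0),
                                                 Event("B", 25.0),
                                                 Event("C", 100.0)])])
        assert ev.timestamp_error(auth, syn, "mean") == pytest.approx(5.0)

    def test_symmetric(self, rng):
        a = log_from_traces([["A", "B", "C"], ["B", "A"]], delay=2.0)
        b = log_from_traces([["A", "C"], ["C", "B", "A"]], delay=5.0)
        assert ev.timestamp_error(a, b, "p90") == \
            pytest.approx(ev.timestamp_error(b, a, "p90"), abs=1e-12)

    def test_absent_activity_warns(self, caplog):
        a = log_from_traces([["A", "B"]])
        b = log_from_traces([["A", "A"]])
        with caplog.at_level("WARNING"):
            ev.timestamp_error(a, b, "mean")
        assert "absent" in caplog.text

    def test_unknown_statistic(self):
        log = log_from_traces([["A"]])
        with pytest.raises(ValueError):
            ev.timestamp_error(log, log, "median")


class TestNegativeSamples:
    def test_zero_noise_identity(self, clinic_log, rng):
        neg = ev.make_negative_samples(clinic_log, 0.0, rng)
        for c1, c2 in zip(clinic_log.cases, neg.cases):
            assert c1.activities == c2.activities
            assert len(c1) == len(c2)

    def test_activity_and_timestamp_counts_match(self, clinic_log, rng):
        neg = ev.make_negative_samples(clinic_log, 0.2, rng)
        for case in neg.cases:
            assert len(case.activities) == len(case.timestamps)
            assert np.all(np.diff(case.timestamps) >= 0)

    def test_timestamps_rescaled_to_unit_interval(self, clinic_log, rng):
        neg = ev.make_negative_samples(clinic_log, 0.3, rng)
        for case in neg.cases:
            assert case.timestamps.min() >= 0.0
            assert case.timestamps.max() <= 1.0

    def test_switch_preserves_multisets(self):
        # a switch-only corruption keeps both multisets; scan seeds until the
        # single drawn op was a switch, then check invariance
        log = log_from_traces([list("ABCDEFG")], delay=1.0)
        neg = None
        for seed in range(50):
            r = np.random.default_rng(seed)
            candidate = ev.make_negative_samples(log, 1.0 / 7, r)
            if sorted(candidate.cases[0].activities) == sorted("ABCDEFG") \
                    and candidate.cases[0].activities != list("ABCDEFG"):
                neg = candidate
                break
        assert neg is not None, "no switch-only corruption found in 50 seeds"

    def test_invalid_ratio(self, clinic_log, rng):
        with pytest.raises(ValueError):
            ev.make_negative_samples(clinic_log, 1.5, rng)


class TestConsensusWorkflow:
    def test_identical_traces(self):
        log = degenerate_log(10, ["A", "B", "C"])
        consensus, branches = ev.consensus_workflow(log)
        assert consensus == ["A", "B", "C"]
        assert branches == {}

    def test_one_deviant_among_many(self):
        traces = [["A", "B", "C"]] * 9 + [["A", "X", "C"]]
        consensus, branches = ev.consensus_workflow(log_from_traces(traces))
        assert consensus == ["A", "B", "C"]
        assert branches.get("X") == 1

    def test_medoid_against_bruteforce(self, rng):
        for trial in range(10):
            traces = [tuple(rng.choice(list("abc"), size=rng.integers(1, 5)))
                      for _ in range(6)]
            got = ev._medoid_index(list(traces))
            totals = [sum(ev.levenshtein(s, t) for t in traces)
                      for s in traces]
            assert totals[got] == min(totals)

    def test_branch_counts_on_fixture(self, clinic_log):
        consensus, branches = ev.consensus_workflow(clinic_log)
        # backbone activities must be in the consensus
        for act in ["arrive", "triage", "assess", "discharge"]:
            assert act in consensus


class TestScorerContracts:
    def test_supervised_score_fractions(self, clinic_log):
        class Stub:
            def __init__(self, vals):
                self.vals = np.asarray(vals)

            def scores(self, log):
                return self.vals

        syn = degenerate_log(4, ["A", "B"])
        assert ev.supervised_score(Stub([0.9, 0.8, 0.7, 0.2]), syn) == 0.75
        assert ev.supervised_score(Stub([1.0] * 4), syn) == 1.0
        assert ev.supervised_score(Stub([0.0] * 4), syn) == 0.0

    def test_small_log_rejected(self):
        log = log_from_traces([["A", "B"]] * 5)
        with pytest.raises(ValueError):
            ev.train_offshelf_classifier(log)


def test_report_metrics_zero_on_identical_logs(small_clinic_log):
    rep = ev.evaluate(small_clinic_log, small_clinic_log, with_classifier=False)
    assert rep.act_error == 0.0
    assert rep.time_error_mean == 0.0
    assert rep.time_error_p90 == 0.0
    assert rep.authentic_spe == rep.synthetic_spe
    d = rep.to_dict()
    assert d["authentic_length"]["mean"] == d["synthetic_length"]["mean"]


def test_scorer_fpr_tpr_consistency(small_clinic_log):
    """Feeding held-out authentic cases to the FPR scorer must reproduce the
    classifier's own positive rate on them (confusion-matrix identity)."""
    cfg = ev.ClassifierConfig(epochs=10, seed=0)
    scorer, _ = ev.train_offshelf_classifier(small_clinic_log, 0.2, 3, cfg,
                                             seed=0)
    scores = scorer.scores(small_clinic_log)
    tpr = float(np.mean(scores > 0.5))
    fpr_as_synthetic = ev.supervised_score(scorer, small_clinic_log)
    assert fpr_as_synthetic == pytest.approx(tpr, abs=1e-12)
    assert tpr + float(np.mean(scores <= 0.5)) == pytest.approx(1.0)


def test_density_export(tmp_path, small_clinic_log):
    out = tmp_path / "dens.csv"
    ev.export_timestamp_densities(small_clinic_log, out)
    lines = out.read_text().splitlines()
    assert lines[0] == "activity,scaled_timestamp"
    n_events = sum(len(c) for c in small_clinic_log.cases)
    assert len(lines) - 1 == n_events
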