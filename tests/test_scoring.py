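"""Agreement statistics, trial filters, paired tests, stratification.

Oracles used here are independent of the implementation path: kappa by an
explicit double loop over trials, exact signed-rank p-values by full
enumeration of sign assignments.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from sleepsonify import (
    ParticipantRecord,
    RaterModel,
    ResponseSet,
    Trial,
    cohens_kappa,
    correct_only,
    filter_rt_outliers,
    paired_compare,
    per_stage_accuracy,
    practice_gate,
    score_report,
    symmetric_confusion,
    synth_responses,
)
from sleepsonify.eeg_io import STAGES


def make_set(truths, responses, rts=None, **kw) -> ResponseSet:
    rts = rts if rts is not None else [1.0] * len(truths)
    return ResponseSet(
        [Trial(i, t, r, rt) for i, (t, r, rt) in
         enumerate(zip(truths, responses, rts))], **kw)


def kappa_bruteforce(truths, responses):
    """Direct double-loop kappa, no matrix algebra shared with the code."""
    n = len(truths)
    p_o = sum(t == r for t, r in zip(truths, responses)) / n
    p_e = 0.0
    for label in STAGES:
        row = sum(t == label for t in truths) / n
        col = sum(r == label for r in responses) / n
        p_e += row * col
    if p_e == 1.0 or len(set(truths)) == 1:
        return None
    return (p_o - p_e) / (1.0 - p_e)


def signed_rank_exact_enumeration(d):
    """Two-sided exact Wilcoxon signed-rank p by enumerating all 2^n signs."""
    d = np.asarray([x for x in d if x != 0], dtype=float)
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([False, True], repeat=n)]
    ws = np.asarray(ws, dtype=float)
    p = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(p, 1.0)


class TestCohensKappa:
    def test_perfect_agreement(self):
        rs = make_set(["W", "N2", "N3", "REM"], ["W", "N2", "N3", "REM"])
        assert cohens_kappa(rs) == pytest.approx(1.0)

    def test_undefined_when_truth_is_constant(self):
        """A block whose true stage never varies has no defined kappa."""
        rs = make_set(["N2"] * 10, ["N2"] * 8 + ["W"] * 2)
        assert cohens_kappa(rs) is None

    def test_hand_computed_two_label_example(self):
        """Confusion [[20,5],[10,15]]: p_o=0.7, p_e=0.5, kappa=0.4."""
        truths = ["W"] * 25 + ["N2"] * 25
        responses = ["W"] * 20 + ["N2"] * 5 + ["W"] * 10 + ["N2"] * 15
        assert cohens_kappa(make_set(truths, responses)) == pytest.approx(0.4)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa(ResponseSet([]))

    def test_matches_bruteforce_on_random_sets(self):
        """Formula kappa equals the double-loop oracle on 200 random sets."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(2, 60))
            truths = [STAGES[i] for i in rng.integers(0, 5, n)]
            responses = [STAGES[i] for i in rng.integers(0, 5, n)]
            got = cohens_kappa(make_set(truths, responses))
            want = kappa_bruteforce(truths, responses)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_invariant_to_trial_order_and_joint_relabeling(self):
        rng = np.random.default_rng(7)
        truths = [STAGES[i] for i in rng.integers(0, 5, 40)]
        responses = [STAGES[i] for i in rng.integers(0, 5, 40)]
        base = cohens_kappa(make_set(truths, responses))
        perm = rng.permutation(40)
        shuffled = cohens_kappa(make_set([truths[i] for i in perm],
                                         [responses[i] for i in perm]))
        assert shuffled == pytest.approx(base)
        relabel = dict(zip(STAGES, ["REM", "N3", "N2", "N1", "W"]))
        relabeled = cohens_kappa(make_set([relabel[t] for t in truths],
                                          [relabel[r] for r in responses]))
        assert relabeled == pytest.approx(base)


class TestPerStageAccuracy:
    def test_wake_worked_example_50_percent(self):
        """5 of 10 true Wake epochs recognised -> Wake accuracy 50%."""
        truths = ["W"] * 10 + ["N2"] * 20
        responses = (["W"] * 5 + ["N2"] * 5) + ["N2"] * 20
        acc = per_stage_accuracy(make_set(truths, responses))
        assert acc["W"] == pytest.approx(50.0)

    def test_all_correct_gives_100_everywhere(self):
        truths = ["W", "N1", "N2", "N3", "REM"] * 3
        acc = per_stage_accuracy(make_set(truths, truths))
        assert acc == {s: pytest.approx(100.0) for s in STAGES}

    def test_absent_stage_omitted(self):
        acc = per_stage_accuracy(make_set(["W", "N2"], ["W", "N2"]))
        assert set(acc) == {"W", "N2"}

    def test_prevalence_weighted_accuracy_equals_overall(self):
        rng = np.random.default_rng(11)
        truths = [STAGES[i] for i in rng.integers(0, 5, 100)]
        responses = [STAGES[i] for i in rng.integers(0, 5, 100)]
        rs = make_set(truths, responses)
        acc = per_stage_accuracy(rs)
        weighted = sum(acc[s] * truths.count(s) for s in acc) / len(truths)
        assert weighted == pytest.approx(100.0 * rs.n_correct / rs.n_trials)


class TestRtFilters:
    def test_identical_rts_survive_at_sigma_zero(self):
        rs = make_set(["W"] * 5, ["W"] * 5, rts=[3.0] * 5)
        assert filter_rt_outliers(rs).n_trials == 5

    def test_extreme_rt_removed(self):
        """RTs {2 x9, 50}: 50 s exceeds mean + 2 sigma and is dropped."""
        rts = [2.0] * 9 + [50.0]
        rs = make_set(["W"] * 10, ["W"] * 10, rts=rts)
        kept = filter_rt_outliers(rs, k=2.0)
        assert kept.n_trials == 9
        assert all(t.rt == 2.0 for t in kept.trials)

    def test_infinite_sigma_is_identity(self):
        rs = make_set(["W"] * 4, ["W"] * 4, rts=[1.0, 2.0, 3.0, 100.0])
        assert filter_rt_outliers(rs, k=np.inf).n_trials == 4

    def test_single_trial_passes_through_with_warning(self):
        rs = make_set(["W"], ["W"], rts=[1.0])
        with pytest.warns(UserWarning):
            assert filter_rt_outliers(rs).n_trials == 1

    def test_never_removes_majority_on_lognormal_data(self):
        """At k=2 on lognormal RTs (n >= 30), kept trials outnumber removed."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(30, 120))
            rts = rng.lognormal(1.5, 0.5, n)
            rs = make_set(["W"] * n, ["W"] * n, rts=list(rts))
            kept = filter_rt_outliers(rs, k=2.0)
            assert kept.n_trials > n - kept.n_trials

    def test_correct_only_subset(self):
        truths = ["W", "N1", "N2", "N3"]
        responses = ["W", "W", "N2", "W"]
        kept = correct_only(make_set(truths, responses))
        assert kept.n_trials == 2
        assert all(t.response == t.true_stage for t in kept.trials)


class TestPracticeGate:
    @pytest.mark.parametrize("median_rt, passes", [
        (0.59, False),  # bot-like
        (5.5, True),    # valid stager
        (2.0, True),    # boundary: strictly-less-than fails, equality passes
    ])
    def test_median_threshold(self, median_rt, passes):
        rs = make_set(["W"] * 5, ["W"] * 5, rts=[median_rt] * 5,
                      block_id="practice")
        assert practice_gate(rs) is passes

    def test_empty_practice_block_rejected(self):
        with pytest.raises(ValueError):
            practice_gate(ResponseSet([], block_id="practice"))


class TestPairedCompare:
    def test_identical_vectors_give_p_1(self):
        with pytest.warns(UserWarning):
            res = paired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0
        assert res.direction == "equal"

    def test_n5_all_positive_exact_p(self):
        """Five positive differences: two-sided exact p = 2/2^5 = 0.0625."""
        res = paired_compare([1.1, 2.3, 3.2, 4.9, 5.5],
                             [1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.p_value == pytest.approx(0.0625)
        assert res.direction == "a>b"

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_full_enumeration(self, seed):
        """Exact signed-rank p equals 2^n enumeration for n <= 12."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        res = paired_compare(a, b, method="signed_rank_exact")
        assert res.p_value == pytest.approx(
            signed_rank_exact_enumeration(a - b), abs=1e-12)

    def test_permutation_agrees_with_exact(self):
        rng = np.random.default_rng(42)
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        exact = paired_compare(a, b, method="signed_rank_exact").p_value
        perm = paired_compare(a, b, method="permutation",
                              n_permutations=20_000, seed=0).p_value
        assert perm == pytest.approx(exact, abs=0.02)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            paired_compare([1.0], [2.0])
        with pytest.raises(ValueError):
            paired_compare([1, 2, 3], [1, 2], method="signed_rank_exact")


def _simulate_cohort(bin_sizes, effect_bin, rng):
    """Cohort where only ``effect_bin`` has a true sound benefit."""
    from sleepsonify.scoring import EXPERIENCE_BINS

    records = []
    truth = [STAGES[i % 5] for i in range(30)]  # one 30-epoch block
    pid = 0
    for bin_name, size in zip(EXPERIENCE_BINS, bin_sizes):
        for _ in range(size):
            p_sound = 0.9 if bin_name == effect_bin else 0.7
            p_nosound = 0.5 if bin_name == effect_bin else 0.7
            blocks = {
                "sound": synth_responses(
                    truth, RaterModel(symmetric_confusion(p_sound),
                                      seed=int(rng.integers(2**31))),
                    block_id="sound", participant_id=str(pid)),
                "no_sound": synth_responses(
                    truth, RaterModel(symmetric_confusion(p_nosound),
                                      seed=int(rng.integers(2**31))),
                    block_id="no_sound", participant_id=str(pid)),
            }
            records.append(ParticipantRecord(str(pid), bin_name, blocks))
            pid += 1
    return records


class TestStratifyByExperience:
    BIN_SIZES = (14, 8, 10, 5, 3)  # cohort-shaped counts

    def test_tables_have_cohort_shaped_sizes(self):
        from sleepsonify import stratify_by_experience
        from sleepsonify.scoring import EXPERIENCE_BINS

        rng = np.random.default_rng(0)
        records = _simulate_cohort(self.BIN_SIZES, "1-10", rng)
        tables = stratify_by_experience(records)
        assert {b: len(t) for b, t in tables.items()} == dict(
            zip(EXPERIENCE_BINS, self.BIN_SIZES))

    def test_single_bin_only(self):
        from sleepsonify import stratify_by_experience

        rng = np.random.default_rng(1)
        records = _simulate_cohort((6, 0, 0, 0, 0), "1-10", rng)
        tables = stratify_by_experience(records)
        assert list(tables) == ["1-10"]

    def test_selective_effect_detected_in_target_bin(self):
        """With a true benefit only in the 1-10 bin, only that bin's
        paired test is significant in >= 80% of simulated cohorts."""
        from sleepsonify import stratify_by_experience

        rng = np.random.default_rng(2024)
        hits = 0
        reps = 30
        for _ in range(reps):
            records = _simulate_cohort(self.BIN_SIZES, "1-10", rng)
            tables = stratify_by_experience(records)
            sig = {b for b, t in tables.items()
                   if len(t) >= 2 and paired_compare(
                       t["kappa_sound"], t["kappa_no_sound"]).p_value < 0.05}
            hits += sig == {"1-10"}
        assert hits / reps >= 0.8


class TestScoreReport:
    def test_report_fields_consistent(self):
        rs = synth_responses([STAGES[i % 5] for i in range(30)],
                             RaterModel(symmetric_confusion(0.8), seed=3))
        rep = score_report(rs)
        assert rep.confusion.sum() == rep.n_trials == 30
        assert all(0.0 <= v <= 100.0 for v in rep.per_stage_accuracy.values())
        assert -1.0 <= rep.kappa <= 1.0
        assert rep.rt_summary["n"] <= rep.n_correct

    def test_json_roundtrip(self, tmp_path):
        import json

        rs = make_set(["W", "N2"], ["W", "N2"], rts=[2.0, 3.0])
        rep = score_report(rs)
        path = tmp_path / "report.json"
        rep.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["n_correct"] == 2
        assert loaded["per_stage_accuracy"]["W"] == 100.0
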