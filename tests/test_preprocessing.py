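"""Exclusion rules and aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

import dislearn as dl
from dislearn import preprocessing as pp
from dislearn.synthetic_data import DesignConfig

from conftest import make_trials


def _trial(pid="p1", task="fixed", block=2, trial=1, cond="absent",
           dloc=np.nan, tloc=0, dist=0.0, rt=500.0, correct=True):
    return (pid, task, block, trial, cond, dloc, tloc, dist, rt, correct)


class TestFilterTrials:
    def test_rt_floor_boundary(self):
        trials = make_trials([
            _trial(trial=1, rt=199.0),
            _trial(trial=2, rt=200.0),
            _trial(trial=3, rt=500.0, correct=False),
            _trial(trial=4, rt=np.nan, correct=False),
        ])
        out, rep = pp.filter_trials(trials)
        assert list(out["trial"]) == [2]
        assert rep.n_removed_error_or_fast == 3
        assert rep.n_trials_out == 1

    def test_counts_on_synthetic_set(self, rng):
        # 100 trials: 7 incorrect, 3 anticipatory among the correct ones
        rows = []
        for i in range(100):
            correct = i >= 7
            rt = 150.0 if correct and i < 10 else 400 + rng.random() * 300
            rows.append(_trial(trial=i + 1, rt=rt, correct=correct))
        out, rep = pp.filter_trials(make_trials(rows))
        assert len(out) == 90
        assert rep.n_removed_error_or_fast == 10

    def test_empty_input(self):
        out, rep = pp.filter_trials(make_trials([]))
        assert out.empty and rep.n_trials_in == 0 and rep.n_trials_out == 0


class TestTrimOutliers:
    def test_constant_cell_untouched(self):
        trials = make_trials([_trial(trial=i, rt=500.0) for i in range(5)])
        out, rep = pp.trim_outliers(trials)
        assert len(out) == 5 and rep.n_removed_outlier == 0

    def test_small_cell_cannot_exceed_threshold(self):
        # in an n-trial cell the largest attainable |z| is (n-1)/sqrt(n),
        # below 2.5 for n = 5: the outlier inflates the cell SD and the
        # brute-force rule retains everything
        rts = [500.0, 510, 505, 495, 2000]
        trials = make_trials([_trial(trial=i, rt=r)
                              for i, r in enumerate(rts)])
        out, rep = pp.trim_outliers(trials)
        arr = np.array(rts)
        keep = np.abs(arr - arr.mean()) <= 2.5 * arr.std(ddof=1)
        assert keep.all()
        assert set(out["rt"]) == set(arr)
        assert rep.n_removed_outlier == 0

    def test_gross_outlier_removed_in_larger_cell(self):
        rts = [500.0, 510, 505, 495, 498, 502, 507, 493, 2000]
        trials = make_trials([_trial(trial=i, rt=r)
                              for i, r in enumerate(rts)])
        out, rep = pp.trim_outliers(trials)
        arr = np.array(rts)
        keep = np.abs(arr - arr.mean()) <= 2.5 * arr.std(ddof=1)
        assert not keep[-1]
        assert 2000 not in set(out["rt"])
        assert set(out["rt"]) == set(arr[keep])
        assert rep.n_removed_outlier == 1

    def test_exactly_2p5_sd_retained(self):
        # craft a 9-trial cell whose extreme value sits at exactly 2.5 SD
        base = np.array([480, 490, 495, 500, 505, 510, 515, 520], float)

        def zscore_of_last(b):
            cell = np.append(base, b)
            return (b - cell.mean()) / cell.std(ddof=1) - 2.5

        b_star = brentq(zscore_of_last, 521, 5000)
        trials = make_trials([_trial(trial=i, rt=r) for i, r in
                              enumerate(np.append(base, b_star))])
        out, _ = pp.trim_outliers(trials)
        assert len(out) == 9  # strict inequality: boundary retained

    def test_matches_brute_force_on_random_cells(self, rng):
        rows = []
        t = 0
        for pid in ("p1", "p2"):
            for block in (2, 3):
                for cond in ("absent", "low"):
                    for _ in range(12):
                        t += 1
                        rows.append(_trial(pid=pid, block=block, trial=t,
                                           cond=cond,
                                           rt=float(rng.normal(600, 80))))
        trials = make_trials(rows)
        out, _ = pp.trim_outliers(trials)
        kept = set()
        for _, cell in trials.groupby(["participant_id", "condition",
                                       "block"]):
            arr = cell["rt"].to_numpy()
            keep = np.abs(arr - arr.mean()) <= 2.5 * arr.std(ddof=1)
            kept.update(cell.index[keep])
        assert set(out.index) == kept

    def test_trim_fraction_on_large_gaussian(self, rng):
        n = 100_000
        trials = make_trials([_trial(trial=i, rt=r) for i, r in
                              enumerate(rng.normal(600, 80, n))])
        out, rep = pp.trim_outliers(trials)
        frac = rep.n_removed_outlier / n
        assert abs(frac - 2 * 0.00621) < 0.005


class TestBlockAndParticipantExclusion:
    def _block(self, pid, block, n_correct, n=48, rt=500.0):
        rows = []
        for i in range(n):
            rows.append(_trial(pid=pid, block=block, trial=i + 1,
                               rt=rt, correct=i < n_correct))
        return rows

    def test_low_accuracy_block_boundary(self):
        trials = make_trials(self._block("p1", 2, 23)
                             + self._block("p1", 3, 24))
        out, rep = pp.drop_low_accuracy_blocks(trials)
        assert set(out["block"]) == {3}
        assert rep.n_blocks_removed == 1
        assert rep.n_removed_block_trials == 48

    def test_injected_bad_block_is_the_one_removed(self):
        rows = []
        for b in range(1, 9):
            rows += self._block("p1", b, 20 if b == 5 else 46)
        out, rep = pp.drop_low_accuracy_blocks(make_trials(rows))
        assert 5 not in set(out["block"])
        assert rep.n_blocks_removed == 1

    def test_participant_exclusion_standard_vs_strict(self):
        rows = []
        # p_bad2: two blocks at 40% -> removed under both criteria
        # p_bad1: exactly one block at 40% -> strict only
        # p_ok: clean
        for pid, bad_blocks in (("p_bad2", [2, 3]), ("p_bad1", [2]),
                                ("p_ok", [])):
            for b in range(1, 9):
                acc = 19 if b in bad_blocks else 45
                rows += self._block(pid, b, acc)
        trials = make_trials(rows)
        kept_std, rep_std = pp.exclude_participants(trials, "standard")
        assert set(kept_std["participant_id"]) == {"p_bad1", "p_ok"}
        assert dict(rep_std.participants_removed)["p_bad2"] \
            == "low_accuracy_multi_block"
        kept_strict, rep_strict = pp.exclude_participants(trials, "strict")
        assert set(kept_strict["participant_id"]) == {"p_ok"}
        assert dict(rep_strict.participants_removed)["p_bad1"] \
            == "strict_any_block"

    def test_no_practice_response_removed(self):
        rows = []
        for b in range(1, 9):
            rows += self._block("p1", b, 46)
            rows += self._block("p2", b, 46)
        trials = make_trials(rows)
        trials.loc[(trials["participant_id"] == "p2")
                   & (trials["block"] == 1), "rt"] = np.nan
        _, rep = pp.exclude_participants(trials, "standard")
        assert dict(rep.participants_removed)["p2"] == "no_practice_responses"

    def test_clean_cohort_no_removals(self, clean_trials):
        _, rep = pp.exclude_participants(clean_trials, "standard")
        assert rep.participants_removed == []


class TestLocationRepeats:
    def test_immediate_repeat_removed(self):
        trials = make_trials([
            _trial(trial=1, cond="low", dloc=3.0, dist=4.25),
            _trial(trial=2, cond="low", dloc=3.0, dist=4.25),
            _trial(trial=3, cond="low", dloc=5.0, dist=7.85),
            _trial(trial=4, cond="low", dloc=3.0, dist=4.25),
        ])
        out = pp.remove_location_repeats(trials)
        assert list(out["trial"]) == [1, 3, 4]

    def test_alternating_nothing_removed(self):
        trials = make_trials([
            _trial(trial=i, cond="low", dloc=float(3 + i % 2))
            for i in range(6)
        ])
        assert len(pp.remove_location_repeats(trials)) == 6

    def test_matches_brute_force_on_random_schedule(self):
        cfg = DesignConfig(tasks=("fixed",), n_participants_per_task=3)
        trials = dl.generate_design(cfg, seed=6)
        out = pp.remove_location_repeats(trials)
        removed = set(trials.index) - set(out.index)
        expected = set()
        for _, sub in trials.groupby("participant_id"):
            sub = sub.sort_values(["block", "trial"])
            prev = None
            for idx, row in sub.iterrows():
                cur = row["distractor_location"]
                if (not np.isnan(cur) and prev is not None
                        and not np.isnan(prev) and cur == prev):
                    expected.add(idx)
                prev = cur
        assert removed == expected


class TestAggregate:
    def test_hand_built_table(self):
        trials = make_trials([
            _trial(trial=1, cond="absent", rt=500),
            _trial(trial=2, cond="absent", rt=520),
            _trial(trial=3, cond="high", dloc=0.0, dist=0.0, tloc=3, rt=600),
            _trial(trial=4, cond="high", dloc=0.0, dist=0.0, tloc=3, rt=640),
            _trial(trial=5, cond="low", dloc=2.0, dist=7.85, tloc=3, rt=700),
            _trial(block=1, trial=6, cond="absent", rt=999),  # practice
        ])
        agg = pp.aggregate(trials, by="condition").set_index("condition")
        assert agg.loc["absent", "mean_rt"] == pytest.approx(510)
        assert agg.loc["high", "mean_rt"] == pytest.approx(620)
        assert agg.loc["low", "mean_rt"] == pytest.approx(700)
        assert agg.loc["absent", "n_trials"] == 2  # practice excluded

    def test_block_condition_keeps_practice(self):
        trials = make_trials([
            _trial(block=1, trial=1, cond="absent", rt=700),
            _trial(block=2, trial=1, cond="absent", rt=600),
        ])
        agg = pp.aggregate(trials, by="block_condition")
        assert set(agg["block"]) == {1, 2}

    def test_target_at_hp_grouping(self):
        trials = make_trials([
            _trial(trial=1, cond="absent", tloc=0, dist=0.0, rt=650),
            _trial(trial=2, cond="absent", tloc=4, dist=11.2, rt=600),
            _trial(trial=3, cond="high", dloc=0.0, dist=0.0, tloc=2, rt=700),
        ])
        agg = pp.aggregate(trials, by="target_at_hp")
        at = agg.set_index("target_at_hp")
        assert at.loc[True, "mean_rt"] == pytest.approx(650)
        assert at.loc[False, "mean_rt"] == pytest.approx(600)

    def test_unknown_grouping_rejected(self, clean_trials):
        with pytest.raises(ValueError, match="grouping"):
            pp.aggregate(clean_trials, by="nope")


class TestPipeline:
    def test_every_removal_accounted(self):
        cfg = DesignConfig(tasks=("fixed", "mixed"),
                           n_participants_per_task=4)
        trials = dl.simulate_experiment(cfg, mode="condition", seed=55)
        out, rep = pp.preprocess(trials)
        assert rep.n_trials_in - rep.n_trials_out == rep.n_removed_total
        assert rep.n_trials_out == len(out)

    def test_idempotent_apart_from_second_trim(self, clean_trials):
        out2, rep2 = pp.filter_trials(clean_trials)
        assert len(out2) == len(clean_trials)
        out3, rep3 = pp.exclude_participants(out2, "standard")
        assert rep3.participants_removed == []
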