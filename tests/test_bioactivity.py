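"""Bioactivity evaluation: task filters, AUROC/AUPRC/RIPtoP against
threshold-sweep oracles, multitask training, Wilcoxon comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

from painttx import (
    BioactivityMatrix,
    MultitaskConfig,
    ProfileMatrix,
    SplitAssignment,
    TaskMetrics,
    compare_feature_types,
    filter_eval_tasks,
    filter_train_tasks,
    group_by_family,
    riptop,
    score_tasks,
    select_tx_strong_cp_weak,
    train_multitask,
)
from painttx.bioactivity import _masked_bce_and_grad


def auroc_oracle(y, s):
    """Pair-counting AUROC with ties counted half."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def auprc_oracle(y, s):
    """Average precision by explicit threshold sweep over unique scores."""
    y = np.asarray(y)
    s = np.asarray(s)
    ap, prev_recall = 0.0, 0.0
    n_pos = y.sum()
    for t in sorted(np.unique(s), reverse=True):
        pred = s >= t
        tp = np.sum(y[pred] == 1)
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def _split_all(cids, where):
    return SplitAssignment({c: where for c in cids})


class TestTaskFilters:
    def _bio(self, per_task):
        """per_task: list of (n_pos, n_neg, n_extra_missing) in train."""
        n_comp = max(p + n for p, n, _ in per_task) + 20
        cids = [f"c{i}" for i in range(n_comp)]
        labels = np.full((n_comp, len(per_task)), np.nan)
        for j, (p, n, _) in enumerate(per_task):
            labels[:p, j] = 1.0
            labels[p:p + n, j] = 0.0
        return BioactivityMatrix(labels, cids, [f"t{j}" for j in range(len(per_task))])

    def test_train_filter_thresholds(self):
        bio = self._bio([(24, 100, 0),   # 24 pos -> out
                         (30, 30, 0),    # 60 observed -> out (floor 100)
                         (50, 50, 0),    # in
                         (25, 75, 0)])   # in (boundary inclusive)
        split = _split_all(bio.compound_ids, "train")
        assert filter_train_tasks(bio, split) == ["t2", "t3"]

    def test_eval_filter_thresholds(self):
        bio = self._bio([(25, 25, 0),    # boundary -> in
                         (100, 0, 0),    # one-sided -> out
                         (24, 26, 0)])   # out
        split = _split_all(bio.compound_ids, "test")
        assert filter_eval_tasks(bio, split) == ["t0"]

    def test_filters_match_brute_force_recount(self, tiny_screen, tiny_split):
        bio, split = tiny_screen.bioactivity, tiny_split
        in_train = {c for c, s in split.assignment.items() if s in ("train", "valid")}
        in_test = {c for c, s in split.assignment.items() if s == "test"}
        want_train, want_eval = [], []
        for j, t in enumerate(bio.task_ids):
            rows = {c: bio.labels[i, j] for i, c in enumerate(bio.compound_ids)}
            tr = [v for c, v in rows.items() if c in in_train and not np.isnan(v)]
            te = [v for c, v in rows.items() if c in in_test and not np.isnan(v)]
            if sum(v == 1 for v in tr) >= 25 and sum(v == 0 for v in tr) >= 25 \
                    and len(tr) >= 100:
                want_train.append(t)
            if sum(v == 1 for v in te) >= 25 and sum(v == 0 for v in te) >= 25:
                want_eval.append(t)
        assert filter_train_tasks(bio, split) == want_train
        assert filter_eval_tasks(bio, split) == want_eval


class TestRiptop:
    def test_identities_over_baseline_grid(self):
        for b in np.linspace(0.01, 0.99, 99):
            assert riptop(b, b) == pytest.approx(0.0)
            assert riptop(1.0, b) == pytest.approx(1.0)

    def test_monotone_in_auprc(self, rng):
        for _ in range(50):
            b = rng.uniform(0.05, 0.95)
            lo, hi = sorted(rng.uniform(0, 1, size=2))
            assert riptop(lo, b) <= riptop(hi, b)

    def test_hand_computed_value(self):
        assert riptop(0.5, 0.2) == pytest.approx(0.375)

    @pytest.mark.parametrize("bad", [0.0, 1.0, 1.3, -0.1])
    def test_invalid_baseline_rejected(self, bad):
        with pytest.raises(ValueError):
            riptop(0.5, bad)


class TestMaskedBCE:
    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.normal(size=(4, 3))
        y = rng.integers(0, 2, size=(4, 3)).astype(float)
        y[0, 1] = np.nan
        _, grad = _masked_bce_and_grad(logits, y)
        eps = 1e-6
        for i in range(4):
            for j in range(3):
                d = np.zeros_like(logits)
                d[i, j] = eps
                hi, _ = _masked_bce_and_grad(logits + d, y)
                lo, _ = _masked_bce_and_grad(logits - d, y)
                assert grad[i, j] == pytest.approx((hi - lo) / (2 * eps), abs=1e-6)

    def test_missing_entries_contribute_nothing(self, rng):
        logits = rng.normal(size=(3, 2))
        y = np.array([[1.0, np.nan], [0.0, np.nan], [1.0, np.nan]])
        loss, grad = _masked_bce_and_grad(logits, y)
        loss2, _ = _masked_bce_and_grad(logits[:, :1], y[:, :1])
        assert loss == pytest.approx(loss2)
        assert np.all(grad[:, 1] == 0.0)


def _scored_setup(rng, n=400, d=8, n_tasks=6, seed=0):
    """Features plus labels where task 0 is linearly separable from feature 0
    and task 1 has permuted (uninformative) labels."""
    cids = [f"c{i}" for i in range(n)]
    X = rng.normal(size=(n, d))
    labels = np.empty((n, n_tasks))
    for j in range(n_tasks):
        w = rng.normal(size=d)
        labels[:, j] = (X @ w > 0).astype(float)
    labels[:, 0] = (X[:, 0] > 0).astype(float)
    labels[:, 1] = rng.permutation(labels[:, 1])
    feats = ProfileMatrix(X, cids, cids, [f"f{k}" for k in range(d)], "CP")
    bio = BioactivityMatrix(labels, cids, [f"t{j}" for j in range(n_tasks)])
    assignment = {}
    for i, c in enumerate(cids):
        assignment[c] = "train" if i % 5 < 3 else ("valid" if i % 5 == 3 else "test")
    return feats, bio, SplitAssignment(assignment)


class TestMultitask:
    def test_history_recorded(self, rng):
        feats, bio, split = _scored_setup(rng)
        cfg = MultitaskConfig(hidden_size=32, n_layers=2, epochs=5,
                              learning_rate=1e-3, seed=0)
        model = train_multitask(feats, bio, split, cfg, task_ids=bio.task_ids)
        assert len(model.history) == 5
        assert all(np.isfinite(h["train_loss"]) for h in model.history)

    def test_separable_task_high_auroc_permuted_task_chance(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            feats, bio, split = _scored_setup(rng, seed=seed)
            # dropout off: the oracle isolates separability, not regularisation
            cfg = MultitaskConfig(hidden_size=32, n_layers=2, epochs=60,
                                  dropout=0.0, learning_rate=3e-3, seed=seed)
            model = train_multitask(feats, bio, split, cfg, task_ids=bio.task_ids)
            metrics = {m.task_id: m for m in
                       score_tasks(model, feats, bio, split)}
            assert metrics["t0"].auroc > 0.95
            assert 0.4 <= metrics["t1"].auroc <= 0.6

    def test_deterministic_given_seed(self, rng):
        feats, bio, split = _scored_setup(rng)
        cfg = MultitaskConfig(hidden_size=16, n_layers=2, epochs=3,
                              learning_rate=1e-3, seed=5)
        a = train_multitask(feats, bio, split, cfg, task_ids=bio.task_ids)
        b = train_multitask(feats, bio, split, cfg, task_ids=bio.task_ids)
        np.testing.assert_array_equal(
            a.predict_scores(feats.values), b.predict_scores(feats.values)
        )

    def test_no_tasks_rejected(self, rng):
        feats, bio, split = _scored_setup(rng)
        with pytest.raises(ValueError, match="task"):
            train_multitask(feats, bio, split, MultitaskConfig(), task_ids=[])


class TestScoreTasks:
    def _metrics_for(self, y, s):
        """Score a single frozen task via a stub model."""
        from painttx.bioactivity import MultitaskModel
        from painttx._nn import MLP

        n = len(y)
        cids = [f"c{i}" for i in range(n)]
        feats = ProfileMatrix(s.reshape(-1, 1), cids, cids, ["f0"], "CP")
        bio = BioactivityMatrix(np.asarray(y, float).reshape(-1, 1), cids, ["t0"])
        split = _split_all(cids, "test")
        net = MLP([1, 1], np.random.default_rng(0))
        net.weights[0][:] = 1.0
        net.biases[0][:] = 0.0
        model = MultitaskModel(net, ["t0"], np.zeros(1), np.ones(1),
                               MultitaskConfig())
        return score_tasks(model, feats, bio, split)

    def test_perfect_ordering_gives_ones(self):
        y = np.array([0, 0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        (m,) = self._metrics_for(y, s)
        assert (m.auroc, m.auprc, m.riptop_auprc) == (1.0, 1.0, 1.0)

    def test_constant_scores_give_half_auroc(self):
        y = np.array([0, 1, 0, 1, 1])
        s = np.zeros(5)
        (m,) = self._metrics_for(y, s)
        assert m.auroc == pytest.approx(0.5)

    def test_matches_threshold_sweep_oracles(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 50))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                y[0], y[-1] = 0, 1
            s = np.round(rng.normal(size=n), 1)  # ties likely
            (m,) = self._metrics_for(y.astype(float), s)
            assert m.auroc == pytest.approx(auroc_oracle(y, s), abs=1e-9)
            assert m.auprc == pytest.approx(auprc_oracle(y, s), abs=1e-9)
            assert m.baseline == pytest.approx(y.mean())

    def test_single_class_task_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="single class"):
            out = self._metrics_for(np.ones(5), np.linspace(0, 1, 5))
        assert out == []


def _tm(task_id, auroc):
    return TaskMetrics(task_id, auroc, 0.5, 0.4, riptop(0.5, 0.4), 30, 30)


class TestSubsetSelection:
    def test_strict_boundaries(self):
        tx = [_tm("a", 0.70), _tm("b", 0.75), _tm("c", 0.9)]
        cp = [_tm("a", 0.5), _tm("b", 0.65), _tm("c", 0.70)]
        assert select_tx_strong_cp_weak(tx, cp) == ["b"]

    def test_matches_brute_force_on_random_table(self, rng):
        ids = [f"t{i}" for i in range(50)]
        tx = [_tm(t, rng.uniform(0.4, 1.0)) for t in ids]
        cp = [_tm(t, rng.uniform(0.4, 1.0)) for t in ids]
        got = set(select_tx_strong_cp_weak(tx, cp))
        tx_d = {m.task_id: m.auroc for m in tx}
        cp_d = {m.task_id: m.auroc for m in cp}
        want = {t for t in ids if tx_d[t] > 0.7 and cp_d[t] < 0.7}
        assert got == want

    def test_mismatched_task_sets_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            select_tx_strong_cp_weak([_tm("a", 0.8)], [_tm("b", 0.5)])


class TestWilcoxon:
    def test_all_positive_differences_exact_p(self):
        a = {f"t{i}": 0.8 + 0.01 * i for i in range(10)}
        b = {f"t{i}": 0.7 + 0.005 * i for i in range(10)}
        res = compare_feature_types(a, b)
        # exhaustive sign-pattern enumeration: W+ spans all 2^10 patterns and
        # only the all-positive one reaches the maximum rank sum
        diffs = np.array([a[t] - b[t] for t in a])
        ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
        w_obs = ranks[diffs > 0].sum()
        count = sum(
            1
            for signs in itertools.product((0, 1), repeat=10)
            if ranks[np.array(signs, bool)].sum() >= w_obs
        )
        assert res.p_value == pytest.approx(count / 2**10)
        assert res.p_value == pytest.approx(2**-10)

    def test_identical_inputs_flagged_degenerate(self):
        a = {f"t{i}": 0.5 for i in range(8)}
        res = compare_feature_types(a, dict(a))
        assert res.degenerate and res.p_value is None

    def test_antisymmetry_of_one_sided_p(self, rng):
        # exact test without ties: p(a>b) + p(b>a) = 1 + P(W = w_obs),
        # with P(W = w_obs) computed by exhaustive sign-pattern enumeration
        a = {f"t{i}": v for i, v in enumerate(rng.normal(size=12))}
        b = {f"t{i}": v for i, v in enumerate(rng.normal(size=12))}
        p_ab = compare_feature_types(a, b).p_value
        p_ba = compare_feature_types(b, a).p_value
        diffs = np.array([a[t] - b[t] for t in sorted(a)])
        ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
        w_obs = ranks[diffs > 0].sum()
        p_at_obs = sum(
            1 for signs in itertools.product((0, 1), repeat=12)
            if ranks[np.array(signs, bool)].sum() == w_obs
        ) / 2**12
        assert p_ab + p_ba == pytest.approx(1 + p_at_obs, abs=1e-12)


class TestGroupByFamily:
    def _metrics(self, rng):
        fams = ["Kinase", "GPCR", None]
        out = {}
        for ft in ("CP", "CL"):
            out[ft] = [
                TaskMetrics(f"t{i}", rng.uniform(0.5, 1), 0.5, 0.4, 0.17,
                            30, 30, family=fams[i % 3])
                for i in range(12)
            ]
        return out

    def test_counts_match_brute_force_tally(self, rng):
        metrics = self._metrics(rng)
        summary, _ = group_by_family(metrics)
        counts = summary.set_index(["family", "feature_type"])["n_tasks"]
        assert counts[("Kinase", "CP")] == 4
        assert counts[("GPCR", "CP")] == 4
        assert counts[("(unannotated)", "CP")] == 4

    def test_pairwise_comparisons_emitted_per_family(self, rng):
        _, comparisons = group_by_family(self._metrics(rng))
        assert len(comparisons) == 3  # one CP-vs-CL comparison per family
        assert all(c.p_value is not None for c in comparisons)
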