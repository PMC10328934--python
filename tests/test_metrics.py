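"""Ranking metrics against brute-force oracles, the de-novo protocol, and
paired comparisons with multiplicity control."""

import numpy as np
import pandas as pd
import pytest

from multidx import (
    auprc,
    auroc,
    bh_adjust,
    chapter_summary,
    compare_models,
    coverage_error,
    denovo_mask,
    per_label_metrics,
    recall_at_k,
)

# ---------------------------------------------------------------------------
# independent oracles: O(n^2) concordance, summation average precision, and
# exhaustive rank enumeration with the same lexicographic tie-break
# ---------------------------------------------------------------------------

def auroc_oracle(scores, truth):
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def auprc_oracle(scores, truth):
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    tp, ap = 0, 0.0
    n_pos = sum(truth)
    # average precision: sum precision at each positive's rank, descending
    # score order; sklearn resolves score ties as a block, so accumulate
    # per distinct threshold
    i = 0
    seen = 0
    while i < len(order):
        j = i
        block_tp = 0
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            block_tp += truth[order[j]]
            j += 1
        seen = j
        tp += block_tp
        if block_tp:
            ap += (tp / seen) * block_tp
        i = j
    return ap / n_pos


def rank_oracle(score_row):
    L = len(score_row)
    return sorted(range(L), key=lambda j: (-score_row[j], j))


def recall_at_k_oracle(S, Y, k):
    vals = []
    for i in range(len(S)):
        true = {j for j in range(S.shape[1]) if Y[i, j]}
        if not true:
            continue
        top = set(rank_oracle(S[i])[:k])
        vals.append(len(true & top) / len(true))
    return float(np.mean(vals))


def coverage_oracle(S, Y):
    vals = []
    for i in range(len(S)):
        true = {j for j in range(S.shape[1]) if Y[i, j]}
        if not true:
            continue
        order = rank_oracle(S[i])
        vals.append(max(order.index(j) for j in true) + 1)
    return float(np.mean(vals))


class TestAuroc:
    def test_hand_example(self):
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_ranking(self):
        assert auroc([0.1, 0.2, 0.9, 0.8], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert auroc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_undefined(self):
        assert auroc([0.1, 0.2], [1, 1]) is None
        assert auroc([0.1, 0.2], [0, 0]) is None

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 200))
            s = np.round(rng.random(n), 2)  # rounded to force ties
            t = rng.integers(0, 2, n)
            if t.min() == t.max():
                continue
            assert auroc(s, t) == pytest.approx(auroc_oracle(s, t), abs=1e-12)


class TestAuprc:
    def test_perfect_ranking(self):
        assert auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_single_positive_ranked_last(self):
        n = 10
        scores = list(np.linspace(1.0, 0.1, n))
        truth = [0] * (n - 1) + [1]
        assert auprc(scores, truth) == pytest.approx(1 / n)

    def test_zero_positives_undefined(self):
        assert auprc([0.4, 0.2], [0, 0]) is None

    def test_null_scores_approach_prevalence(self):
        rng = np.random.default_rng(1)
        n, p = 10_000, 0.15
        t = (rng.random(n) < p).astype(int)
        s = rng.random(n)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(auprc(s, t) - t.mean()) < 3 * se + 0.01

    def test_matches_summation_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(4, 100))
            s = np.round(rng.random(n), 2)
            t = rng.integers(0, 2, n)
            if t.sum() == 0:
                continue
            assert auprc(s, t) == pytest.approx(auprc_oracle(list(s), list(t)),
                                                abs=1e-12)


class TestRecallAtK:
    def test_single_true_label_ranked_first(self):
        S = np.array([[0.9, 0.1, 0.2]])
        Y = np.array([[1, 0, 0]])
        assert recall_at_k(S, Y, 2) == 1.0

    def test_half_recovered(self):
        # two true labels, ranked 1st and last; k excludes the last
        S = np.array([[0.9, 0.5, 0.4, 0.1]])
        Y = np.array([[1, 0, 0, 1]])
        assert recall_at_k(S, Y, 3) == 0.5

    def test_k_equal_label_count_is_one(self):
        rng = np.random.default_rng(3)
        S = rng.random((20, 6))
        Y = (rng.random((20, 6)) < 0.4).astype(int)
        Y[Y.sum(axis=1) == 0, 0] = 1
        assert recall_at_k(S, Y, 6) == 1.0

    def test_nondecreasing_in_k(self):
        rng = np.random.default_rng(4)
        S = rng.random((30, 8))
        Y = (rng.random((30, 8)) < 0.3).astype(int)
        Y[Y.sum(axis=1) == 0, 2] = 1
        vals = [recall_at_k(S, Y, k) for k in range(1, 9)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_k_clamped_with_warning(self, caplog):
        S = np.array([[0.5, 0.4]])
        Y = np.array([[1, 0]])
        assert recall_at_k(S, Y, 10) == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            S = np.round(rng.random((12, 10)), 1)
            Y = (rng.random((12, 10)) < 0.3).astype(int)
            k = int(rng.integers(1, 10))
            if (Y.sum(axis=1) == 0).all():
                continue
            assert recall_at_k(S, Y, k) == pytest.approx(
                recall_at_k_oracle(S, Y, k), abs=1e-12)


class TestCoverageError:
    def test_hand_example(self):
        S = np.array([[0.9, 0.5, 0.8, 0.1]])
        Y = np.array([[1, 0, 1, 0]])  # true {A, C}; ranks 1 and 2
        assert coverage_error(S, Y) == 2.0

    def test_lower_bound_attained(self):
        S = np.array([[0.9, 0.8, 0.1, 0.2]])
        Y = np.array([[1, 1, 0, 0]])
        assert coverage_error(S, Y) == 2.0

    def test_single_true_ranked_last(self):
        S = np.array([[0.9, 0.5, 0.4, 0.1]])
        Y = np.array([[0, 0, 0, 1]])
        assert coverage_error(S, Y) == 4.0

    def test_at_least_mean_true_count(self):
        rng = np.random.default_rng(6)
        S = rng.random((40, 7))
        Y = (rng.random((40, 7)) < 0.4).astype(int)
        Y[Y.sum(axis=1) == 0, 0] = 1
        assert coverage_error(S, Y) >= Y.sum(axis=1).mean()

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            S = np.round(rng.random((12, 10)), 1)
            Y = (rng.random((12, 10)) < 0.3).astype(int)
            assert coverage_error(S, Y) == pytest.approx(
                coverage_oracle(S, Y), abs=1e-12)


class TestDenovoMask:
    def _fixture(self):
        # one patient, six dated encounters; label positive at 3rd and 5th
        enc = pd.DataFrame({
            "encounter_id": [f"E{i}" for i in range(1, 7)],
            "patient_id": ["P1"] * 6,
            "date": pd.to_datetime(
                ["2010-01-01", "2010-02-01", "2010-03-01",
                 "2010-04-01", "2010-05-01", "2010-06-01"]),
        })
        Y = np.array([[0], [0], [1], [0], [1], [0]])
        return enc, Y

    def test_eligible_prefix_through_first_positive(self):
        enc, Y = self._fixture()
        mask = denovo_mask(enc, enc["encounter_id"].tolist(), Y, ["A01"])
        assert mask[:, 0].tolist() == [True, True, True, False, False, False]

    def test_never_positive_all_eligible(self):
        enc, Y = self._fixture()
        mask = denovo_mask(enc, enc["encounter_id"].tolist(), np.zeros((6, 1)), ["A01"])
        assert mask.all()

    def test_same_date_ties_all_eligible(self):
        enc, Y = self._fixture()
        enc.loc[3, "date"] = enc.loc[2, "date"]  # E4 same day as first positive E3
        mask = denovo_mask(enc, enc["encounter_id"].tolist(), Y, ["A01"])
        assert mask[:, 0].tolist() == [True, True, True, True, False, False]

    def test_at_most_one_eligible_positive_without_ties(self):
        rng = np.random.default_rng(8)
        enc = pd.DataFrame({
            "encounter_id": [f"E{i}" for i in range(60)],
            "patient_id": [f"P{i % 10}" for i in range(60)],
            "date": pd.to_datetime("2010-01-01")
            + pd.to_timedelta(rng.choice(3000, 60, replace=False), unit="D"),
        })
        Y = (rng.random((60, 3)) < 0.3).astype(int)
        mask = denovo_mask(enc, enc["encounter_id"].tolist(), Y, list("abc"))
        df = enc.assign(row=np.arange(60))
        for l in range(3):
            for _, grp in df.groupby("patient_id"):
                rows = grp["row"].to_numpy()
                assert (Y[rows, l] * mask[rows, l]).sum() <= 1


class TestCompareModels:
    def test_identical_vectors_p_one(self):
        a = np.linspace(0.5, 0.9, 12)
        stat, p = compare_models(a, a)
        assert p == 1.0

    def test_uniform_improvement_significant(self):
        a = np.linspace(0.5, 0.9, 30)
        b = a + 0.01
        _, p = compare_models(a, b, alternative="greater")
        assert p < 0.001

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(9)
        a = rng.random(20)
        b = a + rng.normal(0, 0.05, 20)
        _, p_ab = compare_models(a, b, alternative="greater")
        _, p_ba = compare_models(b, a, alternative="less")
        assert p_ab == pytest.approx(p_ba)


class TestChapterSummary:
    def _metrics(self, labels, values, mode="overall"):
        return pd.DataFrame({"label": labels, "letter": [l[0] for l in labels],
                             "mode": mode, "auroc": values,
                             "auprc": values, "prevalence": 0.1,
                             "n_eval_encounters": 100})

    def test_bh_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_letter_adjusted_equals_raw(self):
        labels = [f"A{i:02d}" for i in range(5)]
        a = self._metrics(labels, [0.6, 0.62, 0.61, 0.66, 0.64])
        b = self._metrics(labels, [0.7, 0.72, 0.71, 0.76, 0.74])
        out = chapter_summary(a, b)
        assert len(out) == 1
        assert out["p_adjusted"].iloc[0] == pytest.approx(out["p_value"].iloc[0])

    def test_label_counts_partition(self):
        labels = ["A01", "A02", "B01", "B02", "B03", "C01"]
        vals = [0.6, 0.7, 0.65, 0.6, 0.7, 0.8]
        out = chapter_summary(self._metrics(labels, vals),
                              self._metrics(labels, [v + 0.01 for v in vals]))
        assert out["label_count"].sum() == len(labels)

    def test_small_letter_skipped(self):
        labels = ["A01", "A02", "C01"]
        vals = [0.6, 0.7, 0.8]
        out = chapter_summary(self._metrics(labels, vals),
                              self._metrics(labels, [v + 0.05 for v in vals]))
        assert np.isnan(out.set_index("letter").loc["C", "p_value"])


def test_per_label_metrics_undefined_recorded_absent():
    S = np.array([[0.9, 0.1], [0.8, 0.2]])
    Y = np.array([[1, 0], [1, 0]])  # first label all-positive, second all-negative
    df = per_label_metrics(S, Y, ["A01", "B01"])
    assert df["auroc"].isna().all()
    assert df.loc[1, "auprc"] != df.loc[1, "auprc"]  # NaN, not zero
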