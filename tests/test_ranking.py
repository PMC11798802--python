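import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ensemblepharm.consensus import OccurrenceMatrix
from ensemblepharm.ranking import (anova_f, mutual_information, rank_and_vote,
                                   rqa_entropy, spearman_score)


def make_matrix(columns: dict[str, list[int]], labels):
    df = pd.DataFrame(columns)
    freqs = {c: float(df[c].mean()) for c in df.columns}
    feats = {c: None for c in df.columns}
    m = OccurrenceMatrix.__new__(OccurrenceMatrix)
    m.data = df
    m.labels = np.asarray(labels, dtype=int)
    m.frequencies = freqs
    m.features = feats
    return m


# ------------------------------------------------------------------ oracles

def mi_oracle_bits(x, y):
    """Brute-force plug-in MI over the joint table."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    total = 0.0
    for xv in set(x.tolist()):
        for yv in set(y.tolist()):
            pxy = np.sum((x == xv) & (y == yv)) / n
            if pxy == 0:
                continue
            px, py = np.sum(x == xv) / n, np.sum(y == yv) / n
            total += pxy * math.log2(pxy / (px * py))
    return total


def spearman_oracle(x, y):
    """Average ranks computed by hand, then the Pearson formula."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2  # average of 1-based ranks
            i = j
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    denom = math.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    return abs(float((rx * ry).sum() / denom)) if denom else 0.0


def rqa_oracle(x, l_min=2):
    """Exhaustive recurrence-plot scan: build the full NxN matrix and walk
    every diagonal except the line of identity; runs covering a whole
    diagonal (border to border) carry no interior structure and are
    skipped."""
    x = np.asarray(x)
    n = len(x)
    R = np.equal.outer(x, x)
    lengths = []
    for off in range(-(n - 1), n):
        if off == 0:
            continue
        diag_len = n - abs(off)
        run = 0
        for i in range(n):
            j = i + off
            if 0 <= j < n and R[i, j]:
                run += 1
            else:
                if l_min <= run < diag_len:
                    lengths.append(run)
                run = 0
        if l_min <= run < diag_len:
            lengths.append(run)
    if not lengths:
        return 0.0
    vals, counts = np.unique(lengths, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


# ------------------------------------------------------------------- tests

class TestAnovaF:
    def test_equal_group_means_give_zero(self):
        assert anova_f([1, 0, 1, 0], [1, 1, 0, 0]) == 0.0

    def test_perfect_separation_gives_infinity(self):
        assert anova_f([1, 1, 0, 0], [1, 1, 0, 0]) == float("inf")

    def test_matches_scipy_on_mixed_column(self):
        col = [1, 0, 1, 0, 1, 1]
        labels = [1, 1, 1, 0, 0, 0]
        expected = sps.f_oneway(
            np.array(col)[np.array(labels) == 1],
            np.array(col)[np.array(labels) == 0]).statistic
        assert anova_f(col, labels) == pytest.approx(expected, abs=1e-10)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            anova_f([1, 0, 1], [1, 1, 1])

    def test_monotone_in_group_mean_difference(self):
        # across all binary columns of length 6 at fixed labels, F must be a
        # monotone function of |group-mean difference| within fixed group
        # occupancy patterns of equal variance structure; verify against the
        # brute-force scipy oracle instead of the analytic argument
        labels = np.array([1, 1, 1, 0, 0, 0])
        for col in itertools.product([0, 1], repeat=6):
            col = np.array(col)
            g1, g0 = col[labels == 1], col[labels == 0]
            if g1.std() == 0 and g0.std() == 0:
                continue
            expected = sps.f_oneway(g1, g0).statistic
            got = anova_f(col, labels)
            if math.isnan(expected):  # scipy NaNs on zero within-variance
                continue
            assert got == pytest.approx(expected, abs=1e-10)


class TestMutualInformation:
    def test_independent_column_gives_zero(self):
        assert mutual_information([1, 1, 0, 0], [1, 0, 1, 0]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_balanced_identity_is_one_bit(self):
        labels = [1, 1, 0, 0]
        assert mutual_information(labels, labels) == pytest.approx(1.0)

    def test_matches_plugin_oracle(self):
        col, labels = [1, 1, 1, 0], [1, 1, 0, 0]
        assert mutual_information(col, labels) == pytest.approx(
            mi_oracle_bits(col, labels), abs=1e-12)

    @given(st.lists(st.integers(0, 1), min_size=4, max_size=16),
           st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry_and_entropy_bound(self, col, data):
        labels = data.draw(st.lists(st.integers(0, 1), min_size=len(col),
                                    max_size=len(col)))
        if len(set(labels)) < 2 or len(set(col)) < 2:
            return
        mi_xy = mutual_information(col, labels)
        mi_yx = mutual_information(labels, col)
        assert mi_xy == pytest.approx(mi_yx, abs=1e-12)

        def h(v):
            p = np.mean(v)
            return 0.0 if p in (0, 1) else -(p * np.log2(p)
                                             + (1 - p) * np.log2(1 - p))
        assert mi_xy <= min(h(col), h(labels)) + 1e-12


class TestRQAEntropy:
    def test_constant_series_entropy_zero(self):
        assert rqa_entropy([1] * 8) == 0.0
        assert rqa_entropy([0] * 8) == 0.0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="length"):
            rqa_entropy([1, 0], l_min=2)

    def test_matches_exhaustive_oracle_on_periodic_series(self):
        series = [1, 1, 0, 0, 1, 1, 0, 0, 1, 1]
        assert rqa_entropy(series) == pytest.approx(rqa_oracle(series),
                                                    abs=1e-12)

    def test_matches_oracle_on_random_series(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(3, 40))
            series = rng.integers(0, 2, n)
            assert rqa_entropy(series) == pytest.approx(rqa_oracle(series),
                                                        abs=1e-12)

    def test_l_min_filters_short_lines(self):
        series = [1, 0, 1, 0, 1, 1, 0]
        assert rqa_entropy(series, l_min=3) == pytest.approx(
            rqa_oracle(series, l_min=3), abs=1e-12)


class TestSpearman:
    def test_identical_and_inverted_columns_score_one(self):
        labels = [1, 1, 0, 0]
        assert spearman_score(labels, labels) == pytest.approx(1.0)
        inverted = [1 - v for v in labels]
        assert spearman_score(inverted, labels) == pytest.approx(1.0)

    def test_matches_tie_corrected_oracle(self):
        col, labels = [1, 0, 1, 0], [1, 1, 0, 0]
        assert spearman_score(col, labels) == pytest.approx(
            spearman_oracle(col, labels), abs=1e-12)

    def test_constant_column_degenerate_zero(self):
        assert spearman_score([1, 1, 1, 1], [1, 1, 0, 0]) == 0.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        col = rng.integers(0, 2, 30).astype(float)
        labels = rng.integers(0, 2, 30)
        base = spearman_score(col, labels)
        for f in (lambda v: 3 * v + 2, lambda v: np.exp(v),
                  lambda v: v ** 3 + v):
            assert spearman_score(f(col), labels) == pytest.approx(
                base, abs=1e-12)


class TestRankAndVote:
    labels = [1] * 3 + [0] * 7

    def test_k_equals_column_count_selects_everything(self):
        rng = np.random.default_rng(1)
        cols = {f"F{i}": rng.integers(0, 2, 10).tolist() for i in range(5)}
        cols = {k: v for k, v in cols.items() if len(set(v)) > 1}
        m = make_matrix(cols, self.labels)
        table = rank_and_vote(m, k=len(cols))
        assert table["selected"].all()
        assert (table["score"] == 4).all()

    def test_planted_discriminative_column_is_selected(self):
        rng = np.random.default_rng(42)
        cols = {f"N{i}": rng.integers(0, 2, 20).tolist() for i in range(8)}
        labels = [1] * 5 + [0] * 15
        cols["PLANT"] = labels  # perfectly discriminative
        cols = {k: v for k, v in cols.items() if len(set(v)) > 1}
        m = make_matrix(cols, labels)
        table = rank_and_vote(m, k=5)
        assert table.loc["PLANT", "selected"]

    def test_constant_column_dropped_never_selected(self):
        m = make_matrix({"CONST": [1] * 10,
                         "VAR": [1, 0, 1, 0, 1, 0, 1, 0, 1, 0]}, self.labels)
        table = rank_and_vote(m, k=1)
        assert "CONST" not in table.index
        assert "VAR" in table.index

    def test_k_exceeding_surviving_columns_rejected(self):
        m = make_matrix({"A": [1, 0] * 5, "CONST": [1] * 10}, self.labels)
        with pytest.raises(ValueError, match="k="):
            rank_and_vote(m, k=2)

    def test_selected_equals_intersection_of_topk_sets(self):
        rng = np.random.default_rng(99)
        for trial in range(20):
            n, p = 30, 8
            cols = {f"F{i}": rng.integers(0, 2, n).tolist() for i in range(p)}
            cols = {c: v for c, v in cols.items() if len(set(v)) > 1}
            labels = ([1] * 6 + [0] * (n - 6))
            m = make_matrix(cols, labels)
            k = int(rng.integers(1, len(cols) + 1))
            table = rank_and_vote(m, k=k)
            topk = []
            for method in ("f_value", "mi", "rqa_entr", "spearman_abs"):
                order = sorted(table.index,
                               key=lambda f: (-table.at[f, method], f))
                topk.append(set(order[:k]))
            expected = set.intersection(*topk)
            assert set(table.index[table["selected"]]) == expected
            assert len(expected) <= k
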