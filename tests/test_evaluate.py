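import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from targetexpress import (ExpressionProfile, intersect_baseline, loocv,
                           operating_point, paired_wilcoxon, roc_auc,
                           sum_baseline)
from targetexpress.errors import DomainError


def pairwise_auc_oracle(pos, neg):
    """Exact AUC as the pairwise concordance probability, in rationals."""
    wins = sum(
        Fraction(1) if p > q else Fraction(1, 2) if p == q else Fraction(0)
        for p in pos for q in neg
    )
    return wins / (len(pos) * len(neg))


def signed_rank_oracle(diffs):
    """Exact one-sided signed-rank p by enumerating all sign vectors."""
    from scipy.stats import rankdata
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    count = sum(
        1 for signs in itertools.product([0, 1], repeat=n)
        if ranks[np.array(signs, bool)].sum() >= w_obs - 1e-9
    )
    return count / 2**n


class TestRocAuc:
    def test_perfect_separation(self):
        scores = {"a": 0.9, "b": 0.8, "c": 0.2, "d": 0.1}
        labels = {"a": 1, "b": 1, "c": -1, "d": -1}
        assert roc_auc(scores, labels).auc == 1.0

    def test_interleaved_pairs(self):
        scores = {"a": 0.9, "b": 0.2, "c": 0.8, "d": 0.1}
        labels = {"a": 1, "b": 1, "c": -1, "d": -1}
        assert roc_auc(scores, labels).auc == 0.75

    def test_all_tied_is_half(self):
        scores = {k: 1.0 for k in "abcd"}
        labels = {"a": 1, "b": 1, "c": -1, "d": -1}
        assert roc_auc(scores, labels).auc == 0.5

    def test_single_class_errors(self):
        with pytest.raises(DomainError):
            roc_auc({"a": 1.0, "b": 0.5}, {"a": 1, "b": 1})

    @given(
        n_pos=st.integers(1, 25), n_neg=st.integers(1, 25),
        data=st.data(),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_exact_pairwise_oracle(self, n_pos, n_neg, data):
        # integer scores make the rank numerator exactly representable
        pos = data.draw(st.lists(st.integers(0, 12), min_size=n_pos,
                                 max_size=n_pos))
        neg = data.draw(st.lists(st.integers(0, 12), min_size=n_neg,
                                 max_size=n_neg))
        scores = {f"p{i}": float(v) for i, v in enumerate(pos)}
        scores |= {f"n{i}": float(v) for i, v in enumerate(neg)}
        labels = {k: (1 if k.startswith("p") else -1) for k in scores}
        impl = roc_auc(scores, labels).auc
        assert impl == float(pairwise_auc_oracle(pos, neg))

    @given(
        scores=st.lists(
            st.integers(-5000, 5000).map(lambda i: i / 1000),
            min_size=4, max_size=30, unique=True,
        ),
        seed=st.integers(0, 10**6),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariance_and_complement(self, scores, seed):
        rng = np.random.default_rng(seed)
        y = rng.choice([-1, 1], size=len(scores))
        if len(set(y)) < 2:
            y[0], y[1] = 1, -1
        sc = {f"t{i}": s for i, s in enumerate(scores)}
        lab = {f"t{i}": int(v) for i, v in enumerate(y)}
        auc = roc_auc(sc, lab).auc
        # strictly increasing transform leaves AUC unchanged
        sc2 = {k: math.exp(0.3 * v) for k, v in sc.items()}
        assert roc_auc(sc2, lab).auc == pytest.approx(auc)
        # negating scores reflects AUC (no ties: exact complement)
        sc3 = {k: -v for k, v in sc.items()}
        assert roc_auc(sc3, lab).auc == pytest.approx(1 - auc)

    def test_ci_contains_auc_and_is_ordered(self):
        rng = np.random.default_rng(0)
        sc = {f"t{i}": float(v) for i, v in enumerate(rng.normal(size=80))}
        lab = {f"t{i}": (1 if i < 30 else -1) for i in range(80)}
        roc = roc_auc(sc, lab, ci=True)
        lo, hi = roc.ci95
        assert 0 <= lo <= roc.auc <= hi <= 1


class TestOperatingPoint:
    @pytest.mark.parametrize(
        "points,expected",
        [
            ([(1, 0.5), (0.75, 1)], (0.75, 1)),
            ([(1, 1), (0.5, 0.5)], (1, 1)),
            ([(0.8, 0.6), (0.6, 0.8)], (0.8, 0.6)),  # tie -> higher sens
        ],
    )
    def test_min_distance_rule(self, points, expected):
        assert operating_point(points) == expected

    def test_operating_point_is_on_curve(self):
        rng = np.random.default_rng(1)
        sc = {f"t{i}": float(v) for i, v in enumerate(rng.normal(size=50))}
        lab = {f"t{i}": (1 if i < 20 else -1) for i in range(50)}
        roc = roc_auc(sc, lab)
        assert (roc.operating_point[0], roc.operating_point[1]) in roc.points


class TestBaselines:
    def test_intersect_strictly_above_median(self):
        expr = ExpressionProfile({"A": 5, "B": 1, "C": 3, "D": 2, "E": 4})
        out = intersect_baseline({"A": 0.9, "C": 0.8}, expr)
        assert out == {"A": 0.9}  # median 3, C not strictly above

    def test_even_profile_median_is_midpoint(self):
        expr = ExpressionProfile({"A": 1, "B": 2, "C": 3, "D": 4})
        out = intersect_baseline({"B": 1.0, "C": 1.0}, expr)
        assert out == {"C": 1.0}  # median 2.5

    def test_all_below_median_empty(self):
        expr = ExpressionProfile({"A": 1, "B": 2, "C": 9, "D": 9, "E": 9})
        assert intersect_baseline({"A": 1.0, "B": 1.0}, expr) == {}

    def test_sum_baseline_neutral_imputation(self, small_sim):
        from targetexpress import build_matrix
        mat = build_matrix(small_sim.predictions, small_sim.expression)
        ts = sum_baseline(mat, {"context_plus"})
        both = sum_baseline(mat, {"context_plus", "mitg"})
        tid = next(t for t in mat.transcript_ids
                   if mat.imputed.loc[t, "mitg"]
                   and not mat.imputed.loc[t, "context_plus"])
        assert both[tid] == pytest.approx(ts[tid])
        # order invariance
        assert sum_baseline(mat, {"mitg", "context_plus"}) == both


class TestPairedWilcoxon:
    def test_all_positive_n3(self):
        assert paired_wilcoxon([0.7, 0.8, 0.9], [0.6, 0.7, 0.8]) == \
            pytest.approx(0.125)

    def test_all_negative_n3(self):
        assert paired_wilcoxon([0.6, 0.7, 0.8], [0.7, 0.8, 0.9]) == \
            pytest.approx(1.0)

    def test_identical_vectors_degenerate(self):
        assert paired_wilcoxon([0.5, 0.6, 0.7], [0.5, 0.6, 0.7]) == 1.0

    @given(
        diffs=st.lists(
            st.floats(-1, 1).filter(lambda x: abs(x) > 1e-6),
            min_size=3, max_size=10,
        ),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_enumeration_oracle(self, diffs, seed):
        b = np.random.default_rng(seed).uniform(0, 1, len(diffs))
        a = b + np.asarray(diffs)
        # the oracle sees the same float differences the test statistic does
        assert paired_wilcoxon(a, b) == pytest.approx(
            signed_rank_oracle(a - b), abs=1e-12
        )

    def test_large_n_normal_approximation_reasonable(self):
        rng = np.random.default_rng(2)
        b = rng.uniform(size=40)
        a = b + rng.normal(0.3, 0.1, size=40)  # strongly positive shift
        assert paired_wilcoxon(a, b) < 1e-6
        assert 0 < paired_wilcoxon(b, a) <= 1


@pytest.fixture(scope="module")
def experiments():
    from targetexpress import SimConfig, prepare_experiment, \
        simulate_experiments
    cfg = SimConfig(n_transcripts=500, n_experiments=3, seed=7)
    return [prepare_experiment(s, run_qc=False)
            for s in simulate_experiments(cfg)]


class TestLoocv:
    def test_report_structure(self, experiments):
        rep = loocv(experiments, ["raw:context_plus", "te:context_plus"])
        assert rep.auc.shape == (3, 2)
        assert set(rep.auc.index) == {e.experiment_id for e in experiments}
        assert ((rep.auc >= 0) & (rep.auc <= 1)).all().all()

    def test_too_few_eligible_errors(self, experiments):
        with pytest.raises(DomainError):
            loocv(experiments[:1], ["raw:context_plus"])

    def test_no_leakage_of_leftout_experiment(self, experiments, monkeypatch):
        """The left-out experiment's matrix never enters training."""
        import targetexpress.evaluate as ev
        seen = []
        orig = ev.train_ensemble

        def spy(train, **kw):
            seen.append([m.experiment_id for m, _ in train])
            return orig(train, **kw)

        monkeypatch.setattr(ev, "train_ensemble", spy)
        loocv(experiments, ["te:context_plus"])
        ids = [e.experiment_id for e in experiments]
        assert len(seen) == len(ids)
        for left_out, trained_on in zip(ids, seen):
            assert left_out not in trained_on
            assert set(trained_on) == set(ids) - {left_out}
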