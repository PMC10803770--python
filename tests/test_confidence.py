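import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from erad_screen import confidence
from erad_screen.confidence import (
    ConfidenceModel,
    aggregate_features,
    best_intercept,
    compute_features,
    derive_labels,
    fit_model,
    hard_mcc,
    mcc,
    score,
    select_cutoff,
    _design,
)
from erad_screen.errors import TrainingError
from .conftest import make_annotation


def _psm_row(hko, wt, sko, igg, protein="P", exp="expt1"):
    return pd.DataFrame(
        [{"protein_id": protein, "experiment_id": exp,
          "psm_igg": igg, "psm_sko": sko, "psm_wt": wt, "psm_hko": hko}]
    )


class TestFeatures:
    @pytest.mark.parametrize(
        "hko, wt, sko, igg, x1, x2",
        [
            (10, 2, 0, 1, 5.0, 10.0),   # plain ratios
            (0, 5, 3, 2, 0.0, 0.0),     # zero numerator
            (4, 0, 0, 0, 4.0, 4.0),     # denominators floored at 1
            (8, 4, 2, 6, 8 / 6, 8 / 6), # IgG dominates both denominators
        ],
    )
    def test_feature_values(self, hko, wt, sko, igg, x1, x2):
        f = compute_features(_psm_row(hko, wt, sko, igg))
        assert f.loc[0, "x1"] == pytest.approx(x1)
        assert f.loc[0, "x2"] == pytest.approx(x2)

    @settings(max_examples=200, deadline=None)
    @given(
        counts=st.tuples(*[st.integers(0, 100)] * 4),
        k=st.integers(1, 10),
    )
    def test_scale_invariance_above_floor(self, counts, k):
        """Multiplying all four counts by k leaves x1, x2 unchanged while
        the denominators stay above the floor of 1."""
        hko, wt, sko, igg = counts
        if max(wt, igg) < 1 or max(sko, igg) < 1:
            return
        a = compute_features(_psm_row(hko, wt, sko, igg)).loc[0]
        b = compute_features(_psm_row(hko * k, wt * k, sko * k, igg * k)).loc[0]
        assert a["x1"] == pytest.approx(b["x1"])
        assert a["x2"] == pytest.approx(b["x2"])

    def test_features_always_finite_and_nonnegative(self, default_dataset):
        f = compute_features(default_dataset.psm)
        assert np.isfinite(f[["x1", "x2"]].to_numpy()).all()
        assert (f[["x1", "x2"]].to_numpy() >= 0).all()

    def test_aggregation_averages_only_detected_experiments(self):
        psm = pd.concat(
            [
                _psm_row(10, 1, 0, 0, exp="expt1"),  # x = (10, 10)
                _psm_row(0, 5, 5, 0, exp="expt2"),   # hko = 0: ignored
                _psm_row(4, 2, 1, 0, exp="expt3"),   # x = (2, 4)
            ],
            ignore_index=True,
        )
        feats = compute_features(psm)
        agg = aggregate_features(feats, psm).set_index("protein_id")
        assert agg.loc["P", "x1"] == pytest.approx(6.0)
        assert agg.loc["P", "x2"] == pytest.approx(7.0)


class TestLabels:
    def _annot(self):
        rows = [
            make_annotation("OS9"),  # in known list → positive
            make_annotation("A1", localizations="ER", n_glycosylation_sites=2),
            make_annotation("A2", localizations="cytosol",
                            has_signal_peptide=False, n_glycosylation_sites=0),
            make_annotation("A3", localizations="nucleus", n_glycosylation_sites=3),
        ]
        df = pd.DataFrame(rows)
        df["is_keratin_family"] = False
        return df

    def test_label_rules(self):
        labels = derive_labels(self._annot(), ["OS9"]).set_index("protein_id")
        assert labels.loc["OS9", "label"] == "positive"
        # ER + signal peptide + glycans, not known → unlabeled
        assert labels.loc["A1", "label"] == "unlabeled"
        # featureless and outside client compartments → negative
        assert labels.loc["A2", "label"] == "negative"
        # glycosylated but nucleus-only → negative (compartment rule)
        assert labels.loc["A3", "label"] == "negative"

    def test_single_class_rejected(self):
        only_pos = self._annot().iloc[[0]]
        with pytest.raises(TrainingError):
            derive_labels(only_pos, ["OS9"])
        with pytest.raises(TrainingError):
            derive_labels(self._annot(), [])


class TestMcc:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((5, 5, 0, 0), 1.0),
            ((0, 0, 5, 5), -1.0),
            ((1, 1, 1, 1), 0.0),
            ((0, 5, 0, 5), 0.0),  # zero denominator factor → 0 by convention
            ((3, 0, 0, 0), 0.0),
        ],
    )
    def test_closed_forms(self, counts, expected):
        assert mcc(*counts) == pytest.approx(expected)

    @settings(max_examples=200, deadline=None)
    @given(c=st.tuples(*[st.integers(0, 50)] * 4))
    def test_symmetry_and_bounds(self, c):
        tp, tn, fp, fn = c
        v = mcc(tp, tn, fp, fn)
        assert -1.0 <= v <= 1.0
        assert v == pytest.approx(mcc(tn, tp, fn, fp))


class TestScore:
    def test_zero_weights_give_half(self):
        m = ConfidenceModel(0, 0, 0, 0, 1, 1)
        assert score(m, 3.0, 7.0) == pytest.approx(0.5)

    def test_cancelling_logit(self):
        m = ConfidenceModel(-1, 1, 1, 0, 1, 1)
        assert score(m, 1.0, 0.0) == pytest.approx(0.5)

    def test_logistic_symmetry_and_bounds(self, rng):
        w = rng.normal(size=3)
        x = rng.lognormal(size=(50, 2))
        s = score(w, x[:, 0], x[:, 1])
        s_neg = score(-w, x[:, 0], x[:, 1])
        assert np.allclose(s + s_neg, 1.0)
        assert ((s > 0) & (s < 1)).all()

    def test_overflow_safe(self):
        assert score(np.array([1e4, 1e4, 1e4]), 1e3, 1e3) == pytest.approx(1.0)
        assert score(np.array([-1e4, 0, 0]), 0, 0) == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(
        x=st.tuples(st.floats(0, 50), st.floats(0, 50)),
        dx=st.floats(0, 10),
    )
    def test_monotone_in_features_for_positive_weights(self, x, dx):
        w = np.array([-2.0, 0.5, 1.5])
        assert score(w, x[0] + dx, x[1]) >= score(w, x[0], x[1])
        assert score(w, x[0], x[1] + dx) >= score(w, x[0], x[1])


class TestFit:
    def test_separable_labels_reach_perfect_mcc(self):
        """Positives at x1 >= 5 and negatives at x1 <= 1 are separable, so
        the fit must reach a hard MCC of exactly 1."""
        X = np.array([[6.0, 1], [5.0, 2], [8.0, 0.5], [1.0, 1], [0.5, 2], [0.2, 0]])
        y = np.array([1, 1, 1, 0, 0, 0], bool)
        model = fit_model(X, y)
        assert model.achieved_mcc == 1.0
        # reported MCC is realizable by the returned weights
        assert hard_mcc(model.weights, _design(X), y) == 1.0

    def test_reported_mcc_matches_returned_weights(self, rng):
        X = rng.lognormal(0.5, 1.0, (40, 2))
        y = rng.random(40) < 0.4
        y[0] = True
        y[1] = False
        model = fit_model(X, y)
        assert model.achieved_mcc == pytest.approx(
            hard_mcc(model.weights, _design(X), y)
        )

    def test_fit_is_deterministic(self, rng):
        X = rng.lognormal(0.5, 1.0, (60, 2))
        y = np.concatenate([np.ones(20, bool), np.zeros(40, bool)])
        a = fit_model(X, y)
        b = fit_model(X, y)
        assert a.weights.tolist() == b.weights.tolist()
        assert a.achieved_mcc == b.achieved_mcc

    def test_single_class_is_training_error(self):
        with pytest.raises(TrainingError):
            fit_model(np.ones((5, 2)), np.ones(5, bool))

    def test_permuted_labels_carry_no_generalizable_signal(self):
        """With labels permuted against features the fit may overfit its
        training sample (3 free parameters chasing the MCC), but scoring a
        fresh permutation must give MCC ≈ 0."""
        in_sample, out_sample = [], []
        for rep in range(10):
            rng = np.random.default_rng(5000 + rep)
            X = rng.lognormal(0.5, 1.0, (200, 2))
            y = np.zeros(200, bool)
            y[:60] = True
            rng.shuffle(y)
            model = fit_model(X, y, max_iter=800)
            in_sample.append(model.achieved_mcc)
            X2 = rng.lognormal(0.5, 1.0, (200, 2))
            y2 = np.zeros(200, bool)
            y2[:60] = True
            rng.shuffle(y2)
            out_sample.append(hard_mcc(model.weights, _design(X2), y2))
        assert abs(float(np.mean(out_sample))) < 0.1
        assert float(np.mean(in_sample)) < 0.35  # bounded overfit


class TestBestIntercept:
    def test_tie_splits_are_not_reported(self):
        """A split inside a run of equal scores is unrealizable and must
        not inflate the reported MCC."""
        z = np.array([0.0, 0.0, 0.0, 0.0])
        y = np.array([True, False, True, False])
        w0, m = best_intercept(z, y)
        # only all-positive or all-negative splits exist → MCC 0
        assert m == 0.0

    @settings(max_examples=100, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_reported_mcc_is_achieved_by_returned_intercept(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.choice([0.0, 1.0, 2.5, 4.0], 30)
        y = rng.random(30) < 0.5
        if y.all() or not y.any():
            return
        w0, m = best_intercept(z, y)
        pred = z + w0 >= 0
        tp = int((pred & y).sum()); fp = int((pred & ~y).sum())
        fn = int((~pred & y).sum()); tn = int((~pred & ~y).sum())
        assert m == pytest.approx(mcc(tp, tn, fp, fn))


class TestCutoff:
    def _psm(self, rows):
        return pd.DataFrame(
            [
                {"protein_id": p, "experiment_id": e,
                 "psm_igg": i, "psm_sko": s, "psm_wt": w, "psm_hko": h}
                for (p, e, i, s, w, h) in rows
            ]
        )

    def test_cutoff_is_min_anchor_score(self):
        psm = self._psm(
            [
                ("A", "e1", 0, 0, 0, 2), ("A", "e2", 0, 0, 0, 0),
                ("B", "e1", 0, 0, 0, 2), ("B", "e2", 0, 0, 0, 3),
                ("C", "e1", 0, 0, 5, 9), ("C", "e2", 0, 0, 4, 8),
            ]
        )
        scores = pd.Series({"A": 0.63, "B": 0.41, "C": 0.9})
        cutoff, anchors, fallback = select_cutoff(scores, psm)
        assert cutoff == pytest.approx(0.41)
        assert anchors == ["A", "B"]
        assert not fallback

    def test_wt_detection_disqualifies_anchor(self):
        psm = self._psm([("A", "e1", 0, 0, 1, 2), ("A", "e2", 0, 0, 0, 2)])
        cutoff, anchors, fallback = select_cutoff(pd.Series({"A": 0.3}), psm)
        assert fallback and cutoff == 0.5 and anchors == []

    def test_modes(self):
        psm = self._psm([("A", "e1", 0, 0, 0, 2), ("A", "e2", 0, 0, 0, 2),
                         ("B", "e1", 0, 0, 0, 4), ("B", "e2", 0, 0, 0, 0)])
        scores = pd.Series({"A": 0.6, "B": 0.2})
        assert select_cutoff(scores, psm, mode="exact_single")[1] == ["A"]
        assert select_cutoff(scores, psm, mode="exact_sum")[1] == []
        assert select_cutoff(scores, psm, mode="at_least")[1] == ["A", "B"]
        with pytest.raises(ValueError):
            select_cutoff(scores, psm, mode="bogus")

    def test_all_anchor_identical_scores(self):
        psm = self._psm([("A", "e1", 0, 0, 0, 2), ("A", "e2", 0, 0, 0, 0)])
        cutoff, anchors, fallback = select_cutoff(pd.Series({"A": 0.7}), psm)
        assert cutoff == pytest.approx(0.7) and not fallback
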