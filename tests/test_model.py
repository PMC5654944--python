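import itertools
import json

import numpy as np
import pandas as pd
import pytest

from cnarec.model import (
    CNARecurrenceModel, PairwiseLinearSVM, TASK_NAMES, ThreePhaseModel,
    derive_unidentifiable, phase1_trace, predict, train_three_phase, vote,
)
from cnarec.segments import NOREC, REC, UNID
from cnarec.selection import SelectionConfig


def separable_three_class(n_per_class=10):
    """Linearly separable toy data: each class marked by its own bin block."""
    rows, labels = [], []
    for cls, block in ((REC, 0), (NOREC, 2), (UNID, 4)):
        for i in range(n_per_class):
            row = np.zeros(6, dtype=np.int8)
            row[block] = 1
            row[block + 1] = 1
            rows.append(row)
            labels.append(cls)
    X = pd.DataFrame(rows, columns=[f"b{j}" for j in range(6)],
                     index=[f"{c}{i}" for c, i in zip(labels, range(len(labels)))])
    return X, pd.Series(labels, index=X.index, dtype=object)


FEATS = {name: [f"b{j}" for j in range(6)] for name in TASK_NAMES}


class TestVote:
    def brute_force(self, triple):
        counts = {c: triple.count(c) for c in set(triple)}
        top = max(counts.values())
        winners = [c for c, k in counts.items() if k == top]
        return winners[0] if len(winners) == 1 and top >= 2 else UNID

    def test_exhaustive_enumeration_matches_max_wins_oracle(self):
        for triple in itertools.product((REC, NOREC), (NOREC, UNID), (REC, UNID)):
            assert vote(triple) == self.brute_force(list(triple))

    def test_cyclic_tie_resolves_to_unid(self):
        assert vote((NOREC, UNID, REC)) == UNID
        assert vote((REC, NOREC, UNID)) == UNID

    def test_invalid_response_rejected(self):
        with pytest.raises(ValueError):
            vote((UNID, NOREC, REC))  # UNID is not a phase-1 response


class TestPhase1Trace:
    def test_separable_data_low_misclassification(self):
        X, y3 = separable_three_class()
        mask = y3 != UNID
        trace = phase1_trace(X[mask], y3[mask], n_rounds=100, seed=0)
        assert (trace.rates <= 0.05).all()

    def test_planted_ambiguous_patient_flagged(self):
        rng = np.random.default_rng(0)
        n = 40
        y = pd.Series([REC] * 16 + [NOREC] * 24, dtype=object,
                      index=[f"P{i:02d}" for i in range(n)])
        p = np.where(y.values == REC, 0.85, 0.1)
        p[-1] = 0.85  # last patient labelled NOREC, drawn from the REC profile
        X = pd.DataFrame((rng.random((6, n)) < p).T.astype(np.int8),
                         index=y.index, columns=[f"b{j}" for j in range(6)])
        trace = phase1_trace(X, y, n_rounds=200, seed=1)
        assert trace.table.loc["P39", "misclassification_rate"] > 0.5

    def test_counts_are_consistent(self):
        X, y3 = separable_three_class()
        mask = y3 != UNID
        trace = phase1_trace(X[mask], y3[mask], n_rounds=50, seed=2)
        t = trace.table
        assert (t["times_misclassified"] <= t["times_held_out"]).all()
        never = t["times_held_out"] == 0
        assert (t.loc[never, "misclassification_rate"] == 0).all()

    def test_deterministic(self):
        X, y3 = separable_three_class()
        mask = y3 != UNID
        t1 = phase1_trace(X[mask], y3[mask], n_rounds=30, seed=3).table
        t2 = phase1_trace(X[mask], y3[mask], n_rounds=30, seed=3).table
        pd.testing.assert_frame_equal(t1, t2)


class TestDeriveUnidentifiable:
    def make_trace(self, rates, held_out=100):
        from cnarec.model import MisclassificationTrace

        idx = [f"P{i}" for i in range(len(rates))]
        table = pd.DataFrame({
            "times_held_out": [held_out] * len(rates),
            "times_misclassified": [int(r * held_out) for r in rates],
            "misclassification_rate": rates,
        }, index=idx)
        return MisclassificationTrace(table, n_rounds=held_out, seed=0)

    def test_zero_rates_leave_labels_unchanged(self):
        trace = self.make_trace([0.0, 0.0, 0.0])
        labels = pd.Series([REC, NOREC, NOREC], index=trace.table.index, dtype=object)
        labels3, unid = derive_unidentifiable(trace, labels)
        assert unid == [] and (labels3 == labels).all()

    def test_threshold_application(self):
        trace = self.make_trace([0.9, 0.4, 0.6])
        labels = pd.Series([REC, NOREC, NOREC], index=trace.table.index, dtype=object)
        labels3, unid = derive_unidentifiable(trace, labels, theta=0.5)
        assert unid == ["P0", "P2"]
        assert list(labels3) == [UNID, NOREC, UNID]

    def test_evidence_floor(self):
        trace = self.make_trace([0.9], held_out=3)
        labels = pd.Series([NOREC], index=trace.table.index, dtype=object)
        _, unid = derive_unidentifiable(trace, labels, min_held_out=20)
        assert unid == []

    def test_monotone_in_theta(self):
        rng = np.random.default_rng(4)
        rates = rng.random(30).round(2)
        trace = self.make_trace(list(rates))
        labels = pd.Series([NOREC] * 30, index=trace.table.index, dtype=object)
        prev = set(derive_unidentifiable(trace, labels, theta=0.2)[1])
        for theta in (0.3, 0.5, 0.8, 1.0):
            cur = set(derive_unidentifiable(trace, labels, theta=theta)[1])
            assert cur <= prev
            prev = cur

    def test_all_unid_is_error(self):
        trace = self.make_trace([1.0, 1.0])
        labels = pd.Series([REC, NOREC], index=trace.table.index, dtype=object)
        with pytest.raises(ValueError, match="degenerate"):
            derive_unidentifiable(trace, labels)


class TestTrainPredict:
    def test_separable_resubstitution_perfect(self):
        X, y3 = separable_three_class()
        model = train_three_phase(X, y3, FEATS)
        out = predict(model, X)
        assert (out["final"] == y3).all()

    def test_absent_feature_rejected(self):
        X, y3 = separable_three_class()
        feats = dict(FEATS)
        feats["rec_vs_unid"] = ["nope"]
        with pytest.raises(KeyError, match="nope"):
            train_three_phase(X, y3, feats)

    def test_small_class_rejected_by_name(self):
        X, y3 = separable_three_class()
        y3[y3 == UNID] = NOREC
        y3.iloc[-2:] = UNID  # only 2 UNID
        with pytest.raises(ValueError, match="UNID"):
            train_three_phase(X, y3, FEATS)

    def test_batch_equals_rowwise_and_row_order_invariant(self):
        X, y3 = separable_three_class()
        model = train_three_phase(X, y3, FEATS)
        batch = predict(model, X)["final"]
        for i in range(0, len(X), 7):
            single = predict(model, X.iloc[[i]])["final"].iloc[0]
            assert single == batch.iloc[i]
        perm = X.sample(frac=1, random_state=0)
        assert (predict(model, perm)["final"].loc[X.index] == batch).all()

    def test_all_zero_row_prediction_stable(self):
        X, y3 = separable_three_class()
        model = train_three_phase(X, y3, FEATS)
        zero = pd.DataFrame(0, index=["z"], columns=X.columns)
        first = predict(model, zero)["final"].iloc[0]
        for _ in range(3):
            assert predict(model, zero)["final"].iloc[0] == first

    def test_missing_prediction_column_rejected(self):
        X, y3 = separable_three_class()
        model = train_three_phase(X, y3, FEATS)
        with pytest.raises(KeyError, match="b5"):
            predict(model, X.drop(columns=["b5"]))

    def test_paper_style_band_labels_accepted_as_features(self):
        X, y3 = separable_three_class()
        bands = ["8p23.1-p22", "9p13.2-p12", "9p24.3-p24.1",
                 "15q26.2-q26.3", "17p12", "17p12-p11.2"]
        Xb = X.copy()
        Xb.columns = bands
        feats = {name: bands for name in TASK_NAMES}
        model = train_three_phase(Xb, y3, feats)
        assert (predict(model, Xb)["final"] == y3).all()


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, tmp_path):
        X, y3 = separable_three_class()
        model = train_three_phase(X, y3, FEATS)
        path = tmp_path / "model.json"
        model.save(path)
        again = ThreePhaseModel.load(path)
        pd.testing.assert_frame_equal(predict(model, X), predict(again, X))
        payload = json.loads(path.read_text())
        assert payload["format_version"] == 1

    def test_unknown_format_version_rejected(self, tmp_path):
        X, y3 = separable_three_class()
        model = train_three_phase(X, y3, FEATS)
        d = model.to_dict()
        d["format_version"] = 99
        with pytest.raises(ValueError, match="version"):
            ThreePhaseModel.from_dict(d)


@pytest.fixture(scope="module")
def fitted():
    from cnarec.binning import assign_to_bins, bin_scheme_from_cohort
    from cnarec.simulate import SimulationConfig, simulate_cohort

    cohort, truth = simulate_cohort(SimulationConfig(seed=3))
    scheme = bin_scheme_from_cohort(cohort)
    X = assign_to_bins(cohort, scheme)
    y = pd.Series(cohort.outcomes())
    model = CNARecurrenceModel(
        X, y, scheme=scheme,
        selection=SelectionConfig(n_bootstrap=20, n_trees=50),
        n_rounds=150,
    )
    return model.fit(seed=5), truth


class TestModelResults:
    def test_fit_derives_unid_and_three_classes(self, fitted):
        res, truth = fitted
        assert set(res.labels3.unique()) == {REC, NOREC, UNID}
        assert set(res.unid_patients) & set(truth.ambiguous_patients)

    def test_summary_mentions_phases_and_features(self, fitted):
        res, _ = fitted
        text = res.summary()
        assert "phase 1" in text and "phase 3" in text
        assert "UNID" in text

    def test_results_predict_covers_training_patients(self, fitted):
        res, _ = fitted
        out = res.predict()
        assert list(out.index) == list(res.labels3.index)
        assert out["final"].isin([REC, NOREC, UNID]).all()
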