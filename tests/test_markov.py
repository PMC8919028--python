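"""Transition estimation, stationary frequencies, state classification,
and conditional cross-site detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from microstates import markov as mk

from conftest import toy_table


def _inputs_from_series(series_by_patient, site="gut"):
    """Build (labels, meta) from per-patient state sequences."""
    rows, labels = [], {}
    for patient, seq in series_by_patient.items():
        for t, state in enumerate(seq, start=1):
            sid = f"{patient}_{site}_T{t}"
            rows.append({"sample_id": sid, "patient_id": patient,
                         "body_site": site, "time_index": t})
            labels[sid] = state
    return pd.Series(labels), pd.DataFrame(rows)


class TestEstimateTransitions:
    def test_hand_counted_example(self):
        labels, meta = _inputs_from_series({"P1": ["A", "A", "B"], "P2": ["A", "B", "B"]})
        m = mk.estimate_transitions(labels, meta, "gut", states=["A", "B"])
        assert m.counts.to_numpy().tolist() == [[1, 2], [0, 1]]
        assert m.probabilities.loc["A"].tolist() == pytest.approx([1 / 3, 2 / 3])
        assert m.probabilities.loc["B"].tolist() == pytest.approx([0.0, 1.0])

    def test_constant_series_flags_unobserved_origin(self):
        labels, meta = _inputs_from_series({"P1": ["A", "A", "A"]})
        m = mk.estimate_transitions(labels, meta, "gut", states=["A", "B"])
        assert m.probabilities.loc["A", "A"] == 1.0
        assert m.uniform_rows == ["B"]
        assert m.probabilities.loc["B"].tolist() == [0.5, 0.5]

    def test_gap_in_occasions_is_not_a_step(self):
        labels, meta = _inputs_from_series({"P1": ["A", "B", "A"], "P2": ["B", "B", "B"]})
        labels = labels.drop("P1_gut_T2")  # dropped sample leaves a t1->t3 gap
        m = mk.estimate_transitions(labels, meta, "gut", states=["A", "B"])
        # only P2's two steps survive; the gapped t1->t3 pair is not a step
        assert m.n_steps == 2
        assert m.counts.loc["B", "B"] == 2

    def test_no_series_raises(self):
        labels, meta = _inputs_from_series({"P1": ["A"]})
        with pytest.raises(ValueError, match="length >= 2"):
            mk.estimate_transitions(labels, meta, "gut", states=["A"])

    def test_patient_order_invariance(self):
        d1 = {"P1": ["A", "B", "A"], "P2": ["B", "B", "A"]}
        d2 = {"P2": ["B", "B", "A"], "P1": ["A", "B", "A"]}
        m1 = mk.estimate_transitions(*_inputs_from_series(d1), "gut", states=["A", "B"])
        m2 = mk.estimate_transitions(*_inputs_from_series(d2), "gut", states=["A", "B"])
        assert m1.counts.equals(m2.counts)

    def test_smoothing_drives_rows_uniform(self):
        labels, meta = _inputs_from_series({"P1": ["A", "A", "B", "A"]})
        m = mk.estimate_transitions(labels, meta, "gut", smoothing=1e9, states=["A", "B"])
        assert np.allclose(m.probabilities.to_numpy(), 0.5, atol=1e-6)

    def test_parameter_recovery_from_long_series(self):
        from microstates.synth import simulate_state_sequences

        P = np.array([[0.7, 0.2, 0.1], [0.3, 0.5, 0.2], [0.1, 0.1, 0.8]])
        seqs = simulate_state_sequences(P, np.full(3, 1 / 3), n_steps=50,
                                        n_series=200, seed=2)
        names = ["A", "B", "C"]
        series = {f"P{i}": [names[s] for s in seq] for i, seq in enumerate(seqs)}
        labels, meta = _inputs_from_series(series)
        m = mk.estimate_transitions(labels, meta, "gut", states=names)
        assert np.abs(m.probabilities.to_numpy() - P).max() < 0.05


class TestStationary:
    def test_symmetric_cycle(self):
        (pi,) = mk.stationary_distribution([[0, 1], [1, 0]])
        assert pi.tolist() == pytest.approx([0.5, 0.5])

    def test_reducible_identity_has_two_solutions(self):
        pis = mk.stationary_distribution(np.eye(2))
        assert len(pis) == 2
        assert sorted(tuple(p) for p in pis) == [(0.0, 1.0), (1.0, 0.0)]

    def test_two_state_closed_form(self):
        # 0.1 pi1 = 0.5 pi2 -> pi = (5/6, 1/6); matrix-power oracle agrees
        P = np.array([[0.9, 0.1], [0.5, 0.5]])
        (pi,) = mk.stationary_distribution(P)
        assert pi == pytest.approx([5 / 6, 1 / 6])
        power = np.linalg.matrix_power(P, 1024)
        assert np.abs(power - pi).max() < 1e-12

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError):
            mk.stationary_distribution([[0.5, 0.4], [0.5, 0.5]])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hst.integers(min_value=0, max_value=10_000))
    def test_balance_equation_for_random_dense_chains(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.dirichlet(np.ones(4), size=4)
        (pi,) = mk.stationary_distribution(P)
        assert np.abs(pi @ P - pi).max() < 1e-10
        assert pi.sum() == pytest.approx(1.0)


class TestClassification:
    def test_absorbing_state(self):
        labels = mk.classify_states([[1, 0], [0.5, 0.5]])
        assert labels.tolist() == ["recurrent", "transient"]

    def test_irreducible_all_recurrent(self):
        P = np.full((3, 3), 1 / 3)
        assert (mk.classify_states(P) == "recurrent").all()

    def test_matches_reachability_oracle(self):
        # oracle: i recurrent iff every j reachable from i can reach i
        rng = np.random.default_rng(0)
        for _ in range(100):
            P = rng.dirichlet(np.ones(4), size=4)
            P[rng.random((4, 4)) < 0.4] = 0.0
            rowsums = P.sum(axis=1)
            dead = rowsums == 0
            P[dead, rng.integers(0, 4, dead.sum())] = 1.0
            P /= P.sum(axis=1, keepdims=True)
            reach = np.linalg.matrix_power((P > 0).astype(int) + np.eye(4, dtype=int), 4) > 0
            oracle = [
                "recurrent" if all((not reach[i, j]) or reach[j, i] for j in range(4))
                else "transient"
                for i in range(4)
            ]
            assert mk.classify_states(P).tolist() == oracle

    def test_relabeling_invariance(self):
        P = np.array([[1.0, 0.0], [0.5, 0.5]])
        perm = np.array([1, 0])
        Pp = P[np.ix_(perm, perm)]
        assert mk.classify_states(Pp).tolist() == ["transient", "recurrent"]


class TestGraphSummary:
    def _model(self, series):
        labels, meta = _inputs_from_series(series)
        return mk.estimate_transitions(labels, meta, "gut", states=["A", "B"])

    def test_identity_chain_only_self_loops(self):
        m = self._model({"P1": ["A", "A", "A"], "P2": ["B", "B", "B"]})
        edges, stability = mk.transition_graph_summary(m)
        assert set(zip(edges["from_state"], edges["to_state"])) == {("A", "A"), ("B", "B")}
        assert stability == 1.0

    def test_hand_counted_model_edges(self):
        m = self._model({"P1": ["A", "A", "B"], "P2": ["A", "B", "B"]})
        edges, stability = mk.transition_graph_summary(m)
        lookup = {(r.from_state, r.to_state): r.probability for r in edges.itertuples()}
        assert lookup[("A", "A")] == pytest.approx(1 / 3)
        assert lookup[("A", "B")] == pytest.approx(2 / 3)
        assert lookup[("B", "B")] == pytest.approx(1.0)
        assert stability == pytest.approx((1 / 3 + 1.0) / 2)


class TestConditionalDetection:
    def _toy(self):
        # 2 patients x 2 occasions x 2 sites; 2 ASVs
        rows, counts, ids = [], [], []
        detections = {
            # (patient, time, site): (asv1, asv2)
            ("P1", 1, "gut"): (5, 0), ("P1", 1, "oral"): (3, 0),
            ("P1", 2, "gut"): (4, 2), ("P1", 2, "oral"): (0, 1),
            ("P2", 1, "gut"): (7, 1), ("P2", 1, "oral"): (2, 1),
            ("P2", 2, "gut"): (6, 3), ("P2", 2, "oral"): (0, 0),
        }
        for (p, t, s), c in detections.items():
            sid = f"{p}_{s}_T{t}"
            ids.append(sid)
            counts.append(list(c) + [1])  # third ASV keeps samples non-empty
            rows.append({"sample_id": sid, "patient_id": p, "body_site": s,
                         "time_index": t})
        return toy_table(counts, sample_ids=ids), pd.DataFrame(rows)

    def test_direct_count_example(self):
        table, meta = self._toy()
        cd = mk.conditional_detection(table, meta)
        # ASV_1 detected in gut at 4 occasions, in both at 2 of them
        assert cd.per_asv[("oral", "gut")]["ASV_1"] == pytest.approx(0.5)

    def test_always_codetected_gives_one_both_ways(self):
        table, meta = self._toy()
        cd = mk.conditional_detection(table, meta)
        assert cd.per_asv[("gut", "oral")]["ASV_1"] == pytest.approx(1.0)

    def test_never_detected_is_missing_not_zero(self):
        table, meta = self._toy()
        table.data["ASV_3"] = 0
        table.data.loc["P1_gut_T1", "ASV_3"] = 1  # detected at gut only
        cd = mk.conditional_detection(table, meta)
        assert np.isnan(cd.per_asv[("gut", "oral")]["ASV_3"])

    def test_bayes_identity_machine_precision(self, rarefied_cohort):
        rarefied, meta, _ = rarefied_cohort
        cd = mk.conditional_detection(rarefied, meta)
        assert mk.verify_bayes_identity(cd) < 1e-12

    def test_aggregate_is_mean_of_defined_values(self):
        table, meta = self._toy()
        cd = mk.conditional_detection(table, meta)
        col = cd.per_asv[("oral", "gut")]
        assert cd.aggregate.loc["oral", "gut"] == pytest.approx(col.dropna().mean())
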