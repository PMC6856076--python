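"""Ground-truth sampling, linear-Gaussian simulation, recovery scoring."""

import numpy as np
import pytest

from causnet.perturbation import SingleRunNetwork, aggregate
from causnet.simulate import (
    evaluate_recovery,
    load_truth_edges,
    sample_network,
    simulate_dataset,
    write_truth_edges,
)


class TestSampleNetwork:
    def test_row_sparsity_and_spectral_radius(self):
        gt = sample_network(10, 2, seed=0)
        A = gt.coefficient_matrix
        off = A - np.diag(np.diag(A))
        assert all(np.count_nonzero(off[i]) == 2 for i in range(10))
        assert gt.spectral_radius < 1.0
        assert np.all(np.diag(A) > 0)

    def test_effect_size_floor(self):
        gt = sample_network(12, 3, seed=5, min_effect=0.3)
        off = gt.coefficient_matrix[~np.eye(12, dtype=bool)]
        assert np.abs(off[off != 0]).min() >= 0.3

    def test_sign_prob_extremes(self):
        all_act = sample_network(8, 2, sign_prob=0.0, seed=1)
        off = all_act.coefficient_matrix[~np.eye(8, dtype=bool)]
        assert np.all(off[off != 0] > 0)
        all_rep = sample_network(8, 2, sign_prob=1.0, seed=1)
        off = all_rep.coefficient_matrix[~np.eye(8, dtype=bool)]
        assert np.all(off[off != 0] < 0)

    def test_seed_reproducibility(self):
        a = sample_network(9, 2, seed=42)
        b = sample_network(9, 2, seed=42)
        np.testing.assert_array_equal(a.coefficient_matrix, b.coefficient_matrix)
        np.testing.assert_array_equal(a.intercepts, b.intercepts)

    def test_invalid_configurations(self):
        with pytest.raises(ValueError):
            sample_network(5, 5, seed=0)
        with pytest.raises(ValueError):
            sample_network(5, 2, coeff_range=(0.0, 1.0), seed=0)


class TestSimulateDataset:
    def test_zero_noise_replicates_identical(self):
        gt = sample_network(6, 2, seed=2, process_sd=0.0, measurement_sd=0.0)
        ds = simulate_dataset(gt, C=4, T=3, R=3, seed=3)
        assert np.all(ds.values[..., 0:1] == ds.values)

    def test_shift_mode_preserves_dynamics(self):
        """Per-gene shifting changes only the intercept of the transition law."""
        gt = sample_network(5, 2, seed=4, process_sd=0.0, measurement_sd=0.0)
        ds = simulate_dataset(gt, C=6, T=3, R=1, seed=5, nonneg="shift")
        m = ds.means()
        assert m.min() >= 0.0
        A = gt.coefficient_matrix
        # x(t+1) - A x(t) must be constant across conditions and times
        resid = m[:, :, 1] - A @ m[:, :, 0]
        resid2 = m[:, :, 2] - A @ m[:, :, 1]
        np.testing.assert_allclose(resid, resid2, atol=1e-9)
        np.testing.assert_allclose(
            resid, resid[:, :1].repeat(resid.shape[1], axis=1), atol=1e-9
        )

    def test_signed_mode_marks_dataset(self):
        gt = sample_network(5, 2, seed=6)
        ds = simulate_dataset(gt, C=3, T=2, R=2, seed=7, nonneg="none")
        assert ds.signed

    def test_study_shape_round_trips(self, tmp_path):
        from causnet.dataset import load_expression, write_expression

        gt = sample_network(74, 3, seed=8)
        ds = simulate_dataset(gt, C=18, T=3, R=3, seed=9)
        assert ds.shape == (74, 18, 3, 3)
        path = tmp_path / "study.tsv"
        write_expression(ds, path)
        back = load_expression(path)
        np.testing.assert_array_equal(back.values, ds.values)

    def test_trajectories_stay_bounded(self):
        gt = sample_network(8, 2, seed=10, process_sd=0.05)
        rng = np.random.default_rng(11)
        x = gt.fixed_point() + rng.normal(0, 1, size=8)
        for _ in range(1000):
            x = gt.coefficient_matrix @ x + gt.intercepts + rng.normal(0, 0.05, size=8)
        assert np.all(np.abs(x) < 1e3)


def weighted_from_scores(gene_ids, scored_edges):
    """Build a WeightedNetwork whose existence weights equal given scores."""
    denom = 100
    runs = []
    for b in range(denom):
        edges = {
            (r, t, s)
            for r, t, s, w in scored_edges
            if b < round(w * denom)
        }
        runs.append(
            SingleRunNetwork(gene_ids=tuple(gene_ids), edges=frozenset(edges), provenance=str(b))
        )
    return aggregate(runs)


class TestEvaluateRecovery:
    def test_perfect_prediction(self):
        gt = sample_network(6, 2, seed=12)
        scored = [(r, t, s, 1.0) for r, t, s in gt.true_edges()]
        net = weighted_from_scores(gt.gene_ids, scored)
        m = evaluate_recovery(gt, net, threshold=0.5)
        assert (m.precision, m.recall, m.f1, m.sign_accuracy) == (1.0, 1.0, 1.0, 1.0)
        assert m.aupr == pytest.approx(1.0)

    def test_empty_prediction_has_null_precision(self):
        gt = sample_network(6, 2, seed=13)
        net = weighted_from_scores(gt.gene_ids, [])
        m = evaluate_recovery(gt, net, threshold=0.5)
        assert m.precision is None
        assert m.recall == 0.0
        assert m.f1 is None
        assert m.sign_accuracy is None

    def test_wrong_signs_hit_sign_accuracy_only(self):
        gt = sample_network(6, 2, seed=14)
        flip = {"activation": "repression", "repression": "activation"}
        scored = [(r, t, flip[s], 1.0) for r, t, s in gt.true_edges()]
        m = evaluate_recovery(gt, weighted_from_scores(gt.gene_ids, scored), 0.5)
        assert m.precision == 1.0 and m.recall == 1.0
        assert m.sign_accuracy == 0.0

    def test_random_prediction_precision_matches_edge_density(self):
        """E[precision] of uniformly random edges = true-edge density."""
        G, k_true, E = 10, 2, 15
        gt = sample_network(G, k_true, seed=15)
        density = (G * k_true) / (G * (G - 1))
        rng = np.random.default_rng(16)
        pairs = [(i, j) for i in range(G) for j in range(G) if i != j]
        precisions = []
        for _ in range(300):
            chosen = rng.choice(len(pairs), size=E, replace=False)
            scored = [
                (gt.gene_ids[pairs[c][0]], gt.gene_ids[pairs[c][1]], "activation", 1.0)
                for c in chosen
            ]
            m = evaluate_recovery(gt, weighted_from_scores(gt.gene_ids, scored), 0.5)
            precisions.append(m.precision)
        se = np.std(precisions) / np.sqrt(len(precisions))
        assert abs(np.mean(precisions) - density) < 4 * se + 1e-12

    def test_aupr_matches_sklearn_average_precision(self):
        from sklearn.metrics import average_precision_score

        gt = sample_network(8, 2, seed=17)
        truth = {(r, t) for r, t, _ in gt.true_edges()}
        rng = np.random.default_rng(18)
        pairs = [
            (a, b) for a in gt.gene_ids for b in gt.gene_ids if a != b
        ]
        scored = [
            (r, t, "activation", round(rng.uniform(0.01, 1.0), 2)) for r, t in pairs
        ]
        net = weighted_from_scores(gt.gene_ids, scored)
        m = evaluate_recovery(gt, net, 0.5)
        weight_of = {(e.regulator, e.target): e.existence_weight for e in net.edges}
        y_true = [int(p in truth) for p in pairs]
        y_score = [weight_of.get(p, 0.0) for p in pairs]
        # sklearn scores all pairs; restrict to pairs present in the network
        present = [i for i, p in enumerate(pairs) if p in weight_of]
        ap = average_precision_score(
            [y_true[i] for i in present], [y_score[i] for i in present]
        )
        assert m.aupr == pytest.approx(ap, abs=1e-9)

    def test_universe_mismatch_rejected(self):
        gt = sample_network(6, 2, seed=19)
        other = weighted_from_scores(("x", "y"), [("x", "y", "activation", 1.0)])
        with pytest.raises(ValueError, match="universe"):
            evaluate_recovery(gt, other, 0.5)


def test_truth_edges_round_trip(tmp_path):
    gt = sample_network(7, 2, seed=20)
    path = tmp_path / "truth.tsv"
    write_truth_edges(gt, path)
    assert load_truth_edges(path) == gt.true_edges()
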