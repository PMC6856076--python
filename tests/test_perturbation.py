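"""Stage III: truncated-Gaussian perturbation, aggregation, thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from causnet.dataset import ReplicateStats, summarize_replicates
from causnet.perturbation import (
    SingleRunNetwork,
    aggregate,
    perturb_dataset,
    run_perturbation_analysis,
    threshold_network,
)
from conftest import make_dataset


def truncated_moments(mu, sigma):
    """Closed-form mean/variance of N(mu, sigma^2) truncated below at 0."""
    alpha = -mu / sigma
    z = 1.0 - sps.norm.cdf(alpha)
    lam = sps.norm.pdf(alpha) / z
    mean = mu + sigma * lam
    var = sigma**2 * (1.0 + alpha * lam - lam**2)
    return mean, var


def stats_cell(mean, var, n=3, signed=False):
    shape = (1, 1, 2)
    return ReplicateStats(
        mean=np.full(shape, float(mean)),
        sample_variance=np.full(shape, float(var)),
        n=n,
        signed=signed,
    )


def run_net(gene_ids, edges, provenance="p"):
    return SingleRunNetwork(
        gene_ids=tuple(gene_ids), edges=frozenset(edges), provenance=provenance
    )


class TestPerturbDataset:
    def test_zero_variance_reproduces_mean_exactly(self):
        grid = perturb_dataset(stats_cell(5.0, 0.0), np.random.default_rng(0))
        assert np.all(grid == 5.0)

    def test_truncation_keeps_draws_nonnegative(self):
        grid_draws = [
            perturb_dataset(stats_cell(0.0, 4.0), np.random.default_rng(s))
            for s in range(50)
        ]
        assert np.min(grid_draws) >= 0.0

    def test_signed_mode_skips_truncation(self):
        draws = np.array(
            [
                perturb_dataset(stats_cell(0.0, 4.0, signed=True), np.random.default_rng(s))
                for s in range(50)
            ]
        )
        assert draws.min() < 0.0

    @pytest.mark.parametrize("mu, s2", [(1.0, 0.9), (0.0, 1.0), (3.0, 0.3)])
    def test_moments_match_truncated_normal_closed_form(self, mu, s2):
        n_draws, n = 10_000, 3
        rng = np.random.default_rng(123)
        st_ = stats_cell(mu, s2, n=n)
        draws = np.array(
            [perturb_dataset(st_, rng)[0, 0, 0] for _ in range(n_draws)]
        )
        sigma = np.sqrt(s2 / n)  # default sem mode
        m, v = truncated_moments(mu, sigma)
        se_mean = np.sqrt(v / n_draws)
        assert abs(draws.mean() - m) < 3 * se_mean
        # SE of the sample variance ~ sqrt(2/n) * var for near-Gaussian draws
        assert abs(draws.var(ddof=1) - v) < 3 * v * np.sqrt(2.0 / n_draws) + 3 * se_mean**2

    def test_variance_modes_scale_correctly(self):
        # sem draws should be ~sqrt(n) tighter than sample draws
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(1)
        st_ = stats_cell(10.0, 0.9, n=3)
        sem = [perturb_dataset(st_, rng1, "sem")[0, 0, 0] for _ in range(4000)]
        samp = [perturb_dataset(st_, rng2, "sample")[0, 0, 0] for _ in range(4000)]
        assert np.std(samp) / np.std(sem) == pytest.approx(np.sqrt(3), rel=0.1)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            perturb_dataset(stats_cell(1.0, 0.0, n=1), np.random.default_rng(0))


class TestAggregate:
    def test_existence_and_sign_weights(self):
        genes = ("a", "b")
        runs = [run_net(genes, {("a", "b", "activation")}) for _ in range(20)]
        runs += [run_net(genes, set()) for _ in range(80)]
        net = aggregate(runs)
        (edge,) = net.edges
        assert edge.existence_weight == pytest.approx(0.20)
        assert edge.consensus_sign == "activation"
        assert edge.sign_weight == 1.0
        assert edge.n_occurrences == 20

    def test_sign_tie_is_ambiguous(self):
        genes = ("a", "b")
        runs = [run_net(genes, {("a", "b", "activation")}) for _ in range(50)]
        runs += [run_net(genes, {("a", "b", "repression")}) for _ in range(50)]
        net = aggregate(runs)
        (edge,) = net.edges
        assert edge.existence_weight == 1.0
        assert edge.consensus_sign == "ambiguous"
        assert edge.sign_weight == 0.5

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        genes = tuple("abcd")
        runs = []
        for i in range(30):
            edges = set()
            for r in genes:
                for t in genes:
                    if r != t and rng.random() < 0.3:
                        edges.add((r, t, "activation" if rng.random() < 0.5 else "repression"))
            runs.append(run_net(genes, edges, provenance=f"p{i}"))
        forward = aggregate(runs)
        backward = aggregate(runs[::-1])
        assert forward == backward

    @given(st.integers(1, 6), st.integers(0, 5))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_weight_invariants(self, n_present, n_absent):
        genes = ("x", "y")
        runs = [run_net(genes, {("x", "y", "activation")}) for _ in range(n_present)]
        runs += [run_net(genes, set()) for _ in range(n_absent)]
        net = aggregate(runs)
        for e in net.edges:
            assert e.existence_weight == e.n_occurrences / net.n_perturbations
            assert 0 < e.existence_weight <= 1
            assert e.sign_weight >= 0.5

    def test_mixed_universes_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            aggregate([run_net(("a", "b"), set()), run_net(("a", "c"), set())])

    def test_conflicting_signs_in_one_run_rejected(self):
        with pytest.raises(ValueError):
            run_net(("a", "b"), {("a", "b", "activation"), ("a", "b", "repression")})

    def test_self_edges_rejected(self):
        with pytest.raises(ValueError, match="self-edge"):
            run_net(("a", "b"), {("a", "a", "activation")})


class TestThreshold:
    def _net(self):
        genes = ("a", "b", "c")
        runs = [run_net(genes, {("a", "b", "activation"), ("b", "c", "repression")})]
        runs += [run_net(genes, {("a", "b", "activation")}) for _ in range(3)]
        return aggregate(runs)

    def test_zero_threshold_is_identity(self):
        net = self._net()
        assert threshold_network(net, 0.0).edges == net.edges

    def test_above_one_empties(self):
        assert threshold_network(self._net(), 1.01).edges == ()

    def test_study_cutoffs_nest(self):
        net = self._net()
        sets = [
            {(e.regulator, e.target) for e in threshold_network(net, w).edges}
            for w in (0.1, 0.2, 0.6)
        ]
        assert sets[2] <= sets[1] <= sets[0]
        assert threshold_network(net, 0.6).weight_threshold == 0.6


class TestRunPerturbationAnalysis:
    def _noisy_stats(self, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.5, 2.0, size=(4, 8, 3, 1))
        values = base + rng.normal(0, 0.05, size=(4, 8, 3, 3))
        return summarize_replicates(make_dataset(np.abs(values)))

    def test_fixed_seed_is_bit_identical(self):
        stats = self._noisy_stats()
        kwargs = dict(
            gene_ids=[f"g{i}" for i in range(4)],
            condition_ids=[f"c{i}" for i in range(8)],
            time_labels=["T1", "T2", "T3"],
            n_perturbations=10,
            k=2,
            virtual_shift=False,
        )
        a = run_perturbation_analysis(stats, seed=77, **kwargs)
        b = run_perturbation_analysis(stats, seed=77, **kwargs)
        assert a == b
        c = run_perturbation_analysis(stats, seed=78, **kwargs)
        assert a != c  # different master seed perturbs differently

    def test_zero_variance_forces_binary_weights(self):
        values = np.repeat(
            np.random.default_rng(3).uniform(0.5, 2.0, size=(4, 8, 3, 1)), 3, axis=3
        )
        stats = summarize_replicates(make_dataset(values))
        net = run_perturbation_analysis(
            stats,
            [f"g{i}" for i in range(4)],
            [f"c{i}" for i in range(8)],
            ["T1", "T2", "T3"],
            n_perturbations=5,
            seed=1,
            k=2,
            virtual_shift=False,
        )
        for e in net.edges:
            assert e.existence_weight == 1.0
            assert e.sign_weight == 1.0
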