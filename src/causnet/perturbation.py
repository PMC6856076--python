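"""Stage III: perturbation analysis and confidence-weight aggregation.

A perturbation replaces each (gene, condition, time) cell by one draw from
a Gaussian centered at the cell's replicate mean, truncated below at zero
(expression is nonnegative), with variance taken from the replicate sample
variance.  The default variance is the squared standard error s^2/n: the
cell value entering the regression is a *mean*, and s^2/n is the variance
choice under which the scheme matches bootstrapping the replicate mean with
resampling size 2 (for n = 3 replicates, the size-2 bootstrap mean has
variance sum((x_i - xbar)^2)/6 = s^2/3).  Modes ``sample`` (s^2) and
``population`` ((n-1)/n * s^2) are selectable.

Stages I-II run on each perturbed dataset; the B resulting edge sets are
combined into a single weighted network where an edge's *existence weight*
is the fraction of runs containing it and its *sign weight* the fraction of
those runs agreeing with the majority sign.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from causnet.dataset import ReplicateStats, TransitionSet, build_transitions
from causnet.granger import DEFAULT_ALPHA, GrangerResult, prune_fit
from causnet.regression import GramCache, SparseFit, best_subset_fit, classify_sign

__all__ = [
    "SingleRunNetwork",
    "WeightedEdge",
    "WeightedNetwork",
    "perturb_dataset",
    "infer_single_run",
    "aggregate",
    "threshold_network",
    "run_perturbation_analysis",
]

VarianceMode = Literal["sem", "sample", "population"]


@dataclass(frozen=True)
class SingleRunNetwork:
    """Signed directed edges from one Stage I+II pass over one dataset."""

    gene_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str, str]]  # (regulator, target, sign)
    provenance: str = "point-estimate"

    def __post_init__(self) -> None:
        pairs = [(r, t) for r, t, _ in self.edges]
        if len(set(pairs)) != len(pairs):
            raise ValueError("multiple signs for one ordered (regulator, target) pair")
        if any(r == t for r, t in pairs):
            raise ValueError("self-edges are not allowed")


@dataclass(frozen=True)
class WeightedEdge:
    regulator: str
    target: str
    existence_weight: float  # fraction of perturbation runs containing the edge
    consensus_sign: str  # activation | repression | ambiguous
    sign_weight: float  # majority-sign fraction among occurrences, >= 0.5
    n_occurrences: int


@dataclass(frozen=True)
class WeightedNetwork:
    """Perturbation-aggregated network with per-edge confidence weights."""

    gene_ids: tuple[str, ...]
    edges: tuple[WeightedEdge, ...]
    n_perturbations: int
    weight_threshold: float = 0.0

    def edge(self, regulator: str, target: str) -> WeightedEdge | None:
        for e in self.edges:
            if e.regulator == regulator and e.target == target:
                return e
        return None


def perturb_dataset(
    stats_: ReplicateStats,
    rng: np.random.Generator,
    variance_mode: VarianceMode = "sem",
) -> np.ndarray:
    """Draw one truncated-Gaussian value per cell; returns a ``(G, C, T)`` grid.

    Zero-variance cells reproduce their means exactly.  Truncation at zero
    is skipped for datasets loaded in signed mode.
    """
    if stats_.n < 2:
        raise ValueError(
            "perturbation needs >= 2 replicates per cell to estimate a variance"
        )
    if variance_mode == "sem":
        var = stats_.sample_variance / stats_.n
    elif variance_mode == "sample":
        var = stats_.sample_variance
    elif variance_mode == "population":
        var = stats_.sample_variance * (stats_.n - 1) / stats_.n
    else:
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    sd = np.sqrt(var)
    out = stats_.mean.copy()
    positive = sd > 0
    if not positive.any():
        return out
    mu = stats_.mean[positive]
    sigma = sd[positive]
    if stats_.signed:
        out[positive] = rng.normal(mu, sigma)
    else:
        a = (0.0 - mu) / sigma  # lower bound at zero, open above
        out[positive] = stats.truncnorm.rvs(
            a, np.inf, loc=mu, scale=sigma, random_state=rng
        )
    return out


def infer_single_run(
    means: np.ndarray,
    gene_ids: Sequence[str],
    condition_ids: Sequence[str],
    time_labels: Sequence[str],
    k: int = 3,
    alpha: float = DEFAULT_ALPHA,
    virtual_shift: bool = True,
    intercept: bool = True,
    granger_literal: bool = False,
    standardize: bool = False,
    method: str = "exhaustive",
    provenance: str = "point-estimate",
    collect_diagnostics: bool = False,
) -> tuple[
    SingleRunNetwork, list[SparseFit], list[GrangerResult]
]:
    """Run Stages I+II on one mean grid and emit the signed edge set.

    Returns the network plus (when ``collect_diagnostics``) the pruned fits
    and all Granger test results.
    """
    transitions = build_transitions(
        means, gene_ids, condition_ids, time_labels, virtual_shift=virtual_shift
    )
    gram = GramCache(transitions, standardize=standardize)
    edges: set[tuple[str, str, str]] = set()
    fits: list[SparseFit] = []
    granger_results: list[GrangerResult] = []
    for target in transitions.gene_ids:
        fit = best_subset_fit(
            target, transitions, k, intercept=intercept, gram=gram, method=method  # type: ignore[arg-type]
        )
        pruned, results = prune_fit(
            fit,
            transitions,
            alpha=alpha,
            intercept=intercept,
            literal=granger_literal,
            gram=gram,
        )
        for reg, coef in zip(pruned.regulators, pruned.coefficients):
            sign = classify_sign(coef)
            if sign is not None:
                edges.add((reg, target, sign))
        if collect_diagnostics:
            fits.append(pruned)
            granger_results.extend(results)
    net = SingleRunNetwork(
        gene_ids=tuple(gene_ids), edges=frozenset(edges), provenance=provenance
    )
    return net, fits, granger_results


def aggregate(runs: Sequence[SingleRunNetwork]) -> WeightedNetwork:
    """Combine per-perturbation edge sets into existence and sign weights.

    existence_weight = occurrences / n_runs; consensus_sign is the majority
    sign among occurrences ("ambiguous" on an exact tie) and sign_weight the
    majority fraction (0.5 on a tie).  Edge order is deterministic:
    regulator then target in canonical gene order.
    """
    if not runs:
        raise ValueError("no runs to aggregate")
    universe = runs[0].gene_ids
    if any(r.gene_ids != universe for r in runs[1:]):
        raise ValueError("runs cover different gene universes")
    counts: Counter[tuple[str, str, str]] = Counter()
    for run in runs:
        counts.update(run.edges)
    pair_counts: dict[tuple[str, str], dict[str, int]] = {}
    for (reg, tgt, sign), n in counts.items():
        pair_counts.setdefault((reg, tgt), {})[sign] = n
    order = {g: i for i, g in enumerate(universe)}
    edges = []
    for (reg, tgt), by_sign in sorted(
        pair_counts.items(), key=lambda kv: (order[kv[0][0]], order[kv[0][1]])
    ):
        n_occ = sum(by_sign.values())
        n_act = by_sign.get("activation", 0)
        n_rep = by_sign.get("repression", 0)
        if n_act > n_rep:
            consensus, majority = "activation", n_act
        elif n_rep > n_act:
            consensus, majority = "repression", n_rep
        else:
            consensus, majority = "ambiguous", n_act
        edges.append(
            WeightedEdge(
                regulator=reg,
                target=tgt,
                existence_weight=n_occ / len(runs),
                consensus_sign=consensus,
                sign_weight=majority / n_occ,
                n_occurrences=n_occ,
            )
        )
    return WeightedNetwork(
        gene_ids=universe, edges=tuple(edges), n_perturbations=len(runs)
    )


def threshold_network(net: WeightedNetwork, min_weight: float) -> WeightedNetwork:
    """Keep edges with existence weight >= ``min_weight`` (recorded on the result)."""
    if min_weight < 0:
        raise ValueError("min_weight must be >= 0")
    kept = tuple(e for e in net.edges if e.existence_weight >= min_weight)
    return replace(net, edges=kept, weight_threshold=min_weight)


def run_perturbation_analysis(
    stats_: ReplicateStats,
    gene_ids: Sequence[str],
    condition_ids: Sequence[str],
    time_labels: Sequence[str],
    n_perturbations: int = 100,
    seed: int | np.random.SeedSequence = 0,
    k: int = 3,
    alpha: float = DEFAULT_ALPHA,
    virtual_shift: bool = True,
    intercept: bool = True,
    granger_literal: bool = False,
    variance_mode: VarianceMode = "sem",
    standardize: bool = False,
    method: str = "exhaustive",
    progress: "callable | None" = None,
) -> WeightedNetwork:
    """Full Stage III: B perturbed datasets -> B networks -> one weighted network.

    Each perturbation draws from an independent substream spawned
    deterministically from the master seed, so results are bit-identical
    for a fixed seed and invariant to evaluation order.
    """
    if n_perturbations < 1:
        raise ValueError("need at least one perturbation")
    master = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    runs = []
    for b, child in enumerate(master.spawn(n_perturbations)):
        rng = np.random.default_rng(child)
        grid = perturb_dataset(stats_, rng, variance_mode=variance_mode)
        net, _, _ = infer_single_run(
            grid,
            gene_ids,
            condition_ids,
            time_labels,
            k=k,
            alpha=alpha,
            virtual_shift=virtual_shift,
            intercept=intercept,
            granger_literal=granger_literal,
            standardize=standardize,
            method=method,
            provenance=f"perturbation-{b}",
        )
        runs.append(net)
        if progress is not None:
            progress(b + 1, n_perturbations)
    return aggregate(runs)
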