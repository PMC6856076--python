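"""Ground-truth network sampling, linear-Gaussian data simulation, recovery scoring.

The generative model matches the inference model: a discrete-time linear
system over G genes,

    x(t+1) = A x(t) + b + eta_t,     eta_t ~ N(0, process_sd^2 I),

where off-diagonal entries of A are the true signed regulatory
coefficients (exactly ``k_true`` per row), the diagonal holds a
self-persistence term in (0, 1), and b is a basal production vector.  Each
biological replicate observes the latent trajectory plus independent
N(0, measurement_sd^2) noise.  Conditions differ by their initial state,
drawn around the system's fixed point (I - A)^{-1} b -- the analogue of
genotype/photoperiod contrasts that give the regression cross-condition
leverage.

A is rescaled to spectral radius <= 0.95 so trajectories stay bounded;
feedback loops and cycles are permitted (never forced acyclic).  An
effect-size floor keeps true edges statistically visible with only a
handful of time points.

By default the simulation runs on an unconstrained (log-like normalized)
scale and each gene is then shifted by a constant to make every value
positive -- a transformation that preserves the linear dynamics and the
coefficient matrix exactly (only the intercepts absorb the shift).  Hard
clipping at zero is available but breaks linearity and is off by default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from causnet.dataset import ExpressionDataset
from causnet.perturbation import WeightedNetwork

__all__ = [
    "GroundTruthNetwork",
    "RecoveryMetrics",
    "sample_network",
    "simulate_dataset",
    "evaluate_recovery",
    "write_truth_edges",
    "load_truth_edges",
]


@dataclass(frozen=True)
class GroundTruthNetwork:
    """Signed coefficient matrix + intercepts + noise scales of a simulated system.

    ``coefficient_matrix[i, j]`` is the effect of gene j at time t on gene i
    at time t+1 (row = target, column = regulator); off-diagonal nonzeros
    are the true edges.
    """

    gene_ids: tuple[str, ...]
    coefficient_matrix: np.ndarray  # (G, G)
    intercepts: np.ndarray  # (G,)
    process_sd: float
    measurement_sd: float

    def __post_init__(self) -> None:
        A = np.asarray(self.coefficient_matrix, dtype=float)
        object.__setattr__(self, "coefficient_matrix", A)
        object.__setattr__(self, "intercepts", np.asarray(self.intercepts, dtype=float))
        G = len(self.gene_ids)
        if A.shape != (G, G):
            raise ValueError("coefficient matrix shape does not match gene count")
        if self.process_sd < 0 or self.measurement_sd < 0:
            raise ValueError("noise scales must be nonnegative")

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.coefficient_matrix))))

    def true_edges(self) -> set[tuple[str, str, str]]:
        """Off-diagonal nonzeros as (regulator, target, sign) triples."""
        edges = set()
        G = len(self.gene_ids)
        for i, j in itertools.product(range(G), repeat=2):
            if i == j:
                continue
            coef = self.coefficient_matrix[i, j]
            if coef != 0:
                sign = "activation" if coef > 0 else "repression"
                edges.add((self.gene_ids[j], self.gene_ids[i], sign))
        return edges

    def fixed_point(self) -> np.ndarray:
        G = len(self.gene_ids)
        return np.linalg.solve(np.eye(G) - self.coefficient_matrix, self.intercepts)


@dataclass(frozen=True)
class RecoveryMetrics:
    """Agreement of a thresholded inferred network with the ground truth.

    ``precision``/``f1``/``sign_accuracy`` are ``None`` (a distinguished
    null, never silently 0 or 1) when their denominator is empty: no
    predicted edges, or no true positives.
    """

    precision: float | None
    recall: float
    f1: float | None
    sign_accuracy: float | None
    aupr: float
    n_predicted: int
    n_true: int
    threshold: float


def sample_network(
    G: int,
    k_true: int,
    coeff_range: tuple[float, float] = (0.5, 1.0),
    sign_prob: float = 0.5,
    seed: int | np.random.Generator = 0,
    self_persistence: tuple[float, float] = (0.1, 0.5),
    spectral_target: float = 0.95,
    min_effect: float = 0.3,
    process_sd: float = 0.1,
    measurement_sd: float = 0.1,
    intercept_scale: float = 1.0,
) -> GroundTruthNetwork:
    """Draw a random sparse signed ground-truth network.

    Each row (target) receives exactly ``k_true`` distinct off-diagonal
    regulators chosen uniformly; coefficient magnitudes are uniform in
    ``coeff_range`` with negative sign at probability ``sign_prob``; the
    diagonal self-persistence is uniform in ``self_persistence``.  If the
    spectral radius exceeds ``spectral_target`` the whole matrix is scaled
    down to it; draws whose scaled off-diagonal magnitudes fall below
    ``min_effect`` are rejected and redrawn so every true edge stays
    statistically visible.
    """
    if not 1 <= k_true < G:
        raise ValueError("need 1 <= k_true < G")
    low, high = coeff_range
    if not 0 < low <= high:
        raise ValueError("coeff_range must satisfy 0 < low <= high")
    if not 0.0 <= sign_prob <= 1.0:
        raise ValueError("sign_prob must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    for _ in range(200):
        A = np.zeros((G, G))
        for i in range(G):
            others = [j for j in range(G) if j != i]
            regs = rng.choice(others, size=k_true, replace=False)
            mags = rng.uniform(low, high, size=k_true)
            signs = np.where(rng.random(k_true) < sign_prob, -1.0, 1.0)
            A[i, regs] = mags * signs
            A[i, i] = rng.uniform(*self_persistence)
        rho = float(np.max(np.abs(np.linalg.eigvals(A))))
        if rho > spectral_target:
            A *= spectral_target / rho
        off = A[~np.eye(G, dtype=bool)]
        if np.abs(off[off != 0]).min() >= min_effect:
            break
    else:
        raise RuntimeError(
            "could not sample a network meeting the effect-size floor; "
            "raise coeff_range or lower min_effect"
        )
    b = rng.uniform(0.5, 1.5, size=G) * intercept_scale
    gene_ids = tuple(f"G{i + 1:03d}" for i in range(G))
    return GroundTruthNetwork(
        gene_ids=gene_ids,
        coefficient_matrix=A,
        intercepts=b,
        process_sd=process_sd,
        measurement_sd=measurement_sd,
    )


def simulate_dataset(
    gt: GroundTruthNetwork,
    C: int,
    T: int,
    R: int,
    seed: int | np.random.Generator = 0,
    init_sd: float = 1.0,
    nonneg: Literal["shift", "clip", "none"] = "shift",
    shift_margin: float = 0.01,
) -> ExpressionDataset:
    """Simulate a replicated multi-condition time course from the model.

    Per condition, the initial state is N(fixed point, init_sd^2); the
    latent trajectory follows x(t+1) = A x(t) + b + process noise; each
    replicate adds independent measurement noise.  ``nonneg='shift'``
    (default) adds a per-gene constant making all observed values
    >= ``shift_margin`` while preserving the dynamics; ``'clip'`` hard-clips
    at zero (breaks linearity); ``'none'`` returns a signed dataset.
    """
    if T < 2:
        raise ValueError("need at least 2 time points")
    if C < 1 or R < 1:
        raise ValueError("need C >= 1 conditions and R >= 1 replicates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    G = len(gt.gene_ids)
    A, b = gt.coefficient_matrix, gt.intercepts
    xstar = gt.fixed_point()

    latent = np.empty((G, C, T))
    for c in range(C):
        x = xstar + rng.normal(0.0, init_sd, size=G)
        latent[:, c, 0] = x
        for t in range(1, T):
            x = A @ x + b + rng.normal(0.0, gt.process_sd, size=G)
            latent[:, c, t] = x

    obs = latent[..., None] + rng.normal(0.0, gt.measurement_sd, size=(G, C, T, R))

    signed = False
    if nonneg == "shift":
        low = obs.min(axis=(1, 2, 3))
        shift = np.maximum(0.0, shift_margin - low)
        obs = obs + shift[:, None, None, None]
    elif nonneg == "clip":
        obs = np.clip(obs, 0.0, None)
    elif nonneg == "none":
        signed = True
    else:
        raise ValueError(f"unknown nonneg mode {nonneg!r}")

    return ExpressionDataset(
        gene_ids=gt.gene_ids,
        condition_ids=tuple(f"C{c + 1:02d}" for c in range(C)),
        time_labels=tuple(f"T{t + 1}" for t in range(T)),
        values=obs,
        signed=signed,
    )


def _pr_curve(
    truth: set[tuple[str, str]], net: WeightedNetwork
) -> tuple[np.ndarray, np.ndarray]:
    """Precision and recall at each observed existence-weight threshold (descending)."""
    weights = sorted({e.existence_weight for e in net.edges}, reverse=True)
    precisions, recalls = [], []
    for w in weights:
        pred = {(e.regulator, e.target) for e in net.edges if e.existence_weight >= w}
        tp = len(pred & truth)
        precisions.append(tp / len(pred))
        recalls.append(tp / len(truth) if truth else 0.0)
    return np.array(precisions), np.array(recalls)


def _aupr(truth: set[tuple[str, str]], net: WeightedNetwork) -> float:
    """Area under precision-recall, swept over existence weights.

    Step-wise summation sum_i (R_i - R_{i-1}) * P_i over thresholds in
    decreasing order (the average-precision convention).
    """
    if not truth or not net.edges:
        return 0.0
    P, R = _pr_curve(truth, net)
    prev = np.concatenate([[0.0], R[:-1]])
    return float(np.sum((R - prev) * P))


def evaluate_recovery(
    gt: GroundTruthNetwork, net: WeightedNetwork, threshold: float = 0.5
) -> RecoveryMetrics:
    """Score an inferred weighted network against the simulated ground truth.

    True edges are the off-diagonal nonzeros of the coefficient matrix;
    predicted edges are those at existence weight >= ``threshold``.  AUPR
    sweeps all observed weights regardless of ``threshold``.
    """
    if set(net.gene_ids) != set(gt.gene_ids):
        raise ValueError("gene universes differ between truth and network")
    true_signed = gt.true_edges()
    truth = {(r, t) for r, t, _ in true_signed}
    true_sign = {(r, t): s for r, t, s in true_signed}
    pred_edges = [e for e in net.edges if e.existence_weight >= threshold]
    pred = {(e.regulator, e.target) for e in pred_edges}
    tp_pairs = pred & truth
    tp = len(tp_pairs)

    precision = tp / len(pred) if pred else None
    recall = tp / len(truth) if truth else 0.0
    if precision is None or precision + recall == 0:
        f1 = None if precision is None else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    if tp:
        correct = sum(
            1
            for e in pred_edges
            if (e.regulator, e.target) in tp_pairs
            and e.consensus_sign == true_sign[(e.regulator, e.target)]
        )
        sign_accuracy = correct / tp
    else:
        sign_accuracy = None
    return RecoveryMetrics(
        precision=precision,
        recall=recall,
        f1=f1,
        sign_accuracy=sign_accuracy,
        aupr=_aupr(truth, net),
        n_predicted=len(pred),
        n_true=len(truth),
        threshold=threshold,
    )


def write_truth_edges(gt: GroundTruthNetwork, path: str | Path) -> None:
    """Ground-truth edge list TSV: regulator, target, coefficient."""
    rows = []
    G = len(gt.gene_ids)
    for i in range(G):
        for j in range(G):
            if i != j and gt.coefficient_matrix[i, j] != 0:
                rows.append(
                    (gt.gene_ids[j], gt.gene_ids[i], gt.coefficient_matrix[i, j])
                )
    pd.DataFrame(rows, columns=["regulator", "target", "coefficient"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def load_truth_edges(path: str | Path) -> set[tuple[str, str, str]]:
    """Read a truth edge TSV back as (regulator, target, sign) triples."""
    df = pd.read_csv(path, sep="\t", dtype={"regulator": str, "target": str})
    return {
        (row.regulator, row.target, "activation" if row.coefficient > 0 else "repression")
        for row in df.itertuples(index=False)
        if row.coefficient != 0
    }
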