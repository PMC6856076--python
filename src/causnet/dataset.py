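"""Expression-data containers, TSV ingestion, replicate summaries, lagged transitions.

The central container is :class:`ExpressionDataset`, a complete
genes x conditions x times x replicates tensor of normalized expression
values.  "Complete" is enforced: every (gene, condition, time) cell must
hold exactly ``n_replicates`` finite values, because the perturbation stage
needs a replicate variance for every cell and the regression stage needs a
mean for every cell.

Lagged observation pairs are assembled by :func:`build_transitions`.  For a
time grid t_1 < ... < t_T each condition contributes the T-1 consecutive
pairs (t_i -> t_{i+1}); with the *virtual time shift* enabled, the wrapped
pair (t_T -> t_1) is added per condition, treating the first sample of the
day as a stand-in for the sample that would follow the last one -- this is
how regulatory interactions acting overnight enter the regression when the
design only samples within a single day.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "ReplicateStats",
    "TransitionSet",
    "load_expression",
    "write_expression",
    "summarize_replicates",
    "build_transitions",
]

LONG_COLUMNS = ("gene", "condition", "time", "replicate", "value")


class DataValidationError(ValueError):
    """Input data violates a structural or value constraint."""


@dataclass(frozen=True)
class ExpressionDataset:
    """Replicated multi-condition expression time course.

    Parameters
    ----------
    gene_ids, condition_ids, time_labels
        Ordered unique labels for the three outer axes.
    values
        Array of shape ``(G, C, T, R)``; finite, and nonnegative unless
        ``signed`` is set (signed mode admits pre-centered data and
        disables truncation at zero downstream).
    signed
        Allow negative expression values.
    """

    gene_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    time_labels: tuple[str, ...]
    values: np.ndarray
    signed: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(
            self, "condition_ids", tuple(str(c) for c in self.condition_ids)
        )
        object.__setattr__(
            self, "time_labels", tuple(str(t) for t in self.time_labels)
        )
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 4:
            raise DataValidationError(
                f"values must be 4-d (gene, condition, time, replicate); got {values.ndim}-d"
            )
        expected = (len(self.gene_ids), len(self.condition_ids), len(self.time_labels))
        if values.shape[:3] != expected:
            raise DataValidationError(
                f"values shape {values.shape[:3]} does not match labels {expected}"
            )
        if values.shape[3] < 1:
            raise DataValidationError("at least one replicate required")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataValidationError("duplicate gene ids")
        if len(set(self.condition_ids)) != len(self.condition_ids):
            raise DataValidationError("duplicate condition ids")
        if len(set(self.time_labels)) != len(self.time_labels):
            raise DataValidationError("duplicate time labels")
        if len(self.time_labels) < 2:
            raise DataValidationError("need at least 2 time points for a lagged model")
        if not np.all(np.isfinite(values)):
            g, c, t, r = np.argwhere(~np.isfinite(values))[0]
            raise DataValidationError(
                "non-finite value at "
                f"(gene={self.gene_ids[g]}, condition={self.condition_ids[c]}, "
                f"time={self.time_labels[t]}, replicate={r + 1})"
            )
        if not self.signed and np.any(values < 0):
            g, c, t, r = np.argwhere(values < 0)[0]
            raise DataValidationError(
                "negative expression value at "
                f"(gene={self.gene_ids[g]}, condition={self.condition_ids[c]}, "
                f"time={self.time_labels[t]}, replicate={r + 1}); "
                "pass signed=True to allow pre-centered data"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    @property
    def n_times(self) -> int:
        return len(self.time_labels)

    @property
    def n_replicates(self) -> int:
        return self.values.shape[3]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def means(self) -> np.ndarray:
        """Per-cell replicate means, shape ``(G, C, T)``."""
        return self.values.mean(axis=3)

    def subset(
        self,
        genes: Sequence[str] | None = None,
        conditions: Sequence[str] | None = None,
    ) -> "ExpressionDataset":
        """Restrict (and reorder) to the given genes and/or conditions."""
        gidx = _label_indices(self.gene_ids, genes, "gene")
        cidx = _label_indices(self.condition_ids, conditions, "condition")
        return replace(
            self,
            gene_ids=tuple(self.gene_ids[i] for i in gidx),
            condition_ids=tuple(self.condition_ids[i] for i in cidx),
            values=self.values[np.ix_(gidx, cidx)],
        )


def _label_indices(
    existing: tuple[str, ...], wanted: Sequence[str] | None, what: str
) -> list[int]:
    if wanted is None:
        return list(range(len(existing)))
    pos = {label: i for i, label in enumerate(existing)}
    missing = [w for w in wanted if w not in pos]
    if missing:
        raise KeyError(f"unknown {what} id(s): {', '.join(map(str, missing))}")
    return [pos[w] for w in wanted]


@dataclass(frozen=True)
class ReplicateStats:
    """Per-cell replicate mean and unbiased sample variance.

    ``mean`` and ``sample_variance`` have shape ``(G, C, T)``; the variance
    uses the n-1 denominator (0 when ``n == 1``, in which case perturbation
    must not be requested).
    """

    mean: np.ndarray
    sample_variance: np.ndarray
    n: int
    signed: bool = False

    def __post_init__(self) -> None:
        if self.mean.shape != self.sample_variance.shape:
            raise ValueError("mean and variance shapes differ")
        if np.any(self.sample_variance < 0):
            raise ValueError("negative sample variance")


def summarize_replicates(ds: ExpressionDataset) -> ReplicateStats:
    """Per-cell mean and unbiased (n-1) sample variance across replicates."""
    n = ds.n_replicates
    mean = ds.values.mean(axis=3)
    if n >= 2:
        var = ds.values.var(axis=3, ddof=1)
        # exactly-equal replicates must give exactly zero variance, so
        # downstream perturbation reproduces their mean deterministically
        var[np.all(ds.values == ds.values[..., :1], axis=3)] = 0.0
    else:
        var = np.zeros_like(mean)
    return ReplicateStats(mean=mean, sample_variance=var, n=n, signed=ds.signed)


@dataclass(frozen=True)
class TransitionSet:
    """Lagged (source -> destination) observation pairs, stacked over conditions.

    ``predictors[i]`` holds all G genes' expression at the source time of
    row i; ``responses[i]`` the same G genes at the destination time.  Both
    rows come from the same condition.  Row count is ``C*(T-1)`` without the
    virtual shift and ``C*T`` with it.
    """

    gene_ids: tuple[str, ...]
    predictors: np.ndarray  # (n_rows, G), source-time expression
    responses: np.ndarray  # (n_rows, G), destination-time expression
    transition_labels: tuple[tuple[str, str, str], ...]  # (condition, src, dst)
    virtual_shift: bool

    def __post_init__(self) -> None:
        if self.predictors.shape != self.responses.shape:
            raise ValueError("predictor/response shape mismatch")
        if self.predictors.shape[0] != len(self.transition_labels):
            raise ValueError("label count does not match row count")
        if self.predictors.shape[1] != len(self.gene_ids):
            raise ValueError("gene count mismatch")

    @property
    def n_obs(self) -> int:
        return self.predictors.shape[0]


def build_transitions(
    means: np.ndarray,
    gene_ids: Sequence[str],
    condition_ids: Sequence[str],
    time_labels: Sequence[str],
    virtual_shift: bool = False,
) -> TransitionSet:
    """Assemble lagged transition rows from a complete ``(G, C, T)`` mean grid.

    Without the virtual shift each condition contributes the T-1 consecutive
    transitions; with it, the wrapped last->first transition of the same
    condition is appended, so the overnight step contributes a lagged pair.
    """
    means = np.asarray(means, dtype=float)
    if means.ndim != 3:
        raise ValueError("means must be (genes, conditions, times)")
    G, C, T = means.shape
    if T < 2:
        raise ValueError("need at least 2 time points to form a transition")
    if G != len(gene_ids) or C != len(condition_ids) or T != len(time_labels):
        raise ValueError("label lengths do not match mean grid")

    src_idx = list(range(T - 1))
    dst_idx = list(range(1, T))
    if virtual_shift:
        src_idx.append(T - 1)
        dst_idx.append(0)

    rows_pred, rows_resp, labels = [], [], []
    for c in range(C):
        for s, d in zip(src_idx, dst_idx):
            rows_pred.append(means[:, c, s])
            rows_resp.append(means[:, c, d])
            labels.append((str(condition_ids[c]), str(time_labels[s]), str(time_labels[d])))
    return TransitionSet(
        gene_ids=tuple(str(g) for g in gene_ids),
        predictors=np.array(rows_pred),
        responses=np.array(rows_resp),
        transition_labels=tuple(labels),
        virtual_shift=virtual_shift,
    )


def load_expression(
    path: str | Path,
    fmt: str = "long_tsv",
    gene_list: str | Path | None = None,
    signed: bool = False,
) -> ExpressionDataset:
    """Read an expression TSV into a validated :class:`ExpressionDataset`.

    ``long_tsv`` expects header columns ``gene, condition, time, replicate,
    value``; axis orders follow first appearance in the file.  ``wide_tsv``
    expects one row per gene (first column ``gene``) and data columns named
    ``condition:time:replicate``.  An optional ``gene_list`` file (one id
    per line) subsets and reorders the genes.
    """
    path = Path(path)
    if fmt == "long_tsv":
        ds = _load_long(path, signed=signed)
    elif fmt == "wide_tsv":
        ds = _load_wide(path, signed=signed)
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'long_tsv' or 'wide_tsv'")
    if gene_list is not None:
        wanted = [
            line.strip()
            for line in Path(gene_list).read_text().splitlines()
            if line.strip()
        ]
        ds = ds.subset(genes=wanted)
    return ds


def _load_long(path: Path, signed: bool) -> ExpressionDataset:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"gene": str, "condition": str, "time": str},
        float_precision="round_trip",
    )
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    genes = list(pd.unique(df["gene"]))
    conditions = list(pd.unique(df["condition"]))
    times = list(pd.unique(df["time"]))
    reps = sorted(pd.unique(df["replicate"]))
    R = len(reps)
    rep_pos = {r: i for i, r in enumerate(reps)}
    gpos = {g: i for i, g in enumerate(genes)}
    cpos = {c: i for i, c in enumerate(conditions)}
    tpos = {t: i for i, t in enumerate(times)}

    values = np.full((len(genes), len(conditions), len(times), R), np.nan)
    for row in df.itertuples(index=False):
        i = (gpos[row.gene], cpos[row.condition], tpos[row.time], rep_pos[row.replicate])
        if not np.isnan(values[i]):
            raise DataValidationError(
                f"{path}: duplicate row for (gene={row.gene}, condition={row.condition}, "
                f"time={row.time}, replicate={row.replicate})"
            )
        values[i] = row.value
    if np.isnan(values).any():
        g, c, t, r = np.argwhere(np.isnan(values))[0]
        raise DataValidationError(
            f"{path}: incomplete cell (gene={genes[g]}, condition={conditions[c]}, "
            f"time={times[t]}): missing replicate {reps[r]}"
        )
    return ExpressionDataset(
        gene_ids=tuple(genes),
        condition_ids=tuple(conditions),
        time_labels=tuple(times),
        values=values,
        signed=signed,
    )


def _load_wide(path: Path, signed: bool) -> ExpressionDataset:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str}, float_precision="round_trip")
    if df.columns[0] != "gene":
        raise DataValidationError(f"{path}: first column of wide format must be 'gene'")
    genes = list(df["gene"])
    conditions: list[str] = []
    times: list[str] = []
    reps: list[str] = []
    parsed = []
    for col in df.columns[1:]:
        parts = col.split(":")
        if len(parts) != 3:
            raise DataValidationError(
                f"{path}: wide column {col!r} is not 'condition:time:replicate'"
            )
        c, t, r = parts
        parsed.append((c, t, r))
        if c not in conditions:
            conditions.append(c)
        if t not in times:
            times.append(t)
        if r not in reps:
            reps.append(r)
    values = np.full((len(genes), len(conditions), len(times), len(reps)), np.nan)
    for j, (c, t, r) in enumerate(parsed):
        values[:, conditions.index(c), times.index(t), reps.index(r)] = df.iloc[:, j + 1]
    if np.isnan(values).any():
        g, c, t, r = np.argwhere(np.isnan(values))[0]
        raise DataValidationError(
            f"{path}: incomplete cell (gene={genes[g]}, condition={conditions[c]}, "
            f"time={times[t]}): missing replicate {reps[r]}"
        )
    return ExpressionDataset(
        gene_ids=tuple(genes),
        condition_ids=tuple(conditions),
        time_labels=tuple(times),
        values=values,
        signed=signed,
    )


def write_expression(ds: ExpressionDataset, path: str | Path) -> None:
    """Write the dataset in canonical long TSV order (gene, condition, time, replicate)."""
    records = []
    for g, gene in enumerate(ds.gene_ids):
        for c, cond in enumerate(ds.condition_ids):
            for t, time in enumerate(ds.time_labels):
                for r in range(ds.n_replicates):
                    records.append((gene, cond, time, r + 1, ds.values[g, c, t, r]))
    pd.DataFrame.from_records(records, columns=LONG_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
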