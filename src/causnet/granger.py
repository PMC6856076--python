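"""Stage II: Granger-causality pruning of Stage I regulator subsets.

Each of a fit's k regulators is tested one by one for marginal
contribution: the reduced model refits the remaining k-1 regulators (plus
the target's own lag and the intercept) and

    F = (RSS_reduced - RSS_full) / (RSS_full / df_den),

with one numerator degree of freedom and ``df_den = n_obs - p_full`` where
``p_full`` counts all fitted parameters of the full model (k regulators +
self-lag + intercept).  The p value is the upper tail of F(1, df_den).

Decision rule: by default a regulator is **kept** iff p < alpha -- i.e. it
is dropped when its lagged value does not significantly reduce the
prediction error, the standard Granger-causality convention for removing
false-positive regulations.  ``literal=True`` inverts this (drop iff
p < alpha), which some descriptions of the procedure state verbatim; both
conventions are runnable so either reading can be reproduced.

Tests are marginal and simultaneous (each regulator against the fixed other
k-1), with no multiple-testing correction and a single preset level
(default alpha = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from causnet.dataset import TransitionSet
from causnet.regression import GramCache, SparseFit, fit_subset

__all__ = ["GrangerResult", "granger_test", "prune_fit", "DEFAULT_ALPHA"]

DEFAULT_ALPHA = 0.05

#: relative floor below which an RSS counts as numerically zero
_ZERO_RSS_RTOL = 1e-12


@dataclass(frozen=True)
class GrangerResult:
    """Outcome of one marginal F test of a regulator on a target."""

    target: str
    regulator: str
    f_stat: float  # +inf sentinel when the full model fits perfectly
    p_value: float
    kept: bool
    df_num: int
    df_den: int
    rss_full: float
    rss_reduced: float


def granger_test(
    fit: SparseFit,
    regulator: str,
    transitions: TransitionSet,
    alpha: float = DEFAULT_ALPHA,
    intercept: bool = True,
    literal: bool = False,
    gram: GramCache | None = None,
) -> GrangerResult:
    """Marginal F test of one regulator's contribution beyond the other k-1.

    Degenerate cases: if both full and reduced RSS are numerically zero the
    regulator carries no attributable information and is removed; if only
    the full RSS is zero, the perfect fit is attributed to the regulator
    (F = +inf sentinel, p = 0, kept under the default convention).
    """
    if regulator not in fit.regulators:
        raise ValueError(f"{regulator!r} is not a regulator of the fit")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    gram = gram or GramCache(transitions)
    p_full = fit.k + (2 if intercept else 1)
    df_den = fit.n_obs - p_full
    if df_den < 1:
        raise ValueError(
            f"no residual degrees of freedom (n_obs={fit.n_obs}, p={p_full}); "
            "add observations or lower k"
        )
    reduced = fit_subset(
        fit.target,
        transitions,
        [r for r in fit.regulators if r != regulator],
        intercept=intercept,
        gram=gram,
    )
    tpos = transitions.gene_ids.index(fit.target)
    scale = max(1.0, float(gram.yty[tpos]))
    tiny = _ZERO_RSS_RTOL * scale
    rss_full = fit.rss
    rss_red = max(reduced.rss, rss_full)  # nesting: reduced can never fit better

    if rss_full <= tiny and rss_red <= tiny:
        f_stat, p_value, significant = 0.0, 1.0, False
    elif rss_full <= tiny:
        f_stat, p_value, significant = np.inf, 0.0, True
    else:
        f_stat = (rss_red - rss_full) / (rss_full / df_den)
        f_stat = max(f_stat, 0.0)
        p_value = float(stats.f.sf(f_stat, 1, df_den))
        significant = p_value < alpha

    kept = (not significant) if literal else significant
    return GrangerResult(
        target=fit.target,
        regulator=regulator,
        f_stat=float(f_stat),
        p_value=p_value,
        kept=kept,
        df_num=1,
        df_den=df_den,
        rss_full=rss_full,
        rss_reduced=rss_red,
    )


def prune_fit(
    fit: SparseFit,
    transitions: TransitionSet,
    alpha: float = DEFAULT_ALPHA,
    intercept: bool = True,
    literal: bool = False,
    gram: GramCache | None = None,
) -> tuple[SparseFit, tuple[GrangerResult, ...]]:
    """Test each regulator marginally and refit on the survivors.

    All k tests use the original Stage I fit as the full model (no
    sequential re-pruning); the surviving regulators' coefficients are then
    re-estimated in a final least squares.  May return a fit with zero
    regulators (self-lag and intercept only).
    """
    if not fit.regulators:
        return fit, ()
    gram = gram or GramCache(transitions)
    results = tuple(
        granger_test(
            fit, r, transitions, alpha=alpha, intercept=intercept, literal=literal, gram=gram
        )
        for r in fit.regulators
    )
    survivors = [r.regulator for r in results if r.kept]
    if len(survivors) == len(fit.regulators):
        return fit, results
    pruned = fit_subset(fit.target, transitions, survivors, intercept=intercept, gram=gram)
    return pruned, results
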