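"""Stage-to-stage differential expression with re-implemented NB statistics.

This is a deliberately explicit, simplified negative-binomial pipeline:
median-of-ratios size factors, a method-of-moments dispersion estimate shrunk
halfway toward the across-gene mean, a Wald test on the log2 fold change of
normalized stage means (delta-method standard errors from the NB variance
mu + alpha*mu^2), and step-up Benjamini-Hochberg adjustment. It trades the
empirical-Bayes machinery of production DE packages for transparency; with
two replicates per stage the moment estimator is noisy and the halfway
shrinkage carries most of the stabilisation.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stages import STAGES, stage_of_library

SIGNIFICANCE_Q = 0.05
PSEUDOCOUNT = 0.5


def size_factors_median_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    The reference is the per-gene geometric mean over libraries (genes with
    any zero excluded); each library's factor is the median over genes of
    count/reference.
    """
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no gene has nonzero counts in every library")
    ref = np.exp(np.log(mat[nonzero]).mean(axis=1))
    factors = np.median(mat[nonzero] / ref[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    design: Mapping[str, str] | None = None,
    shrink: float = 0.5,
) -> pd.Series:
    """Per-gene NB dispersion by the method of moments, shrunk one-sidedly.

    For each gene, within-stage sample mean/variance of normalized counts are
    pooled over stages with >= 2 replicates:
    ``alpha_raw = max(0, sum(s2 - m) / sum(m^2))``, then
    ``alpha = mean(alpha_raw) + shrink * max(alpha_raw - mean(alpha_raw), 0)``.

    The shrinkage is one-sided: with two replicates the moment estimate has
    about one degree of freedom per stage, and genes whose raw estimate
    undershoots the across-gene mean would otherwise get overconfident Wald
    statistics; flooring at the mean keeps the test's type-I error near its
    nominal level while still letting genuinely noisy genes carry halfway of
    their upward excess.
    """
    design = design or {lib: stage_of_library(lib) for lib in counts.columns}
    norm = counts / size_factors
    groups: dict[str, list[str]] = {}
    for lib, stage in design.items():
        groups.setdefault(stage, []).append(lib)
    rep_groups = [libs for libs in groups.values() if len(libs) >= 2]
    if not rep_groups:
        raise ValueError(
            "no stage has >= 2 replicates; dispersion needs replication "
            "(pool libraries into conditions first)"
        )
    num = np.zeros(len(counts))
    den = np.zeros(len(counts))
    for libs in rep_groups:
        sub = norm[libs].to_numpy()
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        num += s2 - m
        den += m ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, num / den, 0.0)
    raw = np.clip(raw, 0.0, None)
    alpha = raw.mean() + shrink * np.clip(raw - raw.mean(), 0.0, None)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def nb_wald_test(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    dispersions: pd.Series,
    transition: tuple[str, str],
    design: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Wald test of stage A vs stage B on normalized means.

    log2FC = log2((meanB + 0.5) / (meanA + 0.5)); the SE propagates the NB
    variance of each replicate mean to the log2 scale; p is two-sided normal.
    Genes with zero counts in every library of both stages are excluded.
    """
    design = design or {lib: stage_of_library(lib) for lib in counts.columns}
    stage_a, stage_b = transition
    libs_a = [l for l in counts.columns if design[l] == stage_a]
    libs_b = [l for l in counts.columns if design[l] == stage_b]
    if not libs_a or not libs_b:
        missing = stage_a if not libs_a else stage_b
        raise ValueError(f"stage {missing!r} has no libraries in the design")

    norm = counts / size_factors
    keep = (counts[libs_a + libs_b].sum(axis=1) > 0)
    norm = norm.loc[keep]
    alpha = dispersions.loc[keep].to_numpy()

    def group_stats(libs):
        sub = norm[libs].to_numpy()
        mean = sub.mean(axis=1)
        # variance of the mean of n NB draws with mean mu_i and dispersion a
        var = (mean + alpha * mean ** 2) / len(libs)
        return mean, var

    mean_a, var_a = group_stats(libs_a)
    mean_b, var_b = group_stats(libs_b)
    ma, mb = mean_a + PSEUDOCOUNT, mean_b + PSEUDOCOUNT
    l2fc = np.log2(mb / ma)
    ln2 = math.log(2.0)
    se = np.sqrt(var_a / ma ** 2 + var_b / mb ** 2) / ln2
    se = np.where(se > 0, se, np.inf)
    stat = l2fc / se
    p = 2.0 * stats.norm.sf(np.abs(stat))
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "log2_fold_change": l2fc,
            "se": se,
            "stat": stat,
            "p_value": p,
            "q_value": q,
            "significant": q < SIGNIFICANCE_Q,
        },
        index=norm.index,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def all_adjacent_transitions(
    counts: pd.DataFrame,
    design: Mapping[str, str] | None = None,
    ordered_stages: Sequence[str] = STAGES,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Run the NB Wald test for every adjacent stage pair, in stage order."""
    sf = size_factors_median_ratios(counts)
    disp = estimate_dispersion(counts, sf, design)
    out = {}
    for a, b in zip(ordered_stages[:-1], ordered_stages[1:]):
        out[(a, b)] = nb_wald_test(counts, sf, disp, (a, b), design)
    return out


def transition_summary(
    results: Mapping[tuple[str, str], pd.DataFrame],
    ordered_stages: Sequence[str] = STAGES,
) -> pd.DataFrame:
    """Per-transition counts of significantly up/downregulated genes."""
    rows = []
    for a, b in zip(ordered_stages[:-1], ordered_stages[1:]):
        res = results.get((a, b))
        if res is None:
            continue
        sig = res[res["significant"]]
        rows.append(
            {
                "transition": f"{a}->{b}",
                "n_up": int((sig["log2_fold_change"] > 0).sum()),
                "n_down": int((sig["log2_fold_change"] < 0).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("transition")
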