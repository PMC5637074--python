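"""Spearman-threshold coexpression networks, modules and SVD metagenes.

Profiles are the 11 stage-mean CPM values per gene (replicates averaged).
Two genes are connected when their tie-corrected Spearman correlation
exceeds 0.9 (strictly; anticorrelation never connects); connected components
of at least three genes are the co-expression modules, and the largest
module is re-thresholded at 0.925 to separate its submodules. Each module's
characteristic stage profile (metagene) is the first right singular vector
of the member x stage matrix after per-gene z-scoring, oriented to correlate
positively with the members' mean profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .stages import STAGES, stage_of_library

DEFAULT_THRESHOLD = 0.9
DEFAULT_SUB_THRESHOLD = 0.925
DEFAULT_MIN_MODULE_SIZE = 3


def stage_means(
    cpm: pd.DataFrame,
    design: Mapping[str, str] | None = None,
    ordered_stages: Sequence[str] = STAGES,
) -> pd.DataFrame:
    """Genes x stages matrix of replicate-averaged CPM."""
    design = design or {lib: stage_of_library(lib) for lib in cpm.columns}
    missing = [s for s in ordered_stages if s not in set(design.values())]
    if missing:
        raise ValueError(f"stages without libraries: {missing}")
    cols = {}
    for stage in ordered_stages:
        libs = [l for l in cpm.columns if design.get(l) == stage]
        cols[stage] = cpm[libs].mean(axis=1)
    return pd.DataFrame(cols)


def spearman_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene tie-corrected (average-rank) Spearman correlation.

    Constant profiles have no defined rank correlation; their rows/columns
    are set to 0 (diagonal excepted) with a warning rather than propagating
    NaN into the network step.
    """
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 stages for rank correlation")
    x = profiles.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        names = list(profiles.index[constant])
        warnings.warn(
            f"{len(names)} constant profile(s) set to rho=0: {names[:5]}...",
            stacklevel=2,
        )
        # give constant rows arbitrary distinct ranks, then zero them below
        ranks[constant] = np.arange(ranks.shape[1])
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=profiles.index, columns=profiles.index)


def build_network(rho: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> nx.Graph:
    """Undirected graph with an edge wherever rho > threshold (strict)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    genes = list(rho.index)
    g = nx.Graph()
    g.add_nodes_from(genes)
    mat = rho.to_numpy()
    ii, jj = np.nonzero(np.triu(mat > threshold, k=1))
    g.add_edges_from(
        (genes[i], genes[j], {"rho": float(mat[i, j])}) for i, j in zip(ii, jj)
    )
    return g


@dataclass
class CoModule:
    """A co-expression module (or submodule, when ``parent`` is set)."""

    module_id: str
    members: tuple[str, ...]
    metagene: np.ndarray | None = None
    parent: str | None = None


def find_modules(network: nx.Graph, min_size: int = DEFAULT_MIN_MODULE_SIZE) -> list[CoModule]:
    """Connected components of size >= min_size, largest first.

    Ties in size break on the smallest member id, so ids are deterministic.
    """
    comps = [tuple(sorted(c)) for c in nx.connected_components(network) if len(c) >= min_size]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return [CoModule(f"CoMod-{i + 1}", c) for i, c in enumerate(comps)]


def split_largest(
    network: nx.Graph,
    rho: pd.DataFrame,
    sub_threshold: float = DEFAULT_SUB_THRESHOLD,
    min_size: int = DEFAULT_MIN_MODULE_SIZE,
) -> list[CoModule]:
    """Split the largest module by re-thresholding its internal edges.

    Edges within the largest module are kept only where rho > sub_threshold;
    the resulting components of size >= min_size become submodules.
    """
    modules = find_modules(network, min_size)
    if not modules:
        raise ValueError("no modules to split")
    parent = modules[0]
    sub = rho.loc[list(parent.members), list(parent.members)]
    subnet = build_network(sub, sub_threshold)
    out = []
    for i, m in enumerate(find_modules(subnet, min_size)):
        out.append(
            CoModule(f"{parent.module_id}.{i + 1}", m.members, parent=parent.module_id)
        )
    return out


def metagene(
    module_profiles: pd.DataFrame, standardize: bool = True
) -> np.ndarray:
    """Characteristic stage profile: first right singular vector of the module.

    With ``standardize`` (default) each member profile is z-scored across
    stages first, so the metagene reflects profile shape rather than
    expression magnitude. The sign is oriented so the metagene correlates
    positively with the per-stage mean of the member profiles; the returned
    vector has unit Euclidean norm.
    """
    if module_profiles.shape[0] < 2:
        raise ValueError("metagene needs at least 2 member genes")
    x = module_profiles.to_numpy(dtype=float)
    mean_profile = x.mean(axis=0)
    if standardize:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=0, keepdims=True)
        if (sd == 0).any():
            raise ValueError("module contains an all-constant profile")
        x = (x - mu) / sd
    if np.allclose(x, 0):
        raise ValueError("degenerate module: all profiles constant")
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    v = vt[0]
    centered = mean_profile - mean_profile.mean()
    orient = float(np.dot(v, centered if centered.any() else mean_profile))
    if orient < 0:
        v = -v
    return v / np.linalg.norm(v)


def expression_cv(profiles: pd.DataFrame) -> pd.Series:
    """Coefficient of variation (sample sd / mean) of each gene's stage means.

    Zero-mean genes are excluded with a warning: their CV is undefined.
    """
    x = profiles.to_numpy(dtype=float)
    means = x.mean(axis=1)
    zero = means == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} zero-mean gene(s) from CV", stacklevel=2
        )
    sd = x.std(axis=1, ddof=1)
    cv = pd.Series(sd[~zero] / means[~zero], index=profiles.index[~zero], name="cv")
    return cv


def welch_test(group1: Sequence[float], group2: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# I/O helpers

def write_edge_list(network: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\trho\n")
        for a, b, d in sorted(network.edges(data=True)):
            fh.write(f"{a}\t{b}\t{d['rho']:.6f}\n")


def write_modules_tsv(modules: Sequence[CoModule], path) -> None:
    with open(path, "w") as fh:
        fh.write("module\tparent\tgene\n")
        for m in modules:
            for g in m.members:
                fh.write(f"{m.module_id}\t{m.parent or ''}\t{g}\n")


def write_metagenes_tsv(modules: Sequence[CoModule], path) -> None:
    with open(path, "w") as fh:
        fh.write("module\t" + "\t".join(STAGES) + "\n")
        for m in modules:
            if m.metagene is None:
                continue
            fh.write(m.module_id + "\t" + "\t".join(f"{v:.6f}" for v in m.metagene) + "\n")


def write_graphml(network: nx.Graph, path) -> None:
    nx.write_graphml(network, path)
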