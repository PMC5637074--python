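"""Cross-species family-level comparison and the developmental-time model.

Species are compared at the miRNA-family level: only orthologous families
present in every species are kept, family expression is converted to
relative abundance per library, and libraries are then related by
hierarchical clustering and PCA on log-transformed proportions. The
developmental-time model maps hours after oviposition onto percent of
embryo development (18-day embryogenesis at 29 C by default), which is how
stages of species with different absolute timings are aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .stages import HOURS_AFTER_OVIPOSITION, TOTAL_EMBRYO_HOURS


@dataclass(frozen=True)
class StageModel:
    """Embryogenesis timeline: stage -> hours after oviposition."""

    total_hours: float = TOTAL_EMBRYO_HOURS
    stage_hours: Mapping[str, float] = field(
        default_factory=lambda: dict(HOURS_AFTER_OVIPOSITION)
    )

    def __post_init__(self):
        if self.total_hours <= 0:
            raise ValueError("total embryogenesis duration must be positive")
        for s, h in self.stage_hours.items():
            if h < 0:
                raise ValueError(f"negative hours for stage {s}")

    def percent(self, stage: str, decimals: int = 0) -> float:
        return percent_development(self.stage_hours[stage], self.total_hours, decimals)


def percent_development(hours_ao: float, total_hours: float = TOTAL_EMBRYO_HOURS,
                        decimals: int = 0) -> float:
    """Percent of embryo development at ``hours_ao`` hours after oviposition."""
    if total_hours <= 0:
        raise ValueError("total_hours must be positive")
    if hours_ao < 0:
        raise ValueError("hours_ao must be non-negative")
    if hours_ao > total_hours:
        raise ValueError(f"hours_ao {hours_ao} exceeds total duration {total_hours}")
    return round(100.0 * hours_ao / total_hours, decimals)


def shared_family_table(
    family_tables: pd.DataFrame, species_of: Mapping[str, str]
) -> pd.DataFrame:
    """Retain exactly the families with nonzero expression in every species.

    ``family_tables`` is families x libraries; ``species_of`` maps each
    library column to its species.
    """
    species = sorted(set(species_of.values()))
    if len(species) < 2:
        raise ValueError("need at least 2 species to intersect families")
    present = pd.DataFrame(index=family_tables.index)
    for sp in species:
        libs = [l for l in family_tables.columns if species_of[l] == sp]
        if not libs:
            raise ValueError(f"species {sp!r} has no libraries")
        present[sp] = (family_tables[libs] > 0).any(axis=1)
    keep = present.all(axis=1)
    if not keep.any():
        raise ValueError("no family is shared by all species")
    return family_tables.loc[keep]


def relative_abundance(family_table: pd.DataFrame) -> pd.DataFrame:
    """Each library column scaled to proportions summing to 1."""
    totals = family_table.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total library: {', '.join(map(str, zero.index))}")
    return family_table / totals


def _log_transform(proportions: pd.DataFrame) -> pd.DataFrame:
    # heavy-tailed abundances: work on log10(proportion * 1e6 + 1)
    return np.log10(proportions * 1e6 + 1.0)


def correlation_distance_matrix(proportions: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation between library columns of the log table."""
    logged = _log_transform(proportions)
    corr = np.corrcoef(logged.to_numpy().T)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    return pd.DataFrame(d, index=proportions.columns, columns=proportions.columns)


@dataclass
class HClusterResult:
    linkage: np.ndarray
    labels: list[str]
    distance: pd.DataFrame

    def cut(self, k: int) -> dict[str, int]:
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.labels)
        return str(tree).strip()


def hcluster_libraries(
    rel_abundance: pd.DataFrame,
    linkage: str = "average",
    distance: str = "1-pearson",
) -> HClusterResult:
    """Agglomerative clustering of libraries on log-transformed proportions.

    Libraries are processed in sorted-id order so the result is invariant to
    the input column order.
    """
    if rel_abundance.shape[1] < 2:
        raise ValueError("need at least 2 libraries to cluster")
    ordered = rel_abundance[sorted(rel_abundance.columns)]
    if distance == "1-pearson":
        dmat = correlation_distance_matrix(ordered)
    elif distance == "euclidean":
        logged = _log_transform(ordered)
        x = logged.to_numpy().T
        diff = x[:, None, :] - x[None, :, :]
        dmat = pd.DataFrame(
            np.sqrt((diff ** 2).sum(axis=2)), index=ordered.columns, columns=ordered.columns
        )
    else:
        raise ValueError(f"unknown distance {distance!r}")
    z = hierarchy.linkage(squareform(dmat.to_numpy(), checks=False), method=linkage)
    return HClusterResult(linkage=z, labels=list(ordered.columns), distance=dmat)


@dataclass
class PCAResult:
    scores: pd.DataFrame        # libraries x components
    loadings: pd.DataFrame      # families x components
    explained_variance_ratio: np.ndarray
    drivers: list[str]


def pca_drivers(rel_abundance: pd.DataFrame, n_drivers: int = 3) -> PCAResult:
    """PCA of libraries over families, with the families driving PC1/PC2.

    The log-transformed proportion matrix (libraries as rows) is
    column-centered and decomposed by SVD. Components are sign-oriented so
    the first library scores >= 0. Drivers are the n families with the
    largest absolute PC1 loading, |PC2| breaking ties.
    """
    logged = _log_transform(rel_abundance)
    x = logged.to_numpy().T  # libraries x families
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 libraries and >= 2 families")
    centered = x - x.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0):
        raise ValueError("degenerate input: no variance across libraries")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # orient each component so the first library's score is non-negative
    signs = np.where(u[0] < 0, -1.0, 1.0)
    u = u * signs
    vt = vt * signs[:, None]
    scores = u * s
    var_ratio = s ** 2 / (s ** 2).sum()
    comps = [f"PC{i + 1}" for i in range(len(s))]
    scores_df = pd.DataFrame(scores, index=rel_abundance.columns, columns=comps)
    load_df = pd.DataFrame(vt.T, index=rel_abundance.index, columns=comps)

    pc1 = load_df["PC1"].abs()
    pc2 = load_df["PC2"].abs() if len(s) > 1 else pc1 * 0.0
    order = sorted(load_df.index, key=lambda f: (-pc1[f], -pc2[f], f))
    return PCAResult(scores_df, load_df, var_ratio, order[:n_drivers])
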