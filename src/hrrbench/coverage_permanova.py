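"""Consensus-coverage vectors, embedding, and permutation PERMANOVA.

A coverage vector summarizes one analysis unit (sample × titer × method) as
the per-reference proportion of positions covered at or above a depth
threshold (default 10×, inclusive). Vectors are embedded for visualization
with PCA followed by t-SNE (perplexity 30, 5000 iterations, seeded), and
group structure is tested with a from-scratch permutation PERMANOVA on
pairwise distances in the *original* coverage space (not the embedding, to
avoid testing embedding artifacts).

PERMANOVA decomposition (for distance matrix d, n units, g groups):

    SS_total   = (1/n) Σ_{i<j} d²_ij
    SS_within  = Σ_groups (1/n_g) Σ_{i<j in g} d²_ij
    SS_between = SS_total − SS_within
    pseudo-F   = [SS_between/(g−1)] / [SS_within/(n−g)]

The permutation p-value uses the add-one rule
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_permutations), so p is never 0; exact
enumeration over all label permutations is available for small n.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PermanovaResult",
    "coverage_vector",
    "coverage_matrix",
    "distance_matrix",
    "embed",
    "permanova",
]


def coverage_vector(
    depth_table: Union[pd.DataFrame, str],
    reference_lengths: Mapping[str, int],
    min_depth: int = 10,
) -> pd.Series:
    """Per-reference proportion of positions covered at depth ≥ ``min_depth``.

    ``depth_table`` holds rows (reference, position, depth) with 1-based
    positions, the common three-column depth dialect; positions absent from
    the table have depth 0. Row order is irrelevant. Positions exceeding the
    declared reference length raise.
    """
    if isinstance(depth_table, (str,)):
        depth_table = pd.read_csv(
            depth_table, sep="\t", names=["reference", "position", "depth"], header=None
        )
    df = depth_table.copy()
    df.columns = ["reference", "position", "depth"]
    out: Dict[str, float] = {}
    grouped = dict(tuple(df.groupby("reference")))
    for ref, length in reference_lengths.items():
        if length <= 0:
            raise ValueError(f"reference {ref!r} has non-positive length {length}")
        grp = grouped.pop(ref, None)
        if grp is None:
            out[ref] = 0.0
            continue
        pos = grp["position"].to_numpy()
        if (pos < 1).any() or (pos > length).any():
            bad = pos[(pos < 1) | (pos > length)][0]
            raise ValueError(f"reference {ref!r}: position {bad} outside 1..{length}")
        covered = grp.loc[grp["depth"] >= min_depth, "position"].nunique()
        out[ref] = covered / length
    if grouped:
        raise ValueError(f"depth rows for undeclared references: {sorted(grouped)}")
    return pd.Series(out, name="coverage")


def coverage_matrix(
    vectors: Mapping[str, pd.Series],
) -> pd.DataFrame:
    """Stack unit → coverage-vector mappings into a units × references matrix
    with a consistent reference ordering."""
    df = pd.DataFrame(vectors).T
    df = df[sorted(df.columns)]
    if df.isna().any().any():
        raise ValueError("coverage vectors do not share a common reference set")
    return df


def distance_matrix(
    vectors: Union[pd.DataFrame, np.ndarray], metric: str = "euclidean"
) -> np.ndarray:
    """Pairwise distances between coverage vectors.

    Metrics: ``euclidean`` (default), ``braycurtis``, or ``jaccard`` on
    binarized (> 0) vectors.
    """
    x = np.asarray(vectors, dtype=float)
    if metric == "jaccard":
        return squareform(pdist(x > 0, metric="jaccard"))
    if metric in ("euclidean", "braycurtis"):
        return squareform(pdist(x, metric=metric))
    raise ValueError(f"unknown metric {metric!r}")


def embed(
    vectors: Union[pd.DataFrame, np.ndarray],
    perplexity: float = 30.0,
    max_iter: int = 5000,
    seed: int = 0,
    n_pca_components: int = 50,
) -> np.ndarray:
    """PCA (to min(50, n−1) components) followed by t-SNE to 2-D.

    Perplexity must be below the number of units; larger requests are
    auto-shrunk with a warning. Seeded and reproducible.
    """
    from sklearn.decomposition import PCA
    from sklearn.manifold import TSNE

    x = np.asarray(vectors, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 units to embed, got {n}")
    n_comp = max(1, min(n_pca_components, n - 1, x.shape[1]))
    reduced = PCA(n_components=n_comp, random_state=seed).fit_transform(x)
    if perplexity >= n:
        new_perp = max(1.0, (n - 1) / 3)
        warnings.warn(
            f"perplexity {perplexity} >= n_units {n}; shrunk to {new_perp}", stacklevel=2
        )
        perplexity = new_perp
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=max_iter,
        init="pca",
        random_state=seed,
    )
    return tsne.fit_transform(reduced)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    grouping: str = ""
    method: str = "monte-carlo"
    flags: FrozenSet[str] = frozenset()


def _group_indices(groups: Sequence[object]) -> Dict[object, np.ndarray]:
    labels = np.asarray(groups)
    return {g: np.flatnonzero(labels == g) for g in pd.unique(labels)}


def _ss_within(d2: np.ndarray, idx_by_group: Mapping[object, np.ndarray]) -> float:
    ssw = 0.0
    for idx in idx_by_group.values():
        n_g = idx.size
        if n_g > 1:
            ssw += d2[np.ix_(idx, idx)].sum() / (2 * n_g)
    return ssw


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, g: int, n: int, ss_total: float) -> float:
    idx_by_group = {gg: np.flatnonzero(labels == gg) for gg in pd.unique(labels)}
    ssw = _ss_within(d2, idx_by_group)
    ssb = ss_total - ssw
    if ssw <= 0:
        return math.inf if ssb > 0 else math.nan
    return (ssb / (g - 1)) / (ssw / (n - g))


def permanova(
    distance: Union[np.ndarray, pd.DataFrame],
    groups: Sequence[object],
    n_permutations: int = 999,
    seed: int = 0,
    grouping: str = "",
    method: str = "monte-carlo",
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``method="monte-carlo"`` permutes labels ``n_permutations`` times
    (seeded) and applies the add-one p-value rule; ``method="exact"``
    enumerates every label permutation (n ≤ 8) and reports the exact tail
    proportion #{F_perm ≥ F_obs}/n!. All-identical points leave F undefined
    (NaN, flagged DEGENERATE, p = 1).
    """
    d = np.asarray(distance, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance must be a square matrix")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must have a zero diagonal")
    labels = np.asarray(groups)
    if labels.shape[0] != n:
        raise ValueError("groups length must match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    g = uniq.size
    if g < 2:
        raise ValueError("need at least 2 groups")
    if counts.max() < 2:
        raise ValueError("at least one group must have >= 2 members")

    d2 = d**2
    ss_total = d2.sum() / (2 * n)
    f_obs = _pseudo_f(d2, labels, g, n, ss_total)
    if math.isnan(f_obs):
        return PermanovaResult(
            math.nan, 1.0, 0, grouping, method, frozenset({"DEGENERATE"})
        )

    if method == "exact":
        if n > 8:
            raise ValueError("exact enumeration is limited to n <= 8")
        count_ge = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            f_perm = _pseudo_f(d2, labels[list(perm)], g, n, ss_total)
            total += 1
            if f_perm >= f_obs - 1e-12:
                count_ge += 1
        p = count_ge / total
        return PermanovaResult(float(f_obs), p, total, grouping, "exact")

    if method != "monte-carlo":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_permutations):
        f_perm = _pseudo_f(d2, rng.permutation(labels), g, n, ss_total)
        if f_perm >= f_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), p, n_permutations, grouping, "monte-carlo")
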