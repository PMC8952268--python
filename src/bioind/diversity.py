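"""Alpha/beta diversity and the permutation statistics used around them.

Observed ASV richness and Shannon entropy (natural log), Bray-Curtis
dissimilarities, nonmetric multidimensional scaling (NMDS), one-factor
PERMANOVA with Monte-Carlo permutation p-values, and Benjamini-Hochberg FDR
adjustment.  Distance handling is delegated to scikit-bio; NMDS to
scikit-learn's nonmetric MDS with Kruskal stress-1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix as _SkbioDM, permanova as _skbio_permanova
from sklearn.manifold import MDS
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable, TableError


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix with entries in [0, 1]."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise TableError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise TableError("distance matrix not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise TableError("distance matrix diagonal must be zero")
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-9):
            raise TableError("dissimilarities must lie in [0, 1]")
        self.values = v

    def to_skbio(self) -> _SkbioDM:
        return _SkbioDM(self.values, ids=self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    factor: str

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise TableError("p-value out of range")


def observed_asvs(row: np.ndarray) -> int:
    """Number of ASVs with non-zero abundance in one sample."""
    row = np.asarray(row, dtype=float)
    if (row < 0).any():
        raise TableError("negative abundances")
    if row.sum() == 0:
        raise TableError("all-zero sample")
    return int(np.count_nonzero(row))


def shannon(row: np.ndarray) -> float:
    """Shannon entropy H = -sum p_i ln p_i (natural log) of one sample."""
    row = np.asarray(row, dtype=float)
    if (row < 0).any():
        raise TableError("negative abundances")
    total = row.sum()
    if total == 0:
        raise TableError("all-zero sample")
    p = row[row > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity BC(u,v) = sum|u-v| / sum(u+v)."""
    x = table.values()
    if x.shape[0] < 2:
        raise TableError("need at least two samples")
    if (x.sum(axis=1) == 0).any():
        raise TableError("all-zero sample in table")
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, d)


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    eps: float = 1e-6,
) -> tuple[pd.DataFrame, float]:
    """Nonmetric MDS of a dissimilarity matrix.

    Minimizes Kruskal stress-1 via iterative majorization with isotonic
    regression; the best of ``n_restarts`` random initializations is
    returned.  Coordinates are defined only up to rotation/reflection.

    Returns
    -------
    (coordinates, stress):
        DataFrame (samples x k) and the final stress-1 value.
    """
    n = len(dm.sample_ids)
    if k >= n:
        raise TableError("embedding dimension must be below the sample count")
    model = MDS(
        n_components=k,
        metric=False,
        dissimilarity="precomputed",
        n_init=n_restarts,
        max_iter=max_iter,
        eps=eps,
        random_state=seed,
        normalized_stress=True,
    )
    coords = model.fit_transform(dm.values)
    frame = pd.DataFrame(coords, index=dm.sample_ids, columns=[f"NMDS{i+1}" for i in range(k)])
    return frame, float(model.stress_)


def permanova(
    dm: DistanceMatrix,
    grouping: pd.Series | dict | list,
    n_permutations: int = 1000,
    seed: int = 0,
    factor: str = "group",
) -> PermanovaResult:
    """One-factor PERMANOVA (Anderson 2001) with free permutation of labels.

    The pseudo-F is the ratio of among- to within-group variance of squared
    dissimilarities and is deterministic; the p-value is Monte-Carlo,
    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    """
    if isinstance(grouping, dict):
        labels = pd.Series({s: grouping[s] for s in dm.sample_ids})[dm.sample_ids]
    else:
        labels = pd.Series(list(grouping), index=dm.sample_ids)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise TableError("need at least two groups")
    if (counts < 2).any():
        small = list(counts[counts < 2].index)
        raise TableError(f"groups of size one not allowed: {small}")
    res = _skbio_permanova(
        dm.to_skbio(), list(labels), permutations=n_permutations, seed=seed % (2**31)
    )
    return PermanovaResult(
        pseudo_f=float(res["test statistic"]),
        p_value=float(res["p-value"]),
        n_permutations=n_permutations,
        factor=factor,
    )


def pairwise_permanova(
    dm: DistanceMatrix,
    grouping: pd.Series | dict | list,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """All pairwise group contrasts, jointly BH-adjusted over the family."""
    if isinstance(grouping, dict):
        labels = pd.Series({s: grouping[s] for s in dm.sample_ids})[dm.sample_ids]
    else:
        labels = pd.Series(list(grouping), index=dm.sample_ids)
    levels = sorted(labels.unique())
    rows = []
    frame = dm.to_frame()
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            ids = list(labels.index[labels.isin([a, b])])
            sub = DistanceMatrix(ids, frame.loc[ids, ids].to_numpy())
            res = permanova(sub, labels[ids], n_permutations, seed, factor=f"{a} vs {b}")
            rows.append({"contrast": f"{a} vs {b}", "pseudo_f": res.pseudo_f, "p": res.p_value})
    out = pd.DataFrame(rows)
    out["p_adj"] = fdr_adjust(out["p"].to_numpy())
    return out


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise TableError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
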