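"""Embedding of call features and the statistical conventions.

Reduces the six per-call features to a 2-D UMAP embedding, quantifies
overlap between call groups (e.g. natural vs. fictive) in embedding space,
and provides the statistics used throughout: log(1+x) transform, sample
coefficient of variation, Benjamini-Hochberg step-up adjustment, and
mixed-model group contrasts with animal identity as a random effect.

The overlap score is this package's quantitative surrogate for visual
overlap assessment of embedding plots; it is not a statistic defined by
the underlying study and outputs label it as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .calls import FEATURE_NAMES

__all__ = [
    "EmbeddingResult",
    "log1p_transform",
    "coefficient_of_variation",
    "bh_adjust",
    "embed_features",
    "overlap_score",
    "compare_feature_groups",
]


def log1p_transform(values) -> np.ndarray:
    """Elementwise log(1 + x); the normalising transform for feature data.

    Defined for non-negative inputs only (durations, rates, CVs, percent
    changes); monotone, with 0 mapping to 0.
    """
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("log1p transform requires non-negative values")
    return np.log1p(x)


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV requires at least two values")
    mean = float(np.mean(x))
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(np.std(x, ddof=1) / mean)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min_{j >= i} ( m * p_(j) / j ), clipped at 1, reported in
    the input order. Controls the false discovery rate over the m
    simultaneous contrasts.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


@dataclass(frozen=True)
class EmbeddingResult:
    """2-D coordinates per input row plus the parameters that produced them."""

    coords: np.ndarray
    n_neighbors: int
    min_dist: float
    seed: int
    feature_means: np.ndarray = field(repr=False)
    feature_sds: np.ndarray = field(repr=False)

    @property
    def n_rows(self) -> int:
        return self.coords.shape[0]


def embed_features(
    table: pd.DataFrame,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> EmbeddingResult:
    """UMAP embedding of the six features to 2-D.

    Each feature column is z-scored before embedding so no single unit
    (seconds vs. Hz vs. percent) dominates the metric. Delegates to
    umap-learn with a fixed random_state; identical (table, params, seed)
    reproduce identical coordinates.
    """
    import umap  # deferred: numba compilation is slow at import

    X = table.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    if X.shape[0] < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={n_neighbors + 1} rows, got {X.shape[0]}"
        )
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds[sds == 0] = 1.0  # constant feature: leave centred at 0
    Z = (X - means) / sds
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            metric="euclidean",
            random_state=seed,
        )
        coords = reducer.fit_transform(Z)
    return EmbeddingResult(
        coords=np.asarray(coords, dtype=float),
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        seed=seed,
        feature_means=means,
        feature_sds=sds,
    )


def overlap_score(
    embedding: EmbeddingResult,
    group_a: np.ndarray,
    group_b: np.ndarray,
    k: int = 10,
) -> float:
    """Fraction of group-a points with >= 1 group-b point among their k
    nearest neighbours in the embedding (self excluded).

    A symmetric summary is obtained by averaging the two directed scores.
    Invariant under rigid rotation/translation of the coordinates. When
    the point set is smaller than k+1, k is reduced with a warning.
    """
    a_idx = np.asarray(group_a, dtype=int)
    b_idx = np.asarray(group_b, dtype=int)
    if a_idx.size == 0 or b_idx.size == 0:
        raise ValueError("both groups must be non-empty")
    pts = embedding.coords
    n = pts.shape[0]
    if k + 1 > n:
        warnings.warn(f"k reduced from {k} to {n - 1} (only {n} points)")
        k = n - 1
    is_b = np.zeros(n, dtype=bool)
    is_b[b_idx] = True
    tree = cKDTree(pts)
    # k+1 because the query point is its own nearest neighbour
    _, nn = tree.query(pts[a_idx], k=k + 1)
    nn = np.atleast_2d(nn)
    hits = 0
    for row_i, row in zip(a_idx, nn):
        neigh = row[row != row_i][:k]
        hits += bool(is_b[neigh].any())
    return hits / a_idx.size


@dataclass(frozen=True)
class GroupContrast:
    """One pairwise group comparison for one feature."""

    feature: str
    group_a: str
    group_b: str
    estimate: float  # difference of transformed means (a - b)
    p_value: float
    p_adjusted: float = np.nan
    method: str = "mixedlm"


def _fit_pair(
    sub: pd.DataFrame, feature: str, group_col: str, animal_col: str
) -> tuple[float, float, str]:
    """Mixed-model contrast of one feature between two groups.

    Returns (estimate, p, method). The Wald statistic is referred to a t
    distribution with between-animal degrees of freedom (n_animals - 2):
    group is a between-animal factor, so the asymptotic z reference is
    anticonservative at the few-animals-per-group sizes typical of these
    experiments. Falls back to a fixed-effect OLS contrast with a warning
    when the random-effect fit is singular or fails to converge.
    """
    import statsmodels.formula.api as smf
    from scipy.stats import t as t_dist

    data = sub[[feature, group_col, animal_col]].copy()
    data.columns = ["y", "group", "animal"]
    data["y"] = log1p_transform(data["y"].to_numpy())
    n_animals = data["animal"].nunique()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm("y ~ C(group)", data, groups=data["animal"])
            fit = model.fit(reml=True, method="lbfgs")
            name = [n for n in fit.params.index if n.startswith("C(group)")][0]
            est, se = float(fit.params[name]), float(fit.bse[name])
            df = max(n_animals - 2, 1)
            p = 2 * t_dist.sf(abs(est / se), df) if se > 0 else float("nan")
            if np.isfinite(p):
                return est, float(p), "mixedlm"
        except (np.linalg.LinAlgError, ValueError, KeyError, IndexError):
            pass
    warnings.warn(
        f"mixed model singular for {feature}; falling back to fixed-effect OLS"
    )
    ols = smf.ols("y ~ C(group)", data).fit()
    name = [n for n in ols.params.index if n.startswith("C(group)")][0]
    return float(ols.params[name]), float(ols.pvalues[name]), "ols"


def compare_feature_groups(
    table: pd.DataFrame,
    feature: str,
    group_col: str = "source",
    animal_col: str = "animal_id",
) -> list[GroupContrast]:
    """All pairwise group contrasts for one feature.

    The feature is log(1+x) transformed, modelled with the group as a
    fixed effect and animal identity as a random intercept, and every
    pairwise contrast is tested; p-values are BH-adjusted across the
    contrasts. Requires >= 2 groups with >= 2 animals each.
    """
    groups = sorted(table[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups to contrast")
    for g in groups:
        n_animals = table.loc[table[group_col] == g, animal_col].nunique()
        if n_animals < 2:
            raise ValueError(f"group {g!r} has fewer than 2 animals")

    contrasts: list[GroupContrast] = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            sub = table[table[group_col].isin([ga, gb])]
            est, p, method = _fit_pair(sub, feature, group_col, animal_col)
            contrasts.append(
                GroupContrast(
                    feature=feature, group_a=gb, group_b=ga,
                    estimate=est, p_value=p, method=method,
                )
            )
    adj = bh_adjust([c.p_value for c in contrasts])
    return [
        GroupContrast(
            c.feature, c.group_a, c.group_b, c.estimate, c.p_value,
            float(a), c.method,
        )
        for c, a in zip(contrasts, adj)
    ]
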