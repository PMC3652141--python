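"""Multivariate statistics over descriptor tables.

Summary statistics, Pearson correlations, the Grubbs (extreme studentized
deviate) outlier test, ordinary least-squares regression, standardized
path coefficients, ANOSIM, and single-linkage hierarchical clustering —
the statistics used to characterize a screened compound library.

Conventions used throughout:

* standard deviations are sample SDs (n-1 denominator);
* the Grubbs critical value comes from the exact t-quantile formula,
  not lookup tables;
* clustering standardization z-scores columns and drops zero-variance
  columns with a logged notice (raw Euclidean distance would be dominated
  by formula weight);
* ANOSIM permutation p-values include the observed statistic in both
  numerator and denominator, and the RNG seed is a required argument.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .chem_io import DescriptorTable
from .errors import InputError

logger = logging.getLogger(__name__)

#: Table columns treated as numeric properties, in canonical order.
NUMERIC_FIELDS = (
    "log_p", "psa", "n_atoms", "fw", "n_on",
    "n_ohnh", "n_ro5_violations", "n_rot", "volume",
)


def _numeric_frame(t: DescriptorTable, fields: Optional[Sequence[str]] = None) -> pd.DataFrame:
    df = t.to_frame()
    if fields is None:
        fields = [f for f in NUMERIC_FIELDS if f in df.columns]
    else:
        missing = [f for f in fields if f not in df.columns]
        if missing:
            raise InputError(f"table lacks fields: {missing}")
    return df[list(fields)].astype(float)


# ---------------------------------------------------------------------------
# Summary statistics

@dataclasses.dataclass(frozen=True)
class SummaryRow:
    property: str
    mean: float
    minimum: float
    maximum: float
    median: float
    sd: float

    def __post_init__(self) -> None:
        assert self.minimum <= self.median <= self.maximum
        assert self.sd >= 0


def summarize(t: DescriptorTable, fields: Optional[Sequence[str]] = None) -> list[SummaryRow]:
    """Mean/min/max/median/sample-SD for each numeric property."""
    if len(t) < 2:
        raise InputError("summarize requires at least 2 records")
    df = _numeric_frame(t, fields)
    return [
        SummaryRow(
            property=col,
            mean=float(df[col].mean()),
            minimum=float(df[col].min()),
            maximum=float(df[col].max()),
            median=float(df[col].median()),
            sd=float(df[col].std(ddof=1)),
        )
        for col in df.columns
    ]


# ---------------------------------------------------------------------------
# Pearson correlations

def pearson_matrix(t: DescriptorTable, fields: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Pearson product-moment correlation matrix over the named fields.

    Zero-variance fields are excluded with a logged notice; if nothing
    with positive variance remains, an :class:`InputError` is raised.
    """
    if len(t) < 3:
        raise InputError("pearson_matrix requires at least 3 records")
    df = _numeric_frame(t, fields)
    sds = df.std(ddof=1)
    constant = [c for c in df.columns if sds[c] == 0]
    if constant:
        logger.info("pearson_matrix: dropping zero-variance fields %s", constant)
        df = df.drop(columns=constant)
    if df.shape[1] == 0:
        raise InputError("correlation undefined: all requested fields are constant")
    return df.corr(method="pearson")


# ---------------------------------------------------------------------------
# Grubbs' (ESD) outlier test

@dataclasses.dataclass(frozen=True)
class GrubbsResult:
    g_statistic: float
    g_critical: float
    alpha: float
    outlier_flag: bool
    outlier_index: Optional[int]

    def __post_init__(self) -> None:
        assert self.g_statistic >= 0
        assert self.outlier_flag == (self.g_statistic > self.g_critical)


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the exact t-quantile formula.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) where t is the
    upper alpha/(2n) quantile of Student's t with n-2 degrees of freedom.
    """
    if n < 3:
        raise InputError("Grubbs test requires n >= 3")
    tq = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(tq * tq / (n - 2 + tq * tq))


def grubbs_test(values: Sequence[float], alpha: float = 0.05) -> GrubbsResult:
    """Two-sided Grubbs test for a single outlier (the most extreme value)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InputError("Grubbs test requires n >= 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise InputError("Grubbs test undefined for zero-variance data")
    dev = np.abs(x - x.mean())
    idx = int(dev.argmax())
    g = float(dev[idx] / sd)
    gc = grubbs_critical(x.size, alpha)
    flag = g > gc
    return GrubbsResult(
        g_statistic=g,
        g_critical=float(gc),
        alpha=alpha,
        outlier_flag=bool(flag),
        outlier_index=idx if flag else None,
    )


# ---------------------------------------------------------------------------
# Ordinary least squares and path coefficients

@dataclasses.dataclass(frozen=True)
class RegressionFit:
    response: str
    intercept: float
    coefficients: Mapping[str, float]
    r_squared: float
    n: int
    fitted: np.ndarray
    residuals: np.ndarray

    def __post_init__(self) -> None:
        assert -1e-10 <= self.r_squared <= 1 + 1e-10


def ols_fit(
    t: DescriptorTable, response: str, predictors: Sequence[str]
) -> RegressionFit:
    """OLS of ``response`` on ``predictors`` over the table's records."""
    df = _numeric_frame(t, [response] + list(predictors))
    n = len(df)
    if n <= len(predictors) + 1:
        raise InputError(
            f"need n > {len(predictors) + 1} records for {len(predictors)} predictors, got {n}"
        )
    X = sm.add_constant(df[list(predictors)])
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        # name the predictors loading on the null space
        _, s, vt = np.linalg.svd(X.values, full_matrices=False)
        null = np.abs(vt[-1])
        names = [c for c, w in zip(X.columns, null) if w > 1e-8 and c != "const"]
        raise InputError(f"design matrix rank-deficient; collinear predictors: {names}")
    res = sm.OLS(df[response], X).fit()
    coefs = {p: float(res.params[p]) for p in predictors}
    return RegressionFit(
        response=response,
        intercept=float(res.params["const"]),
        coefficients=coefs,
        r_squared=float(res.rsquared),
        n=n,
        fitted=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
    )


@dataclasses.dataclass(frozen=True)
class PathResult:
    """Standardized direct effects of each predictor on the response.

    Single-equation path model: every listed predictor is a direct cause
    of the response, so the path coefficients are the OLS coefficients
    after z-scoring all variables. With strongly collinear predictors the
    standardized weights are unstable and can leave [-1, 1].
    """

    response: str
    coefficients: Mapping[str, float]

    def __post_init__(self) -> None:
        assert all(np.isfinite(v) for v in self.coefficients.values())


def path_coefficients(
    t: DescriptorTable, response: str, predictors: Sequence[str]
) -> PathResult:
    """Standardized OLS coefficients of ``response`` on ``predictors``."""
    df = _numeric_frame(t, [response] + list(predictors))
    sds = df.std(ddof=1)
    constant = [c for c in df.columns if sds[c] == 0]
    if constant:
        raise InputError(f"cannot z-score zero-variance fields: {constant}")
    z = (df - df.mean()) / sds
    X = sm.add_constant(z[list(predictors)])
    res = sm.OLS(z[response], X).fit()
    return PathResult(
        response=response,
        coefficients={p: float(res.params[p]) for p in predictors},
    )


# ---------------------------------------------------------------------------
# ANOSIM

@dataclasses.dataclass(frozen=True)
class AnosimResult:
    r_statistic: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        assert -1 - 1e-12 <= self.r_statistic <= 1 + 1e-12
        assert 0 < self.p_value <= 1


def _anosim_r(ranks: np.ndarray, within_mask: np.ndarray, n: int) -> float:
    rb = ranks[~within_mask].mean()
    rw = ranks[within_mask].mean()
    return float((rb - rw) / (n * (n - 1) / 4.0))


def anosim(
    t: DescriptorTable,
    groups: Sequence,
    n_permutations: int = 999,
    seed: int = 0,
    fields: Optional[Sequence[str]] = None,
) -> AnosimResult:
    """Clarke's analysis of similarities on Euclidean distances.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    with mid-ranks for tied distances. The p-value is the fraction of
    label permutations (observed included) whose R is >= the observed R.
    """
    labels = np.asarray(groups)
    if len(labels) != len(t):
        raise InputError("one group label per record required")
    if len(np.unique(labels)) < 2:
        raise InputError("ANOSIM requires at least 2 groups")
    X = _numeric_frame(t, fields).values
    n = X.shape[0]
    d = pdist(X, metric="euclidean")
    ranks = stats.rankdata(d)  # mid-rank ties
    ii, jj = np.triu_indices(n, k=1)
    within = labels[ii] == labels[jj]
    r_obs = _anosim_r(ranks, within, n)

    rng = np.random.default_rng(seed)
    hits = 1  # observed permutation counts
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        w = perm[ii] == perm[jj]
        if _anosim_r(ranks, w, n) >= r_obs - 1e-12:
            hits += 1
    return AnosimResult(
        r_statistic=r_obs,
        p_value=hits / (n_permutations + 1),
        n_permutations=n_permutations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Hierarchical clustering (single linkage, Euclidean)

@dataclasses.dataclass(frozen=True)
class ClusterTree:
    """Merge sequence of agglomerative single-linkage clustering.

    ``merges[k] = (members_a, members_b, height)`` with members given as
    frozensets of leaf labels; heights are non-decreasing (single-linkage
    property). ``linkage_matrix`` is the scipy condensed form.
    """

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray
    dropped_fields: tuple[str, ...] = ()

    @property
    def merges(self) -> list[tuple[frozenset, frozenset, float]]:
        n = len(self.labels)
        members: dict[int, frozenset] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        out = []
        for k, (a, b, h, _) in enumerate(self.linkage_matrix):
            fa, fb = members[int(a)], members[int(b)]
            out.append((fa, fb, float(h)))
            members[n + k] = fa | fb
        return out

    def last_merging_singleton(self) -> str:
        """The leaf that joins the tree last (the most distant compound)."""
        n = len(self.labels)
        for a, b, _, _ in self.linkage_matrix[::-1]:
            for side in (int(a), int(b)):
                if side < n:
                    return self.labels[side]
        raise InputError("tree has no singleton merges")

    def to_merge_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_a": "+".join(sorted(a)),
                "cluster_b": "+".join(sorted(b)),
                "height": h,
            }
            for a, b, h in self.merges
        ]
        return pd.DataFrame(rows)

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as node depths."""
        n = len(self.labels)
        node_h = {i: 0.0 for i in range(n)}
        reps = {i: str(self.labels[i]).replace(",", "_").replace(" ", "_") for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = h - node_h[a]
            lb = h - node_h[b]
            reps[n + k] = f"({reps[a]}:{la:g},{reps[b]}:{lb:g})"
            node_h[n + k] = h
        return reps[n + len(self.linkage_matrix) - 1] + ";"


def cluster(
    t: DescriptorTable,
    standardize: bool = True,
    fields: Optional[Sequence[str]] = None,
) -> ClusterTree:
    """Single-linkage agglomerative clustering on Euclidean distances.

    With ``standardize`` (default) columns are z-scored (sample SD) and
    zero-variance columns dropped with a logged notice; without it, raw
    Euclidean distance is dominated by the largest-scale property.
    """
    if len(t) < 2:
        raise InputError("clustering requires at least 2 records")
    df = _numeric_frame(t, fields)
    dropped: tuple[str, ...] = ()
    if standardize:
        sds = df.std(ddof=1)
        constant = [c for c in df.columns if sds[c] == 0]
        if constant:
            logger.info("cluster: dropping zero-variance fields %s", constant)
            dropped = tuple(constant)
            df = df.drop(columns=constant)
        df = (df - df.mean()) / df.std(ddof=1)
    Z = linkage(df.values, method="single", metric="euclidean")
    return ClusterTree(
        labels=tuple(str(i) for i in df.index),
        linkage_matrix=Z,
        dropped_fields=dropped,
    )
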