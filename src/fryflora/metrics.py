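"""Normalization, alpha diversity, Yue-Clayton dissimilarity and group tests.

Alpha diversity follows the non-parametric estimators used throughout amplicon
surveys: Good's coverage ``C = 1 - F1/N``, bias-corrected Chao1 richness
``S_obs + F1(F1-1) / (2(F2+1))`` and the coverage-adjusted (Chao-Shen)
Shannon entropy in nats.  These estimators need integer singleton/doubleton
counts, so they are computed on raw pooled counts, not normalized values.

Depth normalization uses cumulative sum scaling (CSS): each sample is divided
by the cumulative count of its reads up to a chosen quantile of its nonzero
count distribution, which damps the influence of a few dominant taxa on
library-size correction.

Community comparison uses the Yue & Clayton theta similarity; the
dissimilarity reported everywhere is ``1 - theta``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.distance import DistanceMatrix

from .tables import CountTable

__all__ = [
    "AlphaRecord",
    "CssModel",
    "TrendFit",
    "GroupComparisonSummary",
    "goods_coverage",
    "chao1",
    "np_shannon",
    "alpha_table",
    "css_fit",
    "css_apply",
    "thetayc",
    "distance_matrix",
    "summarize_group_dissimilarity",
    "log_trend_fit",
    "welch_ttest",
    "letters",
]


def _as_counts(counts: Iterable[float]) -> np.ndarray:
    x = np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts)
    if x.size == 0:
        raise ValueError("empty count vector")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    return x.astype(float)


def goods_coverage(counts: Iterable[float]) -> float:
    """Good's coverage ``1 - F1/N``: estimated fraction of the community sampled."""
    x = _as_counts(counts)
    n = x.sum()
    if n <= 0:
        raise ValueError("total count must be positive")
    f1 = int((x == 1).sum())
    return 1.0 - f1 / n


def chao1(counts: Iterable[float]) -> float:
    """Bias-corrected Chao1 richness ``S_obs + F1(F1-1)/(2(F2+1))``."""
    x = _as_counts(counts)
    if not (x > 0).any():
        raise ValueError("need at least one positive count")
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def np_shannon(counts: Iterable[float]) -> float:
    """Coverage-adjusted (Chao-Shen) Shannon entropy in nats.

    With coverage ``C = 1 - F1/N`` and adjusted proportions ``p~ = C x / N``,
    the estimator is ``H = -sum p~ ln p~ / (1 - (1 - p~)^N)``; the denominator
    corrects for undetected occurrences.  When every read is a singleton the
    coverage is zero and the plug-in Shannon is returned with a warning.
    """
    x = _as_counts(counts)
    x = x[x > 0]
    n = x.sum()
    if n <= 0:
        raise ValueError("total count must be positive")
    c = 1.0 - (x == 1).sum() / n
    p = x / n
    if c == 0.0:
        warnings.warn("all reads are singletons; falling back to plug-in Shannon",
                      stacklevel=2)
        return float(-(p * np.log(p)).sum())
    pa = c * p
    denom = 1.0 - np.power(1.0 - pa, n)
    h = -(pa * np.log(pa)) / denom
    return float(h.sum())


@dataclass(frozen=True)
class AlphaRecord:
    sample_id: str
    np_shannon: float
    chao1: float
    goods_coverage: float
    observed_otus: int


def alpha_table(table: CountTable) -> pd.DataFrame:
    """Per-sample alpha-diversity summary on raw (pooled) counts."""
    rows = []
    for sample in table.sample_ids:
        x = table.data[sample].to_numpy()
        rows.append(
            AlphaRecord(
                sample_id=sample,
                np_shannon=np_shannon(x),
                chao1=chao1(x),
                goods_coverage=goods_coverage(x),
                observed_otus=int((x > 0).sum()),
            )
        )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Cumulative sum scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CssModel:
    """Fitted CSS normalization: per-sample quantiles and scaling factors."""

    percentile: float
    quantiles: pd.Series
    factors: pd.Series
    scale: float = 1000.0


def css_fit(table: CountTable | pd.DataFrame, percentile: float = 0.5,
            scale: float = 1000.0) -> CssModel:
    """Fit CSS scaling factors.

    For each sample j, ``q_j`` is the ``percentile`` quantile of its nonzero
    counts and ``s_j = sum of counts c_ij <= q_j``.  Samples with no nonzero
    count (or a zero quantile) are rejected.
    """
    if not 0.0 < percentile <= 1.0:
        raise ValueError("percentile must lie in (0, 1]")
    data = table.data if isinstance(table, CountTable) else table
    quantiles, factors = {}, {}
    for sample in data.columns:
        col = data[sample].to_numpy().astype(float)
        nz = col[col > 0]
        if nz.size == 0:
            raise ValueError(f"sample {sample!r} has no nonzero counts")
        q = float(np.quantile(nz, percentile))
        if q <= 0:
            raise ValueError(
                f"sample {sample!r}: zero quantile at percentile {percentile}; "
                "try a higher percentile"
            )
        quantiles[sample] = q
        factors[sample] = float(col[col <= q].sum())
    return CssModel(
        percentile=percentile,
        quantiles=pd.Series(quantiles),
        factors=pd.Series(factors),
        scale=scale,
    )


def css_apply(table: CountTable | pd.DataFrame, model: CssModel,
              log2p1: bool = False) -> pd.DataFrame:
    """Apply fitted CSS factors: ``c_ij / s_j * scale`` (optionally log2(x+1))."""
    data = table.data if isinstance(table, CountTable) else table
    missing = [s for s in data.columns if s not in model.factors.index]
    if missing:
        raise ValueError(f"samples without fitted factors: {missing[:5]}")
    norm = data.astype(float) / model.factors[data.columns] * model.scale
    if log2p1:
        norm = np.log2(norm + 1.0)
    return norm


# ---------------------------------------------------------------------------
# Yue-Clayton dissimilarity
# ---------------------------------------------------------------------------

def thetayc(x, y) -> float:
    """Yue-Clayton dissimilarity ``1 - sum(xy) / (sum x^2 + sum y^2 - sum(xy))``.

    ``x`` and ``y`` are proportion vectors over a shared OTU axis.  The value
    is symmetric, lies in [0, 1], is 0 for identical compositions and 1 for
    disjoint supports.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        if not x.index.equals(y.index):
            raise ValueError("mismatched OTU axes")
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("mismatched OTU axes")
    cross = float(xv @ yv)
    denom = float(xv @ xv) + float(yv @ yv) - cross
    if denom <= 0:
        raise ValueError("both vectors are zero")
    theta = cross / denom
    return float(min(1.0, max(0.0, 1.0 - theta)))


def distance_matrix(rel: pd.DataFrame, metric=thetayc) -> DistanceMatrix:
    """Pairwise dissimilarity over the sample columns of a proportion table."""
    samples = list(rel.columns)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    if metric is thetayc:
        mat = rel.to_numpy(dtype=float)
        cross = mat.T @ mat
        sq = np.diag(cross).copy()
        denom = sq[:, None] + sq[None, :] - cross
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = 1.0 - cross / denom
        dist = np.clip(dist, 0.0, 1.0)
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2.0
    else:
        n = len(samples)
        dist = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            d = metric(rel.iloc[:, i].to_numpy(), rel.iloc[:, j].to_numpy())
            dist[i, j] = dist[j, i] = d
    return DistanceMatrix(dist, ids=samples)


@dataclass(frozen=True)
class GroupComparisonSummary:
    """Mean/SE/SD of all cross-group pairwise dissimilarities."""

    label: str
    mean: float
    std_error: float
    std_deviation: float
    n_pairs: int
    degenerate: bool = False


def summarize_group_dissimilarity(dm: DistanceMatrix, group_a: Sequence[str],
                                  group_b: Sequence[str],
                                  label: str = "") -> GroupComparisonSummary:
    """Summarize cross-group dissimilarities between two disjoint sample sets."""
    a, b = list(group_a), list(group_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if set(a) & set(b):
        raise ValueError(f"groups overlap: {sorted(set(a) & set(b))[:5]}")
    values = np.array([dm[i, j] for i in a for j in b], dtype=float)
    n = values.size
    degenerate = n < 2
    sd = 0.0 if degenerate else float(values.std(ddof=1))
    return GroupComparisonSummary(
        label=label or "vs".join(["A", "B"]),
        mean=float(values.mean()),
        std_error=sd / np.sqrt(n),
        std_deviation=sd,
        n_pairs=n,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Trend fits and Welch tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendFit:
    """Least-squares fit of ``y = a + b ln(x + 1)`` with its R^2."""

    intercept: float
    slope: float
    r_squared: float


def log_trend_fit(x: Sequence[float], y: Sequence[float]) -> TrendFit:
    """Fit a logarithmic trend ``y = a + b ln(x+1)`` (x in days post-hatching)."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    if xv.size < 3:
        raise ValueError("need at least 3 points")
    if (xv < 0).any():
        raise ValueError("x must be non-negative")
    if np.allclose(xv, xv[0]):
        raise ValueError("all x values equal; trend undefined")
    t = np.log(xv + 1.0)
    slope, intercept = np.polyfit(t, yv, 1)
    pred = intercept + slope * t
    ss_res = float(((yv - pred) ** 2).sum())
    ss_tot = float(((yv - yv.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return TrendFit(intercept=float(intercept), slope=float(slope),
                    r_squared=float(max(0.0, min(1.0, r2))))


def welch_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Two-tailed Welch t-test (unequal variances).

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom.
    Degenerate zero-variance inputs: equal means give ``(0, df, 1)``, unequal
    means an infinite statistic with ``p = 0``.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.size < 2 or bv.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = av.var(ddof=1), bv.var(ddof=1)
    na, nb = av.size, bv.size
    se2 = va / na + vb / nb
    diff = av.mean() - bv.mean()
    if se2 == 0.0:
        df = float(na + nb - 2)
        if diff == 0.0:
            return 0.0, df, 1.0
        return float(np.sign(diff) * np.inf), df, 0.0
    t = diff / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(1.0, p))


def letters(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display over pairwise Welch t-tests.

    Groups sharing at least one letter are not significantly different at
    ``alpha``.  Letters are assigned to the maximal cliques of the
    non-significance graph, in a deterministic order.
    """
    names = list(groups)
    g = nx.Graph()
    g.add_nodes_from(range(len(names)))
    for i, j in itertools.combinations(range(len(names)), 2):
        _, _, p = welch_ttest(groups[names[i]], groups[names[j]])
        if p >= alpha:
            g.add_edge(i, j)
    cliques = sorted((sorted(c) for c in nx.find_cliques(g)), key=lambda c: (c[0], c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assigned: dict[int, list[str]] = {i: [] for i in range(len(names))}
    for letter, clique in zip(alphabet, cliques):
        for i in clique:
            assigned[i].append(letter)
    return {names[i]: "".join(assigned[i]) for i in range(len(names))}
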