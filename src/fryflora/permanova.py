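"""One-way permutational multivariate analysis of variance (PERMANOVA).

The pseudo-F statistic partitions the total sum of squared dissimilarities
``SS_T = (1/N) sum_{i<j} d_ij^2`` into within-group (``SS_W``, each group's
pair sum divided by its size) and between-group parts, and forms

    F = (SS_A / (a - 1)) / (SS_W / (N - a)).

Significance comes from shuffling group labels over samples; the permutation
p-value includes the observed statistic in numerator and denominator,
``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``, so p is never zero.  For
very small designs an exact p over all distinct label arrangements is
available as an oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

__all__ = ["PermanovaResult", "pseudo_f", "permanova", "permanova_exact"]


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    df_between: int
    df_within: int
    n_samples: int
    n_groups: int
    n_permutations: int
    seed: int | None
    ss_between: float
    ss_within: float
    ss_total: float


def _codes(dm: DistanceMatrix, grouping) -> np.ndarray:
    ids = list(dm.ids)
    if isinstance(grouping, Mapping):
        missing = [s for s in ids if s not in grouping]
        if missing:
            raise ValueError(f"labels missing for samples: {missing[:5]}")
        labels = [grouping[s] for s in ids]
    elif isinstance(grouping, pd.Series):
        missing = [s for s in ids if s not in grouping.index]
        if missing:
            raise ValueError(f"labels missing for samples: {missing[:5]}")
        labels = list(grouping[ids])
    else:
        labels = list(grouping)
        if len(labels) != len(ids):
            raise ValueError("grouping length does not match distance matrix")
    _, codes = np.unique(np.asarray(labels, dtype=object), return_inverse=True)
    return codes


def _validate(codes: np.ndarray) -> tuple[int, np.ndarray]:
    groups, sizes = np.unique(codes, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 2).any():
        small = groups[sizes < 2]
        raise ValueError(f"every group needs >= 2 samples (violated by group {small})")
    return len(groups), sizes


def _f_from_ssw(ss_w: np.ndarray, ss_t: float, n: int, a: int) -> np.ndarray:
    ss_a = ss_t - ss_w
    return (ss_a / (a - 1)) / (ss_w / (n - a))


def _ssw_batch(d2: np.ndarray, codes_batch: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Within-group sum of squares for a batch of label vectors (rows)."""
    ss_w = np.zeros(codes_batch.shape[0])
    for g, n_g in enumerate(sizes):
        mask = (codes_batch == g).astype(float)
        ss_w += ((mask @ d2) * mask).sum(axis=1) / (2.0 * n_g)
    return ss_w


def pseudo_f(dm: DistanceMatrix, grouping) -> float:
    """Observed pseudo-F for a one-way design on a distance matrix."""
    codes = _codes(dm, grouping)
    a, sizes = _validate(codes)
    d2 = np.asarray(dm.data, dtype=float) ** 2
    n = len(codes)
    ss_t = d2.sum() / (2.0 * n)
    ss_w = _ssw_batch(d2, codes[None, :], sizes)[0]
    return float(_f_from_ssw(np.array([ss_w]), ss_t, n, a)[0])


def permanova(dm: DistanceMatrix, grouping, n_perm: int = 10000,
              seed: int | None = None, batch_size: int = 2000) -> PermanovaResult:
    """One-way PERMANOVA with a seeded label-permutation test.

    Parameters
    ----------
    dm : symmetric dissimilarity matrix over samples
    grouping : mapping/Series sample -> group, or a label sequence aligned
        with ``dm.ids``; at least 2 groups of at least 2 samples
    n_perm : number of label permutations (the study standard is 10 000)
    seed : seed of the permutation stream, recorded in the result
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    codes = _codes(dm, grouping)
    a, sizes = _validate(codes)
    d2 = np.asarray(dm.data, dtype=float) ** 2
    n = len(codes)
    ss_t = d2.sum() / (2.0 * n)
    ss_w_obs = _ssw_batch(d2, codes[None, :], sizes)[0]
    f_obs = float(_f_from_ssw(np.array([ss_w_obs]), ss_t, n, a)[0])

    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(batch_size, n_perm - done)
        perm = rng.permuted(np.tile(codes, (b, 1)), axis=1)
        f_perm = _f_from_ssw(_ssw_batch(d2, perm, sizes), ss_t, n, a)
        exceed += int((f_perm >= f_obs).sum())
        done += b
    p = (1.0 + exceed) / (1.0 + n_perm)
    return PermanovaResult(
        pseudo_f=f_obs,
        p_value=float(p),
        df_between=a - 1,
        df_within=n - a,
        n_samples=n,
        n_groups=a,
        n_permutations=n_perm,
        seed=seed,
        ss_between=float(ss_t - ss_w_obs),
        ss_within=float(ss_w_obs),
        ss_total=float(ss_t),
    )


def permanova_exact(dm: DistanceMatrix, grouping, max_n: int = 9) -> tuple[float, float]:
    """Exact permutation p over all distinct label arrangements (small N only).

    Returns ``(F_obs, p_exact)`` where the enumeration includes the observed
    labelling.  Intended as an oracle for designs with at most ``max_n``
    samples.
    """
    codes = _codes(dm, grouping)
    a, sizes = _validate(codes)
    n = len(codes)
    if n > max_n:
        raise ValueError(f"exact enumeration limited to N <= {max_n}")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    ss_t = d2.sum() / (2.0 * n)
    arrangements = np.array(sorted({p for p in itertools.permutations(codes)}))
    f_all = _f_from_ssw(_ssw_batch(d2, arrangements, sizes), ss_t, n, a)
    f_obs = _f_from_ssw(_ssw_batch(d2, codes[None, :], sizes), ss_t, n, a)[0]
    p = float((f_all >= f_obs - 1e-12).sum() / len(f_all))
    return float(f_obs), p
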