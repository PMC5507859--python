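"""Parent-pair shared-OTU core statistics and breeding-state taxonomic shift.

During brood care both discus parents secrete the skin mucus their fry feed
on; the fraction of the mucus community shared between the two parents is a
proxy for a transient parental "core" microbiota.  Sharing between a sample
pair is measured either abundance-weighted (mean over the two samples of the
summed relative abundance of OTUs present in both; the default, matching how
the study reports its percentages) or count-based (Jaccard percentage of the
OTU sets).  A baseline comes from random pairs of non-breeding control fish.

The taxonomic shift ranks OTUs by the signed change in mean relative
abundance (percent) between breeding and non-breeding mucus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
import numpy as np
import pandas as pd

__all__ = [
    "PairSharing",
    "TaxShift",
    "pair_shared_fraction",
    "random_pair_baseline",
    "taxonomic_shift",
]

PERIODS = ("before_MF", "during_MF", "after_MF", "control_random")


@dataclass(frozen=True)
class PairSharing:
    pair: tuple[str, str]
    period: str
    mode: str
    shared_value: float  # percent, 0..100


def pair_shared_fraction(sample_a: pd.Series, sample_b: pd.Series,
                         mode: str = "abundance_weighted") -> float:
    """Percentage of community shared between two mucus samples.

    ``abundance_weighted``: mean over the two samples of the summed relative
    abundance of OTUs present in both (symmetric by construction).
    ``count_based``: ``|intersection| / |union| * 100`` of the presence sets.
    """
    if not sample_a.index.equals(sample_b.index):
        raise ValueError("samples must share an OTU axis")
    a = sample_a.to_numpy(dtype=float)
    b = sample_b.to_numpy(dtype=float)
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("empty sample")
    pa, pb = a / a.sum(), b / b.sum()
    both = (a > 0) & (b > 0)
    if mode == "abundance_weighted":
        return float((pa[both].sum() + pb[both].sum()) / 2.0 * 100.0)
    if mode == "count_based":
        union = (a > 0) | (b > 0)
        return float(both.sum() / union.sum() * 100.0)
    raise ValueError(f"unknown mode {mode!r}")


def random_pair_baseline(control: pd.DataFrame, n_pairs: int = 20,
                         seed: int | None = None,
                         mode: str = "abundance_weighted",
                         allow_replacement: bool = True) -> list[PairSharing]:
    """Sharing between random pairs of control (non-breeding) mucus samples.

    Pairs are distinct unordered sample pairs drawn without replacement from
    all possibilities; if fewer distinct pairs exist than ``n_pairs``, pairs
    are re-drawn with replacement (or an error is raised when
    ``allow_replacement=False``).  Reproducible given ``seed``.
    """
    samples = list(control.columns)
    if len(samples) < 2:
        raise ValueError("need at least 2 control samples")
    all_pairs = list(itertools.combinations(samples, 2))
    rng = np.random.default_rng(seed)
    if n_pairs <= len(all_pairs):
        idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    elif allow_replacement:
        idx = rng.choice(len(all_pairs), size=n_pairs, replace=True)
    else:
        raise ValueError(
            f"{n_pairs} pairs requested but only {len(all_pairs)} distinct pairs exist"
        )
    out = []
    for i in idx:
        a, b = all_pairs[int(i)]
        out.append(
            PairSharing(
                pair=(a, b), period="control_random", mode=mode,
                shared_value=pair_shared_fraction(control[a], control[b], mode),
            )
        )
    return out


@dataclass(frozen=True)
class TaxShift:
    otu_id: str
    taxon: str
    delta: float  # signed percent: mean breeding - mean non-breeding


def taxonomic_shift(breeding: pd.DataFrame, nonbreeding: pd.DataFrame,
                    top_n: int | None = None, taxonomy=None) -> list[TaxShift]:
    """Per-OTU signed change in mean relative abundance, breeding minus not.

    Both tables must be relative abundances on the same normalized scale;
    deltas are reported in percent and sorted by magnitude (descending),
    truncated at ``top_n`` when given.  When both groups are closed to 100%,
    deltas over all OTUs sum to zero.
    """
    if breeding.shape[1] == 0 or nonbreeding.shape[1] == 0:
        raise ValueError("both groups must be non-empty")
    if not breeding.index.equals(nonbreeding.index):
        raise ValueError("groups must share an OTU axis")
    delta = (breeding.mean(axis=1) - nonbreeding.mean(axis=1)) * 100.0
    order = sorted(delta.index, key=lambda o: (-abs(delta[o]), o))
    if top_n is not None:
        order = order[:top_n]
    return [
        TaxShift(
            otu_id=o,
            taxon=taxonomy.label(o) if taxonomy is not None else o,
            delta=float(delta[o]),
        )
        for o in order
    ]
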