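"""Reservoir attribution: shared OTUs, recruitment index, transmission screen.

The recruitment index asks, for a candidate microbial reservoir (tank water,
parental skin mucus, parental feces, adult diet) and a fry developmental
stage: of the OTUs shared between reservoir and fry, how large a slice of
each community do they represent?  With ``direction="fry_over_reservoir"``
(default) the index is

    mean over fry samples of the summed shared-OTU relative abundance
    ------------------------------------------------------------------
    mean over reservoir samples of the summed shared-OTU relative abundance

An index above 1 means the shared taxa occupy a larger community fraction in
the fry than in the reservoir, i.e. taxa that may be rare in the reservoir
have proliferated in the fry gut -- the signature of positive recruitment.
Significance is a two-tailed Welch t-test on the per-sample shared-OTU sums
(one-sample t against the singleton value when a compartment has one sample,
as the adult diet does in this study design).

The vertical-transmission candidate screen mirrors the published table logic:
OTUs shared between breeding-parent mucus and whole larvae during mucus
feeding, undetected in every water sample, and more abundant in larvae than
in the mucus -- ranked by the larvae/mucus abundance ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import welch_ttest
from .tables import CountTable, SampleRecord, Stage, STAGE_ORDER, assign_stage

__all__ = [
    "RESERVOIRS",
    "RESERVOIR_NICHES",
    "STAGE_FRY_NICHE",
    "RecruitmentResult",
    "TransmissionCandidate",
    "SourceAttribution",
    "shared_otus",
    "recruitment_index",
    "recruitment_screen",
    "significant_reservoirs",
    "niche_preference_ratio",
    "transmission_candidates",
    "most_abundant_source",
]

RESERVOIRS = ("water", "parent_mucus", "parent_feces", "adult_diet")

#: which metadata niche holds each reservoir's samples
RESERVOIR_NICHES = {
    "water": ("water",),
    "parent_mucus": ("breeding_mucus",),
    "parent_feces": ("adult_feces",),
    "adult_diet": ("adult_diet",),
}

#: which fry niche is sampled at each developmental stage
STAGE_FRY_NICHE = {
    Stage.PRE: "whole_fry",
    Stage.MUCUS: "whole_fry",
    Stage.POST_EARLY: "fry_feces",
    Stage.POST_LATE: "fry_feces",
}


def _present(rel: pd.DataFrame, min_presence: float = 0.0) -> pd.Series:
    """OTUs detected (> min_presence) in at least one sample column."""
    return (rel > min_presence).any(axis=1)


def shared_otus(fry: pd.DataFrame, reservoir: pd.DataFrame,
                min_presence: float = 0.0) -> set[str]:
    """OTUs detected in >= 1 sample of each compartment (shared OTU axis)."""
    if fry.shape[1] == 0 or reservoir.shape[1] == 0:
        raise ValueError("both compartments must contain samples")
    if not fry.index.equals(reservoir.index):
        raise ValueError("compartments must share an OTU axis")
    both = _present(fry, min_presence) & _present(reservoir, min_presence)
    return set(fry.index[both])


@dataclass(frozen=True)
class RecruitmentResult:
    reservoir: str
    stage: Stage | None
    shared_otus: frozenset[str]
    index: float | None
    p_value: float
    direction: str
    fry_mean: float
    reservoir_mean: float
    n_fry: int
    n_reservoir: int
    one_sample_test: bool = False

    @property
    def defined(self) -> bool:
        return self.index is not None


def _shared_sum_test(fry_sums: np.ndarray, res_sums: np.ndarray) -> tuple[float, bool]:
    """Two-tailed p for fry vs reservoir per-sample shared sums.

    Welch two-sample when both compartments have >= 2 samples; one-sample t
    against the singleton value otherwise; NaN if both are singletons.
    """
    if fry_sums.size >= 2 and res_sums.size >= 2:
        _, _, p = welch_ttest(fry_sums, res_sums)
        return p, False
    if fry_sums.size >= 2:
        res = stats.ttest_1samp(fry_sums, popmean=float(res_sums[0]))
        return float(res.pvalue), True
    if res_sums.size >= 2:
        res = stats.ttest_1samp(res_sums, popmean=float(fry_sums[0]))
        return float(res.pvalue), True
    return float("nan"), True


def recruitment_index(fry: pd.DataFrame, reservoir: pd.DataFrame,
                      stage: Stage | None = None, reservoir_name: str = "",
                      direction: str = "fry_over_reservoir",
                      min_presence: float = 0.0) -> RecruitmentResult:
    """Recruitment index of one reservoir at one fry stage.

    ``fry`` and ``reservoir`` are relative-abundance tables (columns are the
    compartment's samples, columns sum to 1).  An empty shared set yields an
    undefined index (``index=None``) rather than an error.
    """
    if direction not in ("fry_over_reservoir", "reservoir_over_fry"):
        raise ValueError(f"unknown direction {direction!r}")
    shared = shared_otus(fry, reservoir, min_presence)
    n_fry, n_res = fry.shape[1], reservoir.shape[1]
    if not shared:
        return RecruitmentResult(
            reservoir=reservoir_name, stage=stage, shared_otus=frozenset(),
            index=None, p_value=float("nan"), direction=direction,
            fry_mean=0.0, reservoir_mean=0.0, n_fry=n_fry, n_reservoir=n_res,
        )
    shared_list = sorted(shared)
    fry_sums = fry.loc[shared_list].sum(axis=0).to_numpy(dtype=float)
    res_sums = reservoir.loc[shared_list].sum(axis=0).to_numpy(dtype=float)
    fry_mean = float(fry_sums.mean())
    res_mean = float(res_sums.mean())
    if fry_mean <= 0 or res_mean <= 0:
        raise ValueError("shared-OTU mean abundance must be positive in both compartments")
    index = fry_mean / res_mean if direction == "fry_over_reservoir" else res_mean / fry_mean
    p, one_sample = _shared_sum_test(fry_sums, res_sums)
    return RecruitmentResult(
        reservoir=reservoir_name, stage=stage, shared_otus=frozenset(shared),
        index=float(index), p_value=p, direction=direction,
        fry_mean=fry_mean, reservoir_mean=res_mean,
        n_fry=n_fry, n_reservoir=n_res, one_sample_test=one_sample,
    )


def _stage_fry_columns(records: Sequence[SampleRecord], stage: Stage,
                       include_day0: bool = True) -> list[str]:
    cols = []
    for r in records:
        if r.niche != STAGE_FRY_NICHE[stage] or r.dph is None:
            continue
        if not include_day0 and r.dph == 0:
            continue
        if assign_stage(r.dph) is stage:
            cols.append(r.sample_id)
    return cols


def recruitment_screen(rel: pd.DataFrame, records: Sequence[SampleRecord],
                       direction: str = "fry_over_reservoir", alpha: float = 0.05,
                       include_day0: bool = True,
                       min_presence: float = 0.0) -> pd.DataFrame:
    """Recruitment index for every (reservoir, stage) pair of the study design.

    Returns a tidy frame with one row per pair and a ``significant`` flag:
    index > 1 (positive recruitment under the default direction) with Welch
    p below ``alpha``.
    """
    by_niche: dict[str, list[str]] = {}
    for r in records:
        if r.sample_id in rel.columns:
            by_niche.setdefault(r.niche, []).append(r.sample_id)
    rows = []
    for stage in STAGE_ORDER:
        fry_cols = [c for c in _stage_fry_columns(records, stage, include_day0)
                    if c in rel.columns]
        if not fry_cols:
            continue
        fry = rel[fry_cols]
        for reservoir in RESERVOIRS:
            res_cols = [c for niche in RESERVOIR_NICHES[reservoir]
                        for c in by_niche.get(niche, [])]
            if not res_cols:
                continue
            result = recruitment_index(
                fry, rel[res_cols], stage=stage, reservoir_name=reservoir,
                direction=direction, min_presence=min_presence,
            )
            positive = result.defined and result.index > 1.0
            rows.append(
                {
                    "stage": stage.value,
                    "reservoir": reservoir,
                    "n_shared": len(result.shared_otus),
                    "index": result.index,
                    "p_value": result.p_value,
                    "direction": direction,
                    "n_fry": result.n_fry,
                    "n_reservoir": result.n_reservoir,
                    "one_sample_test": result.one_sample_test,
                    "significant": bool(
                        positive and np.isfinite(result.p_value) and result.p_value < alpha
                    ),
                }
            )
    return pd.DataFrame(rows)


def significant_reservoirs(screen: pd.DataFrame) -> dict[str, list[str]]:
    """Stage -> reservoirs flagged as significantly recruited."""
    out: dict[str, list[str]] = {}
    for stage, sub in screen.groupby("stage", sort=False):
        out[stage] = sorted(sub.loc[sub["significant"], "reservoir"])
    return out


def niche_preference_ratio(numerator_abundances: Sequence[float],
                           denominator_abundances: Sequence[float]) -> float:
    """Ratio of mean per-sample relative abundances of one OTU in two niches.

    Used for the whole-larvae / breeding-mucus (WL/BDM) preference ratio.
    A zero denominator mean yields ``inf`` (flagged, excluded from rankings).
    """
    num = float(np.mean(np.asarray(numerator_abundances, dtype=float)))
    den = float(np.mean(np.asarray(denominator_abundances, dtype=float)))
    if den == 0.0:
        return float("inf")
    return num / den


@dataclass(frozen=True)
class TransmissionCandidate:
    """A vertically-transmitted symbiont candidate (abundances in percent)."""

    otu_id: str
    taxon: str
    mean_nbdm_pct: float
    mean_bdm_pct: float
    mean_wl_pct: float
    ratio_wl_bdm: float


def transmission_candidates(whole_larvae: pd.DataFrame, breeding_mucus: pd.DataFrame,
                            water_counts, nonbreeding_mucus: pd.DataFrame | None = None,
                            taxonomy=None, min_presence: float = 0.0,
                            ) -> list[TransmissionCandidate]:
    """Screen for mucus-to-fry vertical-transmission candidates.

    An OTU qualifies when it (1) is shared between breeding mucus and whole
    larvae during mucus feeding, (2) has zero detected counts in every water
    sample, and (3) has a higher mean relative abundance in the larvae than in
    the mucus.  ``whole_larvae`` and ``breeding_mucus`` are relative-abundance
    tables (proportions); ``water_counts`` a CountTable or count frame.
    Results are sorted by the WL/BDM ratio, descending.
    """
    water = water_counts.data if isinstance(water_counts, CountTable) else water_counts
    if whole_larvae.shape[1] == 0 or breeding_mucus.shape[1] == 0 or water.shape[1] == 0:
        raise ValueError("all three compartments must contain samples")
    shared = shared_otus(whole_larvae, breeding_mucus, min_presence)
    water_present = set(water.index[(water > 0).any(axis=1)])
    out = []
    for otu in sorted(shared - water_present):
        wl_mean = float(whole_larvae.loc[otu].mean()) * 100.0
        bdm_mean = float(breeding_mucus.loc[otu].mean()) * 100.0
        if wl_mean <= bdm_mean:
            continue
        nbdm_mean = (
            float(nonbreeding_mucus.loc[otu].mean()) * 100.0
            if nonbreeding_mucus is not None and otu in nonbreeding_mucus.index
            else float("nan")
        )
        ratio = niche_preference_ratio([wl_mean], [bdm_mean])
        out.append(
            TransmissionCandidate(
                otu_id=otu,
                taxon=taxonomy.label(otu) if taxonomy is not None else otu,
                mean_nbdm_pct=nbdm_mean,
                mean_bdm_pct=bdm_mean,
                mean_wl_pct=wl_mean,
                ratio_wl_bdm=float(ratio),
            )
        )
    out.sort(key=lambda c: (-c.ratio_wl_bdm, c.otu_id))
    return out


@dataclass(frozen=True)
class SourceAttribution:
    otu_id: str
    source: str
    tie: bool
    means: Mapping[str, float] = field(default_factory=dict)


def most_abundant_source(otu_id: str, sources: Mapping[str, pd.DataFrame],
                         ) -> SourceAttribution:
    """Label the candidate source compartment where an OTU is most abundant.

    ``sources`` maps compartment label -> relative-abundance table; the fixed
    tie-break order is the mapping's insertion order.  An OTU undetected in
    every source gets the label ``"undetected"``.
    """
    if not sources:
        raise ValueError("need at least one candidate source")
    means: dict[str, float] = {}
    for label, rel in sources.items():
        means[label] = float(rel.loc[otu_id].mean()) if otu_id in rel.index else 0.0
    best = max(means.values())
    if best <= 0.0:
        return SourceAttribution(otu_id=otu_id, source="undetected", tie=False, means=means)
    winners = [label for label, m in means.items() if m == best]
    return SourceAttribution(
        otu_id=otu_id, source=winners[0], tie=len(winners) > 1, means=means
    )
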