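"""Synthetic multi-niche amplicon survey generator with ground truth.

Emulates the study design of a discus-fish brood experiment: seven microbial
niches (tank water, breeding / non-breeding parental skin mucus, adult feces,
adult diet, whole fry, fry feces) sampled over 100 days post-hatching, three
technical replicates per biological sample, roughly a thousand OTUs and
per-replicate read depths in the low thousands.

Generative model, per biological sample:

* every niche has a sparse log-normal base composition over its OTU support;
* fry at each developmental stage are a mixture of reservoir contributions
  (water, parental mucus, adult diet) and an endogenous fry component.  A
  reservoir contributes through its *recruited subset* -- the top OTUs
  covering a configured fraction of its mass, renormalized -- so that shared
  taxa occupy a larger community fraction in the fry than in the reservoir
  (the signature the recruitment index detects);
* a configurable set of vertical-transmission OTUs is planted rare in
  breeding mucus, absent from water, and blooming in fry during mucus feeding;
* planted correlated blocks share a log-normal latent factor across samples;
* compositional noise is Dirichlet (per biological sample), counts are
  multinomial draws at a negative-binomial depth, and technical replicates
  are independent multinomial draws from the same biological composition.

Everything is deterministic given the scenario seed, and every planted
structure is reported in a machine-readable :class:`GroundTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import CountTable, SampleRecord, Stage

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "default_discus_scenario",
    "simulate_scenario",
    "simulate_block_community",
]

#: fry sampling schedule of the emulated experiment (days post-hatching)
FRY_WHOLE_DAYS = (0, 2, 6, 9, 13, 16, 20)
FRY_FECES_DAYS = (50, 54, 66, 69, 75, 82, 89, 96, 100)
WATER_DAYS = (0, 2, 6, 9, 13, 16, 20, 50, 54, 66, 69, 75, 82, 89, 96, 100)
ADULT_FECES_DAYS = (0, 13, 20, 54, 75, 82, 96, 100)
#: breeder mucus schedule: (day or None for T0, breeding period)
MUCUS_SCHEDULE = ((None, "before"), (2, "during"), (14, "during"), (50, "after"))

_RESERVOIR_KEYS = ("water", "parent_mucus", "adult_diet")


def _default_stage_weights() -> dict[str, dict[str, float]]:
    # Mixture weights over {water, parent_mucus, adult_diet, endogenous}; the
    # dominant reservoir per stage mirrors the ontogeny the index must recover:
    # water-dominated before mucus feeding, mucus-dominated during, and
    # diet-dominated after weaning.
    return {
        Stage.PRE.value: {"water": 0.80, "parent_mucus": 0.02,
                          "adult_diet": 0.03, "endogenous": 0.15},
        Stage.MUCUS.value: {"water": 0.06, "parent_mucus": 0.64,
                            "adult_diet": 0.04, "endogenous": 0.26},
        Stage.POST_EARLY.value: {"water": 0.04, "parent_mucus": 0.02,
                                 "adult_diet": 0.62, "endogenous": 0.32},
        Stage.POST_LATE.value: {"water": 0.03, "parent_mucus": 0.015,
                                "adult_diet": 0.60, "endogenous": 0.355},
    }


def _default_transmission_fry_mass() -> dict[str, float]:
    # Fraction of the fry community carried by the planted transmission OTUs
    # at each stage (carved out of the parent_mucus mixture weight); the bloom
    # happens during mucus feeding, with a small persistent remnant afterwards.
    return {
        Stage.PRE.value: 0.0,
        Stage.MUCUS.value: 0.34,
        Stage.POST_EARLY.value: 0.01,
        Stage.POST_LATE.value: 0.005,
    }


def _default_support_sizes() -> dict[str, int]:
    return {
        "water": 120,
        "mucus_core": 60,
        "mucus_individual": 40,
        "control_individual": 30,
        "adult_feces": 100,
        "adult_diet": 80,
        "endog_early": 40,
        "endog_late": 60,
        "background": 300,
        "background_per_niche": 80,
    }


def _default_core_weights() -> dict[str, float]:
    # Mass of the shared parental mucus core by breeding period; the core
    # tightens during brood care and relaxes afterwards.
    return {"before": 0.16, "during": 0.29, "after": 0.20, "control": 0.20}


@dataclass
class ScenarioConfig:
    """Parameters of a simulated multi-niche survey.

    The defaults reproduce the emulated study's layout: 53 biological samples
    (16 water, 4 breeding mucus, 8 non-breeding mucus, 8 adult feces, 1 adult
    diet, 7 whole fry, 9 fry feces), 3 technical replicates each, ~1000 OTUs
    and negative-binomial read depths with mean 3000 per replicate.
    """

    seed: int
    n_otus: int = 1000
    replicates: int = 3
    depth_mean: float = 3000.0
    depth_dispersion: float = 20.0
    dirichlet_concentration: float = 400.0
    lognormal_sigma: float = 1.5
    recruited_mass_fraction: float = 0.4
    support_sizes: dict[str, int] = field(default_factory=_default_support_sizes)
    stage_weights: dict[str, dict[str, float]] = field(
        default_factory=_default_stage_weights)
    transmission_n: int = 12
    transmission_mucus_abundance: float = 1e-4
    transmission_sigma: float = 0.8
    transmission_fry_mass: dict[str, float] = field(
        default_factory=_default_transmission_fry_mass)
    mucus_core_weight: dict[str, float] = field(default_factory=_default_core_weights)
    mucus_cross_seed: float = 0.04
    diet_in_feces_mass: float = 0.05
    background_mass: float = 0.02
    blocks: tuple[tuple[int, float], ...] = ((6, 1.0), (6, 1.0))
    n_control_fish: int = 4
    water_days: tuple[int, ...] = WATER_DAYS
    fry_whole_days: tuple[int, ...] = FRY_WHOLE_DAYS
    fry_feces_days: tuple[int, ...] = FRY_FECES_DAYS
    adult_feces_days: tuple[int, ...] = ADULT_FECES_DAYS

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a scenario seed is mandatory")
        for stage, weights in self.stage_weights.items():
            total = sum(weights.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"stage {stage}: mixture weights sum to {total}, not 1")
            trans = self.transmission_fry_mass.get(stage, 0.0)
            if trans > weights["parent_mucus"] + 1e-12:
                raise ValueError(
                    f"stage {stage}: transmission mass {trans} exceeds the "
                    f"parent_mucus weight {weights['parent_mucus']}"
                )
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")


@dataclass
class GroundTruth:
    """Machine-readable record of every structure planted by the generator."""

    stage_reservoir: dict[str, str]
    transmission_otus: list[str]
    blocks: list[list[str]]
    niche_mean_composition: pd.DataFrame

    def to_json(self, path: str | Path) -> None:
        doc = {
            "stage_reservoir": self.stage_reservoir,
            "transmission_otus": self.transmission_otus,
            "blocks": self.blocks,
            "niche_mean_composition": {
                niche: {o: float(v) for o, v in col.items() if v > 0}
                for niche, col in self.niche_mean_composition.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        comp = pd.DataFrame(doc["niche_mean_composition"]).fillna(0.0)
        return cls(
            stage_reservoir=doc["stage_reservoir"],
            transmission_otus=doc["transmission_otus"],
            blocks=[list(b) for b in doc["blocks"]],
            niche_mean_composition=comp,
        )


def default_discus_scenario(seed: int = 714) -> ScenarioConfig:
    """The stock scenario: the emulated study's full 53-sample layout."""
    return ScenarioConfig(seed=seed)


# ---------------------------------------------------------------------------
# profile machinery
# ---------------------------------------------------------------------------

def _lognormal_profile(rng: np.random.Generator, n_total: int,
                       support: np.ndarray, sigma: float) -> np.ndarray:
    profile = np.zeros(n_total)
    weights = rng.lognormal(mean=0.0, sigma=sigma, size=support.size)
    profile[support] = weights / weights.sum()
    return profile


def _recruited_subset(profile: np.ndarray, mass_fraction: float) -> np.ndarray:
    """Renormalized top-mass slice of a profile (the 'recruitable' taxa)."""
    order = np.argsort(-profile, kind="stable")
    cum = np.cumsum(profile[order])
    cutoff = int(np.searchsorted(cum, mass_fraction)) + 1
    keep = order[:cutoff]
    out = np.zeros_like(profile)
    out[keep] = profile[keep]
    return out / out.sum()


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray,
               fallback: np.ndarray) -> np.ndarray:
    """Dirichlet draw via gammas, safe against underflow at tiny alphas."""
    draw = rng.standard_gamma(alpha)
    total = draw.sum()
    if not np.isfinite(total) or total <= 0:
        return fallback / fallback.sum()
    return draw / total


def _mix(parts: Sequence[tuple[float, np.ndarray]]) -> np.ndarray:
    out = np.zeros_like(parts[0][1])
    for w, profile in parts:
        if w > 0:
            out += w * profile
    total = out.sum()
    if total <= 0:
        raise ValueError("degenerate composition")
    return out / total


class _SampleDraw:
    """Draws counts for biological samples under one scenario's noise model.

    ``pinned`` OTUs (the planted vertical-transmission taxa, whose mucus
    abundance is modelled as host-controlled secretion) keep their exact
    composition value instead of receiving Dirichlet noise; without pinning,
    taxa at ~1e-4 abundance get burst-like realizations (Dirichlet alpha far
    below 1) and would be structurally undetectable in small compartments.
    """

    def __init__(self, cfg: ScenarioConfig, rng: np.random.Generator,
                 block_members: list[np.ndarray], block_loadings: list[float],
                 pinned: np.ndarray | None = None):
        self.cfg = cfg
        self.rng = rng
        self.block_members = block_members
        self.block_loadings = block_loadings
        self.pinned = pinned if pinned is not None else np.array([], dtype=int)

    def replicate_columns(self, composition: np.ndarray, bio_id: str,
                          perturb_blocks: bool = True) -> dict[str, np.ndarray]:
        comp = composition.copy()
        if perturb_blocks:
            for members, loading in zip(self.block_members, self.block_loadings):
                present = comp[members] > 0
                if present.any():
                    z = self.rng.normal()
                    comp[members] *= np.exp(loading * z)
            comp = comp / comp.sum()
        pinned_mask = np.zeros_like(comp, dtype=bool)
        pinned_mask[self.pinned] = True
        pinned_mask &= comp > 0
        pinned_mass = comp[pinned_mask].sum()
        free = (comp > 0) & ~pinned_mask
        alpha = self.cfg.dirichlet_concentration * comp[free]
        draw = _dirichlet(self.rng, alpha, comp[free])
        p = np.zeros_like(comp)
        p[free] = draw * (1.0 - pinned_mass)
        p[pinned_mask] = comp[pinned_mask]
        cols = {}
        disp = self.cfg.depth_dispersion
        for r in range(1, self.cfg.replicates + 1):
            depth = int(self.rng.negative_binomial(
                disp, disp / (disp + self.cfg.depth_mean)))
            depth = max(depth, 1)
            cols[f"{bio_id}_r{r}"] = self.rng.multinomial(depth, p)
        return cols


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def simulate_scenario(config: ScenarioConfig,
                      ) -> tuple[CountTable, list[SampleRecord], GroundTruth]:
    """Simulate replicate-level counts, metadata and ground truth.

    Returns the replicate-level count table (pool with
    :func:`fryflora.tables.pool_replicates` before analysis), one metadata
    record per replicate column, and the planted ground truth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.support_sizes
    n = cfg.n_otus

    # ---- OTU index allocation -------------------------------------------
    cursor = 0

    def take(count: int) -> np.ndarray:
        nonlocal cursor
        if cursor + count > n:
            raise ValueError("n_otus too small for the configured supports")
        block = np.arange(cursor, cursor + count)
        cursor += count
        return block

    idx_water = take(sizes["water"])
    idx_mucus_core = take(sizes["mucus_core"])
    idx_ind = {fish: take(sizes["mucus_individual"]) for fish in ("F1", "F2")}
    idx_ctrl = {f"C{i+1}": take(sizes["control_individual"])
                for i in range(cfg.n_control_fish)}
    idx_feces = take(sizes["adult_feces"])
    idx_diet = take(sizes["adult_diet"])
    idx_endog_early = take(sizes["endog_early"])
    idx_endog_late = take(sizes["endog_late"])
    idx_trans = take(cfg.transmission_n)
    n_bg = min(sizes["background"], n - cursor)
    idx_bg = take(n_bg)
    otu_ids = [f"OTU_{i+1:04d}" for i in range(n)]

    sig = cfg.lognormal_sigma
    per_niche_bg = min(sizes["background_per_niche"], n_bg)

    def bg_profile() -> np.ndarray:
        chosen = rng.choice(idx_bg, size=per_niche_bg, replace=False)
        return _lognormal_profile(rng, n, np.sort(chosen), sig)

    # ---- niche base profiles --------------------------------------------
    water_core = _lognormal_profile(rng, n, idx_water, sig)
    mucus_core = _lognormal_profile(rng, n, idx_mucus_core, sig)
    individual = {fish: _lognormal_profile(rng, n, idx, sig)
                  for fish, idx in {**idx_ind, **idx_ctrl}.items()}
    feces_core = _lognormal_profile(rng, n, idx_feces, sig)
    diet_core = _lognormal_profile(rng, n, idx_diet, sig)
    endog = {
        "early": _lognormal_profile(rng, n, idx_endog_early, sig),
        "late": _lognormal_profile(rng, n, idx_endog_late, sig),
    }
    # mucus-side dose: equal (host-controlled secretion at the configured
    # rare abundance); fry-side bloom: log-normal spread, giving the varied
    # larvae/mucus amplification ratios seen in transmission tables
    trans_mucus = np.zeros(n)
    trans_mucus[idx_trans] = 1.0 / len(idx_trans)
    trans_fry = _lognormal_profile(rng, n, idx_trans, cfg.transmission_sigma)
    bg = {niche: bg_profile() for niche in
          ("water", "mucus", "adult_feces", "adult_diet")}

    bgm = cfg.background_mass
    core_w = cfg.mucus_core_weight

    def mucus_profile(fish: str, period: str) -> np.ndarray:
        w_core = core_w["control" if fish.startswith("C") else period]
        trans_mass = (cfg.transmission_n * cfg.transmission_mucus_abundance
                      if period == "during" and not fish.startswith("C") else 0.0)
        w_ind = 1.0 - w_core - bgm - trans_mass
        parts = [(w_core, mucus_core), (w_ind, individual[fish]), (bgm, bg["mucus"])]
        if trans_mass > 0:
            parts.append((trans_mass, trans_mucus))
        return _mix(parts)

    bdm_mean = (mucus_profile("F1", "during") + mucus_profile("F2", "during")) / 2.0
    # fry feed on BOTH parents, so the recruitable mucus bulk is the shared
    # parental core (present in every breeding-mucus sample), not either
    # fish's individual flora
    mucus_recruited = _recruited_subset(mucus_core, cfg.recruited_mass_fraction)

    # dominant (recruitable) mucus taxa also occur in the tank water, so the
    # transmission screen's "absent from water" criterion can reject them
    water_profile = _mix([
        (1.0 - bgm - cfg.mucus_cross_seed, water_core),
        (bgm, bg["water"]),
        (cfg.mucus_cross_seed, mucus_recruited),
    ])
    diet_profile = _mix([(1.0 - bgm, diet_core), (bgm, bg["adult_diet"])])
    diet_recruited = _recruited_subset(diet_profile, cfg.recruited_mass_fraction)
    # the non-recruited diet tail passes through the adult gut into the feces;
    # this keeps those taxa in >= 2 samples (they survive the prevalence
    # filter) without seeding the fry-dominant recruited slice anywhere else
    diet_tail = diet_profile.copy()
    diet_tail[diet_recruited > 0] = 0.0
    if diet_tail.sum() > 0:
        diet_tail /= diet_tail.sum()
    feces_profile = _mix([
        (1.0 - bgm - cfg.diet_in_feces_mass, feces_core),
        (cfg.diet_in_feces_mass, diet_tail),
        (bgm, bg["adult_feces"]),
    ])

    water_recruited = _recruited_subset(water_profile, cfg.recruited_mass_fraction)

    def fry_composition(stage: Stage) -> np.ndarray:
        w = cfg.stage_weights[stage.value]
        trans_mass = cfg.transmission_fry_mass.get(stage.value, 0.0)
        endog_profile = endog["early"] if stage in (Stage.PRE, Stage.MUCUS) else endog["late"]
        parts = [
            (w["water"], water_recruited),
            (w["parent_mucus"] - trans_mass, mucus_recruited),
            (trans_mass, trans_fry),
            (w["adult_diet"], diet_recruited),
            (w["endogenous"], endog_profile),
        ]
        return _mix(parts)

    # ---- planted correlation blocks -------------------------------------
    # members come from mid-rank water taxa: abundant enough to be detected,
    # outside the recruited top slice so they do not destabilize fry mixtures
    water_order = np.argsort(-water_core, kind="stable")
    block_members, block_loadings = [], []
    offset = 20
    for size, loading in cfg.blocks:
        members = water_order[offset:offset + size]
        block_members.append(np.sort(members))
        block_loadings.append(float(loading))
        offset += size

    draw = _SampleDraw(cfg, rng, block_members, block_loadings, pinned=idx_trans)

    # ---- biological sample layout ---------------------------------------
    columns: dict[str, np.ndarray] = {}
    records: list[SampleRecord] = []
    truth_comp: dict[str, np.ndarray] = {}

    def add(bio_id: str, niche: str, dph: int | None, sample_type: str,
            composition: np.ndarray) -> None:
        for rep_id, counts in draw.replicate_columns(composition, bio_id).items():
            columns[rep_id] = counts
            records.append(SampleRecord(
                sample_id=rep_id, niche=niche, dph=dph,
                sample_type=sample_type, replicate_group=bio_id,
            ))

    for day in cfg.water_days:
        add(f"W_{day:03d}", "water", day, "water", water_profile)
    truth_comp["water"] = water_profile

    for fish in ("F1", "F2"):
        for day, period in MUCUS_SCHEDULE:
            niche = "breeding_mucus" if period == "during" else "nonbreeding_mucus"
            label = "T0" if day is None else f"{day:03d}"
            add(f"M_{fish}_{label}", niche, day, "mucus", mucus_profile(fish, period))
    for fish in sorted(idx_ctrl):
        add(f"M_{fish}_T0", "nonbreeding_mucus", None, "mucus",
            mucus_profile(fish, "control"))
    truth_comp["breeding_mucus"] = bdm_mean
    truth_comp["nonbreeding_mucus"] = _mix([
        (0.5, (mucus_profile("F1", "before") + mucus_profile("F2", "before")) / 2.0),
        (0.5, sum(mucus_profile(f, "control") for f in sorted(idx_ctrl))
         / len(idx_ctrl)),
    ])

    for day in cfg.adult_feces_days:
        add(f"AF_{day:03d}", "adult_feces", day, "feces", feces_profile)
    truth_comp["adult_feces"] = feces_profile

    add("AD_T0", "adult_diet", None, "diet", diet_profile)
    truth_comp["adult_diet"] = diet_profile

    for day in cfg.fry_whole_days:
        stage = Stage.PRE if day <= 3 else Stage.MUCUS
        add(f"WF_{day:03d}", "whole_fry", day, "whole_organism", fry_composition(stage))
    for day in cfg.fry_feces_days:
        stage = Stage.POST_EARLY if day < 80 else Stage.POST_LATE
        add(f"FF_{day:03d}", "fry_feces", day, "feces", fry_composition(stage))
    for stage in (Stage.PRE, Stage.MUCUS, Stage.POST_EARLY, Stage.POST_LATE):
        truth_comp[f"fry_{stage.value}"] = fry_composition(stage)

    table = CountTable(
        pd.DataFrame(columns, index=otu_ids, dtype=np.int64), validate=False
    )

    stage_reservoir = {
        stage: max(_RESERVOIR_KEYS, key=lambda r: cfg.stage_weights[stage][r])
        for stage in cfg.stage_weights
    }
    truth = GroundTruth(
        stage_reservoir=stage_reservoir,
        transmission_otus=[otu_ids[i] for i in idx_trans],
        blocks=[[otu_ids[i] for i in members] for members in block_members],
        niche_mean_composition=pd.DataFrame(truth_comp, index=otu_ids),
    )
    return table, records, truth


# ---------------------------------------------------------------------------
# single-niche correlated-block benchmark
# ---------------------------------------------------------------------------

def simulate_block_community(seed: int, n_samples: int = 40, n_otus: int = 100,
                             n_blocks: int = 2, block_size: int = 6,
                             loading: float = 1.0,
                             concentration: float = 2000.0,
                             depth_mean: float = 9000.0,
                             depth_dispersion: float = 30.0,
                             lognormal_sigma: float = 1.5,
                             ) -> tuple[CountTable, list[SampleRecord], GroundTruth]:
    """One-niche community with planted latent-factor correlation blocks.

    The benchmark behind network-recovery checks: each block of OTUs shares a
    multiplicative log-normal factor ``exp(loading * z_s)`` across samples
    (per-sample ``z_s ~ N(0,1)``), giving pairwise Spearman correlations near
    ``1 / (1 + sigma_noise^2 / loading^2)`` before counting noise.  Block
    members are placed among the dominant OTUs so they fall inside a top-50
    candidate list.  ``loading=0`` removes the planted structure (null case).
    """
    rng = np.random.default_rng(seed)
    base_w = rng.lognormal(0.0, lognormal_sigma, size=n_otus)
    base = base_w / base_w.sum()
    order = np.argsort(-base, kind="stable")
    block_members = [np.sort(order[3 + b * block_size: 3 + (b + 1) * block_size])
                     for b in range(n_blocks)]
    otu_ids = [f"OTU_{i+1:04d}" for i in range(n_otus)]

    columns: dict[str, np.ndarray] = {}
    records = []
    for s in range(n_samples):
        comp = base.copy()
        for members in block_members:
            comp[members] *= np.exp(loading * rng.normal())
        comp /= comp.sum()
        p = _dirichlet(rng, concentration * comp, comp)
        depth = max(int(rng.negative_binomial(
            depth_dispersion, depth_dispersion / (depth_dispersion + depth_mean))), 1)
        sid = f"S_{s+1:03d}"
        columns[sid] = rng.multinomial(depth, p)
        records.append(SampleRecord(sample_id=sid, niche="water", dph=None,
                                    sample_type="water", replicate_group=sid))
    table = CountTable(pd.DataFrame(columns, index=otu_ids, dtype=np.int64),
                       validate=False)
    truth = GroundTruth(
        stage_reservoir={},
        transmission_otus=[],
        blocks=[[otu_ids[i] for i in members] for members in block_members],
        niche_mean_composition=pd.DataFrame({"community": base}, index=otu_ids),
    )
    return table, records, truth
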