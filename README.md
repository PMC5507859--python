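# fryflora

Multi-niche OTU-table analytics for fish gut-microbiota **ontogeny**: how a
developing fish acquires its gut community from the microbial reservoirs
around it — tank water, parental skin mucus, parental feces and the adult
diet.

The motivating system is a mucus-feeding cichlid brood (discus,
*Symphysodon aequifasciata*): free-swimming fry feed exclusively on a
cutaneous mucus secretion from **both** parents for roughly three weeks
post-hatching, opening a vertical transmission route for skin-mucus
symbionts alongside the usual horizontal recruitment from water and food.
`fryflora` packages the downstream analytics such a study needs, for anyone
with 16S OTU count tables from a multi-compartment, multi-timepoint design:

* **tables** — count-table containers and I/O (wide TSV, mothur `.shared`,
  BIOM-JSON v1.0), technical-replicate pooling, the accuracy filters
  (drop OTUs with <50 reads or occurring in a single sample; drop samples
  under 500 reads), developmental-stage binning (0–3, 4–20, 50–80,
  80–100 days post-hatching) and taxonomy labels.
* **metrics** — cumulative sum scaling (CSS) normalization; Good's coverage
  `C = 1 − F1/N`; bias-corrected Chao1 `S_obs + F1(F1−1)/(2(F2+1))`;
  coverage-adjusted (Chao–Shen) non-parametric Shannon entropy; the
  Yue–Clayton dissimilarity
  `1 − θ_YC`, `θ_YC = Σxy / (Σx² + Σy² − Σxy)`; logarithmic trend fits
  `y = a + b·ln(x+1)`; Welch t-tests with compact letter displays.
* **permanova** — one-way PERMANOVA on any distance matrix:
  `F = (SS_A/(a−1)) / (SS_W/(N−a))` with a seeded label-permutation test and
  an exact-enumeration oracle for small designs.
* **recruitment** — the reservoir **recruitment index**: for the OTUs shared
  between fry and a reservoir, the ratio of the mean summed relative
  abundance in the fry over that in the reservoir.  An index above 1 means
  taxa that are rare in the reservoir have proliferated in the fry gut.
  Plus the vertical-transmission candidate screen (shared with breeding
  mucus, absent from water, amplified in larvae) and most-abundant-source
  attribution.
* **conetwork** — co-abundance networks over the 50 most abundant OTUs:
  Spearman ρ ≥ 0.9 with Bonferroni-corrected p ≤ 1e-4 (1225 tests at k=50),
  provenance labelling per developmental stage, GraphML/TSV export.
* **mucus_core** — parent-pair shared-OTU fractions (abundance-weighted or
  Jaccard), random control-pair baselines, and the breeding-state taxonomic
  shift ranking.
* **synthetic** — a fully ground-truthed generator emulating the study
  design (53 biological samples across 7 niches, 3 technical replicates,
  ~1000 OTUs, negative-binomial depths near 3000 reads): planted
  transmission OTUs, planted correlated OTU blocks, per-stage reservoir
  mixtures, Dirichlet-multinomial noise.
* **pipeline / CLI** — `fryflora simulate|qc|normalize|alpha|beta|permanova|
  recruit|network|mucus|all`, writing reproducible, manifest-tracked run
  directories.

## Worked example

Simulate the stock scenario, apply QC and CSS, and ask which reservoir the
fry draw on at each developmental stage:

```python
import fryflora as ff
from fryflora.tables import (pool_replicates, pooled_records,
                             filter_samples, filter_otus)

cfg = ff.default_discus_scenario(seed=1)
table, records, truth = ff.simulate_scenario(cfg)

pooled = pool_replicates(table, records)              # 159 replicates -> 53 samples
qc = filter_otus(filter_samples(pooled, min_depth=500))
meta = [r for r in pooled_records(records) if r.sample_id in qc.sample_ids]

norm = ff.css_apply(qc, ff.css_fit(qc))
rel = norm / norm.sum(axis=0)

screen = ff.recruitment_screen(rel, meta)
print(screen[screen.significant][["stage", "reservoir", "n_shared",
                                  "index", "p_value"]].to_string(index=False))
```

```
           stage    reservoir  n_shared  index      p_value
   pre_mucus_0_3        water        11   2.16 1.509264e-12
      mucus_4_20 parent_mucus        14   5.62 3.402170e-07
post_early_50_80   adult_diet         4   1.30 1.515077e-05
post_late_80_100   adult_diet         4   1.24 2.855608e-03
```

Reading this: before mucus feeding (0–3 DPH) the 11 OTUs shared with the
tank water occupy 2.16× more of the fry community than of the water —
water-borne taxa have been preferentially recruited.  During mucus feeding
(4–20 DPH) the parental mucus takes over (index 5.6, Welch p ≈ 3e-7), and
after weaning the adult diet does.  The generator planted exactly this
ontogeny, and `truth.stage_reservoir` confirms the recovery.

The vertical-transmission screen on the same run finds the planted
mucus-to-fry OTUs:

```python
from fryflora.tables import Stage
wl    = [r.sample_id for r in meta if r.niche == "whole_fry" and r.stage is Stage.MUCUS]
bdm   = [r.sample_id for r in meta if r.niche == "breeding_mucus"]
water = [r.sample_id for r in meta if r.niche == "water"]
cands = ff.transmission_candidates(rel[wl], rel[bdm], qc.subset(samples=water))
print(len(cands), cands[0].otu_id, cands[0].mean_bdm_pct, cands[0].mean_wl_pct)
# 12 OTU_0663 0.003 2.70   (0.003% of the mucus, 2.7% of the larvae)
```

All 12 recovered candidates are planted transmission OTUs (precision and
recall 1.0 at this seed).

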