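# Methods

This note documents the statistical procedures `fryflora` implements, the
choices made where the design was genuinely open, the generative model behind
the synthetic scenario, and what the passing test suite does and does not
demonstrate about real data.

## Data model and QC

A survey is an OTU × sample matrix of raw read counts plus per-sample
metadata: microbial niche (water, breeding mucus, non-breeding mucus, adult
feces, adult diet, whole fry, fry feces), days post-hatching (DPH), sample
type, and a replicate group shared by the technical replicates of one
biological sample.

Processing order is **pool replicates → drop shallow samples → drop
low-information OTUs**.  Pooling sums replicate columns (read totals are
conserved).  Samples under 500 reads are discarded, then OTUs with fewer
than 50 reads in total or detected in fewer than 2 samples.  Filtering
samples first prevents a later-discarded sample from rescuing an OTU's
prevalence count.  Boundary semantics: "fewer than 50" keeps exactly 50;
"only one sample" keeps presence in two.  Presence means count ≥ 1 after
pooling; the threshold is configurable (`min_presence_count`) because no
canonical definition exists for amplicon data.

Fry samples are binned into four developmental stages around the
mucus-feeding window: 0–3 DPH (pre), 4–20 (mucus feeding), 50–79 (early
post) and 80–100 (late post).  Day 80 goes to the late bin — the sampled
days (…, 75 | 82, …) leave the nominal 50–80/80–100 overlap moot.  Days in
the unsampled 21–49 gap are rejected rather than guessed.  Eggs (day 0)
count as pre-stage fry by default, with a switch (`include_day0`) since a
case can be made for excluding unhatched individuals from fry statistics.

## Normalization

Cumulative sum scaling (CSS) corrects depth differences by dividing each
sample by the cumulative count of its reads up to a quantile of its nonzero
count distribution (default percentile l = 0.5, the reference method's
default; the adaptive-percentile search is deliberately out of scope), times
a fixed output scale (1000).  Scaling factors must be positive; a zero
quantile aborts with a pointer to a higher percentile.

One structural note: CSS is a per-sample scalar, so any analysis that
re-closes columns to proportions (as the Yue–Clayton distance requires)
cancels it exactly — the CSS-re-closed table equals the plain
relative-abundance table.  The pipeline still normalizes and re-closes
explicitly, both for faithfulness to standard practice and because the CSS
matrix itself (not re-closed, optionally log2(x+1)) is a useful export.

Alpha diversity is computed on **raw pooled counts**, not CSS output:
Good's coverage, Chao1 and the coverage-adjusted Shannon all need integer
singleton/doubleton counts, which scaling destroys.  Both paths exist; raw
is the default.

## Estimators

* Good's coverage `C = 1 − F1/N` (F1 singleton OTUs, N reads).
* Chao1, bias-corrected: `S_obs + F1(F1−1)/(2(F2+1))`; always ≥ S_obs, with
  equality iff F1 ≤ 1.
* Non-parametric Shannon (Chao–Shen): with `p̃_i = C·x_i/N`,
  `H = −Σ p̃_i ln p̃_i / (1 − (1−p̃_i)^N)`, in nats (natural log throughout).
  The degenerate all-singleton case (C = 0) falls back to plug-in Shannon
  with a warning.
* Yue–Clayton dissimilarity `1 − Σxy/(Σx² + Σy² − Σxy)` on proportion
  vectors over a shared OTU axis; symmetric, in [0, 1], zero iff equal.
* Logarithmic trends are least-squares fits of `y = a + b·ln(x+1)`; the +1
  accommodates day 0.  R² is `1 − SS_res/SS_tot`, defined as 0 for constant
  y.  Stage-wise piecewise fits are obtained by fitting each stage range
  separately.
* Welch t-tests are two-tailed with Welch–Satterthwaite df; zero-variance
  ties give p = 1 (equal means) or p = 0 (unequal).  Compact letter
  displays assign one letter per maximal clique of the pairwise
  non-significance graph, so groups share a letter iff no pairwise test
  separates them.

## PERMANOVA

One-way only — every comparison in the target design is a two-group test.
With `SS_T = (1/N)Σ_{i<j} d²` and within-group sums `SS_W = Σ_g (1/n_g)
Σ_{i<j∈g} d²`, the statistic is `F = (SS_A/(a−1))/(SS_W/(N−a))`.  The
permutation p includes the observed labelling in numerator and denominator,
`p = (1+#{F_perm ≥ F_obs})/(1+n_perm)`, so p > 0 always; the permutation
stream is seeded and the seed recorded.  Default 10 000 permutations.

For two equal-sized groups the wholesale label swap reproduces F exactly,
which puts a floor of roughly `2/C(N, n)` on any permutation p — worth
remembering when reading "p ≤ 0.001"-type claims at n_perm = 999.  An exact
enumeration over all distinct labelings is provided for N ≤ 9 and doubles
as the test oracle.  Because a single "df (residual)" column is ambiguous
between N−a and N−1, pipeline output reports both (`df_within`,
`df_total`).

## Recruitment index

For reservoir R and fry stage s, let S be the OTUs detected in ≥1 sample of
each compartment.  Each sample gets a score: the summed relative abundance
of S.  The index (default direction) is `mean fry score / mean reservoir
score`.  Above 1, the shared taxa occupy a larger community fraction in the
fry than in the reservoir — taxa rare in the reservoir proliferated in the
fry, the signature of positive recruitment.  The opposite division is
available via `direction`; the two are exact reciprocals.

Significance is a two-tailed Welch t-test on the per-sample scores.  When a
compartment has exactly one sample (the adult diet here: one food batch),
the two-sample test is undefined and a one-sample t-test of the other
compartment's scores against the singleton value is used instead, flagged
on the result.  A reservoir is *flagged* when index > 1 **and** p < 0.05:
the index carries the direction (recruitment), the test the evidence; p
alone would also flag reservoirs whose shared taxa are significantly
*depleted* in the fry.

The transmission screen keeps OTUs that are (1) shared between breeding
mucus and whole larvae at 4–20 DPH, (2) have zero detected counts in every
retained water sample, and (3) are more abundant (mean relative abundance)
in the larvae than in the mucus, ranked by the larvae/mucus ratio.  "Every
water sample" spans the whole study by default (stage-matched water is a
parameter).  Ratios with a zero denominator are reported infinite and
excluded from rankings.

## Co-abundance networks

Candidates are the k = 50 most abundant OTUs by mean relative abundance
over **all** samples; correlations are likewise computed across all samples.
Within-stage computation is not offered as a default because per-stage
sample counts (as few as 2) cannot reach Bonferroni-corrected p ≤ 1e-4
under any outcome; stage-specific views come from provenance labelling
(fry-only / reservoir-only / shared, by the presence rule) and node
filtering.  Spearman ρ uses average ranks; raw p is the t approximation
`t = ρ√((n−2)/(1−ρ²))` with n−2 df (exactly ±1 gives p = 0); the Bonferroni
factor is the candidate-pair count k(k−1)/2 (1225 at k = 50), counted over
all candidate pairs even when constant-abundance pairs are skipped
(conservative).  Retention is one-sided on positive ρ — the thresholds
describe co-abundance, not mutual exclusion.

## Parent-pair mucus sharing

`pair_shared_fraction` has two modes because "percent shared OTUs" is
genuinely ambiguous: *abundance-weighted* (default) is the mean over the
two samples of the summed relative abundance of jointly present OTUs —
matching phrasings like "relative abundance of shared OTUs rose from 16% to
29%" — while *count_based* is the Jaccard percentage of presence sets.
Both are symmetric.  The control baseline draws 20 random unordered pairs
of non-breeding fish, without replacement while the pool suffices (with
replacement otherwise, or an error if disabled).  The taxonomic shift is
the signed difference of group mean relative abundances (percent), ranked
by magnitude; under closure the deltas over all OTUs sum to zero.

## Synthetic scenario

The generator emulates the emulated study's layout exactly: 53 biological
samples (16 water, 4 breeding-mucus, 8 non-breeding-mucus, 8 adult-feces,
1 adult-diet, 7 whole-fry, 9 fry-feces) on the real sampling days, 3
technical replicates each, 1000 OTUs.

Per biological sample: a true composition → per-sample Dirichlet draw
(concentration 400; per-taxon CV of a few percent for dominant taxa, strong
overdispersion for rare ones) → per replicate, a multinomial draw at a
negative-binomial depth (mean 3000, dispersion 20).  Replicates share the
biological composition, as technical replicates should.

Niche compositions are sparse log-normal profiles (σ = 1.5) over
partially overlapping supports, plus a 2% "background" mass from a shared
rare-taxon pool.  Fry at each stage are mixtures over {water, parental
mucus, adult diet, endogenous} — but each reservoir contributes through its
**recruited subset**: the top OTUs covering 40% of the reservoir's mass,
renormalized.  This subset structure is what produces recruitment indices
above 1 for the planted dominant reservoir (0–3: water 0.80; 4–20: mucus
0.64; 50–100: diet ≈ 0.6) and below 1 elsewhere.  Three structural choices
keep the cross-compartment logic honest:

* the recruitable mucus bulk is the **shared parental core** (fry feed on
  both parents), and those taxa are cross-seeded into water at 4% total —
  so the water-absence criterion of the transmission screen rejects them,
  as it rejects the dominant shared genera in real surveys;
* the 12 transmission OTUs sit at 1e-4 (0.01%) in every breeding-mucus
  sample and bloom to 34% of the 4–20 DPH fry community with log-normal
  spread (σ = 0.8) across OTUs, giving a wide range of larvae/mucus ratios.
  Their mucus abundance is *pinned* (exempt from Dirichlet noise),
  modelling host-controlled secretion: at Dirichlet α = conc × 1e-4 ≪ 1 the
  realizations would be bursty and the planted taxa structurally
  undetectable in a 4-sample compartment, which would make the screen's
  recall a coin toss rather than a test of the method.  At the configured
  depth the pinned dose yields ≈0.9 expected reads per pooled mucus sample
  — rare but findable, like the published candidates;
* the non-recruited diet tail passes into the adult feces (5% of the feces
  community), so the single diet sample's unique taxa survive the
  two-sample prevalence filter without seeding the fry-dominant recruited
  slice into any other reservoir.

Correlated blocks multiply their members' abundances by `exp(λ·z)` with a
per-sample latent `z ~ N(0,1)` before closure; with idiosyncratic noise of
CV ≈ 0.2 this gives pairwise Spearman ρ ≈ 0.95 at loading λ = 1.  The
single-niche `simulate_block_community` benchmark (40 samples, blocks
placed inside the top-50) exercises network recovery; in the full scenario
blocks sit among mid-rank water taxa so the latent factor does not
destabilize the fry mixtures.  Every planted structure — stage→reservoir
map, transmission OTU ids, block membership, true niche compositions — is
emitted as machine-readable ground truth.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: no phylogenetic or taxonomic signal (labels are
arbitrary); no temporal autocorrelation within a stage (samples are i.i.d.
around the stage composition); no convergence of late fry feces toward the
adult fecal community (the late-stage endogenous component is fry-specific,
so Table-1/2-style fry-vs-parent trajectories are not reproduced); no
compositional bias from PCR/primer chemistry; single-sampled control fish
lose their individual flora to the prevalence filter (a real artifact of
one-sample-per-individual designs, visible here because the truth is
known).  Recruitment-index recovery shows the index separates the planted
mixture structure at study-realistic sample sizes — not that it identifies
sources under arbitrary cross-seeding, which is a known limitation of
shared-abundance attribution generally.

## Numerical and reproducibility notes

* Thetayc distances are computed vectorized from cross-products, clipped to
  [0, 1], symmetrized, and zero-diagonal by construction; identical columns
  give exactly 0.
* Permutation streams, pair draws and scenario generation all run on
  `numpy.random.default_rng` with explicit seeds; a scenario seed is
  mandatory, and fixed seeds give bit-identical count tables.
* Pipeline runs re-executed with the same configuration produce
  byte-identical TSVs; the JSON manifest records package version, seeds,
  input SHA-256 digests and the output inventory.
* Welch tests guard zero-variance and single-sample degeneracies
  explicitly; recruitment results flag one-sample fallbacks, empty shared
  sets and infinite ratios rather than raising mid-pipeline.
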