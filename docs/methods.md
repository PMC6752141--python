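# Methods and design notes

## The recombination clock

A donor tract present in the recipient population since a single admixture
pulse `t` generations ago, in a region of recombination rate `r`
(Morgans/bp), has expected length `L̄ = [(1 − f) r (t − 1)]⁻¹`, where `f` is
the admixture proportion: junctions form at rate `r` per meiosis, but only a
fraction `1 − f` of them are visible (a crossover landing next to another
donor segment merges rather than cuts), and the pulse generation itself
contributes no erosion (at `t = 1` tracts are whole chromosomes).  Tract
abundance as a function of length is exponential with rate `λ = 1/L̄`.
Everything in the package follows from inverting this law.

`f` is always the *observed* genome-wide admixture proportion of the
population (or, for simulated samples, the realized donor fraction of the
sample), never a window-local value: the merging probability a tract
experiences is set by the genomic background, not by the window it sits in.

The pulse assumption is deliberate.  Continuous-migration tract likelihoods
exist but lose power beyond ~100 generations; the validation below shows the
pulse formula's date *difference* stays accurate under continuous gene flow,
which is the quantity this package cares about.

## The two estimators and their biases

**Method 1 (windowed).**  Every tract is assigned, at its full genomic
length, to every 100-kb window it overlaps by ≥1 bp; per window, the mean
assigned length is inverted with the window's `r`, and the population date
is the kernel-density mode of the per-window dates.  Two deliberate
consequences:

* *Overlap length bias.* Long tracts are counted in more windows, so window
  means are length-weighted upward and windowed dates are biased young once
  tract lengths become comparable to the window size.  On synthetic data
  with known truth the bias reaches ~25–30% for mean tract lengths of
  0.3–1 window widths.  This is a property of the windowed procedure itself
  (kept as specified); the regression estimator is the unbiased route.
* *Short-tract filtering bias.* The 50-kb tract floor inflates window means
  further, dragging windowed dates down; the log-slope of the binned length
  distribution is unchanged by left truncation (memorylessness), so Method 2
  is insensitive to the floor.  The test suite asserts exactly this
  contrast.

**Method 2 (regression).**  Windows are sorted by `r` and cut into
`n_categories` (default 11) equal-count groups (remainder windows go to the
lowest-`r` groups); a tract overlapping several windows of one category is
counted once.  Per category, tracts are binned into 20 equal-width length
bins between the observed min and max, bins with ≥5 tracts enter an ordinary
least-squares fit of log count on bin midpoint, and `λ = −slope`.  The
per-category `λ` is then regressed on the category mean `r` through the
origin (unweighted; a `= (1 − f)(t − 1)`), and `t = a/(1 − f) + 1` with a
95% CI from `(a ± 1.96·SE)/(1 − f) + 1`.  Finite tract counts leave a small
(≲5% at ~300 tracts/category, ≲2–3% at ~1,000) downward bias from Poisson
noise in logged bin counts; the recovery tests budget for it explicitly.
Per-category p-values are two-sided slope t-tests; a Bonferroni threshold of
p < 0.0045 is used for flagging only, never for exclusion.

**Mode and CI.**  "The maximum of the distribution" of window dates is read
as the density mode: Gaussian KDE, Silverman bandwidth, density evaluated on
a 4,096-point grid spanning the data range.  For bootstrap tractability
(10,000 replicates by default) the density is computed by linear binning
plus Gaussian smoothing, which agrees with the exact KDE to grid resolution
(cross-checked against `scipy.stats.gaussian_kde` in the tests); the CI is
the 2.5%/97.5% quantiles of replicate modes under resampling with
replacement.  An alternative `mode_rule="max"` (largest resampled value) is
exposed because the phrase is ambiguous; the mode is the default.

## Filters

* Tract length strictly `> 50,000` bp ("longer than 50 kb" read strictly).
* Window `ρ = 4Nₑr` strictly `< 10`/kb.
* `RND_min = d_min/d_out ≤ 0.03` by default; a 95th-percentile quantile rule
  is available because the fixed value and the percentile coincide on the
  study data but not in general.  Windows without an RND value pass the
  screen (they cannot be judged); if no window has one, the screen is
  skipped with a warning.
* All filters are idempotent, monotone in their thresholds, and
  order-independent with respect to assignment.

## Dispersal

`t_diff = t_far − t_near` with interval-arithmetic CI
`[far.lo − near.hi, far.hi − near.lo]`; dispersal `= distance/t_diff` with
CI `[distance/hi, distance/lo]`.  Multiple route distances are averaged
(matching pooled far-side samples).  A non-positive `t_diff` flags the
estimate unusable rather than erroring: it is a legitimate empirical outcome
(the far population dating younger), just not interpretable as dispersal.
No generation time is asserted; everything stays in generations and
km/generation.

## The secondary-contact simulators

The scenario: a donor and a recipient population; `t_c` generations of
contact during which migrant individuals enter the recipient at a constant
expected rate; then `t_diff` generations without gene flow, standing in for
the time tracts spend diffusing between two sampling sites.  The recipient
is sampled at both ends of the no-flow period (4 diploids each by default),
each sample is dated via the clock with its own realized `f` and mean donor
tract length, and the date difference estimates `t_diff`.  In the
infinite-population limit this estimator is exact: during the no-flow
period, junction density grows by `2 r f (1 − f)` per bp per generation, so
the estimated date advances by exactly one generation per generation.

**Forward Wright–Fisher engine** (`simulate`, `simulate_pulse`).  Haplotypes
are junction lists (positions where ancestry flips); each offspring
haplotype takes alternating segments of two uniformly chosen parent
haplotypes with Poisson(`rL`) crossovers at uniform integer positions;
migrants are whole individuals with all-donor parents.  The generation loop
is a numba kernel; all randomness comes from one seeded generator, so runs
are bit-reproducible.  Fractional `migrants_per_generation` values are taken
as a Poisson mean, integral values as an exact count.  Back-migration
(`m₂`) is accepted in the model type but has no effect on recipient tracts
and defaults to 0.  Divergence time and mutation are omitted: ancestry is
tracked by label, so tract detection is exact and the divergence depth is
irrelevant.

The forward engine carries the full drift process, which cuts both ways.
It is the validation tool of choice for the closed-form law: a single pulse
(`f₀` of haplotypes replaced by whole donor chromosomes, then `t − 1`
rounds of reproduction) yields tract lengths that pass a KS test against
`Exponential((1 − f) r (t − 1))` when time depth is small relative to the
population size.  But population size is a *real parameter*: once the time
span approaches `N` generations, within-population genealogies coalesce,
crossovers increasingly join identical-by-descent material, visible junction
formation stalls, and the clock saturates.  Measured on this implementation,
a 1,000-haplotype population run through the sea-bass history (2,300 + 550
generations) recovers only ~25% of the true diffusion time; 10,000
haplotypes recover ~80%.  Small forward populations therefore cannot stand
in for a large marine population over millennia — which motivates the second
engine.

**Coalescent engine** (`simulate_coalescent`).  The same scenario simulated
backward in time with msprime: only the sampled genealogies are computed, so
the recipient runs at its full-scale size, where saturation is negligible,
at a few seconds per replicate.  During the contact window, recipient
lineages migrate (backward) into the donor population at the per-generation
migrant fraction; a census event planted at the onset of contact labels
every lineage, and a sampled segment is a donor tract exactly when its
censused ancestor sits in the donor population (segments are then merged
per haplotype).  The simulation stops at the census — nothing deeper than
the contact onset is needed to call ancestry, so divergence-era parameters
never enter.  The donor population size is set equal to the recipient's; it
only affects coalescence among already-introgressed lineages, not tract
lengths.

**Population scaling.**  The study-scale migrant flow is `N·m₁ = 7`
individuals/generation.  The per-generation migrant *fraction* is what
shapes admixture and tract ages, and it is pinned by the observed admixture
proportion: `m₁ = 1 − (1 − 0.31)^(1/2300) ≈ 1.61e-4`, implying a full-scale
recipient of ≈43,400 diploids — the size the coalescent engine uses, making
"7 migrants per generation" literal.  `sea_bass_model(n_haplotypes=...)`
scales the expected migrant count linearly with `N` so that desk-scale
forward runs preserve the realized admixture; sweep values (1–20
migrants/generation) scale the fraction proportionally.

**Validation results** (recomputed by the test suite and acceptance
script): at the sea-bass parameters with 4 sampled diploids per date, the
median of 10 replicate estimates at a true diffusion time of 550 generations
falls within ±20% of truth; across true values {50, 350, 550, 1,200} the
estimate-on-truth regression slope lies in [0.8, 1.2]; medians are stable
for sample sizes 1–7; and replicate spread inflates at 1 migrant/generation
relative to 7.  A small (~5%) downward tendency at large `t_diff` reflects
residual coalescence over the longest spans.

## Synthetic fixtures

`generate_fixture` draws i.i.d. tract lengths per window from the
exponential law implied by (`t`, `f`, window `r`) — left-truncated lengths
are `min_length` plus an exponential, by memorylessness — and places tracts
at uniform non-overlapping positions on synthetic haplotypes (fully inside
their source window when they fit; rejection-sampled against overlap, with
an explicit packing error when density is infeasible).  Placement is not a
population-genetic model; only lengths and window assignment matter to the
estimators.  Fixtures emulate the length law, a heterogeneous recombination
map, and optional short-tract censoring; they do *not* emulate local-
ancestry-inference error (false, split or merged tract calls), haplotype
phasing error, or age mixtures from continuous migration — passing fixture
tests demonstrates estimator correctness under the model, not robustness to
call error.

## Numerical and degenerate-input choices

* Coordinates 0-based half-open; lengths in bp; a tract ending exactly at a
  window start does not overlap it.  Adjacent equal-ancestry intervals on a
  haplotype merge on read; overlapping ones are rejected as contradictory.
* Degenerate KDE inputs: all-equal values return that value; fewer than two
  values raise.
* Bins with zero count never reach the log (the ≥5-count rule screens them
  first); categories with fewer than two usable bins are marked unusable and
  dropped from the slope regression with a warning.
* Windows with `r = 0` are excluded from dating with a warning; `f = 1`,
  `L̄ ≤ 0`, `r ≤ 0` and non-positive diffusion times raise domain errors.
* Crossover positions are integers in (0, L); duplicate positions cancel
  pairwise in the merge kernel, keeping junction lists strictly increasing.
* Problem sizes in the test suite (population sizes, replicate counts, 300-
  to 1,000-replicate bootstraps) are chosen so the full validation runs on a
  single CPU in minutes while keeping every assertion's Monte-Carlo margin
  explicit in the test.

## Known limitations

* Single-pulse dating applied to continuous-migration histories reads out a
  mass-weighted mean tract age; the *difference* between two sampling points
  is what is validated, absolute dates inherit the mixture.
* The windowed estimator's overlap length bias (above) is inherent to
  full-length-per-window assignment.
* Finite-population saturation bounds what the forward engine can validate;
  quantitative recovery claims rest on the coalescent engine.
* A handful of forward-engine pulse replicates (~1 in 5 at N = 10,000,
  t = 100) drift far enough that their tract-length sample rejects the
  closed form at α = 0.01; the acceptance check therefore tests the median
  KS p-value across replicate simulations.
* Dispersal is an average over the whole route between two sites; local
  barriers between them are invisible at this resolution.
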