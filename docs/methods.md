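# Methods

## Scientific model

The pipeline operationalizes a simple ecological hypothesis for
biocrust wet-up: across wetting time and successional stage, a taxon's
relative abundance should correlate **negatively** with metabolites its
cultured representative consumes and **positively** with metabolites it
releases. The statistic of record is the count of sign-concordant
microbe–metabolite relationships among those evaluated, tested against
Binomial(n, ½) with an exact two-tailed binomial test.

### Exact binomial test

For the symmetric null p₀ = ½ we use the doubling rule
p = min(1, 2·min(P(X ≤ k), P(X ≥ k))); for general p₀ the
minimum-likelihood rule (sum of all pmf values ≤ pmf(k)). Both are
exact pmf summations with no normal approximation. The doubling and
minimum-likelihood rules coincide at p₀ = ½; tests verify the
implementation against full 2ⁿ enumeration for n ≤ 12 and against an
independent exact implementation for general p₀.

### Correlations

Spearman's ρ with average ranks and the two-sided t approximation
(t = ρ·√((n−2)/(1−ρ²)), n−2 df; |ρ| = 1 reported as p = 0), pairwise
complete observations, minimum 4 pairs. One pooled ρ per
(taxon, metabolite) pair across all stages × time points × replicates;
a per-stage stratification is available as an option. Each metabolite
replicate is paired with the single metagenome-derived abundance of its
(stage, time) group — abundance has no replicates in the emulated
design, and the resulting ties are handled by average ranks. BH-FDR is
computed over all evaluable pairs in the marker family. Directionality
uses sign(ρ) only; the |ρ| ≥ 0.5 threshold merely sets the
"highly correlated" flag. A pair whose ρ is missing, undefined
(zero variance) or exactly zero carries no directional information and
is excluded from the binomial trial count rather than counted as a
failure, which would bias the test toward rejection.

### Killed-control significance model

Per metabolite, OLS on log(1 + area) with condition (categorical), time
(continuous) and condition × time; Type II F-tests for the condition
and interaction terms. A metabolite is *biologically controlled* iff it
was never detected in the killed controls (detected = ≥ 50% of
replicates non-missing in at least one (stage, time) cell) or either
p-value < α (default 0.05). Because killed controls derive from a
single late-successional crust, the default comparison restricts active
samples to that stage (a switch compares against all stages). Tukey's
HSD across condition × time cell means is emitted as a supplementary
table but does not enter the verdict — the verdict needs a single
defensible rule, and the model F-tests provide one. Missing areas stay
missing (never imputed as zero) for all statistics.

The log(1 + area) transform is used for both the ANOVA and PCA because
peak areas span decades with roughly constant CV; clustering uses
correlation distance (1 − Pearson) with average linkage, which compares
profile *shapes* after row normalization (each metabolite scaled to its
max cell mean).

### Isolate classification and matching

Fold-change = inoculated / control mean peak area on raw (not log)
means; consumed ≤ 0.5, released ≥ 2, both thresholds inclusive.
Metabolites undetected in control media are unclassifiable and skipped.
No additional significance filter is applied on top of the fold-change
thresholds.

Marker matching uses Needleman–Wunsch global alignment (match +1,
mismatch −1, gap −2; configurable) with identity = identical columns /
full alignment length (gap columns included in the denominator — the
similarity formula is a package choice). Matching is pure argmax with
the full ranked list exposed; ties break by taxon label. The
fragment-identity routine cuts the query genome into non-overlapping
1020-bp fragments, anchors each by exact 16-mers (majority diagonal),
aligns to the anchored window with a banded edit-distance aligner, and
drops fragments with < 70% window coverage or < 30% identity — standard
fragment-ANI conventions; fragments without any k-mer anchor are
likewise dropped, so unrelated genomes yield a flagged undefined
result.

## Synthetic wet-up generator

The generator emulates the emulated study design: stages A–D, sampling
at 0.05 (3 min), 9, 18, 42 and 49.5 h, five active replicates
(n = 100), triplicate stage-D killed controls, one metagenome per
(stage, time) group.

**Abundances.** Each taxon follows
B(t) = scale(stage)·(baseline + amplitude·exp(−(ln t − ln t_peak)² /
(2w²))) — a log-time Gaussian, chosen because it is positive, smooth,
and lets an "early" responder peak at the first sample (3 min) while
"mid"/"late" responders peak at 18 h / 42 h. The default community:
an early autotroph (`cyano_early`, peak 0.05 h, near-zero dry
baseline), a mid heterotrophic bloomer (`firmicute_mid`, peak 18 h), a
late heterotroph (`firmicute_late`, peak 42 h) and a wetting-indifferent
taxon (`actino_flat`, amplitude 0) whose abundance is graded along the
successional axis (scale 0.5 → 1.6 from stage A to D). A constant
"background" pool (20 abundance units) absorbs the unmodeled community
so focal relative abundances stay realistic (the autotroph ~30% right
after wetting, ~1% late).

**Metabolites.** dM/dt = leach·e^(−t/τ) + Σᵢ rᵢBᵢ −
Σᵢ uᵢBᵢ·M/(K + M), forward Euler (default step 0.05 h), pools clamped
at 0; killed mode zeroes all biological terms, reproducing the
gradual abiotic leaching rise of killed controls. The twelve defaults
span released-only, consumed-only, released-and-consumed and
abiotic-only dynamics.

With only five sampled time points, Spearman of a unimodal mid-peaking
abundance against a monotone pool is structurally ≈ 0, so the default
parameters are calibrated to qualitative orderings in which every
ground-truth signed pair is structurally recoverable: sugars start high
(wet-up leachate), are topped up by the early autotroph and drawn down
from the start by the flat taxon and late in the window by the late
heterotroph (so they decline monotonically, like the autotroph's own
trajectory); the mid responder only *releases* (nucleobase byproducts
whose pools peak with it and crash when the late responder consumes
them); the late responder consumes amino acids/sugars and releases a
purine; the flat taxon's consumed pairs are separated along the
successional axis. No absolute abundance scales or uptake kinetics are
asserted — only orderings.

**Observation model.** Peak area = gain·M·e^ε with ε ~ N(0, σ²),
σ = 0.25 (multiplicative lognormal noise; LC/MS areas are positive with
roughly constant CV); areas below the detection limit (default 0) are
missing. Marker reads are Multinomial(read_depth = 20 000, normalized
abundances incl. background). Isolate fold-changes follow the closed
form fc = exp(−u·c_b·T_c)·(1 + r·c_b·T_c/M₀) with culture biomass
c_b = 3 and duration T_c = 24 h, times lognormal noise (σ = 0.2); the
culture constants are set so noise-free fold-changes of truly
consumed/released pairs sit ≥ 2σ from the 0.5 / 2 class boundaries.
Isolate marker sequences are the environmental markers mutated at 10%
per site, mimicking genus-level (≈ 86–92%) marker identity. All
randomness derives from one root seed via named substreams; identical
scenarios give bit-identical outputs.

**What the generator does *not* emulate:** chromatographic artifacts,
retention-time drift, metabolite misidentification, compositional
sequencing biases beyond multinomial sampling, diel cycles,
strain-level heterogeneity between isolate and environmental
populations, or mineral sorption beyond first-order leaching. Passing
tests therefore demonstrate the statistical machinery and its
calibration on data with known truth — not performance on real soils.

## Numerical choices

- Euler integration: the invariant check compares the default step
  (0.05 h) against a 50× finer step with 1% relative tolerance plus an
  absolute floor of 1% of the initial pool; for pools driven to ~0 by
  strong uptake the relative error on the (negligible) terminal value
  is not meaningful.
- Clustering tie-break: deterministic scipy linkage on the input order;
  constant profiles get zero correlation to everything.
- PCA: rows mean-imputed, log(1 + area), centered; eigendecomposition
  of the sample covariance; explained-variance fractions sorted
  non-increasing.
- Identity: argument pair canonically ordered before alignment so
  percent identity is exactly symmetric despite co-optimal alignments.
- The null-calibration check of the binomial test evaluates 44 random
  predictions per run: the exact test is discrete, and its achieved
  size at n = 44 (4.88%) is the closest to the nominal 5% in the
  relevant range (at n = 48 it is only 2.9%), so n = 44 measures the
  machinery's calibration rather than binomial discreteness. The
  size table was computed analytically from the binomial cdf.
- Killed-control type-I calibration uses constant-pool null data so the
  linear time term is correctly specified and the F-test is exact.

## Problem sizes

Defaults keep everything desk-scale: 4 taxa × 12 metabolites,
100 + 15 samples, 450-nt markers, 20 k reads/sample. The recovery check
runs 20 seeded replicates of the full pipeline (~0.3 s each); the null
calibration runs 500 reduced replicates; genome comparisons use ~5-kb
synthetic genomes. These sizes give stable statistics while remaining
instant to run interactively.

## Known limitations

- The killed-control contrast conflates "biological control" with any
  active-vs-killed difference; sorption differences between live and
  autoclaved crust would also register.
- Pooled Spearman across stages assumes relationships are conserved
  across succession; the per-stage option exists but the binomial
  summary uses the pooled signs.
- The exact per-taxon composition of evaluated relationships depends on
  upstream filters; the pipeline reports whatever its inputs yield and
  never hard-codes a trial count.
- Marker-based matching is genus/species-resolution at best; an isolate
  and its closest environmental relative may still differ in substrate
  preference.
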