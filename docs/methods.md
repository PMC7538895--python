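# Methods

This note documents the models behind `baywebs`, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate, and
the numerical choices that matter for reproducing results.

## Community patterning (SOM)

**Model.** A batch Kohonen self-organizing map: a rectangular lattice of
units, each holding a codebook vector in taxon space. Per epoch, every sample
is assigned to its best matching unit (BMU, minimal Euclidean distance) and
each codebook is replaced by the neighbourhood-weighted mean of all samples,
with a Gaussian neighbourhood kernel over lattice distance. Codebooks are
therefore always convex combinations of data rows, bounded per dimension by
the column minima/maxima.

**Preprocessing.** Taxa are retained if they reach the `threshold` (default
0.05) share of total abundance on at least one sampling occasion (a season
when the row index carries one, otherwise each sample); all-zero taxa are
always dropped and filtering away every taxon is an error rather than an
empty table. Columns are then min–max scaled to [0, 1]; a constant column
maps to 0 rather than being dropped so taxon sets stay aligned across
subsets. The scaling is idempotent.

**Schedules.** Two phases, SOM-Toolbox-style and fully configurable:
ordering (radius max(rows, cols)/2 → 1 over 100 epochs) and tuning (radius
1 → 0.5 over 400 epochs), linear decay within each phase. Shrinking the
final tuning radius towards 0 turns the batch update into Lloyd iterations,
which is how the quantization error can collapse to machine precision when
there are at least as many units as distinct samples.

**Initialization.** Linear: codebooks span the plane of the two leading
principal directions of the data, scaled by the corresponding standard
deviations, with the sign of each direction fixed by its largest loading.
This makes training fully deterministic; `init="random"` (uniform within
column ranges) uses `random_state`.

**Grid size.** Candidate unit counts bracket the 5√N heuristic within
×[0.5, 1.5], are capped at the number of samples, and each count contributes
its most nearly square factorization (rows ≥ 2, aspect ratio ≤ 3). When no
count qualifies, the minimal 2×2 grid is proposed. The final grid is the
(TE, QE)-lexicographic minimizer over trained candidates — topographic
preservation first, quantization second — with the full sweep table
returned for inspection.

**Lattice convention.** The lattice is a rectangular index grid with
8-neighbourhood (Chebyshev-1) adjacency for both the topographic error and
the U-matrix. Published SOM work is ambiguous between rectangular and
hexagonal unit shapes; the rectangular reading is implemented and TE would
shift slightly under a hexagonal one.

**Error measures.** QE = mean sample→BMU distance; TE = fraction of samples
whose two best units are not lattice-adjacent (ties in the distance ranking
broken by unit index, stable sort). Training more units than samples is a
warning, not an error: ecological SOMs routinely train 36 units on ~54
samples and empty units still shape the topology.

## Cluster inference

SOM units (including empty ones — the hierarchy is over codebooks, not
samples) are clustered by Ward's minimum-variance method on Euclidean
distance and cut at a chosen k; samples take their BMU's cluster.
Sub-clusters are obtained by re-running the same procedure on the units of
one parent cluster.

**MRPP.** The statistic is the group-size-weighted mean within-group
distance δ = Σⱼ (nⱼ/N)·mean within-group distance. The chance-corrected
agreement is A = 1 − δ_obs/E[δ], where E[δ] is the exact expectation under
random relabelling — the overall mean pairwise distance — so A carries no
Monte Carlo noise. The sampled p-value uses the add-one estimator
p = (1 + #{δ_perm ≤ δ_obs})/(1 + n_perm), which can never report p = 0;
exact mode enumerates all distinct label arrangements and is refused above
10 000. Groups need at least two members; data in which all points are
identical leave A undefined and raise an error. Both a global test and
pairwise cluster contrasts are supported (run MRPP on the subset of two
clusters).

**Environmental contrasts.** Kruskal–Wallis H with midrank tie correction
(H = 0, p = 1 when every observation ties), followed by pairwise
Mann–Whitney U. P-values are unadjusted by default, matching common field
practice for these box-plot contrasts; Holm adjustment is available.

## Indicator and dominant taxa

**IndVal.** For a candidate target group (a single cluster or, by default,
any pair of clusters; the full power set is opt-in for combinatorial cost,
and the all-clusters combination is excluded as uninformative), specificity
A is the group's share of per-group *mean* abundance (the group-size
corrected IndVal.g form; the classic total-abundance form is available) and
fidelity B is the occurrence frequency inside the target. The statistic is
√(A·B), which is 1 exactly when a taxon occurs only inside the target and in
all of its samples. Significance is by label permutation with the add-one
estimator; an exact enumeration mode exists for small designs. Per taxon,
the best-scoring combination is reported.

**Dominance.** D′ᵢⱼ = Fᵢⱼ·Dᵢⱼ·100 with Fᵢⱼ = (Pᵢⱼ/Pⱼ)·100 and
Dᵢⱼ = [Σₖ Nᵢₖ/Nₖ]/Pⱼ, applied exactly as printed; samples with zero total
density are excluded from the relative densities with a warning. Dominant
taxa satisfy Fᵢⱼ > 50 (strict) and Dᵢⱼ greater than the median Dᵢⱼ over taxa
*present* in the cluster — absent taxa would drag the median to zero. A
cluster with a single present taxon cannot satisfy the median rule and is
flagged degenerate instead. Rank-frequency breakpoint detection is not
implemented: only the 5% common-taxon rule is specified precisely enough to
reproduce.

**Associations.** Per (site, season) stratum shared by all taxonomic
groups, the tuple of per-group cluster labels plus the union of the groups'
dominant taxa. Distinct tuples define the multitrophic community types; in a
purely spatial two-region design every group splits estuary/bay and exactly
two types appear.

## Isotope mixing models

**IsoSource enumeration.** All proportion vectors on the simplex lattice at
the given increment (default 1%) are tested; a vector is feasible when its
predicted mixture Σᵢ pᵢ·δᵢ is within the tolerance (default 0.1‰) of the
observed mixture on every isotope. Defaults follow standard IsoSource
practice; both are configuration keys since published applications rarely
state them. The enumeration prunes lattice prefixes whose attainable range
already excludes the target and solves the last two coordinates analytically
as an interval intersection, so six-source systems at 1% run in seconds.
Feasible sets are summarized by per-source medians and 1–99 percentiles; an
empty set is reported explicitly with the Euclidean distance from the
mixture to the source polygon (SLSQP projection) as a diagnostic. Source
standard deviations do not enter the feasibility criterion (classic
IsoSource behaviour); widening the tolerance is the supported way to absorb
source spread.

**TEF handling.** Consumer signatures are corrected by subtraction *before*
enumeration: one primary-consumer step (Δδ¹³C 1.3‰, Δδ¹⁵N 2.2‰) for guild
mixing against producers, one carnivore step (1.3‰, 3.3‰) for predators
against baseline end-members.

**Two-source f.** Computed exactly as printed and clamped to [0, 1] with the
raw value retained: values above 1 (consumers isotopically heavier than the
benthic end-member) are reported as 1.00, and negative dependence is
physically meaningless, so the lower clamp is symmetric. A zero benthic–
pelagic denominator is a configuration error. f is affine-invariant in
δ¹³C.

**Trophic position.** TP = (δ¹⁵N_consumer − δ¹⁵N_baseline)/3.3 + 2 with the
baseline mixed using the *unrounded* f. Reporting precision is f to 2
decimals and TP to 1, matching how such tables are printed. Both
individual-level and taxon-mean estimation are supported; published tables
use taxon means.

**Four end-members.** Motile consumers whose δ¹³C falls outside the local
two-source axis are mixed (after one carnivore TEF step) over the four
baseline end-members of both localities. f is the median feasible proportion
of the focal benthic end-member; the TP baseline is the median-weighted mean
of end-member δ¹⁵N values (medians renormalized). This is one defensible
reading of a procedure whose original baseline construction is not printed;
it is not verifiable against published values beyond qualitative agreement,
and the bundled test asserts only that.

## Synthetic data

The generators emulate a two-channel seasonal survey with known ground
truth:

- **Communities** — sites partitioned between an estuarine and a bay
  cluster with disjoint taxa pools; abundances are log-normal magnitudes
  gated by Bernoulli detection (abundance laws are never printed in surveys;
  long-tailed rank-frequency curves motivate the log-normal). Seasonal
  turnover rotates a sliding window over a shuffled cluster pool; by default
  it applies to plankton (rate 0.33) and not to benthos or nekton, matching
  the observed seasonal stability of those groups. Units are arbitrary
  densities: real surveys never reconcile net/grab/trawl units.
- **Environment** — per-sample Gaussian draws around per-cluster medians
  (e.g. suspended particulate matter highest in one cluster, median
  12.6 mg l⁻¹).
- **Isotopes** — source specimens from Gaussian laws per source; consumer
  specimens as δ = Σᵢ pᵢ·δ_source,ᵢ + TEF + independent Gaussian noise per
  isotope (the simplest defensible error model). Phytoplankton signatures
  use the published cluster-pooled means; other producers are realistic
  synthetic stand-ins anchored to the published extremes of the producer
  ranges.

The bundled pipeline scenario uses three producers per locality (full-rank
two-isotope systems, so the planted diets are identifiable), guild diets
chosen to reproduce the published benthic/pelagic baseline δ¹³C separation
(~2.5‰ estuarine, ~2.9‰ bay) on which two-source identifiability rests, 24
specimens per guild (a guild pools several dominant taxa) and predator
signatures placed on the local baseline axis at planted f and TP.

What the generators do **not** emulate: spatial hydrodynamics and tides,
mechanistic population dynamics, unit heterogeneity between gears,
taxon-specific TEF variation, isotope routing or concentration dependence,
and within-taxon ontogenetic diet shifts. Passing tests therefore show the
inference chain recovers structure *of this planted kind* at survey-realistic
sizes — not that real communities satisfy the generative assumptions.

## Numerical choices and degenerate inputs

- Seeds: every stochastic routine takes an explicit seed; the pipeline
  spawns per-stage child seeds from its single config seed, so outputs are a
  pure function of (inputs, config, seed).
- Lattice feasibility uses ±1e-9 slack when converting analytic intervals to
  integer lattice points; permutation comparisons use ±1e-12 slack so exact
  ties count as exceedances.
- Grid selection ties break lexicographically (TE, then QE, then candidate
  order); Ward uses scipy's implementation, which matches exhaustive
  minimum-variance agglomeration on small instances.
- Empty guilds, empty clusters, zero-total samples, all-identical MRPP
  inputs, mixtures outside the source polygon, and missing baselines all
  raise explicit errors or warnings rather than returning silent results;
  the pipeline tags every failure with its stage.

## Problem sizes

The test suite and the reproduction script run planted-recovery at the
survey's own scale (54 = 9 × 6 samples for plankton/benthos, 18 = 3 × 6 for
nekton), 20 seeds for the recovery median, 50 random matrices for the
QE-improvement check, 1000 simulations × 199 permutations for MRPP type-I
calibration, and 1% increments for mixing enumerations up to six sources.

## Known limitations

- The SOM schedules and the rectangular-lattice TE are one defensible
  convention; QE/TE values from other toolboxes will differ in detail.
- MRPP's A uses the analytic permutation expectation; implementations that
  average sampled δ values will report slightly noisier A.
- At these survey sizes a single-sample cluster misassignment occasionally
  (order a few percent of seeds) adds a spurious third association type to
  the bundled scenario.
- The four-end-member TP baseline construction is a modelling choice, not a
  reproduction of a printed algorithm.
- Underdetermined mixing systems (more than three sources on two isotopes)
  yield feasible *ranges*; medians are then summaries of the feasible
  polytope, not point estimates of the true diet.
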