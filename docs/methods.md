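# Methods

`mtdrift` implements the computational core of a yeast experimental-evolution
study design: populations growing on solid medium under chronic mitochondrial
superoxide stress, serially passaged through ~50 bottleneck/expansion cycles,
phenotyped by colony growth curves, and genotyped by sequencing coverage and
qPCR. The package's five analysis stages and the synthetic-data generators that
exercise them are described here, with the reasoning behind every numerically
consequential choice.

## 1. Growth-curve phenotyping (`mtdrift.growth`)

### Doubling-time estimator

The fitness proxy is the cell doubling time `D` (hours per population
doubling) during the exponential phase. The estimator is model-free:

1. log2-transform the cell counts;
2. median-filter (width 5, nearest-edge padding — transparent on monotone
   noiseless data, so exact curves pass through unchanged);
3. fit least-squares slopes in every sliding window of `window` points;
4. `D = 1 / max(slope)`; the maximising window index is reported.

Curves whose best slope is below 1/24 doublings/h are flagged `no_growth` and
reported at the 24 h sentinel.

**Window default (41 points ≈ 13.7 h at 20-min sampling).** Short windows are
statistically untenable under realistic count noise: at 5% multiplicative
noise a 9-point window has ~7% slope standard error for a 2.5 h grower, and
taking the *maximum* over ~200 windows adds a systematic selection bias of
several percent. A 41-point window recovers ≥98% of positions within 2% of the
noiseless-curve value at 5% noise. The price is a saturation bias for fast
growers whose exponential phase is shorter than the window (see "Ground truth"
below); on real colony data with longer exponential phases the bias is
smaller. The window is a plain parameter for assays with other geometries.

### Spatial normalization

Plates carry founder-control colonies at every fourth position (a regular
2-row × 2-column interleave, mirroring 384 controls in a 1536-colony format).
The controls' log2 doubling times are interpolated into a plate-wide surface:
piecewise-linear on the Delaunay triangulation of control positions (exact at
controls, reproduces planar gradients exactly inside the hull) with
nearest-neighbour extrapolation at plate edges. Then

    log2(D)_norm = log2(D) − surface(position)
    log2(D)_adj  = log2(D_t)_norm − log2(D_0)_norm
    D_hours      = 2^(log2(D)_norm) × D_control,grand

where `D_control,grand` is the grand mean of raw control doubling times. On a
synthetic plate with a pure 10% spatial gradient this removes >99% of the
gradient-induced variance; the residual comes from the one uncontrolled edge
row/column, where extrapolation is flat.

### Generations and adaptation accounting

Per-cycle generations are log2 of the fold expansion; missing interior cycles
are filled with the mean of the nearest observed cycle on each side, missing
end cycles are refused (no anchor). Realized adaptation is expressed as the
percent of the maximum possible doubling-time reduction,

    percent = 100 × (D_init,stress − D_t) / (D_init,stress − D_floor),

with the founder's unstressed doubling time as the physiological floor.
Values outside [0, 100] (measurement noise, transiently deleterious loads) are
clipped with a warning. `additive_combination` sums reductions under the
additive-phenotype assumption used to attribute the second adaptation phase to
chromosome duplications.

The display adjustment `N_adj(t) = 2^(log2 N_t · log2(median N_0) / log2 N_0)`
forces all displayed curves to start at the median initial size while
preserving relative log-scale shape. (The transformation as typeset in the
source literature collapses every curve to a constant; the form implemented
here divides by log2 of the curve's own initial count, which realizes the
stated intent.)

## 2. Individual-based evolution simulator (`mtdrift.evosim`)

The simulator is the null model asking whether nuclear mutations alone could
produce fast adaptation. Haploid cells carry a division time, a set of
mutated genes, a set of duplicated chromosomes and a replicative age.

* **Growth cycle.** From a bottleneck of `N` cells, cells divide
  asynchronously on a continuous-time event queue (a cell entering the cycle
  or born at `t` with division time `D` divides at `t + D`). When the
  population reaches `round(2^{M_t} N)` cells, `N` survivors are drawn
  uniformly without replacement. The cap check runs after every division, so
  the final wave may be partial; ties are broken by insertion order. Division
  clocks reset at the start of each cycle (fresh-plate transfer); the source
  protocol does not state this, and all within-cycle results are insensitive
  to it for homogeneous starts.
* **Replicative aging.** Mothers accumulate divisions and stop dividing at
  `max_divisions` (default 12) but remain alive, countable toward the cap and
  samplable at the bottleneck. Daughters start at age 0.
* **Mutation.** At each division the daughter draws
  Poisson(`mu_snp × genome_bp`) point mutations (defaults 0.33e-9 /bp/division
  over 12 Mb, mean 3.96e-3) and a Bernoulli(`mu_dup` = 4.85e-5) chromosome
  duplication on a uniformly chosen not-yet-duplicated chromosome. A point
  hit is *effectual* (function-abolishing: stop-gain or strongly deleterious
  nonsynonymous) with probability `sites_g / genome_bp` summed over genes,
  else neutral. Genes and chromosomes mutate at most once per lineage;
  effectual hits on an already-mutated gene are redrawn. Site-level collision
  tracking for neutral hits is omitted (a repeat hit on one of 12e6 sites
  within a lineage is vanishingly rare). A `mutate_both` switch lets the
  mother draw mutations too; the default mutates only the daughter, matching
  how per-division rates are measured in mutation-accumulation studies.
* **Diminishing-returns epistasis.** A mutation with effect size `D_r`
  (log2 fold-change of the founder's stressed doubling time) maps the current
  division time `D_G` to

      k   = max((2^{D_r} · D_fs − D_fn) / (D_fs − D_fn), 0)
      D_m = k (D_G − D_fn) + D_fn

  so successive mutations multiply their `k` factors and the division time
  never drops below the unstressed founder value `D_fn` (asserted at every
  application). The typeset form of the `k` numerator is ambiguous in the
  source; the log2 reading is the default and an `epistasis_mode="absolute"`
  switch treats `D_r` as an absolute mutant doubling time in hours.

**Engine.** Cells with identical genotype, age and due time are exchangeable,
so the engine tracks cohorts `(genotype, age, due, count)` rather than cell
objects. Mutated daughters are split off a dividing cohort by an exact pooled
draw (Poisson total assigned multinomially; binomial count of duplicated
daughters placed without replacement), so the process law is identical to the
naive per-cell queue at ~1000× the speed. The bottleneck is a multivariate
hypergeometric draw over cohort counts. Correctness is checked against an
independent per-cell enumeration oracle: for a two-type population at N = 4
the fixation probability and conditional sweep time match the exact
bottleneck Markov chain within Monte-Carlo error.

Desk-scale defaults (`N` = 5,000, `M_t` = 5, 48 replicates) keep a run in
seconds; the full-scale study values (N ≈ 50,000, 1152 replicates, 50 cycles)
are reachable through the config.

## 3. Coverage-based copy number (`mtdrift.cnv`)

Inputs are bedGraph-like depth tracks (0-based half-open); when tracks come
from alignments, reads with MAPQ < 1 are excluded upstream.

* **Windowing.** Non-overlapping tiled windows, length-weighted mean depth;
  a trailing remainder shorter than half a window merges into its neighbour.
  Aneuploidy calling uses 200 bp windows, mtDNA copy number 1 kb windows.
* **Aneuploidy.** Per-window ratio `log2(κ · w_sample / w_founder)` against a
  founder sequenced in the same flow cell, with
  `κ = Σ founder coverage / Σ sample coverage` cancelling library size. A
  chromosome is duplicated when its median ratio ≥ 0.5 (halfway to the log2=1
  expected for a haploid gaining one copy — the threshold is not stated in the
  source and is config-exposed). Founder zero-depth windows are dropped with a
  warning.
* **mtDNA copy number.** Per-window `log2(W_i / W_median,euploid)`, the
  euploid median excluding called-aneuploid chromosomes (aneuploidies are
  called first, founder-normalized, then the euploid median is formed).
  Absolute copies = `2^median(log2 ratio)` over the mtDNA, assuming one
  nuclear genome copy and no sequencing bias; the median makes the estimate
  exact as long as fewer than half the mtDNA windows are deleted. Zero-depth
  windows are floored at −10 log2 units (config-exposed) instead of −∞.
* **Segmentation.** Windows at or below −2 log2 units (≤25% of the
  euploid-relative level) are `lost`; runs shorter than 2 windows are absorbed
  into the flanking state; maximal runs become segments, which always tile the
  molecule and alternate in state. Boundaries are therefore window-quantized
  (±1 kb).
* **Petite class.** From summed retained length: ρ+ at ≥70 kb of the 77 kb
  molecule, ρ− in [2, 70) kb, ρ−− in (0, 2) kb, ρ0 at none. The ρ−− bound is
  reported as <2 kb in one place and <1 kb in another in the source; both
  thresholds are parameters.
* **Gene report.** A gene is lost when ≥50% (configurable) of its span
  overlaps lost segments.

## 4. qPCR relative copy number (`mtdrift.qpcr`)

All Ct values are capped at 30 before any arithmetic (a per-record
`force_cap` flag reproduces the manual override used for known background
signal). With ΔCt = Ct_target − Ct_reference referenced to the baseline
timepoint,

    log2 relative copy number = −(ΔCt_t − ΔCt_0),

the algebraic simplification of `log2(2^{−(ΔCt_t − ΔCt_0)})`; a unit test
asserts the two forms are equal. Replicates are averaged after the log2
transform (the source does not state the order; at the zero-noise round trip
the two orders coincide). Amplification efficiency is assumed 100% (one Ct
per twofold), matching a formula with no efficiency term. Adjacent genes
(in molecule order) whose endpoint changes agree within 0.5 log2 units
(inclusive) are grouped into concerted-change segments.

## 5. Permutation enrichment (`mtdrift.stats`)

For strains ranked by stress resistance, the statistic is the category
fraction among the top k (default 100). The null resamples k-subsets of the
universe uniformly without replacement (implemented by taking the k smallest
of n iid uniform keys per permutation, in chunks); the one-sided p-value is
`(1 + #{null ≥ observed}) / (1 + n_perm)` with `n_perm` = 1e5 by default, so
p is never 0 and its floor is `1/(n_perm+1)`. Tests compare against exhaustive
subset enumeration and the analytic hypergeometric tail on small universes.

## 6. Synthetic data (`mtdrift.synthetic`)

The generators state the world the tests live in; their defaults are the
study's conditions where stated, and field-plausible choices otherwise.

* **Growth plates.** Logistic growth in linear cell count,
  `N(t) = K / (1 + ((K−N0)/N0) 2^{−t/D})`, N0 ≈ 5e4 cells, K ≈ 2e6 (≈5.3
  doublings per 72 h cycle, inside the observed 2.5–6 range), sampled every
  20 min; multiplicative log-normal count noise; controls (93 min doubling
  time) on the 2×2 interleave; an optional linear doubling-time gradient
  along one plate axis distorts controls and samples alike.

  **Ground truth.** Because colonies start at ~2.5% of carrying capacity, the
  logistic's saturation factor (1 − N/K) keeps even the noiseless windowed
  log-slope a few percent below 1/D. The truth table therefore records both
  `true_doubling_h` (the parameter) and `realized_doubling_h` (the value the
  assay contract yields on the noiseless curve, computed with the same window
  width). Round-trip tests check recovery against the realized value — exact
  at zero noise, ≥95% within 2% at 5% noise; the estimator itself is validated
  against exact exponentials and a derivative oracle on a deep-exponential
  logistic, so the round trip is not circular in the estimator's correctness.
  A green round trip establishes noise robustness and pipeline plumbing, not
  that real colonies are logistic.
* **Coverage.** Sixteen nuclear chromosomes at reference lengths plus a 77 kb
  mtDNA; expected tile depth = `mean_depth × local copy number` (30× at copy
  1 by default, mtDNA at 20 copies); deletions as zero- or reduced-copy
  intervals; duplicated chromosomes at 2×; Poisson (default off) or
  negative-binomial noise on tile sums — real sequencing bias (GC, mappability,
  AT-rich mtDNA artefacts) is *not* emulated. The bundled mtDNA gene map uses
  invented coordinates in the field's gene order; it is a synthetic stand-in,
  not the annotated reference.
* **qPCR.** `Ct_target = Ct_ref − log2(copy_rel) + N(0, noise_sd)`; absent
  targets emitted at Ct 35, above the cap.
* **Effect tables.** 4947 genes; 10% of deletions beneficial under stress
  with reductions `38 min × Beta(1.5, 3)` — bounding the best single effects
  by the measured 31–38 min aneuploidy effects on the ~215 min adaptation
  span; the rest deleterious with an exponential (mean 25 min) cost tail;
  effectual-site counts negative-binomial with mean 300/gene (≈1.5M sites
  genome-wide, ~12% of 12 Mb — the stop-gain + deleterious-nonsynonymous
  density is not printed in the source; this choice is fixed and documented,
  not tuned). Chromosome effects: chrII −31 min, chrV −38 min, chrIII
  neutral, others deleterious under stress.

## Known limitations

* The growth estimator's long window overestimates the absolute doubling time
  of very fast growers on strongly saturating curves (uniform-enough across a
  plate that normalized comparisons are unaffected, but the back-converted
  hours inherit it).
* Segment boundaries are window-quantized; no junction-level breakpoint
  detection (deliberately out of scope, as is read alignment).
* The simulator omits mating, meiosis, ploidy change, population structure,
  essential genes and any mitochondrial genome — it is exactly the nuclear
  null model, not a model of the mtDNA editing process itself.
* The enrichment test takes category labels as given; no annotation retrieval.
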