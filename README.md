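# mtdrift

Analysis pipeline for yeast populations adapting to chronic mitochondrial
superoxide stress by mtDNA segmental deletion, covering every computational
stage of such an experiment:

* **growth** — colony doubling times from growth curves, spatial
  normalization against interleaved founder controls, generation counting,
  and adaptation accounting against the physiological floor;
* **evosim** — an individual-based simulator of serially bottlenecked
  populations with point mutations, chromosome duplications, replicative
  aging and diminishing-returns epistasis (the null model for
  nuclear-mutation-driven adaptation);
* **cnv** — windowed sequencing-coverage analysis: founder-normalized
  aneuploidy calls, absolute mtDNA copy number, segmental-deletion calling
  and petite (ρ+/ρ−/ρ−−/ρ0) classification;
* **qpcr** — ΔΔCt relative copy numbers with Ct capping and
  concerted-change gene grouping;
* **stats** — a permutation test for category enrichment among the top-k
  most resistant strains;
* **synthetic** — generators for all of the above inputs with known ground
  truth, so the whole pipeline is testable without any external data.

Who it is for: experimental-evolution and yeast-genomics groups who phenotype
colonies on plates, pool-sequence evolving populations, and want the
between-stage arithmetic (normalization, copy-number calling, null-model
simulation) as tested, reusable code rather than one-off scripts.

## The models at the core

**Doubling time and normalization.** `D` is extracted as the reciprocal of
the maximal sliding-window least-squares slope of log2 cell counts. With a
control surface interpolated over the plate,

    log2(D)_norm = log2(D) − surface(position)
    Doubling time (hours) = 2^(log2(D)_norm) · D_control,grand

**Diminishing-returns epistasis.** A mutation of effect size `D_r` (log2
fold-change of the founder's stressed doubling time `D_fs`) maps the current
division time `D_G` to

    k = max((2^(D_r) · D_fs − D_fn) / (D_fs − D_fn), 0)
    D_m = k (D_G − D_fn) + D_fn

with `D_fn` the unstressed founder doubling time acting as a floor; sequential
mutations multiply their `k` factors.

**mtDNA copy number.** Windowed depth ratios `log2(W_i / W_median,euploid)`
(euploid = nuclear chromosomes without called aneuploidies); absolute copies
`= 2^median` over the 77 kb molecule; contiguous windows ≤ −2 log2 form lost
segments; the summed retained span assigns the ρ class.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

Generate a sample whose mtDNA (20 copies) lost the 14–44 kb segment and which
gained an extra chromosome II, then recover all of it:

```python
from mtdrift.synthetic import SynthCoverageConfig, gen_coverage, mt_gene_bed
from mtdrift.cnv import AneuploidyCaller, MtdnaProfiler, map_segments_to_genes

cfg = SynthCoverageConfig(
    mt_copy_number=20.0,
    mt_deleted_intervals=[(14_000, 44_000)],
    duplicated_chroms=frozenset({"chrII"}),
    noise_model="poisson",
    seed=1,
)
sample, truth = gen_coverage(cfg)
founder, _ = gen_coverage(SynthCoverageConfig(noise_model="poisson", seed=2))

calls = AneuploidyCaller().fit(founder).predict(sample)
dup = calls.loc[calls.call == "duplicated", "chrom"].tolist()
prof = MtdnaProfiler().fit(sample, aneuploid_chroms=dup)
```

This prints (via the calls/attributes shown):

```
chrom  median_log2       call  threshold
chrII     0.977854 duplicated        0.5
mtDNA copy number: 19.98
  retained [     0,  14000)  mean log2 +4.32
  lost     [ 14000,  44000)  mean log2 -10.00
  retained [ 44000,  77000)  mean log2 +4.32
rho class: rho_minus (47 kb retained)
lost genes: ATP8, ATP6, COB, ATP9, VAR1, 21S_RRNA
```

The chromosome II duplication is called from its founder-normalized median
log2 ratio (~1.0, i.e. 2 copies in a haploid), the copy number 19.98 recovers
the simulated 20 because the median over mtDNA windows ignores the deleted
minority, the lost segment's boundaries land on the simulated 14 kb and 44 kb
edges, and 47 kb of retained sequence classifies the population as ρ−
(partial mtDNA retention).

Attribution arithmetic for the slow second adaptation phase — two chromosome
duplications reducing the stressed doubling time by 31 and 38 min, on top of
a 106 min first-phase reduction, against a 215 min maximum span:

```python
from mtdrift.growth import additive_combination, percent_max_adaptation
combined = additive_combination([31.0, 38.0])          # 69.0 min
percent_max_adaptation(308.0 - 106.0 - combined, 308.0, 93.0)   # 81.4 %
```

A thin CLI mirrors the library: `mtdrift growth`, `mtdrift simulate`,
`mtdrift cnv`, `mtdrift qpcr`, `mtdrift enrich`, `mtdrift synth-growth`
(see `mtdrift --help`).

## Acceptance script

`scripts/acceptance.py` recomputes the package's acceptance-target quantities
from scratch by running the library operations on their stated inputs and
writes them as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
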