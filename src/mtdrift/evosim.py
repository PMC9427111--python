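"""Individual-based simulator of serially bottlenecked yeast populations.

The model is the null hypothesis that swift adaptation to mitochondrial
superoxide stress could be driven by nuclear mutations alone.  A clonal
haploid population expands from a bottleneck of ``N`` cells until it
reaches ``2**M_t * N`` cells (one growth cycle), after which ``N`` cells
are subsampled uniformly without replacement to found the next cycle.

Cells divide asynchronously on a continuous-time event queue: a cell
born (or entering a cycle) at time ``t`` with division time ``D``
divides at ``t + D``, producing a daughter of replicative age 0 while
the mother's age increments.  Cells die reproductively after
``max_divisions`` divisions but remain countable.  At the end of each
division the daughter may acquire:

* point mutations, Poisson with mean ``mu_snp * genome_bp`` per
  division; a hit is *effectual* (function-abolishing: stop-gain or
  SIFT < 0.05 nonsynonymous) with probability equal to the fraction of
  the genome covered by effectual sites, in which gene proportionally
  to that gene's effectual site count, otherwise neutral;
* a whole-chromosome duplication, Bernoulli ``mu_dup`` per division, on
  a uniformly chosen not-yet-duplicated chromosome.

Genes, sites and chromosomes mutate at most once per lineage; sites on
duplicated chromosomes do not mutate.

Mutation effects act on the doubling time with diminishing returns: a
mutation of effect size ``D_r`` (log2 fold-change of the founder's
stressed doubling time) rescales the remaining gap above the
physiological floor (the founder's unstressed doubling time) by

    k = max((2**D_r * D_fs - D_fn) / (D_fs - D_fn), 0)
    D_m = k * (D_G - D_fn) + D_fn

so sequential mutations multiply their ``k`` factors and no genotype
ever drops below the floor.

Implementation note: cells with identical genotype, age and division
schedule are exchangeable, so the engine tracks *cohorts* (counts of
such cells) rather than cell objects, drawing the number of mutated
daughters per cohort division from the exact Poisson/binomial law.
The process distribution is identical to a naive per-cell event queue.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mtdrift.growth import percent_max_adaptation

#: Chromosome names of the 16 nuclear chromosomes.
CHROMOSOMES = [
    "chrI", "chrII", "chrIII", "chrIV", "chrV", "chrVI", "chrVII", "chrVIII",
    "chrIX", "chrX", "chrXI", "chrXII", "chrXIII", "chrXIV", "chrXV", "chrXVI",
]


# ---------------------------------------------------------------------------
# configuration and effect tables
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults are desk-scale: N = 5,000 cells per bottleneck, M_t = 5
    generations per cycle, 48 replicates.  Mutation rates are the
    empirical yeast rates (4.85e-5 duplications/division, 0.33e-9 point
    mutations/bp/division over a 12 Mb genome) and cells divide 12 times
    before reproductive death.
    """

    n: int = 5000
    m_t: float | list = 5.0
    n_cycles: int = 50
    mu_dup: float = 4.85e-5
    mu_snp: float = 0.33e-9
    genome_bp: int = 12_000_000
    max_divisions: int = 12
    d_founder_nostress_h: float = 93.0 / 60.0
    d_founder_stress_h: float = 308.0 / 60.0
    n_replicates: int = 48
    epistasis_mode: str = "log2"   # "log2": D_r is a log2 fold-change; "absolute": hours
    mutate_both: bool = False      # also draw mutations for the mother at division
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("bottleneck size n must be >= 1")
        if self.mu_dup < 0 or self.mu_snp < 0:
            raise ValueError("mutation rates must be non-negative")
        if self.max_divisions < 1:
            raise ValueError("max_divisions must be >= 1")
        if not self.d_founder_stress_h > self.d_founder_nostress_h:
            raise ValueError("stressed founder doubling time must exceed unstressed")
        if np.any(np.asarray(self.m_t_schedule()) <= 0):
            raise ValueError("all M_t entries must be positive")
        if self.epistasis_mode not in ("log2", "absolute"):
            raise ValueError("epistasis_mode must be 'log2' or 'absolute'")

    def m_t_schedule(self) -> np.ndarray:
        """Per-cycle generation counts, broadcast to n_cycles."""
        m = np.asarray(self.m_t, dtype=float)
        if m.ndim == 0:
            return np.full(self.n_cycles, float(m))
        if len(m) != self.n_cycles:
            raise ValueError("m_t list length must equal n_cycles")
        return m


@dataclass
class EffectTable:
    """Per-gene and per-chromosome doubling-time effects.

    ``genes`` columns: gene, d_nostress_h, d_stress_h, effectual_sites.
    ``chroms`` columns: chrom, d_nostress_h, d_stress_h (phenotype of a
    strain carrying the duplication).
    """

    genes: pd.DataFrame
    chroms: pd.DataFrame

    def __post_init__(self):
        gene_cols = {"gene", "d_nostress_h", "d_stress_h", "effectual_sites"}
        chrom_cols = {"chrom", "d_nostress_h", "d_stress_h"}
        if not gene_cols.issubset(self.genes.columns):
            raise ValueError(f"gene table must have columns {sorted(gene_cols)}")
        if not chrom_cols.issubset(self.chroms.columns):
            raise ValueError(f"chromosome table must have columns {sorted(chrom_cols)}")
        if (self.genes["d_stress_h"] <= 0).any() or (self.genes["d_nostress_h"] <= 0).any():
            raise ValueError("gene doubling times must be positive")
        if (self.genes["effectual_sites"] < 0).any():
            raise ValueError("effectual site counts must be non-negative")


class _EffectModel:
    """Arrays precomputed from an EffectTable for fast mutation sampling."""

    def __init__(self, table: EffectTable, config: SimConfig):
        g = table.genes
        self.gene_names = g["gene"].to_numpy()
        self.sites = g["effectual_sites"].to_numpy(dtype=np.int64)
        self.total_sites = int(self.sites.sum())
        if self.total_sites > config.genome_bp:
            raise ValueError("effectual sites exceed genome size")
        self.cum_sites = np.cumsum(self.sites)
        fs = config.d_founder_stress_h
        if config.epistasis_mode == "log2":
            self.gene_dr = np.log2(g["d_stress_h"].to_numpy(dtype=float) / fs)
        else:
            self.gene_dr = g["d_stress_h"].to_numpy(dtype=float)
        c = table.chroms.set_index("chrom")
        self.chrom_names = [ch for ch in CHROMOSOMES if ch in c.index]
        if config.epistasis_mode == "log2":
            self.chrom_dr = {ch: float(np.log2(c.loc[ch, "d_stress_h"] / fs))
                             for ch in self.chrom_names}
        else:
            self.chrom_dr = {ch: float(c.loc[ch, "d_stress_h"]) for ch in self.chrom_names}


# ---------------------------------------------------------------------------
# epistasis
# ---------------------------------------------------------------------------

def apply_mutation_effect(d_g: float, d_r: float, d_founder_stress: float,
                          d_founder_nostress: float, mode: str = "log2") -> float:
    """Doubling time after a mutation, under diminishing-returns epistasis.

    ``d_r`` is the mutation's effect size assuming no epistasis: by
    default the log2 fold-change it would impose on the founder's
    stressed doubling time (``mode="log2"``), alternatively the absolute
    mutant doubling time in hours (``mode="absolute"``).
    """
    if not d_founder_stress > d_founder_nostress:
        raise ValueError("degenerate founder phenotypes: stress must exceed no-stress")
    if d_g < d_founder_nostress - 1e-12:
        raise ValueError("genotype doubling time below the physiological floor")
    if mode == "log2":
        mutant_alone = 2.0 ** d_r * d_founder_stress
    elif mode == "absolute":
        mutant_alone = d_r
    else:
        raise ValueError("mode must be 'log2' or 'absolute'")
    k = max((mutant_alone - d_founder_nostress)
            / (d_founder_stress - d_founder_nostress), 0.0)
    d_m = k * (d_g - d_founder_nostress) + d_founder_nostress
    d_m = max(d_m, d_founder_nostress)
    assert d_m >= d_founder_nostress - 1e-12
    return d_m


# ---------------------------------------------------------------------------
# cells, genotypes, populations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Genotype:
    gid: int
    division_time_h: float
    mutated_genes: frozenset
    duplicated_chroms: frozenset
    n_neutral: int = 0
    parent: int | None = None


@dataclass
class CellState:
    """A single simulated cell, for small-scale tests and audits."""

    mutated_genes: set = field(default_factory=set)
    duplicated_chroms: set = field(default_factory=set)
    division_time_h: float = 0.0
    divisions_used: int = 0
    next_division_due: float = 0.0


@dataclass
class MutationEvent:
    kind: str          # "point" | "duplication"
    target: str | None  # gene or chromosome; None for a neutral hit
    d_r: float
    effectual: bool


class Population:
    """A population as cohorts of exchangeable cells.

    Each cohort is (genotype id, replicative age, count).  Genotypes are
    kept in a registry with parent pointers so lineages can be audited.
    """

    def __init__(self, genotypes: dict[int, Genotype], cohorts: list[tuple[int, int, int]]):
        self.genotypes = genotypes
        self.cohorts = [(gid, age, cnt) for gid, age, cnt in cohorts if cnt > 0]
        self._next_gid = max(genotypes) + 1 if genotypes else 0

    @classmethod
    def founders(cls, n: int, config: SimConfig) -> "Population":
        g0 = Genotype(0, config.d_founder_stress_h, frozenset(), frozenset())
        return cls({0: g0}, [(0, 0, n)])

    @classmethod
    def from_cells(cls, cells: list[CellState]) -> "Population":
        genotypes: dict[int, Genotype] = {}
        key_to_gid: dict[tuple, int] = {}
        counts: dict[tuple[int, int], int] = {}
        for cell in cells:
            key = (cell.division_time_h, frozenset(cell.mutated_genes),
                   frozenset(cell.duplicated_chroms))
            if key not in key_to_gid:
                gid = len(key_to_gid)
                key_to_gid[key] = gid
                genotypes[gid] = Genotype(gid, key[0], key[1], key[2])
            gid = key_to_gid[key]
            counts[(gid, cell.divisions_used)] = counts.get((gid, cell.divisions_used), 0) + 1
        return cls(genotypes, [(g, a, c) for (g, a), c in counts.items()])

    @property
    def size(self) -> int:
        return sum(c for _, _, c in self.cohorts)

    def to_cells(self) -> list[CellState]:
        cells = []
        for gid, age, cnt in self.cohorts:
            g = self.genotypes[gid]
            for _ in range(cnt):
                cells.append(CellState(set(g.mutated_genes), set(g.duplicated_chroms),
                                       g.division_time_h, age))
        return cells

    def mean_division_time(self) -> float:
        tot = self.size
        return sum(self.genotypes[g].division_time_h * c for g, _, c in self.cohorts) / tot

    def new_gid(self) -> int:
        gid = self._next_gid
        self._next_gid += 1
        return gid


# ---------------------------------------------------------------------------
# mutation drawing
# ---------------------------------------------------------------------------

def _mutate_genotype(pop: Population, parent: Genotype, n_pt: int, n_dup: int,
                     rng: np.random.Generator, config: SimConfig,
                     model: _EffectModel) -> tuple[Genotype, list[MutationEvent]]:
    """Create a derived genotype after ``n_pt`` point hits and ``n_dup`` duplications."""
    genes = set(parent.mutated_genes)
    chroms = set(parent.duplicated_chroms)
    n_neutral = parent.n_neutral
    d = parent.division_time_h
    events: list[MutationEvent] = []
    for _ in range(n_pt):
        # A uniform position in the genome; hits inside the effectual-site
        # pool abolish that gene's function, all other hits are neutral.
        # Genes already mutated in this lineage are excluded (sites mutate
        # once); rejection is cheap since lineages carry few mutations.
        for _attempt in range(1000):
            r = int(rng.integers(config.genome_bp))
            if r >= model.total_sites:
                gene = None
                break
            gi = int(np.searchsorted(model.cum_sites, r, side="right"))
            if model.gene_names[gi] not in genes:
                gene = gi
                break
        else:  # pragma: no cover - pathological table with all genes mutated
            gene = None
        if gene is None:
            n_neutral += 1
            events.append(MutationEvent("point", None, 0.0, False))
        else:
            name = model.gene_names[gene]
            d_r = float(model.gene_dr[gene])
            d = apply_mutation_effect(d, d_r, config.d_founder_stress_h,
                                      config.d_founder_nostress_h, config.epistasis_mode)
            genes.add(name)
            events.append(MutationEvent("point", name, d_r, True))
    for _ in range(n_dup):
        available = [ch for ch in model.chrom_names if ch not in chroms]
        if not available:
            continue
        ch = available[int(rng.integers(len(available)))]
        d_r = model.chrom_dr[ch]
        d = apply_mutation_effect(d, d_r, config.d_founder_stress_h,
                                  config.d_founder_nostress_h, config.epistasis_mode)
        chroms.add(ch)
        events.append(MutationEvent("duplication", ch, d_r, True))
    child = Genotype(pop.new_gid(), d, frozenset(genes), frozenset(chroms),
                     n_neutral, parent.gid)
    pop.genotypes[child.gid] = child
    return child, events


def draw_mutations(rng: np.random.Generator, mu_snp: float, mu_dup: float,
                   genome_bp: int, effect_table: EffectTable,
                   cell: CellState, config: SimConfig | None = None,
                   _model: _EffectModel | None = None) -> list[MutationEvent]:
    """Draw the mutation events for one cell division (per-cell API).

    Point-mutation count is Poisson(mu_snp * genome_bp); a duplication
    occurs with probability mu_dup on a uniformly chosen not-yet-
    duplicated chromosome.  The cell is updated in place.
    """
    if config is None:
        config = SimConfig(mu_snp=mu_snp, mu_dup=mu_dup, genome_bp=genome_bp)
    model = _model if _model is not None else _EffectModel(effect_table, config)
    n_pt = int(rng.poisson(mu_snp * genome_bp))
    n_dup = int(rng.random() < mu_dup)
    if n_pt == 0 and n_dup == 0:
        return []
    pop = Population({0: Genotype(0, cell.division_time_h,
                                  frozenset(cell.mutated_genes),
                                  frozenset(cell.duplicated_chroms))}, [(0, 0, 1)])
    child, events = _mutate_genotype(pop, pop.genotypes[0], n_pt, n_dup, rng, config, model)
    cell.mutated_genes = set(child.mutated_genes)
    cell.duplicated_chroms = set(child.duplicated_chroms)
    cell.division_time_h = child.division_time_h
    return events


# ---------------------------------------------------------------------------
# growth-cycle engine
# ---------------------------------------------------------------------------

def run_cycle(pop: Population, m_t: float, rng: np.random.Generator,
              config: SimConfig, effect_table: EffectTable,
              _model: _EffectModel | None = None) -> tuple[Population, dict]:
    """Run one growth cycle: expand to 2**m_t * N cells, then bottleneck to N.

    Cells divide on an event queue ordered by next division time (ties
    broken by insertion order); the population cap check runs after each
    division, so the final division wave may be partial.  If every cell
    reaches ``max_divisions`` before the cap, the cycle ends early with
    ``capped=False``.
    """
    model = _model if _model is not None else _EffectModel(effect_table, config)
    n0 = pop.size
    cap = int(round(2.0 ** m_t * n0))
    lam = config.mu_snp * config.genome_bp

    heap: list[list] = []   # [due, seq, gid, age, count]
    seq = 0
    inert: dict[tuple[int, int], int] = {}   # (gid, age) -> count, non-dividing
    for gid, age, cnt in pop.cohorts:
        if age < config.max_divisions:
            heapq.heappush(heap, [pop.genotypes[gid].division_time_h, seq, gid, age, cnt])
            seq += 1
        else:
            inert[(gid, age)] = inert.get((gid, age), 0) + cnt

    total = n0
    t = 0.0
    capped = False

    def place_cells(gid: int, n_cells: int, age: int, born_at: float):
        """Place n_cells of genotype gid at a given age, drawing mutations exactly.

        Each cell independently receives Poisson(lam) point hits and a
        Bernoulli(mu_dup) duplication; the per-cell law is recovered via
        a pooled Poisson draw assigned multinomially plus a binomial
        count of duplicated cells.
        """
        nonlocal seq
        parent = pop.genotypes[gid]
        n_pt_total = int(rng.poisson(lam * n_cells)) if lam > 0 else 0
        n_dup_total = int(rng.binomial(n_cells, config.mu_dup)) if config.mu_dup > 0 else 0
        pt_hits: dict[int, int] = {}
        if n_pt_total:
            for i in rng.integers(0, n_cells, n_pt_total):
                pt_hits[int(i)] = pt_hits.get(int(i), 0) + 1
        dup_idx = (set(int(i) for i in rng.choice(n_cells, n_dup_total, replace=False))
                   if n_dup_total else set())
        affected = set(pt_hits) | dup_idx
        n_plain = n_cells - len(affected)
        if n_plain:
            if age < config.max_divisions:
                heapq.heappush(heap, [born_at + parent.division_time_h, seq,
                                      gid, age, n_plain])
                seq += 1
            else:
                inert[(gid, age)] = inert.get((gid, age), 0) + n_plain
        for i in affected:
            child, _ = _mutate_genotype(pop, parent, pt_hits.get(i, 0),
                                        int(i in dup_idx), rng, config, model)
            if age < config.max_divisions:
                heapq.heappush(heap, [born_at + child.division_time_h, seq,
                                      child.gid, age, 1])
                seq += 1
            else:
                inert[(child.gid, age)] = inert.get((child.gid, age), 0) + 1

    while heap:
        due, _, gid, age, cnt = heapq.heappop(heap)
        t = due
        n_div = min(cnt, cap - total)
        if n_div <= 0:
            inert[(gid, age)] = inert.get((gid, age), 0) + cnt
            capped = True
            break
        if n_div < cnt:   # cap reached mid-cohort; the rest never divide
            inert[(gid, age)] = inert.get((gid, age), 0) + (cnt - n_div)
        new_age = age + 1
        if config.mutate_both:
            # optional reading: both post-division cells draw mutations
            place_cells(gid, n_div, new_age, t)
        elif new_age < config.max_divisions:
            heapq.heappush(heap, [t + pop.genotypes[gid].division_time_h, seq,
                                  gid, new_age, n_div])
            seq += 1
        else:
            inert[(gid, new_age)] = inert.get((gid, new_age), 0) + n_div
        place_cells(gid, n_div, 0, t)
        total += n_div
        if total >= cap:
            capped = True
            break

    # Collect the whole population: pending heap entries + inert cells.
    counts: dict[tuple[int, int], int] = dict(inert)
    for _, _, gid, age, cnt in heap:
        counts[(gid, age)] = counts.get((gid, age), 0) + cnt

    keys = list(counts)
    cvec = np.array([counts[k] for k in keys], dtype=np.int64)
    n_sample = min(n0, int(cvec.sum()))
    taken = rng.multivariate_hypergeometric(cvec, n_sample)
    survivors = [(gid, age, int(k)) for (gid, age), k in zip(keys, taken) if k > 0]
    new_pop = Population(pop.genotypes, survivors)
    new_pop._next_gid = pop._next_gid
    info = {"capped": capped, "final_size": int(cvec.sum()), "t_end_h": t,
            "sampled": n_sample}
    return new_pop, info


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """Replicate trajectories plus per-cycle mutation frequencies."""

    trajectory: pd.DataFrame   # replicate, cycle, generation, mean_d_h, final_size, capped
    mutations: pd.DataFrame    # replicate, cycle, kind, target, count (among survivors)
    config: SimConfig


def _survivor_mutation_counts(pop: Population) -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    for gid, _, cnt in pop.cohorts:
        g = pop.genotypes[gid]
        for gene in g.mutated_genes:
            counts[("point", gene)] = counts.get(("point", gene), 0) + cnt
        for ch in g.duplicated_chroms:
            counts[("duplication", ch)] = counts.get(("duplication", ch), 0) + cnt
    return counts


def run_experiment(config: SimConfig, effect_table: EffectTable) -> SimResult:
    """Run ``config.n_replicates`` independent serial-passage simulations."""
    m_schedule = config.m_t_schedule()
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    model_cfg = _EffectModel(effect_table, config)
    traj_rows = []
    mut_rows = []
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        pop = Population.founders(config.n, config)
        gen = 0.0
        traj_rows.append((rep, 0, 0.0, pop.mean_division_time(), pop.size, True))
        for cycle in range(config.n_cycles):
            pop, info = run_cycle(pop, float(m_schedule[cycle]), rng, config,
                                  effect_table, _model=model_cfg)
            gen += float(m_schedule[cycle])
            traj_rows.append((rep, cycle + 1, gen, pop.mean_division_time(),
                              info["final_size"], info["capped"]))
            for (kind, target), cnt in _survivor_mutation_counts(pop).items():
                mut_rows.append((rep, cycle + 1, kind, target, cnt))
    trajectory = pd.DataFrame(
        traj_rows,
        columns=["replicate", "cycle", "generation", "mean_d_h", "final_size", "capped"],
    )
    mutations = pd.DataFrame(
        mut_rows, columns=["replicate", "cycle", "kind", "target", "count"]
    )
    return SimResult(trajectory=trajectory, mutations=mutations, config=config)


def summarize_trajectory(result: SimResult, d_floor_h: float | None = None,
                         d_init_h: float | None = None) -> pd.DataFrame:
    """Cross-replicate mean adaptation curves on the generations axis.

    Returns per-cycle mean and SEM of the doubling time, the mean log2
    fold reduction relative to the initial stressed doubling time, and
    the mean percent of the maximum possible reduction.  SEM is NaN for
    a single replicate.
    """
    if result.trajectory.empty:
        raise ValueError("empty simulation result")
    cfg = result.config
    d_init = cfg.d_founder_stress_h if d_init_h is None else d_init_h
    d_floor = cfg.d_founder_nostress_h if d_floor_h is None else d_floor_h
    df = result.trajectory.copy()
    df["log2_fold_reduction"] = np.log2(d_init / df["mean_d_h"])
    df["percent_of_max"] = percent_max_adaptation(
        df["mean_d_h"].to_numpy(), d_init, d_floor
    )
    grp = df.groupby(["cycle", "generation"])
    out = grp.agg(
        mean_d_h=("mean_d_h", "mean"),
        sem_d_h=("mean_d_h", lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan),
        log2_fold_reduction=("log2_fold_reduction", "mean"),
        percent_of_max=("percent_of_max", "mean"),
        n_replicates=("mean_d_h", "size"),
    ).reset_index()
    return out
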