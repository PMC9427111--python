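"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here, so each
analysis stage is testable as a round trip against the truth the
generator wrote down:

* colony growth-curve plates with interleaved founder controls and a
  configurable spatial doubling-time gradient (logistic growth in
  linear cell count, multiplicative log-normal count noise);
* sequencing depth tracks over the 16 nuclear chromosomes plus a 77 kb
  mtDNA, with configurable mtDNA copy number, segmental deletions,
  whole-chromosome duplications and Poisson / negative-binomial count
  noise;
* qPCR Ct tables derived from true relative copy numbers (100%
  amplification efficiency: one Ct unit per twofold);
* per-gene / per-chromosome doubling-time effect tables emulating a
  deletion-collection screen.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mtdrift.evosim import CHROMOSOMES, EffectTable

#: Nuclear chromosome lengths (bp) of the S. cerevisiae reference, plus a
#: 77 kb mitochondrial genome.
DEFAULT_CHROM_LENGTHS: dict[str, int] = {
    "chrI": 230_218, "chrII": 813_184, "chrIII": 316_620, "chrIV": 1_531_933,
    "chrV": 576_874, "chrVI": 270_161, "chrVII": 1_090_940, "chrVIII": 562_643,
    "chrIX": 439_888, "chrX": 745_751, "chrXI": 666_816, "chrXII": 1_078_177,
    "chrXIII": 924_431, "chrXIV": 784_333, "chrXV": 1_091_291, "chrXVI": 948_066,
    "chrM": 77_000,
}

#: Synthetic stand-in gene map for the 77 kb mtDNA (name, start, end, strand).
#: Gene order follows the molecule; coordinates are invented for testing,
#: not the annotated reference positions.
MT_GENES: list[tuple[str, int, int, str]] = [
    ("15S_RRNA", 1_000, 3_500, "+"),
    ("COX1", 6_000, 19_000, "+"),
    ("ATP8", 20_500, 21_000, "+"),
    ("ATP6", 22_000, 22_800, "+"),
    ("COB", 25_000, 32_000, "+"),
    ("ATP9", 34_500, 34_800, "+"),
    ("VAR1", 36_500, 37_700, "+"),
    ("21S_RRNA", 40_000, 44_300, "+"),
    ("COX2", 50_000, 50_800, "+"),
    ("COX3", 58_000, 58_800, "+"),
    ("RPM1", 60_000, 60_500, "+"),
]


def mt_gene_bed() -> pd.DataFrame:
    """The synthetic mtDNA gene map as a BED6-shaped DataFrame."""
    return pd.DataFrame(
        [("chrM", s, e, name, 0, strand) for name, s, e, strand in MT_GENES],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )


# ---------------------------------------------------------------------------
# growth plates
# ---------------------------------------------------------------------------

@dataclass
class SynthGrowthConfig:
    """Stated world for a synthetic colony-growth plate.

    Defaults mirror the assay: 384-position plates imaged every 20 min
    over a 72 h growth cycle, colonies starting near 5e4 cells and
    saturating near 2e6, founder controls at every fourth position with
    a 93 min doubling time.
    """

    n_rows: int = 16
    n_cols: int = 24
    control_period: int = 4
    control_layout: str = "subgrid"   # "subgrid" (physical interleave) | "flat"
    control_doubling_h: float = 93.0 / 60.0
    true_doubling_h: float | dict = 2.5
    gradient_amplitude: float = 0.0
    gradient_axis: str = "col"
    n0_mean: float = 5e4
    n0_cv: float = 0.0
    carrying_capacity: float = 2e6
    sampling_interval_h: float = 1.0 / 3.0
    duration_h: float = 72.0
    noise_cv: float = 0.0
    truth_window: int = 41  # window used for the realized-doubling ground truth
    seed: int = 0

    def __post_init__(self):
        if self.control_period < 2:
            raise ValueError("control_period must be >= 2")
        if self.control_layout not in ("subgrid", "flat"):
            raise ValueError("control_layout must be 'subgrid' or 'flat'")
        if self.gradient_axis not in ("row", "col"):
            raise ValueError("gradient_axis must be 'row' or 'col'")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.duration_h <= 0 or self.sampling_interval_h <= 0:
            raise ValueError("duration and sampling interval must be positive")
        if self.carrying_capacity <= self.n0_mean or self.n0_mean <= 0:
            raise ValueError("carrying capacity must exceed the initial size > 0")
        if self.noise_cv < 0 or self.n0_cv < 0:
            raise ValueError("noise levels must be non-negative")
        slowest = max(self._base_doubling().values())
        if slowest <= 0 or self.control_doubling_h <= 0:
            raise ValueError("all doubling times must be positive")
        if self.duration_h < 5 * slowest * (1 + abs(self.gradient_amplitude)):
            raise ValueError("duration must cover >= 5 doublings of the slowest position")

    def is_control(self, r: int, c: int) -> bool:
        """Control-position predicate.

        ``subgrid`` places the controls on a regular 2-D lattice covering
        1/control_period of positions (the physical pinning interleave:
        e.g. every other row x every other column for period 4), which
        covers both plate axes; ``flat`` marks every k-th position in
        row-major order.
        """
        if self.control_layout == "flat":
            return (r * self.n_cols + c) % self.control_period == 0
        p_r = int(np.sqrt(self.control_period))
        while self.control_period % p_r:
            p_r -= 1
        p_c = self.control_period // p_r
        return (r % p_r == 0) and (c % p_c == 0)

    def _base_doubling(self) -> dict[tuple[int, int], float]:
        out = {}
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                if self.is_control(r, c):
                    out[(r, c)] = self.control_doubling_h
                elif isinstance(self.true_doubling_h, dict):
                    out[(r, c)] = float(self.true_doubling_h[(r, c)])
                else:
                    out[(r, c)] = float(self.true_doubling_h)
        return out


@dataclass
class PlateSet:
    """Long-format growth curves, plate layout and the generator's truth.

    The truth table carries two doubling times per position:
    ``true_doubling_h`` is the logistic parameter D_pos (gradient
    included), while ``realized_doubling_h`` is the doubling time the
    assay contract measures on the *noiseless* curve — the reciprocal of
    the maximal sliding-window log2 slope.  The two differ by the
    saturation factor (1 - N/K) of the logistic, a few percent when
    colonies start at ~2.5% of carrying capacity, so round-trip recovery
    is exact (zero noise) or tight (noisy) against the realized value
    and only approximate against the raw parameter.
    """

    curves: pd.DataFrame    # plate, row, col, time_h, cells
    layout: pd.DataFrame    # row, col, is_control
    truth: pd.DataFrame     # row, col, is_control, base/true/realized doubling, n0


def _max_window_slope(times: np.ndarray, log2_counts: np.ndarray, window: int) -> float:
    """Max least-squares slope of log2 counts over sliding windows."""
    n = len(times)
    best = -np.inf
    for i in range(n - window + 1):
        t = times[i:i + window]
        y = log2_counts[i:i + window]
        tc = t - t.mean()
        best = max(best, float((tc * (y - y.mean())).sum() / (tc ** 2).sum()))
    return best


def gen_growth_plate(cfg: SynthGrowthConfig) -> PlateSet:
    """Generate one plate of logistic growth curves with spatial gradient.

    Counts follow N(t) = K / (1 + ((K - N0)/N0) * 2**(-t / D_pos)) with
    D_pos the position's doubling time inflated linearly along the
    column axis by ``gradient_amplitude`` (0.1 = 10% slower at the far
    edge).  Controls sit at every ``control_period``-th flattened
    position and carry the control genotype's doubling time; the
    gradient distorts controls and samples alike, which is what the
    spatial normalization downstream relies on.
    """
    rng = np.random.default_rng(cfg.seed)
    times = np.arange(0.0, cfg.duration_h + 1e-9, cfg.sampling_interval_h)
    base = cfg._base_doubling()
    axis_len = max((cfg.n_rows if cfg.gradient_axis == "row" else cfg.n_cols) - 1, 1)
    realized_cache: dict[float, float] = {}
    rows_c, rows_t, rows_truth = [], [], []
    for r in range(cfg.n_rows):
        for c in range(cfg.n_cols):
            is_control = cfg.is_control(r, c)
            pos_on_axis = r if cfg.gradient_axis == "row" else c
            d_pos = base[(r, c)] * (1.0 + cfg.gradient_amplitude * pos_on_axis / axis_len)
            if cfg.n0_cv > 0:
                sigma = np.sqrt(np.log1p(cfg.n0_cv ** 2))
                n0 = cfg.n0_mean * np.exp(rng.normal(-sigma ** 2 / 2, sigma))
            else:
                n0 = cfg.n0_mean
            k = cfg.carrying_capacity
            counts = k / (1.0 + ((k - n0) / n0) * 2.0 ** (-times / d_pos))
            if cfg.n0_cv == 0:   # same noiseless shape for equal D_pos
                if d_pos not in realized_cache:
                    realized_cache[d_pos] = 1.0 / _max_window_slope(
                        times, np.log2(counts), cfg.truth_window)
                realized = realized_cache[d_pos]
            else:
                realized = 1.0 / _max_window_slope(times, np.log2(counts),
                                                   cfg.truth_window)
            if cfg.noise_cv > 0:
                sigma = np.sqrt(np.log1p(cfg.noise_cv ** 2))
                counts = counts * np.exp(rng.normal(-sigma ** 2 / 2, sigma, len(times)))
            rows_c.append(pd.DataFrame({
                "plate": 0, "row": r, "col": c, "time_h": times, "cells": counts,
            }))
            rows_t.append((r, c, bool(is_control)))
            rows_truth.append((r, c, bool(is_control), base[(r, c)], d_pos, realized, n0))
    curves = pd.concat(rows_c, ignore_index=True)
    layout = pd.DataFrame(rows_t, columns=["row", "col", "is_control"])
    truth = pd.DataFrame(
        rows_truth,
        columns=["row", "col", "is_control", "base_doubling_h", "true_doubling_h",
                 "realized_doubling_h", "n0"],
    )
    return PlateSet(curves=curves, layout=layout, truth=truth)


# ---------------------------------------------------------------------------
# coverage tracks
# ---------------------------------------------------------------------------

@dataclass
class SynthCoverageConfig:
    """Stated world for a synthetic whole-genome depth track.

    ``mt_deleted_intervals`` are 0-based half-open bp intervals on the
    mitochondrial genome at copy number ``mt_deleted_copy`` (0 = clean
    segmental deletion).  ``mean_depth`` is the per-bp depth of a
    single-copy locus.
    """

    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    mt_chrom: str = "chrM"
    mt_copy_number: float = 20.0
    mt_deleted_intervals: list[tuple[int, int]] = field(default_factory=list)
    mt_deleted_copy: float = 0.0
    duplicated_chroms: frozenset = frozenset()
    mean_depth: float = 30.0
    noise_model: str = "none"      # none | poisson | negative-binomial
    nb_dispersion: float = 10.0    # NB shape: larger = closer to Poisson
    tile_bp: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.mt_chrom not in self.chrom_lengths:
            raise ValueError("mt_chrom missing from chrom_lengths")
        if self.noise_model not in ("none", "poisson", "negative-binomial"):
            raise ValueError("unknown noise model")
        if self.tile_bp < 1:
            raise ValueError("tile_bp must be >= 1")
        mt_len = self.chrom_lengths[self.mt_chrom]
        ivs = sorted(self.mt_deleted_intervals)
        for s, e in ivs:
            if not (0 <= s < e <= mt_len):
                raise ValueError("deleted intervals must lie within the mtDNA")
        for (_, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError("deleted intervals must not overlap")
        unknown = set(self.duplicated_chroms) - set(self.chrom_lengths)
        if unknown:
            raise ValueError(f"unknown duplicated chromosomes: {sorted(unknown)}")


def gen_coverage(cfg: SynthCoverageConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a tiled bedGraph-style depth track plus its ground truth.

    Expected depth of a tile is ``mean_depth`` times the local copy
    number (length-weighted where a tile straddles a deletion edge);
    noise, when enabled, is applied to the tile's read-equivalent sum.
    """
    rng = np.random.default_rng(cfg.seed)
    frames = []
    for chrom, length in cfg.chrom_lengths.items():
        edges = np.arange(0, length, cfg.tile_bp, dtype=np.int64)
        starts = edges
        ends = np.minimum(starts + cfg.tile_bp, length)
        widths = (ends - starts).astype(float)
        if chrom == cfg.mt_chrom:
            copy = np.full(len(starts), cfg.mt_copy_number, dtype=float)
            for s, e in cfg.mt_deleted_intervals:
                overlap = (np.minimum(ends, e) - np.maximum(starts, s)).clip(min=0)
                frac = overlap / widths
                copy = copy * (1 - frac) + cfg.mt_deleted_copy * frac
        elif chrom in cfg.duplicated_chroms:
            copy = np.full(len(starts), 2.0)
        else:
            copy = np.ones(len(starts))
        expected_sum = cfg.mean_depth * copy * widths
        if cfg.noise_model == "poisson":
            depth = rng.poisson(expected_sum) / widths
        elif cfg.noise_model == "negative-binomial":
            r = cfg.nb_dispersion
            p = r / (r + expected_sum)
            depth = np.where(expected_sum > 0,
                             rng.negative_binomial(r, np.clip(p, 1e-12, 1.0)), 0.0) / widths
        else:
            depth = expected_sum / widths
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends, "depth": depth,
        }))
    track = pd.concat(frames, ignore_index=True)
    truth = {
        "mt_chrom": cfg.mt_chrom,
        "mt_copy_number": cfg.mt_copy_number,
        "mt_deleted_intervals": [list(iv) for iv in sorted(cfg.mt_deleted_intervals)],
        "mt_deleted_copy": cfg.mt_deleted_copy,
        "duplicated_chroms": sorted(cfg.duplicated_chroms),
        "mean_depth": cfg.mean_depth,
    }
    return track, truth


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------

def gen_qpcr(truth: pd.DataFrame, noise_sd: float = 0.0, seed: int = 0,
             n_replicates: int = 2, ct_reference: float = 15.0,
             absent_ct: float = 35.0) -> pd.DataFrame:
    """Generate a Ct table from true relative copy numbers.

    ``truth`` needs columns gene, timepoint, copy_rel (copy number
    relative to the single-copy nuclear reference).  With 100%
    amplification efficiency, Ct_target = Ct_ref - log2(copy_rel) plus
    Gaussian noise; genes with copy_rel <= 0 are emitted at
    ``absent_ct``, above the downstream Ct cap of 30.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    required = {"gene", "timepoint", "copy_rel"}
    if not required.issubset(truth.columns):
        raise ValueError(f"truth table must have columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    rows = []
    for _, rec in truth.iterrows():
        for rep in range(n_replicates):
            if rec["copy_rel"] > 0:
                ct = ct_reference - np.log2(rec["copy_rel"])
                if noise_sd > 0:
                    ct += rng.normal(0.0, noise_sd)
            else:
                ct = absent_ct
            rows.append((rec["gene"], rec["timepoint"], rep, ct, ct_reference))
    return pd.DataFrame(
        rows, columns=["gene", "timepoint", "replicate", "ct_target", "ct_reference"]
    )


# ---------------------------------------------------------------------------
# effect tables
# ---------------------------------------------------------------------------

@dataclass
class SynthEffectConfig:
    """Stated world for a synthetic deletion-collection effect screen.

    4947 nuclear protein-coding genes on a 12 Mb genome.  A minority of
    gene deletions is beneficial under stress, with reductions bounded
    by the best measured single effects (the 31–38 min chromosome
    duplication effects on a ~215 min adaptation span); most are
    neutral-to-deleterious.  Chromosome II and V duplications reduce the
    stressed doubling time by 31 and 38 min, chromosome III is neutral,
    the others are deleterious under stress — mirroring the measured
    aneuploidy panel.
    """

    n_genes: int = 4947
    genome_bp: int = 12_000_000
    fraction_beneficial_in_stress: float = 0.10
    max_beneficial_reduction_min: float = 38.0
    deleterious_mean_min: float = 25.0
    nostress_deleterious_mean_min: float = 10.0
    effectual_sites_mean: float = 300.0
    effectual_sites_shape: float = 5.0
    d_founder_nostress_h: float = 93.0 / 60.0
    d_founder_stress_h: float = 308.0 / 60.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not 0 <= self.fraction_beneficial_in_stress <= 1:
            raise ValueError("fraction_beneficial_in_stress must be in [0, 1]")
        if self.d_founder_stress_h <= self.d_founder_nostress_h:
            raise ValueError("stressed founder doubling time must exceed unstressed")
        if self.effectual_sites_mean * self.n_genes > self.genome_bp:
            raise ValueError("expected effectual sites exceed the genome size")


def gen_effect_tables(cfg: SynthEffectConfig) -> EffectTable:
    """Generate per-gene and per-chromosome doubling-time effect tables."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    fs = cfg.d_founder_stress_h
    fn = cfg.d_founder_nostress_h

    beneficial = rng.random(n) < cfg.fraction_beneficial_in_stress
    stress = np.empty(n)
    # beneficial deletions: reductions up to the best measured single effects
    red_min = cfg.max_beneficial_reduction_min * rng.beta(1.5, 3.0, n)
    stress[beneficial] = fs - red_min[beneficial] / 60.0
    # deleterious/neutral deletions: exponential cost tail
    cost_min = rng.exponential(cfg.deleterious_mean_min, n)
    stress[~beneficial] = fs + cost_min[~beneficial] / 60.0
    stress = np.clip(stress, fn, None)

    nostress = fn + rng.exponential(cfg.nostress_deleterious_mean_min, n) / 60.0

    p = cfg.effectual_sites_shape / (cfg.effectual_sites_shape + cfg.effectual_sites_mean)
    sites = rng.negative_binomial(cfg.effectual_sites_shape, p, n).astype(np.int64)
    if sites.sum() > cfg.genome_bp:  # pragma: no cover - config validation bounds this
        raise ValueError("generated effectual sites exceed genome size")

    genes = pd.DataFrame({
        "gene": [f"GENE{i:04d}" for i in range(1, n + 1)],
        "d_nostress_h": nostress,
        "d_stress_h": stress,
        "effectual_sites": sites,
    })

    chrom_rows = []
    for ch in CHROMOSOMES:
        if ch == "chrII":
            d_stress = fs - 31.0 / 60.0
        elif ch == "chrV":
            d_stress = fs - 38.0 / 60.0
        elif ch == "chrIII":
            d_stress = fs
        else:
            d_stress = fs + rng.uniform(5.0, 40.0) / 60.0
        d_nostress = fn + rng.uniform(5.0, 30.0) / 60.0
        chrom_rows.append((ch, d_nostress, d_stress))
    chroms = pd.DataFrame(chrom_rows, columns=["chrom", "d_nostress_h", "d_stress_h"])
    return EffectTable(genes=genes, chroms=chroms)
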