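"""Windowed-coverage copy-number analysis.

Nuclear aneuploidies are called from 200 bp windows normalized against a
founder sample sequenced on the same flow cell (depth-ratio scaling
factor kappa cancels library-size differences); mitochondrial copy
number is estimated from 1 kb windows normalized to the euploid nuclear
median, with the absolute copy count read off as 2**median(log2 ratio)
over the mtDNA.  Contiguous lost/retained blocks of the mtDNA and the
derived petite class (rho+, rho-, rho--, rho0) follow.

Depth tracks are consumed as bedGraph-like tables (chrom, start, end,
depth; 0-based half-open).  Reads with MAPQ < 1 are assumed excluded
upstream when the tracks were computed from alignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

ZERO_DEPTH_FLOOR = -10.0  # log2 ratio assigned to zero-depth windows


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def window_depth(track: pd.DataFrame, window_bp: int) -> pd.DataFrame:
    """Mean depth in tiled, non-overlapping windows.

    A trailing partial window shorter than half the window size is
    merged into its neighbour; longer remainders are kept as their own
    window.  Uncovered basepairs count as zero depth.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    required = {"chrom", "start", "end", "depth"}
    if not required.issubset(track.columns):
        raise ValueError(f"track must have columns {sorted(required)}")
    if len(track) == 0:
        raise ValueError("empty depth track")
    out = []
    for chrom, grp in track.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        depths = grp["depth"].to_numpy(dtype=float)
        if np.any(starts >= ends) or np.any(depths < 0):
            raise ValueError("malformed depth track")
        length = int(ends.max())
        edges = list(range(0, length, window_bp)) + [length]
        if len(edges) >= 3 and (edges[-1] - edges[-2]) < window_bp / 2:
            del edges[-2]  # merge short trailing remainder into the last window
        edges = np.asarray(edges, dtype=np.int64)
        n_win = len(edges) - 1
        sums = np.zeros(n_win)
        i0 = np.searchsorted(edges, starts, side="right") - 1
        i1 = np.searchsorted(edges, ends, side="left") - 1
        same = i0 == i1
        np.add.at(sums, i0[same], depths[same] * (ends[same] - starts[same]))
        for s, e, d, a, b in zip(starts[~same], ends[~same], depths[~same],
                                 i0[~same], i1[~same]):
            for w in range(a, b + 1):
                lo = max(s, edges[w])
                hi = min(e, edges[w + 1])
                if hi > lo:
                    sums[w] += d * (hi - lo)
        widths = np.diff(edges).astype(float)
        out.append(pd.DataFrame({
            "chrom": chrom, "start": edges[:-1], "end": edges[1:],
            "depth": sums / widths,
        }))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# mtDNA copy number
# ---------------------------------------------------------------------------

@dataclass
class CopyNumberProfile:
    """Per-window mtDNA log2 ratios against the euploid nuclear median."""

    mt_windows: pd.DataFrame   # chrom, start, end, depth, log2_ratio
    w_median_euploid: float
    copy_number: float
    mt_chrom: str


def mtdna_copy_number(windows: pd.DataFrame, mt_chrom: str = "chrM",
                      aneuploid_chroms=(), zero_floor: float = ZERO_DEPTH_FLOOR
                      ) -> CopyNumberProfile:
    """Estimate absolute mtDNA copy number from windowed depths.

    The euploid median is taken over all nuclear windows excluding
    chromosomes with detected aneuploidies; the absolute copy estimate
    (assuming one nuclear genome copy, no sequencing bias) is
    2**median(log2(W_i / W_median_euploid)) over the mtDNA windows.
    Zero-depth mtDNA windows are floored at ``zero_floor`` log2 units.
    """
    excluded = set(aneuploid_chroms) | {mt_chrom}
    nuclear = windows[~windows["chrom"].isin(excluded)]
    if nuclear.empty:
        raise ValueError("need windows from at least one euploid nuclear chromosome")
    w_med = float(nuclear["depth"].median())
    if w_med <= 0:
        raise ValueError("euploid median depth is zero")
    mt = windows[windows["chrom"] == mt_chrom].copy()
    if mt.empty:
        raise ValueError(f"no windows on {mt_chrom}")
    depth = mt["depth"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.log2(depth / w_med)
    ratio[depth <= 0] = zero_floor
    mt["log2_ratio"] = ratio
    copies = float(2.0 ** np.median(ratio))
    return CopyNumberProfile(mt_windows=mt.reset_index(drop=True),
                             w_median_euploid=w_med, copy_number=copies,
                             mt_chrom=mt_chrom)


# ---------------------------------------------------------------------------
# aneuploidy calling
# ---------------------------------------------------------------------------

@dataclass
class AneuploidyCall:
    chrom: str
    median_log2: float
    call: str        # "euploid" | "duplicated"
    threshold: float


def call_aneuploidies(sample: pd.DataFrame, founder: pd.DataFrame,
                      threshold_log2: float = 0.5,
                      zero_floor: float = ZERO_DEPTH_FLOOR) -> tuple[list[AneuploidyCall], float]:
    """Founder-normalized per-chromosome aneuploidy calls.

    Per-window ratio log2(kappa * w_sample / w_founder) with kappa the
    total founder / total sample coverage (cancels library size); a
    chromosome is called duplicated when its median ratio reaches
    ``threshold_log2`` (default 0.5, halfway to the log2 = 1 expected
    for a haploid gaining one copy).  Returns the calls and kappa.
    """
    key = ["chrom", "start", "end"]
    merged = sample.merge(founder, on=key, suffixes=("_s", "_f"), how="outer",
                          indicator=True)
    if (merged["_merge"] != "both").any():
        raise ValueError("sample and founder windows must share identical coordinates")
    widths = (merged["end"] - merged["start"]).to_numpy(dtype=float)
    ds = merged["depth_s"].to_numpy(dtype=float)
    df_ = merged["depth_f"].to_numpy(dtype=float)
    total_sample = float((ds * widths).sum())
    total_founder = float((df_ * widths).sum())
    if total_sample <= 0 or total_founder <= 0:
        raise ValueError("sample and founder must have positive total coverage")
    kappa = total_founder / total_sample

    keep = df_ > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} windows with zero founder depth")
    with np.errstate(divide="ignore"):
        ratio = np.log2(kappa * ds / np.where(df_ > 0, df_, np.nan))
    ratio[ds <= 0] = zero_floor
    merged = merged.assign(log2_ratio=ratio)[keep]

    calls = []
    for chrom, grp in merged.groupby("chrom", sort=False):
        med = float(grp["log2_ratio"].median())
        call = "duplicated" if med >= threshold_log2 else "euploid"
        calls.append(AneuploidyCall(chrom=chrom, median_log2=med, call=call,
                                    threshold=threshold_log2))
    return calls, kappa


class AneuploidyCaller(BaseEstimator):
    """Founder-referenced aneuploidy caller (fit founder, predict sample).

    Parameters
    ----------
    threshold_log2 : float
        Median log2 ratio at which a chromosome is called duplicated.
    window_bp : int
        Window size applied to both tracks before calling.
    """

    def __init__(self, threshold_log2: float = 0.5, window_bp: int = 200):
        self.threshold_log2 = threshold_log2
        self.window_bp = window_bp

    def fit(self, X: pd.DataFrame, y=None):
        """Store the windowed founder depth track."""
        self.founder_windows_ = window_depth(X, self.window_bp)
        return self

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """Call aneuploidies on a sample track; returns one row per chromosome."""
        sample_windows = window_depth(X, self.window_bp)
        calls, kappa = call_aneuploidies(sample_windows, self.founder_windows_,
                                         self.threshold_log2)
        self.kappa_ = kappa
        return pd.DataFrame([vars(c) for c in calls])


# ---------------------------------------------------------------------------
# mtDNA segmentation and rho classing
# ---------------------------------------------------------------------------

@dataclass
class SegmentCall:
    start: int
    end: int
    state: str        # "retained" | "lost"
    mean_log2: float
    n_windows: int


def segment_mtdna(profile: CopyNumberProfile, loss_threshold_log2: float = -2.0,
                  min_windows: int = 2) -> list[SegmentCall]:
    """Segment the mtDNA into maximal lost/retained blocks.

    A window is lost when its log2 ratio is at or below
    ``loss_threshold_log2`` (default -2, i.e. <= 25% of the euploid-
    median-relative level).  Runs shorter than ``min_windows`` are
    absorbed into the flanking state, then maximal runs are emitted;
    adjacent segments always differ in state and the segments tile the
    mtDNA.
    """
    win = profile.mt_windows.sort_values("start")
    lost = (win["log2_ratio"].to_numpy() <= loss_threshold_log2)

    def runs_of(states: np.ndarray) -> list[list]:
        runs = []
        for i, s in enumerate(states):
            if runs and runs[-1][0] == s:
                runs[-1][2] = i
            else:
                runs.append([s, i, i])
        return runs

    states = lost.copy()
    while True:
        runs = runs_of(states)
        if len(runs) <= 1:
            break
        short = [r for r in runs if (r[2] - r[1] + 1) < min_windows]
        if not short:
            break
        # absorb the leftmost shortest run into its flanks
        r = min(short, key=lambda x: (x[2] - x[1], x[1]))
        states[r[1]:r[2] + 1] = ~r[0]

    starts = win["start"].to_numpy()
    ends = win["end"].to_numpy()
    ratios = win["log2_ratio"].to_numpy()
    segments = []
    for s, i, j in runs_of(states):
        segments.append(SegmentCall(
            start=int(starts[i]), end=int(ends[j]),
            state="lost" if s else "retained",
            mean_log2=float(ratios[i:j + 1].mean()),
            n_windows=j - i + 1,
        ))
    return segments


@dataclass
class RhoClass:
    """Petite classification from the summed retained mtDNA span."""

    label: str        # rho_plus | rho_minus | rho_minus_minus | rho_zero
    retained_kb: float


def classify_rho(segments: list[SegmentCall], intact_kb: float = 70.0,
                 lower_kb: float = 2.0) -> RhoClass:
    """Assign the petite class from retained mtDNA length.

    rho+ at >= ``intact_kb`` retained, rho- in [``lower_kb``,
    ``intact_kb``), rho-- in (0, ``lower_kb``), rho0 at none.
    """
    retained_kb = sum((s.end - s.start) for s in segments if s.state == "retained") / 1000.0
    if retained_kb >= intact_kb:
        label = "rho_plus"
    elif retained_kb >= lower_kb:
        label = "rho_minus"
    elif retained_kb > 0:
        label = "rho_minus_minus"
    else:
        label = "rho_zero"
    return RhoClass(label=label, retained_kb=retained_kb)


def map_segments_to_genes(segments: list[SegmentCall], genes: pd.DataFrame,
                          lost_fraction: float = 0.5) -> pd.DataFrame:
    """Per-gene lost/retained report from segment overlap.

    A gene is lost when at least ``lost_fraction`` of its span overlaps
    lost segments.  ``genes`` is BED-shaped (chrom, start, end, name).
    """
    required = {"start", "end", "name"}
    if not required.issubset(genes.columns):
        raise ValueError("gene annotation must have start, end, name columns")
    mt_len = max(s.end for s in segments)
    g_start = genes["start"].to_numpy(dtype=np.int64)
    g_end = genes["end"].to_numpy(dtype=np.int64)
    if np.any(g_start >= g_end) or np.any(g_start < 0) or np.any(g_end > mt_len):
        raise ValueError("gene annotation outside mtDNA coordinates or malformed")
    lost_ivs = [(s.start, s.end) for s in segments if s.state == "lost"]
    rows = []
    for name, s, e in zip(genes["name"], g_start, g_end):
        overlap = sum(max(0, min(e, le) - max(s, ls)) for ls, le in lost_ivs)
        frac = overlap / (e - s)
        rows.append((name, int(s), int(e), frac,
                     "lost" if frac >= lost_fraction else "retained"))
    return pd.DataFrame(rows, columns=["name", "start", "end",
                                       "lost_overlap_fraction", "state"])


class MtdnaProfiler(BaseEstimator):
    """End-to-end mtDNA profiling: copy number, segments and rho class.

    Parameters mirror the analysis contract: 1 kb windows, loss below
    -2 log2 units, minimum 2-window segments, rho thresholds at 70 and
    2 kb of retained sequence.

    Attributes (after ``fit``)
    --------------------------
    profile_ : CopyNumberProfile
    copy_number_ : float
    segments_ : list[SegmentCall]
    rho_ : RhoClass
    """

    def __init__(self, mt_chrom: str = "chrM", window_bp: int = 1000,
                 loss_threshold_log2: float = -2.0, min_windows: int = 2,
                 intact_kb: float = 70.0, lower_kb: float = 2.0,
                 zero_floor: float = ZERO_DEPTH_FLOOR):
        self.mt_chrom = mt_chrom
        self.window_bp = window_bp
        self.loss_threshold_log2 = loss_threshold_log2
        self.min_windows = min_windows
        self.intact_kb = intact_kb
        self.lower_kb = lower_kb
        self.zero_floor = zero_floor

    def fit(self, X: pd.DataFrame, y=None, *, aneuploid_chroms=()):
        """Profile a depth track (bedGraph-shaped DataFrame)."""
        windows = window_depth(X, self.window_bp)
        self.profile_ = mtdna_copy_number(windows, mt_chrom=self.mt_chrom,
                                          aneuploid_chroms=aneuploid_chroms,
                                          zero_floor=self.zero_floor)
        self.copy_number_ = self.profile_.copy_number
        self.segments_ = segment_mtdna(self.profile_, self.loss_threshold_log2,
                                       self.min_windows)
        self.rho_ = classify_rho(self.segments_, self.intact_kb, self.lower_kb)
        return self
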