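"""qPCR relative copy number (delta-delta-Ct) and concerted-change grouping.

Relative copy number of an mtDNA gene against a single-copy nuclear
reference is -(dCt_t - dCt_0) on the log2 scale, where dCt = Ct_target -
Ct_reference and the subscript 0 is the baseline timepoint.  This is the
algebraic simplification of log2(2**(-(dCt - dCt_0))); a unit test holds
the two forms equal.  All Ct values are capped at 30 before any
arithmetic, so absent targets saturate rather than dominate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CT_CAP = 30.0


def printed_formula(dct_t, dct_0):
    """The relative-copy-number formula in its unsimplified composition."""
    return np.log2(2.0 ** (-(np.asarray(dct_t) - np.asarray(dct_0))))


def cap_and_relative_copy_number(records: pd.DataFrame, cap: float = CT_CAP,
                                 baseline_timepoint=0) -> pd.DataFrame:
    """Per-gene, per-timepoint log2 relative copy number from a Ct table.

    ``records`` needs columns gene, timepoint, replicate, ct_target,
    ct_reference; an optional boolean ``force_cap`` column sets a
    record's target Ct to the cap regardless of its measured value
    (manual override for known background signal).  Ct values above
    ``cap`` are capped, delta-Ct values are referenced to the gene's
    baseline timepoint, and replicates are averaged after the log2
    transform.
    """
    required = {"gene", "timepoint", "replicate", "ct_target", "ct_reference"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    df = records.copy()
    if (df["ct_target"] <= 0).any() or (df["ct_reference"] <= 0).any():
        raise ValueError("Ct values must be positive")
    if "force_cap" in df.columns:
        df.loc[df["force_cap"].astype(bool), "ct_target"] = cap
    df["ct_target"] = df["ct_target"].clip(upper=cap)
    df["ct_reference"] = df["ct_reference"].clip(upper=cap)
    df["dct"] = df["ct_target"] - df["ct_reference"]

    base = (df[df["timepoint"] == baseline_timepoint]
            .groupby("gene")["dct"].mean().rename("dct0"))
    missing = set(df["gene"]) - set(base.index)
    if missing:
        raise ValueError(f"genes without baseline timepoint {baseline_timepoint}: "
                         f"{sorted(missing)}")
    df = df.merge(base, on="gene")
    df["log2_rel_copy"] = -(df["dct"] - df["dct0"])
    out = (df.groupby(["gene", "timepoint"], sort=True)
           .agg(log2_rel_copy=("log2_rel_copy", "mean"),
                n_replicates=("replicate", "nunique"))
           .reset_index())
    return out


def concerted_change_segments(changes: pd.Series | dict, gene_order: list[str],
                              tolerance_log2: float = 0.5,
                              loss_threshold_log2: float = -2.0) -> pd.DataFrame:
    """Group adjacent mtDNA genes with concerted endpoint copy-number change.

    Genes are scanned in their order along the molecule; neighbours
    whose log2 changes agree within ``tolerance_log2`` (inclusive) join
    the same group.  A group is labelled lost when its mean change is at
    or below ``loss_threshold_log2``.
    """
    changes = pd.Series(changes)
    missing = [g for g in gene_order if g not in changes.index]
    if missing:
        raise ValueError(f"no change value for genes: {missing}")
    if len(gene_order) == 0:
        raise ValueError("empty gene order")
    vals = changes.loc[gene_order].to_numpy(dtype=float)
    group_ids = np.zeros(len(gene_order), dtype=int)
    for i in range(1, len(vals)):
        same = abs(vals[i] - vals[i - 1]) <= tolerance_log2
        group_ids[i] = group_ids[i - 1] + (0 if same else 1)
    rows = []
    for gid in range(group_ids.max() + 1):
        idx = np.where(group_ids == gid)[0]
        mean_change = float(vals[idx].mean())
        rows.append((gid, [gene_order[i] for i in idx], mean_change,
                     "lost" if mean_change <= loss_threshold_log2 else "retained"))
    return pd.DataFrame(rows, columns=["group", "genes", "mean_change", "state"])
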