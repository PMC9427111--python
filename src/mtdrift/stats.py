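"""Permutation enrichment test for top-k overrepresentation.

Tests whether a boolean gene/strain category is overrepresented among
the k top-ranked strains (e.g. the 100 most stress-resistant deletion
strains) by resampling k-subsets of the universe uniformly without
replacement.  The p-value carries the +1 correction, so it is never
exactly zero and its floor is 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator


@dataclass
class EnrichmentResult:
    observed_fraction: float
    background_fraction: float
    k: int
    n_perm: int
    p_value: float
    seed: int | None


def permutation_enrichment(labels, k: int, n_perm: int = 100_000,
                           seed: int | None = None,
                           chunk: int = 2000) -> EnrichmentResult:
    """One-sided permutation test for category enrichment in the top k.

    ``labels`` are booleans aligned with the strain ranking (index 0 =
    top-ranked).  The observed statistic is the category fraction among
    the first k entries; the null draws k strains uniformly without
    replacement from the whole universe.  p = (1 + #{null >= observed})
    / (1 + n_perm).
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.ndim != 1 or len(labels) == 0:
        raise ValueError("labels must be a non-empty 1-D boolean array")
    n = len(labels)
    if not 1 <= k <= n:
        raise ValueError("k must satisfy 1 <= k <= number of strains")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    observed = labels[:k].mean()
    background = labels.mean()
    exceed = 0
    remaining = n_perm
    flt = labels.astype(float)
    while remaining > 0:
        m = min(chunk, remaining)
        # random k-subsets via the k smallest of n iid uniform keys per row
        keys = rng.random((m, n))
        top = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null_frac = flt[top].mean(axis=1)
        exceed += int(np.sum(null_frac >= observed - 1e-12))
        remaining -= m
    p = (1 + exceed) / (1 + n_perm)
    return EnrichmentResult(
        observed_fraction=float(observed),
        background_fraction=float(background),
        k=k, n_perm=n_perm, p_value=float(p), seed=seed,
    )


class PermutationEnrichment(BaseEstimator):
    """Estimator wrapper: rank strains by doubling time, test the top k.

    Parameters
    ----------
    k : int
        Size of the top set (most resistant strains = smallest doubling
        time under stress).
    n_perm : int
        Number of resampled k-subsets.
    random_state : int or None
        Seed for the resampling generator.

    Attributes (after ``fit``)
    --------------------------
    result_ : EnrichmentResult
    p_value_, observed_fraction_, background_fraction_ : float
    """

    def __init__(self, k: int = 100, n_perm: int = 100_000,
                 random_state: int | None = None):
        self.k = k
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        """Fit on a table with columns strain, doubling_time, is_category."""
        required = {"strain", "doubling_time", "is_category"}
        if not required.issubset(X.columns):
            raise ValueError(f"table must have columns {sorted(required)}")
        ranked = X.sort_values("doubling_time", kind="mergesort")
        self.result_ = permutation_enrichment(
            ranked["is_category"].to_numpy(), k=self.k, n_perm=self.n_perm,
            seed=self.random_state,
        )
        self.p_value_ = self.result_.p_value
        self.observed_fraction_ = self.result_.observed_fraction
        self.background_fraction_ = self.result_.background_fraction
        return self
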