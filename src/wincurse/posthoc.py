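"""Post-hoc single-variant statistics and ranking (Step 2).

For genes significant at Step 1, each variant is summarized by a naive
single-marker statistic T_i: either the case/control MAF difference
D_i (family "D", natural after a burden test) or its square D_i^2
(family "D2", natural after a variance-component test).  Variants are
then ranked by the absolute statistic, strongest evidence first.
These naive statistics are biased by winner's curse; see
:mod:`wincurse.correct` for the bootstrap adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import CaseControlGenotypes
from .gbt import maf_difference

__all__ = ["PosthocStats", "naive_stats", "rank_variants", "top_k_causal"]

STATISTIC_FAMILIES = ("D", "D2")


@dataclass(frozen=True)
class PosthocStats:
    """Per-variant post-hoc statistics, naive and (optionally) adjusted."""

    variant_ids: tuple[str, ...]
    statistic_family: str  # "D" or "D2"
    naive: np.ndarray
    adjusted: np.ndarray | None = None
    bias_estimate: np.ndarray | None = None
    n_significant_bootstraps: int | None = None

    def __post_init__(self) -> None:
        if self.statistic_family not in STATISTIC_FAMILIES:
            raise ValueError(f"unknown statistic family: {self.statistic_family!r}")
        naive = np.asarray(self.naive, dtype=float)
        object.__setattr__(self, "naive", naive)
        if self.statistic_family == "D2" and (naive < 0).any():
            raise ValueError("squared-difference statistics cannot be negative")
        if self.adjusted is not None:
            adj = np.asarray(self.adjusted, dtype=float)
            object.__setattr__(self, "adjusted", adj)
            bad = (adj != 0) & (np.sign(adj) != np.sign(naive))
            if bad.any():
                raise ValueError("adjusted statistics may not cross zero")

    @property
    def is_adjusted(self) -> bool:
        return self.adjusted is not None

    @property
    def best(self) -> np.ndarray:
        """Adjusted values when available, else naive."""
        return self.adjusted if self.adjusted is not None else self.naive

    def with_adjustment(
        self, adjusted: np.ndarray, bias_estimate: np.ndarray, n_significant: int
    ) -> "PosthocStats":
        return replace(
            self,
            adjusted=adjusted,
            bias_estimate=bias_estimate,
            n_significant_bootstraps=n_significant,
        )

    def to_frame(self, gene: str = "gene") -> pd.DataFrame:
        na = np.full(len(self.naive), np.nan)
        return pd.DataFrame(
            {
                "gene": gene,
                "variant": list(self.variant_ids),
                "family": self.statistic_family,
                "naive": self.naive,
                "adjusted": self.adjusted if self.adjusted is not None else na,
                "bias_estimate": self.bias_estimate if self.bias_estimate is not None else na,
                "n_significant_bootstraps": self.n_significant_bootstraps,
                "rank_naive": rank_variants(self.naive),
                "rank_adjusted": rank_variants(self.adjusted)
                if self.adjusted is not None
                else na,
            }
        )


def naive_stats(geno: CaseControlGenotypes, statistic_family: str = "D") -> PosthocStats:
    """Naive per-variant statistics: D_i or D_i^2 from the sample MAFs."""
    if statistic_family not in STATISTIC_FAMILIES:
        raise ValueError(f"unknown statistic family: {statistic_family!r}")
    d = maf_difference(geno).d_hat
    t = d if statistic_family == "D" else d**2
    return PosthocStats(tuple(geno.variant_ids), statistic_family, t)


def rank_variants(stats) -> np.ndarray:
    """Rank variants by strength of evidence, rank 1 = strongest.

    The ranking key is |T_i| (using adjusted values when a
    :class:`PosthocStats` with an adjustment is passed); ties receive
    midranks, so an all-zero vector ranks every variant (m+1)/2.
    """
    if isinstance(stats, PosthocStats):
        values = stats.best
    else:
        values = np.asarray(stats, dtype=float)
    return rankdata(-np.abs(values), method="average")


def top_k_causal(stats, causal_mask: np.ndarray, k: int = 1) -> float:
    """Probability that the k strongest-ranked variants are all causal.

    Without ties at the k-th position this is 0 or 1.  Rare-variant
    statistics are multiples of 1/(2N) and exact ties are common, so a
    tie spanning the k-th position is credited with the probability
    that a uniformly random tie-break fills the remaining slots with
    causal variants only — the expectation over random tie-breaking,
    deterministic and independent of variant order.
    """
    if isinstance(stats, PosthocStats):
        values = stats.best
    else:
        values = np.asarray(stats, dtype=float)
    causal_mask = np.asarray(causal_mask, dtype=bool)
    score = np.abs(values)
    if k < 1 or k > score.size:
        raise ValueError("k must lie in 1..m")
    kth = np.sort(score)[::-1][k - 1]
    strict = score > kth
    if not causal_mask[strict].all():
        return 0.0
    tied = score == kth
    slots = k - int(strict.sum())
    n_tied = int(tied.sum())
    n_causal_tied = int(causal_mask[tied].sum())
    if n_causal_tied < slots:
        return 0.0
    # hypergeometric chance that all `slots` draws from the tie are causal
    prob = 1.0
    for i in range(slots):
        prob *= (n_causal_tied - i) / (n_tied - i)
    return prob
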