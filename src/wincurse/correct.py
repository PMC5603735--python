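"""Bootstrap resampling correction for winner's curse (Step 2 adjustment).

Naive single-variant statistics computed only in genes that passed a
gene-based test on the same data overstate the evidence — the winner's
curse.  The correction estimates that selection bias by stratified
bootstrap resampling:

1. draw a bootstrap sample with replacement, separately within cases
   and controls, so it again has N+ cases and N- controls;
2. the subjects never drawn form the *residual sample* (on average a
   fraction (1 - 1/N)^N ~ e^-1 ~ 37% of each stratum), an internal
   pseudo-replication set untouched by the selection event;
3. rerun the gene-based test on the bootstrap sample; whenever it is
   significant at the same alpha, record, per variant,
   bias_b(T_i) = T*_ib - T^R_ib, the bootstrap-sample statistic minus
   the residual-sample statistic.

The adjusted statistic subtracts the median of the recorded biases,
clamped so the estimate can never cross zero:

    T_adj = max(T - median_b bias_b, 0)   if T > 0
            min(T - median_b bias_b, 0)   if T < 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import CaseControlGenotypes
from .gbt import beta_weight, burden_pvalue, chi2_mixture_sf, null_variance_d
from .posthoc import PosthocStats

__all__ = [
    "BootstrapRun",
    "DegenerateBootstrapError",
    "bootstrap_once",
    "estimate_bias",
    "adjust",
]


class DegenerateBootstrapError(RuntimeError):
    """A bootstrap replicate left an empty residual stratum."""


@dataclass(frozen=True)
class BootstrapRun:
    """Per-bootstrap bias estimates for one gene.

    ``per_bootstrap_bias`` has one row per usable bootstrap replicate;
    only rows flagged in ``significant`` (gene-based test p* < alpha on
    the bootstrap sample) enter any summary.
    """

    n_bootstrap: int
    alpha: float
    test_family: str
    statistic_family: str
    per_bootstrap_bias: np.ndarray  # (B, m)
    significant: np.ndarray  # (B,) bool
    residual_fraction: np.ndarray  # (B, 2): case and control strata
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.per_bootstrap_bias.shape[0] != self.n_bootstrap:
            raise ValueError("bias matrix must have one row per bootstrap")
        if self.significant.shape != (self.n_bootstrap,):
            raise ValueError("significance mask must have one entry per bootstrap")

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def bias_summary(self, summary: str = "median") -> np.ndarray:
        """Per-variant summary of the bias over significant bootstraps."""
        if self.n_significant == 0:
            raise ValueError("no significant bootstrap replicates to summarize")
        rows = self.per_bootstrap_bias[self.significant]
        if summary == "median":
            return np.median(rows, axis=0)
        if summary == "mean":
            return rows.mean(axis=0)
        raise ValueError(f"unknown summary: {summary!r}")


def _draw_stratum_indices(rng: np.random.Generator, n_cases: int, n_controls: int):
    """Within-stratum resampling indices; case draw precedes control draw
    so every consumer of a shared Generator sees the same resamples."""
    idx_case = rng.integers(0, n_cases, n_cases)
    idx_control = rng.integers(0, n_controls, n_controls)
    return idx_case, idx_control


def bootstrap_once(
    geno: CaseControlGenotypes, seed: int | np.random.Generator
) -> tuple[CaseControlGenotypes, CaseControlGenotypes]:
    """One stratified bootstrap draw: (bootstrap sample, residual sample).

    The bootstrap sample has exactly N+ cases and N- controls drawn with
    replacement within stratum; the residual sample holds each subject
    (once) that was never drawn.  Raises
    :class:`DegenerateBootstrapError` if either residual stratum is
    empty.
    """
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(geno.case_mask)
    control_idx = np.flatnonzero(~geno.case_mask)
    draw_c, draw_n = _draw_stratum_indices(rng, len(case_idx), len(control_idx))
    boot = geno.subset(np.concatenate([case_idx[draw_c], control_idx[draw_n]]))
    resid_c = case_idx[np.setdiff1d(np.arange(len(case_idx)), draw_c)]
    resid_n = control_idx[np.setdiff1d(np.arange(len(control_idx)), draw_n)]
    if len(resid_c) == 0 or len(resid_n) == 0:
        raise DegenerateBootstrapError("empty residual stratum")
    residual = geno.subset(np.concatenate([resid_c, resid_n]))
    return boot, residual


def estimate_bias(
    geno: CaseControlGenotypes,
    test_family: str = "burden",
    statistic_family: str = "D",
    alpha: float = 0.01,
    n_bootstrap: int = 1000,
    seed: int | np.random.Generator | None = None,
    weights: np.ndarray | None = None,
    p_method: str = "moment",
) -> BootstrapRun:
    """Run the bootstrap bias estimation for one gene.

    For each of ``n_bootstrap`` usable replicates the gene-based test
    (``test_family``) is recomputed on the bootstrap sample — with
    Beta(1, 25) weights re-derived from that sample's pooled MAFs
    unless an explicit ``weights`` vector is given — and the
    bootstrap-minus-residual bias of the post-hoc statistic is stored
    together with the replicate's significance flag.  Degenerate
    replicates (an empty residual stratum) are redrawn and do not count
    toward ``n_bootstrap``; with thousands of subjects they are
    unreachable in practice.

    ``p_method`` selects the tail approximation for the
    variance-component gate; the default moment matching is accurate to
    a few percent at the gate threshold and far cheaper than numerical
    inversion across thousands of bootstraps.
    """
    if test_family not in ("burden", "skat"):
        raise ValueError(f"unknown test family: {test_family!r}")
    if statistic_family not in ("D", "D2"):
        raise ValueError(f"unknown statistic family: {statistic_family!r}")
    rng = np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None

    dos = geno.dosages
    case_mask = geno.case_mask
    dos_c = dos[case_mask].astype(np.int64)
    dos_n = dos[~case_mask].astype(np.int64)
    nc, nn = dos_c.shape[0], dos_n.shape[0]
    m = geno.n_variants
    B = int(n_bootstrap)

    boot_cc = np.empty((B, m), dtype=np.int64)  # bootstrap case allele counts
    boot_cn = np.empty((B, m), dtype=np.int64)
    resid_cc = np.empty((B, m), dtype=np.int64)
    resid_cn = np.empty((B, m), dtype=np.int64)
    n_resid = np.empty((B, 2), dtype=np.int64)

    b = 0
    attempts = 0
    max_attempts = max(10 * B, B + 100)
    while b < B:
        if attempts >= max_attempts:
            raise DegenerateBootstrapError(
                "too many degenerate bootstrap replicates; sample is too small"
            )
        attempts += 1
        idx_c, idx_n = _draw_stratum_indices(rng, nc, nn)
        occ_c = np.bincount(idx_c, minlength=nc)
        occ_n = np.bincount(idx_n, minlength=nn)
        res_c = occ_c == 0
        res_n = occ_n == 0
        nr_c = int(res_c.sum())
        nr_n = int(res_n.sum())
        if nr_c == 0 or nr_n == 0:
            continue
        boot_cc[b] = occ_c @ dos_c
        boot_cn[b] = occ_n @ dos_n
        resid_cc[b] = res_c @ dos_c
        resid_cn[b] = res_n @ dos_n
        n_resid[b, 0] = nr_c
        n_resid[b, 1] = nr_n
        b += 1

    # sample MAFs on bootstrap and residual samples
    f_case_b = boot_cc / (2.0 * nc)
    f_ctrl_b = boot_cn / (2.0 * nn)
    f_pool_b = (boot_cc + boot_cn) / (2.0 * (nc + nn))
    d_boot = f_case_b - f_ctrl_b
    d_resid = resid_cc / (2.0 * n_resid[:, [0]]) - resid_cn / (2.0 * n_resid[:, [1]])

    w = beta_weight(f_pool_b) if weights is None else np.broadcast_to(
        np.asarray(weights, dtype=float), (B, m)
    )
    v = null_variance_d(f_pool_b, nc, nn)
    if test_family == "burden":
        q = (w * d_boot).sum(axis=1)
        var_q = (w**2 * v).sum(axis=1)
        p_star = burden_pvalue(q, var_q)
    else:
        q = (w * d_boot**2).sum(axis=1)
        p_star = np.array(
            [chi2_mixture_sf(q[i], w[i] * v[i], method=p_method) for i in range(B)]
        )

    if statistic_family == "D":
        bias = d_boot - d_resid
    else:
        bias = d_boot**2 - d_resid**2

    return BootstrapRun(
        n_bootstrap=B,
        alpha=alpha,
        test_family=test_family,
        statistic_family=statistic_family,
        per_bootstrap_bias=bias,
        significant=p_star < alpha,
        residual_fraction=n_resid / np.array([nc, nn], dtype=float),
        seed=seed_val,
    )


def adjust(
    naive: PosthocStats, run: BootstrapRun, summary: str = "median"
) -> PosthocStats:
    """Apply the clamped median-bias adjustment to naive statistics.

    Subtracts the per-variant ``summary`` (default median) of the
    bootstrap-minus-residual bias, taken over significant bootstraps
    only, then clamps at zero so the adjusted statistic keeps the sign
    of the naive one (or becomes exactly zero).  If no bootstrap was
    significant the naive statistics are returned unchanged and
    flagged as unadjusted.
    """
    if naive.statistic_family != run.statistic_family:
        raise ValueError("statistic families of naive stats and bootstrap run differ")
    if run.n_significant == 0:
        warnings.warn("no significant bootstrap replicates; returning unadjusted statistics")
        return naive
    bias = run.bias_summary(summary)
    raw = naive.naive - bias
    adjusted = np.where(
        naive.naive > 0,
        np.maximum(raw, 0.0),
        np.where(naive.naive < 0, np.minimum(raw, 0.0), 0.0),
    )
    return naive.with_adjustment(adjusted, bias, run.n_significant)
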