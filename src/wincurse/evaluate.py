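"""Simulation-study evaluation: power, bias, MSE and ranking metrics.

:func:`run_study` simulates many replicates of one scenario, applies
the two-step pipeline (gene-based test, then post-hoc statistics with
optional bootstrap adjustment for replicates significant at Step 1) and
aggregates, over the significant replicates only:

* bias      = mean(T_hat - E[T])        per variant,
* MSE       = mean((T_hat - E[T])^2)    per variant,
* mean rank of each variant under |T_hat|,
* the proportion of replicates whose top-1 (top-2) ranked variants are
  all causal.

Conditioning the aggregates on Step-1 significance is deliberate: it is
exactly the selection event that creates winner's curse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import correct, gbt, posthoc
from .simulate import GeneSetting, TruthRecord, _variance_d, replicate_seed, simulate_gene

__all__ = [
    "EvaluationReport",
    "run_study",
    "theoretical_bias",
    "aggregate_tables",
    "POWER_BANDS",
]

#: Step-1 power strata used in the aggregate tables
POWER_BANDS = ((0.0, 0.05), (0.05, 0.2), (0.2, 0.5), (0.5, 1.0))


@dataclass
class EvaluationReport:
    """Aggregated results of a simulation study for one scenario."""

    setting_id: str
    test_family: str
    statistic_family: str
    alpha: float
    n_replicates: int
    step1_power: float
    n_significant_replicates: int
    per_variant: pd.DataFrame
    top1_causal_naive: float
    top1_causal_adjusted: float
    top2_causal_naive: float
    top2_causal_adjusted: float
    truth: TruthRecord
    # raw per-replicate material for downstream diagnostics
    replicate_p: np.ndarray = None  # type: ignore[assignment]
    replicate_q: np.ndarray = None  # type: ignore[assignment]
    significant: np.ndarray = None  # type: ignore[assignment]
    naive_matrix: np.ndarray = None  # type: ignore[assignment]
    adjusted_matrix: np.ndarray = None  # type: ignore[assignment]

    @property
    def adjusted_available(self) -> bool:
        return self.adjusted_matrix is not None and self.adjusted_matrix.size > 0


def _aggregate(matrix: np.ndarray, expected: np.ndarray):
    """(bias, mse) per variant of a (replicates x variants) matrix."""
    err = matrix - expected
    return err.mean(axis=0), (err**2).mean(axis=0)


def run_study(
    setting: GeneSetting,
    test_family: str = "burden",
    statistic_family: str = "D",
    alpha: float | None = None,
    n_replicates: int = 10_000,
    n_bootstrap: int = 1000,
    seed: int = 0,
    adjust: bool = True,
    bias_summary: str = "median",
    p_method: str = "imhof",
) -> EvaluationReport:
    """Simulate one scenario end-to-end and aggregate the evaluation metrics.

    Each replicate r draws its genotypes from a counter-based seed
    (master seed, r), so any single replicate is reproducible in
    isolation; the bootstrap for a significant replicate continues that
    replicate's stream.  ``adjust=False`` skips the bootstrap (naive
    metrics only).
    """
    if alpha is None:
        alpha = setting.alpha
    m = setting.n_variants
    causal = setting.causal_mask

    p_values = np.empty(n_replicates)
    q_values = np.empty(n_replicates)
    naive_rows: list[np.ndarray] = []
    adj_rows: list[np.ndarray] = []
    truth = None

    for r in range(n_replicates):
        rng = np.random.default_rng(replicate_seed(seed, r))
        geno, truth = simulate_gene(setting, rng)
        res = gbt.run_test(geno, test_family, alpha=alpha, method=p_method)
        p_values[r] = res.p_value
        q_values[r] = res.q_value
        if not res.significant:
            continue
        stats = posthoc.naive_stats(geno, statistic_family)
        naive_rows.append(stats.naive)
        if adjust:
            run = correct.estimate_bias(
                geno,
                test_family=test_family,
                statistic_family=statistic_family,
                alpha=alpha,
                n_bootstrap=n_bootstrap,
                seed=rng,
            )
            if run.n_significant > 0:
                adj = correct.adjust(stats, run, summary=bias_summary)
                adj_rows.append(adj.adjusted)
            else:
                # no information to adjust with: statistic stays naive
                adj_rows.append(stats.naive.copy())

    sig_mask = p_values < alpha
    n_sig = int(sig_mask.sum())
    power = n_sig / n_replicates
    expected = truth.expected(statistic_family)

    cols = {
        "variant": [f"v{i + 1}" for i in range(m)],
        "expected_value": expected,
        "causal": causal,
    }
    top = {
        "top1_causal_naive": np.nan,
        "top1_causal_adjusted": np.nan,
        "top2_causal_naive": np.nan,
        "top2_causal_adjusted": np.nan,
    }
    naive_matrix = np.array(naive_rows).reshape(n_sig, m) if n_sig else np.empty((0, m))
    adjusted_matrix = (
        np.array(adj_rows).reshape(len(adj_rows), m) if adjust and adj_rows else None
    )

    if n_sig == 0:
        warnings.warn("no replicate was significant at Step 1; aggregates are undefined")
        for key in (
            "bias_naive",
            "bias_adjusted",
            "mse_naive",
            "mse_adjusted",
            "mean_rank_naive",
            "mean_rank_adjusted",
        ):
            cols[key] = np.full(m, np.nan)
    else:
        bias_n, mse_n = _aggregate(naive_matrix, expected)
        ranks_n = np.apply_along_axis(posthoc.rank_variants, 1, naive_matrix)
        cols["bias_naive"] = bias_n
        cols["mse_naive"] = mse_n
        cols["mean_rank_naive"] = ranks_n.mean(axis=0)
        top["top1_causal_naive"] = np.mean(
            [posthoc.top_k_causal(row, causal, 1) for row in naive_matrix]
        )
        top["top2_causal_naive"] = np.mean(
            [posthoc.top_k_causal(row, causal, 2) for row in naive_matrix]
        )
        if adjusted_matrix is not None:
            bias_a, mse_a = _aggregate(adjusted_matrix, expected)
            ranks_a = np.apply_along_axis(posthoc.rank_variants, 1, adjusted_matrix)
            cols["bias_adjusted"] = bias_a
            cols["mse_adjusted"] = mse_a
            cols["mean_rank_adjusted"] = ranks_a.mean(axis=0)
            top["top1_causal_adjusted"] = np.mean(
                [posthoc.top_k_causal(row, causal, 1) for row in adjusted_matrix]
            )
            top["top2_causal_adjusted"] = np.mean(
                [posthoc.top_k_causal(row, causal, 2) for row in adjusted_matrix]
            )
        else:
            cols["bias_adjusted"] = np.full(m, np.nan)
            cols["mse_adjusted"] = np.full(m, np.nan)
            cols["mean_rank_adjusted"] = np.full(m, np.nan)

    return EvaluationReport(
        setting_id=setting.setting_id,
        test_family=test_family,
        statistic_family=statistic_family,
        alpha=alpha,
        n_replicates=n_replicates,
        step1_power=power,
        n_significant_replicates=n_sig,
        per_variant=pd.DataFrame(cols),
        truth=truth,
        replicate_p=p_values,
        replicate_q=q_values,
        significant=sig_mask,
        naive_matrix=naive_matrix,
        adjusted_matrix=adjusted_matrix,
        **top,
    )


def theoretical_bias(
    setting: GeneSetting,
    statistic_family: str,
    bias_q: float,
    var_q: float,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted post-hoc bias from the gene-level bias decomposition.

    With independent variants the observed bias of the gene statistic
    propagates to variant i in proportion to its weight and sampling
    variance:

        Bias(T_i) = Bias(Q) / Var(Q) * w_i * Var(T_i).

    ``Var(T_i)`` uses the closed binomial forms: Var(D_i) for family
    "D" and, for family "D2", the normal-approximation variance of a
    squared mean, 4 mu^2 sigma^2 + 2 sigma^4.
    """
    if var_q <= 0:
        raise ValueError("var_q must be positive")
    from .simulate import case_control_mafs

    f_plus, f_minus = case_control_mafs(setting.maf, setting.rr)
    w = gbt.beta_weight(setting.maf) if weights is None else np.asarray(weights, float)
    var_d = _variance_d(f_plus, f_minus, setting.n_cases, setting.n_controls)
    if statistic_family == "D":
        var_t = var_d
    elif statistic_family == "D2":
        mu = f_plus - f_minus
        var_t = 4.0 * mu**2 * var_d + 2.0 * var_d**2
    else:
        raise ValueError(f"unknown statistic family: {statistic_family!r}")
    return (bias_q / var_q) * w * var_t


def _power_band(power: float) -> str:
    for lo, hi in POWER_BANDS:
        if lo <= power < hi or (hi == 1.0 and power == 1.0):
            return f"{lo:g}-{hi:g}"
    return "0-0.05"


def aggregate_tables(
    reports: list[EvaluationReport],
    min_significant: int = 2,
    by_power_band: bool = False,
) -> pd.DataFrame:
    """Cross-scenario improvement summary for the bootstrap adjustment.

    Pools variant-by-scenario cells within each (test, statistic,
    alpha) group and reports, for bias and for MSE: the fraction of
    cells improved by the adjustment (for bias, improvement means
    smaller |bias|), the median improvement magnitude among improved
    cells, the median decline among worsened cells, and their ratio.
    Scenarios with fewer than ``min_significant`` significant
    replicates are excluded.  ``by_power_band=True`` additionally
    stratifies by Step-1 power band; strata with no cells yield NaN
    (rendered as "-" in formatted output).
    """
    if not reports:
        raise ValueError("need at least one report")
    cells = []
    for rep in reports:
        if rep.n_significant_replicates < min_significant:
            continue
        if not rep.adjusted_available:
            continue
        pv = rep.per_variant
        for _, row in pv.iterrows():
            cells.append(
                {
                    "test_family": rep.test_family,
                    "statistic_family": rep.statistic_family,
                    "alpha": rep.alpha,
                    "setting_id": rep.setting_id,
                    "power_band": _power_band(rep.step1_power),
                    "bias_change": abs(row["bias_naive"]) - abs(row["bias_adjusted"]),
                    "mse_change": row["mse_naive"] - row["mse_adjusted"],
                }
            )
    if not cells:
        raise ValueError("no scenario passed the minimum-significance filter")
    df = pd.DataFrame(cells)

    keys = ["test_family", "statistic_family", "alpha"]
    if by_power_band:
        keys.append("power_band")
    rows = []
    for metric in ("bias", "mse"):
        change = f"{metric}_change"
        for group_key, sub in df.groupby(keys):
            improved = sub[change] > 0
            declined = sub[change] < 0
            rows.append(
                dict(
                    zip(keys, group_key if isinstance(group_key, tuple) else (group_key,)),
                    metric=metric,
                    n_cells=len(sub),
                    frac_improved=float(improved.mean()),
                    median_improvement=float(sub.loc[improved, change].median())
                    if improved.any()
                    else np.nan,
                    median_decline=float(-sub.loc[declined, change].median())
                    if declined.any()
                    else np.nan,
                )
            )
    out = pd.DataFrame(rows)
    out["improvement_ratio"] = out["median_improvement"] / out["median_decline"]
    return out


def format_table(table: pd.DataFrame) -> str:
    """Render an aggregate table with '-' for empty cells."""
    return table.to_string(index=False, na_rep="-", float_format=lambda x: f"{x:.3g}")
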