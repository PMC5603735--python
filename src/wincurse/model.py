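"""Model/results interface for two-step post-hoc analysis of one gene.

:class:`GeneAssociationModel` wraps a gene's case-control genotypes;
``fit`` runs the gene-based test and, when it is significant, the
bootstrap winner's-curse correction, returning a
:class:`GeneAssociationResults` carrying the test outcome, the naive
and adjusted per-variant statistics, and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import correct, gbt, posthoc
from .data import CaseControlGenotypes

__all__ = ["GeneAssociationModel", "GeneAssociationResults"]

#: post-hoc statistic aligned with each Step-1 test family
ALIGNED_STATISTIC = {"burden": "D", "skat": "D2"}


class GeneAssociationModel:
    """Two-step gene-based association analysis for a single gene.

    Parameters
    ----------
    dosages, status : array-like
        Subjects-by-variants minor-allele dosage matrix and binary
        case (1) / control (0) labels.
    variant_ids : sequence of str, optional
    """

    def __init__(self, dosages, status, variant_ids=None, gene_id: str = "gene"):
        self.data = CaseControlGenotypes(
            dosages=np.asarray(dosages), status=np.asarray(status), variant_ids=variant_ids
        )
        self.gene_id = gene_id

    @classmethod
    def from_genotypes(cls, geno: CaseControlGenotypes, gene_id: str = "gene"):
        obj = cls.__new__(cls)
        obj.data = geno
        obj.gene_id = gene_id
        return obj

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, status_col: str = "status", gene_id: str = "gene"
    ):
        """Build from a DataFrame with a status column and one dosage
        column per variant (a subject_id column is ignored)."""
        variant_cols = [c for c in df.columns if c not in (status_col, "subject_id")]
        return cls(
            df[variant_cols].to_numpy(),
            df[status_col].to_numpy(),
            variant_ids=variant_cols,
            gene_id=gene_id,
        )

    def fit(
        self,
        test: str = "burden",
        statistic: str | None = None,
        alpha: float = 0.01,
        n_bootstrap: int = 1000,
        seed: int | None = None,
        weights: np.ndarray | None = None,
        bias_summary: str = "median",
    ) -> "GeneAssociationResults":
        """Run Step 1 and, if significant, the Step-2 bootstrap correction.

        ``statistic`` defaults to the family aligned with the test
        ("D" after burden, "D2" after skat).  ``n_bootstrap=0`` skips
        the correction; genes failing Step 1 carry no post-hoc
        statistics at all.
        """
        if statistic is None:
            statistic = ALIGNED_STATISTIC[test]
        step1 = gbt.run_test(self.data, test, weights=weights, alpha=alpha)
        stats = None
        run = None
        if step1.significant:
            stats = posthoc.naive_stats(self.data, statistic)
            if n_bootstrap > 0:
                run = correct.estimate_bias(
                    self.data,
                    test_family=test,
                    statistic_family=statistic,
                    alpha=alpha,
                    n_bootstrap=n_bootstrap,
                    seed=seed,
                    weights=weights,
                )
                if run.n_significant > 0:
                    stats = correct.adjust(stats, run, summary=bias_summary)
        return GeneAssociationResults(self, step1, stats, run)


class GeneAssociationResults:
    """Fitted two-step analysis: Step-1 test plus post-hoc statistics."""

    def __init__(self, model, step1, stats, bootstrap_run):
        self.model = model
        self.step1 = step1
        self.posthoc = stats
        self.bootstrap_run = bootstrap_run

    # -- convenience accessors ----------------------------------------
    @property
    def significant(self) -> bool:
        return self.step1.significant

    @property
    def p_value(self) -> float:
        return self.step1.p_value

    @property
    def naive(self) -> np.ndarray | None:
        return None if self.posthoc is None else self.posthoc.naive

    @property
    def adjusted(self) -> np.ndarray | None:
        return None if self.posthoc is None else self.posthoc.adjusted

    def ranks(self, adjusted: bool | None = None) -> np.ndarray | None:
        if self.posthoc is None:
            return None
        if adjusted is None:
            return posthoc.rank_variants(self.posthoc)
        values = self.posthoc.adjusted if adjusted else self.posthoc.naive
        return None if values is None else posthoc.rank_variants(values)

    def to_frame(self) -> pd.DataFrame | None:
        if self.posthoc is None:
            return None
        return self.posthoc.to_frame(gene=self.model.gene_id)

    def summary(self) -> str:
        """Human-readable summary of Step 1 and the per-variant table."""
        data = self.model.data
        lines = [
            "Two-step gene-based association analysis",
            "=" * 44,
            f"Gene:        {self.model.gene_id}",
            f"Subjects:    {data.n_cases} cases / {data.n_controls} controls",
            f"Variants:    {data.n_variants}",
            f"Step 1 test: {self.step1.test_family}  Q = {self.step1.q_value:.4g}  "
            f"p = {self.step1.p_value:.4g}  (alpha = {self.step1.alpha:g})",
        ]
        if not self.significant:
            lines.append("Not significant at Step 1 - no post-hoc analysis performed.")
            return "\n".join(lines)
        if self.bootstrap_run is not None:
            lines.append(
                f"Bootstrap:   {self.bootstrap_run.n_bootstrap} replicates, "
                f"{self.bootstrap_run.n_significant} significant"
            )
        lines.append("")
        df = self.to_frame().drop(columns=["gene"])
        lines.append(df.to_string(index=False, na_rep="-", float_format=lambda x: f"{x:.4g}"))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<GeneAssociationResults {self.model.gene_id}: "
            f"p={self.p_value:.3g}, significant={self.significant}>"
        )
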