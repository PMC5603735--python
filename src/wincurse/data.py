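"""Core data container for case-control genotype data.

The unit of analysis throughout the package is a single gene region: a
subjects-by-variants dosage matrix together with binary case/control
labels.  Bootstrap resampling operates on whole subjects, so genotypes
are always held at subject level, never collapsed to allele counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CaseControlGenotypes"]


@dataclass
class CaseControlGenotypes:
    """Subject-level minor-allele dosages with case/control status.

    Parameters
    ----------
    dosages : ndarray of shape (n_subjects, n_variants)
        Minor-allele counts per subject and variant; entries in {0, 1, 2}.
    status : ndarray of shape (n_subjects,)
        1 for cases, 0 for controls.
    variant_ids : sequence of str, optional
        Variant labels; defaults to ``v1 .. vm``.
    subject_ids : sequence of str, optional
        Subject labels; defaults to ``s1 .. sn``.
    """

    dosages: np.ndarray
    status: np.ndarray
    variant_ids: list[str] = field(default=None)  # type: ignore[assignment]
    subject_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.status = np.asarray(self.status).astype(np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-d (subjects x variants) matrix")
        if self.status.shape != (self.dosages.shape[0],):
            raise ValueError("status length must equal the number of subjects")
        if self.dosages.dtype.kind not in "iu":
            self.dosages = self.dosages.astype(np.int64)
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosage entries must be 0, 1 or 2")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status entries must be 0 or 1")
        if self.variant_ids is None:
            self.variant_ids = [f"v{i + 1}" for i in range(self.n_variants)]
        else:
            self.variant_ids = [str(v) for v in self.variant_ids]
        if len(self.variant_ids) != self.n_variants:
            raise ValueError("variant_ids length must equal the number of variants")
        if self.subject_ids is None:
            self.subject_ids = [f"s{i + 1}" for i in range(self.n_subjects)]
        else:
            self.subject_ids = [str(s) for s in self.subject_ids]
        if len(self.subject_ids) != self.n_subjects:
            raise ValueError("subject_ids length must equal the number of subjects")

    # -- basic shape -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return self.n_subjects - self.n_cases

    # -- allele counts -----------------------------------------------
    @property
    def case_mask(self) -> np.ndarray:
        return self.status == 1

    def case_allele_counts(self) -> np.ndarray:
        """Minor-allele count among cases, per variant (C+)."""
        return self.dosages[self.case_mask].sum(axis=0).astype(np.int64)

    def control_allele_counts(self) -> np.ndarray:
        """Minor-allele count among controls, per variant (C-)."""
        return self.dosages[~self.case_mask].sum(axis=0).astype(np.int64)

    def subset(self, subject_idx: np.ndarray) -> "CaseControlGenotypes":
        """New container holding the given subjects (repeats allowed)."""
        subject_idx = np.asarray(subject_idx)
        return CaseControlGenotypes(
            dosages=self.dosages[subject_idx],
            status=self.status[subject_idx],
            variant_ids=self.variant_ids,
            subject_ids=[self.subject_ids[i] for i in subject_idx],
        )

    # -- I/O helpers ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Dosage matrix as a DataFrame with subject_id and status columns."""
        df = pd.DataFrame(self.dosages, columns=self.variant_ids)
        df.insert(0, "status", self.status)
        df.insert(0, "subject_id", self.subject_ids)
        return df
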