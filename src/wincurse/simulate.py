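"""Case-control genotype simulation for gene-based rare-variant studies.

A simulated gene is a set of m variants with known population minor
allele frequencies (MAF) and per-variant allelic relative risks.  Cases
and controls are drawn independently: every subject's dosage at variant
i is Binomial(2, f) with f the case or control MAF, all variants
independent (no linkage disequilibrium), Hardy-Weinberg within each
stratum.

The canonical study grid holds 50 scenarios: 10 MAF architectures for a
10-variant gene crossed with 5 relative-risk mixes, analysed with 1,500
cases and 1,500 controls.  MAF architectures:

* all-rare: all 10 variants at f = 0.0001 or all at f = 0.001;
* one common neutral variant (f = 0.05 or 0.01) plus 9 rare variants
  (f = 0.0001 or 0.001);
* two common variants (one neutral, one risk-increasing) plus 8 rare.

Relative-risk mixes (% risk-increasing : % neutral : % risk-decreasing
out of the 10 variants): 20:80:0, 50:50:0, 80:20:0, 20:60:20 and the
all-null 0:100:0.  The relative risk of a causal variant is tied to its
MAF — (0.05, 1.2), (0.01, 1.5), (0.001, 2), (0.0001, 8) — with
risk-decreasing variants taking the reciprocal.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import yaml

from .data import CaseControlGenotypes

__all__ = [
    "GeneSetting",
    "TruthRecord",
    "canonical_settings",
    "lowpower_scenario",
    "case_control_mafs",
    "simulate_gene",
    "expected_values",
    "settings_to_yaml",
    "settings_from_yaml",
    "genotypes_to_tsv",
    "genotypes_from_tsv",
    "genotypes_to_vcf",
]

#: relative risk assigned to a risk-increasing variant, keyed by MAF
RISK_LAMBDA = {0.05: 1.2, 0.01: 1.5, 0.001: 2.0, 0.0001: 8.0}


@dataclass(frozen=True)
class GeneSetting:
    """One simulation scenario: per-variant MAF and relative risk.

    ``maf`` holds population minor allele frequencies f_i in (0, 0.5],
    ``rr`` the allelic relative risks (1 = neutral).  ``alpha`` is the
    gene-based-test significance level used downstream.
    """

    setting_id: str
    maf: np.ndarray
    rr: np.ndarray
    n_cases: int = 1500
    n_controls: int = 1500
    alpha: float = 0.01

    def __post_init__(self) -> None:
        object.__setattr__(self, "maf", np.asarray(self.maf, dtype=float))
        object.__setattr__(self, "rr", np.asarray(self.rr, dtype=float))
        if self.maf.ndim != 1 or self.maf.shape != self.rr.shape or self.maf.size < 1:
            raise ValueError("maf and rr must be equal-length 1-d arrays of length >= 1")
        if not ((self.maf > 0) & (self.maf <= 0.5)).all():
            raise ValueError("all MAFs must lie in (0, 0.5]")
        if not (self.rr > 0).all():
            raise ValueError("all relative risks must be positive")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")

    @property
    def n_variants(self) -> int:
        return self.maf.size

    @property
    def causal_mask(self) -> np.ndarray:
        return self.rr != 1.0


@dataclass(frozen=True)
class TruthRecord:
    """Known truth for a simulated scenario.

    ``expected_d`` is E[D_i] = f+_i - f-_i, the population case/control
    MAF difference; ``expected_d2`` is E[D_i^2] = (f+_i - f-_i)^2 +
    Var(D_i), the unconditional mean of the squared sample difference.
    """

    setting: GeneSetting
    case_maf: np.ndarray
    control_maf: np.ndarray
    expected_d: np.ndarray
    expected_d2: np.ndarray
    causal_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.causal_mask is None:
            object.__setattr__(self, "causal_mask", self.setting.causal_mask)

    def expected(self, statistic_family: str) -> np.ndarray:
        if statistic_family == "D":
            return self.expected_d
        if statistic_family == "D2":
            return self.expected_d2
        raise ValueError(f"unknown statistic family: {statistic_family!r}")


def case_control_mafs(f: float, lam: float) -> tuple[float, float]:
    """Map a population MAF and allelic relative risk to case/control MAFs.

    Controls sit at the population frequency (f- = f, rare-disease
    approximation) and cases at f+ = lam*f / (1 + (lam - 1)*f), the
    standard allelic relative-risk mapping.  Neutral variants
    (lam = 1) are exactly frequency-matched between strata.
    """
    f = np.asarray(f, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(f <= 0) or np.any(f >= 1):
        raise ValueError("population MAF must lie in (0, 1)")
    if np.any(lam <= 0):
        raise ValueError("relative risk must be positive")
    f_plus = lam * f / (1.0 + (lam - 1.0) * f)
    if f.ndim == 0:
        return float(f_plus), float(f)
    return f_plus, f.copy()


def _variance_d(f_plus, f_minus, n_cases, n_controls):
    """Var(D_i) for binomial allele counts under HWE within each stratum."""
    f_plus = np.asarray(f_plus, dtype=float)
    f_minus = np.asarray(f_minus, dtype=float)
    return f_plus * (1 - f_plus) / (2 * n_cases) + f_minus * (1 - f_minus) / (2 * n_controls)


def expected_values(setting: GeneSetting) -> TruthRecord:
    """Closed-form expected values of the post-hoc statistics.

    E[D_i] = f+_i - f-_i and E[D_i^2] = E[D_i]^2 + Var(D_i) with
    Var(D_i) = f+(1-f+)/(2N+) + f-(1-f-)/(2N-).
    """
    f_plus, f_minus = case_control_mafs(setting.maf, setting.rr)
    d = f_plus - f_minus
    var_d = _variance_d(f_plus, f_minus, setting.n_cases, setting.n_controls)
    return TruthRecord(
        setting=setting,
        case_maf=np.asarray(f_plus, dtype=float),
        control_maf=np.asarray(f_minus, dtype=float),
        expected_d=np.asarray(d, dtype=float),
        expected_d2=np.asarray(d * d + var_d, dtype=float),
    )


def simulate_gene(
    setting: GeneSetting, seed: int | np.random.Generator
) -> tuple[CaseControlGenotypes, TruthRecord]:
    """Draw one case-control dataset for a scenario.

    Case dosages at variant i are iid Binomial(2, f+_i), control
    dosages Binomial(2, f-_i); variants are independent.  ``seed`` may
    be an integer (fully reproducible) or a Generator whose stream is
    advanced.  Cases precede controls in the returned matrix.
    """
    rng = np.random.default_rng(seed)
    truth = expected_values(setting)
    n_plus, n_minus = setting.n_cases, setting.n_controls
    m = setting.n_variants
    dos = np.empty((n_plus + n_minus, m), dtype=np.int8)
    dos[:n_plus] = rng.binomial(2, truth.case_maf, size=(n_plus, m))
    dos[n_plus:] = rng.binomial(2, truth.control_maf, size=(n_minus, m))
    status = np.zeros(n_plus + n_minus, dtype=np.int8)
    status[:n_plus] = 1
    geno = CaseControlGenotypes(dosages=dos, status=status)
    return geno, truth


def replicate_seed(master_seed: int, replicate: int) -> np.random.SeedSequence:
    """Counter-based per-replicate seed: replicate r is reproducible alone."""
    return np.random.SeedSequence([int(master_seed), int(replicate)])


# ---------------------------------------------------------------------------
# canonical 50-scenario grid
# ---------------------------------------------------------------------------

#: (% risk-increasing, % neutral, % risk-decreasing)
RR_MIXES = [(20, 80, 0), (50, 50, 0), (80, 20, 0), (20, 60, 20), (0, 100, 0)]


def _architectures() -> list[tuple[str, float | None, float, bool]]:
    """(label, common MAF or None, rare MAF, common-risk flag) per architecture."""
    archs: list[tuple[str, float | None, float, bool]] = []
    for rare in (0.0001, 0.001):
        archs.append((f"allrare{rare:g}", None, rare, False))
    for common in (0.05, 0.01):
        for rare in (0.0001, 0.001):
            archs.append((f"common{common:g}-rare{rare:g}", common, rare, False))
    for common in (0.05, 0.01):
        for rare in (0.0001, 0.001):
            archs.append((f"2common{common:g}-rare{rare:g}", common, rare, True))
    return archs


def _build_setting(
    label: str,
    common: float | None,
    rare: float,
    common_risk: bool,
    mix: tuple[int, int, int],
    m: int = 10,
    n_cases: int = 1500,
    n_controls: int = 1500,
    alpha: float = 0.01,
) -> GeneSetting:
    """Lay out one scenario: risk-increasing rares, risk-decreasing rares,
    common variant(s), then neutral rares."""
    n_up = round(mix[0] * m / 100)
    n_down = round(mix[2] * m / 100)
    n_common = 0 if common is None else (2 if common_risk else 1)

    # a designated common risk-increasing variant consumes one "up" slot
    common_up = 1 if (common_risk and n_up >= 1) else 0
    rare_up = n_up - common_up
    rare_down = n_down
    rare_total = m - n_common
    rare_neutral = rare_total - rare_up - rare_down
    if rare_neutral < 0:
        raise ValueError("risk mix does not fit the MAF architecture")

    maf: list[float] = []
    rr: list[float] = []
    maf += [rare] * rare_up
    rr += [RISK_LAMBDA[rare]] * rare_up
    maf += [rare] * rare_down
    rr += [1.0 / RISK_LAMBDA[rare]] * rare_down
    if n_common:
        if common_risk:
            maf += [common]
            rr += [RISK_LAMBDA[common] if common_up else 1.0]
        maf += [common]  # the always-neutral common variant
        rr += [1.0]
    maf += [rare] * rare_neutral
    rr += [1.0] * rare_neutral
    sid = f"{label}-rr{mix[0]}:{mix[1]}:{mix[2]}"
    return GeneSetting(
        setting_id=sid,
        maf=np.array(maf),
        rr=np.array(rr),
        n_cases=n_cases,
        n_controls=n_controls,
        alpha=alpha,
    )


def canonical_settings(alpha: float = 0.01) -> list[GeneSetting]:
    """The 50 canonical scenarios: 10 MAF architectures x 5 risk mixes."""
    out = []
    for label, common, rare, common_risk in _architectures():
        for mix in RR_MIXES:
            out.append(_build_setting(label, common, rare, common_risk, mix, alpha=alpha))
    return out


def lowpower_scenario(alpha: float = 0.01) -> GeneSetting:
    """The worked low-power scenario: 5 rare risk variants (f = 0.0001,
    RR = 8), one common neutral variant (f = 0.01, position 6) and 4
    rare neutral variants, analysed with 1,500 cases and controls."""
    maf = np.array([0.0001] * 5 + [0.01] + [0.0001] * 4)
    rr = np.array([8.0] * 5 + [1.0] * 5)
    return GeneSetting("lowpower-scenario", maf, rr, 1500, 1500, alpha)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def settings_to_yaml(settings: list[GeneSetting], path=None) -> str | None:
    """Serialize scenarios to YAML, one document per scenario."""
    docs = [
        {
            "setting_id": s.setting_id,
            "maf": [float(x) for x in s.maf],
            "rr": [float(x) for x in s.rr],
            "n_cases": int(s.n_cases),
            "n_controls": int(s.n_controls),
            "alpha": float(s.alpha),
        }
        for s in settings
    ]
    text = yaml.safe_dump_all(docs, sort_keys=False)
    if path is None:
        return text
    with open(path, "w") as fh:
        fh.write(text)
    return None


def settings_from_yaml(source) -> list[GeneSetting]:
    """Load scenarios from a YAML path or string."""
    if isinstance(source, str) and "\n" not in source and not source.lstrip().startswith("setting_id"):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source
    out = []
    for doc in yaml.safe_load_all(text):
        if doc is None:
            continue
        out.append(
            GeneSetting(
                setting_id=doc["setting_id"],
                maf=np.array(doc["maf"], dtype=float),
                rr=np.array(doc["rr"], dtype=float),
                n_cases=int(doc.get("n_cases", 1500)),
                n_controls=int(doc.get("n_controls", 1500)),
                alpha=float(doc.get("alpha", 0.01)),
            )
        )
    return out


def genotypes_to_tsv(geno: CaseControlGenotypes, path) -> None:
    """Dosage matrix TSV: subject_id, status, then one column per variant."""
    geno.to_frame().to_csv(path, sep="\t", index=False)


def genotypes_from_tsv(path) -> CaseControlGenotypes:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    variant_ids = [c for c in df.columns if c not in ("subject_id", "status")]
    return CaseControlGenotypes(
        dosages=df[variant_ids].to_numpy(dtype=np.int8),
        status=df["status"].to_numpy(),
        variant_ids=variant_ids,
        subject_ids=[str(s) for s in df["subject_id"]],
    )


def genotypes_to_vcf(geno: CaseControlGenotypes, vcf_path, phenotype_path=None) -> None:
    """Minimal VCF 4.2 export (diploid unphased GT only) plus an optional
    two-column phenotype TSV.

    Dosage d is written as a genotype with d ALT alleles, so ALT is the
    minor allele by construction.
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write("##contig=<ID=1>\n")
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(geno.subject_ids) + "\n")
    for j, vid in enumerate(geno.variant_ids):
        row = [gt_map[int(d)] for d in geno.dosages[:, j]]
        buf.write(f"1\t{j + 1}\t{vid}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(row) + "\n")
    with open(vcf_path, "w") as fh:
        fh.write(buf.getvalue())
    if phenotype_path is not None:
        with open(phenotype_path, "w") as fh:
            fh.write("subject_id\tstatus\n")
            for sid, st in zip(geno.subject_ids, geno.status):
                fh.write(f"{sid}\t{int(st)}\n")
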