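"""SNP censoring filters and hard-calling of imputed genotype posteriors.

Genotyped SNPs are censored on minor allele frequency (< 0.01 by
default), missingness (> 5%) and gross departure from Hardy-Weinberg
equilibrium (p < 1e-20, asymptotic 1-df chi-square). Imputed genotypes
are hard-called when the maximum posterior probability exceeds 0.8
(strict by default, configurable), then censored on call rate (< 95%)
and MAF (< 1%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    MISSING,
    GenotypeTable,
    PosteriorGenotypeTable,
    ValidationError,
)


@dataclass(frozen=True)
class QcThresholds:
    maf_min: float = 0.01
    miss_max: float = 0.05
    hwe_p_min: float = 1e-20
    post_call_min: float = 0.8
    imputed_callrate_min: float = 0.95
    imputed_maf_min: float = 0.01
    post_call_strict: bool = True  # "exceeds" read as strict inequality

    def __post_init__(self) -> None:
        for name in (
            "maf_min",
            "miss_max",
            "hwe_p_min",
            "post_call_min",
            "imputed_callrate_min",
            "imputed_maf_min",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")


@dataclass
class QcReport:
    """Per-SNP QC metrics with pass/fail status and failure reasons."""

    per_snp: pd.DataFrame  # snp_id, metrics..., passed, reasons
    summary: dict[str, int] = field(default_factory=dict)

    @property
    def removed(self) -> list[str]:
        return list(self.per_snp.loc[~self.per_snp["passed"], "snp_id"])

    def reasons_for(self, snp_id: str) -> set[str]:
        row = self.per_snp.loc[self.per_snp["snp_id"] == snp_id, "reasons"]
        if row.empty:
            raise KeyError(snp_id)
        text = row.iloc[0]
        return set(text.split(",")) if text else set()


class UndefinedMafError(ValueError):
    """MAF requested for an all-missing genotype column."""


def snp_maf(calls: np.ndarray) -> float:
    """Minor allele frequency of one SNP's genotype column.

    Returns ``min(p, 1-p)`` where ``p`` is the counted-allele frequency
    among non-missing calls.
    """
    calls = np.asarray(calls)
    ok = calls != MISSING
    n = int(ok.sum())
    if n == 0:
        raise UndefinedMafError("all calls missing; MAF undefined")
    p = float(calls[ok].sum()) / (2 * n)
    return min(p, 1.0 - p)


def hwe_pvalue(n0: int, n1: int, n2: int) -> float:
    """Asymptotic 1-df chi-square goodness-of-fit test against HWE.

    Expected genotype proportions come from the observed allele
    frequency. Monomorphic columns return p = 1 by convention.
    """
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("need at least one genotype")
    p = (2 * n2 + n1) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 1.0
    expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _snp_metrics(table: GenotypeTable) -> pd.DataFrame:
    rows = []
    for j, snp in enumerate(table.snps):
        col = table.calls[:, j]
        ok = col != MISSING
        miss = 1.0 - ok.mean() if len(col) else 1.0
        if ok.any():
            maf = snp_maf(col)
            vals = col[ok]
            hwe = hwe_pvalue(
                int((vals == 0).sum()), int((vals == 1).sum()), int((vals == 2).sum())
            )
        else:
            maf = np.nan
            hwe = np.nan
        rows.append(
            {"snp_id": snp.snp_id, "maf": maf, "missing_frac": miss, "hwe_p": hwe}
        )
    return pd.DataFrame(rows)


def filter_snps(
    table: GenotypeTable, thresholds: QcThresholds = QcThresholds()
) -> tuple[GenotypeTable, QcReport]:
    """Censor SNPs failing MAF, missingness or HWE thresholds.

    All metrics are evaluated on the pre-filter table, so a SNP failing
    several filters is reported with every triggered reason and the
    result does not depend on any filter ordering. Idempotent.
    """
    if table.n_snps == 0:
        raise ValidationError("cannot QC an empty panel")
    metrics = _snp_metrics(table)
    reasons: list[str] = []
    passed: list[bool] = []
    for _, row in metrics.iterrows():
        why = []
        if not (row["maf"] >= thresholds.maf_min):  # NaN fails too
            why.append("maf")
        if row["missing_frac"] > thresholds.miss_max:
            why.append("missing")
        if not (row["hwe_p"] >= thresholds.hwe_p_min):
            why.append("hwe")
        reasons.append(",".join(why))
        passed.append(not why)
    metrics["passed"] = passed
    metrics["reasons"] = reasons
    kept = [s for s, p in zip(table.snp_ids, passed) if p]
    out = table.subset_snps(kept)
    report = QcReport(
        per_snp=metrics,
        summary={
            "n_snps": table.n_snps,
            "n_passed": len(kept),
            "n_removed": table.n_snps - len(kept),
        },
    )
    return out, report


def call_imputed(
    posteriors: PosteriorGenotypeTable, thresholds: QcThresholds = QcThresholds()
) -> tuple[GenotypeTable, QcReport]:
    """Hard-call imputed genotype posteriors, then censor SNPs.

    A cell is called to the argmax genotype when the maximum posterior
    probability exceeds ``post_call_min`` (strictly, unless
    ``post_call_strict`` is off); otherwise it is missing. SNPs are then
    removed when their call rate falls below ``imputed_callrate_min`` or
    their MAF below ``imputed_maf_min``.
    """
    probs = posteriors.probs
    best = probs.argmax(axis=2)
    best_p = probs.max(axis=2)
    if thresholds.post_call_strict:
        called = best_p > thresholds.post_call_min
    else:
        called = best_p >= thresholds.post_call_min
    calls = np.where(called, best, MISSING).astype(np.int8)
    full = GenotypeTable(posteriors.snps, posteriors.sample_ids, calls)

    metrics = _snp_metrics(full)
    metrics = metrics.rename(columns={"missing_frac": "no_call_frac"})
    reasons: list[str] = []
    passed: list[bool] = []
    for _, row in metrics.iterrows():
        why = []
        if not (1.0 - row["no_call_frac"] >= thresholds.imputed_callrate_min):
            why.append("callrate")
        if not (row["maf"] >= thresholds.imputed_maf_min):
            why.append("maf")
        reasons.append(",".join(why))
        passed.append(not why)
    metrics["passed"] = passed
    metrics["reasons"] = reasons
    kept = [s for s, p in zip(full.snp_ids, passed) if p]
    report = QcReport(
        per_snp=metrics.drop(columns=["hwe_p"]),
        summary={
            "n_snps": full.n_snps,
            "n_passed": len(kept),
            "n_removed": full.n_snps - len(kept),
        },
    )
    return full.subset_snps(kept), report
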