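"""Prediction accuracy and cross-platform genotype concordance.

Accuracy compares predicted HLA allele pairs with typed truth: the
headline metric is per-allele accuracy (matched alleles over twice the
called samples, with the pairing of predicted to true alleles chosen to
maximize matches), co-reported with per-sample accuracy (both alleles
matched). Ambiguous truth credits a match to any alternative; samples
with missing truth are excluded from denominators. A frequency
threshold restricts the denominator to truth alleles whose training-set
frequency exceeds the threshold.

Concordance between genotyping platforms uses Cohen's kappa,
kappa = [Pr(a) - Pr(e)] / [1 - Pr(e)], pooled over all SNP-sample
genotype pairs within each observed/imputed source class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .calling import PredictionResult
from .io import MISSING, GenotypeTable, HlaTypingTable, ValidationError
from .nomenclature import AlleleSet, HlaAllele, alleles_match, to_intermediate

CONCORDANCE_CLASSES = ("O-O", "O-I", "I-O", "I-I")


@dataclass
class AccuracyReport:
    locus: str
    resolution: str
    ct: float
    n_evaluated: int
    n_called: int
    call_rate: float
    per_allele_accuracy: float | None
    per_sample_accuracy: float | None
    min_allele_freq: float = 0.0
    n_allele_slots: int = 0
    n_matched: int = 0
    flagged: bool = False  # no called samples -> accuracies undefined


def _reduce(allele: HlaAllele, resolution: str) -> HlaAllele:
    return to_intermediate(allele) if resolution == "intermediate" else allele


def _slot_passes(
    truth_set: AlleleSet,
    min_allele_freq: float,
    training_freqs: Mapping[HlaAllele, float] | None,
) -> bool:
    if min_allele_freq <= 0 or training_freqs is None:
        return True
    return any(
        training_freqs.get(a, 0.0) > min_allele_freq for a in truth_set.alternatives
    )


def accuracy(
    results: Sequence[PredictionResult],
    truth: HlaTypingTable,
    locus: str,
    resolution: str,
    min_allele_freq: float = 0.0,
    training_freqs: Mapping[HlaAllele, float] | None = None,
) -> AccuracyReport:
    """Score called predictions against (possibly ambiguous) truth.

    The two predicted alleles are paired with the two truth slots in
    whichever of the two pairings yields more matches, which handles
    the homozygote/heterozygote asymmetry. Raising ``min_allele_freq``
    only restricts the evaluated slots; it never changes whether an
    individual slot matched.
    """
    n_eval = 0
    n_called = 0
    slots = 0
    matched = 0
    samples_all_pass = 0
    samples_fully_correct = 0
    for r in results:
        pair = truth.get(r.sample_id, locus)
        if pair is None:
            continue  # missing/unresolved truth: excluded from denominators
        n_eval += 1
        if not r.called:
            continue
        n_called += 1
        t1, t2 = (s.at_resolution(resolution) for s in pair)
        p1, p2 = (_reduce(a, resolution) for a in r.best_pair)
        pairing_a = (alleles_match(p1, t1), alleles_match(p2, t2))
        pairing_b = (alleles_match(p1, t2), alleles_match(p2, t1))
        hits = pairing_a if sum(pairing_a) >= sum(pairing_b) else pairing_b
        truth_order = (t1, t2) if sum(pairing_a) >= sum(pairing_b) else (t2, t1)
        ok_slots = [
            _slot_passes(t, min_allele_freq, training_freqs) for t in truth_order
        ]
        slots += sum(ok_slots)
        matched += sum(h for h, ok in zip(hits, ok_slots) if ok)
        if all(ok_slots):
            samples_all_pass += 1
            if all(hits):
                samples_fully_correct += 1
    if n_called == 0 or slots == 0:
        return AccuracyReport(
            locus, resolution, results[0].ct if results else 0.0,
            n_eval, n_called, (n_called / n_eval) if n_eval else 0.0,
            None, None, min_allele_freq, slots, matched, flagged=True,
        )
    return AccuracyReport(
        locus=locus,
        resolution=resolution,
        ct=results[0].ct if results else 0.0,
        n_evaluated=n_eval,
        n_called=n_called,
        call_rate=n_called / n_eval,
        per_allele_accuracy=matched / slots,
        per_sample_accuracy=samples_fully_correct / samples_all_pass
        if samples_all_pass
        else None,
        min_allele_freq=min_allele_freq,
        n_allele_slots=slots,
        n_matched=matched,
    )


# ---------------------------------------------------------------------------
# Cohen's kappa and platform concordance


def kappa(x: Sequence[int], y: Sequence[int]) -> float:
    """Cohen's kappa over genotype categories {0,1,2}.

    Pairs with a missing value on either side are dropped first.
    Conventions: perfect agreement gives 1 even for constant vectors;
    two constant but different vectors give 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValidationError("kappa requires equal-length vectors")
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if len(x) == 0:
        raise ValidationError("kappa undefined: no jointly non-missing pairs")
    pr_a = float((x == y).mean())
    cats = (0, 1, 2)
    px = np.array([(x == c).mean() for c in cats])
    py = np.array([(y == c).mean() for c in cats])
    pr_e = float((px * py).sum())
    if pr_a == 1.0:
        return 1.0
    if 1.0 - pr_e == 0.0:
        return 0.0  # both constant, different categories
    return (pr_a - pr_e) / (1.0 - pr_e)


@dataclass
class ConcordanceInput:
    """Two harmonized genotype tables plus per-SNP source tags.

    Tags map snp_id to ``"observed"`` or ``"imputed"`` on each side.
    Tables must share sample and SNP axes and count the same allele per
    SNP (mismatched counted alleles are an error, never silently
    flipped).
    """

    table_a: GenotypeTable
    table_b: GenotypeTable
    tags_a: Mapping[str, str]
    tags_b: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.table_a.sample_ids != self.table_b.sample_ids:
            raise ValidationError("concordance requires identical sample axes")
        if self.table_a.snp_ids != self.table_b.snp_ids:
            raise ValidationError("concordance requires identical SNP axes")
        for sa, sb in zip(self.table_a.snps, self.table_b.snps):
            if sa.allele_b != sb.allele_b:
                raise ValidationError(
                    f"{sa.snp_id}: counted allele differs between platforms "
                    f"({sa.allele_b} vs {sb.allele_b}); harmonize orientation first"
                )
        for tags in (self.tags_a, self.tags_b):
            for sid in self.table_a.snp_ids:
                if tags.get(sid) not in ("observed", "imputed"):
                    raise ValidationError(f"{sid}: missing or invalid source tag")


@dataclass
class ConcordanceReport:
    kappas: dict[str, float | None]  # per class + "overall"; None = class absent
    n_pairs: dict[str, int] = field(default_factory=dict)


def platform_concordance(ci: ConcordanceInput) -> ConcordanceReport:
    """Pooled per-class kappas between two platform views.

    Classes follow the source tags: observed on both (O-O), observed on
    the first but imputed on the second (O-I), the reverse (I-O),
    imputed on both (I-I), plus the overall pool. Each class pools all
    its SNP-sample genotype pairs into a single 3x3 agreement table;
    pairs missing on either side are excluded. An empty class is
    reported as absent, not as zero.
    """
    per_class: dict[str, list[np.ndarray]] = {c: [] for c in CONCORDANCE_CLASSES}
    for j, sid in enumerate(ci.table_a.snp_ids):
        cls = ("O" if ci.tags_a[sid] == "observed" else "I") + "-" + (
            "O" if ci.tags_b[sid] == "observed" else "I"
        )
        per_class[cls].append(
            np.stack([ci.table_a.calls[:, j], ci.table_b.calls[:, j]])
        )
    kappas: dict[str, float | None] = {}
    n_pairs: dict[str, int] = {}
    pooled_a: list[np.ndarray] = []
    pooled_b: list[np.ndarray] = []
    for cls in CONCORDANCE_CLASSES:
        cols = per_class[cls]
        if not cols:
            kappas[cls] = None
            n_pairs[cls] = 0
            continue
        xa = np.concatenate([c[0] for c in cols])
        xb = np.concatenate([c[1] for c in cols])
        ok = (xa != MISSING) & (xb != MISSING)
        n_pairs[cls] = int(ok.sum())
        kappas[cls] = kappa(xa, xb) if ok.any() else None
        pooled_a.append(xa)
        pooled_b.append(xb)
    xa = np.concatenate(pooled_a) if pooled_a else np.array([], dtype=np.int8)
    xb = np.concatenate(pooled_b) if pooled_b else np.array([], dtype=np.int8)
    ok = (xa != MISSING) & (xb != MISSING)
    n_pairs["overall"] = int(ok.sum())
    kappas["overall"] = kappa(xa, xb) if ok.any() else None
    return ConcordanceReport(kappas=kappas, n_pairs=n_pairs)
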