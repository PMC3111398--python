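"""Joint (HLA allele, SNP haplotype) frequency model fitted by EM.

The model for one HLA locus is a frequency table over *joint
haplotypes*: an HLA allele together with a string of SNP alleles
(``a``/``b``) over an ordered SNP list. Under Hardy-Weinberg random
pairing, an individual's two joint haplotypes are drawn independently,
so the likelihood of a sample with unphased SNP genotypes G (and,
during training, a known unphased HLA genotype) is

    L_i = sum over ordered compatible pairs (g, g') of f_g * f_g'

where a pair is compatible when its allele counts reproduce every
non-missing SNP genotype and (if constrained) its HLA alleles match the
sample's typed pair. Frequencies are estimated by EM on the product of
these per-sample likelihoods; missing SNP genotypes are marginalized,
never imputed. Prediction assigns each unordered HLA allele pair the
total frequency mass of its compatible configurations.

Haplotype space is grown incrementally (one SNP at a time, children of
retained parents only) with pruning at ``prune_eps``, which keeps
models with many SNPs tractable without enumerating all 2^S haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import MISSING, GenotypeTable, HlaTypingTable, SnpRecord, ValidationError
from .nomenclature import AlleleSet, HlaAllele

__all__ = [
    "JointHaplotype",
    "HaplotypeModel",
    "FitDiagnostics",
    "enumerate_compatible_pairs",
    "fit_em",
    "extend_model",
    "drop_snp",
    "posterior_hla",
    "conditional_nll",
]

_PROB_FLOOR = 1e-300
_FULL_ENUM_LIMIT = 4096


@dataclass(frozen=True)
class JointHaplotype:
    """One chromosome's HLA allele plus its SNP alleles (``a``/``b``)."""

    hla: HlaAllele
    snp_alleles: str

    def __str__(self) -> str:
        return f"{self.hla}|{self.snp_alleles or '-'}"


@dataclass
class FitDiagnostics:
    """Per-iteration observed-data log-likelihood and convergence state."""

    loglik: list[float] = dc_field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    final_objective: float | None = None

    @property
    def final_loglik(self) -> float:
        return self.loglik[-1] if self.loglik else float("nan")


def _allele_sort_key(a: HlaAllele):
    return (a.locus, a.field1, a.field2 or "")


def _bits_to_str(bits: np.ndarray) -> str:
    return "".join("b" if int(x) else "a" for x in bits)


def _str_to_bits(s: str) -> np.ndarray:
    return np.array([1 if c == "b" else 0 for c in s], dtype=np.uint8)


class HaplotypeModel:
    """Frequency table over joint haplotypes for one locus and resolution."""

    def __init__(
        self,
        locus: str,
        resolution: str,
        snps: Sequence[SnpRecord],
        alleles: Sequence[HlaAllele],
        hap_hla: np.ndarray,
        hap_bits: np.ndarray,
        freqs: np.ndarray,
        n_train: int = 0,
        prune_eps: float = 1e-5,
    ) -> None:
        self.locus = locus
        self.resolution = resolution
        self.snps = list(snps)
        self.alleles = list(alleles)
        self.hap_hla = np.asarray(hap_hla, dtype=np.intp)
        self.hap_bits = np.asarray(hap_bits, dtype=np.uint8)
        self.freqs = np.asarray(freqs, dtype=float)
        self.n_train = n_train
        self.prune_eps = prune_eps
        self._validate()

    def _validate(self) -> None:
        K = len(self.freqs)
        if self.hap_hla.shape != (K,) or self.hap_bits.shape != (K, len(self.snps)):
            raise ValidationError("inconsistent haplotype array shapes")
        if (self.freqs < 0).any():
            raise ValidationError("negative haplotype frequency")
        if K and abs(self.freqs.sum() - 1.0) > 1e-8:
            raise ValidationError(
                f"haplotype frequencies sum to {self.freqs.sum():.12f}, not 1"
            )
        for a in self.alleles:
            if a.locus != self.locus:
                raise ValidationError(f"allele {a} does not belong to locus {self.locus}")

    # -- views ------------------------------------------------------------

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_haplotypes(self) -> int:
        return len(self.freqs)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def haplotype(self, k: int) -> JointHaplotype:
        return JointHaplotype(
            self.alleles[self.hap_hla[k]], _bits_to_str(self.hap_bits[k])
        )

    def freq_items(self) -> list[tuple[JointHaplotype, float]]:
        items = [(self.haplotype(k), float(self.freqs[k])) for k in range(self.n_haplotypes)]
        return sorted(items, key=lambda t: (_allele_sort_key(t[0].hla), t[0].snp_alleles))

    def freq_of(self, hla: HlaAllele, snp_alleles: str) -> float:
        for k in range(self.n_haplotypes):
            if self.alleles[self.hap_hla[k]] == hla and _bits_to_str(self.hap_bits[k]) == snp_alleles:
                return float(self.freqs[k])
        return 0.0

    def marginal_hla_freqs(self) -> dict[HlaAllele, float]:
        out: dict[HlaAllele, float] = {}
        for k in range(self.n_haplotypes):
            a = self.alleles[self.hap_hla[k]]
            out[a] = out.get(a, 0.0) + float(self.freqs[k])
        return out

    @classmethod
    def from_freqs(
        cls,
        locus: str,
        resolution: str,
        snps: Sequence[SnpRecord],
        freqs: Mapping[tuple[HlaAllele, str], float],
        n_train: int = 0,
        prune_eps: float = 1e-5,
    ) -> "HaplotypeModel":
        alleles = sorted({a for a, _ in freqs}, key=_allele_sort_key)
        aidx = {a: i for i, a in enumerate(alleles)}
        keys = sorted(freqs, key=lambda t: (_allele_sort_key(t[0]), t[1]))
        hap_hla = np.array([aidx[a] for a, _ in keys], dtype=np.intp)
        hap_bits = (
            np.array([_str_to_bits(s) for _, s in keys], dtype=np.uint8)
            if keys
            else np.zeros((0, len(snps)), np.uint8)
        )
        if hap_bits.shape[1] != len(snps):
            raise ValidationError("snp_alleles length does not match the SNP list")
        f = np.array([freqs[k] for k in keys], dtype=float)
        return cls(locus, resolution, snps, alleles, hap_hla, hap_bits, f, n_train, prune_eps)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeModel):
            return NotImplemented
        if (
            self.locus != other.locus
            or self.resolution != other.resolution
            or self.snps != other.snps
        ):
            return False
        a = dict((str(j), f) for j, f in self.freq_items())
        b = dict((str(j), f) for j, f in other.freq_items())
        if a.keys() != b.keys():
            return False
        return all(abs(a[k] - b[k]) <= 1e-12 for k in a)


# ---------------------------------------------------------------------------
# compatibility machinery


def _pair_mask(bits: np.ndarray, geno: np.ndarray) -> np.ndarray:
    """K x K boolean: ordered haplotype pairs whose allele counts
    reproduce every non-missing SNP genotype."""
    K = len(bits)
    mask = np.ones((K, K), dtype=bool)
    for j, g in enumerate(geno):
        if g == MISSING:
            continue
        col = bits[:, j]
        if g == 0:
            v = col == 0
            mask &= v[:, None] & v[None, :]
        elif g == 2:
            v = col == 1
            mask &= v[:, None] & v[None, :]
        else:
            a = col == 0
            b = col == 1
            mask &= (a[:, None] & b[None, :]) | (b[:, None] & a[None, :])
    return mask


def _hla_pair_mask(
    hap_hla: np.ndarray, allowed_pairs: Iterable[tuple[int, int]]
) -> np.ndarray:
    K = len(hap_hla)
    mask = np.zeros((K, K), dtype=bool)
    for i, j in allowed_pairs:
        vi = hap_hla == i
        vj = hap_hla == j
        mask |= vi[:, None] & vj[None, :]
        mask |= vj[:, None] & vi[None, :]
    return mask


def enumerate_compatible_pairs(
    model: HaplotypeModel,
    snp_genotypes: np.ndarray,
    hla_genotype: tuple[AlleleSet, AlleleSet] | None = None,
) -> list[tuple[JointHaplotype, JointHaplotype, float]]:
    """All ordered haplotype pairs explaining a sample's genotypes.

    Missing SNP entries impose no constraint; weights are products of
    model frequencies. An empty list marks a zero-likelihood sample.
    """
    geno = np.asarray(snp_genotypes)
    if geno.shape != (model.n_snps,):
        raise ValidationError(
            f"genotype vector length {geno.shape} does not match model ({model.n_snps} SNPs)"
        )
    mask = _pair_mask(model.hap_bits, geno)
    if hla_genotype is not None:
        allowed = _allowed_allele_pairs(model, hla_genotype)
        mask &= _hla_pair_mask(model.hap_hla, allowed)
    out = []
    ia, ib = np.nonzero(mask)
    for i, j in zip(ia, ib):
        w = float(model.freqs[i] * model.freqs[j])
        if w > 0:
            out.append((model.haplotype(i), model.haplotype(j), w))
    return out


def _allowed_allele_pairs(
    model: HaplotypeModel, hla_genotype: tuple[AlleleSet, AlleleSet]
) -> set[tuple[int, int]]:
    """Unordered index pairs of model alleles consistent with a typed
    (possibly ambiguous) HLA genotype at the model's resolution."""
    s1, s2 = (s.at_resolution(model.resolution) for s in hla_genotype)
    aidx = {a: i for i, a in enumerate(model.alleles)}
    pairs: set[tuple[int, int]] = set()
    for a1 in s1.alternatives:
        for a2 in s2.alternatives:
            if a1 in aidx and a2 in aidx:
                i, j = aidx[a1], aidx[a2]
                pairs.add((min(i, j), max(i, j)))
    return pairs


# ---------------------------------------------------------------------------
# EM core


class _Group:
    """Samples sharing one (genotype row, HLA constraint) configuration."""

    __slots__ = ("count", "ia", "ib")

    def __init__(self, count: int, ia: np.ndarray, ib: np.ndarray) -> None:
        self.count = count
        self.ia = ia
        self.ib = ib


def _build_groups(
    bits: np.ndarray,
    hap_hla: np.ndarray,
    genos: np.ndarray,
    truth_pairs: Sequence[frozenset] | None,
) -> list[_Group]:
    keyed: dict = {}
    for i in range(len(genos)):
        tkey = truth_pairs[i] if truth_pairs is not None else None
        key = (genos[i].tobytes(), tkey)
        keyed[key] = keyed.get(key, 0) + 1
    groups: list[_Group] = []
    for (gbytes, tkey), count in keyed.items():
        geno = np.frombuffer(gbytes, dtype=genos.dtype)
        mask = _pair_mask(bits, geno)
        if tkey is not None:
            mask &= _hla_pair_mask(hap_hla, tkey)
        ia, ib = np.nonzero(mask)
        groups.append(_Group(count, ia, ib))
    return groups


def _run_em(
    groups: list[_Group],
    f0: np.ndarray,
    n_samples: int,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, FitDiagnostics]:
    """EM iterations on grouped samples; returns frequencies whose
    log-likelihood is the last entry of the diagnostics."""
    K = len(f0)
    f = f0.copy()
    diag = FitDiagnostics()
    for it in range(max_iter):
        counts = np.zeros(K)
        ll = 0.0
        for g in groups:
            w = f[g.ia] * f[g.ib]
            s = w.sum()
            if s <= 0.0:
                if len(g.ia) == 0:
                    continue  # incompatible group; handled by caller
                w = np.full(len(g.ia), 1.0 / len(g.ia))
                s = _PROB_FLOOR
            ll += g.count * np.log(max(s, _PROB_FLOOR))
            r = w * (g.count / max(s, _PROB_FLOOR))
            np.add.at(counts, g.ia, r)
            np.add.at(counts, g.ib, r)
        total = counts.sum()
        if total > 0:
            f_new = counts / total
        else:
            f_new = f
        diag.loglik.append(ll)
        diag.n_iter = it + 1
        if it > 0 and diag.loglik[-1] - diag.loglik[-2] < tol * n_samples:
            diag.converged = True
            f = f_new
            break
        f = f_new
    # log-likelihood of the returned frequencies (>= last recorded by EM)
    ll = 0.0
    for g in groups:
        s = float((f[g.ia] * f[g.ib]).sum())
        ll += g.count * np.log(max(s, _PROB_FLOOR))
    diag.loglik.append(ll)
    return f, diag


def _prune(
    bits: np.ndarray,
    hap_hla: np.ndarray,
    f: np.ndarray,
    prune_eps: float,
    genos: np.ndarray,
    truth_pairs,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop haplotypes below ``prune_eps``; re-admit at floor frequency
    any haplotype needed to keep every sample compatible."""
    keep = f >= prune_eps
    if not keep.any():
        keep = f == f.max()
    # re-admit support for samples that would otherwise be inexplicable
    groups_all = _build_groups(bits, hap_hla, genos, truth_pairs)
    for g in groups_all:
        if len(g.ia) == 0:
            continue
        if not (keep[g.ia] & keep[g.ib]).any():
            w = f[g.ia] * f[g.ib]
            best = int(np.argmax(w))
            keep[g.ia[best]] = True
            keep[g.ib[best]] = True
    f = np.where(keep, np.maximum(f, prune_eps), 0.0)[keep]
    f = f / f.sum()
    return bits[keep], hap_hla[keep], f


def _truth_keys(
    truth: HlaTypingTable,
    sample_ids: Sequence[str],
    locus: str,
    resolution: str,
    alleles: Sequence[HlaAllele],
) -> list[frozenset]:
    aidx = {a: i for i, a in enumerate(alleles)}
    keys = []
    for sid in sample_ids:
        pair = truth.get(sid, locus)
        if pair is None:
            raise ValidationError(f"training sample {sid} has no HLA truth at {locus}")
        s1, s2 = (s.at_resolution(resolution) for s in pair)
        allowed = set()
        for a1 in s1.alternatives:
            for a2 in s2.alternatives:
                if a1 in aidx and a2 in aidx:
                    i, j = aidx[a1], aidx[a2]
                    allowed.add((min(i, j), max(i, j)))
        keys.append(frozenset(allowed))
    return keys


def _training_alleles(
    truth: HlaTypingTable, sample_ids: Sequence[str], locus: str, resolution: str
) -> list[HlaAllele]:
    seen: set[HlaAllele] = set()
    for sid in sample_ids:
        pair = truth.get(sid, locus)
        if pair is None:
            raise ValidationError(f"training sample {sid} has no HLA truth at {locus}")
        for s in pair:
            seen.update(s.at_resolution(resolution).alternatives)
    return sorted(seen, key=_allele_sort_key)


def _init_freqs(groups: list[_Group], K: int, rng: np.random.Generator) -> np.ndarray:
    """Frequencies proportional to compatible-configuration counts, plus
    a small symmetric Dirichlet jitter to escape symmetric saddles."""
    cnt = np.zeros(K)
    for g in groups:
        if len(g.ia) == 0:
            continue
        share = g.count / (2.0 * len(g.ia))
        np.add.at(cnt, g.ia, share)
        np.add.at(cnt, g.ib, share)
    if cnt.sum() <= 0:
        cnt = np.ones(K)
    f0 = cnt / cnt.sum()
    jitter = rng.dirichlet(np.ones(K))
    return 0.95 * f0 + 0.05 * jitter


def fit_em(
    genotypes: GenotypeTable,
    truth: HlaTypingTable,
    locus: str,
    resolution: str = "high",
    snp_ids: Sequence[str] | None = None,
    *,
    max_iter: int = 500,
    tol: float = 1e-6,
    prune_eps: float = 1e-5,
    seed: int = 0,
) -> tuple[HaplotypeModel, FitDiagnostics]:
    """Fit the joint haplotype frequency model by EM.

    Small haplotype spaces (alleles x 2^S up to ~4096) are enumerated in
    full; larger ones are grown one SNP at a time from the HLA-only
    model with pruning. Deterministic given ``seed``; the observed-data
    log-likelihood is non-decreasing across iterations.
    """
    table = genotypes if snp_ids is None else genotypes.subset_snps(snp_ids)
    alleles = _training_alleles(truth, table.sample_ids, locus, resolution)
    S = table.n_snps
    A = len(alleles)
    rng = np.random.default_rng(seed)

    if A * (2**S) <= _FULL_ENUM_LIMIT:
        patterns = (
            np.array(
                [[(p >> j) & 1 for j in range(S)] for p in range(2**S)], dtype=np.uint8
            )
            if S
            else np.zeros((1, 0), np.uint8)
        )
        bits = np.repeat(patterns, A, axis=0)
        hap_hla = np.tile(np.arange(A, dtype=np.intp), 2**S)
        return _fit_on_support(
            table, truth, locus, resolution, alleles, bits, hap_hla,
            max_iter=max_iter, tol=tol, prune_eps=prune_eps, rng=rng,
        )

    # incremental growth: HLA-only seed, then one SNP at a time
    base = table.subset_snps([])
    model, diag = _fit_on_support(
        base, truth, locus, resolution, alleles,
        np.zeros((A, 0), np.uint8), np.arange(A, dtype=np.intp),
        max_iter=max_iter, tol=tol, prune_eps=prune_eps, rng=rng,
    )
    for snp in table.snps:
        model, diag = extend_model(
            model, snp, genotypes, truth,
            max_iter=max_iter, tol=tol, seed=int(rng.integers(2**31)),
        )
    return model, diag


def _fit_on_support(
    table: GenotypeTable,
    truth: HlaTypingTable,
    locus: str,
    resolution: str,
    alleles: Sequence[HlaAllele],
    bits: np.ndarray,
    hap_hla: np.ndarray,
    *,
    max_iter: int,
    tol: float,
    prune_eps: float,
    rng: np.random.Generator,
    f0: np.ndarray | None = None,
) -> tuple[HaplotypeModel, FitDiagnostics]:
    truth_pairs = _truth_keys(truth, table.sample_ids, locus, resolution, alleles)
    genos = np.ascontiguousarray(table.calls)
    groups = _build_groups(bits, hap_hla, genos, truth_pairs)
    n = table.n_samples
    if f0 is None:
        f0 = _init_freqs(groups, len(bits), rng)
    else:
        f0 = 0.999 * f0 / f0.sum() + 0.001 * rng.dirichlet(np.ones(len(bits)))
    f, diag = _run_em(groups, f0, n, max_iter, tol)
    bits2, hla2, f2 = _prune(bits, hap_hla, f, prune_eps, genos, truth_pairs)
    if len(f2) != len(f):
        groups2 = _build_groups(bits2, hla2, genos, truth_pairs)
        f2, diag2 = _run_em(groups2, f2, n, max_iter, tol)
        bits2, hla2, f2 = _prune(bits2, hla2, f2, prune_eps, genos, truth_pairs)
        diag.loglik.extend(diag2.loglik)
        diag.n_iter += diag2.n_iter
        diag.converged = diag2.converged
    model = HaplotypeModel(
        locus, resolution, table.snps, list(alleles), hla2, bits2, f2,
        n_train=n, prune_eps=prune_eps,
    )
    return model, diag


def extend_model(
    model: HaplotypeModel,
    new_snp: SnpRecord,
    genotypes: GenotypeTable,
    truth: HlaTypingTable,
    *,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> tuple[HaplotypeModel, FitDiagnostics]:
    """Add one SNP to a fitted model, splitting each retained haplotype
    into its ``a``/``b`` children and re-estimating by warm-started EM.

    Child frequencies start from the parent frequency split by the new
    SNP's allele frequency in the training genotypes.
    """
    if new_snp.snp_id in model.snp_ids:
        raise ValidationError(f"SNP {new_snp.snp_id} already in model")
    col = genotypes.column(new_snp.snp_id)
    ok = col != MISSING
    p_b = float(col[ok].sum()) / (2 * ok.sum()) if ok.any() else 0.5
    p_b = min(max(p_b, 1e-6), 1 - 1e-6)

    K = model.n_haplotypes
    child_bits = np.concatenate(
        [
            np.hstack([model.hap_bits, np.zeros((K, 1), np.uint8)]),
            np.hstack([model.hap_bits, np.ones((K, 1), np.uint8)]),
        ]
    )
    child_hla = np.concatenate([model.hap_hla, model.hap_hla])
    f0 = np.concatenate([model.freqs * (1 - p_b), model.freqs * p_b])

    snp_ids = model.snp_ids + [new_snp.snp_id]
    table = genotypes.subset_snps(snp_ids)
    # keep the model's SNP ordering contract: sorted by position
    order = np.argsort([s.position for s in table.snps], kind="stable")
    table = table.subset_snps([table.snps[i].snp_id for i in order])
    perm = [snp_ids.index(sid) for sid in table.snp_ids]
    child_bits = child_bits[:, perm]

    rng = np.random.default_rng(seed)
    return _fit_on_support(
        table, truth, model.locus, model.resolution, model.alleles,
        child_bits, child_hla,
        max_iter=max_iter, tol=tol, prune_eps=model.prune_eps, rng=rng, f0=f0,
    )


def drop_snp(
    model: HaplotypeModel,
    snp_id: str,
    genotypes: GenotypeTable,
    truth: HlaTypingTable,
    *,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> tuple[HaplotypeModel, FitDiagnostics]:
    """Remove one SNP: marginalize the frequency table over it, then
    re-estimate by warm-started EM."""
    if snp_id not in model.snp_ids:
        raise ValidationError(f"SNP {snp_id} not in model")
    j = model.snp_ids.index(snp_id)
    keep_cols = [c for c in range(model.n_snps) if c != j]
    bits = model.hap_bits[:, keep_cols]
    merged: dict[tuple[int, bytes], float] = {}
    for k in range(model.n_haplotypes):
        key = (int(model.hap_hla[k]), bits[k].tobytes())
        merged[key] = merged.get(key, 0.0) + float(model.freqs[k])
    keys = sorted(merged)
    hap_hla = np.array([k[0] for k in keys], dtype=np.intp)
    hap_bits = (
        np.array([np.frombuffer(k[1], dtype=np.uint8) for k in keys])
        if keys
        else np.zeros((0, len(keep_cols)), np.uint8)
    )
    f0 = np.array([merged[k] for k in keys])
    snp_ids = [model.snps[c].snp_id for c in keep_cols]
    table = genotypes.subset_snps(snp_ids)
    rng = np.random.default_rng(seed)
    return _fit_on_support(
        table, truth, model.locus, model.resolution, model.alleles,
        hap_bits, hap_hla,
        max_iter=max_iter, tol=tol, prune_eps=model.prune_eps, rng=rng, f0=f0,
    )


def marginalize_snp(model: HaplotypeModel, snp_id: str) -> HaplotypeModel:
    """Marginalize the frequency table over one SNP without refitting."""
    j = model.snp_ids.index(snp_id)
    keep_cols = [c for c in range(model.n_snps) if c != j]
    freqs: dict[tuple[HlaAllele, str], float] = {}
    for jh, f in model.freq_items():
        s = jh.snp_alleles[:j] + jh.snp_alleles[j + 1 :]
        key = (jh.hla, s)
        freqs[key] = freqs.get(key, 0.0) + f
    return HaplotypeModel.from_freqs(
        model.locus, model.resolution,
        [model.snps[c] for c in keep_cols], freqs,
        n_train=model.n_train, prune_eps=model.prune_eps,
    )


# ---------------------------------------------------------------------------
# prediction


def _pair_key(a1: HlaAllele, a2: HlaAllele) -> tuple[HlaAllele, HlaAllele]:
    return tuple(sorted((a1, a2), key=_allele_sort_key))  # type: ignore[return-value]


def hla_genotype_prior(model: HaplotypeModel) -> dict[tuple[HlaAllele, HlaAllele], float]:
    """HWE prior over unordered HLA genotype pairs implied by the
    model's marginal allele frequencies."""
    marg = model.marginal_hla_freqs()
    alleles = sorted(marg, key=_allele_sort_key)
    prior: dict[tuple[HlaAllele, HlaAllele], float] = {}
    for i, a1 in enumerate(alleles):
        for a2 in alleles[i:]:
            p = marg[a1] * marg[a2]
            if a1 != a2:
                p *= 2
            if p > 0:
                prior[(a1, a2)] = p
    total = sum(prior.values())
    return {k: v / total for k, v in prior.items()}


def posterior_hla(
    model: HaplotypeModel, snp_genotypes: np.ndarray
) -> tuple[dict[tuple[HlaAllele, HlaAllele], float], bool]:
    """Posterior over unordered HLA genotype pairs given SNP genotypes.

    Returns ``(posterior, fallback)``. Zero-likelihood samples fall back
    to the HWE prior from marginal HLA frequencies (``fallback=True``),
    so prediction never fails.
    """
    geno = np.asarray(snp_genotypes)
    if geno.shape != (model.n_snps,):
        raise ValidationError("genotype vector not aligned to model SNPs")
    mask = _pair_mask(model.hap_bits, geno)
    ia, ib = np.nonzero(mask)
    w = model.freqs[ia] * model.freqs[ib]
    total = float(w.sum())
    if total <= 0.0:
        return hla_genotype_prior(model), True
    post: dict[tuple[HlaAllele, HlaAllele], float] = {}
    for i, j, wij in zip(ia, ib, w):
        key = _pair_key(model.alleles[model.hap_hla[i]], model.alleles[model.hap_hla[j]])
        post[key] = post.get(key, 0.0) + float(wij)
    return {k: v / total for k, v in post.items()}, False


def _pair_matches_truth(
    pair: tuple[HlaAllele, HlaAllele], s1: AlleleSet, s2: AlleleSet
) -> bool:
    a, b = pair
    return (a in s1.alternatives and b in s2.alternatives) or (
        a in s2.alternatives and b in s1.alternatives
    )


def conditional_nll(
    model: HaplotypeModel,
    genotypes: GenotypeTable,
    truth: HlaTypingTable,
) -> float:
    """Negative log-likelihood of the typed HLA genotypes given SNP
    genotypes under the model.

    Ambiguous truth contributes the summed posterior mass over its
    alternatives; prior-fallback samples contribute via the prior.
    """
    table = genotypes.subset_snps(model.snp_ids)
    cache: dict[bytes, dict] = {}
    nll = 0.0
    for i, sid in enumerate(table.sample_ids):
        pair = truth.get(sid, model.locus)
        if pair is None:
            raise ValidationError(f"sample {sid} has no HLA truth at {model.locus}")
        s1, s2 = (s.at_resolution(model.resolution) for s in pair)
        key = table.calls[i].tobytes()
        if key not in cache:
            cache[key] = posterior_hla(model, table.calls[i])[0]
        post = cache[key]
        mass = sum(p for k, p in post.items() if _pair_matches_truth(k, s1, s2))
        nll -= np.log(max(mass, _PROB_FLOOR))
    return float(nll)
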