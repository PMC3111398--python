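"""Forward-and-backward SNP selection over an expanding flanking window.

Selection starts among SNPs inside the HLA gene, repeatedly adds the
candidate that most improves the penalized conditional negative
log-likelihood, removes any selected SNP whose removal improves it,
and widens the search window stepwise into the flanking region when no
move helps. The objective is

    conditional NLL of HLA given SNPs  +  lambda * (K - 1)

where K is the number of retained joint haplotypes, i.e. the free
frequency parameters. lambda = 1 (AIC-like) by default; log(n)/2
(BIC-like) is a standard alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeTable, HlaTypingTable, ValidationError
from .model import (
    HaplotypeModel,
    conditional_nll,
    drop_snp,
    extend_model,
    fit_em,
)

_EPS = 1e-9  # strictness margin for accepted moves


@dataclass
class SearchConfig:
    gene_start: int
    gene_end: int
    window_step: int = 50_000
    max_window: int = 500_000
    penalty_lambda: float = 1.0
    max_snps: int = 100
    seed: int = 0
    force_gene_snps: bool = False
    quick_max_iter: int = 20  # EM cap while ranking candidates
    full_max_iter: int = 500  # confirmation refit after an accepted move

    def __post_init__(self) -> None:
        if self.gene_start >= self.gene_end:
            raise ValidationError("gene_start must be < gene_end")
        if self.window_step <= 0 or self.max_window <= 0:
            raise ValidationError("window sizes must be positive")
        if self.penalty_lambda < 0:
            raise ValidationError("penalty_lambda must be >= 0")

    @staticmethod
    def bic_lambda(n_samples: int) -> float:
        return float(np.log(n_samples) / 2.0)


@dataclass
class TraceEntry:
    action: str  # add | drop | widen | seed | warn | force-add
    detail: str
    obj_before: float
    obj_after: float


@dataclass
class SearchTrace:
    entries: list[TraceEntry] = field(default_factory=list)

    def log(self, action: str, detail: str, before: float, after: float) -> None:
        self.entries.append(TraceEntry(action, detail, before, after))

    def moves(self) -> list[TraceEntry]:
        return [e for e in self.entries if e.action in ("add", "drop")]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "action": e.action,
                    "detail": e.detail,
                    "obj_before": e.obj_before,
                    "obj_after": e.obj_after,
                }
                for e in self.entries
            ]
        )


def penalized_objective(
    model: HaplotypeModel,
    genotypes: GenotypeTable,
    truth: HlaTypingTable,
    penalty_lambda: float,
) -> float:
    """Conditional NLL plus ``lambda * (retained haplotypes - 1)``."""
    K = max(model.n_haplotypes - 1, 0)
    return conditional_nll(model, genotypes, truth) + penalty_lambda * K


def select_snps(
    candidates: GenotypeTable,
    truth: HlaTypingTable,
    locus: str,
    resolution: str,
    config: SearchConfig,
) -> tuple[HaplotypeModel, SearchTrace]:
    """Greedy forward-and-backward selection of predictive SNPs.

    Candidate ranking uses a warm-started, iteration-capped refit; an
    accepted move is re-confirmed with a full refit. Ties are broken by
    distance to the gene midpoint, then lexicographic snp_id.
    Deterministic given ``config.seed``.
    """
    trace = SearchTrace()
    rng = np.random.default_rng(config.seed)
    mid = 0.5 * (config.gene_start + config.gene_end)

    def tie_key(snp):
        return (abs(snp.position - mid), snp.snp_id)

    model, _ = fit_em(
        candidates, truth, locus, resolution, snp_ids=[],
        seed=int(rng.integers(2**31)),
    )
    obj = penalized_objective(model, candidates, truth, config.penalty_lambda)
    trace.log("seed", "HLA-only model", obj, obj)

    if candidates.n_snps == 0:
        trace.log("warn", "no candidate SNPs; returning HLA-only model", obj, obj)
        return model, trace

    if config.force_gene_snps:
        for snp in sorted(candidates.snps, key=tie_key):
            if config.gene_start <= snp.position <= config.gene_end:
                model, _ = extend_model(
                    model, snp, candidates, truth,
                    max_iter=config.full_max_iter, seed=int(rng.integers(2**31)),
                )
                new_obj = penalized_objective(
                    model, candidates, truth, config.penalty_lambda
                )
                trace.log("force-add", snp.snp_id, obj, new_obj)
                obj = new_obj

    window = 0
    while True:
        if model.n_snps >= config.max_snps:
            trace.log("warn", "max_snps reached", obj, obj)
            break
        lo = config.gene_start - window
        hi = config.gene_end + window
        in_window = [
            s
            for s in candidates.snps
            if lo <= s.position <= hi and s.snp_id not in model.snp_ids
        ]

        moved = False

        # forward step: best strictly-improving addition in the window
        best = None
        for snp in sorted(in_window, key=tie_key):
            quick, _ = extend_model(
                model, snp, candidates, truth,
                max_iter=config.quick_max_iter, seed=int(rng.integers(2**31)),
            )
            o = penalized_objective(quick, candidates, truth, config.penalty_lambda)
            if o < obj - _EPS and (best is None or o < best[0] - _EPS):
                best = (o, snp)
        if best is not None:
            snp = best[1]
            full, _ = extend_model(
                model, snp, candidates, truth,
                max_iter=config.full_max_iter, seed=int(rng.integers(2**31)),
            )
            o_full = penalized_objective(full, candidates, truth, config.penalty_lambda)
            if o_full < obj - _EPS:
                trace.log("add", snp.snp_id, obj, o_full)
                model, obj = full, o_full
                moved = True

        # backward step: best strictly-improving removal
        if not moved and model.n_snps > 0:
            best_drop = None
            for sid in sorted(
                model.snp_ids,
                key=lambda s: tie_key(model.snps[model.snp_ids.index(s)]),
            ):
                quick, _ = drop_snp(
                    model, sid, candidates, truth,
                    max_iter=config.quick_max_iter, seed=int(rng.integers(2**31)),
                )
                o = penalized_objective(quick, candidates, truth, config.penalty_lambda)
                if o < obj - _EPS and (best_drop is None or o < best_drop[0] - _EPS):
                    best_drop = (o, sid)
            if best_drop is not None:
                sid = best_drop[1]
                full, _ = drop_snp(
                    model, sid, candidates, truth,
                    max_iter=config.full_max_iter, seed=int(rng.integers(2**31)),
                )
                o_full = penalized_objective(
                    full, candidates, truth, config.penalty_lambda
                )
                if o_full < obj - _EPS:
                    trace.log("drop", sid, obj, o_full)
                    model, obj = full, o_full
                    moved = True

        if moved:
            continue
        if window < config.max_window:
            window = min(window + config.window_step, config.max_window)
            trace.log("widen", f"window={window}", obj, obj)
        else:
            break

    return model, trace
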