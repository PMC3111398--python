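"""Scripted re-enactments of the four evaluation designs on synthetic
cohorts.

The designs mirror the questions the method's empirical evaluation
asks: (1) do imputed SNPs help (*imputed-vs-observed*); (2) are models
transferable across genotyping platforms (*cross-platform*); (3) across
study populations (*cross-population*); and (4) should training sets
mix ethnic groups (*multi-ethnic*). Every design reports per-allele and
per-sample accuracy and call rate at the CT grid {0, 0.5, 0.9} in one
tidy table, reproducibly from (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calling import call_rate, predict_samples
from .evaluation import (
    ConcordanceInput,
    ConcordanceReport,
    accuracy,
    platform_concordance,
)
from .io import GenotypeTable, HlaTypingTable, ValidationError
from .model import HaplotypeModel
from .qc import QcThresholds, call_imputed
from .selection import SearchConfig, select_snps
from .simulate import CohortSpec, PopulationSpec, SimCohort, sample_cohort

CT_GRID = (0.0, 0.5, 0.9)

DESIGNS = ("imputed-vs-observed", "cross-platform", "cross-population", "multi-ethnic")

_RESULT_COLUMNS = [
    "design",
    "cell",
    "locus",
    "resolution",
    "ct",
    "n_evaluated",
    "n_called",
    "call_rate",
    "per_allele_accuracy",
    "per_sample_accuracy",
]


def split_train_validate(
    cohort: SimCohort, fraction: float = 0.5, seed: int = 0
) -> tuple[SimCohort, SimCohort]:
    """Disjoint, exhaustive, seeded split, stratified by population.

    The training side takes ``ceil(n * fraction)`` of each stratum, so
    an odd cohort splits e.g. 1001 -> (501, 500).
    """
    if cohort.n_samples < 2:
        raise ValidationError("cannot split a cohort with fewer than 2 samples")
    rng = np.random.default_rng(seed)
    labels = np.asarray(cohort.population_labels)
    ids = np.asarray(cohort.genotypes.sample_ids)
    train_ids: list[str] = []
    val_ids: list[str] = []
    for lab in sorted(set(labels)):
        stratum = ids[labels == lab]
        perm = rng.permutation(len(stratum))
        n_train = math.ceil(len(stratum) * fraction)
        train_ids.extend(stratum[perm[:n_train]])
        val_ids.extend(stratum[perm[n_train:]])
    return cohort.subset(train_ids), cohort.subset(val_ids)


# ---------------------------------------------------------------------------
# configs


def _default_search(pop: PopulationSpec, seed: int = 0, **kw) -> SearchConfig:
    span = pop.region_end - pop.region_start
    return SearchConfig(
        gene_start=pop.gene_start,
        gene_end=pop.gene_end,
        window_step=max(span // 8, 1),
        max_window=span,
        seed=seed,
        **kw,
    )


@dataclass
class ImputedVsObservedConfig:
    population: PopulationSpec = field(default_factory=lambda: PopulationSpec("pop"))
    n_samples: int = 400
    observed_fraction: float = 0.5  # fraction of SNPs "on the array"
    posterior_concentration: float = 50.0
    split_fraction: float = 0.5
    seed: int = 0
    ct_grid: tuple[float, ...] = CT_GRID
    resolutions: tuple[str, ...] = ("intermediate", "high")
    penalty_lambda: float = 1.0


@dataclass
class CrossPlatformConfig:
    population: PopulationSpec = field(default_factory=lambda: PopulationSpec("pop"))
    n_samples: int = 400
    panel_fraction_a: float = 0.6
    panel_fraction_b: float = 0.6
    posterior_concentration: float = 50.0
    split_fraction: float = 0.5
    seed: int = 0
    ct_grid: tuple[float, ...] = CT_GRID
    resolutions: tuple[str, ...] = ("high",)
    penalty_lambda: float = 1.0


@dataclass
class CrossPopulationConfig:
    population_a: PopulationSpec = field(default_factory=lambda: PopulationSpec("popA"))
    population_b: PopulationSpec = field(default_factory=lambda: PopulationSpec("popB"))
    n_each: int = 300
    split_fraction: float = 0.5
    seed: int = 0
    ct_grid: tuple[float, ...] = CT_GRID
    resolutions: tuple[str, ...] = ("high",)
    penalty_lambda: float = 1.0


@dataclass
class MultiEthnicConfig:
    majority: PopulationSpec = field(default_factory=lambda: PopulationSpec("major"))
    minority: PopulationSpec = field(default_factory=lambda: PopulationSpec("minor"))
    n_majority: int = 300
    n_minority: int = 300
    train_per_group: int = 150
    seed: int = 0
    ct_grid: tuple[float, ...] = CT_GRID
    resolutions: tuple[str, ...] = ("high",)
    penalty_lambda: float = 1.0


_CONFIG_TYPES = {
    "imputed-vs-observed": ImputedVsObservedConfig,
    "cross-platform": CrossPlatformConfig,
    "cross-population": CrossPopulationConfig,
    "multi-ethnic": MultiEthnicConfig,
}


# ---------------------------------------------------------------------------
# shared helpers


def _train(
    genotypes: GenotypeTable,
    truth: HlaTypingTable,
    locus: str,
    resolution: str,
    pop: PopulationSpec,
    penalty_lambda: float,
    seed: int,
) -> HaplotypeModel:
    cfg = _default_search(pop, seed=seed, penalty_lambda=penalty_lambda)
    model, _ = select_snps(genotypes, truth, locus, resolution, cfg)
    return model


def _eval_rows(
    design: str,
    cell: str,
    model: HaplotypeModel,
    val_genotypes: GenotypeTable,
    val_truth: HlaTypingTable,
    ct_grid,
) -> list[dict]:
    rows = []
    for ct in ct_grid:
        results = predict_samples(model, val_genotypes, ct=ct)
        rep = accuracy(results, val_truth, model.locus, model.resolution)
        rows.append(
            {
                "design": design,
                "cell": cell,
                "locus": model.locus,
                "resolution": model.resolution,
                "ct": ct,
                "n_evaluated": rep.n_evaluated,
                "n_called": rep.n_called,
                "call_rate": rep.call_rate,
                "per_allele_accuracy": rep.per_allele_accuracy,
                "per_sample_accuracy": rep.per_sample_accuracy,
            }
        )
    return rows


def _platform_view(
    cohort: SimCohort,
    panel_ids: list[str],
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[GenotypeTable, dict[str, str]]:
    """Observed genotypes on a platform's panel, plus hard-called
    imputed genotypes for the off-panel SNPs. Returns the merged table
    and per-SNP source tags."""
    observed = cohort.genotypes.subset_snps(panel_ids)
    off_panel = [s for s in cohort.genotypes.snp_ids if s not in set(panel_ids)]
    tags = {s: "observed" for s in panel_ids}
    if cohort.posteriors is None:
        raise ValidationError("platform views require posterior_mode cohorts")
    if off_panel:
        imputed_post = cohort.posteriors.subset_snps(off_panel)
        imputed, _ = call_imputed(imputed_post, thresholds)
        for s in imputed.snp_ids:
            tags[s] = "imputed"
        merged = observed.merge_snps(imputed)
    else:
        merged = observed
    return merged, tags


# ---------------------------------------------------------------------------
# designs


def run_design(design: str, config) -> pd.DataFrame:
    """Run one evaluation design; returns the tidy results table."""
    if design not in DESIGNS:
        raise ValidationError(f"unknown design {design!r}")
    expected = _CONFIG_TYPES[design]
    if not isinstance(config, expected):
        raise ValidationError(
            f"design {design!r} requires a {expected.__name__}, got "
            f"{type(config).__name__}"
        )
    runner = {
        "imputed-vs-observed": _run_imputed_vs_observed,
        "cross-platform": _run_cross_platform,
        "cross-population": _run_cross_population,
        "multi-ethnic": _run_multi_ethnic,
    }[design]
    rows = runner(config)
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def _run_imputed_vs_observed(cfg: ImputedVsObservedConfig) -> list[dict]:
    rng = np.random.default_rng(cfg.seed)
    cohort = sample_cohort(
        CohortSpec(
            populations=((cfg.population, cfg.n_samples),),
            seed=int(rng.integers(2**31)),
            posterior_mode=True,
            posterior_concentration=cfg.posterior_concentration,
        )
    )
    all_ids = cohort.genotypes.snp_ids
    n_obs = max(1, int(round(cfg.observed_fraction * len(all_ids))))
    panel = sorted(rng.choice(all_ids, size=n_obs, replace=False))
    train, val = split_train_validate(cohort, cfg.split_fraction, int(rng.integers(2**31)))

    arms: dict[str, tuple[GenotypeTable, GenotypeTable]] = {}
    arms["observed"] = (
        train.genotypes.subset_snps(panel),
        val.genotypes.subset_snps(panel),
    )
    with_imp_train, _ = _platform_view(train, panel)
    with_imp_val, _ = _platform_view(val, panel)
    common = [s for s in with_imp_train.snp_ids if s in set(with_imp_val.snp_ids)]
    arms["with-imputed"] = (
        with_imp_train.subset_snps(common),
        with_imp_val.subset_snps(common),
    )

    rows: list[dict] = []
    for arm, (gt_train, gt_val) in arms.items():
        for resolution in cfg.resolutions:
            model = _train(
                gt_train, train.hla, cohort.locus, resolution,
                cfg.population, cfg.penalty_lambda, int(rng.integers(2**31)),
            )
            rows += _eval_rows(
                "imputed-vs-observed", arm, model, gt_val, val.hla, cfg.ct_grid
            )
    return rows


def _run_cross_platform(cfg: CrossPlatformConfig) -> list[dict]:
    rng = np.random.default_rng(cfg.seed)
    cohort = sample_cohort(
        CohortSpec(
            populations=((cfg.population, cfg.n_samples),),
            seed=int(rng.integers(2**31)),
            posterior_mode=True,
            posterior_concentration=cfg.posterior_concentration,
        )
    )
    all_ids = cohort.genotypes.snp_ids
    panels = {}
    for name, frac in (("A", cfg.panel_fraction_a), ("B", cfg.panel_fraction_b)):
        n = max(1, int(round(frac * len(all_ids))))
        panels[name] = sorted(rng.choice(all_ids, size=n, replace=False))
    train, val = split_train_validate(cohort, cfg.split_fraction, int(rng.integers(2**31)))

    views = {}
    for name, panel in panels.items():
        gt_train, _ = _platform_view(train, panel)
        gt_val, _ = _platform_view(val, panel)
        common = [s for s in gt_train.snp_ids if s in set(gt_val.snp_ids)]
        views[name] = (gt_train.subset_snps(common), gt_val.subset_snps(common))

    rows: list[dict] = []
    for resolution in cfg.resolutions:
        models = {
            name: _train(
                gt_train, train.hla, cohort.locus, resolution,
                cfg.population, cfg.penalty_lambda, int(rng.integers(2**31)),
            )
            for name, (gt_train, _) in views.items()
        }
        for train_name, model in models.items():
            for val_name, (_, gt_val) in views.items():
                usable = [s for s in model.snp_ids if s in set(gt_val.snp_ids)]
                if len(usable) < model.n_snps:
                    # validation platform lacks some selected SNPs: mark
                    # them missing so the model marginalizes over them
                    gt_val = _pad_missing(gt_val, model, usable)
                rows += _eval_rows(
                    "cross-platform",
                    f"train={train_name},validate={val_name}",
                    model, gt_val, val.hla, cfg.ct_grid,
                )
    return rows


def _pad_missing(
    gt_val: GenotypeTable, model: HaplotypeModel, usable: list[str]
) -> GenotypeTable:
    import numpy as _np

    from .io import MISSING as _MISSING

    calls = _np.full((gt_val.n_samples, model.n_snps), _MISSING, dtype=_np.int8)
    for j, sid in enumerate(model.snp_ids):
        if sid in usable:
            calls[:, j] = gt_val.column(sid)
    return GenotypeTable(model.snps, gt_val.sample_ids, calls)


def cross_platform_concordance(
    cohort: SimCohort,
    panel_a: list[str],
    panel_b: list[str],
    thresholds: QcThresholds = QcThresholds(),
) -> ConcordanceReport:
    """Observed/imputed concordance classes between two platform views
    of the same cohort."""
    va, tags_a = _platform_view(cohort, panel_a, thresholds)
    vb, tags_b = _platform_view(cohort, panel_b, thresholds)
    shared = [s for s in va.snp_ids if s in set(vb.snp_ids)]
    ci = ConcordanceInput(
        table_a=va.subset_snps(shared),
        table_b=vb.subset_snps(shared),
        tags_a={s: tags_a[s] for s in shared},
        tags_b={s: tags_b[s] for s in shared},
    )
    return platform_concordance(ci)


def _run_cross_population(cfg: CrossPopulationConfig) -> list[dict]:
    rng = np.random.default_rng(cfg.seed)
    cohort_a = sample_cohort(
        CohortSpec(populations=((cfg.population_a, cfg.n_each),), seed=int(rng.integers(2**31)))
    )
    cohort_b = sample_cohort(
        CohortSpec(populations=((cfg.population_b, cfg.n_each),), seed=int(rng.integers(2**31)))
    )
    train_a, hold_a = split_train_validate(cohort_a, cfg.split_fraction, int(rng.integers(2**31)))
    rows: list[dict] = []
    for resolution in cfg.resolutions:
        model = _train(
            train_a.genotypes, train_a.hla, cohort_a.locus, resolution,
            cfg.population_a, cfg.penalty_lambda, int(rng.integers(2**31)),
        )
        rows += _eval_rows(
            "cross-population", "within-population", model,
            hold_a.genotypes, hold_a.hla, cfg.ct_grid,
        )
        rows += _eval_rows(
            "cross-population", "transfer", model,
            cohort_b.genotypes, cohort_b.hla, cfg.ct_grid,
        )
    return rows


def _run_multi_ethnic(cfg: MultiEthnicConfig) -> list[dict]:
    rng = np.random.default_rng(cfg.seed)
    cohort = sample_cohort(
        CohortSpec(
            populations=((cfg.majority, cfg.n_majority), (cfg.minority, cfg.n_minority)),
            seed=int(rng.integers(2**31)),
        )
    )
    ids = np.asarray(cohort.genotypes.sample_ids)
    labels = np.asarray(cohort.population_labels)
    maj_ids = ids[labels == cfg.majority.name]
    min_ids = ids[labels == cfg.minority.name]
    maj_perm = rng.permutation(len(maj_ids))
    min_perm = rng.permutation(len(min_ids))
    k = cfg.train_per_group
    mixed_train = list(maj_ids[maj_perm[:k]]) + list(min_ids[min_perm[:k]])
    majority_train = list(maj_ids[maj_perm[: 2 * k]])
    val_min = list(min_ids[min_perm[k:]])
    val_maj = list(maj_ids[maj_perm[2 * k :]])

    rows: list[dict] = []
    for resolution in cfg.resolutions:
        models = {}
        for name, train_ids in (("multi-ethnic", mixed_train), ("majority-only", majority_train)):
            sub = cohort.subset(train_ids)
            models[name] = _train(
                sub.genotypes, sub.hla, cohort.locus, resolution,
                cfg.majority, cfg.penalty_lambda, int(rng.integers(2**31)),
            )
        for name, model in models.items():
            for val_name, val_ids in (("minority", val_min), ("majority", val_maj)):
                if not val_ids:
                    continue
                sub = cohort.subset(val_ids)
                rows += _eval_rows(
                    "multi-ethnic",
                    f"model={name},validate={val_name}",
                    model, sub.genotypes, sub.hla, cfg.ct_grid,
                )
    return rows
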