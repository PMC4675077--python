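"""Seeded synthetic two-channel cohorts for IBS-vs-health classification.

The generator emulates a balanced case/control study (default 22 IBS-D +
22 healthy stool samples) with two measurement channels: 115 microbial
genus relative abundances (compositional, rows closed to sum 1) and 19
quantified metabolite concentrations (strictly positive, no closure).

Generative model per feature f and sample s:

    value[s, f] = exp(mu_f + d_f * log(FC) * [s in IBS and f is a driver]
                       + eps_{s,f}),  eps ~ Normal(0, noise_sigma)

where the per-feature baselines mu_f are drawn once per cohort from
Normal(0, baseline_logmean_spread), a small set of disjoint "driver"
features carries a group fold change FC with a random per-driver sign
d_f (+1 elevated in IBS, -1 depressed), and the noise is multiplicative
log-normal.  Genus rows are then closed to sum 1, which distorts the
realized genus fold changes (the metabolite channel is closure-free and
recovers FC up to the log-normal mean correction).

The random stream is ordered (baselines, drivers, samples) so that
``inject_unknown_samples`` can reproduce the cohort's baselines and
driver identities from the seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import FeatureTable, SampleMeta

# offset for the unknown-sample noise stream, independent of training draws
_UNKNOWN_STREAM = 104729


@dataclass
class CohortConfig:
    n_per_group: int = 22
    n_genera: int = 115
    n_metabolites: int = 19
    n_driver_genera: int = 3
    n_driver_metabolites: int = 3
    driver_fold_change: float = 3.0
    noise_sigma: float = 0.6
    baseline_logmean_spread: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be positive")
        if self.n_genera < 1 or self.n_metabolites < 1:
            raise ValueError("feature counts must be positive")
        if not (0 <= self.n_driver_genera <= self.n_genera):
            raise ValueError("n_driver_genera must be in [0, n_genera]")
        if not (0 <= self.n_driver_metabolites <= self.n_metabolites):
            raise ValueError("n_driver_metabolites must be in [0, n_metabolites]")
        if self.driver_fold_change <= 0:
            raise ValueError("driver_fold_change must be > 0")
        if self.noise_sigma <= 0 or self.baseline_logmean_spread <= 0:
            raise ValueError("noise_sigma and baseline_logmean_spread must be > 0")


@dataclass
class CohortTruth:
    """Ground-truth driver identities for parameter-recovery tests."""

    driver_feature_ids: list[str]
    driver_direction: list[int]  # +1 elevated in IBS, -1 depressed
    realized_fold_changes: list[float] = field(default_factory=list)

    def drivers_of(self, prefix: str) -> list[str]:
        return [f for f in self.driver_feature_ids if f.startswith(prefix)]


def _feature_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1:03d}" for i in range(n)]


def _sample_ids(n_per_group: int) -> tuple[list[str], list[str]]:
    ids = [f"IBS{i + 1:02d}" for i in range(n_per_group)]
    ids += [f"HLT{i + 1:02d}" for i in range(n_per_group)]
    groups = ["IBS"] * n_per_group + ["HLT"] * n_per_group
    return ids, groups


def _draw_structure(config: CohortConfig, rng: np.random.Generator):
    """Baselines then driver identities/directions, in a fixed stream order."""
    mu_g = rng.normal(0.0, config.baseline_logmean_spread, config.n_genera)
    mu_m = rng.normal(0.0, config.baseline_logmean_spread, config.n_metabolites)
    drv_g = np.sort(rng.choice(config.n_genera, config.n_driver_genera, replace=False))
    drv_m = np.sort(
        rng.choice(config.n_metabolites, config.n_driver_metabolites, replace=False)
    )
    dir_g = rng.choice([1, -1], config.n_driver_genera)
    dir_m = rng.choice([1, -1], config.n_driver_metabolites)
    return mu_g, mu_m, drv_g, drv_m, dir_g, dir_m


def _group_effect(n_features, drivers, directions, fold) -> np.ndarray:
    eff = np.zeros(n_features)
    eff[drivers] = directions * np.log(fold)
    return eff


def _draw_channel(rng, mu, effect, is_ibs, sigma) -> np.ndarray:
    n = len(is_ibs)
    noise = rng.normal(0.0, sigma, (n, len(mu)))
    logv = mu[None, :] + np.outer(is_ibs.astype(float), effect) + noise
    return np.exp(logv)


def _truth(config, drv_g, drv_m, dir_g, dir_m) -> CohortTruth:
    gids = _feature_ids("genus_", config.n_genera)
    mids = _feature_ids("metab_", config.n_metabolites)
    ids = [gids[i] for i in drv_g] + [mids[i] for i in drv_m]
    dirs = [int(d) for d in dir_g] + [int(d) for d in dir_m]
    folds = [config.driver_fold_change ** d for d in dirs]
    return CohortTruth(ids, dirs, folds)


def generate_cohort(
    config: CohortConfig,
) -> tuple[FeatureTable, FeatureTable, SampleMeta, CohortTruth]:
    """Generate one seeded cohort: genus table, metabolite table, metadata, truth."""
    rng = np.random.default_rng(config.seed)
    mu_g, mu_m, drv_g, drv_m, dir_g, dir_m = _draw_structure(config, rng)
    sample_ids, groups = _sample_ids(config.n_per_group)
    is_ibs = np.array([g == "IBS" for g in groups])

    eff_g = _group_effect(config.n_genera, drv_g, dir_g, config.driver_fold_change)
    eff_m = _group_effect(config.n_metabolites, drv_m, dir_m, config.driver_fold_change)
    genus = _draw_channel(rng, mu_g, eff_g, is_ibs, config.noise_sigma)
    metab = _draw_channel(rng, mu_m, eff_m, is_ibs, config.noise_sigma)
    genus /= genus.sum(axis=1, keepdims=True)  # compositional closure, genera only

    genus_t = FeatureTable(sample_ids, _feature_ids("genus_", config.n_genera),
                           "genus", genus)
    metab_t = FeatureTable(sample_ids, _feature_ids("metab_", config.n_metabolites),
                           "metabolite", metab)
    meta = SampleMeta(sample_ids, groups)
    return genus_t, metab_t, meta, _truth(config, drv_g, drv_m, dir_g, dir_m)


def inject_unknown_samples(
    config: CohortConfig, n_new: int, group: str
) -> tuple[FeatureTable, FeatureTable, CohortTruth]:
    """Draw unlabeled samples from one group's generative distribution.

    Baselines and driver identities are reproduced from the cohort seed;
    the new samples' noise comes from a derived stream so they are
    deterministic and independent of the training cohort's draws.
    """
    if group not in ("IBS", "HLT"):
        raise ValueError(f"group must be IBS or HLT, got {group!r}")
    if n_new < 0:
        raise ValueError("n_new must be >= 0")
    rng = np.random.default_rng(config.seed)
    mu_g, mu_m, drv_g, drv_m, dir_g, dir_m = _draw_structure(config, rng)
    rng_new = np.random.default_rng([config.seed, _UNKNOWN_STREAM])

    is_ibs = np.full(n_new, group == "IBS")
    eff_g = _group_effect(config.n_genera, drv_g, dir_g, config.driver_fold_change)
    eff_m = _group_effect(config.n_metabolites, drv_m, dir_m, config.driver_fold_change)
    genus = _draw_channel(rng_new, mu_g, eff_g, is_ibs, config.noise_sigma)
    metab = _draw_channel(rng_new, mu_m, eff_m, is_ibs, config.noise_sigma)
    if n_new:
        genus /= genus.sum(axis=1, keepdims=True)

    new_ids = [f"NEW{i + 1:02d}" for i in range(n_new)]
    genus_t = FeatureTable(new_ids, _feature_ids("genus_", config.n_genera),
                           "genus", genus)
    metab_t = FeatureTable(new_ids, _feature_ids("metab_", config.n_metabolites),
                           "metabolite", metab)
    return genus_t, metab_t, _truth(config, drv_g, drv_m, dir_g, dir_m)
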