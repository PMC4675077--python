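"""Patient discrimination index (PDI).

The PDI condenses the two fitted channel models into a single per-sample
score: take the top-k discriminating genera and an equal number of
discriminating metabolites (ranked by their PLS weights), and sum the
signed log2 ratios of each variable to its median over ALL training
samples (both groups pooled):

    PDI(x) = sum_i  d_i * log2((x_i + eps_i) / (median_i + eps_i))

with d_i = +1 for variables elevated in IBS and -1 for depressed ones,
so that PDI > 0 marks an IBS-like sample and PDI < 0 a healthy-like one.
eps_i protects against exact zeros in relative abundances: when a
training variable contains zeros, eps_i is half its smallest positive
training value, otherwise 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .io import FeatureTable
from .plsda import PLSDAClassifier, rank_discriminators


@dataclass
class PDIEntry:
    feature_id: str
    channel: str  # genus | metabolite
    direction: int  # +1 elevated in IBS, -1 depressed
    training_median: float
    epsilon: float

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.training_median + self.epsilon <= 0:
            raise ValueError(
                f"{self.feature_id}: median+epsilon must be positive"
            )


@dataclass
class PDIModel:
    entries: list[PDIEntry]
    k: int  # entries per channel

    def __post_init__(self) -> None:
        per_channel = {"genus": 0, "metabolite": 0}
        for e in self.entries:
            per_channel[e.channel] += 1
        if per_channel["genus"] != per_channel["metabolite"]:
            raise ValueError("PDI needs equal numbers of genus and metabolite entries")
        if per_channel["genus"] != self.k:
            raise ValueError(f"expected {self.k} entries per channel")


def _median_and_epsilon(values: np.ndarray) -> tuple[float, float]:
    med = float(np.median(values))
    positive = values[values > 0]
    if np.any(values == 0):
        if positive.size == 0:
            raise ValueError("variable is identically zero in the training cohort")
        eps = 0.5 * float(positive.min())
    else:
        eps = 0.0
    return med, eps


def build_pdi(
    genus_model: PLSDAClassifier,
    metab_model: PLSDAClassifier,
    genus: FeatureTable,
    metab: FeatureTable,
    k: int = 3,
) -> PDIModel:
    """Select top-k variables per channel and freeze their training medians."""
    if k < 1:
        raise ValueError("k must be >= 1")
    entries = []
    for model, table in ((genus_model, genus), (metab_model, metab)):
        for fid, direction in rank_discriminators(model, k):
            col = table.values[:, table.feature_ids.index(fid)]
            med, eps = _median_and_epsilon(col)
            entries.append(PDIEntry(fid, table.kind, direction, med, eps))
    return PDIModel(entries, k)


def compute_pdi(sample_values: Mapping[str, float], model: PDIModel) -> float:
    """PDI of a single sample given a feature_id -> value mapping."""
    total = 0.0
    for e in model.entries:
        if e.feature_id not in sample_values:
            raise KeyError(f"sample is missing selected feature {e.feature_id!r}")
        x = float(sample_values[e.feature_id])
        total += e.direction * np.log2((x + e.epsilon) / (e.training_median + e.epsilon))
    return float(total)


def pdi_cohort(
    genus: FeatureTable, metab: FeatureTable, model: PDIModel
) -> np.ndarray:
    """PDI values for every sample of a two-channel cohort, in sample order."""
    if genus.sample_ids != metab.sample_ids:
        raise ValueError("genus and metabolite tables list different samples")
    gf = genus.to_frame()
    mf = metab.to_frame()
    out = np.empty(genus.n_samples)
    for i, sid in enumerate(genus.sample_ids):
        values = {**gf.loc[sid].to_dict(), **mf.loc[sid].to_dict()}
        out[i] = compute_pdi(values, model)
    return out
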