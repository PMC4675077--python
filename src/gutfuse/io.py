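"""Reading, writing, validating and aligning sample-by-feature tables.

Tables are TSV (UTF-8, '.' decimal), samples as rows and features as
columns; the first header cell names the sample-id column.  Genus tables
hold relative abundances (unitless fractions, optionally compositional);
metabolite tables hold concentrations in arbitrary positive units.
Missing values are not permitted: an empty or non-numeric cell is a parse
error, never silently imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("IBS", "HLT")
KINDS = ("genus", "metabolite")

COMPOSITIONAL_TOL = 1e-6


class TableParseError(ValueError):
    """A cell of an on-disk table could not be parsed as a number."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class FeatureTable:
    """Samples x features matrix of non-negative finite values.

    Parameters
    ----------
    sample_ids, feature_ids : ordered unique identifiers.
    kind : ``"genus"`` or ``"metabolite"``, applied to every feature.
    values : array of shape (n_samples, n_features).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    kind: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("table contains non-finite values")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    def validate(self, compositional: bool = False) -> None:
        """Re-run construction checks; optionally require rows to sum to 1."""
        self.__post_init__()
        if compositional:
            sums = self.values.sum(axis=1)
            bad = np.abs(sums - 1.0) > COMPOSITIONAL_TOL
            if bad.any():
                i = int(np.argmax(bad))
                raise ValueError(
                    f"sample {self.sample_ids[i]!r} is not compositional: "
                    f"row sums to {sums[i]!r}"
                )

    def subset_samples(self, sample_ids: list[str]) -> "FeatureTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        idx = [pos[s] for s in sample_ids]
        return FeatureTable(list(sample_ids), list(self.feature_ids), self.kind,
                            self.values[idx])


@dataclass
class SampleMeta:
    """Per-sample group labels, restricted to the two-level {IBS, HLT} set."""

    sample_ids: list[str]
    group: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.group = [str(g) for g in self.group]
        _check_unique(self.sample_ids, "sample")
        if len(self.group) != len(self.sample_ids):
            raise ValueError("group length does not match sample_ids")
        bad = sorted(set(self.group) - set(GROUPS))
        if bad:
            raise ValueError(f"unknown group labels {bad}; allowed: {GROUPS}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def group_of(self, sample_id: str) -> str:
        return self.group[self.sample_ids.index(sample_id)]

    def subset_samples(self, sample_ids: list[str]) -> "SampleMeta":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return SampleMeta(list(sample_ids), [self.group[pos[s]] for s in sample_ids])


def _parse_numeric_body(raw: pd.DataFrame, path) -> np.ndarray:
    values = np.empty(raw.shape, dtype=float)
    # cell-wise float() parsing: exact round trips and errors that name
    # the offending row/column (pd.to_numeric can be 1 ulp off)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            try:
                if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                    raise ValueError("empty cell")
                values[i, j] = float(cell)
            except (TypeError, ValueError) as exc:
                raise TableParseError(
                    f"{path}: cannot parse cell at sample {raw.index[i]!r}, "
                    f"feature {col!r}: {cell!r}"
                ) from exc
    return values


def read_feature_table(path, kind: str) -> FeatureTable:
    """Read a TSV feature table (first row = features, first column = samples)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = _parse_numeric_body(raw, path)
    return FeatureTable(
        [str(s) for s in raw.index], [str(c) for c in raw.columns], kind, values
    )


def write_feature_table(table: FeatureTable, path) -> None:
    # repr keeps every float exactly round-trippable
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["sample_id"] + list(table.feature_ids)) + "\n")
        for sid, row in zip(table.sample_ids, table.values):
            fh.write("\t".join([sid] + [repr(float(x)) for x in row]) + "\n")


def read_sample_meta(path) -> SampleMeta:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(df.columns):
        raise TableParseError(f"{path}: metadata needs columns {sorted(required)}")
    return SampleMeta(list(df["sample_id"]), list(df["group"]))


def write_sample_meta(meta: SampleMeta, path) -> None:
    pd.DataFrame({"sample_id": meta.sample_ids, "group": meta.group}).to_csv(
        path, sep="\t", index=False
    )


def align_tables(
    genus: FeatureTable, metab: FeatureTable, meta: SampleMeta
) -> tuple[FeatureTable, FeatureTable, SampleMeta]:
    """Restrict all three inputs to their common samples, in one canonical order.

    The canonical order is the metadata order filtered to the intersection,
    which makes the operation idempotent.
    """
    common = set(genus.sample_ids) & set(metab.sample_ids) & set(meta.sample_ids)
    if not common:
        raise ValueError("no samples shared between the genus, metabolite "
                         "and metadata inputs")
    order = [s for s in meta.sample_ids if s in common]
    return (genus.subset_samples(order), metab.subset_samples(order),
            meta.subset_samples(order))
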