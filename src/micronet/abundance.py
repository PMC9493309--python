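"""ASV count tables: parsing, prevalence filtering, and pre-correlation transforms.

The central container is :class:`AbundanceTable` — an integer taxa x samples
count matrix with a sample -> group map, mirroring the filtered ASV tables
that amplicon workflows (QIIME2/DADA2 style) produce. Filtering follows the
common "prevalence with a count floor" rule: a sample *contains* a taxon when
its count reaches ``min_count``, and a taxon is retained when it is contained
in at least ``min_prevalence`` of the samples.

Two sklearn-compatible transformers (:class:`PrevalenceFilter`,
:class:`RelativeAbundance`) expose the same operations on samples x taxa
matrices so they compose with sklearn pipelines; the functional API below
works directly on :class:`AbundanceTable`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


class TableFormatError(ValueError):
    """Raised when a count table or group map violates the expected format."""


@dataclass
class AbundanceTable:
    """Integer count matrix (taxa x samples) with a sample -> group map.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts; index = taxon ids, columns = sample ids.
    groups : pandas.Series
        Group label per sample id; must cover every column of ``counts``.
    """

    counts: pd.DataFrame
    groups: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.groups is None:
            self.groups = pd.Series("all", index=self.counts.columns, name="group")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise TableFormatError(f"duplicate taxon id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise TableFormatError(f"duplicate sample id: {dup!r}")
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise TableFormatError(f"sample {missing[0]!r} missing from group map")
        vals = self.counts.to_numpy()
        if vals.size and (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise TableFormatError(
                f"negative count at taxon {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )
        self.groups = self.groups.loc[self.counts.columns]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def subset_group(self, group: str) -> "AbundanceTable":
        """Table restricted to the samples of one group."""
        samples = [s for s in self.counts.columns if self.groups[s] == group]
        if not samples:
            raise KeyError(f"no samples in group {group!r}")
        return AbundanceTable(self.counts[samples].copy(), self.groups[samples].copy())

    def write(self, path, group_map_path=None) -> None:
        """Write the canonical TSV (first column ``taxon``, header = sample ids)."""
        out = self.counts.copy()
        out.index.name = "taxon"
        out.to_csv(path, sep="\t")
        if group_map_path is not None:
            gm = self.groups.rename("group").rename_axis("sample")
            gm.to_csv(group_map_path, sep="\t")


def read_table(path, group_map_path=None) -> AbundanceTable:
    """Parse a TSV count table (and optional group map) into an AbundanceTable.

    Every cell must be a non-negative integer; the first offending cell is
    named by taxon and sample id in the error message.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.shape[0] == 0:
        raise TableFormatError("no taxa in table")
    if raw.shape[1] == 0:
        raise TableFormatError("no samples in table")
    counts = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns.astype(str))
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw.iloc[:, j], errors="coerce")
        bad = converted.isna() | (converted != np.floor(converted.fillna(0)))
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise TableFormatError(
                f"non-integer count {raw.iloc[i, j]!r} at taxon "
                f"{raw.index[i]!r}, sample {col!r}"
            )
        counts.iloc[:, j] = converted.astype(np.int64)
    counts = counts.astype(np.int64)
    groups = None
    if group_map_path is not None:
        gm = pd.read_csv(group_map_path, sep="\t", index_col=0, dtype=str)
        if gm.shape[1] < 1:
            raise TableFormatError("group map needs two columns (sample, group)")
        groups = gm.iloc[:, 0]
        groups.index = groups.index.astype(str)
    return AbundanceTable(counts, groups)


def prevalence_filter(
    table: AbundanceTable, min_prevalence: float = 0.20, min_count: int = 4
) -> AbundanceTable:
    """Retain taxa contained (count >= ``min_count``) in >= ``min_prevalence`` of samples.

    The prevalence cutoff uses a ceiling, so "at least 20%" of 5 samples means
    >= 1 sample. The sample set is unchanged; retained rows keep their counts.
    """
    if not (0 < min_prevalence <= 1):
        raise ValueError("min_prevalence must be in (0, 1]")
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    need = math.ceil(min_prevalence * table.n_samples)
    present = (table.counts.to_numpy() >= min_count).sum(axis=1)
    keep = present >= need
    if not keep.any():
        warnings.warn("prevalence filter removed all taxa", stacklevel=2)
    return AbundanceTable(table.counts.loc[keep].copy(), table.groups.copy())


def transform_for_correlation(
    table: AbundanceTable, method: str = "log_relative", pseudocount: float = 1e-6
) -> pd.DataFrame:
    """Transform counts into the real matrix fed to the correlation step.

    ``log_relative`` -> ln(count/column_sum + pseudocount); ``relative`` ->
    count/column_sum; ``none`` -> counts as floats. Shape is preserved.
    """
    if table.n_taxa == 0:
        raise TableFormatError("empty table")
    if method == "none":
        return table.counts.astype(float)
    depth = table.counts.sum(axis=0)
    zero = depth[depth == 0]
    if len(zero):
        raise TableFormatError(f"sample {zero.index[0]!r} has zero total count")
    rel = table.counts / depth
    if method == "relative":
        return rel
    if method == "log_relative":
        return np.log(rel + pseudocount)
    raise ValueError(f"unknown transform {method!r}")


class PrevalenceFilter(TransformerMixin, BaseEstimator):
    """sklearn transformer applying the prevalence/count-floor retention rule.

    Operates on samples x taxa matrices (sklearn orientation). ``fit`` learns
    the retained-column mask ``support_``; ``transform`` subsets columns.
    """

    def __init__(self, min_prevalence: float = 0.20, min_count: int = 4):
        self.min_prevalence = min_prevalence
        self.min_count = min_count

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x taxa)")
        if not (0 < self.min_prevalence <= 1):
            raise ValueError("min_prevalence must be in (0, 1]")
        need = math.ceil(self.min_prevalence * X.shape[0])
        self.support_ = (X >= self.min_count).sum(axis=0) >= need
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch with fit")
        return X[:, self.support_]


class RelativeAbundance(TransformerMixin, BaseEstimator):
    """Stateless closure to relative (or log-relative) abundances per sample row."""

    def __init__(self, method: str = "log_relative", pseudocount: float = 1e-6):
        self.method = method
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if self.method == "none":
            return X
        depth = X.sum(axis=1, keepdims=True)
        if (depth == 0).any():
            raise ValueError(f"sample row {int(np.argmax(depth == 0))} has zero total count")
        rel = X / depth
        if self.method == "relative":
            return rel
        if self.method == "log_relative":
            return np.log(rel + self.pseudocount)
        raise ValueError(f"unknown transform {self.method!r}")
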