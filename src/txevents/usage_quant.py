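"""Relative-usage phenotypes from event-level abundance estimates.

Event expression (TPM) is imported from per-sample quantifier tables
and converted to relative usage: each event's TPM divided by the summed
TPM of all events of the same type within the same transcript group of
the same gene.  Usage is a proportion in [0, 1]; a block whose total
TPM is zero in a sample is undefined (NaN) there.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AbundanceMatrix",
    "UsageMatrix",
    "ABUNDANCE_COLUMNS",
    "import_abundance",
    "read_event_metadata",
    "relative_usage",
    "filter_expressed",
    "inverse_normal_transform",
]

ABUNDANCE_COLUMNS = ["Name", "Length", "EffectiveLength", "TPM", "NumReads"]

#: columns identifying a normalisation block
BLOCK_KEYS = ["gene_id", "group_index", "event_type"]


@dataclass
class AbundanceMatrix:
    """Event-level TPM matrix (features x samples) plus feature metadata.

    ``feature_meta`` is indexed by feature id and carries ``gene_id``,
    ``group_index`` and ``event_type`` for every feature.
    """

    tpm: pd.DataFrame
    feature_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.tpm.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.tpm.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("negative TPM values")
        missing = self.tpm.index.difference(self.feature_meta.index)
        if len(missing):
            raise ValueError(
                f"features absent from metadata: {sorted(missing)[:10]}"
            )
        for col in BLOCK_KEYS:
            if col not in self.feature_meta.columns:
                raise ValueError(f"feature metadata lacks column {col!r}")
        self.feature_meta = self.feature_meta.loc[self.tpm.index]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tpm.columns)


@dataclass
class UsageMatrix:
    """Relative usage, same shape as the abundance it came from.

    Within every (gene, group, event type) block and sample the defined
    values sum to one; a block-sample is NaN iff its TPM total is zero.
    """

    usage: pd.DataFrame
    feature_meta: pd.DataFrame

    @property
    def feature_ids(self) -> list[str]:
        return list(self.usage.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.usage.columns)


def read_event_metadata(path: str | Path) -> pd.DataFrame:
    """Read the tab-separated event metadata table written by the builder."""
    meta = pd.read_csv(path, sep="\t", dtype={"group_index": int})
    return meta.set_index("event_id")


def import_abundance(
    files: dict[str, str | Path], meta: pd.DataFrame
) -> AbundanceMatrix:
    """Assemble per-sample quantifier tables into one TPM matrix.

    ``files`` maps sample id to a tab-separated table with columns
    ``Name Length EffectiveLength TPM NumReads``.  All samples must
    quantify the identical feature set, and every feature must appear in
    ``meta`` (indexed by feature id).
    """
    if not files:
        raise ValueError("no abundance files given")
    columns: dict[str, pd.Series] = {}
    reference: pd.Index | None = None
    ref_sample = None
    for sample_id, path in files.items():
        tab = pd.read_csv(path, sep="\t")
        missing_cols = [c for c in ABUNDANCE_COLUMNS if c not in tab.columns]
        if missing_cols:
            raise ValueError(f"{path}: missing columns {missing_cols}")
        tab = tab.set_index("Name")
        if reference is None:
            reference = tab.index
            ref_sample = sample_id
        elif not reference.equals(tab.index):
            diff = reference.symmetric_difference(tab.index)
            raise ValueError(
                f"inconsistent feature sets between samples {ref_sample!r} and "
                f"{sample_id!r}; symmetric difference: {sorted(diff)}"
            )
        columns[sample_id] = tab["TPM"].astype(float)
    tpm = pd.DataFrame(columns)
    unknown = tpm.index.difference(meta.index)
    if len(unknown):
        raise ValueError(f"features absent from metadata: {sorted(unknown)}")
    return AbundanceMatrix(tpm=tpm, feature_meta=meta.loc[tpm.index].copy())


def relative_usage(a: AbundanceMatrix) -> UsageMatrix:
    """TPM divided by the block (gene, group, event type) sum, per sample.

    Zero-total blocks are undefined (NaN) for that sample.  The result
    is invariant to rescaling a sample's block TPMs by any positive
    constant.
    """
    keys = a.feature_meta[BLOCK_KEYS]
    block_sums = a.tpm.groupby(
        [keys[c] for c in BLOCK_KEYS], sort=False
    ).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        usage = a.tpm / block_sums
    usage = usage.where(block_sums > 0)
    return UsageMatrix(usage=usage, feature_meta=a.feature_meta.copy())


def filter_expressed(
    a: AbundanceMatrix,
    condition_of: dict[str, str],
    threshold: float = 1.0,
) -> set[str]:
    """Genes whose mean TPM exceeds ``threshold`` in at least one condition.

    Gene-level TPM is approximated from one event-type block per gene
    (the ``contained`` block when present, else the first available
    block in upstream/contained/downstream order): the block's event
    TPMs are summed per sample and averaged within each condition; the
    gene is retained iff the maximum of those means is strictly greater
    than the threshold.
    """
    missing = [s for s in a.sample_ids if s not in condition_of]
    if missing:
        raise ValueError(f"samples without condition assignment: {missing}")
    conditions = pd.Series({s: condition_of[s] for s in a.sample_ids})
    counts = conditions.value_counts()
    if (counts == 0).any() or len(counts) == 0:
        raise ValueError("empty condition")

    meta = a.feature_meta
    retained: set[str] = set()
    for gene_id, gmeta in meta.groupby("gene_id", sort=False):
        blocks = gmeta.groupby(["group_index", "event_type"], sort=False).groups
        order = ("contained", "upstream", "downstream")
        chosen = min(
            blocks.items(),
            key=lambda kv: (kv[0][1] != "contained", kv[0][0], order.index(kv[0][1])),
        )[1]
        gene_tpm = a.tpm.loc[chosen].sum(axis=0)
        cond_means = gene_tpm.groupby(conditions).mean()
        if cond_means.max() > threshold:
            retained.add(gene_id)
    return retained


def inverse_normal_transform(u: UsageMatrix) -> UsageMatrix:
    """Rank-based mapping of each feature to standard-normal quantiles.

    Ranks (ties averaged) are mapped through ``Phi^{-1}(r / (n + 1))``
    per feature across its defined samples, giving a mean-zero, rank-
    preserving phenotype.  Features constant across samples (or defined
    in fewer than three) are marked undefined and excluded downstream.
    """
    values = u.usage.to_numpy(dtype=float)
    out = np.full_like(values, np.nan)
    for i in range(values.shape[0]):
        row = values[i]
        ok = np.isfinite(row)
        if ok.sum() < 3:
            continue
        x = row[ok]
        if np.allclose(x, x[0]):
            continue  # constant feature: flagged undefined
        ranks = stats.rankdata(x, method="average")
        out[i, ok] = stats.norm.ppf(ranks / (x.size + 1))
    transformed = pd.DataFrame(out, index=u.usage.index, columns=u.usage.columns)
    return UsageMatrix(usage=transformed, feature_meta=u.feature_meta.copy())
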