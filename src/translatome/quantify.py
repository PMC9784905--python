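"""Count-to-TPM conversion, replicate aggregation, and the expressed universe.

TPM (transcripts per million) is the length-normalized relative abundance:
for each sample, ``rate_g = count_g / length_g`` and
``tpm_g = 1e6 * rate_g / sum_h rate_h``, so every non-degenerate column sums
to one million. Replicates are aggregated as the arithmetic mean of their
per-replicate TPM columns (not TPM of pooled counts), keeping replicates
exchangeable. The expressed-gene universe — the background N of every
hypergeometric test downstream — is the set of genes whose mean TPM reaches
a threshold in at least one supplied condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, GeneLengthTable, SampleSheet, ValidationError

logger = logging.getLogger("translatome")


@dataclass(frozen=True)
class TPMMatrix:
    """Gene x sample TPM values; columns ordered as the sample sheet."""

    tpm: pd.DataFrame
    samples: SampleSheet

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tpm.index)

    def to_frame(self) -> pd.DataFrame:
        out = self.tpm.sort_index()
        out.insert(0, "gene_id", out.index)
        return out.reset_index(drop=True)


@dataclass(frozen=True)
class ConditionTPM:
    """Mean TPM over the replicates of one (cell_type, assay) condition."""

    cell_type: str
    assay: str
    mean_tpm: pd.Series

    @property
    def label(self) -> str:
        return f"{self.cell_type}:{self.assay}"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.mean_tpm.index)

    def to_frame(self) -> pd.DataFrame:
        out = self.mean_tpm.sort_index().rename("mean_tpm").reset_index()
        out.columns = ["gene_id", "mean_tpm"]
        out.insert(1, "condition", self.label)
        return out


@dataclass(frozen=True)
class GeneUniverse:
    """Expressed-gene background for overlap and enrichment tests."""

    genes: tuple[str, ...]
    min_mean_tpm: float
    conditions: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": sorted(self.genes)})


def compute_tpm(counts: CountMatrix, lengths: GeneLengthTable) -> TPMMatrix:
    """Convert integer counts to TPM using per-gene effective lengths.

    An all-zero library yields an all-zero TPM column and a logged warning
    rather than an error, so degenerate simulated samples do not abort a run.
    """
    lengths.covers(counts.gene_ids)
    lens = lengths.lengths.reindex(counts.gene_ids).to_numpy(dtype=float)
    rates = counts.counts.to_numpy(dtype=float) / lens[:, None]
    colsum = rates.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        for s in np.array(counts.counts.columns)[zero]:
            logger.warning("sample %s has zero total counts; TPM column set to 0", s)
    safe = np.where(zero, 1.0, colsum)
    tpm = rates / safe * 1e6
    tpm[:, zero] = 0.0
    frame = pd.DataFrame(tpm, index=counts.counts.index, columns=counts.counts.columns)
    return TPMMatrix(tpm=frame, samples=counts.samples)


def mean_by_condition(tpm: TPMMatrix, cell_type: str, assay: str) -> ConditionTPM:
    """Arithmetic mean TPM over the replicate columns of one condition."""
    cols = tpm.samples.select(cell_type=cell_type, assay=assay)
    if not cols:
        raise ValidationError(f"no samples for condition ({cell_type}, {assay})")
    return ConditionTPM(
        cell_type=cell_type, assay=assay, mean_tpm=tpm.tpm[cols].mean(axis=1)
    )


def expressed_universe(
    conditions: Sequence[ConditionTPM], min_mean_tpm: float = 1.0
) -> GeneUniverse:
    """Genes whose mean TPM reaches ``min_mean_tpm`` in at least one condition.

    All conditions must share the same gene index. An empty result is an
    error: it almost always means the threshold is set too high.
    """
    if not conditions:
        raise ValidationError("expressed_universe needs at least one condition")
    index = conditions[0].mean_tpm.index
    for cond in conditions[1:]:
        if not cond.mean_tpm.index.equals(index):
            raise ValidationError(
                f"condition {cond.label} has a different gene universe"
            )
    stacked = np.vstack([c.mean_tpm.to_numpy() for c in conditions])
    keep = (stacked >= min_mean_tpm).any(axis=0)
    genes = tuple(index[keep])
    if not genes:
        raise ValidationError(
            f"no gene passes min_mean_tpm={min_mean_tpm}; lower the threshold"
        )
    return GeneUniverse(
        genes=genes,
        min_mean_tpm=float(min_mean_tpm),
        conditions=tuple(c.label for c in conditions),
    )
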